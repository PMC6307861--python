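"""Time- and ensemble-averaged MSD and anomalous-exponent estimation.

For anomalous diffusion ``MSD(tau) = Gamma * tau^alpha``: in log-log
space ``log(MSD/tau) = log(Gamma) + (alpha - 1) log(tau)``, so the slope
of ``log(MSD/tau)`` against ``log(tau)`` is zero for free Brownian motion
(alpha = 1) and negative for sub-diffusive, confined motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .tracking import Trajectory

__all__ = ["TamsdCurve", "AnomalousFit", "compute_tamsd",
           "AnomalousDiffusionModel", "fit_anomalous"]


@dataclass
class TamsdCurve:
    """Ensemble-averaged time-averaged MSD per lag."""

    lags: np.ndarray      # s
    msd: np.ndarray       # um^2
    n_pairs: np.ndarray   # displacement pairs contributing per lag


@dataclass
class AnomalousFit:
    """Power-law fit MSD(tau) = Gamma tau^alpha."""

    gamma: float
    alpha: float
    lag_range: tuple

    def summary(self) -> str:
        return "\n".join(
            [
                "Anomalous-diffusion fit MSD(tau) = Gamma tau^alpha",
                "=" * 50,
                f"{'Gamma (um^2/s^alpha)':<32}{self.gamma:>12.4f}",
                f"{'alpha':<32}{self.alpha:>12.4f}",
                f"{'lag range (s)':<32}"
                f"{self.lag_range[0]:>6.3g} - {self.lag_range[1]:<6.3g}",
            ]
        )


def compute_tamsd(
    trajectories: Sequence[Trajectory], max_lag_fraction: float = 0.25
) -> TamsdCurve:
    """Time-averaged MSD per trajectory, ensemble-averaged over tracks.

    All overlapping position pairs at each frame lag contribute; the
    ensemble mean weights each trajectory by its pair count. Lags run up
    to ``max_lag_fraction`` of the longest trajectory.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    if not all(len(t) >= 3 for t in trajectories):
        raise ValueError("trajectories must have >= 3 localizations")
    dt = trajectories[0].frame_interval
    max_len = max(int(t.frames[-1] - t.frames[0]) + 1 for t in trajectories)
    kmax = max(1, int(np.floor(max_len * max_lag_fraction)))
    sums = np.zeros(kmax + 1)
    counts = np.zeros(kmax + 1, dtype=np.int64)
    for t in trajectories:
        f, xy = t.frames, t.xy
        n = f.size
        for k in range(1, kmax + 1):
            j = np.searchsorted(f, f + k)
            ok = (j < n) & (f[np.minimum(j, n - 1)] == f + k)
            i = np.nonzero(ok)[0]
            if i.size:
                d = xy[j[i]] - xy[i]
                sums[k] += np.sum(d[:, 0] ** 2 + d[:, 1] ** 2)
                counts[k] += i.size
    keep = counts[1:] > 0
    lags = np.arange(1, kmax + 1)[keep] * dt
    msd = sums[1:][keep] / counts[1:][keep]
    return TamsdCurve(lags=lags, msd=msd, n_pairs=counts[1:][keep])


class AnomalousDiffusionModel:
    """OLS power-law fit to a TAMSD curve in log-log space.

    The default lag range excludes the first lag (dominated by
    localization error) -- the curve passed in is assumed already limited
    to short lags by ``compute_tamsd``.
    """

    def __init__(self, curve: TamsdCurve, lag_range: Optional[tuple] = None):
        self.curve = curve
        if lag_range is None:
            lags = curve.lags
            lag_range = (lags[1] if lags.size > 4 else lags[0], lags[-1])
        self.lag_range = lag_range

    def fit(self) -> AnomalousFit:
        lo, hi = self.lag_range
        m = (self.curve.lags >= lo - 1e-12) & (self.curve.lags <= hi + 1e-12)
        lags = self.curve.lags[m]
        msd = self.curve.msd[m]
        if lags.size < 4:
            raise ValueError("need >= 4 lags in the fit range")
        if np.any(msd <= 0):
            raise ValueError("non-positive MSD values in the fit range")
        slope, intercept = np.polyfit(np.log(lags), np.log(msd / lags), 1)
        return AnomalousFit(
            gamma=float(np.exp(intercept)),
            alpha=float(1.0 + slope),
            lag_range=(float(lo), float(hi)),
        )


def fit_anomalous(curve: TamsdCurve, lag_range: Optional[tuple] = None) -> AnomalousFit:
    """Functional wrapper around :class:`AnomalousDiffusionModel`."""
    return AnomalousDiffusionModel(curve, lag_range).fit()
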