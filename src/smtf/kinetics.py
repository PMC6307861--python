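"""Two-state diffusion kinetics and residence-time estimation.

Two analyses live here, both operating on single-molecule trajectories:

1. **Two-state displacement-distribution fitting** (fast frame rates,
   ~10 ms): the pooled distributions of displacements at multiple
   frameshifts are fit to a mixture of a bound (slow) and a free (fast)
   Brownian population, accounting for localization error and for the
   axial loss of fast molecules from a finite detection slice
   (defocalization). Yields the bound fraction F_bound and apparent
   diffusion coefficients D_bound, D_free.

2. **Residence-time estimation** (slow frame rates, ~500 ms): the survival
   probability of track durations is fit to a double exponential
   ``SP(t) = F exp(-k_ns t) + (1-F) exp(-k_s t)`` whose slow rate k_s mixes
   specific unbinding with photobleaching and defocalization. The same fit
   on a stably bound control (His2B) measures that bias alone, and
   ``k_s_true = k_s - k_bias`` gives the corrected residence time
   ``tau_res = 1 / k_s_true``.

Model classes follow the statsmodels convention: construct from data, call
``fit()``, get a results object with estimates and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize

from .tracking import Trajectory

__all__ = [
    "DisplacementSet",
    "TwoStateFit",
    "SurvivalCurve",
    "DoubleExpFit",
    "ResidenceTimeEstimate",
    "compile_displacements",
    "defocalization_survival",
    "TwoStateDiffusionModel",
    "fit_two_state",
    "survival_probability",
    "ResidenceTimeModel",
    "fit_double_exponential",
    "select_min_duration_threshold",
    "bias_correct_residence_time",
]


# ---------------------------------------------------------------------------
# displacements
# ---------------------------------------------------------------------------

@dataclass
class DisplacementSet:
    """Displacements grouped by frameshift k (time lag k * frame_interval)."""

    displacements: dict[int, np.ndarray]
    frame_interval: float
    n_trajectories: int

    def n_per_shift(self) -> dict[int, int]:
        return {k: v.size for k, v in self.displacements.items()}


def compile_displacements(
    trajectories: Sequence[Trajectory],
    timepoints: int = 8,
    jumps_per_traj: int = 4,
    gaps_allowed: int = 1,
) -> DisplacementSet:
    """Pool displacements at frameshifts ``1 .. timepoints-1``.

    For each trajectory and each frameshift ``k``, at most
    ``jumps_per_traj`` displacements are used (the earliest ones), which
    limits the over-representation of long -- predominantly bound --
    trajectories. A displacement spanning a tracking gap contributes to the
    frameshift given by its true frame difference, so gap-bridged jumps
    land in the correct (longer) lag group.
    """
    if timepoints < 2:
        raise ValueError("timepoints must be >= 2")
    if not trajectories:
        raise ValueError("no trajectories")
    dt = trajectories[0].frame_interval
    groups: dict[int, list[np.ndarray]] = {k: [] for k in range(1, timepoints)}
    for traj in trajectories:
        f = traj.frames
        xy = traj.xy
        n = f.size
        if n < 2:
            continue
        for k in range(1, timepoints):
            # pairs (i, j) with frame difference exactly k
            j = np.searchsorted(f, f + k)
            valid = (j < n) & (f[np.minimum(j, n - 1)] == f + k)
            i = np.nonzero(valid)[0][:jumps_per_traj]
            if i.size:
                d = xy[j[i]] - xy[i]
                groups[k].append(np.hypot(d[:, 0], d[:, 1]))
    return DisplacementSet(
        displacements={
            k: (np.concatenate(v) if v else np.empty(0)) for k, v in groups.items()
        },
        frame_interval=dt,
        n_trajectories=len(trajectories),
    )


# ---------------------------------------------------------------------------
# defocalization
# ---------------------------------------------------------------------------

def defocalization_survival(
    d_free: float, dt: float, slice_depth: float, tol: float = 1e-8
) -> float:
    """Probability of remaining inside the detection slice after ``dt``.

    A molecule with diffusion coefficient ``d_free`` starts uniformly
    distributed in a slab of width ``slice_depth`` with absorbing exits.
    The survival probability is the eigenfunction series

        P(t) = sum_{n odd} 8 / (n pi)^2 * exp(-D n^2 pi^2 t / L^2),

    truncated once terms fall below ``tol``.
    """
    if dt <= 0 or slice_depth <= 0:
        raise ValueError("dt and slice_depth must be positive")
    if d_free < 0:
        raise ValueError("d_free must be >= 0")
    if d_free == 0:
        return 1.0
    L = slice_depth
    s = 0.0
    n = 1
    while True:
        term = 8.0 / (n * np.pi) ** 2 * np.exp(-d_free * (n * np.pi / L) ** 2 * dt)
        s += term
        if term < tol or n > 10001:
            break
        n += 2
    return float(min(s, 1.0))


# ---------------------------------------------------------------------------
# two-state displacement fit
# ---------------------------------------------------------------------------

@dataclass
class TwoStateFit:
    """Result of the two-state displacement-distribution fit."""

    f_bound: float
    d_bound: float
    d_free: float
    sigma_loc: float
    slice_depth: float
    loss: float
    n_init: int
    frame_interval: float = 0.0
    n_displacements: int = 0

    def summary(self) -> str:
        lines = [
            "Two-state displacement-distribution fit",
            "=" * 47,
            f"{'bound fraction F_bound':<32}{self.f_bound:>12.4f}",
            f"{'D_bound (um^2/s)':<32}{self.d_bound:>12.4f}",
            f"{'D_free (um^2/s)':<32}{self.d_free:>12.4f}",
            f"{'localization error sigma (um)':<32}{self.sigma_loc:>12.4f}",
            f"{'detection slice (um)':<32}{self.slice_depth:>12.3f}",
            f"{'sum of squared residuals':<32}{self.loss:>12.3e}",
            f"{'displacements used':<32}{self.n_displacements:>12d}",
            f"{'initializations':<32}{self.n_init:>12d}",
        ]
        return "\n".join(lines)


def _rayleigh_bin_probs(edges: np.ndarray, var_axis: float) -> np.ndarray:
    """P(edge_lo < r <= edge_hi) for a 2-D Gaussian displacement.

    ``var_axis`` is the per-axis variance; the radial CDF is
    ``1 - exp(-R^2 / (2 var_axis))``.
    """
    c = np.exp(-(edges ** 2) / (2.0 * var_axis))
    return c[:-1] - c[1:]


class TwoStateDiffusionModel:
    """Two-population Brownian mixture for displacement distributions.

    The empirical displacement histograms at frameshifts ``k = 1..K`` are
    jointly fit to

        P_k(r) ~ F * Rayleigh(r; 2(D_b k dt + sigma^2))
                 + (1-F) * Z(k dt) * Rayleigh(r; 2(D_f k dt + sigma^2)),

    each lag renormalized to unit mass, where ``Z`` is the defocalization
    survival of the population in the detection slice. State transitions
    within a displacement are not modelled. The localization error sigma
    is a fitted parameter.

    Because displacements are compiled from trajectories (the first
    ``jumps_per_traj`` jumps per lag), a molecule contributing a lag-k
    jump starting at frame i must have remained detectable for (i + k)
    frames. The defocalization weight of each component is therefore the
    slab survival averaged over the jump-start indices,

        A_c(k) = (1/J) sum_{i=0..J-1} S_c((i + k) dt),

    rather than the single-jump survival S_c(k dt); otherwise the free
    component is systematically over-weighted and the bound fraction
    inflated.

    Parameters
    ----------
    displacements : DisplacementSet
    slice_depth : float
        Axial detection range, micrometres.
    bin_width, r_max : float
        Histogram binning (default 10-nm bins to 3 um).
    """

    def __init__(
        self,
        displacements: DisplacementSet,
        slice_depth: float = 0.8,
        bin_width: float = 0.01,
        r_max: float = 3.0,
        sigma_bounds: tuple[float, float] = (0.01, 0.08),
        d_bound_bounds: tuple[float, float] = (1e-4, 0.5),
        d_free_bounds: tuple[float, float] = (0.15, 25.0),
        jumps_per_traj: int = 4,
    ):
        self.ds = displacements
        self.dt = displacements.frame_interval
        self.slice_depth = slice_depth
        self.jumps_per_traj = jumps_per_traj
        self.edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
        self.sigma_bounds = sigma_bounds
        self.d_bound_bounds = d_bound_bounds
        self.d_free_bounds = d_free_bounds
        self.shifts = sorted(
            k for k, v in displacements.displacements.items() if v.size > 0
        )
        if len(self.shifts) < 2:
            raise ValueError("need displacements at >= 2 frameshifts")
        self._emp = {}
        self._n_disp = 0
        for k in self.shifts:
            r = displacements.displacements[k]
            h, _ = np.histogram(r, bins=self.edges)
            tot = h.sum()
            self._emp[k] = h / max(tot, 1)
            self._n_disp += int(tot)

    def _slab_weight(self, d: float, k: int) -> float:
        J = self.jumps_per_traj
        return float(
            np.mean(
                [
                    defocalization_survival(d, (i + k) * self.dt, self.slice_depth)
                    for i in range(J)
                ]
            )
        )

    def _model_hist(self, k: int, f: float, db: float, df: float, sig: float):
        tau = k * self.dt
        pb = _rayleigh_bin_probs(self.edges, 2.0 * (db * tau + sig ** 2))
        pf = _rayleigh_bin_probs(self.edges, 2.0 * (df * tau + sig ** 2))
        m = (
            f * self._slab_weight(db, k) * pb
            + (1.0 - f) * self._slab_weight(df, k) * pf
        )
        s = m.sum()
        return m / s if s > 0 else m

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        f, db, df, sig = theta
        res = [self._emp[k] - self._model_hist(k, f, db, df, sig) for k in self.shifts]
        return np.concatenate(res)

    def fit(self, n_init: int = 5, seed: int = 0) -> TwoStateFit:
        """Least-squares fit; best of ``n_init`` random initializations."""
        rng = np.random.default_rng(seed)
        lo = np.array(
            [0.0, self.d_bound_bounds[0], self.d_free_bounds[0], self.sigma_bounds[0]]
        )
        hi = np.array(
            [1.0, self.d_bound_bounds[1], self.d_free_bounds[1], self.sigma_bounds[1]]
        )
        best = None
        for _ in range(n_init):
            x0 = lo + rng.random(4) * (hi - lo)
            try:
                sol = optimize.least_squares(
                    self._residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-10
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("two-state fit failed for every initialization")
        f, db, df, sig = best.x
        return TwoStateFit(
            f_bound=float(f),
            d_bound=float(db),
            d_free=float(df),
            sigma_loc=float(sig),
            slice_depth=self.slice_depth,
            loss=float(2 * best.cost),
            n_init=n_init,
            frame_interval=self.dt,
            n_displacements=self._n_disp,
        )


def fit_two_state(
    ds: DisplacementSet,
    dt: Optional[float] = None,
    slice_depth: float = 0.8,
    n_init: int = 5,
    seed: int = 0,
    **kwargs,
) -> TwoStateFit:
    """Functional wrapper around :class:`TwoStateDiffusionModel`."""
    if dt is not None and abs(dt - ds.frame_interval) > 1e-12:
        ds = DisplacementSet(ds.displacements, dt, ds.n_trajectories)
    return TwoStateDiffusionModel(ds, slice_depth=slice_depth, **kwargs).fit(
        n_init=n_init, seed=seed
    )


# ---------------------------------------------------------------------------
# survival probability and residence times
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Survival probability of trajectory durations on a frame grid."""

    durations: np.ndarray  # seconds, grid of integer frame counts * dt
    survival: np.ndarray
    n_trajectories: int
    frame_interval: float

    def __post_init__(self):
        self.durations = np.asarray(self.durations, float)
        self.survival = np.asarray(self.survival, float)


def survival_probability(trajectories: Sequence[Trajectory]) -> SurvivalCurve:
    """1 - CDF of trajectory durations.

    ``SP(t)`` is the fraction of trajectories observed for at least ``t``,
    evaluated on the grid of integer frame counts times the frame
    interval. By construction the first grid point has SP = 1.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    dt = trajectories[0].frame_interval
    n_frames = np.array([t.n_frames_observed for t in trajectories])
    kmin, kmax = int(n_frames.min()), int(n_frames.max())
    grid = np.arange(kmin, kmax + 1)
    sp = np.array([(n_frames >= k).mean() for k in grid])
    return SurvivalCurve(
        durations=grid * dt,
        survival=sp,
        n_trajectories=len(trajectories),
        frame_interval=dt,
    )


@dataclass
class DoubleExpFit:
    """Double-exponential fit to a survival-probability curve."""

    f_fast: float
    k_ns: float
    k_s: float
    min_duration_frames: int
    min_prob_cut: float = 1e-3
    degenerate: bool = False
    n_points: int = 0
    loss: float = np.nan

    def summary(self) -> str:
        lines = [
            "Double-exponential survival-probability fit",
            "=" * 47,
            f"{'fast (non-specific) fraction F':<32}{self.f_fast:>12.4f}",
            f"{'k_ns (1/s)':<32}{self.k_ns:>12.4f}",
            f"{'k_s (1/s)':<32}{self.k_s:>12.4f}",
            f"{'min duration (frames)':<32}{self.min_duration_frames:>12d}",
            f"{'SP cut':<32}{self.min_prob_cut:>12.1e}",
            f"{'points fitted':<32}{self.n_points:>12d}",
        ]
        if self.degenerate:
            lines.append("WARNING: k_ns ~ k_s (degenerate two-exponential fit)")
        return "\n".join(lines)


@dataclass
class ResidenceTimeEstimate:
    """Bias-corrected specific residence time."""

    k_s: float
    k_bias: float
    k_s_true: float
    tau_res: float

    def summary(self) -> str:
        return "\n".join(
            [
                "Bias-corrected residence time",
                "=" * 47,
                f"{'apparent slow rate k_s (1/s)':<32}{self.k_s:>12.4f}",
                f"{'bias rate k_bias (1/s)':<32}{self.k_bias:>12.4f}",
                f"{'corrected k_s_true (1/s)':<32}{self.k_s_true:>12.4f}",
                f"{'residence time tau_res (s)':<32}{self.tau_res:>12.3f}",
            ]
        )


def fit_double_exponential(
    sp: SurvivalCurve,
    min_duration_frames: int = 1,
    min_prob_cut: float = 1e-3,
    renormalize: bool = True,
) -> DoubleExpFit:
    """Fit ``F exp(-k_ns t) + (1-F) exp(-k_s t)`` to a survival curve.

    Grid points with duration below ``min_duration_frames`` frames or
    survival below ``min_prob_cut`` are excluded; the remaining curve is
    (by default) renormalized to 1 at its first kept point, with the time
    origin shifted there so that the rate constants keep their meaning.
    """
    dt = sp.frame_interval
    keep = (sp.durations >= min_duration_frames * dt - 1e-9) & (
        sp.survival >= min_prob_cut
    )
    t = sp.durations[keep]
    y = sp.survival[keep]
    if t.size < 5:
        raise ValueError("fewer than 5 usable survival points after cuts")
    t0 = t[0]
    tt = t - t0
    if renormalize:
        y = y / y[0]

    def model(tt, f, kns, ks):
        return f * np.exp(-kns * tt) + (1 - f) * np.exp(-ks * tt)

    def resid(theta):
        return model(tt, *theta) - y

    lo = np.array([0.0, 1e-4, 1e-4])
    hi = np.array([1.0, 200.0, 50.0])
    # deterministic multi-start over plausible rate decades
    starts = []
    for kns0 in (0.5, 2.0, 8.0):
        for ks0 in (0.05, 0.2, 0.8):
            starts.append(np.array([0.5, kns0, ks0]))
    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("double-exponential fit failed")
    f, kns, ks = best.x
    if kns < ks:  # enforce k_ns > k_s by swapping components
        f, kns, ks = 1 - f, ks, kns
    degenerate = kns > 0 and abs(kns - ks) / kns < 0.05
    if degenerate:
        warnings.warn("double-exponential fit is nearly degenerate (k_ns ~ k_s)")
    return DoubleExpFit(
        f_fast=float(f),
        k_ns=float(kns),
        k_s=float(ks),
        min_duration_frames=int(min_duration_frames),
        min_prob_cut=min_prob_cut,
        degenerate=bool(degenerate),
        n_points=int(t.size),
        loss=float(2 * best.cost),
    )


def select_min_duration_threshold(
    sp: SurvivalCurve,
    candidates: Iterable[int] = range(1, 9),
    rel_tol: float = 0.05,
    min_prob_cut: float = 1e-3,
) -> int:
    """Smallest duration threshold at which the slow rate has converged.

    The slow rate ``k_s`` is re-fit for each candidate minimum-duration
    threshold; the smallest ``n`` with ``|k_s(n) - k_s(n+1)| / k_s(n) <
    rel_tol`` is returned. If the scan never converges, the largest
    candidate is returned with a warning.
    """
    cand = sorted(candidates)
    ks = {}
    for n in cand + [cand[-1] + 1]:
        try:
            ks[n] = fit_double_exponential(sp, n, min_prob_cut).k_s
        except ValueError:
            break
    for n in cand:
        if n in ks and (n + 1) in ks:
            if abs(ks[n] - ks[n + 1]) / ks[n] < rel_tol:
                return n
    warnings.warn("slow rate never converged over the threshold scan; using max")
    usable = [n for n in cand if n in ks]
    return usable[-1] if usable else cand[-1]


def bias_correct_residence_time(
    k_s: float, his2b_fit: DoubleExpFit
) -> ResidenceTimeEstimate:
    """Subtract the photobleaching/defocalization bias rate.

    The slower rate of the double-exponential fit to the His2B control
    survival curve measures trajectory loss that is unrelated to
    unbinding; ``k_s_true = k_s - k_bias`` and ``tau_res = 1/k_s_true``.
    """
    k_bias = his2b_fit.k_s
    if k_s <= k_bias:
        raise ValueError("bias exceeds signal: k_s <= k_bias")
    k_true = k_s - k_bias
    return ResidenceTimeEstimate(
        k_s=float(k_s),
        k_bias=float(k_bias),
        k_s_true=float(k_true),
        tau_res=float(1.0 / k_true),
    )


class ResidenceTimeModel:
    """End-to-end residence-time estimation from slow-frame-rate tracks.

    Wraps survival-probability construction, the duration-threshold scan,
    the double-exponential fit, and His2B bias correction into one model
    object.

    Parameters
    ----------
    trajectories : sequence of Trajectory
        Long-exposure (motion-blurred) target-protein tracks.
    control_trajectories : sequence of Trajectory, optional
        His2B-like control tracks recorded under identical imaging. If
        omitted, ``fit`` reports the uncorrected rate only.
    """

    def __init__(
        self,
        trajectories: Sequence[Trajectory],
        control_trajectories: Optional[Sequence[Trajectory]] = None,
        min_prob_cut: float = 1e-3,
        threshold_candidates: Iterable[int] = range(1, 9),
    ):
        self.sp = survival_probability(trajectories)
        self.control_sp = (
            survival_probability(control_trajectories)
            if control_trajectories
            else None
        )
        self.min_prob_cut = min_prob_cut
        self.threshold_candidates = threshold_candidates

    def fit(self) -> "ResidenceTimeResults":
        thr = select_min_duration_threshold(
            self.sp, self.threshold_candidates, min_prob_cut=self.min_prob_cut
        )
        target = fit_double_exponential(self.sp, thr, self.min_prob_cut)
        control = estimate = None
        if self.control_sp is not None:
            cthr = select_min_duration_threshold(
                self.control_sp,
                self.threshold_candidates,
                min_prob_cut=self.min_prob_cut,
            )
            control = fit_double_exponential(self.control_sp, cthr, self.min_prob_cut)
            estimate = bias_correct_residence_time(target.k_s, control)
        return ResidenceTimeResults(
            target_fit=target, control_fit=control, estimate=estimate,
            min_duration_frames=thr,
        )


@dataclass
class ResidenceTimeResults:
    target_fit: DoubleExpFit
    control_fit: Optional[DoubleExpFit]
    estimate: Optional[ResidenceTimeEstimate]
    min_duration_frames: int

    @property
    def tau_res(self) -> float:
        if self.estimate is None:
            return 1.0 / self.target_fit.k_s
        return self.estimate.tau_res

    def summary(self) -> str:
        parts = [self.target_fit.summary()]
        if self.control_fit is not None:
            parts.append("\nControl (bias) fit:\n" + self.control_fit.summary())
        if self.estimate is not None:
            parts.append("\n" + self.estimate.summary())
        return "\n".join(parts)
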