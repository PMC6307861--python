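"""Diagnostic plots for fit results (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np


def plot_survival(sp, fit=None, ax=None):
    """Survival probability on a log scale, with optional fitted curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.semilogy(sp.durations, sp.survival, "o", ms=3, label="data")
    if fit is not None:
        t = np.linspace(sp.durations[0], sp.durations[-1], 200)
        t0 = fit.min_duration_frames * sp.frame_interval
        y = fit.f_fast * np.exp(-fit.k_ns * (t - t0)) + (
            1 - fit.f_fast
        ) * np.exp(-fit.k_s * (t - t0))
        ax.semilogy(t, y, "-", label="double-exponential fit")
    ax.set_xlabel("duration (s)")
    ax.set_ylabel("survival probability")
    ax.legend()
    return ax


def plot_tamsd(curve, fit=None, ax=None):
    """log-log TAMSD/tau; slope 0 corresponds to free diffusion."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(curve.lags, curve.msd / curve.lags, "o-", ms=3, label="TAMSD/tau")
    if fit is not None:
        t = np.array(fit.lag_range)
        ax.loglog(t, fit.gamma * t ** (fit.alpha - 1), "--",
                  label=f"alpha = {fit.alpha:.2f}")
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("MSD/tau (um^2/s)")
    ax.legend()
    return ax


def plot_radial_profile(profile, control=None, ax=None):
    """Locus-centred radial profile with SEM bars, optional control."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(profile.radii, profile.mean, yerr=profile.sem, fmt="o-",
                ms=3, label="locus (TS)")
    if control is not None:
        ax.errorbar(control.radii, control.mean, yerr=control.sem, fmt="s--",
                    ms=3, label="control (RS)")
    ax.axhline(1.0, color="0.6", lw=0.8)
    ax.set_xlabel("radius (um)")
    ax.set_ylabel("normalized intensity")
    ax.legend()
    return ax


def plot_frap(recovery, fit=None, ax=None):
    """Corrected FRAP recovery with the reaction-dominant fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(recovery.time, recovery.curve, ".", ms=2, label="corrected")
    if fit is not None:
        t = recovery.time
        ax.plot(
            t,
            1 - fit.a_amp * np.exp(-fit.k_a * t) - fit.b_amp * np.exp(-fit.k_b * t),
            "-",
            label=f"fit (t1/2 slow = {fit.t_half_slow:.2f} s)",
        )
    ax.set_xlabel("time after bleach (s)")
    ax.set_ylabel("normalized intensity")
    ax.legend()
    return ax
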