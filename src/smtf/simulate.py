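"""Synthetic-data generators with known ground truth.

Every input class the analysis pipeline consumes can be generated here
under a declared observation model, so each stage is verifiable without
external data:

* mixed bound/free Brownian trajectories observed through a finite axial
  slice, with localization error, photobleaching, and a motion-blur gate
  at long exposures;
* nucleus images with amorphous high-density hubs;
* two-channel 4-D volumes with one bright diffraction-limited locus per
  expressing nucleus over a bright cytoplasmic background;
* FRAP recovery traces with control and dark reference spots.

Presets ``zld_like``, ``bcd_like`` and ``his2b_like`` encode the measured
bound fractions, residence times and FRAP half times for the three
protein classes, so recovery tests reference presets rather than magic
numbers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .frap import FrapExperiment
from .hubs import percentile_rank
from .io import Movie
from .tracking import Trajectory

__all__ = [
    "TwoStateSimParams",
    "NucleusSimParams",
    "LocusSimParams",
    "FrapSimParams",
    "load_presets",
    "preset_params",
    "frap_params_from_preset",
    "simulate_trajectories",
    "simulate_trajectories_until",
    "simulate_his2b_control",
    "simulate_nucleus_movie",
    "simulate_bound_molecules_in_hubs",
    "simulate_ms2_volumes",
    "simulate_frap",
]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def load_presets() -> dict:
    """Kinetic parameter presets packaged with the library."""
    text = (
        importlib.resources.files("smtf").joinpath("presets.yaml").read_text()
    )
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class TwoStateSimParams:
    """Parameters of the two-state trajectory generator.

    The observation model: each molecule is bound (specific or
    non-specific) or free at steady state; it performs 2-D Brownian
    motion with its state's diffusion coefficient plus 1-D axial Brownian
    motion in a detection slice of depth ``slice_depth`` with absorbing
    exits. Its observed track ends at the first of unbinding, bleaching,
    axial exit, or movie end. Localizations carry i.i.d. Gaussian error
    ``sigma_loc`` per axis. At exposures >= 100 ms a molecule is rendered
    in a frame only if bound for at least
    ``blur_bound_fraction_threshold`` of the exposure (motion-blur gate);
    free molecules then never render.
    """

    n_molecules: int = 10000
    f_bound: float = 0.5
    d_bound: float = 0.01        # um^2/s
    d_free: float = 3.0          # um^2/s
    sigma_loc: float = 0.03      # um per axis
    frame_interval: float = 0.01  # s
    exposure: float = 0.01       # s
    n_frames: int = 30
    slice_depth: float = 0.8     # um
    k_off_specific: float = 0.18  # 1/s
    k_off_nonspecific: float = 2.0
    f_specific: float = 0.5
    k_bleach: float = 5.0        # 1/s
    blur_bound_fraction_threshold: float = 0.6
    fov_size: float = 10.0       # um, initial-position extent
    n_substeps: int = 8          # axial sub-steps per frame
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.f_bound <= 1:
            raise ValueError("f_bound must be in [0, 1]")
        if not 0 <= self.f_specific <= 1:
            raise ValueError("f_specific must be in [0, 1]")
        for name in ("k_off_specific", "k_off_nonspecific", "k_bleach",
                     "d_bound", "d_free"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.slice_depth > 0:
            raise ValueError("slice_depth must be positive")


def preset_params(
    name: str,
    imaging: str = "fast",
    n_molecules: int = 10000,
    seed: int = 0,
    **overrides,
) -> TwoStateSimParams:
    """Build simulation parameters from a named preset.

    ``imaging="fast"`` configures 10-ms frames for displacement-
    distribution analysis (high excitation, fast bleaching);
    ``imaging="residence"`` configures 500-ms frames for residence-time
    analysis (only bound molecules render, lower bleaching).
    """
    presets = load_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; have {sorted(presets)}")
    p = presets[name]
    tau = p["tau_res_s"]
    k_s = 0.0 if np.isinf(tau) else 1.0 / tau
    common = dict(
        n_molecules=n_molecules,
        f_bound=p["f_bound"],
        d_bound=p["d_bound"],
        d_free=p["d_free"],
        k_off_specific=k_s,
        k_off_nonspecific=p["k_off_nonspecific"],
        f_specific=p["f_specific"],
        seed=seed,
    )
    if imaging == "fast":
        params = TwoStateSimParams(
            frame_interval=0.01, exposure=0.01, n_frames=30, k_bleach=5.0,
            **common,
        )
    elif imaging == "residence":
        params = TwoStateSimParams(
            frame_interval=0.5, exposure=0.5, n_frames=60, k_bleach=0.15,
            f_bound=1.0, **{k: v for k, v in common.items() if k != "f_bound"},
        )
    else:
        raise ValueError("imaging must be 'fast' or 'residence'")
    return replace(params, **overrides) if overrides else params


def _exp_times(rng, rate: float, n: int) -> np.ndarray:
    if rate <= 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, size=n)


def simulate_trajectories(
    params: TwoStateSimParams,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate two-state single-molecule trajectories.

    Returns the observed trajectories (>= 2 rendered frames) and a
    ground-truth table with each molecule's state and true event times.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_molecules
    dt = params.frame_interval
    L = params.slice_depth
    T = params.n_frames * dt
    long_exposure = params.exposure >= 0.1

    bound = rng.random(n) < params.f_bound
    specific = bound & (rng.random(n) < params.f_specific)
    nonspecific = bound & ~specific

    t_unbind = np.full(n, np.inf)
    t_unbind[specific] = _exp_times(rng, params.k_off_specific, int(specific.sum()))
    t_unbind[nonspecific] = _exp_times(
        rng, params.k_off_nonspecific, int(nonspecific.sum())
    )
    t_bleach = _exp_times(rng, params.k_bleach, n)

    d_mol = np.where(bound, params.d_bound, params.d_free)

    # axial exit times: sub-stepped Brownian walk in an absorbing slab,
    # with a Brownian-bridge crossing test between sub-steps so the exit
    # statistics match the continuous process
    t_exit = np.full(n, np.inf)
    if np.isfinite(L):
        half = L / 2
        nsub = params.n_substeps
        dt_sub = dt / nsub
        nstep = params.n_frames * nsub
        chunk = max(1, int(2e7 // max(nstep, 1)))
        for a in range(0, n, chunk):
            b = min(a + chunk, n)
            m = b - a
            z0 = rng.uniform(-half, half, size=m)
            d_sub = d_mol[a:b, None] * dt_sub
            dz = rng.standard_normal((m, nstep)) * np.sqrt(2.0 * d_sub)
            z = np.empty((m, nstep + 1))
            z[:, 0] = z0
            np.cumsum(dz, axis=1, out=z[:, 1:])
            z[:, 1:] += z0[:, None]
            z1, z2 = z[:, :-1], z[:, 1:]
            out = np.abs(z2) > half
            with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                p_up = np.exp(-np.clip((half - z1) * (half - z2), 0, None) / d_sub)
                p_lo = np.exp(-np.clip((z1 + half) * (z2 + half), 0, None) / d_sub)
            u = rng.random((m, nstep))
            killed = out | (u < p_up + p_lo)
            first = np.argmax(killed, axis=1)
            has = killed[np.arange(m), first]
            t_exit[a:b][has] = (first[has] + 1) * dt_sub

    t_end = np.minimum.reduce([t_unbind, t_bleach, t_exit, np.full(n, T)])

    if long_exposure:
        thr = params.blur_bound_fraction_threshold
        n_obs = np.where(
            bound & (t_end >= thr * dt),
            np.floor(t_end / dt - thr).astype(int) + 1,
            0,
        )
    else:
        n_obs = np.floor(t_end / dt).astype(int) + 1
    n_obs = np.clip(n_obs, 0, params.n_frames)

    trajectories: list[Trajectory] = []
    obs = np.nonzero(n_obs >= 2)[0]
    if obs.size:
        kmax = int(n_obs[obs].max())
        chunk = max(1, int(2e7 // max(kmax, 1)))
        for a in range(0, obs.size, chunk):
            idx = obs[a : a + chunk]
            m = idx.size
            sd = np.sqrt(2.0 * d_mol[idx] * dt)
            steps = rng.standard_normal((m, kmax - 1, 2)) * sd[:, None, None]
            x0 = rng.uniform(0, params.fov_size, size=(m, 1, 2))
            pos = np.concatenate(
                [x0, x0 + np.cumsum(steps, axis=1)], axis=1
            )
            noisy = pos + rng.standard_normal(pos.shape) * params.sigma_loc
            for j, mol in enumerate(idx):
                k = int(n_obs[mol])
                trajectories.append(
                    Trajectory(
                        id=int(mol),
                        frames=np.arange(k),
                        xy=noisy[j, :k],
                        frame_interval=dt,
                        exposure=params.exposure,
                    )
                )

    state = np.where(
        specific, "bound_specific", np.where(nonspecific, "bound_nonspecific", "free")
    )
    truth = pd.DataFrame(
        {
            "molecule": np.arange(n),
            "state": state,
            "t_unbind": t_unbind,
            "t_bleach": t_bleach,
            "t_exit": t_exit,
            "t_end": t_end,
            "n_obs_frames": n_obs,
        }
    )
    return trajectories, truth


def simulate_trajectories_until(
    params: TwoStateSimParams, n_trajectories: int, max_batches: int = 50
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate in batches until ``n_trajectories`` are observed.

    Not every simulated molecule yields an observed trajectory (short-
    lived or motion-blurred molecules render in fewer than two frames),
    so benchmarks phrased in trajectory counts accumulate batches here.
    Molecule and trajectory ids are re-indexed to stay unique.
    """
    trajs: list[Trajectory] = []
    truths = []
    offset = 0
    for batch in range(max_batches):
        p = replace(params, seed=params.seed + 7919 * batch)
        t, g = simulate_trajectories(p)
        for tr in t:
            tr.id += offset
        g = g.assign(molecule=g["molecule"] + offset)
        offset += p.n_molecules
        trajs.extend(t)
        truths.append(g)
        if len(trajs) >= n_trajectories:
            break
    return trajs[:n_trajectories], pd.concat(truths, ignore_index=True)


def simulate_his2b_control(params: TwoStateSimParams) -> list[Trajectory]:
    """Stably bound (histone-like) control trajectories.

    The specific class never unbinds; observed tracks end only by
    bleaching, defocalization, or movie end.
    """
    if params.k_off_specific != 0:
        params = replace(params, k_off_specific=0.0)
    trajs, _ = simulate_trajectories(params)
    return trajs


# ---------------------------------------------------------------------------
# nucleus images with hubs
# ---------------------------------------------------------------------------

@dataclass
class NucleusSimParams:
    """Parameters of the hub-bearing nucleus image generator.

    By default nuclei are laid out on a jittered grid at blastoderm-like
    packing so that every local neighbourhood of the image contains
    nuclear signal (the regime the adaptive-threshold segmentation is
    built for).
    """

    image_shape: tuple = (272, 272)
    pixel_size: float = 0.1                      # um
    nucleus_centers: Optional[np.ndarray] = None  # (n, 2) row, col px
    nucleus_radii: Optional[np.ndarray] = None    # px
    n_hubs: int = 3
    hub_sigma: float = 0.4                       # um
    hub_amplitude: float = 0.8                   # relative to background
    background_level: float = 100.0
    noise_sd: float = 5.0
    extranuclear_level: float = 30.0
    hub_percentile: float = 85.0                 # ground-truth hub cut
    seed: int = 0

    def __post_init__(self):
        if self.hub_amplitude < 0:
            raise ValueError("hub_amplitude must be >= 0")


def _default_nucleus_layout(shape, rng, radius: float = 30.0, spacing: float = 2.15):
    """Jittered grid of nuclei at blastoderm-like packing.

    Centres are spread evenly across the field (no empty bands at the
    image edges) with centre-to-centre spacing ~``spacing`` radii, the
    dense cortical packing of syncytial-blastoderm nuclei. Dense packing
    also keeps the adaptive-threshold local mean high everywhere, which
    is the regime the segmentation stage is built for.
    """
    margin = int(radius) + 4
    centers = []
    axes = []
    for dim in shape:
        span = dim - 2 * margin
        n = max(1, int(round(span / (spacing * radius))) + 1)
        axes.append(np.linspace(margin, dim - margin, n))
    for r in axes[0]:
        for c in axes[1]:
            jit = rng.uniform(-3, 3, size=2)
            centers.append([r + jit[0], c + jit[1]])
    centers = np.array(centers)
    radii = np.full(len(centers), radius)
    return centers, radii


def simulate_nucleus_movie(
    params: NucleusSimParams,
) -> tuple[Movie, np.ndarray, np.ndarray]:
    """Nucleus image with hub Gaussians and the matching ground truth.

    Returns ``(movie, hub_mask, nucleus_labels)`` where the hub mask
    marks pixels whose *noiseless* per-nucleus intensity percentile
    exceeds ``params.hub_percentile``.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.image_shape)
    if params.nucleus_centers is None:
        centers, radii = _default_nucleus_layout(shape, rng)
    else:
        centers = np.asarray(params.nucleus_centers, float)
        radii = np.asarray(params.nucleus_radii, float)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    labels = np.zeros(shape, dtype=np.int32)
    noiseless = np.full(shape, params.extranuclear_level, dtype=float)
    sig_px = params.hub_sigma / params.pixel_size
    for i, ((r0, c0), rad) in enumerate(zip(centers, radii), start=1):
        if r0 - rad < 0 or r0 + rad >= shape[0] or c0 - rad < 0 or c0 + rad >= shape[1]:
            raise ValueError("nucleus extends outside the image")
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2
        labels[mask] = i
        field_ = np.full(shape, params.background_level)
        for _ in range(params.n_hubs):
            ang = rng.uniform(0, 2 * np.pi)
            rho = rad * 0.6 * np.sqrt(rng.random())
            hr, hc = r0 + rho * np.sin(ang), c0 + rho * np.cos(ang)
            field_ = field_ + (
                params.hub_amplitude
                * params.background_level
                * np.exp(
                    -((rr - hr) ** 2 + (cc - hc) ** 2) / (2 * sig_px ** 2)
                )
            )
        noiseless[mask] = field_[mask]
    hub_mask = np.zeros(shape, dtype=bool)
    for i in range(1, labels.max() + 1):
        m = labels == i
        pct = percentile_rank(noiseless[m])
        # require genuine hub signal: a hub-free (flat) nucleus has all
        # pixels tied at percentile 100 but contains no hubs
        sel = np.zeros(shape, bool)
        sel[m] = (pct > params.hub_percentile) & (
            noiseless[m] > params.background_level
        )
        hub_mask |= sel
    noisy = noiseless + rng.normal(0, params.noise_sd, size=shape)
    movie = Movie(
        frames=noisy[None],
        pixel_size_xy=params.pixel_size,
        frame_interval=1.0,
        channel_label="tf_bulk",
    )
    return movie, hub_mask, labels


def simulate_bound_molecules_in_hubs(
    hub_mask: np.ndarray,
    nucleus_labels: np.ndarray,
    fold: float,
    n: int,
    seed: int = 0,
    pixel_size: float = 0.1,
    frame_interval: float = 0.1,
) -> list[Trajectory]:
    """Immobile trajectories whose hub density is ``fold`` times the rest.

    Molecules land uniformly within the hub or non-hub nuclear region,
    the region chosen so the expected count *per pixel* inside hubs is
    exactly ``fold`` times the outside density.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    nuc = nucleus_labels > 0
    in_px = np.argwhere(hub_mask & nuc)
    out_px = np.argwhere(~hub_mask & nuc)
    a_in, a_out = len(in_px), len(out_px)
    if a_in == 0 or a_out == 0:
        raise ValueError("hub and non-hub regions must both be non-empty")
    rng = np.random.default_rng(seed)
    q = fold * a_in / (fold * a_in + a_out)
    pick_in = rng.random(n) < q
    trajs = []
    for i in range(n):
        pool = in_px if pick_in[i] else out_px
        r, c = pool[rng.integers(len(pool))]
        x = (c + rng.random()) * pixel_size
        y = (r + rng.random()) * pixel_size
        trajs.append(
            Trajectory(
                id=i,
                frames=np.array([0, 1]),
                xy=np.array([[x, y], [x, y]]),
                frame_interval=frame_interval,
                exposure=0.1,
            )
        )
    return trajs


# ---------------------------------------------------------------------------
# MS2 two-channel volumes
# ---------------------------------------------------------------------------

@dataclass
class LocusSimParams:
    """Parameters of the two-channel MS2-locus volume generator.

    The MCP channel shows a dark nucleoplasm inside nuclei over a bright
    cytoplasm, with one Gaussian locus per expressing nucleus following
    a confined random walk. The TF channel is a nucleoplasmic field with
    optional Gaussian enrichment co-centred on the locus.
    """

    volume_shape: tuple = (12, 128, 128)   # (z, y, x) voxels
    voxel_size_xy: float = 0.1             # um
    voxel_size_z: float = 0.25             # um
    n_timepoints: int = 5
    nucleus_centers: Optional[np.ndarray] = None  # (n, 2) row, col px
    nucleus_radius: float = 40.0           # px
    locus_amplitude: float = 500.0
    locus_sigma: float = 1.5               # voxels, lateral
    tf_enrichment_amplitude: float = 0.5   # relative to nuclear TF level
    tf_enrichment_sigma: float = 0.3       # um
    cytoplasm_level: float = 200.0
    nucleoplasm_level: float = 40.0
    tf_nuclear_level: float = 100.0
    tf_cyto_level: float = 20.0
    noise_sd: float = 3.0
    locus_step_sd: float = 0.05            # um per timepoint
    seed: int = 0

    def __post_init__(self):
        if not self.cytoplasm_level > self.nucleoplasm_level:
            raise ValueError(
                "cytoplasm_level must exceed nucleoplasm_level (the contrast "
                "the in-nucleus detector exploits)"
            )


@dataclass
class MS2Simulation:
    mcp: Movie
    tf: Movie
    path: pd.DataFrame          # ground-truth locus path, um
    nucleus_labels: np.ndarray  # 2-D label map


def simulate_ms2_volumes(params: LocusSimParams) -> MS2Simulation:
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.volume_shape
    if params.nucleus_centers is None:
        centers = np.array([[ny / 2, nx / 4], [ny / 2, 3 * nx / 4]])
    else:
        centers = np.asarray(params.nucleus_centers, float)
    rad = params.nucleus_radius
    rr, cc = np.mgrid[0:ny, 0:nx]
    labels = np.zeros((ny, nx), dtype=np.int32)
    for i, (r0, c0) in enumerate(centers, start=1):
        labels[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2] = i

    zz = np.arange(nz)[:, None, None]
    yy = rr[None]
    xx = cc[None]
    sig_xy = params.locus_sigma
    sig_z = params.locus_sigma * params.voxel_size_xy / params.voxel_size_z
    tf_sig_px = params.tf_enrichment_sigma / params.voxel_size_xy

    # confined random walk per nucleus, in pixels
    loci = centers + rng.uniform(-3, 3, size=centers.shape)
    loci_z = np.full(len(centers), nz / 2.0)
    mcp_frames = np.empty((params.n_timepoints, nz, ny, nx), dtype=np.float32)
    tf_frames = np.empty_like(mcp_frames)
    rows = []
    step_px = params.locus_step_sd / params.voxel_size_xy
    for t in range(params.n_timepoints):
        mcp = np.where(
            labels[None] > 0, params.nucleoplasm_level, params.cytoplasm_level
        ).astype(np.float32) * np.ones((nz, 1, 1), dtype=np.float32)
        tf = np.where(
            labels[None] > 0, params.tf_nuclear_level, params.tf_cyto_level
        ).astype(np.float32) * np.ones((nz, 1, 1), dtype=np.float32)
        for i, (r0, c0) in enumerate(centers):
            if t > 0:
                prop = loci[i] + rng.normal(0, step_px, size=2)
                if (prop[0] - r0) ** 2 + (prop[1] - c0) ** 2 <= (0.5 * rad) ** 2:
                    loci[i] = prop
                loci_z[i] = np.clip(
                    loci_z[i] + rng.normal(0, step_px / 2), 1, nz - 2
                )
            lr, lc, lz = loci[i][0], loci[i][1], loci_z[i]
            if params.locus_amplitude > 0:
                mcp += params.locus_amplitude * np.exp(
                    -((yy - lr) ** 2 + (xx - lc) ** 2) / (2 * sig_xy ** 2)
                    - ((zz - lz) ** 2) / (2 * sig_z ** 2)
                ).astype(np.float32)
            if params.tf_enrichment_amplitude > 0:
                tf += (
                    params.tf_enrichment_amplitude
                    * params.tf_nuclear_level
                    * np.exp(
                        -((yy - lr) ** 2 + (xx - lc) ** 2) / (2 * tf_sig_px ** 2)
                        - ((zz - lz) ** 2) / (2 * (2 * sig_z) ** 2)
                    )
                ).astype(np.float32)
            rows.append(
                {
                    "timepoint": t,
                    "nucleus": i + 1,
                    "x": (lc + 0.5) * params.voxel_size_xy,
                    "y": (lr + 0.5) * params.voxel_size_xy,
                    "z": (lz + 0.5) * params.voxel_size_z,
                }
            )
        mcp_frames[t] = mcp + rng.normal(0, params.noise_sd, size=mcp.shape)
        tf_frames[t] = tf + rng.normal(0, params.noise_sd, size=tf.shape)

    meta = dict(
        pixel_size_xy=params.voxel_size_xy,
        voxel_size_z=params.voxel_size_z,
        frame_interval=5.0,
    )
    return MS2Simulation(
        mcp=Movie(frames=mcp_frames, channel_label="mcp", **meta),
        tf=Movie(frames=tf_frames, channel_label="tf", **meta),
        path=pd.DataFrame(rows),
        nucleus_labels=labels,
    )


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

@dataclass
class FrapSimParams:
    """Parameters of the FRAP trace generator.

    The bleach-spot trace is the reaction-dominant model curve times a
    multiplicative per-frame control drift, plus a dark offset and
    Gaussian noise; control spots carry the same drift, dark spots only
    the offset. Pre-bleach frames sit at unity before corruption.
    """

    a_amp: float = 0.3
    b_amp: float = 0.4
    k_a: float = 2.0             # 1/s
    k_b: float = 0.1386          # 1/s (ln 2 / 5 s)
    frame_interval: float = 0.024
    n_pre: int = 10
    n_post: int = 1000
    noise_sd: float = 0.01       # fraction of pre-bleach intensity
    control_drift: float = 0.9995  # multiplicative decay per frame
    dark_level: float = 0.05
    n_spots: int = 50
    n_control: int = 5
    n_dark: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.a_amp + self.b_amp > 1 + 1e-12:
            raise ValueError("a_amp + b_amp must be <= 1")
        if self.k_a <= 0 or self.k_b <= 0:
            raise ValueError("rates must be positive")


def frap_params_from_preset(name: str, seed: int = 0, **overrides) -> FrapSimParams:
    """FRAP parameters whose slow component matches a preset's half time."""
    presets = load_presets()
    t_half = presets[name]["frap_t_half_slow_s"]
    if not np.isfinite(t_half):
        raise ValueError(f"preset {name!r} has no finite FRAP half time")
    return FrapSimParams(k_b=np.log(2.0) / t_half, seed=seed, **overrides)


def frap_model_curve(params: FrapSimParams) -> np.ndarray:
    """Noise-free recovery curve on the post-bleach frame grid."""
    t = np.arange(params.n_post) * params.frame_interval
    return (
        1.0
        - params.a_amp * np.exp(-params.k_a * t)
        - params.b_amp * np.exp(-params.k_b * t)
    )


def simulate_frap(params: FrapSimParams) -> FrapExperiment:
    rng = np.random.default_rng(params.seed)
    n_frames = params.n_pre + params.n_post
    model = np.concatenate([np.ones(params.n_pre), frap_model_curve(params)])
    drift = params.control_drift ** np.arange(n_frames)

    def noisy(base, n):
        return base[None] + rng.normal(
            0, params.noise_sd, size=(n, n_frames)
        )

    bleach = noisy(model * drift + params.dark_level, params.n_spots)
    control = noisy(drift + params.dark_level, params.n_control)
    dark = noisy(np.full(n_frames, params.dark_level), params.n_dark)
    return FrapExperiment(
        bleach=bleach,
        control=control,
        dark=dark,
        frame_interval=params.frame_interval,
        n_pre=params.n_pre,
    )
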