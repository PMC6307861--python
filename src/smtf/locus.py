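"""MS2 locus detection/tracking and locus-centred TF radial profiles.

An actively transcribing locus tagged with MS2/MCP appears as one bright
diffraction-limited spot per expressing nucleus, sitting in dark
nucleoplasm while the surrounding cytoplasm is bright. Detections are
difference-of-Gaussian blobs, filtered by a line-profile contrast ratio
that rejects extranuclear false positives, and linked in time by nearest
neighbours. Around each tracked locus a window of the transcription-
factor channel is cropped (with an offset in-nucleus control window),
and the windows are averaged into a radial profile normalized to 1 at
the largest radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from .io import Movie

__all__ = [
    "LocusDetection",
    "RadialProfile",
    "detect_loci",
    "contrast_filter",
    "track_loci",
    "crop_windows",
    "average_and_radial_profile",
]


@dataclass
class LocusDetection:
    """One candidate locus in one volume."""

    timepoint: int
    x: float  # um
    y: float
    z: float
    contrast_ratio: float = 1.0
    in_nucleus: Optional[bool] = None
    n_voxels: int = 0


@dataclass
class RadialProfile:
    """Locus-centred mean intensity vs radius, outermost bin = 1."""

    radii: np.ndarray       # um, bin centres
    mean: np.ndarray        # normalized
    sem: np.ndarray
    n_windows: int


def detect_loci(
    volume: np.ndarray,
    dog_sigmas: tuple[float, float] = (1.3, 3.9),
    threshold_mads: float = 10.0,
    size_range: tuple[int, int] = (3, 1000),
    voxel_size_xy: float = 0.1,
    voxel_size_z: float = 0.25,
    timepoint: int = 0,
) -> list[LocusDetection]:
    """Difference-of-Gaussian blob detection in a 3-D volume.

    The DoG response is globally thresholded at ``median +
    threshold_mads * MAD``; connected components outside ``size_range``
    (voxels) are dropped and the survivors reduced to intensity-weighted
    centroids. ``dog_sigmas`` are lateral sigmas in voxels; the axial
    sigmas are scaled by the voxel anisotropy.
    """
    v = np.asarray(volume, dtype=float)
    zscale = voxel_size_xy / voxel_size_z
    s1, s2 = dog_sigmas
    dog = ndi.gaussian_filter(v, (s1 * zscale, s1, s1)) - ndi.gaussian_filter(
        v, (s2 * zscale, s2, s2)
    )
    med = np.median(dog)
    mad = np.median(np.abs(dog - med))
    mask = dog > med + threshold_mads * mad
    lab, nlab = ndi.label(mask)
    out = []
    if nlab == 0:
        return out
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
    for l in range(1, nlab + 1):
        nv = int(sizes[l - 1])
        if not (size_range[0] <= nv <= size_range[1]):
            continue
        sel = lab == l
        w = np.clip(dog[sel], 0, None)
        coords = np.argwhere(sel)
        if w.sum() <= 0:
            continue
        cz, cy, cx = (coords * w[:, None]).sum(axis=0) / w.sum()
        out.append(
            LocusDetection(
                timepoint=timepoint,
                x=(cx + 0.5) * voxel_size_xy,
                y=(cy + 0.5) * voxel_size_xy,
                z=(cz + 0.5) * voxel_size_z,
                n_voxels=nv,
            )
        )
    return out


def contrast_filter(
    detection: LocusDetection,
    volume: np.ndarray,
    half_length: float = 1.0,
    min_ratio: float = 2.0,
    voxel_size_xy: float = 0.1,
    voxel_size_z: float = 0.25,
) -> tuple[bool, LocusDetection]:
    """Keep a detection only if its line-profile contrast is high.

    Along the x and y axes through the centroid, 1-um (``half_length``)
    profiles in each direction are extracted at the centroid's z-plane;
    the mean of the per-profile max/min ratios must reach ``min_ratio``.
    In-nucleus loci sit in dark nucleoplasm (high ratio), extranuclear
    detections in bright background (low ratio). The centroid is refined
    to the profile maximum.
    """
    v = np.asarray(volume, dtype=float)
    nz, ny, nx = v.shape
    iz = int(np.clip(round(detection.z / voxel_size_z - 0.5), 0, nz - 1))
    iy = int(np.clip(round(detection.y / voxel_size_xy - 0.5), 0, ny - 1))
    ix = int(np.clip(round(detection.x / voxel_size_xy - 0.5), 0, nx - 1))
    hl = int(round(half_length / voxel_size_xy))
    x0, x1 = max(ix - hl, 0), min(ix + hl + 1, nx)
    y0, y1 = max(iy - hl, 0), min(iy + hl + 1, ny)
    prof_x = v[iz, iy, x0:x1]
    prof_y = v[iz, y0:y1, ix]
    ratios = []
    for p in (prof_x, prof_y):
        mn = p.min()
        ratios.append(p.max() / mn if mn > 0 else np.inf)
    ratio = float(np.mean(ratios))
    refined = LocusDetection(
        timepoint=detection.timepoint,
        x=(x0 + int(np.argmax(prof_x)) + 0.5) * voxel_size_xy,
        y=(y0 + int(np.argmax(prof_y)) + 0.5) * voxel_size_xy,
        z=detection.z,
        contrast_ratio=ratio,
        in_nucleus=ratio >= min_ratio,
        n_voxels=detection.n_voxels,
    )
    return refined.in_nucleus, refined


def track_loci(
    detections_per_timepoint: Sequence[Sequence[LocusDetection]],
    max_disp: float = 1.0,
) -> list[list[LocusDetection]]:
    """Nearest-neighbour linking of loci across timepoints.

    Pairs are consumed in order of increasing 3-D distance with a
    ``max_disp`` gate; a missed detection splits the track (no gap
    closing).
    """
    tracks: list[list[LocusDetection]] = []
    open_tracks: list[list[LocusDetection]] = []
    for dets in detections_per_timepoint:
        dets = list(dets)
        new_open: list[list[LocusDetection]] = []
        if open_tracks and dets:
            ends = np.array(
                [[tr[-1].x, tr[-1].y, tr[-1].z] for tr in open_tracks]
            )
            pts = np.array([[d.x, d.y, d.z] for d in dets])
            dist = np.linalg.norm(ends[:, None] - pts[None], axis=2)
            ia, ib = np.nonzero(dist <= max_disp)
            order = np.lexsort((ib, ia, dist[ia, ib]))
            used_t, used_d = set(), set()
            for k in order:
                i, j = int(ia[k]), int(ib[k])
                if i in used_t or j in used_d:
                    continue
                used_t.add(i)
                used_d.add(j)
                open_tracks[i].append(dets[j])
                new_open.append(open_tracks[i])
            tracks.extend(
                tr for i, tr in enumerate(open_tracks) if i not in used_t
            )
            for j, d in enumerate(dets):
                if j not in used_d:
                    new_open.append([d])
        else:
            tracks.extend(open_tracks)
            new_open = [[d] for d in dets]
        open_tracks = new_open
    tracks.extend(open_tracks)
    return tracks


def _window_in_nucleus(labels: np.ndarray, r0: int, c0: int, half: int,
                       nucleus: int) -> bool:
    h, w = labels.shape
    r1, r2 = r0 - half, r0 + half + 1
    c1, c2 = c0 - half, c0 + half + 1
    if r1 < 0 or c1 < 0 or r2 > h or c2 > w:
        return False
    return bool(np.all(labels[r1:r2, c1:c2] == nucleus))


def crop_windows(
    track: Sequence[LocusDetection],
    tf_movie: Movie,
    nucleus_labels: np.ndarray,
    window: float = 2.18,
    control_offset: float = 2.6,
    z_projection_depth: float = 5.0,
    angle_step_deg: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Crop locus (TS) and control (RS) windows from the TF channel.

    For each tracked timepoint the TF volume is max-projected over
    ``z_projection_depth`` (a nuclear diameter) around the locus z, and a
    square window of side ``window`` um is cut at the locus. The window
    must lie fully inside the locus's nucleus. The control window centre
    is searched at distance ``control_offset`` by scanning angles in
    ``angle_step_deg`` steps until it is fully in-nucleus; loci with no
    valid control are discarded.

    Returns (ts_stack, rs_stack, log) with stacks of shape (n, s, s).
    """
    px = tf_movie.pixel_size_xy
    dz = tf_movie.voxel_size_z or 1.0
    half = int(round(window / 2 / px))
    side = 2 * half + 1
    off_px = control_offset / px
    ts, rs = [], []
    log = {"kept": 0, "discarded_window": 0, "discarded_control": 0}
    for det in track:
        t = det.timepoint
        vol = tf_movie.frames[t]
        r0 = int(np.floor(det.y / px))
        c0 = int(np.floor(det.x / px))
        if not (0 <= r0 < nucleus_labels.shape[0] and 0 <= c0 < nucleus_labels.shape[1]):
            log["discarded_window"] += 1
            continue
        nucleus = int(nucleus_labels[r0, c0])
        if nucleus == 0 or not _window_in_nucleus(
            nucleus_labels, r0, c0, half, nucleus
        ):
            log["discarded_window"] += 1
            continue
        iz = int(np.clip(round(det.z / dz - 0.5), 0, vol.shape[0] - 1))
        hz = max(1, int(round(z_projection_depth / 2 / dz)))
        proj = vol[max(iz - hz, 0) : iz + hz + 1].max(axis=0)
        ctrl = None
        for ang in np.deg2rad(np.arange(0, 360, angle_step_deg)):
            rc = int(round(r0 + off_px * np.sin(ang)))
            cc = int(round(c0 + off_px * np.cos(ang)))
            if (
                0 <= rc < nucleus_labels.shape[0]
                and 0 <= cc < nucleus_labels.shape[1]
                and _window_in_nucleus(nucleus_labels, rc, cc, half,
                                       int(nucleus_labels[rc, cc]) or -1)
                and nucleus_labels[rc, cc] > 0
            ):
                ctrl = (rc, cc)
                break
        if ctrl is None:
            log["discarded_control"] += 1
            continue
        ts.append(proj[r0 - half : r0 + half + 1, c0 - half : c0 + half + 1])
        rs.append(
            proj[ctrl[0] - half : ctrl[0] + half + 1,
                 ctrl[1] - half : ctrl[1] + half + 1]
        )
        log["kept"] += 1
    ts_stack = np.array(ts) if ts else np.empty((0, side, side))
    rs_stack = np.array(rs) if rs else np.empty((0, side, side))
    return ts_stack, rs_stack, log


def average_and_radial_profile(
    window_stack: np.ndarray, pixel_size: float = 0.1
) -> tuple[np.ndarray, RadialProfile]:
    """Mean window image and its radial profile.

    The profile is computed in 1-pixel annuli about the window centre,
    normalized so the outermost annulus is exactly 1; the standard error
    per annulus is taken across windows.
    """
    stack = np.asarray(window_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("window stack must be non-empty (n, s, s)")
    n, h, w = stack.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.hypot(rr - cy, cc - cx)
    nbins = int(np.floor(min(cy, cx))) + 1
    bin_idx = np.minimum(np.floor(dist).astype(int), nbins - 1)
    inside = np.floor(dist).astype(int) < nbins
    per_window = np.empty((n, nbins))
    for b in range(nbins):
        m = inside & (bin_idx == b)
        per_window[:, b] = stack[:, m].mean(axis=1)
    outer = per_window[:, -1].mean()
    mean = per_window.mean(axis=0) / outer
    mean[-1] = 1.0  # exact by the normalization contract
    sem = per_window.std(axis=0, ddof=1) / np.sqrt(n) / outer if n > 1 else (
        np.zeros(nbins)
    )
    radii = (np.arange(nbins) + 0.5) * pixel_size
    return stack.mean(axis=0), RadialProfile(
        radii=radii, mean=mean, sem=sem, n_windows=n
    )
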