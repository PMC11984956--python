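"""Two-color 3D single-molecule localization post-processing.

The processing chain mirrors standard two-channel 3D SMLM workflows:

1. stage drift is measured by tracking a fiducial bead through the frame
   series, smoothed with a cubic smoothing spline (csaps convention,
   smoothing parameter 1e-6) and subtracted from every localization;
2. localizations are quality-filtered on the lateral Cramér–Rao lower
   bound (default: drop CRLB > 20 nm) and on the mean distance to the
   eight nearest neighbours (drops spurious isolated localizations);
3. the channels are registered by a planar affine estimated from bead
   correspondences at the coverslip, then fine-tuned by iterative 3D
   cross-correlation of a structure imaged in both channels, until the
   incremental shift is below 2 nm on every axis;
4. isolated clusters are sized by per-axis Gaussian fits of their
   localization histograms (1/e^2 full width = 4 sigma) and compared via
   center-of-mass offsets and 3D distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .synthetic import Affine2D

__all__ = [
    "Affine2D",
    "DriftTrace",
    "RegistrationResult",
    "ClusterSummary",
    "ComOffset",
    "track_fiducial_and_fit_drift",
    "apply_drift_correction",
    "filter_quality",
    "estimate_affine",
    "apply_affine_to_locs",
    "refine_registration_3dcc",
    "isolate_cluster",
    "cluster_axis_fit",
    "vesicle_candidate_filter",
    "com_offset",
    "distance_to_structure",
]

AXES = ("x_nm", "y_nm", "z_nm")

#: csaps-convention smoothing parameter (0 = least-squares line,
#: 1 = interpolation).
DEFAULT_SPLINE_SMOOTHING = 1e-6


@dataclass
class DriftTrace:
    """Per-frame stage displacement (nm), zero-referenced to frame 0."""

    displacement_nm: np.ndarray  # (n_frames, 3)
    smoothing: float = DEFAULT_SPLINE_SMOOTHING

    def __post_init__(self) -> None:
        self.displacement_nm = np.asarray(self.displacement_nm, dtype=float)
        if self.displacement_nm.ndim != 2 or self.displacement_nm.shape[1] != 3:
            raise ValueError("displacement must be (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.displacement_nm.shape[0]


@dataclass
class RegistrationResult:
    """Outcome of iterative 3D cross-correlation fine-tuning."""

    shift_nm: np.ndarray  # cumulative shift applied to the moving channel
    iterations: int
    converged: bool
    per_iteration_shifts_nm: list = dc_field(default_factory=list)
    convergence_nm: float = 2.0

    def __post_init__(self) -> None:
        self.shift_nm = np.asarray(self.shift_nm, dtype=float).reshape(3)


@dataclass
class ClusterSummary:
    """Per-axis Gaussian description of an isolated localization cluster."""

    mean_nm: np.ndarray
    sigma_nm: np.ndarray
    width_1e2_nm: np.ndarray  # = 4 * sigma per axis
    com_nm: np.ndarray
    n_locs: int
    fit_ok: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        self.mean_nm = np.asarray(self.mean_nm, dtype=float).reshape(3)
        self.sigma_nm = np.asarray(self.sigma_nm, dtype=float).reshape(3)
        self.width_1e2_nm = np.asarray(self.width_1e2_nm, dtype=float).reshape(3)
        self.com_nm = np.asarray(self.com_nm, dtype=float).reshape(3)


@dataclass
class ComOffset:
    """Per-axis COM offsets between two species and the 3D separation."""

    offset_nm: np.ndarray  # mean_B - mean_A per axis
    separation_nm: float
    summary_a: ClusterSummary
    summary_b: ClusterSummary


# ---------------------------------------------------------------------------
# drift
# ---------------------------------------------------------------------------

def track_fiducial_and_fit_drift(
    locs: pd.DataFrame,
    fiducial_seed_position: tuple[float, float, float],
    smoothing: float = DEFAULT_SPLINE_SMOOTHING,
    capture_radius_nm: float = 250.0,
    min_coverage: float = 0.8,
    max_gap_frames: int = 50,
    n_frames: int | None = None,
) -> DriftTrace:
    """Track one fiducial bead across frames and fit a smooth drift trace.

    Frame by frame, the localization nearest to the running bead position
    (within ``capture_radius_nm``) is taken as the bead; the raw per-frame
    positions are then smoothed per axis with a cubic smoothing spline
    using the csaps convention (objective p * sum-of-squares +
    (1 - p) * curvature; ``smoothing`` is p) and evaluated on every frame.
    The trace is zero-referenced to frame 0.

    Raises when the bead is found in fewer than ``min_coverage`` of the
    frames or lost for a run longer than ``max_gap_frames``.
    """
    if not 0.0 <= smoothing <= 1.0:
        raise ValueError("smoothing parameter must be in [0, 1]")
    if n_frames is None:
        n_frames = int(locs["frame"].max()) + 1
    xyz = locs[list(AXES)].to_numpy(float)
    frames = locs["frame"].to_numpy(int)
    ref = np.asarray(fiducial_seed_position, dtype=float)
    found_frames, found_pos = [], []
    gap = 0
    for f in range(n_frames):
        sel = frames == f
        if sel.any():
            pts = xyz[sel]
            d = np.linalg.norm(pts - ref, axis=1)
            j = int(np.argmin(d))
            if d[j] <= capture_radius_nm:
                found_frames.append(f)
                found_pos.append(pts[j])
                ref = pts[j]
                gap = 0
                continue
        gap += 1
        if gap > max_gap_frames:
            raise ValueError(
                f"fiducial lost for more than {max_gap_frames} consecutive frames"
            )
    if len(found_frames) < min_coverage * n_frames:
        raise ValueError(
            f"fiducial localized in only {len(found_frames)}/{n_frames} frames"
        )
    found_frames = np.asarray(found_frames, dtype=float)
    found_pos = np.asarray(found_pos, dtype=float)
    all_frames = np.arange(n_frames, dtype=float)
    trace = np.empty((n_frames, 3))
    lam = (1.0 - smoothing) / smoothing if smoothing > 0 else None
    for ax in range(3):
        if smoothing >= 1.0 or len(found_frames) < 4:
            trace[:, ax] = np.interp(all_frames, found_frames, found_pos[:, ax])
        else:
            spl = make_smoothing_spline(found_frames, found_pos[:, ax], lam=lam)
            trace[:, ax] = spl(all_frames)
    trace -= trace[0]
    return DriftTrace(displacement_nm=trace, smoothing=smoothing)


def apply_drift_correction(locs: pd.DataFrame, trace: DriftTrace) -> pd.DataFrame:
    """Subtract the drift trace from every localization (by frame)."""
    frames = locs["frame"].to_numpy(int)
    if frames.min() < 0 or frames.max() >= trace.n_frames:
        raise ValueError("localization frame outside the drift trace")
    out = locs.copy()
    shift = trace.displacement_nm[frames]
    for i, ax in enumerate(AXES):
        out[ax] = out[ax].to_numpy(float) - shift[:, i]
    return out


# ---------------------------------------------------------------------------
# quality filtering
# ---------------------------------------------------------------------------

def filter_quality(
    locs: pd.DataFrame,
    crlb_max_nm: float = 20.0,
    nn_k: int = 8,
    nn_mean_dist_max_nm: float = 100.0,
) -> pd.DataFrame:
    """Drop imprecise and spurious localizations.

    Keeps rows with lateral CRLB <= ``crlb_max_nm`` AND mean 3D distance
    to the ``nn_k`` nearest neighbours <= ``nn_mean_dist_max_nm``. With
    fewer than ``nn_k + 1`` rows the neighbour filter is skipped with a
    warning. Never increases the row count; idempotent on well-separated
    cluster/outlier geometries.
    """
    if len(locs) == 0:
        raise ValueError("empty localization table")
    keep = locs["crlb_xy_nm"].to_numpy(float) <= crlb_max_nm
    kept = locs[keep]
    if len(kept) < nn_k + 1:
        warnings.warn(
            "too few localizations for the neighbour filter; skipped", stacklevel=2
        )
        return kept.reset_index(drop=True)
    xyz = kept[list(AXES)].to_numpy(float)
    tree = cKDTree(xyz)
    dists, _ = tree.query(xyz, k=nn_k + 1)  # first neighbour is the point itself
    mean_nn = dists[:, 1:].mean(axis=1)
    return kept[mean_nn <= nn_mean_dist_max_nm].reset_index(drop=True)


# ---------------------------------------------------------------------------
# channel registration
# ---------------------------------------------------------------------------

def estimate_affine(
    bead_positions_moving: np.ndarray,
    bead_positions_target: np.ndarray,
) -> Affine2D:
    """Least-squares planar affine mapping moving bead xy onto target xy.

    Solves min ||A p + t - q||^2 over all correspondences; requires at
    least three non-collinear beads. The RMS residual of the fit is
    attached to the returned transform.
    """
    p = np.asarray(bead_positions_moving, dtype=float)[:, :2]
    q = np.asarray(bead_positions_target, dtype=float)[:, :2]
    if p.shape != q.shape or len(p) < 3:
        raise ValueError("need >= 3 matched bead positions in both channels")
    centered = p - p.mean(axis=0)
    # collinearity check via the singular values of the centered cloud
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("bead positions are collinear; affine is degenerate")
    design = np.column_stack([p, np.ones(len(p))])
    coef, *_ = np.linalg.lstsq(design, q, rcond=None)
    matrix = coef[:2].T
    translation = coef[2]
    aff = Affine2D(matrix=matrix, translation=translation)
    resid = aff.apply(p) - q
    aff._rms_residual_nm = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return aff


def apply_affine_to_locs(
    locs: pd.DataFrame, affine: Affine2D, z_shift_nm: float = 0.0
) -> pd.DataFrame:
    """Apply a planar affine (+ optional z shift) to a localization table."""
    out = locs.copy()
    xy = affine.apply(out[["x_nm", "y_nm"]].to_numpy(float))
    out["x_nm"], out["y_nm"] = xy[:, 0], xy[:, 1]
    out["z_nm"] = out["z_nm"].to_numpy(float) + z_shift_nm
    return out


def _histogram3d(xyz: np.ndarray, edges: list[np.ndarray]) -> np.ndarray:
    hist, _ = np.histogramdd(xyz, bins=edges)
    return hist


def _quadratic_subvoxel(line: np.ndarray, w: int) -> float:
    """Sub-voxel peak offset from an LSQ quadratic over a ±w-voxel window.

    Averaging the quadratic over the window suppresses count noise on the
    broad correlation peaks that extended structures produce; falls back to
    the integer peak when the fit is not concave.
    """
    t = np.arange(-w, w + 1, dtype=float)
    c = np.polyfit(t, line, 2)
    if c[0] >= 0:
        return 0.0
    offset = -c[1] / (2.0 * c[0])
    return float(np.clip(offset, -1.0, 1.0))


def refine_registration_3dcc(
    locs_ref: pd.DataFrame,
    locs_moving: pd.DataFrame,
    voxel_nm: float = 10.0,
    convergence_nm: float = 2.0,
    max_iter: int = 20,
    max_shift_nm: float = 300.0,
    peak_window_voxels: int = 5,
) -> tuple[RegistrationResult, pd.DataFrame]:
    """Iterative 3D cross-correlation fine-tuning of channel registration.

    Both channels are rendered to 3D count histograms on a shared grid
    (``voxel_nm`` voxels); their 3D cross-correlation peak, refined to
    sub-voxel precision with a per-axis least-squares quadratic over a
    ±``peak_window_voxels`` window, gives the shift applied to the moving
    channel. Iterations continue until the incremental shift is below
    ``convergence_nm`` on every axis or ``max_iter`` is reached. Returns
    the registration result (cumulative shift) and the shifted moving
    table.
    """
    if voxel_nm <= 0:
        raise ValueError("voxel_nm must be positive")
    ref_xyz = locs_ref[list(AXES)].to_numpy(float)
    mov = locs_moving.copy()
    if len(ref_xyz) == 0 or len(mov) == 0:
        raise ValueError("both channels need localizations")
    pad = max_shift_nm + 2 * voxel_nm
    lo = np.minimum(ref_xyz.min(axis=0), mov[list(AXES)].to_numpy(float).min(axis=0)) - pad
    hi = np.maximum(ref_xyz.max(axis=0), mov[list(AXES)].to_numpy(float).max(axis=0)) + pad
    edges = [np.arange(lo[i], hi[i] + voxel_nm, voxel_nm) for i in range(3)]
    h_ref = _histogram3d(ref_xyz, edges)

    cumulative = np.zeros(3)
    history: list[np.ndarray] = []
    converged = False
    it = 0
    max_lag = int(np.ceil(max_shift_nm / voxel_nm))
    for it in range(1, max_iter + 1):
        h_mov = _histogram3d(mov[list(AXES)].to_numpy(float), edges)
        corr = signal.correlate(h_ref, h_mov, mode="same", method="fft")
        # restrict the search to physically plausible lags
        center = np.array(corr.shape) // 2
        sl = tuple(
            slice(max(0, c - max_lag), min(s, c + max_lag + 1))
            for c, s in zip(center, corr.shape)
        )
        sub = corr[sl]
        peak = np.unravel_index(np.argmax(sub), sub.shape)
        peak = np.array([p + s.start for p, s in zip(peak, sl)])
        w = peak_window_voxels
        if any(p < w or p >= s - w for p, s in zip(peak, corr.shape)):
            raise ValueError(
                "correlation peak at histogram border; increase max_shift_nm"
            )
        frac = np.zeros(3)
        for ax in range(3):
            idx = [slice(p, p + 1) for p in peak]
            idx[ax] = slice(peak[ax] - w, peak[ax] + w + 1)
            line = corr[tuple(idx)].ravel()
            frac[ax] = _quadratic_subvoxel(line, w)
        lag_voxels = peak + frac - center
        # correlate(ref, mov) peaks at -s when mov = ref shifted by +s,
        # so the correction added to the moving channel is +lag.
        step = lag_voxels * voxel_nm
        for i, ax in enumerate(AXES):
            mov[ax] = mov[ax].to_numpy(float) + step[i]
        cumulative += step
        history.append(step.copy())
        if np.all(np.abs(step) < convergence_nm):
            converged = True
            break
    result = RegistrationResult(
        shift_nm=cumulative,
        iterations=it,
        converged=converged,
        per_iteration_shifts_nm=history,
        convergence_nm=convergence_nm,
    )
    return result, mov


# ---------------------------------------------------------------------------
# cluster isolation and sizing
# ---------------------------------------------------------------------------

def isolate_cluster(
    locs: pd.DataFrame,
    box_roi: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
) -> pd.DataFrame:
    """Localizations inside an axis-aligned box ((x0,x1),(y0,y1),(z0,z1)) nm.

    An explicit, recorded ROI stands in for interactive cluster isolation.
    """
    keep = np.ones(len(locs), dtype=bool)
    for (lo, hi), ax in zip(box_roi, AXES):
        if hi <= lo:
            raise ValueError("ROI bounds must satisfy lo < hi on every axis")
        v = locs[ax].to_numpy(float)
        keep &= (v >= lo) & (v <= hi)
    if not keep.any():
        raise ValueError("ROI selects no localizations")
    return locs[keep].reset_index(drop=True)


def _fit_gaussian_1d(values: np.ndarray, bin_nm: float) -> tuple[float, float, bool]:
    """Gaussian (mu, sigma) from a histogram fit; moment fallback on failure."""
    mu0, sd0 = float(values.mean()), float(values.std(ddof=1))
    if sd0 == 0:
        return mu0, 0.0, False
    edges = np.arange(mu0 - 5 * sd0, mu0 + 5 * sd0 + bin_nm, bin_nm)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, mu, sigma):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    try:
        popt, _ = curve_fit(
            gauss,
            centers,
            counts,
            p0=[counts.max(), mu0, sd0],
            # Poisson count errors: sqrt(N) weights (floored at 1)
            sigma=np.sqrt(np.maximum(counts, 1.0)),
            bounds=([0.0, mu0 - 5 * sd0, bin_nm / 10.0], [np.inf, mu0 + 5 * sd0, 10 * sd0]),
            maxfev=5000,
        )
        return float(popt[1]), float(abs(popt[2])), True
    except (RuntimeError, ValueError):
        return mu0, sd0, False


def cluster_axis_fit(
    locs: pd.DataFrame, bin_nm: float = 10.0, min_locs: int = 50
) -> ClusterSummary:
    """Per-axis Gaussian fit of a cluster's localization histograms.

    The 1/e^2 full width per axis is 4 sigma of the fitted Gaussian (the
    profile falls to e^-2 at +/- 2 sigma); the cluster COM is the triplet
    of fitted means. Falls back to sample moments (flagged) when a fit
    fails to converge.
    """
    if len(locs) < min_locs:
        raise ValueError(f"cluster needs >= {min_locs} localizations")
    means, sigmas, oks = [], [], []
    for ax in AXES:
        mu, sigma, ok = _fit_gaussian_1d(locs[ax].to_numpy(float), bin_nm)
        means.append(mu)
        sigmas.append(sigma)
        oks.append(ok)
    means = np.array(means)
    sigmas = np.array(sigmas)
    return ClusterSummary(
        mean_nm=means,
        sigma_nm=sigmas,
        width_1e2_nm=4.0 * sigmas,
        com_nm=means,
        n_locs=len(locs),
        fit_ok=tuple(oks),
    )


def vesicle_candidate_filter(summary: ClusterSummary, min_dim_nm: float = 120.0) -> bool:
    """True when all three 1/e^2 widths reach ``min_dim_nm`` (inclusive).

    Clusters smaller than the threshold in any direction are too small to
    be vesicles and are excluded from vesicle-candidate counts.
    """
    return bool(np.all(summary.width_1e2_nm >= min_dim_nm))


def com_offset(
    locs_a: pd.DataFrame,
    locs_b: pd.DataFrame,
    bin_nm: float = 10.0,
    min_locs: int = 50,
) -> ComOffset:
    """Center-of-mass separation between two localization clusters.

    One Gaussian is fitted per species per axis; the per-axis offset is the
    difference of fitted means (B - A) and the separation their Euclidean
    norm in 3D.
    """
    sa = cluster_axis_fit(locs_a, bin_nm=bin_nm, min_locs=min_locs)
    sb = cluster_axis_fit(locs_b, bin_nm=bin_nm, min_locs=min_locs)
    offset = sb.com_nm - sa.com_nm
    return ComOffset(
        offset_nm=offset,
        separation_nm=float(np.linalg.norm(offset)),
        summary_a=sa,
        summary_b=sb,
    )


def distance_to_structure(cluster_com, reference_com) -> float:
    """Euclidean 3D distance (nm) between two centers of mass."""
    a = np.asarray(cluster_com, dtype=float).reshape(3)
    b = np.asarray(reference_com, dtype=float).reshape(3)
    return float(np.linalg.norm(a - b))
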