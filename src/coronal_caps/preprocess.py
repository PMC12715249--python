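"""Five-stage sMRI preprocessing: QC, brain extraction, affine spatial
normalization, intensity normalization, and 10-slice coronal grid assembly.

The end product of the chain is a 512x512 8-bit "grid image" per scan:
ten coronal slices at fixed millimetre offsets from the anterior-commissure
analogue (-8..+10 mm, 2 mm apart, 18 mm anterior-posterior span), each
resized to 102x256 and tiled 5x2 with the posterior row on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu
from skimage.transform import resize
from sklearn.cluster import KMeans

from .volume import BrainVolume

log = logging.getLogger(__name__)

SLICE_OFFSETS_MM = (-8, -6, -4, -2, 0, 2, 4, 6, 8, 10)
SNR_REJECT_BELOW = 20.0
MOTION_REJECT_ABOVE = 0.3
SNR_NORM_CEILING = 40.0

SLICE_W, SLICE_H = 102, 256
GRID_SIDE = 512

# ---------------------------------------------------------------------------
# Stage 1: quality control
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    snr: float
    motion_score: float
    uniformity: float
    quality_score: float
    flag: str  # ACCEPT | REJECT


def combine_quality(snr: float, motion_score: float, uniformity: float) -> tuple[float, str]:
    """Weighted quality score with hard rejection gates.

    Rejects iff SNR < 20 or motion score > 0.3 (score forced to 0);
    otherwise 0.4*snr_norm + 0.3*(1-motion) + 0.3*uniformity, where raw
    SNR is normalized as min(snr, 40)/40 so the rejection threshold of
    20 maps to 0.5.
    """
    if snr < SNR_REJECT_BELOW or motion_score > MOTION_REJECT_ABOVE:
        return 0.0, "REJECT"
    snr_norm = min(snr, SNR_NORM_CEILING) / SNR_NORM_CEILING
    score = 0.4 * snr_norm + 0.3 * (1.0 - motion_score) + 0.3 * uniformity
    return float(np.clip(score, 0.0, 1.0)), "ACCEPT"


def _head_mask(data: np.ndarray, smooth_sigma: float = 1.0) -> np.ndarray:
    """Largest connected component above the Otsu threshold (the head)."""
    sm = ndimage.gaussian_filter(data, smooth_sigma)
    try:
        t = threshold_otsu(sm)
    except ValueError:  # constant image
        t = sm.mean()
    fg = sm > t
    if not fg.any() or fg.all():
        raise ValueError("cannot separate foreground from background")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    return fg


def estimate_motion_score(data: np.ndarray, head: np.ndarray) -> float:
    """Normalized ghost-amplitude estimate in [0, 1].

    Motion shows up as an attenuated replica of the head shifted by half
    the field of view along the phase-encode (posterior-anterior) axis.
    The estimator regresses the volume on its half-FOV-shifted copy over
    background voxels where the shifted head is bright, and maps the
    regression amplitude so a half-intensity replica scores 1.0.
    """
    shifted = np.roll(data, data.shape[1] // 2, axis=1)
    p98 = np.percentile(data, 98)
    if p98 <= 0:
        return 0.0
    sm_shift = ndimage.gaussian_filter(shifted, 1.0)
    outside = ~ndimage.binary_dilation(head, iterations=2)
    region = outside & (sm_shift > 0.5 * p98)
    if region.sum() < 100:
        return 0.0
    v, s = data[region], shifted[region]
    var_s = s.var()
    if var_s <= 0:
        return 0.0
    beta = float(np.cov(v, s)[0, 1] / var_s)
    from .cohort import GHOST_FULL_AMPLITUDE

    return float(np.clip(beta / GHOST_FULL_AMPLITUDE, 0.0, 1.0))


def estimate_uniformity(data: np.ndarray, head: np.ndarray) -> float:
    """Intensity homogeneity of the bright (WM-band) tissue.

    1 - IQR/median of the low-pass-filtered intensities over the bright
    (WM-band) tissue, clipped to [0, 1]. The band is selected on a
    flat-fielded image (low-pass divided by a very-low-pass version) so
    that a multiplicative bias field cannot steer the selection; the
    spread is then measured on the un-flattened intensities, which the
    bias field widens.
    """
    lp = ndimage.gaussian_filter(data, 2.0)
    # the flat-field scale tracks the head size so behaviour is consistent
    # across volume geometries
    r_head = (3.0 * head.sum() / (4.0 * np.pi)) ** (1.0 / 3.0)
    flat = lp / np.maximum(ndimage.gaussian_filter(data, 0.35 * r_head), 1e-6)
    band = head & (flat > np.percentile(flat[head], 70))
    vals = lp[band]
    med = np.median(vals)
    if med <= 0:
        return 0.0
    iqr = np.percentile(vals, 75) - np.percentile(vals, 25)
    return float(np.clip(1.0 - iqr / med, 0.0, 1.0))


def quality_control(volume: BrainVolume) -> QCReport:
    """Stage-1 QC: SNR, motion and uniformity estimates plus accept/reject."""
    data = volume.data
    if not np.any(data):
        raise ValueError("empty volume")
    head = _head_mask(data)
    bg = ~ndimage.binary_dilation(head, iterations=2)
    bg_sd = float(data[bg].std())
    snr = float(data[head].mean() / bg_sd) if bg_sd > 0 else np.inf
    motion = estimate_motion_score(data, head)
    uniformity = estimate_uniformity(data, head)
    score, flag = combine_quality(snr, motion, uniformity)
    return QCReport(snr=snr, motion_score=motion, uniformity=uniformity,
                    quality_score=score, flag=flag)


# ---------------------------------------------------------------------------
# Stage 2: brain extraction
# ---------------------------------------------------------------------------

FRACTIONAL_INTENSITY = 0.3


def brain_extraction(
    volume: BrainVolume, fractional_intensity: float = FRACTIONAL_INTENSITY
) -> tuple[BrainVolume, np.ndarray]:
    """Threshold-and-refine skull stripping.

    The initial mask keeps voxels above robust_min + f*(robust_max -
    robust_min) (robust = 2nd/98th percentiles), retains the largest
    connected component, closes it with a 3x3x3 structuring element and
    fills holes. The returned volume is the input times a
    gradient-weighted soft mask (Gaussian-softened edge); background is 0.
    """
    data = volume.data
    rmin, rmax = np.percentile(data, [2, 98])
    t = rmin + fractional_intensity * (rmax - rmin)
    mask = data > t
    if not mask.any():
        raise ValueError("extraction failed: empty mask")
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3), bool))
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise ValueError("extraction failed: empty mask")
    soft = ndimage.gaussian_filter(mask.astype(np.float64), 1.0)
    soft[soft < 1e-2] = 0.0
    out = replace(volume, data=data * soft, labels=None)
    return out, mask


# ---------------------------------------------------------------------------
# Stage 3: affine spatial normalization
# ---------------------------------------------------------------------------


@dataclass
class RegistrationResult:
    registered: BrainVolume
    transform: dict  # translation_mm, rotation_rad, scale, shear
    cost_value: float
    converged: bool = True


def _params_to_matrix(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """12-parameter vector -> (3x3 linear part, translation mm).

    Layout: 3 translations (mm), 3 rotations (rad, x/y/z Euler),
    3 log-scales, 3 shears. Linear part = R @ S @ H.
    """
    t = p[:3]
    rx, ry, rz = p[3:6]
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    S = np.diag(np.exp(p[6:9]))
    H = np.eye(3)
    H[0, 1], H[0, 2], H[1, 2] = p[9:12]
    return Rx @ Ry @ Rz @ S @ H, t


def _center_mm(vol: BrainVolume) -> np.ndarray:
    return (np.asarray(vol.shape) - 1) / 2.0 * np.asarray(vol.spacing)


def resample_onto(moving: BrainVolume, template: BrainVolume, p: np.ndarray,
                  order: int = 1) -> np.ndarray:
    """Resample ``moving`` onto the template lattice under parameters ``p``.

    The transform maps template physical coordinates (mm, about the
    volume center) to moving physical coordinates: x_mov = A x_tmp + t.
    """
    A, t = _params_to_matrix(p)
    sp_t = np.diag(template.spacing)
    sp_m_inv = np.diag(1.0 / np.asarray(moving.spacing))
    M = sp_m_inv @ A @ sp_t
    c_t = (np.asarray(template.shape) - 1) / 2.0
    c_m = (np.asarray(moving.shape) - 1) / 2.0
    offset = sp_m_inv @ (A @ (-np.asarray(template.spacing) * c_t) + t) + c_m
    return ndimage.affine_transform(
        moving.data, M, offset=offset, output_shape=template.shape, order=order,
        mode="constant", cval=0.0,
    )


def correlation_ratio(template_vals: np.ndarray, moving_vals: np.ndarray,
                      n_bins: int = 32) -> float:
    """eta^2 of moving intensity explained by binned template intensity."""
    total_var = moving_vals.var()
    if total_var <= 0:
        return 0.0
    edges = np.linspace(template_vals.min(), template_vals.max(), n_bins + 1)
    idx = np.clip(np.digitize(template_vals, edges[1:-1]), 0, n_bins - 1)
    n_k = np.bincount(idx, minlength=n_bins)
    sum_k = np.bincount(idx, weights=moving_vals, minlength=n_bins)
    sq_k = np.bincount(idx, weights=moving_vals**2, minlength=n_bins)
    nz = n_k > 0
    within = np.sum(sq_k[nz] - sum_k[nz] ** 2 / n_k[nz])
    return float(1.0 - within / (len(moving_vals) * total_var))


def _registration_cost(p, moving_small, template_small) -> float:
    res = resample_onto(moving_small, template_small, np.asarray(p), order=1)
    return 1.0 - correlation_ratio(template_small.data.ravel(), res.ravel())


def _downsample(vol: BrainVolume, factor: int) -> BrainVolume:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol.data, 0.5 * factor)
    data = sm[::factor, ::factor, ::factor]
    return BrainVolume(
        data=data,
        spacing=tuple(s * factor for s in vol.spacing),
        origin=tuple(min(o // factor, n - 1) for o, n in zip(vol.origin, data.shape)),
    )


def _moment_init(moving: BrainVolume, template: BrainVolume) -> np.ndarray:
    """Center-of-mass translation + second-moment (principal-axes) scale init."""
    p = np.zeros(12)

    def moments(vol):
        w = np.clip(vol.data, 0, None)
        tot = w.sum()
        if tot <= 0:
            return np.zeros(3), np.ones(3)
        idx = np.indices(vol.shape).reshape(3, -1)
        mm = idx * np.asarray(vol.spacing)[:, None]
        com = (mm * w.ravel()).sum(axis=1) / tot
        var = ((mm - com[:, None]) ** 2 * w.ravel()).sum(axis=1) / tot
        return com - _center_mm(vol), var

    com_m, var_m = moments(moving)
    com_t, var_t = moments(template)
    p[:3] = com_m - com_t
    p[6:9] = 0.5 * np.log(np.maximum(var_m, 1e-9) / np.maximum(var_t, 1e-9))
    return p


def spatial_normalization(
    brain: BrainVolume,
    template: BrainVolume,
    coarse_factor: int = 2,
    maxiter: int = 30,
) -> RegistrationResult:
    """12-DOF affine registration of ``brain`` onto ``template``.

    Correlation ratio is the similarity metric, initialized by center of
    mass and principal-axes second moments, then refined with Powell
    (rigid stage, then full affine) on a coarsened pair. The output is
    the moving volume resampled onto the template lattice by trilinear
    interpolation. If the optimizer does not converge, the best
    parameters so far are returned with a warning logged.
    """
    if not np.any(brain.data) or not np.any(template.data):
        raise ValueError("both volumes must be nonempty")
    mov_s = _downsample(brain, coarse_factor)
    tmp_s = _downsample(template, coarse_factor)
    p0 = _moment_init(brain, template)
    cost0 = _registration_cost(p0, mov_s, tmp_s)

    converged = True
    rigid_idx = np.arange(6)

    def rigid_cost(q):
        p = p0.copy()
        p[rigid_idx] = q
        return _registration_cost(p, mov_s, tmp_s)

    r1 = optimize.minimize(rigid_cost, p0[rigid_idx], method="Powell",
                           options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-5})
    p1 = p0.copy()
    p1[rigid_idx] = r1.x
    r2 = optimize.minimize(_registration_cost, p1, args=(mov_s, tmp_s), method="Powell",
                           options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-5})
    p_best, cost_best = (np.asarray(r2.x), float(r2.fun))
    if cost_best > cost0:  # optimizer wandered off; keep initialization
        p_best, cost_best = p0, cost0
    if not (r1.success and r2.success):
        converged = False
        log.warning("affine registration did not fully converge; returning best-so-far")

    registered = BrainVolume(
        data=resample_onto(brain, template, p_best, order=1),
        spacing=template.spacing,
        origin=template.origin,
    )
    transform = {
        "translation_mm": p_best[:3].tolist(),
        "rotation_rad": p_best[3:6].tolist(),
        "scale": np.exp(p_best[6:9]).tolist(),
        "shear": p_best[9:12].tolist(),
        "params": p_best.tolist(),
    }
    return RegistrationResult(registered=registered, transform=transform,
                              cost_value=cost_best, converged=converged)


def make_template(shape=(96, 112, 96), spacing=(2.0, 2.0, 2.0)) -> BrainVolume:
    """Noise-free CN-anatomy phantom used as the registration target."""
    from .cohort import PhantomParams, render_phantom

    params = PhantomParams(volume_shape=tuple(shape), voxel_spacing_mm=tuple(spacing),
                           noise_sd=0.0)
    return render_phantom(params, seed=0)


# ---------------------------------------------------------------------------
# Stage 4: intensity normalization
# ---------------------------------------------------------------------------

MIN_WM_VOXELS = 100


def segment_wm(data: np.ndarray, mask: np.ndarray, seed: int = 0) -> tuple[float, float]:
    """3-class intensity clustering of masked voxels; WM = highest-mean class.

    Returns the WM mean and standard deviation. Raises if the WM class
    has fewer than 100 voxels.
    """
    vals = data[mask].reshape(-1, 1)
    if len(vals) < 3 * MIN_WM_VOXELS:
        raise ValueError("segmentation degenerate: mask too small")
    rng = np.random.default_rng(seed)
    sample = vals if len(vals) <= 20000 else vals[rng.choice(len(vals), 20000, replace=False)]
    km = KMeans(n_clusters=3, n_init=3, random_state=seed).fit(sample)
    centers = km.cluster_centers_.ravel()
    wm_cls = int(np.argmax(centers))
    labels = km.predict(vals)
    wm_vals = vals[labels == wm_cls].ravel()
    if len(wm_vals) < MIN_WM_VOXELS:
        raise ValueError("segmentation degenerate: WM class has < 100 voxels")
    return float(wm_vals.mean()), float(wm_vals.std())


def reference_histogram(values: np.ndarray, n_points: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Empirical quantile function (values at equally spaced CDF points)."""
    q = np.linspace(0.0, 1.0, n_points)
    return np.quantile(np.asarray(values, float), q), q


def _match_histogram(vals: np.ndarray, reference: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    ref_vals, ref_cdf = reference
    if np.any(np.diff(ref_cdf) < 0):
        raise ValueError("reference histogram must be monotone")
    order = np.argsort(vals, kind="stable")
    ranks = np.empty(len(vals))
    ranks[order] = (np.arange(len(vals)) + 0.5) / len(vals)
    return np.interp(ranks, ref_cdf, ref_vals)


def intensity_normalization(
    registered: BrainVolume,
    mask: np.ndarray,
    reference: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
) -> BrainVolume:
    """WM z-scoring, optional histogram matching, clipping, 8-bit rescale.

    Masked voxels are z-scored by the WM mean/sd from a 3-class intensity
    segmentation, optionally quantile-matched to a reference histogram,
    clipped at the 99.5th percentile, and rescaled linearly to [0, 255].
    Background voxels are 0.
    """
    if not mask.any():
        raise ValueError("mask is empty")
    data = registered.data
    wm_mean, wm_sd = segment_wm(data, mask, seed=seed)
    if wm_sd <= 0:
        wm_sd = 1.0
    vals = (data[mask] - wm_mean) / wm_sd
    if reference is not None:
        vals = _match_histogram(vals, reference)
    hi = np.percentile(vals, 99.5)
    vals = np.minimum(vals, hi)
    lo = vals.min()
    span = vals.max() - lo
    vals = (vals - lo) / span * 255.0 if span > 0 else np.zeros_like(vals)
    out = np.zeros_like(data)
    out[mask] = vals
    return replace(registered, data=out, labels=None)


# ---------------------------------------------------------------------------
# Stage 5: coronal grid construction
# ---------------------------------------------------------------------------


@dataclass
class GridImage:
    pixels: np.ndarray  # (512, 512) uint8
    slice_positions_mm: tuple
    scan_id: str = ""
    patient_id: str = ""
    diagnosis: str = ""

    def __post_init__(self) -> None:
        if self.pixels.shape != (GRID_SIDE, GRID_SIDE) or self.pixels.dtype != np.uint8:
            raise ValueError("grid must be 512x512 uint8")

    def save_png(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="L").save(str(path))


def construct_grid(
    volume: BrainVolume,
    offsets_mm=SLICE_OFFSETS_MM,
    scan_id: str = "",
    patient_id: str = "",
    diagnosis: str = "",
) -> GridImage:
    """Assemble the 10-slice coronal grid image.

    For each offset y (mm, anterior-commissure-relative, negative =
    posterior) the coronal plane at origin_y + round(y/spacing_y) is
    extracted, bicubic-resized to 102 wide x 256 high, and tiled 5x2:
    offsets 1-5 (posterior) on the top row, 6-10 on the bottom. The
    510x512 mosaic is bicubic-resized to exactly 512x512 and quantized
    to 8 bits.
    """
    data = volume.data
    ny = data.shape[1]
    oy = volume.origin[1]
    sy = volume.spacing[1]
    slices = []
    for y in offsets_mm:
        idx = oy + int(round(y / sy))
        if not (0 <= idx < ny):
            raise ValueError(f"coronal offset {y} mm maps outside the volume (index {idx})")
        # plane: rows = inferior-superior (flipped so superior is up),
        # columns = left-right; no left-right flip anywhere
        plane = data[:, idx, :].T[::-1, :]
        slices.append(resize(plane, (SLICE_H, SLICE_W), order=3, preserve_range=True,
                             anti_aliasing=True))
    n_top = (len(slices) + 1) // 2
    top = np.hstack(slices[:n_top])
    bottom = np.hstack(slices[n_top:])
    mosaic = np.vstack([top, bottom])
    grid = resize(mosaic, (GRID_SIDE, GRID_SIDE), order=3, preserve_range=True,
                  anti_aliasing=False)
    pixels = np.clip(np.rint(grid), 0, 255).astype(np.uint8)
    return GridImage(pixels=pixels, slice_positions_mm=tuple(offsets_mm),
                     scan_id=scan_id, patient_id=patient_id, diagnosis=diagnosis)
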