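"""Pixel-wise velocimetry of stepped M-scan B-scans.

A stepped M-scan B-scan holds a 128-sample complex time series at every
(lateral location, depth) pixel.  The pipeline estimates per-pixel SNR against
a designated noise region, evaluates the SNR-matched classifier on each
pixel's self-normalized intensity series (strictly pixel-pure: no neighbor
information enters the likelihoods), and then suppresses isolated errors by
elementwise multiplication of the 3x3 neighborhood's likelihood curves before
taking the argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, EmptyMaskError
from .network import RELIABILITY_FLOOR_DB, NetworkBank
from .simulator import ScanTiming, VelocityGrid

__all__ = [
    "SteppedMScan",
    "SnrMap",
    "LikelihoodMap",
    "VelocityMap",
    "VesselMask",
    "estimate_snr_map",
    "classify_bscan",
    "filter_likelihood",
    "angiography_mask",
]


@dataclass
class SteppedMScan:
    """Complex B-scan stack: ``data[location, depth, time]``.

    ``axial_pixel_um`` is the axial pixel size in air; physical depth inside
    blood/tissue divides by the refractive index (handled downstream).
    """

    data: np.ndarray
    timing: ScanTiming = field(default_factory=ScanTiming)
    lateral_step_um: float = 3.0
    axial_pixel_um: float = 4.5
    wavelength_nm: float = 1040.0
    doppler_angle_deg: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be [locations x depth x time]")
        if self.data.shape[2] != self.timing.n_samples:
            raise ConfigurationError(
                f"data has {self.data.shape[2]} samples but timing declares "
                f"{self.timing.n_samples}")

    @property
    def n_locations(self) -> int:
        return self.data.shape[0]

    @property
    def n_depth(self) -> int:
        return self.data.shape[1]

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.data) ** 2

    def bscan_duration_s(self) -> float:
        """Acquisition time of one stepped M-scan B-scan."""
        return self.n_locations * self.timing.n_samples * self.timing.ascan_period_s


@dataclass
class SnrMap:
    snr_db: np.ndarray
    noise_floor: float


@dataclass
class LikelihoodMap:
    """Per-pixel velocity likelihood curves ``[loc, depth, class]``."""

    curves: np.ndarray
    grid: VelocityGrid
    reliable: np.ndarray
    filtered: bool = False


@dataclass
class VelocityMap:
    v_mm_s: np.ndarray
    class_index: np.ndarray
    reliability: np.ndarray
    grid: VelocityGrid


@dataclass
class VesselMask:
    mask: np.ndarray
    center_px: tuple[float, float]   # (location, depth), fractional pixels
    equivalent_radius_um: float


def default_noise_region(scan: SteppedMScan, fraction: float = 0.1) -> np.ndarray:
    """Boolean mask selecting the deepest ``fraction`` of pixels."""
    n_noise = max(1, int(round(scan.n_depth * fraction)))
    region = np.zeros((scan.n_locations, scan.n_depth), dtype=bool)
    region[:, scan.n_depth - n_noise:] = True
    return region


def estimate_snr_map(scan: SteppedMScan, noise_region: np.ndarray | None = None,
                     vessel_mask: np.ndarray | None = None) -> SnrMap:
    """Per-pixel SNR in dB against the mean intensity of a noise region.

    ``snr_db = 10 log10(<|a|^2>_time / noise_floor)`` with the noise floor
    taken as the mean intensity over ``noise_region`` (default: deepest 10%
    of pixels).  The region must not intersect a supplied vessel mask.
    """
    if noise_region is None:
        noise_region = default_noise_region(scan)
    noise_region = np.asarray(noise_region, dtype=bool)
    if not noise_region.any():
        raise ValueError("noise region is empty")
    if vessel_mask is not None and np.any(noise_region & np.asarray(vessel_mask, bool)):
        raise ValueError("noise region overlaps the vessel mask")
    mean_i = scan.intensity.mean(axis=2)
    floor = float(mean_i[noise_region].mean())
    if floor <= 0:
        # noise-free synthetic data: every signal pixel is at +inf SNR
        with np.errstate(divide="ignore"):
            snr = np.where(mean_i > 0, np.inf, -np.inf)
        return SnrMap(snr_db=snr, noise_floor=0.0)
    with np.errstate(divide="ignore"):
        snr = 10.0 * np.log10(mean_i / floor)
    return SnrMap(snr_db=snr, noise_floor=floor)


def classify_bscan(scan: SteppedMScan, bank: NetworkBank,
                   snr: SnrMap) -> LikelihoodMap:
    """Evaluate the SNR-matched network on every pixel independently.

    Each pixel's intensity series is self-normalized and classified by the
    network at the nearest trained SNR.  Pixels with zero mean intensity get
    a uniform curve; those and pixels below the reliability floor are marked
    unreliable.
    """
    any_net = next(iter(bank.networks.values()))
    if scan.timing.n_samples != any_net.input_len:
        raise ConfigurationError(
            f"scan has {scan.timing.n_samples}-sample records but the bank "
            f"expects {any_net.input_len}")
    n_loc, n_dep = scan.n_locations, scan.n_depth
    n_classes = bank.grid.n_classes
    intensity = scan.intensity.reshape(n_loc * n_dep, -1)
    means = intensity.mean(axis=1)
    curves = np.full((n_loc * n_dep, n_classes), 1.0 / n_classes)
    reliable = np.ones(n_loc * n_dep, dtype=bool)

    snr_flat = snr.snr_db.reshape(-1).astype(float)
    reliable &= snr_flat >= RELIABILITY_FLOOR_DB
    valid = means > 0
    reliable &= valid

    lv = bank.snr_levels
    clamped = np.clip(snr_flat, lv[0], lv[-1])
    # nearest trained SNR, ties toward the lower level
    d = np.abs(clamped[:, None] - lv[None, :])
    keys = lv[d.argmin(axis=1)]
    X = intensity[valid] / means[valid, None]
    kv = keys[valid]
    probs = np.empty((X.shape[0], n_classes))
    for level in lv:
        sel = kv == level
        if sel.any():
            probs[sel] = bank[level].predict_proba(X[sel])
    curves[valid] = probs
    return LikelihoodMap(curves=curves.reshape(n_loc, n_dep, n_classes),
                         grid=bank.grid,
                         reliable=reliable.reshape(n_loc, n_dep),
                         filtered=False)


def filter_likelihood(lmap: LikelihoodMap) -> VelocityMap:
    """3x3 elementwise likelihood product, then per-pixel argmax.

    Edge pixels multiply over their available neighbors only (no padding).
    The product is formed in log space (the argmax is invariant to the
    normalization).  Argmax ties break toward the lower velocity class and
    are flagged unreliable.
    """
    if lmap.filtered:
        raise ValueError("likelihood map is already filtered")
    logs = np.log(lmap.curves + 1e-300)
    k = np.ones((3, 3, 1))
    summed = ndimage.convolve(logs, k, mode="constant", cval=0.0)
    cls = summed.argmax(axis=2)
    best = np.take_along_axis(summed, cls[..., None], axis=2)[..., 0]
    n_max = (np.abs(summed - best[..., None]) < 1e-12).sum(axis=2)
    ties = n_max > 1
    v = lmap.grid.values_mm_s[cls]
    return VelocityMap(v_mm_s=v, class_index=cls,
                       reliability=lmap.reliable & ~ties, grid=lmap.grid)


def angiography_mask(scan: SteppedMScan, threshold_factor: float = 5.0,
                     min_snr_db: float = 5.0,
                     snr: SnrMap | None = None,
                     n_medium: float = 1.36,
                     min_pixels: int = 10) -> VesselMask:
    """Temporal-decorrelation angiography segmentation of the vessel lumen.

    The motion statistic is the temporal variance of the self-normalized
    intensity at each pixel.  Pixels exceeding ``threshold_factor`` times the
    median statistic of significant-SNR pixels (which are overwhelmingly
    static tissue) are candidates; the mask is the largest connected
    component after hole filling.  ``threshold_factor = 0`` degenerately
    selects all significant pixels (warned).
    """
    if snr is None:
        snr = estimate_snr_map(scan)
    intensity = scan.intensity
    mean_i = intensity.mean(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(mean_i > 0,
                        intensity.var(axis=2) / np.maximum(mean_i, 1e-300) ** 2,
                        0.0)
    significant = snr.snr_db >= min_snr_db
    if not significant.any():
        raise EmptyMaskError("no pixels with significant SNR")
    if threshold_factor <= 0:
        warnings.warn("threshold_factor <= 0 selects every significant pixel",
                      stacklevel=2)
        candidates = significant
    else:
        ref = float(np.median(stat[significant]))
        candidates = significant & (stat > threshold_factor * ref)
    if not candidates.any():
        raise EmptyMaskError("no pixels above the angiography threshold")
    labels, n = ndimage.label(candidates)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    if sizes.max() < min_pixels:
        raise EmptyMaskError(
            f"largest decorrelating component ({int(sizes.max())} px) is "
            f"below the minimum vessel size ({min_pixels} px)")
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    c_loc, c_dep = ndimage.center_of_mass(mask)
    # physical axial pixel size inside the vessel: air size / n_medium
    area_um2 = mask.sum() * scan.lateral_step_um * scan.axial_pixel_um / n_medium
    return VesselMask(mask=mask, center_px=(float(c_loc), float(c_dep)),
                      equivalent_radius_um=float(np.sqrt(area_um2 / np.pi)))
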