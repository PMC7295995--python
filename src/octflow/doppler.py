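"""Doppler (phase-based) reference velocimetry.

Within one 128-sample M-scan the flow is assumed constant, so phase
differences can be formed between any two samples separated by a delay of
``d`` A-scans and every delay carries the same velocity information scaled by
``d``.  The pipeline: per-delay phase-difference images (Kasai-style average
of the complex lag products over the series), bulk-motion correction against
static pixels, 2D phase unwrapping, rejection of corrupted per-delay images,
scaling of the survivors to a one-A-scan delay and averaging, and finally the
conversion  v = (dphi * lambda0) / (4 pi n tau cos(alpha)).

Near-perpendicular Doppler angles (88-92 deg) are rejected as unreliable, and
the Doppler angle itself can be recovered from the depth shift of a vessel
between two B-scan locations a known distance apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.restoration import unwrap_phase

from .exceptions import (
    AllCorruptedError,
    MissingPhaseError,
    RejectedAngleError,
)
from .pipeline import SnrMap, SteppedMScan, estimate_snr_map

__all__ = [
    "DopplerConfig",
    "PhaseDiffStack",
    "DopplerVelocityMap",
    "phase_difference_stack",
    "bulk_motion_correct",
    "unwrap_2d",
    "reject_corrupted",
    "average_and_scale",
    "doppler_velocity",
    "doppler_angle_from_depth_shift",
    "doppler_velocity_map",
    "image_counts",
]


@dataclass(frozen=True)
class DopplerConfig:
    delays: tuple[int, ...] = tuple(range(1, 41))
    lambda0_nm: float = 1040.0
    n_refractive: float = 1.36
    tau_s: float = 10e-6
    static_snr_threshold_db: float = 3.0
    angle_reject_low_deg: float = 88.0
    angle_reject_high_deg: float = 92.0
    discontinuity_threshold: float = 0.01   # fraction of pixels
    consistency_tol_rad: float = 0.15       # scaled-image agreement tolerance

    def __post_init__(self) -> None:
        if len(self.delays) == 0 or min(self.delays) < 1:
            raise ValueError("delays must be positive A-scan counts")


def image_counts(n_samples: int, delays: tuple[int, ...]) -> dict[int, int]:
    """Phase-difference images available per delay: ``n_samples - d``."""
    if max(delays) > n_samples - 1:
        raise ValueError("delay exceeds n_samples - 1")
    return {d: n_samples - d for d in delays}


@dataclass
class PhaseDiffStack:
    """Per-delay stacks of phase-difference images (radians)."""

    images: dict[int, np.ndarray]   # delay -> (n_images, n_loc, n_depth)

    @property
    def counts(self) -> dict[int, int]:
        return {d: im.shape[0] for d, im in self.images.items()}

    @property
    def total_images(self) -> int:
        return sum(self.counts.values())


@dataclass
class DopplerVelocityMap:
    v_mm_s: np.ndarray
    doppler_angle_deg: float
    excluded_images: int = 0
    used_delays: tuple[int, ...] = ()


def _require_complex(scan: SteppedMScan) -> np.ndarray:
    if not np.iscomplexobj(scan.data):
        raise MissingPhaseError("Doppler analysis requires complex-valued data")
    return scan.data


def phase_difference_stack(scan: SteppedMScan, cfg: DopplerConfig = DopplerConfig()
                           ) -> PhaseDiffStack:
    """All phase-difference images: for delay d, ``n_samples - d`` images.

    Each image at start time t is ``arg(a(t+d) conj(a(t)))`` per pixel.
    Stored as float32 to bound memory (a full 40-delay stack on a 100x64
    B-scan is ~100 MB).
    """
    a = _require_complex(scan)
    n = scan.timing.n_samples
    images: dict[int, np.ndarray] = {}
    for d in cfg.delays:
        if d > n - 1:
            raise ValueError(f"delay {d} exceeds n_samples - 1 = {n - 1}")
        prod = a[:, :, d:] * np.conj(a[:, :, :n - d])
        images[d] = np.moveaxis(np.angle(prod), -1, 0).astype(np.float32)
    return PhaseDiffStack(images=images)


def averaged_phase_differences(scan: SteppedMScan,
                               cfg: DopplerConfig = DopplerConfig()
                               ) -> dict[int, np.ndarray]:
    """Per-delay averaged phase-difference image (circular/Kasai average).

    Averaging the complex lag products before taking the argument is the
    circular mean of the individual phase-difference images weighted by
    signal amplitude, and is robust to wrapped samples.
    """
    a = _require_complex(scan)
    n = scan.timing.n_samples
    out = {}
    for d in cfg.delays:
        prod = (a[:, :, d:] * np.conj(a[:, :, :n - d])).mean(axis=2)
        out[d] = np.angle(prod)
    return out


def bulk_motion_correct(img: np.ndarray, static_mask: np.ndarray
                        ) -> tuple[np.ndarray, list[int]]:
    """Remove the per-A-scan common phase offset measured on static pixels.

    For each lateral location (column of the B-scan) the circular mean phase
    of the static pixels is subtracted and the result re-wrapped to
    (-pi, pi].  Columns without any static pixel are left uncorrected and
    returned in the flag list.
    """
    img = np.asarray(img, dtype=float)
    static_mask = np.asarray(static_mask, dtype=bool)
    if static_mask.shape != img.shape:
        raise ValueError("static mask shape mismatch")
    out = img.copy()
    flagged: list[int] = []
    for col in range(img.shape[0]):
        sel = static_mask[col]
        if not sel.any():
            flagged.append(col)
            continue
        offset = np.angle(np.exp(1j * img[col, sel]).mean())
        out[col] = np.angle(np.exp(1j * (img[col] - offset)))
    return out, flagged


def unwrap_2d(img: np.ndarray) -> np.ndarray:
    """Two-dimensional phase unwrapping (reliability-ordered)."""
    img = np.asarray(img, dtype=float)
    return np.asarray(unwrap_phase(img), dtype=float)


def discontinuity_fraction(img: np.ndarray) -> float:
    """Fraction of adjacent-pixel steps exceeding pi after unwrapping."""
    jumps = (np.abs(np.diff(img, axis=0)) > np.pi).sum()
    jumps += (np.abs(np.diff(img, axis=1)) > np.pi).sum()
    total = img.size * 2 - img.shape[0] - img.shape[1]
    return float(jumps) / max(total, 1)


def reject_corrupted(unwrapped: dict[int, np.ndarray],
                     cfg: DopplerConfig = DopplerConfig(),
                     signal_mask: np.ndarray | None = None
                     ) -> tuple[dict[int, np.ndarray], int]:
    """Drop per-delay images corrupted by noise, decorrelation or unwrap errors.

    Two criteria: (i) residual discontinuity density above
    ``cfg.discontinuity_threshold``; (ii) disagreement of the delay-scaled
    image with the shortest surviving delay (median absolute deviation over
    ``signal_mask`` above ``cfg.consistency_tol_rad``), which catches
    smooth-but-wrong unwrapping of marginal delays.  Raises if every image is
    rejected.
    """
    survivors: dict[int, np.ndarray] = {}
    excluded = 0
    for d, img in sorted(unwrapped.items()):
        if discontinuity_fraction(img) > cfg.discontinuity_threshold:
            excluded += 1
            continue
        survivors[d] = img
    if survivors and len(survivors) > 1:
        dref = min(survivors)
        ref = survivors[dref] / dref
        if signal_mask is None:
            # compare where the reference itself reports flow; static pixels
            # agree trivially and would mask inconsistencies
            sel = np.abs(ref) > max(0.05, 0.1 * np.abs(ref).max())
            if not sel.any():
                sel = np.ones_like(ref, bool)
        else:
            sel = np.asarray(signal_mask, bool)
        ok: dict[int, np.ndarray] = {}
        for d, img in survivors.items():
            dev = np.median(np.abs(img / d - ref)[sel])
            if d == dref or dev <= cfg.consistency_tol_rad:
                ok[d] = img
            else:
                excluded += 1
        survivors = ok
    if not survivors:
        raise AllCorruptedError("all phase-difference images were rejected")
    return survivors, excluded


def average_and_scale(per_delay: dict[int, np.ndarray]) -> np.ndarray:
    """Scale each per-delay image to a one-A-scan delay and average."""
    if not per_delay:
        raise ValueError("no phase-difference images to average")
    return np.mean([img / d for d, img in per_delay.items()], axis=0)


def doppler_velocity(dphi: np.ndarray, alpha_deg: float,
                     cfg: DopplerConfig = DopplerConfig()) -> DopplerVelocityMap:
    """Convert a one-A-scan phase-difference image to flow velocity (mm/s).

    ``v = dphi * lambda0 / (4 pi n tau cos(alpha))``.  Angles inside the
    rejection window (cos alpha ~ 0) raise :class:`RejectedAngleError`.
    """
    if cfg.angle_reject_low_deg <= alpha_deg <= cfg.angle_reject_high_deg:
        raise RejectedAngleError(
            f"Doppler angle {alpha_deg} deg inside the rejection window "
            f"[{cfg.angle_reject_low_deg}, {cfg.angle_reject_high_deg}] deg")
    lam_m = cfg.lambda0_nm * 1e-9
    v_m_s = (np.asarray(dphi, float) * lam_m /
             (4.0 * np.pi * cfg.n_refractive * cfg.tau_s *
              math.cos(math.radians(alpha_deg))))
    return DopplerVelocityMap(v_mm_s=v_m_s * 1e3, doppler_angle_deg=alpha_deg)


def doppler_angle_from_depth_shift(z1_um: float, z2_um: float,
                                   dx_um: float) -> float:
    """Doppler angle from the vessel depth shift between two locations.

    With the second location ``dx_um`` further along the vessel and the
    vessel center moving from optical-path-corrected depth ``z1_um`` to
    ``z2_um``, ``alpha = 90 deg + atan((z2 - z1)/dx)``: a vessel diving away
    from the beam (z increasing) has alpha > 90 deg.
    """
    if dx_um <= 0:
        raise ValueError("dx_um must be positive")
    return 90.0 + math.degrees(math.atan((z2_um - z1_um) / dx_um))


def derive_static_mask(scan: SteppedMScan, cfg: DopplerConfig,
                       snr: SnrMap) -> np.ndarray:
    """Static (no-flow) pixels with significant SNR.

    Flowing pixels betray themselves at long delays: either the speckle has
    decorrelated (low lag coherence) or the accumulated Doppler phase is
    large.  Probing two long delays avoids the accidental 2*pi wrap
    coincidence at a single delay.  Short delays are useless here - slow flow
    is indistinguishable from static tissue at one A-scan of separation.
    """
    a = _require_complex(scan)
    n = scan.timing.n_samples
    dmax = min(max(cfg.delays), n - 1)
    probes = {dmax, max(1, dmax - 3)}
    mean_i = (np.abs(a) ** 2).mean(axis=2)
    ok = snr.snr_db > cfg.static_snr_threshold_db
    for d in probes:
        prod = (a[:, :, d:] * np.conj(a[:, :, :n - d])).mean(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(prod) / np.maximum(mean_i, 1e-300)
        ok &= (coh > 0.6) & (np.abs(np.angle(prod)) < 0.4)
    return ok


def doppler_velocity_map(scan: SteppedMScan, alpha_deg: float,
                         cfg: DopplerConfig = DopplerConfig(),
                         static_mask: np.ndarray | None = None,
                         snr: SnrMap | None = None,
                         signal_mask: np.ndarray | None = None
                         ) -> DopplerVelocityMap:
    """Full Doppler reference pipeline on one stepped M-scan B-scan.

    Per delay: circular average of the phase-difference images, bulk-motion
    correction against static pixels, 2D unwrapping with the unwrapped
    surface re-anchored to zero mean phase on the static pixels, corrupted
    image rejection, delay scaling/averaging, velocity conversion.
    """
    if snr is None:
        snr = estimate_snr_map(scan)
    if static_mask is None:
        static_mask = derive_static_mask(scan, cfg, snr)
    avg = averaged_phase_differences(scan, cfg)
    unwrapped: dict[int, np.ndarray] = {}
    for d, img in avg.items():
        corrected, _ = bulk_motion_correct(img, static_mask)
        u = unwrap_2d(corrected)
        if static_mask.any():
            u = u - u[static_mask].mean()
        unwrapped[d] = u
    survivors, excluded = reject_corrupted(unwrapped, cfg, signal_mask=signal_mask)
    dphi1 = average_and_scale(survivors)
    result = doppler_velocity(dphi1, alpha_deg, cfg)
    result.excluded_images = excluded
    result.used_delays = tuple(sorted(survivors))
    return result
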