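"""Forward speckle model and training-library generation.

The signal model follows the classical picture of dynamic light scattering in
OCT: point scatterers drift transversely through the focus of a Gaussian beam
while the detector records the coherent sum of their fields at a fixed A-scan
rate.  Summing many unit-amplitude scatterers with independent uniform phases
yields fully developed (Rayleigh) speckle; translation at speed ``v`` turns the
spatial beam profile into the temporal decorrelation signature the classifier
is trained to read.  Shot noise is modeled as circular complex Gaussian noise
on the field, with variance referenced to the ensemble-mean signal intensity
of the simulated target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np

from .exceptions import (
    CoverageError,
    InvalidGridError,
    MissingPhaseError,
    NormalizationError,
)

__all__ = [
    "BeamModel",
    "ScanTiming",
    "VelocityGrid",
    "ScattererConfig",
    "TimeSeries",
    "LibrarySpec",
    "SignalLibrary",
    "make_velocity_grid",
    "simulate_field",
    "simulate_fields",
    "ensemble_mean_intensity",
    "add_shot_noise",
    "self_normalize",
    "normalize_records",
    "n_records",
    "build_library",
    "save_library",
    "load_library",
]

#: sentinel accepted by :func:`add_shot_noise` for a noise-free record
NOISE_FREE = math.inf


@dataclass(frozen=True)
class BeamModel:
    """Gaussian imaging beam.

    ``e2_diameter_um`` is the lateral width at which the *intensity* profile
    falls to e^-2 (18 um for the system modeled here).  The amplitude profile
    is ``g(x) = exp(-x^2 / w0^2)`` with ``w0 = e2_diameter_um / 2`` so that
    ``|g|^2`` reaches e^-2 at radius ``w0``.  ``axial_fwhm_um`` is carried as
    metadata only; the transverse model has no axial extent.
    """

    e2_diameter_um: float = 18.0
    axial_fwhm_um: float = 10.0

    def __post_init__(self) -> None:
        if self.e2_diameter_um <= 0:
            raise ValueError("e2_diameter_um must be positive")

    @property
    def w0_um(self) -> float:
        return self.e2_diameter_um / 2.0


@dataclass(frozen=True)
class ScanTiming:
    """A-scan timing: 10 us period (100 kHz) and 128 samples per series."""

    ascan_period_s: float = 10e-6
    n_samples: int = 128

    def __post_init__(self) -> None:
        if self.ascan_period_s <= 0:
            raise ValueError("ascan_period_s must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")

    @property
    def duration_s(self) -> float:
        """Total span of one time series (first to last sample)."""
        return (self.n_samples - 1) * self.ascan_period_s


@dataclass(frozen=True)
class VelocityGrid:
    """Logarithmically spaced velocity classes (mm/s)."""

    values_mm_s: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values_mm_s, dtype=float)
        object.__setattr__(self, "values_mm_s", v)
        if v.ndim != 1 or v.size < 2:
            raise InvalidGridError("grid needs at least two velocities")
        if np.any(v <= 0) or np.any(np.diff(v) <= 0):
            raise InvalidGridError("grid must be positive and strictly increasing")

    @property
    def n_classes(self) -> int:
        return int(self.values_mm_s.size)

    @property
    def ratio(self) -> float:
        """Common ratio between consecutive class velocities."""
        v = self.values_mm_s
        return float((v[-1] / v[0]) ** (1.0 / (v.size - 1)))

    def nearest_class(self, v_mm_s: float) -> int:
        return int(np.argmin(np.abs(np.log(self.values_mm_s) - np.log(v_mm_s))))


def make_velocity_grid(n: int, vmin_mm_s: float, vmax_mm_s: float) -> VelocityGrid:
    """Geometric progression of ``n`` velocities from ``vmin`` to ``vmax``.

    The reference configuration is 64 classes from 0.001 mm/s to 2000 mm/s.
    """
    if n < 2:
        raise InvalidGridError("need at least two classes")
    if vmin_mm_s <= 0 or vmax_mm_s <= 0 or vmin_mm_s >= vmax_mm_s:
        raise InvalidGridError("require 0 < vmin < vmax")
    return VelocityGrid(np.geomspace(vmin_mm_s, vmax_mm_s, n))


@dataclass(frozen=True)
class ScattererConfig:
    """Random scatterer field configuration.

    ``density_per_um`` is the linear density of point scatterers along the
    transverse axis (default two per e^-2 beam radius); it acts as a crude
    hematocrit proxy.  ``support_radius_w0`` truncates the beam support used
    to size the scatterer strip.
    """

    density_per_um: float = 2.0 / 9.0
    support_radius_w0: float = 3.0

    def __post_init__(self) -> None:
        if self.density_per_um <= 0:
            raise ValueError("density_per_um must be positive")


@dataclass
class TimeSeries:
    """One intensity time series at a single spatial location."""

    intensity: np.ndarray
    field: np.ndarray | None = None
    snr_db: float = NOISE_FREE

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field is not None:
            self.field = np.asarray(self.field, dtype=complex)
            if self.field.shape != self.intensity.shape:
                raise ValueError("field and intensity shapes differ")


def ensemble_mean_intensity(beam: BeamModel, scatterers: ScattererConfig) -> float:
    """Ensemble-mean intensity of the simulated target.

    For unit-amplitude scatterers at uniform linear density rho the mean
    detected intensity is ``rho * integral g(x)^2 dx = rho * w0 * sqrt(pi/2)``.
    Shot-noise variance is referenced to this value.
    """
    return scatterers.density_per_um * beam.w0_um * math.sqrt(math.pi / 2.0)


def _strip_bounds(v_mm_s: float, beam: BeamModel, timing: ScanTiming,
                  scatterers: ScattererConfig) -> tuple[float, float]:
    half = scatterers.support_radius_w0 * beam.w0_um
    travel = v_mm_s * 1e3 * timing.duration_s  # um
    return -half - travel, half


def simulate_fields(
    v_mm_s: float,
    n_realizations: int,
    beam: BeamModel,
    timing: ScanTiming,
    scatterers: ScattererConfig,
    rng: np.random.Generator,
    *,
    strip_override_um: tuple[float, float] | None = None,
) -> np.ndarray:
    """Simulate ``n_realizations`` complex-field records at one velocity.

    Scatterer positions, amplitudes (unit) and phases are redrawn for every
    realization.  Scatterers sit at ``x_k`` and the beam samples
    ``g(x_k + v t)`` as the field translates, i.e. each record is
    ``a(t) = sum_k exp(i phi_k) g(x_k + v t)``.

    Returns a complex array of shape ``(n_realizations, n_samples)``.
    """
    if v_mm_s < 0:
        raise ValueError("velocity must be nonnegative")
    lo, hi = _strip_bounds(v_mm_s, beam, timing, scatterers)
    if strip_override_um is not None:
        lo, hi = strip_override_um
        req_lo, req_hi = _strip_bounds(v_mm_s, beam, timing, scatterers)
        if lo > req_lo or hi < req_hi:
            raise CoverageError(
                f"strip [{lo}, {hi}] um does not cover required "
                f"[{req_lo}, {req_hi}] um"
            )
    length = hi - lo
    w0 = beam.w0_um
    t_um = v_mm_s * 1e3 * timing.ascan_period_s * np.arange(timing.n_samples)
    out = np.empty((n_realizations, timing.n_samples), dtype=np.complex128)
    # chunk realizations to bound memory at ~ (chunk * N * n_samples) floats
    mean_n = length * scatterers.density_per_um
    chunk = max(1, int(4e6 / max(mean_n, 1.0) / timing.n_samples))
    for start in range(0, n_realizations, chunk):
        stop = min(start + chunk, n_realizations)
        b = stop - start
        counts = rng.poisson(lam=length * scatterers.density_per_um, size=b)
        nmax = int(counts.max()) if b else 0
        if nmax == 0:
            out[start:stop] = 0.0
            continue
        pos = rng.uniform(lo, hi, size=(b, nmax))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(b, nmax))
        valid = np.arange(nmax)[None, :] < counts[:, None]
        amp = np.where(valid, np.exp(1j * phases), 0.0)
        # (b, nmax, n_samples) Gaussian amplitude profile at each time point
        x = pos[:, :, None] + t_um[None, None, :]
        g = np.exp(-(x * x) / (w0 * w0))
        out[start:stop] = np.einsum("bn,bnt->bt", amp, g)
    return out


def simulate_field(
    v_mm_s: float,
    beam: BeamModel,
    timing: ScanTiming,
    scatterers: ScattererConfig,
    rng: np.random.Generator,
) -> TimeSeries:
    """Single noise-free realization of the forward model."""
    a = simulate_fields(v_mm_s, 1, beam, timing, scatterers, rng)[0]
    return TimeSeries(intensity=np.abs(a) ** 2, field=a, snr_db=NOISE_FREE)


def add_shot_noise(
    s: TimeSeries,
    snr_db: float,
    rng: np.random.Generator,
    mean_intensity: float,
) -> TimeSeries:
    """Add circular complex Gaussian noise to the field of a record.

    The noise variance is ``mean_intensity / 10^(snr_db/10)`` where
    ``mean_intensity`` is the *ensemble*-mean signal intensity (fixed target
    brightness), not the per-record mean.  ``snr_db = inf`` returns the input
    unchanged.
    """
    if s.field is None:
        raise MissingPhaseError("shot noise requires the complex field")
    if math.isinf(snr_db) and snr_db > 0:
        return s
    sigma2 = mean_intensity / (10.0 ** (snr_db / 10.0))
    n = math.sqrt(sigma2 / 2.0) * (
        rng.standard_normal(s.field.shape) + 1j * rng.standard_normal(s.field.shape)
    )
    noisy = s.field + n
    return TimeSeries(intensity=np.abs(noisy) ** 2, field=noisy, snr_db=snr_db)


def self_normalize(s: TimeSeries) -> TimeSeries:
    """Scale one record to unity mean intensity over its own samples.

    Normalization uses only the record itself; the complex field (when
    present) is scaled by the square root so that intensity == |field|^2
    remains true.  Idempotent.
    """
    m = float(np.mean(s.intensity))
    if m <= 0:
        raise NormalizationError("record has nonpositive mean intensity")
    f = None if s.field is None else s.field / math.sqrt(m)
    return TimeSeries(intensity=s.intensity / m, field=f, snr_db=s.snr_db)


def normalize_records(intensity: np.ndarray) -> np.ndarray:
    """Row-wise self-normalization of an (N, n_samples) intensity array."""
    intensity = np.asarray(intensity, dtype=float)
    m = intensity.mean(axis=-1, keepdims=True)
    if np.any(m <= 0):
        raise NormalizationError("at least one record has nonpositive mean")
    return intensity / m


# ---------------------------------------------------------------------------
# library generation


@dataclass(frozen=True)
class LibrarySpec:
    """Full description of a training library.

    The reference configuration is 64 velocity classes x 31 SNR levels
    (5..35 dB in 1 dB steps) x 25,000 realizations, split 22,000 train /
    3,000 validation per cell.
    """

    grid: VelocityGrid
    snr_levels_db: tuple[float, ...]
    realizations_per_cell: int = 25_000
    train_count: int = 22_000
    val_count: int = 3_000
    seed: int = 0
    beam: BeamModel = field(default_factory=BeamModel)
    timing: ScanTiming = field(default_factory=ScanTiming)
    scatterers: ScattererConfig = field(default_factory=ScattererConfig)

    def __post_init__(self) -> None:
        levels = tuple(float(x) for x in self.snr_levels_db)
        object.__setattr__(self, "snr_levels_db", levels)
        if len(levels) == 0 or np.any(np.diff(levels) <= 0):
            raise ValueError("snr_levels_db must be non-empty, strictly increasing")
        if self.realizations_per_cell < self.train_count + self.val_count:
            raise ValueError("realizations_per_cell < train + validation counts")

    @classmethod
    def paper_config(cls, seed: int = 0) -> "LibrarySpec":
        return cls(
            grid=make_velocity_grid(64, 0.001, 2000.0),
            snr_levels_db=tuple(float(x) for x in range(5, 36)),
            realizations_per_cell=25_000,
            train_count=22_000,
            val_count=3_000,
            seed=seed,
        )

    @classmethod
    def scaled_default(cls, seed: int = 0) -> "LibrarySpec":
        """Reduced configuration used for desk-scale training runs."""
        return cls(
            grid=make_velocity_grid(12, 5.0, 400.0),
            snr_levels_db=(10.0, 15.0, 20.0),
            realizations_per_cell=1000,
            train_count=800,
            val_count=200,
            seed=seed,
        )

    def scaled(self, realizations: int, train: int, val: int) -> "LibrarySpec":
        return replace(self, realizations_per_cell=realizations,
                       train_count=train, val_count=val)


def n_records(spec: LibrarySpec) -> int:
    """Total record count of a library without materializing it."""
    return spec.grid.n_classes * len(spec.snr_levels_db) * spec.realizations_per_cell


@dataclass
class SignalLibrary:
    """Materialized library: intensities with velocity-class and SNR labels."""

    intensity: np.ndarray        # (N, n_samples) float32, linear scale
    velocity_label: np.ndarray   # (N,) int class index into spec.grid
    snr_label: np.ndarray        # (N,) float dB
    is_train: np.ndarray         # (N,) bool; False = validation record
    spec: LibrarySpec

    def __len__(self) -> int:
        return self.intensity.shape[0]

    def slice_snr(self, snr_db: float) -> "SignalLibrary":
        sel = self.snr_label == float(snr_db)
        if not np.any(sel):
            raise KeyError(f"no records at SNR {snr_db} dB")
        return SignalLibrary(self.intensity[sel], self.velocity_label[sel],
                             self.snr_label[sel], self.is_train[sel], self.spec)

    def train_val_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Self-normalized (X_train, y_train, X_val, y_val)."""
        tr, va = self.is_train, ~self.is_train
        return (normalize_records(self.intensity[tr]), self.velocity_label[tr],
                normalize_records(self.intensity[va]), self.velocity_label[va])


def _cell_rng(spec: LibrarySpec, class_idx: int, snr_idx: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(class_idx, snr_idx))
    return np.random.Generator(np.random.PCG64(ss))


def _simulate_cell(spec: LibrarySpec, class_idx: int, snr_idx: int) -> np.ndarray:
    """Intensity records (float32) of one (velocity, SNR) cell."""
    rng = _cell_rng(spec, class_idx, snr_idx)
    v = float(spec.grid.values_mm_s[class_idx])
    a = simulate_fields(v, spec.realizations_per_cell, spec.beam, spec.timing,
                        spec.scatterers, rng)
    snr = spec.snr_levels_db[snr_idx]
    if not math.isinf(snr):
        sigma2 = ensemble_mean_intensity(spec.beam, spec.scatterers) / 10 ** (snr / 10)
        a = a + math.sqrt(sigma2 / 2.0) * (
            rng.standard_normal(a.shape) + 1j * rng.standard_normal(a.shape)
        )
    return (np.abs(a) ** 2).astype(np.float32)


def build_library(spec: LibrarySpec) -> SignalLibrary:
    """Materialize a library, one cell per (velocity class, SNR level).

    Deterministic for a fixed ``spec.seed``: each cell draws from its own
    seed stream, so the result does not depend on generation order.  The
    first ``train_count`` records of each cell are training records, the next
    ``val_count`` validation; any remainder is kept unlabeled as training
    surplus (mirrors a train/validation split of a larger pool).
    """
    n_cls = spec.grid.n_classes
    n_snr = len(spec.snr_levels_db)
    per = spec.realizations_per_cell
    total = n_cls * n_snr * per
    X = np.empty((total, spec.timing.n_samples), dtype=np.float32)
    yv = np.empty(total, dtype=np.int64)
    ys = np.empty(total, dtype=np.float64)
    tr = np.zeros(total, dtype=bool)
    row = 0
    for ci in range(n_cls):
        for si in range(n_snr):
            X[row:row + per] = _simulate_cell(spec, ci, si)
            yv[row:row + per] = ci
            ys[row:row + per] = spec.snr_levels_db[si]
            tr[row:row + spec.train_count] = True
            row += per
    return SignalLibrary(X, yv, ys, tr, spec)


# ---------------------------------------------------------------------------
# HDF5 shard persistence


def save_library(lib: SignalLibrary, path: str) -> None:
    """Write shards keyed by (velocity class, SNR): /library/v{ii}/snr{db}."""
    spec = lib.spec
    with h5py.File(path, "w") as f:
        root = f.create_group("library")
        root.attrs["seed"] = spec.seed
        root.attrs["n_classes"] = spec.grid.n_classes
        root.attrs["grid_mm_s"] = spec.grid.values_mm_s
        root.attrs["snr_levels_db"] = np.asarray(spec.snr_levels_db)
        root.attrs["realizations_per_cell"] = spec.realizations_per_cell
        root.attrs["train_count"] = spec.train_count
        root.attrs["val_count"] = spec.val_count
        for ci in range(spec.grid.n_classes):
            for snr in spec.snr_levels_db:
                sel = (lib.velocity_label == ci) & (lib.snr_label == snr)
                g = root.create_group(f"v{ci:02d}/snr{snr:g}")
                g.create_dataset("intensity", data=lib.intensity[sel],
                                 dtype=np.float32)
                g.attrs["velocity_mm_s"] = spec.grid.values_mm_s[ci]
                g.attrs["snr_db"] = snr
                g.attrs["seed"] = spec.seed


def load_library(path: str) -> SignalLibrary:
    with h5py.File(path, "r") as f:
        root = f["library"]
        grid = VelocityGrid(np.asarray(root.attrs["grid_mm_s"]))
        spec = LibrarySpec(
            grid=grid,
            snr_levels_db=tuple(root.attrs["snr_levels_db"]),
            realizations_per_cell=int(root.attrs["realizations_per_cell"]),
            train_count=int(root.attrs["train_count"]),
            val_count=int(root.attrs["val_count"]),
            seed=int(root.attrs["seed"]),
        )
        blocks, yv, ys = [], [], []
        for ci in range(grid.n_classes):
            for snr in spec.snr_levels_db:
                d = root[f"v{ci:02d}/snr{snr:g}"]["intensity"][...]
                blocks.append(d)
                yv.append(np.full(d.shape[0], ci, dtype=np.int64))
                ys.append(np.full(d.shape[0], snr))
        X = np.concatenate(blocks)
        per = spec.realizations_per_cell
        tr = np.zeros(X.shape[0], dtype=bool)
        for i in range(0, X.shape[0], per):
            tr[i:i + spec.train_count] = True
        return SignalLibrary(X, np.concatenate(yv), np.concatenate(ys), tr, spec)
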