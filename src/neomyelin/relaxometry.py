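"""Multi-component T2 relaxometry with stimulated-echo correction.

The voxel signal of a multi-echo train is modelled as a superposition of
exponentially decaying water pools,

    S_n = sum_j m(T2_j) * E_n(T2_j; alpha),

where ``E_n`` is the EPG echo amplitude at echo ``n`` for refocusing angle
``alpha`` and ``m`` is a nonnegative spectrum over a fixed log-spaced T2 grid.
Fitting proceeds in two stages per voxel: the local refocusing (flip) angle is
estimated from a coarse three-component fit, then the full spectrum is solved
by (optionally Tikhonov-regularized) nonnegative least squares with EPG basis
curves at that angle.

Spectrum summaries follow the myelin-water convention: spectral mass below
the myelin cutoff (50 ms) is the myelin water fraction v_mwf, mass above the
free-water cutoff (350 ms) is v_iso, and the mid band is tissue water, whose
amplitude-weighted geometric-mean T2 is reported as the tissue T2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import nnls

from .epg import epg_decay_curve

__all__ = [
    "EchoTrain",
    "T2Grid",
    "T2Spectrum",
    "RelaxometrySummary",
    "default_t2_grid",
    "epg_basis",
    "estimate_flip_angle",
    "fit_t2_spectrum",
    "summarize_spectrum",
    "RelaxometrySettings",
    "fit_voxel",
    "fit_volume",
]

#: T2 triplet (ms) for the coarse flip-angle fit: one myelin-band, one
#: tissue-band and one free-water-band component.
FLIP_FIT_T2S = (20.0, 120.0, 800.0)

#: Default T1 (ms) used inside the EPG basis; neonatal-tissue scale.
DEFAULT_T1 = 2000.0

MWF_CUTOFF = 50.0
ISO_CUTOFF = 350.0


@dataclass(frozen=True)
class EchoTrain:
    """A single voxel's multi-echo magnitude signal."""

    te_spacing: float
    signal: np.ndarray

    def __post_init__(self):
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", sig)
        if self.te_spacing <= 0:
            raise ValueError("te_spacing must be positive")
        if sig.ndim != 1 or sig.size < 3:
            raise ValueError("signal must be a 1-D vector with >= 3 echoes")
        if not np.all(np.isfinite(sig)) or np.any(sig < 0):
            raise ValueError("signal must be finite and nonnegative")

    @property
    def n_echoes(self) -> int:
        return self.signal.size


@dataclass(frozen=True)
class T2Grid:
    """Strictly increasing grid of candidate T2 times (ms)."""

    t2_values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.t2_values, dtype=float)
        object.__setattr__(self, "t2_values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("t2_values must be a 1-D vector of length >= 2")
        if vals[0] <= 0 or np.any(np.diff(vals) <= 0):
            raise ValueError("t2_values must be positive and strictly increasing")

    @property
    def n_components(self) -> int:
        return self.t2_values.size


@dataclass(frozen=True)
class T2Spectrum:
    grid: T2Grid
    amplitudes: np.ndarray
    flip_angle: float

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", amps)
        if amps.shape != self.grid.t2_values.shape:
            raise ValueError("amplitudes must match the grid length")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be nonnegative")
        if not (0.0 < self.flip_angle <= 180.0):
            raise ValueError("flip_angle must be in (0, 180] degrees")


@dataclass(frozen=True)
class RelaxometrySummary:
    v_mwf: float
    v_tissue: float
    v_iso: float
    tissue_t2: float

    @classmethod
    def missing(cls) -> "RelaxometrySummary":
        return cls(np.nan, np.nan, np.nan, np.nan)


def default_t2_grid(t2_min: float = 15.0, t2_max: float = 2000.0, n: int = 60) -> T2Grid:
    """Log-spaced T2 grid spanning the myelin and free-water bands."""
    return T2Grid(np.geomspace(t2_min, t2_max, n))


@lru_cache(maxsize=4096)
def _epg_basis_cached(flip_angle: float, t2s: tuple, t1: float, te: float, n: int) -> np.ndarray:
    cols = [epg_decay_curve(flip_angle, t2, t1, te, n) for t2 in t2s]
    arr = np.column_stack(cols)
    arr.setflags(write=False)
    return arr


def epg_basis(
    flip_angle: float,
    t2_values: np.ndarray,
    te_spacing: float,
    n_echoes: int,
    t1: float = DEFAULT_T1,
) -> np.ndarray:
    """Design matrix whose column j is the EPG echo train for T2_j."""
    return _epg_basis_cached(
        float(flip_angle), tuple(np.round(np.asarray(t2_values, float), 6)), float(t1), float(te_spacing), int(n_echoes)
    )


def _nnls_residual(basis: np.ndarray, signal: np.ndarray) -> float:
    _, rnorm = nnls(basis, signal)
    return rnorm


def estimate_flip_angle(
    train: EchoTrain,
    angle_grid: np.ndarray | None = None,
    t2_triplet: tuple = FLIP_FIT_T2S,
    t1: float = DEFAULT_T1,
) -> float:
    """Estimate the local refocusing angle from a coarse three-component fit.

    Each candidate angle defines an EPG basis over a fixed short/mid/long T2
    triplet; the angle whose nonnegative fit best explains the train is
    returned.  Ties are broken toward 180°.  An all-zero train is unfittable
    and returns NaN.
    """
    if train.n_echoes < 8:
        raise ValueError("flip-angle estimation requires >= 8 echoes")
    if angle_grid is None:
        angle_grid = np.arange(90.0, 180.0 + 0.5, 1.0)
    angle_grid = np.asarray(angle_grid, dtype=float)
    if np.any(angle_grid <= 60.0) or np.any(angle_grid > 180.0):
        raise ValueError("angle_grid must lie within (60, 180] degrees")
    if not np.any(train.signal > 0):
        return np.nan

    residuals = np.array(
        [
            _nnls_residual(epg_basis(a, np.array(t2_triplet), train.te_spacing, train.n_echoes, t1), train.signal)
            for a in angle_grid
        ]
    )
    # argmax over reversed-sorted angles so exact ties pick the largest angle
    order = np.argsort(-angle_grid, kind="stable")
    best = order[np.argmin(residuals[order])]
    return float(angle_grid[best])


def fit_t2_spectrum(
    train: EchoTrain,
    grid: T2Grid,
    flip_angle: float,
    regularization: float = 0.0,
    t1: float = DEFAULT_T1,
) -> T2Spectrum:
    """Nonnegative multi-exponential fit of a T2 spectrum with EPG basis.

    Solves ``min_m ||A m - S||^2 + reg * ||m||^2  s.t.  m >= 0`` where column
    j of A is the EPG echo train for grid point T2_j at the supplied
    refocusing angle.  ``regularization`` is the Tikhonov weight lambda
    (0 gives plain NNLS).
    """
    if regularization < 0:
        raise ValueError("regularization must be nonnegative")
    basis = np.asarray(epg_basis(flip_angle, grid.t2_values, train.te_spacing, train.n_echoes, t1))
    if basis.shape[0] != train.n_echoes:
        raise ValueError("echo train length does not match the basis")
    if regularization > 0:
        aug = np.vstack([basis, np.sqrt(regularization) * np.eye(grid.n_components)])
        rhs = np.concatenate([train.signal, np.zeros(grid.n_components)])
    else:
        aug, rhs = basis, train.signal
    amps, _ = nnls(aug, rhs)
    return T2Spectrum(grid=grid, amplitudes=amps, flip_angle=float(flip_angle))


def summarize_spectrum(
    spectrum: T2Spectrum,
    mwf_cutoff: float = MWF_CUTOFF,
    iso_cutoff: float = ISO_CUTOFF,
) -> RelaxometrySummary:
    """Reduce a T2 spectrum to band fractions and a tissue T2.

    v_mwf is the normalized spectral mass strictly below ``mwf_cutoff``,
    v_iso the mass strictly above ``iso_cutoff``; grid points exactly at a
    cutoff count as tissue.  The tissue T2 is the amplitude-weighted
    geometric mean of the mid-band T2 values (NaN when the band is empty).
    """
    if mwf_cutoff >= iso_cutoff:
        raise ValueError("mwf_cutoff must be below iso_cutoff")
    t2s = spectrum.grid.t2_values
    amps = spectrum.amplitudes
    total = amps.sum()
    if total <= 0:
        return RelaxometrySummary.missing()
    lo = t2s < mwf_cutoff
    hi = t2s > iso_cutoff
    mid = ~(lo | hi)
    v_mwf = amps[lo].sum() / total
    v_iso = amps[hi].sum() / total
    v_tissue = amps[mid].sum() / total
    mid_mass = amps[mid].sum()
    if mid_mass > 0:
        tissue_t2 = float(np.exp(np.sum(amps[mid] * np.log(t2s[mid])) / mid_mass))
    else:
        tissue_t2 = np.nan
    return RelaxometrySummary(float(v_mwf), float(v_tissue), float(v_iso), tissue_t2)


@dataclass
class RelaxometrySettings:
    """Tunables of the two-stage voxel-wise relaxometry fit."""

    grid: T2Grid = field(default_factory=default_t2_grid)
    regularization: float = 0.0
    t1: float = DEFAULT_T1
    mwf_cutoff: float = MWF_CUTOFF
    iso_cutoff: float = ISO_CUTOFF
    angle_grid: np.ndarray | None = None


def fit_voxel(train: EchoTrain, settings: RelaxometrySettings) -> tuple[RelaxometrySummary, float]:
    """Two-stage fit of one voxel: flip angle first, spectrum second."""
    alpha = estimate_flip_angle(train, settings.angle_grid, t1=settings.t1)
    if np.isnan(alpha):
        return RelaxometrySummary.missing(), np.nan
    spec = fit_t2_spectrum(train, settings.grid, alpha, settings.regularization, settings.t1)
    return summarize_spectrum(spec, settings.mwf_cutoff, settings.iso_cutoff), alpha


def fit_volume(
    echo_stack: np.ndarray,
    mask: np.ndarray,
    te_spacing: float,
    settings: RelaxometrySettings | None = None,
) -> dict[str, np.ndarray]:
    """Apply the relaxometry fit voxel-wise over a masked 4-D echo stack.

    Returns float maps ``v_mwf``, ``v_tissue``, ``v_iso``, ``tissue_t2`` and
    ``flip_angle`` with NaN outside the mask.
    """
    echo_stack = np.asarray(echo_stack, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if echo_stack.ndim != 4:
        raise ValueError("echo_stack must be 4-D (x, y, z, echo)")
    if mask.shape != echo_stack.shape[:3]:
        raise ValueError("mask shape must match the spatial dimensions of echo_stack")
    if settings is None:
        settings = RelaxometrySettings()

    maps = {k: np.full(mask.shape, np.nan) for k in ("v_mwf", "v_tissue", "v_iso", "tissue_t2", "flip_angle")}
    for idx in zip(*np.nonzero(mask)):
        train = EchoTrain(te_spacing, echo_stack[idx])
        if not np.any(train.signal > 0):
            continue
        summary, alpha = fit_voxel(train, settings)
        maps["v_mwf"][idx] = summary.v_mwf
        maps["v_tissue"][idx] = summary.v_tissue
        maps["v_iso"][idx] = summary.v_iso
        maps["tissue_t2"][idx] = summary.tissue_t2
        maps["flip_angle"][idx] = alpha
    return maps
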