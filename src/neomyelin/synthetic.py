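"""Ground-truth generators for every input the pipeline consumes.

A synthetic voxel is a four-compartment mixture (myelin water, intra-axonal,
extra-axonal, free water) with per-compartment T2 values, a Watson
orientation distribution for the axonal pools, and a local refocusing angle.
The same truth drives both forward models:

* the multi-echo T2 emitter sums EPG echo trains over all four compartments
  at the voxel's flip angle (relaxometry sees all water);
* the DWI emitter sees only the three non-myelin pools (myelin water T2 is
  far below the diffusion echo time), so its fractions are the truth
  fractions renormalized by 1/(1 - v_mwf) — exactly the pool the
  (1 - v_mwf) fusion correction maps back to total-water fractions.

Default compartment T2s are 20 / 110 / 130 / 1500 ms (myelin, intra-axonal,
extra-axonal, free water), placing each pool inside the spectral band the
summaries integrate (< 50 ms myelin, 50-350 ms tissue, > 350 ms free water).
Noise is Rician on magnitudes, with SNR referred to the first echo
(relaxometry) or the b=0 signal (DWI).  Every generator is a pure function
of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diffusion import DiffusionFit, DiffusionProtocol, predict_signal, two_shell_protocol
from .epg import epg_decay_curve
from .relaxometry import DEFAULT_T1

__all__ = [
    "VoxelTruth",
    "PhantomSpec",
    "RegionSpec",
    "emit_t2_signal",
    "emit_dwi_signal",
    "add_rician_noise",
    "make_phantom",
    "make_cohort",
    "tract_weight_map",
    "default_phantom_spec",
]

COMPARTMENT_T2 = {"myelin": 20.0, "intra": 110.0, "extra": 130.0, "free": 1500.0}


@dataclass(frozen=True)
class VoxelTruth:
    """Known four-compartment composition of one voxel."""

    v_mwf: float
    v_in: float
    v_ex: float
    v_iso: float
    kappa: float = 9.0
    orientation: tuple = (0.0, 0.0, 1.0)
    flip_angle: float = 180.0
    t2: dict = field(default_factory=lambda: dict(COMPARTMENT_T2))

    def __post_init__(self):
        fr = np.array([self.v_mwf, self.v_in, self.v_ex, self.v_iso])
        if np.any(fr < -1e-12) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be nonnegative and sum to 1")
        mu = np.asarray(self.orientation, dtype=float)
        if abs(np.linalg.norm(mu) - 1.0) > 1e-6:
            raise ValueError("orientation must be a unit vector")
        if not (0.0 < self.flip_angle <= 180.0):
            raise ValueError("flip_angle must be in (0, 180]")

    @property
    def g_ratio(self) -> float:
        if self.v_in <= 0:
            return np.nan
        return (self.v_mwf / self.v_in + 1.0) ** -0.5


def emit_t2_signal(
    truth: VoxelTruth, te_spacing: float = 12.0, n_echoes: int = 32, t1: float = DEFAULT_T1
) -> np.ndarray:
    """Noiseless multi-echo train of a four-compartment voxel."""
    pools = (
        (truth.v_mwf, truth.t2["myelin"]),
        (truth.v_in, truth.t2["intra"]),
        (truth.v_ex, truth.t2["extra"]),
        (truth.v_iso, truth.t2["free"]),
    )
    signal = np.zeros(n_echoes)
    for frac, t2 in pools:
        if frac > 0:
            signal += frac * epg_decay_curve(truth.flip_angle, t2, t1, te_spacing, n_echoes)
    return signal


def emit_dwi_signal(truth: VoxelTruth, protocol: DiffusionProtocol, s0: float = 1.0) -> np.ndarray:
    """Noiseless multi-shell DWI signal of the DWI-visible pool.

    The myelin compartment contributes nothing; the remaining fractions are
    renormalized to the visible pool (primed fractions), so a round trip
    through the diffusion fit and the (1 - v_mwf) correction recovers the
    total-water truth.
    """
    if truth.v_mwf >= 1:
        raise ValueError("v_mwf must be < 1 for a DWI-visible pool to exist")
    visible = 1.0 - truth.v_mwf
    mu = np.asarray(truth.orientation, dtype=float)
    theta = float(np.arccos(np.clip(mu[2], -1, 1)))
    phi = float(np.arctan2(mu[1], mu[0]))
    fit = DiffusionFit(
        s0=s0,
        v_in_prime=truth.v_in / visible,
        v_ex_prime=truth.v_ex / visible,
        v_iso_prime=truth.v_iso / visible,
        kappa=truth.kappa,
        theta=theta,
        phi=phi,
    )
    return predict_signal(fit, protocol)


def add_rician_noise(signal: np.ndarray, snr: float, reference: float, rng: np.random.Generator) -> np.ndarray:
    """Rician magnitude noise: sqrt((S + n1)^2 + n2^2), sigma = reference/snr."""
    if not np.isfinite(snr) or snr <= 0:
        raise ValueError("snr must be positive and finite")
    sigma = reference / snr
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


# --------------------------------------------------------------------------
# phantoms


@dataclass(frozen=True)
class RegionSpec:
    """A box region of a phantom with a truth and an optional linear ramp.

    ``v_mwf_ramp`` linearly interpolates v_mwf across the region's first
    axis from ``truth.v_mwf`` to ``truth.v_mwf + v_mwf_ramp`` (compensated
    in v_ex so fractions stay on the simplex).
    """

    name: str
    slices: tuple  # (slice, slice, slice)
    truth: VoxelTruth
    v_mwf_ramp: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple = (8, 8, 2)
    regions: tuple = ()
    snr_t2: float = np.inf
    snr_dwi: float = np.inf
    te_spacing: float = 12.0
    n_echoes: int = 32
    seed: int = 0


def default_phantom_spec(snr_t2: float = np.inf, snr_dwi: float = np.inf, seed: int = 0) -> PhantomSpec:
    """Demo phantom: a thalamus-like block with a myelin gradient and a
    PWM-like block with high free-water content, on an unmyelinated
    background."""
    thalamus = RegionSpec(
        name="thalamus",
        slices=(slice(0, 4), slice(0, 8), slice(0, 2)),
        truth=VoxelTruth(v_mwf=0.05, v_in=0.20, v_ex=0.65, v_iso=0.10, kappa=9.0),
        v_mwf_ramp=0.10,
    )
    pwm = RegionSpec(
        name="pwm",
        slices=(slice(4, 8), slice(0, 8), slice(0, 2)),
        truth=VoxelTruth(v_mwf=0.02, v_in=0.10, v_ex=0.48, v_iso=0.40, kappa=4.0),
    )
    return PhantomSpec(shape=(8, 8, 2), regions=(thalamus, pwm), snr_t2=snr_t2, snr_dwi=snr_dwi, seed=seed)


def _region_truths(spec: PhantomSpec) -> dict[tuple, VoxelTruth]:
    truths: dict[tuple, VoxelTruth] = {}
    for region in spec.regions:
        xs = range(*region.slices[0].indices(spec.shape[0]))
        ys = range(*region.slices[1].indices(spec.shape[1]))
        zs = range(*region.slices[2].indices(spec.shape[2]))
        xs = list(xs)
        for x in xs:
            frac = 0.0 if len(xs) == 1 else (x - xs[0]) / (xs[-1] - xs[0])
            dm = region.v_mwf_ramp * frac
            t = region.truth
            truth = replace(t, v_mwf=t.v_mwf + dm, v_ex=t.v_ex - dm)
            for y in ys:
                for z in zs:
                    truths[(x, y, z)] = truth
    return truths


def make_phantom(spec: PhantomSpec, protocol: DiffusionProtocol | None = None) -> dict:
    """Render a phantom: echo stack, DWI stack, truth maps, mask and weights.

    Deterministic under (spec, seed): identical calls return identical
    arrays bit-for-bit.
    """
    if protocol is None:
        protocol = two_shell_protocol()
    rng = np.random.default_rng(spec.seed)
    truths = _region_truths(spec)

    echo = np.zeros(spec.shape + (spec.n_echoes,))
    dwi = np.zeros(spec.shape + (protocol.n_volumes,))
    mask = np.zeros(spec.shape, dtype=bool)
    keys = ("v_mwf", "v_in", "v_ex", "v_iso", "kappa", "g_ratio", "flip_angle")
    truth_maps = {k: np.full(spec.shape, np.nan) for k in keys}

    # cache forward signals per distinct truth (regions are piecewise constant)
    t2_cache: dict[int, np.ndarray] = {}
    dwi_cache: dict[int, np.ndarray] = {}
    for idx, truth in truths.items():
        h = hash(
            (truth.v_mwf, truth.v_in, truth.v_ex, truth.v_iso, truth.kappa, truth.orientation, truth.flip_angle)
        )
        if h not in t2_cache:
            t2_cache[h] = emit_t2_signal(truth, spec.te_spacing, spec.n_echoes)
            dwi_cache[h] = emit_dwi_signal(truth, protocol)
        clean_t2, clean_dwi = t2_cache[h], dwi_cache[h]
        if np.isfinite(spec.snr_t2):
            echo[idx] = add_rician_noise(clean_t2, spec.snr_t2, clean_t2[0], rng)
        else:
            echo[idx] = clean_t2
        if np.isfinite(spec.snr_dwi):
            b0_ref = clean_dwi[protocol.b0_mask].mean()
            dwi[idx] = add_rician_noise(clean_dwi, spec.snr_dwi, b0_ref, rng)
        else:
            dwi[idx] = clean_dwi
        mask[idx] = True
        truth_maps["v_mwf"][idx] = truth.v_mwf
        truth_maps["v_in"][idx] = truth.v_in
        truth_maps["v_ex"][idx] = truth.v_ex
        truth_maps["v_iso"][idx] = truth.v_iso
        truth_maps["kappa"][idx] = truth.kappa
        truth_maps["g_ratio"][idx] = truth.g_ratio
        truth_maps["flip_angle"][idx] = truth.flip_angle

    weights = tract_weight_map(spec.shape, spec.regions) if spec.regions else np.zeros(spec.shape)
    return {
        "echo": echo,
        "dwi": dwi,
        "mask": mask,
        "truth": truth_maps,
        "weights": weights,
        "protocol": protocol,
        "te_spacing": spec.te_spacing,
    }


def tract_weight_map(shape: tuple, regions: tuple, sigma: float = 1.5) -> np.ndarray:
    """Tractography-like visitation weights: a Gaussian-profile tube between
    the centroids of the first two regions (or centered in a single region).

    This emulates the shape of probabilistic-tractography visitation counts
    without any fiber tracking.
    """
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1).astype(float)

    def centroid(region: RegionSpec) -> np.ndarray:
        return np.array(
            [(sl.indices(n)[0] + sl.indices(n)[1] - 1) / 2.0 for sl, n in zip(region.slices, shape)]
        )

    a = centroid(regions[0])
    b = centroid(regions[1]) if len(regions) > 1 else a
    ab = b - a
    denom = max(float(ab @ ab), 1e-12)
    t = np.clip(((grid - a) @ ab) / denom, 0.0, 1.0)
    nearest = a + t[..., None] * ab
    dist2 = np.sum((grid - nearest) ** 2, axis=-1)
    return np.exp(-dist2 / (2.0 * sigma**2))


# --------------------------------------------------------------------------
# cohorts


def make_cohort(
    n_subjects: int,
    intercept: float,
    slope_per_week: float,
    noise_sd: float,
    seed: int,
    ega_range: tuple = (27.0, 58.0),
    parameter: str = "value",
    region: str = "region",
    paired: bool = False,
) -> pd.DataFrame:
    """Synthetic cohort with a linear parameter-vs-EGA trend.

    Values follow ``intercept + slope * EGA + N(0, noise_sd)`` with scan EGAs
    uniform on ``ega_range``.  With ``paired=True`` each subject gets an
    early (27-34 week) and late (38-50 week) scan sharing the subject id,
    mirroring a two-time-point longitudinal design.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        if paired:
            egas = [rng.uniform(27.0, 34.0), rng.uniform(38.0, 50.0)]
        else:
            egas = [rng.uniform(*ega_range)]
        ega_birth = rng.uniform(24.0, 30.0)
        for scan_id, ega in enumerate(egas):
            rows.append(
                {
                    "subject_id": s,
                    "scan_id": scan_id,
                    "ega_birth": min(ega_birth, ega),
                    "ega_scan": ega,
                    "region": region,
                    "parameter": parameter,
                    "value": intercept + slope_per_week * ega + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame(rows)
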