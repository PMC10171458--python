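"""Phantoms with known stretched-exponential ground truth and synthetic
specimen cohorts.

No patient data accompany the study design this pipeline implements, so
everything downstream is exercised on synthetic inputs with known truth:

* a digital DWI phantom -- a tissue block containing normal-appearing,
  low-grade-like and high-grade-like compartments with distinct (DDC, alpha)
  ranges (high-grade-like tissue has the lowest alpha, i.e. the greatest
  intravoxel diffusion heterogeneity), sampled on a 128x128 / 24 cm / 4 mm
  acquisition grid over 22 b values with Rician magnitude noise whose scale
  shrinks as 1/sqrt(NEX);
* a specimen cohort whose pathology indices are driven by the local truth
  through a monotone linear link with Gaussian residuals: the proliferation
  index pMIB-1 decreases with local DDC and the microvascular density
  CD34-MVD decreases with local alpha; WHO grade comes from thresholds on a
  latent malignancy score. Field-level counts add Poisson / Beta sampling
  noise on top.

All randomness flows from one root seed through named substreams
(``numpy.random.SeedSequence(seed, spawn_key=(STREAM[name],))``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, CoordinateError, DomainError
from .model import sem_signal
from .pathology_quant import FieldMeasurement, Specimen
from .roi_extraction import BiopsyTarget, place_roi
from .scheme import BValueScheme

__all__ = [
    "PhantomTruth",
    "NoiseModel",
    "LinkageParams",
    "sem_signal",
    "add_rician_noise",
    "make_phantom",
    "make_biopsy_targets",
    "make_specimen_cohort",
    "simulate_fields",
]

#: Substream indices of the root seed (documented stream-splitting rule).
STREAM = {"truth": 0, "noise": 1, "targets": 2, "cohort": 3, "fields": 4, "reader": 5}

#: Tissue label codes.
BACKGROUND, NORMAL, LGG_LIKE, HGG_LIKE = 0, 1, 2, 3

#: Per-class (DDC low, DDC high) in mm^2/s and (alpha low, alpha high).
#: High-grade-like tissue has the lowest alpha and, reflecting its higher
#: cellularity, lower DDC than the low-grade-like compartment.
CLASS_DDC = {NORMAL: (0.7e-3, 0.9e-3), LGG_LIKE: (1.1e-3, 1.5e-3), HGG_LIKE: (0.7e-3, 1.1e-3)}
CLASS_ALPHA = {NORMAL: (0.85, 0.95), LGG_LIKE: (0.72, 0.85), HGG_LIKE: (0.50, 0.68)}

DEFAULT_CLASS_FRACTIONS = {NORMAL: 0.5, LGG_LIKE: 0.25, HGG_LIKE: 0.25}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child generator of the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(STREAM[name],))
    )


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth maps of a digital phantom."""

    ddc_map: np.ndarray
    alpha_map: np.ndarray
    s0_map: np.ndarray
    label_map: np.ndarray
    voxel_size: tuple[float, float, float] = (1.875, 1.875, 4.0)

    def __post_init__(self) -> None:
        shapes = {self.ddc_map.shape, self.alpha_map.shape,
                  self.s0_map.shape, self.label_map.shape}
        if len(shapes) != 1:
            raise ConfigurationError("all truth maps must share one shape")
        tissue = self.label_map != BACKGROUND
        if np.any((self.alpha_map[tissue] <= 0) | (self.alpha_map[tissue] > 1)):
            raise DomainError("tissue alpha must lie in (0, 1]")
        if np.any((self.ddc_map < 0) | (self.ddc_map > 1e-2)):
            raise DomainError("ddc must lie in [0, 1e-2] mm^2/s")
        if np.any(self.s0_map < 0):
            raise DomainError("s0 must be non-negative")
        if np.any(self.s0_map[~tissue] != 0):
            raise DomainError("background voxels must have s0 = 0")

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.label_map != BACKGROUND


@dataclass(frozen=True)
class NoiseModel:
    """Rician magnitude-noise model with a per-b NEX schedule.

    The noise scale at an acquired b value is ``sigma0 / sqrt(NEX(b))``:
    averaging NEX excitations shrinks the complex-channel noise by
    1/sqrt(NEX).
    """

    sigma0: float
    nex_schedule: dict[float, int]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 < 0:
            raise ConfigurationError("sigma0 must be non-negative")
        bs = sorted(self.nex_schedule)
        nexs = [self.nex_schedule[b] for b in bs]
        if any(n not in (1, 2, 3, 4) for n in nexs):
            raise ConfigurationError("NEX values must be in {1, 2, 3, 4}")
        if any(b - a < 0 for a, b in zip(nexs, nexs[1:])):
            raise ConfigurationError("NEX must be non-decreasing in b")

    @classmethod
    def from_scheme(cls, scheme: BValueScheme, sigma0: float, seed: int = 0) -> "NoiseModel":
        return cls(sigma0, dict(zip(scheme.b_values.tolist(), scheme.nex.tolist())), seed)

    def sigma_at(self, b: float) -> float:
        if b not in self.nex_schedule:
            raise ConfigurationError(f"b={b} not covered by the NEX schedule")
        return self.sigma0 / np.sqrt(self.nex_schedule[b])


def add_rician_noise(signal, noise: NoiseModel, b_values, rng: np.random.Generator | None = None):
    """Apply magnitude (Rician) noise per b value.

    Each sample becomes sqrt((s + n1)^2 + n2^2) with n1, n2 i.i.d. zero-mean
    Gaussians of scale sigma0/sqrt(NEX(b)); the last axis of ``signal`` must
    align with ``b_values``. Deterministic given ``noise.seed`` (or an
    explicit ``rng``).
    """
    s = np.asarray(signal, dtype=float)
    b = np.atleast_1d(np.asarray(b_values, dtype=float))
    if s.shape[-1] != b.size:
        raise ConfigurationError("last signal axis must align with b_values")
    if np.any(s < 0):
        raise DomainError("signal must be non-negative")
    sigma = np.array([noise.sigma_at(bi) for bi in b])
    if noise.sigma0 == 0:
        return s.copy()
    rng = rng or np.random.default_rng(noise.seed)
    n1 = rng.normal(0.0, 1.0, s.shape) * sigma
    n2 = rng.normal(0.0, 1.0, s.shape) * sigma
    return np.sqrt((s + n1) ** 2 + n2 ** 2)


def _make_truth(shape, class_fractions, rng, voxel_size) -> PhantomTruth:
    nx, ny, nz = shape
    label = np.zeros(shape, dtype=np.int8)
    # tissue block: central box with a one-eighth background margin per side
    mx, my, mz = max(nx // 8, 1), max(ny // 8, 1), nz // 8
    tis = np.zeros(shape, dtype=bool)
    tis[mx:nx - mx, my:ny - my, mz:nz - mz if mz else nz] = True
    # split the tissue box into x-slabs matching the class fractions
    xs = np.nonzero(tis.any(axis=(1, 2)))[0]
    fracs = [class_fractions.get(c, 0.0) for c in (NORMAL, LGG_LIKE, HGG_LIKE)]
    total = sum(fracs)
    edges = np.cumsum([f / total for f in fracs])[:-1]
    cut = [xs[0] + int(round(e * xs.size)) for e in edges]
    for c, (lo, hi) in zip(
        (NORMAL, LGG_LIKE, HGG_LIKE),
        zip([xs[0]] + cut, cut + [xs[-1] + 1]),
    ):
        sl = np.zeros(shape, dtype=bool)
        sl[lo:hi] = True
        label[tis & sl] = c

    ddc = np.zeros(shape)
    alpha = np.ones(shape)
    s0 = np.zeros(shape)
    for c in (NORMAL, LGG_LIKE, HGG_LIKE):
        m = label == c
        n = int(m.sum())
        if n == 0:
            continue
        ddc[m] = rng.uniform(*CLASS_DDC[c], size=n)
        alpha[m] = rng.uniform(*CLASS_ALPHA[c], size=n)
        s0[m] = rng.uniform(80.0, 120.0, size=n)
    return PhantomTruth(ddc, alpha, s0, label, voxel_size)


def make_phantom(
    shape: tuple[int, int, int],
    scheme: BValueScheme | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    class_fractions: dict[int, float] | None = None,
    voxel_size: tuple[float, float, float] = (1.875, 1.875, 4.0),
):
    """Build a phantom and its noisy DWI volume.

    Default geometry follows the acquisition protocol: 1.875 mm in-plane
    pixels (24 cm field of view on a 128x128 matrix) and 4 mm slices; pass a
    smaller ``shape`` for fast tests. Returns ``(PhantomTruth, DWIVolume)``.
    """
    from .sem_fit import DWIVolume  # local import avoids a module cycle

    if any(s <= 0 for s in shape) or len(shape) != 3:
        raise ConfigurationError("shape must be three positive integers")
    scheme = scheme or BValueScheme.default()
    noise = noise if noise is not None else NoiseModel.from_scheme(scheme, sigma0=0.0)
    truth = _make_truth(shape, class_fractions or DEFAULT_CLASS_FRACTIONS,
                        substream(seed, "truth"), voxel_size)
    clean = sem_signal(
        truth.s0_map[..., None], truth.ddc_map[..., None],
        np.clip(truth.alpha_map, 1e-6, 1.0)[..., None], scheme.b_values,
    )
    data = add_rician_noise(clean, noise, scheme.b_values, rng=substream(seed, "noise"))
    return truth, DWIVolume(data=data, scheme=scheme, voxel_size=voxel_size)


@dataclass(frozen=True)
class LinkageParams:
    """Monotone link from local truth to specimen-level pathology indices.

    pMIB-1 (%) = clip(beta0 + beta1 * DDC_local*1e3 + N(0, noise_sd_mib), 0, 100)
    CD34-MVD (vessels/mm^2) = max(gamma0 + gamma1 * alpha_local + N(0, noise_sd_cd34), 0)

    Negative default slopes encode the observed directions: proliferation
    rises as local DDC falls, vascular density rises as local alpha falls.
    WHO grade comes from two strictly increasing thresholds on the latent
    malignancy score z(-alpha_local) + z(-DDC_local).
    """

    beta0: float = 28.0
    beta1: float = -15.0
    gamma0: float = 70.0
    gamma1: float = -60.0
    noise_sd_mib: float = 6.0
    noise_sd_cd34: float = 8.0
    grade_thresholds: tuple[float, float] = (-1.90, 1.65)
    n_fields_range: tuple[int, int] = (3, 20)
    field_area_mm2: float = 0.5
    beta_concentration: float = 100.0

    def __post_init__(self) -> None:
        if not self.grade_thresholds[0] < self.grade_thresholds[1]:
            raise ConfigurationError("grade_thresholds must be strictly increasing")
        lo, hi = self.n_fields_range
        if not (3 <= lo <= hi <= 20):
            raise ConfigurationError("n_fields_range must lie within [3, 20]")


def make_biopsy_targets(
    truth: PhantomTruth,
    n_targets: int = 32,
    n_patients: int = 21,
    seed: int = 0,
    tumor_only: bool = True,
    roi_area_mm2: float = 105.0,
) -> list[BiopsyTarget]:
    """Sample biopsy targets inside the (tumor) tissue, constrained so the
    whole in-plane measurement ROI stays within tissue (the sampling site
    sits in the solid part, not at the margin).

    Patients are assigned round-robin so some contribute several specimens,
    as in a multi-specimen biopsy series.
    """
    from scipy.ndimage import minimum_filter

    rng = substream(seed, "targets")
    labels = (np.isin(truth.label_map, (LGG_LIKE, HGG_LIKE)) if tumor_only
              else truth.tissue_mask)
    side = max(int(round(np.sqrt(roi_area_mm2) / truth.voxel_size[0])), 1)
    half = side // 2
    ok = minimum_filter(truth.tissue_mask.astype(np.uint8),
                        size=(side, side, 1)).astype(bool)
    nx, ny, _ = labels.shape
    ok[:half] = ok[nx - half:] = False
    ok[:, :half] = ok[:, ny - half:] = False
    candidates = np.argwhere(labels & ok)
    if candidates.shape[0] < n_targets:
        raise CoordinateError("tissue region too small for the requested targets")
    picks = candidates[rng.choice(candidates.shape[0], size=n_targets, replace=False)]
    return [
        BiopsyTarget(
            target_id=f"spec_{t:03d}",
            patient_id=f"pat_{t % n_patients:03d}",
            center=(int(i), int(j), int(k)),
            source_image="T1C" if t % 2 == 0 else "T2FLAIR",
        )
        for t, (i, j, k) in enumerate(picks)
    ]


def _local_means(truth: PhantomTruth, target: BiopsyTarget, area_mm2: float):
    roi = place_roi(target, truth.voxel_size[0], area_mm2, truth.ddc_map.shape)
    ii, jj, kk = roi.indices
    return float(truth.ddc_map[ii, jj, kk].mean()), float(truth.alpha_map[ii, jj, kk].mean())


def make_specimen_cohort(
    truth: PhantomTruth,
    targets: list[BiopsyTarget],
    link: LinkageParams | None = None,
    seed: int = 0,
    n_missing_mib1: int = 1,
    roi_area_mm2: float = 105.0,
) -> list[Specimen]:
    """Generate one specimen per biopsy target, driven by the local truth.

    ``n_missing_mib1`` specimens are emitted without MIB-1 field data,
    mirroring cohorts in which the proliferation index is unavailable for a
    subset of specimens.
    """
    link = link or LinkageParams()
    rng = substream(seed, "cohort")
    locs = [_local_means(truth, t, roi_area_mm2) for t in targets]
    ddc_loc = np.array([d for d, _ in locs])
    alpha_loc = np.array([a for _, a in locs])

    pmib = np.clip(
        link.beta0 + link.beta1 * ddc_loc * 1e3
        + (rng.normal(0, link.noise_sd_mib, ddc_loc.size) if link.noise_sd_mib else 0.0),
        0.0, 100.0,
    )
    mvd = np.maximum(
        link.gamma0 + link.gamma1 * alpha_loc
        + (rng.normal(0, link.noise_sd_cd34, alpha_loc.size) if link.noise_sd_cd34 else 0.0),
        0.0,
    )

    def z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    latent = z(-alpha_loc) + z(-ddc_loc)
    t1, t2 = link.grade_thresholds
    grades = np.where(latent < t1, 2, np.where(latent < t2, 3, 4))

    missing = set(
        rng.choice(len(targets), size=min(n_missing_mib1, len(targets)), replace=False).tolist()
    )
    specimens = []
    for idx, tgt in enumerate(targets):
        nf = int(rng.integers(link.n_fields_range[0], link.n_fields_range[1] + 1))
        fields = simulate_fields(
            (float(mvd[idx]), float(pmib[idx])),
            n_fields=nf,
            field_area=link.field_area_mm2,
            seed=int(rng.integers(0, 2**31 - 1)),
            beta_concentration=link.beta_concentration,
            mib1_available=idx not in missing,
        )
        specimens.append(
            Specimen(
                specimen_id=tgt.target_id,
                patient_id=tgt.patient_id,
                who_grade=int(grades[idx]),
                fields=fields,
                mvd_true=float(mvd[idx]),
                pmib1_true=float(pmib[idx]),
            )
        )
    return specimens


def simulate_fields(
    specimen_truth: tuple[float, float],
    n_fields: int,
    field_area: float,
    seed: int = 0,
    beta_concentration: float = 100.0,
    mib1_available: bool = True,
) -> list[FieldMeasurement]:
    """Per-field microscope measurements for one specimen.

    Vessel counts are Poisson with mean ``mvd_true * field_area``; MIB-1
    positive fractions are Beta with mean ``pmib_true / 100`` and the given
    concentration (degenerate at 0 or 100%).
    """
    import warnings

    mvd_true, pmib_true = specimen_truth
    if mvd_true < 0 or pmib_true < 0:
        raise DomainError("specimen-level means must be non-negative")
    if field_area <= 0:
        raise DomainError("field_area must be positive")
    if not 3 <= n_fields <= 20:
        warnings.warn(f"n_fields={n_fields} outside the usual [3, 20] range",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mvd_true * field_area, size=n_fields)
    p = min(pmib_true / 100.0, 1.0)
    if not mib1_available:
        fracs = np.full(n_fields, np.nan)
    elif p <= 0:
        fracs = np.zeros(n_fields)
    elif p >= 1:
        fracs = np.ones(n_fields)
    else:
        k = beta_concentration
        fracs = rng.beta(p * k, (1 - p) * k, size=n_fields)
    return [
        FieldMeasurement(
            field_id=i,
            cd34_count=int(c),
            field_area=field_area,
            mib1_positive_fraction=float(f),
        )
        for i, (c, f) in enumerate(zip(counts, fracs))
    ]
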