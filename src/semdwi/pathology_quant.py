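"""Specimen-level pathology indices from field-level microscope measurements.

Two indices are computed per biopsy specimen from its 3-20 microscope
fields (assessed at x200 magnification):

* CD34-MVD, the microvascular density, as a pooled ratio
  C = A / B with A the total CD34-labelled vessel count over all fields and
  B the total field area (vessels/mm^2);
* pMIB-1, the MIB-1/Ki-67 proliferation index, as the mean per-field
  positive fraction expressed as a percentage, C = (A / B) * 100 with A the
  sum of per-field positive fractions and B the field count.

The stated MIB-1 formula mixes a cell count with a per-field percentage;
the fraction-mean reading is the only one bounded in [0, 100] and matching
worked percentages of a few percent, so it is the default. A literal
cells-per-field reading is available via ``mode="cells_per_field"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, FormatError

__all__ = [
    "FieldMeasurement",
    "Specimen",
    "cd34_mvd",
    "pmib1",
    "load_specimen_table",
    "write_field_table",
    "specimen_summary_frame",
    "FIELD_TABLE_COLUMNS",
]

FIELD_TABLE_COLUMNS = [
    "specimen_id", "patient_id", "who_grade", "field_id",
    "cd34_count", "field_area_mm2", "mib1_positive_fraction",
]


@dataclass(frozen=True)
class FieldMeasurement:
    """One microscope field. ``mib1_positive_fraction`` is NaN when the
    MIB-1 stain is unavailable for the specimen."""

    field_id: int
    cd34_count: int
    field_area: float
    mib1_positive_fraction: float
    mib1_positive_count: float = float("nan")  # raw cells, literal-mode only
    magnification: int = 200  # provenance only

    def __post_init__(self) -> None:
        if self.cd34_count < 0:
            raise DomainError("cd34_count must be non-negative")
        if self.field_area <= 0:
            raise DomainError("field_area must be positive")
        f = self.mib1_positive_fraction
        if np.isfinite(f) and not 0.0 <= f <= 1.0:
            raise DomainError("mib1_positive_fraction must lie in [0, 1]")


@dataclass
class Specimen:
    """A biopsy specimen with its WHO grade and field measurements.

    ``mvd_true`` / ``pmib1_true`` carry the generator's specimen-level
    values when the specimen is synthetic (None for loaded data); the
    derived ``cd34_mvd`` / ``pmib1`` properties always come from the
    fields.
    """

    specimen_id: str
    patient_id: str
    who_grade: int
    fields: list[FieldMeasurement] = field(default_factory=list)
    mvd_true: float | None = None
    pmib1_true: float | None = None

    def __post_init__(self) -> None:
        if self.who_grade not in (2, 3, 4):
            raise DomainError(f"who_grade must be 2, 3 or 4, got {self.who_grade}")
        if not 3 <= len(self.fields) <= 20:
            warnings.warn(
                f"specimen {self.specimen_id}: {len(self.fields)} fields "
                "outside the usual [3, 20] range", stacklevel=2,
            )

    @property
    def cd34_mvd(self) -> float:
        return cd34_mvd(self.fields)

    @property
    def pmib1_available(self) -> bool:
        return any(np.isfinite(f.mib1_positive_fraction) for f in self.fields)

    @property
    def pmib1(self) -> float:
        if not self.pmib1_available:
            return float("nan")
        return pmib1([f for f in self.fields if np.isfinite(f.mib1_positive_fraction)])


def cd34_mvd(fields: list[FieldMeasurement]) -> float:
    """Pooled microvascular density: total count / total area (vessels/mm^2).

    The pooled ratio -- not the mean of per-field densities -- is used; the
    two differ when field areas are unequal.
    """
    if not fields:
        raise DomainError("no fields")
    total_area = sum(f.field_area for f in fields)
    if total_area <= 0:
        raise DomainError("zero total field area")
    return sum(f.cd34_count for f in fields) / total_area


def pmib1(fields: list[FieldMeasurement], mode: str = "fraction_mean") -> float:
    """Proliferation index (%) over the specimen's fields.

    ``fraction_mean`` (default): mean of per-field positive fractions x 100.
    ``cells_per_field``: sum of raw positive-cell counts divided by the
    field count (the literal reading; unbounded, needs
    ``mib1_positive_count`` on every field).
    """
    if not fields:
        raise DomainError("no fields")
    if mode == "fraction_mean":
        fracs = np.array([f.mib1_positive_fraction for f in fields], dtype=float)
        if np.any(~np.isfinite(fracs)):
            raise DomainError("MIB-1 fraction missing in one or more fields")
        return float(fracs.mean() * 100.0)
    if mode == "cells_per_field":
        counts = np.array([f.mib1_positive_count for f in fields], dtype=float)
        if np.any(~np.isfinite(counts)):
            raise DomainError("cells_per_field mode needs mib1_positive_count per field")
        return float(counts.sum() / len(fields))
    raise ConfigurationError(f"unknown pmib1 mode {mode!r}")


def load_specimen_table(path) -> list[Specimen]:
    """Load specimens from the field-level CSV written by the simulator.

    Schema: ``specimen_id, patient_id, who_grade, field_id, cd34_count,
    field_area_mm2, mib1_positive_fraction`` (fraction blank/NaN when the
    MIB-1 stain is unavailable). Duplicate field ids within a specimen are
    rejected.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in FIELD_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    specimens = []
    for sid, g in df.groupby("specimen_id", sort=True):
        if g["field_id"].duplicated().any():
            dup = g.loc[g["field_id"].duplicated(), "field_id"].iloc[0]
            raise FormatError(f"specimen {sid}: duplicate field_id {dup}")
        pids = g["patient_id"].unique()
        grades = g["who_grade"].unique()
        if len(pids) != 1 or len(grades) != 1:
            raise FormatError(f"specimen {sid}: inconsistent patient/grade rows")
        try:
            fields = [
                FieldMeasurement(
                    field_id=int(r.field_id),
                    cd34_count=int(r.cd34_count),
                    field_area=float(r.field_area_mm2),
                    mib1_positive_fraction=float(r.mib1_positive_fraction)
                    if np.isfinite(r.mib1_positive_fraction) else float("nan"),
                )
                for r in g.itertuples()
            ]
        except (DomainError, ValueError) as exc:
            raise FormatError(f"specimen {sid}: {exc}") from exc
        specimens.append(
            Specimen(str(sid), str(pids[0]), int(grades[0]), fields)
        )
    if not specimens:
        raise FormatError(f"{path}: no specimen rows")
    return specimens


def write_field_table(specimens: list[Specimen], path) -> pd.DataFrame:
    """Write the field-level CSV; returns the frame written."""
    rows = [
        {
            "specimen_id": s.specimen_id,
            "patient_id": s.patient_id,
            "who_grade": s.who_grade,
            "field_id": f.field_id,
            "cd34_count": f.cd34_count,
            "field_area_mm2": f.field_area,
            "mib1_positive_fraction": f.mib1_positive_fraction,
        }
        for s in specimens
        for f in s.fields
    ]
    df = pd.DataFrame(rows, columns=FIELD_TABLE_COLUMNS)
    df.to_csv(path, index=False)
    return df


def specimen_summary_frame(specimens: list[Specimen]) -> pd.DataFrame:
    """Specimen-level table with the derived indices."""
    return pd.DataFrame(
        {
            "specimen_id": [s.specimen_id for s in specimens],
            "patient_id": [s.patient_id for s in specimens],
            "who_grade": [s.who_grade for s in specimens],
            "cd34_mvd": [s.cd34_mvd for s in specimens],
            "pmib1": [s.pmib1 for s in specimens],
            "n_fields": [len(s.fields) for s in specimens],
            "pmib1_available": [s.pmib1_available for s in specimens],
        }
    )
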