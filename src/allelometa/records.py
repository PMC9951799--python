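"""Reading, validation and normalization of study-level control/treatment records.

The unit of data entry is one control/treatment comparison from a published
allelopathy experiment: group means, dispersions (SD or SE), sample sizes, and
the moderators used downstream as fixed or random effects (study identifiers,
trait, method, duration, dose, species names and origins, year published).
Tables are delimited text (CSV by default, TSV behind a flag); dispersion kind
is a per-row column because source studies report either SDs or SEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TRAITS = ("germination", "growth")
GROWTH_COMPARTMENTS = ("aboveground", "belowground", "total", "n/a")
ORIGINS = ("native", "nonnative")
MATERIAL_CONDITIONS = ("fresh", "dry", "n/a")
MATERIAL_PARTS = ("aboveground", "belowground", "mixed", "n/a")

#: preference order for growth measurements when a study reports several
GROWTH_PREFERENCE = ("aboveground", "belowground", "total")

REQUIRED_COLUMNS = [
    "study_id", "substudy_id", "trait", "growth_compartment", "method_category",
    "duration_days", "grass_species", "recipient_species", "grass_origin",
    "recipient_origin", "dose_value", "dose_unit", "material_condition",
    "material_part", "solvent_polarity", "year_published",
    "control_mean", "control_dispersion", "control_n",
    "treatment_mean", "treatment_dispersion", "treatment_n",
]


@dataclass(frozen=True)
class GroupStats:
    """Summary statistics for one experimental group (control or treatment)."""

    mean: float
    sd: float
    n: int

    def validate(self) -> list[str]:
        problems = []
        if not math.isfinite(self.mean):
            problems.append("mean is not finite")
        if not math.isfinite(self.sd) or self.sd < 0:
            problems.append("sd must be finite and >= 0")
        if self.n < 2:
            problems.append("n must be >= 2 (variance formulas divide by n)")
        return problems


@dataclass(frozen=True)
class StudyRecord:
    """One control/treatment comparison with all moderators."""

    study_id: str
    substudy_id: str
    trait: str
    growth_compartment: str
    method_category: str
    duration_days: float
    grass_species: str
    recipient_species: str
    grass_origin: str
    recipient_origin: str
    dose_value: float | None
    dose_unit: str
    material_condition: str
    material_part: str
    solvent_polarity: str
    year_published: int
    control: GroupStats
    treatment: GroupStats

    @property
    def key(self) -> tuple:
        """Tuple that jointly identifies a row."""
        return (self.study_id, self.substudy_id, self.trait,
                self.recipient_species, self.grass_species, self.dose_value)

    def validate(self) -> list[str]:
        problems = []
        if self.trait not in TRAITS:
            problems.append(f"trait {self.trait!r} not in {TRAITS}")
        if self.growth_compartment not in GROWTH_COMPARTMENTS:
            problems.append(f"growth_compartment {self.growth_compartment!r} invalid")
        if self.trait == "growth" and self.growth_compartment == "n/a":
            problems.append("growth records must name a compartment")
        for name, val in (("grass_origin", self.grass_origin),
                          ("recipient_origin", self.recipient_origin)):
            if val not in ORIGINS:
                problems.append(f"{name} {val!r} not in {ORIGINS}")
        if not (self.duration_days > 0):
            problems.append("duration_days must be > 0")
        if self.dose_value is not None and not (self.dose_value > 0):
            problems.append("dose_value must be > 0 when present")
        for label, grp in (("control", self.control), ("treatment", self.treatment)):
            problems.extend(f"{label}: {p}" for p in grp.validate())
        return problems


@dataclass
class RowError:
    """A rejected input row with the reasons it failed validation."""

    row_index: int
    reasons: list[str]
    raw: dict = field(default_factory=dict)


@dataclass
class ReadResult:
    records: list[StudyRecord]
    rejects: list[RowError]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def normalize_dispersion(raw_value: float, kind: str, n: int) -> float:
    """Convert a reported dispersion to a standard deviation.

    ``kind='sd'`` is returned unchanged; ``kind='se'`` is scaled by sqrt(n)
    since se = sd / sqrt(n).
    """
    if raw_value < 0:
        raise ValueError(f"dispersion must be >= 0, got {raw_value}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    kind = kind.strip().lower()
    if kind == "sd":
        return float(raw_value)
    if kind == "se":
        return float(raw_value) * math.sqrt(n)
    raise ValueError(f"dispersion kind must be 'sd' or 'se', got {kind!r}")


def select_growth_measure(available: Iterable[str]) -> str:
    """Pick the growth compartment to analyse when several were reported.

    Aboveground is preferred, then belowground, then total.
    """
    avail = set(available)
    if not avail:
        raise ValueError("no growth compartments available")
    for choice in GROWTH_PREFERENCE:
        if choice in avail:
            return choice
    raise ValueError(f"no recognized growth compartment in {sorted(avail)}")


def _parse_row(row: pd.Series, idx: int, dispersion_kind_column: str) -> StudyRecord:
    def num(col, required=True):
        v = row[col]
        if pd.isna(v) or (isinstance(v, str) and not v.strip()):
            if required:
                raise ValueError(f"{col} is missing")
            return None
        return float(v)

    kind = str(row.get(dispersion_kind_column, "sd"))
    n_c = int(num("control_n"))
    n_t = int(num("treatment_n"))
    if n_c < 2 or n_t < 2:
        raise ValueError("group sample sizes must be >= 2")
    control = GroupStats(num("control_mean"),
                         normalize_dispersion(num("control_dispersion"), kind, n_c), n_c)
    treatment = GroupStats(num("treatment_mean"),
                           normalize_dispersion(num("treatment_dispersion"), kind, n_t), n_t)
    return StudyRecord(
        study_id=str(row["study_id"]),
        substudy_id=str(row["substudy_id"]),
        trait=str(row["trait"]).strip().lower(),
        growth_compartment=str(row["growth_compartment"]).strip().lower(),
        method_category=str(row["method_category"]),
        duration_days=num("duration_days"),
        grass_species=str(row["grass_species"]).strip(),
        recipient_species=str(row["recipient_species"]).strip(),
        grass_origin=str(row["grass_origin"]).strip().lower(),
        recipient_origin=str(row["recipient_origin"]).strip().lower(),
        dose_value=num("dose_value", required=False),
        dose_unit=str(row["dose_unit"]),
        material_condition=str(row["material_condition"]).strip().lower(),
        material_part=str(row["material_part"]).strip().lower(),
        solvent_polarity=str(row["solvent_polarity"]),
        year_published=int(num("year_published")),
        control=control,
        treatment=treatment,
    )


def read_study_table(path: str | Path,
                     dispersion_kind_column: str = "dispersion_kind",
                     tsv: bool = False) -> ReadResult:
    """Read a delimited study table into validated :class:`StudyRecord` objects.

    Rows that fail parsing or validation are collected as :class:`RowError`
    entries (never silently dropped); a missing required column is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # keep_default_na=False: "n/a" is a legitimate category level, not NaN
    df = pd.read_csv(path, sep="\t" if tsv else ",", dtype=str,
                     keep_default_na=False, na_values=[""])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"study table is missing required columns: {missing}")
    records: list[StudyRecord] = []
    rejects: list[RowError] = []
    for idx, row in df.iterrows():
        try:
            rec = _parse_row(row, idx, dispersion_kind_column)
        except (ValueError, KeyError, TypeError) as exc:
            rejects.append(RowError(int(idx), [str(exc)], row.to_dict()))
            continue
        problems = rec.validate()
        if problems:
            rejects.append(RowError(int(idx), problems, row.to_dict()))
        else:
            records.append(rec)
    return ReadResult(records, rejects)


def records_to_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    """Flatten StudyRecords to the canonical tabular form (inverse of reading)."""
    rows = []
    for r in records:
        row = {f.name: getattr(r, f.name) for f in dc_fields(r)
               if f.name not in ("control", "treatment")}
        row.update(control_mean=r.control.mean, control_dispersion=r.control.sd,
                   control_n=r.control.n, treatment_mean=r.treatment.mean,
                   treatment_dispersion=r.treatment.sd, treatment_n=r.treatment.n,
                   dispersion_kind="sd")
        rows.append(row)
    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS + ["dispersion_kind"])
    return df


def write_study_table(records: Sequence[StudyRecord], path: str | Path,
                      tsv: bool = False) -> None:
    """Write records back to a delimited table; floats use the shortest
    round-trip representation so read -> write -> read is bit-stable."""
    df = records_to_frame(records)
    df.to_csv(path, sep="\t" if tsv else ",", index=False)


def write_rejects(rejects: Sequence[RowError], path: str | Path,
                  tsv: bool = False) -> None:
    rows = [{"row_index": e.row_index, "reasons": "; ".join(e.reasons), **e.raw}
            for e in rejects]
    pd.DataFrame(rows).to_csv(path, sep="\t" if tsv else ",", index=False)
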