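"""Lipid matrix and sample-metadata I/O, prevalence filtering, coverage.

The on-disk interchange format is deliberately plain: a TSV/CSV matrix with
a ``species`` first column and one column of molar amounts (pmol per µL
plasma) per sample, and a metadata table with columns ``sample_id,
subject_id, intervention, timepoint`` (``eTRE|lTRE``, ``before|after``).
Blank cells are genuine missing values (non-detects), never zero.

Species seen in fewer than a threshold fraction of all samples — 70% by
default — are removed before analysis; the filter report records how much
of each sample's total molar content the retained species still cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .nomenclature import NomenclatureError, SpeciesAnnotation, parse_species

__all__ = [
    "Intervention",
    "Timepoint",
    "SampleMeta",
    "LipidMatrix",
    "FilterReport",
    "SchemaError",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "prevalence_filter",
]


class SchemaError(ValueError):
    """A file violates the documented column/row schema."""


class MatrixParseError(ValueError):
    """One or more species row labels failed to parse; all offenders listed."""

    def __init__(self, errors: dict[str, str]):
        self.errors = dict(errors)
        lines = "\n".join(f"  {name}: {msg}" for name, msg in self.errors.items())
        super().__init__(f"{len(self.errors)} unparseable species row(s):\n{lines}")


class Intervention(str, Enum):
    ETRE = "eTRE"
    LTRE = "lTRE"


class Timepoint(str, Enum):
    BEFORE = "before"
    AFTER = "after"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    subject_id: str
    intervention: Intervention
    timepoint: Timepoint


@dataclass
class LipidMatrix:
    """Species × sample molar amounts plus the crossover design metadata.

    ``amounts`` is a float DataFrame indexed by canonical species name with
    one column per sample; missing measurements are NaN.
    """

    species: list[SpeciesAnnotation]
    samples: list[SampleMeta]
    amounts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.amounts.shape != (len(self.species), len(self.samples)):
            raise SchemaError(
                f"amounts shape {self.amounts.shape} does not match "
                f"{len(self.species)} species x {len(self.samples)} samples"
            )
        observed = self.amounts.to_numpy()
        if np.nanmin(observed, initial=0.0) < 0:
            raise SchemaError("molar amounts must be non-negative")
        triples = {(s.subject_id, s.intervention, s.timepoint) for s in self.samples}
        if len(triples) != len(self.samples):
            raise SchemaError("(subject, intervention, timepoint) triples not unique")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "subject_id": [s.subject_id for s in self.samples],
                "intervention": [s.intervention.value for s in self.samples],
                "timepoint": [s.timepoint.value for s in self.samples],
            }
        )


@dataclass
class FilterReport:
    n_species_in: int
    n_species_out: int
    threshold: float
    coverage_per_sample: pd.Series = field(repr=False)
    mean_coverage: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        df = self.coverage_per_sample.rename("retained_coverage").to_frame()
        df.insert(0, "n_species_in", self.n_species_in)
        df.insert(1, "n_species_out", self.n_species_out)
        df.insert(2, "threshold", self.threshold)
        df["mean_coverage"] = self.mean_coverage
        return df.rename_axis("sample_id").reset_index()


def _read_table(path: str | Path) -> pd.DataFrame:
    # comma/tab auto-detection; decimal point only
    return pd.read_csv(path, sep=None, engine="python")


def read_metadata(meta_file: str | Path) -> list[SampleMeta]:
    df = _read_table(meta_file)
    required = ["sample_id", "subject_id", "intervention", "timepoint"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata file missing column(s): {missing}")
    samples = []
    for row in df.itertuples(index=False):
        try:
            intervention = Intervention(row.intervention)
            timepoint = Timepoint(row.timepoint)
        except ValueError as exc:
            raise SchemaError(f"sample {row.sample_id!r}: {exc}") from None
        samples.append(
            SampleMeta(str(row.sample_id), str(row.subject_id), intervention, timepoint)
        )
    return samples


def write_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    LipidMatrix(
        species=[], samples=list(samples), amounts=pd.DataFrame(
            index=pd.Index([], name="species"),
            columns=[s.sample_id for s in samples], dtype=float,
        )
    ).meta_frame().to_csv(path, sep="\t", index=False)


def read_matrix(matrix_file: str | Path, meta_file: str | Path) -> LipidMatrix:
    """Read a species × sample matrix and its sample metadata.

    Every row label must parse under the shorthand grammar (all failures
    are aggregated into one :class:`MatrixParseError`) and every matrix
    column must have a metadata row.  Blank cells stay missing.
    """
    samples = read_metadata(meta_file)
    df = _read_table(matrix_file)
    if df.columns[0] != "species":
        raise SchemaError(
            f"first matrix column must be 'species', got {df.columns[0]!r}"
        )
    df = df.set_index("species")

    by_id = {s.sample_id: s for s in samples}
    unknown = [c for c in df.columns if c not in by_id]
    if unknown:
        raise SchemaError(f"matrix sample(s) absent from metadata: {unknown}")
    ordered = [by_id[c] for c in df.columns]

    species: list[SpeciesAnnotation] = []
    errors: dict[str, str] = {}
    for name in df.index:
        try:
            species.append(parse_species(str(name)))
        except NomenclatureError as exc:
            errors[str(name)] = f"{type(exc).__name__}: {exc}"
    if errors:
        raise MatrixParseError(errors)

    return LipidMatrix(species=species, samples=ordered, amounts=df.astype(float))


def write_matrix(
    matrix: LipidMatrix, path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write the matrix (and optionally metadata) as TSV; NaN becomes blank."""
    matrix.amounts.rename_axis("species").to_csv(path, sep="\t", na_rep="")
    if meta_path is not None:
        write_metadata(matrix.samples, meta_path)


def presence_mask(amounts: pd.DataFrame) -> pd.DataFrame:
    """Presence = non-missing AND strictly positive.

    Shotgun exports encode non-detects as blanks or zeros interchangeably;
    both count as absent for the prevalence filter.
    """
    return amounts.notna() & (amounts > 0)


def prevalence_filter(
    matrix: LipidMatrix, threshold: float = 0.70, *, count_zero_as_present: bool = False
) -> tuple[LipidMatrix, FilterReport]:
    """Drop species present in less than ``threshold`` of all samples.

    A species observed in exactly ``threshold`` of the samples is retained
    (the exclusion rule is "less than", so the boundary stays in).
    Prevalence pools every sample across interventions and timepoints.
    ``coverage_per_sample`` is the retained molar sum divided by the total
    molar sum of that sample — how much of the measured lipid content
    survives the filter.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    n_samples = len(matrix.samples)
    if n_samples == 0 or not matrix.species:
        empty = pd.Series(dtype=float, index=pd.Index(matrix.sample_ids, name="sample_id"))
        report = FilterReport(0, 0, threshold, empty, float("nan"))
        return matrix, report

    if count_zero_as_present:
        present = matrix.amounts.notna()
    else:
        present = presence_mask(matrix.amounts)
    fraction = present.sum(axis=1) / n_samples
    keep = fraction >= threshold

    kept_amounts = matrix.amounts.loc[keep.to_numpy()]
    kept_species = [sp for sp, k in zip(matrix.species, keep) if k]
    filtered = LipidMatrix(kept_species, list(matrix.samples), kept_amounts)

    total = matrix.amounts.sum(axis=0, skipna=True)
    retained = kept_amounts.sum(axis=0, skipna=True)
    with np.errstate(invalid="ignore"):
        coverage = retained / total
    coverage.index.name = "sample_id"
    report = FilterReport(
        n_species_in=len(matrix.species),
        n_species_out=len(kept_species),
        threshold=threshold,
        coverage_per_sample=coverage,
        mean_coverage=float(coverage.mean()) if len(coverage) else math.nan,
    )
    return filtered, report
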