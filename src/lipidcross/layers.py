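"""Derived analysis layers over a filtered lipid matrix.

Six views of the same measurements are analysed in parallel: the species
themselves, per-class totals, fatty-acid totals, desaturase/elongase
activity indices, and double-bond and chain-length subgroups within each
class.  All layers except the indices are molar amounts and partition the
species layer, so per-sample sums are conserved; the indices are
dimensionless ratios of fatty-acid amounts.

Fatty-acid totals are assessed *within complex lipids*: each resolved
acyl/alkyl chain of a species contributes that species' full molar amount
to its ``C:DB;OH`` key.  Sum species (chains unresolved) and cholesterol
contribute nothing and are tallied in a skip report, as are sphingolipids,
whose long-chain base is not a fatty acid.  The activity indices are
amount ratios of the product and substrate fatty acid of one enzyme — a
surrogate marker convention, not a direct activity measurement:

======  ==========================  ===============================
index   enzyme                      ratio
======  ==========================  ===============================
D5D     delta-5 desaturase (FADS1)  FA 20:4 / FA 20:3
D6D     delta-6 desaturase (FADS2)  FA 18:3 / FA 18:2
D9D (C16)     stearoyl-CoA desaturase   FA 16:1 / FA 16:0
D9D (C18)     stearoyl-CoA desaturase   FA 18:1 / FA 18:0
D9D (C16+18)  stearoyl-CoA desaturase   (16:1 + 18:1) / (16:0 + 18:0)
ELOVL5  elongase 5                  FA 20:3 / FA 18:3
ELOVL6  elongase 6                  FA 18:0 / FA 16:0
======  ==========================  ===============================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix_io import LipidMatrix, SampleMeta
from .nomenclature import ChainKind, Level

__all__ = [
    "Layer",
    "FeatureTable",
    "IndexDefinition",
    "DEFAULT_INDICES",
    "FaSkipReport",
    "species_table",
    "class_totals",
    "fa_totals",
    "enzyme_indices",
    "db_subgroups",
    "length_subgroups",
    "all_layers",
]


class Layer(str, Enum):
    SPECIES = "species"
    CLASS = "class"
    FATTY_ACID = "fatty_acid"
    INDEX = "index"
    DB_SUBGROUP = "db_subgroup"
    LENGTH_SUBGROUP = "length_subgroup"


@dataclass
class FeatureTable:
    """A feature × sample table for one analysis layer.

    Feature keys are serialized text: ``PC 34:1;0`` (species), ``PC``
    (class), ``18:1;0`` (fatty acid), ``ELOVL6`` (index), ``PC|db=1`` and
    ``PC|C=34`` (subgroups).
    """

    layer: Layer
    values: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("feature keys must be unique within a table")
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("value columns must match sample metadata order")

    @property
    def features(self) -> list[str]:
        return [str(f) for f in self.values.index]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# layer: {self.layer.value}\n")
            self.values.rename_axis("feature").to_csv(fh, sep="\t", na_rep="")


@dataclass(frozen=True)
class IndexDefinition:
    """An enzyme-activity index: ratio of summed fatty-acid amounts.

    ``numerator_fa``/``denominator_fa`` are ``C:DB`` keys (hydroxylation 0
    implied); composite indices sum several keys before dividing.
    """

    name: str
    numerator_fa: tuple[str, ...]
    denominator_fa: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.numerator_fa) == set(self.denominator_fa):
            raise ValueError(f"index {self.name}: numerator equals denominator")


DEFAULT_INDICES: tuple[IndexDefinition, ...] = (
    IndexDefinition("D5D", ("20:4",), ("20:3",)),
    IndexDefinition("D6D", ("18:3",), ("18:2",)),
    IndexDefinition("D9D (C16)", ("16:1",), ("16:0",)),
    IndexDefinition("D9D (C18)", ("18:1",), ("18:0",)),
    IndexDefinition("D9D (C16+18)", ("16:1", "18:1"), ("16:0", "18:0")),
    IndexDefinition("ELOVL5", ("20:3",), ("18:3",)),
    IndexDefinition("ELOVL6", ("18:0",), ("16:0",)),
)


@dataclass
class FaSkipReport:
    """Species that contribute nothing to fatty-acid totals and why."""

    skipped: dict[str, str] = field(default_factory=dict)
    skipped_share_of_content: float = float("nan")
    ether_chains: list[str] = field(default_factory=list)


def _table(layer: Layer, values: pd.DataFrame, matrix: LipidMatrix) -> FeatureTable:
    return FeatureTable(layer=layer, values=values, samples=list(matrix.samples))


def species_table(matrix: LipidMatrix) -> FeatureTable:
    """The identity layer: the (filtered) species matrix itself."""
    return _table(Layer.SPECIES, matrix.amounts.copy(), matrix)


def _grouped_totals(
    matrix: LipidMatrix, layer: Layer, key_of: "callable"
) -> FeatureTable:
    keys = [key_of(sp) for sp in matrix.species]
    grouped = matrix.amounts.groupby(pd.Index(keys, name="feature"), sort=False)
    # missing member values are excluded from the sum; a feature whose
    # members are all missing in a sample stays missing there
    values = grouped.sum(min_count=1)
    return _table(layer, values, matrix)


def class_totals(matrix: LipidMatrix) -> FeatureTable:
    """Per-class molar totals: one feature per lipid class present."""
    return _grouped_totals(matrix, Layer.CLASS, lambda sp: sp.lipid_class)


def db_subgroups(matrix: LipidMatrix) -> FeatureTable:
    """Totals of species sharing class and total double-bond count."""
    return _grouped_totals(
        matrix,
        Layer.DB_SUBGROUP,
        lambda sp: f"{sp.lipid_class}|db={sp.total_double_bonds}",
    )


def length_subgroups(matrix: LipidMatrix) -> FeatureTable:
    """Totals of species sharing class and total carbon count."""
    return _grouped_totals(
        matrix,
        Layer.LENGTH_SUBGROUP,
        lambda sp: f"{sp.lipid_class}|C={sp.total_carbons}",
    )


def fa_totals(
    matrix: LipidMatrix, *, include_ether_chains: bool = True
) -> tuple[FeatureTable, FaSkipReport]:
    """Fatty-acid amounts within complex lipids, keyed ``C:DB;OH``.

    Each resolved chain contributes the full species amount to its key;
    a species therefore contributes once per chain.  Unresolved species
    (sum species, cholesterol) and sphingolipids are skipped and reported.
    Alkyl ether chains contribute under their key by default and are
    flagged in the report; pass ``include_ether_chains=False`` to omit
    them.
    """
    report = FaSkipReport()
    contributions: dict[str, pd.Series] = {}
    zero = pd.Series(0.0, index=matrix.amounts.columns)

    sphingo = {"SM", "Cer"}
    for i, sp in enumerate(matrix.species):
        name = str(matrix.amounts.index[i])
        if sp.lipid_class == "Chol":
            report.skipped[name] = "no fatty acid (sterol)"
            continue
        if sp.lipid_class in sphingo:
            # long-chain base is not an FA; the grammar never resolves
            # sphingoid base vs N-acyl, so sphingolipids are skipped whole
            report.skipped[name] = "sphingolipid (chains not FA-resolvable)"
            continue
        if sp.level is not Level.SUBSPECIES or not sp.chains:
            report.skipped[name] = "sum species (chains unresolved)"
            continue
        amounts = matrix.amounts.iloc[i]
        for chain in sp.chains:
            if chain.kind is ChainKind.ALKYL_ETHER:
                report.ether_chains.append(f"{name} [{chain.key}]")
                if not include_ether_chains:
                    continue
            acc = contributions.setdefault(chain.key, zero.copy())
            contributions[chain.key] = acc.add(amounts.fillna(0.0), fill_value=0.0)

    if contributions:
        values = pd.DataFrame(contributions).T
        values.index.name = "feature"
        values = values[matrix.amounts.columns]
    else:
        values = pd.DataFrame(
            index=pd.Index([], name="feature"), columns=matrix.amounts.columns,
            dtype=float,
        )

    total = float(np.nansum(matrix.amounts.to_numpy()))
    skipped_total = float(
        np.nansum(matrix.amounts.loc[list(report.skipped)].to_numpy())
    ) if report.skipped else 0.0
    report.skipped_share_of_content = skipped_total / total if total > 0 else float("nan")

    return _table(Layer.FATTY_ACID, values, matrix), report


def enzyme_indices(
    fa_table: FeatureTable, definitions: Sequence[IndexDefinition] = DEFAULT_INDICES
) -> FeatureTable:
    """Desaturase/elongase activity indices from a fatty-acid table.

    FA keys are matched on ``C:DB`` with hydroxylation 0, pooled across
    all lipid classes (one global FA pool per sample).  An index is
    missing wherever its denominator is absent or zero — missingness is
    the contract, not an error.
    """
    if fa_table.layer is not Layer.FATTY_ACID:
        raise ValueError("enzyme_indices expects a fatty_acid layer table")
    fa = fa_table.values
    n_cols = fa.shape[1]

    def pool(keys: tuple[str, ...]) -> pd.Series:
        rows = [f"{k};0" for k in keys if f"{k};0" in fa.index]
        if not rows:
            return pd.Series(np.nan, index=fa.columns)
        return fa.loc[rows].sum(min_count=1)

    out = {}
    for d in definitions:
        num, den = pool(d.numerator_fa), pool(d.denominator_fa)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = num / den
        ratio[(den <= 0) | den.isna()] = np.nan
        out[d.name] = ratio
    values = pd.DataFrame(out).T if out else pd.DataFrame(
        index=pd.Index([], name="feature"), columns=fa.columns, dtype=float
    )
    values.index.name = "feature"
    assert values.shape[1] == n_cols
    return FeatureTable(Layer.INDEX, values, list(fa_table.samples))


def all_layers(
    matrix: LipidMatrix,
    index_definitions: Sequence[IndexDefinition] = DEFAULT_INDICES,
) -> dict[Layer, FeatureTable]:
    """Compute all six layers; returns a layer → table mapping."""
    fa, _ = fa_totals(matrix)
    return {
        Layer.SPECIES: species_table(matrix),
        Layer.CLASS: class_totals(matrix),
        Layer.FATTY_ACID: fa,
        Layer.INDEX: enzyme_indices(fa, index_definitions),
        Layer.DB_SUBGROUP: db_subgroups(matrix),
        Layer.LENGTH_SUBGROUP: length_subgroups(matrix),
    }
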