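"""Synthetic crossover-lipidomics trials with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
panel of ~300 species across the 14 plasma classes named in the canonical
shorthand grammar (a mix of sum species, resolved ``_``/``/`` subspecies,
ether and sphingolipid forms); log-normal molar amounts with a per-species
location, a per-subject random effect shared across that subject's four
samples, and independent replicate noise; a two-intervention before/after
crossover; multiplicative intervention effects injected on chosen classes
or species patterns, applied only to "after" samples of the targeted arm;
and missingness from a random dropout rate plus a deterministic detection
floor, exercising both presence definitions of the prevalence filter.

Amounts follow  amount = exp(mu_class + a_species + b_subject + eps) × m,
with  a ~ N(0, sigma_species),  b ~ N(0, sigma_subject),
eps ~ N(0, sigma_noise)  and m the product of applicable effect
multipliers.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import fnmatch
import itertools
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix_io import Intervention, LipidMatrix, SampleMeta, Timepoint
from .nomenclature import parse_species

__all__ = [
    "Effect",
    "TrialConfig",
    "SyntheticTruth",
    "generate_trial",
    "generate_de_table",
    "DEFAULT_CLASS_COUNTS",
    "DEFAULT_LOG_MEANS",
]

# Species counts per class for the default 300-species panel, mirroring the
# relative richness of shotgun plasma panels (glycerolipids and PCs are the
# largest families; cholesterol is a single species).
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "Chol": 1,
    "CE": 20,
    "TAG": 55,
    "DAG": 15,
    "PC": 60,
    "PC O-": 22,
    "PE": 25,
    "PE O-": 15,
    "PI": 14,
    "LPC": 12,
    "LPC O-": 5,
    "LPE": 8,
    "SM": 24,
    "Cer": 24,
}

# Log-scale per-species location by class (amounts in pmol/µL plasma);
# chosen so class totals resemble a plasma lipidome dominated by
# cholesterol, CE, TAG and PC, with sparse lyso and ceramide pools.
DEFAULT_LOG_MEANS: dict[str, float] = {
    "Chol": 8.0,
    "CE": 4.8,
    "TAG": 2.9,
    "DAG": 0.7,
    "PC": 3.2,
    "PC O-": 1.0,
    "PE": 0.9,
    "PE O-": 1.0,
    "PI": 1.9,
    "LPC": 2.5,
    "LPC O-": -0.9,
    "LPE": -0.5,
    "SM": 2.8,
    "Cer": -0.9,
}

# Acyl chains common in plasma lipids; covers every fatty acid the
# activity indices consume (16:0/16:1/18:x/20:3/20:4).
_CHAIN_POOL: tuple[tuple[int, int], ...] = (
    (16, 0), (16, 1), (18, 0), (18, 1), (18, 2), (18, 3),
    (20, 3), (20, 4), (20, 5), (22, 5), (22, 6),
    (14, 0), (15, 0), (17, 0), (17, 1), (24, 0), (24, 1),
)

# wider pool for single-chain (lyso) classes, which cannot combine chains
_LYSO_CHAIN_POOL: tuple[tuple[int, int], ...] = _CHAIN_POOL + (
    (12, 0), (13, 0), (19, 0), (19, 1), (20, 0), (20, 1),
    (20, 2), (22, 0), (22, 1), (22, 4), (26, 0), (26, 1),
)


@dataclass(frozen=True)
class Effect:
    """A multiplicative intervention effect on a class or species pattern.

    ``target`` is a class code (``Cer``) or an fnmatch species pattern
    (``PC 34:*``); the multiplier applies to "after" samples of the
    targeted intervention only.
    """

    intervention: Intervention
    target: str
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("effect multipliers must be > 0")


@dataclass
class TrialConfig:
    n_subjects: int = 30
    n_species: int = 300
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    log_mean_by_class: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_MEANS)
    )
    sigma_species: float = 0.8
    sigma_subject: float = 0.35
    sigma_noise: float = 0.1
    effects: list[Effect] = field(default_factory=list)
    missing_rate: float = 0.03
    detection_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_species < 1:
            raise ValueError("n_subjects and n_species must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for s in (self.sigma_species, self.sigma_subject, self.sigma_noise):
            if s < 0:
                raise ValueError("sigma parameters must be >= 0")
        unknown = set(self.class_counts) - set(DEFAULT_CLASS_COUNTS)
        if unknown:
            raise ValueError(f"unknown class code(s) in class_counts: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated trial.

    ``affected_features`` maps each aggregate layer to the feature keys
    that any affected species rolls up into; derived deterministically
    from the species panel.
    """

    affected_species: dict[Intervention, list[str]]
    multipliers: dict[tuple[str, str], float]  # (intervention, species) -> m
    affected_features: dict[str, dict[str, set[str]]]  # layer -> interv -> keys
    seed: int
    config: TrialConfig


def _species_panel(config: TrialConfig) -> list[str]:
    """Deterministic per-class name pools, truncated to the configured counts."""
    total = sum(config.class_counts.values())
    if config.n_species != total:
        # rescale counts proportionally, keeping Chol at one species
        scale = (config.n_species - 1) / max(total - 1, 1)
        counts = {}
        for cls, c in config.class_counts.items():
            counts[cls] = 1 if cls == "Chol" else max(1, round(c * scale))
        # adjust the largest class to hit the exact total
        drift = config.n_species - sum(counts.values())
        largest = max((c for c in counts if c != "Chol"), key=counts.get)
        counts[largest] = max(1, counts[largest] + drift)
    else:
        counts = dict(config.class_counts)

    names: list[str] = []
    for cls, k in counts.items():
        pool = _class_pool(cls)
        if k > len(pool):
            raise ValueError(
                f"class {cls!r}: requested {k} species but the name pool "
                f"holds only {len(pool)}"
            )
        names.extend(pool[:k])
    return names


def _two_chain_pool(cls: str, sep_cycle: Sequence[str]) -> list[str]:
    prefix = cls if cls.endswith("O-") else cls + " "
    out, seen = [], set()
    i = 0
    for (c1, d1), (c2, d2) in itertools.combinations_with_replacement(_CHAIN_POOL, 2):
        style = sep_cycle[i % len(sep_cycle)]
        if style == "sum":
            name = f"{prefix}{c1 + c2}:{d1 + d2};0"
        else:
            name = f"{prefix}{c1}:{d1};0{style}{c2}:{d2};0"
        if name not in seen:
            seen.add(name)
            out.append(name)
            i += 1
    return out


def _class_pool(cls: str) -> list[str]:
    if cls == "Chol":
        return ["Chol"]
    if cls == "CE":
        return [
            f"CE {c}:{d};0"
            for c in (14, 15, 16, 17, 18, 19, 20, 22, 24)
            for d in range(0, 5)
        ]
    if cls == "TAG":
        return [
            f"TAG {c}:{d};0"
            for c in range(40, 62, 2)
            for d in range(0, 12)
        ]
    if cls in ("LPC", "LPE"):
        return [f"{cls} {c}:{d};0" for c, d in _LYSO_CHAIN_POOL]
    if cls == "LPC O-":
        return [f"LPC O-{c}:{d};0" for c, d in _LYSO_CHAIN_POOL]
    if cls in ("SM", "Cer"):
        return [
            f"{cls} {c}:{d};2"
            for c in range(30, 48, 2)
            for d in range(1, 6)
        ]
    if cls == "DAG":
        # resolved two-acyl subspecies plus occasional sum species
        return _two_chain_pool(cls, ("_", "sum"))
    if cls in ("PC", "PE", "PI"):
        # mostly unresolved '_' subspecies, some sum species, a few '/' forms
        return _two_chain_pool(cls, ("_", "_", "sum", "/"))
    if cls in ("PC O-", "PE O-"):
        return _two_chain_pool(cls, ("/", "sum"))
    raise ValueError(f"no name pool for class {cls!r}")


def _affects(effect: Effect, name: str, cls: str) -> bool:
    return effect.target == cls or fnmatch.fnmatchcase(name, effect.target)


def generate_trial(config: TrialConfig) -> tuple[LipidMatrix, SyntheticTruth]:
    """Simulate one crossover trial; fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    names = _species_panel(config)
    species = [parse_species(n) for n in names]
    classes = [sp.lipid_class for sp in species]

    samples = [
        SampleMeta(f"{subj}_{iv.value}_{tp.value}", subj, iv, tp)
        for subj in (f"S{i + 1:02d}" for i in range(config.n_subjects))
        for iv in Intervention
        for tp in Timepoint
    ]

    n_sp, n_sm = len(names), len(samples)
    a = rng.normal(0.0, config.sigma_species, size=n_sp)
    b_subject = {
        subj: rng.normal(0.0, config.sigma_subject)
        for subj in dict.fromkeys(s.subject_id for s in samples)
    }
    mu = np.array([config.log_mean_by_class[c] for c in classes])
    eps = rng.normal(0.0, config.sigma_noise, size=(n_sp, n_sm))

    log_amounts = mu[:, None] + a[:, None] + eps
    for j, s in enumerate(samples):
        log_amounts[:, j] += b_subject[s.subject_id]

    multiplier = np.ones((n_sp, n_sm))
    truth_mult: dict[tuple[str, str], float] = {}
    affected: dict[Intervention, set[str]] = {iv: set() for iv in Intervention}
    for eff in config.effects:
        for i, (name, cls) in enumerate(zip(names, classes)):
            if not _affects(eff, name, cls):
                continue
            if eff.multiplier != 1.0:
                affected[eff.intervention].add(name)
                key = (eff.intervention.value, name)
                truth_mult[key] = truth_mult.get(key, 1.0) * eff.multiplier
            for j, s in enumerate(samples):
                if s.intervention is eff.intervention and s.timepoint is Timepoint.AFTER:
                    multiplier[i, j] *= eff.multiplier

    amounts = np.exp(log_amounts) * multiplier
    dropout = rng.random(size=(n_sp, n_sm)) < config.missing_rate
    amounts[dropout] = np.nan
    amounts[amounts < config.detection_floor] = np.nan

    frame = pd.DataFrame(
        amounts, index=pd.Index(names, name="species"),
        columns=[s.sample_id for s in samples],
    )
    matrix = LipidMatrix(species=species, samples=samples, amounts=frame)

    affected_features: dict[str, dict[str, set[str]]] = {
        layer: {iv.value: set() for iv in Intervention}
        for layer in ("species", "class", "db_subgroup", "length_subgroup")
    }
    by_name = dict(zip(names, species))
    for iv, hit in affected.items():
        for name in hit:
            sp = by_name[name]
            affected_features["species"][iv.value].add(name)
            affected_features["class"][iv.value].add(sp.lipid_class)
            affected_features["db_subgroup"][iv.value].add(
                f"{sp.lipid_class}|db={sp.total_double_bonds}"
            )
            affected_features["length_subgroup"][iv.value].add(
                f"{sp.lipid_class}|C={sp.total_carbons}"
            )

    truth = SyntheticTruth(
        affected_species={iv: sorted(v) for iv, v in affected.items()},
        multipliers=truth_mult,
        affected_features=affected_features,
        seed=config.seed,
        config=config,
    )
    return matrix, truth


def truth_to_json(truth: SyntheticTruth) -> dict:
    """JSON-serializable view of the ground truth (for the run manifest)."""
    return {
        "seed": truth.seed,
        "affected_species": {
            iv.value: names for iv, names in truth.affected_species.items()
        },
        "multipliers": {f"{iv}|{sp}": m for (iv, sp), m in truth.multipliers.items()},
        "affected_features": {
            layer: {iv: sorted(keys) for iv, keys in per_iv.items()}
            for layer, per_iv in truth.affected_features.items()
        },
        "config": {
            **{
                k: v for k, v in asdict(truth.config).items() if k != "effects"
            },
            "effects": [
                {"intervention": e.intervention.value, "target": e.target,
                 "multiplier": e.multiplier}
                for e in truth.config.effects
            ],
        },
    }


def generate_de_table(
    pathway,
    n_genes: int,
    affected: Sequence[tuple[str, float]] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a differential-expression table (gene, log2fc, pvalue, mean_fpkm).

    Background genes get small log2FC noise, uniform p-values and
    log-normal FPKM; ``affected`` genes get their stated log2FC with
    p < 0.05 and mean FPKM > 1, so they pass the overlay significance
    filter.  Pathway gene-set members not listed as affected are included
    as background so the overlay has realistic non-significant members.
    """
    rng = np.random.default_rng(seed)
    affected_names = [g for g, _ in affected]
    if len(set(affected_names)) != len(affected_names):
        raise ValueError("duplicate gene symbols in affected list")

    pool = sorted(getattr(pathway, "gene_members", set()) - set(affected_names))
    background = pool[: max(0, n_genes - len(affected_names))]
    extra = n_genes - len(affected_names) - len(background)
    background += [f"GENE{i + 1:05d}" for i in range(max(0, extra))]

    rows = []
    for gene, lfc in affected:
        rows.append(
            {
                "gene": gene,
                "log2fc": float(lfc),
                "pvalue": float(rng.uniform(1e-5, 0.04)),
                "mean_fpkm": float(rng.uniform(2.0, 60.0)),
            }
        )
    for gene in background:
        rows.append(
            {
                "gene": gene,
                "log2fc": float(rng.normal(0.0, 0.15)),
                "pvalue": float(rng.uniform(0.0, 1.0)),
                "mean_fpkm": float(np.exp(rng.normal(1.0, 1.5))),
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue", "mean_fpkm"])
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene symbols in generated table")
    return df.iloc[:n_genes].reset_index(drop=True)
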