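"""Lipid-class pathway over-representation analysis and gene overlay.

Significantly altered lipid species are merged to their classes, and each
pathway's compound set is tested for over-representation among the hit
classes with a one-sided hypergeometric test against the universe of
classes mappable to at least one pathway, BH-corrected across pathways.
A differential-gene-expression table (gene, log2FC, p, mean FPKM) can
then be overlaid onto an enriched pathway's gene set; genes must show
mean FPKM > 1 and p < 0.05 to appear, and are labelled up/down by the
sign of log2FC.

Pathway annotations are supplied as GMT-style files (one pathway per
line: id, name, members...).  A miniature hand-constructed annotation
covering glycerophospholipid and sphingolipid metabolism ships with the
package for tests and examples; it is a synthetic stand-in, with
domain-plausible membership, not an export of any pathway database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import scipy.stats as sps

from .crossover_stats import bh_adjust
from .nomenclature import SpeciesAnnotation

__all__ = [
    "PathwayAnnotation",
    "EnrichmentResult",
    "GeneOverlay",
    "read_gmt",
    "bundled_pathways",
    "merge_hits_to_classes",
    "class_enrichment",
    "overlay_genes",
]


@dataclass
class PathwayAnnotation:
    pathway_id: str
    pathway_name: str
    compound_members: set[str] = field(default_factory=set)
    gene_members: set[str] = field(default_factory=set)


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    k_overlap: int
    n_hits: int
    K_pathway: int
    N_universe: int
    p_raw: float
    q_bh: float
    overlapping_members: list[str]


@dataclass
class GeneOverlay:
    pathway_id: str
    entries: pd.DataFrame  # gene, log2fc, pvalue, mean_fpkm, direction


def read_gmt(path: str | Path) -> list[PathwayAnnotation]:
    """Read a GMT-style set file: ``id <tab> name <tab> member...``."""
    pathways = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs id, name and >=1 member: {line!r}")
        pathways.append(
            PathwayAnnotation(parts[0], parts[1], compound_members=set(parts[2:]))
        )
    return pathways


def bundled_pathways() -> list[PathwayAnnotation]:
    """The packaged miniature pathway annotation (synthetic stand-in)."""
    data = resources.files("lipidcross") / "data"
    compounds = read_gmt(data / "synthetic_pathways_compounds.gmt")
    genes = {p.pathway_id: p for p in read_gmt(data / "synthetic_pathways_genes.gmt")}
    for p in compounds:
        g = genes.get(p.pathway_id)
        if g is not None:
            p.gene_members = set(g.compound_members)
    return compounds


def merge_hits_to_classes(
    significant_species: Iterable[SpeciesAnnotation],
) -> set[str]:
    """Collapse significant species to the set of their lipid classes."""
    return {sp.lipid_class for sp in significant_species}


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """One-sided over-representation tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def class_enrichment(
    hits: set[str],
    universe: set[str],
    annotations: Sequence[PathwayAnnotation],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric ORA of hit classes against pathway sets.

    The universe must contain the hits and should be restricted to
    classes mappable to at least one pathway; universe members outside
    every pathway dilute the test and are rejected here.  Pathways with
    no member in the universe are skipped.  BH correction runs across the
    tested pathways.
    """
    if not hits <= universe:
        raise ValueError(f"hits outside universe: {sorted(hits - universe)}")
    mappable = set().union(*(p.compound_members for p in annotations)) if annotations else set()
    stray = universe - mappable
    if stray:
        raise ValueError(
            f"universe members not mappable to any pathway: {sorted(stray)}"
        )
    N = len(universe)
    n = len(hits)
    results = []
    for p in annotations:
        members = p.compound_members & universe
        if not members:
            continue  # pathway disjoint from universe: skipped
        K = len(members)
        overlap = sorted(members & hits)
        k = len(overlap)
        results.append(
            EnrichmentResult(
                pathway_id=p.pathway_id,
                pathway_name=p.pathway_name,
                k_overlap=k,
                n_hits=n,
                K_pathway=K,
                N_universe=N,
                p_raw=hypergeom_tail(k, N, K, n),
                q_bh=float("nan"),
                overlapping_members=overlap,
            )
        )
    q = bh_adjust([r.p_raw for r in results])
    for r, qv in zip(results, q):
        r.q_bh = float(qv)
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in results],
            "pathway_name": [r.pathway_name for r in results],
            "k_overlap": [r.k_overlap for r in results],
            "n_hits": [r.n_hits for r in results],
            "K_pathway": [r.K_pathway for r in results],
            "N_universe": [r.N_universe for r in results],
            "p_raw": [r.p_raw for r in results],
            "q_bh": [r.q_bh for r in results],
            "overlapping_members": [";".join(r.overlapping_members) for r in results],
        }
    )


def overlay_genes(
    de_table: pd.DataFrame,
    pathway: PathwayAnnotation,
    *,
    fpkm_min: float = 1.0,
    p_max: float = 0.05,
) -> GeneOverlay:
    """Map significant differentially expressed genes onto a pathway.

    A gene passes with mean FPKM strictly above ``fpkm_min`` and raw p
    strictly below ``p_max``, and must belong to the pathway's gene set.
    Direction is the sign of log2FC.
    """
    required = ["gene", "log2fc", "pvalue", "mean_fpkm"]
    missing = [c for c in required if c not in de_table.columns]
    if missing:
        raise ValueError(f"DE table missing column(s): {missing}")
    mask = (
        (de_table["mean_fpkm"] > fpkm_min)
        & (de_table["pvalue"] < p_max)
        & de_table["gene"].isin(pathway.gene_members)
    )
    passed = de_table.loc[mask, required].copy()
    passed["direction"] = ["up" if v > 0 else "down" for v in passed["log2fc"]]
    passed = passed.sort_values("gene", kind="stable").reset_index(drop=True)
    return GeneOverlay(pathway_id=pathway.pathway_id, entries=passed)
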