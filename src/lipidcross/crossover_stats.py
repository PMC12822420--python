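"""Paired contrasts for a two-intervention crossover design.

Each subject is measured before and after each intervention (early and
late time-restricted eating, eTRE/lTRE).  Within-intervention change is
the per-subject after-minus-before delta; the between-intervention
difference is the per-subject lTRE delta minus the eTRE delta.  Features
are tested with the paired Wilcoxon signed-rank test (two-sided) and
corrected with Benjamini–Hochberg within each (layer × contrast) family.
Fold changes are ratios of mean amounts — the volcano-plot x-axis — while
the additive delta carries a Student-t 95% confidence interval.

Wilcoxon convention: zero differences are discarded before ranking; the
null distribution is exact (full sign-flip enumeration) for n <= 25 with
untied absolute differences, otherwise a normal approximation with tie
and continuity correction is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .layers import FeatureTable
from .matrix_io import Intervention, Timepoint

__all__ = [
    "ContrastKind",
    "Direction",
    "WilcoxonResult",
    "ContrastResult",
    "wilcoxon_signed_rank",
    "bh_adjust",
    "within_contrast",
    "between_contrast",
    "volcano_table",
    "results_frame",
    "describe_features",
    "EXACT_N_MAX",
    "MIN_PAIRS_POWERED",
]

ALPHA_DEFAULT = 0.05
# exact sign-flip null up to this n (no ties among |d|); asymptotic beyond
EXACT_N_MAX = 25
# features with fewer complete pairs are flagged underpowered
MIN_PAIRS_POWERED = 3


class ContrastKind(str, Enum):
    WITHIN_ETRE = "within_eTRE"
    WITHIN_LTRE = "within_lTRE"
    BETWEEN = "between"


class Direction(str, Enum):
    UP = "up"
    DOWN = "down"
    NONE = "none"


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = min of the signed-rank sums
    p_value: float
    n_used: int  # pairs remaining after discarding zero differences
    degenerate: bool  # all differences zero (p fixed at 1)
    exact: bool  # exact enumeration vs normal approximation


def wilcoxon_signed_rank(
    pairs: Iterable[tuple[float, float]], *, zero_method: str = "wilcox"
) -> WilcoxonResult | None:
    """Two-sided paired Wilcoxon signed-rank test on (a, b) value pairs.

    Pairs with a missing member are dropped.  Returns ``None`` when no
    pairs remain; a degenerate result with p = 1 when every difference is
    zero.  ``zero_method`` follows the scipy naming ("wilcox" discards
    zero differences, "pratt" ranks them then drops their ranks).
    """
    arr = np.asarray(
        [(a, b) for a, b in pairs if not (math.isnan(a) or math.isnan(b))], dtype=float
    )
    if arr.size == 0:
        return None
    d = arr[:, 1] - arr[:, 0]
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return WilcoxonResult(0.0, 1.0, 0, degenerate=True, exact=True)

    n_eff = int(nonzero.size) if zero_method == "wilcox" else int(d.size)
    ties = np.unique(np.abs(nonzero)).size < nonzero.size
    use_exact = n_eff <= EXACT_N_MAX and not ties and zero_method == "wilcox"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on ties/zeros in exact mode
        res = sps.wilcoxon(
            d,
            zero_method=zero_method,
            alternative="two-sided",
            correction=not use_exact,
            method="exact" if use_exact else "approx",
        )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_used=n_eff,
        degenerate=False,
        exact=use_exact,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN entries pass through.

    Missing p-values are excluded from the family size m and returned as
    NaN in their original positions.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        if ((p[mask] < 0) | (p[mask] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


@dataclass
class ContrastResult:
    """Per-feature output of one paired contrast."""

    feature: str
    layer: str
    kind: ContrastKind
    n_pairs: int
    delta_mean: float
    delta_ci95: tuple[float, float]
    fold_change: float
    p_raw: float
    q_bh: float
    direction: Direction
    underpowered: bool
    degenerate: bool
    # between contrasts only: alternative delta-ratio convention
    delta_fold_change: float = float("nan")


def _t_ci(deltas: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = deltas.size
    if n < 2:
        return (float("nan"), float("nan"))
    mean = float(np.mean(deltas))
    sem = float(np.std(deltas, ddof=1)) / math.sqrt(n)
    if sem == 0:
        return (mean, mean)
    lo, hi = sps.t.interval(level, df=n - 1, loc=mean, scale=sem)
    return (float(lo), float(hi))


def _paired_frames(
    table: FeatureTable, intervention: Intervention
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(before, after) value frames with one column per subject, aligned."""
    before_ids, after_ids = {}, {}
    for s in table.samples:
        if s.intervention is intervention:
            bucket = before_ids if s.timepoint is Timepoint.BEFORE else after_ids
            bucket[s.subject_id] = s.sample_id
    subjects = sorted(set(before_ids) & set(after_ids))
    before = table.values[[before_ids[su] for su in subjects]]
    after = table.values[[after_ids[su] for su in subjects]]
    before.columns = after.columns = subjects
    return before, after


def _finalize(
    rows: list[ContrastResult], alpha: float
) -> list[ContrastResult]:
    q = bh_adjust([r.p_raw for r in rows])
    for r, qv in zip(rows, q):
        r.q_bh = float(qv)
        if not math.isnan(qv) and qv < alpha and not math.isnan(r.fold_change):
            r.direction = (
                Direction.UP if r.fold_change > 1
                else Direction.DOWN if r.fold_change < 1
                else Direction.NONE
            )
        else:
            r.direction = Direction.NONE
    return rows


def within_contrast(
    table: FeatureTable,
    intervention: Intervention,
    *,
    alpha: float = ALPHA_DEFAULT,
) -> list[ContrastResult]:
    """Before-vs-after paired contrast within one intervention arm.

    Per feature: Wilcoxon signed-rank p on (before, after) pairs,
    after-minus-before delta with t-based 95% CI, fold change
    mean(after)/mean(before), and BH q within this (layer × contrast)
    family.
    """
    before, after = _paired_frames(table, intervention)
    kind = (
        ContrastKind.WITHIN_ETRE
        if intervention is Intervention.ETRE
        else ContrastKind.WITHIN_LTRE
    )
    rows: list[ContrastResult] = []
    for feat in table.values.index:
        b = before.loc[feat].to_numpy(dtype=float)
        a = after.loc[feat].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        n = int(ok.sum())
        wres = wilcoxon_signed_rank(zip(b[ok], a[ok]))
        deltas = a[ok] - b[ok]
        mean_b = float(np.mean(b[ok])) if n else float("nan")
        mean_a = float(np.mean(a[ok])) if n else float("nan")
        fc = mean_a / mean_b if n and mean_b != 0 else float("nan")
        rows.append(
            ContrastResult(
                feature=str(feat),
                layer=table.layer.value,
                kind=kind,
                n_pairs=n,
                delta_mean=float(np.mean(deltas)) if n else float("nan"),
                delta_ci95=_t_ci(deltas),
                fold_change=fc,
                p_raw=wres.p_value if wres is not None else float("nan"),
                q_bh=float("nan"),
                direction=Direction.NONE,
                underpowered=n < MIN_PAIRS_POWERED,
                degenerate=wres.degenerate if wres is not None else False,
            )
        )
    return _finalize(rows, alpha)


def between_contrast(
    table: FeatureTable, *, alpha: float = ALPHA_DEFAULT
) -> list[ContrastResult]:
    """eTRE-vs-lTRE contrast on per-subject within-arm deltas.

    Only subjects complete in both arms contribute.  The Wilcoxon test is
    paired on (Δ_eTRE, Δ_lTRE); the additive summary is
    mean(Δ_lTRE − Δ_eTRE) with its t CI (late-minus-early convention).
    Two fold-change conventions are emitted: ``fold_change`` =
    FC_eTRE / FC_lTRE (ratio of within-arm mean fold changes, matching an
    "eTRE versus lTRE" axis) and ``delta_fold_change`` =
    mean(Δ_eTRE) / mean(Δ_lTRE).
    """
    b_e, a_e = _paired_frames(table, Intervention.ETRE)
    b_l, a_l = _paired_frames(table, Intervention.LTRE)
    subjects = sorted(set(b_e.columns) & set(b_l.columns))
    b_e, a_e = b_e[subjects], a_e[subjects]
    b_l, a_l = b_l[subjects], a_l[subjects]

    rows: list[ContrastResult] = []
    for feat in table.values.index:
        be, ae = b_e.loc[feat].to_numpy(float), a_e.loc[feat].to_numpy(float)
        bl, al = b_l.loc[feat].to_numpy(float), a_l.loc[feat].to_numpy(float)
        ok = ~(np.isnan(be) | np.isnan(ae) | np.isnan(bl) | np.isnan(al))
        n = int(ok.sum())
        d_e = ae[ok] - be[ok]
        d_l = al[ok] - bl[ok]
        wres = wilcoxon_signed_rank(zip(d_e, d_l))
        diff = d_l - d_e
        fc_e = float(np.mean(ae[ok]) / np.mean(be[ok])) if n and np.mean(be[ok]) != 0 else float("nan")
        fc_l = float(np.mean(al[ok]) / np.mean(bl[ok])) if n and np.mean(bl[ok]) != 0 else float("nan")
        fc = fc_e / fc_l if fc_l and not math.isnan(fc_l) and not math.isnan(fc_e) else float("nan")
        mean_de = float(np.mean(d_e)) if n else float("nan")
        mean_dl = float(np.mean(d_l)) if n else float("nan")
        dfc = mean_de / mean_dl if n and mean_dl != 0 else float("nan")
        rows.append(
            ContrastResult(
                feature=str(feat),
                layer=table.layer.value,
                kind=ContrastKind.BETWEEN,
                n_pairs=n,
                delta_mean=float(np.mean(diff)) if n else float("nan"),
                delta_ci95=_t_ci(diff),
                fold_change=fc,
                p_raw=wres.p_value if wres is not None else float("nan"),
                q_bh=float("nan"),
                direction=Direction.NONE,
                underpowered=n < MIN_PAIRS_POWERED,
                degenerate=wres.degenerate if wres is not None else False,
                delta_fold_change=dfc,
            )
        )
    return _finalize(rows, alpha)


def results_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    """Flatten contrast results into the TSV-ready results table."""
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "layer": [r.layer for r in results],
            "contrast": [r.kind.value for r in results],
            "n_pairs": [r.n_pairs for r in results],
            "delta_mean": [r.delta_mean for r in results],
            "delta_ci95_low": [r.delta_ci95[0] for r in results],
            "delta_ci95_high": [r.delta_ci95[1] for r in results],
            "fold_change": [r.fold_change for r in results],
            "delta_fold_change": [r.delta_fold_change for r in results],
            "p_raw": [r.p_raw for r in results],
            "q_bh": [r.q_bh for r in results],
            "direction": [r.direction.value for r in results],
            "underpowered": [r.underpowered for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )


def volcano_table(
    results: Sequence[ContrastResult], *, alpha: float = ALPHA_DEFAULT
) -> pd.DataFrame:
    """Volcano-plot-ready table for one contrast family.

    Adds −log10(p) and the BH significance flag; ``bh_threshold_p`` is the
    largest raw p among BH-significant features (the horizontal threshold
    line) and is NaN when nothing survives correction — no significance
    threshold can be established.
    """
    df = results_frame(results)
    if df.empty:
        df = df.reindex(
            columns=list(df.columns) + ["neg_log10_p", "significant_bh", "bh_threshold_p"]
        )
        return df[
            ["feature", "fold_change", "neg_log10_p", "p_raw", "q_bh",
             "significant_bh", "bh_threshold_p"]
        ]
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p_raw"])
    df["significant_bh"] = df["q_bh"] < alpha
    sig = df.loc[df["significant_bh"], "p_raw"]
    df["bh_threshold_p"] = sig.max() if len(sig) else float("nan")
    return df[
        ["feature", "fold_change", "neg_log10_p", "p_raw", "q_bh",
         "significant_bh", "bh_threshold_p"]
    ]


def describe_features(table: FeatureTable, *, alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """Descriptive statistics per feature: mean (SD), median (IQR).

    A Shapiro–Wilk normality label at the given alpha is attached for
    choosing which summary to report; it is descriptive only.
    """
    out = []
    for feat in table.values.index:
        x = table.values.loc[feat].dropna().to_numpy(float)
        if x.size >= 3 and np.ptp(x) > 0:
            normal = bool(sps.shapiro(x).pvalue >= alpha)
        else:
            normal = False
        out.append(
            {
                "feature": str(feat),
                "n": int(x.size),
                "mean": float(np.mean(x)) if x.size else float("nan"),
                "sd": float(np.std(x, ddof=1)) if x.size > 1 else float("nan"),
                "median": float(np.median(x)) if x.size else float("nan"),
                "q25": float(np.percentile(x, 25)) if x.size else float("nan"),
                "q75": float(np.percentile(x, 75)) if x.size else float("nan"),
                "normal_distribution": normal,
            }
        )
    return pd.DataFrame(out)
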