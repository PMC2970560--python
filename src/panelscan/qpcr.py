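"""qPCR relative quantification and the genotype-expression (eQTL) arm.

Amplification efficiency per gene comes from a dilution standard curve of Cq
against log10 concentration: the per-cycle amplification factor is
10**(-1/slope) (2.0 for a perfect doubling, slope -1/log10(2) ≈ -3.32), and
percent efficiency is (factor - 1) * 100. Note the widespread shorthand of
calling the *factor* expression "efficiency": a factor of 2.05 is reported as
E = 105%. Both numbers are carried on :class:`StandardCurve`.

Target-gene quantities are efficiency-corrected (quantity ∝ factor**(-Cq)) and
normalized by the geometric mean of three reference genes. Group differences
are tested with the Kruskal-Wallis statistic plus Dunn's pairwise
multiple-comparison z tests; genotype-expression association uses the
tie-corrected Spearman rank correlation with the genotype coded as the count
of the reference-disease risk allele (0/1/2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "ExpressionSample",
    "NormalizedExpression",
    "DunnComparison",
    "GroupComparison",
    "CorrelationResult",
    "fit_standard_curve",
    "normalize_expression",
    "normalize_cohort",
    "group_comparison",
    "genotype_expression_correlation",
]


@dataclass(frozen=True)
class StandardCurve:
    """Dilution-series fit: Cq = intercept + slope * log10(concentration)."""

    slope: float
    intercept: float
    r_squared: float
    amp_factor: float
    efficiency_pct: float


@dataclass(frozen=True)
class ExpressionSample:
    sample_id: str
    group: str
    tissue: str
    cq_target: float
    cq_refs: tuple[float, float, float]
    genotype: int | None = None  # risk-allele count 0/1/2, None = unknown


@dataclass(frozen=True)
class NormalizedExpression:
    sample_id: str
    rel_quantity: float


def fit_standard_curve(log10_conc, cq) -> StandardCurve:
    """Least-squares standard curve with efficiency derived from the slope.

    Requires at least two distinct concentrations and a negative fitted slope
    (Cq must fall as template rises); a positive slope indicates an inverted
    dilution series and raises.
    """
    x = np.asarray(log10_conc, dtype=float)
    y = np.asarray(cq, dtype=float)
    if x.size != y.size or x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need >= 2 points at >= 2 distinct concentrations")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"fitted slope {fit.slope:.4g} is non-negative: inverted dilution series?"
        )
    amp = 10.0 ** (-1.0 / fit.slope)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        amp_factor=float(amp),
        efficiency_pct=(float(amp) - 1.0) * 100.0,
    )


def _quantity(amp_factor: float, cq: float) -> float:
    # relative quantity up to a shared scale; smaller Cq = more template
    return amp_factor ** (-cq)


def normalize_expression(
    sample: ExpressionSample,
    target_curve: StandardCurve,
    ref_curves: Sequence[StandardCurve],
) -> NormalizedExpression | None:
    """Efficiency-corrected target quantity over the geometric mean of the
    reference-gene quantities. Samples with any missing Cq are excluded
    (returned as None) with a warning."""
    if len(ref_curves) != len(sample.cq_refs):
        raise ValueError("one reference curve per reference Cq is required")
    cqs = (sample.cq_target, *sample.cq_refs)
    if any(c is None or not math.isfinite(c) for c in cqs):
        warnings.warn(
            f"sample {sample.sample_id}: missing Cq value, excluded", stacklevel=2
        )
        return None
    q_target = _quantity(target_curve.amp_factor, sample.cq_target)
    q_refs = [_quantity(c.amp_factor, cq) for c, cq in zip(ref_curves, sample.cq_refs)]
    gmean = math.exp(sum(math.log(q) for q in q_refs) / len(q_refs))
    return NormalizedExpression(sample.sample_id, q_target / gmean)


def normalize_cohort(
    cohort: pd.DataFrame,
    target_curve: StandardCurve,
    ref_curves: Sequence[StandardCurve],
) -> pd.DataFrame:
    """Vectorized normalization of a cohort table.

    Expects columns cq_target and cq_ref1..cq_refK (K = len(ref_curves));
    rows with any missing Cq are dropped with a warning. Returns the input
    columns plus ``rel_quantity``.
    """
    ref_cols = [f"cq_ref{i + 1}" for i in range(len(ref_curves))]
    cq_cols = ["cq_target", *ref_cols]
    ok = cohort[cq_cols].notna().all(axis=1)
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} sample(s) dropped for missing Cq", stacklevel=2
        )
    kept = cohort[ok].copy()
    q_target = target_curve.amp_factor ** (-kept["cq_target"].to_numpy(float))
    log_refs = [
        -kept[col].to_numpy(float) * math.log(curve.amp_factor)
        for col, curve in zip(ref_cols, ref_curves)
    ]
    gmean = np.exp(np.mean(log_refs, axis=0))
    kept["rel_quantity"] = q_target / gmean
    return kept.reset_index(drop=True)


@dataclass(frozen=True)
class DunnComparison:
    group_a: str
    group_b: str
    z: float
    pvalue: float  # two-sided, unadjusted
    adjusted_p: float  # Bonferroni over all pairs


@dataclass(frozen=True)
class GroupComparison:
    h: float
    pvalue: float
    n_groups: int
    pairwise: tuple[DunnComparison, ...]


def group_comparison(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise post-hoc tests.

    Dunn z statistics compare mean ranks over the pooled sample with the
    usual tie correction; pairwise p-values are two-sided normal and
    Bonferroni-adjusted over all pairs. With every observation identical the
    test is vacuous: H = 0, p = 1.
    """
    names = [g for g in groups if len(groups[g]) > 0]
    if len(names) < 2:
        raise ValueError("group_comparison needs >= 2 non-empty groups")
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n_total = pooled.size

    if np.all(pooled == pooled[0]):
        pairwise = tuple(
            DunnComparison(a, b, 0.0, 1.0, 1.0) for a, b in combinations(names, 2)
        )
        return GroupComparison(0.0, 1.0, len(names), pairwise)

    h, p = stats.kruskal(*values)

    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [v.size for v in values])
    mean_ranks = {
        g: ranks[offsets[i] : offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(combinations(range(len(names)), 2))
    pairwise = []
    for i, j in pairs:
        se = math.sqrt(var_base * (1.0 / values[i].size + 1.0 / values[j].size))
        z = (mean_ranks[names[i]] - mean_ranks[names[j]]) / se if se > 0 else 0.0
        p_un = 2.0 * stats.norm.sf(abs(z))
        pairwise.append(
            DunnComparison(
                names[i], names[j], float(z), float(p_un),
                min(1.0, float(p_un) * len(pairs)),
            )
        )
    return GroupComparison(float(h), float(p), len(names), tuple(pairwise))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    pvalue: float
    n: int
    note: str | None = None


def genotype_expression_correlation(
    genotype,
    rel_quantity,
    tissue: Sequence[str] | None = None,
) -> dict[str, CorrelationResult]:
    """Tie-corrected Spearman correlation of risk-allele count vs expression.

    Returns results keyed ``"all"`` plus one entry per tissue when a tissue
    vector is supplied. Samples with missing genotype are dropped; fewer than
    3 usable samples raise; a subgroup with constant genotype (or constant
    expression) has an undefined rank correlation and is reported with
    rho = NaN and an explanatory note.
    """
    g = np.asarray(genotype, dtype=float)
    x = np.asarray(rel_quantity, dtype=float)
    if g.size != x.size:
        raise ValueError("genotype and rel_quantity lengths differ")
    ok = np.isfinite(g) & np.isfinite(x)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 samples with non-missing genotype, got {int(ok.sum())}")

    def one(mask) -> CorrelationResult:
        gg, xx = g[mask], x[mask]
        n = int(mask.sum())
        if n < 3:
            return CorrelationResult(math.nan, math.nan, n, "fewer than 3 samples")
        if np.unique(gg).size < 2:
            return CorrelationResult(math.nan, math.nan, n, "all genotypes identical")
        if np.unique(xx).size < 2:
            return CorrelationResult(math.nan, math.nan, n, "all expression values identical")
        rho, p = stats.spearmanr(gg, xx)
        return CorrelationResult(float(rho), float(p), n)

    out = {"all": one(ok)}
    if tissue is not None:
        tissue = np.asarray(tissue)
        for t in pd.unique(tissue):
            out[str(t)] = one(ok & (tissue == t))
    return out
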