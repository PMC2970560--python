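"""Per-SNP QC and directionally constrained case-control association testing.

The design replicates a candidate-panel replication study: for each marker the
risk allele and its effect direction are fixed in advance by the reference
disease (here, Crohn's disease), and association in the replication cohort is
assessed with a one-sided Fisher exact test on 2N allele counts — the rejection
region only contains tables where the established risk allele is over-
represented in cases. An effect in the opposite direction therefore yields a
large p-value by construction; there is no folding or two-sided fallback.

Quality control mirrors standard genotyping practice: per-sample and per-marker
call-rate filtering, and an exact Hardy-Weinberg test in controls (departure in
controls flags genotyping artefacts, not association).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "MISSING",
    "MarkerRecord",
    "AlleleTable",
    "AssociationResult",
    "QCReport",
    "build_allele_table",
    "one_sided_fisher",
    "one_sided_fisher_counts",
    "bonferroni_adjust",
    "hwe_exact_test",
    "call_rate_filter",
    "run_panel",
    "results_to_frame",
]

#: Symbol marking a missing allele call in genotype tables.
MISSING = "."


@dataclass(frozen=True)
class MarkerRecord:
    """A panel SNP with its reference-disease risk allele.

    Parameters
    ----------
    snp_id : str
        Marker identifier (rsID or synthetic id).
    chrom : str
        Chromosome label.
    pos : int
        1-based base position.
    risk_allele : str
        Allele over-represented in the reference disease; fixes the direction
        of the one-sided test.
    other_allele : str
        The alternative allele.
    established : bool
        True for loci already known to affect the replication disease (e.g.
        MHC, IL23R); these are reported with nominal p only and excluded from
        the family-wise correction over "new" tests.
    """

    snp_id: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    established: bool = False

    def __post_init__(self) -> None:
        if self.risk_allele == self.other_allele:
            raise ValueError(
                f"{self.snp_id}: risk and other allele must differ "
                f"(both {self.risk_allele!r})"
            )
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class AlleleTable:
    """2x2 allele-count table (case/control x risk/other), on the 2N scale."""

    case_risk: int
    case_other: int
    ctrl_risk: int
    ctrl_other: int

    def __post_init__(self) -> None:
        counts = (self.case_risk, self.case_other, self.ctrl_risk, self.ctrl_other)
        if any(c < 0 for c in counts):
            raise ValueError(f"allele counts must be non-negative, got {counts}")
        if sum(counts) == 0:
            raise ValueError("allele table is empty (all counts zero)")

    @property
    def total(self) -> int:
        return self.case_risk + self.case_other + self.ctrl_risk + self.ctrl_other

    @property
    def case_total(self) -> int:
        return self.case_risk + self.case_other

    @property
    def risk_total(self) -> int:
        return self.case_risk + self.ctrl_risk

    def case_risk_frequency(self) -> float:
        return self.case_risk / self.case_total if self.case_total else math.nan

    def ctrl_risk_frequency(self) -> float:
        n = self.ctrl_risk + self.ctrl_other
        return self.ctrl_risk / n if n else math.nan


@dataclass(frozen=True)
class AssociationResult:
    """Per-SNP output of the directional association pipeline."""

    snp_id: str
    nominal_p: float
    adjusted_p: float  # NaN for established loci (outside the corrected family)
    n_tests: int
    direction: int  # +1: risk allele enriched in cases; -1: depleted
    call_rate_case: float
    call_rate_ctrl: float
    hwe_p_ctrl: float
    established: bool = False
    table: AlleleTable | None = field(default=None, compare=False)


def build_allele_table(
    case_genotypes: Iterable[tuple[str, str]],
    ctrl_genotypes: Iterable[tuple[str, str]],
    marker: MarkerRecord,
) -> AlleleTable:
    """Count risk/other alleles by arm from unordered allele-pair genotypes.

    A genotype with any missing allele (``"."``) is dropped entirely (pairwise
    deletion); each fully called genotype contributes two allele counts. Any
    allele symbol outside ``{risk_allele, other_allele}`` raises, naming the
    SNP and the offending symbol.
    """
    counts = {"case": [0, 0], "ctrl": [0, 0]}
    for arm, genotypes in (("case", case_genotypes), ("ctrl", ctrl_genotypes)):
        for a1, a2 in genotypes:
            if a1 == MISSING or a2 == MISSING:
                continue
            for allele in (a1, a2):
                if allele == marker.risk_allele:
                    counts[arm][0] += 1
                elif allele == marker.other_allele:
                    counts[arm][1] += 1
                else:
                    raise ValueError(
                        f"{marker.snp_id}: allele {allele!r} is neither risk "
                        f"({marker.risk_allele!r}) nor other "
                        f"({marker.other_allele!r})"
                    )
    return AlleleTable(
        case_risk=counts["case"][0],
        case_other=counts["case"][1],
        ctrl_risk=counts["ctrl"][0],
        ctrl_other=counts["ctrl"][1],
    )


def one_sided_fisher_counts(case_risk, case_other, ctrl_risk, ctrl_other):
    """Vectorized one-sided Fisher exact p: P(X >= case_risk) given margins.

    X is hypergeometric with population size N = all alleles, K = total risk
    alleles, and draw size n = case alleles. Accepts scalars or arrays.
    """
    case_risk = np.asarray(case_risk)
    n_total = case_risk + case_other + ctrl_risk + ctrl_other
    n_risk = case_risk + ctrl_risk
    n_case = case_risk + case_other
    # sf(k) = P(X > k), so P(X >= x) = sf(x - 1)
    p = hypergeom.sf(case_risk - 1, n_total, n_risk, n_case)
    return np.clip(p, 0.0, 1.0)


def one_sided_fisher(table: AlleleTable, mid_p: bool = False) -> float:
    """One-sided Fisher exact test in the pre-specified risk direction.

    Returns the hypergeometric tail probability ``P(X >= case_risk)`` with all
    margins fixed — one-sided in the direction "risk allele enriched in
    cases". The observed table is included in the tail (the standard exact
    convention); ``mid_p=True`` subtracts half the observed-table probability
    instead.

    A degenerate table (a zero row or column margin) carries no directional
    information: the function warns and returns p = 1.0.
    """
    margins = (
        table.case_total,
        table.ctrl_risk + table.ctrl_other,
        table.risk_total,
        table.case_other + table.ctrl_other,
    )
    if min(margins) == 0:
        warnings.warn(
            f"degenerate 2x2 table (zero margin): {table}; returning p = 1.0",
            stacklevel=2,
        )
        return 1.0
    p = float(
        one_sided_fisher_counts(
            table.case_risk, table.case_other, table.ctrl_risk, table.ctrl_other
        )
    )
    if mid_p:
        p -= 0.5 * float(
            hypergeom.pmf(table.case_risk, table.total, table.risk_total, table.case_total)
        )
    return min(max(p, 0.0), 1.0)


def bonferroni_adjust(p: float, n_tests: int) -> float:
    """Family-wise adjusted p-value min(1, p * n_tests)."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return min(1.0, p * n_tests)


def hwe_exact_test(n_hom_risk: int, n_het: int, n_hom_other: int) -> float:
    """Exact Hardy-Weinberg test conditional on the observed allele counts.

    Enumerates every heterozygote count compatible with the allele totals
    (parity-constrained) and sums the conditional probabilities of all
    configurations no more probable than the observed one. Monomorphic
    markers have a single configuration and return p = 1.
    """
    counts = (n_hom_risk, n_het, n_hom_other)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_hom_risk + n_het  # copies of one allele
    n_b = 2 * n_hom_other + n_het
    n_minor = min(n_a, n_b)
    if n_minor == 0:
        return 1.0

    # log P(het = h | n, allele counts) up to the common constant
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_minor = (n_minor - hets) // 2
    homs_major = (max(n_a, n_b) - hets) // 2
    lgamma = np.vectorize(math.lgamma)
    log_w = (
        hets * math.log(2.0)
        - lgamma(hets + 1.0)
        - lgamma(homs_minor + 1.0)
        - lgamma(homs_major + 1.0)
    )
    log_w -= log_w.max()
    prob = np.exp(log_w)
    prob /= prob.sum()
    p_obs = prob[np.searchsorted(hets, n_het)]
    # 1e-12 relative slack absorbs float noise in probability ties
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-12)].sum()))


@dataclass
class QCReport:
    """Outcome of call-rate filtering: retained rows plus exclusion lists."""

    retained: pd.DataFrame
    excluded_samples: pd.DataFrame  # columns: sample_id, call_rate
    excluded_markers: pd.DataFrame  # columns: snp_id, call_rate
    threshold: float

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_samples) + len(self.excluded_markers)


def _missing_mask(table: pd.DataFrame) -> pd.Series:
    return (table["allele1"] == MISSING) | (table["allele2"] == MISSING)


def call_rate_filter(genotypes: pd.DataFrame, threshold: float = 0.97) -> QCReport:
    """Drop samples, then markers, whose fraction of called genotypes is below
    ``threshold``.

    ``genotypes`` is a long table with columns sample_id, snp_id, allele1,
    allele2 ("." = missing). Samples are filtered on their call rate across
    markers first; marker call rates are then computed over the retained
    samples. An empty result is permitted (with a warning).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    called = ~_missing_mask(genotypes)
    sample_rate = called.groupby(genotypes["sample_id"]).mean()
    bad_samples = sample_rate[sample_rate < threshold]
    kept = genotypes[~genotypes["sample_id"].isin(bad_samples.index)]

    called_kept = ~_missing_mask(kept)
    marker_rate = called_kept.groupby(kept["snp_id"]).mean()
    bad_markers = marker_rate[marker_rate < threshold]
    kept = kept[~kept["snp_id"].isin(bad_markers.index)]

    if kept.empty:
        warnings.warn("call-rate filter removed every genotype record", stacklevel=2)
    return QCReport(
        retained=kept.reset_index(drop=True),
        excluded_samples=bad_samples.rename("call_rate").reset_index(),
        excluded_markers=bad_markers.rename("call_rate").reset_index(),
        threshold=threshold,
    )


def _genotype_counts(rows: pd.DataFrame, marker: MarkerRecord) -> tuple[int, int, int]:
    """(hom risk, het, hom other) from long-format rows of one marker."""
    a1, a2 = rows["allele1"], rows["allele2"]
    called = (a1 != MISSING) & (a2 != MISSING)
    dosage = (a1 == marker.risk_allele).astype(int) + (a2 == marker.risk_allele).astype(int)
    dosage = dosage[called]
    return int((dosage == 2).sum()), int((dosage == 1).sum()), int((dosage == 0).sum())


def run_panel(
    case_table: pd.DataFrame,
    ctrl_table: pd.DataFrame,
    markers: Sequence[MarkerRecord],
    n_tests: int | None = None,
    call_rate_threshold: float = 0.97,
    mid_p: bool = False,
) -> list[AssociationResult]:
    """Run QC and the directional association test over a marker panel.

    Established markers (known loci) get a nominal p only; the Bonferroni
    family defaults to the non-established markers. Markers listed in the
    panel but absent from either genotype table raise with the missing ids.
    """
    marker_ids = [m.snp_id for m in markers]
    for name, table in (("case", case_table), ("control", ctrl_table)):
        missing = sorted(set(marker_ids) - set(table["snp_id"].unique()))
        if missing:
            raise ValueError(
                f"markers absent from {name} genotypes: {', '.join(missing)}"
            )

    case_qc = call_rate_filter(case_table, call_rate_threshold)
    ctrl_qc = call_rate_filter(ctrl_table, call_rate_threshold)
    cases, ctrls = case_qc.retained, ctrl_qc.retained

    if n_tests is None:
        n_tests = sum(not m.established for m in markers)

    results: list[AssociationResult] = []
    case_by_snp = dict(tuple(cases.groupby("snp_id")))
    ctrl_by_snp = dict(tuple(ctrls.groupby("snp_id")))
    for marker in markers:
        crows = case_by_snp.get(marker.snp_id, cases.iloc[0:0])
        krows = ctrl_by_snp.get(marker.snp_id, ctrls.iloc[0:0])
        table = build_allele_table(
            zip(crows["allele1"], crows["allele2"]),
            zip(krows["allele1"], krows["allele2"]),
            marker,
        )
        p = one_sided_fisher(table, mid_p=mid_p)
        direction = 1 if table.case_risk_frequency() >= table.ctrl_risk_frequency() else -1
        adj = math.nan if marker.established else bonferroni_adjust(p, n_tests)
        results.append(
            AssociationResult(
                snp_id=marker.snp_id,
                nominal_p=p,
                adjusted_p=adj,
                n_tests=n_tests,
                direction=direction,
                call_rate_case=float((~_missing_mask(crows)).mean()) if len(crows) else math.nan,
                call_rate_ctrl=float((~_missing_mask(krows)).mean()) if len(krows) else math.nan,
                hwe_p_ctrl=hwe_exact_test(*_genotype_counts(krows, marker)),
                established=marker.established,
                table=table,
            )
        )
    return results


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten AssociationResults (with allele counts) into a DataFrame."""
    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "snp_id": r.snp_id,
                "case_risk": t.case_risk if t else math.nan,
                "case_other": t.case_other if t else math.nan,
                "ctrl_risk": t.ctrl_risk if t else math.nan,
                "ctrl_other": t.ctrl_other if t else math.nan,
                "nominal_p": r.nominal_p,
                "adjusted_p": r.adjusted_p,
                "direction": r.direction,
                "hwe_p_ctrl": r.hwe_p_ctrl,
                "call_rate_case": r.call_rate_case,
                "call_rate_ctrl": r.call_rate_ctrl,
                "established": r.established,
            }
        )
    return pd.DataFrame(rows)
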