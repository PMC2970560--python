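"""Synthetic genotype panels, p-value panels, and qPCR expression cohorts.

Every generator takes an explicit seed and draws from a single
``numpy.random.Generator`` created inside the call — identical seeds give
bit-identical output and there is no hidden global state. The generators
emulate the statistical structure the downstream analysis assumes:

* case-control genotypes in Hardy-Weinberg equilibrium, with a multiplicative
  allelic odds-ratio shifting the risk-allele frequency in cases;
* a p-value panel that is a mixture of exact Uniform(0,1) nulls and
  power-function alternatives enriched at small values;
* Cq-level qPCR data (target + three reference genes) carrying an additive
  per-allele eQTL effect on log expression;
* a dilution series for standard-curve fitting.

None of the generators model linkage disequilibrium or population structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import MarkerRecord

__all__ = [
    "PanelSpec",
    "PValuePanelSpec",
    "ExpressionCohortSpec",
    "GenotypePanel",
    "simulate_case_control_genotypes",
    "simulate_pvalue_panel",
    "simulate_expression_cohort",
    "simulate_standard_curve",
    "case_allele_frequency",
]

GROUPS = ("control", "CD", "UC", "AS")
TISSUES = ("colon", "ileum")


def _broadcast(values, n: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.size == 1:
        arr = np.full(n, arr[0])
    if arr.size != n:
        raise ValueError(f"{name} must be scalar or length {n}, got {arr.size}")
    return arr


@dataclass(frozen=True)
class PanelSpec:
    """Design of a simulated case-control genotype panel.

    ``maf`` is the control (population) risk-allele frequency in (0, 0.5];
    ``odds_ratio`` the allelic odds ratio (> 0, 1.0 = null). Both may be
    scalars or per-SNP sequences of length ``n_snps``.
    """

    n_snps: int
    n_cases: int
    n_controls: int
    maf: float | Sequence[float] = 0.3
    odds_ratio: float | Sequence[float] = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError(f"n_snps must be >= 1, got {self.n_snps}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        maf = _broadcast(self.maf, self.n_snps, "maf")
        if np.any((maf <= 0.0) | (maf > 0.5)):
            raise ValueError(f"every maf must lie in (0, 0.5], got {self.maf}")
        orr = _broadcast(self.odds_ratio, self.n_snps, "odds_ratio")
        if np.any(orr <= 0.0):
            raise ValueError(f"every odds_ratio must be > 0, got {self.odds_ratio}")

    @property
    def maf_array(self) -> np.ndarray:
        return _broadcast(self.maf, self.n_snps, "maf")

    @property
    def or_array(self) -> np.ndarray:
        return _broadcast(self.odds_ratio, self.n_snps, "odds_ratio")


def case_allele_frequency(maf: float, odds_ratio: float) -> float:
    """Risk-allele frequency in cases under a multiplicative allelic OR.

    Solves OR = [p/(1-p)] / [f/(1-f)] for p given the control frequency f:
    p = OR*f / (1 - f + OR*f).
    """
    return odds_ratio * maf / (1.0 - maf + odds_ratio * maf)


@dataclass(frozen=True)
class GenotypePanel:
    """Simulated panel: markers plus risk-allele dosage matrices (0/1/2)."""

    markers: tuple[MarkerRecord, ...]
    case_dosage: np.ndarray  # (n_cases, n_snps)
    control_dosage: np.ndarray  # (n_controls, n_snps)

    def allele_counts(self) -> pd.DataFrame:
        """Per-SNP 2N risk/other allele counts for both arms."""
        case_risk = self.case_dosage.sum(axis=0)
        ctrl_risk = self.control_dosage.sum(axis=0)
        return pd.DataFrame(
            {
                "snp_id": [m.snp_id for m in self.markers],
                "case_risk": case_risk,
                "case_other": 2 * self.case_dosage.shape[0] - case_risk,
                "ctrl_risk": ctrl_risk,
                "ctrl_other": 2 * self.control_dosage.shape[0] - ctrl_risk,
            }
        )

    def to_long(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Expand to the long genotype dialect (one row per sample x SNP)."""
        frames = []
        for arm, dosage in (("case", self.case_dosage), ("control", self.control_dosage)):
            n_samples, n_snps = dosage.shape
            sample_ids = np.repeat(
                [f"{arm}{i + 1}" for i in range(n_samples)], n_snps
            )
            snp_ids = np.tile([m.snp_id for m in self.markers], n_samples)
            risk = np.array([m.risk_allele for m in self.markers])
            other = np.array([m.other_allele for m in self.markers])
            d = dosage.ravel()
            a1 = np.where(d >= 1, np.tile(risk, n_samples), np.tile(other, n_samples))
            a2 = np.where(d == 2, np.tile(risk, n_samples), np.tile(other, n_samples))
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_ids,
                        "arm": arm,
                        "snp_id": snp_ids,
                        "allele1": a1,
                        "allele2": a2,
                    }
                )
            )
        return frames[0], frames[1]


def simulate_case_control_genotypes(
    spec: PanelSpec, n_established: int = 0
) -> GenotypePanel:
    """Draw case and control genotypes under HWE with a per-SNP allelic OR.

    Controls are Binomial(2, maf) risk-allele dosages; cases are Binomial(2,
    p_case) with p_case from :func:`case_allele_frequency`. The first
    ``n_established`` markers are flagged as established loci.
    """
    rng = np.random.default_rng(spec.seed)
    maf, orr = spec.maf_array, spec.or_array
    p_case = case_allele_frequency(maf, orr)
    control = rng.binomial(2, maf, size=(spec.n_controls, spec.n_snps))
    case = rng.binomial(2, p_case, size=(spec.n_cases, spec.n_snps))
    markers = tuple(
        MarkerRecord(
            snp_id=f"snp{i + 1}",
            chrom="1",
            pos=1000 * (i + 1),
            risk_allele="A",
            other_allele="G",
            established=i < n_established,
        )
        for i in range(spec.n_snps)
    )
    return GenotypePanel(markers=markers, case_dosage=case, control_dosage=control)


@dataclass(frozen=True)
class PValuePanelSpec:
    """Mixture panel of m p-values: ``n_alt`` power-function alternatives
    (CDF p**alt_shape, enriched at small p for alt_shape < 1) among exact
    Uniform(0,1) nulls."""

    m: int
    n_alt: int = 0
    alt_shape: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not 0 <= self.n_alt <= self.m:
            raise ValueError(f"n_alt must be in [0, m={self.m}], got {self.n_alt}")
        if not 0.0 < self.alt_shape <= 1.0:
            raise ValueError(f"alt_shape must be in (0, 1], got {self.alt_shape}")


def simulate_pvalue_panel(spec: PValuePanelSpec) -> pd.DataFrame:
    """Draw the p-value panel; returns columns snp_id, p, is_alt.

    Alternatives are U**(1/alt_shape) draws (power-function law); with
    alt_shape = 1 they degenerate to uniform. Row order is shuffled so
    alternatives are not positionally identifiable.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.m)
    p = u.copy()
    p[: spec.n_alt] = u[: spec.n_alt] ** (1.0 / spec.alt_shape)
    is_alt = np.zeros(spec.m, dtype=bool)
    is_alt[: spec.n_alt] = True
    order = rng.permutation(spec.m)
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1}" for i in range(spec.m)],
            "p": p[order],
            "is_alt": is_alt[order],
        }
    )


@dataclass(frozen=True)
class ExpressionCohortSpec:
    """Design of a simulated qPCR expression cohort.

    Per sample: genotype ~ HWE(genotype_maf); log expression of the target is
    a group baseline plus ``eqtl_beta`` per risk allele plus N(0, 0.25²)
    biological noise; Cq values for the target and three constant reference
    genes are back-computed assuming 100% amplification efficiency (one Cq
    per doubling) and jittered with N(0, cq_noise_sd²) technical noise.
    ``group_effects`` (natural-log scale) defaults to no group differences.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"control": 21, "CD": 39, "UC": 10, "AS": 14}
    )
    eqtl_beta: float = 0.0
    genotype_maf: float = 0.35
    cq_noise_sd: float = 0.15
    seed: int = 0
    group_effects: Mapping[str, float] | None = None
    biological_sd: float = 0.25
    missing_genotype_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError(f"group sizes must be >= 0, got {dict(self.group_sizes)}")
        if self.cq_noise_sd < 0:
            raise ValueError(f"cq_noise_sd must be >= 0, got {self.cq_noise_sd}")
        if self.biological_sd < 0:
            raise ValueError(f"biological_sd must be >= 0, got {self.biological_sd}")
        if not 0.0 < self.genotype_maf < 1.0:
            raise ValueError(f"genotype_maf must be in (0, 1), got {self.genotype_maf}")
        if not 0.0 <= self.missing_genotype_rate <= 1.0:
            raise ValueError("missing_genotype_rate must be in [0, 1]")


# Cq intercepts at unit relative quantity; values in a realistic biopsy range.
_TARGET_CQ0 = 26.0
_REF_CQ0 = (19.0, 21.5, 23.0)
_LOG2E = float(np.log2(np.e))


def simulate_expression_cohort(spec: ExpressionCohortSpec) -> pd.DataFrame:
    """Draw an expression cohort; one row per sample.

    Columns: sample_id, group, tissue, genotype (0/1/2 risk-allele count,
    NaN when masked missing), cq_target, cq_ref1..cq_ref3.
    """
    rng = np.random.default_rng(spec.seed)
    effects = dict(spec.group_effects or {})
    rows_group, rows_n = zip(*[(g, n) for g, n in spec.group_sizes.items() if n > 0]) if any(
        n > 0 for n in spec.group_sizes.values()
    ) else ((), ())
    groups = np.repeat(rows_group, rows_n) if rows_group else np.array([], dtype=object)
    n = groups.size
    genotype = rng.binomial(2, spec.genotype_maf, size=n).astype(float)
    tissue = rng.choice(TISSUES, size=n, p=[0.6, 0.4])
    baseline = np.array([effects.get(g, 0.0) for g in groups])
    log_expr = (
        baseline
        + spec.eqtl_beta * genotype
        + rng.normal(0.0, spec.biological_sd, size=n)
    )
    # one PCR cycle per doubling of template: Cq drops by log2(e) per ln-unit
    cq_target = _TARGET_CQ0 - _LOG2E * log_expr + rng.normal(0.0, spec.cq_noise_sd, n)
    refs = {
        f"cq_ref{j + 1}": _REF_CQ0[j] + rng.normal(0.0, spec.cq_noise_sd, n)
        for j in range(3)
    }
    if spec.missing_genotype_rate > 0:
        genotype[rng.random(n) < spec.missing_genotype_rate] = np.nan
    return pd.DataFrame(
        {
            "sample_id": [f"s{i + 1}" for i in range(n)],
            "group": groups,
            "tissue": tissue,
            "genotype": genotype,
            "cq_target": cq_target,
            **refs,
        }
    )


def simulate_standard_curve(
    slope: float,
    intercept: float = 38.0,
    n_points: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dilution series (log10 concentration, Cq) on a line plus Cq noise.

    ``slope`` is Cq per log10 dilution and must be negative (Cq falls as
    template rises); points sit at log10 concentrations 0, -1, ..., -(n-1).
    """
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    log10_conc = -np.arange(n_points, dtype=float)
    cq = intercept + slope * log10_conc + rng.normal(0.0, noise_sd, n_points)
    return pd.DataFrame({"log10_conc": log10_conc, "cq": cq})
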