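"""Combined p-value evidence by Monte Carlo, with a rank-truncation scan.

A panel of m association tests may carry real signal even when no single test
survives family-wise correction. The combined statistic

    S = sum_i ln(1 / p_i)

is large when the p-value distribution is skewed toward small values. Under m
independent uniform nulls, each ln(1/p) is Exp(1), so S ~ Gamma(m, 1) and
2S ~ chi-squared with 2m degrees of freedom — Fisher's combination test. The
significance of an observed S is assessed empirically against null statistics
simulated from uniform draws (default 10,000), with the closed-form Gamma tail
available as a cross-check.

The sequential truncation scan then asks *how many* tests carry signal: drop
the smallest p-value, recombine the remainder, and repeat. The step at which
the remaining distribution stops being significantly skewed bounds the number
of likely true alternatives from below.

The statistic is computed in nats. The empirical Monte Carlo p is invariant to
the log base (observed and null statistics scale together); only the
closed-form Gamma tail fixes the base.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma

__all__ = [
    "EvidenceResult",
    "ScanStep",
    "ScanResult",
    "combined_statistic",
    "monte_carlo_null",
    "exceedance_pvalue",
    "empirical_p",
    "closed_form_p",
    "combined_evidence",
    "sequential_scan",
    "figure_series",
]


@dataclass(frozen=True)
class EvidenceResult:
    """Combined evidence for one panel of p-values.

    ``empirical_p`` is the exceedance fraction n_exceed / n_sims (ties count
    as exceedance); ``closed_form_p`` the Gamma(m, 1) upper tail at S.
    """

    m: int
    statistic: float
    n_sims: int
    n_exceed: int
    empirical_p: float
    closed_form_p: float
    seed: int | None = None


@dataclass(frozen=True)
class ScanStep:
    step: int
    dropped_snp_id: str | None  # None at step 0
    remaining_m: int
    result: EvidenceResult


@dataclass(frozen=True)
class ScanResult:
    steps: tuple[ScanStep, ...]
    drop_order: tuple[str, ...]  # snp ids by ascending nominal p, stable ties

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [s.step for s in self.steps],
                "dropped_snp": [s.dropped_snp_id or "" for s in self.steps],
                "m": [s.remaining_m for s in self.steps],
                "statistic": [s.result.statistic for s in self.steps],
                "n_exceed": [s.result.n_exceed for s in self.steps],
                "empirical_p": [s.result.empirical_p for s in self.steps],
                "closed_form_p": [s.result.closed_form_p for s in self.steps],
            }
        )


def _validated_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("every p-value must lie in (0, 1]")
    return p


def combined_statistic(pvals) -> float:
    """S = sum of ln(1/p_i), in nats; 0 iff every p equals 1."""
    p = _validated_pvals(pvals)
    return float(-np.log(p).sum())


def monte_carlo_null(
    m: int, n_sims: int = 10_000, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate ``n_sims`` null statistics, each sum of m ln(1/r) terms with
    r ~ Uniform(0, 1)."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    if rng is None:
        rng = np.random.default_rng(seed)
    # 1 - random() lies in (0, 1], keeping every log finite
    return -np.log1p(-rng.random((n_sims, m))).sum(axis=1)


def exceedance_pvalue(n_exceed: int, n_sims: int, add_one: bool = False) -> float:
    """Monte Carlo p estimate from an exceedance count.

    Default is the plain ratio n_exceed / n_sims; ``add_one=True`` gives the
    (n+1)/(N+1) estimator that never returns zero.
    """
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    if not 0 <= n_exceed <= n_sims:
        raise ValueError(f"n_exceed must be in [0, {n_sims}], got {n_exceed}")
    if add_one:
        return (n_exceed + 1) / (n_sims + 1)
    return n_exceed / n_sims


def empirical_p(
    statistic: float, null_stats: np.ndarray, add_one: bool = False
) -> tuple[int, float]:
    """Exceedance count and Monte Carlo p of ``statistic`` against null draws.

    Ties count as exceedance (a null that *reaches* the observed value is
    evidence against significance — the conservative convention). When no
    null reaches the statistic a warning notes that the true p is only
    bounded above by 1/n_sims.
    """
    null_stats = np.asarray(null_stats, dtype=float)
    if null_stats.size == 0:
        raise ValueError("null_stats must be non-empty")
    n_exceed = int((null_stats >= statistic).sum())
    if n_exceed == 0 and not add_one:
        warnings.warn(
            "no null statistic reached the observed value; the true p-value "
            f"is only bounded above by 1/n_sims = {1.0 / null_stats.size:.2e}",
            stacklevel=2,
        )
    return n_exceed, exceedance_pvalue(n_exceed, null_stats.size, add_one=add_one)


def closed_form_p(statistic: float, m: int) -> float:
    """Gamma(shape=m, scale=1) upper tail at S (Fisher's method: 2S ~ chi2_2m)."""
    if statistic < 0:
        raise ValueError(f"statistic must be >= 0, got {statistic}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return float(gamma.sf(statistic, a=m))


def combined_evidence(
    pvals,
    n_sims: int = 10_000,
    seed: int | None = None,
    add_one: bool = False,
    rng: np.random.Generator | None = None,
) -> EvidenceResult:
    """Combined statistic plus its Monte Carlo and closed-form p-values."""
    p = _validated_pvals(pvals)
    s = combined_statistic(p)
    nulls = monte_carlo_null(p.size, n_sims=n_sims, seed=seed, rng=rng)
    n_exceed, emp = empirical_p(s, nulls, add_one=add_one)
    return EvidenceResult(
        m=p.size,
        statistic=s,
        n_sims=n_sims,
        n_exceed=n_exceed,
        empirical_p=emp,
        closed_form_p=closed_form_p(s, p.size),
        seed=seed,
    )


def sequential_scan(
    pvals,
    snp_ids: Sequence[str] | None = None,
    n_sims: int = 10_000,
    seed: int = 0,
    add_one: bool = False,
) -> ScanResult:
    """Rank-truncation scan: drop the smallest p, recombine, repeat.

    Step 0 combines all m p-values; step k removes the k smallest (ties kept
    in stable input order) and recombines the remainder, down to two values.
    A fresh null is simulated at each step (m changes), with the step's seed
    derived deterministically from ``(seed, step)``. Step-k statistics follow
    by exact subtraction of ln(1/p_dropped) from the previous step.
    """
    p = _validated_pvals(pvals)
    if p.size < 2:
        raise ValueError(f"sequential_scan needs >= 2 p-values, got {p.size}")
    if snp_ids is None:
        snp_ids = [f"p{i + 1}" for i in range(p.size)]
    if len(snp_ids) != p.size:
        raise ValueError("snp_ids length must match pvals")

    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    drop_order = tuple(str(snp_ids[i]) for i in order)

    steps = []
    s = combined_statistic(p)
    for k in range(p.size - 1):
        if k > 0:
            s += math.log(p_sorted[k - 1])  # remove ln(1/p) of the dropped SNP
        m_k = p.size - k
        nulls = monte_carlo_null(m_k, n_sims=n_sims, rng=np.random.default_rng([seed, k]))
        n_exceed, emp = empirical_p(s, nulls, add_one=add_one)
        steps.append(
            ScanStep(
                step=k,
                dropped_snp_id=drop_order[k - 1] if k > 0 else None,
                remaining_m=m_k,
                result=EvidenceResult(
                    m=m_k,
                    statistic=s,
                    n_sims=n_sims,
                    n_exceed=n_exceed,
                    empirical_p=emp,
                    closed_form_p=closed_form_p(s, m_k),
                    seed=seed,
                ),
            )
        )
    return ScanResult(steps=tuple(steps), drop_order=drop_order)


def figure_series(
    pvals,
    n_tests: int,
    scan: ScanResult,
    snp_ids: Sequence[str] | None = None,
    alpha: float = 0.05,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """The four aligned display series, SNPs ordered by increasing p.

    Per rank i (1-based) on the log_base(1/p) scale: ``nominal`` for the
    observed p; ``bonferroni`` for min(1, p * n_tests); ``expected_null`` for
    the null order-statistic mean i/(m+1); and ``scan_p`` for the empirical p
    of the scan step whose subset starts at this SNP (the marker plus all
    less significant ones). A zero empirical p is displayed at its Monte
    Carlo bound 1/n_sims; the last rank has no scan step and is NaN. The
    DataFrame's ``attrs["alpha_line"]`` holds the log_base(1/alpha) reference.
    """
    p = _validated_pvals(pvals)
    if snp_ids is None:
        snp_ids = [f"p{i + 1}" for i in range(p.size)]
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    m = p.size
    logb = math.log(log_base)

    def inv_log(x):
        return -np.log(x) / logb

    scan_p = np.full(m, np.nan)
    for step in scan.steps:
        val = step.result.empirical_p
        if val == 0.0:
            val = 1.0 / step.result.n_sims  # display at the Monte Carlo bound
        scan_p[step.step] = inv_log(val)

    df = pd.DataFrame(
        {
            "rank": np.arange(1, m + 1),
            "snp_id": [str(snp_ids[i]) for i in order],
            "p": p_sorted,
            "nominal": inv_log(p_sorted),
            "bonferroni": inv_log(np.minimum(1.0, p_sorted * n_tests)),
            "expected_null": inv_log(np.arange(1, m + 1) / (m + 1)),
            "scan_p": scan_p,
        }
    )
    df.attrs["alpha_line"] = float(inv_log(np.array(alpha)))
    df.attrs["log_base"] = log_base
    return df


def plot_figure_series(series: pd.DataFrame, path=None):
    """Render the four series (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.plot(series["rank"], series["nominal"], "o-", color="gray", label="nominal")
    ax.plot(series["rank"], series["bonferroni"], "s-", color="tab:blue", label="Bonferroni")
    ax.plot(series["rank"], series["expected_null"], "-", color="black", label="expected null")
    ax.plot(series["rank"], series["scan_p"], "^-", color="tab:red", label="scan p")
    ax.axhline(series.attrs.get("alpha_line", math.log10(20)), ls="--", color="k", lw=0.8)
    base = series.attrs.get("log_base", 10)
    ax.set_xlabel("SNP rank (increasing p)")
    ax.set_ylabel(f"log{base:g}(1/p)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
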