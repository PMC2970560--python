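"""File formats, run configuration, and the end-to-end pipeline driver.

Formats are deliberately plain:

* genotype TSV (long): sample_id, arm (case|control), snp_id, allele1,
  allele2, with "." for a missing allele;
* minimal VCF v4.2 (GT only) as an alternative genotype carrier, with the
  sample-to-arm mapping supplied separately;
* marker TSV: snp_id, chrom, pos, risk_allele, other_allele, established;
* expression CSV (long): sample_id, group, tissue, gene, cq, genotype;
* standard-curve CSV: gene, log10_conc, cq.

Positions are 1-based. ``run_all`` composes the stages (load, qc,
association, scan, expression) deterministically from a master seed and
writes a JSON manifest sufficient to reproduce every output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    MISSING,
    MarkerRecord,
    call_rate_filter,
    results_to_frame,
    run_panel,
)
from .evidence import figure_series, sequential_scan
from .qpcr import (
    fit_standard_curve,
    genotype_expression_correlation,
    group_comparison,
    normalize_cohort,
)

__all__ = [
    "GENOTYPE_COLUMNS",
    "RunConfig",
    "StageError",
    "read_markers",
    "write_markers",
    "read_genotypes",
    "write_genotypes",
    "write_vcf",
    "read_expression",
    "write_expression",
    "read_standard_curves",
    "run_all",
]

logger = logging.getLogger("panelscan")

GENOTYPE_COLUMNS = ["sample_id", "arm", "snp_id", "allele1", "allele2"]
ARMS = ("case", "control")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# markers

def read_markers(path) -> list[MarkerRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"snp_id", "chrom", "pos", "risk_allele", "other_allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    est = df.get("established", pd.Series(["0"] * len(df)))
    return [
        MarkerRecord(
            snp_id=row.snp_id,
            chrom=row.chrom,
            pos=int(row.pos),
            risk_allele=row.risk_allele,
            other_allele=row.other_allele,
            established=str(e).strip().lower() in {"1", "true", "yes"},
        )
        for row, e in zip(df.itertuples(index=False), est)
    ]


def write_markers(markers: Sequence[MarkerRecord], path) -> None:
    pd.DataFrame(
        {
            "snp_id": [m.snp_id for m in markers],
            "chrom": [m.chrom for m in markers],
            "pos": [m.pos for m in markers],
            "risk_allele": [m.risk_allele for m in markers],
            "other_allele": [m.other_allele for m in markers],
            "established": [int(m.established) for m in markers],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes

def _validate_genotype_frame(
    df: pd.DataFrame, markers: Sequence[MarkerRecord] | None, origin: str
) -> None:
    # +2: header line plus 1-based numbering
    lines = df.index.to_numpy() + 2
    bad_arm = ~df["arm"].isin(ARMS)
    if bad_arm.any():
        ln = lines[bad_arm.to_numpy()][0]
        raise ValueError(f"{origin}:{ln}: arm must be one of {ARMS}")
    dup = df.duplicated(subset=["sample_id", "snp_id"], keep=False)
    if dup.any():
        ln = ", ".join(map(str, lines[dup.to_numpy()][:10]))
        raise ValueError(f"{origin}: duplicate (sample, snp) pairs at lines {ln}")
    if markers is not None:
        allowed = {m.snp_id: {m.risk_allele, m.other_allele, MISSING} for m in markers}
        unknown = ~df["snp_id"].isin(allowed)
        if unknown.any():
            i = int(np.flatnonzero(unknown.to_numpy())[0])
            raise ValueError(
                f"{origin}:{lines[i]}: unknown SNP id {df['snp_id'].iloc[i]!r}"
            )
        for col in ("allele1", "allele2"):
            ok = [
                a in allowed[s]
                for s, a in zip(df["snp_id"], df[col])
            ]
            bad = ~np.asarray(ok)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"{origin}:{lines[i]}: allele {df[col].iloc[i]!r} not valid "
                    f"for SNP {df['snp_id'].iloc[i]!r}"
                )


def read_genotypes(
    path,
    fmt: str | None = None,
    markers: Sequence[MarkerRecord] | None = None,
    sample_arms: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read genotypes as (case, control) long tables.

    ``fmt`` is "tsv" or "vcf" (inferred from the suffix when None). VCF
    input needs ``sample_arms`` (sample id -> case|control) and ``markers``
    to map REF/ALT onto the panel's risk/other symbols.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing_cols = set(GENOTYPE_COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
        _validate_genotype_frame(df, markers, str(path))
    elif fmt == "vcf":
        df = _read_vcf(path, sample_arms)
        _validate_genotype_frame(df, markers, str(path))
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    case = df[df["arm"] == "case"].drop(columns="arm").reset_index(drop=True)
    ctrl = df[df["arm"] == "control"].drop(columns="arm").reset_index(drop=True)
    return case, ctrl


def _read_vcf(path, sample_arms: Mapping[str, str] | None) -> pd.DataFrame:
    import pysam

    if sample_arms is None:
        raise ValueError("VCF input requires a sample_arms mapping")
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alleles = (rec.ref, *(rec.alts or ()))
            for sample, call in rec.samples.items():
                gt = call.get("GT", (None, None))
                decoded = [
                    MISSING if i is None else alleles[i] for i in (gt + (None,))[:2]
                ]
                arm = sample_arms.get(sample)
                if arm is None:
                    raise ValueError(f"{path}: sample {sample!r} has no arm mapping")
                rows.append((sample, arm, rec.id, decoded[0], decoded[1]))
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def write_genotypes(case: pd.DataFrame, ctrl: pd.DataFrame, path) -> None:
    """Write (case, control) long tables as one genotype TSV."""
    parts = []
    for arm, df in (("case", case), ("control", ctrl)):
        out = df.copy()
        if "arm" not in out.columns:
            out.insert(1, "arm", arm)
        parts.append(out[GENOTYPE_COLUMNS])
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_vcf(panel, path) -> None:
    """Write a GenotypePanel as a minimal VCF v4.2 (GT field only)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chroms = {m.chrom for m in panel.markers}
    for c in sorted(chroms):
        header.contigs.add(c)
    samples = [f"case{i + 1}" for i in range(panel.case_dosage.shape[0])] + [
        f"control{i + 1}" for i in range(panel.control_dosage.shape[0])
    ]
    for s in samples:
        header.add_sample(s)
    dosage = np.vstack([panel.case_dosage, panel.control_dosage])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, m in enumerate(panel.markers):
            rec = out.new_record(
                contig=m.chrom,
                start=m.pos - 1,  # pysam is 0-based; file stays 1-based
                alleles=(m.other_allele, m.risk_allele),
                id=m.snp_id,
            )
            for i, s in enumerate(samples):
                d = int(dosage[i, j])
                rec.samples[s]["GT"] = (1, 1) if d == 2 else ((0, 1) if d == 1 else (0, 0))
            out.write(rec)


def sample_arms_for_panel(panel) -> dict[str, str]:
    """The sample->arm mapping matching write_vcf's naming."""
    arms = {f"case{i + 1}": "case" for i in range(panel.case_dosage.shape[0])}
    arms.update(
        {f"control{i + 1}": "control" for i in range(panel.control_dosage.shape[0])}
    )
    return arms


# ---------------------------------------------------------------------------
# expression

def write_expression(cohort: pd.DataFrame, path, ref_genes=("ref1", "ref2", "ref3")) -> None:
    """Write a wide cohort table (cq_target, cq_ref*) as the long CSV dialect."""
    rows = []
    for row in cohort.itertuples(index=False):
        geno = getattr(row, "genotype", math.nan)
        geno = "" if geno is None or (isinstance(geno, float) and math.isnan(geno)) else int(geno)
        rows.append((row.sample_id, row.group, row.tissue, "target", row.cq_target, geno))
        for i, gene in enumerate(ref_genes):
            rows.append(
                (row.sample_id, row.group, row.tissue, gene,
                 getattr(row, f"cq_ref{i + 1}"), geno)
            )
    pd.DataFrame(
        rows, columns=["sample_id", "group", "tissue", "gene", "cq", "genotype"]
    ).to_csv(path, index=False)


def read_expression(
    path, target_gene: str = "target", ref_genes=("ref1", "ref2", "ref3")
) -> pd.DataFrame:
    """Read the long expression CSV back into the wide cohort layout."""
    df = pd.read_csv(path)
    required = {"sample_id", "group", "tissue", "gene", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    wide = df.pivot_table(index="sample_id", columns="gene", values="cq", aggfunc="first")
    genes = [target_gene, *ref_genes]
    absent = [g for g in genes if g not in wide.columns]
    if absent:
        raise ValueError(f"{path}: genes absent from table: {absent}")
    meta = df.drop_duplicates("sample_id").set_index("sample_id")
    out = pd.DataFrame(
        {
            "sample_id": wide.index,
            "group": meta.loc[wide.index, "group"].to_numpy(),
            "tissue": meta.loc[wide.index, "tissue"].to_numpy(),
            "genotype": pd.to_numeric(
                meta.loc[wide.index, "genotype"], errors="coerce"
            ).to_numpy()
            if "genotype" in meta.columns
            else np.nan,
            "cq_target": wide[target_gene].to_numpy(),
        }
    )
    for i, g in enumerate(ref_genes):
        out[f"cq_ref{i + 1}"] = wide[g].to_numpy()
    return out.reset_index(drop=True)


def read_standard_curves(path) -> dict[str, pd.DataFrame]:
    """Read the per-gene dilution series CSV (gene, log10_conc, cq)."""
    df = pd.read_csv(path)
    missing = {"gene", "log10_conc", "cq"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {str(g): sub[["log10_conc", "cq"]].reset_index(drop=True)
            for g, sub in df.groupby("gene")}


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    marker_path: str
    genotype_path: str
    out_dir: str
    genotype_format: str | None = None
    expression_path: str | None = None
    standard_curve_path: str | None = None
    target_gene: str = "target"
    reference_genes: tuple[str, ...] = ("ref1", "ref2", "ref3")
    n_sims: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    n_tests: int | None = None
    call_rate_threshold: float = 0.97

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError(f"n_sims must be >= 1, got {self.n_sims}")
        for name in ("alpha", "call_rate_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def run_all(config: RunConfig) -> dict:
    """Run every stage and write outputs plus a JSON manifest.

    Stages: load, qc, association, scan, expression. Any stage failure is
    re-raised as :class:`StageError` naming the stage. Given the same config
    and master seed the outputs are byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        def wrap(fn):
            logger.info("stage %s: start", name)
            try:
                counts = fn() or {}
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                raise StageError(name, exc) from exc
            manifest["stages"][name] = {"status": "completed", **counts}
            logger.info("stage %s: done %s", name, counts)
        return wrap

    state: dict = {}

    @stage("load")
    def _load():
        state["markers"] = read_markers(config.marker_path)
        arms = None
        fmt = config.genotype_format
        if fmt == "vcf" or str(config.genotype_path).endswith(".vcf"):
            arm_path = Path(str(config.genotype_path) + ".arms.tsv")
            if arm_path.exists():
                arm_df = pd.read_csv(arm_path, sep="\t", dtype=str)
                arms = dict(zip(arm_df["sample_id"], arm_df["arm"]))
        state["case"], state["ctrl"] = read_genotypes(
            config.genotype_path, fmt=fmt, markers=state["markers"], sample_arms=arms
        )
        if config.expression_path:
            state["expression"] = read_expression(
                config.expression_path, config.target_gene, config.reference_genes
            )
            state["curves"] = read_standard_curves(config.standard_curve_path)
        return {
            "n_markers": len(state["markers"]),
            "n_case_records": len(state["case"]),
            "n_ctrl_records": len(state["ctrl"]),
        }

    @stage("qc")
    def _qc():
        reports = {}
        for arm in ("case", "ctrl"):
            rep = call_rate_filter(state[arm], config.call_rate_threshold)
            reports[arm] = rep
            state[arm] = rep.retained
        return {
            "excluded_case_samples": len(reports["case"].excluded_samples),
            "excluded_ctrl_samples": len(reports["ctrl"].excluded_samples),
            "excluded_markers": len(reports["case"].excluded_markers)
            + len(reports["ctrl"].excluded_markers),
        }

    @stage("association")
    def _association():
        results = run_panel(
            state["case"],
            state["ctrl"],
            state["markers"],
            n_tests=config.n_tests,
            call_rate_threshold=0.0,  # qc stage already filtered
        )
        state["assoc"] = results
        frame = results_to_frame(results)
        path = out_dir / "association.tsv"
        frame.to_csv(path, sep="\t", index=False)
        manifest["outputs"]["association"] = str(path)
        return {
            "n_tested": len(results),
            "n_established": sum(r.established for r in results),
        }

    @stage("scan")
    def _scan():
        new = [r for r in state["assoc"] if not r.established]
        pvals = [r.nominal_p for r in new]
        ids = [r.snp_id for r in new]
        scan = sequential_scan(pvals, ids, n_sims=config.n_sims, seed=config.seed)
        state["scan"] = scan
        scan_path = out_dir / "scan.tsv"
        scan.to_frame().to_csv(scan_path, sep="\t", index=False)
        series = figure_series(
            pvals, n_tests=new[0].n_tests if new else 1, scan=scan,
            snp_ids=ids, alpha=config.alpha,
        )
        series_path = out_dir / "figure_series.tsv"
        series.to_csv(series_path, sep="\t", index=False)
        manifest["outputs"]["scan"] = str(scan_path)
        manifest["outputs"]["figure_series"] = str(series_path)
        return {
            "n_combined": len(pvals),
            "step0_empirical_p": scan.steps[0].result.empirical_p,
        }

    @stage("expression")
    def _expression():
        if "expression" not in state:
            return {"skipped": True}
        curves = {g: fit_standard_curve(d["log10_conc"], d["cq"])
                  for g, d in state["curves"].items()}
        target_curve = curves[config.target_gene]
        ref_curves = [curves[g] for g in config.reference_genes]
        norm = normalize_cohort(state["expression"], target_curve, ref_curves)
        norm_path = out_dir / "expression_normalized.tsv"
        norm.to_csv(norm_path, sep="\t", index=False)
        comparison = group_comparison(
            {g: sub["rel_quantity"].to_numpy() for g, sub in norm.groupby("group")}
        )
        comp_path = out_dir / "group_comparison.tsv"
        pd.DataFrame(
            [
                {"group_a": c.group_a, "group_b": c.group_b, "z": c.z,
                 "p": c.pvalue, "adjusted_p": c.adjusted_p}
                for c in comparison.pairwise
            ]
        ).to_csv(comp_path, sep="\t", index=False)
        corr = genotype_expression_correlation(
            norm["genotype"], norm["rel_quantity"], norm["tissue"]
        )
        corr_path = out_dir / "correlation.json"
        corr_path.write_text(
            json.dumps(
                {k: dataclasses.asdict(v) for k, v in corr.items()}, indent=2
            )
        )
        manifest["outputs"]["expression_normalized"] = str(norm_path)
        manifest["outputs"]["group_comparison"] = str(comp_path)
        manifest["outputs"]["correlation"] = str(corr_path)
        return {
            "n_samples": len(norm),
            "kruskal_p": comparison.pvalue,
            "rho_all": corr["all"].rho,
        }

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=float))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
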