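"""End-to-end runs: expression-variability calling and phenotype summaries.

Each pipeline reads tabular text inputs, runs the corresponding analysis and
writes deterministic text outputs (per-sample gene lists, a divergence TSV,
a versioned JSON report; or a summary TSV per line plus a JSON of test
results).  INFO logging narrates the checkpoints a reviewer would audit:
passing-gene counts, the derived cutoff, and per-sample variable counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import read_expression_table
from .phenostats import (
    DegenerateVarianceError,
    adjusted_rank_transform,
    levene_test,
    percent_reduction,
    qpcr_relative_scale,
    round_half_up,
    significance_stars,
    summarize_trait,
)
from .variability import VariabilityConfig, VariabilityResult, analyze_variability

logger = logging.getLogger(__name__)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def run_expression_pipeline(
    table_path: str | Path,
    out_dir: str | Path,
    config: VariabilityConfig,
    sidecar_path: str | Path | None = None,
) -> VariabilityResult:
    """Floor -> divergence -> cutoff -> calls -> overlaps/correlations -> report.

    Writes, under ``out_dir``: ``variable_genes.<sample>.txt`` (one id per
    line, sorted), ``divergence.tsv`` (gene x per-sample d, NA where the gene
    fails the floor), ``high_divergence.<sample>.txt``, and ``report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_expression_table(table_path, sidecar_path)
    result = analyze_variability(table, config)

    for sample, genes in result.variable_genes.items():
        (out / f"variable_genes.{sample}.txt").write_text(
            "".join(f"{g}\n" for g in sorted(genes)), encoding="utf-8"
        )
    for sample, genes in result.high_divergence.items():
        (out / f"high_divergence.{sample}.txt").write_text(
            "".join(f"{g}\n" for g in sorted(genes)), encoding="utf-8"
        )
    div = pd.DataFrame(
        {s: d for s, d in result.divergence.items()}
    ).reindex(table.gene_ids)
    div.index.name = "gene_id"
    div.to_csv(out / "divergence.tsv", sep="\t", float_format="%.10g",
               na_rep="NA", lineterminator="\n")
    _write_json(result.to_report(), out / "report.json")
    logger.info("expression pipeline complete: %s", out / "report.json")
    return result


def run_phenotype_pipeline(
    traits_path: str | Path,
    out_dir: str | Path,
    reference_line: str | None = None,
    levene_center: str = "mean",
) -> dict:
    """Per-line trait summary with Levene-vs-reference stars and percent reduction.

    Input: long-format TSV with columns line, genotype, treatment,
    photoperiod, temperature, trait, value.  When both genotype and treatment
    vary, the adjusted rank transform factorial tests are run as well.
    Writes ``summary.tsv`` and ``tests.json``; returns the JSON document.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(traits_path, sep="\t")
    required = {"line", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"trait table must have columns {sorted(required)}")

    lines = list(dict.fromkeys(df["line"]))
    if reference_line is not None and reference_line not in lines:
        raise ValueError(f"reference line {reference_line!r} not in trait table")

    groups = {ln: df.loc[df["line"] == ln, "value"].to_numpy(float)
              for ln in lines}
    ref = reference_line if reference_line is not None else (
        lines[0] if len(lines) > 1 else None
    )

    rows = []
    tests: dict = {"levene_vs_reference": {}, "reference_line": ref}
    for ln in lines:
        v = groups[ln]
        if np.ptp(v) == 0:
            # constant population: CV = 0, dispersion comparison undefined
            rows.append({
                "line": ln, "n": v.size, "mean": float(v.mean()),
                "cv": 0.0, "var": 0.0, "levene_p": "NA", "stars": "",
                "reduction_pct": "" if ref is None or ln == ref else
                round_half_up(percent_reduction(groups[ref].mean(), v.mean()), 1),
                "warning": "constant values; Levene undefined",
            })
            continue
        s = summarize_trait(v)
        row = {
            "line": ln, "n": s.n, "mean": s.mean, "cv": s.cv, "var": s.variance,
            "levene_p": "NA", "stars": "", "reduction_pct": "", "warning": "",
        }
        if ref is not None and ln != ref:
            row["reduction_pct"] = round_half_up(
                percent_reduction(float(groups[ref].mean()), s.mean), 1
            )
            try:
                res = levene_test([groups[ref], v], center=levene_center)
                row["levene_p"] = res.p_value
                row["stars"] = significance_stars(res.p_value)
                tests["levene_vs_reference"][ln] = {
                    "statistic": res.statistic, "df": list(res.df),
                    "p_value": res.p_value, "method": res.method,
                }
            except DegenerateVarianceError:
                row["warning"] = "Levene undefined vs reference"
        rows.append(row)

    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False,
                   float_format="%.6g", lineterminator="\n")

    if {"genotype", "treatment"}.issubset(df.columns):
        if df["genotype"].nunique() >= 2 and df["treatment"].nunique() >= 2:
            counts = df.groupby(["genotype", "treatment"]).size()
            if (counts >= 2).all() and len(counts) == (
                df["genotype"].nunique() * df["treatment"].nunique()
            ):
                art = adjusted_rank_transform(
                    df["value"].to_numpy(float), df["genotype"], df["treatment"]
                )
                tests["adjusted_rank_transform"] = {
                    name: {"statistic": r.statistic, "df": list(r.df),
                           "p_value": r.p_value}
                    for name, r in (("genotype", art.factor_a),
                                    ("treatment", art.factor_b),
                                    ("interaction", art.interaction))
                }
    _write_json(tests, out / "tests.json")
    logger.info("phenotype pipeline complete: %s", out / "summary.tsv")
    return tests


def run_qpcr_pipeline(
    qpcr_path: str | Path,
    out_dir: str | Path,
    reference_gene: str = "UBC",
    reference_line: str | None = None,
) -> dict:
    """Normalise and min-scale a qRT-PCR table; Levene per gene vs a reference line.

    Input TSV: first column gene_id, remaining columns ``<line>__<individual>``;
    one row must be the reference gene.  Scaling is done within each line.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(qpcr_path, sep="\t", index_col=0)
    if reference_gene not in df.index:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    line_of = {}
    for c in df.columns:
        if "__" not in c:
            raise ValueError(f"column {c!r} is not '<line>__<individual>'")
        line_of[c] = c.rsplit("__", 1)[0]
    lines = list(dict.fromkeys(line_of.values()))
    if reference_line is None:
        reference_line = lines[0]
    if reference_line not in lines:
        raise ValueError(f"reference line {reference_line!r} not in table")

    scaled_parts = []
    for line in lines:
        cols = [c for c in df.columns if line_of[c] == line]
        block = df.loc[df.index != reference_gene, cols]
        scaled_parts.append(
            qpcr_relative_scale(block, df.loc[reference_gene, cols].to_numpy())
        )
    scaled = pd.concat(scaled_parts, axis=1)
    scaled.index.name = "gene_id"
    scaled.to_csv(out / "qpcr_scaled.tsv", sep="\t", float_format="%.10g",
                  lineterminator="\n")

    comparisons: dict = {"reference_line": reference_line, "genes": {}}
    ref_cols = [c for c in scaled.columns if line_of[c] == reference_line]
    for gene in scaled.index:
        comparisons["genes"][gene] = {}
        for line in lines:
            if line == reference_line:
                continue
            cols = [c for c in scaled.columns if line_of[c] == line]
            try:
                res = levene_test(
                    [scaled.loc[gene, ref_cols].to_numpy(),
                     scaled.loc[gene, cols].to_numpy()]
                )
                comparisons["genes"][gene][line] = {
                    "statistic": res.statistic, "p_value": res.p_value,
                    "stars": significance_stars(res.p_value),
                }
            except DegenerateVarianceError:
                comparisons["genes"][gene][line] = {
                    "statistic": None, "p_value": None, "stars": "",
                    "warning": "degenerate variance",
                }
    _write_json(comparisons, out / "qpcr_levene.json")
    return comparisons
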