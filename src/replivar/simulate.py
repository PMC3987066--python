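"""Synthetic expression tables and trait populations with known ground truth.

The expression generator works on the log2(FPKM + 1) scale: each gene gets a
true level t_g ~ Normal(baseline_log2_mean, baseline_log2_sd^2), shared
across samples; each replicate observes t_g plus Normal replicate noise with
standard deviation sigma_rep for stable genes and lambda_s * sigma_rep for
the genes in that sample's hypervariable set.  FPKM = max(2^x - 1, 0), so
for genes passing the FPKM floor the caller's divergence statistic is
exactly the simulated |noise difference| and analytic expectations are
available: stable-gene divergence is HalfNormal(sigma_rep * sqrt(2)).

Default configuration mirrors the study design the analysis assumes: four
samples (wild-type/mutant x long-day/short-day), two biological replicates
each, ~20,000 genes with most passing an FPKM > 0.5 floor, and a mutant
long-day sample carrying a sizeable hypervariable subset with inflated
replicate noise.

Trait populations draw Normal(mean, (cv * mean)^2) per individual with
redraw-on-nonpositive truncation; a factorial variant crosses genotype with
a treatment to feed the adjusted rank transform test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import (
    GeneExpressionTable,
    SampleInfo,
    write_expression_table,
    write_sample_sidecar,
)
from .phenostats import TraitSample
from .variability import VariabilityConfig, analyze_variability


@dataclass(frozen=True)
class SampleSimSpec:
    """Per-sample simulation parameters.

    hypervariable_fraction of the genes (uniformly random, or partially
    shared with ``overlap_with``'s set) get replicate noise inflated by
    ``noise_multiplier``.
    """

    label: str
    genotype: str = "wild-type"
    photoperiod: str = "long-day"
    hypervariable_fraction: float = 0.0
    noise_multiplier: float = 1.0
    overlap_with: str | None = None
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.hypervariable_fraction < 1:
            raise ValueError("hypervariable_fraction must be in [0, 1)")
        if self.noise_multiplier < 1:
            raise ValueError("noise_multiplier must be >= 1")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")


def _default_samples() -> tuple[SampleSimSpec, ...]:
    return (
        SampleSimSpec("WT_LD", "wild-type", "long-day",
                      hypervariable_fraction=0.005, noise_multiplier=2.0),
        SampleSimSpec("MUT_LD", "mutant", "long-day",
                      hypervariable_fraction=0.10, noise_multiplier=4.0,
                      overlap_with="WT_LD", overlap_fraction=0.7),
        SampleSimSpec("WT_SD", "wild-type", "short-day",
                      hypervariable_fraction=0.02, noise_multiplier=2.0),
        SampleSimSpec("MUT_SD", "mutant", "short-day",
                      hypervariable_fraction=0.015, noise_multiplier=2.0,
                      overlap_with="WT_SD", overlap_fraction=0.3),
    )


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Full parameterisation (including seed) of the expression generator."""

    n_genes: int = 20000
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    replicate_noise_sd: float = 0.15
    samples: tuple[SampleSimSpec, ...] = field(default_factory=_default_samples)
    replicate_labels: tuple[str, str] = ("R1", "R2")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.baseline_log2_sd <= 0:
            raise ValueError("baseline_log2_sd must be positive")
        if self.replicate_noise_sd <= 0:
            raise ValueError("replicate_noise_sd must be positive")
        if len(self.replicate_labels) != 2:
            raise ValueError("exactly two replicate labels required")
        labels = [s.label for s in self.samples]
        if len(set(labels)) != len(labels):
            raise ValueError("sample labels must be unique")
        for s in self.samples:
            if s.overlap_with is not None and s.overlap_with not in labels:
                raise ValueError(
                    f"overlap_with {s.overlap_with!r} is not a sample label"
                )

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ExpressionSimConfig":
        doc = dict(doc)
        if "samples" in doc:
            doc["samples"] = tuple(SampleSimSpec(**s) for s in doc["samples"])
        if "replicate_labels" in doc:
            doc["replicate_labels"] = tuple(doc["replicate_labels"])
        return cls(**doc)


def high_separation_config(seed: int = 0, n_genes: int = 20000) -> ExpressionSimConfig:
    """The committed benchmark scenario for caller sensitivity.

    A clean reference (no hypervariable genes) plus a mutant long-day sample
    with 10% hypervariable genes at 12x replicate noise.  Against a top-1%
    reference cutoff, stable divergence is HalfNormal(sigma*sqrt(2)) and the
    cutoff sits near its 99.5th two-sided quantile (z = 2.576), so expected
    sensitivity is 2*(1 - Phi(2.576/lambda)): about 0.83 at lambda = 12 —
    the regime where recovery of the planted set should be reliable.  (At
    lambda = 4 the same formula gives only ~0.52, so that regime is *not* a
    high-separation benchmark.)
    """
    return ExpressionSimConfig(
        n_genes=n_genes,
        replicate_noise_sd=0.15,
        samples=(
            SampleSimSpec("WT_LD", "wild-type", "long-day"),
            SampleSimSpec("MUT_LD", "mutant", "long-day",
                          hypervariable_fraction=0.10, noise_multiplier=12.0),
        ),
        seed=seed,
    )


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[GeneExpressionTable, dict[str, frozenset]]:
    """Simulate an expression table; returns (table, per-sample hypervariable sets)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    t = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)

    hyper_idx: dict[str, np.ndarray] = {}
    columns: dict[tuple[str, str], np.ndarray] = {}
    samples: dict[str, SampleInfo] = {}
    for spec in config.samples:
        k = round(spec.hypervariable_fraction * n)
        if spec.overlap_with is not None and k > 0:
            other = hyper_idx.get(spec.overlap_with, np.array([], dtype=int))
            n_shared = min(round(spec.overlap_fraction * min(k, other.size)), k)
            shared = rng.choice(other, size=n_shared, replace=False) \
                if n_shared else np.array([], dtype=int)
            pool = np.setdiff1d(np.arange(n), shared)
            rest = rng.choice(pool, size=k - n_shared, replace=False)
            idx = np.sort(np.concatenate([shared, rest]).astype(int))
        else:
            idx = np.sort(rng.choice(n, size=k, replace=False)) if k else \
                np.array([], dtype=int)
        hyper_idx[spec.label] = idx
        sd = np.full(n, config.replicate_noise_sd)
        sd[idx] *= spec.noise_multiplier
        for rep in config.replicate_labels:
            x = t + rng.normal(0.0, 1.0, n) * sd
            columns[(spec.label, rep)] = np.maximum(np.exp2(x) - 1.0, 0.0)
        samples[spec.label] = SampleInfo(
            label=spec.label, genotype=spec.genotype, photoperiod=spec.photoperiod
        )

    values = pd.DataFrame(
        columns, index=pd.Index(gene_ids, name="gene_id")
    )
    values.columns = pd.MultiIndex.from_tuples(
        values.columns, names=["sample", "replicate"]
    )
    truth = {label: frozenset(gene_ids[idx]) for label, idx in hyper_idx.items()}
    return GeneExpressionTable(values, samples), truth


def estimate_replicate_noise(divergence: Sequence[float]) -> float:
    """Half-normal scale fitted to divergences; estimates sigma_rep * sqrt(2).

    Uses the robust median estimator median(d) / Phi^{-1}(3/4), insensitive
    to a small contaminating fraction of hypervariable genes.
    """
    d = np.asarray(divergence, dtype=float)
    if d.size == 0:
        raise ValueError("empty divergence vector")
    return float(np.median(d) / stats.norm.ppf(0.75))


@dataclass(frozen=True)
class LineSpec:
    """Target mean and CV of one line's trait population."""

    label: str
    mean: float
    cv: float
    genotype: str = "wild-type"

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("line mean must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


@dataclass(frozen=True)
class FactorialEffects:
    """Additive effects on the cell means of a genotype x treatment design."""

    treatment_effect: float = 0.0
    interaction_effect: float = 0.0
    treatments: tuple[str, str] = ("control", "stress")


def _default_lines() -> tuple[LineSpec, ...]:
    # anchored to the published root-length populations: wild-type mean
    # 40.53 mm, CV 0.052; over-expressor mean 31.89 mm, CV 0.164
    return (
        LineSpec("wild-type", 40.53, 0.052, genotype="wild-type"),
        LineSpec("mutant-ov", 31.89, 0.164, genotype="mutant"),
    )


@dataclass(frozen=True)
class TraitSimConfig:
    """Full parameterisation (including seed) of the trait generator."""

    lines: tuple[LineSpec, ...] = field(default_factory=_default_lines)
    n_per_line: int = 40
    trait: str = "root length"
    units: str = "mm"
    factorial: FactorialEffects | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_line < 2:
            raise ValueError("n_per_line must be >= 2")
        if not self.lines:
            raise ValueError("at least one line required")

    @classmethod
    def from_dict(cls, doc: Mapping) -> "TraitSimConfig":
        doc = dict(doc)
        if "lines" in doc:
            doc["lines"] = tuple(LineSpec(**ln) for ln in doc["lines"])
        if doc.get("factorial"):
            fac = dict(doc["factorial"])
            if "treatments" in fac:
                fac["treatments"] = tuple(fac["treatments"])
            doc["factorial"] = FactorialEffects(**fac)
        return cls(**doc)


def _draw_positive(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws truncated by redraw at 0 (preserves the target mean ~exactly
    whenever mean/sd is large, as it is for all realistic trait populations)."""
    v = rng.normal(mean, sd, n)
    while True:
        bad = v <= 0
        if not bad.any():
            return v
        v[bad] = rng.normal(mean, sd, int(bad.sum()))


def simulate_traits(config: TraitSimConfig) -> list[TraitSample]:
    """Simulate trait populations; one TraitSample per line (x treatment)."""
    rng = np.random.default_rng(config.seed)
    out: list[TraitSample] = []
    for line in config.lines:
        sd = line.cv * line.mean
        if config.factorial is None:
            if sd == 0:
                v = np.full(config.n_per_line, line.mean)
            else:
                v = _draw_positive(rng, line.mean, sd, config.n_per_line)
            out.append(TraitSample(
                line=line.label, values=v, trait=config.trait, units=config.units,
                factors={"genotype": line.genotype, "treatment": "control"},
            ))
            continue
        fac = config.factorial
        for treatment in fac.treatments:
            mean = line.mean
            if treatment != fac.treatments[0]:
                mean += fac.treatment_effect
                if line.genotype == "mutant":
                    mean += fac.interaction_effect
            if mean <= 0:
                raise ValueError(
                    f"non-positive cell mean for {line.label}/{treatment}"
                )
            if sd == 0:
                v = np.full(config.n_per_line, mean)
            else:
                v = _draw_positive(rng, mean, sd, config.n_per_line)
            out.append(TraitSample(
                line=line.label, values=v, trait=config.trait, units=config.units,
                factors={"genotype": line.genotype, "treatment": treatment},
            ))
    return out


def traits_to_frame(samples: Sequence[TraitSample]) -> pd.DataFrame:
    """Long-format trait table (one row per individual) for TSV output."""
    rows = []
    for s in samples:
        for v in s.values:
            rows.append({
                "line": s.line,
                "genotype": s.factors.get("genotype", "unspecified"),
                "treatment": s.factors.get("treatment", "control"),
                "photoperiod": s.factors.get("photoperiod", "long-day"),
                "temperature": s.factors.get("temperature", "23C"),
                "trait": s.trait,
                "value": float(v),
            })
    return pd.DataFrame(rows)


def make_fixture_bundle(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a small deterministic fixture bundle and its ground-truth manifest.

    Contents: a 200-gene expression table + sample sidecar, a long-format
    trait TSV, a qRT-PCR table (genes x line__individual, incl. a UBC
    reference row), and ``manifest.json`` recording the planted hypervariable
    sets and the caller's expected counts on the bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr_cfg = ExpressionSimConfig(
        n_genes=200,
        samples=(
            SampleSimSpec("WT_LD", "wild-type", "long-day"),
            SampleSimSpec("MUT_LD", "mutant", "long-day",
                          hypervariable_fraction=0.10, noise_multiplier=12.0),
            SampleSimSpec("WT_SD", "wild-type", "short-day",
                          hypervariable_fraction=0.02, noise_multiplier=4.0),
            SampleSimSpec("MUT_SD", "mutant", "short-day",
                          hypervariable_fraction=0.02, noise_multiplier=4.0,
                          overlap_with="WT_SD", overlap_fraction=0.5),
        ),
        seed=seed,
    )
    table, truth = simulate_expression(expr_cfg)
    write_expression_table(table, out / "expression.tsv")
    write_sample_sidecar(table.samples, out / "samples.yaml")

    trait_cfg = TraitSimConfig(seed=seed + 1)
    traits = simulate_traits(trait_cfg)
    traits_to_frame(traits).to_csv(out / "traits.tsv", sep="\t", index=False,
                                   float_format="%.10g", lineterminator="\n")

    rng = np.random.default_rng(seed + 2)
    lines = ("Col", "ov-line")
    individuals = 6
    genes = ["VAR1", "VAR2", "STAB1", "STAB2", "UBC"]
    cols = {}
    for line in lines:
        noisy = 1.0 if line == "Col" else 2.0
        for i in range(1, individuals + 1):
            col = {}
            for g in genes:
                if g == "UBC":
                    col[g] = float(np.exp(rng.normal(0.0, 0.05)))
                elif g.startswith("VAR"):
                    col[g] = float(np.exp(rng.normal(1.0, 0.3 * noisy)))
                else:
                    col[g] = float(np.exp(rng.normal(1.0, 0.1)))
            cols[f"{line}__{i}"] = col
    qpcr = pd.DataFrame(cols).loc[genes]
    qpcr.index.name = "gene_id"
    qpcr.to_csv(out / "qpcr.tsv", sep="\t", float_format="%.10g",
                lineterminator="\n")

    # expected report computed from the table as re-read from disk, so the
    # manifest matches exactly what any consumer of the bundle recomputes
    from .expression import read_expression_table

    table_rt = read_expression_table(out / "expression.tsv", out / "samples.yaml")
    var_cfg = VariabilityConfig(reference_sample="WT_LD")
    result = analyze_variability(table_rt, var_cfg)
    manifest = {
        "seed": seed,
        "expression_config": {
            "n_genes": expr_cfg.n_genes,
            "replicate_noise_sd": expr_cfg.replicate_noise_sd,
            "samples": [
                {"label": s.label, "hypervariable_fraction": s.hypervariable_fraction,
                 "noise_multiplier": s.noise_multiplier}
                for s in expr_cfg.samples
            ],
        },
        "hypervariable_genes": {k: sorted(v) for k, v in truth.items()},
        "expected_report": result.to_report(),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
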