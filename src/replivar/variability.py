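"""Between-replicate expression-divergence analysis.

For each sample (a pair of biological replicates) the per-gene divergence

    d_g = | log2(FPKM_{g,R1} + 1) - log2(FPKM_{g,R2} + 1) |

is computed over the genes whose FPKM exceeds a floor (default 0.5) in both
replicates.  A cutoff is derived from a designated reference sample as the
divergence separating its top fraction (default the top 1%) of passing
genes; genes in any sample with divergence strictly above that cutoff are
called *variable*.  Summaries cover per-sample variable counts, pairwise
shared/specific overlaps, between-replicate Pearson correlations, shared-gene
R-squared, and the high-divergence subset (at least a given fold difference
between replicates, default 3-fold on the pseudocounted scale).

For well-expressed genes (FPKM much larger than the pseudocount) a divergence
of log2(1.5) corresponds to roughly a 1.5-fold expression difference on the
natural scale, which is the usual reading of a top-1% cutoff in this design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .expression import GeneExpressionTable

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class DegenerateDataError(ValueError):
    """A statistic is undefined on this input (e.g. zero variance)."""


@dataclass(frozen=True)
class VariabilityConfig:
    """Parameters of the variable-gene caller.

    fpkm_floor
        A gene enters a sample's divergence map only if FPKM exceeds this
        floor (strictly) in *both* replicates.  Default 0.5.
    pseudocount
        Added to FPKM before the log2 transform.  Default 1.0.
    reference_sample
        Sample whose top divergence fraction defines the cutoff — the
        wild-type long-day sample in the original design.
    reference_top_fraction
        Fraction of the reference sample's passing genes taken as its top
        set.  Default 0.01 (top 1%).
    high_divergence_fold
        Fold difference (pseudocounted scale) defining the high-divergence
        subset: d >= log2(fold).  Default 3.0.
    correlation_gene_set
        Default gene set for between-replicate correlations: ``"passing"``
        (floor applied) or ``"all"``.
    """

    reference_sample: str
    fpkm_floor: float = 0.5
    pseudocount: float = 1.0
    reference_top_fraction: float = 0.01
    high_divergence_fold: float = 3.0
    correlation_gene_set: str = "passing"

    def __post_init__(self) -> None:
        if self.fpkm_floor < 0:
            raise ValueError("fpkm_floor must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not 0 < self.reference_top_fraction < 1:
            raise ValueError("reference_top_fraction must be in (0, 1)")
        if self.high_divergence_fold <= 1:
            raise ValueError("high_divergence_fold must be > 1")
        if self.correlation_gene_set not in ("passing", "all"):
            raise ValueError("correlation_gene_set must be 'passing' or 'all'")


def log_expression(fpkm, pseudocount: float = 1.0):
    """log2(FPKM + pseudocount); accepts scalars or arrays, monotone in FPKM."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    arr = np.asarray(fpkm, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("FPKM values must be non-negative")
    out = np.log2(arr + pseudocount)
    if np.isscalar(fpkm) or arr.ndim == 0:
        return float(out)
    if isinstance(fpkm, pd.Series):
        return pd.Series(out, index=fpkm.index)
    return out


def replicate_divergence(
    table: GeneExpressionTable, sample: str, config: VariabilityConfig
) -> tuple[frozenset, pd.Series]:
    """Passing-gene set and divergence map for one sample.

    Returns the genes with FPKM strictly above the floor in both replicates
    and, for those genes only, d_g = |log2(F_R1 + c) - log2(F_R2 + c)|.
    Genes failing the floor are absent from the map (not set to 0), so they
    can never be called variable in that sample.
    """
    r1, r2 = table.replicate_pair(sample)
    passing = (r1 > config.fpkm_floor) & (r2 > config.fpkm_floor)
    x1 = log_expression(r1[passing], config.pseudocount)
    x2 = log_expression(r2[passing], config.pseudocount)
    d = (x1 - x2).abs()
    d.name = "divergence"
    return frozenset(d.index), d


@dataclass(frozen=True)
class CutoffResult:
    """Cutoff derived from a reference divergence map.

    cutoff
        The (k+1)-th largest divergence, where k = ceil(fraction * N); genes
        strictly above it form the reference top set.  ``-inf`` when k = N.
    top_count
        k, the intended reference top-set size (exact absent ties).
    reference_top_set
        Genes with divergence strictly above the cutoff in the reference.
    n_ties_at_cutoff
        Number of genes exactly at the cutoff value; ties deflate the called
        set, never inflate it.
    """

    cutoff: float
    top_count: int
    reference_top_set: frozenset
    n_ties_at_cutoff: int


def derive_cutoff(
    divergence: Mapping[str, float] | pd.Series, fraction: float
) -> CutoffResult:
    """Derive the variability cutoff from the reference sample's divergences."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    d = pd.Series(divergence, dtype=float)
    n = len(d)
    if n == 0:
        raise ValueError("empty divergence map: cannot derive a cutoff")
    k = math.ceil(fraction * n)
    order = np.sort(d.to_numpy())[::-1]
    cutoff = float("-inf") if k >= n else float(order[k])
    top = frozenset(d.index[d.to_numpy() > cutoff])
    n_ties = int(np.sum(d.to_numpy() == cutoff))
    if len(top) != k:
        logger.info(
            "cutoff ties: intended top count %d, called %d (%d genes tied at %.6g)",
            k, len(top), n_ties, cutoff,
        )
    return CutoffResult(cutoff=cutoff, top_count=k,
                        reference_top_set=top, n_ties_at_cutoff=n_ties)


def call_variable_genes(
    divergence: Mapping[str, float] | pd.Series, cutoff: float
) -> frozenset:
    """Genes with divergence strictly greater than the cutoff."""
    d = pd.Series(divergence, dtype=float)
    return frozenset(d.index[d.to_numpy() > cutoff])


@dataclass(frozen=True)
class OverlapSummary:
    specific_a: int
    shared: int
    specific_b: int

    def astuple(self) -> tuple[int, int, int]:
        return (self.specific_a, self.shared, self.specific_b)


def overlap_summary(set_a: Iterable, set_b: Iterable) -> OverlapSummary:
    """Counts of A-specific, shared, and B-specific genes."""
    a, b = set(set_a), set(set_b)
    return OverlapSummary(len(a - b), len(a & b), len(b - a))


def _log_pair(table, sample, config, gene_subset):
    r1, r2 = table.replicate_pair(sample)
    if gene_subset is not None:
        genes = [g for g in gene_subset]
        missing = [g for g in genes if g not in table.values.index]
        if missing:
            raise KeyError(f"genes not in table: {sorted(missing)[:5]}")
        r1, r2 = r1.loc[genes], r2.loc[genes]
    elif config.correlation_gene_set == "passing":
        keep = (r1 > config.fpkm_floor) & (r2 > config.fpkm_floor)
        r1, r2 = r1[keep], r2[keep]
    x = log_expression(r1, config.pseudocount)
    y = log_expression(r2, config.pseudocount)
    if len(x) < 3:
        raise DegenerateDataError(
            f"need >= 3 genes for correlation in {sample!r}, have {len(x)}"
        )
    return np.asarray(x, float), np.asarray(y, float)


def replicate_correlation(
    table: GeneExpressionTable,
    sample: str,
    config: VariabilityConfig,
    gene_subset: Iterable | None = None,
) -> float:
    """Pearson correlation of log2(FPKM + c) between the two replicates.

    Defaults to the floor-passing genes; pass ``gene_subset`` to restrict to
    an explicit list (the floor is then not applied).
    """
    x, y = _log_pair(table, sample, config, gene_subset)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError(
            f"correlation undefined for {sample!r}: a replicate has zero variance"
        )
    return float(stats.pearsonr(x, y).statistic)


def shared_gene_r2(
    table: GeneExpressionTable,
    sample: str,
    gene_subset: Iterable,
    config: VariabilityConfig,
) -> float:
    """R-squared of the least-squares fit of replicate 2 on replicate 1 log values.

    Restricted to ``gene_subset``; equals the squared Pearson correlation for
    this simple linear regression.
    """
    x, y = _log_pair(table, sample, config, gene_subset)
    if np.ptp(x) == 0:
        raise DegenerateDataError(
            f"R^2 undefined for {sample!r}: predictor replicate has zero variance"
        )
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2)


def high_divergence_subset(
    divergence: Mapping[str, float] | pd.Series, fold: float
) -> frozenset:
    """Genes whose replicates differ by at least ``fold`` on the pseudocounted
    scale: d >= log2(fold), inclusive boundary."""
    if fold <= 1:
        raise ValueError("fold must be > 1")
    d = pd.Series(divergence, dtype=float)
    return frozenset(d.index[d.to_numpy() >= math.log2(fold)])


@dataclass
class VariabilityResult:
    """Full output of the variable-gene caller for one expression table."""

    config: VariabilityConfig
    passing_genes: dict[str, frozenset]
    divergence: dict[str, pd.Series]
    cutoff: float
    reference_top_count: int
    n_ties_at_cutoff: int
    variable_genes: dict[str, frozenset]
    correlations: dict[str, float | None]
    high_divergence: dict[str, frozenset]
    pairwise_overlaps: dict[tuple[str, str], OverlapSummary] = field(default_factory=dict)
    shared_r2: dict[tuple[str, str], dict] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {s: len(g) for s, g in self.variable_genes.items()}

    def to_report(self) -> dict:
        """Deterministic JSON-serialisable summary (counts raw and as fractions)."""
        samples = sorted(self.variable_genes)
        report = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "reference_sample": self.config.reference_sample,
            "cutoff": self.cutoff,
            "reference_top_count": self.reference_top_count,
            "n_ties_at_cutoff": self.n_ties_at_cutoff,
            "samples": {},
            "pairwise_overlaps": {},
            "shared_gene_r2": {},
        }
        for s in samples:
            n_pass = len(self.passing_genes[s])
            n_var = len(self.variable_genes[s])
            report["samples"][s] = {
                "n_passing": n_pass,
                "n_variable": n_var,
                "fraction_variable": (n_var / n_pass) if n_pass else None,
                "n_high_divergence": len(self.high_divergence[s]),
                "replicate_pearson_r": self.correlations.get(s),
            }
        for (a, b), ov in sorted(self.pairwise_overlaps.items()):
            report["pairwise_overlaps"][f"{a}|{b}"] = {
                "specific_a": ov.specific_a,
                "shared": ov.shared,
                "specific_b": ov.specific_b,
            }
        for (a, b), entry in sorted(self.shared_r2.items()):
            report["shared_gene_r2"][f"{a}|{b}"] = entry
        return report


def analyze_variability(
    table: GeneExpressionTable, config: VariabilityConfig
) -> VariabilityResult:
    """Run the full caller: floor -> divergence -> cutoff -> calls -> summaries.

    The cutoff comes from ``config.reference_sample``; overlap summaries and
    shared-gene R-squared are produced for every pair of samples sharing a
    photoperiod (and for all pairs when factor levels are unspecified).
    """
    ref = config.reference_sample
    if ref not in table.sample_labels:
        raise KeyError(
            f"reference sample {ref!r} not in table (samples: {table.sample_labels})"
        )
    passing: dict[str, frozenset] = {}
    divergence: dict[str, pd.Series] = {}
    for s in table.sample_labels:
        passing[s], divergence[s] = replicate_divergence(table, s, config)
        logger.info("sample %s: %d genes pass the FPKM floor", s, len(passing[s]))

    cut = derive_cutoff(divergence[ref], config.reference_top_fraction)
    logger.info(
        "reference %s: cutoff %.6g (top count %d of %d passing)",
        ref, cut.cutoff, cut.top_count, len(divergence[ref]),
    )

    variable = {s: call_variable_genes(divergence[s], cut.cutoff)
                for s in table.sample_labels}
    for s, genes in variable.items():
        logger.info("sample %s: %d variable genes", s, len(genes))

    correlations: dict[str, float | None] = {}
    for s in table.sample_labels:
        try:
            correlations[s] = replicate_correlation(table, s, config)
        except DegenerateDataError:
            logger.warning("correlation undefined for sample %s", s)
            correlations[s] = None

    high = {s: high_divergence_subset(divergence[s], config.high_divergence_fold)
            for s in table.sample_labels}

    labels = table.sample_labels
    overlaps: dict[tuple[str, str], OverlapSummary] = {}
    shared_r2: dict[tuple[str, str], dict] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            pa, pb = table.samples[a].photoperiod, table.samples[b].photoperiod
            if pa != pb and "unspecified" not in (pa, pb):
                continue
            overlaps[(a, b)] = overlap_summary(variable[a], variable[b])
            shared = sorted(variable[a] & variable[b])
            entry: dict = {"n_shared": len(shared)}
            if len(shared) >= 3:
                for s in (a, b):
                    try:
                        entry[s] = shared_gene_r2(table, s, shared, config)
                    except DegenerateDataError:
                        entry[s] = None
            shared_r2[(a, b)] = entry

    return VariabilityResult(
        config=config,
        passing_genes=passing,
        divergence=divergence,
        cutoff=cut.cutoff,
        reference_top_count=cut.top_count,
        n_ties_at_cutoff=cut.n_ties_at_cutoff,
        variable_genes=variable,
        correlations=correlations,
        high_divergence=high,
        pairwise_overlaps=overlaps,
        shared_r2=shared_r2,
    )
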