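"""Gene-level expression tables: container, TSV I/O, and FPKM computation.

The central container is :class:`GeneExpressionTable`, a gene x (sample,
replicate) matrix of non-negative FPKM values.  FPKM (fragments per kilobase
of transcript exon model per million mapped fragments) is computed by the
literal normalisation formula from raw fragment counts, exon-model lengths
and the per-library total of mapped fragments; no hit-adjusted library-size
corrections are applied.

Tables are read and written as tab-separated text with one row per gene and
one column per ``<sample>__<replicate>`` pair.  Sample factor levels
(genotype, photoperiod) live in a small YAML sidecar, not in the column
names, so labels containing underscores stay unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

COLUMN_SEP = "__"


class ExpressionTableError(ValueError):
    """An expression table violates its invariants or cannot be parsed."""


@dataclass(frozen=True)
class SampleInfo:
    """Factor levels attached to one sample (one pair of biological replicates)."""

    label: str
    genotype: str = "unspecified"
    photoperiod: str = "unspecified"


@dataclass(frozen=True)
class GeneModel:
    """A gene's summed exon length in bases, the FPKM length denominator."""

    gene_id: str
    exon_model_length: int

    def __post_init__(self) -> None:
        if self.exon_model_length < 1:
            raise ValueError(
                f"exon model length for {self.gene_id!r} must be >= 1, "
                f"got {self.exon_model_length}"
            )


@dataclass
class GeneExpressionTable:
    """Gene x (sample, replicate) matrix of non-negative expression values.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene id with a two-level column
        MultiIndex ``(sample, replicate)``.  Every column must be complete:
        a missing entry is a hard error, never a silent NaN.
    samples
        Optional mapping from sample label to :class:`SampleInfo`.  Samples
        present in ``values`` but absent here get unspecified factor levels.
    """

    values: pd.DataFrame
    samples: dict[str, SampleInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = self.values.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise ExpressionTableError(
                "values must have a two-level (sample, replicate) column MultiIndex"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ExpressionTableError(f"duplicate gene ids: {dups}")
        arr = self.values.to_numpy(dtype=float, na_value=np.nan)
        if np.isnan(arr).any():
            raise ExpressionTableError("missing expression values are not allowed")
        if not np.isfinite(arr).all():
            raise ExpressionTableError("expression values must be finite")
        if arr.size and arr.min() < 0:
            raise ExpressionTableError("expression values must be non-negative")
        self.values = self.values.astype(float)
        for s in self.sample_labels:
            self.samples.setdefault(s, SampleInfo(label=s))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def sample_labels(self) -> list[str]:
        seen: list[str] = []
        for s, _ in self.values.columns:
            if s not in seen:
                seen.append(s)
        return seen

    def replicates(self, sample: str) -> list[str]:
        reps = [r for s, r in self.values.columns if s == sample]
        if not reps:
            raise KeyError(f"unknown sample {sample!r}")
        return reps

    def replicate_pair(self, sample: str) -> tuple[pd.Series, pd.Series]:
        """The two replicate columns of ``sample``; errors unless exactly two."""
        reps = self.replicates(sample)
        if len(reps) != 2:
            raise ExpressionTableError(
                f"sample {sample!r} has {len(reps)} replicates; "
                "variability analysis requires exactly 2"
            )
        return self.values[(sample, reps[0])], self.values[(sample, reps[1])]


def compute_fpkm(
    fragment_counts: Mapping[str, int],
    gene_models: Mapping[str, int] | Iterable[GeneModel],
    total_mapped_fragments: int,
) -> pd.Series:
    """FPKM per gene from fragment counts and exon-model lengths.

    FPKM_g = counts_g * 1e9 / (exon_model_length_g * total_mapped_fragments).
    Paired-end fragments, not reads, are the counting unit.
    """
    if total_mapped_fragments <= 0:
        raise ValueError(
            f"total_mapped_fragments must be positive, got {total_mapped_fragments}"
        )
    if not isinstance(gene_models, Mapping):
        gene_models = {m.gene_id: m.exon_model_length for m in gene_models}
    missing = [g for g in fragment_counts if g not in gene_models]
    if missing:
        raise KeyError(f"no gene model for gene(s): {sorted(missing)}")
    genes = list(fragment_counts)
    counts = np.asarray([fragment_counts[g] for g in genes], dtype=float)
    if counts.size and counts.min() < 0:
        raise ValueError("fragment counts must be non-negative")
    lengths = np.asarray([gene_models[g] for g in genes], dtype=float)
    if lengths.size and lengths.min() < 1:
        raise ValueError("exon model lengths must be >= 1")
    fpkm = counts * 1e9 / (lengths * float(total_mapped_fragments))
    return pd.Series(fpkm, index=pd.Index(genes, name="gene_id"), name="fpkm")


def write_expression_table(table: GeneExpressionTable, path: str | Path) -> None:
    """Write a table as TSV with deterministic column order and formatting.

    Floats are printed with 10 significant digits, so read/write round-trips
    are lossless well past the 1e-9 relative level.
    """
    df = table.values.copy()
    df.columns = [f"{s}{COLUMN_SEP}{r}" for s, r in df.columns]
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def read_expression_table(
    path: str | Path, sidecar: str | Path | None = None
) -> GeneExpressionTable:
    """Read a TSV expression matrix written by :func:`write_expression_table`.

    Ragged rows, missing cells, non-numeric or negative values and duplicate
    gene ids all raise :class:`ExpressionTableError` naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ExpressionTableError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup_mask = df.index.duplicated()
        pos = int(np.nonzero(dup_mask)[0][0])
        raise ExpressionTableError(
            f"{path}: duplicate gene id {df.index[pos]!r} at line {pos + 2}"
        )
    tuples = []
    for c in df.columns:
        if COLUMN_SEP not in c:
            raise ExpressionTableError(
                f"{path}: column {c!r} does not follow the "
                f"'<sample>{COLUMN_SEP}<replicate>' dialect"
            )
        sample, rep = c.rsplit(COLUMN_SEP, 1)
        tuples.append((sample, rep))
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ExpressionTableError(f"{path}: non-numeric value ({exc})") from exc
    na_rows = df.isna().any(axis=1).to_numpy()
    if na_rows.any():
        pos = int(np.nonzero(na_rows)[0][0])
        raise ExpressionTableError(
            f"{path}: missing value at line {pos + 2} (gene {df.index[pos]!r})"
        )
    neg_rows = (df < 0).any(axis=1).to_numpy()
    if neg_rows.any():
        pos = int(np.nonzero(neg_rows)[0][0])
        raise ExpressionTableError(
            f"{path}: negative value at line {pos + 2} (gene {df.index[pos]!r})"
        )
    df.columns = pd.MultiIndex.from_tuples(tuples, names=["sample", "replicate"])
    samples = read_sample_sidecar(sidecar) if sidecar is not None else {}
    return GeneExpressionTable(df, samples)


def write_sample_sidecar(samples: Mapping[str, SampleInfo], path: str | Path) -> None:
    """Write the sample -> factor-level sidecar as YAML."""
    doc = {
        "samples": {
            label: {"genotype": info.genotype, "photoperiod": info.photoperiod}
            for label, info in samples.items()
        }
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def read_sample_sidecar(path: str | Path) -> dict[str, SampleInfo]:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    out: dict[str, SampleInfo] = {}
    for label, fields in (doc.get("samples") or {}).items():
        fields = fields or {}
        out[label] = SampleInfo(
            label=label,
            genotype=fields.get("genotype", "unspecified"),
            photoperiod=fields.get("photoperiod", "unspecified"),
        )
    return out
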