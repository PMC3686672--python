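"""RPKM normalisation and organ-of-origin classification of shell-matrix-protein genes.

Bulk RNA-seq of a multi-organ atlas (one library per organ) locates where
shell-matrix-protein (SMP) genes are transcribed.  Expression is quantified
as RPKM (reads per kilobase of gene model per million mapped reads) and a
gene is called *expressed* in an organ when its RPKM strictly exceeds a
threshold (default 5).  SMP genes silent in the shell-secreting mantle but
clearly expressed elsewhere point to a multi-organ origin of shell proteins;
excluding the hemolymph as well rules out circulating hemocytes as the
apparent source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CountMatrix",
    "ExpressionMatrix",
    "ExpressionThresholds",
    "OriginClassification",
    "compute_rpkm",
    "call_expressed",
    "classify_shell_protein_origin",
    "summarize_organ_distribution",
]

ORIGIN_CLASSES = (
    "mantle_expressed",
    "non_mantle",
    "non_mantle_non_hemolymph",
    "unexpressed_everywhere",
)


class ValidationError(ValueError):
    """Raised when an input container or configuration violates its contract."""


@dataclass
class CountMatrix:
    """Gene-level read counts: genes on rows, sequencing libraries on columns.

    Parameters
    ----------
    counts
        Non-negative integer counts, indexed by gene id, one column per
        library (sample).
    gene_lengths
        Gene-model length in bp, indexed identically to ``counts``.
    library_sizes
        Total mapped reads per library.  When omitted, the column sums of
        ``counts`` are used — count tables rarely carry alignment totals.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample label: {dup!r}")
        if (np.asarray(self.counts) < 0).any():
            raise ValidationError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()][0]
            raise ValidationError(f"missing gene length for {missing!r}")
        if (self.gene_lengths <= 0).any():
            raise ValidationError("gene lengths must be positive")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
            if self.library_sizes.isna().any():
                missing = self.library_sizes.index[self.library_sizes.isna()][0]
                raise ValidationError(f"missing library size for sample {missing!r}")
            if (self.library_sizes <= 0).any():
                bad = self.library_sizes.index[self.library_sizes <= 0][0]
                raise ValidationError(f"non-positive library size for sample {bad!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_labels(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, labels: Sequence[str]) -> "CountMatrix":
        labels = list(labels)
        missing = [s for s in labels if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown sample label(s): {missing}")
        return CountMatrix(
            counts=self.counts[labels].copy(),
            gene_lengths=self.gene_lengths.copy(),
            library_sizes=self.library_sizes[labels].copy(),
        )


@dataclass
class ExpressionMatrix:
    """RPKM values on the same (gene, sample) axes as the source counts."""

    rpkm: pd.DataFrame
    gene_lengths: pd.Series

    @property
    def gene_ids(self) -> pd.Index:
        return self.rpkm.index

    @property
    def sample_labels(self) -> pd.Index:
        return self.rpkm.columns


@dataclass
class ExpressionThresholds:
    """Expression-calling thresholds.

    ``expressed_min_rpkm``: a gene is expressed in an organ when its RPKM is
    strictly greater than this value (RPKM below it is treated as
    unexpressed; equality falls on the unexpressed side).
    ``fold_min``: minimum fold change, relative to the mantle RPKM of the
    same gene, required of another organ for the non-mantle origin call.
    """

    expressed_min_rpkm: float = 5.0
    fold_min: float = 2.0

    def __post_init__(self) -> None:
        if self.expressed_min_rpkm <= 0:
            raise ValidationError("expressed_min_rpkm must be > 0")
        if self.fold_min <= 0:
            raise ValidationError("fold_min must be > 0")


@dataclass
class OriginClassification:
    """Per-SMP-gene organ-of-origin classes with their supporting RPKM values.

    ``table`` has one row per SMP gene with columns:

    - ``origin_class``: one of ``mantle_expressed``, ``non_mantle``,
      ``non_mantle_non_hemolymph``, ``unexpressed_everywhere`` (mutually
      exclusive; the hemolymph-excluding class is reported in preference to
      plain ``non_mantle`` when both rules fire)
    - ``mantle_rpkm``, ``hemolymph_rpkm``
    - ``best_other_organ``, ``best_other_rpkm``: the non-mantle organ with
      the highest RPKM
    - ``rule_non_mantle`` / ``rule_non_mantle_non_hemolymph``: boolean
      flags for the two (nested) selection rules, so that the
      hemolymph-excluding set is visible as a subset of the non-mantle set
    """

    table: pd.DataFrame
    thresholds: ExpressionThresholds = field(default_factory=ExpressionThresholds)

    def genes_in_class(self, origin_class: str) -> pd.Index:
        if origin_class not in ORIGIN_CLASSES:
            raise ValidationError(f"unknown origin class {origin_class!r}")
        return self.table.index[self.table["origin_class"] == origin_class]

    def class_counts(self) -> pd.Series:
        return self.table["origin_class"].value_counts().reindex(
            ORIGIN_CLASSES, fill_value=0
        )


def compute_rpkm(counts: CountMatrix) -> ExpressionMatrix:
    """RPKM = 1e9 * count / (gene length in bp * library size).

    A zero count maps to RPKM 0 for any length and depth.
    """
    lib = counts.library_sizes
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValidationError(f"zero or negative library size for sample {bad!r}")
    denom = np.outer(counts.gene_lengths.to_numpy(float), lib.to_numpy(float))
    rpkm = counts.counts.to_numpy(float) * 1e9 / denom
    return ExpressionMatrix(
        rpkm=pd.DataFrame(rpkm, index=counts.gene_ids, columns=counts.sample_labels),
        gene_lengths=counts.gene_lengths.copy(),
    )


def call_expressed(
    expr: ExpressionMatrix,
    thresholds: ExpressionThresholds | None = None,
) -> pd.DataFrame:
    """Boolean (gene, sample) matrix: expressed iff RPKM strictly > threshold."""
    thresholds = thresholds or ExpressionThresholds()
    return expr.rpkm > thresholds.expressed_min_rpkm


def classify_shell_protein_origin(
    expr: ExpressionMatrix,
    smp_gene_ids: Iterable[str],
    mantle_label: str = "Man",
    hemolymph_label: str = "Hem",
    thresholds: ExpressionThresholds | None = None,
) -> OriginClassification:
    """Classify each SMP gene by the organ profile of its expression.

    A gene is ``non_mantle`` when it is unexpressed in the mantle
    (RPKM < threshold) and at least one other organ has RPKM above the
    threshold and at least ``fold_min`` times the mantle RPKM.  It is
    ``non_mantle_non_hemolymph`` when additionally the hemolymph RPKM is
    below the threshold — the stricter rule that excludes circulating
    hemocytes as the apparent source.  ``mantle_expressed`` requires mantle
    RPKM above the threshold; everything else is
    ``unexpressed_everywhere``.
    """
    thresholds = thresholds or ExpressionThresholds()
    for label in (mantle_label, hemolymph_label):
        if label not in expr.sample_labels:
            raise ValidationError(f"unknown organ label {label!r}")
    smp_gene_ids = pd.Index(smp_gene_ids)
    missing = smp_gene_ids.difference(expr.gene_ids)
    if len(missing):
        raise ValidationError(f"SMP gene id(s) absent from matrix: {list(missing[:5])}")

    sub = expr.rpkm.loc[smp_gene_ids]
    mantle = sub[mantle_label]
    hemolymph = sub[hemolymph_label]
    others = sub.drop(columns=[mantle_label])
    best_other_organ = others.idxmax(axis=1)
    best_other = others.max(axis=1)

    t = thresholds.expressed_min_rpkm
    fold = thresholds.fold_min
    # any non-mantle organ above the expression threshold and >= fold x mantle
    qualifying = (others.gt(t)) & (others.ge(fold * mantle, axis=0))
    rule_non_mantle = mantle.lt(t) & qualifying.any(axis=1)
    rule_non_mantle_non_hem = rule_non_mantle & hemolymph.lt(t)

    origin_class = pd.Series("unexpressed_everywhere", index=smp_gene_ids, dtype=object)
    origin_class[mantle.gt(t)] = "mantle_expressed"
    origin_class[rule_non_mantle] = "non_mantle"
    origin_class[rule_non_mantle_non_hem] = "non_mantle_non_hemolymph"

    table = pd.DataFrame(
        {
            "origin_class": origin_class,
            "mantle_rpkm": mantle,
            "hemolymph_rpkm": hemolymph,
            "best_other_organ": best_other_organ,
            "best_other_rpkm": best_other,
            "rule_non_mantle": rule_non_mantle,
            "rule_non_mantle_non_hemolymph": rule_non_mantle_non_hem,
        }
    )
    table.index.name = "gene_id"
    return OriginClassification(table=table, thresholds=thresholds)


def summarize_organ_distribution(
    expr: ExpressionMatrix,
    smp_gene_ids: Iterable[str],
    thresholds: ExpressionThresholds | None = None,
) -> pd.DataFrame:
    """Per-organ expressed-SMP-gene count and summed SMP RPKM.

    Mirrors the two standard atlas summaries: how many SMP genes each organ
    expresses, and where the bulk of SMP transcription sits.
    """
    thresholds = thresholds or ExpressionThresholds()
    smp_gene_ids = pd.Index(smp_gene_ids)
    missing = smp_gene_ids.difference(expr.gene_ids)
    if len(missing):
        raise ValidationError(f"SMP gene id(s) absent from matrix: {list(missing[:5])}")
    sub = expr.rpkm.loc[smp_gene_ids]
    out = pd.DataFrame(
        {
            "n_expressed": (sub > thresholds.expressed_min_rpkm).sum(axis=0).astype(int),
            "total_rpkm": sub.sum(axis=0),
        }
    )
    out.index.name = "organ"
    return out
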