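"""Hypergeometric term over-representation with FDR adjustment.

Given a study set of genes (e.g. the persistently damage-upregulated set,
or the shell-matrix-protein set) inside a population, each annotation term
is scored by the upper-tail hypergeometric probability of drawing at least
the observed number of annotated genes when sampling the study set without
replacement:

    p = sum_{i=x}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

with N the population size, K the term's annotated genes in the
population, n the study-set size and x the overlap.  Only
over-representation is tested.  Benjamini-Hochberg q-values are reported
alongside the raw p-values.

The population defaults to every gene supplied, including unannotated
ones; ``restrict_to_annotated=True`` shrinks the universe to genes
carrying at least one term, which changes every p-value — the choice is
exposed rather than hidden.  No ontology-graph propagation is performed:
genes are tested against the terms they are directly annotated with.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ValidationError

__all__ = ["AnnotationMap", "EnrichmentResult", "hypergeom_enrich", "bh_adjust"]


@dataclass
class AnnotationMap:
    """Gene -> term assignments with optional term metadata.

    ``table``: two columns, ``gene_id`` and ``term_id`` (one row per
    assignment; duplicates are dropped).  ``term_meta``: optional frame
    indexed by ``term_id`` with ``label`` and ``term_class`` columns
    (e.g. BP/MF/CC or ``pathway``).
    """

    table: pd.DataFrame
    term_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"gene_id", "term_id"}
        if not required.issubset(self.table.columns):
            raise ValidationError("annotation table needs gene_id and term_id columns")
        self.table = self.table[["gene_id", "term_id"]].drop_duplicates()
        if self.term_meta is not None and self.term_meta.index.has_duplicates:
            raise ValidationError("duplicate term ids in term metadata")

    def terms_for(self, gene_id: str) -> set:
        return set(self.table.loc[self.table["gene_id"] == gene_id, "term_id"])

    def genes_for(self, term_id: str) -> set:
        return set(self.table.loc[self.table["term_id"] == term_id, "gene_id"])


@dataclass
class EnrichmentResult:
    """Per-term overlap counts and (adjusted) over-representation p-values.

    ``table`` columns: ``term_id``, ``label``, ``term_class``, ``K``
    (annotated in population), ``n`` (study size), ``x`` (annotated in
    study set), ``N`` (population size), ``p``, ``q``.
    """

    table: pd.DataFrame
    population_size: int
    study_size: int

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> pd.DataFrame:
        col = "q" if adjusted else "p"
        return self.table[self.table[col] < alpha]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    study_set: Iterable[str],
    population: Iterable[str],
    annotations: AnnotationMap,
    restrict_to_annotated: bool = False,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of every term in the population.

    Every term annotated to at least one population gene is reported, with
    p = P(overlap >= x) computed through the stable survival function of
    the hypergeometric distribution and q from Benjamini-Hochberg across
    the reported terms.
    """
    study = pd.Index(pd.unique(pd.Series(list(study_set))))
    pop = pd.Index(pd.unique(pd.Series(list(population))))
    offenders = study.difference(pop)
    if len(offenders):
        raise ValidationError(
            f"study gene(s) absent from population: {sorted(offenders)[:10]}"
        )

    ann = annotations.table[annotations.table["gene_id"].isin(pop)]
    if restrict_to_annotated:
        pop = pd.Index(pd.unique(ann["gene_id"]))
        study = study.intersection(pop)

    N = len(pop)
    n = len(study)
    by_term = ann.groupby("term_id")["gene_id"]
    K = by_term.nunique()
    study_genes = set(study)
    x = by_term.agg(lambda g: len(study_genes.intersection(g)))

    p = stats.hypergeom.sf(x.to_numpy() - 1, N, K.to_numpy(), n)
    table = pd.DataFrame(
        {
            "term_id": K.index,
            "K": K.to_numpy(int),
            "n": n,
            "x": x.to_numpy(int),
            "N": N,
            "p": p,
        }
    ).reset_index(drop=True)
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []

    if annotations.term_meta is not None:
        meta = annotations.term_meta.reindex(table["term_id"])
        table.insert(1, "label", meta.get("label", pd.Series(index=meta.index)).to_numpy())
        table.insert(2, "term_class",
                     meta.get("term_class", pd.Series(index=meta.index)).to_numpy())
    else:
        table.insert(1, "label", table["term_id"])
        table.insert(2, "term_class", "NA")

    table = table.sort_values("p", kind="stable").reset_index(drop=True)
    return EnrichmentResult(table=table, population_size=N, study_size=n)
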