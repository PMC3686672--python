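"""TSV readers and writers for count matrices, manifests, gene lists and annotations.

All files are tab-separated UTF-8 without quoting (gene identifiers with
commas are common; tabs are not).  The count-table layout is::

    gene_id<TAB>length<TAB><sample1><TAB><sample2>...

one row per gene, integer counts.  The samples manifest has columns
``sample``, ``role`` (``organ_atlas``/``timecourse``), ``side``
(``left``/``right``/``NA``), ``date`` (a day label or ``control``) and
``organ`` (or ``NA``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .expression import CountMatrix, ValidationError

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_manifest",
    "write_manifest",
    "read_gene_list",
    "write_gene_list",
    "read_annotations",
    "write_table",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.10g"


def read_count_matrix(path, manifest: pd.DataFrame | None = None) -> CountMatrix:
    """Read a counts TSV into a validated :class:`CountMatrix`.

    When a manifest is given, its sample labels must all be present among
    the count columns.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id" or df.columns[1] != "length":
        raise ValidationError(
            f"{path}: first two columns must be 'gene_id' and 'length', "
            f"got {list(df.columns[:2])}"
        )
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicated gene_id {dup.iloc[0]!r}")
    df = df.set_index("gene_id")
    counts = df.drop(columns=["length"])
    for col in counts.columns:
        vals = counts[col]
        as_float = pd.to_numeric(vals, errors="coerce")
        if as_float.isna().any():
            line = int(np.argmax(as_float.isna().to_numpy())) + 2  # header is line 1
            raise ValidationError(f"{path}: malformed count in column {col!r}, line {line}")
        if not np.allclose(as_float, np.round(as_float)):
            line = int(np.argmax(~np.isclose(as_float, np.round(as_float)))) + 2
            raise ValidationError(
                f"{path}: non-integer count in column {col!r}, line {line}"
            )
    counts = counts.astype(np.int64)
    cm = CountMatrix(counts=counts, gene_lengths=df["length"].astype(float))
    if manifest is not None:
        missing = [s for s in manifest["sample"] if s not in cm.sample_labels]
        if missing:
            raise ValidationError(f"manifest sample(s) missing from {path}: {missing}")
    return cm


def write_count_matrix(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.gene_lengths.astype(int))
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise ValidationError(f"{path}: manifest needs a 'sample' column")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicated sample label {dup!r}")
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_annotations(path, term_meta_path=None):
    """Read a two-column (gene_id, term_id) TSV, optionally with term metadata."""
    from .enrichment import AnnotationMap

    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"}.issubset(table.columns):
        raise ValidationError(f"{path}: needs 'gene_id' and 'term_id' columns")
    meta = None
    if term_meta_path is not None:
        meta = pd.read_csv(term_meta_path, sep="\t", dtype=str).set_index("term_id")
    return AnnotationMap(table=table, term_meta=meta)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a results table with a fixed float format for reproducible bytes."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
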