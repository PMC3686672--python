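"""Exact differential expression between two unreplicated count libraries.

Each treated library is compared with its same-side control library one
gene at a time.  With a single library per condition there is no dispersion
to estimate, so significance comes from an exact conditional test on the
pair of counts: given the control count ``x`` from a library of depth
``N1``, the treated count ``Y`` under the null of equal transcription rates
follows

    P(Y = y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

the conditional law of Audic & Claverie's comparison of digital expression
profiles.  This is a negative-binomial distribution with ``x+1`` successes
and success probability ``N1/(N1+N2)``, which makes both tails computable
in a numerically stable way through the regularised incomplete beta
function for counts up to millions of reads.

The two-sided p-value doubles the smaller tail (capped at 1).  Calls use a
hard threshold (default p < 1e-3, strict) with direction taken from the
depth-normalised rates; no multiple-testing correction is applied at this
step — persistence across sampling dates is the multiplicity device
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import CountMatrix, ValidationError

__all__ = [
    "LibraryPair",
    "DECallSet",
    "exact_two_library_test",
    "fisher_two_library_test",
    "call_de",
    "de_count_table",
]

CONTROL_DATE = "control"


@dataclass
class LibraryPair:
    """Counts for one gene in two libraries, with the library depths."""

    x: int
    y: int
    n1: float
    n2: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValidationError("counts must be non-negative")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValidationError("library depths must be positive")

    def p_value(self) -> float:
        return float(exact_two_library_test(self.x, self.y, self.n1, self.n2))


def exact_two_library_test(x, y, n1, n2):
    """Two-sided exact conditional p-value for one or many genes.

    Vectorised over ``x`` and ``y`` (``n1``/``n2`` may be scalars or
    arrays).  Conditioning is on the first (control) count; the test is not
    exactly invariant under swapping the two libraries at very small
    counts, a known property of the conditional construction.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("counts must be non-negative")
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 <= 0).any() or (n2 <= 0).any():
        raise ValidationError("library depths must be positive")
    # Y | x ~ NegBin(r = x + 1, p = n1 / (n1 + n2))
    p_succ = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p_succ)      # P(Y <= y)
    upper = stats.nbinom.sf(y - 1, x + 1, p_succ)   # P(Y >= y)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def fisher_two_library_test(x: int, y: int, n1: float, n2: float) -> float:
    """Fisher's exact test on the 2x2 table (count, depth-count) per library.

    Provided for sensitivity analysis against the conditional test; not
    vectorised, and slow for deep libraries.
    """
    if x < 0 or y < 0:
        raise ValidationError("counts must be non-negative")
    n1i, n2i = int(round(n1)), int(round(n2))
    table = [[x, n1i - x], [y, n2i - y]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class DECallSet:
    """Per (gene, side, date) exact-test p-values and up/down/none calls.

    ``table`` is long-format with columns ``gene_id``, ``side``, ``date``,
    ``p_value``, ``direction``.  ``direction`` is ``none`` whenever
    ``p >= alpha`` or the depth-normalised rates tie.
    """

    table: pd.DataFrame
    alpha: float
    dates: dict  # side -> ordered list of date labels

    def call_matrix(self, side: str, direction: str) -> pd.DataFrame:
        """Boolean genes x dates matrix of calls for one side and direction."""
        sub = self.table[self.table["side"] == side]
        if sub.empty:
            raise ValidationError(f"no calls for side {side!r}")
        mat = (
            sub.assign(hit=sub["direction"] == direction)
            .pivot(index="gene_id", columns="date", values="hit")
        )
        return mat[self.dates[side]]


def _direction(p: np.ndarray, x: np.ndarray, y: np.ndarray,
               n1: float, n2: float, alpha: float) -> np.ndarray:
    """Direction labels: strict p < alpha, rate ties resolve to 'none'."""
    rate_c = x / n1
    rate_t = y / n2
    out = np.full(p.shape, "none", dtype=object)
    sig = p < alpha
    out[sig & (rate_t > rate_c)] = "up"
    out[sig & (rate_t < rate_c)] = "down"
    return out


def call_de(
    counts: CountMatrix,
    manifest: pd.DataFrame,
    alpha: float = 1e-3,
) -> DECallSet:
    """Exact-test DE calls of every treated library against its side control.

    ``manifest`` needs columns ``sample``, ``side``, ``date`` where
    ``date == "control"`` marks the side's control library; every listed
    sample must be a column of ``counts``.
    """
    required = {"sample", "side", "date"}
    if not required.issubset(manifest.columns):
        raise ValidationError(f"manifest must have columns {sorted(required)}")
    missing = [s for s in manifest["sample"] if s not in counts.sample_labels]
    if missing:
        raise ValidationError(f"manifest sample(s) absent from counts: {missing[:5]}")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")

    records = []
    dates: dict = {}
    for side, grp in manifest.groupby("side", sort=False):
        ctrl_rows = grp[grp["date"].astype(str) == CONTROL_DATE]
        if len(ctrl_rows) != 1:
            raise ValidationError(
                f"side {side!r} needs exactly one control sample, found {len(ctrl_rows)}"
            )
        ctrl = ctrl_rows["sample"].iloc[0]
        treated = grp[grp["date"].astype(str) != CONTROL_DATE]
        if treated.empty:
            raise ValidationError(f"side {side!r} has no treated samples")
        dates[side] = [str(d) for d in treated["date"]]
        x = counts.counts[ctrl].to_numpy()
        n1 = float(counts.library_sizes[ctrl])
        for _, row in treated.iterrows():
            y = counts.counts[row["sample"]].to_numpy()
            n2 = float(counts.library_sizes[row["sample"]])
            p = exact_two_library_test(x, y, n1, n2)
            records.append(
                pd.DataFrame(
                    {
                        "gene_id": counts.gene_ids,
                        "side": side,
                        "date": str(row["date"]),
                        "p_value": p,
                        "direction": _direction(p, x, y, n1, n2, alpha),
                    }
                )
            )
    table = pd.concat(records, ignore_index=True)
    return DECallSet(table=table, alpha=alpha, dates=dates)


def de_count_table(calls: DECallSet) -> pd.DataFrame:
    """Numbers of up- and downregulated genes per (side, date)."""
    rows = []
    for side, date_list in calls.dates.items():
        sub = calls.table[calls.table["side"] == side]
        for date in date_list:
            at = sub[sub["date"] == date]
            rows.append(
                {
                    "side": side,
                    "date": date,
                    "n_up": int((at["direction"] == "up").sum()),
                    "n_down": int((at["direction"] == "down").sum()),
                }
            )
    return pd.DataFrame(rows)
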