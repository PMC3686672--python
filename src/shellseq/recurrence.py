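"""Recurrence of differential-expression calls across a time course.

A gene genuinely responding to shell damage should be called upregulated
on the damaged side on most sampling dates, whereas chance calls scatter:
if per-date calls were independent noise, the number of genes called on
exactly ``k`` of the ``n`` dates should fall off rapidly with ``k``.  This
module counts per-gene recurrence, formalises that random-decay null two
ways, and selects the persistently upregulated genes.

Null models
-----------
``binomial``
    Per-date call probabilities ``p_1..p_n`` (by default estimated from the
    contralateral, undamaged side) with independence across dates gives the
    recurrence count a Poisson-binomial law; expected gene numbers at each
    ``k`` follow in closed form.
``permutation``
    Each date's call vector is shuffled across genes independently,
    preserving the per-date call counts exactly; the recurrence histogram
    is averaged over replicates.  This is the stricter, assumption-light
    check, and its replicates also provide a Monte-Carlo tail p-value for
    the excess of highly recurrent genes.

Both nulls assume exchangeability of dates (no temporal autocorrelation is
modelled) and independence across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DECallSet
from .expression import ValidationError

__all__ = [
    "RecurrenceProfile",
    "NullSpec",
    "NullRecurrence",
    "RecurrenceDistribution",
    "count_recurrence",
    "estimate_date_probs",
    "poisson_binomial_pmf",
    "null_recurrence",
    "excess_statistic",
    "select_persistent_genes",
]


@dataclass
class RecurrenceProfile:
    """Per-gene recurrence count ``k``: dates (of ``n``) with a given call."""

    k: pd.Series  # int per gene
    n_dates: int
    side: str
    direction: str

    def __post_init__(self) -> None:
        if ((self.k < 0) | (self.k > self.n_dates)).any():
            raise ValidationError("recurrence counts must lie in [0, n_dates]")

    def histogram(self) -> np.ndarray:
        """Observed gene counts at exactly k = 0..n dates."""
        return np.bincount(self.k.to_numpy(int), minlength=self.n_dates + 1).astype(float)

    def cumulative_histogram(self) -> np.ndarray:
        """Observed gene counts at >= k dates, k = 0..n."""
        return self.histogram()[::-1].cumsum()[::-1]


@dataclass
class NullSpec:
    """Configuration of the random-recurrence null.

    ``date_probs`` are the per-date marginal call probabilities for the
    binomial (Poisson-binomial) mode; when ``None`` they are estimated from
    the data handed to :func:`null_recurrence`.
    """

    mode: str = "permutation"
    date_probs: np.ndarray | None = None
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("binomial", "permutation"):
            raise ValidationError(f"unknown null mode {self.mode!r}")
        if self.date_probs is not None:
            self.date_probs = np.asarray(self.date_probs, dtype=float)
            if ((self.date_probs < 0) | (self.date_probs > 1)).any():
                raise ValidationError("date_probs must lie in [0, 1]")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")


@dataclass
class NullRecurrence:
    """Expected recurrence histogram under a null, plus permutation replicates."""

    expected: np.ndarray  # length n + 1, sums to n_genes
    n_genes: int
    mode: str
    date_probs: np.ndarray | None = None
    replicate_histograms: np.ndarray | None = None  # (R, n + 1), permutation mode


@dataclass
class RecurrenceDistribution:
    """Observed vs expected recurrence histogram with the tail excess test."""

    table: pd.DataFrame  # k, observed, expected, excess, observed_cum, expected_cum
    n_genes: int
    tail_k: int
    observed_tail: float
    expected_tail: float
    tail_p: float


def count_recurrence(calls: DECallSet, side: str, direction: str) -> RecurrenceProfile:
    """Number of dates on which each gene carries the given call."""
    mat = calls.call_matrix(side, direction)
    return RecurrenceProfile(
        k=mat.sum(axis=1).astype(int),
        n_dates=mat.shape[1],
        side=side,
        direction=direction,
    )


def estimate_date_probs(calls: DECallSet, side: str, direction: str) -> np.ndarray:
    """Empirical per-date call fraction for one side and direction."""
    mat = calls.call_matrix(side, direction)
    return mat.mean(axis=0).to_numpy(float)


def poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """PMF of a sum of independent Bernoulli(p_d), by direct convolution.

    Exact (up to float rounding) and fast for the handful of dates used
    here; k runs 0..n.
    """
    probs = np.asarray(probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValidationError("probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def null_recurrence(
    n_genes: int,
    null: NullSpec,
    call_matrix: pd.DataFrame | None = None,
) -> NullRecurrence:
    """Expected gene counts at each recurrence level under the null.

    Binomial mode needs per-date probabilities (from ``null.date_probs`` or
    estimated from ``call_matrix``); permutation mode needs the full
    boolean genes x dates ``call_matrix`` and averages the histogram over
    independent per-date shuffles.
    """
    if null.mode == "binomial":
        probs = null.date_probs
        if probs is None:
            if call_matrix is None:
                raise ValidationError(
                    "binomial null needs date_probs or a call matrix to estimate them"
                )
            probs = call_matrix.mean(axis=0).to_numpy(float)
        expected = n_genes * poisson_binomial_pmf(probs)
        return NullRecurrence(expected=expected, n_genes=n_genes,
                              mode="binomial", date_probs=np.asarray(probs, float))

    if call_matrix is None:
        raise ValidationError("permutation null needs the call matrix")
    mat = call_matrix.to_numpy(bool)
    if mat.shape[0] != n_genes:
        raise ValidationError("call matrix row count must equal n_genes")
    n = mat.shape[1]
    rng = np.random.default_rng(null.seed)
    hists = np.empty((null.n_permutations, n + 1))
    for r in range(null.n_permutations):
        shuffled = rng.permuted(mat, axis=0)  # independent shuffle per date
        hists[r] = np.bincount(shuffled.sum(axis=1), minlength=n + 1)
    return NullRecurrence(
        expected=hists.mean(axis=0),
        n_genes=n_genes,
        mode="permutation",
        replicate_histograms=hists,
    )


def excess_statistic(
    profile: RecurrenceProfile,
    null_result: NullRecurrence,
    k_min: int = 6,
    tie_break: str = "conservative",
    seed: int | None = None,
) -> RecurrenceDistribution:
    """Observed-minus-expected recurrence counts and the k >= k_min tail test.

    The tail p-value asks whether the number of genes called on at least
    ``k_min`` dates exceeds what the null produces.  In permutation mode it
    is the add-one-corrected fraction of replicates whose tail count
    reaches the observed one; ``tie_break="randomized"`` breaks ties in the
    discrete counts with uniform jitter, which makes the p-value exactly
    uniform under the null (useful for calibration checks) at the cost of
    a randomised decision.  In binomial mode the tail count of independent
    genes is Binomial(G, q) with q the Poisson-binomial tail mass, giving
    an analytic p-value.
    """
    n = profile.n_dates
    if not 0 <= k_min <= n:
        raise ValidationError(f"k_min must lie in [0, {n}]")
    if tie_break not in ("conservative", "randomized"):
        raise ValidationError(f"unknown tie_break {tie_break!r}")
    observed = profile.histogram()
    expected = null_result.expected
    if len(expected) != n + 1:
        raise ValidationError("null and profile disagree on the number of dates")

    obs_tail = float(observed[k_min:].sum())
    exp_tail = float(expected[k_min:].sum())

    if null_result.mode == "permutation":
        reps = null_result.replicate_histograms[:, k_min:].sum(axis=1)
        if tie_break == "randomized":
            rng = np.random.default_rng(seed)
            jitter = rng.uniform(0, 1, size=len(reps) + 1)
            tail_p = (1.0 + np.sum(reps + jitter[:-1] >= obs_tail + jitter[-1])) / (
                len(reps) + 1.0
            )
        else:
            tail_p = (1.0 + np.sum(reps >= obs_tail)) / (len(reps) + 1.0)
    else:
        q = float(poisson_binomial_pmf(null_result.date_probs)[k_min:].sum())
        tail_p = float(stats.binom.sf(obs_tail - 1, null_result.n_genes, q))

    table = pd.DataFrame(
        {
            "k": np.arange(n + 1),
            "observed": observed,
            "expected": expected,
            "excess": observed - expected,
            "observed_cum": observed[::-1].cumsum()[::-1],
            "expected_cum": expected[::-1].cumsum()[::-1],
        }
    )
    return RecurrenceDistribution(
        table=table,
        n_genes=null_result.n_genes,
        tail_k=k_min,
        observed_tail=obs_tail,
        expected_tail=exp_tail,
        tail_p=float(tail_p),
    )


def select_persistent_genes(profile: RecurrenceProfile, k_min: int = 6) -> pd.Index:
    """Genes with calls on at least ``k_min`` of the ``n`` dates."""
    if k_min > profile.n_dates:
        raise ValidationError(
            f"k_min={k_min} exceeds the number of dates ({profile.n_dates})"
        )
    if k_min < 0:
        raise ValidationError("k_min must be non-negative")
    return profile.k.index[profile.k >= k_min]
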