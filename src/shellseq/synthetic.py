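"""Synthetic count-data generation with known ground truth.

Two simulated designs mirror the two experiments the pipeline analyses:

* an **organ atlas** — one pooled RNA-seq library per organ (eight organs,
  mantle first), in which a configurable fraction of shell-matrix-protein
  (SMP) genes is injected with a non-mantle expression profile (silent in
  the mantle, clearly expressed in some other organ, optionally silent in
  the hemolymph as well);
* a **shell-damage time course** — left/right mantle libraries for a
  control plus seven post-damage sampling dates, in which a configurable
  fraction of genes carries a persistent fold-change in the damaged-side
  (left) libraries on a chosen number of dates, and another fraction is
  only transiently perturbed.  The right side is always a pure null.

Counts are drawn per gene per library from a negative binomial
(gamma-Poisson) with a common dispersion; dispersion 0 gives the Poisson
limit.  Each condition is a single library of pooled individuals, so no
replicate structure exists to simulate.  Per-gene baseline levels are
log-normal and globally normalised so that expected RPKM values are on the
scale of their targets and expected column sums match the nominal library
sizes.  Every injected signal is recorded in a :class:`TruthLabels` object
together with the expected (noise-free) values, so downstream stages can
be scored for parameter recovery against the construction itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import CountMatrix, ValidationError

__all__ = [
    "AtlasScenario",
    "TimeCourseScenario",
    "TruthLabels",
    "simulate_organ_atlas",
    "simulate_damage_timecourse",
    "simulate_annotations",
]

DEFAULT_ORGANS = ("Man", "Fgo", "Amu", "Hem", "Dgl", "Gil", "Lpa", "Mgo")

# Injected non-mantle-origin profile, in RPKM units (the expression
# threshold is 5): silent organs sit well below it, the "home" organ well
# above it, leaving comfortable margins against counting noise.
_LOW_RPKM = (0.5, 2.5)
_BACKGROUND_RPKM = (0.5, 4.0)
_HOME_RPKM = (12.0, 60.0)
_HEM_EXPRESSED_RPKM = (8.0, 30.0)


def _check_fraction(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")


def _from_dict(cls, data: dict):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown {cls.__name__} field(s): {sorted(unknown)}")
    return cls(**data)


@dataclass
class AtlasScenario:
    """Configuration of a simulated eight-organ expression atlas."""

    n_genes: int = 10_000
    organ_labels: Sequence[str] = DEFAULT_ORGANS
    library_sizes: float | Sequence[float] | None = None  # None: ~1e7 with jitter
    gene_length_range: tuple[int, int] = (300, 10_000)
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    frac_shell_protein: float = 0.1
    frac_nonmantle_origin: float = 0.10
    frac_nonhemolymph_within_nonmantle: float = 0.8
    mantle_boost: float = 4.0
    mantle_label: str = "Man"
    hemolymph_label: str = "Hem"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        labels = list(self.organ_labels)
        if len(set(labels)) != len(labels):
            raise ValidationError("organ_labels must be unique")
        for lab, name in ((self.mantle_label, "mantle_label"),
                          (self.hemolymph_label, "hemolymph_label")):
            if lab not in labels:
                raise ValidationError(f"{name} {lab!r} missing from organ_labels")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ValidationError("gene_length_range must be a positive interval")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.baseline_log_sd < 0:
            raise ValidationError("baseline_log_sd must be >= 0")
        if self.mantle_boost <= 0:
            raise ValidationError("mantle_boost must be positive")
        _check_fraction(self.frac_shell_protein, "frac_shell_protein")
        _check_fraction(self.frac_nonmantle_origin, "frac_nonmantle_origin")
        _check_fraction(self.frac_nonhemolymph_within_nonmantle,
                        "frac_nonhemolymph_within_nonmantle")
        if self.library_sizes is not None and not np.isscalar(self.library_sizes):
            sizes = np.asarray(self.library_sizes, dtype=float)
            if len(sizes) != len(labels):
                raise ValidationError("library_sizes must give one value per organ")
            if (sizes <= 0).any():
                raise ValidationError("library_sizes must be positive")
        elif np.isscalar(self.library_sizes) and self.library_sizes is not None:
            if float(self.library_sizes) <= 0:
                raise ValidationError("library_sizes must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "AtlasScenario":
        return _from_dict(cls, data)


@dataclass
class TimeCourseScenario:
    """Configuration of a simulated left/right mantle damage time course."""

    n_genes: int = 10_000
    dates: Sequence[int] = (1, 3, 5, 9, 13, 17, 21)
    sides: Sequence[str] = ("left", "right")
    library_sizes: float | None = None  # None: ~1e7 with jitter per library
    gene_length_range: tuple[int, int] = (300, 10_000)
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.0
    frac_damage_responsive: float = 0.02
    effect_fold: float = 4.0
    persistence: int = 7
    frac_transient: float = 0.01
    damaged_side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        dates = list(self.dates)
        if len(dates) == 0 or any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValidationError("dates must be strictly increasing")
        if len(set(self.sides)) != len(list(self.sides)):
            raise ValidationError("sides must be unique")
        if self.damaged_side not in self.sides:
            raise ValidationError(f"damaged_side {self.damaged_side!r} not among sides")
        if not 0 <= self.persistence <= len(dates):
            raise ValidationError(
                f"persistence must lie in [0, {len(dates)}], got {self.persistence}"
            )
        if self.effect_fold <= 0:
            raise ValidationError("effect_fold must be positive")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ValidationError("gene_length_range must be a positive interval")
        _check_fraction(self.frac_damage_responsive, "frac_damage_responsive")
        _check_fraction(self.frac_transient, "frac_transient")
        if self.frac_damage_responsive + self.frac_transient > 1:
            raise ValidationError(
                "frac_damage_responsive + frac_transient must not exceed 1"
            )
        if self.library_sizes is not None and float(self.library_sizes) <= 0:
            raise ValidationError("library_sizes must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "TimeCourseScenario":
        return _from_dict(cls, data)

    def sample_labels(self) -> list[str]:
        labels = []
        for side in self.sides:
            labels.append(f"{side}_control")
            labels.extend(f"{side}_d{d}" for d in self.dates)
        return labels

    def manifest(self) -> pd.DataFrame:
        """Samples manifest (sample, side, date) matching the count columns."""
        rows = []
        for side in self.sides:
            rows.append({"sample": f"{side}_control", "side": side, "date": "control"})
            rows.extend(
                {"sample": f"{side}_d{d}", "side": side, "date": str(d)}
                for d in self.dates
            )
        return pd.DataFrame(rows)


@dataclass
class TruthLabels:
    """Ground-truth flags for simulated genes, plus the noise-free values.

    ``table`` is indexed by gene id with columns ``is_smp``,
    ``origin_class`` (atlas), ``is_damage_responsive``, ``is_transient``
    and ``n_effect_dates`` (time course).  ``expected_rpkm`` /
    ``expected_counts`` hold the construction's expected values so the
    generator can serve as its own oracle.
    """

    table: pd.DataFrame
    expected_rpkm: pd.DataFrame | None = None
    expected_counts: pd.DataFrame | None = None

    def smp_genes(self) -> pd.Index:
        return self.table.index[self.table["is_smp"]]

    def genes_where(self, column: str) -> pd.Index:
        return self.table.index[self.table[column].astype(bool)]


def _gene_ids(n: int) -> pd.Index:
    width = max(5, len(str(n)))
    return pd.Index([f"g{i:0{width}d}" for i in range(1, n + 1)], name="gene_id")


def _draw_counts(rng: np.random.Generator, mean: np.ndarray,
                 dispersion: float) -> np.ndarray:
    """Negative-binomial draw with Var = mu + dispersion * mu^2 (0: Poisson)."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def _baseline_rpkm(rng: np.random.Generator, n: int, lengths: np.ndarray,
                   log_mean: float, log_sd: float) -> np.ndarray:
    """Log-normal relative levels, scaled so that sum(rpkm * length) = 1e9.

    With that normalisation the expected read total of a baseline library
    equals its nominal size, as it would in a real count table.
    """
    base = rng.lognormal(log_mean, log_sd, n)
    return base * 1e9 / float(np.sum(base * lengths))


def _library_sizes(rng: np.random.Generator, labels: Sequence[str],
                   configured) -> pd.Series:
    if configured is None:
        sizes = 1e7 * rng.lognormal(0.0, 0.15, len(labels))
    elif np.isscalar(configured):
        sizes = np.full(len(labels), float(configured))
    else:
        sizes = np.asarray(configured, dtype=float)
    return pd.Series(np.round(sizes), index=pd.Index(labels), dtype=float)


def simulate_organ_atlas(scenario: AtlasScenario) -> tuple[CountMatrix, TruthLabels]:
    """Simulate the eight-organ atlas with injected non-mantle SMP genes.

    SMP genes not injected with a non-mantle profile get their mantle level
    multiplied by ``mantle_boost`` (the mantle is the main shell-forming
    organ, so SMP transcription concentrates there).  Injected genes are
    written directly in RPKM units with margins around the expression
    threshold; see the module constants.  Cardinalities are exact:
    ``floor(frac_shell_protein * n_genes)`` SMP genes, of which
    ``floor(frac_nonmantle_origin * n_smp)`` are non-mantle, of which
    ``floor(frac_nonhemolymph_within_nonmantle * n_nonmantle)`` are also
    hemolymph-silent.
    """
    rng = np.random.default_rng(scenario.seed)
    organs = list(scenario.organ_labels)
    n = scenario.n_genes
    gene_ids = _gene_ids(n)
    lo, hi = scenario.gene_length_range
    lengths = rng.integers(lo, hi + 1, n).astype(float)
    rpkm0 = _baseline_rpkm(rng, n, lengths,
                           scenario.baseline_log_mean, scenario.baseline_log_sd)

    n_smp = int(np.floor(scenario.frac_shell_protein * n))
    smp_idx = rng.choice(n, size=n_smp, replace=False)
    n_nonmantle = int(np.floor(scenario.frac_nonmantle_origin * n_smp))
    nonmantle_idx = rng.choice(smp_idx, size=n_nonmantle, replace=False)
    n_nonhem = int(np.floor(
        scenario.frac_nonhemolymph_within_nonmantle * n_nonmantle))
    nonhem_idx = rng.choice(nonmantle_idx, size=n_nonhem, replace=False)
    nonhem_set = set(nonhem_idx.tolist())
    plain_nonmantle_idx = np.array(
        [i for i in nonmantle_idx if i not in nonhem_set], dtype=int)

    i_man = organs.index(scenario.mantle_label)
    i_hem = organs.index(scenario.hemolymph_label)

    target = np.tile(rpkm0[:, None], (1, len(organs)))
    boosted = np.setdiff1d(smp_idx, nonmantle_idx)
    target[boosted, i_man] *= scenario.mantle_boost

    def _inject(idx: np.ndarray, hemolymph_silent: bool) -> None:
        for i in idx:
            row = rng.uniform(*_BACKGROUND_RPKM, len(organs))
            row[i_man] = rng.uniform(*_LOW_RPKM)
            if hemolymph_silent:
                row[i_hem] = rng.uniform(*_LOW_RPKM)
                home_choices = [j for j in range(len(organs))
                                if j not in (i_man, i_hem)]
            else:
                row[i_hem] = rng.uniform(*_HEM_EXPRESSED_RPKM)
                home_choices = [j for j in range(len(organs)) if j != i_man]
            home = home_choices[rng.integers(len(home_choices))]
            row[home] = rng.uniform(*_HOME_RPKM)
            target[i] = row

    _inject(plain_nonmantle_idx, hemolymph_silent=False)
    _inject(nonhem_idx, hemolymph_silent=True)

    lib = _library_sizes(rng, organs, scenario.library_sizes)
    mean = target * lengths[:, None] * lib.to_numpy()[None, :] / 1e9
    counts = _draw_counts(rng, mean, scenario.dispersion)

    origin = np.array(["unexpressed_everywhere"] * n, dtype=object)
    origin[target[:, i_man] > 5.0] = "mantle_expressed"
    origin[plain_nonmantle_idx] = "non_mantle"
    origin[nonhem_idx] = "non_mantle_non_hemolymph"

    is_smp = np.zeros(n, dtype=bool)
    is_smp[smp_idx] = True
    truth_table = pd.DataFrame(
        {
            "is_smp": is_smp,
            "origin_class": origin,
            "is_damage_responsive": False,
            "is_transient": False,
        },
        index=gene_ids,
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=organs),
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length"),
        library_sizes=lib,
    )
    truth = TruthLabels(
        table=truth_table,
        expected_rpkm=pd.DataFrame(target, index=gene_ids, columns=organs),
    )
    return cm, truth


def simulate_damage_timecourse(
    scenario: TimeCourseScenario,
) -> tuple[CountMatrix, TruthLabels]:
    """Simulate left/right mantle libraries over a damage time course.

    Responsive genes carry ``effect_fold`` on ``persistence`` randomly
    chosen dates in the damaged-side treated libraries only; transient
    genes carry it on one or two random dates.  Controls and the
    contralateral side are baseline draws, so the undamaged side is a pure
    null against which the recurrence machinery can be calibrated.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_genes
    gene_ids = _gene_ids(n)
    lo, hi = scenario.gene_length_range
    lengths = rng.integers(lo, hi + 1, n).astype(float)
    rpkm0 = _baseline_rpkm(rng, n, lengths,
                           scenario.baseline_log_mean, scenario.baseline_log_sd)

    n_resp = int(np.floor(scenario.frac_damage_responsive * n))
    n_trans = int(np.floor(scenario.frac_transient * n))
    chosen = rng.choice(n, size=n_resp + n_trans, replace=False)
    resp_idx, trans_idx = chosen[:n_resp], chosen[n_resp:]

    dates = [str(d) for d in scenario.dates]
    n_dates = len(dates)
    labels = scenario.sample_labels()
    lib = _library_sizes(rng, labels, scenario.library_sizes)

    # fold-change multiplier per (gene, sample); controls stay at 1
    effect = pd.DataFrame(1.0, index=gene_ids, columns=labels)
    damaged = scenario.damaged_side
    n_effect_dates = np.zeros(n, dtype=int)
    for i in resp_idx:
        on = rng.choice(n_dates, size=scenario.persistence, replace=False)
        n_effect_dates[i] = scenario.persistence
        for d in on:
            effect.iloc[i, effect.columns.get_loc(f"{damaged}_d{dates[d]}")] = (
                scenario.effect_fold
            )
    for i in trans_idx:
        k = int(rng.integers(1, 3))  # 1 or 2 dates
        on = rng.choice(n_dates, size=k, replace=False)
        n_effect_dates[i] = k
        for d in on:
            effect.iloc[i, effect.columns.get_loc(f"{damaged}_d{dates[d]}")] = (
                scenario.effect_fold
            )

    mean = (
        rpkm0[:, None]
        * effect.to_numpy()
        * lengths[:, None]
        * lib.to_numpy()[None, :]
        / 1e9
    )
    counts = _draw_counts(rng, mean, scenario.dispersion)

    is_resp = np.zeros(n, dtype=bool)
    is_resp[resp_idx] = True
    is_trans = np.zeros(n, dtype=bool)
    is_trans[trans_idx] = True
    truth_table = pd.DataFrame(
        {
            "is_smp": False,
            "origin_class": "NA",
            "is_damage_responsive": is_resp,
            "is_transient": is_trans,
            "n_effect_dates": n_effect_dates,
        },
        index=gene_ids,
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=labels),
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length"),
        library_sizes=lib,
    )
    truth = TruthLabels(
        table=truth_table,
        expected_counts=pd.DataFrame(mean, index=gene_ids, columns=labels),
    )
    return cm, truth


def simulate_null_call_matrix(
    n_genes: int = 800,
    n_dates: int = 7,
    alpha: float = 0.05,
    side: str = "right",
    direction: str = "up",
    seed: int = 0,
) -> pd.DataFrame:
    """Null per-date call matrix with an *independent control per date*.

    In the damage design every treated library is compared against the one
    control library of its side, which correlates null calls across dates
    (a low control draw makes a gene look upregulated on every date at
    once).  For calibration checks of the recurrence null — which assumes
    per-date independence — this helper instead simulates each date as its
    own two-library null experiment with a fresh control, and assembles
    the boolean genes x dates call matrix.
    """
    from .diffexpr import call_de

    cols = {}
    for d in range(n_dates):
        scenario = TimeCourseScenario(
            n_genes=n_genes,
            dates=(d + 1,),
            frac_damage_responsive=0.0,
            frac_transient=0.0,
            persistence=0,
            seed=seed * n_dates + d,
        )
        counts, _ = simulate_damage_timecourse(scenario)
        calls = call_de(counts, scenario.manifest(), alpha=alpha)
        mat = calls.call_matrix(side, direction)
        cols[str(d + 1)] = mat.iloc[:, 0]
    return pd.DataFrame(cols)


def simulate_annotations(
    gene_ids: Sequence[str],
    n_terms: int = 100,
    mean_terms_per_gene: float = 2.0,
    enriched_term: str | None = None,
    enriched_genes: Sequence[str] | None = None,
    enriched_prob: float = 0.6,
    term_classes: Sequence[str] = ("BP", "MF", "CC"),
    seed: int = 0,
):
    """Random gene -> term annotation with an optionally enriched term.

    Each gene draws Poisson(``mean_terms_per_gene``) terms uniformly.  When
    ``enriched_term``/``enriched_genes`` are given, each listed gene
    additionally carries that term with probability ``enriched_prob``,
    planting a known over-representation signal.  Returns an
    :class:`~shellseq.enrichment.AnnotationMap`.
    """
    from .enrichment import AnnotationMap

    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    term_ids = [f"T{i:04d}" for i in range(1, n_terms + 1)]
    rows = []
    for g in gene_ids:
        for t in rng.choice(n_terms, size=rng.poisson(mean_terms_per_gene)):
            rows.append((g, term_ids[t]))
    if enriched_term is not None and enriched_genes is not None:
        for g in enriched_genes:
            if rng.uniform() < enriched_prob:
                rows.append((g, enriched_term))
    table = pd.DataFrame(rows, columns=["gene_id", "term_id"])
    all_terms = sorted(set(table["term_id"]))
    meta = pd.DataFrame(
        {
            "label": [f"synthetic term {t}" for t in all_terms],
            "term_class": [term_classes[i % len(term_classes)]
                           for i in range(len(all_terms))],
        },
        index=pd.Index(all_terms, name="term_id"),
    )
    return AnnotationMap(table=table, term_meta=meta)
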