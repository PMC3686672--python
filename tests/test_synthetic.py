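"""Ground-truth construction and statistical contracts of the generators."""

import numpy as np
import pandas as pd
import pytest

from shellseq import (
    AtlasScenario,
    TimeCourseScenario,
    ValidationError,
    simulate_annotations,
    simulate_damage_timecourse,
    simulate_organ_atlas,
)
from shellseq.synthetic import _draw_counts


def test_atlas_determinism():
    scenario = AtlasScenario(n_genes=500, seed=123)
    a_counts, a_truth = simulate_organ_atlas(scenario)
    b_counts, b_truth = simulate_organ_atlas(AtlasScenario(n_genes=500, seed=123))
    pd.testing.assert_frame_equal(a_counts.counts, b_counts.counts)
    pd.testing.assert_frame_equal(a_truth.table, b_truth.table)
    pd.testing.assert_series_equal(a_counts.library_sizes, b_counts.library_sizes)


def test_timecourse_determinism():
    scenario = TimeCourseScenario(n_genes=500, seed=321)
    a, _ = simulate_damage_timecourse(scenario)
    b, _ = simulate_damage_timecourse(TimeCourseScenario(n_genes=500, seed=321))
    pd.testing.assert_frame_equal(a.counts, b.counts)


def test_truth_cardinalities_are_exact_floors():
    sc = AtlasScenario(n_genes=1234, frac_shell_protein=0.27,
                       frac_nonmantle_origin=0.31,
                       frac_nonhemolymph_within_nonmantle=0.5, seed=5)
    _, truth = simulate_organ_atlas(sc)
    n_smp = int(np.floor(0.27 * 1234))
    assert truth.table["is_smp"].sum() == n_smp
    n_nonmantle = int(np.floor(0.31 * n_smp))
    nm = truth.table["origin_class"].isin(["non_mantle", "non_mantle_non_hemolymph"])
    assert nm.sum() == n_nonmantle
    n_nonhem = int(np.floor(0.5 * n_nonmantle))
    assert (truth.table["origin_class"] == "non_mantle_non_hemolymph").sum() == n_nonhem

    tc = TimeCourseScenario(n_genes=1111, frac_damage_responsive=0.07,
                            frac_transient=0.013, seed=5)
    _, tc_truth = simulate_damage_timecourse(tc)
    assert tc_truth.table["is_damage_responsive"].sum() == int(np.floor(0.07 * 1111))
    assert tc_truth.table["is_transient"].sum() == int(np.floor(0.013 * 1111))


@pytest.mark.parametrize(
    "kwargs,field",
    [
        (dict(n_genes=0), "n_genes"),
        (dict(frac_shell_protein=1.2), "frac_shell_protein"),
        (dict(organ_labels=("Man", "Man")), "organ_labels"),
        (dict(gene_length_range=(0, 100)), "gene_length_range"),
        (dict(dispersion=-0.1), "dispersion"),
    ],
)
def test_atlas_scenario_validation_names_field(kwargs, field):
    with pytest.raises(ValidationError, match=field):
        AtlasScenario(**kwargs)


@pytest.mark.parametrize(
    "kwargs,field",
    [
        (dict(dates=(1, 1, 3)), "dates"),
        (dict(persistence=9), "persistence"),
        (dict(frac_damage_responsive=-0.1), "frac_damage_responsive"),
        (dict(effect_fold=0), "effect_fold"),
    ],
)
def test_timecourse_scenario_validation_names_field(kwargs, field):
    with pytest.raises(ValidationError, match=field):
        TimeCourseScenario(**kwargs)


def test_unknown_scenario_key_rejected():
    with pytest.raises(ValidationError, match="no_such_knob"):
        AtlasScenario.from_dict({"no_such_knob": 1})


def test_no_nonmantle_injection_when_fraction_zero():
    sc = AtlasScenario(n_genes=800, frac_nonmantle_origin=0.0, seed=2)
    _, truth = simulate_organ_atlas(sc)
    smp_classes = set(truth.table.loc[truth.smp_genes(), "origin_class"])
    assert smp_classes <= {"mantle_expressed", "unexpressed_everywhere"}


def test_injected_profiles_respect_thresholds():
    """Expected RPKM of injected genes sits on the right side of every rule."""
    sc = AtlasScenario(n_genes=2000, seed=13)
    _, truth = simulate_organ_atlas(sc)
    exp = truth.expected_rpkm
    nm = truth.table["origin_class"].isin(["non_mantle", "non_mantle_non_hemolymph"])
    sub = exp[nm.to_numpy()]
    assert (sub["Man"] < 5).all()
    others = sub.drop(columns=["Man"])
    qualifies = (others.gt(5) & others.ge(2 * sub["Man"], axis=0)).any(axis=1)
    assert qualifies.all()
    nonhem = truth.table["origin_class"] == "non_mantle_non_hemolymph"
    assert (exp.loc[nonhem.to_numpy(), "Hem"] < 5).all()


def test_null_timecourse_sides_are_exchangeable():
    """With no injections the two sides share expected counts up to depth."""
    sc = TimeCourseScenario(n_genes=400, frac_damage_responsive=0.0,
                            frac_transient=0.0, persistence=0,
                            library_sizes=1e7, seed=8)
    _, truth = simulate_damage_timecourse(sc)
    exp = truth.expected_counts
    for d in sc.dates:
        np.testing.assert_allclose(exp[f"left_d{d}"], exp[f"right_d{d}"], rtol=1e-12)
    np.testing.assert_allclose(exp["left_control"], exp["right_control"], rtol=1e-12)


def test_persistent_effect_is_exact_fold_on_every_date():
    sc = TimeCourseScenario(n_genes=400, persistence=7, effect_fold=4.0,
                            library_sizes=1e7, seed=8)
    _, truth = simulate_damage_timecourse(sc)
    exp = truth.expected_counts
    resp = truth.genes_where("is_damage_responsive")
    for d in sc.dates:
        np.testing.assert_allclose(
            exp.loc[resp, f"left_d{d}"], 4.0 * exp.loc[resp, "left_control"],
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            exp.loc[resp, f"right_d{d}"], exp.loc[resp, "right_control"], rtol=1e-12
        )


def test_expected_column_sums_match_library_sizes():
    sc = TimeCourseScenario(n_genes=3000, frac_damage_responsive=0.0,
                            frac_transient=0.0, persistence=0, seed=4)
    counts, truth = simulate_damage_timecourse(sc)
    ratio = truth.expected_counts.sum(axis=0) / counts.library_sizes
    np.testing.assert_allclose(ratio, 1.0, rtol=1e-9)


def test_negative_binomial_moments():
    """Draws match the mean/dispersion parameterisation Var = mu + phi mu^2."""
    rng = np.random.default_rng(17)
    n, mu, phi = 200_000, 100.0, 0.3
    draws = _draw_counts(rng, np.full(n, mu), phi).astype(float)
    target_var = mu + phi * mu**2
    se_mean = draws.std(ddof=1) / np.sqrt(n)
    assert abs(draws.mean() - mu) <= 3 * se_mean
    m = draws - draws.mean()
    se_var = np.sqrt((np.mean(m**4) - np.var(draws) ** 2) / n)
    assert abs(draws.var(ddof=1) - target_var) <= 3 * se_var
    # dispersion zero is the Poisson limit
    pois = _draw_counts(np.random.default_rng(18), np.full(n, mu), 0.0).astype(float)
    se_var_p = np.sqrt((np.mean((pois - pois.mean()) ** 4) - np.var(pois) ** 2) / n)
    assert abs(pois.var(ddof=1) - mu) <= 3 * se_var_p


def test_annotation_simulator_plants_enrichment():
    genes = [f"g{i}" for i in range(300)]
    target = genes[:40]
    ann = simulate_annotations(genes, n_terms=30, enriched_term="T0001",
                               enriched_genes=target, enriched_prob=0.9, seed=6)
    hit = ann.genes_for("T0001")
    in_target = len(hit & set(target)) / len(target)
    background = len(hit - set(target)) / (len(genes) - len(target))
    assert in_target > 5 * background
    again = simulate_annotations(genes, n_terms=30, enriched_term="T0001",
                                 enriched_genes=target, enriched_prob=0.9, seed=6)
    pd.testing.assert_frame_equal(ann.table, again.table)
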