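import numpy as np
import pandas as pd
import pytest

from shellseq import (
    AtlasScenario,
    TimeCourseScenario,
    call_de,
    simulate_damage_timecourse,
    simulate_organ_atlas,
)
from shellseq.expression import CountMatrix, ExpressionMatrix


@pytest.fixture(scope="session")
def atlas():
    """Moderate seeded atlas with injected non-mantle SMP genes."""
    scenario = AtlasScenario(n_genes=4000, seed=7)
    counts, truth = simulate_organ_atlas(scenario)
    return scenario, counts, truth


@pytest.fixture(scope="session")
def timecourse():
    """Seeded damage time course with persistent and transient injections."""
    scenario = TimeCourseScenario(n_genes=3000, seed=11)
    counts, truth = simulate_damage_timecourse(scenario)
    return scenario, counts, truth


@pytest.fixture(scope="session")
def timecourse_calls(timecourse):
    scenario, counts, _ = timecourse
    return call_de(counts, scenario.manifest(), alpha=1e-3)


def make_expression(rpkm_rows: dict, organs) -> ExpressionMatrix:
    """ExpressionMatrix from a {gene: [rpkm per organ]} dict."""
    df = pd.DataFrame.from_dict(rpkm_rows, orient="index", columns=list(organs))
    df.index.name = "gene_id"
    return ExpressionMatrix(rpkm=df.astype(float),
                            gene_lengths=pd.Series(1000.0, index=df.index))


def make_counts(counts: np.ndarray, lengths=None, samples=None,
                library_sizes=None) -> CountMatrix:
    counts = np.asarray(counts)
    genes = pd.Index([f"g{i}" for i in range(counts.shape[0])], name="gene_id")
    samples = pd.Index(samples or [f"s{i}" for i in range(counts.shape[1])])
    lengths = pd.Series(lengths if lengths is not None else 1000.0, index=genes)
    lib = None
    if library_sizes is not None:
        lib = pd.Series(np.asarray(library_sizes, dtype=float), index=samples)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=lengths,
        library_sizes=lib,
    )
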