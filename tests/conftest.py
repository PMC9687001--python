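"""Shared fixtures: the default synthetic experiment and derived tables.

Session-scoped so the genome-scale objects are built once for the whole
suite.
"""

import numpy as np
import pandas as pd
import pytest

import polymodes as pm


@pytest.fixture(scope="session")
def default_sim() -> pm.SyntheticExperiment:
    """The default synthetic experiment: 4000 genes, 6 stages, seed 1234."""
    return pm.generate(pm.GeneratorConfig())


@pytest.fixture(scope="session")
def default_tpm(default_sim) -> pd.DataFrame:
    return pm.compute_tpm(default_sim.counts,
                          default_sim.annotation["transcript_length"])


@pytest.fixture(scope="session")
def default_assignments(default_sim, default_tpm) -> pd.DataFrame:
    return pd.concat(
        [pm.classify_stage(default_tpm, default_sim.sheet, s) for s in pm.STAGES],
        ignore_index=True)


@pytest.fixture(scope="session")
def clean_genes(default_sim) -> pd.Index:
    """Planted-mode genes untouched by program/trend/discordance dynamics."""
    t = default_sim.truth_genes
    return t.index[(t["program"] == "neither") & (t["trend_slope"] == 0)
                   & (t["discordant_class"] == "")]


@pytest.fixture(scope="session")
def null_nb_experiment():
    """5000-gene two-group null NB simulation (phi=0.2, n=3 vs 3)."""
    rng = np.random.default_rng(20240917)
    mu = rng.lognormal(np.log(100), 1.0, size=5000)
    r = 1 / 0.2
    y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(5000, 6))
    counts = pd.DataFrame(y, index=[f"g{i}" for i in range(5000)],
                          columns=list("abcdef"))
    groups = np.array(["A"] * 3 + ["B"] * 3)
    return counts, groups


@pytest.fixture(scope="session")
def null_de(null_nb_experiment) -> pd.DataFrame:
    """Default-path LRT on the null experiment (dispersion estimated)."""
    counts, groups = null_nb_experiment
    return pm.de_two_group(counts, groups, "A", "B")


@pytest.fixture()
def small_sheet() -> pd.DataFrame:
    return pm.make_sample_sheet(stages=("GV", "8C"), n_fraction_replicates=1,
                                n_transcriptome_replicates=2)
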