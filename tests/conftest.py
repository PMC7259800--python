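import numpy as np
import pytest

from glypheno import features, io, simulate


@pytest.fixture(scope="session")
def example_annotations():
    """Annotations of the worked-example mutations (R515S, A389V, ...)."""
    df = io.read_annotation_table(io._fixture_path("annotations_examples"))
    return features.annotations_from_frame(df)


@pytest.fixture(scope="session")
def clinical_cohorts():
    """Both packaged clinical cohorts as validated CohortTables."""
    return {
        "homozygous": io.fixture_cohort("table4_homozygous_cos"),
        "heterozygous": io.fixture_cohort("table5_heterozygous_cos"),
    }


@pytest.fixture(scope="session")
def noisy_cohort():
    """Study-condition synthetic cohort (n=200, sd=1) with latent truth."""
    cfg = simulate.SimulationConfig(seed=11, noise_sd=1.0, n_patients=200)
    ann = simulate.simulate_annotations(cfg)
    records, truth = simulate.simulate_cohort(cfg, ann)
    return records, truth


@pytest.fixture(scope="session")
def docking_set(tmp_path_factory):
    """Synthetic decoy set with a planted best pose, parsed back from PDB."""
    from glypheno import ranking

    sim = simulate.simulate_docking_set(n_models=15, seed=3)
    path = tmp_path_factory.mktemp("decoys") / "decoys.pdb"
    path.write_text(sim.pdb_text)
    models = ranking.parse_models(path)
    return sim, models


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
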