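import numpy as np
import pandas as pd
import pytest

from insectprint.chemistry import load_marker_table
from insectprint.pipeline import RunConfig, build_blockset, run_pipeline
from insectprint.synthetic_data import SyntheticConfig, generate_cohort, split_train_test


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline result on the default study-design cohort (seed 42)."""
    return run_pipeline(RunConfig())


@pytest.fixture(scope="session")
def marker_ions():
    """The distinct planted (block, m/z) marker ions of the bundled table."""
    return {(r.block, round(r.theoretical_mz, 4)) for r in load_marker_table()}


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced 2-samples-per-species cohort for fast I/O and property tests."""
    cfg = SyntheticConfig(
        species_counts={s: 2 for s in (
            "Acheta domesticus", "Bombyx mori", "Hermetia illucens", "Tenebrio molitor"
        )},
        n_background=12,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_setup():
    """No-signal cohort (marker_fold=1, seed 42): preprocessed blocks + labels."""
    cfg = SyntheticConfig(seed=42, marker_fold=1.0)
    samples, spectra = generate_cohort(cfg)
    samples = split_train_test(samples, n_test=8, seed=42)
    labels = {s.sample_id: s.species for s in samples}
    train_ids = {s.sample_id for s in samples if s.role == "train"}
    blocks = build_blockset(spectra, train_ids)
    return blocks, labels, train_ids


def make_matrix(data, block="meohneg", state="raw", sample_ids=None):
    """Build a FeatureMatrix from a dense array (helper for unit tests)."""
    from insectprint.preprocessing import FeatureMatrix

    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    index = pd.MultiIndex.from_tuples(
        [(sid, 1) for sid in sample_ids], names=["sample_id", "replicate"]
    )
    cols = 100.0 + np.arange(data.shape[1], dtype=float)
    return FeatureMatrix(
        block=block, values=pd.DataFrame(data, index=index, columns=cols),
        scaling_state=state,
    )
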