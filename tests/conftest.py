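import pytest
from hypothesis import HealthCheck, settings

from fragfocus.chem_io import Dataset, MoleculeRecord
from fragfocus.ensemble import TuningConfig, labels_to_y, split_train_test, train_ensemble
from fragfocus.featurizer import FeaturizerConfig, featurize
from fragfocus.fragment_miner import MiningConfig, mine_fragments
from fragfocus.synthetic_data import BenchmarkConfig, generate_benchmark

settings.register_profile(
    "default", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


def make_dataset(smiles, name="test", prefix="m"):
    return Dataset([MoleculeRecord(f"{prefix}{i}", s) for i, s in enumerate(smiles)], name)


@pytest.fixture(scope="session")
def small_benchmark():
    """A 150-compound labeled benchmark with three planted scaffolds."""
    ds, scaffolds = generate_benchmark(BenchmarkConfig(n_active=30, n_inactive=120, seed=7))
    return ds, scaffolds


@pytest.fixture(scope="session")
def small_library(small_benchmark):
    ds, _ = small_benchmark
    lib = mine_fragments(
        ds.subset("active"), ds.subset("inactive"), MiningConfig(max_fragment_atoms=8)
    )
    return lib.top(40)


@pytest.fixture(scope="session")
def trained(small_benchmark, small_library):
    """A quickly tuned six-member ensemble on the small benchmark."""
    ds, scaffolds = small_benchmark
    cfg = FeaturizerConfig()
    X = featurize(ds, small_library, cfg)
    y = labels_to_y([r.label for r in ds])
    X_train, X_test, y_train, y_test = split_train_test(X, y, fraction=0.9, seed=7)
    model = train_ensemble(X_train, y_train, tuning=TuningConfig(n_trials=2, cv_folds=3, seed=7))
    return {
        "ds": ds,
        "scaffolds": scaffolds,
        "lib": small_library,
        "cfg": cfg,
        "model": model,
        "X": X,
        "y": y,
        "X_train": X_train,
        "X_test": X_test,
        "y_train": y_train,
        "y_test": y_test,
    }
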