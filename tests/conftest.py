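import numpy as np
import pytest

from algaftir import synthetic
from algaftir.pipeline import RunConfig, run
from algaftir.preprocess import PreprocessConfig


@pytest.fixture(scope="session")
def axis():
    return synthetic.DEFAULT_AXIS


@pytest.fixture(scope="session")
def noiseless_ds():
    return synthetic.make_dataset("noiseless", seed=11)


@pytest.fixture(scope="session")
def paper_like_ds():
    return synthetic.make_dataset("paper_like", seed=11)


def run_config_for(ds, *, methods=("ulra", "opls", "mcr"), seed=11, **kw):
    """Standard run configuration for a synthetic dataset bundle."""
    defaults = dict(
        spectra=ds.spectra,
        composition=ds.composition,
        references=ds.references,
        outliers={
            "lipid": ds.truth["lipid_outliers"],
            "carbohydrate": ds.truth["carb_outliers"],
        },
        methods=methods,
        seed=seed,
    )
    if ds.truth["preset"] == "noiseless":
        # drift-free data: baseline estimation would only clip peak bases
        defaults["preprocess"] = PreprocessConfig(do_baseline=False)
        defaults["opls_components"] = "auto"
        defaults["outliers"] = {}
    defaults.update(kw)
    return RunConfig(**defaults)


@pytest.fixture(scope="session")
def paper_like_result(paper_like_ds):
    return run(run_config_for(paper_like_ds))


@pytest.fixture(scope="session")
def noiseless_result(noiseless_ds):
    return run(run_config_for(noiseless_ds))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
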