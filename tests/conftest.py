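import warnings

import numpy as np
import pandas as pd
import pytest

from gscoex.adjust import clean_expression, fit_gene_models
from gscoex.network import NetworkParams
from gscoex.synth import SimulationConfig, generate_study, small_config


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study (300 genes, 8 modules, 2 score-coupled)."""
    return generate_study(small_config(seed=0))


@pytest.fixture(scope="session")
def small_network_params():
    return NetworkParams(power=6, min_module_size=15)


@pytest.fixture(scope="session")
def small_adjusted(small_study):
    """Preserve/remove adjusted matrices of the small study for GS3_SCZ."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = fit_gene_models(
            small_study.expression, small_study.covariates, "GS3_SCZ"
        )
        pres = clean_expression(small_study.expression, fits, "preserve")
        rem = clean_expression(small_study.expression, fits, "remove")
    return pres, rem


def make_expression(values: np.ndarray, prefix: str = "g") -> pd.DataFrame:
    genes = [f"{prefix}{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


@pytest.fixture
def planted_two_blocks(rng):
    """100 genes in two 50-gene blocks (within-block r ~ 0.8, between ~ 0)."""
    n = 100
    f = rng.normal(size=(2, n))
    X = np.vstack(
        [
            np.sqrt(0.8) * f[0] + np.sqrt(0.2) * rng.normal(size=(50, n)),
            np.sqrt(0.8) * f[1] + np.sqrt(0.2) * rng.normal(size=(50, n)),
        ]
    )
    return make_expression(X), ["A"] * 50 + ["B"] * 50
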