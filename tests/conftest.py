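import numpy as np
import pandas as pd
import pytest

from metfactor.data import (ECDesignSet, Kinship, ModelInputs, TraitMatrix,
                            quantitative_term)
from metfactor.sampler import PosteriorSamples, SamplerConfig
from metfactor.simulate import SimConfig, simulate_met


@pytest.fixture(scope="session")
def small_met():
    """Small fully observed simulated MET with a univariate EC."""
    cfg = SimConfig(n_lines=100, t_train=10, t_test=0, k_true=3, z_cols=20,
                    ec_mode="univariate", seed=11)
    return simulate_met(cfg)


@pytest.fixture(scope="session")
def recovery_fixture():
    """n=100, t=10, k_true=2-ish fixture for parameter-recovery checks."""
    cfg = SimConfig(n_lines=100, t_train=10, t_test=0, k_true=3, z_cols=20,
                    main_effect_prop=0.5, unpredictable_prop=0.0,
                    ec_mode="univariate", seed=42)
    return simulate_met(cfg)


def toy_inputs(n=6, t=4, seed=0, missing=()):
    """Tiny deterministic ModelInputs for plumbing tests."""
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal((n, t))
    for (i, j) in missing:
        vals[i, j] = np.nan
    rows = [f"g{i}" for i in range(n)]
    cols = [f"e{j}" for j in range(t)]
    meta = pd.DataFrame({
        "location": [f"L{j % 2}" for j in range(t)],
        "year": [2014 + j for j in range(t)],
        "state": [f"S{j % 2}" for j in range(t)],
        "tester": [f"T{j % 2}" for j in range(t)],
    }, index=cols)
    tm = TraitMatrix.from_values(vals, rows, cols, meta)
    K = Kinship(np.eye(n), rows)
    ec = ECDesignSet.build(t, [quantitative_term("E", np.arange(t, dtype=float))])
    return ModelInputs(tm, K, ec)


def synthetic_posterior(D=4, n=3, k=2, t=2, P=1, seed=0):
    """Hand-buildable PosteriorSamples for prediction arithmetic tests."""
    rng = np.random.default_rng(seed)
    cfg = SamplerConfig(k_max=k, n_iter=2, burn_in=1, thin=1)
    return PosteriorSamples(
        F=rng.standard_normal((D, n, k)),
        U_F=rng.standard_normal((D, n, k)),
        Lambda=rng.standard_normal((D, k, t)),
        A=rng.standard_normal((D, P, k)),
        U_R=rng.standard_normal((D, n, t)),
        B=rng.standard_normal((D, 1, t)),
        h2_F=np.full((D, k), 0.5),
        tau=np.ones((D, k)),
        loglik=np.zeros(D),
        config=cfg,
        term_slices={"intercept": slice(0, 1)},
        row_ids=[f"g{i}" for i in range(n)],
        col_ids=[f"e{j}" for j in range(t)],
    )
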