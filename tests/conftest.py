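import numpy as np
import pandas as pd
import pytest

from nomepipe import hmm, synthetic


def make_calls(pos, meth, total, chrom="chr1", context="GCH", strand="+"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=np.int64),
            "strand": strand,
            "context": context,
            "n_meth": np.asarray(meth, dtype=np.int64),
            "n_total": np.asarray(total, dtype=np.int64),
        }
    )


@pytest.fixture(scope="session")
def fitted_series():
    """A series simulated from known parameters plus its EM fit (shared)."""
    true = hmm.BetaBinomialHMMParams(
        alpha=(0.5, 6.0), beta=(9.5, 2.0),
        transition=((0.98, 0.02), (0.02, 0.98)), initial=(0.5, 0.5),
    )
    calls, states = hmm.sample_series(true, 20_000, seed=5)
    fit = hmm.fit_hmm(calls, max_iter=50, tol=1e-7)
    return true, calls, states, fit


@pytest.fixture(scope="session")
def small_promoter_study():
    """A compact two-sample promoter study used across promoter tests."""
    truths = synthetic.default_promoter_truths(
        n_uu=20, n_mu=20, n_mm=8, n_fail=6, spacing=6000, seed=0
    )
    length = 5000 + len(truths) * 6000 + 5000
    cfg = synthetic.SimulationConfig(seed=0)
    study = synthetic.simulate_promoter_study(truths, cfg, length=length)
    return truths, study
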