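import numpy as np
import pytest

from epidomain.hmm import HMMParams
from epidomain.simulate import MARKS, make_fixture_bundle, reference_params


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Tiny self-consistent synthetic dataset, generated once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    return make_fixture_bundle(outdir, scale="tiny", seed=11)


@pytest.fixture(scope="session")
def three_state_params() -> HMMParams:
    return reference_params(3, mean_domain_len=10.0)


@pytest.fixture(scope="session")
def two_state_params() -> HMMParams:
    return reference_params(2, mean_domain_len=10.0)


def random_hmm_params(rng: np.random.Generator, S: int, m: int) -> HMMParams:
    """A random, valid diagonal-Gaussian HMM for oracle comparisons."""
    T = rng.dirichlet(np.ones(S) * 2.0, size=S)
    return HMMParams(
        means=rng.normal(0.0, 3.0, size=(S, m)),
        variances=rng.uniform(0.3, 3.0, size=(S, m)),
        transition=T,
        initial=rng.dirichlet(np.ones(S)),
    )


def enumerate_paths(X: np.ndarray, params: HMMParams):
    """Brute-force oracle: joint probability of every state path.

    Returns (paths, log joint probabilities); independent of the package's
    recursions (scipy Gaussian densities plus a direct sum of initial,
    transition and emission terms over every enumerated path).
    """
    from itertools import product

    from scipy.stats import norm

    n = len(X)
    S = params.n_states
    # (n, S) per-position per-state emission log densities via scipy
    logB = np.stack(
        [
            norm.logpdf(X, loc=params.means[s], scale=np.sqrt(params.variances[s])).sum(axis=1)
            for s in range(S)
        ],
        axis=1,
    )
    paths = np.array(list(product(range(S), repeat=n)), dtype=np.int64)
    logps = (
        np.log(params.initial)[paths[:, 0]]
        + np.log(params.transition)[paths[:, :-1], paths[:, 1:]].sum(axis=1)
        + logB[np.arange(n)[None, :], paths].sum(axis=1)
    )
    return [tuple(p) for p in paths], logps
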