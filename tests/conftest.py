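import numpy as np
import pytest

from ctsridge import OmicsDataset


def make_dataset(n=60, H=3, K=2, L=1, seed=0, beta=None, alpha=None,
                 gamma=None, scale=None, noise=0.05):
    """Small random dataset; if a scale is given, Y is generated from the
    mixture mean model with normalized-scale noise."""
    rng = np.random.default_rng(seed)
    W = rng.dirichlet(np.linspace(5, 2, H), n)
    X = rng.normal(size=(n, K))
    X -= X.mean(axis=0)
    C = rng.normal(size=(n, L)) if L else np.zeros((n, 0))
    if C.size:
        C -= C.mean(axis=0)
    if scale is None:
        Y = rng.uniform(0.05, 0.95, size=(3, n))
    else:
        from ctsridge import ParameterVector, bulk_mean, get_scale
        sc = get_scale(scale)
        alpha = np.zeros(H) if alpha is None else np.asarray(alpha, float)
        beta = np.zeros((H, K)) if beta is None else np.asarray(beta, float)
        gamma = np.zeros(L) if gamma is None else np.asarray(gamma, float)
        mu = bulk_mean(ParameterVector(alpha, beta, gamma),
                       OmicsDataset(Y=np.zeros((1, n)), W=W, X=X, C=C,
                                    markers=["_"], samples=list(range(n)),
                                    cell_types=list(range(H)),
                                    traits=list(range(K)),
                                    covariates=list(range(L))), sc)
        Y = sc.g(mu + noise * rng.normal(size=(3, n)))
    return OmicsDataset(
        Y=Y, W=W, X=X, C=C,
        markers=[f"m{i}" for i in range(Y.shape[0])],
        samples=[f"s{i}" for i in range(n)],
        cell_types=[f"ct{h}" for h in range(H)],
        traits=[f"x{k}" for k in range(K)],
        covariates=[f"c{l}" for l in range(L)],
    )


@pytest.fixture
def small_dataset():
    return make_dataset(seed=1)
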