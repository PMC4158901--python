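import numpy as np
import pytest

from propcoloc.association import RegressionFit
from propcoloc import simulator as sim


def make_fit(b, V, ids=None, kind="quantitative", n=1000, loglik=-10.0):
    """RegressionFit with explicit coefficients, for oracle tests."""
    b = np.asarray(b, float)
    V = np.asarray(V, float)
    ids = ids if ids is not None else [f"x{i}" for i in range(len(b))]
    bic = -2.0 * loglik + (len(b) + 1) * np.log(n)
    return RegressionFit(list(ids), b, V, kind, n, loglik, float(bic))


def random_fit_pair(rng, q=3, scale=1.0):
    """A random pair of conformable fits with positive-definite covariances."""
    b1 = rng.normal(size=q)
    b2 = rng.normal(size=q)
    A1 = rng.normal(size=(q, q))
    A2 = rng.normal(size=(q, q))
    V1 = scale * (A1 @ A1.T + np.eye(q) * 0.2)
    V2 = scale * (A2 @ A2.T + np.eye(q) * 0.2)
    return make_fit(b1, V1), make_fit(b2, V2)


@pytest.fixture(scope="session")
def small_panel():
    """1,000 haplotypes over 40 SNPs with block LD, MAF >= 5%."""
    return sim.make_panel(n_hap=1000, n_snp=40, block_size=10, rho=0.9,
                          seed=11)


@pytest.fixture(scope="session")
def cc_pair(small_panel):
    """Two screened case-control cohorts sharing one causal variant."""
    causal = small_panel.snp_ids[7]
    g1, y1 = sim.simulate_case_control(small_panel, causal, rr=1.5,
                                       n_case=600, n_control=600, seed=21,
                                       sample_prefix="a")
    g2, y2 = sim.simulate_case_control(small_panel, causal, rr=1.5,
                                       n_case=600, n_control=600, seed=22,
                                       sample_prefix="b")
    return g1, y1, g2, y2, causal
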