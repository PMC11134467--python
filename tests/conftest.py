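import numpy as np
import pytest

from asecross import SampleInfo, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small error-free, overdispersion-free dataset written to disk.

    Used by the round-trip tests: with error_rate = 0 and rho = 0 the
    counting stage must reproduce the simulator's planted counts exactly.
    """
    cfg = SimConfig(
        n_genes=30,
        frac_maternal=0.1,
        frac_cis_head=0.1,
        frac_cis_body=0.1,
        effect_prop=0.9,
        depth_mean=30,
        overdispersion_rho=0.0,
        error_rate=0.0,
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("sim_small")
    data = simulate_dataset(cfg, outdir)
    return cfg, data, outdir


@pytest.fixture
def samples_5_4():
    """The study's replicate structure: five HB and four BH F1 males."""
    return [SampleInfo(f"HB{i+1}", "HB") for i in range(5)] + [
        SampleInfo(f"BH{i+1}", "BH") for i in range(4)
    ]


def irls_quasibinomial(successes, totals, max_iter=200, tol=1e-13):
    """Independently coded IRLS fit of the intercept-only quasi-binomial GLM.

    Iterates Fisher scoring on the logit scale; dispersion is the Pearson
    statistic over N - 1 df, and the test is two-sided t. Serves as the
    oracle for the closed-form fit in asecross.stats.
    """
    from scipy import stats as sps

    s = np.asarray(successes, float)
    n = np.asarray(totals, float)
    keep = n > 0
    s, n = s[keep], n[keep]
    beta = 0.0
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-beta))
        w = n * p * (1 - p)
        beta_new = beta + (s.sum() - n.sum() * p) / w.sum()
        if abs(beta_new - beta) < tol:
            beta = beta_new
            break
        beta = beta_new
    p = 1.0 / (1.0 + np.exp(-beta))
    df = len(n) - 1
    phi = float(np.sum((s - n * p) ** 2 / (n * p * (1 - p))) / df)
    se = float(np.sqrt(phi / (n.sum() * p * (1 - p))))
    t = beta / se
    p_value = float(2 * sps.t.sf(abs(t), df))
    return {"beta": float(beta), "se": se, "phi": phi, "p_value": p_value,
            "p_hat": float(p), "df_resid": df}


def bh_brute_force(pvals):
    """Literal step-up definition: q_(i) = min_{j >= i} min(1, p_(j) m / j)."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order):
        q[idx] = min(
            min(1.0, p[order[rank_j]] * m / (rank_j + 1))
            for rank_j in range(rank_i, m)
        )
    return q
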