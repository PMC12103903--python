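import numpy as np
import pytest
import scipy.optimize

from scmcgf import generate_synthetic


@pytest.fixture(scope="session")
def small_synth():
    """120 cells x 400 genes, 3 well-separated clusters."""
    return generate_synthetic(
        n_cells=120, n_genes=400, n_clusters=3, effect=8.0, dropout=0.3, seed=42
    )


def simplex_qp_oracle(linear, quad, zero_index=None):
    """Independent generic solver for min q*||s||^2 + linear . s on the
    probability simplex (optionally with one coordinate pinned to 0),
    via SLSQP.  Used to cross-check closed-form graph/U updates."""
    n = linear.size
    free = np.arange(n) if zero_index is None else np.delete(np.arange(n), zero_index)
    lin = linear[free]

    # equivalent projection form: min || s + lin/(2 quad) ||^2, better scaled
    target = -lin / (2.0 * quad)

    def f(s):
        return float(np.dot(s - target, s - target))

    def grad(s):
        return 2.0 * (s - target)

    res = scipy.optimize.minimize(
        f,
        np.full(free.size, 1.0 / free.size),
        jac=grad,
        method="trust-constr",
        bounds=scipy.optimize.Bounds(0.0, np.inf),
        constraints=[scipy.optimize.LinearConstraint(np.ones(free.size), 1.0, 1.0)],
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 2000},
    )
    assert res.status in (1, 2), res.message

    # active-set polish: exact KKT solve on the support suggested by the
    # solver, with primal/dual feasibility restoration
    active = res.x > 1e-7
    if not active.any():
        active[np.argmax(target)] = True
    for _ in range(10 * free.size):
        idx = np.flatnonzero(active)
        tau = (target[idx].sum() - 1.0) / idx.size
        s_act = target[idx] - tau
        if s_act.min() < -1e-14:
            active[idx[np.argmin(s_act)]] = False
            continue
        inactive = np.flatnonzero(~active)
        if inactive.size and np.max(target[inactive]) > tau + 1e-14:
            active[inactive[np.argmax(target[inactive])]] = True
            continue
        break
    x = np.zeros(free.size)
    idx = np.flatnonzero(active)
    x[idx] = target[idx] - (target[idx].sum() - 1.0) / idx.size
    out = np.zeros(n)
    out[free] = x
    return out


@pytest.fixture
def qp_oracle():
    return simplex_qp_oracle
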