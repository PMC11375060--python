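import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_cohort():
    """A 300-sample cohort with one planted subtype shift and one planted
    hazard gene, shared across tests that only need plumbing."""
    from glycoscreen import SimConfig, simulate_cohort

    cfg = SimConfig(
        seed=7,
        n_samples=300,
        n_genes=12,
        planted_subtype_log2fc={"G0001": 1.0},
        planted_log_hr={"G0002": float(np.log(2.0))},
    )
    return simulate_cohort(cfg)


# ---------------------------------------------------------------------------
# independent oracles, kept free of the implementation paths they check


def efron_partial_loglik(beta, x, times, events):
    """Efron partial log-likelihood for a single covariate, written from the
    textbook formula (independent of the fitting code)."""
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    eta = beta * x
    theta = np.exp(eta)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        d = int(tied.sum())
        risk = times >= t
        sum_risk = theta[risk].sum()
        sum_tied = theta[tied].sum()
        ll += eta[tied].sum()
        for j in range(d):
            ll -= np.log(sum_risk - (j / d) * sum_tied)
    return ll


def grid_maximize_beta(x, times, events, lo=-5.0, hi=5.0):
    """Brute-force maximizer of the Efron partial likelihood: coarse grid
    then golden-section refinement to ~1e-8."""
    from scipy.optimize import minimize_scalar

    grid = np.linspace(lo, hi, 2001)
    vals = [efron_partial_loglik(b, x, times, events) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    res = minimize_scalar(
        lambda b: -efron_partial_loglik(b, x, times, events),
        bounds=(max(lo, b0 - 0.02), min(hi, b0 + 0.02)),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x)
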