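import numpy as np
import pandas as pd
import pytest

from patfit import (
    CohortFilter,
    IndividualRecord,
    MutationParams,
    Pedigree,
    SimulationConfig,
    assign_families,
    build_anchor_table,
    simulate_pedigree,
)

#: window wide enough that no simulated anchor is excluded by birth year
WIDE_WINDOW = CohortFilter(birth_year_window=(1000.0, 3000.0))


def tiny_pedigree() -> Pedigree:
    """Two-generation toy pedigree: one couple, three children."""
    recs = [
        IndividualRecord("fa", None, None, "male", 1700.0, 1760.0, (1724.0,)),
        IndividualRecord("mo", None, None, "female", 1705.0, 1770.0, (1724.0,)),
        IndividualRecord("c1", "fa", "mo", "male", 1725.0, 1725.5, ()),
        IndividualRecord("c2", "fa", "mo", "female", 1730.0, np.nan, (1752.0,)),
        IndividualRecord("c3", "fa", "mo", "female", 1735.0, 1790.0, ()),
        # c2's children
        IndividualRecord("g1", None, "c2", "male", 1755.0, np.nan, ()),
        IndividualRecord("g2", None, "c2", "female", 1758.0, np.nan, ()),
    ]
    ped = Pedigree.from_records(recs)
    assign_families(ped)
    return ped


@pytest.fixture
def toy_pedigree():
    return tiny_pedigree()


@pytest.fixture(scope="session")
def null_anchor_table():
    """Mid-sized anchor table with no mutation effect and no confounding."""
    cfg = SimulationConfig(
        preset="historical_sweden",
        n_families=1500,
        seed=314,
        mutation=MutationParams(s_bar=0.0, slope_m=0.0),
    )
    ped, truth = simulate_pedigree(cfg)
    anchors = build_anchor_table(ped, WIDE_WINDOW)
    return anchors, truth


@pytest.fixture(scope="session")
def effect_anchor_table():
    """Anchor table simulated with the default mutation-load mechanism on."""
    cfg = SimulationConfig(
        preset="historical_sweden",
        n_families=2500,
        seed=2718,
        mutation=MutationParams(s_bar=0.004, slope_m=2.0),
    )
    ped, truth = simulate_pedigree(cfg)
    anchors = build_anchor_table(ped, WIDE_WINDOW)
    return anchors, truth


def mc_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n))


def cluster_se(values: pd.Series, clusters: pd.Series) -> float:
    """MC standard error of a mean for family-clustered observations.

    Siblings share latent family draws (e.g. the fertility frailty), so the
    naive iid standard error understates the Monte-Carlo noise.
    """
    ybar = values.mean()
    g = pd.DataFrame({"y": values, "c": clusters}).groupby("c")["y"].agg(["sum", "count"])
    return float(np.sqrt(((g["sum"] - g["count"] * ybar) ** 2).sum()) / len(values))


def grid_marginal_loglik(family, y, X, groups, beta, sigma, npts=4001, span=10.0):
    """Independent dense-grid (trapezoid) oracle for the AGH marginal likelihood.

    Integrates each family's likelihood over the random intercept on an
    equally spaced grid of ``npts`` points spanning ±``span`` prior sds.
    """
    from scipy.stats import norm

    from patfit.glmm.families import get_family

    fam = get_family(family)
    eta = np.asarray(X) @ np.asarray(beta)
    y = np.asarray(y, dtype=float)
    us = np.linspace(-span * sigma, span * sigma, npts)
    total = 0.0
    for g in range(int(np.max(groups)) + 1):
        m = np.asarray(groups) == g
        ll = np.array([fam.loglik(y[m], eta[m] + u).sum() for u in us])
        integrand = ll + norm.logpdf(us, 0.0, sigma)
        mx = integrand.max()
        total += np.log(np.trapezoid(np.exp(integrand - mx), us)) + mx
    return total
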