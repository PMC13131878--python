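"""Shared fixtures: the emulated 104-mouse study and its population fit.

Both are session-scoped because the population fit is the most
expensive object in the suite; every test that needs a fitted study
shares the same one.
"""


import pytest

from tgitte.nlme import TGIPopulationEstimator
from tgitte.pk import default_pk_parameters
from tgitte.synthetic import default_design, default_population, generate_study


@pytest.fixture(scope="session")
def pk():
    return default_pk_parameters()


@pytest.fixture(scope="session")
def truth_population():
    return default_population()


@pytest.fixture(scope="session")
def paper_study(pk, truth_population):
    """One synthetic study at the emulated design (104 mice, 7 arms)."""
    return generate_study(default_design(), truth_population, pk, seed=20260930)


@pytest.fixture(scope="session")
def paper_fit(paper_study, pk):
    """Population TGI fit of the shared study.

    The recommended recipe: a deterministic two-stage (ITS) fit for
    initialization, refined by SAEM with simulated annealing.
    """
    stage1 = TGIPopulationEstimator(
        pk=pk, mode="two-stage", loglik_method="none", compute_ebes=False
    )
    stage1.fit(paper_study)
    est = TGIPopulationEstimator(
        pk=pk,
        mode="saem",
        init=stage1.population_model_,
        saem_iterations=(300, 200),
        mcmc_sweeps=3,
        loglik_method="none",
        seed=7,
    )
    est.fit(paper_study)
    return est
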