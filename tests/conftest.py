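import numpy as np
import pytest

from sevbayes import (
    BinomialDesign,
    BinomialOutcome,
    DesignAnalysisSpec,
    IntervalHypothesis,
    NormalTestSpec,
    simulate_bfda,
)


@pytest.fixture(scope="session")
def water_plant_spec() -> NormalTestSpec:
    """The cooling-system test: H0: mu <= 150 degF, sigma=10, n=100, alpha=2.5%."""
    return NormalTestSpec(mu0=150.0, sigma=10.0, n=100, alpha=0.025)


@pytest.fixture(scope="session")
def h_specific() -> IntervalHypothesis:
    """Specific treatment hypothesis: theta_A in [0.2,0.3], theta_B in [0.7,0.8]."""
    return IntervalHypothesis("H_s", (0.2, 0.3), (0.7, 0.8))


@pytest.fixture(scope="session")
def h_vague() -> IntervalHypothesis:
    """Vague treatment hypothesis: theta_A in [0,0.5], theta_B in [0.5,1]."""
    return IntervalHypothesis("H_v", (0.0, 0.5), (0.5, 1.0))


@pytest.fixture(scope="session")
def design_20() -> BinomialDesign:
    return BinomialDesign(20, 20)


@pytest.fixture(scope="session")
def design_4() -> BinomialDesign:
    return BinomialDesign(4, 4)


@pytest.fixture(scope="session")
def aligned_20() -> BinomialOutcome:
    """Outcome aligned with both hypotheses at N=20: S_A = N/4, S_B = 3N/4."""
    return BinomialOutcome(5, 15)


@pytest.fixture(scope="session")
def aligned_4() -> BinomialOutcome:
    return BinomialOutcome(1, 3)


@pytest.fixture(scope="session")
def bfda_n36_result():
    """One full-size BFDA run at the reference design, shared across tests."""
    spec = DesignAnalysisSpec(
        n_per_group=36, effect_size_d=0.4, n_sims=10_000, seed=20220815
    )
    return simulate_bfda(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
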