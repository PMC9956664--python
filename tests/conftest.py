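import numpy as np
import pytest

from iolopt.formulas import nominal_constants
from iolopt.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def random_eyes(rng, n):
    """Uncorrelated but physiologically valid eyes for oracle sweeps."""
    return {
        "AL": rng.uniform(20.5, 28.0, n),
        "CCT": rng.uniform(480.0, 640.0, n),
        "ACD": rng.uniform(2.4, 4.0, n),
        "LT": rng.uniform(3.8, 5.5, n),
        "R1": rng.uniform(7.0, 8.6, n),
        "R2": rng.uniform(7.0, 8.6, n),
        "PIOL": rng.uniform(6.0, 30.0, n),
    }


@pytest.fixture(scope="session")
def noisefree_cohorts():
    """One noise-free cohort per formula, generated by that formula."""
    out = {}
    for formula in ("hofferq", "holladay1", "haigis", "castrop"):
        cfg = CohortConfig(
            n=150,
            noise_sd=0.0,
            rounding=0.0,
            seed=314,
            truth_formula=formula,
            truth_constants=nominal_constants(formula),
        )
        out[formula] = (generate_cohort(cfg), cfg)
    return out


@pytest.fixture(scope="session")
def noisy_cohort():
    """A realistic noisy cohort with a Haigis ground truth."""
    cfg = CohortConfig(n=300, seed=99)
    return generate_cohort(cfg), cfg
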