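import numpy as np
import pytest

from densityfeedback.density_feedback import calibrate_feedback
from densityfeedback.life_history import (
    LifeHistory,
    SpeciesTarget,
    load_species_table,
    synthesize_life_history,
)


@pytest.fixture(scope="session")
def species_table():
    return load_species_table()


@pytest.fixture(scope="session")
def species_by_abbr(species_table):
    return {t.abbr: t for t in species_table}


@pytest.fixture(scope="session")
def all_life_histories(species_table):
    """Synthesized life histories for all 21 species (deterministic)."""
    return {t.abbr: synthesize_life_history(t) for t in species_table}


@pytest.fixture(scope="session")
def dm(all_life_histories):
    """Fast life history (spot-tailed quoll analogue): short projections."""
    return all_life_histories["DM"]


@pytest.fixture(scope="session")
def quoll_feedback(dm):
    fp, rec = calibrate_feedback(dm, c=2.0, rng_seed=1, validate=False)
    return fp


@pytest.fixture()
def toy_two_age():
    """2x2 life history with lambda exactly 1: S = [0.5, 0], m = [0, 2]."""
    target = SpeciesTarget(abbr="XX", group="toy", mass=5.0, gl_target=2.3, q=92)
    return LifeHistory(
        species=target,
        omega=1,
        S=np.array([0.5, 0.0]),
        m=np.array([0.0, 2.0]),
        terminal_survival_zeroed=True,
        D=0.01,
        A=250_000.0,
    )
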