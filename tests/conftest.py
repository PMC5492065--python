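import numpy as np
import pytest

import stagehmm as sh
from stagehmm.states import ALLOWED_DESTINATIONS, N_STAGES, N_STATES, STAGES, live_index


def random_vital_rates(rng: np.random.Generator) -> sh.VitalRates:
    """A random valid rate set: uniform survival, Dirichlet growth on the mask."""
    phi = rng.uniform(0.0, 1.0, N_STAGES)
    psi = np.zeros((N_STAGES, N_STAGES))
    for i, stage in enumerate(STAGES):
        dests = ALLOWED_DESTINATIONS[stage]
        probs = rng.dirichlet(np.ones(len(dests)))
        for d, p in zip(dests, probs):
            psi[live_index(d), i] = p
    return sh.VitalRates(phi=phi, psi=psi)


def random_detection(rng: np.random.Generator) -> sh.DetectionParams:
    p_live = rng.uniform(0.05, 0.95, N_STAGES)
    p_dead = rng.uniform(0.05, 0.95, N_STAGES)
    p_dead[0] = p_dead[-1] = 0.0
    return sh.DetectionParams(p_live=p_live, p_dead=p_dead)


def random_history(rng: np.random.Generator, px: np.ndarray, po: np.ndarray, T: int):
    """Simulate one valid encounter history (first detection alive) of length T."""
    for _ in range(200):
        state = int(rng.integers(0, N_STAGES))  # start in a random live stage
        cats = np.zeros(T, dtype=np.int64)
        for t in range(T):
            cats[t] = rng.choice(N_STATES, p=po[:, state])
            if t < T - 1:
                state = int(rng.choice(N_STATES, p=px[:, state]))
        det = np.flatnonzero(cats != 0)
        if det.size and 1 <= cats[det[0]] <= N_STAGES:
            cats[: det[0]] = 0
            return cats
    raise RuntimeError("could not simulate a detectable history")


@pytest.fixture(scope="session")
def rate_rng():
    return np.random.default_rng(20260901)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest constant-model cohort shared across tests (no predation trend)."""
    cfg = sh.CohortConfig(seed=42, n_individuals=150, predation_slope=0.0)
    histories, tables, truth = sh.generate_cohort(cfg)
    return cfg, histories, tables, truth
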