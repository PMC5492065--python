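"""State spaces and transition/observation kernels for juvenile demography.

The demographic process tracks an individual through seven developmental
stages (egg, five instars, pupa) in one of three statuses: live, newly dead
(a corpse still discoverable in the field), or dead (absorbing, gone).  The
15 states are ordered

    0..6   live     egg, I1, I2, I3, I4, I5, pupa
    7..13  newly dead (same stage order)
    14     dead (absorbing)

The one-step (3-day) transition kernel ``PX`` is column stochastic: column
``i`` holds the probabilities of every possible fate of an individual
currently in state ``i``, so each column sums to one.  It is a block matrix

    PX = [ J  Z ]      J: live -> live      (survive and grow)
         [ M  U ]      M: live -> dead space (die while molting or not)
                       Z: dead -> live, identically zero
                       U: dead-space internals (newly dead -> absorbing)

The observation kernel ``PO`` is also column stochastic.  Rows are the 15
observation categories (not seen, seen live per stage, seen dead per stage);
column ``s`` distributes the true state ``s`` over "not seen" (probability
``1 - p_s``) and the single matching seen category (``p_s``).  There is no
misclassification mass: an individual seen as a third instar *is* a third
instar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STAGES",
    "INSTARS",
    "N_STAGES",
    "N_STATES",
    "ABSORBING",
    "ALLOWED_DESTINATIONS",
    "StageSpace",
    "VitalRates",
    "DetectionParams",
    "TransitionMatrix",
    "ObservationMatrix",
    "build_transition_matrix",
    "build_observation_matrix",
    "evolve_state",
    "live_index",
    "newly_dead_index",
]

STAGES: tuple[str, ...] = ("egg", "I1", "I2", "I3", "I4", "I5", "pupa")
INSTARS: tuple[str, ...] = ("I1", "I2", "I3", "I4", "I5")
N_STAGES = 7
N_STATES = 15
ABSORBING = 14

#: Allowed growth destinations per stage (stasis listed first).  Eggs hatch
#: into first instars; early instars may skip a stage in one 3-day step;
#: fourth instars molt to fifth; fifth instars pupate; the pupa is terminal
#: within this model (pupal maturation is outside the observable window).
ALLOWED_DESTINATIONS: dict[str, tuple[str, ...]] = {
    "egg": ("egg", "I1"),
    "I1": ("I1", "I2", "I3"),
    "I2": ("I2", "I3", "I4"),
    "I3": ("I3", "I4", "I5"),
    "I4": ("I4", "I5"),
    "I5": ("I5", "pupa"),
    "pupa": ("pupa",),
}

_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

#: Boolean mask, mask[j, i] True when growth from stage i to stage j is allowed.
TRANSITION_MASK = np.zeros((N_STAGES, N_STAGES), dtype=bool)
for _src, _dests in ALLOWED_DESTINATIONS.items():
    for _d in _dests:
        TRANSITION_MASK[_STAGE_INDEX[_d], _STAGE_INDEX[_src]] = True


#: Observation-category codes in row order of the observation kernel:
#: not seen, seen live per stage, seen dead per stage.  ``DE`` and ``DP``
#: (dead egg / dead pupa) are structural placeholders that never occur in
#: data because those corpses are unobservable.
CATEGORY_CODES: tuple[str, ...] = (
    "NS",
    "E", "L1", "L2", "L3", "L4", "L5", "P",
    "DE", "D1", "D2", "D3", "D4", "D5", "DP",
)
CATEGORY_NS = 0


def live_category(stage: str) -> int:
    """Observation-category index for seeing a live individual in ``stage``."""
    return 1 + _STAGE_INDEX[stage]


def dead_category(stage: str) -> int:
    """Observation-category index for seeing a corpse in ``stage``."""
    return 1 + N_STAGES + _STAGE_INDEX[stage]


def live_index(stage: str) -> int:
    """State index of a live individual in ``stage``."""
    return _STAGE_INDEX[stage]


def newly_dead_index(stage: str) -> int:
    """State index of a newly dead individual in ``stage``."""
    return N_STAGES + _STAGE_INDEX[stage]


@dataclass(frozen=True)
class StageSpace:
    """The fixed 15-state space: 7 live stages, 7 newly-dead stages, 1 absorbing."""

    live_stages: tuple[str, ...] = STAGES
    newly_dead_stages: tuple[str, ...] = STAGES
    absorbing: str = "dead"

    @property
    def total_states(self) -> int:
        return 2 * len(self.live_stages) + 1

    def state_label(self, index: int) -> str:
        if index < N_STAGES:
            return f"live:{self.live_stages[index]}"
        if index < 2 * N_STAGES:
            return f"newly_dead:{self.newly_dead_stages[index - N_STAGES]}"
        if index == ABSORBING:
            return self.absorbing
        raise IndexError(f"state index {index} out of range 0..{ABSORBING}")


_SIMPLEX_TOL = 1e-12


@dataclass
class VitalRates:
    """Per-stage survival and growth over one 3-day step.

    Parameters
    ----------
    phi : (7,) array
        Stage-specific survival probability per step, ordered as `STAGES`.
    psi : (7, 7) array
        Growth kernel conditional on survival: ``psi[j, i]`` is the
        probability of moving from stage ``i`` to stage ``j``.  Each column
        is a simplex supported on `ALLOWED_DESTINATIONS`.  Egg hatching and
        pupation are simply the egg and I5 columns of this kernel.
    """

    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != (N_STAGES,):
            raise ValueError(f"phi must have shape ({N_STAGES},), got {self.phi.shape}")
        if self.psi.shape != (N_STAGES, N_STAGES):
            raise ValueError(
                f"psi must have shape ({N_STAGES}, {N_STAGES}), got {self.psi.shape}"
            )
        for i, stage in enumerate(STAGES):
            if not 0.0 <= self.phi[i] <= 1.0:
                raise ValueError(f"phi out of [0, 1] for stage {stage!r}: {self.phi[i]}")
            col = self.psi[:, i]
            if np.any(col < -_SIMPLEX_TOL) or np.any(col > 1 + _SIMPLEX_TOL):
                raise ValueError(f"psi column for stage {stage!r} has entries outside [0, 1]")
            if abs(col.sum() - 1.0) > _SIMPLEX_TOL:
                raise ValueError(
                    f"psi column for stage {stage!r} sums to {col.sum()!r}, not 1"
                )
            if np.any(col[~TRANSITION_MASK[:, i]] != 0.0):
                raise ValueError(
                    f"psi column for stage {stage!r} puts mass on a forbidden transition"
                )


@dataclass
class DetectionParams:
    """Stage-specific detection probabilities for live and newly dead individuals.

    Newly dead eggs and pupae are structurally unobservable (only instar
    corpses are ever recovered), so their ``p_dead`` entries must be zero.
    """

    p_live: np.ndarray
    p_dead: np.ndarray

    def __post_init__(self) -> None:
        self.p_live = np.asarray(self.p_live, dtype=float)
        self.p_dead = np.asarray(self.p_dead, dtype=float)
        for name, arr in (("p_live", self.p_live), ("p_dead", self.p_dead)):
            if arr.shape != (N_STAGES,):
                raise ValueError(f"{name} must have shape ({N_STAGES},), got {arr.shape}")
            bad = (arr < 0) | (arr > 1)
            if np.any(bad):
                stage = STAGES[int(np.argmax(bad))]
                raise ValueError(f"{name} out of [0, 1] for stage {stage!r}")
        if self.p_dead[live_index("egg")] != 0.0 or self.p_dead[live_index("pupa")] != 0.0:
            raise ValueError("p_dead must be 0 for egg and pupa (corpses unobservable)")


@dataclass
class TransitionMatrix:
    """A validated 15x15 column-stochastic demographic kernel."""

    PX: np.ndarray

    def __post_init__(self) -> None:
        self.PX = np.asarray(self.PX, dtype=float)
        if self.PX.shape != (N_STATES, N_STATES):
            raise ValueError(f"PX must be {N_STATES}x{N_STATES}, got {self.PX.shape}")
        if np.any(self.PX < 0) or np.any(self.PX > 1):
            raise ValueError("PX entries must lie in [0, 1]")
        sums = self.PX.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > _SIMPLEX_TOL):
            raise ValueError(f"PX columns must sum to 1 (found {sums})")
        if np.any(self.J_to_dead_block != 0.0):
            raise ValueError("Z block (dead -> live) must be identically zero")

    @property
    def J(self) -> np.ndarray:
        """Live -> live block (survive-and-grow)."""
        return self.PX[:N_STAGES, :N_STAGES]

    @property
    def M(self) -> np.ndarray:
        """Live -> dead-space block (newly dead rows plus absorbing row)."""
        return self.PX[N_STAGES:, :N_STAGES]

    @property
    def J_to_dead_block(self) -> np.ndarray:
        """Z block: dead space -> live, structurally zero."""
        return self.PX[:N_STAGES, N_STAGES:]

    @property
    def U(self) -> np.ndarray:
        """Dead-space internal block (newly dead -> absorbing)."""
        return self.PX[N_STAGES:, N_STAGES:]

    # Convenience alias matching the block-letter naming in the docstring.
    Z = J_to_dead_block


@dataclass
class ObservationMatrix:
    """A validated 15x15 column-stochastic observation kernel."""

    PO: np.ndarray

    def __post_init__(self) -> None:
        self.PO = np.asarray(self.PO, dtype=float)
        if self.PO.shape != (N_STATES, N_STATES):
            raise ValueError(f"PO must be {N_STATES}x{N_STATES}, got {self.PO.shape}")
        if np.any(self.PO < 0) or np.any(self.PO > 1):
            raise ValueError("PO entries must lie in [0, 1]")
        sums = self.PO.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > _SIMPLEX_TOL):
            raise ValueError(f"PO columns must sum to 1 (found {sums})")


def build_transition_matrix(
    vital: VitalRates, *, partition_dying_by_growth: bool = False
) -> TransitionMatrix:
    """Assemble the 15x15 kernel ``PX`` from survival and growth rates.

    Each live -> live element is the product of surviving and growing,
    ``J[j, i] = phi_i * psi[j, i]``.  Dying mass ``1 - phi_i`` lands in the
    newly dead rows.  By default it stays in the current stage (most deaths
    are predation, leaving a corpse of the stage that died); with
    ``partition_dying_by_growth=True`` it is instead partitioned across
    stages by the same growth kernel, ``M[j, i] = (1 - phi_i) * psi[j, i]``,
    recording deaths during molting in the *new* stage.  Every newly dead
    state moves to the absorbing state with probability one, and the
    absorbing state is a self-loop.
    """
    px = np.zeros((N_STATES, N_STATES))
    phi, psi = vital.phi, vital.psi
    px[:N_STAGES, :N_STAGES] = psi * phi[np.newaxis, :]
    if partition_dying_by_growth:
        px[N_STAGES : 2 * N_STAGES, :N_STAGES] = psi * (1.0 - phi)[np.newaxis, :]
    else:
        px[N_STAGES : 2 * N_STAGES, :N_STAGES] = np.diag(1.0 - phi)
    px[ABSORBING, N_STAGES : 2 * N_STAGES] = 1.0
    px[ABSORBING, ABSORBING] = 1.0
    return TransitionMatrix(px)


def build_observation_matrix(det: DetectionParams) -> ObservationMatrix:
    """Assemble the 15x15 observation kernel ``PO`` from detection probabilities.

    Observation categories (rows) mirror the state ordering: row 0 is "not
    seen", rows 1..7 are "seen live" per stage, rows 8..14 are "seen dead"
    per stage.  The absorbing dead state is never seen.
    """
    po = np.zeros((N_STATES, N_STATES))
    for i in range(N_STAGES):
        po[0, i] = 1.0 - det.p_live[i]
        po[1 + i, i] = det.p_live[i]
        po[0, N_STAGES + i] = 1.0 - det.p_dead[i]
        po[1 + N_STAGES + i, N_STAGES + i] = det.p_dead[i]
    po[0, ABSORBING] = 1.0
    return ObservationMatrix(po)


def evolve_state(px: TransitionMatrix | np.ndarray, x: np.ndarray) -> np.ndarray:
    """One step of the state equation: returns ``PX @ x`` for a distribution ``x``."""
    mat = px.PX if isinstance(px, TransitionMatrix) else np.asarray(px, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape != (N_STATES,):
        raise ValueError(f"state distribution must have shape ({N_STATES},), got {x.shape}")
    out = mat @ x
    if abs(out.sum() - 1.0) > 1e-10:
        raise ValueError("state distribution no longer sums to 1; invalid kernel or input")
    return out
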