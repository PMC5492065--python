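"""Exact marginal likelihood of encounter histories under the hidden Markov model.

The joint model is

    X_t | X_{t-1} ~ Categorical(PX x_{t-1})      (demographic process)
    Y_t | X_t     ~ Categorical(PO x_t)          (observation process)

and the likelihood of an observed category sequence marginalizes the hidden
state path.  `individual_loglik` does this with the scaled forward
algorithm, conditioning on the state at first detection (individuals enter
the marked sample when first seen alive, so the recursion starts from a
unit mass on that live state).  `brute_force_loglik` is an independent
oracle that enumerates every hidden path explicitly; it is exponential in
history length and only usable on short histories.

`DatasetLikelihood` is the production evaluator: it packs a whole dataset
into flat arrays, groups (individual, occasion) cells into covariate
classes, and runs a numba-compiled forward pass, so MCMC can evaluate the
full-data likelihood in well under a millisecond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .covariates import CovariateSet, ModelStructure, ParameterVector
from .states import CATEGORY_NS, N_STAGES, N_STATES

__all__ = [
    "EncounterHistory",
    "individual_loglik",
    "brute_force_loglik",
    "DatasetLikelihood",
    "dataset_deviance",
]

_LIVE_CATS = frozenset(range(1, 1 + N_STAGES))
_DEAD_CATS = frozenset(range(1 + N_STAGES, N_STATES))


@dataclass
class EncounterHistory:
    """One individual's observation record across its plot's survey occasions.

    ``categories`` holds one observation-category index per occasion
    (`stagehmm.states.CATEGORY_CODES` order), ``days`` the integer survey-day
    index of each occasion, ``plant_ids`` the plant searched, and
    ``lengths`` the measured body length in mm (NaN when not measured).
    """

    individual_id: str
    plot_id: str
    plant_ids: list
    days: np.ndarray
    categories: np.ndarray
    lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=np.int64)
        self.categories = np.asarray(self.categories, dtype=np.int64)
        T = len(self.categories)
        if self.lengths is None:
            self.lengths = np.full(T, np.nan)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if not (len(self.days) == T == len(self.plant_ids) == len(self.lengths)):
            raise ValueError(f"inconsistent occasion counts for individual {self.individual_id}")
        if np.any(self.categories < 0) or np.any(self.categories >= N_STATES):
            raise ValueError(f"unknown observation category for individual {self.individual_id}")
        detected = np.flatnonzero(self.categories != CATEGORY_NS)
        if detected.size == 0:
            raise ValueError(f"individual {self.individual_id} has no detections")
        if int(self.categories[detected[0]]) not in _LIVE_CATS:
            raise ValueError(
                f"individual {self.individual_id}: first detection must be a live stage"
            )
        dead_at = [t for t in detected if int(self.categories[t]) in _DEAD_CATS]
        if dead_at:
            after = self.categories[dead_at[0] + 1 :]
            if np.any(after != CATEGORY_NS):
                raise ValueError(
                    f"individual {self.individual_id}: observations after a dead "
                    "recovery must be 'not seen' (dead recovery is terminal)"
                )

    @property
    def first_detection(self) -> int:
        """Occasion index of the first detection."""
        return int(np.flatnonzero(self.categories != CATEGORY_NS)[0])

    @property
    def first_state(self) -> int:
        """Live-state index at first detection (category index minus one)."""
        return int(self.categories[self.first_detection]) - 1

    @property
    def n_occasions(self) -> int:
        return len(self.categories)


def _as_categories(history) -> np.ndarray:
    if isinstance(history, EncounterHistory):
        return history.categories
    return np.asarray(history, dtype=np.int64)


def _po_at(po: np.ndarray, t: int) -> np.ndarray:
    return po[t] if po.ndim == 3 else po


def _conditioning(cats: np.ndarray) -> tuple[int, int]:
    det = np.flatnonzero(cats != CATEGORY_NS)
    if det.size == 0:
        raise ValueError("history has no detections")
    t0 = int(det[0])
    cat0 = int(cats[t0])
    if cat0 not in _LIVE_CATS:
        raise ValueError("first detection must be a live-stage category")
    return t0, cat0 - 1


def individual_loglik(history, px_seq: np.ndarray, po: np.ndarray) -> float:
    """Marginal log-likelihood of one encounter history via the forward pass.

    ``px_seq`` has shape (T-1, 15, 15); ``px_seq[t-1]`` is the kernel for
    the transition into occasion ``t`` (built from covariates at the source
    occasion).  ``po`` is either a single (15, 15) kernel or one per
    occasion, shape (T, 15, 15).  Returns ``-inf`` for impossible histories.
    """
    cats = _as_categories(history)
    T = len(cats)
    px_seq = np.asarray(px_seq, dtype=float)
    if px_seq.shape != (T - 1, N_STATES, N_STATES):
        raise ValueError(
            f"px_seq must have shape ({T - 1}, {N_STATES}, {N_STATES}), got {px_seq.shape}"
        )
    po = np.asarray(po, dtype=float)
    t0, s0 = _conditioning(cats)
    alpha = np.zeros(N_STATES)
    alpha[s0] = 1.0
    logscale = 0.0
    for t in range(t0 + 1, T):
        alpha = px_seq[t - 1] @ alpha
        alpha = alpha * _po_at(po, t)[cats[t]]
        s = alpha.sum()
        if s <= 0.0:
            return -np.inf
        logscale += np.log(s)
        alpha /= s
    return float(logscale)


def brute_force_loglik(history, px_seq: np.ndarray, po: np.ndarray) -> float:
    """Oracle log-likelihood by explicit summation over all hidden-state paths.

    Same conditioning as `individual_loglik`.  Refuses histories longer than
    6 occasions (the path count is 15^(T - 1 - t0)).
    """
    cats = _as_categories(history)
    T = len(cats)
    if T > 6:
        raise ValueError("brute force is limited to histories of at most 6 occasions")
    px_seq = np.asarray(px_seq, dtype=float)
    po = np.asarray(po, dtype=float)
    t0, s0 = _conditioning(cats)
    L = T - 1 - t0
    if L == 0:
        return 0.0
    paths = np.indices((N_STATES,) * L).reshape(L, -1)
    prob = np.ones(paths.shape[1])
    prev = np.full(paths.shape[1], s0)
    for m in range(L):
        t = t0 + 1 + m
        cur = paths[m]
        prob = prob * px_seq[t - 1][cur, prev] * _po_at(po, t)[cats[t]][cur]
        prev = cur
    total = prob.sum()
    return float(np.log(total)) if total > 0 else -np.inf


@dataclass
class _PackedData:
    cats: np.ndarray
    first_occ: np.ndarray
    first_state: np.ndarray
    n_occ: np.ndarray
    cls_idx: np.ndarray
    x_surv: np.ndarray
    x_grow: np.ndarray


class DatasetLikelihood:
    """Fast full-dataset log-likelihood for one model structure.

    Packs the encounter histories once, deduplicates (individual, occasion)
    covariate values into classes, and evaluates the forward algorithm with
    numba.  Transition kernels are rebuilt from the parameter vector at
    every call, one per covariate class.
    """

    def __init__(
        self,
        histories,
        structure: ModelStructure,
        covariates: CovariateSet | None = None,
        partition_dying_by_growth: bool = False,
    ):
        if len(histories) == 0:
            raise ValueError("no encounter histories supplied")
        needs_cov = structure.survival_form != "constant" or structure.growth_form != "constant"
        if needs_cov and covariates is None:
            raise ValueError(f"structure {structure.label} requires a CovariateSet")
        self.structure = structure
        self.partition_dying_by_growth = partition_dying_by_growth
        n = len(histories)
        T = max(h.n_occasions for h in histories)
        cats = np.zeros((n, T), dtype=np.int64)
        first_occ = np.empty(n, dtype=np.int64)
        first_state = np.empty(n, dtype=np.int64)
        n_occ = np.empty(n, dtype=np.int64)
        for k, h in enumerate(histories):
            cats[k, : h.n_occasions] = h.categories
            first_occ[k] = h.first_detection
            first_state[k] = h.first_state
            n_occ[k] = h.n_occasions
        if covariates is not None:
            xs, xg = covariates.for_structure(structure)
            if xs.shape != (n, T):
                raise ValueError(
                    f"covariate arrays have shape {xs.shape}, expected ({n}, {T})"
                )
        else:
            xs = np.zeros((n, T))
            xg = np.zeros((n, T))
        # The transition into occasion t is driven by covariates at t-1.
        pairs = np.stack([xs, xg], axis=-1).reshape(-1, 2)
        uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
        src_cls = inv.reshape(n, T)
        cls_idx = np.zeros((n, T), dtype=np.int64)
        cls_idx[:, 1:] = src_cls[:, :-1]
        self._packed = _PackedData(
            cats=cats,
            first_occ=first_occ,
            first_state=first_state,
            n_occ=n_occ,
            cls_idx=cls_idx,
            x_surv=np.ascontiguousarray(uniq[:, 0]),
            x_grow=np.ascontiguousarray(uniq[:, 1]),
        )
        self._death_mult = np.ones(len(uniq))
        self._group_of = np.asarray(structure.group_of_instar, dtype=np.int64)
        self.n_histories = n

    def kernels(self, params: ParameterVector) -> tuple[np.ndarray, np.ndarray]:
        """Per-class transition kernels and the observation kernel."""
        p = self._packed
        b1 = params.b1 if params.b1 is not None else np.empty(0)
        a1 = params.a1 if params.a1 is not None else np.empty(0)
        px = _kernels.build_px_stack(
            params.b0, b1, self._group_of, params.a0, a1,
            params.egg_survival, params.egg_hatch, params.pupation,
            p.x_surv, p.x_grow, self._death_mult, self.partition_dying_by_growth,
        )
        p_live = np.concatenate([params.p_live, [params.pupa_p_live]])
        p_dead = np.concatenate([[0.0], params.p_dead, [0.0]])
        po = _kernels.build_po(p_live, p_dead)
        return px, po

    def loglik(self, params: ParameterVector) -> float:
        px, po = self.kernels(params)
        p = self._packed
        return float(
            _kernels.forward_loglik_packed(
                p.cats, p.first_occ, p.first_state, p.n_occ, p.cls_idx, px, po
            )
        )

    def deviance(self, params: ParameterVector) -> float:
        """-2 x total log-likelihood; +inf when any history is impossible."""
        return -2.0 * self.loglik(params)


def dataset_deviance(
    params: ParameterVector,
    structure: ModelStructure,
    histories,
    covariates: CovariateSet | None = None,
) -> float:
    """Deviance of a dataset at one parameter vector (convenience wrapper)."""
    return DatasetLikelihood(histories, structure, covariates).deviance(params)
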