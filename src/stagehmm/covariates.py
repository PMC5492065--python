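"""Covariate construction and link functions mapping parameters to vital rates.

Survival uses a logit link; growth uses a multinomial logit with stasis as
the reference category, so the probabilities of all transitions out of a
stage sum to one by construction.  Candidate model structures combine a
survival form (constant, or linear in survey date or caterpillar density),
a survival stage-grouping (every instar separate, or first-to-fourth instars
pooled as distinct from fifth), and a growth form (constant, or linear in
survey date or 3-day mean air temperature).  The full default grid is the
3 x 2 x 3 = 18 candidate set.

Egg survival, egg hatching, and pupation are rarely informed by field data
(eggs and pupae are nearly unobservable) and are carried as free
probabilities under informative beta priors rather than as logit-linear
terms; covariates never act on them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import (
    ALLOWED_DESTINATIONS,
    INSTARS,
    N_STAGES,
    STAGES,
    VitalRates,
    live_category,
    live_index,
)

__all__ = [
    "SURVIVAL_FORMS",
    "SURVIVAL_GROUPINGS",
    "GROWTH_FORMS",
    "ModelStructure",
    "ParameterVector",
    "ParameterLayout",
    "CovariateSet",
    "Standardizer",
    "enumerate_model_grid",
    "survival_probability",
    "growth_probabilities",
    "assemble_vital_rates",
    "size_scaled_density",
    "interval_mean_temperature",
    "build_covariates",
]

SURVIVAL_FORMS = ("constant", "date", "density")
SURVIVAL_GROUPINGS = ("full_stage", "early_grouped")
GROWTH_FORMS = ("constant", "date", "temperature")

#: Growth intercept layout: one multinomial-logit intercept per non-stasis
#: destination of each instar with free growth (I1..I4; egg hatching and
#: pupation are informative-prior parameters, the pupa is terminal).
GROWTH_INTERCEPTS: tuple[tuple[str, str], ...] = (
    ("I1", "I2"), ("I1", "I3"),
    ("I2", "I3"), ("I2", "I4"),
    ("I3", "I4"), ("I3", "I5"),
    ("I4", "I5"),
)
#: One shared growth slope per instar (shared across its destinations).
GROWTH_SLOPE_STAGES: tuple[str, ...] = ("I1", "I2", "I3", "I4")


@dataclass(frozen=True)
class ModelStructure:
    """One cell of the candidate model grid."""

    survival_form: str = "constant"
    survival_grouping: str = "full_stage"
    growth_form: str = "constant"

    def __post_init__(self) -> None:
        if self.survival_form not in SURVIVAL_FORMS:
            raise ValueError(f"survival_form must be one of {SURVIVAL_FORMS}")
        if self.survival_grouping not in SURVIVAL_GROUPINGS:
            raise ValueError(f"survival_grouping must be one of {SURVIVAL_GROUPINGS}")
        if self.growth_form not in GROWTH_FORMS:
            raise ValueError(f"growth_form must be one of {GROWTH_FORMS}")

    @property
    def survival_groups(self) -> tuple[str, ...]:
        if self.survival_grouping == "full_stage":
            return INSTARS
        return ("I1_4", "I5")

    @property
    def group_of_instar(self) -> tuple[int, ...]:
        """Index into the survival-group axis for each instar I1..I5."""
        if self.survival_grouping == "full_stage":
            return (0, 1, 2, 3, 4)
        return (0, 0, 0, 0, 1)

    @property
    def label(self) -> str:
        return (
            f"phi({self.survival_form},{self.survival_grouping})"
            f"/psi({self.growth_form})"
        )


def enumerate_model_grid(
    survival_forms: tuple[str, ...] = SURVIVAL_FORMS,
    groupings: tuple[str, ...] = SURVIVAL_GROUPINGS,
    growth_forms: tuple[str, ...] = GROWTH_FORMS,
) -> list[ModelStructure]:
    """Cartesian product of the allowed options, in deterministic order.

    Survival form varies slowest, grouping next, growth form fastest.  The
    defaults reproduce the 18-model candidate set.
    """
    for name, opts in (
        ("survival_forms", survival_forms),
        ("groupings", groupings),
        ("growth_forms", growth_forms),
    ):
        if len(opts) == 0:
            raise ValueError(f"{name} must list at least one option")
    return [
        ModelStructure(s, g, r)
        for s, g, r in itertools.product(survival_forms, groupings, growth_forms)
    ]


@dataclass
class ParameterVector:
    """Free parameters of one model structure.

    ``b0``/``b1`` are survival intercepts and slopes per survival group
    (length 5 for ``full_stage``, 2 for ``early_grouped``); ``a0`` holds the
    seven growth intercepts in `GROWTH_INTERCEPTS` order and ``a1`` the four
    shared per-stage growth slopes.  ``p_live`` covers egg and the five
    instars (pupae are never seen once they leave the plant, so their live
    detection is the fixed ``pupa_p_live``); ``p_dead`` covers the five
    instars.  ``egg_survival``, ``egg_hatch`` and ``pupation`` are the
    informative-prior demographic probabilities.
    """

    b0: np.ndarray
    a0: np.ndarray
    p_live: np.ndarray
    p_dead: np.ndarray
    egg_survival: float
    egg_hatch: float
    pupation: float
    b1: np.ndarray | None = None
    a1: np.ndarray | None = None
    pupa_p_live: float = 0.0

    def __post_init__(self) -> None:
        self.b0 = np.atleast_1d(np.asarray(self.b0, dtype=float))
        self.a0 = np.atleast_1d(np.asarray(self.a0, dtype=float))
        self.p_live = np.atleast_1d(np.asarray(self.p_live, dtype=float))
        self.p_dead = np.atleast_1d(np.asarray(self.p_dead, dtype=float))
        if self.b1 is not None:
            self.b1 = np.atleast_1d(np.asarray(self.b1, dtype=float))
        if self.a1 is not None:
            self.a1 = np.atleast_1d(np.asarray(self.a1, dtype=float))
        if self.a0.shape != (len(GROWTH_INTERCEPTS),):
            raise ValueError(f"a0 must have length {len(GROWTH_INTERCEPTS)}")
        if self.p_live.shape != (6,):
            raise ValueError("p_live must have length 6 (egg, I1..I5)")
        if self.p_dead.shape != (5,):
            raise ValueError("p_dead must have length 5 (I1..I5)")
        for name in ("b0", "a0", "b1", "a1"):
            arr = getattr(self, name)
            if arr is not None and not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
        for name in ("p_live", "p_dead"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("egg_survival", "egg_hatch", "pupation", "pupa_p_live"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


class ParameterLayout:
    """Flat packing of a `ParameterVector` for one structure.

    Defines the free-parameter names, their order, the sampling blocks, and
    the natural <-> unconstrained transforms (logit for probabilities,
    identity for linear coefficients).
    """

    COEF, PROB = "coef", "prob"

    def __init__(self, structure: ModelStructure):
        self.structure = structure
        groups = structure.survival_groups
        names: list[str] = []
        kinds: list[str] = []
        blocks: list[str] = []

        def add(name: str, kind: str, block: str) -> None:
            names.append(name)
            kinds.append(kind)
            blocks.append(block)

        for g in groups:
            add(f"b0[{g}]", self.COEF, "survival")
        self.has_b1 = structure.survival_form != "constant"
        if self.has_b1:
            for g in groups:
                add(f"b1[{g}]", self.COEF, "survival")
        for src, dst in GROWTH_INTERCEPTS:
            add(f"a0[{src}->{dst}]", self.COEF, "growth")
        self.has_a1 = structure.growth_form != "constant"
        if self.has_a1:
            for s in GROWTH_SLOPE_STAGES:
                add(f"a1[{s}]", self.COEF, "growth")
        for s in ("egg",) + INSTARS:
            add(f"p_live[{s}]", self.PROB, "detection")
        for s in INSTARS:
            add(f"p_dead[{s}]", self.PROB, "detection")
        add("egg_survival", self.PROB, "informative")
        add("egg_hatch", self.PROB, "informative")
        add("pupation", self.PROB, "informative")

        self.names: tuple[str, ...] = tuple(names)
        self.kinds: tuple[str, ...] = tuple(kinds)
        self.block_names: tuple[str, ...] = ("survival", "growth", "detection", "informative")
        self.blocks: dict[str, np.ndarray] = {
            b: np.array([i for i, bl in enumerate(blocks) if bl == b], dtype=np.int64)
            for b in self.block_names
        }
        self.n_groups = len(groups)
        self.size = len(names)
        self._prob_mask = np.array([k == self.PROB for k in kinds])
        # Slices in packing order.
        i = 0
        self.sl_b0 = slice(i, i + self.n_groups); i += self.n_groups
        if self.has_b1:
            self.sl_b1 = slice(i, i + self.n_groups); i += self.n_groups
        else:
            self.sl_b1 = None
        na0 = len(GROWTH_INTERCEPTS)
        self.sl_a0 = slice(i, i + na0); i += na0
        if self.has_a1:
            self.sl_a1 = slice(i, i + len(GROWTH_SLOPE_STAGES)); i += len(GROWTH_SLOPE_STAGES)
        else:
            self.sl_a1 = None
        self.sl_p_live = slice(i, i + 6); i += 6
        self.sl_p_dead = slice(i, i + 5); i += 5
        self.i_egg_survival, self.i_egg_hatch, self.i_pupation = i, i + 1, i + 2

    # -- packing ---------------------------------------------------------
    def natural(self, pv: ParameterVector) -> np.ndarray:
        """Flatten a ParameterVector to a natural-scale vector."""
        x = np.empty(self.size)
        x[self.sl_b0] = pv.b0
        if self.has_b1:
            if pv.b1 is None:
                raise ValueError(f"structure {self.structure.label} requires b1")
            x[self.sl_b1] = pv.b1
        x[self.sl_a0] = pv.a0
        if self.has_a1:
            if pv.a1 is None:
                raise ValueError(f"structure {self.structure.label} requires a1")
            x[self.sl_a1] = pv.a1
        x[self.sl_p_live] = pv.p_live
        x[self.sl_p_dead] = pv.p_dead
        x[self.i_egg_survival] = pv.egg_survival
        x[self.i_egg_hatch] = pv.egg_hatch
        x[self.i_pupation] = pv.pupation
        return x

    def from_natural(self, x: np.ndarray) -> ParameterVector:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.size,):
            raise ValueError(f"expected vector of length {self.size}, got {x.shape}")
        return ParameterVector(
            b0=x[self.sl_b0].copy(),
            b1=x[self.sl_b1].copy() if self.has_b1 else None,
            a0=x[self.sl_a0].copy(),
            a1=x[self.sl_a1].copy() if self.has_a1 else None,
            p_live=x[self.sl_p_live].copy(),
            p_dead=x[self.sl_p_dead].copy(),
            egg_survival=float(x[self.i_egg_survival]),
            egg_hatch=float(x[self.i_egg_hatch]),
            pupation=float(x[self.i_pupation]),
        )

    def unconstrained(self, pv: ParameterVector) -> np.ndarray:
        """Natural -> unconstrained (logit on every probability entry)."""
        x = self.natural(pv)
        z = x.copy()
        p = np.clip(x[self._prob_mask], 1e-12, 1 - 1e-12)
        z[self._prob_mask] = np.log(p) - np.log1p(-p)
        return z

    def from_unconstrained(self, z: np.ndarray) -> ParameterVector:
        x = np.asarray(z, dtype=float).copy()
        x[self._prob_mask] = 1.0 / (1.0 + np.exp(-x[self._prob_mask]))
        return self.from_natural(x)

    def natural_from_unconstrained(self, z: np.ndarray) -> np.ndarray:
        x = np.asarray(z, dtype=float).copy()
        x[self._prob_mask] = 1.0 / (1.0 + np.exp(-x[self._prob_mask]))
        return x

    @property
    def prob_mask(self) -> np.ndarray:
        return self._prob_mask.copy()


# ---------------------------------------------------------------------------
# Link functions
# ---------------------------------------------------------------------------

def _logistic(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + np.exp(-z))
    e = np.exp(z)
    return e / (1.0 + e)


def _covariate_or_error(x: float | None, form: str, what: str) -> float:
    if form == "constant":
        return 0.0
    if x is None or (isinstance(x, float) and np.isnan(x)):
        raise ValueError(f"{what} model has form {form!r} but no covariate value was supplied")
    return float(x)


def survival_probability(
    stage: str,
    covariate: float | None,
    params: ParameterVector,
    structure: ModelStructure,
) -> float:
    """Per-step survival probability for a live stage (pupa excluded).

    Instar survival is ``logistic(b0 + b1 * x)`` with ``x`` the survival
    covariate selected by the structure (0 under the constant form); egg
    survival is the informative-prior probability and ignores covariates.
    """
    if stage == "pupa":
        raise ValueError("pupa survival is not modeled (terminal stage)")
    if stage == "egg":
        return float(params.egg_survival)
    if stage not in INSTARS:
        raise ValueError(f"unknown stage {stage!r}")
    g = structure.group_of_instar[INSTARS.index(stage)]
    z = params.b0[g]
    if structure.survival_form != "constant":
        x = _covariate_or_error(covariate, structure.survival_form, "survival")
        if params.b1 is None:
            raise ValueError(f"structure {structure.label} requires b1")
        z = z + params.b1[g] * x
    return _logistic(z)


def growth_probabilities(
    stage: str,
    covariate: float | None,
    params: ParameterVector,
    structure: ModelStructure,
) -> np.ndarray:
    """Growth simplex over `ALLOWED_DESTINATIONS[stage]` (stasis first).

    Instars I1..I4 use a multinomial logit with stasis as the reference
    category and one shared slope per stage; egg hatching and pupation are
    the informative-prior probabilities; the pupa is pure stasis.
    """
    dests = ALLOWED_DESTINATIONS[stage]
    if stage == "egg":
        return np.array([1.0 - params.egg_hatch, params.egg_hatch])
    if stage == "I5":
        return np.array([1.0 - params.pupation, params.pupation])
    if stage == "pupa":
        return np.array([1.0])
    idx = [i for i, (src, _) in enumerate(GROWTH_INTERCEPTS) if src == stage]
    z = params.a0[idx].astype(float).copy()
    if structure.growth_form != "constant":
        x = _covariate_or_error(covariate, structure.growth_form, "growth")
        if params.a1 is None:
            raise ValueError(f"structure {structure.label} requires a1")
        z = z + params.a1[GROWTH_SLOPE_STAGES.index(stage)] * x
    # Stasis is the reference category (linear predictor 0); guard overflow.
    m = max(0.0, float(np.max(z)))
    e = np.exp(np.concatenate(([0.0], z)) - m)
    out = e / e.sum()
    if len(out) != len(dests):
        raise AssertionError("intercept layout inconsistent with allowed destinations")
    return out


def assemble_vital_rates(
    params: ParameterVector,
    structure: ModelStructure,
    survival_covariate: float | None = None,
    growth_covariate: float | None = None,
) -> VitalRates:
    """Compose the link functions into a full `VitalRates` for one step."""
    phi = np.empty(N_STAGES)
    psi = np.zeros((N_STAGES, N_STAGES))
    for i, stage in enumerate(STAGES):
        if stage == "pupa":
            phi[i] = 1.0
        else:
            phi[i] = survival_probability(stage, survival_covariate, params, structure)
        probs = growth_probabilities(stage, growth_covariate, params, structure)
        for dest, p in zip(ALLOWED_DESTINATIONS[stage], probs):
            psi[live_index(dest), i] = p
    return VitalRates(phi=phi, psi=psi)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def size_scaled_density(lengths_mm, metric: str = "size") -> float:
    """Caterpillar density on one plant at one occasion.

    ``metric="size"`` returns the summed body lengths (a biomass proxy);
    ``metric="count"`` returns the number of caterpillars.
    """
    arr = np.asarray(list(lengths_mm), dtype=float)
    if arr.size and np.any(arr < 0):
        raise ValueError("lengths must be nonnegative")
    if metric == "size":
        return float(arr.sum())
    if metric == "count":
        return float(arr.size)
    raise ValueError(f"unknown density metric {metric!r}")


def interval_mean_temperature(
    hourly: pd.DataFrame,
    start_day: float,
    n_days: float = 3.0,
    max_missing_frac: float = 0.1,
) -> float:
    """Mean hourly temperature over the half-open interval [start, start + n_days).

    ``hourly`` must have columns ``hour`` (hours since season start) and
    ``temp``.  Up to ``max_missing_frac`` of the expected hourly records may
    be missing; the mean is taken over the available hours.
    """
    h0, h1 = start_day * 24.0, (start_day + n_days) * 24.0
    window = hourly[(hourly["hour"] >= h0) & (hourly["hour"] < h1)]
    temps = window["temp"].dropna()
    expected = int(round(n_days * 24))
    missing = 1.0 - len(temps) / expected
    if missing > max_missing_frac:
        raise ValueError(
            f"interval [{start_day}, {start_day + n_days}) days is missing "
            f"{missing:.0%} of its hourly records (> {max_missing_frac:.0%})"
        )
    return float(temps.mean())


@dataclass
class Standardizer:
    """Stored z-standardization so linear predictors are unit-free and invertible."""

    mean: float
    sd: float

    @classmethod
    def fit(cls, values: np.ndarray) -> "Standardizer":
        v = np.asarray(values, dtype=float)
        sd = float(v.std())
        return cls(mean=float(v.mean()), sd=sd if sd > 0 else 1.0)

    def transform(self, v):
        return (np.asarray(v, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


_LIVE_INSTAR_CATEGORIES = tuple(live_category(s) for s in INSTARS)


@dataclass
class CovariateSet:
    """Per individual x occasion covariates for the linear predictors.

    All three covariates are z-standardized with stored mean/sd.  Values at
    occasion ``t`` drive the transition over the interval [t, t+1).
    """

    x_date: np.ndarray
    x_density: np.ndarray
    x_temperature: np.ndarray | None
    standardizers: dict[str, Standardizer] = field(default_factory=dict)

    def for_structure(self, structure: ModelStructure) -> tuple[np.ndarray, np.ndarray]:
        """Select the (survival, growth) covariate arrays for a structure."""
        zeros = np.zeros_like(self.x_date)
        if structure.survival_form == "constant":
            xs = zeros
        elif structure.survival_form == "date":
            xs = self.x_date
        else:
            xs = self.x_density
        if structure.growth_form == "constant":
            xg = zeros
        elif structure.growth_form == "date":
            xg = self.x_date
        else:
            if self.x_temperature is None:
                raise ValueError(
                    "temperature covariates were not assembled but the structure "
                    "includes a temperature growth form"
                )
            xg = self.x_temperature
        return xs, xg


def build_covariates(
    histories,
    temperature: pd.DataFrame | None = None,
    density_metric: str = "size",
) -> CovariateSet:
    """Assemble standardized date, density, and temperature covariates.

    ``histories`` is a sequence of encounter histories (see
    `stagehmm.likelihood.EncounterHistory`).  Density at (plant, occasion)
    is computed from *observed* co-occupants: the lengths of live instars
    detected there, i.e. what a field worker could tally.  ``temperature``
    is a table with columns plot_id, occasion (1-based), mean_temp; it may
    be omitted if no temperature model will be fitted.
    """
    n = len(histories)
    if n == 0:
        raise ValueError("no encounter histories supplied")
    T = max(len(h.days) for h in histories)

    x_date = np.zeros((n, T))
    for k, h in enumerate(histories):
        x_date[k, : len(h.days)] = h.days

    # Observed per-(plot, plant, occasion) density.
    tallies: dict[tuple, list[float]] = {}
    for h in histories:
        for t in range(len(h.days)):
            if h.categories[t] in _LIVE_INSTAR_CATEGORIES:
                ln = h.lengths[t]
                key = (h.plot_id, h.plant_ids[t], t)
                tallies.setdefault(key, []).append(0.0 if np.isnan(ln) else ln)
    x_dens = np.zeros((n, T))
    for k, h in enumerate(histories):
        for t in range(len(h.days)):
            vals = tallies.get((h.plot_id, h.plant_ids[t], t), [])
            x_dens[k, t] = size_scaled_density(vals, metric=density_metric)

    x_temp = None
    if temperature is not None:
        temp_map = {
            (row.plot_id, int(row.occasion)): float(row.mean_temp)
            for row in temperature.itertuples()
        }
        x_temp = np.zeros((n, T))
        for k, h in enumerate(histories):
            for t in range(len(h.days)):
                key = (h.plot_id, t + 1)
                if key not in temp_map:
                    raise ValueError(f"no temperature record for plot {h.plot_id}, occasion {t + 1}")
                x_temp[k, t] = temp_map[key]

    standardizers = {}
    for name, arr in (("date", x_date), ("density", x_dens), ("temperature", x_temp)):
        if arr is None:
            continue
        std = Standardizer.fit(arr.ravel())
        arr[:] = std.transform(arr)
        standardizers[name] = std

    return CovariateSet(
        x_date=x_date,
        x_density=x_dens,
        x_temperature=x_temp,
        standardizers=standardizers,
    )
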