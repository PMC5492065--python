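"""CSV/YAML/JSON formats for encounter data, covariates, and run configuration.

Encounter files are plain CSV, one row per individual x occasion:

    individual_id, plot_id, plant_id, occasion, day, category, length_mm

``occasion`` is 1-based; ``day`` is the 0-based integer day index from
season start; ``category`` is one of NS, E, L1..L5, P, D1..D5 (dead eggs
and pupae are never recoverable in the field, so they have no codes);
``length_mm`` is optional.  All CSVs are UTF-8, comma-separated, with "."
as the decimal mark.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import (
    GROWTH_FORMS,
    SURVIVAL_FORMS,
    SURVIVAL_GROUPINGS,
    ModelStructure,
    enumerate_model_grid,
)
from .likelihood import EncounterHistory
from .mcmc import MCMCSettings, PriorSpec
from .states import CATEGORY_CODES, N_STAGES

__all__ = [
    "ENCOUNTER_COLUMNS",
    "FILE_CATEGORIES",
    "RunConfig",
    "read_encounter_file",
    "write_encounter_file",
    "read_temperature_file",
    "write_temperature_file",
    "config_hash",
]

ENCOUNTER_COLUMNS = [
    "individual_id", "plot_id", "plant_id", "occasion", "day", "category", "length_mm",
]

#: Categories that may appear in files (structural DE/DP codes excluded).
FILE_CATEGORIES = tuple(c for c in CATEGORY_CODES if c not in ("DE", "DP"))
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORY_CODES)}
_LIVE_CODES = set(CATEGORY_CODES[1 : 1 + N_STAGES])
_DEAD_CODES = set(CATEGORY_CODES[1 + N_STAGES :])


def write_encounter_file(histories, path) -> None:
    """Write encounter histories as CSV (one row per occasion, NS included)."""
    rows = []
    for h in histories:
        for t in range(h.n_occasions):
            ln = h.lengths[t]
            rows.append(
                {
                    "individual_id": h.individual_id,
                    "plot_id": h.plot_id,
                    "plant_id": h.plant_ids[t],
                    "occasion": t + 1,
                    "day": int(h.days[t]),
                    "category": CATEGORY_CODES[int(h.categories[t])],
                    "length_mm": "" if np.isnan(ln) else f"{ln:.3f}",
                }
            )
    pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS).to_csv(path, index=False)


def read_encounter_file(path) -> list[EncounterHistory]:
    """Read and validate an encounter CSV into `EncounterHistory` objects.

    Validation failures (unknown category, duplicate individual/occasion,
    a live observation after a dead recovery, a first detection that is not
    a live stage) raise with the offending row number (1-based, excluding
    the header).
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "plot_id": str, "plant_id": str})
    missing = [c for c in ENCOUNTER_COLUMNS if c != "length_mm" and c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "length_mm" not in df.columns:
        df["length_mm"] = np.nan

    seen: set[tuple[str, int]] = set()
    per_ind: dict[str, list] = {}
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        cat = str(row.category)
        if cat not in FILE_CATEGORIES:
            raise ValueError(f"{path} row {pos}: unknown category {cat!r}")
        key = (row.individual_id, int(row.occasion))
        if key in seen:
            raise ValueError(
                f"{path} row {pos}: duplicate (individual_id, occasion) = {key}"
            )
        seen.add(key)
        per_ind.setdefault(row.individual_id, []).append((pos, row))

    histories = []
    for ind, rows in per_ind.items():
        rows.sort(key=lambda pr: int(pr[1].occasion))
        dead_seen_at = None
        for pos, row in rows:
            cat = str(row.category)
            if dead_seen_at is not None and cat != "NS":
                raise ValueError(
                    f"{path} row {pos}: individual {ind} observed after a dead "
                    f"recovery (row {dead_seen_at}); dead recovery is terminal"
                )
            if cat in _DEAD_CODES:
                dead_seen_at = pos
        try:
            histories.append(
                EncounterHistory(
                    individual_id=str(ind),
                    plot_id=str(rows[0][1].plot_id),
                    plant_ids=[str(r.plant_id) for _, r in rows],
                    days=np.array([int(r.day) for _, r in rows]),
                    categories=np.array([_CAT_INDEX[str(r.category)] for _, r in rows]),
                    lengths=np.array(
                        [float(r.length_mm) if pd.notna(r.length_mm) and r.length_mm != "" else np.nan
                         for _, r in rows]
                    ),
                )
            )
        except ValueError as err:
            raise ValueError(f"{path} rows {[p for p, _ in rows]}: {err}") from err
    return histories


def write_temperature_file(table: pd.DataFrame, path) -> None:
    table[["plot_id", "occasion", "mean_temp"]].to_csv(path, index=False)


def read_temperature_file(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plot_id": str})
    missing = [c for c in ("plot_id", "occasion", "mean_temp") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


_KNOWN_KEYS = {
    "seed", "survival_forms", "groupings", "growth_forms",
    "priors", "mcmc", "density_metric", "aicc_n",
}
_PRIOR_KEYS = {"coef_sd", "egg_survival", "egg_hatch", "pupation"}
_MCMC_KEYS = {"chains", "burn_in", "samples"}


@dataclass
class RunConfig:
    """Validated run configuration (YAML); unknown keys are rejected."""

    seed: int = 0
    survival_forms: tuple[str, ...] = SURVIVAL_FORMS
    groupings: tuple[str, ...] = SURVIVAL_GROUPINGS
    growth_forms: tuple[str, ...] = GROWTH_FORMS
    priors: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    density_metric: str = "size"
    aicc_n: str = "individuals"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
        if "priors" in raw:
            bad = set(raw["priors"]) - _PRIOR_KEYS
            if bad:
                raise ValueError(f"{path}: unknown prior keys {sorted(bad)}")
        if "mcmc" in raw:
            bad = set(raw["mcmc"]) - _MCMC_KEYS
            if bad:
                raise ValueError(f"{path}: unknown mcmc keys {sorted(bad)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) and k.endswith("s") and k != "priors"
                     else v for k, v in raw.items()})
        return cfg

    def prior_spec(self) -> PriorSpec:
        p = self.priors
        needed = {"egg_survival", "egg_hatch", "pupation"}
        missing = needed - set(p)
        if missing:
            raise ValueError(f"priors must specify beta parameters for {sorted(missing)}")
        return PriorSpec(
            egg_survival=tuple(p["egg_survival"]),
            egg_hatch=tuple(p["egg_hatch"]),
            pupation=tuple(p["pupation"]),
            coef_sd=float(p.get("coef_sd", 100.0)),
        )

    def settings(self, seed: int | None = None) -> MCMCSettings:
        m = self.mcmc
        return MCMCSettings(
            chains=int(m.get("chains", 3)),
            burn_in=int(m.get("burn_in", 120_000)),
            samples=int(m.get("samples", 10_000)),
            seed=self.seed if seed is None else seed,
        )

    def model_grid(self) -> list[ModelStructure]:
        return enumerate_model_grid(
            tuple(self.survival_forms), tuple(self.groupings), tuple(self.growth_forms)
        )

    def as_dict(self) -> dict:
        return asdict(self)


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping (for run logs)."""
    if hasattr(obj, "as_dict"):
        obj = obj.as_dict()
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
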