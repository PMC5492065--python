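"""Descriptive cohort summaries: corpse-encounter trend, abundance, lengths.

The per-capita predation trend is a Poisson log-linear regression of corpse
counts on survey day with a log-abundance offset, the standard equivalent
of regressing corpses encountered per capita; the fitted slope is reported
as a percent change per day, 100 (exp(slope) - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .states import INSTARS, STAGES, dead_category, live_category

__all__ = [
    "CorpseTrend",
    "fit_corpse_trend",
    "corpse_series",
    "abundance_series",
    "stage_mean_lengths",
]


@dataclass
class CorpseTrend:
    """Fitted per-capita corpse-encounter trend."""

    intercept: float
    slope: float            # per day, on the log scale
    slope_se: float

    @property
    def percent_per_day(self) -> float:
        """Daily percent change in the per-capita corpse-encounter rate."""
        return 100.0 * (np.exp(self.slope) - 1.0)


def fit_corpse_trend(
    corpse_counts, abundance, day, use_offset: bool = True
) -> CorpseTrend:
    """Poisson regression of corpse counts on survey day.

    ``corpse_counts`` are the corpses encountered at each survey,
    ``abundance`` the live caterpillars the survey was exposed to (entering
    as a log offset, making the fit per capita), and ``day`` the plot's
    survey-day index.  With ``use_offset=False`` the counts are modeled
    without exposure adjustment.  Rows with zero abundance are dropped
    (they carry no per-capita information).
    """
    counts = np.asarray(corpse_counts, dtype=float)
    expo = np.asarray(abundance, dtype=float)
    day = np.asarray(day, dtype=float)
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("corpse counts must be nonnegative integers")
    if use_offset:
        keep = expo > 0
        counts, expo, day = counts[keep], expo[keep], day[keep]
    if counts.sum() == 0:
        raise ValueError("all corpse counts are zero; the trend slope is undefined")
    X = sm.add_constant(day)
    offset = np.log(expo) if use_offset else None
    fit = sm.GLM(counts, X, family=sm.families.Poisson(), offset=offset).fit(tol=1e-10)
    return CorpseTrend(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
    )


_LIVE_CAT_OF_STAGE = {s: live_category(s) for s in STAGES}
_DEAD_INSTAR_CATS = {dead_category(s) for s in INSTARS}
_LIVE_INSTAR_CATS = {live_category(s) for s in INSTARS}


def corpse_series(histories) -> pd.DataFrame:
    """Per (plot, occasion) corpse counts with lagged live-instar exposure.

    Rows start at each plot's second occasion; ``abundance`` is the number
    of live instars detected at the previous occasion of the same plot,
    the exposure for corpses found at the current one.
    """
    live = {}
    dead = {}
    days = {}
    for h in histories:
        for t in range(h.n_occasions):
            key = (h.plot_id, t)
            days[key] = int(h.days[t])
            c = int(h.categories[t])
            if c in _LIVE_INSTAR_CATS:
                live[key] = live.get(key, 0) + 1
            elif c in _DEAD_INSTAR_CATS:
                dead[key] = dead.get(key, 0) + 1
    rows = []
    for (plot, t), day in sorted(days.items()):
        if t == 0:
            continue
        rows.append(
            {
                "plot_id": plot,
                "occasion": t + 1,
                "day": day,
                "corpses": dead.get((plot, t), 0),
                "abundance": live.get((plot, t - 1), 0),
            }
        )
    return pd.DataFrame(rows)


def abundance_series(histories) -> pd.DataFrame:
    """Detected live counts by stage and size-scaled density, per occasion.

    Returns one row per occasion with per-stage counts, the total count,
    and the total size-scaled density (summed lengths of detected live
    instars, in mm).  An empty input yields an empty frame.
    """
    cols = {s: {} for s in STAGES}
    dens: dict[int, float] = {}
    occs: set[int] = set()
    for h in histories:
        for t in range(h.n_occasions):
            occs.add(t)
            c = int(h.categories[t])
            for s in STAGES:
                if c == _LIVE_CAT_OF_STAGE[s]:
                    cols[s][t] = cols[s].get(t, 0) + 1
                    if s in INSTARS and not np.isnan(h.lengths[t]):
                        dens[t] = dens.get(t, 0.0) + float(h.lengths[t])
    idx = sorted(occs)
    df = pd.DataFrame({"occasion": [t + 1 for t in idx]})
    for s in STAGES:
        df[s] = [cols[s].get(t, 0) for t in idx]
    df["total"] = df[list(STAGES)].sum(axis=1)
    df["size_scaled_density"] = [dens.get(t, 0.0) for t in idx]
    return df


def stage_mean_lengths(histories) -> pd.Series:
    """Arithmetic mean recorded length (mm) per instar.

    Instars with no recorded lengths are omitted with a warning.
    """
    import warnings

    acc: dict[str, list[float]] = {s: [] for s in INSTARS}
    for h in histories:
        for t in range(h.n_occasions):
            c = int(h.categories[t])
            for s in INSTARS:
                if c == _LIVE_CAT_OF_STAGE[s] and not np.isnan(h.lengths[t]):
                    acc[s].append(float(h.lengths[t]))
    out = {}
    for s in INSTARS:
        if acc[s]:
            out[s] = float(np.mean(acc[s]))
        else:
            warnings.warn(f"no recorded lengths for stage {s}; omitted from means")
    return pd.Series(out, name="mean_length_mm")
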