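"""Population-weighted exposure concentrations and inhalation intake.

The population-weighted average concentration for group d is

    PopWtdConc_d = sum_m C_m * Pop_{m,d} / sum_m Pop_{m,d}

over tracts m.  Annual inhalation intake converts concentration to the
mass of PM2.5 the exposed population breathes in a year:

    intake = sum_m C_m * BR * days * Pop_m * 1e-6   [grams]

with BR the average breathing rate (default 15 m^3/person/day) and the
1e-6 factor converting micrograms to grams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transport import TractConcentrations

DEFAULT_BREATHING_RATE = 15.0  # m^3 per person per day
DEFAULT_DAYS = 365


@dataclass
class ExposureSummary:
    pop_wtd_conc_total: float
    pop_wtd_conc_by_group: dict[str, float]
    intake_total_g: float
    intake_by_category_g: dict[str, float]
    breathing_rate: float = DEFAULT_BREATHING_RATE
    days: int = DEFAULT_DAYS

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", "pop_wtd_conc", self.pop_wtd_conc_total)]
        rows += [(g, "pop_wtd_conc", v) for g, v in self.pop_wtd_conc_by_group.items()]
        rows += [("total", "intake_g", self.intake_total_g)]
        rows += [(c, "intake_g", v) for c, v in self.intake_by_category_g.items()]
        return pd.DataFrame(rows, columns=["key", "metric", "value"])


def _align(conc: pd.Series, pops: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    pops = pops.reindex(conc.index)
    if pops.isna().any():
        raise ValueError("population series does not cover all tracts")
    return conc.to_numpy(dtype=float), pops.to_numpy(dtype=float)


def pop_weighted_concentration(conc: pd.Series, pops: pd.Series) -> float:
    """Population-weighted mean of tract concentrations for one group.

    ``conc`` and ``pops`` are indexed by tract_id.  Raises on zero total
    population (the mean is undefined).
    """
    c, p = _align(conc, pops)
    ptot = p.sum()
    if ptot <= 0:
        raise ValueError("group population is zero; weighted mean undefined")
    return float((c * p).sum() / ptot)


def inhalation_intake(
    conc: pd.Series,
    pops: pd.Series,
    breathing_rate: float = DEFAULT_BREATHING_RATE,
    days: int = DEFAULT_DAYS,
) -> float:
    """Annual population inhalation intake in grams.

    Per-person intake in each tract (C_m x BR x days, micrograms) times
    the tract population, summed and converted to grams.
    """
    if breathing_rate <= 0:
        raise ValueError("breathing rate must be positive")
    c, p = _align(conc, pops)
    if (c < 0).any():
        raise ValueError("negative concentrations are not physical here")
    return float((c * p).sum() * breathing_rate * days * 1e-6)


def exposure_summary(
    tract_conc: TractConcentrations,
    tracts: pd.DataFrame,
    groups: list[str] | None = None,
    breathing_rate: float = DEFAULT_BREATHING_RATE,
    days: int = DEFAULT_DAYS,
) -> ExposureSummary:
    """Full exposure summary: total and per-group weighted
    concentrations plus total and per-category intake."""
    from .synthetic import ALL_GROUPS

    groups = list(ALL_GROUPS) if groups is None else groups
    total = tract_conc.total
    pops = tracts.set_index("tract_id")["pop_total"]
    by_group = {
        g: pop_weighted_concentration(total, tracts.set_index("tract_id")[f"pop_{g}"])
        for g in groups
        if tracts[f"pop_{g}"].sum() > 0
    }
    intake_by_cat = {
        cat: inhalation_intake(tract_conc.values[cat], pops, breathing_rate, days)
        for cat in tract_conc.categories
    }
    return ExposureSummary(
        pop_wtd_conc_total=pop_weighted_concentration(total, pops),
        pop_wtd_conc_by_group=by_group,
        intake_total_g=inhalation_intake(total, pops, breathing_rate, days),
        intake_by_category_g=intake_by_cat,
        breathing_rate=breathing_rate,
        days=days,
    )


def source_shares(
    intake_by_category: dict[str, float],
    groupings: dict[str, list[str]] | None = None,
) -> dict[str, float]:
    """Fractional contribution of each category (and optional named
    groupings of categories, e.g. "all OGV") to total intake."""
    if not intake_by_category:
        raise ValueError("empty intake decomposition")
    total = sum(intake_by_category.values())
    if total <= 0:
        raise ValueError("total intake must be positive")
    shares = {c: v / total for c, v in intake_by_category.items()}
    for name, cats in (groupings or {}).items():
        shares[name] = sum(intake_by_category.get(c, 0.0) for c in cats) / total
    return shares


#: Category groupings used in reporting (all-OGV, in-harbor OGV, etc.).
STANDARD_GROUPINGS = {
    "all_ogv": [
        "ogv_cruise", "ogv_rsz", "ogv_maneuver", "ogv_berth",
        "ogv_shift", "ogv_anchorage",
    ],
    "ogv_in_harbor": ["ogv_maneuver", "ogv_berth", "ogv_shift", "ogv_anchorage"],
    "ogv_in_harbor_plus_chc": [
        "ogv_maneuver", "ogv_berth", "ogv_shift", "ogv_anchorage", "chc",
    ],
    "embodied": [
        "cement_plant", "ready_mix_plant", "asphalt_plant", "aggregate_plant",
        "refinery", "delivery_route",
    ],
}
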