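"""Mitigation strategies as inventory transformations.

A strategy is a set of per-category multipliers in [0, 1] (0 means
elimination) plus an optional drayage-truck electrification action.
Because the source-receptor operator is linear, applying a multiplier
strategy to the inventory and re-running transport is equivalent to
scaling the corresponding concentration components -- which the tests
exploit as an exact oracle.

The shipped catalog holds the 21 standard strategies: a 2045 truck-fleet
scenario, full truck electrification, 20% reductions of individual port
and facility sources, elimination of in-harbor ship and harbor-craft
emissions, and a combine-all scenario.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .inventory import DIRECT_CATEGORIES, EMBODIED_CATEGORIES, Inventory

logger = logging.getLogger(__name__)

#: Selector aliases -> category lists.
SELECTOR_ALIASES = {
    "ogv_in_harbor": ["ogv_maneuver", "ogv_berth", "ogv_shift", "ogv_anchorage"],
    "all_ogv": [
        "ogv_cruise", "ogv_rsz", "ogv_maneuver", "ogv_berth",
        "ogv_shift", "ogv_anchorage",
    ],
    "port_all": ["che", "port_rail", "port_other", "in_port_trucking"],
    "all_facilities": [
        "cement_plant", "ready_mix_plant", "asphalt_plant", "aggregate_plant",
        "refinery",
    ],
    "all": list(DIRECT_CATEGORIES) + list(EMBODIED_CATEGORIES),
}


@dataclass
class Strategy:
    """Named transformation of an inventory."""

    name: str
    multipliers: dict[str, float] = field(default_factory=dict)  # selector -> m
    truck_mode: str | None = None  # None, "year2045", "full"

    def __post_init__(self) -> None:
        for sel, m in self.multipliers.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"multiplier for {sel!r} must be in [0, 1]")
        if self.truck_mode not in (None, "year2045", "full"):
            raise ValueError(f"unknown truck mode {self.truck_mode!r}")

    def category_multipliers(self, known: list[str]) -> dict[str, float]:
        """Expand selector aliases to per-category multipliers."""
        out: dict[str, float] = {}
        for sel, m in self.multipliers.items():
            cats = SELECTOR_ALIASES.get(sel, [sel])
            resolved = [c for c in cats if c in known]
            if not resolved:
                raise KeyError(f"selector {sel!r} matches no inventory category")
            for c in resolved:
                out[c] = out.get(c, 1.0) * m
        return out


def apply_strategy(inv: Inventory, strategy: Strategy,
                   truck_factors: pd.DataFrame | None = None) -> Inventory:
    """Return a new inventory with the strategy applied.

    Multipliers scale the selected categories' masses; electrification
    rebuilds the in-port trucking records (and the truck-fuel share of
    refinery records) from the substituted factor table.
    """
    records = inv.records.copy()
    mults = strategy.category_multipliers(inv.categories)
    for cat, m in mults.items():
        sel = records["category"] == cat
        records.loc[sel, "tonnes_per_year"] *= m
    if strategy.truck_mode is not None:
        records = _electrify_records(records, strategy.truck_mode, truck_factors)
    meta = dict(inv.metadata)
    meta["scenario"] = strategy.name
    return Inventory(records, metadata=meta)


def _electrify_records(
    records: pd.DataFrame, mode: str, truck_factors: pd.DataFrame | None
) -> pd.DataFrame:
    records = records.copy()
    trucking = records["category"] == "in_port_trucking"
    truck_fuel = (records["category"] == "refinery") & (records["end_use"] == "truck_fuel")
    if not trucking.any() or not truck_fuel.any():
        raise ValueError(
            "inventory lacks in-port trucking or truck-fuel refinery records"
        )
    if mode == "full":
        # grid power from nonemitting sources: both the tailpipe and the
        # fuel-refining records go to zero
        records.loc[trucking | truck_fuel, "tonnes_per_year"] = 0.0
        return records
    if truck_factors is None:
        raise ValueError("year2045 mode requires a truck factor table")
    cur = truck_factors.loc["diesel_current"]
    new = truck_factors.loc["diesel_2045"]
    for sel in (trucking, truck_fuel):
        sub = records.loc[sel]
        ratio = sub["species"].map(
            lambda sp: float(new[sp]) / float(cur[sp]) if float(cur[sp]) > 0 else 0.0
        )
        records.loc[sel, "tonnes_per_year"] = sub["tonnes_per_year"] * ratio.to_numpy()
    return records


def electrify_trucks(inv: Inventory, mode: str,
                     truck_factors: pd.DataFrame | None = None) -> Inventory:
    """Electrify the drayage fleet: ``full`` zeroes trucking and its fuel
    refining; ``year2045`` rebuilds both from the 2045 diesel factors."""
    return apply_strategy(
        inv, Strategy(name=f"truck_{mode}", truck_mode=mode), truck_factors
    )


def combine_strategies(strategies: list[Strategy], name: str = "combined") -> Strategy:
    """Compose strategies: per category the multipliers multiply (an
    elimination absorbs); truck-mode substitutions are last-wins with a
    logged warning on conflict."""
    if not strategies:
        raise ValueError("cannot combine an empty strategy list")
    mults: dict[str, float] = {}
    truck_mode = None
    for s in strategies:
        for sel, m in s.multipliers.items():
            mults[sel] = mults.get(sel, 1.0) * m
        if s.truck_mode is not None:
            if truck_mode is not None and truck_mode != s.truck_mode:
                logger.warning(
                    "conflicting truck modes %r and %r; keeping %r",
                    truck_mode, s.truck_mode, s.truck_mode,
                )
            truck_mode = s.truck_mode
    return Strategy(name=name, multipliers=mults, truck_mode=truck_mode)


def standard_catalog() -> dict[str, Strategy]:
    """The 21 shipped mitigation strategies, keyed by name."""
    cat: dict[str, Strategy] = {}

    def add(name: str, **kw) -> None:
        cat[name] = Strategy(name=name, **kw)

    add("Truck 2045 Scenario", truck_mode="year2045")
    add("Truck Electrification", truck_mode="full")
    add("Rail Reduction (20%)", multipliers={"port_rail": 0.8})
    add("Trucking Reduction (20%)", multipliers={"in_port_trucking": 0.8})
    add("OGV Cruise Reduction (20%)", multipliers={"ogv_cruise": 0.8})
    add("OGV In-Harbor Reduction (20%)", multipliers={"ogv_in_harbor": 0.8})
    add("CHC Reduction (20%)", multipliers={"chc": 0.8})
    add("OGV RSZ Reduction (20%)", multipliers={"ogv_rsz": 0.8})
    add("OGV + CHC All Reduction (20%)", multipliers={"all_ogv": 0.8, "chc": 0.8})
    add("Port CHE Reduction (20%)", multipliers={"che": 0.8})
    add("Port Other Reduction (20%)", multipliers={"port_other": 0.8})
    add("Port Rail Reduction (20%)", multipliers={"port_rail": 0.8})
    add("Port + CHC All Reduction (20%)", multipliers={"port_all": 0.8, "chc": 0.8})
    add("Cement (20%)", multipliers={"cement_plant": 0.8})
    add("RMC (20%)", multipliers={"ready_mix_plant": 0.8})
    add("Asphalt Reduction (20%)", multipliers={"asphalt_plant": 0.8})
    add("Aggregate Reduction (20%)", multipliers={"aggregate_plant": 0.8})
    add("Refineries Reduction (20%)", multipliers={"refinery": 0.8})
    add("All Facility Reduction (20%)", multipliers={"all_facilities": 0.8})
    add(
        "OGV Harbor + CHC Emission Elimination",
        multipliers={"ogv_in_harbor": 0.0, "chc": 0.0},
    )
    cat["Combine All"] = combine_strategies(list(cat.values()), name="Combine All")
    return cat


def scenario_report(
    baseline: dict[str, float], scenarios: dict[str, dict[str, float]]
) -> pd.DataFrame:
    """Delta table: absolute and percent reductions per scenario.

    ``baseline`` and each scenario dict carry the same metric keys
    (e.g. intake_g, pop_wtd_conc, damages_usd).  Scenarios are ranked by
    percent intake reduction where available.
    """
    rows = []
    for scen, metrics in scenarios.items():
        if set(metrics) != set(baseline):
            raise ValueError(f"scenario {scen!r} metrics do not match baseline")
        for key, base in baseline.items():
            val = metrics[key]
            rows.append(
                {
                    "scenario": scen,
                    "metric": key,
                    "baseline": base,
                    "value": val,
                    "reduction_abs": base - val,
                    "reduction_pct": 100.0 * (base - val) / base if base != 0 else 0.0,
                }
            )
    df = pd.DataFrame(rows)
    rank_key = "intake_g" if "intake_g" in baseline else list(baseline)[0]
    order = (
        df[df["metric"] == rank_key]
        .sort_values("reduction_pct", ascending=False)["scenario"]
        .tolist()
    )
    df["rank"] = df["scenario"].map({s: i + 1 for i, s in enumerate(order)})
    return df.sort_values(["rank", "metric"]).reset_index(drop=True)
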