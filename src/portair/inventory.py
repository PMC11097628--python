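"""Spatially resolved multi-species annual emissions inventory.

Direct sources (ocean-going vessels by operating mode, commercial harbor
craft, cargo handling equipment, rail, in-port drayage trucking) are
combined with embodied sources driven by the port's pavement maintenance
cycle: material production at the nearest plants, truck delivery of the
materials, and fuel refining for the trucks.

Units are tonnes per year throughout.  An inventory is a flat record
table; each record belongs to one source category and one species and is
allocated over grid cells by weights summing to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .synthetic import SPECIES, GridSpec, SourceLayout

#: Inventory record columns.  ``tonnes_per_year`` is the record's total
#: annual mass; ``weight`` its allocation to ``cell_id`` (weights sum to
#: 1 over the record's cells).  ``end_use`` tags refinery records by the
#: fuel consumer so electrification scenarios can zero the truck-fuel
#: share only.
RECORD_COLUMNS = ["category", "species", "cell_id", "weight", "tonnes_per_year", "end_use"]

#: Direct port-operation categories.
DIRECT_CATEGORIES = (
    "ogv_cruise",
    "ogv_rsz",
    "ogv_maneuver",
    "ogv_berth",
    "ogv_shift",
    "ogv_anchorage",
    "chc",
    "che",
    "port_rail",
    "port_other",
    "in_port_trucking",
)

#: Embodied (supply-chain) categories.
EMBODIED_CATEGORIES = (
    "cement_plant",
    "ready_mix_plant",
    "asphalt_plant",
    "aggregate_plant",
    "refinery",
    "delivery_route",
)

CATEGORY_FOR_MATERIAL = {
    "cement": "cement_plant",
    "concrete": "ready_mix_plant",
    "asphalt": "asphalt_plant",
    "aggregate": "aggregate_plant",
}

#: Default material densities, kg/m^3 (config-overridable; pavement
#: engineering handbook magnitudes).
DEFAULT_DENSITIES = {"concrete": 2400.0, "asphalt": 2350.0, "aggregate": 1600.0}

#: Cement demand per tonne of ready-mix concrete (mass fraction).
CEMENT_PER_CONCRETE_TONNE = 0.14


@dataclass
class LayerSpec:
    """Pavement cross-section and resurfacing assumptions.

    ``layers`` is an ordered top-down list of (material, thickness_m,
    replaced).  The default mirrors a container-berth design: 10 cm
    concrete over 2.5 cm aggregate over 7.5 cm asphalt over a 47 cm
    compacted aggregate base that is never replaced during maintenance.
    """

    layers: list[tuple[str, float, bool]] = dc_field(
        default_factory=lambda: [
            ("concrete", 0.10, True),
            ("aggregate", 0.025, True),
            ("asphalt", 0.075, True),
            ("compacted_base", 0.47, False),
        ]
    )
    port_area_km2: float = 5.3
    resurfacing_fraction: float = 0.05

    def __post_init__(self) -> None:
        if any(t <= 0 for _, t, _ in self.layers):
            raise ValueError("layer thicknesses must be positive")
        if not 0.0 <= self.resurfacing_fraction <= 1.0:
            raise ValueError("resurfacing_fraction must be in [0, 1]")
        if self.port_area_km2 <= 0:
            raise ValueError("port_area_km2 must be positive")


@dataclass
class Inventory:
    """A validated collection of emission source records."""

    records: pd.DataFrame
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        validate_records(self.records)

    def total_by_species(self) -> pd.Series:
        """Total allocated mass per species (t/yr)."""
        alloc = self.records["tonnes_per_year"] * self.records["weight"]
        return alloc.groupby(self.records["species"]).sum()

    def total_by_category(self) -> pd.Series:
        alloc = self.records["tonnes_per_year"] * self.records["weight"]
        return alloc.groupby(self.records["category"]).sum()

    @property
    def categories(self) -> list[str]:
        return sorted(self.records["category"].unique())


def validate_records(records: pd.DataFrame) -> None:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if (records["tonnes_per_year"] < 0).any():
        raise ValueError("record masses must be nonnegative")
    bad_sp = set(records["species"]) - set(SPECIES)
    if bad_sp:
        raise ValueError(f"unknown species: {sorted(bad_sp)}")
    wsum = records.groupby(["category", "species", "end_use"])["weight"].sum()
    off = wsum[(wsum - 1.0).abs() > 1e-9]
    if len(off):
        raise ValueError(f"allocation weights must sum to 1: {off.index.tolist()}")


def _records_at_point(
    category: str,
    masses: dict[str, float],
    grid: GridSpec,
    x: float,
    y: float,
    end_use: str = "",
) -> pd.DataFrame:
    cell = grid.cell_containing(x, y)
    rows = [
        (category, sp, cell, 1.0, float(m), end_use)
        for sp, m in masses.items()
        if sp in SPECIES
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# Embodied-materials chain
# ---------------------------------------------------------------------------


def compute_maintenance_materials(
    spec: LayerSpec,
    densities: dict[str, float] | None = None,
    cement_per_concrete: float = CEMENT_PER_CONCRETE_TONNE,
) -> pd.DataFrame:
    """Annual material demand implied by the resurfacing cycle.

    volume(material) = port_area x resurfacing_fraction x total replaced
    thickness of that material; mass = volume x density.  Layers flagged
    not-replaced contribute zero.  Cement demand is derived from the
    concrete mass via ``cement_per_concrete``.

    Returns a DataFrame indexed by material with columns ``volume_m3``
    and ``mass_tonnes``.
    """
    dens = dict(DEFAULT_DENSITIES if densities is None else densities)
    area_m2 = spec.port_area_km2 * 1e6
    vols: dict[str, float] = {}
    for material, thickness, replaced in spec.layers:
        vols[material] = vols.get(material, 0.0) + (
            area_m2 * spec.resurfacing_fraction * thickness if replaced else 0.0
        )
    rows = {}
    for material, vol in vols.items():
        if vol == 0.0:
            rows[material] = (0.0, 0.0)
            continue
        if material not in dens:
            raise KeyError(f"no density configured for material {material!r}")
        rows[material] = (vol, vol * dens[material] / 1000.0)  # kg -> t
    demand = pd.DataFrame(rows, index=["volume_m3", "mass_tonnes"]).T
    demand.index.name = "material"
    if "concrete" in demand.index and cement_per_concrete > 0:
        cmass = demand.loc["concrete", "mass_tonnes"] * cement_per_concrete
        demand.loc["cement"] = (0.0, cmass)
    return demand


def assign_nearest_facility(
    port_xy: tuple[float, float], facilities: pd.DataFrame
) -> dict[str, str]:
    """Pick, per material, the facility nearest the port.

    Ties break to the lexicographically smallest facility id.  Raises
    ``KeyError`` if a material in the table has no facility (caller
    should pass a table restricted to required materials).
    """
    if facilities.empty:
        raise KeyError("no facilities available")
    out: dict[str, str] = {}
    px, py = port_xy
    for material, sub in facilities.groupby("material"):
        d = np.hypot(sub["x"] - px, sub["y"] - py)
        best = sub.assign(_d=d).sort_values(["_d", "id"]).iloc[0]
        out[str(material)] = str(best["id"])
    return out


def material_emissions(
    demand: pd.DataFrame,
    assignment: dict[str, str],
    facilities: pd.DataFrame,
    plant_factors: pd.DataFrame,
    grid: GridSpec,
) -> pd.DataFrame:
    """Emission records from producing the demanded materials.

    One record per (facility, species): mass = demanded mass x the
    plant's per-tonne factor, allocated to the facility's grid cell.
    Materials absent from the factor table (e.g., the compacted base,
    which is never produced) must have zero demand.
    """
    fac = facilities.set_index("id")
    frames = []
    for material, row in demand.iterrows():
        mass = float(row["mass_tonnes"])
        if material not in CATEGORY_FOR_MATERIAL:
            if mass > 0:
                raise KeyError(f"no production category for material {material!r}")
            continue
        if material not in plant_factors.index:
            raise KeyError(f"no plant factors for material {material!r}")
        if material not in assignment:
            raise KeyError(f"no facility assigned for material {material!r}")
        f = fac.loc[assignment[material]]
        masses = {sp: mass * float(plant_factors.loc[material, sp]) for sp in SPECIES}
        frames.append(
            _records_at_point(
                CATEGORY_FOR_MATERIAL[material], masses, grid, float(f["x"]), float(f["y"])
            )
        )
    if not frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def delivery_emissions(
    route: LineString,
    mass_tonnes: float,
    truck_capacity: float,
    truck_factors: pd.Series,
    grid: GridSpec,
) -> tuple[pd.DataFrame, int]:
    """Truck-delivery emission records along ``route``.

    trips = ceil(mass / capacity); per-species mass = trips x route
    length (km) x factor (t per vehicle-km), allocated to grid cells in
    proportion to the route length inside each cell.

    Returns (records, trips).
    """
    if truck_capacity <= 0:
        raise ValueError("truck capacity must be positive")
    if mass_tonnes < 0:
        raise ValueError("delivery mass must be nonnegative")
    trips = int(math.ceil(mass_tonnes / truck_capacity))
    idx = grid.query(route)
    seg = []
    for i in idx:
        L = route.intersection(grid.cells["geometry"].iloc[i]).length
        if L > 0:
            seg.append((grid.cells["cell_id"].iloc[i], L))
    total_len = sum(L for _, L in seg)
    if total_len <= 0:
        raise ValueError("route does not intersect the grid")
    km = route.length / 1000.0
    rows = []
    for sp in SPECIES:
        m = trips * km * float(truck_factors[sp])
        for cell, L in seg:
            rows.append(("delivery_route", sp, cell, L / total_len, m, ""))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS), trips


def refinery_emissions(
    fuel_tonnes_by_use: dict[str, float],
    refinery_factors: pd.Series,
    grid: GridSpec,
    refinery_xy: tuple[float, float],
) -> pd.DataFrame:
    """Records for refining the fuel consumed by trucks, tagged by end use."""
    frames = []
    for end_use, fuel in fuel_tonnes_by_use.items():
        if fuel < 0:
            raise ValueError("fuel demand must be nonnegative")
        masses = {sp: fuel * float(refinery_factors[sp]) for sp in SPECIES}
        frames.append(
            _records_at_point("refinery", masses, grid, *refinery_xy, end_use=end_use)
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Direct sources
# ---------------------------------------------------------------------------

#: Default direct-source annual masses (t/yr) by category and species.
#: Synthetic magnitudes shaped so ship categories dominate and carry
#: high NOx/SO2 relative to primary PM, as marine inventories do.
DEFAULT_DIRECT_MASSES = {
    "ogv_cruise": {"pm25": 40.0, "nox": 600.0, "voc": 25.0, "so2": 200.0, "nh3": 0.5},
    "ogv_rsz": {"pm25": 25.0, "nox": 380.0, "voc": 16.0, "so2": 130.0, "nh3": 0.3},
    "ogv_maneuver": {"pm25": 20.0, "nox": 300.0, "voc": 14.0, "so2": 100.0, "nh3": 0.3},
    "ogv_berth": {"pm25": 45.0, "nox": 650.0, "voc": 30.0, "so2": 220.0, "nh3": 0.6},
    "ogv_shift": {"pm25": 10.0, "nox": 150.0, "voc": 7.0, "so2": 50.0, "nh3": 0.15},
    "ogv_anchorage": {"pm25": 8.0, "nox": 120.0, "voc": 6.0, "so2": 40.0, "nh3": 0.1},
    "chc": {"pm25": 20.0, "nox": 280.0, "voc": 12.0, "so2": 8.0, "nh3": 0.2},
    "che": {"pm25": 12.0, "nox": 160.0, "voc": 9.0, "so2": 1.5, "nh3": 0.15},
    "port_rail": {"pm25": 6.0, "nox": 90.0, "voc": 5.0, "so2": 1.0, "nh3": 0.1},
    "port_other": {"pm25": 5.0, "nox": 60.0, "voc": 4.0, "so2": 0.8, "nh3": 0.08},
}

#: In-port drayage activity fixture: annual vehicle-km inside the port
#: boundary (terminal-to-freeway legs) and idling expressed as
#: equivalent vehicle-km.
DEFAULT_TRUCK_VKM = 9.0e7
#: Truck fuel burn, tonnes of diesel per vehicle-km.
TRUCK_FUEL_PER_VKM = 3.6e-4


def build_direct_inventory(
    layout: SourceLayout,
    grid: GridSpec,
    truck_factors: pd.Series,
    masses: dict[str, dict[str, float]] | None = None,
    truck_vkm: float = DEFAULT_TRUCK_VKM,
) -> pd.DataFrame:
    """Direct-source records: OGV modes, CHC, CHE, rail, other, and
    in-port trucking (activity x per-km factors)."""
    masses = DEFAULT_DIRECT_MASSES if masses is None else masses
    at_port = {
        "ogv_maneuver", "ogv_berth", "ogv_shift", "ogv_anchorage",
        "chc", "che", "port_rail", "port_other",
    }
    frames = []
    for cat, m in masses.items():
        if cat == "ogv_cruise":
            xy = layout.cruise_xy
        elif cat == "ogv_rsz":
            xy = layout.rsz_xy
        elif cat in at_port:
            xy = layout.port_xy
        else:
            raise ValueError(f"unknown direct category {cat!r}")
        frames.append(_records_at_point(cat, m, grid, *xy))
    truck_masses = {sp: truck_vkm * float(truck_factors[sp]) for sp in SPECIES}
    frames.append(_records_at_point("in_port_trucking", truck_masses, grid, *layout.port_xy))
    return pd.concat(frames, ignore_index=True)


def build_embodied_inventory(
    spec: LayerSpec,
    layout: SourceLayout,
    factors: dict[str, pd.DataFrame],
    grid: GridSpec,
    densities: dict[str, float] | None = None,
    truck_capacity: float = 20.0,
    truck_vkm: float = DEFAULT_TRUCK_VKM,
    fuel_per_vkm: float = TRUCK_FUEL_PER_VKM,
) -> pd.DataFrame:
    """Embodied records: material production, delivery trucking, and
    fuel refining for both delivery and in-port drayage trucks."""
    demand = compute_maintenance_materials(spec, densities)
    assignment = assign_nearest_facility(layout.port_xy, layout.facilities)
    prod = material_emissions(demand, assignment, layout.facilities,
                              factors["plants"], grid)
    total_mass = float(demand["mass_tonnes"].sum())
    deliv, trips = delivery_emissions(
        layout.delivery_route, total_mass, truck_capacity,
        factors["trucks"].loc["diesel_current"], grid,
    )
    route_km = layout.delivery_route.length / 1000.0
    fuel = {
        "truck_fuel": truck_vkm * fuel_per_vkm,
        "delivery_fuel": trips * route_km * fuel_per_vkm,
    }
    refin = refinery_emissions(fuel, factors["refinery"].loc["fuel"], grid,
                               layout.refinery_xy)
    return pd.concat([prod, deliv, refin], ignore_index=True)


def assemble_inventory(
    direct: pd.DataFrame,
    embodied: pd.DataFrame,
    scenario: str = "baseline",
    year: int = 2020,
) -> Inventory:
    """Concatenate and validate direct + embodied records.

    Duplicate (category, species, cell, end_use) rows are rejected:
    a record's allocation must be written once.
    """
    frames = [df for df in (direct, embodied) if df is not None and len(df)]
    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=RECORD_COLUMNS)
    )
    dup = records.duplicated(subset=["category", "species", "cell_id", "end_use"])
    if dup.any():
        offenders = records.loc[dup, ["category", "species", "cell_id"]]
        raise ValueError(
            "duplicate conflicting records for "
            f"{offenders.drop_duplicates().to_records(index=False).tolist()}"
        )
    return Inventory(records, metadata={"year": year, "scenario": scenario})


def category_summary(inv: Inventory) -> pd.DataFrame:
    """Total t/yr per category x species (wide table)."""
    alloc = inv.records.assign(
        mass=inv.records["tonnes_per_year"] * inv.records["weight"]
    )
    return (
        alloc.pivot_table(index="category", columns="species", values="mass",
                          aggfunc="sum", fill_value=0.0)
        .reindex(columns=list(SPECIES), fill_value=0.0)
    )
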