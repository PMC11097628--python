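"""Synthetic exposure domains for testing and demonstration.

Real applications of this package consume a census tract table, an
emissions inventory, and a precomputed source-receptor matrix (SRM) from
a reduced-complexity air quality model.  None of those are redistributable
here, so this module generates stand-ins with the statistical structure
the downstream analysis assumes:

* a planar square domain (meters) tiled by rectangular census tracts,
  with lognormal tract populations calibrated to target quartiles;
* six race/ethnicity groups plus an explicit "other" remainder so the
  demographic partition is exhaustive, with an optional segregation
  gradient that concentrates one focal group near the port;
* a variable-resolution analysis grid (fine cells where population
  density is high, coarse elsewhere);
* a Gaussian-kernel source-receptor matrix: the concentration response
  at a receptor falls off as exp(-d^2 / (2 sigma^2)) with distance d from
  the source, and precursor species are scaled by secondary-formation
  yields;
* emission-factor tables for material plants, drayage trucks (current
  diesel, 2045 diesel, electric), and refineries.

All geometry is in projected planar meters.  Every generator takes an
integer seed and is reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import LineString, Point, Polygon, box
from shapely.strtree import STRtree

#: The six U.S. census race/ethnicity labels used in the equity analysis.
CENSUS_GROUPS = (
    "white",
    "black",
    "asian",
    "hispanic_latino",
    "native_american",
    "pacific_islander",
)

#: Exhaustive partition: the six census groups plus the remainder.
ALL_GROUPS = CENSUS_GROUPS + ("other",)

#: Emitted species tracked by the inventory and the SRM: primary PM2.5
#: and the four secondary-PM precursors.
SPECIES = ("pm25", "nox", "voc", "so2", "nh3")

#: Default group mix (fractions of total population; sums to 1).
DEFAULT_GROUP_MIX = {
    "white": 0.35,
    "black": 0.10,
    "asian": 0.25,
    "hispanic_latino": 0.22,
    "native_american": 0.005,
    "pacific_islander": 0.005,
    "other": 0.07,
}

#: Side length of the square synthetic domain, meters.
DOMAIN_SIZE = 60_000.0

#: Port location: near the west edge, mid-latitude of the domain.
PORT_XY = (6_000.0, 30_000.0)


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------


@dataclass
class GridSpec:
    """A variable-resolution analysis grid tiling the domain.

    ``cells`` has columns ``cell_id`` (str), ``geometry`` (shapely
    Polygon) and ``res_class`` ("fine" or "coarse").  Cells tile the
    domain without overlap; fine cells occur where population density is
    higher.
    """

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.cells = self.cells.reset_index(drop=True)
        self._tree = STRtree(list(self.cells["geometry"]))

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells["cell_id"].to_numpy()

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of cell centroid coordinates."""
        return np.array([[g.centroid.x, g.centroid.y] for g in self.cells["geometry"]])

    def cell_containing(self, x: float, y: float) -> str:
        """Return the cell_id of the cell containing point (x, y)."""
        pt = Point(x, y)
        idx = self._tree.query(pt, predicate="intersects")
        if len(idx) == 0:
            raise ValueError(f"point ({x}, {y}) lies outside the grid")
        # on shared edges several cells match; take the lowest cell_id
        ids = sorted(self.cells["cell_id"].iloc[idx])
        return ids[0]

    def query(self, geom) -> np.ndarray:
        """Indices of cells whose bounding boxes intersect ``geom``."""
        return self._tree.query(geom)


def _tract_layout(n_tracts: int, size: float) -> list[Polygon]:
    """Tile a size x size square with n_tracts rectangles, row-major."""
    ncols = max(1, int(math.ceil(math.sqrt(n_tracts))))
    nrows = int(math.ceil(n_tracts / ncols))
    w, h = size / ncols, size / nrows
    polys = []
    for k in range(n_tracts):
        r, c = divmod(k, ncols)
        polys.append(box(c * w, r * h, (c + 1) * w, (r + 1) * h))
    # the last row may be short; stretch its rectangles to cover the strip
    n_last = n_tracts - (nrows - 1) * ncols
    if 0 < n_last < ncols:
        w_last = size / n_last
        y0 = (nrows - 1) * h
        for j in range(n_last):
            polys[(nrows - 1) * ncols + j] = box(j * w_last, y0, (j + 1) * w_last, size)
    return polys


def generate_tracts(
    n_tracts: int = 200,
    pop_quartiles: tuple[float, float] = (3500.0, 6000.0),
    group_mix: dict[str, float] | None = None,
    segregation: float = 0.5,
    focal_group: str = "black",
    seed: int = 0,
    domain_size: float = DOMAIN_SIZE,
    port_xy: tuple[float, float] = PORT_XY,
    income_gradient: float = 0.5,
    proximity_scale: float = 12_000.0,
) -> pd.DataFrame:
    """Generate a synthetic census tract table.

    Parameters
    ----------
    n_tracts
        Number of tracts tiling the square domain.
    pop_quartiles
        Target (25th, 75th) percentiles of tract population.  Tract
        populations are lognormal with median and spread solved from
        these quartiles.
    group_mix
        Mapping group -> population share over the six census groups
        plus ``"other"``; must sum to 1.  Defaults to
        :data:`DEFAULT_GROUP_MIX`.
    segregation
        Gradient strength in [0, 1].  At 0 every tract has identical
        group shares; at larger values the focal group's share is
        boosted in tracts close to the port (and its domain-wide share
        is renormalized back to the mix value), displacing that group's
        population centroid toward the port.
    focal_group
        The group subjected to the segregation gradient.
    income_gradient
        Fractional depression of mean income near the port (tracts at
        the port have mean income reduced by this fraction relative to
        the far field), so low-income quintiles co-locate with exposure.
    proximity_scale
        e-folding distance (m) of the proximity kernel used for both the
        segregation and income gradients.

    Returns
    -------
    pandas.DataFrame
        Columns: tract_id, geometry, pop_total, pop_<group> for each of
        the seven groups, mean_income, quintile (empty; assigned later).
        Group populations partition pop_total exactly.
    """
    if n_tracts < 1:
        raise ValueError("n_tracts must be >= 1")
    mix = dict(DEFAULT_GROUP_MIX if group_mix is None else group_mix)
    unknown = set(mix) - set(ALL_GROUPS)
    if unknown:
        raise ValueError(f"unknown groups in mix: {sorted(unknown)}")
    for g in ALL_GROUPS:
        mix.setdefault(g, 0.0)
    total_mix = sum(mix.values())
    if abs(total_mix - 1.0) > 1e-6:
        raise ValueError(f"group_mix must sum to 1, got {total_mix:.6f}")
    if not 0.0 <= segregation <= 1.0:
        raise ValueError("segregation must be in [0, 1]")
    if focal_group not in ALL_GROUPS:
        raise ValueError(f"unknown focal group {focal_group!r}")

    rng = np.random.default_rng(seed)
    polys = _tract_layout(n_tracts, domain_size)

    # lognormal populations: median = sqrt(q25*q75); sigma from the
    # quartile ratio (z_{0.75} = 0.674490 for the standard normal)
    q25, q75 = pop_quartiles
    mu = 0.5 * (math.log(q25) + math.log(q75))
    sigma = math.log(q75 / q25) / (2 * 0.6744898) if q75 > q25 else 0.0
    pop_total = np.round(np.exp(rng.normal(mu, sigma, size=n_tracts))).astype(int)
    pop_total = np.maximum(pop_total, 1)

    cx = np.array([p.centroid.x for p in polys])
    cy = np.array([p.centroid.y for p in polys])
    dist = np.hypot(cx - port_xy[0], cy - port_xy[1])
    prox = np.exp(-dist / proximity_scale)  # 1 at the port, -> 0 far away

    # focal-group share: boost near the port, renormalized so the
    # domain-wide share matches the mix
    base_focal = mix[focal_group]
    weight = (1.0 - segregation) + segregation * prox * n_tracts / max(prox.sum(), 1e-12)
    focal_share = base_focal * weight
    # keep shares feasible
    focal_share = np.clip(focal_share, 0.0, 0.95)
    # renormalize so the population-weighted mean share equals base_focal
    if base_focal > 0 and focal_share @ pop_total > 0:
        focal_share *= base_focal * pop_total.sum() / (focal_share @ pop_total)
        focal_share = np.clip(focal_share, 0.0, 0.95)

    shares = {}
    other_groups = [g for g in ALL_GROUPS if g != focal_group]
    rest_mix = np.array([mix[g] for g in other_groups])
    rest_total = rest_mix.sum()
    for j, g in enumerate(other_groups):
        frac = rest_mix[j] / rest_total if rest_total > 0 else 0.0
        shares[g] = (1.0 - focal_share) * frac
    shares[focal_group] = focal_share

    # integerize per tract with the remainder folded into "other" so the
    # partition is exact
    pops = {}
    for g in ALL_GROUPS:
        if g == "other":
            continue
        pops[g] = np.floor(shares[g] * pop_total).astype(int)
    assigned = sum(pops.values())
    pops["other"] = pop_total - assigned

    income_base = 90_000.0
    mean_income = (
        income_base
        * (1.0 - income_gradient * prox)
        * np.exp(rng.normal(0.0, 0.25, size=n_tracts))
    )

    table = pd.DataFrame(
        {
            "tract_id": [f"T{k:04d}" for k in range(n_tracts)],
            "geometry": polys,
            "pop_total": pop_total,
            **{f"pop_{g}": pops[g] for g in ALL_GROUPS},
            "mean_income": np.round(mean_income, 2),
            "quintile": pd.array([pd.NA] * n_tracts, dtype="string"),
        }
    )
    validate_tracts(table)
    return table


def validate_tracts(tracts: pd.DataFrame) -> None:
    """Check tract-table invariants; raise ValueError on violation."""
    if tracts["tract_id"].duplicated().any():
        dupes = tracts.loc[tracts["tract_id"].duplicated(), "tract_id"].tolist()
        raise ValueError(f"duplicate tract_ids: {dupes}")
    group_cols = [f"pop_{g}" for g in ALL_GROUPS]
    if (tracts[group_cols].to_numpy() < 0).any() or (tracts["pop_total"] < 0).any():
        raise ValueError("populations must be nonnegative")
    if (tracts["mean_income"] < 0).any():
        raise ValueError("incomes must be nonnegative")
    part = tracts[group_cols].sum(axis=1)
    if not np.array_equal(part.to_numpy(), tracts["pop_total"].to_numpy()):
        raise ValueError("group populations must partition pop_total exactly")


def generate_grid(
    tracts: pd.DataFrame,
    coarse_size: float = 6_000.0,
    refine: int = 3,
    density_quantile: float = 0.75,
    domain_size: float = DOMAIN_SIZE,
) -> GridSpec:
    """Build a variable-resolution grid over the tract domain.

    The domain is tiled by coarse square cells; coarse cells whose
    population density (from the overlapping tracts) is in the top
    quartile are subdivided ``refine`` x ``refine`` into fine cells.
    This mirrors, qualitatively, the variable grids reduced-complexity
    air quality models use: fine resolution where people are.
    """
    n = int(round(domain_size / coarse_size))
    if n < 1:
        raise ValueError("coarse_size larger than the domain")
    tract_tree = STRtree(list(tracts["geometry"]))
    dens = tracts["pop_total"].to_numpy() / np.array(
        [g.area for g in tracts["geometry"]]
    )

    coarse = []
    cell_density = []
    for r in range(n):
        for c in range(n):
            cell = box(c * coarse_size, r * coarse_size, (c + 1) * coarse_size, (r + 1) * coarse_size)
            idx = tract_tree.query(cell, predicate="intersects")
            if len(idx):
                areas = np.array(
                    [cell.intersection(tracts["geometry"].iloc[i]).area for i in idx]
                )
                w = areas.sum()
                d = float((dens[idx] * areas).sum() / w) if w > 0 else 0.0
            else:
                d = 0.0
            coarse.append(cell)
            cell_density.append(d)

    cell_density = np.array(cell_density)
    thresh = np.quantile(cell_density, density_quantile)
    rows = []
    k = 0
    for cell, d in zip(coarse, cell_density):
        if d > thresh and refine > 1:
            x0, y0, x1, y1 = cell.bounds
            fw, fh = (x1 - x0) / refine, (y1 - y0) / refine
            for i in range(refine):
                for j in range(refine):
                    rows.append(
                        (
                            f"C{k:05d}",
                            box(x0 + j * fw, y0 + i * fh, x0 + (j + 1) * fw, y0 + (i + 1) * fh),
                            "fine",
                        )
                    )
                    k += 1
        else:
            rows.append((f"C{k:05d}", cell, "coarse"))
            k += 1
    return GridSpec(pd.DataFrame(rows, columns=["cell_id", "geometry", "res_class"]))


# ---------------------------------------------------------------------------
# Source-receptor matrix
# ---------------------------------------------------------------------------

#: Secondary PM2.5 formation yields per precursor (dimensionless; the
#: primary-PM coefficient is scaled by this factor for each precursor).
DEFAULT_SECONDARY_YIELDS = {"pm25": 1.0, "nox": 0.01, "voc": 0.005, "so2": 0.05, "nh3": 0.10}

#: Peak (zero-distance) concentration response, ug m^-3 per tonne yr^-1.
#: A box-model magnitude argument (annual emission diluted into a
#: few-km mixing volume with ~hourly residence) puts the source-cell
#: response in the 1e-3..1e-2 range; 4e-3 lands near-port concentrations
#: from a few-hundred-tonne inventory at a few tenths of a ug/m3.
DEFAULT_PEAK_COEFF = 4.0e-3


def generate_sr_matrix(
    grid: GridSpec,
    kernel_scale: float = 6_000.0,
    secondary_yields: dict[str, float] | None = None,
    peak_coeff: float = DEFAULT_PEAK_COEFF,
    seed: int = 0,
) -> xr.DataArray:
    """Build a Gaussian-kernel source-receptor matrix on ``grid``.

    The primary-PM coefficient from source cell i to receptor cell j is

        K_ij = peak_coeff * exp(-d_ij^2 / (2 * kernel_scale^2))

    with d_ij the centroid distance; each precursor species' block is
    K times its secondary-formation yield.  Coefficients are
    nonnegative and non-increasing with distance by construction.

    Returns an ``xarray.DataArray`` with dims (species, source, receptor)
    in ug m^-3 per tonne yr^-1.  ``seed`` is accepted for interface
    uniformity; the kernel itself is deterministic.
    """
    if len(grid.cells) == 0:
        raise ValueError("empty grid")
    if kernel_scale <= 0:
        raise ValueError("kernel_scale must be > 0")
    yields = dict(DEFAULT_SECONDARY_YIELDS if secondary_yields is None else secondary_yields)
    for sp, y in yields.items():
        if not 0.0 <= y <= 1.0:
            raise ValueError(f"yield for {sp} must be in [0, 1]")

    cent = grid.centroids()
    d2 = ((cent[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
    kernel = peak_coeff * np.exp(-d2 / (2.0 * kernel_scale**2))
    data = np.stack([kernel * yields.get(sp, 0.0) for sp in SPECIES])
    return xr.DataArray(
        data,
        dims=("species", "source", "receptor"),
        coords={
            "species": list(SPECIES),
            "source": grid.cell_ids,
            "receptor": grid.cell_ids,
        },
        name="sr_coefficient",
        attrs={
            "units": "ug m-3 per tonne yr-1",
            "kernel_scale_m": kernel_scale,
            "peak_coeff": peak_coeff,
        },
    )


# ---------------------------------------------------------------------------
# Source layout and emission-factor fixtures
# ---------------------------------------------------------------------------


@dataclass
class SourceLayout:
    """Synthetic geography of emission sources.

    Positions are planar meters.  ``facilities`` has columns
    id, material, x, y.  ``delivery_route`` runs from the ready-mix
    plant to the port.
    """

    port_xy: tuple[float, float]
    cruise_xy: tuple[float, float]
    rsz_xy: tuple[float, float]
    facilities: pd.DataFrame
    refinery_xy: tuple[float, float]
    delivery_route: LineString = field(repr=False, default=None)


def generate_source_layout(
    seed: int = 0,
    port_xy: tuple[float, float] = PORT_XY,
    domain_size: float = DOMAIN_SIZE,
) -> SourceLayout:
    """Place the port, shipping lane waypoints, material plants, and a
    refinery in the synthetic domain.

    OGV cruise happens near the domain's west edge (open water), the
    reduced-speed zone between the edge and the harbor.  Material plants
    sit 8-20 km inland of the port, the refinery farther north --
    emulating facilities embedded in populated areas.
    """
    rng = np.random.default_rng(seed)
    px, py = port_xy
    cruise = (1_000.0, py + 4_000.0)
    rsz = (3_500.0, py + 2_000.0)
    mats = ["cement", "concrete", "asphalt", "aggregate"]
    rows = []
    for i, m in enumerate(mats):
        ang = rng.uniform(-0.9, 0.9)
        r = rng.uniform(8_000.0, 20_000.0)
        x = min(max(px + r * math.cos(ang), 500.0), domain_size - 500.0)
        y = min(max(py + r * math.sin(ang), 500.0), domain_size - 500.0)
        rows.append((f"F{i:02d}", m, round(x, 1), round(y, 1)))
    facilities = pd.DataFrame(rows, columns=["id", "material", "x", "y"])
    refinery = (px + 9_000.0, min(py + 22_000.0, domain_size - 500.0))
    rmc = facilities.loc[facilities["material"] == "concrete"].iloc[0]
    route = LineString([(rmc["x"], rmc["y"]), (px, py)])
    return SourceLayout(
        port_xy=port_xy,
        cruise_xy=cruise,
        rsz_xy=rsz,
        facilities=facilities,
        refinery_xy=refinery,
        delivery_route=route,
    )


def generate_factor_fixtures(seed: int = 0) -> dict[str, pd.DataFrame]:
    """Emission-factor tables (synthetic stand-ins for regulatory data).

    Returns a dict with three tables:

    ``plants``
        index: material; columns: species; units tonne emitted per
        tonne of material produced.
    ``trucks``
        index: fleet ("diesel_current", "diesel_2045", "electric");
        columns: species; units tonne per vehicle-km.  The 2045 diesel
        row is strictly below the current row; the electric row is all
        zeros (grid power from nonemitting sources).
    ``refinery``
        index: ("fuel",); columns: species; tonne emitted per tonne of
        fuel produced.

    The magnitudes are plausible-order synthetic values, not measured
    factors; a small seeded jitter keeps replicate fixtures distinct.
    """
    rng = np.random.default_rng(seed)

    def jitter(x):
        return x * rng.uniform(0.9, 1.1)

    base_plants = {
        # t emitted per t produced
        "cement": {"pm25": 4e-4, "nox": 1.5e-3, "voc": 5e-5, "so2": 6e-4, "nh3": 2e-5},
        "concrete": {"pm25": 1.5e-4, "nox": 2e-4, "voc": 3e-5, "so2": 5e-5, "nh3": 1e-5},
        "asphalt": {"pm25": 2.5e-4, "nox": 4e-4, "voc": 4e-4, "so2": 1.5e-4, "nh3": 1e-5},
        "aggregate": {"pm25": 3e-4, "nox": 1e-4, "voc": 2e-5, "so2": 3e-5, "nh3": 5e-6},
    }
    plants = pd.DataFrame(
        {m: {sp: jitter(v) for sp, v in row.items()} for m, row in base_plants.items()}
    ).T.reindex(columns=list(SPECIES))
    plants.index.name = "material"

    diesel = {sp: jitter(v) for sp, v in
              {"pm25": 3e-8, "nox": 1.2e-6, "voc": 1e-7, "so2": 5e-9, "nh3": 8e-9}.items()}
    trucks = pd.DataFrame(
        {
            "diesel_current": diesel,
            "diesel_2045": {sp: 0.45 * v for sp, v in diesel.items()},
            "electric": {sp: 0.0 for sp in SPECIES},
        }
    ).T.reindex(columns=list(SPECIES))
    trucks.index.name = "fleet"

    refinery = pd.DataFrame(
        {"fuel": {sp: jitter(v) for sp, v in
                  {"pm25": 1e-4, "nox": 4e-4, "voc": 6e-4, "so2": 5e-4, "nh3": 2e-5}.items()}}
    ).T.reindex(columns=list(SPECIES))
    refinery.index.name = "product"

    return {"plants": plants, "trucks": trucks, "refinery": refinery}
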