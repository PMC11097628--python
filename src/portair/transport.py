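"""Apply the linear source-receptor operator and map cells to tracts.

The source-receptor matrix (SRM) is a precomputed linear operator:
concentration change at each receptor cell per unit annual emission of
each species at each source cell.  Applying it to an inventory is a
weighted sum of matrix rows; everything downstream (scenario deltas,
category attribution) exploits that linearity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .inventory import Inventory
from .synthetic import GridSpec

logger = logging.getLogger(__name__)

#: Values whose magnitude falls below this are clamped to exactly 0 to
#: avoid sign noise in downstream ratio statistics.
CLAMP_TOL = 1e-300


@dataclass
class ConcentrationField:
    """Receptor-cell PM2.5 concentration deltas, decomposed by source
    category.

    ``values`` is indexed by receptor cell_id with one column per
    category (ug m^-3); ``total`` sums the decomposition.
    """

    values: pd.DataFrame

    @property
    def total(self) -> pd.Series:
        return self.values.sum(axis=1)

    @property
    def categories(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TractConcentrations:
    """Tract-level concentration deltas with category decomposition."""

    values: pd.DataFrame  # index tract_id, columns categories

    @property
    def total(self) -> pd.Series:
        return self.values.sum(axis=1)

    @property
    def categories(self) -> list[str]:
        return list(self.values.columns)


def apply_srm(inv: Inventory, srm: xr.DataArray) -> ConcentrationField:
    """Concentration field from an inventory through the SRM.

    For every record, delta conc at each receptor is
    mass x allocation weight x coefficient(species, source cell, .),
    accumulated per source category.
    """
    species = set(np.atleast_1d(srm["species"].values))
    cells = pd.Index(np.atleast_1d(srm["source"].values))
    bad_sp = set(inv.records["species"]) - species
    if bad_sp:
        raise ValueError(f"inventory species not in SRM: {sorted(bad_sp)}")
    bad_cells = set(inv.records["cell_id"]) - set(cells)
    if bad_cells:
        raise ValueError(f"inventory cells not in SRM grid: {sorted(bad_cells)[:5]}")

    receptors = np.atleast_1d(srm["receptor"].values)
    categories = inv.categories
    out = pd.DataFrame(0.0, index=pd.Index(receptors, name="cell_id"), columns=categories)

    coeff = srm.transpose("species", "source", "receptor").values
    sp_pos = {s: i for i, s in enumerate(np.atleast_1d(srm["species"].values))}
    cell_pos = {c: i for i, c in enumerate(cells)}

    rec = inv.records
    mass = (rec["tonnes_per_year"] * rec["weight"]).to_numpy()
    for cat in categories:
        sel = rec["category"] == cat
        acc = np.zeros(len(receptors))
        for sp, cell, m in zip(rec.loc[sel, "species"], rec.loc[sel, "cell_id"], mass[sel.to_numpy()]):
            if m == 0.0:
                continue
            acc += m * coeff[sp_pos[sp], cell_pos[cell], :]
        out[cat] = acc
    clamped = (out.abs() < CLAMP_TOL) & (out != 0.0)
    if clamped.to_numpy().any():
        logger.warning("clamped %d sub-tolerance concentrations to 0",
                       int(clamped.to_numpy().sum()))
        out = out.where(~clamped, 0.0)
    return ConcentrationField(out)


def tract_cell_weights(tracts: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Tract x cell area-overlap weight matrix (rows sum to 1).

    Row m gives the fraction of tract m's grid-covered area lying in
    each cell; reusable across fields on the same geometry (scenario
    re-runs).  Tracts with no grid overlap are an error.
    """
    W = np.zeros((len(tracts), len(grid.cells)))
    no_overlap = []
    for r, (tract_id, geom) in enumerate(zip(tracts["tract_id"], tracts["geometry"])):
        idx = grid.query(geom)
        areas = np.array(
            [geom.intersection(grid.cells["geometry"].iloc[i]).area for i in idx]
        )
        keep = areas > 0
        if not keep.any():
            no_overlap.append(tract_id)
            continue
        W[r, np.asarray(idx)[keep]] = areas[keep] / areas[keep].sum()
    if no_overlap:
        raise ValueError(f"tracts with zero grid overlap: {no_overlap}")
    return pd.DataFrame(
        W, index=pd.Index(tracts["tract_id"], name="tract_id"), columns=grid.cell_ids
    )


def grid_to_tracts(
    field: ConcentrationField,
    tracts: pd.DataFrame,
    grid: GridSpec,
    weights: pd.DataFrame | None = None,
) -> TractConcentrations:
    """Area-weighted aggregation of cell values onto tract polygons.

    A tract's value (per category) is the average of the overlapping
    cells' values weighted by intersection area; the weights sum to 1
    for every tract.  ``weights`` may carry a precomputed
    :func:`tract_cell_weights` matrix.
    """
    vals = field.values.reindex(grid.cell_ids)
    if vals.isna().any().any():
        missing = vals.index[vals.isna().any(axis=1)].tolist()
        raise ValueError(f"field missing cells present in grid: {missing[:5]}")
    if weights is None:
        weights = tract_cell_weights(tracts, grid)
    out = pd.DataFrame(
        weights.to_numpy() @ vals.to_numpy(),
        index=weights.index,
        columns=field.categories,
    )
    return TractConcentrations(out)


def concentration_vs_distance(
    field: ConcentrationField,
    grid: GridSpec,
    origin: tuple[float, float],
    bins: np.ndarray,
) -> pd.DataFrame:
    """Mean receptor concentration by distance-from-origin bin.

    ``bins`` are increasing edges in meters.  Empty bins are reported
    as NaN (missing), never as zero.
    """
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be strictly increasing")
    cent = grid.centroids()
    d = np.hypot(cent[:, 0] - origin[0], cent[:, 1] - origin[1])
    total = field.total.reindex(grid.cell_ids).to_numpy()
    which = np.digitize(d, bins) - 1
    means = []
    for b in range(len(bins) - 1):
        sel = which == b
        means.append(float(np.mean(total[sel])) if sel.any() else np.nan)
    out = pd.DataFrame(
        {"bin_lo_m": bins[:-1], "bin_hi_m": bins[1:], "mean_conc": means}
    )
    n_empty = int(out["mean_conc"].isna().sum())
    if n_empty:
        logger.warning("%d empty distance bins recorded as missing", n_empty)
    return out
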