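"""Readers and writers for the package's table and geometry formats.

Tract tables round-trip through GeoJSON (planar coordinates in the
``crs``-free sense: projected meters) or CSV with a WKT geometry column.
The source-receptor matrix round-trips through a long-form CSV
(species, source, receptor, coefficient).  All writers sort rows so a
write -> read -> write cycle is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from shapely import wkt
from shapely.geometry import mapping, shape

from .inventory import Inventory
from .synthetic import ALL_GROUPS, SPECIES, GridSpec

_TRACT_PROPS = ["pop_total"] + [f"pop_{g}" for g in ALL_GROUPS] + ["mean_income", "quintile"]


def tracts_to_geojson(tracts: pd.DataFrame, path: str | Path) -> None:
    feats = []
    for _, row in tracts.iterrows():
        props = {"tract_id": row["tract_id"]}
        for k in _TRACT_PROPS:
            v = row[k]
            props[k] = None if pd.isna(v) else (int(v) if k.startswith("pop") else v)
        feats.append(
            {"type": "Feature", "geometry": mapping(row["geometry"]), "properties": props}
        )
    doc = {"type": "FeatureCollection", "features": feats}
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")


def tracts_from_geojson(path: str | Path) -> pd.DataFrame:
    doc = json.loads(Path(path).read_text())
    rows = []
    for f in doc["features"]:
        row = dict(f["properties"])
        row["geometry"] = shape(f["geometry"])
        rows.append(row)
    df = pd.DataFrame(rows)
    df["quintile"] = df["quintile"].astype("string")
    return df[["tract_id", "geometry"] + _TRACT_PROPS]


def tracts_to_csv(tracts: pd.DataFrame, path: str | Path) -> None:
    out = tracts.copy()
    out["geometry"] = [g.wkt for g in out["geometry"]]
    out.sort_values("tract_id").to_csv(path, index=False)


def tracts_from_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"quintile": "string"},
                     float_precision="round_trip")
    df["geometry"] = [wkt.loads(g) for g in df["geometry"]]
    return df


def inventory_to_csv(inv: Inventory, path: str | Path) -> None:
    inv.records.sort_values(
        ["category", "species", "cell_id", "end_use"]
    ).to_csv(path, index=False)


def inventory_from_csv(path: str | Path, metadata: dict | None = None) -> Inventory:
    df = pd.read_csv(path, keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    df["end_use"] = df["end_use"].astype(str)
    return Inventory(df, metadata=metadata or {})


def srm_to_csv(srm: xr.DataArray, path: str | Path) -> None:
    df = srm.to_dataframe().reset_index()
    df = df.sort_values(["species", "source", "receptor"])
    df.to_csv(path, index=False)


def srm_from_csv(path: str | Path) -> xr.DataArray:
    df = pd.read_csv(path, float_precision="round_trip")
    name = [c for c in df.columns if c not in ("species", "source", "receptor")][0]
    arr = df.set_index(["species", "source", "receptor"])[name].to_xarray()
    return arr.transpose("species", "source", "receptor")


def grid_to_geojson(grid: GridSpec, path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(row["geometry"]),
            "properties": {"cell_id": row["cell_id"], "res_class": row["res_class"]},
        }
        for _, row in grid.cells.iterrows()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}, sort_keys=True) + "\n"
    )


def grid_from_geojson(path: str | Path) -> GridSpec:
    doc = json.loads(Path(path).read_text())
    rows = [
        (f["properties"]["cell_id"], shape(f["geometry"]), f["properties"]["res_class"])
        for f in doc["features"]
    ]
    return GridSpec(pd.DataFrame(rows, columns=["cell_id", "geometry", "res_class"]))


def factors_to_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.sort_index().to_csv(path)


def factors_from_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return df.reindex(columns=list(SPECIES))


def concentrations_to_csv(values: pd.DataFrame, path: str | Path) -> None:
    long = values.stack().rename("conc").reset_index()
    long.columns = [values.index.name or "id", "category", "conc"]
    long.sort_values([long.columns[0], "category"]).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
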