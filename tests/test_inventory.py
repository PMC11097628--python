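"""Emissions inventory: maintenance materials, facility sourcing,
embodied records, delivery allocation, and assembly conservation."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from portair import (
    assemble_inventory,
    assign_nearest_facility,
    compute_maintenance_materials,
    delivery_emissions,
    material_emissions,
)
from portair.inventory import (
    RECORD_COLUMNS,
    LayerSpec,
    build_direct_inventory,
    build_embodied_inventory,
    category_summary,
)
from portair.synthetic import SPECIES


class TestMaintenanceMaterials:
    def test_hand_arithmetic_concrete_volume(self):
        # 5.3 km^2 x 5%/yr x 0.10 m concrete = 26,500 m^3
        spec = LayerSpec(port_area_km2=5.3, resurfacing_fraction=0.05)
        demand = compute_maintenance_materials(spec)
        assert demand.loc["concrete", "volume_m3"] == pytest.approx(26_500.0)
        assert demand.loc["concrete", "mass_tonnes"] == pytest.approx(26_500 * 2.4)

    def test_zero_fraction_zero_demand(self):
        demand = compute_maintenance_materials(LayerSpec(resurfacing_fraction=0.0))
        assert (demand["mass_tonnes"] == 0).all()

    def test_compacted_base_never_replaced(self):
        demand = compute_maintenance_materials(LayerSpec(resurfacing_fraction=0.05))
        assert demand.loc["compacted_base", "volume_m3"] == 0.0
        assert demand.loc["compacted_base", "mass_tonnes"] == 0.0

    def test_demand_linear_in_resurfacing_fraction(self):
        d1 = compute_maintenance_materials(LayerSpec(resurfacing_fraction=0.02))
        d2 = compute_maintenance_materials(LayerSpec(resurfacing_fraction=0.04))
        np.testing.assert_allclose(
            2 * d1["mass_tonnes"].to_numpy(), d2["mass_tonnes"].to_numpy(), rtol=1e-12
        )

    def test_unknown_material_without_density_rejected(self):
        spec = LayerSpec(layers=[("mystery", 0.1, True)])
        with pytest.raises(KeyError, match="mystery"):
            compute_maintenance_materials(spec)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            LayerSpec(resurfacing_fraction=1.5)


class TestNearestFacility:
    def test_single_candidate(self):
        fac = pd.DataFrame({"id": ["F1"], "material": ["concrete"], "x": [5.0], "y": [5.0]})
        assert assign_nearest_facility((0, 0), fac) == {"concrete": "F1"}

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(42)
        fac = pd.DataFrame(
            {
                "id": [f"F{i}" for i in range(5)],
                "material": ["asphalt"] * 5,
                "x": rng.uniform(0, 100, 5),
                "y": rng.uniform(0, 100, 5),
            }
        )
        port = (30.0, 70.0)
        got = assign_nearest_facility(port, fac)["asphalt"]
        d = np.hypot(fac["x"] - port[0], fac["y"] - port[1])
        assert got == fac["id"].iloc[int(np.argmin(d))]

    def test_equidistant_tie_breaks_lexicographically(self):
        fac = pd.DataFrame(
            {
                "id": ["FB", "FA"],
                "material": ["cement", "cement"],
                "x": [10.0, -10.0],
                "y": [0.0, 0.0],
            }
        )
        assert assign_nearest_facility((0, 0), fac) == {"cement": "FA"}


class TestMaterialEmissions:
    def test_unit_product(self, layout, factors, grid):
        demand = pd.DataFrame(
            {"volume_m3": [0.0], "mass_tonnes": [1000.0]},
            index=pd.Index(["concrete"], name="material"),
        )
        pf = factors["plants"].copy()
        pf.loc["concrete"] = 0.002
        assignment = assign_nearest_facility(layout.port_xy, layout.facilities)
        recs = material_emissions(demand, assignment, layout.facilities, pf, grid)
        pm = recs[recs["species"] == "pm25"]["tonnes_per_year"].iloc[0]
        assert pm == pytest.approx(2.0)

    def test_zero_demand_zero_records(self, layout, factors, grid):
        demand = compute_maintenance_materials(LayerSpec(resurfacing_fraction=0.0))
        assignment = assign_nearest_facility(layout.port_xy, layout.facilities)
        recs = material_emissions(demand, assignment, layout.facilities,
                                  factors["plants"], grid)
        assert (recs["tonnes_per_year"] == 0).all()

    def test_per_facility_totals_match_tabular_oracle(self, layout, factors, grid):
        spec = LayerSpec(resurfacing_fraction=0.05)
        demand = compute_maintenance_materials(spec)
        assignment = assign_nearest_facility(layout.port_xy, layout.facilities)
        recs = material_emissions(demand, assignment, layout.facilities,
                                  factors["plants"], grid)
        # independent spreadsheet-style oracle: demand x factor per material
        for material, cat in [("concrete", "ready_mix_plant"), ("cement", "cement_plant"),
                              ("asphalt", "asphalt_plant"), ("aggregate", "aggregate_plant")]:
            expect = demand.loc[material, "mass_tonnes"] * factors["plants"].loc[material]
            got = recs[recs["category"] == cat].set_index("species")["tonnes_per_year"]
            for sp in SPECIES:
                assert got[sp] == pytest.approx(expect[sp], rel=1e-12)

    def test_missing_factor_rejected(self, layout, grid, factors):
        demand = pd.DataFrame(
            {"volume_m3": [1.0], "mass_tonnes": [10.0]},
            index=pd.Index(["concrete"], name="material"),
        )
        with pytest.raises(KeyError, match="concrete"):
            material_emissions(
                demand, {"concrete": "F01"}, layout.facilities,
                factors["plants"].drop(index="concrete"), grid,
            )


class TestDeliveryEmissions:
    def test_zero_mass_zero_trips(self, two_cell_grid, factors):
        route = LineString([(100, 500), (1900, 500)])
        recs, trips = delivery_emissions(
            route, 0.0, 20.0, factors["trucks"].loc["diesel_current"], two_cell_grid
        )
        assert trips == 0
        assert (recs["tonnes_per_year"] == 0).all()

    def test_single_cell_route_gets_weight_one(self, two_cell_grid, factors):
        route = LineString([(100, 500), (900, 500)])  # 800 m inside cell A
        recs, _ = delivery_emissions(
            route, 100.0, 20.0, factors["trucks"].loc["diesel_current"], two_cell_grid
        )
        assert set(recs["cell_id"]) == {"A"}
        assert (recs["weight"] == 1.0).all()

    def test_split_allocation_matches_segment_lengths(self, two_cell_grid, factors):
        # 300 m in cell A, 700 m in cell B
        route = LineString([(700, 500), (1700, 500)])
        recs, trips = delivery_emissions(
            route, 100.0, 20.0, factors["trucks"].loc["diesel_current"], two_cell_grid
        )
        w = recs[recs["species"] == "pm25"].set_index("cell_id")["weight"]
        assert w["A"] == pytest.approx(0.3, rel=1e-9)
        assert w["B"] == pytest.approx(0.7, rel=1e-9)
        assert trips == 5  # ceil(100/20)
        pm = recs[recs["species"] == "pm25"]["tonnes_per_year"].iloc[0]
        expect = trips * 1.0 * factors["trucks"].loc["diesel_current", "pm25"]  # 1 km route
        assert pm == pytest.approx(expect, rel=1e-9)

    def test_route_outside_grid_rejected(self, two_cell_grid, factors):
        route = LineString([(5000, 5000), (6000, 5000)])
        with pytest.raises(ValueError, match="route"):
            delivery_emissions(route, 10.0, 20.0,
                               factors["trucks"].loc["diesel_current"], two_cell_grid)


class TestAssembly:
    def test_empty_embodied_equals_direct(self, layout, grid, factors):
        direct = build_direct_inventory(layout, grid,
                                        factors["trucks"].loc["diesel_current"])
        inv = assemble_inventory(direct, pd.DataFrame(columns=RECORD_COLUMNS))
        pd.testing.assert_frame_equal(inv.records, direct.reset_index(drop=True))

    def test_at_least_14_categories(self, inventory):
        assert len(inventory.categories) >= 14

    def test_species_totals_conserved(self, layout, grid, factors):
        direct = build_direct_inventory(layout, grid,
                                        factors["trucks"].loc["diesel_current"])
        embodied = build_embodied_inventory(
            LayerSpec(resurfacing_fraction=0.05), layout, factors, grid
        )
        inv = assemble_inventory(direct, embodied)

        def totals(df):
            return (df["tonnes_per_year"] * df["weight"]).groupby(df["species"]).sum()

        expect = totals(direct).add(totals(embodied), fill_value=0.0)
        got = inv.total_by_species()
        pd.testing.assert_series_equal(got.sort_index(), expect.sort_index(),
                                       check_names=False, rtol=1e-12)

    def test_duplicate_conflicting_records_rejected(self, layout, grid, factors):
        direct = build_direct_inventory(layout, grid,
                                        factors["trucks"].loc["diesel_current"])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_inventory(direct, direct.copy())

    def test_doubling_plant_factors_doubles_embodied_emissions(self, layout, grid, factors):
        spec = LayerSpec(resurfacing_fraction=0.05)
        e1 = build_embodied_inventory(spec, layout, factors, grid)
        doubled = dict(factors)
        doubled["plants"] = factors["plants"] * 2.0
        e2 = build_embodied_inventory(spec, layout, doubled, grid)
        plants = e1["category"].str.endswith("_plant")
        np.testing.assert_allclose(
            2 * e1.loc[plants, "tonnes_per_year"].to_numpy(),
            e2.loc[plants, "tonnes_per_year"].to_numpy(),
            rtol=1e-12,
        )

    def test_category_summary_totals(self, inventory):
        summ = category_summary(inventory)
        assert summ.to_numpy().sum() == pytest.approx(
            inventory.total_by_species().sum(), rel=1e-12
        )
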