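"""Landscape I/O, hive sites, synthetic generator and scenario realizations."""

import numpy as np
import pytest
from shapely.geometry import box

from beeforage import (
    CLOVER,
    OILSEED_RAPE,
    HiveSite,
    LandPatch,
    LandscapeSpec,
    SyntheticLandscapeParams,
    enumerate_hive_sites,
    generate_synthetic_landscape,
    hive_patch_distance,
    load_landscape,
    save_landscape,
    scenario_alternative_fields,
    scenario_flower_strips,
    scenario_off_field,
)


@pytest.fixture(scope="module")
def small_landscape():
    params = SyntheticLandscapeParams(
        extent=2000, n_target=8, n_alternative=3, n_offfield=40
    )
    return generate_synthetic_landscape(params, seed=42)


class TestIO:
    def test_geojson_round_trip(self, small_landscape, tmp_path):
        path = tmp_path / "ls.geojson"
        save_landscape(small_landscape, str(path))
        back = load_landscape(str(path))
        assert len(back.patches) == len(small_landscape.patches)
        for a, b in zip(small_landscape.patches, back.patches):
            assert a.id == b.id and a.category == b.category
            assert a.area == pytest.approx(b.area)

    def test_csv_wkt_round_trip(self, small_landscape, tmp_path):
        path = tmp_path / "ls.csv"
        save_landscape(small_landscape, str(path))
        back = load_landscape(str(path))
        assert len(back.patches) == len(small_landscape.patches)
        assert back.patches[0].geometry.equals(small_landscape.patches[0].geometry)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            LandPatch(id="z", geometry=box(0, 0, 0, 0), category="target-field")

    def test_unknown_resource_rejected(self):
        doc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon",
                                 "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]]},
                    "properties": {"id": "x", "category": "target-field",
                                   "resource": "sunflower"},
                }
            ],
        }
        with pytest.raises(ValueError, match="unknown resource"):
            load_landscape(doc)

    def test_memory_and_file_agree(self, small_landscape, tmp_path):
        path = tmp_path / "ls.geojson"
        save_landscape(small_landscape, str(path))
        import json

        with open(path) as fh:
            doc = json.load(fh)
        from_mem = load_landscape(doc)
        from_file = load_landscape(str(path))
        assert [p.id for p in from_mem.patches] == [p.id for p in from_file.patches]


class TestHiveSites:
    def test_square_field_has_twenty_border_cells(self):
        # a 4x4-cell field: the 8-adjacent exterior ring is 6*6 - 16 = 20 cells
        field = LandPatch(id="f", geometry=box(0, 0, 100, 100),
                          category="target-field", resource="oilseed_rape")
        ls = LandscapeSpec(patches=[field], resolution=25.0)
        sites = enumerate_hive_sites(ls, sample_fraction=1.0)
        assert len(sites) == 20
        assert all(s.adjacent_patch_id == "f" for s in sites)

    def test_two_disjoint_fields_union(self):
        f1 = LandPatch(id="f1", geometry=box(0, 0, 100, 100), category="target-field")
        f2 = LandPatch(id="f2", geometry=box(1000, 1000, 1100, 1100),
                       category="target-field")
        ls = LandscapeSpec(patches=[f1, f2], resolution=25.0)
        assert len(enumerate_hive_sites(ls, sample_fraction=1.0)) == 40

    def test_sample_fraction_one_returns_all(self, small_landscape):
        full = enumerate_hive_sites(small_landscape, sample_fraction=1.0)
        part = enumerate_hive_sites(small_landscape, sample_fraction=0.2, seed=5)
        assert 0 < len(part) < len(full)

    def test_sample_is_seed_stable(self, small_landscape):
        a = enumerate_hive_sites(small_landscape, 0.25, seed=9)
        b = enumerate_hive_sites(small_landscape, 0.25, seed=9)
        assert a == b

    def test_no_targets_warns_and_returns_empty(self):
        off = LandPatch(id="o", geometry=box(0, 0, 10, 10), category="off-field")
        with pytest.warns(UserWarning):
            assert enumerate_hive_sites(LandscapeSpec(patches=[off])) == []


class TestDistances:
    def test_floor_at_half_cell(self):
        site = HiveSite(x=112.5, y=50.0, adjacent_patch_id="f")
        geom = box(0, 0, 100, 100)  # 12.5 m from the site centre
        assert hive_patch_distance(site, geom, 25.0) == 12.5
        near = box(0, 0, 110, 100)  # 2.5 m away: floored
        assert hive_patch_distance(site, near, 25.0) == 12.5

    def test_analytic_rectangle(self):
        site = HiveSite(x=0.0, y=0.0, adjacent_patch_id="f")
        geom = box(-50, 900, 50, 1100)  # centred 1 km north, half-extent 100
        assert hive_patch_distance(site, geom, 25.0) == pytest.approx(900.0)

    def test_translation_invariance(self):
        from shapely.affinity import translate

        site = HiveSite(x=10.0, y=20.0, adjacent_patch_id="f")
        geom = box(200, 300, 400, 500)
        d0 = hive_patch_distance(site, geom)
        site2 = HiveSite(x=10.0 + 777, y=20.0 - 55, adjacent_patch_id="f")
        d1 = hive_patch_distance(site2, translate(geom, 777, -55))
        assert d0 == pytest.approx(d1)


class TestSyntheticGenerator:
    def test_seed_reproducibility(self):
        params = SyntheticLandscapeParams(extent=2000, n_target=5, n_alternative=2,
                                          n_offfield=20)
        a = generate_synthetic_landscape(params, seed=7)
        b = generate_synthetic_landscape(params, seed=7)
        assert [p.id for p in a.patches] == [p.id for p in b.patches]
        assert all(pa.geometry.equals(pb.geometry)
                   for pa, pb in zip(a.patches, b.patches))

    def test_requested_counts_present(self, small_landscape):
        assert len(small_landscape.by_category("target-field")) == 8
        assert len(small_landscape.by_category("alternative-field")) == 3
        assert len(small_landscape.by_category("off-field")) == 40

    def test_total_target_area_close_to_requested(self):
        params = SyntheticLandscapeParams(
            extent=4000, n_target=10, n_alternative=0, n_offfield=0,
            target_total_ha=60.0,
        )
        ls = generate_synthetic_landscape(params, seed=3)
        total = sum(p.area for p in ls.by_category("target-field")) / 1e4
        assert total == pytest.approx(60.0, rel=0.05)

    def test_fields_do_not_overlap(self, small_landscape):
        fields = [p.geometry for p in small_landscape.patches
                  if p.category.endswith("-field") and p.category != "off-field"]
        for i in range(len(fields)):
            for j in range(i + 1, len(fields)):
                assert not fields[i].intersects(fields[j])

    def test_infeasible_packing_raises(self):
        params = SyntheticLandscapeParams(
            extent=400, n_target=50, field_area_ha=(8, 10), max_tries=10,
            n_alternative=0, n_offfield=0,
        )
        with pytest.raises(RuntimeError, match="could not place"):
            generate_synthetic_landscape(params, seed=0)


class TestAlternativeFieldsScenario:
    def test_p_one_treats_everything(self, small_landscape):
        real = scenario_alternative_fields(small_landscape, p=1.0, seed=1)
        targets = [p for p in real.patches if p.category == "target-field"]
        assert targets and all(p.treated for p in targets)

    def test_p_zero_treats_nothing(self, small_landscape):
        real = scenario_alternative_fields(small_landscape, p=0.0, seed=1)
        assert not any(p.treated for p in real.patches)

    def test_alternatives_never_treated_and_rescaled(self, small_landscape):
        real = scenario_alternative_fields(small_landscape, p=1.0, sugar_mult=1.2, seed=1)
        alts = [p for p in real.patches if p.category == "alternative-field"]
        assert alts and not any(p.treated for p in alts)
        assert all(p.rt.e_R == pytest.approx(0.47 * 1.2 * 17.2) for p in alts)

    def test_treated_count_binomial(self, small_landscape):
        n = len(small_landscape.by_category("target-field"))
        p = 0.4
        counts = [
            sum(q.treated for q in scenario_alternative_fields(
                small_landscape, p, seed=s).patches)
            for s in range(400)
        ]
        mean = np.mean(counts)
        se = np.sqrt(n * p * (1 - p) / 400)
        assert abs(mean - n * p) < 4 * se


class TestFlowerStripsScenario:
    def test_p_zero_adds_nothing(self, small_landscape):
        real = scenario_flower_strips(small_landscape, p=0.0, w=2.0, seed=1)
        assert not any(p.category == "flower-strip" for p in real.patches)
        assert real.managed_area == 0.0

    def test_square_field_arithmetic(self):
        field = LandPatch(id="f", geometry=box(0, 0, 400, 400),
                          category="target-field")
        ls = LandscapeSpec(patches=[field])
        real = scenario_flower_strips(ls, p=1.0, w=2.0, seed=0)
        strips = [p for p in real.patches if p.category == "flower-strip"]
        assert len(strips) == 4
        assert all(s.area == pytest.approx(800.0) for s in strips)
        host = next(p for p in real.patches if p.id == "f")
        assert host.area == pytest.approx(160_000 - 3_200)

    def test_area_conservation_per_field(self, small_landscape):
        real = scenario_flower_strips(small_landscape, p=0.7, w=5.0, seed=2)
        strips_by_host = {}
        for p in real.patches:
            if p.category == "flower-strip":
                host = p.id.rsplit("-strip", 1)[0]
                strips_by_host[host] = strips_by_host.get(host, 0.0) + p.area
        for t in small_landscape.by_category("target-field"):
            realized = next(p for p in real.patches if p.id == t.id)
            assert realized.area + strips_by_host.get(t.id, 0.0) == pytest.approx(t.area)

    def test_expected_strip_count(self, small_landscape):
        n_fields = len(small_landscape.by_category("target-field"))
        counts = [
            sum(p.category == "flower-strip"
                for p in scenario_flower_strips(small_landscape, 0.5, 2.0, seed=s).patches)
            for s in range(300)
        ]
        assert np.mean(counts) / n_fields == pytest.approx(4 * 0.5, abs=0.2)

    def test_oversized_strips_rejected(self):
        tiny = LandPatch(id="f", geometry=box(0, 0, 30, 30), category="target-field")
        with pytest.raises(ValueError, match="strip area"):
            scenario_flower_strips(LandscapeSpec(patches=[tiny]), p=1.0, w=10.0, seed=0)

    def test_strips_match_medium_quality_offfield_resource(self, small_landscape):
        real_s = scenario_flower_strips(small_landscape, p=1.0, w=2.0, seed=0)
        real_o = scenario_off_field(small_landscape, p=1.0, quality_mult=1.0, seed=0)
        strip_rt = next(p.rt for p in real_s.patches if p.category == "flower-strip")
        off_rt = next(p.rt for p in real_o.patches if p.category == "off-field")
        assert strip_rt == off_rt == CLOVER


class TestOffFieldScenario:
    def test_p_zero_no_resources(self, small_landscape):
        real = scenario_off_field(small_landscape, p=0.0, seed=1)
        assert not any(p.category == "off-field" for p in real.patches)

    def test_quality_scales_density(self, small_landscape):
        real = scenario_off_field(small_landscape, p=1.0, quality_mult=0.5, seed=1)
        offs = [p for p in real.patches if p.category == "off-field"]
        assert offs and all(p.rt.F0 == pytest.approx(CLOVER.F0 / 2) for p in offs)

    def test_selected_count_binomial(self, small_landscape):
        n = len(small_landscape.by_category("off-field"))
        p = 0.3
        counts = [
            sum(q.category == "off-field" for q in scenario_off_field(
                small_landscape, p, seed=s).patches)
            for s in range(400)
        ]
        se = np.sqrt(n * p * (1 - p) / 400)
        assert abs(np.mean(counts) - n * p) < 4 * se

    def test_nested_across_p_for_fixed_seed(self, small_landscape):
        lo = {p.id for p in scenario_off_field(small_landscape, 0.3, seed=9).patches
              if p.category == "off-field"}
        hi = {p.id for p in scenario_off_field(small_landscape, 0.7, seed=9).patches
              if p.category == "off-field"}
        assert lo <= hi


def test_realizations_reproducible(small_landscape):
    a = scenario_alternative_fields(small_landscape, 0.5, seed=123)
    b = scenario_alternative_fields(small_landscape, 0.5, seed=123)
    assert [(p.id, p.treated) for p in a.patches] == [(p.id, p.treated) for p in b.patches]
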