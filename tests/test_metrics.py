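"""Defaunation surfaces, loss bands, range loss, downsizing, Tukey-Kramer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from defauna.hexgrid import VectorRegion, build_hexgrid
from defauna.metrics import (
    augment_historical,
    defaunation_by_hexcell,
    defaunation_raster,
    downsizing,
    historical_composition,
    loss_band_summary,
    protection_comparison,
    species_range_loss,
)

from conftest import make_raster


class TestDefaunationRaster:
    def test_identical_rasters_zero(self):
        h = make_raster(np.full((3, 3), 4.0))
        d = defaunation_raster(h, h.copy())
        assert (d.difference.values == 0).all()

    def test_arithmetic_and_percent(self):
        h = make_raster([[5.0]])
        c = make_raster([[2.0]])
        d = defaunation_raster(h, c)
        assert d.difference.values[0, 0] == 3.0
        assert d.percent_loss.values[0, 0] == pytest.approx(60.0)

    def test_zero_historical_percent_missing_gain_preserved(self):
        h = make_raster([[0.0]])
        c = make_raster([[1.0]])
        d = defaunation_raster(h, c)
        assert d.difference.values[0, 0] == -1.0
        assert not d.percent_loss.valid_mask()[0, 0]

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            defaunation_raster(make_raster(np.zeros((2, 2))),
                               make_raster(np.zeros((3, 3))))


class TestHexcellRecords:
    def test_constant_defaunation(self):
        d = make_raster(np.full((20, 20), 3.0))
        grid = build_hexgrid(VectorRegion.from_bounds(0, 0, 20, 20), 4.0)
        cov = {"ls": make_raster(np.full((20, 20), 0.5))}
        cells = defaunation_by_hexcell(d, grid, cov)
        np.testing.assert_allclose(cells["defaunation"], 3.0)
        np.testing.assert_allclose(cells["ls"], 0.5)

    def test_checkerboard_mean(self):
        vals = np.indices((20, 20)).sum(axis=0) % 2 * 6.0
        d = make_raster(vals)
        grid = build_hexgrid(VectorRegion.from_bounds(2, 2, 18, 18), 3.0)
        cells = defaunation_by_hexcell(d, grid, {})
        inner = cells["defaunation"]
        assert inner.mean() == pytest.approx(3.0, abs=0.3)

    def test_missing_covariate_row_dropped(self):
        d = make_raster(np.full((20, 20), 1.0))
        cov_vals = np.full((20, 20), 2.0)
        cov_vals[:, :10] = -9999.0  # left half missing
        grid = build_hexgrid(VectorRegion.from_bounds(0, 0, 20, 20), 4.0)
        cells = defaunation_by_hexcell(d, grid, {"c": make_raster(cov_vals)})
        all_cells = defaunation_by_hexcell(d, grid, {})
        assert len(cells) < len(all_cells)

    def test_richness_mask_restricts_to_fauna(self):
        d = make_raster(np.full((20, 20), 1.0))
        rich = np.zeros((20, 20))
        rich[:, 10:] = 10.0
        grid = build_hexgrid(VectorRegion.from_bounds(0, 0, 20, 20), 4.0)
        masked = defaunation_by_hexcell(
            d, grid, {}, historical=make_raster(rich), min_historical_richness=5.0
        )
        full = defaunation_by_hexcell(d, grid, {})
        assert 0 < len(masked) < len(full)


class TestLossBands:
    def test_hand_counted_fractions(self):
        pct = make_raster([[10.0, 30.0, 55.0, 60.0]])
        bands = loss_band_summary(pct)
        assert bands["over_50"] == pytest.approx(0.5)
        assert bands["20_to_49"] == pytest.approx(0.25)
        assert bands["under_20"] == pytest.approx(0.25)

    def test_all_zero_in_lowest_band(self):
        bands = loss_band_summary(make_raster(np.zeros((3, 3))))
        assert bands["under_20"] == 1.0

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(50)
        pct = make_raster(rng.uniform(-40, 110, size=(12, 12)))
        bands = loss_band_summary(pct)
        assert sum(bands.values()) == pytest.approx(1.0)


def toy_assemblage_world():
    """Two species, three sites; binary maps on a 4x4 grid."""
    maps = {
        "spA": make_raster(np.ones((4, 4))),
        "spB": make_raster(np.pad(np.ones((2, 2)), (0, 2))),  # NW quarter only
    }
    asm = pd.DataFrame(
        {
            "site_id": ["s1", "s2", "s3"],
            "x": [0.5, 1.5, 3.5],
            "y": [3.5, 2.5, 0.5],
            "protection": ["none", "strict", "none"],
            "spA": [1, 1, 0],
            "spB": [0, 1, 0],
        }
    )
    return maps, asm


class TestRangeLoss:
    def test_hand_counted_loss_and_area(self):
        maps, asm = toy_assemblage_world()
        out = species_range_loss(maps, asm).set_index("species_id")
        # spA predicted at all 3 sites, occupied at 2 -> loss 1/3
        a = out.loc["spA"]
        assert a.n_assemblages_predicted == 3
        assert a.n_assemblages_occupied == 2
        assert a.loss_fraction == pytest.approx(1 / 3)
        assert a.historical_area_km2 == pytest.approx(16.0)
        assert a.lost_area_km2 == pytest.approx(16.0 / 3)
        # spB predicted at s1, s2 (NW quarter), occupied at s2 -> loss 1/2
        b = out.loc["spB"]
        assert b.n_assemblages_predicted == 2
        assert b.loss_fraction == pytest.approx(0.5)

    def test_full_occupancy_zero_loss(self):
        maps, asm = toy_assemblage_world()
        asm["spA"] = 1
        out = species_range_loss(maps, asm).set_index("species_id")
        assert out.loc["spA", "loss_fraction"] == 0.0

    def test_commission_counted_not_in_loss(self):
        maps, asm = toy_assemblage_world()
        asm.loc[2, "spB"] = 1  # occupied at s3 where not predicted
        out = species_range_loss(maps, asm).set_index("species_id")
        assert out.loc["spB", "n_commission"] == 1
        assert out.loc["spB", "loss_fraction"] == pytest.approx(0.5)

    def test_zero_predicted_not_assessable(self):
        maps, asm = toy_assemblage_world()
        maps["spB"] = make_raster(np.zeros((4, 4)))
        out = species_range_loss(maps, asm).set_index("species_id")
        assert not out.loc["spB", "assessable"]

    def test_matches_brute_force_on_synthetic_world(self, small_world):
        maps = {s.species_id: s.range_map for s in small_world.pool}
        asm = small_world.assemblages
        out = species_range_loss(maps, asm).set_index("species_id")
        rows, cols = maps[small_world.species_ids[0]].index_of(
            asm["x"].to_numpy(), asm["y"].to_numpy()
        )
        for sp in small_world.species_ids:
            predicted = maps[sp].values[rows, cols] > 0
            occupied = asm[sp].to_numpy() > 0
            n_pred = predicted.sum()
            if n_pred == 0:
                assert not out.loc[sp, "assessable"]
                continue
            loss = 1 - (predicted & occupied).sum() / n_pred
            assert out.loc[sp, "loss_fraction"] == pytest.approx(loss)


class TestDownsizing:
    def _three_species(self):
        hist = pd.DataFrame(
            {"site_id": ["s1"], "x": [0.5], "y": [0.5], "protection": ["none"],
             "a": [1], "b": [1], "c": [1]}
        )
        cont = hist.copy()
        cont[["b", "c"]] = 0
        mass = pd.Series({"a": 2.0, "b": 10.0, "c": 300.0})
        return cont, hist, mass

    def test_hand_arithmetic(self):
        cont, hist, mass = self._three_species()
        records, summary = downsizing(cont, hist, mass)
        r = records.iloc[0]
        assert r.aggregate_mass_hist_kg == pytest.approx(312.0)
        assert r.aggregate_mass_cont_kg == pytest.approx(2.0)
        assert r.mean_mass_hist_kg == pytest.approx(104.0)
        assert r.mean_mass_cont_kg == pytest.approx(2.0)
        assert r.retained_fraction == pytest.approx(2.0 / 312.0)  # 0.64%
        assert r.species_lost == 2

    def test_identical_compositions_no_downsizing(self):
        cont, hist, mass = self._three_species()
        records, summary = downsizing(hist, hist, mass)
        assert records.iloc[0].retained_fraction == pytest.approx(1.0)
        assert summary["total_biomass_loss_kg"] == pytest.approx(0.0)

    def test_missing_mass_names_species(self):
        cont, hist, mass = self._three_species()
        with pytest.raises(KeyError, match="c"):
            downsizing(cont, hist, mass.drop("c"))

    def test_total_loss_consistency(self, small_world):
        asm = small_world.assemblages
        hist = small_world.truth.historical
        mass = small_world.trait_table()["body_mass_g"] / 1000
        records, summary = downsizing(asm, hist, mass)
        per_site = (
            records.aggregate_mass_hist_kg - records.aggregate_mass_cont_kg
        ).sum()
        assert summary["total_biomass_loss_kg"] == pytest.approx(per_site)

    def test_synthetic_world_downsizes(self, small_world):
        asm = small_world.assemblages
        hist = small_world.truth.historical
        mass = small_world.trait_table()["body_mass_g"] / 1000
        _, summary = downsizing(asm, hist, mass)
        assert summary["mean_mass_cont_kg"] < summary["mean_mass_hist_kg"]

    def test_augment_historical_removes_gains(self, small_world):
        asm = small_world.assemblages
        sp = small_world.species_ids
        hist = small_world.truth.historical.copy()
        hist[sp] = 0  # a maximally wrong model
        fixed = augment_historical(hist, asm)
        np.testing.assert_array_equal(
            fixed[sp].to_numpy() >= asm[sp].to_numpy(), True
        )


class TestProtectionComparison:
    def _records(self, groups):
        rows = []
        for name, vals in groups.items():
            rows += [{"protection": name, "retained_fraction": v} for v in vals]
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        vals = [0.2, 0.4, 0.6, 0.8]
        table = protection_comparison(self._records(
            {"a": vals, "b": vals, "c": vals}
        ))
        assert (table["p"] > 0.95).all()
        assert not table["significant"].any()

    def test_two_equal_groups_q_is_sqrt2_t(self):
        rng = np.random.default_rng(51)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 12)
        table = protection_comparison(self._records({"a": a, "b": b}))
        t_stat, _ = stats.ttest_ind(a, b)
        assert table["q"].iloc[0] == pytest.approx(np.sqrt(2) * abs(t_stat))

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(52)
        a, b = rng.normal(0, 1, 14), rng.normal(10, 1, 14)
        table = protection_comparison(self._records({"a": a, "b": b}))
        assert table["p"].iloc[0] < 0.001
        # permutation oracle: observed |mean diff| never beaten by shuffles
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        beat = 0
        for _ in range(10_000):
            rng.shuffle(pooled)
            beat += abs(pooled[:14].mean() - pooled[14:].mean()) >= obs
        assert beat / 10_000 < 0.001

    def test_matches_statsmodels_tukeyhsd(self):
        sm_stats = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(53)
        groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(0.8, 1, 15),
                  "c": rng.normal(0.3, 1, 8)}
        ours = protection_comparison(self._records(groups))
        data = np.concatenate(list(groups.values()))
        labels = sum(([k] * len(v) for k, v in groups.items()), [])
        theirs = sm_stats.pairwise_tukeyhsd(data, labels)
        np.testing.assert_allclose(
            ours["p"].to_numpy(), theirs.pvalues, atol=1e-4
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            protection_comparison(self._records({"a": [1.0, 2.0]}))

    def test_tiny_zero_variance_group_handled(self):
        table = protection_comparison(
            self._records({"a": [1.0, 1.0], "b": [0.0, 0.5, 1.5]})
        )
        assert np.isfinite(table["p"]).all()


class TestHistoricalComposition:
    def test_reads_binary_map_at_site_cell(self):
        maps, asm = toy_assemblage_world()
        hist = historical_composition(maps, asm)
        assert hist["spA"].tolist() == [1, 1, 1]
        assert hist["spB"].tolist() == [1, 1, 0]
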