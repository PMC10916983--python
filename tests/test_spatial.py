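"""Spatial pipeline: assignment, matrix building, filters, distances, bins."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_cells
from mirglia.exceptions import ConfigurationError, IntegrityError, ParameterError, ValidationError
from mirglia.segmented import BreakpointFit
from mirglia.spatial import (
    BIN_LABELS,
    annotate_microglia,
    assign_spots,
    bin_cells,
    bin_profile,
    breakpoint_density,
    build_cell_matrix,
    classify_deposits,
    compare_groups,
    distance_to_nearest_deposit,
    filter_matrix,
)


def spots_df(rows):
    return pd.DataFrame(rows, columns=["gene", "x", "y"])


def nuclei_df(rows):
    return pd.DataFrame(rows, columns=["id", "x", "y"])


class TestAssignSpots:
    def test_nearest_within_radius(self):
        spots = spots_df([("g", 0.0, 0.0)])
        nuclei = nuclei_df([(1, 3.0, 0.0), (2, 20.0, 0.0)])
        out = assign_spots(spots, nuclei)
        assert out["nucleus_id"].iloc[0] == 1

    def test_exact_boundary_unassigned(self):
        """'closer than 10 μm' is strict: a spot at exactly 10.0 stays unassigned."""
        spots = spots_df([("g", 0.0, 0.0)])
        nuclei = nuclei_df([(1, 10.0, 0.0)])
        out = assign_spots(spots, nuclei, max_dist=10.0)
        assert out["nucleus_id"].isna().iloc[0]

    def test_tie_broken_to_lowest_id(self):
        spots = spots_df([("g", 0.0, 0.0)])
        nuclei = nuclei_df([(7, 5.0, 0.0), (3, -5.0, 0.0)])
        out = assign_spots(spots, nuclei)
        assert out["nucleus_id"].iloc[0] == 3

    def test_matches_all_pairs_oracle(self, rng):
        """Chunked assignment equals a naive all-pairs nearest-neighbor scan."""
        for trial in range(5):
            n_spots, n_nuc = 300, 40
            spots = spots_df(
                list(zip(["g"] * n_spots, rng.uniform(0, 100, n_spots), rng.uniform(0, 100, n_spots)))
            )
            nuclei = nuclei_df(
                list(zip(range(n_nuc), rng.uniform(0, 100, n_nuc), rng.uniform(0, 100, n_nuc)))
            )
            out = assign_spots(spots, nuclei, max_dist=10.0, chunk_size=37)
            for i, spot in spots.iterrows():
                best_id, best_d = None, np.inf
                for _, nuc in nuclei.iterrows():
                    d = np.hypot(spot["x"] - nuc["x"], spot["y"] - nuc["y"])
                    if d < best_d or (d == best_d and nuc["id"] < best_id):
                        best_id, best_d = nuc["id"], d
                expected = best_id if best_d < 10.0 else None
                got = out["nucleus_id"].iloc[i]
                assert (pd.isna(got) and expected is None) or got == expected

    def test_no_anchors_all_unassigned(self):
        out = assign_spots(spots_df([("g", 0, 0)]), nuclei_df([]))
        assert out["nucleus_id"].isna().all()


class TestBuildCellMatrix:
    def test_split_counts(self):
        spots = spots_df([("a", 0, 0), ("a", 1, 0), ("b", 0, 1), ("a", 50, 50), ("b", 51, 50)])
        nuclei = nuclei_df([(1, 0.0, 0.0), (2, 50.0, 50.0)])
        assigned = assign_spots(spots, nuclei)
        cells = build_cell_matrix(assigned, nuclei)
        assert cells.obs.loc[1, "total_transcripts"] == 3
        assert cells.obs.loc[2, "total_transcripts"] == 2
        assert cells.counts.loc[1, "a"] == 2 and cells.counts.loc[2, "b"] == 1

    def test_conservation_and_zero_count_nuclei(self):
        spots = spots_df([("a", 0, 0), ("a", 500, 500)])  # second is unassignable
        nuclei = nuclei_df([(1, 0.0, 0.0), (2, 100.0, 100.0)])
        assigned = assign_spots(spots, nuclei)
        cells = build_cell_matrix(assigned, nuclei)
        assert cells.counts.to_numpy().sum() == assigned["nucleus_id"].notna().sum()
        assert cells.obs.loc[2, "total_transcripts"] == 0  # kept with zero counts

    def test_unknown_nucleus_id_raises(self):
        spots = spots_df([("a", 0, 0)]).assign(nucleus_id=pd.array([99], dtype="Int64"))
        with pytest.raises(IntegrityError):
            build_cell_matrix(spots, nuclei_df([(1, 0.0, 0.0)]))


class TestFilterMatrix:
    def test_planted_survivor_counts(self):
        # 3 cells pass the 30-transcript cut, 2 fail; gene support then decides genes
        counts = {
            "c1": {"a": 20, "b": 10},        # 30: kept (inclusive)
            "c2": {"a": 29, "b": 0},         # 29: removed
            "c3": {"a": 15, "b": 20},        # kept
            "c4": {"a": 30, "b": 5},         # kept
            "c5": {"a": 1, "b": 1},          # removed
        }
        cells = make_cells(counts)
        out = filter_matrix(cells, min_transcripts_per_cell=30, min_cells_per_gene=3)
        assert set(out.counts.index) == {"c1", "c3", "c4"}
        assert set(out.genes) == {"a", "b"}
        # gene below support threshold drops out
        out2 = filter_matrix(cells, min_transcripts_per_cell=30, min_cells_per_gene=4)
        assert out2.genes == []

    def test_gene_support_boundary(self):
        counts = {f"c{i}": {"a": 40, "b": 40 if i < 2 else 0} for i in range(3)}
        out = filter_matrix(make_cells(counts), 30, 3)
        assert out.genes == ["a"]  # b expressed in only 2 of 3 surviving cells

    def test_idempotent(self):
        counts = {f"c{i}": {"a": 35, "b": 2} for i in range(5)}
        once = filter_matrix(make_cells(counts), 30, 3)
        twice = filter_matrix(once, 30, 3)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestAnnotateMicroglia:
    def test_marker_rule(self):
        cells = make_cells({"c1": {"Aif1": 2, "x": 30}, "c2": {"Aif1": 0, "x": 30}})
        out = annotate_microglia(cells)
        assert out.obs.loc["c1", "is_microglia"] and not out.obs.loc["c2", "is_microglia"]

    def test_min_count_gate(self):
        cells = make_cells({"c1": {"Aif1": 2, "x": 1}})
        out = annotate_microglia(cells, min_count=3)
        assert not out.obs["is_microglia"].iloc[0]

    def test_missing_marker_raises(self):
        with pytest.raises(ConfigurationError):
            annotate_microglia(make_cells({"c1": {"x": 1}}))


class TestClassifyDeposits:
    @pytest.mark.parametrize("diameter, expected", [(30, "small"), (5, "small"), (40, "small"),
                                                    (45, "big"), (4, "unclassified")])
    def test_size_classes(self, diameter, expected):
        deposits = pd.DataFrame({"id": [1], "x": [0.0], "y": [0.0], "diameter": [diameter]})
        assert classify_deposits(deposits)["size_class"].iloc[0] == expected

    def test_non_positive_diameter_raises(self):
        deposits = pd.DataFrame({"id": [1], "x": [0.0], "y": [0.0], "diameter": [-1.0]})
        with pytest.raises(ValidationError):
            classify_deposits(deposits)


class TestDistanceToDeposit:
    def _cells(self, coords):
        return make_cells({k: {"g": 1} for k in coords}, coords)

    def test_edge_mode_subtracts_radius(self):
        cells = self._cells({"c1": (25.0, 0.0)})
        deposits = pd.DataFrame({"id": [1], "x": [0.0], "y": [0.0], "diameter": [10.0]})
        out = distance_to_nearest_deposit(cells, deposits, mode="edge")
        assert out.obs["dist_to_deposit"].iloc[0] == pytest.approx(20.0)

    def test_inside_deposit_clamped_to_zero(self):
        cells = self._cells({"c1": (2.0, 0.0)})
        deposits = pd.DataFrame({"id": [1], "x": [0.0], "y": [0.0], "diameter": [10.0]})
        out = distance_to_nearest_deposit(cells, deposits, mode="edge")
        assert out.obs["dist_to_deposit"].iloc[0] == 0.0

    def test_matches_all_pairs_oracle(self, rng):
        coords = {f"c{i}": (rng.uniform(0, 100), rng.uniform(0, 100)) for i in range(30)}
        cells = self._cells(coords)
        deposits = pd.DataFrame(
            {"id": range(5), "x": rng.uniform(0, 100, 5), "y": rng.uniform(0, 100, 5),
             "diameter": rng.uniform(5, 40, 5)}
        )
        for mode in ("edge", "center"):
            out = distance_to_nearest_deposit(cells, deposits, mode=mode)
            for cid, (cx, cy) in coords.items():
                ds = []
                for _, dep in deposits.iterrows():
                    d = np.hypot(cx - dep["x"], cy - dep["y"])
                    if mode == "edge":
                        d = max(0.0, d - dep["diameter"] / 2)
                    ds.append(d)
                assert out.obs.loc[cid, "dist_to_deposit"] == pytest.approx(min(ds))

    def test_no_deposits_gives_inf(self):
        cells = self._cells({"c1": (0.0, 0.0)})
        out = distance_to_nearest_deposit(cells, pd.DataFrame(columns=["id", "x", "y", "diameter"]))
        assert np.isinf(out.obs["dist_to_deposit"].iloc[0])


class TestBinCells:
    def _binned(self, distances):
        cells = make_cells({f"c{i}": {"g": 1} for i in range(len(distances))})
        cells.obs["dist_to_deposit"] = distances
        return bin_cells(cells)

    @pytest.mark.parametrize(
        "distance, expected",
        [(0.0, "colocalized"), (0.1, "close"), (9.0, "close"), (9.1, "medium_close"),
         (17.0, "medium_close"), (20.0, "medium_far"), (27.0, "medium_far"), (30.0, "far")],
    )
    def test_boundary_ownership(self, distance, expected):
        out = self._binned([distance])
        assert out.obs["distance_bin"].iloc[0] == expected

    def test_partition(self, rng):
        out = self._binned(list(rng.uniform(0, 60, 200)) + [0.0])
        counts = out.obs["distance_bin"].value_counts()
        assert counts.sum() == 201
        assert set(counts.index) <= set(BIN_LABELS)

    def test_unsorted_breaks_raise(self):
        cells = make_cells({"c1": {"g": 1}})
        cells.obs["dist_to_deposit"] = [1.0]
        with pytest.raises(ParameterError):
            bin_cells(cells, breaks=(0, 17, 9, 27))


class TestCompareGroups:
    def test_null_identical_groups(self):
        counts = {f"c{i}": {"a": 5} for i in range(20)}
        cells = make_cells(counts)
        cells.obs["grp"] = [i < 10 for i in range(20)]
        table = compare_groups(cells, "grp")
        assert table["p_value"].iloc[0] == 1.0

    def test_planted_difference_significant(self, rng):
        counts = {}
        for i in range(100):
            counts[f"a{i}"] = {"g": int(rng.poisson(10)), "h": int(rng.poisson(5))}
            counts[f"b{i}"] = {"g": int(rng.poisson(5)), "h": int(rng.poisson(5))}
        cells = make_cells(counts)
        cells.obs["grp"] = [c.startswith("a") for c in cells.counts.index]
        table = compare_groups(cells, "grp").set_index("gene")
        assert table.loc["g", "p_adjusted"] < 0.05
        assert table.loc["h", "p_adjusted"] > 0.05

    def test_all_null_bh_rejections_near_zero(self, rng):
        counts = {f"c{i}": {f"g{j}": int(rng.poisson(5)) for j in range(50)} for i in range(60)}
        cells = make_cells(counts)
        cells.obs["grp"] = [i < 30 for i in range(60)]
        table = compare_groups(cells, "grp")
        assert (table["p_adjusted"] < 0.05).sum() == 0


class TestBreakpointDensity:
    def _fit(self, psi):
        return BreakpointFit(gene="g", psi_hat=psi, ci_low=psi - 1, ci_high=psi + 1,
                             slopes=(0.1, -0.1), converged=True, n_iterations=3,
                             n_breakpoints=1, bic=0.0)

    def test_point_mass_peaks_at_value(self):
        grid, dens = breakpoint_density([self._fit(20.0)] * 5)
        assert grid[np.argmax(dens)] == pytest.approx(20.0, abs=0.5)

    def test_two_clusters_bimodal(self, rng):
        fits = [self._fit(10 + rng.normal(0, 0.5)) for _ in range(20)]
        fits += [self._fit(30 + rng.normal(0, 0.5)) for _ in range(20)]
        grid, dens = breakpoint_density(fits)
        mid = dens[(grid > 17) & (grid < 23)].max()
        assert dens[(grid > 8) & (grid < 12)].max() > 2 * mid
        assert dens[(grid > 28) & (grid < 32)].max() > 2 * mid

    def test_integrates_to_one(self, rng):
        fits = [self._fit(float(p)) for p in rng.uniform(5, 35, 30)]
        grid, dens = breakpoint_density(fits)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_no_converged_fits_empty(self):
        f = self._fit(20.0)
        bad = BreakpointFit(gene="g", psi_hat=float("nan"), ci_low=0, ci_high=0,
                            slopes=(0.0,), converged=False, n_iterations=50,
                            n_breakpoints=0, bic=0.0)
        grid, dens = breakpoint_density([bad])
        assert grid.size == 0 and dens.size == 0
        assert breakpoint_density([f])[0].size > 0


class TestBinProfile:
    def _cells_with_bins(self, rng):
        distances = np.concatenate([np.zeros(10), rng.uniform(1, 9, 10),
                                    rng.uniform(10, 17, 10), rng.uniform(18, 27, 10),
                                    rng.uniform(28, 60, 10)])
        counts = {}
        for i, d in enumerate(distances):
            counts[f"c{i}"] = {"rising": int(d), "flat": 5}
        cells = make_cells(counts)
        cells.obs["dist_to_deposit"] = distances
        return bin_cells(cells)

    def test_constant_gene_row_z_is_zero(self, rng):
        profile = bin_profile(self._cells_with_bins(rng), ["flat"], scaling="row_z")
        assert np.allclose(profile.loc["flat"].to_numpy(dtype=float), 0.0)

    def test_monotone_profile_unit_interval(self, rng):
        profile = bin_profile(self._cells_with_bins(rng), ["rising"], scaling="unit_interval")
        row = profile.loc["rising"].to_numpy(dtype=float)
        assert row.min() == 0.0 and row.max() == 1.0
        assert (np.diff(row) >= 0).all()

    def test_row_z_standardization(self, rng):
        profile = bin_profile(self._cells_with_bins(rng), ["rising"], scaling="row_z")
        row = profile.loc["rising"].to_numpy(dtype=float)
        assert row.mean() == pytest.approx(0.0, abs=1e-9)
        assert row.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_missing_panel_gene_raises(self, rng):
        with pytest.raises(ConfigurationError):
            bin_profile(self._cells_with_bins(rng), ["ghost"])
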