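"""Cutoff classification, group statistics and spatial reconstruction."""

import numpy as np
import pandas as pd
import pytest

import oracles
from melreg.errors import InvalidParameterError, ValidationError
from melreg.simulate import SimulationConfig, simulate_cell_table, truth_schemes
from melreg.spatial import (
    DEFAULT_LEVELS,
    LEVEL_COLORS,
    MarkerLevelScheme,
    classify_marker_levels,
    cooccurrence_summary,
    marker_by_group_comparison,
    quantile_schemes,
    read_cell_table,
    reconstruction_export,
    write_cell_table,
)


def tiny_cells():
    return pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3"],
            "x": [0.0, 1.0, 2.0],
            "y": [0.0, 1.0, 2.0],
            "tissue_class": ["tumor", "tumor", "stroma"],
            "ZEB1_nuclear": [120.0, 3.0, 1.0],
            "SOX10_nuclear": [2.0, 110.0, 1.0],
            "NGFR_membrane": [90.0, 0.5, 0.2],
        }
    )


class TestCellTableIO:
    def test_fixture_reads_as_written(self, tmp_path):
        path = tmp_path / "cells.csv"
        tiny_cells().to_csv(path, index=False)
        cells = read_cell_table(path)
        assert len(cells) == 3
        assert cells.loc[0, "ZEB1_nuclear"] == 120.0
        assert (cells["tissue_class"] == "tumor").sum() == 2  # non-tumor retained

    def test_negative_intensity_rejected(self, tmp_path):
        bad = tiny_cells()
        bad.loc[0, "ZEB1_nuclear"] = -1.0
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="negative intensity"):
            read_cell_table(path)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        tiny_cells().drop(columns=["x"]).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="'x'"):
            read_cell_table(path)

    def test_column_mapping(self, tmp_path):
        df = tiny_cells().rename(columns={"cell_id": "Cell ID", "ZEB1_nuclear": "Nucleus ZEB1 Mean"})
        path = tmp_path / "mapped.csv"
        df.to_csv(path, index=False)
        cells = read_cell_table(
            path, column_map={"Cell ID": "cell_id", "Nucleus ZEB1 Mean": "ZEB1_nuclear"}
        )
        assert "ZEB1_nuclear" in cells.columns

    def test_round_trip_identity(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_cells_spatial=100)
        cells, _ = simulate_cell_table(cfg)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cell_table(cells, p1)
        write_cell_table(read_cell_table(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestSchemes:
    def test_cutoff_count_must_match_levels(self):
        with pytest.raises(ValidationError):
            MarkerLevelScheme("ZEB1", ("a", "b", "c"), (1.0,))

    def test_unordered_cutoffs_rejected(self):
        with pytest.raises(ValidationError):
            MarkerLevelScheme("ZEB1", ("a", "b", "c"), (2.0, 1.0))

    def test_quantile_schemes_have_expected_shape(self):
        cfg = SimulationConfig(seed=4, n_cells_spatial=300)
        cells, _ = simulate_cell_table(cfg)
        schemes = {s.marker: s for s in quantile_schemes(cells)}
        assert len(schemes["ZEB1"].cutoffs) == 3
        assert len(schemes["SOX10"].cutoffs) == 2
        assert len(schemes["NGFR"].cutoffs) == 1


class TestClassification:
    SCHEME = MarkerLevelScheme(
        "ZEB1", ("not_expressed", "low", "intermediate", "high"), (2.0, 10.0, 50.0)
    )

    def test_above_top_cutoff_is_high(self):
        cells = tiny_cells()
        calls = classify_marker_levels(cells, [self.SCHEME])
        assert calls.loc["c1", "ZEB1"] == "high"
        assert calls.loc["c2", "ZEB1"] == "low"

    def test_lower_cutoff_is_inclusive(self):
        cells = tiny_cells()
        cells.loc[0, "ZEB1_nuclear"] = 50.0  # exactly at the high cutoff
        calls = classify_marker_levels(cells, [self.SCHEME])
        assert calls.loc["c1", "ZEB1"] == "high"

    def test_ngfr_vocabulary_is_binary(self):
        cfg = SimulationConfig(seed=5, n_cells_spatial=300)
        cells, _ = simulate_cell_table(cfg)
        calls = classify_marker_levels(cells, truth_schemes())
        assert set(calls["NGFR"].cat.categories) == {"not_expressed", "high"}
        assert set(calls["NGFR"].unique()) <= {"not_expressed", "high"}

    def test_non_tumor_cells_excluded(self):
        calls = classify_marker_levels(tiny_cells(), [self.SCHEME])
        assert list(calls.index) == ["c1", "c2"]

    def test_matches_binning_oracle_and_partitions(self, rng):
        n = 1000
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "x": rng.uniform(0, 100, n),
                "y": rng.uniform(0, 100, n),
                "tissue_class": "tumor",
                "ZEB1_nuclear": rng.lognormal(2, 1.5, n),
            }
        )
        calls = classify_marker_levels(cells, [self.SCHEME])
        cutoffs, levels = self.SCHEME.cutoffs, self.SCHEME.levels
        for cid, inten in zip(cells["cell_id"], cells["ZEB1_nuclear"]):
            want = levels[0]
            for lev, c in zip(levels[1:], cutoffs):
                if inten >= c:
                    want = lev
            assert calls.loc[cid, "ZEB1"] == want
        assert calls["ZEB1"].value_counts().sum() == n  # partition

    def test_monotone_in_intensity(self, rng):
        cells = tiny_cells()
        calls = classify_marker_levels(cells, [self.SCHEME])
        order = {lev: i for i, lev in enumerate(self.SCHEME.levels)}
        a, b = cells.iloc[0], cells.iloc[1]
        assert a["ZEB1_nuclear"] > b["ZEB1_nuclear"]
        assert order[str(calls.loc["c1", "ZEB1"])] >= order[str(calls.loc["c2", "ZEB1"])]


class TestGroupComparison:
    def make_cells(self, groups: dict, rng):
        rows = []
        i = 0
        for level, (n, mean) in groups.items():
            for _ in range(n):
                rows.append(
                    {
                        "cell_id": f"c{i}",
                        "x": 0.0,
                        "y": 0.0,
                        "tissue_class": "tumor",
                        "ZEB1_nuclear": {"not_expressed": 1, "low": 5,
                                         "intermediate": 25, "high": 125}[level],
                        "SOX10_nuclear": max(0.01, float(rng.normal(mean, 1.0))),
                    }
                )
                i += 1
        cells = pd.DataFrame(rows)
        schemes = [
            MarkerLevelScheme("ZEB1", DEFAULT_LEVELS["ZEB1"], (2.24, 11.2, 55.9)),
        ]
        return cells, classify_marker_levels(cells, schemes)

    def test_bonferroni_arithmetic(self, rng):
        cells, calls = self.make_cells(
            {"not_expressed": (20, 10), "low": (20, 10), "intermediate": (20, 10),
             "high": (20, 10)}, rng
        )
        res = marker_by_group_comparison(calls, cells, "SOX10", "ZEB1")
        assert res["n_tests"] == 6
        t = res["tests"]
        assert np.allclose(t["p_bonferroni"], np.minimum(1.0, 6 * t["pvalue"]))

    def test_small_groups_excluded_with_warning(self, rng):
        cells, calls = self.make_cells(
            {"not_expressed": (20, 10), "high": (20, 5), "low": (1, 10)}, rng
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = marker_by_group_comparison(calls, cells, "SOX10", "ZEB1")
        assert set(res["summary"].index) == {"not_expressed", "high"}

    def test_medians_reported(self, rng):
        cells, calls = self.make_cells({"not_expressed": (30, 20), "high": (30, 5)}, rng)
        res = marker_by_group_comparison(calls, cells, "SOX10", "ZEB1")
        med = res["summary"]["median"]
        assert med["not_expressed"] > med["high"]

    def test_matches_exact_enumeration_small_groups(self, rng):
        """Two-sided Mann-Whitney p equals exhaustive relabelling for n <= 8."""
        for n1, n2 in [(4, 5), (6, 6), (8, 7)]:
            x = rng.normal(1.0, 1.0, n1)
            y = rng.normal(0.0, 1.0, n2)
            from scipy.stats import mannwhitneyu

            got = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            want = oracles.exact_mannwhitney_two_sided(x, y)
            assert got == pytest.approx(want, abs=1e-12)

    def test_strict_dominance_hits_exact_tail(self, rng):
        """All of group A above all of group B: p equals the exact two-sided
        tail 2/C(n1+n2, n1)."""
        cells, calls = self.make_cells({"not_expressed": (6, 100), "high": (6, 50)}, rng)
        res = marker_by_group_comparison(calls, cells, "SOX10", "ZEB1")
        from math import comb

        p = res["tests"]["pvalue"].iloc[0]
        assert p == pytest.approx(2 / comb(12, 6), abs=1e-12)

    def test_type_one_error_calibrated(self):
        """Identically distributed groups: the Bonferroni-adjusted comparison
        stays non-significant at 0.05 in >= 95% of seeded replicates."""
        rng = np.random.default_rng(200)
        n_rep, n_sig = 200, 0
        for _ in range(n_rep):
            cells, calls = self.make_cells(
                {"not_expressed": (25, 10), "intermediate": (25, 10), "high": (25, 10)},
                rng,
            )
            res = marker_by_group_comparison(calls, cells, "SOX10", "ZEB1")
            if (res["tests"]["p_bonferroni"] < 0.05).any():
                n_sig += 1
        assert n_rep - n_sig >= 0.95 * n_rep


class TestCooccurrence:
    def test_identical_cells_single_nonzero(self):
        calls = pd.DataFrame(
            {
                "ZEB1": pd.Categorical(["high"] * 5, categories=DEFAULT_LEVELS["ZEB1"]),
                "NGFR": pd.Categorical(["high"] * 5, categories=DEFAULT_LEVELS["NGFR"]),
            },
            index=pd.Index([f"c{i}" for i in range(5)], name="cell_id"),
        )
        table = cooccurrence_summary(calls, ["ZEB1", "NGFR"])
        assert table.sum() == 5
        assert (table > 0).sum() == 1
        assert table.loc[("high", "high")] == 5
        assert len(table) == 4 * 2  # full Cartesian product, zeros included

    def test_marginals_match_per_marker_compositions(self):
        cfg = SimulationConfig(seed=9, n_cells_spatial=400)
        cells, _ = simulate_cell_table(cfg)
        calls = classify_marker_levels(cells, truth_schemes())
        table = cooccurrence_summary(calls, ["ZEB1", "NGFR", "SOX9"])
        assert table.sum() == len(calls)
        for marker in ("ZEB1", "NGFR", "SOX9"):
            marg = table.groupby(level=marker).sum()
            counts = calls[marker].value_counts()
            for level in marg.index:
                assert marg[level] == counts.get(level, 0)


class TestReconstruction:
    def test_color_convention(self):
        cells = tiny_cells()
        scheme = TestClassification.SCHEME
        calls = classify_marker_levels(cells, [scheme])
        export = reconstruction_export(cells, calls, "ZEB1")
        by_cell = export.set_index("cell_id")
        assert by_cell.loc["c1", "color"] == "red"  # high
        assert by_cell.loc["c2", "color"] == "blue"  # low
        assert set(export["color"]) <= set(LEVEL_COLORS.values())

    def test_empty_selection(self):
        cells = tiny_cells().iloc[:0]
        calls = classify_marker_levels(cells, [TestClassification.SCHEME])
        export = reconstruction_export(cells, calls, "ZEB1")
        assert export.empty

    def test_export_import_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=12, n_cells_spatial=150)
        cells, _ = simulate_cell_table(cfg)
        calls = classify_marker_levels(cells, truth_schemes())
        export = reconstruction_export(cells, calls, "ZEB1")
        path = tmp_path / "recon.csv"
        export.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert np.allclose(back[["x", "y"]], export[["x", "y"]])
        assert list(back["level"]) == list(export["level"])
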