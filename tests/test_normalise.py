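"""Reference-grid and row/column-median normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phenoplate as pp
from phenoplate.exceptions import (
    DegenerateGridError,
    DimensionMismatchError,
    ZeroMedianError,
)
from phenoplate.normalise import PlateLayout
from phenoplate.synthetic import SimulationConfig, simulate_experiment, simulate_fitness_plate


def brute_force_rowcol(values):
    """Independent loop-based row-then-column median normalisation."""
    out = np.array(values, dtype=float)
    for i in range(out.shape[0]):
        med = np.nanmedian(out[i, :])
        for j in range(out.shape[1]):
            out[i, j] = out[i, j] / med
    for j in range(out.shape[1]):
        med = np.nanmedian(out[:, j])
        for i in range(out.shape[0]):
            out[i, j] = out[i, j] / med
    return out


class TestMakeLayout:
    def test_384_topleft96(self):
        layout = pp.make_layout(384)
        assert int(layout.is_grid.sum()) == 96
        # one grid colony at the top-left of every 2x2 block
        assert layout.is_grid[::2, ::2].all()
        assert not layout.is_grid[1::2, :].any() and not layout.is_grid[:, 1::2].any()

    def test_96_none_has_no_grid(self):
        assert int(pp.make_layout(96, grid_scheme="none").is_grid.sum()) == 0

    def test_1536_grid_reaches_all_borders(self):
        layout = pp.make_layout(1536)
        assert int(layout.is_grid.sum()) == 96
        rows, cols = np.nonzero(layout.is_grid)
        assert rows.min() == 0 and rows.max() == 31
        assert cols.min() == 0 and cols.max() == 47


class TestReferenceSurface:
    def test_constant_grid_gives_constant_surface(self):
        layout = pp.make_layout(384)
        values = np.full((16, 24), np.nan)
        values[layout.is_grid] = 50.0
        surface = pp.build_reference_surface(values, layout)
        assert np.allclose(surface.expected, 50.0)

    def test_plane_is_reproduced(self):
        layout = pp.make_layout(384)
        values = 40.0 + 2.0 * np.arange(16)[:, None] + np.zeros((16, 24))
        surface = pp.build_reference_surface(values, layout)
        assert np.allclose(surface.expected, values, atol=1e-6)

    def test_zero_grid_colony_excluded_and_flagged(self):
        layout = pp.make_layout(384)
        values = np.full((16, 24), 50.0)
        values[0, 0] = 0.0  # (0, 0) is a grid position
        surface = pp.build_reference_surface(values, layout)
        assert surface.n_grid_used == 95
        assert any("missing grid colony" in f for f in surface.flags)
        assert np.isfinite(surface.expected).all()

    def test_too_few_grid_colonies(self):
        layout = pp.make_layout(384)
        values = np.full((16, 24), np.nan)
        values[0, 0] = values[0, 2] = 50.0
        with pytest.raises(DegenerateGridError):
            pp.build_reference_surface(values, layout)

    def test_collinear_grid_colonies(self):
        strain = np.full((16, 24), "s", dtype=object)
        is_grid = np.zeros((16, 24), dtype=bool)
        is_grid[0, [0, 4, 8, 12]] = True
        layout = PlateLayout(strain, is_grid)
        values = np.full((16, 24), 50.0)
        with pytest.raises(DegenerateGridError):
            pp.build_reference_surface(values, layout)


class TestGridNormalise:
    def test_plane_self_normalises_to_one(self):
        layout = pp.make_layout(384)
        values = 40.0 + 2.0 * np.arange(16)[:, None] + np.zeros((16, 24))
        corrected = pp.grid_normalise(values, layout)
        assert np.allclose(corrected, 1.0, atol=1e-9)

    def test_doubled_colony_scores_two(self):
        layout = pp.make_layout(384)
        values = np.full((16, 24), 50.0)
        values[1, 1] = 100.0  # non-grid position
        corrected = pp.grid_normalise(values, layout)
        assert corrected[1, 1] == pytest.approx(2.0, rel=1e-9)
        assert corrected[3, 3] == pytest.approx(1.0, rel=1e-9)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, k):
        layout = pp.make_layout(384)
        rng = np.random.default_rng(0)
        values = rng.lognormal(4, 0.1, (16, 24))
        a = pp.grid_normalise(values, layout)
        b = pp.grid_normalise(k * values, layout)
        assert np.allclose(a, b, rtol=1e-9)

    def test_gradient_cancels_for_all_strains(self):
        """Corrected values are position-independent under a shared gradient."""
        from phenoplate.synthetic import simulate_wild_strain_plate
        from scipy.stats import pearsonr

        layout, values, _ = simulate_wild_strain_plate(seed=3)
        corrected = pp.grid_normalise(values, layout)
        finite = np.isfinite(corrected)
        rows = np.repeat(np.arange(32)[:, None], 48, axis=1)
        r = pearsonr(corrected[finite], rows[finite]).statistic
        assert abs(r) <= 0.05

    def test_effect_recovery_within_5pct(self):
        """Known relative-fitness classes recovered under gradient + noise."""
        layout = pp.make_layout(384)
        rng = np.random.default_rng(42)
        free = np.argwhere(~layout.is_grid)
        effects = {"grid": 1.0}
        fvals = [0.5, 0.8, 1.0, 1.2]
        for k, idx in enumerate(rng.permutation(len(free))):
            r, c = free[idx]
            effects[layout.strain[r, c]] = fvals[k % 4] if k < 128 else 1.0
        cfg = SimulationConfig(
            format=384, gradient_amplitude=0.4, noise_cv=0.05, seed=7,
            strain_effects=effects,
        )
        values, _ = simulate_fitness_plate(cfg, layout)
        corrected = pp.grid_normalise(values, layout)
        df = pd.DataFrame(
            {
                "f": [effects[s] for s in layout.strain.ravel()],
                "corrected": corrected.ravel(),
                "grid": layout.is_grid.ravel(),
            }
        )
        means = df[~df.grid].groupby("f")["corrected"].mean()
        for f in fvals:
            assert means[f] == pytest.approx(f, rel=0.05)


class TestRowcolMedianNormalise:
    def test_constant_plate(self):
        assert np.allclose(pp.rowcol_median_normalise(np.full((5, 7), 7.0)), 1.0)

    def test_hand_computed_2x2(self):
        """[[2,4],[6,12]]: row medians (3,9), then column medians -> all 1."""
        out = pp.rowcol_median_normalise(np.array([[2.0, 4.0], [6.0, 12.0]]))
        assert np.allclose(out, 1.0, atol=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            values = rng.lognormal(0, 0.3, (16, 24))
            assert np.allclose(
                pp.rowcol_median_normalise(values), brute_force_rowcol(values), atol=1e-12
            )

    def test_median_robust_to_minority_effects(self):
        """Neutral strains stay at 1 when 10% of strains have effect 0.5."""
        rng = np.random.default_rng(2)
        values = np.outer(np.linspace(1, 2, 16), np.ones(24)) * 100.0
        affected = rng.uniform(size=(16, 24)) < 0.10
        values[affected] *= 0.5
        out = pp.rowcol_median_normalise(values)
        assert np.nanmedian(out[~affected]) == pytest.approx(1.0, abs=0.02)
        assert np.nanmedian(out[affected]) == pytest.approx(0.5, abs=0.05)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_idempotent_on_separable_plates(self, seed):
        """Row x column (rank-1) effects are removed in one pass: the result
        is all ones, and a second application leaves it untouched."""
        rng = np.random.default_rng(seed)
        values = np.outer(rng.lognormal(0, 0.4, 8), rng.lognormal(0, 0.4, 12))
        once = pp.rowcol_median_normalise(values)
        assert np.allclose(once, 1.0, atol=1e-12)
        assert np.allclose(pp.rowcol_median_normalise(once), once, atol=1e-12)

    def test_zero_median_raises(self):
        values = np.ones((3, 3))
        values[1, :] = 0.0
        with pytest.raises(ZeroMedianError):
            pp.rowcol_median_normalise(values)

    def test_missing_rows_propagate(self):
        values = np.ones((4, 4))
        values[2, :] = np.nan
        out = pp.rowcol_median_normalise(values)
        assert np.isnan(out[2, :]).all()
        assert np.allclose(out[[0, 1, 3], :], 1.0)


class TestAggregateExperiment:
    def _write_experiment(self, tmp_path, seed=0):
        cfg = SimulationConfig(seed=seed, noise_cv=0.05, gradient_amplitude=0.3)
        return simulate_experiment(
            cfg, tmp_path, conditions=["ctrl", "drug"], n_replicates=1, n_strains=50
        )

    def test_method_none_keeps_raw(self, tmp_path):
        edt = self._write_experiment(tmp_path)
        table = pp.aggregate_experiment(edt, method="none", value_column="value")
        assert len(table) == 2 * 16 * 24
        finite = table["raw_value"].notna() & (table["raw_value"] != 0)
        assert np.allclose(
            table.loc[finite, "corrected_value"], table.loc[finite, "raw_value"]
        )

    def test_deterministic_reload(self, tmp_path):
        edt = self._write_experiment(tmp_path)
        a = pp.aggregate_experiment(edt, method="grid+rowcol", value_column="value")
        b = pp.aggregate_experiment(edt, method="grid+rowcol", value_column="value")
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_per_plate_method_override(self, tmp_path):
        edt_path = self._write_experiment(tmp_path)
        edt = pd.read_csv(edt_path)
        edt["method"] = ["grid+rowcol", "rowcol"]
        table = pp.aggregate_experiment(
            pd.DataFrame(edt).assign(
                data_path=[str(tmp_path / p) for p in edt["data_path"]],
                layout_path=str(tmp_path / "layout.csv"),
                grid_path=str(tmp_path / "layout_grid.csv"),
            ),
            method="grid",
            value_column="value",
        )
        methods = table.groupby("plate_id")["normalisation_method"].first()
        assert set(methods) == {"grid+rowcol", "rowcol"}

    def test_missing_file_names_plate(self, tmp_path):
        edt = pd.DataFrame({"plate_id": ["p1"], "data_path": ["nope.csv"]})
        with pytest.raises(FileNotFoundError, match="p1"):
            pp.aggregate_experiment(edt, method="none")

    def test_shape_mismatch_raises(self, tmp_path):
        # matrix dialect: data matrix shape must equal the layout shape
        pd.DataFrame(np.ones((4, 6))).to_csv(tmp_path / "plate.csv",
                                             header=False, index=False)
        layout = pp.make_layout(96, grid_scheme="none")
        layout.to_csv(tmp_path / "layout.csv", tmp_path / "grid.csv")
        edt = pd.DataFrame(
            {
                "plate_id": ["p1"],
                "data_path": [str(tmp_path / "plate.csv")],
                "layout_path": [str(tmp_path / "layout.csv")],
            }
        )
        with pytest.raises(DimensionMismatchError):
            pp.aggregate_experiment(edt, method="none", data_format="matrix")

    def test_long_data_out_of_layout_bounds_raises(self, tmp_path):
        data = pd.DataFrame({"row": [0, 11], "col": [0, 30], "value": [1.0, 2.0]})
        data.to_csv(tmp_path / "plate.csv", index=False)
        layout = pp.make_layout(96, grid_scheme="none")
        layout.to_csv(tmp_path / "layout.csv", tmp_path / "grid.csv")
        edt = pd.DataFrame(
            {
                "plate_id": ["p1"],
                "data_path": [str(tmp_path / "plate.csv")],
                "layout_path": [str(tmp_path / "layout.csv")],
            }
        )
        with pytest.raises(DimensionMismatchError):
            pp.aggregate_experiment(edt, method="none")

    def test_missing_values_conserved_and_flagged(self, tmp_path):
        """Normalisation never un-misses a value; new gaps carry a flag."""
        edt = self._write_experiment(tmp_path)
        raw = pp.aggregate_experiment(edt, method="none", value_column="value")
        corrected = pp.aggregate_experiment(edt, method="grid+rowcol", value_column="value")
        assert corrected["corrected_value"].isna().sum() >= raw["corrected_value"].isna().sum()
        new_missing = corrected["corrected_value"].isna() & corrected["raw_value"].notna()
        assert (corrected.loc[new_missing, "qc_flags"] != "").all()
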