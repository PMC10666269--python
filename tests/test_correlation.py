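import numpy as np
import pytest

from oxidna.correlation import (
    DegenerateWindowError,
    ScatterSet,
    build_scatter,
    correlation_matrix,
    cross_strand_counts,
    grid_reduce,
    regime_filter,
    regress_classify,
)
from oxidna.ensemble import STEP_PARAMETER_NAMES
from oxidna.synthetic import GeneratorSpec, PlantSpec, gen_ensemble

from conftest import make_ensemble


def scatter_from_points(pts, x_sigma=1.0, y_sigma=1.0, x_mean=None, y_mean=None):
    pts = np.asarray(pts, dtype=float)
    return ScatterSet(
        x_name="twist",
        y_name="shift",
        points=pts,
        x_mean=float(pts[:, 0].mean()) if x_mean is None else x_mean,
        x_sigma=x_sigma,
        y_mean=float(pts[:, 1].mean()) if y_mean is None else y_mean,
        y_sigma=y_sigma,
    )


class TestBuildScatter:
    def test_point_count_is_frames_times_steps(self):
        e = gen_ensemble(GeneratorSpec("s", "CTCT", n_frames=50, seed=1, negative_jitter_frac=0))
        s = build_scatter(e, "twist", "shift")
        assert s.points.shape[0] <= 50 * 3
        assert s.points.shape[0] >= 0.95 * 50 * 3  # 2.5 sigma keeps ~99%

    def test_constant_parameter_degenerate(self):
        # two-base frames: a single identical step per frame, so zero variance
        e = make_ensemble(n_frames=5, sequence="CT", dq=(0.6, 0.4))
        with pytest.raises(DegenerateWindowError):
            build_scatter(e, "twist", "shift")

    def test_same_axis_rejected(self):
        e = make_ensemble(n_frames=2)
        with pytest.raises(ValueError):
            build_scatter(e, "twist", "twist")

    def test_points_inside_one_sigma_all_kept(self):
        e = gen_ensemble(GeneratorSpec("s", "CTCT", n_frames=30, seed=2, negative_jitter_frac=0))
        s = build_scatter(e, "rise", "roll")
        (x_lo, x_hi), (y_lo, y_hi) = s.x_limits, s.y_limits
        assert np.all((s.points[:, 0] >= x_lo) & (s.points[:, 0] <= x_hi))
        assert np.all((s.points[:, 1] >= y_lo) & (s.points[:, 1] <= y_hi))


class TestGridReduce:
    def test_single_point(self):
        g = grid_reduce(scatter_from_points([(0.0, 0.0, 1.5)]))
        assert g.points.shape[0] == 1

    def test_cell_keeps_max_n(self):
        # both points sit well inside the same grid cell of the centered window
        g = grid_reduce(scatter_from_points([(0.30, 0.30, 1.2), (0.32, 0.32, 1.9)], x_mean=0.0, y_mean=0.0))
        assert g.points.shape[0] == 1
        assert g.points[0, 2] == 1.9

    @pytest.mark.parametrize("seed", [0, 1])
    def test_equals_brute_force_cell_scan(self, seed):
        """Grid reduction must agree with an exhaustive per-cell max scan."""
        rng = np.random.default_rng(seed)
        pts = np.column_stack(
            [rng.normal(0, 1, 5000), rng.normal(0, 2, 5000), rng.uniform(1, 2, 5000)]
        )
        s = ScatterSet("twist", "shift", pts, 0.0, 1.0, 0.0, 2.0)
        got = grid_reduce(s).points
        # oracle: independent exhaustive scan over all 400 cells
        (x_lo, x_hi), (y_lo, y_hi) = s.x_limits, s.y_limits
        inside = pts[
            (pts[:, 0] >= x_lo) & (pts[:, 0] <= x_hi) & (pts[:, 1] >= y_lo) & (pts[:, 1] <= y_hi)
        ]
        expected = []
        for i in range(20):
            for j in range(20):
                cx_lo, cx_hi = x_lo + i * (x_hi - x_lo) / 20, x_lo + (i + 1) * (x_hi - x_lo) / 20
                cy_lo, cy_hi = y_lo + j * (y_hi - y_lo) / 20, y_lo + (j + 1) * (y_hi - y_lo) / 20
                mask = (
                    (inside[:, 0] >= cx_lo)
                    & (inside[:, 0] < cx_hi if i < 19 else inside[:, 0] <= cx_hi)
                    & (inside[:, 1] >= cy_lo)
                    & (inside[:, 1] < cy_hi if j < 19 else inside[:, 1] <= cy_hi)
                )
                cell = inside[mask]
                if len(cell):
                    expected.append(cell[np.argmax(cell[:, 2])])
        expected = np.array(expected)
        assert got.shape == expected.shape
        order_g = np.lexsort(got.T)
        order_e = np.lexsort(expected.T)
        assert np.allclose(got[order_g], expected[order_e])

    def test_at_most_400_points(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.normal(0, 1, 10000), rng.normal(0, 1, 10000), rng.uniform(1, 2, 10000)])
        s = ScatterSet("rise", "tilt", pts, 0.0, 1.0, 0.0, 1.0)
        assert grid_reduce(s).points.shape[0] <= 400


class TestRegimeFilter:
    @pytest.fixture
    def grid(self):
        pts = np.array([(0, 0, 1.8), (1, 1, 1.75), (2, 2, 1.2)], dtype=float)
        return grid_reduce(ScatterSet("twist", "shift", pts, 1.0, 1.0, 1.0, 1.0))

    def test_high_keeps_above_threshold(self, grid):
        assert regime_filter(grid, "high").shape[0] == 2

    def test_low_keeps_none_here(self, grid):
        assert regime_filter(grid, "low").shape[0] == 0

    def test_all_uses_full_scatter(self, grid):
        assert regime_filter(grid, "all").shape[0] == 3

    def test_unknown_regime(self, grid):
        with pytest.raises(ValueError):
            regime_filter(grid, "medium")


class TestRegressClassify:
    def test_exact_diagonal_is_positive_slope_one(self):
        """Points on the (-2.5s,-2.5s) -> (2.5s,2.5s) diagonal define s_norm = 1."""
        for sx, sy in [(1.0, 1.0), (0.5, 40.0), (12.0, 0.8)]:
            t = np.linspace(-2.5, 2.5, 30)
            pts = np.column_stack([sx * t, sy * t, np.full_like(t, 1.9)])
            c = regress_classify(pts, sx, sy)
            assert c.s_norm == pytest.approx(1.0)
            assert c.label == "positive"

    def test_exact_antidiagonal_is_negative(self):
        t = np.linspace(-2.5, 2.5, 30)
        pts = np.column_stack([2.0 * t, -7.0 * t, np.full_like(t, 1.9)])
        c = regress_classify(pts, 2.0, 7.0)
        assert c.s_norm == pytest.approx(-1.0)
        assert c.label == "negative"

    def test_s_norm_invariant_under_unit_rescaling(self):
        """Angstrom -> nm and degree -> radian rescaling leaves s_norm fixed."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2, 200)
        y = 0.6 * x + rng.normal(0, 1, 200)
        pts = np.column_stack([x, y, np.full(200, 1.8)])
        c1 = regress_classify(pts, x.std(), y.std())
        scaled = np.column_stack([x / 10.0, np.radians(y), pts[:, 2]])
        c2 = regress_classify(scaled, x.std() / 10.0, np.radians(y).std())
        assert c2.s_norm == pytest.approx(c1.s_norm, rel=1e-9)

    def test_independent_cloud_labeled_none(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.normal(0, 1, 400), rng.normal(0, 1, 400), np.full(400, 1.8)])
        assert regress_classify(pts, 1.0, 1.0).label == "none"

    def test_minimum_point_gate(self):
        t = np.linspace(-1, 1, 5)
        pts = np.column_stack([t, t, np.full_like(t, 1.9)])
        assert regress_classify(pts, 1.0, 1.0, min_points=10).label == "none"

    def test_empty_input(self):
        c = regress_classify(np.empty((0, 3)), 1.0, 1.0)
        assert c.label == "none"
        assert c.n_points == 0


class TestCorrelationMatrix:
    def test_planted_coupling_recovered_in_high_regime(self):
        spec = GeneratorSpec(
            "s", "CTCT", n_frames=200, seed=11, charge_model=[6.0] * 4,
            plant=PlantSpec(pair=("twist", "shift"), rho=0.85, condition="high_n"),
        )
        m = correlation_matrix(gen_ensemble(spec), regime="high")
        assert m.label("twist", "shift") == "positive"
        assert m.label("shift", "twist") == "positive"  # symmetric lookup

    def test_negative_plant_recovered(self):
        spec = GeneratorSpec(
            "s", "CTCT", n_frames=200, seed=12, charge_model=[6.0] * 4,
            plant=PlantSpec(pair=("rise", "tilt"), rho=-0.85, condition="high_n"),
        )
        m = correlation_matrix(gen_ensemble(spec), regime="high")
        assert m.label("rise", "tilt") == "negative"

    def test_independent_ensemble_all_none(self):
        e = gen_ensemble(GeneratorSpec("s", "CTCT", n_frames=200, seed=13, charge_model=[6.0] * 4))
        m = correlation_matrix(e, regime="high")
        assert all(c.label == "none" for c in m.cells.values())

    def test_matrix_covers_all_fifteen_pairs(self):
        e = gen_ensemble(GeneratorSpec("s", "CTCT", n_frames=50, seed=14))
        m = correlation_matrix(e)
        assert len(m.cells) == 15
        names = set(STEP_PARAMETER_NAMES)
        assert all(a in names and b in names for a, b in m.cells)


class TestCrossStrandCounts:
    def _matrix_with(self, labels):
        e = gen_ensemble(GeneratorSpec("s", "CTCT", n_frames=30, seed=15))
        m = correlation_matrix(e)
        cells = dict(m.cells)
        from dataclasses import replace

        for pair, label in labels.items():
            cells[pair] = replace(cells[pair], label=label)
        return type(m)(strand_id=m.strand_id, regime=m.regime, cells=cells)

    def test_all_positive_counts_ten(self):
        ms = [self._matrix_with({("shift", "twist"): "positive"}) for _ in range(10)]
        df = cross_strand_counts(ms)
        row = df[(df.x_name == "shift") & (df.y_name == "twist")].iloc[0]
        assert row.positive == 10

    def test_nine_positive_one_none(self):
        ms = [self._matrix_with({("shift", "twist"): "positive"}) for _ in range(9)]
        ms.append(self._matrix_with({}))
        df = cross_strand_counts(ms)
        row = df[(df.x_name == "shift") & (df.y_name == "twist")].iloc[0]
        assert row.positive == 9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cross_strand_counts([])
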