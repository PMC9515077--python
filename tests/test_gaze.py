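import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fillin import gaze
from fillin.synth import GazeRecord, simulate_gaze


def record_from_xy(x, y, rate_hz=60.0):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return GazeRecord(t_s=np.arange(len(x)) / rate_hz, x_deg=x, y_deg=y,
                      valid=np.ones(len(x), bool), rate_hz=rate_hz)


def standardized_sample(n=500, rho=0.0, seed=0):
    """Sample whose *sample* moments are exactly (1, 1, rho)."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a = (a - a.mean()) / a.std(ddof=1)
    b = b - b.mean()
    b -= (b @ a) / (a @ a) * a  # exact zero sample correlation
    b /= b.std(ddof=1)
    x = a
    y = rho * a + np.sqrt(1 - rho**2) * b
    y /= y.std(ddof=1)
    return x, y


class TestClean:
    def test_stationary_gaze_is_identity(self):
        g = record_from_xy(np.zeros(100), np.zeros(100))
        cleaned = gaze.clean(g)
        assert cleaned.n == 100

    def test_sixty_deg_per_s_jump_removed(self):
        x = np.zeros(50)
        x[25:] = 1.0  # 1 deg in one 60 Hz frame = 60 deg/s
        cleaned = gaze.clean(record_from_xy(x, np.zeros(50)))
        assert cleaned.n == 49
        assert 25 / 60.0 not in cleaned.t_s

    def test_off_screen_samples_removed(self):
        x = np.zeros(20)
        x[5] = 30.0
        cleaned = gaze.clean(record_from_xy(x, np.zeros(20)),
                             screen_bounds=(14.0, 10.5))
        assert cleaned.n == 19

    def test_matches_brute_force_filter_oracle(self):
        g = simulate_gaze(duration_s=60, blink_rate=0.3, saccade_rate=0.3, seed=0)
        cleaned = gaze.clean(g)
        # oracle: sequential scan applying the same three rules
        keep = []
        prev = None  # index of last kept sample
        for i in range(g.n):
            if not g.valid[i] or np.isnan(g.x_deg[i]) or np.isnan(g.y_deg[i]):
                continue
            if abs(g.x_deg[i]) > 14.0 or abs(g.y_deg[i]) > 10.5:
                continue
            if prev is not None and i - prev == 1:
                v = np.hypot(g.x_deg[i] - g.x_deg[prev],
                             g.y_deg[i] - g.y_deg[prev]) * g.rate_hz
                if v > 30.0:
                    prev = i  # sample discarded, but it still ends a movement
                    continue
            keep.append(i)
            prev = i
        assert cleaned.n == len(keep)
        assert np.allclose(cleaned.x_deg, g.x_deg[keep])

    def test_everything_removed_raises(self):
        g = record_from_xy(np.full(10, 99.0), np.zeros(10))
        with pytest.raises(ValueError, match="survive"):
            gaze.clean(g)


class TestBcea:
    def test_closed_form_unit_circle(self):
        x, y = standardized_sample(n=400, rho=0.0, seed=1)
        b = gaze.bcea(record_from_xy(x, y), k=1.0)
        assert b.bcea == pytest.approx(2 * np.pi, rel=1e-9)

    def test_probability_area_at_k1_is_63_2_percent(self):
        assert gaze.probability_area(1.0) * 100 == pytest.approx(63.2, abs=0.05)

    def test_correlation_shrinks_area(self):
        x, y = standardized_sample(n=400, rho=0.6, seed=2)
        b = gaze.bcea(record_from_xy(x, y), k=1.0)
        assert b.bcea == pytest.approx(2 * np.pi * np.sqrt(1 - b.rho**2), rel=1e-6)
        assert b.bcea < 2 * np.pi

    def test_containment_fraction_matches_probability_area(self):
        rng = np.random.default_rng(3)
        n = 10000
        cov = np.array([[0.09, 0.018], [0.018, 0.0625]])
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        rec = record_from_xy(xy[:, 0], xy[:, 1])
        for k in (0.5, 1.0, 2.0):
            b = gaze.bcea(rec, k=k)
            d = xy - np.asarray(b.center)
            m2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(b.cov), d)
            frac = np.mean(m2 <= 2 * k)
            assert frac == pytest.approx(1 - np.exp(-k), abs=0.01)

    def test_scaling_property(self):
        x, y = standardized_sample(n=300, rho=0.3, seed=4)
        b1 = gaze.bcea(record_from_xy(x, y))
        b2 = gaze.bcea(record_from_xy(2.5 * x, 2.5 * y))
        assert b2.bcea == pytest.approx(2.5**2 * b1.bcea, rel=1e-9)

    def test_axis_swap_invariance(self):
        x, y = standardized_sample(n=300, rho=0.4, seed=5)
        y = 1.7 * y
        assert gaze.bcea(record_from_xy(x, y)).bcea == pytest.approx(
            gaze.bcea(record_from_xy(y, x)).bcea, rel=1e-12)

    def test_degenerate_zero_variance(self):
        b = gaze.bcea(record_from_xy(np.zeros(10), np.arange(10.0)))
        assert b.bcea == 0.0 and b.degenerate


class TestEllipseContains:
    def test_own_center_inside(self):
        x, y = standardized_sample(n=100, seed=6)
        b = gaze.bcea(record_from_xy(x, y))
        assert gaze.ellipse_contains(b, b.center)

    def test_ten_sigma_point_outside(self):
        x, y = standardized_sample(n=100, seed=7)
        b = gaze.bcea(record_from_xy(x, y))
        assert not gaze.ellipse_contains(b, (10.0, 10.0))

    def test_agrees_with_rasterized_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            xy = rng.multivariate_normal(
                rng.normal(0, 0.2, 2),
                np.array([[0.1, 0.03], [0.03, 0.06]]) * rng.uniform(0.5, 2),
                size=200)
            b = gaze.bcea(record_from_xy(xy[:, 0], xy[:, 1]), k=1.0)
            # oracle: the k-contour in the eigenbasis is an axis-aligned
            # ellipse; test points via the parametric form
            evals, evecs = np.linalg.eigh(b.cov)
            axes = np.sqrt(2 * b.k * evals)
            pts = rng.normal(b.center, 0.5, size=(200, 2))
            rel = (pts - b.center) @ evecs
            inside_oracle = (rel[:, 0] / axes[0])**2 + (rel[:, 1] / axes[1])**2 <= 1
            inside = np.array([gaze.ellipse_contains(b, p) for p in pts])
            assert np.array_equal(inside, inside_oracle)

    def test_degenerate_rejected(self):
        b = gaze.bcea(record_from_xy(np.zeros(10), np.arange(10.0)))
        with pytest.raises(ValueError):
            gaze.ellipse_contains(b, (0.0, 0.0))


class TestBootstrapContrast:
    def test_identical_conditions_not_significant(self):
        v = np.array([1.0, 1.2, 0.9, 1.1, 1.05, 0.95])
        res = gaze.bootstrap_contrast(v, v, n_iter=1000, seed=0)
        assert res["mean_diff"] == 0.0
        assert res["p"] > 0.5

    def test_huge_separation_extreme_p(self):
        a = np.array([10.0, 10.1, 9.9, 10.05, 9.95, 10.0])
        b = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 1.0])
        res = gaze.bootstrap_contrast(a, b, n_iter=1000, seed=1)
        # sign-resampling null with n = 6 pairs: the one-tail p floor is the
        # all-positive-signs probability 2^-6 ~ 0.016, below the 0.025 level
        assert res["p_upper"] == pytest.approx(2**-6, abs=0.01)
        assert res["p_upper"] < 0.025

    def test_validity_on_null_simulations(self):
        # rejection rate at the nominal two-tail level over 500 null draws
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            a = rng.standard_normal(6)
            b = rng.standard_normal(6)
            res = gaze.bootstrap_contrast(a, b, n_iter=400, seed=rng)
            if min(res["p_upper"], res["p_lower"]) < 0.025:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_needs_pairs(self):
        with pytest.raises(ValueError):
            gaze.bootstrap_contrast(np.array([1.0]), np.array([2.0]))


class TestRmAnova:
    def test_equals_squared_paired_t(self):
        from scipy import stats
        rng = np.random.default_rng(3)
        a, b = rng.normal(2, 1, 6), rng.normal(2, 1, 6)
        res = gaze.rm_anova_2(a, b)
        t, p = stats.ttest_rel(a, b)
        assert res["F"] == pytest.approx(t**2, rel=1e-10)
        assert res["p"] == pytest.approx(p, rel=1e-10)

    def test_identical_vectors_give_zero_f(self):
        v = np.array([1.0, 2.0, 3.0])
        assert gaze.rm_anova_2(v, v)["F"] == 0.0

    def test_df_structure_for_six_participants(self):
        rng = np.random.default_rng(4)
        res = gaze.rm_anova_2(rng.normal(size=6), rng.normal(size=6))
        assert res["df"] == (1, 5)

    def test_matches_pingouin_reference(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(5)
        a, b = rng.normal(1, 0.3, 8), rng.normal(1.2, 0.3, 8)
        res = gaze.rm_anova_2(a, b)
        df = pd.DataFrame({
            "subject": list(range(8)) * 2,
            "cond": ["a"] * 8 + ["b"] * 8,
            "y": np.concatenate([a, b]),
        })
        ref = pg.rm_anova(data=df, dv="y", within="cond", subject="subject")
        assert res["F"] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res["p"] == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)


class TestDensityMap:
    def test_single_point_peaks_at_one(self):
        g = record_from_xy(np.full(50, 0.3), np.full(50, -0.2))
        d = gaze.density_map(g)
        assert d["density"].max() == 1.0
        ix, iy = np.unravel_index(np.argmax(d["density"]), d["density"].shape)
        xc = 0.5 * (d["x_edges"][ix] + d["x_edges"][ix + 1])
        yc = 0.5 * (d["y_edges"][iy] + d["y_edges"][iy + 1])
        assert xc == pytest.approx(0.3, abs=0.05)
        assert yc == pytest.approx(-0.2, abs=0.05)

    def test_max_normalized_for_any_input(self):
        g = simulate_gaze(duration_s=30, seed=9)
        d = gaze.density_map(gaze.clean(g))
        assert d["density"].max() == pytest.approx(1.0)

    def test_centroid_near_sample_mean(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0.2, 0.3, 2000)
        y = rng.normal(-0.1, 0.3, 2000)
        d = gaze.density_map(record_from_xy(x, y))
        xs = 0.5 * (d["x_edges"][:-1] + d["x_edges"][1:])
        ys = 0.5 * (d["y_edges"][:-1] + d["y_edges"][1:])
        w = d["density"] / d["density"].sum()
        cx = (w.sum(axis=1) * xs).sum()
        cy = (w.sum(axis=0) * ys).sum()
        bin_w = xs[1] - xs[0]
        assert cx == pytest.approx(x.mean(), abs=bin_w)
        assert cy == pytest.approx(y.mean(), abs=bin_w)


class TestGazeCsv:
    def test_round_trip(self, tmp_path):
        g = simulate_gaze(duration_s=5, seed=11)
        gaze.write_gaze_csv(g, tmp_path / "g.csv")
        back = gaze.read_gaze_csv(tmp_path / "g.csv")
        assert np.allclose(back.x_deg, g.x_deg, equal_nan=True)
        assert np.array_equal(back.valid, g.valid)
        assert back.rate_hz == pytest.approx(60.0)

    def test_pixel_dialect(self, tmp_path):
        import pandas as pd
        pd.DataFrame({"t": [0.0, 1 / 60], "x_px": [10.0, 20.0],
                      "y_px": [0.0, -10.0]}).to_csv(tmp_path / "px.csv", index=False)
        g = gaze.read_gaze_csv(tmp_path / "px.csv", deg_per_px=0.035)
        assert g.x_deg[1] == pytest.approx(0.7)
        with pytest.raises(ValueError, match="deg_per_px"):
            gaze.read_gaze_csv(tmp_path / "px.csv")


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.1, 3.0))
def test_property_bcea_scales_quadratically(seed, s):
    rng = np.random.default_rng(seed)
    x, y = rng.standard_normal(50), rng.standard_normal(50)
    b1 = gaze.bcea(record_from_xy(x, y))
    b2 = gaze.bcea(record_from_xy(s * x, s * y))
    assert b2.bcea == pytest.approx(s * s * b1.bcea, rel=1e-6)
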