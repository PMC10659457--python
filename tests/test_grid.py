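"""Grid nesting checks and exact zonal aggregation against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from urbansat import (
    GridNestingError,
    GridSpec,
    RasterLayer,
    aggregate_fraction,
    aggregate_mean,
    aggregate_sum,
    aggregate_threshold_fraction,
    check_nesting,
)
from urbansat.grid import read_ascii_grid, write_ascii_grid

from conftest import make_coarse_grid, make_fine_grid, random_categorical, random_continuous


# ---------------------------------------------------------------------------
# brute-force zonal oracle: assigns each fine pixel to a coarse cell by its
# center coordinates and explicit interval membership, then loops

def _oracle_zonal(layer, coarse, stat, **kw):
    fine = layer.grid
    sums = np.zeros(coarse.shape)
    hits = np.zeros(coarse.shape)
    n_valid = np.zeros(coarse.shape, dtype=int)
    valid = layer.valid_mask()
    for i in range(fine.n_rows):
        for j in range(fine.n_cols):
            x, y = fine.cell_center(i, j)
            cell = None
            for r in range(coarse.n_rows):
                y_top = coarse.origin_y - r * coarse.cell_h
                y_bot = y_top - coarse.cell_h
                if not (y_bot < y <= y_top):
                    continue
                for c in range(coarse.n_cols):
                    x_lo = coarse.origin_x + c * coarse.cell_w
                    if x_lo <= x < x_lo + coarse.cell_w:
                        cell = (r, c)
                        break
                break
            assert cell is not None
            if not valid[i, j]:
                continue
            r, c = cell
            n_valid[r, c] += 1
            v = layer.values[i, j]
            if stat == "fraction":
                hits[r, c] += int(v in kw["codes"])
            elif stat == "threshold":
                if kw["direction"] == "gt":
                    hits[r, c] += int(v > kw["threshold"])
                else:
                    hits[r, c] += int(v >= kw["threshold"])
            else:
                sums[r, c] += v
    rep = check_nesting(fine, coarse)
    block = rep.factor_x * rep.factor_y
    cov_min = kw.get("coverage_min", 0.0)
    out = np.full(coarse.shape, np.nan)
    for r in range(coarse.n_rows):
        for c in range(coarse.n_cols):
            if n_valid[r, c] == 0 or n_valid[r, c] < cov_min * block:
                continue
            if stat in ("fraction", "threshold"):
                out[r, c] = hits[r, c] / n_valid[r, c]
            elif stat == "sum":
                out[r, c] = sums[r, c]
            else:
                out[r, c] = sums[r, c] / n_valid[r, c]
    return out


class TestCheckNesting:
    def test_integer_factors(self):
        fine = make_fine_grid(30, 40, cell=0.001)
        coarse = GridSpec(10.0, 50.0, 0.01, 0.01, 3, 4)
        rep = check_nesting(fine, coarse)
        assert (rep.factor_x, rep.factor_y) == (10, 10)

    def test_identity_grids(self):
        g = make_fine_grid()
        rep = check_nesting(g, g)
        assert (rep.factor_x, rep.factor_y) == (1, 1)

    def test_non_integer_ratio(self):
        fine = GridSpec(10.0, 50.0, 0.003, 0.003, 10, 10)
        coarse = GridSpec(10.0, 50.0, 0.01, 0.01, 3, 3)
        with pytest.raises(GridNestingError, match="non-integer"):
            check_nesting(fine, coarse)

    def test_origin_offset(self):
        fine = make_fine_grid()
        coarse = GridSpec(10.0005, 50.0, 0.01, 0.01, 3, 3)
        with pytest.raises(GridNestingError, match="origin"):
            check_nesting(fine, coarse)

    def test_crs_mismatch(self):
        fine = make_fine_grid()
        coarse = GridSpec(10.0, 50.0, 0.01, 0.01, 3, 3, crs="EPSG:32633")
        with pytest.raises(GridNestingError, match="CRS"):
            check_nesting(fine, coarse)

    def test_coarse_must_cover_fine(self):
        fine = make_fine_grid(30, 30)
        coarse = GridSpec(10.0, 50.0, 0.01, 0.01, 2, 3)
        with pytest.raises(GridNestingError, match="cover"):
            check_nesting(fine, coarse)


class TestAggregators:
    def setup_method(self):
        self.fine = make_fine_grid(20, 20)
        self.coarse = make_coarse_grid(self.fine, 10)

    def test_fraction_all_one_code(self):
        layer = RasterLayer(
            self.fine, np.full(self.fine.shape, 50), nodata=-1, kind="categorical"
        )
        out = aggregate_fraction(layer, self.coarse, {50})
        assert np.all(out.values == 1.0)

    def test_fraction_disjoint_codes(self):
        layer = RasterLayer(
            self.fine, np.full(self.fine.shape, 50), nodata=-1, kind="categorical"
        )
        out = aggregate_fraction(layer, self.coarse, {80})
        assert np.all(out.values == 0.0)

    def test_fraction_known_count(self):
        vals = np.full((10, 10), 40)
        vals.flat[:37] = 111  # 37 forest pixels in the single 10x10 cell
        grid = make_fine_grid(10, 10)
        coarse = make_coarse_grid(grid, 10)
        layer = RasterLayer(grid, vals, nodata=-1, kind="categorical")
        out = aggregate_fraction(layer, coarse, {111})
        assert out.values[0, 0] == pytest.approx(0.37)

    def test_fraction_empty_codes_error(self):
        layer = RasterLayer(
            self.fine, np.full(self.fine.shape, 50), nodata=-1, kind="categorical"
        )
        with pytest.raises(ValueError, match="empty"):
            aggregate_fraction(layer, self.coarse, set())

    def test_sum_uniform(self):
        layer = RasterLayer(self.fine, np.full(self.fine.shape, 3.0))
        out = aggregate_sum(layer, self.coarse)
        assert np.allclose(out.values, 300.0)

    def test_sum_conservation_with_nodata(self):
        rng = np.random.default_rng(0)
        layer = random_continuous(self.fine, rng, nodata_frac=0.2)
        out = aggregate_sum(layer, self.coarse)
        assert np.nansum(out.values) == pytest.approx(
            np.nansum(layer.values), rel=1e-12
        )

    def test_all_nodata_cell_is_nodata(self):
        vals = np.ones(self.fine.shape)
        vals[:10, :10] = np.nan
        layer = RasterLayer(self.fine, vals)
        for agg in (aggregate_sum, aggregate_mean):
            out = agg(layer, self.coarse)
            assert np.isnan(out.values[0, 0])
            assert np.isfinite(out.values[1, 1])

    def test_sum_rejects_categorical(self):
        layer = RasterLayer(
            self.fine, np.full(self.fine.shape, 50), nodata=-1, kind="categorical"
        )
        with pytest.raises(TypeError):
            aggregate_sum(layer, self.coarse)

    def test_mean_uniform(self):
        layer = RasterLayer(self.fine, np.full(self.fine.shape, 7.5))
        out = aggregate_mean(layer, self.coarse)
        assert np.allclose(out.values, 7.5)

    def test_threshold_examples(self):
        grid = make_fine_grid(2, 2)
        coarse = make_coarse_grid(grid, 2)
        layer = RasterLayer(grid, np.array([[0.1, 0.3], [0.25, 0.15]]))
        out = aggregate_threshold_fraction(layer, coarse, 0.2, "gt")
        assert out.values[0, 0] == pytest.approx(0.5)
        above = aggregate_threshold_fraction(layer, coarse, 0.9, "gt")
        assert above.values[0, 0] == 0.0
        all_over = aggregate_threshold_fraction(
            RasterLayer(grid, np.full((2, 2), 0.5)), coarse, 0.2, "gt"
        )
        assert all_over.values[0, 0] == 1.0

    def test_ge_includes_boundary(self):
        grid = make_fine_grid(2, 2)
        coarse = make_coarse_grid(grid, 2)
        layer = RasterLayer(grid, np.full((2, 2), 0.2))
        assert aggregate_threshold_fraction(layer, coarse, 0.2, "gt").values[0, 0] == 0.0
        assert aggregate_threshold_fraction(layer, coarse, 0.2, "ge").values[0, 0] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        """All four aggregators agree exactly with the per-pixel double loop."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        factor = int(rng.choice([2, 5]))
        fine = make_fine_grid(n, n)
        coarse = make_coarse_grid(fine, factor)
        if fine.n_rows % factor:
            coarse = GridSpec(
                fine.origin_x, fine.origin_y,
                fine.cell_w * factor, fine.cell_h * factor,
                -(-n // factor), -(-n // factor),
            )
        cat = random_categorical(fine, rng, nodata_frac=0.15)
        cont = random_continuous(fine, rng, nodata_frac=0.15)
        got = aggregate_fraction(cat, coarse, {50, 80}, coverage_min=0.3)
        want = _oracle_zonal(cat, coarse, "fraction", codes={50, 80}, coverage_min=0.3)
        np.testing.assert_array_equal(got.values, want)
        got = aggregate_sum(cont, coarse)
        want = _oracle_zonal(cont, coarse, "sum")
        np.testing.assert_allclose(got.values, want, rtol=1e-12)
        got = aggregate_mean(cont, coarse, coverage_min=0.3)
        want = _oracle_zonal(cont, coarse, "mean", coverage_min=0.3)
        np.testing.assert_allclose(got.values, want, rtol=1e-12)
        got = aggregate_threshold_fraction(cont, coarse, 5.0, "gt", coverage_min=0.3)
        want = _oracle_zonal(
            cont, coarse, "threshold", threshold=5.0, direction="gt", coverage_min=0.3
        )
        np.testing.assert_array_equal(got.values, want)

    def test_fraction_partition_sums_to_one(self):
        rng = np.random.default_rng(3)
        cat = random_categorical(self.fine, rng, nodata_frac=0.1)
        total = np.zeros(self.coarse.shape)
        for code in (30, 40, 50, 80, 111):
            total += aggregate_fraction(cat, self.coarse, {code}, coverage_min=0.0).values
        assert np.allclose(total, 1.0)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_aggregate_invariants(seed):
    """Fractions in [0,1]; cell means bounded by pixel min/max; sums conserve."""
    rng = np.random.default_rng(seed)
    fine = make_fine_grid(12, 12)
    coarse = make_coarse_grid(fine, 4)
    cont = random_continuous(fine, rng, nodata_frac=0.2)
    cat = random_categorical(fine, rng, nodata_frac=0.2)
    frac = aggregate_fraction(cat, coarse, {50}, coverage_min=0.0).values
    ok = np.isfinite(frac)
    assert np.all((frac[ok] >= 0) & (frac[ok] <= 1))
    mean = aggregate_mean(cont, coarse, coverage_min=0.0).values
    ok = np.isfinite(mean)
    assert np.all(mean[ok] >= np.nanmin(cont.values) - 1e-12)
    assert np.all(mean[ok] <= np.nanmax(cont.values) + 1e-12)
    s = aggregate_sum(cont, coarse).values
    assert np.nansum(s) == pytest.approx(np.nansum(cont.values), rel=1e-12, abs=1e-12)


class TestAsciiIO:
    def test_roundtrip_continuous(self, tmp_path):
        rng = np.random.default_rng(1)
        grid = make_fine_grid(8, 12)
        layer = random_continuous(grid, rng, nodata_frac=0.2)
        path = tmp_path / "layer.asc"
        write_ascii_grid(layer, path)
        back = read_ascii_grid(path)
        assert back.grid == grid
        np.testing.assert_allclose(back.values, layer.values, rtol=1e-9)

    def test_roundtrip_categorical(self, tmp_path):
        rng = np.random.default_rng(2)
        grid = make_fine_grid(8, 8)
        layer = random_categorical(grid, rng, nodata_frac=0.1)
        path = tmp_path / "lulc.asc"
        write_ascii_grid(layer, path)
        back = read_ascii_grid(path, kind="categorical")
        assert back.grid == grid
        np.testing.assert_array_equal(
            back.values == -9999, layer.values == -1
        )
        mask = layer.values != -1
        np.testing.assert_array_equal(back.values[mask], layer.values[mask])
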