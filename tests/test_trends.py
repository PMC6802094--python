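import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baciveg.composites import build_composites
from baciveg.config import AnalysisConfig
from baciveg.indices import apply_qa_mask, compute_index_stack
from baciveg.trends import (
    Epoch,
    epochs_for,
    estimate_epoch_slopes,
    pa_sufficiency,
    pixel_validity,
    sen_slope,
)
from conftest import brute_force_sen


def test_collinear_points_recover_exact_slope():
    pts = [(0, 0), (1, 1), (2, 2), (3, 3), (4, 4)]
    assert sen_slope(pts) == pytest.approx(1.0)


def test_worked_example():
    # median of the 6 pairwise slopes {2, 0.5, 1, -1, 0.5, 2} = 0.75,
    # value confirmed by the brute-force oracle
    pts = [(0, 0), (1, 2), (2, 1), (3, 3)]
    assert brute_force_sen(*zip(*pts)) == pytest.approx(0.75)
    assert sen_slope(pts) == pytest.approx(0.75)


def test_constant_series_has_zero_slope():
    assert sen_slope([(i, 3.0) for i in range(6)]) == pytest.approx(0.0)


def test_all_equal_timestamps_raise():
    with pytest.raises(ValueError):
        sen_slope([(1.0, 0.0), (1.0, 2.0), (1.0, 5.0)])


@settings(derandomize=True, max_examples=300)
@given(
    n=st.integers(2, 8),
    seed=st.integers(0, 2**31 - 1),
)
def test_oracle_equivalence_small_series(n, seed):
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(0, 10, n))
    if len(np.unique(x)) < 2:
        return
    y = rng.normal(size=n)
    assert sen_slope(x=x, y=y) == pytest.approx(brute_force_sen(x, y), abs=1e-12)


@settings(derandomize=True, max_examples=100)
@given(
    n=st.integers(3, 12),
    a=st.floats(-5, 5, allow_nan=False),
    b=st.floats(-5, 5, allow_nan=False),
    c=st.floats(-5, 5, allow_nan=False),
    seed=st.integers(0, 1000),
)
def test_estimator_equivariance(n, a, b, c, seed):
    rng = np.random.default_rng(seed)
    x = np.arange(n, dtype=float)
    y = rng.normal(size=n)
    s = sen_slope(x=x, y=y)
    assert sen_slope(x=x, y=a * y + b) == pytest.approx(a * s + 0.0, abs=1e-9)
    assert sen_slope(x=x + c, y=y) == pytest.approx(s, abs=1e-9)


def test_robustness_to_single_outlier():
    x = np.arange(10, dtype=float)
    y = 2.0 * x
    y_corrupt = y.copy()
    y_corrupt[4] = 1e6
    assert sen_slope(x=x, y=y_corrupt) == pytest.approx(2.0)


def test_siegel_repeated_medians_on_collinear_and_outlier_data():
    x = np.arange(10, dtype=float)
    y = 2.0 * x + 1.0
    assert sen_slope(x=x, y=y, estimator="siegel") == pytest.approx(2.0)
    y[3] = -50.0
    assert sen_slope(x=x, y=y, estimator="siegel") == pytest.approx(2.0)


def test_epoch_split_declaration_year_in_after():
    epochs = epochs_for(1993, range(1984, 2013))
    assert epochs["before"] == Epoch("before", 1984, 1992)
    assert epochs["after"] == Epoch("after", 1993, 2012)


def test_epoch_split_alternate_convention():
    cfg = AnalysisConfig(declaration_year_in_after=False)
    epochs = epochs_for(1993, range(1984, 2013), cfg)
    assert epochs["before"].end == 1993
    assert epochs["after"].start == 1994


def test_epoch_outside_range_is_an_error():
    with pytest.raises(ValueError):
        epochs_for(1970, range(1984, 2013))


def _composites_with_valid_years(small_stack, n_bad_years, epoch_years):
    """Mask entire years inside the epoch for pixel (0, 0)."""
    from baciveg.raster import QA_CLOUD

    stack = small_stack.copy()
    bad = epoch_years[:n_bad_years]
    for year in bad:
        stack.qa[stack.years == year, 0, 0] = QA_CLOUD
    return build_composites(compute_index_stack(apply_qa_mask(stack)))


def test_pixel_validity_boundary():
    """Pixels need at least 5 valid composite years: 5 keeps, 4 drops."""
    years = np.arange(1984, 1993)
    values = np.full((9, 1, 1), 0.4)
    stamps = years[:, None, None] - 1984 + 0.5
    from baciveg.composites import AnnualCompositeSeries
    from baciveg.raster import SceneGrid

    grid = SceneGrid(1, 1)
    epoch = Epoch("before", 1984, 1992)
    for n_valid, expect in [(5, True), (4, False), (0, False)]:
        v = values.copy()
        v[n_valid:] = np.nan
        series = AnnualCompositeSeries(
            grid=grid,
            years=years,
            values={"brownest": v, "driest": v},
            stamps={"brownest": stamps.astype(float), "driest": stamps.astype(float)},
            n_valid={"brownest": np.isfinite(v).astype(int),
                     "driest": np.isfinite(v).astype(int)},
        )
        assert bool(pixel_validity(series, epoch)[0, 0]) is expect


def test_pa_sufficiency_boundary():
    """PA dropped only when strictly more than 20% of its area is
    insufficient: 19% retained, 21% dropped, 0% retained."""
    pa_mask = np.ones((10, 10), dtype=bool)
    for pct, expect in [(19, True), (20, True), (21, False), (0, True)]:
        validity = np.ones((10, 10), dtype=bool)
        validity.ravel()[:pct] = False
        assert pa_sufficiency(validity, pa_mask) is expect


def test_pa_sufficiency_empty_mask_is_an_error():
    with pytest.raises(ValueError):
        pa_sufficiency(np.ones((3, 3), bool), np.zeros((3, 3), bool))


def test_noiseless_slope_recovery(small_stack, small_truth):
    comp = build_composites(compute_index_stack(apply_qa_mask(small_stack)))
    maps = estimate_epoch_slopes(comp, 1993)
    for track in ("brownest", "driest"):
        np.testing.assert_allclose(
            maps.slopes[(track, "after")], small_truth.slope_after[track], atol=1e-9
        )
        np.testing.assert_allclose(
            maps.slopes[(track, "before")], small_truth.slope_before[track], atol=1e-9
        )


def test_fully_masked_pixel_has_no_slope(small_stack):
    from baciveg.raster import QA_CLOUD

    stack = small_stack.copy()
    stack.qa[:, 1, 2] = QA_CLOUD
    comp = build_composites(compute_index_stack(apply_qa_mask(stack)))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        maps = estimate_epoch_slopes(comp, 1993)
    assert np.isnan(maps.slopes[("brownest", "after")][1, 2])
    assert not maps.valid[("brownest", "after")][1, 2]
    assert maps.valid[("brownest", "after")][0, 0]


def test_siegel_estimator_on_maps(small_stack, small_truth):
    cfg = AnalysisConfig(estimator="siegel")
    comp = build_composites(compute_index_stack(apply_qa_mask(small_stack)), config=cfg)
    maps = estimate_epoch_slopes(comp, 1993, cfg)
    np.testing.assert_allclose(
        maps.slopes[("brownest", "after")], small_truth.slope_after["brownest"],
        atol=1e-9,
    )
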