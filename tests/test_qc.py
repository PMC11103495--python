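import numpy as np
import pandas as pd
import pytest

from tripodd.qc import (
    NormalizationSpec,
    QCError,
    filter_outliers,
    gate_epithelial,
    normalize_exposure,
    run_qc_chain,
    subtract_autofluorescence,
    zscore_to_control,
)


def _table(**columns) -> pd.DataFrame:
    df = pd.DataFrame(columns)
    if "cell_id" not in df.columns:
        df.insert(0, "cell_id", np.arange(1, len(df) + 1))
    return df


def test_exposure_of_one_is_identity():
    cells = _table(mean_CK8=[1.0, 2.0], af_Cy3=[0.5, 0.5])
    out = normalize_exposure(cells, {"CK8": 1.0, "Cy3": 1.0})
    pd.testing.assert_frame_equal(out, cells)


def test_exposure_division():
    cells = _table(mean_CK8=[500.0])
    out = normalize_exposure(cells, {"CK8": 250.0})
    assert out.loc[0, "mean_CK8"] == pytest.approx(2.0)


@pytest.mark.parametrize("exposures", [{}, {"CK8": 0.0}, {"CK8": -5.0}])
def test_missing_or_nonpositive_exposure_rejected(exposures):
    cells = _table(mean_CK8=[1.0])
    with pytest.raises(QCError):
        normalize_exposure(cells, exposures)


def test_af_subtraction_same_wavelength():
    cells = _table(mean_CK8=[10.0, 0.0, 2.0], af_Cy3=[3.0, 0.0, 3.0])
    out = subtract_autofluorescence(cells, {"CK8": "Cy3"})
    # marker 10, AF 3 -> 7; AF 0 leaves value unchanged; negatives retained
    assert out["mean_CK8"].tolist() == [7.0, 0.0, -1.0]


def test_af_subtraction_requires_wavelength_mapping():
    cells = _table(mean_CK8=[1.0], af_Cy3=[0.1])
    with pytest.raises(QCError):
        subtract_autofluorescence(cells, {})


def test_size_filter_on_1_to_100_matches_quantile_oracle():
    """Linear-interpolation quantiles on 1..100: q05=5.95, q95=95.05."""
    sizes = np.arange(1, 101)
    cells = _table(nuclear_size=sizes, af_Cy3=np.zeros(100))
    out, report = filter_outliers(cells, NormalizationSpec())
    assert report["size_thresholds"] == pytest.approx([5.95, 95.05])
    assert len(out) == 90
    assert out["nuclear_size"].min() == 6 and out["nuclear_size"].max() == 95


def test_constant_af_removes_nothing():
    cells = _table(nuclear_size=np.full(50, 10.0), af_Cy3=np.full(50, 2.0))
    out, report = filter_outliers(cells, NormalizationSpec())
    assert report["n_af_removed"] == 0
    assert len(out) == 50


def test_af_filter_flags_exactly_top_5_percent():
    rng = np.random.default_rng(0)
    af = rng.permutation(np.arange(1.0, 201.0))  # known ordering, shuffled
    cells = _table(nuclear_size=np.full(200, 10.0), af_Cy3=af)
    out, report = filter_outliers(cells, NormalizationSpec())
    # sort-based oracle: exactly the 10 largest AF values are removed
    expected_removed = set(cells.sort_values("af_Cy3", ascending=False)["cell_id"][:10])
    assert set(report["af_outlier_ids"]) == expected_removed
    assert len(out) == 190


def test_filter_is_idempotent_at_fixed_thresholds():
    rng = np.random.default_rng(1)
    cells = _table(nuclear_size=rng.uniform(5, 20, 300), af_Cy3=rng.uniform(0, 1, 300))
    spec = NormalizationSpec()
    once, report = filter_outliers(cells, spec)
    af_thr = report["af_threshold"]
    lo, hi = report["size_thresholds"]
    again = once[
        (once["af_Cy3"] <= af_thr)
        & (once["nuclear_size"] >= lo)
        & (once["nuclear_size"] <= hi)
    ]
    assert len(again) == len(once)


def test_empty_table_rejected():
    with pytest.raises(QCError):
        filter_outliers(_table(nuclear_size=[], af_Cy3=[]), NormalizationSpec())


def test_bimodal_gate_separates_modes():
    rng = np.random.default_rng(2)
    n = 400
    high = rng.normal(100.0, 2.0, n // 2)  # modes ~10+ SDs apart
    low = rng.normal(2.0, 0.5, n - n // 2)
    ck8 = np.concatenate([high, low])
    ecad = np.concatenate([high, low])
    cells = _table(mean_CK8=ck8, mean_ECad=ecad)
    out, report = gate_epithelial(cells, NormalizationSpec())
    # the recovered threshold separates the mode centers ...
    thr = report["thresholds"]["CK8"]
    assert 2.0 < thr < 100.0
    # ... every true high-mode cell is retained, and at most a stray
    # low-mode tail sample leaks through
    high_ids = set(cells["cell_id"][: n // 2])
    assert high_ids <= set(out["cell_id"])
    leaked = set(out["cell_id"]) - high_ids
    assert len(leaked) <= 0.01 * n


def test_fixed_permissive_gate_keeps_all():
    cells = _table(mean_CK8=[5.0, 6.0], mean_ECad=[5.0, 6.0])
    spec = NormalizationSpec(gate_method="fixed", gate_thresholds={"CK8": 1.0, "ECad": 1.0})
    out, _ = gate_epithelial(cells, spec)
    assert len(out) == 2


def test_gate_retaining_zero_cells_errors():
    cells = _table(mean_CK8=[0.1, 0.2], mean_ECad=[0.1, 0.2])
    spec = NormalizationSpec(gate_method="fixed", gate_thresholds={"CK8": 1.0, "ECad": 1.0})
    with pytest.raises(QCError):
        gate_epithelial(cells, spec)


def test_cell_at_control_median_scores_zero():
    cells = _table(
        mean_CK8=[1.0, 2.0, 3.0, 2.0],
        cohort=["control", "control", "control", "treated"],
    )
    out, stats = zscore_to_control(cells, NormalizationSpec(), columns=["mean_CK8"])
    assert out.loc[3, "mean_CK8"] == pytest.approx(0.0)
    assert stats["mean_CK8"]["control_median"] == 2.0


def test_zscore_hand_computed_example():
    """Control {0,0,10,10}: median 5, sample SD sqrt(100/3); z(10) ~ 0.866."""
    cells = _table(
        mean_CK8=[0.0, 0.0, 10.0, 10.0, 10.0],
        cohort=["control"] * 4 + ["treated"],
    )
    out, _ = zscore_to_control(cells, NormalizationSpec(), columns=["mean_CK8"])
    assert out.loc[4, "mean_CK8"] == pytest.approx(5.0 / np.sqrt(100.0 / 3.0), abs=1e-9)
    assert out.loc[4, "mean_CK8"] == pytest.approx(0.866, abs=1e-3)


def test_control_median_is_exactly_zero_after_zscore():
    rng = np.random.default_rng(3)
    n = 101  # odd, so the median is an order statistic
    cells = _table(
        mean_CK8=rng.normal(5, 2, n + 40),
        dta_mean=rng.normal(1, 0.5, n + 40),
        cohort=["control"] * n + ["treated"] * 40,
    )
    out, _ = zscore_to_control(cells, NormalizationSpec())
    ctrl = out[out["cohort"] == "control"]
    assert float(ctrl["mean_CK8"].median()) == 0.0
    assert float(ctrl["dta_mean"].median()) == 0.0


def test_constant_control_column_rejected():
    cells = _table(mean_CK8=[1.0, 1.0, 1.0, 5.0], cohort=["control"] * 3 + ["treated"])
    with pytest.raises(QCError):
        zscore_to_control(cells, NormalizationSpec(), columns=["mean_CK8"])


def test_missing_control_cohort_rejected():
    cells = _table(mean_CK8=[1.0, 2.0], cohort=["treated", "treated"])
    with pytest.raises(QCError):
        zscore_to_control(cells, NormalizationSpec(), columns=["mean_CK8"])


def test_chain_preserves_cell_identity():
    rng = np.random.default_rng(4)
    n = 300
    cells = _table(
        nuclear_size=rng.uniform(50, 150, n),
        mean_CK8=rng.lognormal(3, 0.3, n) * 100,
        mean_ECad=rng.lognormal(3, 0.3, n) * 150,
        af_Cy3=rng.uniform(0.5, 1.5, n) * 50,
        af_Cy5=rng.uniform(0.2, 0.8, n) * 50,
        cohort=["control"] * (n // 2) + ["treated"] * (n - n // 2),
    )
    out, _ = run_qc_chain(
        cells,
        NormalizationSpec(epithelial_markers=("CK8", "ECad")),
        exposures={"CK8": 100.0, "ECad": 150.0, "Cy3": 50.0, "Cy5": 50.0},
        channel_wavelength_map={"CK8": "Cy3", "ECad": "Cy5"},
        zscore=True,
    )
    assert out["cell_id"].is_unique
    assert set(out["cell_id"]) <= set(cells["cell_id"])
    assert len(out) < len(cells)
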