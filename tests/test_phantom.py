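import dataclasses

import numpy as np
import pytest

import tripodd as tp
from tripodd.calibration import calibrate_from_series
from tripodd.phantom import ROUND_PLAN


def _series_from(titration):
    df = titration.mean_intensities()
    return {
        probe: tp.TitrationSeries(
            probe, tuple(sub["concentration"]), tuple(sub["mean_intensity"])
        )
        for probe, sub in df.groupby("probe")
    }


def test_same_seed_reproduces_stack_and_truth_bitwise():
    config = tp.PhantomConfig(n_cells=25, field_size=(320, 320), seed=9)
    stack_a, truth_a = tp.generate_phantom(config)
    stack_b, truth_b = tp.generate_phantom(config)
    for round_a, round_b in zip(stack_a, stack_b):
        assert set(round_a) == set(round_b)
        for name in round_a:
            assert np.array_equal(round_a[name].pixels, round_b[name].pixels)
    assert truth_a.cells.equals(truth_b.cells)


def test_full_occupancy_zeroes_dta_and_balances_channels(noiseless_sf):
    config = tp.PhantomConfig(
        n_cells=20,
        field_size=(320, 320),
        occupancy_f=1.0,
        noise_sigma=0.0,
        autofluorescence_levels={"DAPI": 0, "Cy2": 2.0, "Cy3": 0, "Cy5": 0},
        seed=2,
    )
    stack, truth = tp.generate_phantom(config)
    assert np.all(truth.cells["dta_true"] == 0.0)
    inside = truth.cell_labels > 0
    i_t = stack[0]["probe_T"].pixels
    i_unt = stack[0]["probe_UnT"].pixels
    # targeted equals the SF-scaled untargeted channel inside cells
    np.testing.assert_allclose(i_t[inside], i_unt[inside] / truth.sf_true, rtol=1e-12)


def test_empty_phantom_has_no_cells_only_background():
    config = tp.PhantomConfig(n_cells=0, field_size=(256, 256), noise_sigma=0.0, seed=1)
    stack, truth = tp.generate_phantom(config)
    assert len(truth.cells) == 0
    assert stack[0]["DAPI"].pixels.max() == 0.0
    af_cy2 = stack[0]["AF_Cy2"].pixels
    exp = config.exposure_ms["AF_Cy2"]
    assert af_cy2.max() == pytest.approx(exp * config.autofluorescence_levels["Cy2"])


def test_rounds_follow_plan_with_dapi_everywhere():
    config = tp.PhantomConfig(n_cells=10, field_size=(256, 256), seed=3)
    stack, _ = tp.generate_phantom(config)
    assert len(stack) == len(ROUND_PLAN)
    for round_images, plan in zip(stack, ROUND_PLAN):
        assert set(round_images) == set(plan)
        assert "DAPI" in round_images


def test_round_images_are_base_displaced_by_true_shift():
    shifts = ((0.0, 0.0), (12.0, -9.0), (-6.0, 15.0), (3.0, 4.0))
    config = tp.PhantomConfig(
        n_cells=15, field_size=(320, 320), noise_sigma=0.0, round_shifts=shifts, seed=4
    )
    stack, truth = tp.generate_phantom(config)
    from scipy import ndimage as ndi

    base_dapi = stack[0]["DAPI"].pixels
    shifted = ndi.shift(base_dapi, shifts[1], order=1, cval=0.0)
    np.testing.assert_allclose(stack[1]["DAPI"].pixels, shifted, atol=1e-9)


def test_pixelwise_ratio_recovers_truth_without_noise(clean_phantom, noiseless_sf):
    _, stack, truth = clean_phantom
    inside = truth.cell_labels > 0
    i_t = stack[0]["probe_T"].pixels
    i_unt = stack[0]["probe_UnT"].pixels
    ratio_dta = noiseless_sf.sf * i_t[inside] / i_unt[inside] - 1.0
    expected = truth.cells["dta_true"].to_numpy()[truth.cell_labels[inside] - 1]
    np.testing.assert_allclose(ratio_dta, expected, atol=1e-9)


def test_occupancy_strictly_decreases_truth_dta():
    base = tp.PhantomConfig(n_cells=30, field_size=(320, 320), seed=6)
    previous = None
    for f in (0.0, 0.3, 0.6, 0.9):
        _, truth = tp.generate_phantom(dataclasses.replace(base, occupancy_f=f))
        dta = truth.cells["dta_true"].to_numpy()
        if previous is not None:
            assert np.all(dta < previous)
        previous = dta


def test_titration_noiseless_means_and_downstream_sf():
    ts = tp.generate_titration(3.0, 6.0, [1, 2, 4], noise_sigma=0.0, seed=0)
    means = [img.mean() for img in ts.targeted]
    assert means == pytest.approx([3.0, 6.0, 12.0])
    series = _series_from(ts)
    sf = calibrate_from_series(series["targeted"], series["untargeted"])
    assert sf.sf == pytest.approx(2.0, abs=1e-12)


def test_titration_reproducible_for_fixed_seed():
    a = tp.generate_titration(3.0, 6.0, [1, 2, 4], noise_sigma=0.5, seed=5)
    b = tp.generate_titration(3.0, 6.0, [1, 2, 4], noise_sigma=0.5, seed=5)
    for img_a, img_b in zip(a.targeted + a.untargeted, b.targeted + b.untargeted):
        assert np.array_equal(img_a, img_b)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"concentrations": [2.0, 2.0]},
        {"concentrations": [1.0, -2.0]},
        {"concentrations": [1.0, 2.0], "slope_t": 0.0},
    ],
)
def test_titration_rejects_degenerate_inputs(kwargs):
    args = {"slope_t": 3.0, "slope_unt": 6.0, **kwargs}
    with pytest.raises(ValueError):
        tp.generate_titration(**args)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"occupancy_f": 1.5},
        {"slope_t": -1.0},
        {"round_shifts": ((0, 0), (500, 0), (0, 0), (0, 0)), "field_size": (256, 256)},
        {"noise_model": "speckle"},
    ],
)
def test_config_invariants_enforced(kwargs):
    with pytest.raises(ValueError):
        tp.PhantomConfig(**kwargs)
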