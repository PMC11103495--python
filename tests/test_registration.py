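import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tripodd.registration import (
    RegistrationError,
    RigidTransform,
    apply_transform,
    register_control_points,
    register_rounds,
)


def test_identical_images_register_to_identity(noisy_phantom):
    _, stack, _ = noisy_phantom
    dapi = stack[0]["DAPI"]
    tf = register_rounds(dapi, dapi)
    assert abs(tf.dy) < 1e-6 and abs(tf.dx) < 1e-6 and tf.theta == 0.0
    assert tf.score > 0.99


def test_phantom_round_shifts_recovered(noisy_phantom):
    _, stack, truth = noisy_phantom
    ref = stack[0]["DAPI"]
    for k in range(1, len(stack)):
        tf = register_rounds(ref, stack[k]["DAPI"])
        true_dy, true_dx = truth.round_shifts[k]
        assert tf.dy == pytest.approx(true_dy, abs=0.5)
        assert tf.dx == pytest.approx(true_dx, abs=0.5)


def test_pure_noise_pair_raises_low_confidence():
    rng = np.random.default_rng(0)
    a = rng.uniform(size=(128, 128))
    b = rng.uniform(size=(128, 128))
    with pytest.raises(RegistrationError):
        register_rounds(a, b)


def test_registration_reduces_dapi_mismatch(noisy_phantom):
    _, stack, _ = noisy_phantom
    ref = stack[0]["DAPI"].pixels
    mov = stack[2]["DAPI"].pixels
    tf = register_rounds(ref, mov)
    aligned = apply_transform(mov, tf.inverse())
    mse_before = float(np.mean((mov - ref) ** 2))
    mse_after = float(np.mean((aligned - ref) ** 2))
    assert mse_after <= 0.1 * mse_before


def test_registration_composition_consistency(noisy_phantom):
    """A->B and B->C composed agree with direct A->C within 0.5 px."""
    _, stack, _ = noisy_phantom
    a, b, c = (stack[k]["DAPI"] for k in (0, 1, 2))
    t_ab = register_rounds(a, b)  # b relative to a
    t_bc = register_rounds(b, c)  # c relative to b
    t_ac = register_rounds(a, c)
    composed = t_ab.compose(t_bc)
    assert composed.dy == pytest.approx(t_ac.dy, abs=0.5)
    assert composed.dx == pytest.approx(t_ac.dx, abs=0.5)


def test_control_points_identity_for_aligned_pairs():
    pts = [((1.0, 2.0), (1.0, 2.0)), ((5.0, -3.0), (5.0, -3.0)), ((0.0, 9.0), (0.0, 9.0))]
    tf = register_control_points(pts)
    assert tf.is_identity(tol=1e-9)
    assert tf.score == pytest.approx(1.0)


def test_control_points_recover_known_rigid_transform():
    rng = np.random.default_rng(1)
    moving = rng.uniform(-50, 50, size=(8, 2))
    true = RigidTransform(dy=4.25, dx=-7.5, theta=0.3)
    fixed = true.transform_points(moving)
    tf = register_control_points(list(zip(fixed, moving)))
    assert tf.dy == pytest.approx(true.dy, abs=1e-6)
    assert tf.dx == pytest.approx(true.dx, abs=1e-6)
    assert tf.theta == pytest.approx(true.theta, abs=1e-9)


@pytest.mark.parametrize(
    "pairs",
    [
        [((0.0, 0.0), (1.0, 1.0))],
        [((1.0, 1.0), (2.0, 2.0)), ((1.0, 1.0), (2.0, 2.0))],
    ],
)
def test_control_points_underdetermined_rejected(pairs):
    with pytest.raises(ValueError):
        register_control_points(pairs)


def test_apply_identity_leaves_image_unchanged():
    rng = np.random.default_rng(2)
    img = rng.uniform(size=(32, 32))
    out = apply_transform(img, RigidTransform(0.0, 0.0))
    assert np.array_equal(out, img)


def test_shift_and_unshift_round_trip():
    rng = np.random.default_rng(3)
    img = np.zeros((64, 64))
    img[16:48, 16:48] = rng.uniform(size=(32, 32))
    once = apply_transform(img, RigidTransform(1.0, 0.0))
    back = apply_transform(once, RigidTransform(-1.0, 0.0))
    np.testing.assert_allclose(back[2:-2, 2:-2], img[2:-2, 2:-2], atol=1e-9)


def test_recovered_transform_aligns_round_below_noise(noisy_phantom):
    config, stack, _ = noisy_phantom
    ref = stack[0]["DAPI"].pixels
    mov = stack[1]["DAPI"].pixels
    tf = register_rounds(ref, mov)
    aligned, valid = apply_transform(mov, tf.inverse(), return_valid=True)
    mad = float(np.mean(np.abs(aligned[valid] - ref[valid])))
    # residual should be at the acquisition-noise scale, not the signal scale
    assert mad < 4 * config.noise_sigma


def test_out_of_field_pixels_flagged():
    img = np.ones((20, 20))
    out, valid = apply_transform(img, RigidTransform(5.0, 0.0), return_valid=True)
    assert not valid[:5].any()
    assert valid[6:].all()
    assert np.all(out[:4] == 0.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    dy=st.floats(-20, 20),
    dx=st.floats(-20, 20),
    theta=st.floats(-np.pi / 2, np.pi / 2),
)
def test_transform_inverse_round_trip_property(dy, dx, theta):
    tf = RigidTransform(dy=dy, dx=dx, theta=theta)
    round_trip = tf.compose(tf.inverse())
    assert abs(round_trip.dy) < 1e-6
    assert abs(round_trip.dx) < 1e-6
    assert abs(round_trip.theta) < 1e-9


def test_transform_json_round_trip(tmp_path):
    tf = RigidTransform(dy=1.5, dx=-2.25, theta=0.1, score=0.8)
    path = tmp_path / "tf.json"
    tf.to_json(path)
    assert RigidTransform.from_json(path) == tf
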