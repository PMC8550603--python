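"""Lattice geometry, jitter statistics, DoG rendering and observer draws."""

import numpy as np
import pytest
from scipy import stats

from regtex import (SimulatedObserver, apply_jitter, make_grid,
                    measure_displacement, mean_displacement_analytic,
                    render_texture, simulate_observer)
from regtex.stimuli import (ELEMENT_DIAMETERS, GRID_SPECS, JITTER_RANGES,
                            ElementLayout, dog_profile)


@pytest.mark.parametrize("level,n,pitch", [(1, 9, 17.52), (2, 7, 21.41),
                                           (3, 6, 25.30)])
def test_grid_counts_and_pitch(level, n, pitch):
    layout = make_grid(level)
    assert len(layout.centers) == n * n
    xs = np.unique(np.round(layout.centers[:, 0], 6))
    assert len(xs) == n
    assert np.allclose(np.diff(xs), pitch)
    assert np.allclose(layout.centers.mean(axis=0), 0.0)


@pytest.mark.parametrize("level", [1, 2, 3])
def test_grid_square_symmetry(level):
    """The lattice is invariant under 90-degree rotation about its centre."""
    pts = make_grid(level).centers
    rotated = pts[:, ::-1] * np.array([1.0, -1.0])
    original = {tuple(np.round(p, 6)) for p in pts}
    assert {tuple(np.round(p, 6)) for p in rotated} == original


def test_grid_invalid_level():
    with pytest.raises(ValueError, match="spacing_level"):
        make_grid(4)


def test_zero_jitter_is_identity():
    layout = make_grid(2)
    out = apply_jitter(layout, 1, jitter_range=0.0, seed=0)
    assert np.array_equal(out.centers, layout.grid_centers)


def test_jitter_offsets_bounded_by_half_range():
    layout = make_grid(1)
    out = apply_jitter(layout, 1, ELEMENT_DIAMETERS[1], seed=3)
    assert np.max(np.abs(out.offsets)) <= JITTER_RANGES[1] / 2 + 1e-12


@pytest.mark.parametrize("policy", ["global", "sequential"])
def test_overlap_rejection_invariant(policy):
    out = apply_jitter(make_grid(1), 5, ELEMENT_DIAMETERS[3], seed=11,
                       policy=policy)
    assert out.min_pair_distance() >= ELEMENT_DIAMETERS[3]


def test_impossible_placement_raises():
    with pytest.raises(RuntimeError, match="overlap|settle"):
        apply_jitter(make_grid(3), 1, seed=0, min_separation=40.0,
                     max_redraws=50, max_sweeps=5)


def test_unconstrained_displacement_matches_analytic():
    """Monte-Carlo mean Euclidean offset agrees with the closed form."""
    rng = np.random.default_rng(5)
    for level, width in JITTER_RANGES.items():
        xy = rng.uniform(-width / 2, width / 2, size=(200_000, 2))
        mc = np.hypot(xy[:, 0], xy[:, 1]).mean()
        assert mc == pytest.approx(mean_displacement_analytic(width),
                                   rel=3e-3)


def test_overlap_rejection_never_raises_mean_displacement():
    """Conditioning on non-overlap removes large relative offsets."""
    rng = np.random.default_rng(6)
    grid = make_grid(1)
    cons = [apply_jitter(grid, 5, ELEMENT_DIAMETERS[3], seed=rng).displacements.mean()
            for _ in range(30)]
    assert np.mean(cons) <= mean_displacement_analytic(JITTER_RANGES[5]) + 0.02


def test_measure_displacement_summary():
    grid = make_grid(1)
    zero = ElementLayout(centers=grid.grid_centers.copy(),
                         grid_centers=grid.grid_centers)
    summary = measure_displacement([zero, zero])
    assert summary.mean == 0.0 and summary.sd == 0.0

    centers = grid.grid_centers.copy()
    centers[0] += [3.0, 4.0]
    one = ElementLayout(centers=centers, grid_centers=grid.grid_centers)
    assert measure_displacement([one]).mean == pytest.approx(5.0 / 81)


def test_render_empty_layout_uniform():
    empty = ElementLayout(centers=np.empty((0, 2)),
                          grid_centers=np.empty((0, 2)))
    img = render_texture(empty, 1, background_level=0.25)
    assert img.pixels.shape == (256, 256)
    assert np.all(img.pixels == 0.25)


def test_render_zero_balance_and_geometry():
    layout = apply_jitter(make_grid(1), 3, ELEMENT_DIAMETERS[2], seed=9)
    img = render_texture(layout, 2)
    peak = dog_profile(np.array([0.0]), ELEMENT_DIAMETERS[2])[0]
    # zero-balanced elements: image mean stays at background
    assert abs(img.pixels.mean()) < 0.005 * peak
    assert img.pixel_pitch == pytest.approx(2.91 * 60 / 256)
    assert np.all(np.isfinite(img.pixels))


def test_dog_profile_zero_integral():
    r = np.linspace(0, 40, 40001)
    vals = dog_profile(r, ELEMENT_DIAMETERS[1])
    integral = np.trapezoid(vals * 2 * np.pi * r, r)
    assert abs(integral) < 1e-6 * np.trapezoid(
        np.abs(vals) * 2 * np.pi * r, r)
    # centre sigma is diameter / 4: value at one sigma
    sigma = ELEMENT_DIAMETERS[1] / 4
    assert sigma == pytest.approx(2.4325)


def test_render_counts_clipped_elements():
    centers = np.array([[86.0, 0.0]])
    layout = ElementLayout(centers=centers, grid_centers=centers)
    img = render_texture(layout, 3, apply_aperture=False)
    assert img.clipped_elements == 1


def test_self_pair_choice_is_symmetric(pairs45):
    obs = SimulatedObserver(condition_means=np.zeros(45))
    table = simulate_observer(obs, [(0, 0)], 4000, seed=2)
    agg = table.aggregate()
    p = agg["n_first"].iloc[0] / agg["n_total"].iloc[0]
    assert p == pytest.approx(0.5, abs=0.03)


def test_dominant_mean_always_wins():
    means = np.zeros(45)
    means[3] = 50.0
    obs = SimulatedObserver(condition_means=means)
    table = simulate_observer(obs, [(3, 10)], 200, seed=4)
    agg = table.aggregate()
    assert agg["n_first"].iloc[0] == agg["n_total"].iloc[0]


def test_choice_probability_matches_probit():
    """Empirical choice rate equals Phi(dmu / sqrt(sd_a^2 + sd_b^2))."""
    means = np.zeros(45)
    means[0], means[1] = 0.8, 0.0
    sds = np.full(45, 0.9)
    sds[1] = 1.4
    obs = SimulatedObserver(condition_means=means, sds=sds, sd_mode="varied")
    table = simulate_observer(obs, [(0, 1)], 20_000, seed=8)
    agg = table.aggregate()
    p_hat = agg["n_first"].iloc[0] / agg["n_total"].iloc[0]
    expected = stats.norm.cdf(0.8 / np.hypot(0.9, 1.4))
    assert p_hat == pytest.approx(expected, abs=0.012)


def test_fixed_mode_rejects_unequal_sds():
    with pytest.raises(ValueError, match="equal SDs"):
        SimulatedObserver(condition_means=np.zeros(45),
                          sds=np.linspace(0.5, 1.5, 45), sd_mode="fixed")


def test_texture_png_roundtrip(tmp_path):
    from regtex.stimuli import load_texture, save_texture

    layout = apply_jitter(make_grid(2), 4, ELEMENT_DIAMETERS[1], seed=12)
    img = render_texture(layout, 1)
    path = tmp_path / "texture.png"
    save_texture(img, path, metadata={"seed": 12, "spacing_level": 2})
    back, meta = load_texture(path)
    assert meta["spacing_level"] == 2
    assert back.pixel_pitch == pytest.approx(img.pixel_pitch)
    span = img.pixels.max() - img.pixels.min()
    assert np.max(np.abs(back.pixels - img.pixels)) < span / 2 ** 15
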