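"""Log-Gabor bank, energy normalizations and distribution statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from regtex.stimuli import ELEMENT_DIAMETERS, apply_jitter, make_grid, render_texture
from regtex.wavelets import (EnergySpectrum, LogGaborBank, compute_energy,
                             condition_parameter_table, distribution_stats,
                             mean_normalize, model_parameters)


def texture_spectrum(bank, spacing, size, jitter, seed, **kwargs):
    layout = apply_jitter(make_grid(spacing), jitter,
                          ELEMENT_DIAMETERS[size], seed=seed)
    image = render_texture(layout, size, raster_size=bank.image_size)
    return compute_energy(image, bank, **kwargs)


def test_bank_defaults(bank):
    assert bank.n_filters == 600
    assert bank.center_sfs[0] == pytest.approx(0.23)
    assert bank.center_sfs[-1] == pytest.approx(512.0)
    ratios = bank.center_sfs[1:] / bank.center_sfs[:-1]
    assert np.allclose(ratios, (512 / 0.23) ** (1 / 49))
    assert len(bank.orientations_deg) == 12
    assert np.allclose(np.diff(bank.orientations_deg), 15.0)


def test_zero_dc_response(bank):
    spec = compute_energy(np.full((256, 256), 3.7), bank,
                          square_pixels=False)
    assert np.allclose(spec.re, 0.0)


def test_energy_quadratic_in_contrast(bank):
    spec1 = texture_spectrum(bank, 2, 2, 3, seed=1)
    layout = apply_jitter(make_grid(2), 3, ELEMENT_DIAMETERS[2], seed=1)
    image = render_texture(layout, 2)
    spec3 = compute_energy(image.pixels * 3.0, bank)
    # squaring + linear filtering + RMS: scaling the image by c scales RE by c^2
    assert np.allclose(spec3.re, spec1.re * 9.0, rtol=1e-10)


def test_orientation_selectivity(bank):
    x = np.arange(256)
    grating = np.sin(2 * np.pi * 20 * x / 256)[None, :].repeat(256, axis=0)
    spec = compute_energy(grating, bank, square_pixels=False)
    by_ori = spec.re.sum(axis=0)
    # variation along x = wavevector at 0 degrees
    assert bank.orientations_deg[np.argmax(by_ori)] == 0.0


def test_input_validation(bank):
    with pytest.raises(ValueError, match="square"):
        compute_energy(np.zeros((256, 128)), bank)
    bad = np.zeros((256, 256))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        compute_energy(bad, bank)


def test_mean_normalization_equates_totals(bank):
    spec = texture_spectrum(bank, 1, 2, 2, seed=2)
    ne_ori = mean_normalize(spec, "equate-orientations").ne
    assert np.allclose(ne_ori.sum(axis=0), 50.0)
    ne_sf = mean_normalize(spec, "equate-sfs").ne
    assert np.allclose(ne_sf.sum(axis=1), 12.0)


def test_normalized_energy_contrast_invariant(bank):
    layout = apply_jitter(make_grid(3), 4, ELEMENT_DIAMETERS[1], seed=4)
    image = render_texture(layout, 1)
    ne_a = mean_normalize(compute_energy(image.pixels, bank),
                          "equate-orientations").ne
    ne_b = mean_normalize(compute_energy(image.pixels * 0.2, bank),
                          "equate-orientations").ne
    assert np.allclose(ne_a, ne_b, rtol=1e-9)


def test_literal_normalization_flattens_marginal(bank):
    """The printed index order makes the downstream marginal identically 1."""
    spec = texture_spectrum(bank, 2, 1, 3, seed=5)
    lit = mean_normalize(spec, "literal-orientation")
    assert np.allclose(lit.ne.mean(axis=1), 1.0)


def test_moment_statistics_against_scipy():
    rng = np.random.default_rng(12)
    for _ in range(20):
        x = rng.gamma(2.0, size=rng.integers(5, 60))
        st = distribution_stats(x, include_fwhm=False)
        assert st.kurtosis == pytest.approx(
            sps.kurtosis(x, fisher=False, bias=True), abs=1e-12)
        assert st.skew == pytest.approx(sps.skew(x, bias=True), abs=1e-12)
        assert st.sd == pytest.approx(np.std(x), abs=1e-12)
        assert st.peakedness == x.max()


def test_moment_examples():
    st = distribution_stats([1, 2, 3, 4, 5])
    assert st.skew == pytest.approx(0.0, abs=1e-12)
    assert st.kurtosis == pytest.approx(1.7)
    assert distribution_stats([0, 1, 2, 1, 0]).fwhm == pytest.approx(2.0)
    # a multiset of values symmetric about its mean has zero skew
    sym = distribution_stats([0, 1, 3, 5, 6])
    assert sym.skew == pytest.approx(0.0, abs=1e-12)


def test_fwhm_multimodal_warns():
    with pytest.warns(RuntimeWarning, match="multi"):
        st = distribution_stats([0, 2, 0, 2, 0])
    assert st.fwhm == pytest.approx(3.0)   # outermost crossings at 0.5, 3.5


def test_constant_vector_rejected():
    with pytest.raises(ValueError, match="constant"):
        distribution_stats([1.0, 1.0, 1.0])


def test_identical_orientation_channels_have_zero_spread():
    re = np.tile(np.linspace(1, 5, 50)[:, None], (1, 12))
    spec = EnergySpectrum(re=re, sf_cpi=np.geomspace(0.23, 512, 50),
                          orientations_deg=np.arange(12) * 15.0)
    params = model_parameters(mean_normalize(spec, "equate-orientations"),
                              "sf_x_ori")
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in params.values())


def test_model_requires_matching_normalization(bank):
    spec = texture_spectrum(bank, 1, 1, 1, seed=6)
    with pytest.raises(ValueError, match="normalized"):
        model_parameters(spec, "sf")
    with pytest.raises(ValueError, match="equate-sfs"):
        model_parameters(mean_normalize(spec, "equate-orientations"), "ori")


def test_sf_models_report_five_statistics_orientation_models_four(bank):
    spec = texture_spectrum(bank, 1, 3, 1, seed=7)
    sf = model_parameters(mean_normalize(spec, "equate-orientations"), "sf")
    assert set(sf) == {"kurtosis", "skew", "fwhm", "peakedness", "sd"}
    ori = model_parameters(mean_normalize(spec, "equate-sfs"), "ori")
    assert set(ori) == {"kurtosis", "skew", "peakedness", "sd"}


def test_lattice_orientation_marginal_peaks_on_grid_axes(bank):
    spec = texture_spectrum(bank, 1, 1, 1, seed=8)
    x = mean_normalize(spec, "equate-sfs").ne.mean(axis=0)
    top2 = set(bank.orientations_deg[np.argsort(x)[::-1][:2]])
    assert top2 == {0.0, 90.0}


def test_rotation_permutes_orientation_channels(bank):
    layout = apply_jitter(make_grid(2), 5, ELEMENT_DIAMETERS[2], seed=9)
    image = render_texture(layout, 2).pixels
    spec = compute_energy(image, bank)
    spec_rot = compute_energy(np.rot90(image), bank)
    permuted = np.roll(spec.re, 6, axis=1)
    # frequency-grid asymmetry at the Nyquist row leaves tiny residuals in
    # the (near-empty) channels above the image Nyquist frequency
    assert np.allclose(spec_rot.re, permuted, rtol=5e-2,
                       atol=1e-3 * permuted.max())
    # cross-orientation spreads are invariant under the permutation
    p = model_parameters(mean_normalize(spec, "equate-orientations"),
                         "sf_x_ori")
    p_rot = model_parameters(mean_normalize(spec_rot, "equate-orientations"),
                             "sf_x_ori")
    for key in p:
        assert p_rot[key] == pytest.approx(p[key], rel=5e-2, abs=1e-4)


def test_jitter_spreads_energy_across_orientations(bank):
    """Higher jitter lowers the skew spread across orientation channels."""
    def skew_std(jitter, seed):
        spec = texture_spectrum(bank, 1, 3, jitter, seed=seed)
        ne = mean_normalize(spec, "equate-orientations")
        return model_parameters(ne, "sf_x_ori")["skew_std"]

    low = np.mean([skew_std(1, s) for s in range(3)])
    high = np.mean([skew_std(5, s) for s in range(3)])
    assert high < low


def test_condition_table_shape_and_determinism(bank):
    a = condition_parameter_table(models=("ori",), n_samples=1, seed=3,
                                  bank=bank)
    b = condition_parameter_table(models=("ori",), n_samples=1, seed=3,
                                  bank=bank)
    assert a.shape == (45, 4)
    assert a.equals(b)


def test_squaring_changes_spectrum(bank):
    spec_sq = texture_spectrum(bank, 1, 3, 1, seed=10)
    spec_lin = texture_spectrum(bank, 1, 3, 1, seed=10, square_pixels=False)
    assert not np.allclose(spec_sq.re, spec_lin.re)
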