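"""Log-Gabor filter-bank energy analysis and regularity encoding models.

Each texture raster is analysed by a polar-separable log-Gabor bank
(by default 50 log-spaced spatial frequencies from 0.23 to 512 cycles per
image at 12 orientations 0-165 deg in 15-deg steps).  Pixel values are
squared before filtering to expose above-background contrast energy; the
pixelwise RMS magnitude of each complex filter response is then divided by
the square of the filter's spatial size (taken as image size / centre
frequency).  The RMS is evaluated in the frequency domain via Parseval's
identity, which is exact and avoids 600 inverse FFTs per image.

Channel energies are mean-normalized to equate the total response either
across the 12 orientations (for the SF-based models) or across the 50 SF
levels (for the orientation-based models), making every model statistic
invariant to global image contrast.

Four read-out models summarise the normalized energy surface:

* ``sf``       -- kurtosis, skew, FWHM, peakedness and SD of the
  orientation-averaged SF distribution;
* ``sf_x_ori`` -- the same five statistics per orientation channel,
  reduced to their sample SD across the 12 orientations (the skew SD of
  this model is the best regularity predictor);
* ``ori``      -- kurtosis, skew, peakedness and SD of the SF-averaged
  orientation distribution (FWHM is omitted: the orientation distribution
  is bimodal with sharp edges);
* ``ori_x_sf`` -- per-SF orientation statistics reduced to their sample SD
  across the 50 SFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .conditions import all_conditions
from .stimuli import (ELEMENT_DIAMETERS, TextureImage, apply_jitter,
                      make_grid, render_texture)

__all__ = [
    "LogGaborBank", "EnergySpectrum", "DistributionStats",
    "build_filter_bank", "compute_energy", "mean_normalize",
    "distribution_stats", "model_parameters", "condition_parameter_table",
    "MODEL_NAMES", "MODEL_STATISTICS",
]

MODEL_NAMES = ("sf", "sf_x_ori", "ori", "ori_x_sf")

#: Statistics each model reports, in canonical order.
MODEL_STATISTICS = {
    "sf": ("kurtosis", "skew", "fwhm", "peakedness", "sd"),
    "sf_x_ori": ("kurtosis_std", "skew_std", "fwhm_std", "peakedness_std",
                 "sd_std"),
    "ori": ("kurtosis", "skew", "peakedness", "sd"),
    "ori_x_sf": ("kurtosis_std", "skew_std", "peakedness_std", "sd_std"),
}

#: Normalization mode each model's statistics assume.
MODEL_NORMALIZATION = {
    "sf": "equate-orientations",
    "sf_x_ori": "equate-orientations",
    "ori": "equate-sfs",
    "ori_x_sf": "equate-sfs",
}


@dataclass
class LogGaborBank:
    """Polar-separable log-Gabor filter bank in the frequency domain.

    The radial transfer of channel m is a Gaussian on log frequency,
    exp(-(ln(f/f_m))^2 / (2 ln(sigma_on_f)^2)) with zero DC response;
    the angular transfer of channel n is a Gaussian in orientation with
    spread ``ori_spread_factor`` x (half the orientation spacing).  Centre
    frequencies are log-spaced so successive SFs keep a constant ratio
    ((512 / 0.23)^(1/49) ~ 1.17 at the defaults); channels above the image
    Nyquist frequency are retained as frequency-domain truncations.
    """

    image_size: int = 256
    n_sf: int = 50
    sf_min_cpi: float = 0.23
    sf_max_cpi: float = 512.0
    n_orientations: int = 12
    sigma_on_f: float = 0.65
    ori_spread_factor: float = 1.2
    center_sfs: np.ndarray = field(init=False)
    orientations_deg: np.ndarray = field(init=False)
    _radial_sq: np.ndarray = field(init=False, repr=False)
    _angular_sq: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.n_sf < 2:
            raise ValueError("n_sf must be >= 2")
        if not 0 < self.sf_min_cpi < self.sf_max_cpi:
            raise ValueError("need 0 < sf_min_cpi < sf_max_cpi")
        self.center_sfs = np.geomspace(self.sf_min_cpi, self.sf_max_cpi,
                                       self.n_sf)
        self.orientations_deg = np.arange(self.n_orientations) * (
            180.0 / self.n_orientations)

        n = self.image_size
        f = np.fft.fftfreq(n) * n                 # cycles per image
        fx, fy = np.meshgrid(f, f)
        radius = np.hypot(fx, fy).ravel()
        theta = np.arctan2(fy, fx).ravel()

        with np.errstate(divide="ignore"):
            logr = np.log(np.where(radius > 0, radius, 1.0))
        denom = 2.0 * np.log(self.sigma_on_f) ** 2
        rad = np.exp(-(logr[None, :] - np.log(self.center_sfs)[:, None]) ** 2
                     / denom)
        rad[:, radius == 0] = 0.0                 # zero DC gain
        self._radial_sq = rad ** 2

        spacing = np.pi / self.n_orientations
        sigma_theta = self.ori_spread_factor * spacing / 2.0
        angles = np.deg2rad(self.orientations_deg)
        # single-sided (analytic) angular window: wrapped distance to the
        # channel angle on the full circle
        d = theta[None, :] - angles[:, None]
        d = np.angle(np.exp(1j * d))
        ang = np.exp(-d ** 2 / (2.0 * sigma_theta ** 2))
        self._angular_sq = ang ** 2

    @property
    def n_filters(self) -> int:
        return self.n_sf * self.n_orientations

    @property
    def filter_sizes(self) -> np.ndarray:
        """Spatial envelope scale per SF channel: image size / centre SF."""
        return self.image_size / self.center_sfs

    def transfer(self, m: int, n: int) -> np.ndarray:
        """Frequency-domain magnitude of filter (SF index m, orientation n)."""
        shape = (self.image_size, self.image_size)
        return np.sqrt(self._radial_sq[m] * self._angular_sq[n]).reshape(shape)

    def rms_responses(self, image: np.ndarray) -> np.ndarray:
        """(n_sf, n_orientations) pixelwise RMS magnitude of each response.

        Uses Parseval: for a complex response r = ifft2(H . F),
        mean |r|^2 = sum |H F|^2 / N^4.
        """
        F = np.fft.fft2(image)
        power = (F.real ** 2 + F.imag ** 2).ravel()
        e2 = (self._radial_sq * power[None, :]) @ self._angular_sq.T
        return np.sqrt(e2) / self.image_size ** 2


def build_filter_bank(n_sf: int = 50, sf_min_cpi: float = 0.23,
                      sf_max_cpi: float = 512.0, n_orientations: int = 12,
                      image_size: int = 256, **kwargs) -> LogGaborBank:
    """Construct a :class:`LogGaborBank` (defaults: 600 filters)."""
    return LogGaborBank(image_size=image_size, n_sf=n_sf,
                        sf_min_cpi=sf_min_cpi, sf_max_cpi=sf_max_cpi,
                        n_orientations=n_orientations, **kwargs)


@dataclass
class EnergySpectrum:
    """Raw and normalized filter-bank energies of one image or condition."""

    re: np.ndarray                  # (n_sf, n_ori) size-normalized RMS
    sf_cpi: np.ndarray
    orientations_deg: np.ndarray
    ne: np.ndarray | None = None
    normalization: str = "none"

    @property
    def n_sf(self) -> int:
        return self.re.shape[0]

    @property
    def n_orientations(self) -> int:
        return self.re.shape[1]

    @property
    def log_sf(self) -> np.ndarray:
        return np.log10(self.sf_cpi)


def compute_energy(image: TextureImage | np.ndarray, bank: LogGaborBank,
                   *, square_pixels: bool = True) -> EnergySpectrum:
    """Raw size-normalized RMS energy of an image through the bank.

    Pixels are squared first (second-order contrast energy; set
    ``square_pixels=False`` for the linear variant) and each channel's RMS
    response is divided by the square of the filter's spatial size.
    """
    pixels = image.pixels if isinstance(image, TextureImage) else np.asarray(image)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError("image must be a square 2-D raster")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image contains non-finite values")
    if pixels.shape[0] != bank.image_size:
        raise ValueError(
            f"image size {pixels.shape[0]} does not match bank size "
            f"{bank.image_size}")
    work = pixels ** 2 if square_pixels else pixels
    rms = bank.rms_responses(work)
    re = rms / bank.filter_sizes[:, None] ** 2
    return EnergySpectrum(re=re, sf_cpi=bank.center_sfs.copy(),
                          orientations_deg=bank.orientations_deg.copy())


NormalizationMode = Literal["equate-orientations", "equate-sfs", "none",
                            "literal-orientation", "literal-sf"]


def mean_normalize(spectrum: EnergySpectrum,
                   mode: NormalizationMode = "equate-orientations"
                   ) -> EnergySpectrum:
    """Mean-normalize channel energies so totals are equated.

    ``equate-orientations`` divides each orientation channel by its mean
    energy across SF, so every orientation's total over the 50 SFs is the
    same constant (50) for every orientation and condition.  ``equate-sfs``
    divides each SF channel by its mean across orientations (total 12 per
    SF).  The ``literal-*`` modes divide along the opposite axis (each SF
    by its orientation mean, or each orientation by its SF mean *per SF*),
    kept for audit: they force the downstream marginal to be identically
    flat and are not used by the encoding models.
    """
    re = spectrum.re
    if mode == "none":
        ne = re.copy()
    elif mode == "equate-orientations":
        ne = re / re.mean(axis=0, keepdims=True)
    elif mode == "equate-sfs":
        ne = re / re.mean(axis=1, keepdims=True)
    elif mode == "literal-orientation":
        # as printed for the SF-model normalization: divide each SF row by
        # its mean across orientations (makes the SF marginal constant)
        ne = re / re.mean(axis=1, keepdims=True)
    elif mode == "literal-sf":
        ne = re / re.mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(spectrum, ne=ne, normalization=mode)


@dataclass
class DistributionStats:
    """Shape statistics of one marginal energy distribution."""

    kurtosis: float
    skew: float
    peakedness: float
    sd: float
    fwhm: float | None = None

    def as_dict(self, include_fwhm: bool = True) -> dict[str, float]:
        d = {"kurtosis": self.kurtosis, "skew": self.skew,
             "peakedness": self.peakedness, "sd": self.sd}
        if include_fwhm:
            d["fwhm"] = self.fwhm
        return d


def _fwhm(values: np.ndarray, axis: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation on ``axis``.

    Uses the outermost half-maximum crossings; emits a warning when the
    profile re-crosses the half level in between (multimodality).  Edges
    that never fall below the half level contribute the axis endpoint.
    """
    peak_idx = int(np.argmax(values))
    half = values[peak_idx] / 2.0
    above = values >= half

    crossings = np.flatnonzero(np.diff(above.astype(int)) != 0)
    if len(crossings) > 2:
        warnings.warn("multiple half-maximum crossings; using outermost "
                      "(multimodal distribution)", RuntimeWarning,
                      stacklevel=3)

    def interp(i):  # crossing between samples i and i+1
        v0, v1 = values[i], values[i + 1]
        t = (half - v0) / (v1 - v0)
        return axis[i] + t * (axis[i + 1] - axis[i])

    rising = [i for i in crossings if values[i] < half <= values[i + 1]]
    falling = [i for i in crossings if values[i] >= half > values[i + 1]]
    left = interp(rising[0]) if rising else axis[0]
    right = interp(falling[-1]) if falling else axis[-1]
    return float(right - left)


def distribution_stats(values: Sequence[float],
                       axis: Sequence[float] | None = None,
                       *, include_fwhm: bool = True) -> DistributionStats:
    """Population-moment shape statistics of a marginal distribution.

    Kurtosis and skew are moment ratios of the energy *values* themselves
    (E(x - mu)^4 / sigma^4 and E(x - mu)^3 / sigma^3 with population, 1/N,
    moments); peakedness is the maximum value and ``sd`` the population
    standard deviation.  FWHM is measured on ``axis`` (default: unit-spaced
    sample positions) and skipped with ``include_fwhm=False`` for
    distributions whose shape makes a half-maximum width meaningless.
    A constant vector has sigma = 0 and undefined moment ratios: rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D vector of length >= 3")
    mu = x.mean()
    sigma2 = np.mean((x - mu) ** 2)
    if sigma2 == 0:
        raise ValueError("constant vector: moment statistics undefined "
                         "(sigma = 0)")
    sigma = np.sqrt(sigma2)
    kurt = float(np.mean((x - mu) ** 4) / sigma ** 4)
    skew = float(np.mean((x - mu) ** 3) / sigma ** 3)
    fwhm = None
    if include_fwhm:
        ax = np.arange(len(x), dtype=float) if axis is None else np.asarray(axis, dtype=float)
        if ax.shape != x.shape:
            raise ValueError("axis must match values in length")
        fwhm = _fwhm(x, ax)
    return DistributionStats(kurtosis=kurt, skew=skew,
                             peakedness=float(x.max()), sd=float(sigma),
                             fwhm=fwhm)


def model_parameters(spectrum: EnergySpectrum, model: str) -> dict[str, float]:
    """Read-out statistics of one encoding model for one spectrum.

    The spectrum must be normalized with the mode the model assumes
    (``equate-orientations`` for the SF-based models, ``equate-sfs`` for
    the orientation-based ones).  Cross-channel standard deviations use the
    sample (N-1) divisor.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"model must be one of {MODEL_NAMES}, got {model!r}")
    expected = MODEL_NORMALIZATION[model]
    if spectrum.ne is None or spectrum.normalization != expected:
        raise ValueError(
            f"model {model!r} requires a spectrum normalized with "
            f"{expected!r} (got {spectrum.normalization!r})")
    ne = spectrum.ne
    log_sf = spectrum.log_sf

    if model == "sf":
        x = ne.mean(axis=1)
        return distribution_stats(x, axis=log_sf).as_dict()
    if model == "ori":
        x = ne.mean(axis=0)
        return distribution_stats(x, include_fwhm=False).as_dict(False)
    if model == "sf_x_ori":
        per_channel = [distribution_stats(ne[:, n], axis=log_sf)
                       for n in range(spectrum.n_orientations)]
        return {f"{stat}_std": float(np.std(
                    [getattr(s, stat) for s in per_channel], ddof=1))
                for stat in ("kurtosis", "skew", "fwhm", "peakedness", "sd")}
    per_sf = [distribution_stats(ne[m, :], include_fwhm=False)
              for m in range(spectrum.n_sf)]
    return {f"{stat}_std": float(np.std(
                [getattr(s, stat) for s in per_sf], ddof=1))
            for stat in ("kurtosis", "skew", "peakedness", "sd")}


def condition_parameter_table(
    models: Sequence[str] = MODEL_NAMES,
    *,
    n_samples: int = 10,
    seed: int | None = 0,
    bank: LogGaborBank | None = None,
    raster_size: int = 256,
    square_pixels: bool = True,
    placement_policy: str = "global",
) -> pd.DataFrame:
    """Per-condition encoding-model parameters from freshly generated stimuli.

    For each of the 45 conditions, ``n_samples`` textures are generated
    (jittered with overlap rejection and rendered), analysed through the
    bank, and the requested models' statistics averaged over samples.
    Columns are ``<model>_<statistic>``; rows follow the canonical
    condition order.
    """
    for model in models:
        if model not in MODEL_NAMES:
            raise ValueError(f"unknown model {model!r}")
    if bank is None:
        bank = LogGaborBank(image_size=raster_size)
    rng = np.random.default_rng(seed)
    need_ori = any(MODEL_NORMALIZATION[m] == "equate-sfs" for m in models)
    need_sf = any(MODEL_NORMALIZATION[m] == "equate-orientations"
                  for m in models)

    rows = []
    for cond in all_conditions():
        acc: dict[str, list[float]] = {}
        grid = make_grid(cond.spacing_level)
        diameter = ELEMENT_DIAMETERS[cond.size_level]
        for _ in range(n_samples):
            layout = apply_jitter(grid, cond.jitter_level, diameter,
                                  seed=rng, policy=placement_policy)
            image = render_texture(layout, cond.size_level,
                                   raster_size=bank.image_size)
            spec = compute_energy(image, bank, square_pixels=square_pixels)
            spec_sf = mean_normalize(spec, "equate-orientations") if need_sf else None
            spec_ori = mean_normalize(spec, "equate-sfs") if need_ori else None
            for model in models:
                source = (spec_sf if MODEL_NORMALIZATION[model]
                          == "equate-orientations" else spec_ori)
                for stat, value in model_parameters(source, model).items():
                    acc.setdefault(f"{model}_{stat}", []).append(value)
        rows.append({name: float(np.mean(vals)) for name, vals in acc.items()})
    table = pd.DataFrame(rows, index=range(len(rows)))
    table.index.name = "condition"
    return table
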