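"""Lattice-texture stimulus generation and observer simulation.

Textures are square lattices of zero-balanced difference-of-Gaussians (DoG)
micropatterns whose positions are perturbed by uniform jitter, presented
within a circular aperture.  All geometry is expressed in arcmin of visual
angle.  The module also provides the paired-comparison observer simulator:
each condition is assigned a normally distributed internal regularity value
and the stimulus drawing the larger value on a trial is chosen.

Three groups of facts fix the default geometry:

* notional grids: 9x9 at 17.52 arcmin pitch, 7x7 at 21.41, 6x6 at 25.30
  for spacing levels 1-3;
* element diameters 9.73, 12.65, 15.57 arcmin for size levels 1-3, with the
  DoG centre-Gaussian sigma equal to diameter / 4 (2.43 arcmin at size 1)
  and a surround of twice that sigma, amplitude-balanced to zero integral;
* jitter ranges 2.92, 3.89, 5.84, 7.79, 9.73 arcmin for levels 1-5,
  interpreted as the *full width* of the per-coordinate uniform offset
  distribution.  Under that reading the expected Euclidean displacement is
  (w/2) * (sqrt(2) + asinh(1)) / 3, i.e. 1.12, 1.49, 2.23, 2.98 and 3.72
  arcmin for the five levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .conditions import StimulusCondition, all_conditions

__all__ = [
    "GridSpec",
    "ElementLayout",
    "TextureImage",
    "SimulatedObserver",
    "GRID_SPECS",
    "ELEMENT_DIAMETERS",
    "JITTER_RANGES",
    "APERTURE_DEG",
    "make_grid",
    "apply_jitter",
    "measure_displacement",
    "render_texture",
    "mean_displacement_analytic",
    "simulate_observer",
    "synthetic_observer_means",
]

APERTURE_DEG = 2.91          # circular aperture diameter, degrees
ARCMIN_PER_DEG = 60.0

#: Jitter range (full width of the per-coordinate uniform offset), arcmin.
JITTER_RANGES = {1: 2.92, 2: 3.89, 3: 5.84, 4: 7.79, 5: 9.73}

#: DoG element diameter, arcmin, per size level.
ELEMENT_DIAMETERS = {1: 9.73, 2: 12.65, 3: 15.57}


@dataclass(frozen=True)
class GridSpec:
    """Notional square lattice for one spacing level."""

    n_per_side: int
    pitch: float                       # inter-element distance, arcmin
    aperture_diameter: float = APERTURE_DEG   # degrees

    @property
    def n_elements(self) -> int:
        return self.n_per_side ** 2

    @property
    def extent(self) -> float:
        """Edge length of the lattice (outermost centre to centre), arcmin."""
        return (self.n_per_side - 1) * self.pitch


GRID_SPECS = {
    1: GridSpec(9, 17.52),
    2: GridSpec(7, 21.41),
    3: GridSpec(6, 25.30),
}


@dataclass
class ElementLayout:
    """Element geometry of one texture: jittered and notional positions."""

    centers: np.ndarray          # (n, 2) jittered positions, arcmin
    grid_centers: np.ndarray     # (n, 2) unjittered lattice positions
    element_diameter: float | None = None   # arcmin; None when unjittered
    spacing_level: int | None = None
    jitter_level: int | None = None
    seed: int | None = None

    @property
    def offsets(self) -> np.ndarray:
        return self.centers - self.grid_centers

    @property
    def displacements(self) -> np.ndarray:
        """Per-element Euclidean offset magnitude, arcmin."""
        return np.hypot(self.offsets[:, 0], self.offsets[:, 1])

    def min_pair_distance(self) -> float:
        d = np.sqrt(((self.centers[:, None, :]
                      - self.centers[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        return float(d.min())

    def to_frame(self):
        """Tabular form: element index, grid x/y, jittered x/y (arcmin)."""
        import pandas as pd

        return pd.DataFrame({
            "element": np.arange(len(self.centers)),
            "grid_x": self.grid_centers[:, 0],
            "grid_y": self.grid_centers[:, 1],
            "x": self.centers[:, 0],
            "y": self.centers[:, 1],
        })


@dataclass
class TextureImage:
    """Square luminance raster of a rendered texture."""

    pixels: np.ndarray           # (n, n) normalized luminance
    pixel_pitch: float           # arcmin per pixel
    background_level: float = 0.0
    clipped_elements: int = 0    # elements extending beyond the raster
    excluded_elements: int = 0   # elements dropped at the aperture edge

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def make_grid(spacing_level: int) -> ElementLayout:
    """Centred, unjittered square lattice for a spacing level (1-3)."""
    if spacing_level not in GRID_SPECS:
        raise ValueError(
            f"spacing_level must be one of {sorted(GRID_SPECS)}, "
            f"got {spacing_level}")
    spec = GRID_SPECS[spacing_level]
    coords = (np.arange(spec.n_per_side) - (spec.n_per_side - 1) / 2.0) * spec.pitch
    xx, yy = np.meshgrid(coords, coords)
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    return ElementLayout(centers=centers.copy(), grid_centers=centers,
                         spacing_level=spacing_level)


def mean_displacement_analytic(width: float) -> float:
    """Expected Euclidean displacement for uniform jitter of full width ``width``.

    With x, y independent uniform on [-w/2, w/2],
    E sqrt(x^2 + y^2) = (w/2) (sqrt(2) + ln(1 + sqrt(2))) / 3.
    """
    a = width / 2.0
    return a * (math.sqrt(2.0) + math.log(1.0 + math.sqrt(2.0))) / 3.0


def _redraw(rng, grid_point, half_width, others, min_sep, max_redraws,
            context, strict=True):
    """Draw a jittered position for one element, avoiding ``others``.

    With ``strict=False`` the last candidate is returned even if it still
    overlaps (the caller resolves the conflict in a later sweep).
    """
    min_sep_sq = min_sep * min_sep
    cand = grid_point
    for _ in range(max_redraws):
        cand = grid_point + rng.uniform(-half_width, half_width, 2)
        if others.shape[0] == 0 or min_sep <= 0.0:
            return cand
        d2 = ((others - cand) ** 2).sum(axis=1)
        if d2.min() >= min_sep_sq:
            return cand
    if strict:
        raise RuntimeError(
            f"could not place element without overlap after {max_redraws} "
            f"redraws ({context})")
    return cand


def apply_jitter(
    layout: ElementLayout,
    jitter_level: int,
    element_diameter: float | None = None,
    seed: int | np.random.Generator | None = None,
    *,
    jitter_range: float | None = None,
    min_separation: float | None = None,
    policy: Literal["global", "sequential"] = "global",
    max_redraws: int = 1000,
    max_sweeps: int = 500,
) -> ElementLayout:
    """Jitter element positions uniformly, rejecting overlapping placements.

    Each element's offset is drawn independently per coordinate from a
    uniform distribution of full width equal to the level's jitter range
    (``jitter_range`` overrides the level lookup).  Two elements overlap when
    their centre distance falls below ``min_separation`` (default: the
    element diameter, i.e. touching equal circles).  Pass
    ``min_separation=0`` (or ``element_diameter=None``) for unconstrained
    jitter.

    Two placement policies are available:

    ``"global"`` (default)
        All elements are jittered, then any element overlapping any other is
        redrawn within the same range, repeatedly, until the entire layout is
        overlap-free.  The final configuration is valid against *all* other
        elements, which is the constraint the displacement statistics of the
        study stimuli reflect.
    ``"sequential"``
        Elements are placed in raster order and each is only checked against
        the ones already placed.

    Raises ``RuntimeError`` naming the condition when a valid placement
    cannot be found within ``max_redraws`` draws per element (or the layout
    does not settle within ``max_sweeps`` global sweeps).
    """
    if jitter_level not in JITTER_RANGES and jitter_range is None:
        raise ValueError(
            f"jitter_level must be one of {sorted(JITTER_RANGES)}, "
            f"got {jitter_level}")
    width = JITTER_RANGES[jitter_level] if jitter_range is None else jitter_range
    if min_separation is None:
        min_separation = 0.0 if element_diameter is None else float(element_diameter)

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    grid = layout.grid_centers
    n = grid.shape[0]
    context = (f"spacing={layout.spacing_level}, jitter level={jitter_level}, "
               f"min separation={min_separation:.2f} arcmin")

    if width == 0.0:
        centers = grid.copy()
    elif policy == "sequential":
        centers = np.empty_like(grid)
        for i in range(n):
            centers[i] = _redraw(rng, grid[i], width / 2, centers[:i],
                                 min_separation, max_redraws,
                                 f"element {i}, {context}")
    elif policy == "global":
        centers = grid + rng.uniform(-width / 2, width / 2, grid.shape)
        if min_separation > 0.0:
            min_sep_sq = min_separation ** 2
            for _ in range(max_sweeps):
                d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
                np.fill_diagonal(d2, np.inf)
                bad = np.flatnonzero((d2 < min_sep_sq).any(axis=1))
                if bad.size == 0:
                    break
                for i in bad:
                    others = np.delete(centers, i, axis=0)
                    centers[i] = _redraw(rng, grid[i], width / 2, others,
                                         min_separation, max_redraws,
                                         f"element {i}, {context}",
                                         strict=False)
            else:
                raise RuntimeError(
                    f"layout did not settle in {max_sweeps} sweeps ({context})")
    else:
        raise ValueError(f"unknown placement policy {policy!r}")

    seed_record = seed if isinstance(seed, int) else None
    return ElementLayout(centers=centers, grid_centers=grid,
                         element_diameter=element_diameter,
                         spacing_level=layout.spacing_level,
                         jitter_level=jitter_level, seed=seed_record)


@dataclass
class DisplacementSummary:
    """Mean/SD of per-image mean Euclidean element displacement, arcmin."""

    per_image_means: np.ndarray
    mean: float
    sd: float


def measure_displacement(layouts: Sequence[ElementLayout]) -> DisplacementSummary:
    """Summarise element displacement over a collection of layouts.

    Each layout contributes the mean Euclidean offset of its elements; the
    summary reports those per-image means together with their grand mean
    and standard deviation.
    """
    per_image = np.array([float(lay.displacements.mean()) for lay in layouts])
    return DisplacementSummary(per_image_means=per_image,
                               mean=float(per_image.mean()),
                               sd=float(per_image.std()))


def dog_profile(r: np.ndarray, diameter: float, amplitude: float = 1.0,
                surround_sigma_ratio: float = 2.0) -> np.ndarray:
    """Radial zero-balanced DoG profile (light centre, dark surround).

    Centre sigma is diameter / 4; the surround sigma is
    ``surround_sigma_ratio`` times larger with its amplitude set so the 2-D
    integral vanishes (A_c sigma_c^2 = A_s sigma_s^2).
    """
    sigma_c = diameter / 4.0
    sigma_s = surround_sigma_ratio * sigma_c
    a_s = amplitude / surround_sigma_ratio ** 2
    return (amplitude * np.exp(-r ** 2 / (2 * sigma_c ** 2))
            - a_s * np.exp(-r ** 2 / (2 * sigma_s ** 2)))


def render_texture(
    layout: ElementLayout,
    size_level: int | None = None,
    raster_size: int = 256,
    *,
    element_diameter: float | None = None,
    aperture_deg: float = APERTURE_DEG,
    background_level: float = 0.0,
    amplitude: float = 1.0,
    surround_sigma_ratio: float = 2.0,
    apply_aperture: bool = True,
) -> TextureImage:
    """Render a layout as a square raster of DoG micropatterns.

    The raster spans the circular aperture (default 2.91 deg, giving about
    0.682 arcmin/pixel at 256 pixels).  The notional lattices extend
    slightly beyond the circular aperture at their corners, so elements
    whose nominal footprint would cross the aperture edge are not drawn
    (``excluded_elements`` counts them); this keeps the image mean at the
    background level, as the zero-balanced DoG profile demands.  Elements
    whose residual Gaussian tails extend beyond the raster are clipped
    with a ``clipped_elements`` count.
    """
    if element_diameter is None:
        if size_level is None:
            raise ValueError("provide size_level or element_diameter")
        if size_level not in ELEMENT_DIAMETERS:
            raise ValueError(
                f"size_level must be one of {sorted(ELEMENT_DIAMETERS)}, "
                f"got {size_level}")
        element_diameter = ELEMENT_DIAMETERS[size_level]

    aperture_arcmin = aperture_deg * ARCMIN_PER_DEG
    pitch = aperture_arcmin / raster_size          # arcmin per pixel
    img = np.zeros((raster_size, raster_size), dtype=float)

    # pixel-centre coordinates, arcmin, origin at raster centre
    coords = (np.arange(raster_size) - (raster_size - 1) / 2.0) * pitch
    support = 3.0 * surround_sigma_ratio * element_diameter / 4.0  # 3 surround sigmas
    aperture_radius = aperture_arcmin / 2.0
    clipped = 0
    excluded = 0
    for cx, cy in layout.centers:
        if apply_aperture and math.hypot(cx, cy) > (aperture_radius
                                                    - element_diameter / 2.0):
            excluded += 1
            continue
        ix0 = int(np.searchsorted(coords, cx - support))
        ix1 = int(np.searchsorted(coords, cx + support))
        iy0 = int(np.searchsorted(coords, cy - support))
        iy1 = int(np.searchsorted(coords, cy + support))
        if ix0 == 0 or iy0 == 0 or ix1 >= raster_size or iy1 >= raster_size:
            clipped += 1
        ix0, iy0 = max(ix0, 0), max(iy0, 0)
        ix1, iy1 = min(ix1, raster_size), min(iy1, raster_size)
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        xs = coords[ix0:ix1] - cx
        ys = coords[iy0:iy1] - cy
        r = np.hypot(xs[None, :], ys[:, None])
        img[iy0:iy1, ix0:ix1] += dog_profile(
            r, element_diameter, amplitude, surround_sigma_ratio)

    return TextureImage(pixels=img + background_level, pixel_pitch=pitch,
                        background_level=background_level,
                        clipped_elements=clipped,
                        excluded_elements=excluded)


def save_texture(image: TextureImage, path, *, bit_depth: int = 16,
                 metadata: dict | None = None) -> None:
    """Write a texture as a grayscale PNG/TIFF with a JSON metadata sidecar.

    Pixel values are linearly quantized to the requested bit depth; the
    sidecar (``<path>.json``) records the value range, pixel pitch and any
    extra metadata (condition levels, seed) needed to reconstruct the
    luminance raster.
    """
    from PIL import Image
    import json
    from pathlib import Path

    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    px = image.pixels
    vmin, vmax = float(px.min()), float(px.max())
    scale = (2 ** bit_depth - 1) / (vmax - vmin) if vmax > vmin else 1.0
    quant = np.round((px - vmin) * scale)
    if bit_depth == 8:
        Image.fromarray(quant.astype(np.uint8), mode="L").save(path)
    else:
        Image.fromarray(quant.astype(np.uint16), mode="I;16").save(path)
    sidecar = {
        "vmin": vmin, "vmax": vmax, "bit_depth": bit_depth,
        "pixel_pitch_arcmin": image.pixel_pitch,
        "background_level": image.background_level,
        **(metadata or {}),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_texture(path) -> tuple[TextureImage, dict]:
    """Read a texture written by :func:`save_texture` and its metadata."""
    from PIL import Image
    import json
    from pathlib import Path

    meta = json.loads(Path(str(path) + ".json").read_text())
    quant = np.asarray(Image.open(path), dtype=float)
    scale = (meta["vmax"] - meta["vmin"]) / (2 ** meta["bit_depth"] - 1)
    pixels = quant * scale + meta["vmin"]
    image = TextureImage(pixels=pixels,
                         pixel_pitch=meta["pixel_pitch_arcmin"],
                         background_level=meta["background_level"])
    return image, meta


# ---------------------------------------------------------------------------
# Observer simulation
# ---------------------------------------------------------------------------

#: Fixed per-condition SD whose paired decision noise has unit variance,
#: i.e. the scale of the probit decision model.
UNIT_DECISION_SD = 1.0 / math.sqrt(2.0)


@dataclass
class SimulatedObserver:
    """Noisy observer: one normal internal-regularity value per condition.

    On each trial one value is drawn per stimulus from the stimulus
    condition's normal distribution and the larger draw is reported as
    "more regular".  With per-condition SDs sigma_A, sigma_B the choice
    probability for pair (A, B) is Phi((mu_A - mu_B) / sqrt(sigma_A^2 +
    sigma_B^2)).  The default fixed SD of 1/sqrt(2) makes the paired noise
    SD exactly 1, the identifiability scale of the probit model, so fitted
    regularity estimates recover the means one-to-one.
    """

    condition_means: np.ndarray                  # (45,)
    sds: np.ndarray = field(default=None)        # (45,) positive
    sd_mode: Literal["fixed", "varied"] = "fixed"
    seed: int | None = None

    def __post_init__(self):
        self.condition_means = np.asarray(self.condition_means, dtype=float)
        n = self.condition_means.shape[0]
        if self.sds is None:
            self.sds = np.full(n, UNIT_DECISION_SD)
        else:
            self.sds = np.broadcast_to(
                np.asarray(self.sds, dtype=float), (n,)).copy()
        if np.any(self.sds <= 0):
            raise ValueError("observer SDs must be positive")
        if self.sd_mode == "fixed" and not np.allclose(self.sds, self.sds[0]):
            raise ValueError("fixed sd_mode requires equal SDs")


def synthetic_observer_means(
    jitter_effects: Sequence[float] = (0.0, -0.9, -1.8, -2.7, -3.6),
    spacing_effects: Sequence[float] = (0.0, 0.11, 0.25),
    size_effects: Sequence[float] = (0.0, -0.25, -0.13),
    spacing_jitter_gain: Sequence[float] = (1.25, 1.0, 0.67),
    size_jitter_gain: Sequence[float] = (0.80, 1.0, 1.21),
) -> np.ndarray:
    """Default 45-condition regularity means for a synthetic observer.

    Emulates the qualitative structure of human regularity scales: a strong
    monotone decrease with jitter, small additive spacing and size effects,
    and multiplicative spacing-x-jitter / size-x-jitter interactions (the
    jitter effect is stronger at small spacing and large size).  Values are
    in decision-noise SD units relative to the reference condition
    (spacing 1, size 1, jitter 1).
    """
    means = np.empty(len(all_conditions()))
    for cond in all_conditions():
        i, j, k = cond.spacing_level, cond.size_level, cond.jitter_level
        means[cond.index] = (spacing_effects[i - 1] + size_effects[j - 1]
                             + jitter_effects[k - 1]
                             * spacing_jitter_gain[i - 1]
                             * size_jitter_gain[j - 1])
    return means


def jitter_only_observer_means(gain: float = 2.0) -> np.ndarray:
    """Means of an idealised observer driven by jitter level only."""
    means = np.empty(len(all_conditions()))
    for cond in all_conditions():
        means[cond.index] = -gain * (cond.jitter_level - 1)
    return means


def simulate_observer(observer: SimulatedObserver,
                      pairs: Iterable[tuple[int, int]],
                      n_reps: int,
                      seed: int | np.random.Generator | None = None):
    """Simulate paired-comparison responses for a list of condition-index pairs.

    For each pair and repetition one value is drawn per condition from its
    normal distribution; the stimulus with the larger draw is chosen
    (response 0 = first stimulus judged more regular, 1 = second).  Returns a
    :class:`regtex.conjoint.PairResponseTable`.
    """
    from .conjoint import PairResponseTable, table_from_pair_counts

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pairs = list(pairs)
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    mu, sd = observer.condition_means, observer.sds
    draws_a = rng.normal(mu[a][:, None], sd[a][:, None], (len(pairs), n_reps))
    draws_b = rng.normal(mu[b][:, None], sd[b][:, None], (len(pairs), n_reps))
    # ties broken in favour of the first stimulus (probability-zero event)
    second_wins = (draws_b > draws_a).sum(axis=1)
    return table_from_pair_counts(a, b, n_reps - second_wins, n_reps)
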