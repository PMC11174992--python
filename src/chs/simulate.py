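"""Virtual landscapes and virtual species for pipeline validation.

Real niche-model studies run on downloaded climate/soil/UV rasters and
herbarium occurrences; neither can back a test suite.  This module builds
the same objects synthetically: spatially autocorrelated continuous
predictors with a requested cross-correlation structure, a patchy
categorical soil map, a virtual species whose true suitability is a known
function of a predictor subset, occurrence samples drawn from that truth,
and "future" stacks produced by additive shifts of the baseline (soil and
UV layers held fixed, matching the convention that non-climate constraints
are kept at their present state when projecting).

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .occurrences import OccurrenceSet
from .raster import GridGeoref, RasterStack

SOIL_LAYER = "soil"
UV_LAYER = "uv"


@dataclass
class LandscapeSpec:
    """Parameters of a synthetic environmental stack.

    ``cross_correlation`` is the target Pearson correlation matrix of the
    continuous climate layers (imposed by Cholesky mixing of smoothed
    Gaussian fields, so it is approximate on finite grids).
    ``correlation_length`` is the Gaussian smoothing radius in cells and
    controls spatial autocorrelation.
    """

    grid_rows: int = 100
    grid_cols: int = 100
    cell_size_deg: float = 0.05
    origin_lon: float = 100.0
    origin_lat: float = 35.0
    n_continuous: int = 4
    correlation_length: float = 8.0
    cross_correlation: np.ndarray | None = None
    n_soil_classes: int = 5
    nodata_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.n_soil_classes < 2:
            raise ValueError("need at least 2 soil classes")
        if self.cross_correlation is None:
            self.cross_correlation = np.eye(self.n_continuous)
        self.cross_correlation = np.asarray(self.cross_correlation, float)
        c = self.cross_correlation
        if c.shape != (self.n_continuous, self.n_continuous):
            raise ValueError("cross_correlation shape mismatch")
        if not np.allclose(c, c.T):
            raise ValueError("cross_correlation must be symmetric")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("cross_correlation must be positive semi-definite")

    @property
    def georef(self) -> GridGeoref:
        return GridGeoref(
            n_rows=self.grid_rows,
            n_cols=self.grid_cols,
            cell_size=self.cell_size_deg,
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
        )

    @property
    def continuous_names(self) -> list[str]:
        return [f"bio{i + 1}" for i in range(self.n_continuous)]


@dataclass
class VirtualSpecies:
    """A species with known environmental response.

    ``envelope`` responses are rectangular niches (suitability 1 inside all
    per-variable bounds, 0 outside); ``logistic`` responses pass a linear
    predictor through the inverse logit.
    """

    response_variables: list[str]
    response_kind: str  # "envelope" | "logistic"
    envelope_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    logistic_coefficients: dict[str, float] = field(default_factory=dict)
    logistic_intercept: float = 0.0
    true_suitability: np.ndarray | None = None
    true_presence_mask: np.ndarray | None = None


def _smooth_field(rng: np.random.Generator, shape, length: float) -> np.ndarray:
    """Standardized Gaussian random field with autocorrelation scale ``length``."""
    z = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(z, sigma=length, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_stack(spec: LandscapeSpec) -> RasterStack:
    """Build the synthetic predictor stack for a landscape spec.

    Continuous climate layers are smoothed white-noise fields linearly mixed
    through the Cholesky factor of ``spec.cross_correlation``; a soil class
    map comes from quantile-slicing an auxiliary smoothed field into
    contiguous patches; a UV layer is one more smoothed field.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    shape = (spec.grid_rows, spec.grid_cols)

    fields = np.stack(
        [_smooth_field(rng, shape, spec.correlation_length)
         for _ in range(spec.n_continuous)]
    )
    # eigendecomposition square root: tolerates semi-definite targets
    w, v = np.linalg.eigh(spec.cross_correlation)
    root = v @ np.diag(np.sqrt(np.clip(w, 0, None))) @ v.T
    mixed = np.tensordot(root, fields, axes=(1, 0))

    stack = RasterStack(georef=spec.georef)
    if spec.nodata_fraction > 0:
        aux = _smooth_field(rng, shape, spec.correlation_length)
        cut = np.quantile(aux, spec.nodata_fraction)
        stack.valid = aux >= cut
    for name, layer in zip(spec.continuous_names, mixed):
        stack.add_layer(name, layer)

    soil_field = _smooth_field(rng, shape, spec.correlation_length)
    edges = np.quantile(soil_field, np.linspace(0, 1, spec.n_soil_classes + 1))
    soil = np.clip(np.digitize(soil_field, edges[1:-1]), 0, spec.n_soil_classes - 1)
    stack.add_layer(SOIL_LAYER, soil.astype(float), categorical=True)

    stack.add_layer(UV_LAYER, _smooth_field(rng, shape, spec.correlation_length))
    return stack


def generate_species(stack: RasterStack, response: VirtualSpecies,
                     seed: int = 0) -> VirtualSpecies:
    """Fill in the true suitability grid for a response definition."""
    missing = [v for v in response.response_variables if v not in stack.layers]
    if missing:
        raise ValueError(f"response variables not in stack: {missing}")

    if response.response_kind == "envelope":
        suit = np.ones(stack.georef.shape)
        for name in response.response_variables:
            lo, hi = response.envelope_bounds[name]
            layer = stack.layers[name]
            suit *= ((layer >= lo) & (layer <= hi)).astype(float)
    elif response.response_kind == "logistic":
        eta = np.full(stack.georef.shape, response.logistic_intercept)
        for name in response.response_variables:
            eta = eta + response.logistic_coefficients.get(name, 0.0) * stack.layers[name]
        suit = 1.0 / (1.0 + np.exp(-eta))
    else:
        raise ValueError(f"unknown response_kind {response.response_kind!r}")

    suit = np.where(stack.valid, suit, 0.0)
    response.true_suitability = suit
    response.true_presence_mask = (suit > 0.5) & stack.valid
    return response


def sample_occurrences(species: VirtualSpecies, stack: RasterStack, n: int,
                       detection_prob: float = 1.0, seed: int = 0,
                       species_name: str = "virtualis") -> OccurrenceSet:
    """Draw ``n`` occurrence cells without replacement.

    Sampling probability is proportional to true suitability times the
    detection probability; nodata cells can never be drawn.  Returns cell
    centers as an occurrence table.
    """
    if species.true_suitability is None:
        raise ValueError("species has no true_suitability; run generate_species")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    p = species.true_suitability * detection_prob * stack.valid
    flat = p.ravel()
    eligible = np.flatnonzero(flat > 0)
    if n > eligible.size:
        raise ValueError(f"requested {n} occurrences but only {eligible.size} "
                         "cells have positive sampling probability")
    if n == 0:
        return OccurrenceSet.from_arrays(species_name, np.array([]), np.array([]))
    weights = flat[eligible] / flat[eligible].sum()
    chosen = rng.choice(eligible, size=n, replace=False, p=weights)
    row, col = np.unravel_index(chosen, stack.georef.shape)
    lon, lat = stack.georef.cell_center(row, col)
    return OccurrenceSet.from_arrays(species_name, lon, lat)


def shift_scenario(stack: RasterStack, deltas: dict[str, float]) -> RasterStack:
    """Additively shift continuous climate layers to mimic a future scenario.

    Categorical (soil) layers reject offsets; soil and UV stay unchanged in
    projections, so shifting them is a caller error.
    """
    bad = [k for k in deltas if k in stack.categorical]
    if bad:
        raise ValueError(f"cannot offset categorical layers: {bad}")
    unknown = [k for k in deltas if k not in stack.layers]
    if unknown:
        raise ValueError(f"offsets for unknown layers: {unknown}")
    out = stack.copy()
    for name, d in deltas.items():
        out.layers[name] = out.layers[name] + d
    return out
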