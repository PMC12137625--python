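"""Virtual-ecologist data generator.

Builds everything the downstream analysis consumes, with known ground
truth: spatially autocorrelated environmental and driver surfaces, true
species distributions under a logistic suitability model, occurrence
records produced by a biased and imperfect collection process, and
pixel-level quality-assessment observation stacks for the surface-water
stage.

The collection process mirrors the mechanism studied in inventory-gap
analyses: collectors visit grid cells with probabilities shaped by
"driver" covariates grouped as *safety*, *attractiveness*, and
*accessibility* (e.g. collectors avoid high-landslide-risk cells and
favour road-accessible ones), and at each visit detect each truly present
species with a fixed probability. Effort weights follow an exponential
linear model of the standardized drivers; this functional form is the
package's own choice (no canonical effort model exists in the
literature for this setting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit

from .grids import GridSystem

__all__ = [
    "Landscape",
    "TrueSpecies",
    "SamplingDesign",
    "generate_landscape",
    "generate_species",
    "species_from_coefficients",
    "effort_weights_from_bias",
    "simulate_visits",
    "sample_occurrences",
    "generate_qa_stack",
]

logger = logging.getLogger(__name__)

DRIVER_GROUPS = ("safety", "attractiveness", "accessibility")


@dataclass
class Landscape:
    """Grids of environmental predictors and collection-bias drivers.

    ``env_layers`` are z-scored Gaussian random fields (suitability
    predictors); ``driver_layers`` are nonnegative, right-skewed surfaces
    (densities, risks) assigned to one of the three driver groups.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    env_layers: dict[str, np.ndarray]
    driver_layers: dict[str, np.ndarray]
    driver_groups: dict[str, str]

    def __post_init__(self) -> None:
        shape = (self.n_rows, self.n_cols)
        for name, layer in {**self.env_layers, **self.driver_layers}.items():
            if layer.shape != shape:
                raise ValueError(f"layer '{name}' shape {layer.shape} != grid {shape}")
            if not np.all(np.isfinite(layer)):
                raise ValueError(f"layer '{name}' contains non-finite values")
        if set(self.driver_groups) != set(self.driver_layers):
            raise ValueError("driver_groups must cover exactly the driver layers")
        bad = set(self.driver_groups.values()) - set(DRIVER_GROUPS)
        if bad:
            raise ValueError(f"unknown driver groups: {bad}")

    @property
    def grid(self) -> GridSystem:
        return GridSystem(self.n_rows, self.n_cols, cell_size=self.cell_size)

    def env_matrix(self) -> np.ndarray:
        """Cells x env-layers design matrix (row-major flattening)."""
        return np.column_stack([g.ravel() for g in self.env_layers.values()])


@dataclass
class TrueSpecies:
    """Ground-truth distribution of one virtual species."""

    species_id: str
    beta: np.ndarray          # coefficients over env layers
    intercept: float
    true_suitability: np.ndarray   # in [0, 1]
    true_presence: np.ndarray      # binary
    prevalence: float

    def presence_cells(self) -> set[tuple[int, int]]:
        rows, cols = np.nonzero(self.true_presence)
        return set(zip(rows.tolist(), cols.tolist()))


@dataclass
class SamplingDesign:
    """Parameters of the simulated collection campaign.

    ``effort_weights`` may be left None, in which case
    :func:`sample_occurrences` derives them from its ``driver_bias``
    argument. ``exhaustive=True`` replaces the multinomial allocation with
    exactly one visit to every cell (a census design).
    """

    total_effort: int
    detection_prob: float = 1.0
    seed: int = 0
    effort_weights: np.ndarray | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.total_effort < 1 and not self.exhaustive:
            raise ValueError("total_effort must be >= 1")
        if not (0 < self.detection_prob <= 1):
            raise ValueError("detection_prob must be in (0, 1]")
        if self.effort_weights is not None:
            s = float(np.sum(self.effort_weights))
            if abs(s - 1.0) > 1e-9:
                raise ValueError("effort_weights must sum to 1")
            if np.any(self.effort_weights < 0):
                raise ValueError("effort_weights must be nonnegative")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], smoothness: float) -> np.ndarray:
    """Z-scored Gaussian random field; sigma of the filter in cell units."""
    field_ = rng.standard_normal(shape)
    if smoothness > 0:
        field_ = gaussian_filter(field_, sigma=smoothness, mode="reflect")
    sd = field_.std()
    if sd == 0:  # pathological but possible at extreme smoothing
        return np.zeros(shape)
    return (field_ - field_.mean()) / sd


def generate_landscape(
    n_rows: int,
    n_cols: int,
    n_env: int,
    n_drivers_per_group: int,
    smoothness: float = 3.0,
    seed: int = 0,
    cell_size: float = 100.0,
    driver_scale: float = 10.0,
) -> Landscape:
    """Generate a landscape of autocorrelated env and driver surfaces.

    Env layers are z-scored smoothed white noise. Driver layers are
    ``driver_scale * exp(z)`` of independent smoothed fields — nonnegative
    and right-skewed like the density/risk covariates they stand in for, so
    the log10(n+1) transform used downstream is meaningful.
    """
    if n_rows < 4 or n_cols < 4:
        raise ValueError("n_rows and n_cols must be >= 4")
    if n_env < 2:
        raise ValueError("n_env must be >= 2")
    if n_drivers_per_group < 1:
        raise ValueError("n_drivers_per_group must be >= 1")
    if smoothness < 0:
        raise ValueError("smoothness must be nonnegative")

    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)
    env_layers = {f"env_{i + 1}": _smooth_field(rng, shape, smoothness) for i in range(n_env)}
    driver_layers: dict[str, np.ndarray] = {}
    driver_groups: dict[str, str] = {}
    for group in DRIVER_GROUPS:
        for j in range(n_drivers_per_group):
            name = f"{group}_{j + 1}"
            driver_layers[name] = driver_scale * np.exp(_smooth_field(rng, shape, smoothness))
            driver_groups[name] = group
    return Landscape(n_rows, n_cols, cell_size, env_layers, driver_layers, driver_groups)


def species_from_coefficients(
    landscape: Landscape,
    species_id: str,
    beta: np.ndarray,
    intercept: float,
    seed: int = 0,
) -> TrueSpecies:
    """Build a species from explicit logistic coefficients.

    Suitability is ``logistic(intercept + beta . env)`` per cell; presence is
    a Bernoulli draw from the suitability.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(landscape.env_layers),):
        raise ValueError("beta length must match the number of env layers")
    eta = intercept + landscape.env_matrix() @ beta
    suit = expit(eta).reshape(landscape.n_rows, landscape.n_cols)
    rng = np.random.default_rng(seed)
    presence = (rng.random(suit.shape) < suit).astype(np.int8)
    return TrueSpecies(
        species_id=species_id,
        beta=beta,
        intercept=float(intercept),
        true_suitability=suit,
        true_presence=presence,
        prevalence=float(presence.mean()),
    )


def _calibrate_intercept(eta0: np.ndarray, target: float) -> float:
    """Intercept such that mean(logistic(eta0 + b)) == target."""

    def f(b: float) -> float:
        return float(expit(eta0 + b).mean()) - target

    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:  # can't happen for target in (0,1), guard anyway
        return 0.0
    return brentq(f, lo, hi, xtol=1e-10)


def generate_species(
    landscape: Landscape,
    n_species: int,
    beta_scale: float = 1.5,
    seed: int = 0,
) -> list[TrueSpecies]:
    """Generate virtual species with logistic suitability over the env layers.

    Coefficients are Normal(0, beta_scale); each species' intercept is
    calibrated by root finding so that its expected prevalence hits a target
    drawn uniformly from [0.05, 0.5] — the median prevalence therefore falls
    inside that band by construction.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if beta_scale <= 0:
        raise ValueError("beta_scale must be positive")
    rng = np.random.default_rng(seed)
    env = landscape.env_matrix()
    out: list[TrueSpecies] = []
    for i in range(n_species):
        beta = rng.normal(0.0, beta_scale, size=env.shape[1])
        target = rng.uniform(0.05, 0.5)
        intercept = _calibrate_intercept(env @ beta, target)
        sp_seed = int(rng.integers(0, 2**31 - 1))
        out.append(
            species_from_coefficients(landscape, f"species_{i + 1:03d}", beta, intercept, seed=sp_seed)
        )
    return out


def effort_weights_from_bias(
    landscape: Landscape, driver_bias: dict[str, float] | None
) -> np.ndarray:
    """Per-cell visit probabilities: exp of a linear score on z-scored drivers.

    An empty/None bias map yields uniform weights. Weights sum to 1.
    """
    shape = (landscape.n_rows, landscape.n_cols)
    score = np.zeros(shape)
    if driver_bias:
        unknown = set(driver_bias) - set(landscape.driver_layers)
        if unknown:
            raise ValueError(f"driver_bias refers to unknown drivers: {sorted(unknown)}")
        for name, b in driver_bias.items():
            layer = landscape.driver_layers[name]
            sd = layer.std()
            z = (layer - layer.mean()) / sd if sd > 0 else np.zeros(shape)
            score += b * z
    w = np.exp(score - score.max())
    return w / w.sum()


def simulate_visits(
    design: SamplingDesign,
    landscape: Landscape,
    driver_bias: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-cell visit counts for the campaign (integer grid).

    Multinomial allocation of ``total_effort`` over cells with the design's
    (or bias-derived) weights; exhaustive designs visit every cell once.
    """
    if design.exhaustive:
        return np.ones((landscape.n_rows, landscape.n_cols), dtype=int)
    if design.effort_weights is not None:
        w = np.asarray(design.effort_weights, dtype=float)
        if w.shape != (landscape.n_rows, landscape.n_cols):
            raise ValueError("effort_weights shape must match the landscape")
    else:
        w = effort_weights_from_bias(landscape, driver_bias)
    rng = np.random.default_rng(design.seed)
    counts = rng.multinomial(design.total_effort, w.ravel())
    return counts.reshape(landscape.n_rows, landscape.n_cols)


def sample_occurrences(
    species: list[TrueSpecies],
    design: SamplingDesign,
    driver_bias: dict[str, float] | None,
    landscape: Landscape,
) -> pd.DataFrame:
    """Simulate the collection campaign and return an occurrence table.

    For every visit to a cell, each species truly present there is recorded
    independently with ``detection_prob``; each record's coordinates are the
    cell's extent jittered uniformly (so downstream point-to-cell assignment
    is exercised). Columns: species, lon, lat, source, flags.
    """
    if not species:
        raise ValueError("species list must be non-empty")
    visits = simulate_visits(design, landscape, driver_bias)
    rng = np.random.default_rng(None if design.seed is None else design.seed + 1)
    s = landscape.cell_size
    rows_out: list[tuple[str, float, float]] = []
    visited = np.nonzero(visits)
    for r, c in zip(*visited):
        v = int(visits[r, c])
        for sp in species:
            if not sp.true_presence[r, c]:
                continue
            n_rec = int(rng.binomial(v, design.detection_prob))
            if n_rec == 0:
                continue
            u = rng.random(n_rec)
            t = rng.random(n_rec)
            xs = (c + u) * s
            ys = (r + t) * s
            for x, y in zip(xs, ys):
                rows_out.append((sp.species_id, float(x), float(y)))
    df = pd.DataFrame(rows_out, columns=["species", "lon", "lat"])
    df["source"] = "simulated"
    df["flags"] = ""
    logger.info("sampled %d occurrence records from %d visits", len(df), int(visits.sum()))
    return df


def generate_qa_stack(
    n_rows: int,
    n_cols: int,
    n_obs: int,
    water_prob: np.ndarray,
    cloud_prob: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate per-pixel satellite observation stacks.

    Each pixel is observed ``n_obs`` times; an observation survives QA
    screening with probability ``1 - cloud_prob``, and a surviving
    observation shows water with the pixel's ``water_prob``. Returns
    ``(valid_count, water_count)`` integer grids with
    ``water_count <= valid_count`` everywhere.
    """
    water_prob = np.asarray(water_prob, dtype=float)
    if water_prob.shape != (n_rows, n_cols):
        raise ValueError("water_prob must have shape (n_rows, n_cols)")
    if np.any((water_prob < 0) | (water_prob > 1)):
        raise ValueError("water_prob must lie in [0, 1]")
    if not (0 <= cloud_prob < 1):
        raise ValueError("cloud_prob must be in [0, 1)")
    if n_obs < 0:
        raise ValueError("n_obs must be nonnegative")
    rng = np.random.default_rng(seed)
    valid = rng.binomial(n_obs, 1.0 - cloud_prob, size=(n_rows, n_cols))
    water = rng.binomial(valid, water_prob)
    return valid, water
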