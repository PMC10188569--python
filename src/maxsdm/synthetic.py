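"""Synthetic bioclimatic landscapes with a known true suitability surface.

The generator emulates the structure of a WorldClim-style predictor stack:
~19 spatially smooth, mutually correlated layers (temperature-like,
precipitation-like and seasonality-like ranges), a true suitability surface
driven by three of them through plateau-Gaussian responses, occurrence
points sampled proportionally to that surface, and "future scenario" stacks
produced by additive/multiplicative climate deltas.  Everything is
deterministic under a seed, so every downstream stage of the pipeline is
testable without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .raster import RasterGrid, RasterStack, write_esri_ascii
from .samples import OccurrenceSet

__all__ = [
    "SyntheticConfig",
    "ScenarioDelta",
    "gen_climate_stack",
    "true_suitability",
    "sample_occurrences",
    "apply_climate_delta",
]

# physically plausible value ranges per layer role
ROLE_RANGES = {
    "temperature": (10.0, 35.0),
    "precipitation": (0.0, 2500.0),
    "seasonality": (20.0, 200.0),
}

# WorldClim-style layer roles: bio1-bio11 thermal, bio12-bio19 moisture,
# bio4/bio15 are seasonality indices
_DEFAULT_ROLES = {
    **{f"bio{i}": "temperature" for i in range(1, 12)},
    **{f"bio{i}": "precipitation" for i in range(12, 20)},
    "bio4": "seasonality",
    "bio15": "seasonality",
}

# driver -> (plateau low, plateau high, Gaussian falloff width); the plateaus
# are the reported suitable ranges for annual mean temperature, annual
# precipitation and precipitation seasonality.  Falloff widths are ~6% of
# each role's landscape range so that the jointly suitable core occupies a
# minority of the landscape — a species with a defined climatic niche
# rather than one for which most of the map is habitat.
DEFAULT_RESPONSES: dict[str, tuple[float, float, float]] = {
    "bio1": (22.0, 28.0, 1.5),
    "bio12": (300.0, 1000.0, 150.0),
    "bio15": (70.0, 160.0, 12.0),
}

# (source, clone, target Pearson r); includes pairs above the |r| >= 0.8
# screening threshold, mimicking the strong collinearity of real bioclim sets
DEFAULT_CORRELATION_PLAN: list[tuple[str, str, float]] = [
    ("bio1", "bio6", 0.90),
    ("bio1", "bio11", 0.92),
    ("bio5", "bio10", 0.85),
    ("bio12", "bio16", 0.88),
    ("bio12", "bio13", 0.82),
    ("bio17", "bio14", 0.90),
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic landscape.

    Defaults mirror the study conditions: 19 predictor layers at roughly
    2.5 arc-minute resolution, 125 occurrence points, three driver
    variables with plateau optima 22-28 (temperature-like), 300-1000
    (annual-precipitation-like) and 70-160 (seasonality-like).
    """

    nrows: int = 100
    ncols: int = 100
    xll: float = 70.0
    yll: float = 8.0
    cellsize: float = 1.0 / 24.0  # 2.5 arc-min in degrees
    n_variables: int = 19
    n_occurrences: int = 125
    seed: int = 0
    smooth_cells: int = 5  # moving-average kernel width
    correlation_plan: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_CORRELATION_PLAN)
    )
    responses: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSES)
    )

    def __post_init__(self) -> None:
        for var, (low, high, width) in self.responses.items():
            if not low < high:
                raise ValueError(f"response for {var}: optimum low must be < high")
            if width <= 0:
                raise ValueError(f"response for {var}: falloff width must be > 0")
        for src, clone, r in self.correlation_plan:
            if not 0 < abs(r) <= 1:
                raise ValueError(f"target r for {clone} must satisfy 0 < |r| <= 1")
        if self.n_occurrences < 1:
            raise ValueError("n_occurrences must be >= 1")

    @property
    def variable_names(self) -> list[str]:
        return [f"bio{i}" for i in range(1, self.n_variables + 1)]

    def role(self, name: str) -> str:
        return _DEFAULT_ROLES.get(name, "temperature")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], smooth: int) -> np.ndarray:
    """Random linear gradient plus moving-average-smoothed white noise,
    standardized to zero mean / unit variance."""
    nrows, ncols = shape
    lat = np.linspace(0, 1, nrows)[:, None] * np.ones((1, ncols))
    lon = np.ones((nrows, 1)) * np.linspace(0, 1, ncols)[None, :]
    # gradients weighted below the noise so unplanned layer pairs stay only
    # weakly correlated; planned correlations are built explicitly
    a, b = rng.normal(scale=0.6, size=2)
    noise = ndimage.uniform_filter(rng.normal(size=shape), size=max(1, smooth), mode="nearest")
    c = rng.uniform(0.8, 1.2)
    field_ = a * lat + b * lon + c * noise / max(noise.std(), 1e-12)
    field_ -= field_.mean()
    sd = field_.std()
    return field_ / max(sd, 1e-12)


def _rescale(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    zmin, zmax = z.min(), z.max()
    if zmax - zmin < 1e-12:
        return np.full_like(z, (lo + hi) / 2)
    return lo + (z - zmin) * (hi - lo) / (zmax - zmin)


def gen_climate_stack(config: SyntheticConfig) -> RasterStack:
    """Generate an aligned stack of pseudo-bioclimatic layers.

    Each base layer is a random latitudinal/longitudinal gradient plus
    smoothed seeded noise, min-max rescaled into its role's plausible
    range.  Clone layers in the correlation plan are built as
    ``r * standardized(source) + sqrt(1 - r^2) * independent`` with the
    independent field residualized against the source, so the sample
    Pearson correlation equals the target almost exactly; affine rescaling
    preserves it.
    """
    rng = np.random.default_rng(config.seed)
    names = config.variable_names
    shape = (config.nrows, config.ncols)
    clones = {clone: (src, r) for src, clone, r in config.correlation_plan}
    for src, clone, _ in config.correlation_plan:
        if src not in names or clone not in names:
            raise ValueError(f"correlation plan references unknown variable: {src}/{clone}")
        if src in clones:
            raise ValueError(f"correlation plan: source {src} is itself a clone")

    std_fields: dict[str, np.ndarray] = {}
    for name in names:
        if name in clones:
            continue
        std_fields[name] = _smooth_field(rng, shape, config.smooth_cells)
    for name in names:
        if name not in clones:
            continue
        src, r = clones[name]
        base = std_fields[src]
        indep = _smooth_field(rng, shape, config.smooth_cells)
        # project out the source so the in-sample correlation is exact
        indep = indep - (indep * base).mean() / (base * base).mean() * base
        indep /= max(indep.std(), 1e-12)
        z = r * base + np.sqrt(1 - r * r) * indep
        std_fields[name] = z

    stack = RasterStack()
    for name in names:
        lo, hi = ROLE_RANGES[config.role(name)]
        values = _rescale(std_fields[name], lo, hi)
        stack.add(
            name,
            RasterGrid(
                nrows=config.nrows, ncols=config.ncols, xll=config.xll,
                yll=config.yll, cellsize=config.cellsize, values=values,
            ),
        )
    return stack


def _plateau_gaussian(x: np.ndarray, low: float, high: float, width: float) -> np.ndarray:
    """1 inside [low, high]; Gaussian falloff with the given width outside."""
    dist = np.where(x < low, low - x, np.where(x > high, x - high, 0.0))
    return np.exp(-0.5 * (dist / width) ** 2)


def true_suitability(stack: RasterStack, config: SyntheticConfig) -> RasterGrid:
    """Product of per-driver plateau-Gaussian responses, in [0, 1].

    Nodata cells (in any driver layer) map to nodata.
    """
    for var in config.responses:
        if var not in stack:
            raise KeyError(f"driver variable {var!r} missing from stack")
    ref = stack.reference
    suit = np.ones((ref.nrows, ref.ncols))
    valid = stack.subset(list(config.responses)).valid_mask()
    for var, (low, high, width) in config.responses.items():
        suit *= _plateau_gaussian(stack[var].values, low, high, width)
    out = np.where(valid, suit, ref.nodata)
    return ref.with_values(out)


def sample_occurrences(
    truth: RasterGrid, n: int, seed: int | None = None
) -> OccurrenceSet:
    """Draw n occurrence cells without replacement, P(cell) ∝ suitability.

    Each point is then placed uniformly at random inside its cell.
    """
    rng = np.random.default_rng(seed)
    mask = truth.valid_mask & (truth.values > 0)
    flat = np.flatnonzero(mask.ravel())
    if flat.size < n:
        raise ValueError(
            f"only {flat.size} positive-suitability cells available, need {n}"
        )
    w = truth.values.ravel()[flat]
    chosen = rng.choice(flat, size=n, replace=False, p=w / w.sum())
    records = []
    for idx in chosen:
        r, c = divmod(int(idx), truth.ncols)
        lon0 = truth.xll + c * truth.cellsize
        lat0 = truth.yll + (truth.nrows - 1 - r) * truth.cellsize
        records.append(
            (lon0 + rng.uniform(0, truth.cellsize), lat0 + rng.uniform(0, truth.cellsize))
        )
    return OccurrenceSet(records, species="synthetic")


@dataclass
class ScenarioDelta:
    """Per-variable additive offset and multiplicative factor.

    ``out = factor * layer + offset``; variables not listed are unchanged.
    """

    offsets: dict[str, float] = field(default_factory=dict)
    factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"factor for {var} must be > 0, got {f}")


def apply_climate_delta(stack: RasterStack, delta: ScenarioDelta) -> RasterStack:
    """Apply a climate delta layerwise, preserving nodata cells."""
    out = RasterStack()
    for name in stack.names:
        grid = stack[name]
        factor = delta.factors.get(name, 1.0)
        offset = delta.offsets.get(name, 0.0)
        values = np.where(
            grid.valid_mask, factor * grid.values + offset, grid.nodata
        )
        out.add(name, grid.with_values(values))
    return out


def write_synthetic_dataset(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Emit .asc layers, the truth layer, an occurrences CSV and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = gen_climate_stack(config)
    truth = true_suitability(stack, config)
    occ = sample_occurrences(truth, config.n_occurrences, config.seed)
    for name in stack.names:
        write_esri_ascii(stack[name], outdir / f"{name}.asc")
    write_esri_ascii(truth, outdir / "truth.asc")
    with open(outdir / "occurrences.csv", "w") as fh:
        fh.write("species,longitude,latitude\n")
        for lon, lat in occ.records:
            fh.write(f"{occ.species},{lon!r},{lat!r}\n")
    manifest = {
        "nrows": config.nrows,
        "ncols": config.ncols,
        "cellsize": config.cellsize,
        "n_variables": config.n_variables,
        "n_occurrences": config.n_occurrences,
        "seed": config.seed,
        "responses": {k: list(v) for k, v in config.responses.items()},
        "correlation_plan": [list(t) for t in config.correlation_plan],
        "layers": stack.names,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
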