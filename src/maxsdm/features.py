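"""MaxEnt feature expansions: linear, quadratic, product, threshold, hinge.

Scaling bounds and knots are fitted once from the pooled presence and
background samples and stored, so training and projection use identical
transforms.  Inputs outside the fitted bounds are clamped before
transformation; every feature value lies in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .samples import SampleMatrix

__all__ = [
    "Feature",
    "FeatureDefinitions",
    "FeatureMatrix",
    "fit_feature_defs",
    "transform_features",
    "FEATURE_CLASSES",
]

log = logging.getLogger("maxsdm")

FEATURE_CLASSES = ("L", "Q", "P", "T", "H")


@dataclass(frozen=True)
class Feature:
    """One design-matrix column: class, source variable(s), optional knot."""

    fid: str
    fclass: str  # one of L, Q, P, T, H
    variables: tuple[str, ...]  # 1 variable, or 2 for products
    knot: float | None = None
    direction: str | None = None  # hinge only: "forward" | "reverse"


@dataclass
class FeatureDefinitions:
    """Fitted feature specification: bounds, knots and the feature list."""

    bounds: dict[str, tuple[float, float]]  # variable -> (min, max), pooled
    classes: tuple[str, ...]
    n_knots: int
    knots: dict[str, np.ndarray] = field(default_factory=dict)
    features: list[Feature] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        return list(self.bounds)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def to_dict(self) -> dict:
        return {
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "classes": list(self.classes),
            "n_knots": self.n_knots,
            "knots": {k: v.tolist() for k, v in self.knots.items()},
            "features": [
                {
                    "fid": f.fid,
                    "fclass": f.fclass,
                    "variables": list(f.variables),
                    "knot": f.knot,
                    "direction": f.direction,
                }
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureDefinitions":
        defs = cls(
            bounds={k: tuple(v) for k, v in d["bounds"].items()},
            classes=tuple(d["classes"]),
            n_knots=int(d["n_knots"]),
            knots={k: np.asarray(v, dtype=float) for k, v in d["knots"].items()},
        )
        defs.features = [
            Feature(
                fid=f["fid"],
                fclass=f["fclass"],
                variables=tuple(f["variables"]),
                knot=f["knot"],
                direction=f["direction"],
            )
            for f in d["features"]
        ]
        return defs


@dataclass
class FeatureMatrix:
    """Points × features design matrix, all entries in [0, 1]."""

    values: np.ndarray
    defs: FeatureDefinitions

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.values.shape[0]


def fit_feature_defs(
    presence: SampleMatrix,
    background: SampleMatrix,
    classes: set[str] | tuple[str, ...] | str = ("L", "Q", "P", "T", "H"),
    n_knots: int = 50,
) -> FeatureDefinitions:
    """Fit scaling bounds and knots from pooled presence + background samples.

    Feature counts for V usable variables: |L| = |Q| = V, |P| = V(V-1)/2,
    |T| = V*n_knots, |H| = 2*V*n_knots.  Threshold and hinge knots sit at
    evenly spaced quantiles of the pooled values, excluding the 0th and
    100th percentiles.  Variables constant over the pooled sample are
    excluded with a warning.
    """
    classes = tuple(c for c in FEATURE_CLASSES if c in set(classes))
    if not classes:
        raise ValueError("at least one feature class must be enabled")
    shared = [v for v in presence.variables if v in set(background.variables)]
    if not shared:
        raise ValueError("presence and background share no variables")
    pooled = pd.concat([presence.data[shared], background.data[shared]], ignore_index=True)

    bounds: dict[str, tuple[float, float]] = {}
    for var in shared:
        lo, hi = float(pooled[var].min()), float(pooled[var].max())
        if hi - lo < 1e-12:
            log.warning("variable %s is constant over pooled samples; excluded", var)
            continue
        bounds[var] = (lo, hi)
    if not bounds:
        raise ValueError("all variables are constant; no features can be built")
    variables = list(bounds)

    defs = FeatureDefinitions(bounds=bounds, classes=classes, n_knots=n_knots)
    if "T" in classes or "H" in classes:
        q = np.linspace(0, 1, n_knots + 2)[1:-1]
        for var in variables:
            defs.knots[var] = np.sort(np.quantile(pooled[var].to_numpy(), q))

    feats: list[Feature] = []
    if "L" in classes:
        feats += [Feature(f"L({v})", "L", (v,)) for v in variables]
    if "Q" in classes:
        feats += [Feature(f"Q({v})", "Q", (v,)) for v in variables]
    if "P" in classes:
        for i, vi in enumerate(variables):
            for vj in variables[i + 1:]:
                feats.append(Feature(f"P({vi},{vj})", "P", (vi, vj)))
    if "T" in classes:
        for v in variables:
            for k, knot in enumerate(defs.knots[v]):
                feats.append(Feature(f"T({v},{k})", "T", (v,), knot=float(knot)))
    if "H" in classes:
        for v in variables:
            for k, knot in enumerate(defs.knots[v]):
                feats.append(
                    Feature(f"Hf({v},{k})", "H", (v,), knot=float(knot), direction="forward")
                )
                feats.append(
                    Feature(f"Hr({v},{k})", "H", (v,), knot=float(knot), direction="reverse")
                )
    defs.features = feats
    return defs


def transform_features(samples: SampleMatrix | pd.DataFrame, defs: FeatureDefinitions) -> FeatureMatrix:
    """Apply the fitted feature transforms to a sample matrix.

    Values outside the stored bounds are clamped to them first, so
    projection onto novel climates never leaves [0, 1].
    """
    data = samples.data if isinstance(samples, SampleMatrix) else samples
    missing = [v for v in defs.variables if v not in data.columns]
    if missing:
        raise KeyError(f"samples missing variable(s): {missing}")

    clamped: dict[str, np.ndarray] = {}
    scaled: dict[str, np.ndarray] = {}
    for var, (lo, hi) in defs.bounds.items():
        x = np.clip(data[var].to_numpy(dtype=float), lo, hi)
        clamped[var] = x
        scaled[var] = (x - lo) / (hi - lo)

    cols = np.empty((len(data), defs.n_features))
    for j, f in enumerate(defs.features):
        if f.fclass == "L":
            cols[:, j] = scaled[f.variables[0]]
        elif f.fclass == "Q":
            cols[:, j] = scaled[f.variables[0]] ** 2
        elif f.fclass == "P":
            cols[:, j] = scaled[f.variables[0]] * scaled[f.variables[1]]
        elif f.fclass == "T":
            cols[:, j] = (clamped[f.variables[0]] > f.knot).astype(float)
        else:  # hinge
            var = f.variables[0]
            lo, hi = defs.bounds[var]
            x, k = clamped[var], f.knot
            if f.direction == "forward":
                denom = max(hi - k, 1e-12)
                cols[:, j] = np.maximum(0.0, (x - k) / denom)
            else:
                denom = max(k - lo, 1e-12)
                cols[:, j] = np.maximum(0.0, (k - x) / denom)
    return FeatureMatrix(np.clip(cols, 0.0, 1.0), defs)
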