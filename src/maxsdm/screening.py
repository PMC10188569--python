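"""Pairwise Pearson correlation among predictor layers and greedy
multicollinearity pruning at |r| >= 0.8 (inclusive threshold)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterStack

__all__ = ["CorrelationMatrix", "correlation_matrix", "greedy_select"]

log = logging.getLogger("maxsdm")


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over jointly valid cells."""

    variables: list[str]
    matrix: np.ndarray
    degenerate: list[str]  # constant layers whose correlations are set to 0

    def r(self, a: str, b: str) -> float:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.variables, columns=self.variables)


def correlation_matrix(stack: RasterStack) -> CorrelationMatrix:
    """Pearson r per layer pair over the complete-case valid-cell set.

    A constant layer has undefined correlations; these are recorded as 0
    and the layer is flagged degenerate (with a warning).
    """
    names = stack.names
    values, _ = stack.to_matrix(names)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 jointly valid cells for correlation")
    sd = values.std(axis=0)
    degenerate = [n for n, s in zip(names, sd) if s < 1e-12]
    if degenerate:
        log.warning("constant layer(s) %s: correlations recorded as 0", degenerate)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.atleast_2d(corr)
    bad = np.array([s < 1e-12 for s in sd])
    corr[bad, :] = 0.0
    corr[:, bad] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return CorrelationMatrix(names, corr, degenerate)


def greedy_select(
    corr: CorrelationMatrix,
    priority: list[str] | None = None,
    threshold: float = 0.8,
) -> list[str]:
    """Greedy screen: scan in priority order, keep a variable iff
    |r| < threshold against every variable already kept.

    ``priority`` must be a permutation of the variables (highest priority
    first); default is the matrix's own order.  The threshold is inclusive:
    |r| exactly at the threshold removes.  The retained set never contains
    a pair at or above the threshold, and output preserves priority order.
    """
    priority = list(priority) if priority is not None else list(corr.variables)
    if sorted(priority) != sorted(corr.variables):
        raise ValueError("priority must be a permutation of the correlation variables")
    kept: list[str] = []
    for var in priority:
        if all(abs(corr.r(var, k)) < threshold for k in kept):
            kept.append(var)
    return kept
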