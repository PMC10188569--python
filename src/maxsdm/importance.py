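"""Variable importance: percent contribution, permutation importance,
jackknife gains, and response curves.

Percent contribution is path-dependent: it credits each accepted solver
update's gain increase to the updated feature's source variable, so it is
reproducible only conditional on the optimizer path.  Permutation
importance is shipped alongside as the path-independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import transform_features
from .metrics import auc_rank
from .model import MaxentModel, predict_cloglog, train
from .samples import SampleMatrix

__all__ = [
    "percent_contribution",
    "permutation_importance",
    "JackknifeResult",
    "jackknife_gains",
    "response_curve",
    "univariate_gains",
]

log = logging.getLogger("maxsdm")


def percent_contribution(model: MaxentModel) -> dict[str, float]:
    """Percent contribution per variable from the solver's gain trace.

    Each accepted update's increase in regularized gain is credited to the
    updated feature's source variable; product features split credit 50/50
    between their two variables.  Negative credits are floored at zero at
    aggregation and the result is normalized to sum to 100.  A model with
    an empty trace (uniform model) returns all zeros.
    """
    fid_to_feature = {f.fid: f for f in model.defs.features}
    credits = {v: 0.0 for v in model.defs.variables}
    prev_gain = 0.0
    for _, gain, fid in model.gain_trace:
        inc = gain - prev_gain
        prev_gain = gain
        feat = fid_to_feature[fid]
        share = inc / len(feat.variables)
        for v in feat.variables:
            credits[v] += share
    credits = {v: max(0.0, c) for v, c in credits.items()}
    total = sum(credits.values())
    if total <= 0:
        log.warning("empty gain trace: percent contributions are all zero")
        return {v: 0.0 for v in credits}
    return {v: 100.0 * c / total for v, c in credits.items()}


def permutation_importance(
    model: MaxentModel,
    presence: SampleMatrix,
    background: SampleMatrix,
    seed: int | None = None,
) -> dict[str, float]:
    """Permutation importance: per-variable drop in training AUC.

    Each variable's column is shuffled jointly across presence and
    background, the model is re-applied (not re-fitted), and the AUC drop
    ``max(0, AUC_orig - AUC_perm)`` is normalized to sum to 100.
    """
    rng = np.random.default_rng(seed)
    pooled = pd.concat(
        [presence.data, background.data], ignore_index=True
    )
    n_p = len(presence)
    s_p = predict_cloglog(model, transform_features(presence, model.defs))
    s_b = predict_cloglog(model, transform_features(background, model.defs))
    auc_orig = auc_rank(s_p, s_b)
    drops: dict[str, float] = {}
    for var in model.defs.variables:
        shuffled = pooled.copy()
        shuffled[var] = rng.permutation(shuffled[var].to_numpy())
        fm = transform_features(shuffled, model.defs)
        scores = predict_cloglog(model, fm)
        auc_perm = auc_rank(scores[:n_p], scores[n_p:])
        drops[var] = max(0.0, auc_orig - auc_perm)
    total = sum(drops.values())
    if total <= 0:
        return {v: 0.0 for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}


@dataclass
class JackknifeResult:
    """Per-variable with-only / without gains plus the all-variable gain."""

    table: pd.DataFrame  # index: variable; columns: with_only, without[, *_test]
    full_gain: float
    full_test_gain: float | None = None


def _test_gain(model: MaxentModel, test_presence: SampleMatrix) -> float:
    """Regularized gain evaluated on held-out presences."""
    fm = transform_features(test_presence, model.defs)
    eta = fm.values @ model.lam
    penalty = float(model.beta @ np.abs(model.lam))
    f_test = model.log_z - float(eta.mean()) + penalty
    return float(np.log(model.n_background) - f_test)


def jackknife_gains(
    presence: SampleMatrix,
    background: SampleMatrix,
    test_presence: SampleMatrix | None = None,
    variables: list[str] | None = None,
    **train_kwargs,
) -> JackknifeResult:
    """Jackknife variable importance by regularized gain.

    For each variable, fit a model with only that variable and one without
    it, recording the regularized training gain of each (and the test gain
    when a held-out presence set is supplied).
    """
    variables = variables or list(presence.variables)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    full = train(presence, background, **train_kwargs)
    rows = {}
    for v in variables:
        only = train(
            SampleMatrix(presence.data[[v]], "presence"),
            SampleMatrix(background.data[[v]], "background"),
            **train_kwargs,
        )
        rest = [u for u in variables if u != v]
        without = train(
            SampleMatrix(presence.data[rest], "presence"),
            SampleMatrix(background.data[rest], "background"),
            **train_kwargs,
        )
        row = {"with_only": only.gain, "without": without.gain}
        if test_presence is not None:
            row["with_only_test"] = _test_gain(only, SampleMatrix(test_presence.data[[v]], "presence"))
            row["without_test"] = _test_gain(without, SampleMatrix(test_presence.data[rest], "presence"))
        rows[v] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    full_test = _test_gain(full, test_presence) if test_presence is not None else None
    return JackknifeResult(table=table, full_gain=full.gain, full_test_gain=full_test)


def response_curve(
    model: MaxentModel,
    variable: str,
    presence: SampleMatrix,
    background: SampleMatrix | None = None,
    n_points: int = 100,
    mode: str = "marginal",
    **train_kwargs,
) -> pd.DataFrame:
    """Suitability response of one variable.

    ``marginal``: sweep the variable across its fitted [min, max] with all
    other variables held at their presence-sample means.  ``univariate``:
    fit a fresh single-variable model and sweep it (requires background).
    Returns a data frame with columns ``value`` and ``cloglog``.
    """
    if variable not in model.defs.bounds:
        raise KeyError(f"variable {variable!r} not in model")
    lo, hi = model.defs.bounds[variable]
    sweep = np.linspace(lo, hi, n_points)
    if mode == "marginal":
        means = presence.data[model.defs.variables].mean()
        grid = pd.DataFrame({v: np.full(n_points, means[v]) for v in model.defs.variables})
        grid[variable] = sweep
        scores = predict_cloglog(model, transform_features(grid, model.defs))
    elif mode == "univariate":
        if background is None:
            raise ValueError("univariate mode requires background samples")
        uni = train(
            SampleMatrix(presence.data[[variable]], "presence"),
            SampleMatrix(background.data[[variable]], "background"),
            **train_kwargs,
        )
        lo, hi = uni.defs.bounds[variable]
        sweep = np.linspace(lo, hi, n_points)
        scores = predict_cloglog(uni, transform_features(pd.DataFrame({variable: sweep}), uni.defs))
    else:
        raise ValueError("mode must be 'marginal' or 'univariate'")
    return pd.DataFrame({"value": sweep, "cloglog": scores})


def univariate_gains(
    presence: SampleMatrix, background: SampleMatrix, **train_kwargs
) -> dict[str, float]:
    """Training gain of each single-variable model.

    Used as the default screening priority: variables with higher
    univariate gain are preferred when pruning correlated pairs.
    """
    gains = {}
    for v in presence.variables:
        m = train(
            SampleMatrix(presence.data[[v]], "presence"),
            SampleMatrix(background.data[[v]], "background"),
            **train_kwargs,
        )
        gains[v] = m.gain
    return gains
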