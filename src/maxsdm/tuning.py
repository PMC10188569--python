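"""Candidate-model tuning: feature-class x regularization-multiplier grid,
k-fold cross-validation metrics, AICc with small-sample correction, and
delta-AICc selection.

The full design space is the 31 non-empty subsets of {L, Q, P, T, H}
crossed with regularization multipliers 0.5 to 5 in steps of 0.5 — 310
candidates.  The candidate minimizing AICc (delta-AICc = 0) is selected;
ties break by parsimony (fewest nonzero coefficients), then smaller RM,
then the feature-class string.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .features import FEATURE_CLASSES, transform_features
from .metrics import auc_rank
from .model import MaxentModel, predict_cloglog, predict_raw, train
from .samples import SampleMatrix

__all__ = [
    "TuningRecord",
    "kfold_partition",
    "aicc",
    "evaluate_candidate",
    "enumerate_candidates",
    "tune_grid",
    "DEFAULT_RMS",
]

DEFAULT_RMS: tuple[float, ...] = tuple(np.arange(0.5, 5.01, 0.5))


@dataclass
class TuningRecord:
    """One candidate's cross-validation metrics and AICc."""

    fc: str  # e.g. "LHT", ordered L,Q,P,T,H
    rm: float
    auc_val_avg: float = math.nan
    auc_diff_avg: float = math.nan
    or10p_avg: float = math.nan
    aicc: float = math.nan  # nan = undefined (K >= n-1)
    delta_aicc: float = math.nan
    k: int = 0
    model: MaxentModel | None = field(default=None, repr=False)


def kfold_partition(n: int, k: int, seed: int | None = None) -> np.ndarray:
    """Random k-fold labels, fold sizes differing by at most 1; seeded."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % k
    return labels[rng.permutation(n)]


def aicc(
    model: MaxentModel,
    presence_scores_raw: np.ndarray,
    landscape_scores_raw: np.ndarray,
) -> float:
    """AICc of a full-data model under the landscape-normalized raw output.

    ``p(x)`` is the raw prediction renormalized to sum to 1 over all valid
    landscape cells; the log-likelihood sums ``ln p`` over the presences.
    K counts coefficients with |lambda| > 1e-12.  Returns NaN (undefined)
    when K >= n - 1, where the correction term blows up.
    """
    n = presence_scores_raw.shape[0]
    k = model.n_nonzero
    if k >= n - 1:
        return math.nan
    total = landscape_scores_raw.sum()
    if total <= 0 or np.any(presence_scores_raw <= 0):
        return math.nan
    lnl = float(np.sum(np.log(presence_scores_raw / total)))
    return 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)


def aicc_from_model(
    model: MaxentModel, presence: SampleMatrix, landscape: SampleMatrix
) -> float:
    """Convenience wrapper computing raw scores then :func:`aicc`."""
    p_raw = predict_raw(model, transform_features(presence, model.defs))
    g_raw = predict_raw(model, transform_features(landscape, model.defs))
    return aicc(model, p_raw, g_raw)


def or10p_threshold(train_scores: np.ndarray) -> float:
    """Training 10-percentile omission threshold: the score of the
    ceil(0.1 * m)-th lowest training presence (count-based, inclusive)."""
    m = train_scores.shape[0]
    idx = math.ceil(0.1 * m)  # 1-based rank
    return float(np.sort(train_scores)[idx - 1])


def evaluate_candidate(
    fc: str,
    rm: float,
    presence: SampleMatrix,
    background: SampleMatrix,
    folds: np.ndarray,
    n_knots: int = 50,
    max_iter: int = 5000,
    tol: float = 1e-4,
) -> TuningRecord:
    """k-fold cross-validation metrics for one (FC, RM) candidate.

    Per fold: fit on the other folds, then record validation AUC
    (held-out presences vs background), the training-minus-validation AUC
    difference, and the 10-percentile omission rate of validation
    presences below the training threshold.
    """
    fc = canonical_fc(fc)
    n = len(presence)
    if folds.shape[0] != n:
        raise ValueError("fold labels must match presence count")
    aucs_val, auc_diffs, or10ps = [], [], []
    for fold in np.unique(folds):
        val_mask = folds == fold
        if not val_mask.any():
            continue
        if val_mask.sum() == 0 or (~val_mask).sum() == 0:
            raise ValueError(f"fold {fold} leaves an empty side")
        p_train = SampleMatrix(presence.data[~val_mask].reset_index(drop=True), "presence")
        p_val = SampleMatrix(presence.data[val_mask].reset_index(drop=True), "presence")
        if len(p_val) == 0:
            raise ValueError(f"fold {fold} has zero validation presences")
        m = train(p_train, background, classes=fc, rm=rm, n_knots=n_knots,
                  max_iter=max_iter, tol=tol)
        s_train = predict_cloglog(m, transform_features(p_train, m.defs))
        s_val = predict_cloglog(m, transform_features(p_val, m.defs))
        s_bg = predict_cloglog(m, transform_features(background, m.defs))
        auc_t = auc_rank(s_train, s_bg)
        auc_v = auc_rank(s_val, s_bg)
        aucs_val.append(auc_v)
        auc_diffs.append(auc_t - auc_v)
        thr = or10p_threshold(s_train)
        or10ps.append(float(np.mean(s_val < thr)))
    return TuningRecord(
        fc=fc, rm=rm,
        auc_val_avg=float(np.mean(aucs_val)),
        auc_diff_avg=float(np.mean(auc_diffs)),
        or10p_avg=float(np.mean(or10ps)),
    )


def canonical_fc(fc) -> str:
    """Normalize a feature-class set to its canonical L,Q,P,T,H-ordered string."""
    s = set(fc)
    unknown = s - set(FEATURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown feature class(es): {sorted(unknown)}")
    return "".join(c for c in FEATURE_CLASSES if c in s)


def enumerate_candidates(
    fc_universe: tuple[str, ...] = FEATURE_CLASSES,
    rms: tuple[float, ...] = DEFAULT_RMS,
) -> list[tuple[str, float]]:
    """All non-empty feature-class subsets crossed with the RM values.

    The default universe yields (2^5 - 1) x 10 = 310 candidates.
    """
    combos = []
    for size in range(1, len(fc_universe) + 1):
        for combo in combinations(fc_universe, size):
            combos.append(canonical_fc(combo))
    return [(fc, float(rm)) for fc in combos for rm in rms]


def tune_grid(
    presence: SampleMatrix,
    background: SampleMatrix,
    landscape: SampleMatrix,
    fc_universe: tuple[str, ...] = FEATURE_CLASSES,
    rms: tuple[float, ...] = DEFAULT_RMS,
    k: int = 10,
    seed: int | None = None,
    n_knots: int = 50,
    max_iter: int = 5000,
    tol: float = 1e-4,
    cv_metrics: bool = True,
) -> tuple[list[TuningRecord], TuningRecord]:
    """Evaluate the candidate grid and select the delta-AICc = 0 record.

    AICc is computed on a model fitted to *all* occurrences (no split),
    with the raw output renormalized over the landscape cells.  With
    ``cv_metrics=False`` only the AICc part is computed (the CV columns
    stay NaN), which is much cheaper on large grids.
    """
    folds = kfold_partition(len(presence), k, seed) if cv_metrics else None
    records: list[TuningRecord] = []
    for fc, rm in enumerate_candidates(fc_universe, rms):
        if cv_metrics:
            rec = evaluate_candidate(fc, rm, presence, background, folds,
                                     n_knots=n_knots, max_iter=max_iter, tol=tol)
        else:
            rec = TuningRecord(fc=fc, rm=rm)
        full = train(presence, background, classes=fc, rm=rm, n_knots=n_knots,
                     max_iter=max_iter, tol=tol)
        rec.k = full.n_nonzero
        rec.aicc = aicc_from_model(full, presence, landscape)
        rec.model = full
        records.append(rec)

    defined = [r for r in records if not math.isnan(r.aicc)]
    if not defined:
        raise ValueError(
            "AICc undefined for every candidate (K >= n-1 throughout); "
            "more occurrences are needed relative to model complexity"
        )
    best_aicc = min(r.aicc for r in defined)
    for r in records:
        r.delta_aicc = r.aicc - best_aicc if not math.isnan(r.aicc) else math.nan
    zero = [r for r in records if not math.isnan(r.delta_aicc) and r.delta_aicc == 0.0]
    selected = min(zero, key=lambda r: (r.k, r.rm, r.fc))
    return records, selected


def records_to_frame(records: list[TuningRecord], selected: TuningRecord | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "fc": [r.fc for r in records],
            "rm": [r.rm for r in records],
            "auc_val_avg": [r.auc_val_avg for r in records],
            "auc_diff_avg": [r.auc_diff_avg for r in records],
            "or10p_avg": [r.or10p_avg for r in records],
            "aicc": [r.aicc for r in records],
            "delta_aicc": [r.delta_aicc for r in records],
            "k": [r.k for r in records],
        }
    )
    if selected is not None:
        df["selected"] = [(r.fc, r.rm) == (selected.fc, selected.rm) for r in records]
    return df
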