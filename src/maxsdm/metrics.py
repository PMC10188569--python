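"""Presence-background discrimination and calibration metrics.

Background points stand in for absences ("pseudo-specificity"): true
absences do not exist in presence-only modelling, so specificity is the
fraction of background scored below the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, spearmanr

from .features import FeatureMatrix, transform_features
from .model import MaxentModel, predict_cloglog, train
from .samples import SampleMatrix

__all__ = [
    "auc_rank",
    "maxsss_threshold",
    "tss_at_threshold",
    "continuous_boyce_index",
    "EvaluationReport",
    "split_evaluate",
    "cv_evaluate",
    "evaluation_table",
]


def auc_rank(presence_scores, background_scores) -> float:
    """Rank (Mann-Whitney) AUC: P(presence > background) with ties at 1/2.

    Invariant under strictly monotone transforms of the scores.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([p, b]))
    r_p = ranks[: p.size].sum()
    return float((r_p - p.size * (p.size + 1) / 2) / (p.size * b.size))


def _sens_spec(p: np.ndarray, b: np.ndarray, t: float) -> tuple[float, float]:
    sens = float(np.mean(p >= t))  # presence predicted positive when score >= t
    spec = float(np.mean(b < t))
    return sens, spec


def maxsss_threshold(presence_scores, background_scores) -> float:
    """Smallest threshold maximizing sensitivity + specificity.

    Candidates are the unique observed scores (presence and background
    pooled); sensitivity counts presences scoring >= t, specificity counts
    background scoring < t.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be nonempty")
    candidates = np.unique(np.concatenate([p, b]))
    best_t, best_ss = candidates[0], -np.inf
    for t in candidates:
        ss = sum(_sens_spec(p, b, t))
        if ss > best_ss + 1e-12:
            best_t, best_ss = t, ss
    return float(best_t)


def tss_at_threshold(presence_scores, background_scores, t: float) -> float:
    """True skill statistic sensitivity + specificity - 1 at threshold t."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    sens, spec = _sens_spec(p, b, t)
    return sens + spec - 1.0


def continuous_boyce_index(
    presence_scores,
    landscape_scores,
    n_windows: int = 101,
    window_width_fraction: float = 0.1,
) -> tuple[float, bool]:
    """Continuous Boyce index over moving score windows.

    Windows of width ``window_width_fraction x (score range)`` with centers
    evenly spaced so the windows jointly span [min, max] of the landscape
    scores.  For each window the predicted-to-expected ratio P/E compares
    the share of presences with the share of landscape cells; CBI is the
    Spearman rank correlation between P/E and window center (windows with
    E = 0 dropped).  Returns ``(cbi, degenerate)``; degenerate cases
    (constant scores, < 3 usable windows, constant P/E) yield 0 with the
    flag set.
    """
    p = np.asarray(presence_scores, dtype=float)
    g = np.asarray(landscape_scores, dtype=float)
    if p.size < 5:
        raise ValueError("need at least 5 presence scores for CBI")
    lo, hi = float(g.min()), float(g.max())
    if hi - lo < 1e-12:
        return 0.0, True
    width = window_width_fraction * (hi - lo)
    centers = np.linspace(lo + width / 2, hi - width / 2, n_windows)
    ratios, used_centers = [], []
    for c in centers:
        a, b = c - width / 2, c + width / 2
        e_share = np.mean((g >= a) & (g <= b))
        if e_share == 0:
            continue
        p_share = np.mean((p >= a) & (p <= b))
        ratios.append(p_share / e_share)
        used_centers.append(c)
    if len(ratios) < 3 or np.ptp(ratios) < 1e-12:
        return 0.0, True
    rho = spearmanr(ratios, used_centers).statistic
    return float(rho), False


def train_test_split_indices(
    n: int, train_fraction: float = 0.75, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random split; the test side takes ``ceil((1 - fraction) * n)``
    records (32 of 125 at 75:25).  Returns (train indices, test indices)."""
    n_test = math.ceil((1.0 - train_fraction) * n)
    if n_test == 0 or n_test == n:
        raise ValueError("degenerate split: empty train or test side")
    perm = np.random.default_rng(seed).permutation(n)
    return perm[n_test:], perm[:n_test]


@dataclass
class EvaluationReport:
    """Train/test metrics for one replicate of a split evaluation."""

    auc_train: float
    auc_test: float
    tss_train: float
    tss_test: float
    cbi_train: float
    cbi_test: float
    threshold: float
    replicate: str = "75:25"


def split_evaluate(
    presence: SampleMatrix,
    background: SampleMatrix,
    train_fraction: float = 0.75,
    seed: int | None = None,
    classes=("L", "H", "T"),
    rm: float = 2.0,
    n_knots: int = 50,
    max_iter: int = 5000,
    tol: float = 1e-4,
    replicate: str = "75:25",
) -> EvaluationReport:
    """Random train/test split evaluation.

    The test side takes ``ceil((1 - train_fraction) * n)`` presences (32 of
    125 at the default 75:25 split).  The model is fitted on the training
    presences; the maxSSS threshold comes from the training scores and is
    reused on the test side.  CBI uses the background scores as the
    landscape reference.
    """
    n = len(presence)
    if n < 4:
        raise ValueError("need at least 4 occurrences to split")
    train_idx, test_idx = train_test_split_indices(n, train_fraction, seed)

    p_train = SampleMatrix(presence.data.iloc[train_idx].reset_index(drop=True), "presence")
    p_test = SampleMatrix(presence.data.iloc[test_idx].reset_index(drop=True), "presence")
    model = train(
        p_train, background, classes=classes, rm=rm, n_knots=n_knots,
        max_iter=max_iter, tol=tol, seed=seed,
    )
    s_train = predict_cloglog(model, transform_features(p_train, model.defs))
    s_test = predict_cloglog(model, transform_features(p_test, model.defs))
    s_bg = predict_cloglog(model, transform_features(background, model.defs))

    t = maxsss_threshold(s_train, s_bg)
    cbi_train, _ = continuous_boyce_index(s_train, s_bg)
    cbi_test, _ = continuous_boyce_index(s_test, s_bg)
    return EvaluationReport(
        auc_train=auc_rank(s_train, s_bg),
        auc_test=auc_rank(s_test, s_bg),
        tss_train=tss_at_threshold(s_train, s_bg, t),
        tss_test=tss_at_threshold(s_test, s_bg, t),
        cbi_train=cbi_train,
        cbi_test=cbi_test,
        threshold=t,
        replicate=replicate,
    )


def _evaluate_split(
    p_train: SampleMatrix,
    p_test: SampleMatrix,
    background: SampleMatrix,
    replicate: str,
    classes=("L", "H", "T"),
    rm: float = 2.0,
    n_knots: int = 50,
    max_iter: int = 5000,
    tol: float = 1e-4,
    seed: int | None = None,
) -> EvaluationReport:
    model = train(p_train, background, classes=classes, rm=rm, n_knots=n_knots,
                  max_iter=max_iter, tol=tol, seed=seed)
    s_train = predict_cloglog(model, transform_features(p_train, model.defs))
    s_test = predict_cloglog(model, transform_features(p_test, model.defs))
    s_bg = predict_cloglog(model, transform_features(background, model.defs))
    t = maxsss_threshold(s_train, s_bg)
    cbi_train, _ = continuous_boyce_index(s_train, s_bg)
    cbi_test, _ = continuous_boyce_index(s_test, s_bg)
    return EvaluationReport(
        auc_train=auc_rank(s_train, s_bg),
        auc_test=auc_rank(s_test, s_bg),
        tss_train=tss_at_threshold(s_train, s_bg, t),
        tss_test=tss_at_threshold(s_test, s_bg, t),
        cbi_train=cbi_train,
        cbi_test=cbi_test,
        threshold=t,
        replicate=replicate,
    )


def cv_evaluate(
    presence: SampleMatrix,
    background: SampleMatrix,
    k: int = 10,
    seed: int | None = None,
    **model_kw,
) -> list[EvaluationReport]:
    """k-fold cross-validated evaluation, one report per replicate.

    Each fold in turn is the test side; the maxSSS threshold always comes
    from the fold's training scores.
    """
    from .tuning import kfold_partition

    folds = kfold_partition(len(presence), k, seed)
    reports = []
    for fold in range(k):
        test_mask = folds == fold
        p_train = SampleMatrix(presence.data[~test_mask].reset_index(drop=True), "presence")
        p_test = SampleMatrix(presence.data[test_mask].reset_index(drop=True), "presence")
        reports.append(
            _evaluate_split(p_train, p_test, background,
                            replicate=f"Replication {fold + 1}", seed=seed, **model_kw)
        )
    return reports


def evaluation_table(
    presence: SampleMatrix,
    background: SampleMatrix,
    k: int = 10,
    seed: int | None = None,
    train_fraction: float = 0.75,
    **model_kw,
):
    """Replicate x metric table: k CV replicates, their average, and one
    random-sampling (75:25 by default) row."""
    import pandas as pd

    reports = cv_evaluate(presence, background, k=k, seed=seed, **model_kw)
    rows = [
        {
            "replicate": r.replicate,
            "auc_train": r.auc_train, "tss_train": r.tss_train, "cbi_train": r.cbi_train,
            "auc_test": r.auc_test, "tss_test": r.tss_test, "cbi_test": r.cbi_test,
        }
        for r in reports
    ]
    avg = {key: float(np.mean([row[key] for row in rows])) for key in rows[0] if key != "replicate"}
    rows.append({"replicate": "Average", **avg})
    split = split_evaluate(presence, background, train_fraction=train_fraction,
                           seed=seed, **model_kw)
    pct = int(round(100 * train_fraction))
    rows.append({
        "replicate": f"Random sampling ({pct}:{100 - pct})",
        "auc_train": split.auc_train, "tss_train": split.tss_train, "cbi_train": split.cbi_train,
        "auc_test": split.auc_test, "tss_test": split.tss_test, "cbi_test": split.cbi_test,
    })
    return pd.DataFrame(rows)
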