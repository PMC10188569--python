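"""The maximum-entropy presence-background density model.

The model is a Gibbs distribution over background cells,
``q_lambda(x) = exp(lambda . f(x)) / Z``, fitted by minimizing the convex
L1-regularized objective

    f(lambda) = -(1/m) sum_i ln q_lambda(x_i)  +  sum_j beta_j |lambda_j|

over the m presence points, with Z the partition sum over the N background
cells.  Optimization is coordinate-wise proximal Newton with
soft-thresholding and backtracking, which yields a per-feature gain trace
(used downstream for percent-contribution accounting).  Convergence is
declared when a full sweep improves the objective by less than ``tol``,
matching the convention of a convergence threshold on objective change.

Outputs:

* raw: ``exp(lambda . f(x)) / Z`` with Z frozen from training — sums to 1
  over the training background;
* cloglog: ``1 - exp(-e^H * raw)``, H the entropy of the fitted raw
  distribution — an interpretable suitability score in (0, 1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .features import FeatureDefinitions, FeatureMatrix, fit_feature_defs, transform_features
from .samples import SampleMatrix

__all__ = [
    "MaxentModel",
    "regularization_vector",
    "fit_maxent",
    "predict_raw",
    "predict_cloglog",
    "train",
]

log = logging.getLogger("maxsdm")

# per-class base regularization vs presence sample size m, interpolated and
# clamped outside the tabulated range (reference-software defaults)
_BETA_TABLES = {
    "L": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "Q": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "P": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "T": ([10, 100], [2.0, 1.0]),
    "H": ([10, 100], [0.5, 0.5]),
}


def regularization_vector(
    defs: FeatureDefinitions, presence_features: FeatureMatrix, rm: float
) -> np.ndarray:
    """Per-feature L1 weights ``beta_j = RM * beta_class(m) * sd_j / sqrt(m)``.

    ``sd_j`` is the standard deviation of feature j over the presences,
    floored at ``1/sqrt(m)`` (the scaled feature range is 1) so beta stays
    strictly positive even for presence-constant features.  Linear in RM.
    """
    F = presence_features.values
    m = F.shape[0]
    if m < 2:
        raise ValueError("need at least 2 presence points to estimate feature spread")
    sd = F.std(axis=0)
    floor = 1.0 / np.sqrt(m)
    sd = np.maximum(sd, floor)
    beta = np.empty(defs.n_features)
    for j, feat in enumerate(defs.features):
        xs, ys = _BETA_TABLES[feat.fclass]
        beta_class = float(np.interp(m, xs, ys))
        beta[j] = rm * beta_class * sd[j] / np.sqrt(m)
    return beta


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model.

    Attributes
    ----------
    defs : FeatureDefinitions
        Feature transforms shared by training and projection.
    lam, beta : numpy.ndarray
        Coefficients and L1 weights, one per feature.
    log_z : float
        Log partition sum over the training background (frozen).
    entropy : float
        Entropy H (nats) of the fitted raw distribution over background;
        0 <= H <= ln N.
    m, n_background : int
        Presence and background counts.
    gain_trace : list of (update index, regularized gain, feature id)
        One entry per accepted coordinate update; the regularized gain
        ``G = ln N - f(lambda)`` is nondecreasing along the trace.
    """

    defs: FeatureDefinitions
    lam: np.ndarray
    beta: np.ndarray
    rm: float
    log_z: float
    entropy: float
    m: int
    n_background: int
    objective: float
    converged: bool
    n_updates: int
    gain_trace: list[tuple[int, float, str]] = field(default_factory=list)
    seed: int | None = None

    @property
    def z(self) -> float:
        return float(np.exp(self.log_z))

    @property
    def gain(self) -> float:
        """Regularized training gain G = ln N - f(lambda)."""
        return float(np.log(self.n_background) - self.objective)

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.lam) > 1e-12))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "defs": self.defs.to_dict(),
            "lam": self.lam.tolist(),
            "beta": self.beta.tolist(),
            "rm": self.rm,
            "log_z": self.log_z,
            "entropy": self.entropy,
            "m": self.m,
            "n_background": self.n_background,
            "objective": self.objective,
            "converged": self.converged,
            "n_updates": self.n_updates,
            "gain_trace": [list(t) for t in self.gain_trace],
            "seed": self.seed,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "MaxentModel":
        return cls(
            defs=FeatureDefinitions.from_dict(d["defs"]),
            lam=np.asarray(d["lam"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            rm=d["rm"],
            log_z=d["log_z"],
            entropy=d["entropy"],
            m=d["m"],
            n_background=d["n_background"],
            objective=d["objective"],
            converged=d["converged"],
            n_updates=d["n_updates"],
            gain_trace=[tuple(t) for t in d["gain_trace"]],
            seed=d.get("seed"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "MaxentModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _objective(eta_bg: np.ndarray, mean_eta_pres: float, lam: np.ndarray, beta: np.ndarray) -> float:
    # f = ln Z - mean(eta over presences) + sum beta |lambda|
    return float(logsumexp(eta_bg) - mean_eta_pres + beta @ np.abs(lam))


def fit_maxent(
    presence: FeatureMatrix,
    background: FeatureMatrix,
    beta: np.ndarray,
    max_iter: int = 5000,
    tol: float = 1e-4,
    rm: float = 1.0,
    seed: int | None = None,
) -> MaxentModel:
    """Fit the L1-regularized Gibbs model by coordinate proximal Newton.

    ``max_iter`` caps the total number of coordinate updates; convergence
    is declared when a full sweep over features improves the objective by
    less than ``tol``.  The background matrix is expected to already
    include the presence rows when the caller wants the standard
    add-samples-to-background normalization (:func:`train` does this).
    """
    Fp, Fb = presence.values, background.values
    m, J = Fp.shape
    N = Fb.shape[0]
    if m == 0:
        raise ValueError("empty presence set")
    if Fb.shape[1] != J:
        raise ValueError("presence and background feature counts differ")
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (J,):
        raise ValueError("beta length must equal feature count")

    pbar = Fp.mean(axis=0)  # empirical feature means over presences
    lam = np.zeros(J)
    eta_b = np.zeros(N)
    mean_eta_p = 0.0
    f_cur = _objective(eta_b, mean_eta_p, lam, beta)
    if not np.isfinite(f_cur):
        raise FloatingPointError(
            "non-finite objective at start; check feature scaling"
        )

    trace: list[tuple[int, float, str]] = []
    n_updates = 0
    converged = False
    log_n = np.log(N)
    while n_updates < max_iter:
        f_sweep_start = f_cur
        for j in range(J):
            if n_updates >= max_iter:
                break
            # stabilized softmax over background
            shift = eta_b.max()
            w = np.exp(eta_b - shift)
            q = w / w.sum()
            col = Fb[:, j]
            mu = float(q @ col)
            g = mu - pbar[j]
            h = float(q @ (col * col)) - mu * mu
            h = max(h, 1e-9)
            z = lam[j] - g / h
            lam_new = np.sign(z) * max(abs(z) - beta[j] / h, 0.0)
            step = lam_new - lam[j]
            if step == 0.0:
                continue
            # backtracking on the true objective
            accepted = False
            for _ in range(30):
                cand = lam[j] + step
                eta_b_c = eta_b + step * col
                mean_eta_p_c = mean_eta_p + step * pbar[j]
                lam_c = lam.copy()
                lam_c[j] = cand
                f_c = _objective(eta_b_c, mean_eta_p_c, lam_c, beta)
                if not np.isfinite(f_c):
                    raise FloatingPointError(
                        "non-finite objective during fit; check feature scaling"
                    )
                if f_c <= f_cur + 1e-12:
                    accepted = f_c < f_cur - 1e-15
                    lam, eta_b, mean_eta_p, f_cur = lam_c, eta_b_c, mean_eta_p_c, f_c
                    break
                step /= 2.0
            if accepted:
                n_updates += 1
                trace.append((n_updates, float(log_n - f_cur), presence.defs.features[j].fid))
        if f_sweep_start - f_cur < tol:
            converged = True
            break

    # final distribution, entropy, partition
    log_z = float(logsumexp(eta_b))
    log_q = eta_b - log_z
    q = np.exp(log_q)
    entropy = float(-(q @ log_q))
    entropy = min(max(entropy, 0.0), log_n)
    if not converged:
        log.warning("fit_maxent: max_iter=%d reached before convergence", max_iter)
    return MaxentModel(
        defs=presence.defs,
        lam=lam,
        beta=beta,
        rm=rm,
        log_z=log_z,
        entropy=entropy,
        m=m,
        n_background=N,
        objective=f_cur,
        converged=converged,
        n_updates=n_updates,
        gain_trace=trace,
        seed=seed,
    )


def predict_raw(model: MaxentModel, features: FeatureMatrix) -> np.ndarray:
    """Gibbs probability ``exp(lambda . f(x)) / Z`` with Z frozen from
    training; sums to 1 over the training background rows."""
    if features.values.shape[1] != model.lam.shape[0]:
        raise ValueError(
            f"feature count {features.values.shape[1]} != model's {model.lam.shape[0]}"
        )
    return np.exp(features.values @ model.lam - model.log_z)


def predict_cloglog(model: MaxentModel, features: FeatureMatrix) -> np.ndarray:
    """Complementary log-log suitability ``1 - exp(-e^H * raw)`` in (0, 1);
    strictly increasing in raw."""
    raw = predict_raw(model, features)
    return 1.0 - np.exp(-np.exp(model.entropy) * raw)


def train(
    presence: SampleMatrix,
    background: SampleMatrix,
    classes: set[str] | tuple[str, ...] | str = ("L", "H", "T"),
    rm: float = 2.0,
    n_knots: int = 50,
    max_iter: int = 5000,
    tol: float = 1e-4,
    add_samples_to_background: bool = True,
    seed: int | None = None,
) -> MaxentModel:
    """End-to-end fit from raw sample matrices.

    Fits feature definitions on pooled samples, builds the design matrices,
    computes the regularization vector, optionally appends presence rows to
    the background (the standard normalization domain), and fits.  Default
    settings are feature classes L+H+T with RM = 2.
    """
    defs = fit_feature_defs(presence, background, classes=classes, n_knots=n_knots)
    fp = transform_features(presence, defs)
    fb = transform_features(background, defs)
    beta = regularization_vector(defs, fp, rm)
    if add_samples_to_background:
        fb = FeatureMatrix(np.vstack([fb.values, fp.values]), defs)
    return fit_maxent(fp, fb, beta, max_iter=max_iter, tol=tol, rm=rm, seed=seed)
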