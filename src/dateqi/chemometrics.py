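"""Replicate-aware splitting, NIPALS PLSR, grouped cross-validation and
the chemometric figure-of-merit suite.

Calibration follows standard spectroscopy practice: the sample set is
partitioned 70/20/10 into training / testing / independent-validation
subsets with replicate-group integrity (all scans of one measurement
occasion stay together), latent variables are selected by grouped
cross-validated RMSECV, and models are reported with R^2, RMSEC,
RMSECV, RMSEP, REP% = RMSEP / mean(y) * 100 and
RER = range(y) / RMSEP.  RER > 10 with REP < 10% is the conventional
bar for a reliable calibration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

__all__ = [
    "SplitPlan",
    "PLSRModel",
    "MetricsReport",
    "split_dataset",
    "plsr_fit",
    "plsr_predict",
    "cross_validate_lv",
    "compute_metrics",
    "aggregate_combined",
    "round_half_up",
    "r_squared",
    "rmse",
]


class InfeasibleSplitError(ValueError):
    pass


class DegenerateResponseError(ValueError):
    pass


# ------------------------------------------------------------- splitting

@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    fractions: tuple[float, float, float]
    seed: int

    def partition_of(self) -> dict[str, str]:
        out = {}
        for name, ids in (
            ("train", self.train_ids),
            ("test", self.test_ids),
            ("validation", self.validation_ids),
        ):
            for sid in ids:
                out[sid] = name
        return out


def _largest_remainder_targets(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([-(r - b) for r, b in zip(raw, base)], kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base


def split_dataset(
    sample_ids: Sequence[str],
    replicate_group_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
) -> SplitPlan:
    """Partition samples into train/test/validation with group integrity.

    Replicate groups are shuffled with ``seed`` and assigned greedily to
    the partition with the largest remaining deficit (largest-remainder
    targets), so with singleton groups and divisible n the printed
    70/20/10 counts are exact.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(sample_ids) != len(replicate_group_ids):
        raise ValueError("sample and group id lists must have equal length")

    groups: dict[str, list[str]] = {}
    for sid, gid in zip(sample_ids, replicate_group_ids):
        groups.setdefault(str(gid), []).append(str(sid))

    n = len(sample_ids)
    targets = _largest_remainder_targets(n, fractions)
    biggest_group = max(len(v) for v in groups.values())
    if biggest_group > min(targets):
        raise InfeasibleSplitError(
            f"a replicate group of size {biggest_group} exceeds the smallest "
            f"partition target {min(targets)}"
        )

    rng = np.random.default_rng(seed)
    keys = sorted(groups)
    rng.shuffle(keys)

    buckets: list[list[str]] = [[], [], []]
    deficits = list(map(float, targets))
    for key in keys:
        members = groups[key]
        # most-underfilled partition; ties resolve toward train first
        j = int(np.argmax(deficits))
        buckets[j].extend(members)
        deficits[j] -= len(members)
    return SplitPlan(
        train_ids=tuple(buckets[0]),
        test_ids=tuple(buckets[1]),
        validation_ids=tuple(buckets[2]),
        fractions=tuple(fractions),
        seed=seed,
    )


# ----------------------------------------------------------------- PLSR

@dataclass
class PLSRModel:
    """Univariate-response PLS regression model (NIPALS).

    Mean-centered X and y, no variance scaling (all predictors share
    derivative-absorbance units).  ``coefficients`` maps centered X to
    centered y; prediction is (X - x_mean) @ coefficients + y_mean.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x A
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    coefficients: np.ndarray  # p

    def to_json(self, path=None) -> str:
        payload = {
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PLSRModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            n_components=payload["n_components"],
            x_mean=np.asarray(payload["x_mean"], dtype=float),
            y_mean=float(payload["y_mean"]),
            weights=np.asarray(payload["weights"], dtype=float),
            x_loadings=np.asarray(payload["x_loadings"], dtype=float),
            y_loadings=np.asarray(payload["y_loadings"], dtype=float),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
        )


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    # B = W (P'W)^-1 q ; P'W is upper triangular and well-conditioned here
    return W @ np.linalg.solve(P.T @ W, q)


def plsr_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSRModel:
    """NIPALS PLS1 with deflation of X and y.

    For a univariate response the inner weight iteration converges in one
    pass; the loop is retained with a weight-change tolerance for
    numerical hygiene.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have incompatible shapes")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    if np.ptp(y) == 0.0:
        raise DegenerateResponseError("y has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-300:
            # residual X carries no covariance with y; stop early
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        w /= norm
        for _ in range(max_iter):
            t = Xc @ w
            tt = float(t @ t)
            qa = float(yc @ t) / tt
            w_new = Xc.T @ (yc * qa)
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = Xc @ w
        tt = float(t @ t)
        pvec = Xc.T @ t / tt
        qa = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pvec)
        yc = yc - t * qa
        W[:, a], P[:, a], q[a] = w, pvec, qa

    ncomp = W.shape[1]
    return PLSRModel(
        n_components=ncomp,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=_coefficients(W, P, q) if ncomp else np.zeros(p),
    )


def plsr_predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X must have {model.x_mean.size} columns matching the training grid"
        )
    return (X - model.x_mean) @ model.coefficients + model.y_mean


def plsr_scores(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Latent-variable scores T for (possibly new) rows of X."""
    Xc = np.asarray(X, dtype=float) - model.x_mean
    T = np.zeros((Xc.shape[0], model.n_components))
    for a in range(model.n_components):
        t = Xc @ model.weights[:, a]
        Xc = Xc - np.outer(t, model.x_loadings[:, a])
        T[:, a] = t
    return T


# ------------------------------------------------- grouped cross-validation

def make_group_folds(
    groups: Sequence[str], k_folds: int, seed: int = 0
) -> list[np.ndarray]:
    """Index folds that respect replicate groups, balanced by sample count."""
    groups = [str(g) for g in groups]
    uniq: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        uniq.setdefault(g, []).append(i)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if len(uniq) < k_folds:
        raise ValueError(
            f"only {len(uniq)} replicate groups for {k_folds} folds"
        )
    rng = np.random.default_rng(seed)
    keys = sorted(uniq)
    rng.shuffle(keys)
    sizes = np.zeros(k_folds)
    folds: list[list[int]] = [[] for _ in range(k_folds)]
    for key in keys:
        j = int(np.argmin(sizes))
        folds[j].extend(uniq[key])
        sizes[j] += len(uniq[key])
    return [np.array(sorted(f), dtype=int) for f in folds]


@dataclass(frozen=True)
class LVSelection:
    rmsecv_per_lv: np.ndarray  # index a-1 -> RMSECV with a components
    selected_lv: int
    cv_predictions: np.ndarray  # at the selected LV, aligned with input rows


def cross_validate_lv(
    X: np.ndarray,
    y: np.ndarray,
    groups: Sequence[str],
    max_components: int = 10,
    k_folds: int = 10,
    seed: int = 0,
) -> LVSelection:
    """Grouped k-fold RMSECV over 1..max_components latent variables.

    The selected LV count is the global RMSECV minimum, ties broken
    toward fewer components.  With k equal to the number of singleton
    groups this reduces to leave-one-out.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    folds = make_group_folds(groups, k_folds, seed)
    max_components = min(max_components, X.shape[1])
    preds = np.full((max_components, y.size), np.nan)
    for fold in folds:
        mask = np.ones(y.size, dtype=bool)
        mask[fold] = False
        a_max = min(max_components, int(mask.sum()) - 1)
        model = plsr_fit(X[mask], y[mask], a_max)
        # per-component predictions from the accumulated loadings
        T = plsr_scores(model, X[fold])
        base = np.full(fold.size, model.y_mean)
        for a in range(model.n_components):
            base = base + T[:, a] * model.y_loadings[a]
            preds[a, fold] = base
        for a in range(model.n_components, max_components):
            preds[a, fold] = base  # rank-exhausted: constant beyond a_max
    rmsecv = np.sqrt(np.nanmean((preds - y[None, :]) ** 2, axis=1))
    # global minimum with ties toward fewer components; RMSECVs within a
    # machine-precision band of the minimum count as ties, so a noiseless
    # rank-k generator selects k instead of chasing rounding jitter
    best = float(np.min(rmsecv))
    tol = max(1e-8 * best, 1e-12 * float(np.std(y)))
    selected = int(np.argmax(rmsecv <= best + tol)) + 1
    return LVSelection(
        rmsecv_per_lv=rmsecv,
        selected_lv=selected,
        cv_predictions=preds[selected - 1].copy(),
    )


# -------------------------------------------------------------- metrics

def rmse(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("paired vectors must have equal length")
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))


def r_squared(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_res = float(np.sum((y_obs - y_pred) ** 2))
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


@dataclass(frozen=True)
class MetricsReport:
    r_squared: float  # calibration R^2
    rmsec: float
    rmsecv: float
    r_squared_cv: float
    rmsep: float
    r_squared_pred: float
    rep_percent: float
    rer: float
    y_mean: float  # of the independent prediction set
    y_range: float

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "rmsec": self.rmsec,
            "rmsecv": self.rmsecv,
            "r_squared_cv": self.r_squared_cv,
            "rmsep": self.rmsep,
            "r_squared_pred": self.r_squared_pred,
            "rep_percent": self.rep_percent,
            "rer": self.rer,
            "y_mean": self.y_mean,
            "y_range": self.y_range,
        }


def compute_metrics(
    y_cal: np.ndarray,
    y_pred_cal: np.ndarray,
    y_cv: np.ndarray,
    y_pred_cv: np.ndarray,
    y_test: np.ndarray,
    y_pred_test: np.ndarray,
) -> MetricsReport:
    """Full figure-of-merit suite across calibration / CV / prediction.

    REP and RER are computed on the independent prediction set; by
    construction RER * RMSEP equals the observed range and
    REP * mean(y) equals 100 * RMSEP.  A perfect prediction set (RMSEP
    = 0) reports both as infinity with a warning.
    """
    rmsec = rmse(y_cal, y_pred_cal)
    rmsecv = rmse(y_cv, y_pred_cv)
    rmsep = rmse(y_test, y_pred_test)
    y_test = np.asarray(y_test, dtype=float)
    y_mean = float(y_test.mean())
    y_range = float(np.ptp(y_test))
    if rmsep == 0.0:
        warnings.warn("RMSEP is zero; REP and RER reported as infinite")
        rep, rer = float("inf"), float("inf")
    else:
        rep = rmsep / y_mean * 100.0
        rer = y_range / rmsep
    return MetricsReport(
        r_squared=r_squared(y_cal, y_pred_cal),
        rmsec=rmsec,
        rmsecv=rmsecv,
        r_squared_cv=r_squared(y_cv, y_pred_cv),
        rmsep=rmsep,
        r_squared_pred=r_squared(y_test, y_pred_test),
        rep_percent=rep,
        rer=rer,
        y_mean=y_mean,
        y_range=y_range,
    )


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal half-up rounding on the shortest repr of ``value``."""
    return float(
        Decimal(repr(float(value))).quantize(
            Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP
        )
    )


def aggregate_combined(per_cultivar: Sequence[dict]) -> dict:
    """Combined summary row: arithmetic means of per-cultivar RMSEP /
    REP / RER, rounded half-up at 3 / 2 / 1 decimals respectively."""
    if len(per_cultivar) < 2:
        raise ValueError("need at least two per-cultivar reports to combine")

    def _get(rep, key):
        return rep[key] if isinstance(rep, dict) else getattr(rep, key)

    def _mean(key):
        # exact decimal mean so e.g. (8.12 + 8.75)/2 rounds from 8.435,
        # not from its float representation 8.43499...
        vals = [Decimal(repr(float(_get(r, key)))) for r in per_cultivar]
        return sum(vals) / len(vals)

    def _round(value: Decimal, ndigits: int) -> float:
        return float(
            value.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)
        )

    return {
        "rmsep": _round(_mean("rmsep"), 3),
        "rep_percent": _round(_mean("rep_percent"), 2),
        "rer": _round(_mean("rer"), 1),
    }
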