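"""Binary classifiers (LS-SVM, PLS-DA, KNN) and the repeated-split evaluator.

All three models are implemented here directly:

* **LS-SVM** — least-squares support vector machine with an RBF kernel
  ``K(u, v) = exp(-||u - v||^2 / sigma_k^2)``.  Training solves the single
  KKT linear system

      [[0, 1^T], [1, K + I/gamma]] @ [b; alpha] = [0; y],   y in {-1, +1}

  instead of a quadratic program; hyperparameters (gamma, sigma_k) come
  from 10-fold cross-validation over a log grid.
* **PLS-DA** — PLS1 regression (NIPALS) on 0/1 class coding, thresholded
  at 0.5, with the number of latent variables chosen by leave-one-out
  cross-validation (ties to fewer components).  At full rank the fit
  coincides with ordinary least squares.
* **KNN** — Euclidean majority vote with odd K tuned by 10-fold
  cross-validation over {1, 3, ..., 15}; distance ties resolve toward the
  smaller training index.

The evaluator repeats a stratified 7:3 train/test split (default 30
times), standardizes features on each training fold, fits the requested
model and reports TP rate (bruised recalled), TN rate (sound recalled)
and overall accuracy as means with standard errors over repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

__all__ = [
    "LssvmModel",
    "PlsdaModel",
    "KnnModel",
    "EvalReport",
    "lssvm_fit",
    "lssvm_cv_select",
    "plsda_fit",
    "knn_fit_predict",
    "knn_cv_select",
    "evaluate",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_SIGMA_GRID",
]

DEFAULT_GAMMA_GRID = tuple(np.logspace(-1, 4, 7))
DEFAULT_SIGMA_GRID = tuple(np.logspace(-1, 2, 7))
DEFAULT_K_GRID = (1, 3, 5, 7, 9, 11, 13, 15)


# ---------------------------------------------------------------- LS-SVM


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aa = (a**2).sum(axis=1)[:, None]
    bb = (b**2).sum(axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * a @ b.T, 0.0)


@dataclass
class LssvmModel:
    alpha: np.ndarray
    bias: float
    gamma: float
    sigma_k: float
    x_train: np.ndarray
    kkt_residual: float

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        k = np.exp(-_sq_dists(np.atleast_2d(x), self.x_train) / self.sigma_k**2)
        return k @ self.alpha + self.bias

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Labels in {-1, +1}; a decision value of exactly 0 maps to +1."""
        return np.where(self.decision_function(x) >= 0, 1, -1)


def lssvm_fit(x: np.ndarray, y: np.ndarray, gamma: float, sigma_k: float) -> LssvmModel:
    """Solve the LS-SVM KKT system for labels y in {-1, +1}."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if gamma <= 0 or sigma_k <= 0:
        raise ValueError("gamma and sigma_k must be > 0")
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be -1/+1")
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    n = len(y)
    k = np.exp(-_sq_dists(x, x) / sigma_k**2)
    a = np.zeros((n + 1, n + 1))
    a[0, 1:] = 1.0
    a[1:, 0] = 1.0
    a[1:, 1:] = k + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    try:
        sol = linalg.solve(a, rhs)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "singular KKT system; try a larger regularization gamma"
        ) from exc
    residual = float(np.abs(a @ sol - rhs).max())
    if not np.isfinite(residual) or residual > 1e-6:
        raise linalg.LinAlgError(
            f"ill-conditioned KKT system (residual {residual:.2e}); "
            "try a larger regularization gamma"
        )
    return LssvmModel(
        alpha=sol[1:],
        bias=float(sol[0]),
        gamma=float(gamma),
        sigma_k=float(sigma_k),
        x_train=x,
        kkt_residual=residual,
    )


def lssvm_cv_select(
    x: np.ndarray,
    y: np.ndarray,
    gamma_grid=DEFAULT_GAMMA_GRID,
    sigma_grid=DEFAULT_SIGMA_GRID,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(gamma, sigma_k, cv_error) minimizing stratified k-fold error.

    Ties resolve to the first grid point in (gamma, sigma) iteration order.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    folds = min(folds, int(np.bincount(((y + 1) // 2).astype(int)).min()))
    skf = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    d2 = _sq_dists(x, x)
    best = None
    for gamma in gamma_grid:
        for sigma_k in sigma_grid:
            k_full = np.exp(-d2 / sigma_k**2)
            errs = 0
            total = 0
            for tr, te in splits:
                n = len(tr)
                a = np.zeros((n + 1, n + 1))
                a[0, 1:] = 1.0
                a[1:, 0] = 1.0
                a[1:, 1:] = k_full[np.ix_(tr, tr)] + np.eye(n) / gamma
                rhs = np.concatenate([[0.0], y[tr]])
                try:
                    sol = linalg.solve(a, rhs)
                except linalg.LinAlgError:
                    errs += len(te)
                    total += len(te)
                    continue
                dec = k_full[np.ix_(te, tr)] @ sol[1:] + sol[0]
                pred = np.where(dec >= 0, 1.0, -1.0)
                errs += int((pred != y[te]).sum())
                total += len(te)
            err = errs / total
            if best is None or err < best[2]:
                best = (float(gamma), float(sigma_k), err)
    return best


# ---------------------------------------------------------------- PLS-DA


def _pls1_components(x: np.ndarray, y: np.ndarray, ncomp: int):
    """NIPALS PLS1: weights W, loadings P and y-loadings q per component."""
    e = x.copy()
    f = y.astype(np.float64).copy()
    w_list, p_list, q_list = [], [], []
    for _ in range(ncomp):
        w = e.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = e @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p = e.T @ t / tt
        q = float(f @ t / tt)
        e = e - np.outer(t, p)
        f = f - q * t
        w_list.append(w)
        p_list.append(p)
        q_list.append(q)
    return np.array(w_list).T, np.array(p_list).T, np.array(q_list)


def _pls1_coefs(w: np.ndarray, p: np.ndarray, q: np.ndarray, ncomp: int) -> np.ndarray:
    wk = w[:, :ncomp]
    pk = p[:, :ncomp]
    qk = q[:ncomp]
    return wk @ linalg.solve(pk.T @ wk, qk)


@dataclass
class PlsdaModel:
    n_latent: int
    coefs: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    threshold: float = 0.5

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.x_mean) @ self.coefs + self.y_mean

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Labels in {0, 1} by thresholding the regression score at 0.5."""
        return (self.decision_function(x) > self.threshold).astype(int)


def _plsda_fit_fixed(x: np.ndarray, y: np.ndarray, ncomp: int) -> PlsdaModel:
    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    w, p, q = _pls1_components(x - x_mean, y - y_mean, ncomp)
    ncomp_eff = min(ncomp, q.size)
    if ncomp_eff == 0:
        coefs = np.zeros(x.shape[1])
    else:
        coefs = _pls1_coefs(w, p, q, ncomp_eff)
    return PlsdaModel(n_latent=ncomp_eff, coefs=coefs, x_mean=x_mean, y_mean=y_mean)


def plsda_fit(x: np.ndarray, y: np.ndarray, max_lv: int = 10, select: str = "loo") -> PlsdaModel:
    """PLS-DA on 0/1 labels with the latent-variable count chosen by LOO-CV.

    ``max_lv`` is capped at min(n_features, n_samples - 1); ``select="none"``
    skips the cross-validation and uses ``max_lv`` components directly.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    n, p_dim = x.shape
    cap = min(p_dim, n - 1)
    max_lv = min(max_lv, cap)
    if select == "none":
        return _plsda_fit_fixed(x, y, max_lv)
    errors = np.zeros(max_lv)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xm = x[mask].mean(axis=0)
        ym = y[mask].mean()
        w, pl, q = _pls1_components(x[mask] - xm, y[mask] - ym, max_lv)
        avail = q.size
        for lv in range(1, max_lv + 1):
            k = min(lv, avail)
            if k == 0:
                pred = ym
            else:
                coefs = _pls1_coefs(w, pl, q, k)
                pred = (x[i] - xm) @ coefs + ym
            errors[lv - 1] += int((pred > 0.5) != bool(y[i]))
    best_lv = int(np.argmin(errors)) + 1  # argmin ties -> fewer components
    return _plsda_fit_fixed(x, y, best_lv)


# ------------------------------------------------------------------ KNN


@dataclass
class KnnModel:
    k: int
    x_train: np.ndarray
    y_train: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        return knn_fit_predict(self.x_train, self.y_train, x, self.k)


def knn_fit_predict(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, k: int
) -> np.ndarray:
    """Euclidean K-nearest-neighbor majority vote (K odd, binary labels)."""
    if k % 2 == 0:
        raise ValueError("K must be odd to avoid vote ties")
    x_train = np.asarray(x_train, dtype=np.float64)
    x_test = np.atleast_2d(np.asarray(x_test, dtype=np.float64))
    y_train = np.asarray(y_train)
    if k > len(y_train):
        raise ValueError("K exceeds the number of training samples")
    d2 = _sq_dists(x_test, x_train)
    # stable sort: equal distances rank by smaller training index
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    votes = y_train[order]
    pos = (votes == np.max(y_train)).sum(axis=1)
    return np.where(pos * 2 > k, np.max(y_train), np.min(y_train))


def knn_cv_select(
    x: np.ndarray,
    y: np.ndarray,
    k_grid=DEFAULT_K_GRID,
    folds: int = 10,
    seed: int = 0,
) -> tuple[int, float]:
    """(K, cv_error) minimizing stratified k-fold error over odd K values."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    counts = pd.Series(y).value_counts()
    folds = max(2, min(folds, int(counts.min())))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    best = None
    for k in k_grid:
        errs = 0
        total = 0
        for tr, te in splits:
            if k > len(tr):
                errs += len(te)
                total += len(te)
                continue
            pred = knn_fit_predict(x[tr], y[tr], x[te], k)
            errs += int((pred != y[te]).sum())
            total += len(te)
        err = errs / total
        if best is None or err < best[1]:
            best = (int(k), err)
    return best


# ------------------------------------------------------------- evaluation


@dataclass
class EvalReport:
    """TP/TN/ACC (percent) summarized over repeated stratified 7:3 splits."""

    model: str
    source_image: str | None
    degree_scope: str
    n_repetitions: int
    tp_rates: np.ndarray
    tn_rates: np.ndarray
    accuracies: np.ndarray

    def _mean_se(self, arr: np.ndarray) -> tuple[float, float]:
        se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        return float(arr.mean()), se

    @property
    def tp_mean(self) -> float:
        return self._mean_se(self.tp_rates)[0]

    @property
    def tn_mean(self) -> float:
        return self._mean_se(self.tn_rates)[0]

    @property
    def acc_mean(self) -> float:
        return self._mean_se(self.accuracies)[0]

    @property
    def tp_se(self) -> float:
        return self._mean_se(self.tp_rates)[1]

    @property
    def tn_se(self) -> float:
        return self._mean_se(self.tn_rates)[1]

    @property
    def acc_se(self) -> float:
        return self._mean_se(self.accuracies)[1]

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "source_image": self.source_image,
            "degree": self.degree_scope,
            "tp_mean": self.tp_mean,
            "tp_se": self.tp_se,
            "tn_mean": self.tn_mean,
            "tn_se": self.tn_se,
            "acc_mean": self.acc_mean,
            "acc_se": self.acc_se,
            "n_reps": self.n_repetitions,
        }


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _fit_predict(model: str, xtr, ytr, xte, seed: int) -> np.ndarray:
    """ytr in {0,1}; returns 0/1 predictions for xte."""
    if model == "lssvm":
        ypm = 2.0 * ytr - 1.0
        gamma, sigma_k, _ = lssvm_cv_select(xtr, ypm, seed=seed)
        fitted = lssvm_fit(xtr, ypm, gamma, sigma_k)
        return (fitted.predict(xte) > 0).astype(int)
    if model == "plsda":
        fitted = plsda_fit(xtr, ytr)
        return fitted.predict(xte)
    if model == "knn":
        k, _ = knn_cv_select(xtr, ytr, seed=seed)
        return knn_fit_predict(xtr, ytr, xte, k).astype(int)
    raise ValueError(f"unknown model {model!r}; expected lssvm/plsda/knn")


def evaluate(
    features: pd.DataFrame,
    model: str = "lssvm",
    degree_scope: str = "ALL",
    source_image: str | None = None,
    n_reps: int = 30,
    split: float = 0.7,
    subset: list[str] | None = None,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified 7:3 evaluation of one model on a feature table.

    ``features`` must carry sample_id / degree / source_image columns plus
    the feature columns.  The scope defines positives — bruised samples of
    the stated degree, or all of S1..S3 for "ALL" — against the sound S0
    class.  ``subset`` optionally restricts to a list of feature columns
    (e.g. a random-frog top-10).  Rows are canonically sorted by sample_id
    before any seeded split so the report is invariant to input ordering.
    """
    if degree_scope not in {"S1", "S2", "S3", "ALL"}:
        raise ValueError(f"unknown degree scope {degree_scope!r}")
    df = features
    if source_image is not None:
        df = df[df["source_image"] == source_image]
    pos_degrees = {"ALL": ("S1", "S2", "S3")}.get(degree_scope, (degree_scope,))
    df = df[df["degree"].isin(pos_degrees + ("S0",))]
    df = df.sort_values("sample_id").reset_index(drop=True)
    meta_cols = {"sample_id", "degree", "label", "source_image"}
    feat_cols = [c for c in df.columns if c not in meta_cols]
    if subset is not None:
        missing = set(subset) - set(feat_cols)
        if missing:
            raise ValueError(f"unknown subset features: {sorted(missing)}")
        feat_cols = list(subset)
    x = df[feat_cols].to_numpy(dtype=np.float64)
    y = (df["degree"] != "S0").to_numpy().astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both bruised and sound samples are required")

    sss = StratifiedShuffleSplit(n_splits=n_reps, train_size=split, random_state=seed)
    tp, tn, acc = [], [], []
    for rep, (tr, te) in enumerate(sss.split(x, y)):
        xtr, xte = _standardize(x[tr], x[te])
        pred = _fit_predict(model, xtr, y[tr], xte, seed=seed + rep)
        yte = y[te]
        tp.append(100.0 * (pred[yte == 1] == 1).mean())
        tn.append(100.0 * (pred[yte == 0] == 0).mean())
        acc.append(100.0 * (pred == yte).mean())
    return EvalReport(
        model=model,
        source_image=source_image,
        degree_scope=degree_scope,
        n_repetitions=n_reps,
        tp_rates=np.array(tp),
        tn_rates=np.array(tn),
        accuracies=np.array(acc),
    )
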