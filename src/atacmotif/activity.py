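"""Motif activity inference by penalized linear regression.

Each accessible chromatin site's accessibility log2 fold-change is modeled
as a linear combination of the motifs it contains::

    log2fc_i = beta0 + sum_m N[i, m] * beta_m + eps_i

where ``N`` is the ACS x motif match matrix.  The per-motif coefficient
``beta_m`` is the motif's *activity*: positive when the motif's presence
associates with sites opening in the treatment condition (adult), negative
when it associates with closing sites (repressor-like, the SCRT1 pattern).
The fit is an elastic net,

    (1/2n) ||y - beta0 - X beta||^2 + lambda * (alpha ||beta||_1
                                                + (1-alpha)/2 ||beta||_2^2),

solved by cyclic coordinate descent with soft-thresholding on the Gram
matrix, with the penalty chosen by k-fold cross-validation along a
geometric lambda path (lambda_min or 1-SE rule).  Predictors are
standardized internally; coefficients are reported on the original scale.
The default alpha = 0.5 blends L1 sparsity with an L2 term that spreads
weight across correlated motif columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_ALPHA_FLOOR = 1e-3  # for the lambda grid when alpha ~ 0 (glmnet convention)


def _soft_threshold(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    ok = scale > 0
    Xs = np.zeros_like(X, dtype=float)
    Xs[:, ok] = (X[:, ok] - mean[ok]) / scale[ok]
    return Xs, mean, scale, ok


def _cd_solve(G: np.ndarray, c: np.ndarray, lam: float, alpha: float,
              beta: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, int]:
    """Cyclic coordinate descent with soft-thresholding on the Gram system."""
    p = len(c)
    Gb = G @ beta
    diag = np.diag(G).copy()
    denom = diag + lam * (1.0 - alpha)
    thresh = lam * alpha
    for it in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            rho = c[j] - Gb[j] + diag[j] * beta[j]
            new = _soft_threshold(rho, thresh) / denom[j]
            delta = new - beta[j]
            if delta != 0.0:
                Gb += G[:, j] * delta
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            return beta, it + 1
    raise RuntimeError(f"coordinate descent did not converge in {max_iter} sweeps")


def elastic_net_fit(X, y, lam: float, alpha: float, standardize: bool = True,
                    tol: float = 1e-7, max_iter: int = 100_000
                    ) -> tuple[np.ndarray, float]:
    """Solve one elastic-net problem; returns (coefficients, intercept).

    Coefficients are on the original predictor scale.  Constant columns are
    dropped (coefficient 0) with a warning when standardizing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    if X.shape[0] != len(y) or X.shape[0] < 2:
        raise ValueError("X and y must share n >= 2 rows")
    if lam < 0 or not 0 <= alpha <= 1:
        raise ValueError("need lambda >= 0 and alpha in [0, 1]")
    n, p = X.shape
    y_mean = y.mean()
    yc = y - y_mean
    if standardize:
        Xs, x_mean, x_scale, ok = _standardize(X)
        if not ok.all():
            warnings.warn(f"dropping {int((~ok).sum())} constant column(s)")
    else:
        Xs, x_mean = X, np.zeros(p)
        x_scale, ok = np.ones(p), np.ones(p, dtype=bool)
    G = (Xs.T @ Xs) / n
    d = np.diag(G).copy()
    d[d == 0] = 1.0  # dropped/constant columns: keep the system well-posed
    np.fill_diagonal(G, d)
    c = (Xs.T @ yc) / n
    beta = np.zeros(p)
    beta, _ = _cd_solve(G, c, lam, alpha, beta, tol, max_iter)
    beta[~ok] = 0.0
    coef = np.where(ok, beta / np.where(x_scale > 0, x_scale, 1.0), 0.0)
    intercept = y_mean - float(coef @ x_mean)
    return coef, intercept


def kkt_violation(X, y, coef, intercept, lam: float, alpha: float) -> float:
    """Maximum KKT stationarity violation of an elastic-net solution.

    Computed on the standardized problem: for every predictor ``j`` with
    gradient ``g_j = <x_j, r>/n``, active coordinates must satisfy
    ``g_j - lam*(1-alpha)*b_j = lam*alpha*sign(b_j)`` and inactive ones
    ``|g_j| <= lam*alpha``.  Returns the largest absolute violation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    Xs, x_mean, x_scale, ok = _standardize(X)
    b = np.asarray(coef, dtype=float) * np.where(x_scale > 0, x_scale, 1.0)
    yc = y - y.mean()
    r = yc - Xs @ b
    g = (Xs.T @ r) / n
    viol = np.where(
        b != 0,
        np.abs(g - lam * (1 - alpha) * b - lam * alpha * np.sign(b)),
        np.clip(np.abs(g) - lam * alpha, 0.0, None),
    )
    return float(viol[ok].max()) if ok.any() else 0.0


def lambda_max(X, y, alpha: float) -> float:
    """Smallest penalty nulling every coefficient (standardized problem)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    Xs, _, _, ok = _standardize(X)
    c = np.abs(Xs.T @ (y - y.mean())) / n
    return float(c[ok].max()) / max(alpha, _ALPHA_FLOOR)


def elastic_net_path(X, y, lambdas, alpha: float, tol: float = 1e-7,
                     max_iter: int = 100_000) -> np.ndarray:
    """Warm-started coefficient path (len(lambdas) x p, original scale)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    yc = y - y.mean()
    Xs, _, x_scale, ok = _standardize(X)
    G = (Xs.T @ Xs) / n
    np.fill_diagonal(G, 1.0)
    c = (Xs.T @ yc) / n
    beta = np.zeros(p)
    out = np.zeros((len(lambdas), p))
    for i, lam in enumerate(lambdas):
        beta, _ = _cd_solve(G, c, float(lam), alpha, beta, tol, max_iter)
        beta[~ok] = 0.0
        out[i] = np.where(ok, beta / np.where(x_scale > 0, x_scale, 1.0), 0.0)
    return out


def _predict(X, y_train_mean, x_mean, coef):
    return y_train_mean + (X - x_mean) @ coef


def cv_lambda_path(X, y, alpha: float = 0.5, n_folds: int = 10,
                   n_lambda: int = 100, seed: int = 0,
                   lambda_min_ratio: float = 1e-4) -> pd.DataFrame:
    """Cross-validated MSE along a geometric lambda path.

    Folds are assigned by a seeded shuffle; the path is warm-started from
    lambda_max (all-zero solution) downward.  Returns a frame with columns
    ``lam, cv_mean, cv_se`` and attrs ``lambda_min``/``lambda_1se``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"n = {n} smaller than n_folds = {n_folds}")
    lam_hi = lambda_max(X, y, alpha)
    if lam_hi == 0:
        lam_hi = 1e-3  # y orthogonal to all predictors; any path selects zero
    lambdas = np.geomspace(lam_hi, lam_hi * lambda_min_ratio, n_lambda)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, n_folds)
    if min(len(f) for f in folds) < 1:
        raise ValueError("degenerate fold sizes")
    errs = np.zeros((n_folds, len(lambdas)))
    for f, test in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        path = elastic_net_path(X[mask], y[mask], lambdas, alpha)
        x_mean = X[mask].mean(axis=0)
        y_mean = y[mask].mean()
        for i in range(len(lambdas)):
            pred = _predict(X[test], y_mean, x_mean, path[i])
            errs[f, i] = np.mean((y[test] - pred) ** 2)
    cv_mean = errs.mean(axis=0)
    cv_se = errs.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mean))
    within = np.flatnonzero(cv_mean <= cv_mean[i_min] + cv_se[i_min])
    i_1se = int(within.min())  # largest lambda within one SE (grid is descending)
    table = pd.DataFrame({"lam": lambdas, "cv_mean": cv_mean, "cv_se": cv_se})
    table.attrs["lambda_min"] = float(lambdas[i_min])
    table.attrs["lambda_1se"] = float(lambdas[i_1se])
    return table


# ---------------------------------------------------------------------------
# model / results


class MotifActivityModel:
    """Elastic-net regression of ACS log2 fold-change on motif matches.

    Parameters
    ----------
    match_matrix : MotifMatchMatrix or DataFrame (ACS x motifs).
    log2fc : Series per ACS (all ACS, not only the significant ones).
    alpha : elastic-net mixing (1 = lasso); default 0.5.
    min_matches : motifs matching fewer ACS than this are dropped.
    """

    def __init__(self, match_matrix, log2fc: pd.Series, alpha: float = 0.5,
                 min_matches: int = 10):
        N = match_matrix.N if hasattr(match_matrix, "N") else match_matrix
        if not isinstance(log2fc, pd.Series):
            log2fc = pd.Series(np.asarray(log2fc, dtype=float), index=N.index)
        missing = N.index.symmetric_difference(log2fc.index)
        if len(missing):
            raise ValueError(
                f"match matrix and log2fc indexes differ on {len(missing)} ids, "
                f"e.g. {list(missing[:5])}")
        log2fc = log2fc.reindex(N.index)
        keep = (N > 0).sum(axis=0) >= min_matches
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} motif(s) matching fewer than "
                f"{min_matches} ACS")
        self.N = N.loc[:, keep]
        self.log2fc = log2fc
        self.alpha = float(alpha)

    def fit(self, rule: str = "min", n_folds: int = 10, n_lambda: int = 100,
            seed: int = 0) -> "MotifActivityResults":
        """Cross-validate lambda, refit on all ACS, report per-motif activity."""
        if rule not in ("min", "1se"):
            raise ValueError("rule must be 'min' or '1se'")
        X = self.N.to_numpy(dtype=float)
        y = self.log2fc.to_numpy(dtype=float)
        cv = cv_lambda_path(X, y, self.alpha, n_folds=n_folds,
                            n_lambda=n_lambda, seed=seed)
        lam = cv.attrs["lambda_min" if rule == "min" else "lambda_1se"]
        lambdas = cv["lam"].to_numpy()
        path = elastic_net_path(X, y, lambdas[lambdas >= lam], self.alpha)
        coef = path[-1]
        table = pd.DataFrame({
            "activity": coef,
            "selected": coef != 0.0,
        }, index=self.N.columns.rename("motif_id"))
        table = table.reindex(table["activity"].abs()
                              .sort_values(ascending=False).index)
        return MotifActivityResults(self, table, float(lam), self.alpha, rule, cv)


@dataclass
class MotifActivityResults:
    """Per-motif activities at the cross-validated penalty."""

    model: MotifActivityModel
    table: pd.DataFrame  # activity, selected; sorted by |activity|
    lambda_: float
    alpha: float
    rule: str
    cv_table: pd.DataFrame

    @property
    def activities(self) -> pd.Series:
        return self.table["activity"]

    def summary(self) -> str:
        sel = self.table[self.table["selected"]]
        lines = [
            "Motif activity (elastic net on motif-match matrix)",
            f"  ACS: {len(self.model.log2fc)}   motifs: {len(self.table)}   "
            f"alpha: {self.alpha}   lambda ({self.rule}): {self.lambda_:.4g}",
            f"  selected motifs (activity != 0): {len(sel)}",
        ]
        for motif, row in sel.head(10).iterrows():
            lines.append(f"    {motif}: activity={row['activity']:+.3f}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["lambda"] = self.lambda_
        out["alpha"] = self.alpha
        out.to_csv(path, sep="\t", index_label="motif_id", lineterminator="\n")

    def plot_cv(self, ax=None):
        """CV error (mean +- SE) along the lambda path, chosen lambda marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cv = self.cv_table
        ax.errorbar(np.log10(cv["lam"]), cv["cv_mean"], yerr=cv["cv_se"],
                    fmt=".-", lw=0.8, ms=3)
        ax.axvline(np.log10(self.lambda_), color="tab:red", ls="--",
                   label=f"lambda_{self.rule}")
        ax.set_xlabel("log10 lambda")
        ax.set_ylabel("CV mean squared error")
        ax.legend()
        return ax


def motif_activity(match_matrix, log2fc, alpha: float = 0.5, rule: str = "min",
                   seed: int = 0, min_matches: int = 10) -> MotifActivityResults:
    """One-call wrapper around :class:`MotifActivityModel`."""
    return MotifActivityModel(match_matrix, log2fc, alpha=alpha,
                              min_matches=min_matches).fit(rule=rule, seed=seed)
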