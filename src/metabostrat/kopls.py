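"""Kernel-based orthogonal projections to latent structures (K-OPLS).

A kernelized variant of OPLS for a single binary response: one predictive
latent component plus ``ao`` Y-orthogonal components that absorb systematic
variation in the predictors uncorrelated with the class.  Everything is
expressed through the (centered) Gram matrix, so only kernel evaluations of
the data are needed; with a linear kernel the model is algebraically
identical to primal OPLS, which is the correctness oracle used by the tests.

Model estimation is the dual form of the OPLS deflation.  Writing ``u`` for
the centered response and ``K_1`` for the centered training kernel:

* predictive score  ``t_p = K_1 u / sqrt(u' K_1 u)``  (i.e. ``t_p = X w`` with
  the unit weight ``w = X'u / ||X'u||``);
* each orthogonal score ``t_o = K_i t_p / (t_p' t_p) - t_p`` followed by
  deflation ``K_{i+1} = (I - P) K_i (I - P)``, ``P = t_o t_o' / (t_o' t_o)``,
  and ``t_p <- (I - P) t_p``;
* prediction regresses the final ``t_p`` on ``u``.

Classification uses the {0, 1} coding with a 0.5 decision threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .metrics import ModelReport, auc, auc_ci, confusion_metrics

__all__ = [
    "KoplsConfig",
    "KOPLS",
    "KOPLSResults",
    "gaussian_kernel",
    "linear_kernel",
    "center_kernel_train",
    "center_kernel_test",
    "fit_kopls",
    "predict_kopls",
    "fit_statistics",
    "grid_search_accv",
    "median_pairwise_distance",
    "DEFAULT_SIGMA_GRID",
    "DEFAULT_AO_GRID",
]

# grid of kernel widths, as multiples of the median pairwise distance, and of
# Y-orthogonal component counts searched by default
DEFAULT_SIGMA_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0)
DEFAULT_AO_GRID = (0, 1, 2, 3, 4, 5)

_EPS = 1e-12


@dataclass
class KoplsConfig:
    """Kernel width, number of Y-orthogonal components, and CV folds.

    ``sigma`` may be a positive float or the string ``"median"``, resolving
    to the median pairwise Euclidean distance of the training samples — a
    scale-free default appropriate for sum-normalized intensities.
    """

    sigma: float | str = "median"
    ao: int = 1
    n_folds: int = 10

    def __post_init__(self):
        if isinstance(self.sigma, str):
            if self.sigma != "median":
                raise ValueError("sigma must be a positive number or 'median'")
        elif self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.ao < 0 or int(self.ao) != self.ao:
            raise ValueError("ao must be a non-negative integer")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")


def gaussian_kernel(X1, X2, sigma: float) -> np.ndarray:
    """Gaussian (RBF) Gram matrix K[i, j] = exp(-||x1_i - x2_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("feature dimensions must match")
    sq1 = np.sum(X1 * X1, axis=1)[:, None]
    sq2 = np.sum(X2 * X2, axis=1)[None, :]
    d2 = np.maximum(sq1 + sq2 - 2.0 * X1 @ X2.T, 0.0)
    return np.exp(-d2 / (2.0 * sigma ** 2))


def linear_kernel(X1, X2) -> np.ndarray:
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    return X1 @ X2.T


def median_pairwise_distance(X, max_samples: int = 200) -> float:
    """Median nonzero pairwise Euclidean distance (deterministic subsample)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n > max_samples:
        idx = np.linspace(0, n - 1, max_samples).astype(int)
        X = X[idx]
    d2 = np.sum(X * X, axis=1)[:, None] + np.sum(X * X, axis=1)[None, :] - 2 * X @ X.T
    d = np.sqrt(np.maximum(d2[np.triu_indices(X.shape[0], k=1)], 0.0))
    d = d[d > 0]
    return float(np.median(d)) if d.size else 1.0


def resolve_sigma(sigma, X) -> float:
    return median_pairwise_distance(X) if isinstance(sigma, str) else float(sigma)


@dataclass
class KernelCenteringStats:
    col_mean: np.ndarray  # mean over training rows, one per training sample
    grand_mean: float


def center_kernel_train(K):
    """Double-center a square training kernel; returns (Kc, stats).

    Equivalent to centering the feature map: Kc = (I - 11'/n) K (I - 11'/n).
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("training kernel must be square")
    col_mean = K.mean(axis=0)
    grand = float(K.mean())
    Kc = K - col_mean[None, :] - col_mean[:, None] + grand
    return Kc, KernelCenteringStats(col_mean=col_mean, grand_mean=grand)


def center_kernel_test(K_test_train, stats: KernelCenteringStats):
    """Center a test x train cross-kernel with the training centering stats."""
    K = np.atleast_2d(np.asarray(K_test_train, dtype=float))
    if K.shape[1] != stats.col_mean.size:
        raise ValueError("cross-kernel column count must equal the training size")
    return K - K.mean(axis=1, keepdims=True) - stats.col_mean[None, :] + stats.grand_mean


@dataclass
class KoplsState:
    """Everything needed to reproduce fitted values and predict new samples."""

    y_mean: float
    c: float                       # sqrt(u' K_1 u), the predictive weight norm
    yc: np.ndarray                 # centered training response
    tp: np.ndarray                 # final predictive score (after deflation)
    b: float                       # regression of y on tp
    To: list = field(default_factory=list)        # orthogonal scores t_o,k
    tp_stages: list = field(default_factory=list)  # t_p at each stage k
    u_k: list = field(default_factory=list)        # K_k t_o / (t_o' t_o)
    s_k: list = field(default_factory=list)        # t_o' K_k t_o / (t_o' t_o)^2
    d_k: list = field(default_factory=list)        # t_o' t_p / (t_o' t_o)
    ao: int = 0
    r2x: float = np.nan
    r2y: float = np.nan
    fitted: np.ndarray = None

    @property
    def n_train(self) -> int:
        return self.yc.size


def fit_kopls(Kc, y, ao: int) -> KoplsState:
    """Estimate a K-OPLS model from a centered training kernel.

    Parameters
    ----------
    Kc : ndarray (n, n)
        Centered training kernel.
    y : ndarray of {0, 1}
        Binary response; centered internally.
    ao : int
        Number of Y-orthogonal components.  If an orthogonal direction
        degenerates (no Y-orthogonal variation left) estimation stops early
        and the fitted model carries fewer components.
    """
    Kc = np.asarray(Kc, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if Kc.shape != (n, n):
        raise ValueError("kernel / response size mismatch")
    if ao < 0:
        raise ValueError("ao must be non-negative")
    if ao >= n:
        raise ValueError("ao must be smaller than the number of samples")
    ymean = float(y.mean())
    yc = y - ymean
    if np.allclose(yc, 0.0):
        raise ValueError("response has zero variance")

    c2 = float(yc @ Kc @ yc)
    if c2 <= _EPS:
        raise ValueError("response is orthogonal to the kernel; cannot fit")
    c = np.sqrt(c2)
    trace_k1 = float(np.trace(Kc))

    state = KoplsState(y_mean=ymean, c=c, yc=yc, tp=None, b=0.0)
    Ki = Kc.copy()
    tp = Kc @ yc / c
    for _ in range(ao):
        tptp = float(tp @ tp)
        if tptp <= _EPS:
            break
        to = Ki @ tp / tptp - tp
        toto = float(to @ to)
        if toto <= _EPS * max(tptp, 1.0):
            break  # no Y-orthogonal variation remains
        u = Ki @ to / toto
        s = float(to @ u) / toto
        d = float(to @ tp) / toto
        state.To.append(to)
        state.tp_stages.append(tp.copy())
        state.u_k.append(u)
        state.s_k.append(s)
        state.d_k.append(d)
        # deflate kernel and predictive score
        Ki = Ki - np.outer(to, u) - np.outer(u, to) + s * np.outer(to, to)
        Ki = 0.5 * (Ki + Ki.T)
        tp = tp - d * to
    state.ao = len(state.To)
    state.tp = tp

    tptp = float(tp @ tp)
    if tptp <= _EPS:
        raise ValueError("predictive score degenerated")
    state.b = float(tp @ yc) / tptp
    state.fitted = state.b * tp + ymean
    ss_tot = float(yc @ yc)
    state.r2y = 1.0 - float(np.sum((y - state.fitted) ** 2)) / ss_tot
    # explained fraction of the centered-kernel trace after removing the
    # predictive and orthogonal components; with the rank-1 projector P,
    # trace((I-P) Ki (I-P)) = trace(Ki) - tp' Ki tp / (tp' tp)
    res_trace = float(np.trace(Ki)) - float(tp @ (Ki @ tp)) / tptp
    state.r2x = 1.0 - res_trace / trace_k1 if trace_k1 > _EPS else np.nan
    return state


def predict_kopls(state: KoplsState, Kc_test_train) -> np.ndarray:
    """Continuous predictions for test samples from a centered cross-kernel.

    The cross-kernel must be computed against the model's training samples
    with the model's kernel and centered with the training statistics.
    Class decisions are ``yhat >= 0.5``.
    """
    Ks = np.atleast_2d(np.asarray(Kc_test_train, dtype=float))
    if Ks.shape[1] != state.n_train:
        raise ValueError("cross-kernel column count must equal the training size")
    tps = Ks @ state.yc / state.c
    for to, tpk, u, s, d in zip(
        state.To, state.tp_stages, state.u_k, state.s_k, state.d_k
    ):
        tptp = float(tpk @ tpk)
        toto = float(to @ to)
        tos = Ks @ tpk / tptp - tps
        Ks = Ks - np.outer(Ks @ to / toto, to) - np.outer(tos, u) + s * np.outer(tos, to)
        tps = tps - d * tos
    return state.b * tps + state.y_mean


def fit_statistics(X, y, config: KoplsConfig, seed: int = 0):
    """(r2x, r2y, q2y) for a Gaussian K-OPLS model on (X, y).

    r2x / r2y come from the full-data fit; q2y = 1 - PRESS / SS_tot over
    ``config.n_folds`` stratified cross-validation folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    sigma = resolve_sigma(config.sigma, X)
    Kc, _ = center_kernel_train(gaussian_kernel(X, X, sigma))
    state = fit_kopls(Kc, y, config.ao)

    counts = np.bincount(y.astype(int), minlength=2)
    if config.n_folds > counts.min():
        raise ValueError(
            f"n_folds={config.n_folds} exceeds the smaller class count {counts.min()}"
        )
    press = 0.0
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        Ktr = gaussian_kernel(X[tr], X[tr], sigma)
        Kc_tr, stats_tr = center_kernel_train(Ktr)
        st = fit_kopls(Kc_tr, y[tr], config.ao)
        Kte = center_kernel_test(gaussian_kernel(X[te], X[tr], sigma), stats_tr)
        yhat = predict_kopls(st, Kte)
        press += float(np.sum((y[te] - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return state.r2x, state.r2y, 1.0 - press / ss_tot


def grid_search_accv(
    X,
    y,
    sigma_grid=None,
    ao_grid=DEFAULT_AO_GRID,
    n_folds: int = 10,
    seed: int = 0,
    relative_sigma: bool = True,
):
    """Cross-validated accuracy (ACCV) over a (sigma, ao) grid.

    ACCV is the pooled classification accuracy over stratified CV folds.
    When ``relative_sigma`` is true the sigma grid is interpreted as
    multiples of the median pairwise distance of X.  Returns
    ``(surface, best_sigma, best_ao)`` where ``surface`` is a DataFrame with
    sigma rows and ao columns.  Ties are broken toward smaller ao, then
    smaller sigma.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if sigma_grid is None:
        sigma_grid = DEFAULT_SIGMA_GRID
    sigma_grid = [float(s) for s in sigma_grid]
    ao_grid = [int(a) for a in ao_grid]
    if not sigma_grid or not ao_grid:
        raise ValueError("sigma and ao grids must be nonempty")
    scale = median_pairwise_distance(X) if relative_sigma else 1.0
    sigmas = [s * scale for s in sigma_grid]

    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"the smaller class ({counts.min()}) cannot populate {n_folds} folds; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    correct = np.zeros((len(sigmas), len(ao_grid)))
    for i, sig in enumerate(sigmas):
        K = gaussian_kernel(X, X, sig)
        for tr, te in folds:
            Kc_tr, stats_tr = center_kernel_train(K[np.ix_(tr, tr)])
            Kte = center_kernel_test(K[np.ix_(te, tr)], stats_tr)
            for j, ao in enumerate(ao_grid):
                st = fit_kopls(Kc_tr, y[tr], ao)
                pred = (predict_kopls(st, Kte) >= 0.5).astype(int)
                correct[i, j] += int(np.sum(pred == y[te]))
    accv = correct / y.size
    surface = pd.DataFrame(accv, index=sigmas, columns=ao_grid)
    surface.index.name = "sigma"
    surface.columns.name = "ao"
    best = accv.max()
    # smaller ao first, then smaller sigma
    best_i, best_j = min(
        ((i, j) for i in range(len(sigmas)) for j in range(len(ao_grid))
         if accv[i, j] >= best - 1e-15),
        key=lambda ij: (ao_grid[ij[1]], sigmas[ij[0]]),
    )
    return surface, sigmas[best_i], ao_grid[best_j]


class KOPLS:
    """Gaussian-kernel OPLS classifier for a binary response.

    Parameters
    ----------
    X : array-like (n_samples, n_features)
    y : array-like of {0, 1}
        1 is the positive (minority) class.
    sigma : float or "median"
        Gaussian kernel width; "median" uses the median pairwise distance.
    n_ortho : int
        Number of Y-orthogonal components (Ao).
    kernel : "gaussian" or "linear"
        The linear kernel exists for validation against primal OPLS.

    Examples
    --------
    >>> model = KOPLS(X, y, sigma="median", n_ortho=2)
    >>> res = model.fit()
    >>> res.predict_class(X_new)
    """

    def __init__(self, X, y, sigma="median", n_ortho: int = 0, kernel: str = "gaussian"):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be 2-D with one row per response entry")
        if kernel not in ("gaussian", "linear"):
            raise ValueError("kernel must be 'gaussian' or 'linear'")
        self.kernel = kernel
        self.sigma = resolve_sigma(sigma, self.X) if kernel == "gaussian" else None
        self.n_ortho = int(n_ortho)

    def _gram(self, X1, X2):
        if self.kernel == "gaussian":
            return gaussian_kernel(X1, X2, self.sigma)
        return linear_kernel(X1, X2)

    def fit(self) -> "KOPLSResults":
        K = self._gram(self.X, self.X)
        Kc, stats = center_kernel_train(K)
        state = fit_kopls(Kc, self.y, self.n_ortho)
        return KOPLSResults(self, state, stats)


class KOPLSResults:
    """Fitted K-OPLS model: scores, fit statistics, prediction, evaluation."""

    def __init__(self, model: KOPLS, state: KoplsState, centering: KernelCenteringStats):
        self.model = model
        self.state = state
        self.centering = centering

    # -- accessors ---------------------------------------------------------
    @property
    def sigma(self):
        return self.model.sigma

    @property
    def n_ortho(self) -> int:
        return self.state.ao

    @property
    def scores_predictive(self) -> np.ndarray:
        return self.state.tp

    @property
    def scores_orthogonal(self) -> np.ndarray:
        if not self.state.To:
            return np.empty((self.state.n_train, 0))
        return np.column_stack(self.state.To)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.state.fitted

    @property
    def r2x(self) -> float:
        return self.state.r2x

    @property
    def r2y(self) -> float:
        return self.state.r2y

    # -- prediction --------------------------------------------------------
    def predict(self, X_new) -> np.ndarray:
        """Continuous predictions on the original {0, 1} response scale."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.model.X.shape[1]:
            raise ValueError("feature dimension mismatch with the training data")
        K = self.model._gram(X_new, self.model.X)
        return predict_kopls(self.state, center_kernel_test(K, self.centering))

    def predict_class(self, X_new) -> np.ndarray:
        return (self.predict(X_new) >= 0.5).astype(int)

    # -- evaluation --------------------------------------------------------
    def cross_validate(self, n_folds: int = 10, seed: int = 0):
        """(q2y, accv) by refitting on stratified folds of the training data."""
        cfg = KoplsConfig(
            sigma=self.sigma if self.sigma is not None else 1.0,
            ao=self.n_ortho, n_folds=n_folds,
        )
        X, y = self.model.X, self.model.y.astype(int)
        counts = np.bincount(y, minlength=2)
        if counts.min() < n_folds:
            raise ValueError("n_folds exceeds the smaller class count")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        press, n_correct = 0.0, 0
        for tr, te in skf.split(X, y):
            Kc_tr, stats_tr = center_kernel_train(self.model._gram(X[tr], X[tr]))
            st = fit_kopls(Kc_tr, y[tr], self.n_ortho)
            Kte = center_kernel_test(self.model._gram(X[te], X[tr]), stats_tr)
            yhat = predict_kopls(st, Kte)
            press += float(np.sum((y[te] - yhat) ** 2))
            n_correct += int(np.sum((yhat >= 0.5).astype(int) == y[te]))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - press / ss_tot, n_correct / y.size

    def evaluate(self, X_eval, y_eval, n_folds: int = 10, seed: int = 0) -> ModelReport:
        """Full report: CV statistics on the training data plus classification
        metrics of this fitted model on the evaluation set."""
        scores = self.predict(X_eval)
        pred = (scores >= 0.5).astype(int)
        cm = confusion_metrics(y_eval, pred)
        a = auc(y_eval, scores)
        lo, hi = auc_ci(y_eval, scores)
        q2y, accv = self.cross_validate(n_folds=n_folds, seed=seed)
        return ModelReport(
            sigma=float(self.sigma) if self.sigma is not None else float("nan"),
            ao=self.n_ortho, accv=accv, r2x=self.r2x, r2y=self.r2y, q2y=q2y,
            total_accuracy=cm.total_accuracy, balanced_accuracy=cm.balanced_accuracy,
            auc=a, auc_ci_low=lo, auc_ci_high=hi,
            sensitivity=cm.sensitivity, specificity=cm.specificity,
        )

    def score_plot_frame(self) -> pd.DataFrame:
        """First predictive vs first Y-orthogonal score, one row per sample."""
        out = pd.DataFrame({"tp1": self.scores_predictive})
        out["to1"] = self.scores_orthogonal[:, 0] if self.state.To else np.nan
        out["y"] = self.model.y.astype(int)
        return out

    def summary(self) -> str:
        lines = [
            "K-OPLS classification results",
            "=" * 34,
            f"kernel:            {self.model.kernel}"
            + (f" (sigma={self.sigma:.4g})" if self.sigma is not None else ""),
            f"n_samples:         {self.state.n_train}",
            f"Y-orthogonal (Ao): {self.n_ortho}",
            f"R2X:               {self.r2x:.4f}",
            f"R2Y:               {self.r2y:.4f}",
        ]
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        st = self.state
        payload = {
            "schema": "metabostrat-kopls-1",
            "kernel": self.model.kernel,
            "sigma": self.sigma,
            "X_train": self.model.X.tolist(),
            "y_train": self.model.y.tolist(),
            "state": {
                "y_mean": st.y_mean, "c": st.c, "b": st.b, "ao": st.ao,
                "r2x": st.r2x, "r2y": st.r2y,
                "yc": st.yc.tolist(), "tp": st.tp.tolist(),
                "fitted": st.fitted.tolist(),
                "To": [t.tolist() for t in st.To],
                "tp_stages": [t.tolist() for t in st.tp_stages],
                "u_k": [u.tolist() for u in st.u_k],
                "s_k": st.s_k, "d_k": st.d_k,
            },
            "centering": {
                "col_mean": self.centering.col_mean.tolist(),
                "grand_mean": self.centering.grand_mean,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "KOPLSResults":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema") != "metabostrat-kopls-1":
            raise ValueError("unrecognized model file schema")
        model = KOPLS(
            np.array(payload["X_train"]), np.array(payload["y_train"]),
            sigma=payload["sigma"] if payload["sigma"] is not None else 1.0,
            n_ortho=payload["state"]["ao"], kernel=payload["kernel"],
        )
        s = payload["state"]
        state = KoplsState(
            y_mean=s["y_mean"], c=s["c"], yc=np.array(s["yc"]),
            tp=np.array(s["tp"]), b=s["b"],
            To=[np.array(t) for t in s["To"]],
            tp_stages=[np.array(t) for t in s["tp_stages"]],
            u_k=[np.array(u) for u in s["u_k"]],
            s_k=list(s["s_k"]), d_k=list(s["d_k"]),
            ao=s["ao"], r2x=s["r2x"], r2y=s["r2y"], fitted=np.array(s["fitted"]),
        )
        centering = KernelCenteringStats(
            col_mean=np.array(payload["centering"]["col_mean"]),
            grand_mean=payload["centering"]["grand_mean"],
        )
        return cls(model, state, centering)
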