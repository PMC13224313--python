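"""Longitudinal support-vector models for next-session BCI prediction.

Each subject contributes a matrix ``X_i`` of shape (s, f): one row of f
features per training session. A temporal trend vector ``beta = (1, b_1,
..., b_{s-1})`` collapses the rows into a single profile

    x~_i = X_i^T beta = x_{i,1} + b_1 x_{i,2} + ... + b_{s-1} x_{i,s}

and the Gram matrix ``G_ij = beta^T X_i X_j^T beta = <x~_i, x~_j>`` feeds a
standard dual SVM. ``beta`` and the dual solution are estimated by
alternating optimization: (i) solve the dual epsilon-SVR / soft-margin SVC
quadratic program on G(beta); (ii) holding the dual-weighted data profile
``u = sum_j a_j X_j^T beta`` fixed, predictions become linear in beta
(``yhat_i = (X_i u)^T beta + b``), and the free components of beta
(beta[0] = 1 is eliminated by substitution) minimize the ridge-regularized
SVM primal loss — making the loop a block coordinate descent on a single
objective. Iterate until ||beta_new - beta_old|| < tol.

With a single session (s = 1) the model degenerates exactly to the standard
linear SVR/SVC.

The inner QP is solved by scikit-learn's libsvm backend with a precomputed
kernel; the alternating beta estimation is what this module adds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence
import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.svm import SVC, SVR


# ---------------------------------------------------------------------------
# Algebra helpers
# ---------------------------------------------------------------------------

def _as_tensor(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:  # single subject
        X = X[None]
    if X.ndim != 3:
        raise ValueError("X must be (n_subjects, s, f) or a list of (s, f) matrices")
    return X


def collapse_profile(X_i: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Collapse one subject's session rows: ``x~_i = X_i^T beta`` (length f)."""
    X_i = np.asarray(X_i, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X_i.ndim != 2 or X_i.shape[0] != beta.shape[0]:
        raise ValueError(f"shape mismatch: X_i {X_i.shape} vs beta {beta.shape}")
    return X_i.T @ beta


def gram_matrix(X, beta: np.ndarray) -> np.ndarray:
    """Temporal-covariance Gram matrix ``G_ij = beta^T X_i X_j^T beta``.

    Symmetric positive semidefinite by construction (an inner-product matrix
    of the collapsed profiles).
    """
    X = _as_tensor(X)
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(f"shape mismatch: sessions {X.shape[1]} vs beta {beta.shape[0]}")
    prof = np.einsum("nsf,s->nf", X, beta)
    return prof @ prof.T


def update_beta(
    X,
    dual_coef: np.ndarray,
    targets: np.ndarray,
    bias: float,
    beta_old: np.ndarray,
    ridge: float,
    loss: str = "squared",
    C: float = 1.0,
    epsilon: float = 0.0,
) -> np.ndarray:
    """Update the temporal trend given the current dual solution.

    The dual solution fixes the weight profile ``u = sum_j a_j X_j^T
    beta_old``, making the model prediction for subject i linear in beta:
    ``f_i = (X_i u)^T beta + b`` with design rows ``A_i = (X_i u)^T``.
    ``beta[0] = 1`` is eliminated by substitution; the free components then
    minimize, depending on ``loss``:

    ``"squared"``
        ``||y - b - A beta||^2 + ridge * ||beta_free||^2`` — the closed-form
        ridge system ``(A_f^T A_f + ridge I) beta_free = A_f^T (y - b -
        A[:, 0])``. A singular system at ridge = 0 raises, suggesting
        ridge > 0.
    ``"hinge"`` / ``"epsilon_insensitive"``
        ``C * sum_i loss(y_i, f_i) + ridge/2 * ||beta_free||^2`` — the SVM
        primal loss itself with the margin weights held fixed, so the
        alternating fit is a block coordinate descent on one objective and
        the loop's objective decreases monotonically. Solved numerically
        (convex, piecewise-linear plus quadratic, s - 1 unknowns).
    """
    X = _as_tensor(X)
    a = np.asarray(dual_coef, dtype=float)
    y = np.asarray(targets, dtype=float)
    beta_old = np.asarray(beta_old, dtype=float)
    s = X.shape[1]
    if s == 1:
        return np.ones(1)
    u = np.einsum("j,jsf,s->f", a, X, beta_old)
    A = np.einsum("nsf,f->ns", X, u)
    Af = A[:, 1:]
    if loss == "squared":
        rhs_vec = y - bias - A[:, 0]
        M = Af.T @ Af + ridge * np.eye(s - 1)
        if ridge == 0.0 and np.linalg.matrix_rank(M) < s - 1:
            raise np.linalg.LinAlgError(
                "singular beta-update system at ridge=0; use ridge > 0"
            )
        beta_free = np.linalg.solve(M, Af.T @ rhs_vec)
        return np.concatenate([[1.0], beta_free])
    if loss not in ("hinge", "epsilon_insensitive"):
        raise ValueError(f"unknown beta-update loss {loss!r}")

    def objective(bf):
        f = A[:, 0] + Af @ bf + bias
        if loss == "hinge":
            data_term = np.maximum(0.0, 1.0 - y * f).sum()
        else:
            data_term = np.maximum(0.0, np.abs(f - y) - epsilon).sum()
        return C * data_term + 0.5 * ridge * (bf @ bf)

    from scipy.optimize import minimize

    res = minimize(
        objective, beta_old[1:], method="Powell",
        options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 5000},
    )
    return np.concatenate([[1.0], res.x])


def label_control(score: float, threshold: float = 57.0) -> int:
    """Binary BCI-control label: 1 iff score strictly exceeds the chance level."""
    if not 0 <= score <= 100:
        raise ValueError(f"score must be in [0, 100], got {score}")
    return int(score > threshold)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class _LongitudinalSVMBase(BaseEstimator):
    def __init__(self, C=1.0, ridge=1e-3, tol=1e-6, max_iter=100):
        self.C = C
        self.ridge = ridge
        self.tol = tol
        self.max_iter = max_iter

    def _validate(self, X, y):
        X = _as_tensor(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of subjects")
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in X or y")
        return X, y

    def _alternate(self, X, y, solve_qp: Callable, targets: np.ndarray,
                   loss: str, epsilon: float = 0.0):
        """Run the alternating QP / beta-update loop; returns fit state."""
        n, s, f = X.shape
        beta = np.ones(s)
        trace: list[dict] = []
        converged = False
        a = np.zeros(n)
        bias = 0.0
        best = (np.inf, beta, a, bias)  # smallest ||delta beta|| iterate
        for it in range(self.max_iter):
            G = gram_matrix(X, beta)
            a, bias, objective = solve_qp(G)
            beta_new = update_beta(
                X, a, targets, bias, beta, self.ridge,
                loss=loss, C=self.C, epsilon=epsilon,
            )
            delta = float(np.linalg.norm(beta_new - beta))
            trace.append({"iter": it, "delta_beta": delta, "objective": objective})
            if delta < best[0]:
                best = (delta, beta_new, a, bias)
            beta = beta_new
            if delta < self.tol:
                converged = True
                break
            if not np.isfinite(delta) or np.linalg.norm(beta) > 1e8:
                break  # diverging alternation; fall back to best iterate
        if not converged:
            _, beta, a, bias = best
        return beta, a, bias, converged, trace

    def _kernel_to_train(self, X):
        X = _as_tensor(X)
        prof = np.einsum("nsf,s->nf", X, self.beta_)
        train_prof = np.einsum("nsf,s->nf", self.X_fit_, self.beta_)
        return prof @ train_prof.T


class LongitudinalSVR(_LongitudinalSVMBase, RegressorMixin):
    """Epsilon-insensitive support-vector regression with a temporal trend.

    Parameters
    ----------
    C : float
        Box constraint of the dual variables.
    epsilon : float
        Width of the insensitive tube, in target units (here BCI %).
    ridge : float
        Regularization of the beta-update linear system.
    tol, max_iter : float, int
        Alternating-loop stopping rule on ||delta beta||.

    Attributes
    ----------
    beta_ : ndarray (s,)
        Temporal trend, ``beta_[0] == 1``.
    dual_coef_ : ndarray (n_subjects,)
        ``gamma* - gamma`` per training subject (0 for non-support subjects).
    intercept_ : float
    converged_ : bool
    trace_ : list of dict
        Per-iteration ``delta_beta`` and dual objective.
    """

    def __init__(self, C=10.0, epsilon=1.0, ridge=1e-3, tol=1e-6, max_iter=100):
        super().__init__(C=C, ridge=ridge, tol=tol, max_iter=max_iter)
        self.epsilon = epsilon

    def fit(self, X, y):
        X, y = self._validate(X, y)

        def solve_qp(G):
            svr = SVR(kernel="precomputed", C=self.C, epsilon=self.epsilon, tol=1e-8,
                      max_iter=200_000)
            with warnings.catch_warnings():
                # transient degenerate Gram matrices mid-alternation may hit
                # the iteration guard; the loop recovers on the next iterate
                warnings.simplefilter("ignore", ConvergenceWarning)
                svr.fit(G, y)
            a = np.zeros(len(y))
            a[svr.support_] = svr.dual_coef_.ravel()
            obj = float(a @ y - 0.5 * a @ G @ a - self.epsilon * np.abs(a).sum())
            return a, float(svr.intercept_[0]), obj

        state = self._alternate(X, y, solve_qp, targets=y,
                                loss="epsilon_insensitive", epsilon=self.epsilon)
        self.beta_, self.dual_coef_, self.intercept_, self.converged_, self.trace_ = state
        self.X_fit_ = X
        self.n_iter_ = len(self.trace_)
        return self

    def predict(self, X):
        K = self._kernel_to_train(X)
        return K @ self.dual_coef_ + self.intercept_


class LongitudinalSVC(_LongitudinalSVMBase, ClassifierMixin):
    """Soft-margin support-vector classification with a temporal trend.

    Labels are {0, 1}; internally mapped to {-1, +1}. The beta update
    regresses the decision values onto the signed labels.

    Attributes mirror :class:`LongitudinalSVR`, with ``dual_coef_`` holding
    the label-weighted duals ``y'_j alpha_j``.
    """

    def __init__(self, C=10.0, ridge=1e-3, tol=1e-6, max_iter=100):
        super().__init__(C=C, ridge=ridge, tol=tol, max_iter=max_iter)

    def fit(self, X, y):
        X, y = self._validate(X, y)
        classes = np.unique(y)
        if not np.isin(classes, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")
        if classes.size < 2:
            raise ValueError("training set contains a single class")
        self.classes_ = np.array([0, 1])
        y_signed = 2.0 * y - 1.0

        def solve_qp(G):
            svc = SVC(kernel="precomputed", C=self.C, tol=1e-8, max_iter=200_000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                svc.fit(G, y)
            a = np.zeros(len(y))
            a[svc.support_] = svc.dual_coef_.ravel()  # already y'_j * alpha_j
            obj = float(np.abs(a).sum() - 0.5 * a @ G @ a)
            return a, float(svc.intercept_[0]), obj

        state = self._alternate(X, y, solve_qp, targets=y_signed, loss="hinge")
        self.beta_, self.dual_coef_, self.intercept_, self.converged_, self.trace_ = state
        self.X_fit_ = X
        self.n_iter_ = len(self.trace_)
        return self

    def decision_function(self, X):
        K = self._kernel_to_train(X)
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


# ---------------------------------------------------------------------------
# Baselines and dataset plumbing
# ---------------------------------------------------------------------------

def fit_baseline(X, y, kind: str, C: float = 10.0, epsilon: float = 1.0,
                 representation: str = "concat"):
    """Standard linear SVR/SVC without temporal modelling.

    ``representation="concat"`` (default) flattens each subject's (s, f)
    session block to a vector of length s*f; ``"mean"`` averages the session
    rows to a length-f vector instead. Returns a fitted estimator whose
    ``predict`` accepts the same (n, s, f) layout.
    """
    if representation not in ("concat", "mean"):
        raise ValueError(f"unknown baseline representation {representation!r}")

    def _flatten(Xn):
        Xn = _as_tensor(Xn)
        if representation == "mean":
            return Xn.mean(axis=1)
        return Xn.reshape(Xn.shape[0], -1)

    if kind == "svr":
        est = SVR(kernel="linear", C=C, epsilon=epsilon)
    elif kind == "svc":
        est = SVC(kernel="linear", C=C)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    est.fit(_flatten(X), np.asarray(y).ravel())

    class _Wrapped:
        def predict(self, Xn):
            return est.predict(_flatten(Xn))

        def decision_function(self, Xn):
            return est.decision_function(_flatten(Xn))

    return _Wrapped()


def shuffle_sessions(X, seed: int) -> np.ndarray:
    """Independently permute each subject's session rows (control condition)."""
    X = _as_tensor(X).copy()
    rng = np.random.default_rng(seed)
    for i in range(X.shape[0]):
        X[i] = X[i][rng.permutation(X.shape[1])]
    return X


@dataclass
class LongitudinalDataset:
    """Per-subject session-by-feature matrices plus session-4 targets."""

    subjects: list[str]
    X: np.ndarray                   # (n, s_train, f)
    scores: np.ndarray              # session-(s_train+1) BCI score, %
    labels: np.ndarray              # binary control labels
    feature_names: tuple[str, ...] = ("d_lambda_ms", "d_alpha")


def build_longitudinal_dataset(
    deltas, scores, params: tuple[float, float],
    train_sessions: int = 3, target_session: int = 4, threshold: float = 57.0,
) -> LongitudinalDataset:
    """Assemble X_i (train-session delta features) and session-4 targets."""
    k, d = params
    sub = deltas[(deltas["theta_k"] == k) & (deltas["min_dur_ms"] == d)]
    subjects = sorted(sub["subject"].unique())
    X = np.zeros((len(subjects), train_sessions, 2))
    yscore = np.zeros(len(subjects))
    for i, sid in enumerate(subjects):
        g = sub[sub["subject"] == sid].set_index("session")
        for s in range(1, train_sessions + 1):
            if s not in g.index:
                raise ValueError(f"subject {sid} missing session {s} deltas")
            X[i, s - 1] = [g.loc[s, "d_lambda_ms"], g.loc[s, "d_alpha"]]
        row = scores[(scores["subject"] == sid) & (scores["session"] == target_session)]
        if row.empty:
            raise ValueError(f"subject {sid} missing session-{target_session} score")
        yscore[i] = float(row["score"].iloc[0])
    labels = np.array([label_control(s, threshold) for s in yscore])
    return LongitudinalDataset(subjects=subjects, X=X, scores=yscore, labels=labels)


# ---------------------------------------------------------------------------
# Leave-one-out evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-fold LOO predictions plus aggregate error and beta diagnostics."""

    kind: str
    subjects: list[str]
    predictions: np.ndarray
    truths: np.ndarray
    betas: np.ndarray               # (n_folds, s_train)
    converged: list[bool]
    rmse: float | None = None
    accuracy: float | None = None
    confusion: dict | None = None
    flagged_folds: list[str] = field(default_factory=list)

    def beta_cosine(self) -> tuple[float, float]:
        return beta_stability(self.betas)[0]

    def beta_delta(self) -> tuple[float, float]:
        return beta_stability(self.betas)[1]


def _standardize(train: np.ndarray, *others: np.ndarray):
    """Per-feature z-scaling fitted on the training tensor only."""
    mu = train.mean(axis=(0, 1), keepdims=True)
    sd = train.std(axis=(0, 1), keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return tuple((arr - mu) / sd for arr in (train, *others))


def _fit_one(kind, Xtr, ytr, C, epsilon, ridge, tol, max_iter):
    if kind == "lsvr":
        est = LongitudinalSVR(C=C, epsilon=epsilon, ridge=ridge, tol=tol,
                              max_iter=max_iter).fit(Xtr, ytr)
        return est, est.beta_, est.converged_
    if kind == "lsvc":
        est = LongitudinalSVC(C=C, ridge=ridge, tol=tol, max_iter=max_iter).fit(Xtr, ytr)
        return est, est.beta_, est.converged_
    if kind in ("svr", "svc"):
        return fit_baseline(Xtr, ytr, kind=kind, C=C, epsilon=epsilon), None, True
    raise ValueError(f"unknown model kind {kind!r}")


def _inner_loo_score(kind, Xtr, ytr, C, epsilon, ridge, tol, max_iter, regression):
    """Inner leave-one-out error of one hyperparameter combo on a training set."""
    m = Xtr.shape[0]
    preds = np.zeros(m)
    for j in range(m):
        mask = np.arange(m) != j
        if not regression and len(np.unique(ytr[mask])) < 2:
            preds[j] = float(ytr[mask][0])
            continue
        est, _, _ = _fit_one(kind, Xtr[mask], ytr[mask], C, epsilon, ridge, tol, max_iter)
        preds[j] = float(est.predict(Xtr[j:j + 1])[0])
    if regression:
        return -float(np.sqrt(np.mean((preds - ytr) ** 2)))
    return float(np.mean(preds.astype(int) == ytr))


def loo_evaluate(
    dataset: LongitudinalDataset,
    kind: str,
    C: float = 10.0,
    epsilon: float = 1.0,
    ridge: float = 1e-3,
    tol: float = 1e-6,
    max_iter: int = 100,
    scale: bool = True,
    shuffle_seed: int | None = None,
    grid_C: Sequence[float] | None = None,
    grid_epsilon: Sequence[float] | None = None,
) -> EvaluationReport:
    """Leave-one-subject-out evaluation of a model specification.

    ``kind`` is one of ``lsvr``, ``lsvc``, ``svr``, ``svc``. Each fold trains
    on the remaining subjects' training-session features and session-4
    targets and predicts the held-out subject. ``shuffle_seed`` activates the
    random-sessions control (each subject's session order permuted before
    training and prediction).

    If ``grid_C`` (and for regression ``grid_epsilon``) is given,
    hyperparameters are tuned per outer fold by an inner leave-one-out over
    the training subjects only; ties break toward the smaller C (stronger
    regularization), then smaller epsilon.
    """
    X_all = dataset.X
    if shuffle_seed is not None:
        X_all = shuffle_sessions(X_all, seed=shuffle_seed)
    n = X_all.shape[0]
    if n < 3:
        raise ValueError("LOO evaluation needs >= 3 subjects")
    regression = kind in ("lsvr", "svr")
    truths = dataset.scores if regression else dataset.labels
    preds = np.zeros(n)
    betas = np.ones((n, X_all.shape[1]))
    converged: list[bool] = []
    flagged: list[str] = []
    combos = None
    if grid_C is not None:
        eps_grid = list(grid_epsilon) if (regression and grid_epsilon) else [epsilon]
        combos = [(c, e) for c in grid_C for e in eps_grid]
    for i in range(n):
        mask = np.arange(n) != i
        Xtr, Xte = X_all[mask], X_all[i:i + 1]
        ytr = truths[mask]
        if scale:
            Xtr, Xte = _standardize(Xtr, Xte)
        if not regression and len(np.unique(ytr)) < 2:
            flagged.append(dataset.subjects[i])
            preds[i] = float(ytr[0])
            converged.append(False)
            continue
        C_i, eps_i = C, epsilon
        if combos is not None:
            scores = [
                _inner_loo_score(kind, Xtr, ytr, c, e, ridge, tol, max_iter, regression)
                for c, e in combos
            ]
            best = max(range(len(combos)),
                       key=lambda k: (scores[k], -combos[k][0], -combos[k][1]))
            C_i, eps_i = combos[best]
        est, beta, conv = _fit_one(kind, Xtr, ytr, C_i, eps_i, ridge, tol, max_iter)
        if beta is not None:
            betas[i] = beta
        converged.append(conv)
        preds[i] = float(est.predict(Xte)[0])
    report = EvaluationReport(
        kind=kind, subjects=list(dataset.subjects), predictions=preds,
        truths=truths.astype(float), betas=betas, converged=converged,
        flagged_folds=flagged,
    )
    if regression:
        report.rmse = float(np.sqrt(np.mean((preds - truths) ** 2)))
    else:
        pl = preds.astype(int)
        report.accuracy = float(np.mean(pl == truths))
        report.confusion = {
            "tp": int(((pl == 1) & (truths == 1)).sum()),
            "tn": int(((pl == 0) & (truths == 0)).sum()),
            "fp": int(((pl == 1) & (truths == 0)).sum()),
            "fn": int(((pl == 0) & (truths == 1)).sum()),
        }
    return report


def beta_stability(betas: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
    """Fold-wise beta diagnostics.

    Returns ``((cosine_mean, cosine_sd), (delta_mean, delta_sd))`` where the
    cosine is over all fold pairs and ``delta = ||beta_fold - mean beta||``.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 2 or betas.shape[0] < 2:
        raise ValueError("need >= 2 fold betas")
    norms = np.linalg.norm(betas, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-vector beta")
    unit = betas / norms[:, None]
    cosines = [float(unit[i] @ unit[j]) for i, j in combinations(range(len(betas)), 2)]
    center = betas.mean(axis=0)
    deltas = np.linalg.norm(betas - center, axis=1)
    return (
        (float(np.mean(cosines)), float(np.std(cosines))),
        (float(np.mean(deltas)), float(np.std(deltas))),
    )
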