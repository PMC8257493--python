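"""Logistic PCA of binary phenotype matrices and variant-function prediction.

The phenotype matrix codes presence of a propagated term as 1 and absence as
0, so ordinary PCA (a Gaussian model) is a poor fit.  Logistic PCA instead
projects *natural parameters*: each observation x_ij is represented by the
saturated-model natural parameter theta~_ij = m (2 x_ij - 1), and the model
seeks a column offset mu and an orthonormal p × k loading matrix U minimizing
the Bernoulli deviance of

    Theta = 1 mu' + (Theta~ - 1 mu') U U'

The scale m bounds the fitted log-odds (larger m = more saturated fit).  The
fit uses a majorization–minimization scheme: with the standard quadratic bound
on the logistic loss (curvature 1/4), each iteration forms working responses
Z = Theta + 4 (X - sigmoid(Theta)) and updates U from the top-k eigenvectors
of  B'Z_c + Z_c'B - B'B  (B and Z_c column-centred by mu), which monotonically
decreases the deviance.  Deviance explained is reported against the
column-mean (k = 0) null model, cumulatively over leading components.

Components are scored against external labels (broad phenotype groups, or
gain- vs loss-of-function) with standard ROC/PR machinery, and the best
separating component is thresholded at the Youden cutoff to predict variant
function for individuals whose variants lack electrophysiology, with an
empirical positive-predictive-value curve read off the labeled individuals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.metrics import (
    f1_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticPCA",
    "fit_logistic_pca",
    "select_m",
    "ClassifierEval",
    "evaluate_component",
    "predict_variant_function",
]


def _bernoulli_deviance(X: np.ndarray, Theta: np.ndarray) -> float:
    # stable: log p = -log(1+e^-t), log(1-p) = -log(1+e^t)
    log_p = -np.logaddexp(0.0, -Theta)
    log_q = -np.logaddexp(0.0, Theta)
    return float(-2.0 * (X * log_p + (1.0 - X) * log_q).sum())


class LogisticPCA:
    """Low-rank logistic PCA via majorization–minimization.

    Parameters
    ----------
    n_components:
        Rank k of the projection.
    m:
        Natural-parameter scale; the saturated log-odds are ±m.
    tol:
        Relative deviance-change convergence tolerance.
    max_iter:
        Iteration cap; non-convergence flags the result, it is not an error.

    Attributes (after :meth:`fit`)
    ------------------------------
    loadings_ : (p, k) orthonormal columns, eigenvalue-ordered.
    scores_ : (n, k) individual scores, (Theta~ - 1 mu')U.
    mu_ : (p,) column offsets.
    deviance_explained_ : per-component fractions of null deviance.
    cumulative_deviance_explained_ : running totals over leading components.
    converged_, n_iter_ : convergence diagnostics.
    columns_, dropped_columns_ : retained / constant-dropped column names.
    """

    def __init__(self, n_components: int = 3, m: float = 4.0, tol: float = 1e-6,
                 max_iter: int = 500, random_state: int | None = None):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if m <= 0:
            raise ValueError("m must be positive")
        self.n_components = n_components
        self.m = float(m)
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state  # reserved; the SVD init is deterministic

    # -- fitting -------------------------------------------------------------

    def fit(self, X) -> "LogisticPCA":
        X, columns, index = _as_binary_matrix(X)
        keep = (X.min(axis=0) != X.max(axis=0))
        self.dropped_columns_ = [c for c, k in zip(columns, keep) if not k]
        if self.dropped_columns_:
            logger.info("dropping %d constant column(s)", len(self.dropped_columns_))
        X = X[:, keep]
        self.columns_ = [c for c, k in zip(columns, keep) if k]
        self.index_ = index
        n, p = X.shape
        k = self.n_components
        if k > min(n, p):
            raise ValueError(f"n_components={k} exceeds min(n, p)={min(n, p)}")

        Tld = self.m * (2.0 * X - 1.0)
        colmeans = X.mean(axis=0).clip(1e-6, 1 - 1e-6)
        mu = np.asarray(logit(colmeans), dtype=float)
        self.null_deviance_ = _bernoulli_deviance(X, np.broadcast_to(mu, X.shape))

        B = Tld - mu
        U = np.linalg.svd(B, full_matrices=False)[2][:k].T

        last = np.inf
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            B = Tld - mu
            Theta = mu + B @ U @ U.T
            Z = Theta + 4.0 * (X - expit(Theta))
            Zc = Z - mu
            H = B.T @ Zc
            H = H + H.T - B.T @ B
            vals, vecs = np.linalg.eigh(H)
            order = np.argsort(vals)[::-1][:k]
            U = vecs[:, order]
            mu = np.mean(Z - B @ U @ U.T, axis=0)
            dev = _bernoulli_deviance(X, mu + (Tld - mu) @ U @ U.T)
            if np.isfinite(last) and last - dev <= self.tol * max(abs(last), 1.0):
                self.converged_ = True
                last = dev
                break
            last = dev
        else:
            it = self.max_iter
            logger.warning("logistic PCA did not converge in %d iterations", self.max_iter)
        self.n_iter_ = it
        self.deviance_ = last

        self.mu_ = mu
        B = Tld - mu
        # the eigen-order of the majorizer need not match deviance contribution;
        # order components by the deviance each explains on its own
        singles = []
        for j in range(k):
            u = U[:, j:j + 1]
            singles.append(_bernoulli_deviance(X, mu + B @ u @ u.T))
        order = np.argsort(singles)
        U = U[:, order]
        self.loadings_ = U
        self.scores_ = B @ U
        self._orient(X)

        # deviance explained by the leading j components, against the k=0 model
        cum = []
        for j in range(1, k + 1):
            Uj = self.loadings_[:, :j]
            dev_j = _bernoulli_deviance(X, mu + B @ Uj @ Uj.T)
            cum.append(1.0 - dev_j / self.null_deviance_)
        self.cumulative_deviance_explained_ = np.asarray(cum)
        self.deviance_explained_ = np.diff(np.concatenate([[0.0], cum]))
        return self

    def _orient(self, X: np.ndarray) -> None:
        # fix the sign indeterminacy: each component's score must correlate
        # positively with presence of its top-loading term
        for j in range(self.loadings_.shape[1]):
            top = int(np.abs(self.loadings_[:, j]).argmax())
            x = X[:, top]
            if x.std() == 0:
                continue
            r = np.corrcoef(self.scores_[:, j], x)[0, 1]
            if r < 0:
                self.loadings_[:, j] *= -1
                self.scores_[:, j] *= -1

    def transform(self, X) -> np.ndarray:
        """Scores of new binary rows over the fitted components."""
        X, columns, _ = _as_binary_matrix(X)
        if list(columns) != list(self.columns_):
            df = pd.DataFrame(X, columns=columns)
            X = df.reindex(columns=self.columns_, fill_value=0).to_numpy(dtype=float)
        Tld = self.m * (2.0 * X - 1.0)
        return (Tld - self.mu_) @ self.loadings_

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.scores_.shape[1])]
        return pd.DataFrame(self.scores_, index=self.index_, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.loadings_.shape[1])]
        return pd.DataFrame(self.loadings_, index=pd.Index(self.columns_, name="term"),
                            columns=cols)


def _as_binary_matrix(X):
    if isinstance(X, pd.DataFrame):
        columns, index = list(X.columns), X.index
        arr = X.to_numpy()
    else:
        arr = np.asarray(X)
        columns = [f"x{j}" for j in range(arr.shape[1])]
        index = pd.RangeIndex(arr.shape[0])
    arr = arr.astype(float)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("matrix entries must be binary 0/1")
    return arr, columns, index


def fit_logistic_pca(X, k: int = 3, m: float = 4.0, tol: float = 1e-6,
                     max_iter: int = 500, seed: int | None = None) -> LogisticPCA:
    """Functional wrapper around :class:`LogisticPCA`."""
    return LogisticPCA(n_components=k, m=m, tol=tol, max_iter=max_iter,
                       random_state=seed).fit(X)


def select_m(X, k: int = 3, grid: Sequence[float] = (2, 4, 6, 8, 10),
             n_folds: int = 5, seed: int = 0, **fit_kw) -> tuple[float, pd.Series]:
    """Choose the natural-parameter scale m by cross-validated held-out deviance.

    Rows are split into *n_folds* folds; for each candidate m the model is fit
    on the training rows and the held-out rows are projected onto the fitted
    subspace, accumulating their Bernoulli deviance.  Returns the minimizing m
    and the per-m CV deviances.
    """
    X, columns, _ = _as_binary_matrix(X)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    fold = rng.permutation(n) % n_folds
    results = {}
    for m in grid:
        total = 0.0
        for f in range(n_folds):
            train, test = X[fold != f], X[fold == f]
            keep = train.min(axis=0) != train.max(axis=0)
            model = LogisticPCA(n_components=k, m=m, **fit_kw).fit(train[:, keep])
            Xt = test[:, keep]
            Tld = m * (2.0 * Xt - 1.0)
            S = (Tld - model.mu_) @ model.loadings_
            Theta = model.mu_ + S @ model.loadings_.T
            total += _bernoulli_deviance(Xt, Theta)
        results[float(m)] = total
    series = pd.Series(results).sort_index()
    best = float(series.idxmin())
    return best, series


# -- classifier evaluation ---------------------------------------------------


@dataclass
class ClassifierEval:
    """ROC/PR summary of a continuous score against binary labels."""

    auc: float
    roc: pd.DataFrame            # fpr, tpr, threshold
    cutoff: float                # Youden-optimal threshold (score >= cutoff -> positive)
    sensitivity: float
    specificity: float
    pr: pd.DataFrame             # precision, recall, threshold
    f1: float                    # F1 at the Youden cutoff
    ppv_curve: pd.DataFrame = field(repr=False, default=None)  # threshold sweep, both directions

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "cutoff": self.cutoff, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "f1": self.f1,
        }


def evaluate_component(scores, labels) -> ClassifierEval:
    """Evaluate one component's scores against binary labels.

    AUC is the tie-corrected rank statistic; the operating cutoff maximizes
    Youden's J = sensitivity + specificity - 1 (ties resolved toward higher
    sensitivity); PR curve and F1 are reported at that same cutoff, and the
    PPV curve sweeps thresholds in both directions (P(positive | score >= t)
    and P(negative | score <= t)).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes (0 and 1)")

    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    j = tpr - fpr
    best = max(range(len(j)), key=lambda i: (j[i], tpr[i]))
    cutoff = float(thr[best]) if np.isfinite(thr[best]) else float(s.max())
    sens, spec = float(tpr[best]), float(1 - fpr[best])

    precision, recall, pr_thr = precision_recall_curve(y, s)
    f1 = float(f1_score(y, (s >= cutoff).astype(int)))

    uniq = np.unique(s)
    ppv_pos = np.array([y[s >= t].mean() for t in uniq])
    ppv_neg = np.array([1 - y[s <= t].mean() for t in uniq])
    ppv = pd.DataFrame({"threshold": uniq, "ppv_high_side": ppv_pos,
                        "ppv_low_side": ppv_neg})
    return ClassifierEval(
        auc=auc,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        pr=pd.DataFrame({"precision": precision[:-1], "recall": recall[:-1],
                         "threshold": pr_thr}) if len(pr_thr) else
           pd.DataFrame(columns=["precision", "recall", "threshold"]),
        f1=f1,
        ppv_curve=ppv,
    )


def predict_variant_function(
    scores: pd.Series,
    functional: Mapping[str, str] | pd.Series,
    variant_labels: Mapping[str, str] | pd.Series | None = None,
) -> tuple[pd.DataFrame, ClassifierEval]:
    """Predict GoF vs LoF from one component's scores.

    Parameters
    ----------
    scores:
        Per-individual component scores (index = individual id).
    functional:
        Known labels for a subset of individuals: ``"GoF"`` / ``"LoF"``
        (others absent or ``"unclassified"``).  Both classes must be present.
    variant_labels:
        Optional individual -> variant label mapping carried into the output
        (a variant may then appear on several rows when carried by
        phenotypically different individuals).

    The component is oriented so higher scores mean GoF, thresholded at the
    Youden cutoff from the labeled subset.  Each individual's PPV is read from
    the empirical curve: for a GoF call, the fraction of labeled GoF among
    labeled individuals scoring at or above them; symmetrically for LoF.
    """
    scores = pd.Series(scores, dtype=float)
    func = pd.Series(dict(functional) if not isinstance(functional, pd.Series) else functional)
    func = func[func.isin(["GoF", "LoF"])]
    func = func[func.index.isin(scores.index)]
    if func.empty or func.nunique() < 2:
        raise ValueError("need labeled individuals of both GoF and LoF classes")

    labeled_scores = scores[func.index]
    y = (func == "GoF").astype(int)
    if labeled_scores[y == 1].mean() < labeled_scores[y == 0].mean():
        scores = -scores
        labeled_scores = -labeled_scores
    ev = evaluate_component(labeled_scores.to_numpy(), y.to_numpy())

    ls = labeled_scores.to_numpy()
    ly = y.to_numpy()

    def ppv_at(s: float, call: str) -> float:
        # the empirical curve is clamped at the most extreme labeled score, so
        # an unlabeled individual beyond the labeled range inherits that value
        if call == "GoF":
            sel = ls >= min(s, ls.max())
            return float(ly[sel].mean())
        sel = ls <= max(s, ls.min())
        return float(1 - ly[sel].mean())

    rows = []
    for ind, s in scores.items():
        call = "GoF" if s >= ev.cutoff else "LoF"
        rows.append((ind, s, call, ppv_at(float(s), call), func.get(ind, "unclassified")))
    out = pd.DataFrame(rows, columns=["individual_id", "score", "predicted", "ppv", "known"])
    if variant_labels is not None:
        vl = pd.Series(dict(variant_labels) if not isinstance(variant_labels, pd.Series)
                       else variant_labels)
        out.insert(1, "variant", out["individual_id"].map(vl))
    return out.set_index("individual_id"), ev
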