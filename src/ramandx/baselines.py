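"""Conventional chemometric classifiers under a common fit/score contract.

Four comparators, each exposing a continuous decision value suitable for
ROC analysis:

* ``plsda`` — partial least squares regression against a 0/1 class
  coding; the continuous predicted response is the score.
* ``pclda`` — linear discriminant analysis in a PCA space retaining 95%
  of the training variance (component count capped at
  ``min(n_train - 2, n_features)``); the positive-class posterior is the
  score.
* ``svm`` — support vector machine on standardized features (linear
  kernel, C=1 by default); the signed decision value is the score.
* ``lr`` — deliberately *unregularized* logistic regression fitted by
  iteratively reweighted least squares (the canonical GLM algorithm) with
  a capped iteration budget.  With more features than cases the training
  classes are perfectly separable, the ML estimate does not exist, and
  the capped IRLS iterate scores the test set near chance; once
  augmentation pushes the case count past the feature count the fit is a
  proper ML estimate and becomes competitive.  Any default penalty (or a
  gradient-descent solver, whose early iterates are implicitly
  regularized) would silently erase that phenomenon, so the plain IRLS
  fit is used, with separation warnings recorded on the state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .core import LabeledSpectrumSet, ParameterError, RamanDXError

METHODS = ("plsda", "pclda", "svm", "lr")


class FitError(RamanDXError):
    """Degenerate training matrix or unknown method."""


@dataclass
class BaselineConfig:
    pls_components: int = 10
    pca_variance_retained: float = 0.95
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    lr_max_iter: int = 25
    #: when True (and a validation set is given), the PLS component count
    #: is chosen from `tune_grid` by validation AUC instead of fixed
    tune: bool = False
    tune_grid: tuple[int, ...] = (2, 3, 5, 8, 10, 15, 20)

    def __post_init__(self) -> None:
        if self.pls_components < 1:
            raise ParameterError("pls_components must be >= 1")
        if not 0 < self.pca_variance_retained <= 1:
            raise ParameterError("pca_variance_retained must be in (0, 1]")


@dataclass
class BaselineState:
    method: str
    model: object
    warnings: list[str] = field(default_factory=list)


def fit_baseline(
    method: str,
    train: LabeledSpectrumSet,
    val: LabeledSpectrumSet | None = None,
    cfg: BaselineConfig | None = None,
) -> BaselineState:
    """Fit one of the four comparators on the training set.

    ``val`` is accepted for interface parity with the neural model (the
    comparators do not use early stopping or tuning by default).
    """
    cfg = cfg or BaselineConfig()
    train.require_both_classes()
    X, y = train.spectra, train.labels
    if np.ptp(X) == 0:
        raise FitError("zero-variance feature matrix")
    caught: list[str] = []
    if method == "plsda":
        cap = min(train.n - 1, X.shape[1])
        if cfg.tune and val is not None and val.has_both_classes():
            from sklearn.metrics import roc_auc_score

            best, best_auc = None, -np.inf
            for k in sorted({min(k, cap) for k in cfg.tune_grid}):
                cand = PLSRegression(n_components=k).fit(X, y.astype(float))
                auc = roc_auc_score(
                    val.labels, np.asarray(cand.predict(val.spectra)).ravel()
                )
                if auc > best_auc:
                    best, best_auc = cand, auc
            model = best
            caught.append(f"tuned pls_components={model.n_components}")
        else:
            model = PLSRegression(n_components=min(cfg.pls_components, cap))
            model.fit(X, y.astype(float))
    elif method == "pclda":
        cap = max(1, min(train.n - 2, X.shape[1]))
        pca = PCA(n_components=cfg.pca_variance_retained, svd_solver="full")
        scores = pca.fit_transform(X)
        if pca.n_components_ > cap:
            pca = PCA(n_components=cap, svd_solver="full")
            scores = pca.fit_transform(X)
        lda = LinearDiscriminantAnalysis()
        lda.fit(scores, y)
        model = (pca, lda)
    elif method == "svm":
        if cfg.svm_kernel == "linear":
            # hinge-loss dual formulation via liblinear: the same model as
            # a kernelized linear SVM but tractable on augmented sets
            svc = LinearSVC(C=cfg.svm_c, loss="hinge", dual=True, max_iter=20_000)
        else:
            svc = SVC(kernel=cfg.svm_kernel, C=cfg.svm_c, gamma="scale")
        model = make_pipeline(StandardScaler(), svc)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            model.fit(X, y)
        caught = [str(w.message) for w in rec]
    elif method == "lr":
        # unpenalized ML via IRLS; features rescaled only for conditioning
        scale = float(X.std()) or 1.0
        design = sm.add_constant(X / scale, has_constant="add")
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            glm = sm.GLM(y.astype(float), design, family=sm.families.Binomial())
            fit = glm.fit(maxiter=cfg.lr_max_iter)
        caught = [str(w.message) for w in rec]
        model = (fit, scale)
    else:
        raise FitError(f"unknown baseline method {method!r}")
    return BaselineState(method, model, caught)


def score_baseline(state: BaselineState, dataset: LabeledSpectrumSet) -> np.ndarray:
    """Continuous per-spectrum score, increasing with cancer likelihood."""
    X = dataset.spectra
    if state.method == "plsda":
        s = np.asarray(state.model.predict(X)).ravel()
    elif state.method == "pclda":
        pca, lda = state.model
        s = lda.predict_proba(pca.transform(X))[:, 1]
    elif state.method == "svm":
        s = state.model.decision_function(X)
    else:  # lr
        fit, scale = state.model
        s = np.asarray(fit.predict(sm.add_constant(X / scale, has_constant="add")))
    if not np.all(np.isfinite(s)):
        raise FitError(f"{state.method} produced non-finite scores")
    return s


def pclda_component_count(state: BaselineState) -> int:
    if state.method != "pclda":
        raise ParameterError("not a pclda state")
    return int(state.model[0].n_components_)
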