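"""Delay-embedded multinomial choice model of signal selection.

Predicts, frame by frame, whether a courting male produces song,
vibration or no signal from the 1 s history of 19 kinematic cues.  Each
cue history is compressed onto four log-spaced raised cosines
(:class:`~courtsig.basis.RaisedCosineBasis`), classes are balanced by
subsampling, and an L2-regularized multinomial logistic regression is
fitted with 10-fold cross-validation on 90/10 train/test splits, 10
times with independent splits and balancing.  Temporal filters are
recovered by back-projecting the basis and summarized by their integral:
a positive integral means high cue values over the preceding second
promote the signal.

The estimators follow scikit-learn conventions (``fit``, ``predict``,
``get_params``; fitted attributes end in ``_``) and compose with
sklearn pipelines.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .basis import RaisedCosineBasis

__all__ = [
    "CLASS_ORDER",
    "DelayEmbedder",
    "delay_embed",
    "balance",
    "SignalChoiceGLM",
    "per_cue_models",
]

#: canonical class order used for filters and confusion matrices
CLASS_ORDER = ("song", "vibration", "none")


def delay_embed(X, basis: RaisedCosineBasis, mask=None):
    """Project each cue's 1 s history onto the basis, per frame.

    Parameters
    ----------
    X : (n_frames, n_cues) array
        Cue series (z-scored) at ``basis.rate_hz``.
    basis : RaisedCosineBasis
    mask : boolean (n_frames,) array, optional
        Frames eligible as prediction targets (e.g. valid courtship
        frames).  The history may extend into masked frames; only the
        target frame must be unmasked.

    Returns
    -------
    design : (n_rows, n_cues * n_basis) array
        Column order: cue-major (cue 0 bases 0..3, cue 1 bases 0..3, ...).
        Row t's (i, j) entry is ``sum_tau B[tau, j] * X[t - tau, i]`` over
        lags 1..n_lags.
    frames : (n_rows,) int array
        Original frame index of each design row.  Frames with incomplete
        history are dropped.
    """
    X = np.asarray(X, dtype=float)
    n, n_cues = X.shape
    L = basis.n_lags
    if n <= L:
        warnings.warn("delay_embed: fewer frames than the lag window; empty design")
        return np.empty((0, n_cues * basis.n_basis)), np.empty(0, dtype=int)
    cols = np.empty((n, n_cues * basis.n_basis))
    for i in range(n_cues):
        for j in range(basis.n_basis):
            z = np.convolve(X[:, i], basis.B[:, j])[: n - 1]
            cols[0, i * basis.n_basis + j] = 0.0
            cols[1:, i * basis.n_basis + j] = z
    keep = np.zeros(n, dtype=bool)
    keep[L:] = True
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    frames = np.nonzero(keep)[0]
    return cols[frames], frames


def balance(X, y, seed=0):
    """Equalize class counts by subsampling without replacement.

    Returns ``(X_balanced, y_balanced, rows)`` where ``rows`` indexes the
    retained rows of the input.  Every class present keeps
    ``min`` class-count rows; a missing class is an error.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balancing requires at least two classes present")
    n_keep = counts.min()
    rng = np.random.default_rng(seed)
    rows = []
    for c in classes:
        idx = np.nonzero(y == c)[0]
        rows.append(rng.choice(idx, size=n_keep, replace=False))
    rows = np.sort(np.concatenate(rows))
    return X[rows], y[rows], rows


class DelayEmbedder(TransformerMixin, BaseEstimator):
    """Sklearn transformer wrapping :func:`delay_embed`.

    ``transform`` keeps the row count (zero-padded history for the first
    ``n_lags`` frames) so it composes with pipelines; use
    ``burn_in_`` to drop the frames without a full history, or call
    :func:`delay_embed` directly to get the dropped-row form.
    """

    def __init__(self, n_basis=4, window_s=1.0, rate_hz=50.0):
        self.n_basis = n_basis
        self.window_s = window_s
        self.rate_hz = rate_hz

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.basis_ = RaisedCosineBasis(
            n_basis=self.n_basis, window_s=self.window_s, rate_hz=self.rate_hz
        )
        self.n_features_in_ = X.shape[1]
        self.burn_in_ = self.basis_.n_lags
        return self

    def transform(self, X):
        check_is_fitted(self, "basis_")
        X = np.asarray(X, dtype=float)
        n, n_cues = X.shape
        basis = self.basis_
        out = np.empty((n, n_cues * basis.n_basis))
        for i in range(n_cues):
            for j in range(basis.n_basis):
                z = np.convolve(X[:, i], basis.B[:, j])[: n - 1]
                out[0, i * basis.n_basis + j] = 0.0
                out[1:, i * basis.n_basis + j] = z
        return out


class SignalChoiceGLM(ClassifierMixin, BaseEstimator):
    """Balanced, cross-validated multinomial logistic choice model.

    ``fit`` takes an already delay-embedded design matrix
    (n_frames x n_cues*n_basis) and the per-frame labels.  Per repeat it
    (re)balances the classes, splits 90/10, fits
    ``LogisticRegressionCV`` (L2, 10-fold, up to 500 iterations) on the
    training part and evaluates a row-normalized confusion matrix on the
    held-out part.

    Parameters
    ----------
    n_basis, window_s, rate_hz : basis geometry used for back-projection.
    Cs : int
        Size of the log-spaced regularization grid (1e-4..1e4).
    cv : int
        CV folds for the regularization search.
    max_iter : int
        Iteration cap for the solver.
    tol : float
        Solver convergence tolerance (1e-3; filters and accuracies are
        insensitive to tightening it further).
    test_size : float
        Held-out fraction per repeat.
    n_repeats : int
        Independent balance+split+fit repetitions.
    balance_data, balance_before_split : bool
        Class balancing on/off, and whether it precedes the split
        (the default) or is applied to the training part only.
    random_state : int or None
        Seeds balancing, splits and CV folds.

    Attributes
    ----------
    classes_ : class labels in canonical order (song, vibration, none).
    weights_ : (3, n_cues, n_basis) mean basis-space weights over repeats.
    intercepts_ : (3,) mean intercepts.
    filters_ : (3, n_cues, n_lags) back-projected temporal filters.
    filter_integrals_ : (3, n_cues) sum of filter values over lags.
    confusions_ : list of per-repeat row-normalized (3, 3) matrices.
    accuracies_ : per-repeat mean of the confusion diagonal.
    accuracy_ : mean over repeats.
    Cs_ : per-repeat selected regularization strengths.
    repeats_ : per-repeat dicts with the fitted estimator, weights,
        filters and test confusion.
    converged_ : False if any repeat hit the iteration cap.
    """

    def __init__(
        self,
        n_basis=4,
        window_s=1.0,
        rate_hz=50.0,
        Cs=10,
        cv=10,
        max_iter=500,
        tol=1e-3,
        test_size=0.1,
        n_repeats=10,
        balance_data=True,
        balance_before_split=True,
        random_state=None,
    ):
        self.n_basis = n_basis
        self.window_s = window_s
        self.rate_hz = rate_hz
        self.Cs = Cs
        self.cv = cv
        self.max_iter = max_iter
        self.tol = tol
        self.test_size = test_size
        self.n_repeats = n_repeats
        self.balance_data = balance_data
        self.balance_before_split = balance_before_split
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        present = set(np.unique(y))
        class_order = [c for c in CLASS_ORDER if c in present]
        class_order += sorted(present - set(CLASS_ORDER))
        if len(class_order) < 2:
            raise ValueError("need at least two classes to fit")
        self.classes_ = np.asarray(class_order, dtype=object)
        n_classes = len(class_order)
        d = X.shape[1]
        if d % self.n_basis:
            raise ValueError(
                f"{d} design columns are not a multiple of n_basis={self.n_basis}"
            )
        n_cues = d // self.n_basis
        basis = RaisedCosineBasis(
            n_basis=self.n_basis, window_s=self.window_s, rate_hz=self.rate_hz
        )
        self.basis_ = basis
        root = np.random.default_rng(self.random_state)

        self.repeats_ = []
        self.converged_ = True
        for rep in range(self.n_repeats):
            seed = int(root.integers(2**31 - 1))
            Xr, yr = X, y
            if self.balance_data and self.balance_before_split:
                Xr, yr, _ = balance(Xr, yr, seed=seed)
            Xtr, Xte, ytr, yte = train_test_split(
                Xr,
                yr,
                test_size=self.test_size,
                random_state=seed % (2**32 - 1),
                stratify=yr,
            )
            if self.balance_data and not self.balance_before_split:
                Xtr, ytr, _ = balance(Xtr, ytr, seed=seed)
            est = LogisticRegressionCV(
                Cs=self.Cs,
                cv=self.cv,
                max_iter=self.max_iter,
                tol=self.tol,
                l1_ratios=(0.0,),
                scoring="accuracy",
                random_state=seed % (2**32 - 1),
                n_jobs=None,
                use_legacy_attributes=True,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                # the iteration cap mirrors the fitting protocol; hitting it
                # is recorded in converged_ rather than spamming per-fold
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(Xtr, ytr)
            if getattr(est, "n_iter_", None) is not None and np.any(
                est.n_iter_ >= self.max_iter
            ):
                self.converged_ = False
            # reorder sklearn's lexicographic classes to canonical order
            order = [list(est.classes_).index(c) for c in class_order]
            coef = est.coef_[order]
            if n_classes == 2 and coef.shape[0] == 1:  # sklearn binary coding
                coef = np.vstack([coef, -coef]) / 2.0
            W = coef.reshape(n_classes, n_cues, self.n_basis)
            C_sel = float(np.atleast_1d(est.C_)[0])
            cm = confusion_matrix(yte, est.predict(Xte), labels=class_order)
            with np.errstate(invalid="ignore"):
                cm_norm = cm / cm.sum(axis=1, keepdims=True)
            self.repeats_.append(
                {
                    "estimator": est,
                    "weights": W,
                    "intercepts": est.intercept_[order]
                    if n_classes > 2
                    else np.array([est.intercept_[0], -est.intercept_[0]]) / 2.0,
                    "filters": basis.back_project(W),
                    "confusion": cm_norm,
                    "accuracy": float(np.nanmean(np.diag(cm_norm))),
                    "C": C_sel,
                    "seed": seed,
                }
            )
        self.weights_ = np.mean([r["weights"] for r in self.repeats_], axis=0)
        self.intercepts_ = np.mean([r["intercepts"] for r in self.repeats_], axis=0)
        self.filters_ = basis.back_project(self.weights_)
        self.filter_integrals_ = self.filters_.sum(axis=-1)
        self.confusions_ = [r["confusion"] for r in self.repeats_]
        self.accuracies_ = np.array([r["accuracy"] for r in self.repeats_])
        self.accuracy_ = float(self.accuracies_.mean())
        self.Cs_ = np.array([r["C"] for r in self.repeats_])
        return self

    def predict(self, X):
        check_is_fitted(self, "repeats_")
        return self.repeats_[0]["estimator"].predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "repeats_")
        est = self.repeats_[0]["estimator"]
        proba = est.predict_proba(np.asarray(X, dtype=float))
        order = [list(est.classes_).index(c) for c in self.classes_]
        return proba[:, order]


def per_cue_models(
    X_cues,
    labels,
    mask=None,
    mode: str = "restrict",
    cue_names=None,
    seed: int = 0,
    **glm_kwargs,
):
    """Fit one model per cue to measure each cue's own information.

    ``mode="restrict"`` keeps only the target cue's basis columns;
    ``mode="shuffle_others"`` keeps all columns but randomly permutes the
    other cues' time series (destroying their temporal relation to the
    labels) before embedding.  Returns ``{cue_name: fitted model}``.
    """
    if mode not in ("restrict", "shuffle_others"):
        raise ValueError(f"unknown mode {mode!r}")
    X_cues = np.asarray(X_cues, dtype=float)
    n_cues = X_cues.shape[1]
    if cue_names is None:
        cue_names = [f"cue_{i}" for i in range(n_cues)]
    if len(cue_names) != n_cues:
        raise ValueError("cue_names length must match the cue count")
    glm_kwargs.setdefault("random_state", seed)
    proto = SignalChoiceGLM(**glm_kwargs)
    basis = RaisedCosineBasis(
        n_basis=proto.n_basis, window_s=proto.window_s, rate_hz=proto.rate_hz
    )
    rng = np.random.default_rng(seed)
    out = {}
    labels = np.asarray(labels)
    for i, name in enumerate(cue_names):
        if mode == "restrict":
            design, frames = delay_embed(X_cues[:, [i]], basis, mask=mask)
        else:
            Xs = X_cues.copy()
            for j in range(n_cues):
                if j != i:
                    Xs[:, j] = Xs[rng.permutation(Xs.shape[0]), j]
            design, frames = delay_embed(Xs, basis, mask=mask)
        model = SignalChoiceGLM(**glm_kwargs)
        model.fit(design, labels[frames])
        out[name] = model
    return out
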