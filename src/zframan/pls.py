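"""PLS-DA developmental fingerprinting: NIPALS PLS2 on stage-indicator
responses, Q2 component selection by leave-one-animal-out cross-validation,
and the scalar-projection / vector-module statistics.

The model regresses a centred one-column-per-stage indicator matrix Y on the
autoscaled descriptor matrix X with NIPALS PLS2.  The number of significant
components A* is chosen by requiring each additional component to raise the
cross-validated Q2 by more than a configurable gain.  The fingerprint
couples the Y-loadings (stages) with the X-loadings (descriptors) in the
space of the first A* components: the default scalar projection

    s_kj = sum_a q_ka p_ja ||t_a||^2 / n

is the model-reconstructed covariance between descriptor j and the stage-k
indicator — positive when the descriptor sits above its average at that
stage — and the per-descriptor vector module

    m_j = sqrt(sum_k s_kj^2)

aggregates the projections into an importance score that tracks the
variable importance in projection (VIP).  A direction-only projection
(q_k . p_j / ||p_j||, the length of q_k projected onto the descriptor's
loading direction) and the raw inner product are selectable alternatives;
likewise the module's "length of the sum" |sum_k s_kj| and absolute-sum
readings.  The defaults are the combination under which the module behaves
as the documented importance measure (max-module descriptor carries the
class separation; ranking correlates with VIP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .features import FeatureScaler

__all__ = [
    "PLSModel",
    "FingerprintTable",
    "PLSFingerprint",
    "fit_pls",
    "cross_validate_q2",
    "select_components",
    "scalar_projections",
    "vector_module",
    "vip_scores",
    "fingerprint",
    "encode_stages",
]

MODULE_DEFINITIONS = ("norm", "abs_sum", "sum_abs")


def encode_stages(y, classes=None) -> tuple[np.ndarray, np.ndarray]:
    """Centred one-column-per-stage indicator matrix for PLS-DA."""
    y = np.asarray(y)
    if classes is None:
        classes = np.unique(y)
    classes = np.asarray(classes)
    Y = (y[:, None] == classes[None, :]).astype(float)
    return Y, classes


def _nipals_pls2(Xc, Yc, n_components, tol=1e-12, max_iter=2000):
    """NIPALS PLS2 on centred X, Y.  Returns W, T, P, Q (columns = components).

    Sign convention: each weight vector's largest-|.| element is positive, so
    loadings and projections are reproducible across runs and
    implementations.
    """
    X = Xc.copy()
    Y = Yc.copy()
    n, p = X.shape
    m = Y.shape[1]
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((m, n_components))
    ss_y0 = float(np.sum(Yc**2))
    r2 = np.zeros(n_components)
    for a in range(n_components):
        u = Y[:, np.argmax(np.var(Y, axis=0))]
        if np.allclose(u, 0) or np.allclose(X, 0):
            W, T, P, Q, r2 = W[:, :a], T[:, :a], P[:, :a], Q[:, :a], r2[:a]
            break
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = X @ w
            tt = float(t @ t)
            if tt == 0:
                break
            q = Y.T @ t / tt
            nq = float(q @ q)
            u = Y @ q / nq if nq > 0 else u
            if t_old is not None and np.linalg.norm(t - t_old) < tol * max(
                1.0, np.linalg.norm(t)
            ):
                break
            t_old = t
        tt = float(t @ t)
        if tt == 0:
            W, T, P, Q, r2 = W[:, :a], T[:, :a], P[:, :a], Q[:, :a], r2[:a]
            break
        pvec = X.T @ t / tt
        # fix the sign ambiguity
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t, pvec, q = -w, -t, -pvec, -q
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, pvec, q
        X = X - np.outer(t, pvec)
        Y = Y - np.outer(t, q)
        r2[a] = 1.0 - float(np.sum(Y**2)) / ss_y0 if ss_y0 > 0 else 0.0
    return W, T, P, Q, r2


def _regression_coefs(W, P, Q, a):
    """B such that Yhat_centred = Xc @ B using the first ``a`` components."""
    Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:, :a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)


@dataclass
class PLSModel:
    """Fitted PLS-DA model for one organ."""

    x_weights: np.ndarray  # (p, A)
    x_scores: np.ndarray  # (n, A)
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (m, A)
    r2: np.ndarray  # cumulative, per component
    classes: np.ndarray  # stage hpf values
    x_mean: np.ndarray
    y_mean: np.ndarray
    feature_names: list[str]
    q2: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        """Predicted (uncentred) stage-indicator matrix."""
        a = self.n_components if n_components is None else n_components
        B = _regression_coefs(self.x_weights, self.x_loadings, self.y_loadings, a)
        Xc = np.asarray(X, dtype=float) - self.x_mean
        return Xc @ B + self.y_mean


def fit_pls(X, y, A_max: int, classes=None) -> PLSModel:
    """NIPALS PLS2 of the centred stage-indicator matrix on X.

    ``X`` is the (already autoscaled) descriptor matrix; centring is applied
    internally.  ``A_max`` beyond the feasible rank is truncated with a
    warning.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.shape(X)[1])
    ]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("discriminant analysis needs >= 2 classes")
    Y, classes = encode_stages(y, classes)
    n, p = X.shape
    feasible = min(p, n - 1)
    if A_max > feasible:
        warnings.warn(
            f"A_max={A_max} exceeds feasible rank {feasible}; truncating",
            stacklevel=2,
        )
        A_max = feasible
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    W, T, P, Q, r2 = _nipals_pls2(X - x_mean, Y - y_mean, A_max)
    return PLSModel(
        x_weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=Q,
        r2=r2,
        classes=classes,
        x_mean=x_mean,
        y_mean=y_mean,
        feature_names=names,
    )


def cross_validate_q2(X, y, A_max: int, groups) -> np.ndarray:
    """Per-component Q2 by leave-one-animal-out cross-validation.

    All rows of one animal are held out together (rows from the same animal
    are dependent).  Q2(a) = 1 - PRESS(a)/SS with PRESS summed over held-out
    predictions of the stage-indicator matrix and SS the total centred-Y sum
    of squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 3:
        raise ValueError("leave-one-animal-out needs >= 3 animals")
    Y_full, classes = encode_stages(y)
    ss = float(np.sum((Y_full - Y_full.mean(axis=0)) ** 2))
    press = np.zeros(A_max)
    for g in uniq:
        test = groups == g
        train = ~test
        if np.unique(y[train]).size < 2:
            continue
        Xtr, ytr = X[train], y[train]
        Ytr, _ = encode_stages(ytr, classes)
        xm, ym = Xtr.mean(axis=0), Ytr.mean(axis=0)
        W, T, P, Q, _ = _nipals_pls2(Xtr - xm, Ytr - ym, A_max)
        got = W.shape[1]
        Xc_test = X[test] - xm
        Y_test = Y_full[test]
        for a in range(1, A_max + 1):
            aa = min(a, got)
            if aa == 0:
                pred = np.tile(ym, (Xc_test.shape[0], 1))
            else:
                B = _regression_coefs(W, P, Q, aa)
                pred = Xc_test @ B + ym
            press[a - 1] += float(np.sum((pred - Y_test) ** 2))
    return 1.0 - press / ss if ss > 0 else np.zeros(A_max)


def select_components(r2, q2, q2_gain: float = 0.01) -> int:
    """Number of significant components from the R2/Q2 comparison.

    A* is the largest a such that every component up to a raises Q2 by
    strictly more than ``q2_gain`` over the previous one (Q2(0) = 0);
    at least one component is always retained.
    """
    q2 = np.asarray(q2, dtype=float)
    a_star = 0
    prev = 0.0
    for a, val in enumerate(q2, start=1):
        # strict gain, robust to float representation of the threshold
        if val - prev > q2_gain + 1e-12:
            a_star = a
            prev = val
        else:
            break
    return max(a_star, 1)


PROJECTION_DEFINITIONS = ("covariance", "loading", "raw")


def scalar_projections(
    model: PLSModel, a_star: int, normalisation: str = "covariance"
) -> pd.DataFrame:
    """Stage x descriptor scalar projections over the first ``a_star`` components.

    The projection couples stage class k's Y-loading row q_k with descriptor
    j's X-loading row p_j in the space of the significant components.  Three
    readings are provided:

    - ``"covariance"`` (default): s_kj = sum_a q_ka p_ja ||t_a||^2 / n, the
      model-reconstructed covariance between descriptor j and the stage-k
      indicator — an integrated measure of descriptor/stage covariation
      whose per-descriptor norm tracks variable importance (VIP);
    - ``"loading"``: s_kj = (q_k . p_j)/||p_j||, the signed length of q_k
      projected onto descriptor j's loading direction (equivalently
      ||q_k|| cos angle(q_k, p_j)); direction-only, so its modules compare
      stage geometry but not descriptor importance;
    - ``"raw"``: s_kj = q_k . p_j.

    Positive s_kj means the descriptor sits above its average at stage k.
    """
    if a_star > model.n_components:
        raise ValueError(
            f"a_star={a_star} exceeds fitted components {model.n_components}"
        )
    if normalisation not in PROJECTION_DEFINITIONS:
        raise ValueError(f"normalisation must be one of {PROJECTION_DEFINITIONS}")
    P = model.x_loadings[:, :a_star]  # (p, A*)
    Q = model.y_loadings[:, :a_star]  # (m, A*)
    if normalisation == "covariance":
        t2 = (model.x_scores[:, :a_star] ** 2).sum(axis=0)
        n = model.x_scores.shape[0]
        S = (Q * t2[None, :]) @ P.T / n
    elif normalisation == "raw":
        S = Q @ P.T
    else:
        norms = np.linalg.norm(P, axis=1)
        zero = norms == 0
        if zero.any():
            warnings.warn(
                "zero-norm X-loading(s); their projections are set to 0",
                stacklevel=2,
            )
        safe = np.where(zero, 1.0, norms)
        S = (Q @ P.T) / safe[None, :]
        S[:, zero] = 0.0
    return pd.DataFrame(S, index=list(model.classes), columns=model.feature_names)


def vector_module(
    projections: pd.DataFrame | np.ndarray,
    definition: str = "norm",
    normalise: bool = False,
) -> pd.Series:
    """Per-descriptor importance aggregated over stages.

    definition: "norm" (default) sqrt(sum_k s^2); "abs_sum" |sum_k s| (the
    literal length of the summed projections); "sum_abs" sum_k |s|.
    ``normalise=True`` rescales so the largest module is 1.
    """
    S = (
        projections
        if isinstance(projections, pd.DataFrame)
        else pd.DataFrame(np.atleast_2d(projections))
    )
    if definition == "norm":
        m = np.sqrt((S**2).sum(axis=0))
    elif definition == "abs_sum":
        m = S.sum(axis=0).abs()
    elif definition == "sum_abs":
        m = S.abs().sum(axis=0)
    else:
        raise ValueError(f"unknown module definition {definition!r}")
    if normalise and m.max() > 0:
        m = m / m.max()
    return m


def vip_scores(model: PLSModel, a_star: int | None = None) -> pd.Series:
    """Variable importance in projection over the first ``a_star`` components.

    VIP_j = sqrt(p * sum_a ssy_a (w_ja)^2 / sum_a ssy_a) with ssy_a the Y
    sum of squares explained by component a and w the (unit-norm) X-weights.
    """
    a = model.n_components if a_star is None else a_star
    W = model.x_weights[:, :a]
    incr = np.diff(np.concatenate([[0.0], model.r2[:a]]))
    incr = np.clip(incr, 0.0, None)
    p = W.shape[0]
    denom = incr.sum()
    if denom <= 0:
        return pd.Series(np.zeros(p), index=model.feature_names)
    vip = np.sqrt(p * (W**2 @ incr) / denom)
    return pd.Series(vip, index=model.feature_names)


@dataclass
class FingerprintTable:
    """Stage x descriptor projections plus one vector module per descriptor."""

    organ: str
    projections: pd.DataFrame  # rows = stages, columns = descriptors
    modules: pd.Series  # index = descriptors, sorted descending
    n_components: int
    r2: np.ndarray
    q2: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV layout: rows descriptors by descending module, then one
        signed projection column per stage."""
        df = pd.DataFrame({"module": self.modules})
        for stage in self.projections.index:
            df[f"s{stage}"] = self.projections.loc[stage, df.index]
        df.insert(0, "descriptor", df.index)
        return df.reset_index(drop=True)


class PLSFingerprint(BaseEstimator):
    """PLS-DA developmental-stage fingerprint estimator (sklearn-style).

    fit(X, y, groups) runs autoscaling (optional), NIPALS PLS2 with stage
    classes as the response, leave-one-animal-out Q2, component selection and
    the scalar-projection / vector-module statistics.

    Parameters
    ----------
    n_components : int or "auto"
        Number of components, or "auto" to select by the Q2-gain rule.
    max_components : int or None
        Cap on fitted components (None: min(p, n-1, 10)).
    q2_gain : float
        Minimum Q2 improvement a component must bring to be retained.
    scale : bool
        Autoscale X internally (use False if X is already scaled).
    module : str
        Vector-module definition: "norm", "abs_sum" or "sum_abs".
    normalise_modules : bool
        Rescale modules so the largest equals 1.
    mode : str
        "plsda" (centred stage-indicator Y, default) or "pls1" (single
        numeric y = hpf).

    Attributes (after fit)
    ----------------------
    model_ : PLSModel; n_components_ : selected A*; r2_, q2_ : per-component
    diagnostics; projections_ : stage x descriptor DataFrame;
    modules_ : descriptor Series sorted descending; vip_ : VIP scores.
    """

    def __init__(
        self,
        n_components="auto",
        max_components=None,
        q2_gain: float = 0.01,
        scale: bool = True,
        projection: str = "covariance",
        module: str = "norm",
        normalise_modules: bool = False,
        mode: str = "plsda",
    ):
        self.n_components = n_components
        self.max_components = max_components
        self.q2_gain = q2_gain
        self.scale = scale
        self.projection = projection
        self.module = module
        self.normalise_modules = normalise_modules
        self.mode = mode

    def fit(self, X, y, groups=None):
        if self.mode not in ("plsda", "pls1"):
            raise ValueError("mode must be 'plsda' or 'pls1'")
        if self.module not in MODULE_DEFINITIONS:
            raise ValueError(f"module must be one of {MODULE_DEFINITIONS}")
        if self.projection not in PROJECTION_DEFINITIONS:
            raise ValueError(
                f"projection must be one of {PROJECTION_DEFINITIONS}"
            )
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        if self.scale:
            self.scaler_ = FeatureScaler().fit(Xdf)
            Xs = self.scaler_.transform(Xdf)
        else:
            self.scaler_ = None
            Xs = Xdf.astype(float)
        y = np.asarray(y)
        n, p = Xs.shape
        a_cap = self.max_components or min(p, n - 1, 10)
        a_cap = min(a_cap, p, n - 1)
        if self.mode == "pls1":
            model = _fit_pls1(Xs, y, a_cap)
        else:
            model = fit_pls(Xs, y, a_cap)
        a_fit = model.n_components
        if groups is not None and np.unique(groups).size >= 3 and a_fit > 0:
            if self.mode == "pls1":
                q2 = _cross_validate_q2_pls1(Xs, y, a_fit, groups)
            else:
                q2 = cross_validate_q2(Xs, y, a_fit, groups)
        else:
            q2 = np.full(a_fit, np.nan)
        model.q2 = q2
        if self.n_components == "auto":
            if np.all(np.isnan(q2)):
                a_star = 1
            else:
                a_star = select_components(model.r2, q2, self.q2_gain)
        else:
            a_star = min(int(self.n_components), a_fit)
        self.model_ = model
        self.classes_ = model.classes
        self.n_components_ = a_star
        self.r2_ = model.r2
        self.q2_ = q2
        self.projections_ = scalar_projections(model, a_star, self.projection)
        mods = vector_module(self.projections_, self.module, self.normalise_modules)
        self.modules_ = mods.sort_values(ascending=False, kind="stable")
        self.vip_ = vip_scores(model, a_star)
        self.feature_names_in_ = list(Xdf.columns)
        return self

    def predict(self, X):
        """Predicted stage per row (argmax of the indicator prediction)."""
        check_is_fitted(self, "model_")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        Xs = self.scaler_.transform(Xdf) if self.scaler_ is not None else Xdf
        pred = self.model_.predict(np.asarray(Xs, float), self.n_components_)
        if self.mode == "pls1":
            return pred.ravel()
        return self.classes_[np.argmax(pred, axis=1)]

    def fingerprint_table(self, organ: str = "") -> FingerprintTable:
        check_is_fitted(self, "model_")
        return FingerprintTable(
            organ=organ,
            projections=self.projections_,
            modules=self.modules_,
            n_components=self.n_components_,
            r2=self.r2_,
            q2=self.q2_,
        )


def _cross_validate_q2_pls1(X, y, A_max, groups) -> np.ndarray:
    """Leave-one-animal-out Q2 for the single-numeric-response variant."""
    X = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)[:, None]
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 3:
        raise ValueError("leave-one-animal-out needs >= 3 animals")
    ss = float(np.sum((yv - yv.mean()) ** 2))
    press = np.zeros(A_max)
    for g in uniq:
        test = groups == g
        train = ~test
        Xtr, ytr = X[train], yv[train]
        xm, ym = Xtr.mean(axis=0), ytr.mean(axis=0)
        W, T, P, Q, _ = _nipals_pls2(Xtr - xm, ytr - ym, A_max)
        got = W.shape[1]
        Xc_test = X[test] - xm
        for a in range(1, A_max + 1):
            aa = min(a, got)
            if aa == 0:
                pred = np.tile(ym, (Xc_test.shape[0], 1))
            else:
                B = _regression_coefs(W, P, Q, aa)
                pred = Xc_test @ B + ym
            press[a - 1] += float(np.sum((pred - yv[test]) ** 2))
    return 1.0 - press / ss if ss > 0 else np.zeros(A_max)


def _fit_pls1(X, y, A_max) -> PLSModel:
    """PLS1 variant: single numeric response (hpf)."""
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.shape(X)[1])
    ]
    X = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)[:, None]
    x_mean = X.mean(axis=0)
    y_mean = yv.mean(axis=0)
    W, T, P, Q, r2 = _nipals_pls2(X - x_mean, yv - y_mean, min(A_max, X.shape[1]))
    return PLSModel(
        x_weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=Q,
        r2=r2,
        classes=np.array(["hpf"], dtype=object),
        x_mean=x_mean,
        y_mean=y_mean,
        feature_names=names,
    )


def fingerprint(
    matrix: pd.DataFrame,
    organ: str = "",
    q2_gain: float = 0.01,
    projection: str = "covariance",
    module: str = "norm",
    normalise_modules: bool = False,
    mode: str = "plsda",
    n_components="auto",
) -> FingerprintTable:
    """End-to-end fingerprint for one organ's feature matrix.

    ``matrix`` is the output of :func:`zframan.features.build_features`
    (unscaled, with animal_id/stage_hpf columns).  Composes autoscaling,
    PLS-DA, leave-one-animal-out Q2, component selection and the projection /
    module statistics.
    """
    from .features import split_features

    X, y, groups = split_features(matrix)
    est = PLSFingerprint(
        n_components=n_components,
        q2_gain=q2_gain,
        projection=projection,
        module=module,
        normalise_modules=normalise_modules,
        mode=mode,
    ).fit(X, y, groups)
    return est.fingerprint_table(organ)
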