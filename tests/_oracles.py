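"""Independent reference implementations used only to cross-check results."""

import numpy as np


def svd_pls2(Xc, Yc, n_components):
    """SVD-based PLS2: per component the weight vector is the leading left
    singular vector of the X'Y cross-covariance, followed by the usual score/
    loading computation and deflation.  Independent of the NIPALS iteration.
    """
    X = Xc.copy()
    Y = Yc.copy()
    p = X.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    for a in range(n_components):
        U, s, Vt = np.linalg.svd(X.T @ Y, full_matrices=False)
        if s.size == 0 or s[0] < 1e-14:
            W, P, Q = W[:, :a], P[:, :a], Q[:, :a]
            break
        w = U[:, 0]
        t = X @ w
        tt = float(t @ t)
        if tt == 0:
            W, P, Q = W[:, :a], P[:, :a], Q[:, :a]
            break
        pvec = X.T @ t / tt
        q = Y.T @ t / tt
        W[:, a], P[:, a], Q[:, a] = w, pvec, q
        X = X - np.outer(t, pvec)
        Y = Y - np.outer(t, q)
    return W, P, Q


def svd_pls2_predict(Xc_train, Yc_train, Xc_test, n_components):
    W, P, Q = svd_pls2(Xc_train, Yc_train, n_components)
    if W.shape[1] == 0:
        return np.zeros((Xc_test.shape[0], Yc_train.shape[1]))
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return Xc_test @ B
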