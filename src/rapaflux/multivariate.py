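"""PCA sample mapping, PLS-DA biomarker scoring (VIP) and yield correlation.

PLS is fitted by NIPALS with deflation of both blocks.  For biomarker
discovery the response is a one-hot treatment matrix (PLS-DA); for yield
association it is the centered rapamycin titer.  Each metabolite's influence
is summarized by its variable importance in projection,

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),

with SSY_a = ||q_a||^2 t_a' t_a the response variance captured by component
a and p the number of metabolites; the scores satisfy sum_j VIP_j^2 = p.
Metabolites with VIP > 1 carry above-average weight and are reported as
candidate biomarkers (a second tier flags VIP > 1.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (ConvergenceError, DegenerateResponseError,
                         ParameterError)

_SIGN_TOL = 1e-12


def _fix_sign(vec: np.ndarray) -> float:
    """Return -1/+1 so that the largest-|value| entry becomes positive."""
    idx = int(np.argmax(np.abs(vec)))
    return -1.0 if vec[idx] < 0 else 1.0


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame                  # samples x components
    loadings: pd.DataFrame                # metabolites x components
    explained_variance_ratio: np.ndarray  # per component


def pca(X: pd.DataFrame | np.ndarray, n_components: int = 2) -> PCAResult:
    """SVD principal components of an already-normalized matrix.

    ``scores = X @ loadings``; no internal centering is applied, so feed
    autoscaled (or at least column-centered) data.  Loading signs are fixed
    by making each column's largest-|value| element positive.
    """
    Xv = np.asarray(X, float)
    n, p = Xv.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ParameterError(
            f"n_components must lie in [1, {min(n - 1, p)}], got {n_components}")
    U, s, Vt = np.linalg.svd(Xv, full_matrices=False)
    total = float(np.sum(s ** 2))
    evr = (s[:n_components] ** 2 / total) if total > 0 else np.zeros(n_components)
    loadings = Vt[:n_components].T
    for a in range(n_components):
        loadings[:, a] *= _fix_sign(loadings[:, a])
    scores = Xv @ loadings
    comp = [f"PC{a + 1}" for a in range(n_components)]
    s_idx = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    m_idx = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(p)
    return PCAResult(
        scores=pd.DataFrame(scores, index=s_idx, columns=comp),
        loadings=pd.DataFrame(loadings, index=m_idx, columns=comp),
        explained_variance_ratio=np.asarray(evr),
    )


# ---------------------------------------------------------------------------
# PLS (NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """A fitted PLS model (NIPALS) with its VIP biomarker scores."""

    n_components: int
    weights: pd.DataFrame        # W: metabolites x A, unit-norm columns
    scores: pd.DataFrame         # T: samples x A
    x_loadings: pd.DataFrame     # P: metabolites x A
    y_loadings: np.ndarray       # Q: A x n_responses
    response_kind: str           # "class_onehot" | "yield"
    x_mean: np.ndarray
    y_mean: np.ndarray
    ssy: np.ndarray = field(default=None)  # per-component response variance
    vip: pd.Series = field(default=None)

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients B with Y_hat = (X - x_mean) B + y_mean."""
        W = self.weights.to_numpy()
        P = self.x_loadings.to_numpy()
        return W @ np.linalg.solve(P.T @ W, self.y_loadings)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xv = np.asarray(X, float)
        return (Xv - self.x_mean) @ self.coefficients + self.y_mean


def plsda_fit(X: pd.DataFrame | np.ndarray,
              Y: pd.DataFrame | pd.Series | np.ndarray,
              n_components: int = 2,
              max_iter: int = 500,
              tol: float = 1e-12) -> PLSModel:
    """NIPALS PLS of X against a one-hot class matrix or a yield vector.

    Both blocks are centered internally and deflated after each component;
    every weight vector has unit norm and component signs follow the
    largest-|weight| convention, so refitting the same data is bit-stable.
    """
    Xv = np.asarray(X, float)
    Yv = np.asarray(Y, float)
    if Yv.ndim == 1:
        Yv = Yv[:, None]
    n, p = Xv.shape
    if Yv.shape[0] != n:
        raise ParameterError("X and Y sample counts differ")
    if not 1 <= n_components <= min(n - 1, p):
        raise ParameterError(
            f"n_components must lie in [1, {min(n - 1, p)}], got {n_components}")
    if np.allclose(Yv.std(axis=0), 0):
        raise DegenerateResponseError("response Y has no variance")
    multi = Yv.shape[1] > 1
    response_kind = "class_onehot" if multi else "yield"

    x_mean = Xv.mean(axis=0)
    y_mean = Yv.mean(axis=0)
    E = Xv - x_mean
    F = Yv - y_mean

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((n_components, Yv.shape[1]))
    ssy = np.zeros(n_components)

    for a in range(n_components):
        u = F[:, int(np.argmax(F.var(axis=0)))]
        w = np.zeros(p)
        for it in range(max_iter):
            w_new = E.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                raise ConvergenceError(
                    f"component {a + 1}: X residual orthogonal to response")
            w_new /= norm
            t = E @ w_new
            tt = float(t @ t)
            if tt == 0:
                raise ConvergenceError(f"component {a + 1}: degenerate scores")
            q = F.T @ t / tt
            if not multi:
                w = w_new
                break
            u = F @ q / float(q @ q)
            delta = np.linalg.norm(w_new - w)
            if delta < tol:
                w = w_new
                break
            w = w_new
        else:
            # near-degenerate response eigenvalues make the power iteration
            # crawl; any leading direction within the degenerate subspace is
            # an equally valid component, so accept small residual motion
            if delta < 1e-6:
                warnings.warn(
                    f"component {a + 1}: weight change {delta:.1e} after "
                    f"{max_iter} iterations (near-degenerate response); "
                    "accepting current direction")
            else:
                raise ConvergenceError(
                    f"component {a + 1} did not converge in {max_iter} "
                    f"iterations (last change {delta:.1e})")
        t = E @ w
        tt = float(t @ t)
        q = F.T @ t / tt
        sign = _fix_sign(w)
        w, t, q = sign * w, sign * t, sign * q
        pvec = E.T @ t / tt
        E = E - np.outer(t, pvec)
        F = F - np.outer(t, q)
        W[:, a], T[:, a], P[:, a], Q[a] = w, t, pvec, q
        ssy[a] = float(q @ q) * tt

    comp = [f"LV{a + 1}" for a in range(n_components)]
    s_idx = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    m_idx = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(p)
    model = PLSModel(
        n_components=n_components,
        weights=pd.DataFrame(W, index=m_idx, columns=comp),
        scores=pd.DataFrame(T, index=s_idx, columns=comp),
        x_loadings=pd.DataFrame(P, index=m_idx, columns=comp),
        y_loadings=Q,
        response_kind=response_kind,
        x_mean=x_mean, y_mean=y_mean, ssy=ssy,
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PLSModel) -> pd.Series:
    """Variable importance in projection; satisfies sum(VIP^2) = p."""
    W = model.weights.to_numpy()
    p = W.shape[0]
    ssy = model.ssy
    if ssy is None or len(ssy) < 1:
        raise ParameterError("model carries no fitted components")
    # columns of W are unit norm already; normalize defensively
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    contrib = (Wn ** 2) @ ssy
    vip = np.sqrt(p * contrib / float(np.sum(ssy)))
    return pd.Series(vip, index=model.weights.index, name="VIP")


def one_hot(conditions: pd.Series) -> pd.DataFrame:
    """Treatment labels -> one-hot response matrix with sorted class columns."""
    return pd.get_dummies(conditions).astype(float).sort_index(axis=1)


def select_biomarkers(vip: pd.Series, threshold: float = 1.0,
                      tier2_threshold: float = 1.5) -> pd.DataFrame:
    """Metabolites with VIP strictly above threshold, descending VIP.

    Ties are broken by metabolite name so output order is deterministic; the
    ``tier2`` column flags the strongest candidates (VIP > 1.5 by default).
    """
    if not threshold > 0:
        raise ParameterError("threshold must be positive")
    picked = vip[vip > threshold]
    df = picked.rename("VIP").rename_axis("metabolite").reset_index()
    df = df.sort_values(["VIP", "metabolite"],
                        ascending=[False, True], kind="mergesort")
    df["tier2"] = df["VIP"] > tier2_threshold
    return df.reset_index(drop=True)


def yield_correlation(X: pd.DataFrame, yields: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each metabolite with the yield trait.

    Returns (metabolite, r, rank) sorted by |r| descending, sign retained;
    constant metabolites have undefined correlation and are excluded with a
    warning.
    """
    y = np.asarray(yields, float)
    if not np.all(np.isfinite(y)):
        raise ParameterError("yield vector contains non-finite values")
    if np.std(y) == 0:
        raise DegenerateResponseError("yield vector is constant")
    yc = y - y.mean()
    rows = []
    for met in X.columns:
        x = X[met].to_numpy(float)
        sx = x.std()
        if sx == 0:
            warnings.warn(f"metabolite '{met}' is constant; correlation undefined")
            continue
        r = float((x - x.mean()) @ yc / (len(x) * sx * yc.std()))
        rows.append((met, r))
    df = pd.DataFrame(rows, columns=["metabolite", "r"])
    df["abs_r"] = df["r"].abs()
    df = df.sort_values(["abs_r", "metabolite"],
                        ascending=[False, True], kind="mergesort")
    df = df.drop(columns="abs_r").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
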