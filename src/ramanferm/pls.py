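"""PLS1 regression, venetian-blinds cross-validation, latent-variable selection.

One model per analyte (PLS1).  Components are extracted by sequential
deflation (NIPALS for a single response): w ∝ X'y, t = Xw, p = X't/t't,
q = y't/t't, X <- X - t p'.  The regression vector on centered data is
b = W (P'W)^{-1} q.  Cross-validation uses interleaved ("venetian blinds")
folds over acquisition order, with EMSC and centering refit inside each
training split so no preprocessing information leaks into the held-out fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import WavenumberGrid
from .preprocessing import EmscBasis, emsc_correct

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-12


@dataclass
class PLSModel:
    """A fitted PLS1 model on centered data."""

    weights: np.ndarray      # W, (p, k)
    x_loadings: np.ndarray   # P, (p, k)
    y_loadings: np.ndarray   # q, (k,)
    scores: np.ndarray       # T, (n, k)
    n_lv: int                # latent variables actually requested
    k_effective: int         # components actually extracted (rank limit)
    rmsec: float             # training RMSE at n_lv

    def regression_vector(self, n_lv: int | None = None) -> np.ndarray:
        """b = W (P'W)^{-1} q using the first ``n_lv`` components."""
        k = min(self.n_lv if n_lv is None else n_lv, self.k_effective)
        W, P, q = self.weights[:, :k], self.x_loadings[:, :k], self.y_loadings[:k]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict_centered(self, x_centered: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        """Centered-scale predictions y_c = X_c b."""
        x_centered = np.atleast_2d(x_centered)
        if x_centered.shape[1] != self.weights.shape[0]:
            raise ValueError("channel count does not match the training grid")
        return x_centered @ self.regression_vector(n_lv)


def fit_pls1(x_centered: np.ndarray, y_centered: np.ndarray, n_lv: int,
             allow_early_stop: bool = False) -> PLSModel:
    """Fit PLS1 by sequential deflation on centered X and y.

    Raises if ``n_lv`` exceeds the data's effective rank (unless
    ``allow_early_stop``, in which case the model keeps the components it
    could extract — used inside cross-validation on near-noiseless folds).
    """
    X = np.array(x_centered, dtype=float)
    y = np.array(y_centered, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y sample counts differ")
    if n_lv < 1:
        raise ValueError("need at least one latent variable")
    if n_lv > min(n, p):
        raise ValueError(f"n_lv={n_lv} exceeds the rank bound min(n, p)={min(n, p)}")
    y_scale = float(np.linalg.norm(y))
    if y_scale == 0.0 or np.allclose(y, y[0]):
        raise ValueError("y has zero variance; nothing to regress on")

    Xd, yd = X.copy(), y.copy()
    x_scale = max(float(np.linalg.norm(Xd)), 1.0)
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    k_eff = 0
    for k in range(n_lv):
        w = Xd.T @ yd
        w_norm = float(np.linalg.norm(w))
        if w_norm <= _RANK_TOL * x_scale * y_scale:
            if allow_early_stop:
                break
            raise ValueError(f"n_lv={n_lv} exceeds the effective rank ({k} components extractable)")
        w /= w_norm
        t = Xd @ w
        tt = float(t @ t)
        if tt <= (_RANK_TOL * x_scale) ** 2:
            if allow_early_stop:
                break
            raise ValueError(f"n_lv={n_lv} exceeds the effective rank ({k} components extractable)")
        p_k = Xd.T @ t / tt
        q_k = float(yd @ t / tt)
        Xd -= np.outer(t, p_k)
        yd = yd - q_k * t
        W[:, k], P[:, k], T[:, k], q[k] = w, p_k, t, q_k
        k_eff = k + 1

    W, P, T, q = W[:, :max(k_eff, 1)], P[:, :max(k_eff, 1)], T[:, :max(k_eff, 1)], q[:max(k_eff, 1)]
    model = PLSModel(weights=W, x_loadings=P, y_loadings=q, scores=T,
                     n_lv=n_lv, k_effective=k_eff, rmsec=0.0)
    residual = y - model.predict_centered(X)
    model.rmsec = float(np.sqrt(np.mean(residual**2)))
    return model


def venetian_blinds_folds(n_samples: int, n_folds: int = 7) -> np.ndarray:
    """Interleaved fold assignment: sample at acquisition position i -> fold i mod k."""
    if n_folds < 2:
        raise ValueError("need at least two folds")
    if n_samples < n_folds:
        raise ValueError(f"cannot split {n_samples} samples into {n_folds} folds")
    return np.arange(n_samples) % n_folds


@dataclass
class CVResult:
    """Per-LV error curves from venetian-blinds cross-validation."""

    rmsecv: np.ndarray       # pooled held-out RMSE per LV count (1..max_lv)
    rmsec: np.ndarray        # full-data training RMSE per LV count
    folds: np.ndarray        # fold assignment used

    @property
    def max_lv(self) -> int:
        return self.rmsecv.size


def _center_fit_apply(x_train, x_test, y_train):
    xm = x_train.mean(axis=0)
    ym = float(y_train.mean())
    return x_train - xm, x_test - xm, y_train - ym, ym


def cross_validate(x_raw: np.ndarray, y: np.ndarray, max_lv: int, n_folds: int = 7,
                   grid: WavenumberGrid | None = None, emsc: bool = True) -> CVResult:
    """Venetian-blinds cross-validation with per-fold preprocessing refit.

    ``x_raw`` are cropped but uncorrected spectra in acquisition order.  For
    every fold, the EMSC reference (training mean) and the centering means
    are re-estimated on the training split only, the held-out split is
    corrected and centered with those, and predictions are made at every LV
    count.  RMSECV pools held-out residuals across folds; RMSEC comes from a
    full-data refit.
    """
    from .dataset import SpectralDataset  # local import to avoid cycle at module load

    X = np.asarray(x_raw, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if max_lv < 1:
        raise ValueError("max_lv must be at least 1")
    if emsc and grid is None:
        raise ValueError("EMSC refit inside folds needs the wavenumber grid")
    folds = venetian_blinds_folds(X.shape[0], n_folds)

    def preprocess(train_x, test_x):
        if not emsc:
            return train_x, test_x
        ds_train = SpectralDataset(grid=grid, intensities=train_x, stage="cropped")
        basis = EmscBasis.from_dataset(ds_train)
        corr_train, _ = emsc_correct(ds_train, basis)
        ds_test = SpectralDataset(grid=grid, intensities=test_x, stage="cropped")
        corr_test, _ = emsc_correct(ds_test, basis)
        return corr_train.intensities, corr_test.intensities

    residuals = np.zeros((X.shape[0], max_lv))
    for f in range(n_folds):
        test = folds == f
        train = ~test
        if np.allclose(y[train], y[train][0]):
            raise ValueError(f"fold {f}: training y has zero variance")
        xt, xv = preprocess(X[train], X[test])
        xt_c, xv_c, yt_c, ym = _center_fit_apply(xt, xv, y[train])
        model = fit_pls1(xt_c, yt_c, min(max_lv, min(xt_c.shape)), allow_early_stop=True)
        for k in range(1, max_lv + 1):
            pred = model.predict_centered(xv_c, n_lv=k) + ym
            residuals[test, k - 1] = y[test] - pred
    rmsecv = np.sqrt(np.mean(residuals**2, axis=0))

    xt, _ = preprocess(X, X[:1])
    xt_c = xt - xt.mean(axis=0)
    y_c = y - y.mean()
    full = fit_pls1(xt_c, y_c, min(max_lv, min(xt_c.shape)), allow_early_stop=True)
    rmsec = np.array([
        float(np.sqrt(np.mean((y_c - full.predict_centered(xt_c, n_lv=k)) ** 2)))
        for k in range(1, max_lv + 1)
    ])
    return CVResult(rmsecv=rmsecv, rmsec=rmsec, folds=folds)


def select_latent_variables(cv: CVResult, tau: float = 0.05,
                            override: int | None = None) -> int:
    """Elbow of the RMSECV curve: smallest n whose step to n+1 improves ≤ tau.

    The relative improvement (RMSECV[n] - RMSECV[n+1]) / RMSECV[n] is
    compared non-strictly against ``tau`` (with a small float slack), so a
    step that improves by exactly tau already counts as the elbow.  A flat
    curve selects 1.  ``override`` wins unconditionally and is logged.
    """
    if cv.rmsecv.size == 0:
        raise ValueError("empty cross-validation curve")
    if override is not None:
        logger.info("latent-variable selection overridden manually: n_lv=%d "
                    "(RMSECV curve: %s)", override, np.array2string(cv.rmsecv, precision=4))
        return int(override)
    r = cv.rmsecv
    logger.info("RMSECV curve: %s (elbow threshold tau=%g)",
                np.array2string(r, precision=6), tau)
    for n in range(1, r.size):
        denom = r[n - 1]
        improvement = (r[n - 1] - r[n]) / denom if denom > 0 else 0.0
        if improvement <= tau + 1e-12:
            return n
    return int(r.size)
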