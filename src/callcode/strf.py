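"""LN spectrotemporal receptive field estimation.

The encoding model convolves a 31-channel x 10-lag weight matrix with the
stimulus cochleagram and passes the result through a double-exponential
point nonlinearity

    y = b + a * exp(-exp(-k * (x - s))),

fit by minimizing squared PSTH error (an L2 penalty on the weights
stabilizes the fit).  Nested cross-validation uses 10 nonoverlapping
contiguous validation segments; the mean STRF over folds is masked by a
permutation significance test (matrix scrambling, two-tailed, BH-FDR over
the 310 cells) before complexity scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy import stats as sps

from .cochleagram import Cochleagram, N_CHANNELS
from .neurons import N_LAGS, TrialRaster, lagged_design
from .stats import fdr_bh

N_FOLDS = 10


@dataclass
class Nonlinearity:
    """Double-exponential output nonlinearity parameters."""

    base: float
    amplitude: float
    shift: float
    curvature: float

    def __call__(self, x):
        z = -self.curvature * (np.asarray(x, dtype=float) - self.shift)
        return self.base + self.amplitude * np.exp(-np.exp(np.clip(z, -700, 30)))


@dataclass
class LNModel:
    weights: np.ndarray            # (31, 10) mean STRF over folds
    nonlinearity: Nonlinearity
    fold_weights: np.ndarray       # (10, 31, 10)
    fold_nonlinearities: list
    r_folds: np.ndarray
    r_mean: float
    r_significant: bool
    significance_mask: np.ndarray | None = None
    masked_strf: np.ndarray | None = None


@dataclass
class STRFMetrics:
    sparsity: float
    kurtosis: float
    defined: bool = True


def _laplacian_gram(n_ch: int = N_CHANNELS, n_lag: int = N_LAGS) -> np.ndarray:
    """L.T @ L for the discrete Laplacian on the channel x lag grid.

    Penalizing ||L w||^2 encodes the expectation that receptive fields are
    smooth in frequency and time; it suppresses high-frequency weight noise
    that a plain ridge penalty cannot distinguish from structure.
    """
    n = n_ch * n_lag
    L = np.zeros((n, n))
    for c in range(n_ch):
        for lag in range(n_lag):
            i = c * n_lag + lag
            for dc, dl in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                c2, l2 = c + dc, lag + dl
                if 0 <= c2 < n_ch and 0 <= l2 < n_lag:
                    L[i, c2 * n_lag + l2] = -1.0
                    L[i, i] += 1.0
    return L.T @ L


_LTL = _laplacian_gram()


def _fit_nonlinearity(u: np.ndarray, y: np.ndarray) -> Nonlinearity:
    """Least-squares double-exponential fit for a fixed linear drive."""
    su = u.std() or 1.0

    def loss4(p):
        b, a, s, k = p
        z = np.clip(-k * (u - s), -700.0, 30.0)
        yh = b + a * np.exp(-np.exp(z))
        return np.mean((yh - y) ** 2)

    p0 = [max(float(np.percentile(y, 5)), 0.0),
          max(float(np.percentile(y, 98) - np.percentile(y, 5)), 1.0),
          float(np.median(u)), 2.0 / su]
    res = minimize(loss4, p0, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
    b, a, s, k = res.x
    return Nonlinearity(base=float(b), amplitude=float(max(a, 1e-6)),
                        shift=float(s), curvature=float(max(k, 1e-6)))


def _fit_single(X, y, l2, smoothness, maxiter, ftol):
    """One LN fit: regularized linear stage, nonlinearity stage, then joint
    gradient refinement of (weights, base, amplitude, shift).

    The curvature is fixed after the nonlinearity stage; this removes the
    scale degeneracy (w, k, s) -> (c w, k/c, c s) that would otherwise let
    the optimizer evade the weight penalties.
    """
    n = len(y)
    A = X.T @ X + (l2 * n) * np.eye(X.shape[1]) + (smoothness * n) * _LTL
    w0 = np.linalg.solve(A, X.T @ (y - y.mean()))
    nl0 = _fit_nonlinearity(X @ w0, y)
    k = nl0.curvature

    def loss_grad(theta):
        w, b, a, s = theta[:-3], theta[-3], theta[-2], theta[-1]
        u = X @ w
        # upper clip keeps exp(z) finite so 0 * exp(z) products stay 0
        z = np.clip(-k * (u - s), -700.0, 30.0)
        ez = np.exp(z)
        g = np.exp(-ez)
        resid = b + a * g - y
        lw = _LTL @ w
        loss = resid @ resid / n + l2 * (w @ w) + smoothness * (w @ lw)
        c = (2.0 / n) * resid
        dg = a * g * ez      # dyhat/du = dg * k ; dyhat/ds = -dg * k
        grad_w = X.T @ (c * dg * k) + 2 * l2 * w + 2 * smoothness * lw
        return loss, np.concatenate(
            [grad_w, [c.sum(), c @ g, -(c * dg).sum() * k]])

    theta0 = np.concatenate([w0, [nl0.base, nl0.amplitude, nl0.shift]])
    bounds = [(None, None)] * X.shape[1] + [
        (0.0, None), (1e-6, None), (None, None)]
    res = minimize(loss_grad, theta0, jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": maxiter, "ftol": ftol})
    w = res.x[:-3]
    return w, Nonlinearity(base=float(res.x[-3]), amplitude=float(res.x[-2]),
                           shift=float(res.x[-1]), curvature=k)


def cv_folds(n_frames: int, n_folds: int = N_FOLDS):
    """Contiguous, nonoverlapping validation segments covering all frames."""
    edges = np.linspace(0, n_frames, n_folds + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_folds)]


def fit_ln_model(cochleagram: Cochleagram, psth: np.ndarray, seed: int = 0,
                 l2: float = 1e-4, smoothness: float = 1e-3,
                 maxiter: int = 10_000, ftol: float = 1e-6,
                 n_boot: int = 1000, compute_mask: bool = True,
                 n_shuffles: int = 1000) -> LNModel:
    """Fit the LN model with 10-fold nested cross-validation.

    ``psth`` is the trial-averaged rate in 20 ms bins aligned with the
    cochleagram frames.  Deterministic given ``seed`` (used for the r
    bootstrap and the significance-mask scrambling).
    """
    psth = np.asarray(psth, dtype=float)
    if not np.all(np.isfinite(psth)):
        raise ValueError("psth contains non-finite values")
    if len(psth) != cochleagram.n_frames:
        raise ValueError("psth length must equal cochleagram frame count")
    if len(psth) < N_FOLDS * 4:
        raise ValueError("too few frames for 10-fold cross-validation")

    X = lagged_design(cochleagram.values)
    folds = cv_folds(len(psth))
    fold_ws, fold_nls, r_folds = [], [], []
    val_pred, val_obs = [], []
    for lo, hi in folds:
        train = np.ones(len(psth), dtype=bool)
        train[lo:hi] = False
        w, nl = _fit_single(X[train], psth[train], l2, smoothness,
                            maxiter, ftol)
        fold_ws.append(w.reshape(N_CHANNELS, N_LAGS))
        fold_nls.append(nl)
        pred = nl(X[lo:hi] @ w)
        obs = psth[lo:hi]
        val_pred.append(pred)
        val_obs.append(obs)
        if pred.std() == 0 or obs.std() == 0:
            r_folds.append(0.0)
        else:
            r_folds.append(float(np.corrcoef(pred, obs)[0, 1]))
    fold_ws = np.stack(fold_ws)
    r_folds = np.asarray(r_folds)
    mean_w = fold_ws.mean(axis=0)
    mean_nl = Nonlinearity(
        base=float(np.mean([nl.base for nl in fold_nls])),
        amplitude=float(np.mean([nl.amplitude for nl in fold_nls])),
        shift=float(np.mean([nl.shift for nl in fold_nls])),
        curvature=float(np.mean([nl.curvature for nl in fold_nls])))

    rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)), 0x57F]))
    pred_all = np.concatenate(val_pred)
    obs_all = np.concatenate(val_obs)
    r_sig = _bootstrap_r_significant(pred_all, obs_all, n_boot, rng)

    model = LNModel(weights=mean_w, nonlinearity=mean_nl,
                    fold_weights=fold_ws, fold_nonlinearities=fold_nls,
                    r_folds=r_folds, r_mean=float(r_folds.mean()),
                    r_significant=r_sig)
    if compute_mask:
        mask, masked = significance_mask(fold_ws, n_shuffles=n_shuffles,
                                         seed=seed)
        model.significance_mask = mask
        model.masked_strf = masked
    return model


def _bootstrap_r_significant(pred, obs, n_boot, rng) -> bool:
    """True when the bootstrap 95% CI of r (over time bins) excludes 0."""
    n = len(obs)
    if n < 3 or pred.std() == 0 or obs.std() == 0:
        return False
    rs = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        p, o = pred[idx], obs[idx]
        rs[i] = 0.0 if (p.std() == 0 or o.std() == 0) else np.corrcoef(p, o)[0, 1]
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return bool(lo > 0.0 or hi < 0.0)


def predict_response(model: LNModel, cochleagram: Cochleagram) -> np.ndarray:
    """Predicted PSTH: causal convolution (lags 0-180 ms) + nonlinearity."""
    if cochleagram.values.shape[0] != model.weights.shape[0]:
        raise ValueError("cochleagram channel grid does not match model")
    X = lagged_design(cochleagram.values)
    return model.nonlinearity(X @ model.weights.ravel())


def significance_mask(fold_estimates: np.ndarray, n_shuffles: int = 1000,
                      seed: int = 0, q: float = 0.05):
    """Permutation significance mask for the mean STRF.

    The null scrambles each fold's weight matrix (random permutation of all
    cell positions, independently per fold per shuffle) and re-averages
    across folds, giving a null distribution of mean weights per cell.
    Two-tailed permutation p-values are BH-FDR corrected across the 310
    cells.  Returns (mask, masked mean STRF).
    """
    fold_estimates = np.asarray(fold_estimates, dtype=float)
    if fold_estimates.ndim != 3 or len(fold_estimates) < 2:
        raise ValueError("need >= 2 fold estimate matrices")
    n_folds, n_ch, n_lag = fold_estimates.shape
    obs = fold_estimates.mean(axis=0)
    if np.all(obs == 0):
        return np.zeros_like(obs, dtype=bool), np.zeros_like(obs)
    flat = fold_estimates.reshape(n_folds, -1)
    n_cells = flat.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)), 0xA5]))
    null = np.empty((n_shuffles, n_cells))
    for i in range(n_shuffles):
        scrambled = np.empty_like(flat)
        for f in range(n_folds):
            scrambled[f] = flat[f, rng.permutation(n_cells)]
        null[i] = scrambled.mean(axis=0)
    obs_flat = obs.ravel()
    # uncorrected permutation p (floor at 0): with the +1 small-sample
    # correction, a lone extreme cell could never clear BH-FDR across 310
    # comparisons at any feasible shuffle count
    p_hi = (null >= obs_flat[None, :]).mean(axis=0)
    p_lo = (null <= obs_flat[None, :]).mean(axis=0)
    p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
    reject, _ = fdr_bh(p, q=q)
    mask = reject.reshape(n_ch, n_lag)
    return mask, obs * mask


def strf_complexity(masked_strf: np.ndarray) -> STRFMetrics:
    """STRF sparsity (max|W| / sd(W)) and excess kurtosis of all cells."""
    W = np.asarray(masked_strf, dtype=float)
    if W.size == 0:
        raise ValueError("empty STRF")
    sd = W.std(ddof=0)
    if sd == 0:
        return STRFMetrics(sparsity=np.nan, kurtosis=np.nan, defined=False)
    return STRFMetrics(
        sparsity=float(np.abs(W).max() / sd),
        kurtosis=float(sps.kurtosis(W.ravel(), fisher=True, bias=True)))


def concatenated_psth(raster: TrialRaster, coch: Cochleagram) -> np.ndarray:
    """Trial-mean rate in 20 ms bins over the concatenated stimulus order."""
    parts = []
    bounds = coch.stimulus_boundaries
    for i, sid in enumerate(coch.stimulus_ids):
        n_frames = int(bounds[i + 1] - bounds[i])
        p = raster.psth(sid, bin_s=coch.frame_step,
                        t0=0.0, t1=n_frames * coch.frame_step)
        parts.append(p[:n_frames])
    return np.concatenate(parts)


class STRFModel:
    """Sklearn-style LN-STRF estimator.

    ``fit(X, y)`` takes the cochleagram as ``X`` (n_frames, n_channels) and
    the PSTH as ``y``; fitted attributes are ``weights_``,
    ``nonlinearity_``, ``fold_weights_``, ``r_folds_``, ``r_mean_``,
    ``r_significant_``, ``significance_mask_`` and ``masked_strf_``.
    """

    def __init__(self, l2=1e-4, smoothness=1e-3, maxiter=10_000, ftol=1e-6,
                 n_boot=1000, n_shuffles=1000, compute_mask=True,
                 random_state=0):
        self.l2 = l2
        self.smoothness = smoothness
        self.maxiter = maxiter
        self.ftol = ftol
        self.n_boot = n_boot
        self.n_shuffles = n_shuffles
        self.compute_mask = compute_mask
        self.random_state = random_state

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "l2", "smoothness", "maxiter", "ftol", "n_boot", "n_shuffles",
            "compute_mask", "random_state")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        coch = Cochleagram(values=X.T)
        model = fit_ln_model(
            coch, y, seed=self.random_state, l2=self.l2,
            smoothness=self.smoothness, maxiter=self.maxiter,
            ftol=self.ftol, n_boot=self.n_boot,
            compute_mask=self.compute_mask, n_shuffles=self.n_shuffles)
        self.model_ = model
        self.weights_ = model.weights
        self.nonlinearity_ = model.nonlinearity
        self.fold_weights_ = model.fold_weights
        self.r_folds_ = model.r_folds
        self.r_mean_ = model.r_mean
        self.r_significant_ = model.r_significant
        self.significance_mask_ = model.significance_mask
        self.masked_strf_ = model.masked_strf
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return predict_response(self.model_, Cochleagram(values=X.T))

    def score(self, X, y):
        pred = self.predict(X)
        y = np.asarray(y, dtype=float)
        if pred.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(pred, y)[0, 1])


def save_model(model: LNModel, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=model.weights)
        f.create_dataset("fold_weights", data=model.fold_weights)
        f.create_dataset("r_folds", data=model.r_folds)
        nl = model.nonlinearity
        f.attrs["nonlinearity"] = [nl.base, nl.amplitude, nl.shift, nl.curvature]
        f.attrs["r_mean"] = model.r_mean
        f.attrs["r_significant"] = model.r_significant
        if model.significance_mask is not None:
            f.create_dataset("significance_mask",
                             data=model.significance_mask.astype(np.uint8))
            f.create_dataset("masked_strf", data=model.masked_strf)
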