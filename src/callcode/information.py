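"""Stimulus-specific information (SSI) and mutual information analysis.

Responses are symbolized as spike counts in sliding windows (half-window
slide) over a fixed analysis span from 50 ms before onset to 1,457 ms.
Per time bin, the information a specific response pattern conveys is

    I_SP(resp) = H(stim) - H(stim | resp),

and the stimulus-specific information is its response-conditional average,

    I_SSI(stim) = sum_resp p(resp | stim) * I_SP(resp).

The prior-weighted average of I_SSI over stimuli equals the mutual
information between stimulus and response for that bin.  Finite-sampling
bias is corrected by subtracting an all-way shuffled I_SSI estimate
(stimulus labels permuted within each bin; mean of 100 randomizations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neurons import TrialRaster
from .selectivity import response_kurtosis

WINDOW_SIZES_MS = (14.0, 50.0, 100.0, 200.0, 300.0, 400.0)
SPAN_S = (-0.050, 1.457)


@dataclass(frozen=True)
class InfoConfig:
    window_ms: float = 100.0
    span_s: tuple = SPAN_S
    n_shuffles: int = 100
    #: 'mean_plus_sd' (mean + 1 SD of the MI time course) or 'sd'
    high_mi_threshold: str = "mean_plus_sd"
    #: shuffle scope: 'within_bin' label permutation or 'global'
    shuffle_scope: str = "within_bin"

    @property
    def slide_ms(self) -> float:
        return self.window_ms / 2.0


def bin_starts(config: InfoConfig) -> np.ndarray:
    """Window start times (s) on the half-window-slide lattice."""
    w = config.window_ms / 1000.0
    slide = w / 2.0
    t0, t1 = config.span_s
    n = int(np.floor((t1 - t0 - w) / slide + 1e-9)) + 1
    return t0 + slide * np.arange(n)


def symbolize(raster: TrialRaster, config: InfoConfig | None = None) -> np.ndarray:
    """Spike-count symbols, shape (n_stimuli, n_trials, n_bins).

    Responses to stimuli longer than the span are truncated; bins are
    aligned identically across stimuli.  Requires equal trial counts.
    """
    if config is None:
        config = InfoConfig()
    starts = bin_starts(config)
    w = config.window_ms / 1000.0
    sids = raster.stimulus_ids
    counts = np.zeros((len(sids), raster.n_trials, len(starts)), dtype=np.int64)
    for i, sid in enumerate(sids):
        for k in range(raster.n_trials):
            if (sid, k) not in raster.spikes:
                raise ValueError(
                    f"missing trial {k} for {sid}: equal trial counts required")
            t = raster.spike_times(sid, k)
            for j, s in enumerate(starts):
                counts[i, k, j] = np.count_nonzero((t >= s) & (t < s + w))
    return counts


def _issi_one_bin(counts: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """I_SSI per stimulus for one bin; counts is (n_stim, n_trials)."""
    n_stim, n_trials = counts.shape
    symbols, inv = np.unique(counts.ravel(), return_inverse=True)
    inv = inv.reshape(n_stim, n_trials)
    n_sym = len(symbols)
    p_r_given_s = np.zeros((n_stim, n_sym))
    for s in range(n_stim):
        p_r_given_s[s] = np.bincount(inv[s], minlength=n_sym) / n_trials
    p_r = prior @ p_r_given_s
    with np.errstate(divide="ignore", invalid="ignore"):
        p_s_given_r = (prior[:, None] * p_r_given_s) / p_r[None, :]
    p_s_given_r = np.where(p_r[None, :] > 0, p_s_given_r, 0.0)
    h_total = -np.sum(prior * np.log2(prior, where=prior > 0,
                                      out=np.zeros_like(prior)))
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log2(p_s_given_r, where=p_s_given_r > 0,
                       out=np.zeros_like(p_s_given_r))
    h_cond = -np.sum(p_s_given_r * logp, axis=0)  # per response symbol
    i_sp = h_total - h_cond
    return p_r_given_s @ i_sp


def stimulus_specific_information(symbols: np.ndarray,
                                  prior: np.ndarray | None = None) -> np.ndarray:
    """Raw (uncorrected) I_SSI matrix, shape (n_stimuli, n_bins), in bits."""
    symbols = np.asarray(symbols)
    if symbols.ndim != 3:
        raise ValueError("symbols must be (n_stimuli, n_trials, n_bins)")
    n_stim, _, n_bins = symbols.shape
    if n_stim < 2:
        raise ValueError("need at least 2 stimuli")
    if prior is None:
        prior = np.full(n_stim, 1.0 / n_stim)
    prior = np.asarray(prior, dtype=float)
    issi = np.empty((n_stim, n_bins))
    for j in range(n_bins):
        issi[:, j] = _issi_one_bin(symbols[:, :, j], prior)
    return issi


def mutual_information(issi: np.ndarray,
                       prior: np.ndarray | None = None) -> np.ndarray:
    """Per-bin MI: the prior-weighted average of I_SSI across stimuli."""
    n_stim = issi.shape[0]
    if prior is None:
        prior = np.full(n_stim, 1.0 / n_stim)
    return np.asarray(prior, dtype=float) @ issi


@dataclass
class SSIResult:
    issi: np.ndarray               # bias-corrected (n_stim, n_bins)
    mi: np.ndarray                 # bias-corrected per-bin MI
    issi_raw: np.ndarray
    mi_raw: np.ndarray
    bias: np.ndarray               # mean shuffled I_SSI
    bin_starts: np.ndarray
    high_mi_bins: np.ndarray | None = None
    si_mi: float = np.nan
    issi_psth_corr: float = np.nan
    issi_psth_slope: float = np.nan


def bias_corrected_issi(symbols: np.ndarray, prior: np.ndarray | None = None,
                        n_shuffles: int = 100, seed: int = 0,
                        config: InfoConfig | None = None) -> SSIResult:
    """I_SSI with all-way shuffle bias correction.

    Per shuffle, stimulus labels are permuted across all (stimulus, trial)
    responses jointly within each bin; the mean shuffled I_SSI is
    subtracted cell-wise.  Deterministic given ``seed``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if config is None:
        config = InfoConfig()
    symbols = np.asarray(symbols)
    n_stim, n_trials, n_bins = symbols.shape
    if prior is None:
        prior = np.full(n_stim, 1.0 / n_stim)
    prior = np.asarray(prior, dtype=float)
    issi_raw = stimulus_specific_information(symbols, prior)
    rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)), 0x1F]))
    bias = np.zeros((n_stim, n_bins))
    flat = symbols.reshape(n_stim * n_trials, n_bins)
    for _ in range(n_shuffles):
        if config.shuffle_scope == "global":
            perm = rng.permutation(n_stim * n_trials)
            shuf = flat[perm].reshape(n_stim, n_trials, n_bins)
            bias += stimulus_specific_information(shuf, prior)
        else:
            for j in range(n_bins):
                perm = rng.permutation(n_stim * n_trials)
                col = flat[perm, j].reshape(n_stim, n_trials)
                bias[:, j] += _issi_one_bin(col, prior)
    bias /= n_shuffles
    issi = issi_raw - bias
    return SSIResult(issi=issi, mi=mutual_information(issi, prior),
                     issi_raw=issi_raw,
                     mi_raw=mutual_information(issi_raw, prior),
                     bias=bias, bin_starts=bin_starts(config))


def binned_psth(raster: TrialRaster, config: InfoConfig | None = None) -> np.ndarray:
    """Trial-mean spike count per analysis window, (n_stimuli, n_bins)."""
    if config is None:
        config = InfoConfig()
    return symbolize(raster, config).mean(axis=1)


def mi_sparsity_and_coupling(result: SSIResult, psth: np.ndarray,
                             config: InfoConfig | None = None) -> SSIResult:
    """MI sparsity index and I_SSI-PSTH coupling; updates ``result``.

    High-MI bins exceed mean + 1 SD of the MI time course; SI_MI is the
    mean, over those bins, of the excess kurtosis of the per-stimulus
    I_SSI values.  Coupling pools all (stimulus, bin) pairs: Pearson
    correlation and least-squares slope of I_SSI on PSTH.
    """
    if config is None:
        config = InfoConfig()
    mi = result.mi
    if len(mi) < 2:
        raise ValueError("need at least 2 bins")
    threshold = mi.std(ddof=0)
    if config.high_mi_threshold == "mean_plus_sd":
        threshold += mi.mean()
    high = mi > threshold
    result.high_mi_bins = high
    if high.any():
        kurts = []
        for j in np.flatnonzero(high):
            vals = result.issi[:, j]
            if vals.std(ddof=0) > 0:
                kurts.append(response_kurtosis(vals))
        result.si_mi = float(np.mean(kurts)) if kurts else np.nan
    else:
        result.si_mi = np.nan

    psth = np.asarray(psth, dtype=float)
    if psth.shape != result.issi.shape:
        raise ValueError("psth must align with the issi matrix")
    x = psth.ravel()
    y = result.issi.ravel()
    if x.std(ddof=0) == 0:
        result.issi_psth_corr = np.nan
        result.issi_psth_slope = np.nan
    else:
        result.issi_psth_corr = float(np.corrcoef(x, y)[0, 1])
        result.issi_psth_slope = float(
            np.cov(x, y, ddof=0)[0, 1] / x.var(ddof=0))
    return result


class StimulusInformation:
    """Sklearn-style SSI analyzer for a trial raster.

    After ``fit(raster)``: ``issi_`` (bias-corrected stimulus x bin
    matrix), ``mi_``, ``high_mi_bins_``, ``si_mi_``, ``psth_corr_``,
    ``psth_slope_``, ``bin_starts_``.
    """

    def __init__(self, window_ms=100.0, n_shuffles=100,
                 high_mi_threshold="mean_plus_sd",
                 shuffle_scope="within_bin", random_state=0):
        self.window_ms = window_ms
        self.n_shuffles = n_shuffles
        self.high_mi_threshold = high_mi_threshold
        self.shuffle_scope = shuffle_scope
        self.random_state = random_state

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "window_ms", "n_shuffles", "high_mi_threshold",
            "shuffle_scope", "random_state")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, raster: TrialRaster, y=None):
        config = InfoConfig(window_ms=self.window_ms,
                            n_shuffles=self.n_shuffles,
                            high_mi_threshold=self.high_mi_threshold,
                            shuffle_scope=self.shuffle_scope)
        symbols = symbolize(raster, config)
        result = bias_corrected_issi(symbols, n_shuffles=self.n_shuffles,
                                     seed=self.random_state, config=config)
        psth = symbols.mean(axis=1)
        mi_sparsity_and_coupling(result, psth, config)
        self.result_ = result
        self.issi_ = result.issi
        self.mi_ = result.mi
        self.high_mi_bins_ = result.high_mi_bins
        self.si_mi_ = result.si_mi
        self.psth_corr_ = result.issi_psth_corr
        self.psth_slope_ = result.issi_psth_slope
        self.bin_starts_ = result.bin_starts
        return self
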