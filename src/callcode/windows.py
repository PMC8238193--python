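"""Automated detection of significant excitatory response windows.

A seed/grow/finalize scheme on a sliding-window lattice: seed windows are
found with relaxed criteria (rate above spontaneous by 6 SEM and an
FDR-corrected one-tailed t-test at p <= 0.1), grown by adding neighboring
windows under intermediate criteria (10 SEM, p <= 0.01), cleaned of bursty
trials (z > 1.96 replaced by the window mean), and accepted only if the
final window passes stringent criteria (14 SEM, p <= 1e-4, responses on at
least 60% of trials).  Nearby windows are coalesced when the merged window
still passes.  If no window is found for any stimulus, criteria are relaxed
in a fixed order (trial fraction to 50%, burst z to 2.5, window to
200/100 ms) and detection is re-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .neurons import TrialRaster
from .stats import fdr_bh


@dataclass
class SpontaneousStats:
    """Trial-wise spontaneous rate estimate pooled across stimuli.

    ``mean`` and ``sem`` come from the full pre-onset segments (one rate
    per trial) and feed the SEM-multiple rate criteria.  For the t-tests,
    ``segment_rates(width)`` re-chops the pre-onset spikes into
    window-length-matched segments so the null variance matches the
    windowed-rate variance; an unmatched null (0.5 s segments against
    0.1 s windows) would make the tests strongly anticonservative.
    """

    mean: float
    sem: float
    trialwise: np.ndarray
    #: pre-onset spike times per trial segment, in [-pre_window, 0) s
    pre_spikes: list | None = None
    pre_window: float = 0.5

    def __post_init__(self):
        if self.sem < 0:
            raise ValueError("sem must be nonnegative")
        if len(self.trialwise) == 0:
            raise ValueError("no spontaneous segments")
        self._segment_cache = {}

    def segment_rates(self, width_s: float) -> np.ndarray:
        """Spontaneous rates in segments of (at most) ``width_s`` seconds."""
        if self.pre_spikes is None:
            return self.trialwise
        width = min(float(width_s), self.pre_window)
        key = round(width, 6)
        if key not in self._segment_cache:
            n_seg = max(int(self.pre_window / width), 1)
            edges = -self.pre_window + width * np.arange(n_seg + 1)
            rates = [np.histogram(t, edges)[0] / width
                     for t in self.pre_spikes]
            self._segment_cache[key] = np.concatenate(rates)
        return self._segment_cache[key]


@dataclass(frozen=True)
class WindowConfig:
    win_ms: float = 100.0
    slide_ms: float = 50.0
    search_start_ms: float = 50.0       # post-onset
    search_end_offset_ms: float = 100.0  # post-offset
    seed_sem_mult: float = 6.0
    grow_sem_mult: float = 10.0
    final_sem_mult: float = 14.0
    p_soft: float = 0.1
    p_add: float = 0.01
    p_final: float = 1e-4
    burst_z: float = 1.96
    min_trial_frac: float = 0.6
    coalesce_gap_ms: float = 100.0

    def __post_init__(self):
        if not self.p_final < self.p_add < self.p_soft:
            raise ValueError("require p_final < p_add < p_soft")
        if not (self.seed_sem_mult < self.grow_sem_mult < self.final_sem_mult):
            raise ValueError("require seed < grow < final SEM multipliers")

    def relaxed(self, level: int) -> "WindowConfig":
        """Relaxation schedule, applied cumulatively in the stated order."""
        cfg = self
        if level >= 1:
            cfg = replace(cfg, min_trial_frac=0.5)
        if level >= 2:
            cfg = replace(cfg, burst_z=2.5)
        if level >= 3:
            cfg = replace(cfg, win_ms=200.0, slide_ms=100.0)
        return cfg


@dataclass
class ResponseWindow:
    stimulus_id: str
    start_ms: float
    end_ms: float
    mean_rate: float
    p_value: float
    responsive_trial_fraction: float

    def __post_init__(self):
        if self.start_ms >= self.end_ms:
            raise ValueError("window start must precede end")

    @property
    def length_ms(self) -> float:
        return self.end_ms - self.start_ms


def estimate_spontaneous(raster: TrialRaster) -> SpontaneousStats:
    """Mean and SEM of trial-wise spontaneous rates from pre-onset segments."""
    if raster.pre_window <= 0:
        raise ValueError("raster has no pre-onset segments")
    rates, pre_spikes = [], []
    for sid in raster.stimulus_ids:
        for trial in range(raster.n_trials):
            t = raster.spike_times(sid, trial)
            t = t[(t >= -raster.pre_window) & (t < 0.0)]
            pre_spikes.append(t)
            rates.append(len(t) / raster.pre_window)
    rates = np.asarray(rates, dtype=float)
    sem = rates.std(ddof=1) / np.sqrt(len(rates)) if len(rates) > 1 else 0.0
    return SpontaneousStats(mean=float(rates.mean()), sem=float(sem),
                            trialwise=rates, pre_spikes=pre_spikes,
                            pre_window=raster.pre_window)


def _one_tailed_p(window_rates: np.ndarray, spont_rates: np.ndarray) -> float:
    """One-tailed (greater) two-sample t-test p-value, degenerate-safe.

    Callers pass spontaneous rates from window-length-matched segments so
    that the two samples share their null variance (see SpontaneousStats).
    """
    if window_rates.std(ddof=0) == 0 and spont_rates.std(ddof=0) == 0:
        return 0.0 if window_rates.mean() > spont_rates.mean() else 1.0
    p = sps.ttest_ind(window_rates, spont_rates, alternative="greater").pvalue
    return 1.0 if np.isnan(p) else float(p)


def _burst_replaced(rates: np.ndarray, burst_z: float) -> np.ndarray:
    sd = rates.std(ddof=1) if len(rates) > 1 else 0.0
    if sd == 0:
        return rates
    z = (rates - rates.mean()) / sd
    out = rates.copy()
    out[z > burst_z] = rates.mean()
    return out


class _StimulusData:
    """Precomputed per-trial spike-count machinery for one stimulus."""

    def __init__(self, raster: TrialRaster, sid: str):
        self.sid = sid
        self.duration_ms = raster.durations[sid] * 1000.0
        self.trains = [raster.spike_times(sid, k) * 1000.0
                       for k in range(raster.n_trials)]

    def trial_rates(self, start_ms: float, end_ms: float) -> np.ndarray:
        width_s = (end_ms - start_ms) / 1000.0
        return np.array([
            np.count_nonzero((t >= start_ms) & (t < end_ms)) / width_s
            for t in self.trains])

    def trial_frac(self, start_ms: float, end_ms: float) -> float:
        present = [np.any((t >= start_ms) & (t < end_ms)) for t in self.trains]
        return float(np.mean(present))


def _final_check(data: _StimulusData, start: float, end: float,
                 spont: SpontaneousStats, cfg: WindowConfig,
                 n_comparisons: int = 1):
    """Burst-replace then test the three stringent final criteria.

    The final p-value is Bonferroni-corrected for the number of candidate
    windows the neuron was scanned with: the t-test family covers the
    whole lattice, and leaving the final threshold uncorrected would make
    the detector's false-positive rate scale with stimulus duration.
    """
    rates = _burst_replaced(data.trial_rates(start, end), cfg.burst_z)
    mean_rate = float(rates.mean())
    p_raw = _one_tailed_p(rates, spont.segment_rates((end - start) / 1000.0))
    p = min(1.0, p_raw * max(n_comparisons, 1))
    frac = data.trial_frac(start, end)
    ok = (mean_rate > spont.mean + cfg.final_sem_mult * spont.sem
          and p <= cfg.p_final and frac >= cfg.min_trial_frac)
    return ok, mean_rate, p, frac


def _detect_for_config(raster: TrialRaster, spont: SpontaneousStats,
                       cfg: WindowConfig) -> dict[str, list[ResponseWindow]]:
    per_stim: dict[str, list[ResponseWindow]] = {}
    datas = {sid: _StimulusData(raster, sid) for sid in raster.stimulus_ids}

    # --- stage 1: candidate seed windows, FDR-corrected jointly per neuron
    candidates = []  # (sid, start_ms, raw_p, passes_rate)
    for sid, data in datas.items():
        span_end = data.duration_ms + cfg.search_end_offset_ms
        start = cfg.search_start_ms
        while start + cfg.win_ms <= span_end + 1e-9:
            rates = data.trial_rates(start, start + cfg.win_ms)
            p = _one_tailed_p(rates,
                              spont.segment_rates(cfg.win_ms / 1000.0))
            rate_ok = rates.mean() > spont.mean + cfg.seed_sem_mult * spont.sem
            candidates.append((sid, start, p, rate_ok))
            start += cfg.slide_ms
    if not candidates:
        return {sid: [] for sid in raster.stimulus_ids}
    n_comparisons = len(candidates)
    raw_p = np.array([c[2] for c in candidates])
    _, p_adj = fdr_bh(raw_p, q=cfg.p_soft)
    seeds: dict[str, list[tuple[float, float]]] = {
        sid: [] for sid in raster.stimulus_ids}
    for (sid, start, _, rate_ok), pa in zip(candidates, p_adj):
        if rate_ok and pa <= cfg.p_soft:
            seeds[sid].append((pa, start))

    # --- stages 2-5 per stimulus
    for sid, data in datas.items():
        span_end = data.duration_ms + cfg.search_end_offset_ms
        accepted: list[ResponseWindow] = []
        for _, seed_start in sorted(seeds[sid]):
            if any(w.start_ms <= seed_start and seed_start + cfg.win_ms <= w.end_ms
                   for w in accepted):
                continue  # seed already covered by an accepted window
            start, end = seed_start, seed_start + cfg.win_ms

            # greedy symmetric growth; left neighbor tried first each pass
            def _try_grow(new_start, new_end, nb_start):
                if new_start < cfg.search_start_ms or new_end > span_end + 1e-9:
                    return False
                nb = data.trial_rates(nb_start, nb_start + cfg.win_ms)
                if _one_tailed_p(
                        nb, spont.segment_rates(cfg.win_ms / 1000.0)) > cfg.p_soft:
                    return False
                enl = data.trial_rates(new_start, new_end)
                if enl.mean() <= spont.mean + cfg.grow_sem_mult * spont.sem:
                    return False
                return _one_tailed_p(
                    enl, spont.segment_rates((new_end - new_start) / 1000.0)
                ) <= cfg.p_add

            grown = True
            while grown:
                grown = False
                if _try_grow(start - cfg.slide_ms, end, start - cfg.slide_ms):
                    start -= cfg.slide_ms
                    grown = True
                if _try_grow(start, end + cfg.slide_ms,
                             end + cfg.slide_ms - cfg.win_ms):
                    end += cfg.slide_ms
                    grown = True

            ok, mean_rate, p, frac = _final_check(
                data, start, end, spont, cfg, n_comparisons)
            if not ok:
                continue
            win = ResponseWindow(sid, start, end, mean_rate, p, frac)
            # resolve overlap with previously accepted windows
            overlapping = [w for w in accepted
                           if w.start_ms < win.end_ms and win.start_ms < w.end_ms]
            if overlapping:
                lo = min([win.start_ms] + [w.start_ms for w in overlapping])
                hi = max([win.end_ms] + [w.end_ms for w in overlapping])
                mok, mrate, mp, mfrac = _final_check(
                    data, lo, hi, spont, cfg, n_comparisons)
                if mok:
                    for w in overlapping:
                        accepted.remove(w)
                    accepted.append(ResponseWindow(sid, lo, hi, mrate, mp, mfrac))
                # else: keep existing windows, drop the new overlapping one
            else:
                accepted.append(win)

        # --- coalesce nearby windows when the merged window still passes
        accepted.sort(key=lambda w: w.start_ms)
        merged = True
        while merged and len(accepted) > 1:
            merged = False
            for i in range(len(accepted) - 1):
                a, b = accepted[i], accepted[i + 1]
                if b.start_ms - a.end_ms < cfg.coalesce_gap_ms:
                    ok, mrate, mp, mfrac = _final_check(
                        data, a.start_ms, b.end_ms, spont, cfg,
                        n_comparisons)
                    if ok:
                        accepted[i: i + 2] = [ResponseWindow(
                            sid, a.start_ms, b.end_ms, mrate, mp, mfrac)]
                        merged = True
                        break
        per_stim[sid] = accepted
    return per_stim


def detect_response_windows(raster: TrialRaster,
                            spont: SpontaneousStats | None = None,
                            config: WindowConfig | None = None,
                            allow_relaxation: bool = True):
    """Detect excitatory response windows for every stimulus of a raster.

    Returns ``(windows_per_stimulus, relaxation_level)``.  Relaxation is
    applied neuron-wide, only when no stimulus yields a window.
    """
    if config is None:
        config = WindowConfig()
    if spont is None:
        spont = estimate_spontaneous(raster)
    if raster.n_trials < 5:
        raise ValueError("need at least 5 trials per stimulus")
    max_level = 3 if allow_relaxation else 0
    for level in range(max_level + 1):
        result = _detect_for_config(raster, spont, config.relaxed(level))
        if any(result.values()):
            return result, level
    return result, max_level


def inhibitory_flag(raster: TrialRaster, spont: SpontaneousStats,
                    config: WindowConfig | None = None) -> bool:
    """True when any stimulus shows a predominantly suppressed response.

    Suppression = mean rate over the full analysis span below spontaneous
    by the seed SEM multiple.  Flag only; suppressed intervals never yield
    windows.
    """
    if config is None:
        config = WindowConfig()
    for sid in raster.stimulus_ids:
        data = _StimulusData(raster, sid)
        rates = data.trial_rates(config.search_start_ms,
                                 data.duration_ms + config.search_end_offset_ms)
        if rates.mean() < spont.mean - config.seed_sem_mult * spont.sem:
            return True
    return False


class ResponseWindowDetector:
    """Sklearn-style wrapper around the window-detection procedure.

    Parameters mirror :class:`WindowConfig`.  After :meth:`fit`, the
    detected windows are in ``windows_`` (dict stimulus -> list of
    :class:`ResponseWindow`), the relaxation level in ``relaxation_level_``,
    spontaneous statistics in ``spontaneous_``, and the inhibitory flag in
    ``inhibitory_``.
    """

    def __init__(self, **config_kwargs):
        self.config_kwargs = dict(config_kwargs)

    def get_params(self, deep=True):
        return dict(self.config_kwargs)

    def set_params(self, **params):
        self.config_kwargs.update(params)
        return self

    def fit(self, raster: TrialRaster, y=None):
        config = WindowConfig(**self.config_kwargs)
        self.spontaneous_ = estimate_spontaneous(raster)
        self.windows_, self.relaxation_level_ = detect_response_windows(
            raster, self.spontaneous_, config)
        self.inhibitory_ = inhibitory_flag(raster, self.spontaneous_, config)
        return self

    def to_frame(self, neuron_id: str = "") -> pd.DataFrame:
        rows = [
            (neuron_id, sid, w.start_ms, w.end_ms, w.mean_rate, w.p_value,
             w.responsive_trial_fraction, self.relaxation_level_)
            for sid, wins in self.windows_.items() for w in wins
        ]
        return pd.DataFrame(rows, columns=[
            "neuron_id", "stimulus_id", "start_ms", "end_ms", "rate", "p",
            "trial_frac", "relaxation_level"])
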