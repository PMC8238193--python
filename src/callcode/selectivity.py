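"""Call selectivity, temporal response metrics, and sparseness.

Call selectivity counts the call categories (of 8) for which at least one
exemplar evoked at least one significant response window.  Sparseness is
quantified two ways: the excess ("reduced") kurtosis of trial-wise firing
rates pooled over all stimuli in the standard analysis span, and the
activity fraction

    A = (sum_i r_i / N)^2 / sum_i (r_i^2 / N),

which ranges from 1/N (one-hot responses) to 1 (uniform, dense responses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .neurons import TrialRaster
from .windows import ResponseWindow


@dataclass
class SelectivityProfile:
    neuron_id: str
    responsive_categories: set
    call_selectivity: int
    n_windows: dict            # stimulus_id -> window count
    fractional_length: dict    # stimulus_id -> summed window length / duration
    sparseness_kurtosis: float = np.nan
    activity_fraction: float = np.nan
    best_frequency: float = np.nan
    best_level: float = np.nan
    bandwidth_oct: float = np.nan


def category_of(stimulus_id: str) -> str:
    """Category label from a 'category-exemplar' stimulus id."""
    return stimulus_id.rsplit("-", 1)[0]


def selectivity_profile(windows: dict[str, list[ResponseWindow]],
                        call_durations: dict[str, float],
                        category_map: dict[str, str] | None = None,
                        neuron_id: str = "") -> SelectivityProfile:
    """Selectivity and temporal response metrics from detected windows."""
    if category_map is None:
        category_map = {sid: category_of(sid) for sid in call_durations}
    responsive = set()
    n_windows, frac_len = {}, {}
    for sid, wins in windows.items():
        if sid not in call_durations:
            raise KeyError(f"window references unknown stimulus {sid!r}")
        n_windows[sid] = len(wins)
        total_ms = sum(w.length_ms for w in wins)
        frac_len[sid] = min(total_ms / (call_durations[sid] * 1000.0), 1.0)
        if wins:
            responsive.add(category_map[sid])
    for sid in call_durations:
        n_windows.setdefault(sid, 0)
        frac_len.setdefault(sid, 0.0)
    return SelectivityProfile(
        neuron_id=neuron_id, responsive_categories=responsive,
        call_selectivity=len(responsive), n_windows=n_windows,
        fractional_length=frac_len)


def response_kurtosis(trialwise_rates) -> float:
    """Excess kurtosis (4th standardized central moment - 3) of rates."""
    r = np.asarray(trialwise_rates, dtype=float)
    if len(r) < 4:
        raise ValueError("need at least 4 rate values")
    if r.std(ddof=0) == 0:
        raise ValueError("kurtosis undefined for zero-variance rates")
    return float(sps.kurtosis(r, fisher=True, bias=True))


def activity_fraction(trialwise_rates) -> float:
    """Activity fraction A in (0, 1]; 1/N for one-hot, 1 for uniform rates."""
    r = np.asarray(trialwise_rates, dtype=float)
    if len(r) == 0:
        raise ValueError("empty rate vector")
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    denom = np.mean(r**2)
    if denom == 0:
        raise ValueError("activity fraction undefined for all-zero rates")
    return float(np.mean(r) ** 2 / denom)


def pooled_response_rates(raster: TrialRaster,
                          start_ms: float = 50.0,
                          end_offset_ms: float = 100.0) -> np.ndarray:
    """Trial-wise rates over the single span [onset+50 ms, offset+100 ms],
    pooled across all stimuli and trials (16 x 10 = 160 values by default).
    """
    rates = []
    for sid in raster.stimulus_ids:
        t0 = start_ms / 1000.0
        t1 = raster.durations[sid] + end_offset_ms / 1000.0
        rates.append(raster.trial_rates(sid, t0, t1))
    return np.concatenate(rates)


def tone_summary(tuning, spontaneous_rate: float = 0.0):
    """Best frequency, best level, and rectangle-fit bandwidth from tuning.

    ``tuning`` is a DataFrame with columns (frequency, level, rate).  The
    bandwidth is the width in octaves of an equal-area rectangle: height
    fixed at the peak excess rate above spontaneous at the best level,
    width such that the rectangle area equals the total excess area of the
    tuning curve (integrated in octave units).  Flat tuning (no rate above
    spontaneous) yields NaN bandwidth.
    """
    mean_rates = tuning.groupby(["frequency", "level"])["rate"].mean()
    best_freq, best_level = mean_rates.idxmax()
    curve = (tuning[tuning["level"] == best_level]
             .groupby("frequency")["rate"].mean().sort_index())
    freqs = curve.index.to_numpy(dtype=float)
    if len(freqs) < 2:
        raise ValueError("tuning must cover at least 2 frequencies")
    excess = np.clip(curve.to_numpy() - spontaneous_rate, 0.0, None)
    peak = excess.max()
    if peak <= 0:
        return float(best_freq), float(best_level), float("nan")
    octaves = np.log2(freqs / freqs[0])
    area = np.trapezoid(excess, octaves)
    bandwidth = area / peak
    return float(best_freq), float(best_level), float(bandwidth)
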