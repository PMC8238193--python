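"""Ground-truth LN neurons and the inhomogeneous-Poisson spike simulator.

Three archetypes stand in for the processing stages studied:

* ``vMGB-like`` and ``L4-like``: a single spectrally tuned linear subunit
  with a low drive threshold and a smooth (softplus) output nonlinearity,
  producing dense, spectrally driven responses.
* ``L2/3-like``: ``conjunction_k`` >= 2 subunits that must be simultaneously
  super-threshold for the neuron to fire (an AND-gate over feature
  detectors), realizing a high-threshold pooling scheme.  Per-subunit
  thresholds are calibrated on the default call library so that the gate
  opens for frames belonging to at most two call categories.

Spikes are drawn from an inhomogeneous Poisson process whose rate is the
gated LN drive plus a stage-typical spontaneous rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calls import generate_call_library
from .cochleagram import (CENTER_FREQS, FRAME_STEP, N_CHANNELS, Cochleagram,
                          compute_cochleagram)

N_LAGS = 10  # 200 ms of stimulus history at the 20 ms frame step

#: stage-typical median spontaneous rates (spk/s)
STAGE_SPONT_MEDIAN = {"vMGB-like": 3.67, "L4-like": 2.31, "L2/3-like": 1.51}
STAGES = tuple(STAGE_SPONT_MEDIAN)


def lagged_design(values: np.ndarray, n_lags: int = N_LAGS) -> np.ndarray:
    """Causal lagged design matrix: X[t, c*n_lags + l] = values[c, t - l].

    Frames before stimulus onset are treated as silence (zeros).
    """
    n_ch, n_t = values.shape
    X = np.zeros((n_t, n_ch * n_lags))
    for lag in range(n_lags):
        X[lag:, lag::n_lags] = values[:, : n_t - lag].T
    return X


def _gabor_blob(center_channel: float, center_lag: float,
                sigma_ch: float, sigma_lag: float) -> np.ndarray:
    ch = np.arange(N_CHANNELS)[:, None]
    lag = np.arange(N_LAGS)[None, :]
    f = np.exp(-((ch - center_channel) ** 2 / (2 * sigma_ch**2)
                 + (lag - center_lag) ** 2 / (2 * sigma_lag**2)))
    return f / f.sum()


@dataclass
class GroundTruthNeuron:
    """A simulated LN neuron with known filter, nonlinearity, and gating."""

    neuron_id: str
    stage: str
    subunit_filters: np.ndarray       # (n_subunits, 31, 10)
    subunit_thresholds: np.ndarray    # (n_subunits,)
    conjunction_k: int
    gain: float
    drive_threshold: float
    curvature: float                  # softplus sharpness for linear stages
    spontaneous_rate: float
    best_frequency: float

    def __post_init__(self):
        if self.spontaneous_rate <= 0:
            raise ValueError("spontaneous_rate must be positive")
        if self.stage in ("vMGB-like", "L4-like") and self.conjunction_k != 1:
            raise ValueError(f"{self.stage} must have conjunction_k = 1")
        if self.stage == "L2/3-like" and self.conjunction_k < 2:
            raise ValueError("L2/3-like must have conjunction_k >= 2")

    @property
    def filter(self) -> np.ndarray:
        """Summed linear filter (31 channels x 10 lags)."""
        return self.subunit_filters.sum(axis=0)

    def drive(self, coch_values: np.ndarray) -> np.ndarray:
        """Driven firing rate (spk/s, excluding spontaneous) per frame."""
        if coch_values.shape[0] != N_CHANNELS:
            raise ValueError(
                f"cochleagram has {coch_values.shape[0]} channels, "
                f"expected {N_CHANNELS}")
        X = lagged_design(coch_values)
        d = X @ self.subunit_filters.reshape(len(self.subunit_filters), -1).T
        g = d.sum(axis=1)
        n_above = (d > self.subunit_thresholds[None, :]).sum(axis=1)
        gate = n_above >= self.conjunction_k
        if self.stage == "L2/3-like":
            driven = np.where(gate, self.gain *
                              np.clip(g - self.drive_threshold, 0, None), 0.0)
        else:
            beta = self.curvature
            driven = self.gain * np.logaddexp(0, beta * (g - self.drive_threshold)) / beta
            driven = np.where(gate, driven, 0.0)
        return driven

    def rate_profile(self, coch: Cochleagram, post_window: float = 1.0) -> np.ndarray:
        """Total rate (spont + driven) per frame over [0, duration + post]."""
        n_post = int(np.ceil(post_window / FRAME_STEP))
        padded = np.concatenate(
            [coch.values, np.zeros((N_CHANNELS, n_post))], axis=1)
        return self.spontaneous_rate + self.drive(padded)


@dataclass
class TrialRaster:
    """Trial-wise spike times for one neuron across a stimulus set.

    Spike times are in seconds relative to stimulus onset, sorted, within
    ``[-pre_window, duration + post_window]``.
    """

    neuron_id: str
    spikes: dict                      # (stimulus_id, trial) -> sorted array
    durations: dict                   # stimulus_id -> seconds
    n_trials: int = 10
    pre_window: float = 0.5
    post_window: float = 1.0
    stimulus_order: list = field(default_factory=list)

    def __post_init__(self):
        if not self.stimulus_order:
            self.stimulus_order = list(self.durations)
        for (sid, trial), t in self.spikes.items():
            t = np.asarray(t, dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError(f"unsorted spike times for {sid}/{trial}")
            hi = self.durations[sid] + self.post_window
            if len(t) and (t[0] < -self.pre_window - 1e-9 or t[-1] > hi + 1e-9):
                raise ValueError(f"spike outside recorded range for {sid}/{trial}")
            self.spikes[(sid, trial)] = t

    @property
    def stimulus_ids(self) -> list:
        return list(self.stimulus_order)

    def spike_times(self, stimulus_id: str, trial: int) -> np.ndarray:
        return self.spikes.get((stimulus_id, trial), np.empty(0))

    def count(self, stimulus_id: str, trial: int,
              t0: float, t1: float) -> int:
        t = self.spike_times(stimulus_id, trial)
        return int(np.count_nonzero((t >= t0) & (t < t1)))

    def trial_rates(self, stimulus_id: str, t0: float, t1: float) -> np.ndarray:
        """Per-trial firing rate (spk/s) in [t0, t1)."""
        width = t1 - t0
        return np.array([self.count(stimulus_id, k, t0, t1) / width
                         for k in range(self.n_trials)])

    def psth(self, stimulus_id: str, bin_s: float = FRAME_STEP,
             t0: float = 0.0, t1: float | None = None) -> np.ndarray:
        """Trial-averaged rate (spk/s) in fixed bins over [t0, t1)."""
        if t1 is None:
            t1 = self.durations[stimulus_id]
        edges = t0 + bin_s * np.arange(int(round((t1 - t0) / bin_s)) + 1)
        counts = np.zeros(len(edges) - 1)
        for k in range(self.n_trials):
            counts += np.histogram(self.spike_times(stimulus_id, k), edges)[0]
        return counts / (self.n_trials * bin_s)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.neuron_id, sid, trial, t)
            for (sid, trial), times in sorted(self.spikes.items())
            for t in times
        ]
        return pd.DataFrame(
            rows, columns=["neuron_id", "stimulus_id", "trial", "spike_time_s"])

    def to_json(self, path) -> None:
        import json

        payload = {
            "neuron_id": self.neuron_id,
            "n_trials": self.n_trials,
            "pre_window": self.pre_window,
            "post_window": self.post_window,
            "durations": self.durations,
            "stimulus_order": self.stimulus_order,
            "spikes": {f"{sid}|{trial}": times.tolist()
                       for (sid, trial), times in sorted(self.spikes.items())},
        }
        with open(path, "w") as f:
            json.dump(payload, f)

    @classmethod
    def from_json(cls, path) -> "TrialRaster":
        import json

        with open(path) as f:
            payload = json.load(f)
        spikes = {}
        for key, times in payload["spikes"].items():
            sid, trial = key.rsplit("|", 1)
            spikes[(sid, int(trial))] = np.asarray(times, dtype=float)
        return cls(neuron_id=payload["neuron_id"], spikes=spikes,
                   durations=payload["durations"],
                   n_trials=payload["n_trials"],
                   pre_window=payload["pre_window"],
                   post_window=payload["post_window"],
                   stimulus_order=payload["stimulus_order"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, durations: dict,
                   n_trials: int = 10, pre_window: float = 0.5,
                   post_window: float = 1.0) -> "TrialRaster":
        neuron_id = str(df["neuron_id"].iloc[0]) if len(df) else "unknown"
        spikes = {}
        for sid in durations:
            for trial in range(n_trials):
                sel = (df["stimulus_id"] == sid) & (df["trial"] == trial)
                spikes[(sid, trial)] = np.sort(
                    df.loc[sel, "spike_time_s"].to_numpy(dtype=float))
        return cls(neuron_id=neuron_id, spikes=spikes, durations=dict(durations),
                   n_trials=n_trials, pre_window=pre_window,
                   post_window=post_window)


def _linear_neuron(stage: str, neuron_id: str, rng: np.random.Generator,
                   spont: float) -> GroundTruthNeuron:
    bf = float(np.exp(rng.uniform(np.log(500.0), np.log(12_800.0))))
    center_ch = np.log2(bf / CENTER_FREQS[0]) * 5.0
    sigma_oct = 0.5 if stage == "vMGB-like" else 0.3
    blob = _gabor_blob(center_ch, rng.uniform(0.8, 2.2), sigma_oct * 5.0,
                       rng.uniform(0.5, 1.0))
    sub = blob[None, :, :]
    return GroundTruthNeuron(
        neuron_id=neuron_id, stage=stage, subunit_filters=sub,
        subunit_thresholds=np.array([-np.inf]), conjunction_k=1,
        gain=1.0, drive_threshold=0.0, curvature=8.0,
        spontaneous_rate=spont, best_frequency=bf)


def _subunit_drives(neuron_filters: np.ndarray,
                    coch_values: np.ndarray) -> np.ndarray:
    X = lagged_design(coch_values)
    return X @ neuron_filters.reshape(len(neuron_filters), -1).T


# raw summed drive before thresholding, used during calibration
def _drive_raw(self, coch_values: np.ndarray) -> np.ndarray:
    return _subunit_drives(self.subunit_filters, coch_values).sum(axis=1)


GroundTruthNeuron.drive_raw = _drive_raw


def _conjunction_neuron(neuron_id: str, rng: np.random.Generator,
                        cochs: list[Cochleagram],
                        categories: list[str],
                        spont: float) -> GroundTruthNeuron:
    k = int(rng.choice([2, 3], p=[0.7, 0.3]))
    target = int(rng.integers(len(cochs)))
    C = cochs[target].values
    # pick a high-energy frame (with a full 200 ms history) as the feature
    energy = C.sum(axis=0)
    valid = np.arange(N_LAGS, C.shape[1])
    top = valid[energy[valid] >= np.quantile(energy[valid], 0.75)]
    t_star = int(rng.choice(top))
    segment = C[:, t_star - N_LAGS + 1: t_star + 1]  # (31, 10), col j = lag 9-j
    ch_energy = segment.sum(axis=1).copy()
    filters, centers = [], []
    for _ in range(k):
        c = int(np.argmax(ch_energy))
        lag = N_LAGS - 1 - int(np.argmax(segment[c]))
        filters.append(_gabor_blob(c, lag, 0.25 * 5.0, 0.6))
        centers.append(c)
        lo, hi = max(0, c - 3), min(N_CHANNELS, c + 4)
        ch_energy[lo:hi] = -np.inf
    sub = np.stack(filters)

    drives = [_subunit_drives(sub, coch.values) for coch in cochs]
    # conjunction score m(t) = min_i d_i(t) / p99_i; the gate with threshold
    # scale beta (theta_i = beta * p99_i) opens exactly where m(t) > beta
    all_d = np.concatenate(drives, axis=0)
    d_ref = np.maximum(np.percentile(all_d, 99, axis=0), 1e-12)
    cat_max: dict[str, float] = {}
    for cat, d in zip(categories, drives):
        m = (d / d_ref[None, :]).min(axis=1)
        cat_max[cat] = max(cat_max.get(cat, -np.inf), float(m.max()))
    ranked = sorted(cat_max.values(), reverse=True)
    # beta just above the third-ranked category keeps <= 2 categories
    # super-threshold; the floor keeps gating temporally sparse
    beta = max(float(np.nextafter(ranked[2], np.inf)), 0.65 * ranked[0])
    thresholds = beta * d_ref
    theta_g = float(beta * d_ref.sum())
    # peak gated drive across the library sets the gain
    g_max = theta_g
    for d in drives:
        gate = np.all(d > thresholds[None, :], axis=1)
        if gate.any():
            g_max = max(g_max, float(d.sum(axis=1)[gate].max()))
    target_peak = rng.uniform(40.0, 80.0)
    gain = target_peak / max(g_max - theta_g, 1e-9)
    bf = float(CENTER_FREQS[centers[0]])
    return GroundTruthNeuron(
        neuron_id=neuron_id, stage="L2/3-like", subunit_filters=sub,
        subunit_thresholds=thresholds, conjunction_k=k, gain=gain,
        drive_threshold=theta_g, curvature=np.inf,
        spontaneous_rate=spont, best_frequency=bf)


def generate_population(n_per_stage: int, seed: int,
                        calls: list | None = None) -> list[GroundTruthNeuron]:
    """Generate ``3 * n_per_stage`` ground-truth neurons (one set per stage).

    Thresholds and gains are calibrated against the call library (the
    default library generated with the same ``seed`` unless ``calls`` is
    given), so that L2/3-like conjunction gates open for at most two call
    categories.  Deterministic given (n_per_stage, seed).
    """
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    if calls is None:
        calls = generate_call_library(seed)
    cochs = [compute_cochleagram(w) for w in calls]
    categories = [w.spec.category for w in calls]

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x909]))
    neurons: list[GroundTruthNeuron] = []
    for stage in STAGES:
        med = STAGE_SPONT_MEDIAN[stage]
        for i in range(n_per_stage):
            spont = float(np.exp(rng.normal(np.log(med), 0.35)))
            nid = f"{stage.split('-')[0]}-{i:03d}"
            if stage == "L2/3-like":
                neurons.append(
                    _conjunction_neuron(nid, rng, cochs, categories, spont))
            else:
                # threshold near the median library drive keeps responses
                # dense; gain sets the peak driven rate
                n = _linear_neuron(stage, nid, rng, spont)
                g = np.concatenate([n.drive_raw(c.values) for c in cochs])
                q = 0.5 if stage == "vMGB-like" else 0.6
                thr = float(np.quantile(g, q))
                peak = float(np.quantile(g, 0.999))
                n.drive_threshold = thr
                n.gain = rng.uniform(30.0, 60.0) / max(peak - thr, 1e-9)
                neurons.append(n)
    return neurons


def simulate_raster(neuron: GroundTruthNeuron, stimuli: list[Cochleagram],
                    trials: int, seed: int, pre_window: float = 0.5,
                    post_window: float = 1.0) -> TrialRaster:
    """Simulate an inhomogeneous-Poisson raster for one neuron.

    Rate per 20 ms frame = spontaneous + gated LN drive; the pre-onset
    window carries spontaneous activity only.  Deterministic given seed.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)), 0x5A]))
    spikes, durations, order = {}, {}, []
    for coch in stimuli:
        sid = coch.stimulus_ids[0] if coch.stimulus_ids else f"stim{len(order)}"
        duration = coch.duration
        durations[sid] = duration
        order.append(sid)
        rate = neuron.rate_profile(coch, post_window=post_window)
        n_frames = len(rate)
        for trial in range(trials):
            pre_n = rng.poisson(neuron.spontaneous_rate * pre_window)
            pre_t = np.sort(rng.uniform(-pre_window, 0.0, pre_n))
            counts = rng.poisson(rate * FRAME_STEP)
            total = int(counts.sum())
            offsets = rng.uniform(0.0, FRAME_STEP, total)
            frame_idx = np.repeat(np.arange(n_frames), counts)
            stim_t = np.sort(frame_idx * FRAME_STEP + offsets)
            stim_t = stim_t[stim_t < duration + post_window]
            spikes[(sid, trial)] = np.concatenate([pre_t, stim_t])
    return TrialRaster(neuron_id=neuron.neuron_id, spikes=spikes,
                       durations=durations, n_trials=trials,
                       pre_window=pre_window, post_window=post_window,
                       stimulus_order=order)


def simulate_tone_tuning(neuron: GroundTruthNeuron,
                         freqs: np.ndarray | None = None,
                         levels: np.ndarray | None = None,
                         trials: int = 10, seed: int = 0,
                         tone_duration: float = 0.05) -> pd.DataFrame:
    """Mean firing rate on a (frequency, level) pure-tone grid.

    Default grid: 7 octaves, 200 Hz to 25.6 kHz at 10 steps/octave (71
    frequencies), levels at 20 dB spacing.  Returns a tidy DataFrame with
    columns (frequency, level, rate).
    """
    from .calls import SAMPLE_RATE, TARGET_RMS

    if freqs is None:
        freqs = 200.0 * 2.0 ** (np.arange(71) / 10.0)
    if levels is None:
        levels = np.array([30.0, 50.0, 70.0])
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    levels = np.atleast_1d(np.asarray(levels, dtype=float))
    if freqs.size == 0 or levels.size == 0:
        raise ValueError("empty tone grid")

    rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)), 0x70]))
    fs = SAMPLE_RATE
    t = np.arange(int(tone_duration * fs)) / fs
    analysis = tone_duration + 0.2  # include offset response driven by lags
    rows = []
    for level in levels:
        amp = np.sqrt(2.0) * TARGET_RMS * 10.0 ** ((level - 70.0) / 20.0)
        for f in freqs:
            x = amp * np.sin(2 * np.pi * f * t)
            coch = compute_cochleagram(x, sample_rate=fs)
            rate = neuron.rate_profile(
                Cochleagram(values=coch.values), post_window=0.2)
            expected = float(rate.sum() * FRAME_STEP)
            counts = rng.poisson(expected, trials)
            rows.append((f, level, counts.mean() / analysis))
    return pd.DataFrame(rows, columns=["frequency", "level", "rate"])
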