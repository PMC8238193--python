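"""Cochleagram: log-spaced, rate-level-transformed spectrographic input.

The stimulus representation for receptive-field estimation: a short-time
spectrogram weighted onto 31 log-spaced channels (5 steps/octave, 250 Hz
to 16 kHz inclusive), at a 20 ms frame step, with band levels in dB passed
through a weighted sum of three sigmoidal rate-level functions standing in
for low-, medium-, and high-threshold auditory-nerve fiber classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

N_CHANNELS = 31
STEPS_PER_OCT = 5
F_LO = 250.0
FRAME_STEP = 0.020  # s
FRAME_LEN = 0.040  # s (analysis window; 50% overlap with 20 ms hop)

#: channel center frequencies, ratio 2^(1/5) between neighbors, 250 Hz..16 kHz
CENTER_FREQS = F_LO * 2.0 ** (np.arange(N_CHANNELS) / STEPS_PER_OCT)


@dataclass(frozen=True)
class RateLevelParams:
    """Three-sigmoid rate-level transformation (one per fiber class).

    Each class c maps band level L (dB re unit-amplitude tone) to
    ``saturation * expit(slope * (L - threshold))``; the output is the
    weight-normalized sum over classes.  Thresholds must be ordered
    low < medium < high.
    """

    thresholds: tuple = (-60.0, -40.0, -20.0)
    slope: float = 0.3
    saturation: float = 1.0
    weights: tuple = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        if not (self.thresholds[0] < self.thresholds[1] < self.thresholds[2]):
            raise ValueError("fiber-class thresholds must be ordered low < med < high")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "weights", tuple(w / w.sum()))

    def apply(self, level_db: np.ndarray) -> np.ndarray:
        out = np.zeros_like(level_db, dtype=float)
        for thr, w in zip(self.thresholds, self.weights):
            out += w * self.saturation * expit(self.slope * (level_db - thr))
        return out


@dataclass
class Cochleagram:
    """Channel x frame matrix of normalized auditory-nerve-like rates."""

    values: np.ndarray  # (31, n_frames), in [0, saturation]
    center_freqs: np.ndarray = field(
        default_factory=lambda: CENTER_FREQS.copy())
    frame_step: float = FRAME_STEP
    #: frame indices delimiting concatenated stimuli: starts plus final end
    stimulus_boundaries: np.ndarray = field(
        default_factory=lambda: np.array([0]))
    stimulus_ids: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_step


def _triangular_weights(fft_freqs: np.ndarray) -> np.ndarray:
    """(n_channels, n_bins) triangular weights in log2-frequency space.

    Bandwidth equals channel spacing (1/5 octave to each neighbor).
    """
    spacing = 1.0 / STEPS_PER_OCT
    with np.errstate(divide="ignore"):
        logf = np.log2(fft_freqs, where=fft_freqs > 0,
                       out=np.full_like(fft_freqs, -np.inf))
    logc = np.log2(CENTER_FREQS)
    dist = np.abs(logf[None, :] - logc[:, None]) / spacing
    w = np.clip(1.0 - dist, 0.0, None)
    return w


def compute_cochleagram(waveform, params: RateLevelParams | None = None,
                        sample_rate: int | None = None) -> Cochleagram:
    """Compute the cochleagram of one waveform.

    ``waveform`` is a CallWaveform or a plain sample array (then
    ``sample_rate`` is required).  Frame count is ``ceil(duration / 20 ms)``;
    the final frame is zero-padded.  Output is polarity-invariant and
    monotone in overall level.
    """
    if params is None:
        params = RateLevelParams()
    if hasattr(waveform, "samples"):
        x = np.asarray(waveform.samples, dtype=np.float64)
        fs = waveform.sample_rate
    else:
        x = np.asarray(waveform, dtype=np.float64)
        if sample_rate is None:
            raise ValueError("sample_rate required for plain sample arrays")
        fs = sample_rate
    if fs < 32_000:
        raise ValueError(f"sample rate {fs} Hz below the 32 kHz minimum")
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains non-finite samples")
    hop = int(round(FRAME_STEP * fs))
    nwin = int(round(FRAME_LEN * fs))
    if len(x) < hop:
        raise ValueError("waveform shorter than one 20 ms frame")

    n_frames = int(np.ceil(len(x) / hop))
    x = np.pad(x, (0, n_frames * hop + (nwin - hop) - len(x)))
    idx = np.arange(nwin)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hanning(nwin)[None, :]
    spec = np.fft.rfft(frames, axis=1)
    # normalize so a unit-amplitude sine at a bin center has |X| ~ 1
    spec /= np.hanning(nwin).sum() / 2.0
    power = np.abs(spec) ** 2

    fft_freqs = np.fft.rfftfreq(nwin, 1.0 / fs)
    tri = _triangular_weights(fft_freqs)
    band = tri @ power.T  # (channels, frames)
    with np.errstate(divide="ignore"):
        level_db = 10.0 * np.log10(band, where=band > 0,
                                   out=np.full_like(band, -np.inf))
    values = params.apply(level_db)
    ids = [waveform.stimulus_id] if hasattr(waveform, "stimulus_id") else []
    return Cochleagram(values=values,
                       stimulus_boundaries=np.array([0, n_frames]),
                       stimulus_ids=ids)


def concatenate_cochleagrams(items: list[Cochleagram]) -> Cochleagram:
    """Concatenate cochleagrams in time, recording stimulus boundaries."""
    if not items:
        raise ValueError("empty cochleagram list")
    for it in items[1:]:
        if not np.allclose(it.center_freqs, items[0].center_freqs):
            raise ValueError("mismatched channel grids")
        if it.frame_step != items[0].frame_step:
            raise ValueError("mismatched frame steps")
    values = np.concatenate([it.values for it in items], axis=1)
    bounds = [0]
    ids = []
    for it in items:
        bounds.append(bounds[-1] + it.n_frames)
        ids.extend(it.stimulus_ids)
    return Cochleagram(values=values,
                       center_freqs=items[0].center_freqs.copy(),
                       frame_step=items[0].frame_step,
                       stimulus_boundaries=np.array(bounds),
                       stimulus_ids=ids)


def save_cochleagram(coch: Cochleagram, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=coch.values)
        f.create_dataset("center_freqs", data=coch.center_freqs)
        f.create_dataset("boundaries", data=coch.stimulus_boundaries)
        f.attrs["frame_step"] = coch.frame_step
        f.attrs["stimulus_ids"] = ",".join(coch.stimulus_ids)


def load_cochleagram(path) -> Cochleagram:
    import h5py

    with h5py.File(path, "r") as f:
        ids = f.attrs.get("stimulus_ids", "")
        return Cochleagram(
            values=f["values"][()],
            center_freqs=f["center_freqs"][()],
            frame_step=float(f.attrs["frame_step"]),
            stimulus_boundaries=f["boundaries"][()],
            stimulus_ids=[s for s in str(ids).split(",") if s],
        )
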