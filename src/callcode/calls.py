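"""Synthetic conspecific-call stimuli.

Generates a library of 16 call-like waveforms (8 categories x 2 exemplars)
from parametric motifs -- harmonic stacks, FM sweeps, pulse trains, and
noise-burst sequences.  The motifs are deliberately caricatures: downstream
analyses only require spectrotemporally structured, category-distinct
stimuli, not acoustically realistic vocalizations.

All waveforms are synthesized at 100 kHz, RMS-equalized, and nominally
presented at 70 dB SPL (level 70 dB corresponds to the common RMS after
normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

SAMPLE_RATE = 100_000
#: lowest / highest permissible spectral parameter (Hz)
F_MIN, F_MAX = 200.0, 25_600.0
#: common RMS amplitude after normalization (defines the 70 dB SPL reference)
TARGET_RMS = 0.05

CATEGORIES = (
    "purr",
    "chirp",
    "wheek",
    "teeth-chatter",
    "rumble",
    "whine",
    "scream",
    "other",
)

MOTIFS = ("harmonic-stack", "FM-sweep", "pulse-train", "noise-burst-sequence")


class MotifParameterError(ValueError):
    """A motif parameter is outside the permissible spectral or temporal range."""


@dataclass(frozen=True)
class CallSpec:
    """Parametric description of one synthetic call exemplar."""

    category: str
    exemplar_id: int
    duration: float
    motif: str
    params: dict = field(default_factory=dict)
    level_db: float = 70.0

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise MotifParameterError(f"unknown category {self.category!r}")
        if self.motif not in MOTIFS:
            raise MotifParameterError(f"unknown motif {self.motif!r}")
        if not 0.4 <= self.duration <= 3.5:
            raise MotifParameterError(
                f"duration {self.duration} s outside [0.4, 3.5] s"
            )
        for key in ("f0", "f1", "carrier", "band_lo", "band_hi"):
            if key in self.params:
                f = self.params[key]
                for fi in np.atleast_1d(f):
                    if not F_MIN <= fi <= F_MAX:
                        raise MotifParameterError(
                            f"{key}={fi} Hz outside [{F_MIN}, {F_MAX}] Hz"
                        )


@dataclass
class CallWaveform:
    """One synthetic call: audio samples plus its generating spec."""

    samples: np.ndarray
    sample_rate: int
    spec: CallSpec

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def stimulus_id(self) -> str:
        return f"{self.spec.category}-{self.spec.exemplar_id}"


# Default library: two exemplars per category, differing in at least one
# motif parameter.  Durations sum to ~35 s across the 16 calls.
_DEFAULT_SPECS = [
    # purr: slow pulse train of low-frequency energy
    ("purr", 1, 2.5, "pulse-train",
     dict(pulse_rate=10.0, carrier=[400.0, 800.0], pulse_width=0.030)),
    ("purr", 2, 2.3, "pulse-train",
     dict(pulse_rate=12.0, carrier=[350.0, 700.0], pulse_width=0.030)),
    # chirp: sequences of short upward FM sweeps
    ("chirp", 1, 0.6, "FM-sweep",
     dict(f0=2000.0, f1=8000.0, syllable=0.12, gap=0.08, harmonics=2)),
    ("chirp", 2, 0.5, "FM-sweep",
     dict(f0=2500.0, f1=9000.0, syllable=0.10, gap=0.06, harmonics=2)),
    # wheek: long rising whistle
    ("wheek", 1, 1.8, "FM-sweep",
     dict(f0=1000.0, f1=4000.0, syllable=0.5, gap=0.15, harmonics=3)),
    ("wheek", 2, 2.0, "FM-sweep",
     dict(f0=1200.0, f1=3500.0, syllable=0.6, gap=0.2, harmonics=3)),
    # teeth chatter: fast broadband pulse train (low + high band)
    ("teeth-chatter", 1, 2.8, "pulse-train",
     dict(pulse_rate=18.0, carrier=[1000.0, 8000.0], pulse_width=0.018)),
    ("teeth-chatter", 2, 2.6, "pulse-train",
     dict(pulse_rate=22.0, carrier=[1200.0, 7000.0], pulse_width=0.015)),
    # rumble: low harmonic stack with slow amplitude modulation
    ("rumble", 1, 3.0, "harmonic-stack",
     dict(f0=300.0, harmonics=8, am_rate=4.0)),
    ("rumble", 2, 3.2, "harmonic-stack",
     dict(f0=350.0, harmonics=7, am_rate=5.0)),
    # whine: mid harmonic stack with rising fundamental
    ("whine", 1, 2.4, "harmonic-stack",
     dict(f0=500.0, harmonics=6, f0_end=700.0)),
    ("whine", 2, 2.2, "harmonic-stack",
     dict(f0=600.0, harmonics=5, f0_end=800.0)),
    # scream: high harmonic stack, many harmonics
    ("scream", 1, 1.5, "harmonic-stack",
     dict(f0=1200.0, harmonics=10)),
    ("scream", 2, 1.4, "harmonic-stack",
     dict(f0=1500.0, harmonics=8)),
    # other: irregular noise bursts
    ("other", 1, 3.4, "noise-burst-sequence",
     dict(band_lo=1000.0, band_hi=10000.0, burst_rate=3.0)),
    ("other", 2, 3.0, "noise-burst-sequence",
     dict(band_lo=2000.0, band_hi=12000.0, burst_rate=4.0)),
]


def default_call_specs() -> list[CallSpec]:
    return [
        CallSpec(category=c, exemplar_id=e, duration=d, motif=m, params=p)
        for c, e, d, m, p in _DEFAULT_SPECS
    ]


def _ramp(x: np.ndarray, fs: int, ramp_s: float = 0.01) -> np.ndarray:
    n = min(int(ramp_s * fs), len(x) // 2)
    if n > 0:
        env = np.sin(0.5 * np.pi * np.arange(n) / n) ** 2
        x[:n] *= env
        x[-n:] *= env[::-1]
    return x


def _harmonic_stack(spec: CallSpec, fs: int, rng: np.random.Generator):
    p = spec.params
    t = np.arange(int(spec.duration * fs)) / fs
    f0, f0_end = p["f0"], p.get("f0_end", p["f0"])
    # linear fundamental glide; phase is the integral of instantaneous freq
    finst = f0 + (f0_end - f0) * t / spec.duration
    phase0 = 2 * np.pi * np.cumsum(finst) / fs
    x = np.zeros_like(t)
    for h in range(1, int(p.get("harmonics", 6)) + 1):
        fh_max = max(f0, f0_end) * h
        if fh_max > min(F_MAX, fs / 2):
            break
        x += np.sin(h * phase0 + rng.uniform(0, 2 * np.pi)) / h
    if "am_rate" in p:
        x *= 0.6 + 0.4 * np.sin(2 * np.pi * p["am_rate"] * t + rng.uniform(0, 2 * np.pi))
    return x


def _fm_sweep(spec: CallSpec, fs: int, rng: np.random.Generator):
    p = spec.params
    n = int(spec.duration * fs)
    x = np.zeros(n)
    syl, gap = p["syllable"], p["gap"]
    n_syl = int(syl * fs)
    t_syl = np.arange(n_syl) / fs
    # logarithmic sweep from f0 to f1 over the syllable
    octs = np.log2(p["f1"] / p["f0"])
    finst = p["f0"] * 2 ** (octs * t_syl / syl)
    phase = 2 * np.pi * np.cumsum(finst) / fs
    start = 0
    while start + n_syl <= n:
        seg = np.zeros(n_syl)
        for h in range(1, int(p.get("harmonics", 1)) + 1):
            if p["f1"] * h > min(F_MAX, fs / 2):
                break
            seg += np.sin(h * phase + rng.uniform(0, 2 * np.pi)) / h
        x[start:start + n_syl] = _ramp(seg, fs, 0.005)
        start += int((syl + gap) * fs)
    return x


def _pulse_train(spec: CallSpec, fs: int, rng: np.random.Generator):
    p = spec.params
    n = int(spec.duration * fs)
    x = np.zeros(n)
    period = int(fs / p["pulse_rate"])
    n_pulse = int(p["pulse_width"] * fs)
    t_pulse = np.arange(n_pulse) / fs
    env = np.hanning(n_pulse)
    for start in range(0, n - n_pulse, period):
        pulse = np.zeros(n_pulse)
        for fc in np.atleast_1d(p["carrier"]):
            pulse += np.sin(2 * np.pi * fc * t_pulse + rng.uniform(0, 2 * np.pi))
        x[start:start + n_pulse] += env * pulse
    return x


def _noise_bursts(spec: CallSpec, fs: int, rng: np.random.Generator):
    from scipy.signal import butter, sosfilt

    p = spec.params
    n = int(spec.duration * fs)
    x = np.zeros(n)
    sos = butter(4, [p["band_lo"], p["band_hi"]], btype="band", fs=fs, output="sos")
    mean_period = 1.0 / p["burst_rate"]
    t = 0.0
    while t < spec.duration - 0.1:
        width = rng.uniform(0.08, 0.25)
        start = int(t * fs)
        stop = min(start + int(width * fs), n)
        burst = sosfilt(sos, rng.standard_normal(stop - start))
        x[start:stop] += _ramp(burst, fs, 0.005)
        t += mean_period * rng.uniform(0.7, 1.3)
    return x


_SYNTH = {
    "harmonic-stack": _harmonic_stack,
    "FM-sweep": _fm_sweep,
    "pulse-train": _pulse_train,
    "noise-burst-sequence": _noise_bursts,
}


def synthesize_call(spec: CallSpec, seed_seq: np.random.SeedSequence | int,
                    sample_rate: int = SAMPLE_RATE) -> CallWaveform:
    """Render one CallSpec to audio, apply onset/offset ramps and RMS-equalize."""
    rng = np.random.default_rng(seed_seq)
    x = _SYNTH[spec.motif](spec, sample_rate, rng)
    x = _ramp(x.astype(np.float64), sample_rate)
    rms = np.sqrt(np.mean(x**2))
    if rms <= 0:
        raise MotifParameterError(f"{spec.category}-{spec.exemplar_id}: silent render")
    x *= TARGET_RMS / rms
    return CallWaveform(samples=x, sample_rate=sample_rate, spec=spec)


def generate_call_library(seed: int, overrides: list[CallSpec] | None = None,
                          sample_rate: int = SAMPLE_RATE) -> list[CallWaveform]:
    """Generate the 16-call stimulus library (8 categories x 2 exemplars).

    Deterministic given ``seed``.  ``overrides`` replaces the default spec
    table (must still be valid CallSpecs).
    """
    specs = overrides if overrides is not None else default_call_specs()
    root = np.random.SeedSequence([int(seed), 0x5EED])
    children = root.spawn(len(specs))
    return [synthesize_call(s, c, sample_rate) for s, c in zip(specs, children)]


def write_wav(waveform: CallWaveform, path: str | Path) -> None:
    wavfile.write(str(path), waveform.sample_rate,
                  waveform.samples.astype(np.float32))


def read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    rate, data = wavfile.read(str(path))
    return rate, np.asarray(data, dtype=np.float64)
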