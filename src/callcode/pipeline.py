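"""End-to-end analysis: simulate -> cochleagram -> windows -> selectivity ->
STRF -> information -> stage statistics, with a stage-contrast report.

The report compares the three simulated stages on every metric (medians,
pairwise Cliff's delta, Dunn-Sidak p) and records the sign of each
superficial-vs-granular (L2/3-like vs L4-like) contrast.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import generate_call_library
from .cochleagram import compute_cochleagram, concatenate_cochleagrams
from .information import StimulusInformation
from .neurons import STAGES, generate_population, simulate_raster
from .selectivity import (activity_fraction, pooled_response_rates,
                          response_kurtosis, selectivity_profile)
from .stats import kruskal_dunn_sidak
from .strf import STRFModel, concatenated_psth, strf_complexity
from .windows import ResponseWindowDetector

log = logging.getLogger("callcode")

METRICS = ("call_selectivity", "sparseness_kurtosis", "activity_fraction",
           "r_mean", "strf_sparsity", "strf_kurtosis", "si_mi",
           "issi_psth_corr", "issi_psth_slope")


@dataclass
class RunConfig:
    seed: int = 1
    n_per_stage: int = 20
    trials: int = 10
    out_dir: str | None = None
    #: permutation shuffles for the STRF significance mask
    strf_shuffles: int = 1000
    #: bootstrap resamples for validation-r significance
    strf_boot: int = 200
    #: L-BFGS iteration cap per STRF fold fit
    strf_maxiter: int = 600
    #: shuffles for SSI bias correction
    info_shuffles: int = 100
    info_window_ms: float = 100.0
    window_config: dict = field(default_factory=dict)
    log_level: str = "INFO"


@dataclass
class StageContrastReport:
    medians: pd.DataFrame          # metric x stage
    pairwise: pd.DataFrame         # metric, pair, cliffs_delta, p_adj
    omnibus: pd.DataFrame          # metric, H, p
    sign_l23_vs_l4: dict           # metric -> -1 / 0 / +1 (median contrast)
    per_neuron: pd.DataFrame
    underpowered: bool = False


def analyze_neuron(neuron, raster, coch_concat, config: RunConfig) -> dict:
    """All per-neuron metrics for one simulated neuron."""
    det = ResponseWindowDetector(**config.window_config).fit(raster)
    profile = selectivity_profile(det.windows_, raster.durations,
                                  neuron_id=neuron.neuron_id)
    pooled = pooled_response_rates(raster)
    try:
        kurt = response_kurtosis(pooled)
    except ValueError:
        kurt = np.nan
    try:
        act = activity_fraction(pooled)
    except ValueError:
        act = np.nan

    psth = concatenated_psth(raster, coch_concat)
    strf = STRFModel(n_boot=config.strf_boot, n_shuffles=config.strf_shuffles,
                     maxiter=config.strf_maxiter,
                     random_state=config.seed).fit(coch_concat.values.T, psth)
    metrics = strf_complexity(strf.masked_strf_)

    info = StimulusInformation(window_ms=config.info_window_ms,
                               n_shuffles=config.info_shuffles,
                               random_state=config.seed).fit(raster)
    return {
        "neuron_id": neuron.neuron_id,
        "stage": neuron.stage,
        "spontaneous_rate": neuron.spontaneous_rate,
        "call_selectivity": profile.call_selectivity,
        "n_windows_total": sum(profile.n_windows.values()),
        "mean_fractional_length": float(
            np.mean(list(profile.fractional_length.values()))),
        "relaxation_level": det.relaxation_level_,
        "inhibitory_flag": det.inhibitory_,
        "sparseness_kurtosis": kurt,
        "activity_fraction": act,
        "r_mean": strf.r_mean_,
        "r_significant": strf.r_significant_,
        "strf_sparsity": metrics.sparsity,
        "strf_kurtosis": metrics.kurtosis,
        "si_mi": info.si_mi_,
        "issi_psth_corr": info.psth_corr_,
        "issi_psth_slope": info.psth_slope_,
    }


def run_full_analysis(config: RunConfig) -> StageContrastReport:
    """Run the complete pipeline; fully reproducible from (config, seed)."""
    logging.basicConfig(level=config.log_level)
    rootseq = np.random.SeedSequence([abs(int(config.seed)), 0xCA11])
    calls = generate_call_library(config.seed)
    cochs = [compute_cochleagram(w) for w in calls]
    coch_concat = concatenate_cochleagrams(cochs)
    neurons = generate_population(config.n_per_stage, config.seed, calls=calls)

    rows = []
    raster_frames = []
    child_seeds = rootseq.generate_state(len(neurons)) % (2**31)
    for neuron, s in zip(neurons, child_seeds):
        raster = simulate_raster(neuron, cochs, config.trials, int(s))
        rows.append(analyze_neuron(neuron, raster, coch_concat, config))
        raster_frames.append(raster.to_frame())
        log.info("analyzed %s (%s)", neuron.neuron_id, neuron.stage)
    per_neuron = pd.DataFrame(rows)

    medians = per_neuron.groupby("stage")[list(METRICS)].median().T
    underpowered = config.n_per_stage < 2
    pair_rows, omni_rows = [], []
    sign = {}
    for metric in METRICS:
        groups = {s: per_neuron.loc[(per_neuron.stage == s) & per_neuron[metric].notna(),
                                    metric].to_numpy() for s in STAGES}
        med_l23 = np.nanmedian(groups["L2/3-like"]) if len(groups["L2/3-like"]) else np.nan
        med_l4 = np.nanmedian(groups["L4-like"]) if len(groups["L4-like"]) else np.nan
        sign[metric] = int(np.sign(med_l23 - med_l4)) if np.isfinite(
            med_l23 - med_l4) else 0
        if underpowered or any(len(g) < 2 for g in groups.values()):
            omni_rows.append((metric, np.nan, np.nan))
            continue
        cmp = kruskal_dunn_sidak(groups)
        omni_rows.append((metric, cmp.statistic, cmp.p_value))
        for pair, p_adj in cmp.pairwise_p.items():
            pair_rows.append((metric, f"{pair[0]} vs {pair[1]}",
                              cmp.pairwise_delta[pair], p_adj))
    pairwise = pd.DataFrame(
        pair_rows, columns=["metric", "pair", "cliffs_delta", "p_adj"])
    omnibus = pd.DataFrame(omni_rows, columns=["metric", "H", "p"])

    report = StageContrastReport(
        medians=medians, pairwise=pairwise, omnibus=omnibus,
        sign_l23_vs_l4=sign, per_neuron=per_neuron,
        underpowered=underpowered)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_neuron.to_csv(out / "per_neuron.csv", index=False)
        pd.concat(raster_frames).to_csv(out / "rasters.csv", index=False)
        medians.to_csv(out / "report.csv")
        pairwise.to_csv(out / "pairwise.csv", index=False)
        with open(out / "report.json", "w") as f:
            json.dump({
                "config": asdict(config),
                "medians": medians.to_dict(),
                "sign_l23_vs_l4": sign,
                "omnibus": omnibus.to_dict(orient="records"),
                "pairwise": pairwise.to_dict(orient="records"),
            }, f, indent=2, default=float)
    return report


#: expected direction of the L2/3-like minus L4-like median contrast
EXPECTED_SIGNS = {
    "call_selectivity": -1,
    "sparseness_kurtosis": +1,
    "activity_fraction": -1,
    "r_mean": -1,
    "si_mi": +1,
    "issi_psth_slope": +1,
}
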