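import numpy as np
import pytest

import callcode as cc


@pytest.fixture(scope="session")
def call_library():
    return cc.generate_call_library(seed=1)


@pytest.fixture(scope="session")
def cochleagrams(call_library):
    return [cc.compute_cochleagram(w) for w in call_library]


@pytest.fixture(scope="session")
def coch_concat(cochleagrams):
    return cc.concatenate_cochleagrams(cochleagrams)


@pytest.fixture(scope="session")
def population(call_library):
    return cc.generate_population(5, seed=1, calls=call_library)


def poisson_raster(rate_fn, durations, n_trials=10, seed=0, pre=0.5, post=1.0):
    """Build a TrialRaster with per-stimulus piecewise-constant rates.

    ``rate_fn(sid)`` returns a list of (t0, t1, rate_spk_s) segments covering
    [0, duration + post]; spontaneous activity fills the pre-onset window at
    the rate of the first segment unless a ('pre', rate) entry is given.
    """
    rng = np.random.default_rng(seed)
    spikes = {}
    for sid, dur in durations.items():
        segments = rate_fn(sid)
        pre_rate = dict((s[0], s[1]) for s in segments if s[0] == "pre").get(
            "pre", segments[0][2])
        segs = [s for s in segments if s[0] != "pre"]
        for trial in range(n_trials):
            times = []
            n = rng.poisson(pre_rate * pre)
            times.append(rng.uniform(-pre, 0.0, n))
            for t0, t1, rate in segs:
                n = rng.poisson(rate * (t1 - t0))
                times.append(rng.uniform(t0, t1, n))
            spikes[(sid, trial)] = np.sort(np.concatenate(times))
    return cc.TrialRaster(neuron_id="synthetic", spikes=spikes,
                          durations=dict(durations), n_trials=n_trials,
                          pre_window=pre, post_window=post)
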