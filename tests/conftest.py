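import numpy as np
import pytest

from chemofc import lfp, synth


@pytest.fixture(scope="session")
def tapers():
    return lfp.dpss_tapers()


@pytest.fixture(scope="session")
def small_lfp_cfg():
    """Reduced-scale LFP config: short periods, few contacts."""
    return dict(contacts_per_array=4,
                period_durations=dict(pre=240.0, waiting=30.0, post=240.0))


def make_lfp_session(seed, cond="DCZ", gain=4.0, contacts=4,
                     pre=240.0, post=240.0, waiting=30.0, plan=None, **kw):
    cfg = synth.SynthConfig(seed=seed, contacts_per_array=contacts,
                            coupling_gain=gain,
                            period_durations=dict(pre=pre, waiting=waiting,
                                                  post=post), **kw)
    if plan is None:
        plan = synth.default_period_plan(cond)
    sess, truth = synth.generate_lfp_session(cfg, cond, plan)
    periods = lfp.PeriodDefinition.from_injection(
        sess.injection_s, cond, pre_s=pre, post_s=post, waiting_s=waiting)
    return cfg, sess, truth, periods


def sinusoid_trials(freq_hz, lag_rad, n_trials=50, fs=1000.0, n=4000,
                    seed=0):
    """Pairs of unit sinusoids with a fixed phase lag, random per-trial phase."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    trials = []
    for _ in range(n_trials):
        ph = rng.uniform(0, 2 * np.pi)
        x = np.sin(2 * np.pi * freq_hz * t + ph)
        y = np.sin(2 * np.pi * freq_hz * t + ph - lag_rad)
        trials.append(np.stack([x, y]))
    return np.stack(trials)
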