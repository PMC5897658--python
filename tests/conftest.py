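import numpy as np
import pytest

import channelkit as ck

WT_RATES = dict(k_d=0.17, k_r=0.69)
V558I_RATES = dict(k_d=4.06, k_r=1.12)
L825V_RATES = dict(k_d=0.11, k_r=0.83)

K_C = 200.0
K_B = 25.0


def k_o_for_po(p_o_percent: float, k_c: float = K_C) -> float:
    """Invert P_o = 100 k_o/(k_o+k_c)."""
    return k_c * p_o_percent / (100.0 - p_o_percent)


def make_block_protocol(ctrl_dur=10.0, mk_dur=30.0, mk=1.0, exchange_tau=0.012):
    return ck.ApplicationProtocol(epochs=[
        {"t_start": 0.0, "t_end": ctrl_dur, "glutamate": 1000.0, "glycine": 30.0},
        {"t_start": ctrl_dur, "t_end": ctrl_dur + mk_dur,
         "glutamate": 1000.0, "glycine": 30.0, "mk801": mk},
    ], exchange_tau=exchange_tau)


def make_block_trace(k_d, k_r, p_o_percent, noise_frac=0.0, seed=0,
                     ctrl_dur=10.0, mk_dur=30.0, sampling_rate=10000.0,
                     exchange_tau=0.012, k_u=0.0, scale=500.0):
    """Combined control + MK-801 trace with known ground-truth P_o."""
    rates = ck.RateSet(k_d=k_d, k_r=k_r, k_o=k_o_for_po(p_o_percent),
                       k_c=K_C, k_b=K_B, k_u=k_u)
    protocol = make_block_protocol(ctrl_dur, mk_dur, exchange_tau=exchange_tau)
    noise = ck.NoiseSpec(sd=noise_frac * scale, seed=seed)
    return ck.generate_whole_cell_trace(rates, protocol, scale=scale,
                                        sampling_rate=sampling_rate, noise=noise)


@pytest.fixture(scope="session")
def wt_rates():
    return ck.RateSet(k_o=27.8, k_c=K_C, k_b=K_B, **WT_RATES)


@pytest.fixture(scope="session")
def v558i_rates():
    return ck.RateSet(k_o=k_o_for_po(0.66), k_c=K_C, k_b=K_B, **V558I_RATES)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
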