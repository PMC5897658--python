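"""MK-801 block-onset fitting and the two-step open-probability procedure."""

import numpy as np
import pytest

import channelkit as ck
from channelkit.model_core import O, steady_state
from channelkit.model_core import _simulate_segment
from conftest import make_block_trace, make_block_protocol, k_o_for_po, K_C, K_B


def fast_trace(k_d, k_r, p_o, **kw):
    """Reduced problem size for unit tests (2 kHz, shorter epochs)."""
    kw.setdefault("sampling_rate", 2000.0)
    kw.setdefault("ctrl_dur", 8.0)
    kw.setdefault("mk_dur", 15.0)
    return make_block_trace(k_d, k_r, p_o, **kw)


class TestFitPo:
    def test_noiseless_wt_round_trip(self):
        desens, po = ck.two_step_pipeline(fast_trace(0.17, 0.69, 12.2))
        assert po.converged
        assert po.p_o == pytest.approx(12.2, abs=0.3)
        # Eq-5 consistency between the stored k_o and P_o is exact
        assert po.p_o == pytest.approx(100 * po.k_o / (po.k_o + K_C), rel=1e-12)

    def test_noiseless_low_po_round_trip(self):
        _, po = ck.two_step_pipeline(fast_trace(4.06, 1.12, 0.66, mk_dur=25.0))
        assert po.p_o == pytest.approx(0.66, abs=0.1)

    def test_pinned_scale_matches_free_scale(self):
        trace = fast_trace(0.17, 0.69, 10.0)
        _, free = ck.two_step_pipeline(trace, scale_mode="free")
        _, pinned = ck.two_step_pipeline(trace, scale_mode="pinned")
        assert pinned.p_o == pytest.approx(free.p_o, rel=0.01)

    def test_zero_opening_rate_flags_nonconvergence(self):
        rates = ck.RateSet(k_d=0.17, k_r=0.69, k_o=0.0, k_c=K_C, k_b=K_B)
        prot = make_block_protocol(ctrl_dur=2.0, mk_dur=5.0)
        t = np.arange(0, 7.0, 5e-4)
        # no openings -> no current; emulate a recorded flat leak-subtracted trace
        trace = ck.CurrentTrace(t=t, i=np.full_like(t, -20.0), sampling_rate=2000.0,
                                protocol=prot)
        desens = ck.DesensFit(i_p=-20.0, i_ss=-20.0, tau_d=1.0, d=0.0,
                              k_d=0.0, k_r=1.0)
        with pytest.warns(UserWarning, match="does not decay"):
            po = ck.fit_po(trace, desens)
        assert not po.converged

    def test_missing_mk_epoch_raises(self):
        rates = ck.RateSet(k_d=0.17, k_r=0.69, k_o=27.8, k_c=K_C)
        prot = ck.ApplicationProtocol(
            epochs=[{"t_start": 0.0, "t_end": 2.0, "glutamate": 1000.0}])
        tr = ck.generate_whole_cell_trace(rates, prot, sampling_rate=2000.0)
        with pytest.raises(ck.ProtocolError):
            ck.fit_po(tr)

    def test_missing_control_epoch_raises(self):
        rates = ck.RateSet(k_d=0.17, k_r=0.69, k_o=27.8, k_c=K_C, k_b=K_B)
        prot = ck.ApplicationProtocol(
            epochs=[{"t_start": 0.0, "t_end": 2.0, "glutamate": 1000.0, "mk801": 1.0}])
        tr = ck.generate_whole_cell_trace(rates, prot, sampling_rate=2000.0)
        with pytest.raises(ck.ProtocolError, match="control"):
            ck.two_step_pipeline(tr)

    def test_block_onset_rate_increases_with_k_o(self):
        """In the slow-block regime the initial block rate scales with
        k_b·[MK]·P_o, so the time to half-block shrinks as k_o grows."""
        halves = []
        for k_o in (1.0, 5.0, 27.8, 100.0):
            rates = ck.RateSet(k_d=0.17, k_r=0.69, k_o=k_o, k_c=K_C, k_b=K_B)
            p0 = steady_state(rates, 0.0).p
            t = np.arange(0, 60.0, 1e-3)
            occ, _ = _simulate_segment(rates, 0.0, 1.0, 0.0, t, p0)
            p_o = occ[:, O]
            half = t[np.nonzero(p_o <= p_o[0] / 2)[0][0]]
            halves.append(half)
        assert all(a > b for a, b in zip(halves, halves[1:]))


class TestFitPoWithUnblock:
    def test_reduces_to_irreversible_case(self):
        # step-1 rates supplied exactly, isolating the k_u -> 0 reduction
        # from the small bias of the desensitization stage
        trace = fast_trace(0.17, 0.69, 12.2)
        k_d, k_r = 0.17, 0.69
        d = k_d / (k_d + k_r)
        desens = ck.DesensFit(i_p=-500.0, i_ss=-500.0 * (1 - d),
                              tau_d=1 / (k_d + k_r), d=d, k_d=k_d, k_r=k_r)
        po0 = ck.fit_po(trace, desens)
        pou = ck.fit_po_with_unblock(trace, desens)
        assert pou.k_u < 1e-3
        assert pou.p_o == pytest.approx(po0.p_o, rel=0.01)

    def test_recovers_unblocking_rate(self):
        trace = fast_trace(0.17, 0.69, 12.2, k_u=0.5, mk_dur=25.0)
        _, po = ck.two_step_pipeline(trace, ku_free=True)
        assert po.k_u == pytest.approx(0.5, rel=0.05)
        assert po.p_o == pytest.approx(12.2, rel=0.05)

    def test_larger_k_u_leaves_larger_plateau(self):
        plateaus = []
        for k_u in (0.0, 0.2, 1.0):
            rates = ck.RateSet(k_d=0.17, k_r=0.69, k_o=27.8, k_c=K_C, k_b=K_B, k_u=k_u)
            p0 = steady_state(rates, 0.0).p
            t = np.arange(0, 40.0, 1e-3)
            occ, _ = _simulate_segment(rates, 0.0, 1.0, 0.0, t, p0)
            plateaus.append(occ[-1, O])
        assert plateaus[0] < plateaus[1] < plateaus[2]
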