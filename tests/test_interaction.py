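"""Advisors, joint responses, and the two interaction protocols."""

import numpy as np
import pytest

from biasloop._rng import spawn_rng
from biasloop.agents import EmotionAgentState, RdkAgentState
from biasloop.interaction import (
    AdvisorSpec,
    ProtocolConfig,
    advisor_response,
    joint_response,
    latin_square_orders,
    run_emotion_session,
    run_rdk_session,
)
from biasloop.stimuli import MORE_SAD, build_balanced_set, make_rdk_schedule


class TestAdvisors:
    def test_accurate_echoes_evidence(self, rng):
        spec = AdvisorSpec("accurate")
        for ev in make_rdk_schedule():
            assert advisor_response(spec, ev, rng) == ev

    def test_biased_mean_offset_over_session(self):
        # three 30-trial blocks; sampling error at n = 90 covers the nominal 24.5
        rng = spawn_rng(17, "biased_offset")
        spec = AdvisorSpec("biased")
        schedule = make_rdk_schedule() * 3
        offsets = [advisor_response(spec, ev, rng) - ev
                   for ev in schedule if ev <= 51]   # avoid clipped trials
        se = 49 / np.sqrt(12) / np.sqrt(len(offsets))
        assert np.mean(offsets) == pytest.approx(24.5, abs=4 * se)

    def test_noisy_error_matches_folded_normal(self):
        # pre-clipping mean |error| of zero-mean Gaussian = sd * sqrt(2/pi)
        rng = spawn_rng(23, "noisy")
        spec = AdvisorSpec("noisy", clip_range=(-1e9, 1e9))
        errs = [abs(advisor_response(spec, 50.0, rng) - 50.0) for _ in range(10_000)]
        expected = 28.46 * np.sqrt(2 / np.pi)
        assert np.mean(errs) == pytest.approx(expected, abs=1.0)

    def test_biased_and_noisy_errors_match_within_2pp(self):
        # the two partner algorithms are error-matched by construction
        rng = spawn_rng(29, "match")
        unclipped = dict(clip_range=(-1e9, 1e9))
        biased = [abs(advisor_response(AdvisorSpec("biased", **unclipped), 50.0, rng) - 50.0)
                  for _ in range(10_000)]
        noisy = [abs(advisor_response(AdvisorSpec("noisy", **unclipped), 50.0, rng) - 50.0)
                 for _ in range(10_000)]
        assert abs(np.mean(biased) - np.mean(noisy)) < 2.0

    def test_clipping_keeps_scale(self, rng):
        spec = AdvisorSpec("noisy", noise_sd=80.0)
        vals = [advisor_response(spec, ev, rng) for ev in (0, 50, 100) for _ in range(200)]
        assert min(vals) >= 0.0 and max(vals) <= 100.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            AdvisorSpec("oracle")


class TestJointResponse:
    def test_printed_worked_example(self):
        assert joint_response(53, 73, 0.4) == pytest.approx(65.0)

    def test_weight_extremes(self):
        assert joint_response(20, 80, 1.0) == 20.0
        assert joint_response(20, 80, 0.0) == 80.0

    @pytest.mark.parametrize("w", [-0.1, 1.1])
    def test_weight_domain(self, w):
        with pytest.raises(ValueError):
            joint_response(50, 50, w)


def test_latin_square_orders_are_the_three_rotations():
    orders = latin_square_orders()
    assert orders == [
        ("accurate", "biased", "noisy"),
        ("biased", "noisy", "accurate"),
        ("noisy", "accurate", "biased"),
    ]
    for kind in ("accurate", "biased", "noisy"):
        assert sorted(o.index(kind) for o in orders) == [0, 1, 2]


class TestEmotionSession:
    protocol = ProtocolConfig(baseline_blocks=1, interaction_blocks=2, trials_per_block=30)

    def _arrays(self, seed=31):
        return build_balanced_set(50, spawn_rng(seed, "emo_arrays"))[:90]

    def test_agreeing_advisor_rarely_changes(self):
        rng = spawn_rng(37, "agree")
        agent = EmotionAgentState(sensitivity_sd=0.0, learning_rate=0.0)
        log = run_emotion_session(agent, lambda a, r: a.objective_class,
                                  self.protocol, self._arrays(), rng)
        inter = log[log.phase == "interaction"]
        assert (inter.own_class == inter.partner_class).all()
        assert inter.changed.mean() <= 0.02

    def test_non_learning_agent_has_flat_criterion(self):
        rng = spawn_rng(41, "flat")
        agent = EmotionAgentState(sensitivity_sd=8.0, learning_rate=0.0)
        log = run_emotion_session(agent, lambda a, r: MORE_SAD if r.random() < 0.5 else 0,
                                  self.protocol, self._arrays(), rng)
        assert (log.criterion == 0.0).all()

    def test_learning_agent_drifts_toward_sad_partner(self):
        protocol = ProtocolConfig(baseline_blocks=1, interaction_blocks=5,
                                  trials_per_block=50)
        first, last = [], []
        for i in range(30):
            rng = spawn_rng(43, "drift", i)
            agent = EmotionAgentState(sensitivity_sd=9.7, learning_rate=0.1)
            arrays = build_balanced_set(160, rng)[: protocol.n_trials]
            log = run_emotion_session(
                agent, lambda a, r: MORE_SAD if r.random() < 0.65 else 0,
                protocol, arrays, rng,
            )
            inter = log[log.phase == "interaction"]
            by_block = (inter.own_class == "more_sad").groupby(inter.block).mean()
            first.append(by_block.iloc[0])
            last.append(by_block.iloc[-1])
        assert np.mean(last) > np.mean(first)

    def test_change_flag_consistency(self):
        rng = spawn_rng(47, "flags")
        agent = EmotionAgentState(sensitivity_sd=8.0)
        log = run_emotion_session(agent, lambda a, r: MORE_SAD,
                                  self.protocol, self._arrays(), rng)
        base = log[log.phase == "baseline"]
        assert base.changed.isna().all()
        inter = log[log.phase == "interaction"]
        changed = inter[inter.changed.astype(bool)]
        assert (changed.final_class == changed.partner_class).all()
        kept = inter[~inter.changed.astype(bool)]
        assert (kept.final_class == kept.own_class).all()

    def test_insufficient_arrays_rejected(self, rng):
        agent = EmotionAgentState()
        with pytest.raises(ValueError):
            run_emotion_session(agent, lambda a, r: MORE_SAD, self.protocol,
                                self._arrays()[:10], rng)


class TestRdkSession:
    def test_perfect_agent_accurate_partner_zero_error(self):
        rng = spawn_rng(53, "perfect")
        agent = RdkAgentState(offset=0.0, noise_sd=0.0, learning_rate=0.01)
        log = run_rdk_session(agent, [AdvisorSpec("accurate")] * 3, rng)
        assert np.allclose(log.own_estimate, log.evidence)
        inter = log[log.phase == "interaction"]
        assert np.allclose(inter.joint_estimate, inter.evidence)

    def test_weight_committed_before_reveal(self):
        """w is a pre-reveal policy: identical across trials regardless of
        what the partner later returns, and the joint response is the exact
        weighted mean of the logged components."""
        rng = spawn_rng(59, "commit")
        agent = RdkAgentState(offset=2.0, noise_sd=5.0, weight_on_self=0.4)
        log = run_rdk_session(agent, [AdvisorSpec("biased"), AdvisorSpec("noisy")], rng)
        inter = log[log.phase == "interaction"]
        assert (inter.w == 0.4).all()
        recomputed = 0.4 * inter.own_estimate + 0.6 * inter.partner_estimate
        assert np.allclose(inter.joint_estimate, recomputed)

    def test_each_block_presents_full_schedule(self):
        rng = spawn_rng(61, "blocks")
        log = run_rdk_session(RdkAgentState(), [AdvisorSpec("accurate")] * 2, rng)
        for _, block in log.groupby("block"):
            assert sorted(block.evidence) == sorted(make_rdk_schedule())

    def test_offset_drifts_upward_with_biased_partner(self):
        rng = spawn_rng(67, "drift")
        agent = RdkAgentState(offset=0.0, noise_sd=8.0, learning_rate=0.01)
        log = run_rdk_session(agent, [AdvisorSpec("biased")] * 5, rng)
        offsets = log.groupby("block")["offset"].mean()
        assert offsets.iloc[-1] > offsets.iloc[1] > offsets.iloc[0]
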