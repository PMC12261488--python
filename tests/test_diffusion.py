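import math

import numpy as np
import pytest

from tcrdiff._autograd import Tensor
from tcrdiff.corpus import BindingPair, TcrRecord
from tcrdiff.diffusion import (
    EarlyStopping,
    GeneratorConfig,
    ScheduleError,
    UNet,
    ancestral_sample,
    diffusion_loss,
    forward_sample,
    linear_schedule,
    load_checkpoint,
    reverse_step,
    save_checkpoint,
    sinusoidal_embed,
    step_kernel_sample,
    train_generator,
)
from tcrdiff.seq_codec import one_hot_encode


class ZeroNet:
    """Stub denoiser predicting no noise."""

    def __call__(self, x, t, cond):
        return Tensor(np.zeros_like(np.asarray(x, dtype=float)))


class TestLinearSchedule:
    def test_endpoints_exact(self):
        s = linear_schedule(10, 1e-4, 0.1)
        assert s.beta[0] == 1e-4
        assert s.beta[-1] == 0.1

    def test_alpha_bar_matches_direct_product(self):
        s = linear_schedule(10, 1e-4, 0.1)
        direct = math.prod(1.0 - b for b in s.beta)
        assert abs(s.alpha_bar[-1] - direct) < 1e-12
        assert abs(s.alpha_bar[-1] - 0.59506) < 1e-4

    def test_algebraic_invariants(self):
        s = linear_schedule(25, 1e-4, 0.05)
        assert np.all(s.alpha == 1.0 - s.beta)
        assert np.all(np.diff(s.beta) >= 0)
        assert np.all(np.diff(s.alpha_bar) < 0)
        ratios = s.alpha_bar[1:] / s.alpha_bar[:-1]
        assert np.allclose(ratios, s.alpha[1:], rtol=0, atol=1e-15)

    @pytest.mark.parametrize("args", [(0, 1e-4, 0.1), (10, 0.0, 0.1), (10, 0.2, 0.1), (10, 1e-4, 1.0)])
    def test_invalid_bounds(self, args):
        with pytest.raises(ScheduleError):
            linear_schedule(*args)


class TestForwardProcess:
    def test_noiseless_limit(self):
        s = linear_schedule(10)
        x0 = one_hot_encode("ATGTGG", 9).matrix.T
        xt = forward_sample(x0, 4, s, np.zeros_like(x0))
        assert np.allclose(xt, np.sqrt(s.alpha_bar[3]) * x0)

    def test_shape_mismatch(self):
        s = linear_schedule(10)
        with pytest.raises(ValueError):
            forward_sample(np.zeros((2, 3)), 1, s, np.zeros((3, 2)))

    def test_step_kernel_noiseless(self):
        s = linear_schedule(10)
        x = np.ones((4, 6))
        assert np.allclose(step_kernel_sample(x, 3, s, np.zeros_like(x)),
                           np.sqrt(1.0 - s.beta[2]) * x)

    def test_step_kernel_small_beta_is_near_identity(self):
        s = linear_schedule(5, 1e-10, 1e-9)
        x = np.ones((2, 2))
        assert np.allclose(step_kernel_sample(x, 1, s, np.zeros_like(x)), x, atol=1e-9)

    def test_per_sample_timesteps_broadcast(self):
        s = linear_schedule(10)
        x0 = np.ones((3, 4, 6))
        eps = np.zeros_like(x0)
        xt = forward_sample(x0, np.array([1, 5, 10]), s, eps)
        for i, t in enumerate([1, 5, 10]):
            assert np.allclose(xt[i], np.sqrt(s.alpha_bar[t - 1]))


class TestSinusoidalEmbed:
    def test_t_zero(self):
        v = sinusoidal_embed(0, 8)
        assert np.allclose(v[:4], 0.0)
        assert np.allclose(v[4:], 1.0)

    def test_bounded(self):
        for t in range(0, 50):
            v = sinusoidal_embed(t, 64)
            assert np.all(np.abs(v) <= 1.0)

    def test_distinct_timesteps(self):
        vs = [sinusoidal_embed(t, 64) for t in range(1, 11)]
        for i in range(10):
            for j in range(i + 1, 10):
                assert not np.allclose(vs[i], vs[j])

    def test_odd_dim_rejected(self):
        with pytest.raises(ValueError):
            sinusoidal_embed(3, 7)


class TestDiffusionLoss:
    def setup_method(self):
        self.s = linear_schedule(10)
        self.x0 = one_hot_encode("ATGTGGGCC", 12).matrix.T[None]
        self.cond = np.zeros(1024)

    def test_oracle_network_gives_zero(self):
        rng = np.random.default_rng(0)
        eps = rng.standard_normal(self.x0.shape)

        class Oracle:
            def __call__(self, x, t, cond):
                return Tensor(eps)

        loss = diffusion_loss(Oracle(), self.x0, self.cond, 5, eps, self.s)
        assert float(loss.data) == 0.0

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        eps = rng.standard_normal(self.x0.shape)
        loss = diffusion_loss(ZeroNet(), self.x0, self.cond, 3, eps, self.s)
        assert float(loss.data) >= 0.0


class TestReverseProcess:
    def test_zero_noise_step_formula(self):
        s = linear_schedule(10)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 4, 6))
        for t in (1, 5, 10):
            out = reverse_step(x, t, np.zeros_like(x), s, z=0.0)
            assert np.allclose(out, x / np.sqrt(s.alpha[t - 1]))

    def test_sampler_shapes_and_determinism(self):
        s = linear_schedule(10)
        a = ancestral_sample(ZeroNet(), np.zeros(1024), 3, s, seed=7, l_max=12)
        b = ancestral_sample(ZeroNet(), np.zeros(1024), 3, s, seed=7, l_max=12)
        assert len(a) == 3
        assert all(m.shape == (12, 4) for m in a)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_different_seed_differs(self):
        s = linear_schedule(10)
        a = ancestral_sample(ZeroNet(), np.zeros(1024), 1, s, seed=7, l_max=12)
        b = ancestral_sample(ZeroNet(), np.zeros(1024), 1, s, seed=8, l_max=12)
        assert not np.array_equal(a[0], b[0])


class TestEarlyStopping:
    def test_stops_after_third_subthreshold_epoch(self):
        # improvements: 0.01, 0.0005, 0.0004, 0.0003 — halt on the third
        losses = [0.5, 0.49, 0.4895, 0.4891, 0.4888]
        stopper = EarlyStopping(delta=0.001, patience=3)
        decisions = [stopper.update(l) for l in losses]
        assert decisions == [False, False, False, False, True]

    def test_streak_resets_on_improvement(self):
        stopper = EarlyStopping(delta=0.001, patience=3)
        for loss in [0.5, 0.4999, 0.4998, 0.49, 0.4899, 0.4898]:
            assert not stopper.update(loss)


def _tiny_pairs(n=6):
    cdr3b = "CASSLGQF"
    from tcrdiff.seq_codec import back_translate

    return [
        BindingPair(
            tcr=TcrRecord(cdr3b=cdr3b, nt=back_translate(cdr3b), epitope="GILGFVFTL"),
            epitope="GILGFVFTL",
            label=1,
        )
        for _ in range(n)
    ]


def tiny_config(**kw):
    base = dict(channels=(8, 16), max_epochs=5, batch_size=4, lr=1e-3,
                early_stop_delta=0.0, early_stop_patience=10 ** 9, seed=0)
    base.update(kw)
    return GeneratorConfig(**base)


class TestTrainGenerator:
    def test_deterministic_trace(self):
        a = train_generator(_tiny_pairs(), config=tiny_config())[2]
        b = train_generator(_tiny_pairs(), config=tiny_config())[2]
        assert a == b

    def test_overfits_single_sequence(self):
        net, s, trace = train_generator(
            _tiny_pairs(20), config=tiny_config(max_epochs=30, lr=3e-3)
        )
        assert trace[-1] < trace[0]

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            train_generator([], config=tiny_config())

    def test_early_stopping_halts_training(self):
        cfg = tiny_config(max_epochs=50, early_stop_delta=10.0, early_stop_patience=2)
        _, _, trace = train_generator(_tiny_pairs(), config=cfg)
        # improvement can never reach delta=10: baseline epoch + patience epochs
        assert len(trace) == 3


class TestUNetContract:
    def test_output_matches_input_shape(self):
        cfg = tiny_config()
        net = UNet(cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((3, 4, cfg.l_max))
        out = net(x, 2, np.zeros(1024))
        assert out.data.shape == x.shape

    def test_bottleneck_width_is_channel_ladder_top(self):
        cfg = GeneratorConfig()
        assert cfg.bottleneck == 512
        tiny = tiny_config()
        net = UNet(tiny, np.random.default_rng(0))
        h = net.encode(np.zeros((2, 4, tiny.l_max)), 0, np.zeros(1024))
        assert h.data.shape[1] == tiny.bottleneck

    def test_length_not_divisible_rejected(self):
        with pytest.raises(ValueError):
            UNet(GeneratorConfig(l_max=70, channels=(8, 16, 32)), np.random.default_rng(0))


def test_checkpoint_round_trip(tmp_path):
    cfg = tiny_config()
    net, schedule, _ = train_generator(_tiny_pairs(), config=cfg)
    path = str(tmp_path / "gen.ckpt")
    save_checkpoint(net, schedule, path)
    net2, schedule2 = load_checkpoint(path)
    assert np.array_equal(schedule.beta, schedule2.beta)
    x = np.random.default_rng(3).standard_normal((2, 4, cfg.l_max))
    assert np.allclose(net(x, 1, np.zeros(1024)).data, net2(x, 1, np.zeros(1024)).data)
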