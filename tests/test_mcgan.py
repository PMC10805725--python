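"""Multi-channel GAN contracts: channel plumbing, schedule, training, stitching."""

import dataclasses

import numpy as np
import pytest

from pars_stain import mcgan
from pars_stain.mcgan import (
    MCGANConfig,
    PatchGrid,
    build_models,
    colorize,
    discard_surplus_channels,
    expand_target_channels,
    lr_for_epoch,
    tent_weights,
    train,
)
from pars_stain.signals import ChannelImage, ChannelStack, RegisteredPair, RGBImage


def tiny_cfg(**kw):
    base = dict(
        n_input_channels=4,
        patch_size=16,
        max_epochs=2,
        downsampling_depth=2,
        ngf=4,
        ndf=4,
        n_disc_layers=2,
        seed=0,
    )
    base.update(kw)
    return MCGANConfig(**base)


def random_pairs(rng, n_pairs, n_channels=4, size=16):
    pairs = []
    for _ in range(n_pairs):
        chans = [
            ChannelImage(f"c{i}", rng.random((size, size))) for i in range(n_channels)
        ]
        truth = RGBImage(rng.random((size, size, 3)))
        pairs.append(RegisteredPair(ChannelStack(chans), truth))
    return pairs


class TestChannelPlumbing:
    def test_expand_identity_for_three(self, rng):
        rgb = RGBImage(rng.random((5, 5, 3)))
        out = expand_target_channels(rgb, 3)
        assert np.array_equal(out, rgb.values)

    def test_expand_duplicates_blue(self, rng):
        rgb = RGBImage(rng.random((5, 5, 3)))
        out = expand_target_channels(rgb, 5)
        assert out.shape == (5, 5, 5)
        assert np.array_equal(out[:, :, :3], rgb.values)
        assert np.array_equal(out[:, :, 3], rgb.values[:, :, 2])
        assert np.array_equal(out[:, :, 4], rgb.values[:, :, 2])

    def test_expand_rejects_fewer_than_three(self, rng):
        with pytest.raises(ValueError, match="RGB"):
            expand_target_channels(RGBImage(rng.random((2, 2, 3))), 2)

    def test_discard_keeps_first_three_and_clips(self, rng):
        img = rng.standard_normal((4, 4, 6))
        out = discard_surplus_channels(img)
        assert out.values.shape == (4, 4, 3)
        assert np.array_equal(out.values, np.clip(img[:, :, :3], 0, 1))
        again = discard_surplus_channels(out.values)
        assert np.array_equal(again.values, out.values)  # idempotent

    def test_discard_rejects_fewer_than_three(self, rng):
        with pytest.raises(ValueError):
            discard_surplus_channels(rng.random((4, 4, 2)))

    def test_expand_discard_roundtrip_bit_exact(self, rng):
        rgb = RGBImage(rng.random((6, 7, 3)))
        for n in (3, 4, 6):
            back = discard_surplus_channels(expand_target_channels(rgb, n))
            assert np.array_equal(back.values, rgb.values)


class TestPatchGrid:
    def test_grid_covers_image_with_clamped_border(self):
        g = PatchGrid.from_shape(100, 70, 32, 16)
        covered = np.zeros((100, 70), dtype=bool)
        for r, c in g.coords:
            covered[r : r + 32, c : c + 32] = True
        assert covered.all()
        assert max(r for r, _ in g.coords) == 100 - 32
        assert max(c for _, c in g.coords) == 70 - 32

    def test_stride_must_not_exceed_patch(self):
        with pytest.raises(ValueError, match="stride"):
            PatchGrid.from_shape(64, 64, 16, 17)

    def test_overlap_half_gives_half_stride(self):
        g = PatchGrid.from_overlap(64, 64, 32, 0.5)
        assert g.stride == 16


class TestConfigAndSchedule:
    def test_patch_depth_compatibility_checked_before_training(self):
        cfg = tiny_cfg(patch_size=18)  # not a multiple of 2**depth = 4
        with pytest.raises(ValueError, match="multiple"):
            build_models(cfg)

    def test_lr_schedule_matches_closed_form_table(self):
        cfg = tiny_cfg(max_epochs=20, lr=1e-3, lr_decay_interval=5)
        # decay starts at epoch 10; 2 whole intervals -> factors 2/3, 1/3
        expected = [1e-3] * 10 + [2e-3 / 3] * 5 + [1e-3 / 3] * 5
        got = [lr_for_epoch(cfg, e) for e in range(20)]
        assert got == pytest.approx(expected)

    def test_lr_never_negative_and_monotone(self):
        cfg = tiny_cfg(max_epochs=37, lr_decay_interval=4)
        lrs = [lr_for_epoch(cfg, e) for e in range(37)]
        assert all(x >= 0 for x in lrs)
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))


class TestBuildModels:
    def test_generator_preserves_channel_count(self, rng):
        cfg = tiny_cfg()
        bundle = build_models(cfg)
        x = rng.standard_normal((1, 4, 16, 16))
        y, _ = bundle.generator_AB.forward(x)
        assert y.shape == x.shape

    def test_discriminator_is_patchwise(self, rng):
        bundle = build_models(tiny_cfg())
        p, _ = bundle.discriminator_B.forward(rng.standard_normal((1, 4, 16, 16)))
        assert p.shape[1] == 1
        assert p.shape[2] > 1 and p.shape[3] > 1  # score map, not a scalar

    def test_same_seed_gives_identical_parameters(self):
        b1 = build_models(tiny_cfg())
        b2 = build_models(tiny_cfg())
        for p1, p2 in zip(b1.generator_AB.params(), b2.generator_AB.params()):
            assert np.array_equal(p1.value, p2.value)


class TestTraining:
    def test_smoke_run_records_finite_losses(self, rng):
        pairs = random_pairs(rng, 8)
        bundle = train(pairs, tiny_cfg())
        h = bundle.history
        assert len(h["generator"]) == 2
        assert len(h["discriminator"]) == 2
        assert len(h["cycle"]) == 2
        for key in ("generator", "discriminator", "cycle"):
            assert np.all(np.isfinite(h[key]))

    def test_reproducible_loss_history(self, rng):
        pairs = random_pairs(rng, 4)
        h1 = train(pairs, tiny_cfg()).history
        h2 = train(pairs, tiny_cfg()).history
        assert h1 == h2

    def test_identity_task_reduces_cycle_loss(self, rng):
        # truth = first three input channels: the mapping is learnable, so
        # the smoothed cycle loss must drop below its first-epoch value
        pairs = []
        for _ in range(6):
            chans = [ChannelImage(f"c{i}", rng.random((16, 16))) for i in range(4)]
            truth = RGBImage(np.stack([c.values for c in chans[:3]], axis=2))
            pairs.append(RegisteredPair(ChannelStack(chans), truth))
        bundle = train(pairs, tiny_cfg(max_epochs=6, supervised_weight=10.0))
        cyc = bundle.history["cycle"]
        assert min(cyc[1:]) < cyc[0]

    def test_early_stopping_halts_on_plateau(self, rng):
        # an easy identity-like task plateaus quickly; with a short patience
        # the loop must halt well before max_epochs
        pairs = []
        for _ in range(2):
            chans = [ChannelImage(f"c{i}", rng.random((16, 16))) for i in range(4)]
            truth = RGBImage(np.stack([c.values for c in chans[:3]], axis=2))
            pairs.append(RegisteredPair(ChannelStack(chans), truth))
        cfg = tiny_cfg(
            max_epochs=60, supervised_weight=10.0,
            early_stop_patience=3, plateau_window=2, plateau_rel_tol=0.5,
        )
        bundle = train(pairs, cfg)
        assert len(bundle.history["generator"]) < 60

    def test_channel_mismatch_raises(self, rng):
        pairs = random_pairs(rng, 2, n_channels=3)
        with pytest.raises(ValueError, match="channels"):
            train(pairs, tiny_cfg(n_input_channels=4))


class _StubGen:
    """Test stub: constant image, or a patch-dependent bias."""

    def __init__(self, n, value=0.0, bias_per_call=0.0):
        self.n = n
        self.value = value
        self.bias = bias_per_call
        self.calls = 0

    def forward(self, x):
        out = np.full_like(x, self.value + self.calls * self.bias)
        self.calls += 1
        return out, None


class TestColorize:
    def _stack(self, rng, size=32, n=4):
        return ChannelStack(
            [ChannelImage(f"c{i}", rng.random((size, size))) for i in range(n)]
        )

    def test_single_patch_equals_generator_output(self, rng):
        cfg = tiny_cfg(patch_size=32)
        bundle = build_models(cfg)
        stack = self._stack(rng)
        grid = PatchGrid.from_shape(32, 32, 32, 32)
        out = colorize(bundle, stack, grid)
        y, _ = bundle.generator_AB.forward(stack.as_array()[None] * 2 - 1)
        expected = discard_surplus_channels(((y[0] + 1) / 2).transpose(1, 2, 0))
        assert out.values == pytest.approx(expected.values, abs=1e-12)

    def test_constant_generator_gives_constant_output(self, rng):
        bundle = build_models(tiny_cfg())
        bundle.generator_AB = _StubGen(4, value=0.2)
        grid = PatchGrid.from_shape(32, 32, 16, 8)
        out = colorize(bundle, self._stack(rng), grid)
        assert np.allclose(out.values, 0.6)  # (0.2 + 1) / 2

    def test_blending_matches_weighted_sum_oracle(self, rng):
        # stub adds a per-call bias: stitched output must equal the direct
        # per-pixel weighted accumulation of the same patch outputs
        bundle = build_models(tiny_cfg())
        stub = _StubGen(4, value=-0.5, bias_per_call=0.01)
        bundle.generator_AB = stub
        stack = self._stack(rng)
        grid = PatchGrid.from_shape(32, 32, 16, 8)
        out = colorize(bundle, stack, grid)

        w = tent_weights(16)
        num = np.zeros((32, 32, 3))
        den = np.zeros((32, 32))
        for k, (r, c) in enumerate(grid.coords):
            val = (( -0.5 + k * 0.01) + 1) / 2
            num[r : r + 16, c : c + 16] += w[:, :, None] * val
            den[r : r + 16, c : c + 16] += w
        oracle = np.clip(num / den[:, :, None], 0, 1)
        assert out.values == pytest.approx(oracle, abs=1e-12)

    def test_blending_weights_normalize_to_one(self):
        # the per-pixel weights used for stitching sum to 1 after division
        w = tent_weights(16)
        grid = PatchGrid.from_shape(48, 40, 16, 8)
        den = np.zeros((48, 40))
        for r, c in grid.coords:
            den[r : r + 16, c : c + 16] += w
        assert np.all(den > 0)
        norm = np.zeros((48, 40))
        for r, c in grid.coords:
            norm[r : r + 16, c : c + 16] += w / den[r : r + 16, c : c + 16]
        assert norm == pytest.approx(np.ones((48, 40)))


class TestCheckpoints:
    def test_save_load_round_trip(self, tmp_path, rng):
        pairs = random_pairs(rng, 2)
        bundle = train(pairs, tiny_cfg(max_epochs=1))
        mcgan.save_bundle(tmp_path / "ckpt", bundle)
        back = mcgan.load_bundle(tmp_path / "ckpt")
        assert dataclasses.asdict(back.cfg) == dataclasses.asdict(bundle.cfg)
        assert back.history == bundle.history
        for p1, p2 in zip(
            bundle.generator_AB.params(), back.generator_AB.params()
        ):
            assert np.array_equal(p1.value, p2.value)
        stack = ChannelStack(
            [ChannelImage(f"c{i}", rng.random((16, 16))) for i in range(4)]
        )
        grid = PatchGrid.from_shape(16, 16, 16, 16)
        assert np.array_equal(
            colorize(bundle, stack, grid).values, colorize(back, stack, grid).values
        )
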