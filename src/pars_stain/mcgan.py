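"""Multi-channel cycleGAN for virtual H&E colorization.

The colorization model translates an N-channel PARS stack (domain A) into
RGB H&E (domain B) with a cycle-consistent GAN: generators G: A→B and
F_gen: B→A (UNet, stride-2 kernel-4 convolutions) and patch-wise
discriminators D_A, D_B (PatchGAN, stride-2 kernel-4 layers with a final
stride-1 layer).  Because an N-channel generator emits N channels while
H&E is RGB, the target domain's last (blue) channel is duplicated to N
channels for training and the surplus N−3 generated channels are discarded
at read-out.

Training uses the least-squares adversarial objective, cycle-consistency
weight 10 and identity weight 0.5x that, Adam(beta1=0.5, beta2=0.999) at
lr 2e-4 held constant for the first half of training then decayed linearly
in steps of ``lr_decay_interval`` epochs, a replay buffer of 50 generated
images for discriminator updates, and registered A/B pairs fed as
corresponding items.  Whole-image inference runs the generator on
overlapping patches (~50% overlap) blended with separable triangular
weights.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _nn
from .signals import ChannelStack, RegisteredPair, RGBImage

__all__ = [
    "MCGANConfig",
    "ModelBundle",
    "PatchGrid",
    "expand_target_channels",
    "discard_surplus_channels",
    "build_models",
    "lr_for_epoch",
    "train",
    "colorize",
    "tent_weights",
    "save_bundle",
    "load_bundle",
]


@dataclass
class MCGANConfig:
    """Hyperparameters of the multi-channel cycleGAN.

    Defaults follow the training protocol of the full-scale model
    (256-pixel patches, 200 epochs max, lr 2e-4 with linear step decay
    every 10 epochs, Adam betas 0.5/0.999); ``downsampling_depth``, ``ngf``
    and ``ndf`` are reduced for small phantom patches.
    ``supervised_weight`` (default 0) adds a paired L1 term on registered
    pairs; the scaled-down selection studies enable it for stability.
    """

    n_input_channels: int = 4
    patch_size: int = 256
    max_epochs: int = 200
    early_stop_patience: int = 10
    lr: float = 2e-4
    lr_decay_interval: int = 10
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    cycle_weight: float = 10.0
    identity_weight: float = 5.0
    seed: int = 0
    downsampling_depth: int = 6
    ngf: int = 64
    ndf: int = 64
    n_disc_layers: int = 3
    batch_size: int = 1
    buffer_size: int = 50
    paired: bool = True
    supervised_weight: float = 0.0
    plateau_rel_tol: float = 1e-3
    plateau_window: int = 5

    def validate(self) -> None:
        if self.n_input_channels < 1:
            raise ValueError("n_input_channels must be >= 1")
        if self.patch_size % (2**self.downsampling_depth) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} must be a multiple of "
                f"2**downsampling_depth = {2 ** self.downsampling_depth}"
            )
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.cycle_weight < 0 or self.identity_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if not (0 <= self.adam_beta1 < 1 and 0 <= self.adam_beta2 < 1):
            raise ValueError("Adam betas must lie in [0, 1)")


@dataclass
class ModelBundle:
    """Generators, discriminators and the training history."""

    generator_AB: _nn.UNetGenerator
    generator_BA: _nn.UNetGenerator
    discriminator_A: _nn.PatchDiscriminator
    discriminator_B: _nn.PatchDiscriminator
    cfg: MCGANConfig
    history: dict = field(default_factory=lambda: {
        "generator": [],
        "discriminator": [],
        "cycle": [],
        "lr": [],
    })


@dataclass(frozen=True)
class PatchGrid:
    """Top-left patch coordinates covering an image, clamped at borders."""

    patch_size: int
    stride: int
    coords: tuple[tuple[int, int], ...]

    @staticmethod
    def _starts(extent: int, patch: int, stride: int) -> list[int]:
        starts = list(range(0, extent - patch + 1, stride))
        if starts[-1] != extent - patch:
            starts.append(extent - patch)
        return starts

    @classmethod
    def from_shape(
        cls, height: int, width: int, patch_size: int, stride: int
    ) -> "PatchGrid":
        if stride > patch_size:
            raise ValueError("stride must not exceed patch_size (need overlap >= 0)")
        if stride < 1:
            raise ValueError("stride must be >= 1")
        if patch_size > height or patch_size > width:
            raise ValueError("patch larger than the image")
        coords = tuple(
            (r, c)
            for r in cls._starts(height, patch_size, stride)
            for c in cls._starts(width, patch_size, stride)
        )
        return cls(patch_size=patch_size, stride=stride, coords=coords)

    @classmethod
    def from_overlap(
        cls, height: int, width: int, patch_size: int, overlap: float = 0.5
    ) -> "PatchGrid":
        """Grid with the given fractional overlap (~50% avoids seams)."""
        if not (0 <= overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        stride = max(1, int(round(patch_size * (1 - overlap))))
        return cls.from_shape(height, width, patch_size, stride)


# ---------------------------------------------------------------------------
# channel plumbing
# ---------------------------------------------------------------------------


def expand_target_channels(rgb: RGBImage, n: int) -> np.ndarray:
    """Duplicate the last (B) channel so the RGB target has ``n`` channels.

    Returns an (H, W, n) array [R, G, B, B, ..., B]; identity for n == 3.
    """
    if n < 3:
        raise ValueError("target domain is RGB; n must be >= 3")
    v = rgb.values
    if n == 3:
        return v.copy()
    return np.concatenate([v, np.repeat(v[:, :, 2:3], n - 3, axis=2)], axis=2)


def discard_surplus_channels(img: np.ndarray) -> RGBImage:
    """Keep the first three channels of an (H, W, C>=3) array, clipped to [0, 1]."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("need at least 3 channels")
    return RGBImage(np.clip(img[:, :, :3], 0.0, 1.0))


# ---------------------------------------------------------------------------
# model construction and schedule
# ---------------------------------------------------------------------------


def build_models(cfg: MCGANConfig) -> ModelBundle:
    """Seeded construction of both generators and both discriminators."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_input_channels
    g_ab = _nn.UNetGenerator(n, n, cfg.downsampling_depth, cfg.ngf, rng)
    g_ba = _nn.UNetGenerator(n, n, cfg.downsampling_depth, cfg.ngf, rng)
    d_a = _nn.PatchDiscriminator(n, cfg.ndf, cfg.n_disc_layers, rng)
    d_b = _nn.PatchDiscriminator(n, cfg.ndf, cfg.n_disc_layers, rng)
    return ModelBundle(g_ab, g_ba, d_a, d_b, cfg=replace(cfg))


def lr_for_epoch(cfg: MCGANConfig, epoch: int) -> float:
    """Learning rate for a 0-based epoch.

    Constant at ``cfg.lr`` for the first half of ``max_epochs``, then
    decayed linearly toward zero in steps of ``lr_decay_interval`` epochs:
    factor ``1 - k / (n_steps + 1)`` in the k-th decay interval, where
    ``n_steps`` is the number of whole intervals in the decay phase.
    """
    decay_start = cfg.max_epochs // 2
    if epoch < decay_start:
        return cfg.lr
    n_steps = max(1, math.ceil((cfg.max_epochs - decay_start) / cfg.lr_decay_interval))
    k = (epoch - decay_start) // cfg.lr_decay_interval + 1
    return cfg.lr * max(0.0, 1.0 - k / (n_steps + 1))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _to_tensors(pairs: list[RegisteredPair], cfg: MCGANConfig):
    n, p = cfg.n_input_channels, cfg.patch_size
    A, B = [], []
    for pair in pairs:
        if len(pair.stack) != n:
            raise ValueError(
                f"pair has {len(pair.stack)} channels, config expects {n}"
            )
        if (pair.stack.height, pair.stack.width) != (p, p):
            raise ValueError(f"patches must be {p}x{p}")
        A.append(pair.stack.as_array() * 2.0 - 1.0)
        b = expand_target_channels(pair.truth, n).transpose(2, 0, 1)
        B.append(b * 2.0 - 1.0)
    return np.stack(A), np.stack(B)


def train(pairs: list[RegisteredPair], cfg: MCGANConfig) -> ModelBundle:
    """Optimize the cycleGAN objective on registered A/B patch pairs.

    Per step: LSGAN adversarial losses for both generators, cycle losses
    ``cycle_weight * (|F(G(a)) - a| + |G(F(b)) - b|)``, identity losses
    ``identity_weight * (|G(b) - b| + |F(a) - a|)`` and, when
    ``supervised_weight > 0`` and pairing is on, paired L1 terms between
    each generator output and its registered counterpart; then
    discriminator updates against replay-buffered fakes.  Stops at ``max_epochs`` or when
    the ``plateau_window``-epoch moving average of the generator loss fails
    to improve by ``plateau_rel_tol`` for ``early_stop_patience`` epochs.

    Deterministic for a fixed seed, data and thread configuration.
    """
    cfg.validate()
    if not pairs:
        raise ValueError("no training pairs")
    A, B = _to_tensors(pairs, cfg)
    bundle = build_models(cfg)
    g_ab, g_ba = bundle.generator_AB, bundle.generator_BA
    d_a, d_b = bundle.discriminator_A, bundle.discriminator_B
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    buf_a = _nn.ImageBuffer(cfg.buffer_size, rng)
    buf_b = _nn.ImageBuffer(cfg.buffer_size, rng)
    opt_g = _nn.Adam(
        g_ab.params() + g_ba.params(), cfg.lr, cfg.adam_beta1, cfg.adam_beta2
    )
    opt_da = _nn.Adam(d_a.params(), cfg.lr, cfg.adam_beta1, cfg.adam_beta2)
    opt_db = _nn.Adam(d_b.params(), cfg.lr, cfg.adam_beta1, cfg.adam_beta2)

    lam, lam_idt, lam_sup = cfg.cycle_weight, cfg.identity_weight, cfg.supervised_weight
    ma_hist: list[float] = []
    best_ma = math.inf
    stall = 0
    for epoch in range(cfg.max_epochs):
        lr = lr_for_epoch(cfg, epoch)
        opt_g.lr = opt_da.lr = opt_db.lr = lr
        order = rng.permutation(len(pairs))
        order_b = order if cfg.paired else rng.permutation(len(pairs))
        ep_g, ep_d, ep_cyc = [], [], []
        for i0 in range(0, len(order), cfg.batch_size):
            ia = order[i0 : i0 + cfg.batch_size]
            ib = order_b[i0 : i0 + cfg.batch_size]
            a, b = A[ia], B[ib]

            # --- generator update -----------------------------------------
            opt_g.zero_grad()
            fake_b, t_g1 = g_ab.forward(a)
            rec_a, t_f1 = g_ba.forward(fake_b)
            fake_a, t_f2 = g_ba.forward(b)
            rec_b, t_g2 = g_ab.forward(fake_a)

            p_b, t_db = d_b.forward(fake_b)
            adv_ab, d_pb = _nn.lsgan_loss(p_b, 1.0)
            p_a, t_da = d_a.forward(fake_a)
            adv_ba, d_pa = _nn.lsgan_loss(p_a, 1.0)
            cyc_a, d_rec_a = _nn.l1_loss(rec_a, a)
            cyc_b, d_rec_b = _nn.l1_loss(rec_b, b)

            sup_total = 0.0
            d_fake_b = d_b.backward(t_db, d_pb, accumulate=False)
            d_fake_b = d_fake_b + g_ba.backward(t_f1, lam * d_rec_a)
            d_fake_a = d_a.backward(t_da, d_pa, accumulate=False)
            d_fake_a = d_fake_a + g_ab.backward(t_g2, lam * d_rec_b)
            if lam_sup > 0 and cfg.paired:
                ls_b, d_sup_b = _nn.l1_loss(fake_b, b)
                ls_a, d_sup_a = _nn.l1_loss(fake_a, a)
                d_fake_b = d_fake_b + lam_sup * d_sup_b
                d_fake_a = d_fake_a + lam_sup * d_sup_a
                sup_total = lam_sup * (ls_a + ls_b)
            g_ab.backward(t_g1, d_fake_b)
            g_ba.backward(t_f2, d_fake_a)

            idt_total = 0.0
            if lam_idt > 0:
                idt_b, t_g3 = g_ab.forward(b)
                li_b, d_idt_b = _nn.l1_loss(idt_b, b)
                g_ab.backward(t_g3, lam_idt * d_idt_b)
                idt_a, t_f3 = g_ba.forward(a)
                li_a, d_idt_a = _nn.l1_loss(idt_a, a)
                g_ba.backward(t_f3, lam_idt * d_idt_a)
                idt_total = lam_idt * (li_a + li_b)
            opt_g.step()

            loss_g = adv_ab + adv_ba + lam * (cyc_a + cyc_b) + idt_total + sup_total
            loss_cyc = cyc_a + cyc_b

            # --- discriminator updates ------------------------------------
            fb = buf_b.query(fake_b)
            opt_db.zero_grad()
            p_real, t1 = d_b.forward(b)
            l_r, d_r = _nn.lsgan_loss(p_real, 1.0)
            d_b.backward(t1, 0.5 * d_r)
            p_fake, t2 = d_b.forward(fb)
            l_f, d_f = _nn.lsgan_loss(p_fake, 0.0)
            d_b.backward(t2, 0.5 * d_f)
            opt_db.step()
            loss_db = 0.5 * (l_r + l_f)

            fa = buf_a.query(fake_a)
            opt_da.zero_grad()
            p_real, t1 = d_a.forward(a)
            l_r, d_r = _nn.lsgan_loss(p_real, 1.0)
            d_a.backward(t1, 0.5 * d_r)
            p_fake, t2 = d_a.forward(fa)
            l_f, d_f = _nn.lsgan_loss(p_fake, 0.0)
            d_a.backward(t2, 0.5 * d_f)
            opt_da.step()
            loss_da = 0.5 * (l_r + l_f)

            if not (math.isfinite(loss_g) and math.isfinite(loss_da + loss_db)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i0 // cfg.batch_size}: "
                    f"G={loss_g}, D_A={loss_da}, D_B={loss_db}"
                )
            ep_g.append(loss_g)
            ep_d.append(0.5 * (loss_da + loss_db))
            ep_cyc.append(loss_cyc)

        bundle.history["generator"].append(float(np.mean(ep_g)))
        bundle.history["discriminator"].append(float(np.mean(ep_d)))
        bundle.history["cycle"].append(float(np.mean(ep_cyc)))
        bundle.history["lr"].append(lr)

        # early stopping on the smoothed generator loss
        w = cfg.plateau_window
        gl = bundle.history["generator"]
        if len(gl) >= w:
            ma = float(np.mean(gl[-w:]))
            ma_hist.append(ma)
            if ma < best_ma * (1.0 - cfg.plateau_rel_tol):
                best_ma = ma
                stall = 0
            else:
                stall += 1
            if stall >= cfg.early_stop_patience:
                break
    return bundle


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def tent_weights(patch_size: int, eps: float = 1e-3) -> np.ndarray:
    """Separable triangular blending weights peaking at the patch center.

    Strictly positive (floored at ``eps``) so border pixels covered by a
    single patch are still defined after normalization.
    """
    x = np.arange(patch_size, dtype=float)
    t = 1.0 - np.abs(2.0 * x / (patch_size - 1) - 1.0)
    t = np.maximum(t, eps)
    return np.outer(t, t)


def colorize(
    bundle: ModelBundle, stack: ChannelStack, grid: PatchGrid
) -> RGBImage:
    """Stitch generator outputs over an overlapping patch grid.

    Each patch is passed through ``generator_AB``, the surplus N−3 channels
    are discarded, and the patches are blended by per-pixel weighted
    averaging with triangular weights (weights at every output pixel
    normalize to 1).
    """
    n = bundle.cfg.n_input_channels
    if len(stack) != n:
        raise ValueError(f"stack has {len(stack)} channels, model expects {n}")
    H, W = stack.height, stack.width
    p = grid.patch_size
    x = stack.as_array() * 2.0 - 1.0
    w2d = tent_weights(p)
    num = np.zeros((H, W, 3))
    den = np.zeros((H, W))
    for r, c in grid.coords:
        patch = x[:, r : r + p, c : c + p][None]
        y, _ = bundle.generator_AB.forward(patch)
        rgb = discard_surplus_channels(
            ((y[0] + 1.0) / 2.0).transpose(1, 2, 0)
        ).values
        num[r : r + p, c : c + p] += w2d[:, :, None] * rgb
        den[r : r + p, c : c + p] += w2d
    if np.any(den == 0):
        raise ValueError("patch grid does not cover the image")
    return RGBImage(np.clip(num / den[:, :, None], 0.0, 1.0))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_NETS = ("generator_AB", "generator_BA", "discriminator_A", "discriminator_B")


def save_bundle(path: str | Path, bundle: ModelBundle) -> None:
    """Weights as compressed npz plus a JSON manifest (cfg + history)."""
    path = Path(path)
    arrays = {}
    for net_name in _NETS:
        net = getattr(bundle, net_name)
        for i, p in enumerate(net.params()):
            arrays[f"{net_name}.{i}"] = p.value
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    manifest = {"cfg": asdict(bundle.cfg), "history": bundle.history}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_bundle(path: str | Path) -> ModelBundle:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg = MCGANConfig(**manifest["cfg"])
    bundle = build_models(cfg)
    bundle.history = manifest["history"]
    with np.load(path.with_suffix(".npz")) as data:
        for net_name in _NETS:
            net = getattr(bundle, net_name)
            for i, p in enumerate(net.params()):
                p.value[...] = data[f"{net_name}.{i}"]
    return bundle
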