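"""Synthetic tissue phantoms with the statistical structure of PARS data.

A phantom emulates what the downstream algorithms consume, not the optics:
per-pixel non-radiative time-domain signals that are noisy linear mixtures
of a few characteristic shapes tied to structure classes (cell nuclei, red
blood cells, connective tissue over a signal-free background), a
co-registered radiative raster responding in the 266 nm window, and a
deterministic class-to-color pseudo-H&E ground truth.  Shape templates are
damped sinusoids with class-specific frequency and decay: DNA-like shapes
peak in the 266 nm excitation window, hemoglobin-like shapes in the 532 nm
window (~500 ns later).

Everything is seeded; the same spec yields bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .kstar import FeatureSet, angular_distance, learn_features, unmix
from .mcgan import PatchGrid
from .signals import (
    EX266,
    EX532,
    ChannelImage,
    ChannelStack,
    RGBImage,
    RegisteredPair,
    TDSignalRaster,
    extract_conventional_channels,
    post_excitation_window,
    preprocess_channel,
)

__all__ = [
    "TissueClass",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomResult",
    "FOVData",
    "PhantomDataset",
    "damped_pulse",
    "skin_phantom_spec",
    "brain_phantom_spec",
    "generate_phantom",
    "make_dataset",
    "save_spec",
    "load_spec",
]

BACKGROUND = "background"

# pseudo-H&E palette: hematoxylin-dark nuclei, eosin-pink stroma, red RBCs
CLASS_COLORS = {
    "nucleus": (0.38, 0.22, 0.55),
    "rbc": (0.78, 0.12, 0.18),
    "connective": (0.95, 0.62, 0.75),
    BACKGROUND: (1.0, 1.0, 1.0),
}


def damped_pulse(
    times_ns: np.ndarray, onset_ns: float, period_ns: float, decay_ns: float
) -> np.ndarray:
    """Unit-norm decaying sinusoid starting at ``onset_ns`` (zero before)."""
    u = np.asarray(times_ns, dtype=float) - onset_ns
    s = np.where(
        u >= 0, np.exp(-np.maximum(u, 0.0) / decay_ns) * np.sin(2 * np.pi * u / period_ns), 0.0
    )
    n = np.linalg.norm(s)
    if n == 0:
        raise ValueError("pulse is identically zero on the sampling grid")
    return s / n


@dataclass(frozen=True)
class TissueClass:
    """One structure class: its TD shape, radiative response and H&E color."""

    name: str
    td_shape: np.ndarray  # unit-norm, length n_samples
    radiative_amplitude: float
    color: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "td_shape", np.asarray(self.td_shape, dtype=float))
        if abs(np.linalg.norm(self.td_shape) - 1.0) > 1e-8:
            raise ValueError(f"class {self.name!r}: td_shape must be unit-norm")
        if any(not (0 <= c <= 1) for c in self.color):
            raise ValueError("colors must lie in [0, 1]")


@dataclass
class PhantomSpec:
    """Full description of a synthetic field of view."""

    height: int = 128
    width: int = 128
    n_samples: int = 256
    time_step_ns: float = 4.0
    ex266_ns: float = 96.0
    ex532_ns: float = 596.0
    classes: tuple[TissueClass, ...] = ()
    noise_sd: float = 0.02
    baseline_level: float = 0.05
    seed: int = 0
    # geometry (densities per 1000 pixels, radii in pixels)
    nuclei_per_kpx: float = 1.6
    nucleus_radius: tuple[float, float] = (3.0, 6.0)
    rbc_per_kpx: float = 2.5
    rbc_radius: tuple[float, float] = (2.0, 3.5)
    connective_fill: float = 0.85
    connective_scale_px: float = 8.0
    edge_sigma: float = 0.4
    amplitude_jitter: float = 0.1
    weight_cap: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.classes:
            return
        for c in self.classes:
            if c.td_shape.shape != (self.n_samples,):
                raise ValueError("class shapes must have length n_samples")
        for i, a in enumerate(self.classes):
            for b in self.classes[i + 1 :]:
                d = angular_distance(a.td_shape, b.td_shape)
                if d <= 0.1:
                    raise ValueError(
                        f"TD shapes of {a.name!r} and {b.name!r} are nearly "
                        f"collinear (angular distance {d:.3f} <= 0.1)"
                    )

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.time_step_ns

    @property
    def schedule(self) -> tuple[tuple[str, float], ...]:
        return ((EX266, self.ex266_ns), (EX532, self.ex532_ns))

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.classes)

    @property
    def basis(self) -> np.ndarray:
        """(n_classes, n_samples) matrix of generating shapes."""
        return np.stack([c.td_shape for c in self.classes], axis=0)


@dataclass
class PhantomTruth:
    """Per-pixel class labels and mixing weights plus the generating basis."""

    class_names: tuple[str, ...]
    labels: np.ndarray  # (H, W) index into class_names, len(class_names) = background
    weights: np.ndarray  # (H, W, n_classes), >= 0, per-pixel sum <= weight_cap
    basis: np.ndarray  # (n_classes, n_samples)
    weight_cap: float = 1.0

    def __post_init__(self) -> None:
        if self.weights.min() < 0:
            raise ValueError("weights must be non-negative")
        total = self.weights.sum(axis=2)
        if total.max() > self.weight_cap + 1e-9:
            raise ValueError("per-pixel weights exceed the stated cap")


@dataclass
class PhantomResult:
    nr: TDSignalRaster
    radiative: TDSignalRaster
    truth: PhantomTruth
    he: RGBImage

    def __iter__(self):
        return iter((self.nr, self.radiative, self.truth, self.he))


def _default_shapes(spec_times: np.ndarray, ex266: float, ex532: float):
    """Class shapes share a common 266 nm response plus a class-specific
    term, so they are mutually correlated (as extracted time-domain
    features are in practice) while remaining well separated angularly."""
    common = damped_pulse(spec_times, ex266, period_ns=140.0, decay_ns=200.0)

    def _mix(alpha, pulse):
        v = alpha * common + pulse
        return v / np.linalg.norm(v)

    nucleus = _mix(1.0, 0.55 * damped_pulse(spec_times, ex266, 70.0, 110.0))
    connective = _mix(1.0, 0.55 * damped_pulse(spec_times, ex266, 250.0, 320.0))
    rbc = _mix(0.6, damped_pulse(spec_times, ex532, 100.0, 140.0))
    return nucleus, rbc, connective


def skin_phantom_spec(
    height: int = 128, width: int = 128, seed: int = 0, noise_sd: float = 0.02, **kw
) -> PhantomSpec:
    """Skin-like phantom: nuclei, red blood cells and connective tissue
    (three signal-bearing classes)."""
    base = PhantomSpec(height=height, width=width, seed=seed, noise_sd=noise_sd, **kw)
    t = base.times_ns
    nucleus, rbc, connective = _default_shapes(t, base.ex266_ns, base.ex532_ns)
    classes = (
        TissueClass("nucleus", nucleus, 0.15, CLASS_COLORS["nucleus"]),
        TissueClass("rbc", rbc, 0.35, CLASS_COLORS["rbc"]),
        TissueClass("connective", connective, 1.0, CLASS_COLORS["connective"]),
    )
    return replace(base, classes=classes)


def brain_phantom_spec(
    height: int = 128, width: int = 128, seed: int = 0, noise_sd: float = 0.02, **kw
) -> PhantomSpec:
    """Brain-like phantom: dense nuclei over connective-like parenchyma,
    no red blood cells (two signal-bearing classes)."""
    base = PhantomSpec(
        height=height,
        width=width,
        seed=seed,
        noise_sd=noise_sd,
        nuclei_per_kpx=3.0,
        rbc_per_kpx=0.0,
        connective_fill=0.9,
        **kw,
    )
    t = base.times_ns
    # brain gray matter: nuclear and parenchymal responses are strongly
    # correlated (both UV-driven), so the class-specific terms are weaker
    # than in the skin phantom
    common = damped_pulse(t, base.ex266_ns, period_ns=140.0, decay_ns=200.0)
    nucleus = common + 0.3 * damped_pulse(t, base.ex266_ns, 70.0, 110.0)
    nucleus = nucleus / np.linalg.norm(nucleus)
    connective = common + 0.3 * damped_pulse(t, base.ex266_ns, 250.0, 320.0)
    connective = connective / np.linalg.norm(connective)
    classes = (
        TissueClass("nucleus", nucleus, 0.15, CLASS_COLORS["nucleus"]),
        TissueClass("connective", connective, 1.0, CLASS_COLORS["connective"]),
    )
    return replace(base, classes=classes)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _paint_disks(
    mask: np.ndarray,
    rng: np.random.Generator,
    count: int,
    radius_range: tuple[float, float],
) -> None:
    H, W = mask.shape
    for _ in range(count):
        cy = rng.uniform(0, H)
        cx = rng.uniform(0, W)
        r = rng.uniform(*radius_range)
        y0, y1 = max(0, int(cy - r) - 1), min(H, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(W, int(cx + r) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _class_weight_maps(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """(H, W, n_classes) soft mixing weights; background is the residual."""
    H, W = spec.height, spec.width
    names = spec.class_names
    kpx = H * W / 1000.0

    conn_m = np.zeros((H, W), dtype=bool)
    if "connective" in names:
        fld = gaussian_filter(
            rng.standard_normal((H, W)), sigma=spec.connective_scale_px
        )
        conn_m = fld > np.quantile(fld, 1.0 - spec.connective_fill)
    nuc_m = np.zeros((H, W), dtype=bool)
    if "nucleus" in names:
        _paint_disks(nuc_m, rng, int(round(spec.nuclei_per_kpx * kpx)), spec.nucleus_radius)
    rbc_m = np.zeros((H, W), dtype=bool)
    if "rbc" in names:
        _paint_disks(rbc_m, rng, int(round(spec.rbc_per_kpx * kpx)), spec.rbc_radius)

    # priority: RBC > nucleus > connective
    nuc_m = nuc_m & ~rbc_m
    hard = {
        "nucleus": nuc_m.astype(float),
        "rbc": rbc_m.astype(float),
        "connective": (conn_m & ~nuc_m & ~rbc_m).astype(float),
    }
    weights = np.zeros((H, W, len(names)))
    jitter = gaussian_filter(rng.standard_normal((H, W)), sigma=6.0)
    sd = jitter.std()
    jitter = jitter / sd if sd > 0 else jitter
    for k, nm in enumerate(names):
        w = hard[nm]
        if spec.edge_sigma > 0:
            w = gaussian_filter(w, sigma=spec.edge_sigma)
        w = w * np.clip(1.0 + spec.amplitude_jitter * jitter, 0.5, 1.5)
        weights[:, :, k] = np.clip(w, 0.0, None)
    total = weights.sum(axis=2)
    over = total > spec.weight_cap
    if np.any(over):
        weights[over] *= (spec.weight_cap / total[over])[:, None]
    return weights


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_RAD_PULSE = dict(period_ns=50.0, decay_ns=40.0)


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Generate one co-registered field of view from a seeded spec.

    Per pixel, the NR signal is ``baseline + sum_c weight_c * shape_c +
    Gaussian noise``; the radiative raster responds (with class-specific
    amplitude) to a short pulse in the 266 nm window only; the pseudo-H&E
    image is the per-pixel blend of class colors over a white background.
    """
    if not spec.classes:
        raise ValueError("spec declares no tissue classes")
    rng = np.random.default_rng(spec.seed)
    weights = _class_weight_maps(spec, rng)
    basis = spec.basis

    clean = np.einsum("hwc,cn->hwn", weights, basis)
    nr_sig = spec.baseline_level + clean
    rad_pulse = damped_pulse(spec.times_ns, spec.ex266_ns, **_RAD_PULSE)
    rad_amp = np.array([c.radiative_amplitude for c in spec.classes])
    rad_sig = np.einsum("hwc,c,n->hwn", weights, rad_amp, rad_pulse)
    if spec.noise_sd > 0:
        nr_sig = nr_sig + rng.normal(0.0, spec.noise_sd, nr_sig.shape)
        rad_sig = rad_sig + rng.normal(0.0, spec.noise_sd, rad_sig.shape)

    nr = TDSignalRaster(nr_sig, spec.time_step_ns, spec.schedule)
    rad = TDSignalRaster(rad_sig, spec.time_step_ns, spec.schedule)

    total = weights.sum(axis=2)
    labels = np.argmax(weights, axis=2)
    labels = np.where(total < 0.15, len(spec.classes), labels)
    truth = PhantomTruth(
        class_names=spec.class_names + (BACKGROUND,),
        labels=labels,
        weights=weights,
        basis=basis,
        weight_cap=spec.weight_cap,
    )

    colors = np.array([c.color for c in spec.classes])
    rgb = np.einsum("hwc,ck->hwk", weights, colors) + (1.0 - total)[:, :, None]
    he = RGBImage(np.clip(rgb, 0.0, 1.0))
    return PhantomResult(nr=nr, radiative=rad, truth=truth, he=he)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class FOVData:
    """One field of view with its full co-registered channel stack."""

    nr: TDSignalRaster
    radiative: TDSignalRaster
    phantom_truth: PhantomTruth
    truth: RGBImage
    stack: ChannelStack


@dataclass
class PhantomDataset:
    train: list[RegisteredPair]
    val: list[RegisteredPair]
    test: list[RegisteredPair]
    train_fovs: list[FOVData]
    val_fovs: list[FOVData]
    test_fovs: list[FOVData]
    feature_set: FeatureSet
    patch_size: int
    stride: int


def _grid_count(extent: int, patch: int, stride: int) -> int:
    if extent == patch:
        return 1
    return int(np.ceil((extent - patch) / stride)) + 1


def choose_stride(
    heights_widths: list[tuple[int, int]], patch_size: int, target_patches: int
) -> int:
    """Stride whose clamped-grid patch count best approximates the target."""
    best_s, best_err = patch_size, float("inf")
    for s in range(1, patch_size + 1):
        total = sum(
            _grid_count(h, patch_size, s) * _grid_count(w, patch_size, s)
            for h, w in heights_widths
        )
        err = abs(total - target_patches)
        if err < best_err or (err == best_err and s > best_s):
            best_s, best_err = s, err
    return best_s


def build_fov(
    phantom: PhantomResult,
    feature_set: FeatureSet,
    guard_ns: float = 0.0,
    energy_mode: str = "squared",
) -> FOVData:
    """Assemble the full channel array A = [NR_532, NR_266, R_266, m_f1..m_fK]."""
    conv = extract_conventional_channels(
        phantom.nr, phantom.radiative, guard_ns=guard_ns, energy_mode=energy_mode
    )
    window = post_excitation_window(phantom.nr)
    feats = unmix(phantom.nr, feature_set, window)
    feat_channels = [preprocess_channel(img) for img in feats.images]
    stack = ChannelStack(list(conv.channels) + feat_channels)
    return FOVData(
        nr=phantom.nr,
        radiative=phantom.radiative,
        phantom_truth=phantom.truth,
        truth=phantom.he,
        stack=stack,
    )


def split_counts(n: int, split: tuple[float, float, float]) -> tuple[int, int, int]:
    """Floor each split share; the remainder goes to the training split."""
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    counts = [int(np.floor(r * n)) for r in split]
    counts[0] += n - sum(counts)
    return tuple(counts)


def _fov_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))


def make_dataset(
    spec: PhantomSpec,
    n_fovs: int = 3,
    patch_size: int = 64,
    target_patches: int = 60,
    split: tuple[float, float, float] = (0.7, 0.1, 0.2),
    K: int = 3,
    subset_fraction: float = 0.05,
    feature_seed: int = 0,
    guard_ns: float = 0.0,
    energy_mode: str = "squared",
) -> PhantomDataset:
    """Generate FOVs, learn features on training data, cut patch pairs.

    Whole FOV *regions* (not patches) are assigned to the train/val/test
    splits so that overlapping patches can never leak across splits.
    Features are learned from the first training FOV only and applied
    everywhere, mirroring deployment on unseen data.
    """
    if patch_size > min(spec.height, spec.width):
        raise ValueError("patch_size exceeds the field of view")
    phantoms = [
        generate_phantom(replace(spec, seed=_fov_seed(spec.seed, i)))
        for i in range(n_fovs)
    ]
    n_tr, n_val, n_te = split_counts(n_fovs, split)
    groups = {
        "train": phantoms[:n_tr],
        "val": phantoms[n_tr : n_tr + n_val],
        "test": phantoms[n_tr + n_val :],
    }
    if not groups["train"]:
        raise ValueError("no training FOV; increase n_fovs")
    window = post_excitation_window(groups["train"][0].nr)
    fs = learn_features(
        groups["train"][0].nr,
        window,
        K,
        subset_fraction=subset_fraction,
        seed=feature_seed,
    )
    fovs = {
        k: [build_fov(p, fs, guard_ns, energy_mode) for p in v]
        for k, v in groups.items()
    }
    dims = [(spec.height, spec.width)] * n_fovs
    stride = choose_stride(dims, patch_size, target_patches)
    pairs: dict[str, list[RegisteredPair]] = {}
    for k, fov_list in fovs.items():
        out = []
        for fov in fov_list:
            grid = PatchGrid.from_shape(spec.height, spec.width, patch_size, stride)
            for r, c in grid.coords:
                sub = ChannelStack(
                    [
                        ChannelImage(ch.name, ch.values[r : r + patch_size, c : c + patch_size])
                        for ch in fov.stack.channels
                    ]
                )
                tr = RGBImage(fov.truth.values[r : r + patch_size, c : c + patch_size])
                out.append(RegisteredPair(stack=sub, truth=tr))
        pairs[k] = out
    return PhantomDataset(
        train=pairs["train"],
        val=pairs["val"],
        test=pairs["test"],
        train_fovs=fovs["train"],
        val_fovs=fovs["val"],
        test_fovs=fovs["test"],
        feature_set=fs,
        patch_size=patch_size,
        stride=stride,
    )


# ---------------------------------------------------------------------------
# spec (de)serialization
# ---------------------------------------------------------------------------


def save_spec(path: str | Path, spec: PhantomSpec) -> None:
    d = {
        k: getattr(spec, k)
        for k in (
            "height",
            "width",
            "n_samples",
            "time_step_ns",
            "ex266_ns",
            "ex532_ns",
            "noise_sd",
            "baseline_level",
            "seed",
            "nuclei_per_kpx",
            "rbc_per_kpx",
            "connective_fill",
            "connective_scale_px",
            "edge_sigma",
            "amplitude_jitter",
            "weight_cap",
        )
    }
    d["nucleus_radius"] = list(spec.nucleus_radius)
    d["rbc_radius"] = list(spec.rbc_radius)
    d["classes"] = [
        {
            "name": c.name,
            "radiative_amplitude": c.radiative_amplitude,
            "color": list(c.color),
            "td_shape": c.td_shape.tolist(),
        }
        for c in spec.classes
    ]
    Path(path).write_text(yaml.safe_dump(d))


def load_spec(path: str | Path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    classes = tuple(
        TissueClass(
            name=c["name"],
            td_shape=np.asarray(c["td_shape"], dtype=float),
            radiative_amplitude=float(c["radiative_amplitude"]),
            color=tuple(c["color"]),
        )
        for c in d.pop("classes", [])
    )
    d["nucleus_radius"] = tuple(d.get("nucleus_radius", (3.0, 6.0)))
    d["rbc_radius"] = tuple(d.get("rbc_radius", (1.5, 3.0)))
    return PhantomSpec(classes=classes, **d)
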