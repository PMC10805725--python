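"""Time-resolved PARS rasters and conventional channel extraction.

Photon absorption remote sensing (PARS) records, at every pixel, a
time-resolved non-radiative (NR) trace: intensity modulations of a probe
beam following one or more excitation pulses (here 266 nm targeting
DNA/RNA and 532 nm targeting hemoglobin, the 532 nm pulse firing ~500 ns
after the 266 nm one).  This module holds the raster containers and the
conventional per-pixel reductions:

* NR integral per excitation wavelength (post-excitation modulation energy),
* radiative amplitude (peak emission following excitation),
* scattering baseline (mean probe intensity before excitation),

plus the display preprocessing applied to every channel before it enters
the colorization model (percentile saturation, rescale to [0, 1], color
reversal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "EX266",
    "EX532",
    "NR_266",
    "NR_532",
    "R_266",
    "SCATTER",
    "TDSignalRaster",
    "TimeWindow",
    "ChannelImage",
    "ChannelStack",
    "RGBImage",
    "RegisteredPair",
    "WindowError",
    "DegenerateContrastWarning",
    "post_excitation_window",
    "split_excitation_windows",
    "extract_nr_integral",
    "extract_amplitude",
    "extract_scatter_baseline",
    "preprocess_channel",
    "extract_conventional_channels",
    "save_raster",
    "load_raster",
    "write_channel_tiff",
    "read_channel_tiff",
    "write_png",
    "channel_path",
]

EX266 = "EX266"
EX532 = "EX532"
VALID_LABELS = (EX266, EX532)

NR_266 = "NR_266"
NR_532 = "NR_532"
R_266 = "R_266"
SCATTER = "SCATTER"


class WindowError(ValueError):
    """Raised when excitation peaks cannot be separated into disjoint windows."""


class DegenerateContrastWarning(UserWarning):
    """Emitted when a channel has no contrast (constant image)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeWindow:
    """Half-open, 0-based sample index range [start_index, end_index)."""

    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_index < self.end_index):
            raise ValueError(
                f"invalid window [{self.start_index}, {self.end_index})"
            )

    def validate(self, n_samples: int) -> None:
        if self.end_index > n_samples:
            raise ValueError(
                f"window [{self.start_index}, {self.end_index}) exceeds "
                f"{n_samples} samples"
            )

    def __len__(self) -> int:
        return self.end_index - self.start_index

    @property
    def slice(self) -> slice:
        return slice(self.start_index, self.end_index)


@dataclass
class TDSignalRaster:
    """Per-pixel time-resolved signal cube.

    Parameters
    ----------
    signals
        Array of shape (height, width, n_samples); sample ``i`` is acquired
        at time ``i * time_step_ns``.
    time_step_ns
        Sampling interval in nanoseconds.
    schedule
        Ordered ``(label, event_time_ns)`` pairs, one per excitation event.
    """

    signals: np.ndarray
    time_step_ns: float
    schedule: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals)
        if self.signals.ndim != 3:
            raise ValueError("signals must be (height, width, n_samples)")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples per signal")
        if not self.time_step_ns > 0:
            raise ValueError("time_step_ns must be positive")
        if not np.isfinite(self.signals).all():
            raise ValueError("signals contain non-finite values")
        self.schedule = tuple((str(l), float(t)) for l, t in self.schedule)
        times = [t for _, t in self.schedule]
        labels = [l for l, _ in self.schedule]
        for lab in labels:
            if lab not in VALID_LABELS:
                raise ValueError(f"unknown excitation label {lab!r}")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate excitation labels in schedule")
        span = self.n_samples * self.time_step_ns
        if any(not (0 <= t < span) for t in times):
            raise ValueError("schedule times must lie within the trace")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")
        if EX266 in labels and EX532 in labels:
            if times[labels.index(EX532)] <= times[labels.index(EX266)]:
                raise ValueError("EX532 must follow EX266")

    @property
    def height(self) -> int:
        return self.signals.shape[0]

    @property
    def width(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    @property
    def first_event_index(self) -> int:
        """Sample index of (at/after) the first excitation event."""
        t0 = self.schedule[0][1]
        return ceil(t0 / self.time_step_ns)

    def baseline(self) -> np.ndarray:
        """Per-pixel pre-excitation baseline.

        Mean of the samples strictly before the first excitation event;
        zero when the first event coincides with the first sample.
        """
        i0 = self.first_event_index
        if i0 == 0:
            return np.zeros((self.height, self.width), dtype=self.signals.dtype)
        return self.signals[:, :, :i0].mean(axis=2)


@dataclass
class ChannelImage:
    """A named single-channel image."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("ChannelImage values must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError(f"channel {self.name!r} contains non-finite values")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class ChannelStack:
    """Ordered, named, co-dimensioned grayscale channels (the input array A)."""

    channels: list[ChannelImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ValueError("ChannelStack needs at least one channel")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel names: {names}")
        h, w = self.channels[0].values.shape
        for c in self.channels:
            if c.values.shape != (h, w):
                raise ValueError("channels must share dimensions")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels)

    @property
    def height(self) -> int:
        return self.channels[0].height

    @property
    def width(self) -> int:
        return self.channels[0].width

    def __len__(self) -> int:
        return len(self.channels)

    def get(self, name: str) -> ChannelImage:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    def select(self, names: "list[str] | tuple[str, ...]") -> "ChannelStack":
        return ChannelStack([self.get(n) for n in names])

    def as_array(self) -> np.ndarray:
        """Channels stacked into a (N, height, width) array."""
        return np.stack([c.values for c in self.channels], axis=0)


@dataclass
class RGBImage:
    """Three-channel real image with values in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("RGBImage must be (height, width, 3)")
        if not np.isfinite(self.values).all():
            raise ValueError("RGB values must be finite")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("RGB values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class RegisteredPair:
    """A channel stack with its co-registered RGB H&E ground truth."""

    stack: ChannelStack
    truth: RGBImage

    def __post_init__(self) -> None:
        if (self.stack.height, self.stack.width) != (
            self.truth.height,
            self.truth.width,
        ):
            raise ValueError("stack and truth must share dimensions")


# ---------------------------------------------------------------------------
# channel extraction
# ---------------------------------------------------------------------------


def post_excitation_window(raster: TDSignalRaster) -> TimeWindow:
    """Window spanning the full trace from the first excitation event on.

    This is the default clustering window for time-domain feature learning:
    it covers both excitation peaks.
    """
    return TimeWindow(raster.first_event_index, raster.n_samples)


def split_excitation_windows(
    raster: TDSignalRaster, guard_ns: float = 0.0
) -> dict[str, TimeWindow]:
    """Partition the trace into one post-excitation window per event.

    The window for event ``i`` starts at the first sample at/after
    ``event_time + guard_ns`` and ends just before the next event (or at the
    end of the trace for the last event).  Windows are disjoint and ordered.

    Raises
    ------
    WindowError
        If two events are closer than ``guard_ns`` (unseparable peaks) or a
        window would be empty.
    """
    if guard_ns < 0:
        raise ValueError("guard_ns must be non-negative")
    if not raster.schedule:
        raise ValueError("schedule is empty")
    dt = raster.time_step_ns
    n = raster.n_samples
    events = list(raster.schedule)
    windows: dict[str, TimeWindow] = {}
    for i, (label, t) in enumerate(events):
        if i + 1 < len(events):
            t_next = events[i + 1][1]
            if t_next - t < guard_ns:
                raise WindowError(
                    f"events {label} and {events[i + 1][0]} are separated by "
                    f"{t_next - t:g} ns < guard {guard_ns:g} ns; peaks not separable"
                )
            end = ceil(t_next / dt)
        else:
            end = n
        start = ceil((t + guard_ns) / dt)
        if start >= end:
            raise WindowError(
                f"window for {label} is empty (guard {guard_ns:g} ns too large)"
            )
        windows[label] = TimeWindow(start, end)
    return windows


def _baseline_deviation(
    raster: TDSignalRaster, window: TimeWindow
) -> np.ndarray:
    window.validate(raster.n_samples)
    base = raster.baseline()
    return raster.signals[:, :, window.slice] - base[:, :, None]


def extract_nr_integral(
    raster: TDSignalRaster, window: TimeWindow, mode: str = "squared"
) -> ChannelImage:
    """Integrate the post-excitation modulation energy of the NR signal.

    Per pixel: the sum over the window of squared (``mode="squared"``,
    default) or absolute (``mode="abs"``) deviations of the signal from its
    pre-excitation baseline, multiplied by the time step.  Non-negative.
    """
    if mode not in ("squared", "abs"):
        raise ValueError("mode must be 'squared' or 'abs'")
    dev = _baseline_deviation(raster, window)
    if mode == "squared":
        vals = np.square(dev).sum(axis=2) * raster.time_step_ns
    else:
        vals = np.abs(dev).sum(axis=2) * raster.time_step_ns
    return ChannelImage(name="NR", values=vals)


def extract_amplitude(raster: TDSignalRaster, window: TimeWindow) -> ChannelImage:
    """Maximum absolute deviation from the pre-excitation baseline."""
    dev = _baseline_deviation(raster, window)
    return ChannelImage(name="AMP", values=np.abs(dev).max(axis=2))


def extract_scatter_baseline(
    raster: TDSignalRaster, pre_window: TimeWindow
) -> ChannelImage:
    """Mean transmitted detection intensity prior to any excitation."""
    pre_window.validate(raster.n_samples)
    if pre_window.end_index > raster.first_event_index:
        raise ValueError(
            "pre_window overlaps the first excitation event "
            f"(sample {raster.first_event_index})"
        )
    vals = raster.signals[:, :, pre_window.slice].mean(axis=2)
    return ChannelImage(name=SCATTER, values=vals)


def preprocess_channel(
    img: ChannelImage,
    saturation_fraction: float = 0.01,
    reverse: bool = True,
) -> ChannelImage:
    """Normalize a channel for model input / display.

    Values are clipped at the ``saturation_fraction`` and
    ``1 - saturation_fraction`` empirical quantiles (linear-interpolation
    convention), rescaled to [0, 1], and optionally color-reversed
    (``out = 1 - rescaled``) so bright tissue appears dark like stained
    ground truth.  A constant (zero-contrast) image yields all zeros
    (all ones after reversal) with a :class:`DegenerateContrastWarning`.
    """
    if not (0 <= saturation_fraction < 0.5):
        raise ValueError("saturation_fraction must be in [0, 0.5)")
    v = np.asarray(img.values, dtype=float)
    lo, hi = np.quantile(v, [saturation_fraction, 1.0 - saturation_fraction])
    if hi <= lo:
        warnings.warn(
            f"channel {img.name!r} has degenerate contrast (constant image)",
            DegenerateContrastWarning,
            stacklevel=2,
        )
        out = np.zeros_like(v)
    else:
        out = (np.clip(v, lo, hi) - lo) / (hi - lo)
    if reverse:
        out = 1.0 - out
    return ChannelImage(name=img.name, values=out)


def extract_conventional_channels(
    nr_raster: TDSignalRaster,
    radiative_raster: TDSignalRaster,
    guard_ns: float = 0.0,
    energy_mode: str = "squared",
    preprocess: bool = True,
    saturation_fraction: float = 0.01,
) -> ChannelStack:
    """Build the conventional channel stack [NR_532, NR_266, R_266].

    NR integrals are computed per excitation window of the non-radiative
    raster; the radiative amplitude is taken from the 266 nm window of the
    radiative raster (the 532 nm radiative response is not used).  Channels
    are preprocessed unless ``preprocess=False``.
    """
    nr_windows = split_excitation_windows(nr_raster, guard_ns)
    rad_windows = split_excitation_windows(radiative_raster, guard_ns)
    if EX266 not in nr_windows or EX532 not in nr_windows:
        raise ValueError("need both EX266 and EX532 events in the NR raster")
    nr532 = extract_nr_integral(nr_raster, nr_windows[EX532], energy_mode)
    nr266 = extract_nr_integral(nr_raster, nr_windows[EX266], energy_mode)
    r266 = extract_amplitude(radiative_raster, rad_windows[EX266])
    channels = [
        ChannelImage(NR_532, nr532.values),
        ChannelImage(NR_266, nr266.values),
        ChannelImage(R_266, r266.values),
    ]
    if preprocess:
        channels = [
            preprocess_channel(c, saturation_fraction=saturation_fraction)
            for c in channels
        ]
    return ChannelStack(channels)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SCHEDULE_DTYPE = np.dtype([("label", "S8"), ("time_ns", "<f8")])


def save_raster(path: str | Path, raster: TDSignalRaster) -> None:
    """Write a raster to HDF5 (datasets /signals, /time_step_ns, /schedule)."""
    sched = np.array(
        [(l.encode(), t) for l, t in raster.schedule], dtype=_SCHEDULE_DTYPE
    )
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=raster.signals.astype(np.float32))
        f.create_dataset("time_step_ns", data=float(raster.time_step_ns))
        f.create_dataset("schedule", data=sched)
        f.attrs["height"] = raster.height
        f.attrs["width"] = raster.width


def load_raster(path: str | Path) -> TDSignalRaster:
    with h5py.File(path, "r") as f:
        signals = f["signals"][...]
        dt = float(f["time_step_ns"][()])
        sched = [
            (row["label"].decode(), float(row["time_ns"])) for row in f["schedule"][...]
        ]
    return TDSignalRaster(signals=signals, time_step_ns=dt, schedule=tuple(sched))


def channel_path(directory: str | Path, fov: str, channel: str, ext: str = "tif") -> Path:
    """Filename convention ``<fov>_<CHANNEL>.<ext>``."""
    return Path(directory) / f"{fov}_{channel}.{ext}"


def write_channel_tiff(path: str | Path, img: "ChannelImage | RGBImage") -> None:
    tifffile.imwrite(str(path), np.asarray(img.values, dtype=np.float32))


def read_channel_tiff(path: str | Path, name: str | None = None):
    vals = tifffile.imread(str(path))
    if vals.ndim == 3 and vals.shape[2] == 3:
        return RGBImage(values=np.clip(vals.astype(float), 0.0, 1.0))
    if name is None:
        stem = Path(path).stem
        # convention <fov>_<CHANNEL>; channel names may contain underscores
        name = stem.split("_", 1)[1] if "_" in stem else stem
    return ChannelImage(name=name, values=vals.astype(float))


def write_png(path: str | Path, img: "ChannelImage | RGBImage") -> None:
    """8-bit PNG for display; values are assumed to lie in [0, 1]."""
    vals = np.clip(np.asarray(img.values, dtype=float), 0.0, 1.0)
    iio.imwrite(str(path), (vals * 255).round().astype(np.uint8))
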