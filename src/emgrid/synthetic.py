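"""Synthetic grid EMG with known ground truth.

The analysis downstream consumes only the spatial distribution of RMS
amplitude, so sources are modeled at the level of second-order
statistics: each source is a band-limited, zero-mean Gaussian carrier
whose contribution to every channel is scaled by an isotropic 2-D
Gaussian spatial profile centered at the (ground-truth) source position.
Monopolar surface EMG over a muscle's main innervation zone shows a
single compact amplitude peak, which is exactly the structure this
produces. Motor-unit action-potential trains, volume-conductor layers
and force-EMG coupling are deliberately not modeled.

Channel ``i`` of a recording is

    x_i(t) = sum_s  w_s(i) * e_s(t) + n_i(t)

with ``w_s(i) = exp(-d_is^2 / (2 spread_s^2))`` (``d_is`` the distance
from electrode ``i`` to the source center), ``e_s`` a unit-RMS
band-limited carrier scaled to ``rms_amplitude``, and ``n_i`` white
Gaussian noise with RMS ``noise_rms``. Carriers of distinct sources are
independent; all randomness flows from a single seed through
deterministic substreams.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .errors import InvalidSpecError, UnknownChannelError
from .grid import GridLayout

__all__ = [
    "SourceSpec",
    "GroundTruth",
    "RecordingMeta",
    "Recording",
    "ForceProfile",
    "generate_recording",
    "generate_force",
    "inject_bad_channels",
]


@dataclass(frozen=True)
class SourceSpec:
    """One spatially localized EMG source.

    center_mm : (x, y) ground-truth position in the grid frame.
    spread_mm : spatial SD of the Gaussian amplitude profile.
    rms_amplitude : carrier RMS at the source center, signal units.
    band_hz : (low, high) pass band of the carrier.
    """

    center_mm: tuple[float, float]
    spread_mm: float = 10.0
    rms_amplitude: float = 1.0
    band_hz: tuple[float, float] = (20.0, 350.0)

    def __post_init__(self):
        if not self.spread_mm > 0:
            raise InvalidSpecError(f"spread must be positive, got {self.spread_mm}")
        if self.rms_amplitude < 0:
            raise InvalidSpecError("rms_amplitude must be >= 0")
        low, high = self.band_hz
        if not 0 < low < high:
            raise InvalidSpecError(f"invalid band {self.band_hz}")


@dataclass(frozen=True)
class GroundTruth:
    """Provenance record of a synthetic recording."""

    sources: tuple[SourceSpec, ...] = ()
    noise_rms: float = 0.1
    bad_channels: tuple[str, ...] = ()
    bad_channel_mode: str = "noisy"
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "sources", tuple(self.sources))
        object.__setattr__(self, "bad_channels", tuple(self.bad_channels))
        if self.noise_rms < 0:
            raise InvalidSpecError("noise_rms must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RecordingMeta:
    """Subject / task / anatomy metadata attached to a recording."""

    subject: str | None = None
    task: str | None = None
    level_pct_mvc: float | None = None
    forearm_length_mm: float | None = None
    forearm_circumference_mm: float | None = None
    layout_name: str = "standard_128"
    band_hz: tuple[float, float] | None = None  # set by bandpass
    ground_truth: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingMeta":
        m = cls(**{k: d.get(k) for k in cls.__dataclass_fields__})
        if m.band_hz is not None:
            m.band_hz = tuple(m.band_hz)
        if m.layout_name is None:
            m.layout_name = "standard_128"
        return m


@dataclass
class Recording:
    """Multichannel monopolar recording.

    data : (n_samples, n_channels) float array, columns in layout order.
    fs : sampling rate, samples/s.
    force : optional per-sample force signal, same length as data.
    meta : :class:`RecordingMeta`.
    """

    data: np.ndarray
    fs: float
    force: np.ndarray | None = None
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidSpecError("data must be 2-D (samples x channels)")
        if not self.fs > 0:
            raise InvalidSpecError("fs must be positive")
        if self.force is not None:
            self.force = np.asarray(self.force, dtype=float)
            if self.force.shape != (self.data.shape[0],):
                raise InvalidSpecError("force length must match data")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class ForceProfile:
    """Force trace with its ground-truth plateau window (samples)."""

    signal: np.ndarray
    fs: float
    plateau: tuple[int, int]  # half-open sample range
    plateau_level: float


def _bandlimited_noise(n: int, fs: float, band: tuple[float, float], rng) -> np.ndarray:
    """Unit-RMS zero-mean Gaussian noise confined to a frequency band."""
    low, high = band
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise InvalidSpecError(
            f"band {band} contains no DFT bin at n={n}, fs={fs}"
        )
    coeff = np.zeros(len(freqs), dtype=complex)
    k = int(mask.sum())
    coeff[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(coeff, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms


def generate_recording(
    layout: GridLayout,
    truth: GroundTruth,
    duration_s: float = 5.0,
    fs: float = 2048.0,
) -> Recording:
    """Simulate a grid recording from a :class:`GroundTruth`.

    Reproducible: a fixed (layout, truth, duration, fs) gives
    bit-identical output. The ground truth is recorded in the returned
    recording's metadata.
    """
    if not duration_s > 0:
        raise InvalidSpecError("duration_s must be positive")
    n = int(round(duration_s * fs))
    for s in truth.sources:
        if not s.band_hz[1] < fs / 2:
            raise InvalidSpecError(
                f"source band {s.band_hz} incompatible with fs={fs}"
            )
    ss = np.random.SeedSequence(truth.seed)
    streams = ss.spawn(len(truth.sources) + 2)
    data = np.zeros((n, layout.n_channels))
    for s, child in zip(truth.sources, streams[: len(truth.sources)]):
        rng = np.random.default_rng(child)
        carrier = _bandlimited_noise(n, fs, s.band_hz, rng)
        d2 = np.sum((layout.positions - np.asarray(s.center_mm)) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * s.spread_mm**2))
        data += carrier[:, None] * (s.rms_amplitude * w)[None, :]
    if truth.noise_rms > 0:
        rng = np.random.default_rng(streams[-2])
        data += rng.normal(0.0, truth.noise_rms, size=data.shape)
    rec = Recording(
        data=data,
        fs=fs,
        meta=RecordingMeta(
            layout_name=layout.spec.name, ground_truth=truth.to_dict()
        ),
    )
    if truth.bad_channels:
        rec = inject_bad_channels(
            rec,
            truth.bad_channels,
            mode=truth.bad_channel_mode,
            seed=int(streams[-1].generate_state(1)[0] % (2**31)),
            layout=layout,
        )
        rec.meta.ground_truth = truth.to_dict()
    return rec


def generate_force(
    plateau_level: float,
    duration_s: float,
    fs: float = 2048.0,
    ramp_s: float = 1.0,
    noise_rms: float = 0.0,
    seed: int = 0,
) -> ForceProfile:
    """Trapezoidal force trace: linear ramp up, plateau, ramp down.

    Measurement noise (white, RMS ``noise_rms``) is added to the whole
    trace. The plateau sample range is returned as ground truth for
    epoch-selection tests.
    """
    if not (duration_s > 0 and fs > 0 and ramp_s >= 0):
        raise InvalidSpecError("non-physical force parameters")
    if not 2 * ramp_s < duration_s:
        raise InvalidSpecError("ramps longer than the contraction")
    if noise_rms < 0:
        raise InvalidSpecError("noise_rms must be >= 0")
    n = int(round(duration_s * fs))
    n_ramp = int(round(ramp_s * fs))
    f = np.full(n, float(plateau_level))
    if n_ramp > 0:
        up = np.linspace(0.0, plateau_level, n_ramp, endpoint=False)
        f[:n_ramp] = up
        f[n - n_ramp :] = up[::-1]
    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_rms, size=n)
    return ForceProfile(
        signal=f, fs=fs, plateau=(n_ramp, n - n_ramp), plateau_level=plateau_level
    )


def inject_bad_channels(
    recording: Recording,
    channels,
    mode: str = "noisy",
    seed: int = 0,
    noise_multiple: float = 20.0,
    layout: GridLayout | None = None,
) -> Recording:
    """Replace listed channels with a pathological signal.

    Modes
    -----
    ``flat`` : constant zero (lost contact).
    ``saturated`` : the original signal amplified and clipped at a rail
    equal to its own RMS (amplifier saturation).
    ``noisy`` : white Gaussian noise at ``noise_multiple`` times the
    recording's median channel RMS (bad skin-electrode impedance).

    Channels are addressed by layout identifier when ``layout`` is
    given, otherwise by integer column index. The input recording is not
    modified.
    """
    channels = list(channels)
    if mode not in ("flat", "saturated", "noisy"):
        raise InvalidSpecError(f"unknown bad-channel mode {mode!r}")
    idx = []
    for ch in channels:
        if isinstance(ch, (int, np.integer)):
            if not 0 <= int(ch) < recording.n_channels:
                raise UnknownChannelError(f"channel index {ch} out of range")
            idx.append(int(ch))
        else:
            if layout is None:
                raise UnknownChannelError(
                    "layout required to address channels by identifier"
                )
            idx.append(layout.index(ch))
    data = recording.data.copy()
    if idx:
        rng = np.random.default_rng(seed)
        if mode == "flat":
            data[:, idx] = 0.0
        elif mode == "saturated":
            for i in idx:
                x = recording.data[:, i]
                rail = np.sqrt(np.mean(x**2))
                if rail == 0:
                    rail = 1.0
                data[:, i] = np.clip(4.0 * x, -rail, rail)
        else:  # noisy
            rms = np.sqrt(np.mean(recording.data**2, axis=0))
            ref = float(np.median(rms))
            if ref == 0:
                ref = 1.0
            data[:, idx] = rng.normal(
                0.0, noise_multiple * ref, size=(recording.n_samples, len(idx))
            )
    return Recording(
        data=data,
        fs=recording.fs,
        force=None if recording.force is None else recording.force.copy(),
        meta=replace(recording.meta),
    )
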