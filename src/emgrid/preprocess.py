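"""Conditioning of raw grid recordings.

Three concerns, each a small deterministic operation:

* zero-phase band-pass filtering (order-4 Butterworth applied
  forward-backward; the literature standard 10-400 Hz band is the
  default). Zero phase is chosen so filtering never shifts the analysis
  epoch relative to the force trace;
* automated bad-channel detection and repair. Channels with bad
  skin-electrode contact are flagged by three heuristics (flatness,
  saturation, excess RMS relative to grid neighbors) that replace the
  operator's visual inspection of the raw signals, then replaced by the
  unweighted mean of their valid 4-connected neighbors — the usual
  "linear interpolation of the neighboring channels";
* selection of the analysis epoch: either the window of steadiest force
  (minimum sliding-window standard deviation of the force signal,
  1-sample step, earliest window on ties) or the central window of the
  contraction when no force was tracked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import (
    InsufficientDataError,
    InvalidConfigError,
    MissingDataError,
    UnrecoverableChannelError,
)
from .grid import GridLayout
from .synthetic import Recording

__all__ = [
    "BadChannelPolicy",
    "PreprocessConfig",
    "EpochWindow",
    "bandpass",
    "detect_bad_channels",
    "replace_bad_channels",
    "select_epoch",
]


@dataclass(frozen=True)
class BadChannelPolicy:
    """Thresholds for automated bad-channel detection.

    flat_rel_var : channel is a flatness candidate when its variance is
        below this fraction of the median channel variance.
    sat_fraction : channel flagged saturated when more than this
        fraction of samples sit exactly at its extreme values.
    neighbor_rms_ratio : channel is an excess-RMS candidate when its
        RMS exceeds this multiple of the median RMS of its 4-connected
        neighbors (neighbor-relative, so the compact amplitude peak of
        a genuine source is not flagged) ...
    global_rms_factor : ... and additionally exceeds this multiple of
        the grid-median RMS.
    corr_veto : flatness / excess-RMS candidates whose absolute
        correlation with any 4-neighbor reaches this value are kept: a
        surface source propagates coherently to adjacent electrodes,
        whereas a bad contact produces signal uncorrelated with its
        neighborhood. (Saturation is decided by the rail fraction
        alone: clipping preserves the underlying waveform shape.)
    """

    flat_rel_var: float = 1e-12
    sat_fraction: float = 0.01
    neighbor_rms_ratio: float = 5.0
    global_rms_factor: float = 3.0
    corr_veto: float = 0.7


@dataclass(frozen=True)
class PreprocessConfig:
    band: tuple[float, float] = (10.0, 400.0)
    epoch_s: float = 3.0
    #: "steadiest" (force required), "central", or "auto"
    #: (steadiest when a force channel exists, central otherwise)
    epoch_mode: str = "auto"
    badchan: BadChannelPolicy = field(default_factory=BadChannelPolicy)
    #: operator-supplied channels always treated as bad
    manual_bad_channels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.epoch_mode not in ("steadiest", "central", "auto"):
            raise InvalidConfigError(f"unknown epoch_mode {self.epoch_mode!r}")
        if not self.epoch_s > 0:
            raise InvalidConfigError("epoch_s must be positive")
        object.__setattr__(
            self, "manual_bad_channels", tuple(self.manual_bad_channels)
        )


@dataclass(frozen=True)
class EpochWindow:
    """Half-open sample range of the analysis epoch.

    ``criterion_value`` is the attained force standard deviation in
    steadiest-force mode, None in central mode.
    """

    start: int
    end: int
    criterion_value: float | None = None

    @property
    def n_samples(self) -> int:
        return self.end - self.start


def bandpass(recording: Recording, band: tuple[float, float] = (10.0, 400.0)) -> Recording:
    """Zero-phase order-4 Butterworth band-pass, all channels.

    Sample count is preserved (forward-backward filtering with the
    scipy default padding). The applied band is recorded in the
    returned recording's metadata.
    """
    low, high = band
    nyq = recording.fs / 2.0
    if not 0 < low < high < nyq:
        raise InvalidConfigError(
            f"band {band} invalid for fs={recording.fs} (Nyquist {nyq})"
        )
    sos = sps.butter(4, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    data = sps.sosfiltfilt(sos, recording.data, axis=0)
    meta = replace(recording.meta)
    meta.band_hz = (float(low), float(high))
    return Recording(
        data=data,
        fs=recording.fs,
        force=None if recording.force is None else recording.force.copy(),
        meta=meta,
    )


def detect_bad_channels(
    recording: Recording,
    layout: GridLayout,
    policy: BadChannelPolicy | None = None,
) -> list[str]:
    """Flag flat, saturated and excess-RMS channels.

    Deterministic given the policy; an empty result is valid. Intended
    to run on the *raw* recording — saturation rails do not survive
    zero-phase filtering.
    """
    if recording.n_samples == 0:
        raise InsufficientDataError("empty recording")
    policy = policy or BadChannelPolicy()
    x = recording.data
    var = x.var(axis=0)
    rms = np.sqrt(np.mean(x**2, axis=0))
    med_var = float(np.median(var))
    med_rms = float(np.median(rms))
    tiny = np.finfo(float).tiny

    flat = var <= policy.flat_rel_var * max(med_var, tiny)

    mx = x.max(axis=0)
    mn = x.min(axis=0)
    span = mx - mn
    atol = 1e-12 * np.maximum(np.abs(mx), np.abs(mn))
    at_rail = (x >= mx - atol).mean(axis=0) + (x <= mn + atol).mean(axis=0)
    saturated = (at_rail > policy.sat_fraction) & (span > 0)

    excess = np.zeros(recording.n_channels, dtype=bool)
    for i, ch in enumerate(layout.channels):
        nbr = [layout.index(nb) for nb in layout.neighbors(ch, 4)]
        if not nbr:
            continue
        ref = float(np.median(rms[nbr]))
        excess[i] = rms[i] > policy.neighbor_rms_ratio * max(ref, tiny) and rms[
            i
        ] > policy.global_rms_factor * max(med_rms, tiny)

    # coherence veto: a genuine surface source reaches adjacent
    # electrodes with the same waveform, a bad contact does not
    bad = saturated.copy()
    for i in np.nonzero((flat | excess) & ~saturated)[0]:
        ch = layout.channels[int(i)]
        nbr = [layout.index(nb) for nb in layout.neighbors(ch, 4)]
        coherent = False
        xi = x[:, i] - x[:, i].mean()
        si = np.sqrt((xi**2).sum())
        for j in nbr:
            xj = x[:, j] - x[:, j].mean()
            denom = si * np.sqrt((xj**2).sum())
            if denom > 0 and abs(float(xi @ xj)) / denom >= policy.corr_veto:
                coherent = True
                break
        bad[i] = not coherent
    return [ch for i, ch in enumerate(layout.channels) if bad[i]]


def replace_bad_channels(
    recording: Recording,
    layout: GridLayout,
    bad,
) -> Recording:
    """Replace bad channels by the mean of their valid 4-neighbors.

    The replacement is computed sample-wise from the *original* signals
    of the non-bad 4-connected neighbors (bad channels never contribute
    to each other's repair), so the operation is idempotent for a fixed
    bad set. A bad channel with no valid neighbor raises
    :class:`UnrecoverableChannelError`.
    """
    bad = list(bad)
    bad_set = set(bad)
    data = recording.data.copy()
    for ch in bad:
        nbr = [nb for nb in layout.neighbors(ch, 4) if nb not in bad_set]
        if not nbr:
            raise UnrecoverableChannelError(
                f"bad channel {ch} has no valid neighbor to interpolate from"
            )
        cols = sorted(layout.index(nb) for nb in nbr)  # deterministic order
        data[:, layout.index(ch)] = recording.data[:, cols].mean(axis=1)
    return Recording(
        data=data,
        fs=recording.fs,
        force=None if recording.force is None else recording.force.copy(),
        meta=replace(recording.meta),
    )


def _sliding_std(f: np.ndarray, w: int) -> np.ndarray:
    """Standard deviation of every length-w window (step 1 sample)."""
    c1 = np.concatenate([[0.0], np.cumsum(f)])
    c2 = np.concatenate([[0.0], np.cumsum(f * f)])
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = s2 / w - (s1 / w) ** 2
    return np.sqrt(np.clip(var, 0.0, None))


def select_epoch(recording: Recording, config: PreprocessConfig | None = None) -> EpochWindow:
    """Choose the analysis epoch of a recording.

    Steadiest-force mode minimizes the sliding-window standard
    deviation of the force signal (exhaustive 1-sample-step search;
    earliest window on ties, with a tiny relative tolerance so exact
    ties are not broken by rounding). Central mode returns the centered
    window.
    """
    config = config or PreprocessConfig()
    w = int(round(config.epoch_s * recording.fs))
    n = recording.n_samples
    if w <= 0:
        raise InvalidConfigError("epoch shorter than one sample")
    if w > n:
        raise InsufficientDataError(
            f"recording ({n} samples) shorter than epoch ({w} samples)"
        )
    mode = config.epoch_mode
    if mode == "auto":
        mode = "steadiest" if recording.force is not None else "central"
    if mode == "central":
        start = (n - w) // 2
        return EpochWindow(start=start, end=start + w, criterion_value=None)
    if recording.force is None:
        raise MissingDataError("steadiest-force epoch selection requires a force channel")
    std = _sliding_std(recording.force, w)
    mn = float(std.min())
    tol = 1e-9 * max(mn, float(std.max()) * 1e-3) + 1e-15
    start = int(np.argmax(std <= mn + tol))
    return EpochWindow(start=start, end=start + w, criterion_value=float(std[start]))
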