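"""Amplitude maps, watershed segmentation and barycenter localization.

The spatial fingerprint of a contraction is the per-channel RMS of the
monopolar signals over the analysis epoch, arranged on the electrode
grid. Localization proceeds:

1. **equalize** the map — a rank transform onto [0, 1] over the valid
   cells (deterministic, parameter-free, strictly monotone; ties share
   a value);
2. **watershed** the negated equalized map, seeded from its regional
   maxima, to partition the grid into clusters of distinct activity;
3. keep the **primary cluster** — the one containing the highest raw
   amplitude (lowest label on exact ties);
4. extract the **relevant channels** — channels of the primary cluster
   whose raw amplitude is strictly higher than 70% of the cluster
   maximum;
5. the **barycenter** of the relevant channels (unweighted coordinate
   mean by default) estimates the source position, reported both in mm
   in the grid frame and normalized by the subject's forearm
   circumference (X) and length (Y) so subjects are comparable.

Because equalization is rank-based and the 70% cutoff is relative, the
whole chain is invariant to global amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as sk_label
from skimage.morphology import local_maxima
from skimage.segmentation import watershed as sk_watershed

from .errors import (
    EmptySegmentationError,
    EmptySelectionError,
    InsufficientDataError,
    InvalidConfigError,
    InvalidMetadataError,
)
from .grid import GridLayout
from .preprocess import (
    EpochWindow,
    PreprocessConfig,
    bandpass,
    detect_bad_channels,
    replace_bad_channels,
    select_epoch,
)
from .synthetic import Recording

__all__ = [
    "AmplitudeMap",
    "SegmentationConfig",
    "LocalizationResult",
    "compute_rms_map",
    "equalize_map",
    "segment_map",
    "select_primary_cluster",
    "relevant_channels",
    "barycenter",
    "normalize_barycenter",
    "localize",
]


@dataclass(frozen=True)
class AmplitudeMap:
    """Per-channel RMS values tied to a grid layout."""

    values: np.ndarray  # (n_channels,) >= 0, layout channel order
    layout: GridLayout

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.layout.n_channels,):
            raise InvalidConfigError(
                f"expected {self.layout.n_channels} values, got {v.shape}"
            )
        object.__setattr__(self, "values", v)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.layout.valid_mask

    def to_grid(self, fill: float = np.nan) -> np.ndarray:
        return self.layout.to_grid(self.values, fill=fill)


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the segmentation / localization stage.

    threshold_fraction : relative amplitude cutoff for relevant
        channels (strict inequality), default 0.70.
    connectivity : 4 or 8, used for both regional maxima and watershed
        flooding.
    threshold_base : "cluster" (default; 70% of the primary-cluster
        maximum) or "global" (70% of the whole-map maximum) for
        sensitivity analyses.
    barycenter_weighting : "unweighted" or "amplitude".
    smooth : apply a masked 3x3 mean filter to the map before
        equalization (off by default).
    """

    threshold_fraction: float = 0.70
    connectivity: int = 8
    equalization: str = "rank"
    threshold_base: str = "cluster"
    barycenter_weighting: str = "unweighted"
    smooth: bool = False

    def __post_init__(self):
        if not 0 < self.threshold_fraction < 1:
            raise InvalidConfigError("threshold_fraction must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise InvalidConfigError("connectivity must be 4 or 8")
        if self.equalization != "rank":
            raise InvalidConfigError(f"unknown equalization {self.equalization!r}")
        if self.threshold_base not in ("cluster", "global"):
            raise InvalidConfigError("threshold_base must be 'cluster' or 'global'")
        if self.barycenter_weighting not in ("unweighted", "amplitude"):
            raise InvalidConfigError(
                "barycenter_weighting must be 'unweighted' or 'amplitude'"
            )


def compute_rms_map(
    recording: Recording, window: EpochWindow, layout: GridLayout
) -> AmplitudeMap:
    """Per-channel RMS over a sample window, arranged on the layout."""
    if not (0 <= window.start < window.end <= recording.n_samples):
        raise InsufficientDataError(
            f"window [{window.start}, {window.end}) outside recording "
            f"of {recording.n_samples} samples"
        )
    seg = recording.data[window.start : window.end]
    return AmplitudeMap(values=np.sqrt(np.mean(seg**2, axis=0)), layout=layout)


def equalize_map(amap: AmplitudeMap) -> AmplitudeMap:
    """Rank-equalize a map onto [0, 1] over valid cells.

    Distinct input values map to (rank-1)/(n_distinct-1); equal inputs
    share a value; order is preserved. A constant map (degenerate) maps
    to all zeros and yields a single cluster downstream.
    """
    v = amap.values
    uniq, inv = np.unique(v, return_inverse=True)
    if len(uniq) == 1:
        return AmplitudeMap(values=np.zeros_like(v), layout=amap.layout)
    eq = inv.astype(float) / (len(uniq) - 1)
    return AmplitudeMap(values=eq, layout=amap.layout)


def _smooth_map(amap: AmplitudeMap) -> AmplitudeMap:
    """Masked 3x3 mean filter (invalid cells excluded from the mean)."""
    g = amap.to_grid(fill=0.0)
    m = amap.valid_mask.astype(float)
    from scipy.ndimage import uniform_filter

    num = uniform_filter(g * m, size=3, mode="constant")
    den = uniform_filter(m, size=3, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 0, num / den, 0.0)
    return AmplitudeMap(values=amap.layout.from_grid(sm), layout=amap.layout)


def segment_map(amap: AmplitudeMap, config: SegmentationConfig | None = None) -> np.ndarray:
    """Watershed clustering of an amplitude map.

    The map is (optionally smoothed and) rank-equalized; markers are
    the regional maxima of the equalized map; the negated map is then
    flooded within the valid-cell mask. Returns per-channel integer
    labels >= 1 (each valid cell belongs to exactly one cluster).
    """
    config = config or SegmentationConfig()
    if config.smooth:
        amap = _smooth_map(amap)
    eq = equalize_map(amap)
    conn = 2 if config.connectivity == 8 else 1
    valid = amap.valid_mask
    g = eq.to_grid(fill=-1.0)  # below the [0, 1] range of valid cells
    maxima = local_maxima(g, connectivity=conn) & valid
    markers = sk_label(maxima, connectivity=conn)
    if markers.max() == 0:
        # constant map: the whole valid region is one plateau
        markers = valid.astype(int)
    labels2d = sk_watershed(-g, markers=markers, mask=valid, connectivity=conn)
    return amap.layout.from_grid(labels2d).astype(int)


def select_primary_cluster(labels: np.ndarray, amap: AmplitudeMap) -> int:
    """Cluster containing the highest raw amplitude (lowest id on ties)."""
    labels = np.asarray(labels)
    ids = np.unique(labels[labels > 0])
    if len(ids) == 0:
        raise EmptySegmentationError("segmentation produced no clusters")
    peaks = np.array([amap.values[labels == i].max() for i in ids])
    return int(ids[int(np.argmax(peaks))])  # argmax -> first (lowest id) on ties


def relevant_channels(
    amap: AmplitudeMap,
    labels: np.ndarray,
    primary: int,
    config: SegmentationConfig | None = None,
) -> list[str]:
    """Channels of the primary cluster strictly above the threshold.

    The cutoff is ``threshold_fraction`` times the maximum raw
    amplitude within the primary cluster (or the global map maximum
    with ``threshold_base="global"``); the comparison is strict, so a
    channel exactly at the cutoff is excluded. The peak channel itself
    always passes (for any positive peak).
    """
    config = config or SegmentationConfig()
    labels = np.asarray(labels)
    in_cluster = labels == primary
    if not in_cluster.any():
        raise EmptySegmentationError(f"cluster {primary} is empty")
    base = (
        amap.values[in_cluster].max()
        if config.threshold_base == "cluster"
        else amap.values.max()
    )
    cut = config.threshold_fraction * base
    keep = in_cluster & (amap.values > cut)
    if not keep.any():
        # degenerate all-zero cluster: keep the whole cluster
        keep = in_cluster
    return [ch for ch, k in zip(amap.layout.channels, keep) if k]


def barycenter(
    layout: GridLayout,
    channels,
    amap: AmplitudeMap | None = None,
    config: SegmentationConfig | None = None,
) -> tuple[float, float]:
    """Coordinate mean of a channel set, in mm in the grid frame.

    Unweighted by default; with ``barycenter_weighting="amplitude"``
    each channel is weighted by its map amplitude.
    """
    config = config or SegmentationConfig()
    channels = list(channels)
    if not channels:
        raise EmptySelectionError("barycenter of an empty channel set")
    idx = [layout.index(ch) for ch in channels]
    pos = layout.positions[idx]
    if config.barycenter_weighting == "amplitude":
        if amap is None:
            raise InvalidConfigError("amplitude weighting requires the map")
        w = amap.values[idx]
        if w.sum() <= 0:
            w = np.ones_like(w)
        b = (pos * w[:, None]).sum(axis=0) / w.sum()
    else:
        b = pos.mean(axis=0)
    return (float(b[0]), float(b[1]))


def normalize_barycenter(
    bary_mm: tuple[float, float],
    forearm_length_mm: float,
    circumference_mm: float,
) -> tuple[float, float]:
    """Dimensionless anatomical coordinates.

    X = x / proximal forearm circumference (medio-lateral),
    Y = y / forearm length (proximal-distal).
    """
    if forearm_length_mm is None or circumference_mm is None:
        raise InvalidMetadataError("anatomy measures are required")
    if not (forearm_length_mm > 0 and circumference_mm > 0):
        raise InvalidMetadataError(
            f"non-positive anatomy: length={forearm_length_mm}, "
            f"circumference={circumference_mm}"
        )
    x, y = bary_mm
    return (x / circumference_mm, y / forearm_length_mm)


@dataclass
class LocalizationResult:
    """Full audit trail of one localization run."""

    amplitude_map: AmplitudeMap
    equalized_map: AmplitudeMap
    labels: np.ndarray
    primary_cluster: int
    relevant_channels: list[str]
    barycenter_mm: tuple[float, float]
    barycenter_norm: tuple[float, float] | None
    epoch: EpochWindow
    bad_channels: list[str]
    meta: "object" = None  # RecordingMeta of the input
    pre_config: PreprocessConfig = field(default_factory=PreprocessConfig)
    seg_config: SegmentationConfig = field(default_factory=SegmentationConfig)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "rms": [float(v) for v in self.amplitude_map.values],
            "equalized": [float(v) for v in self.equalized_map.values],
            "labels": [int(v) for v in self.labels],
            "primary_cluster": int(self.primary_cluster),
            "relevant_channels": list(self.relevant_channels),
            "barycenter_mm": [float(v) for v in self.barycenter_mm],
            "barycenter_norm": (
                None
                if self.barycenter_norm is None
                else [float(v) for v in self.barycenter_norm]
            ),
            "epoch": {
                "start": int(self.epoch.start),
                "end": int(self.epoch.end),
                "criterion_value": (
                    None
                    if self.epoch.criterion_value is None
                    else float(self.epoch.criterion_value)
                ),
            },
            "bad_channels": list(self.bad_channels),
            "meta": None if self.meta is None else self.meta.to_dict(),
            "pre_config": asdict(self.pre_config),
            "seg_config": asdict(self.seg_config),
        }


def _stage(name: str, exc: Exception) -> Exception:
    exc.stage = name
    return exc


def localize(
    recording: Recording,
    layout: GridLayout,
    pre_cfg: PreprocessConfig | None = None,
    seg_cfg: SegmentationConfig | None = None,
) -> LocalizationResult:
    """End-to-end localization of one recording.

    Chain: bad-channel detection (raw signals) -> band-pass ->
    bad-channel replacement -> epoch selection -> RMS map ->
    equalization -> watershed -> primary cluster -> 70% threshold ->
    barycenter -> anatomical normalization. Every intermediate is kept
    in the result. Stage errors carry the stage name in ``exc.stage``.

    Anatomical normalization needs forearm length and circumference in
    the recording metadata; when absent, ``barycenter_norm`` is None.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    seg_cfg = seg_cfg or SegmentationConfig()
    from .errors import EmgridError

    def run(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except EmgridError as exc:
            raise _stage(stage, exc)

    bad = run(
        "detect_bad_channels", detect_bad_channels, recording, layout, pre_cfg.badchan
    )
    bad = sorted(set(bad) | set(pre_cfg.manual_bad_channels), key=layout.index)
    filt = run("bandpass", bandpass, recording, pre_cfg.band)
    if bad:
        filt = run("replace_bad_channels", replace_bad_channels, filt, layout, bad)
    window = run("select_epoch", select_epoch, filt, pre_cfg)
    amap = run("compute_rms_map", compute_rms_map, filt, window, layout)
    eq = run("equalize_map", equalize_map, amap)
    labels = run("segment_map", segment_map, amap, seg_cfg)
    primary = run("select_primary_cluster", select_primary_cluster, labels, amap)
    chans = run("relevant_channels", relevant_channels, amap, labels, primary, seg_cfg)
    bary = run("barycenter", barycenter, layout, chans, amap, seg_cfg)
    meta = recording.meta
    if (
        meta.forearm_length_mm is not None
        and meta.forearm_circumference_mm is not None
    ):
        norm = run(
            "normalize_barycenter",
            normalize_barycenter,
            bary,
            meta.forearm_length_mm,
            meta.forearm_circumference_mm,
        )
    else:
        norm = None
    return LocalizationResult(
        amplitude_map=amap,
        equalized_map=eq,
        labels=labels,
        primary_cluster=primary,
        relevant_channels=chans,
        barycenter_mm=bary,
        barycenter_norm=norm,
        epoch=window,
        bad_channels=bad,
        meta=meta,
        pre_config=pre_cfg,
        seg_config=seg_cfg,
    )
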