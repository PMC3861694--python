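# Methods

This note documents the models, algorithms and numerical choices behind
`emgrid`, and what the synthetic validation does and does not show.

## Grid geometry

A grid is declared by `GridSpec`: rows × columns, electrode pitch (mm),
rectangular exclusions, and the column aligned to the anatomical
reference line. The packaged `standard_128` layout is 12 × 12 at 10 mm
pitch with two 4 × 2 blocks removed at the ulnar proximal and distal
corners (so the four ulnar columns exist only in the eight central
rows), reference column 3 — 128 electrodes. Coordinates:
`x = (col − reference_col)·pitch` (medio-lateral, positive radial),
`y = (row − 1)·pitch` (proximal → distal). Channels are ordered
row-major, proximal-to-distal then ulnar-to-radial; file I/O depends on
this ordering. The grid is treated as planar; forearm curvature is
absorbed by the anatomical normalization, not modeled.

## Synthetic EMG model

The analysis consumes only second-order statistics (per-channel RMS),
so sources are simulated at that level rather than as motor-unit
action-potential trains. Channel *i* records

    x_i(t) = Σ_s w_s(i) · e_s(t) + n_i(t),
    w_s(i) = exp(−d_is² / (2·spread²)),

where `e_s` is a zero-mean Gaussian carrier confined to a frequency
band (default 20–350 Hz) and normalized to exact unit RMS before
scaling by `rms_amplitude`, `d_is` is the electrode-to-center distance,
and `n_i` is white Gaussian noise. Consequently the expected channel
RMS is `sqrt(w² a² + σ²)` — a single compact peak over the source, the
structure monopolar montages show over a muscle's main innervation
zone. Carriers of distinct sources are independent; crosstalk is a
second, weaker source. All randomness derives from one seed through
`numpy` `SeedSequence` substreams, making every recording bit-reproducible.

Deliberately not modeled: layered volume conduction, fiber anisotropy,
motor-unit recruitment/rate coding, and force–EMG coupling (force
traces are independent trapezoids: linear ramps, noisy plateau, with
the plateau range recorded as ground truth).

Defaults used as the study conditions: isotropic spread 10 mm
(active-region footprint ≈ 2–3 cm across, matching the compact spots
the method targets), source RMS 1.0 at 20% MVC scaling linearly with
%MVC, noise RMS 0.1 (SNR 10 at the lowest force level — the hardest
analyzed condition), fs 2048 samples/s, contraction durations 10 s
(20/50% MVC force-tracked) and 5 s (others), per-subject center offset
SD 3 mm, per-contraction jitter SD 1 mm, two isolated bad channels per
recording, subject anatomy drawn from N(252, 18²) mm length and
N(255, 22²) mm circumference. No quantitative SNR is available for real
recordings of this kind; 10 was chosen once as a conservative,
realistic operating point and not revisited.

## Preprocessing

**Filtering.** Order-4 Butterworth band-pass (default 10–400 Hz)
applied forward–backward (`sosfiltfilt`): the literature fixes only the
band, and zero phase guarantees filtering never shifts the epoch
relative to the force trace. Sample count is preserved.

**Bad channels.** Automated heuristics replace the operator's visual
inspection of raw signals, and therefore run on the *raw* recording
(saturation rails do not survive zero-phase filtering):

* *flat*: variance below 10⁻¹² of the median channel variance;
* *saturated*: more than 1% of samples exactly at the channel's
  extreme values;
* *excess RMS*: RMS above 5× the median RMS of the channel's
  4-connected neighbors **and** above 3× the grid-median RMS.

Flat and excess-RMS candidates are kept (not flagged) when their
absolute correlation with any 4-neighbor reaches 0.7: a genuine surface
source propagates coherently to adjacent electrodes, while a bad
contact produces signal uncorrelated with its neighborhood. This veto
matters because any purely amplitude-relative rule misfires on
low-noise recordings — the flank of a Gaussian amplitude profile has
unbounded neighbor ratios once the noise floor is far enough below it.
Saturation is exempt from the veto since clipping preserves the
underlying waveform shape. A global spatial-outlier rule (k robust SDs
above the cross-channel median) was considered and rejected: with a
genuinely localized source the cross-channel RMS MAD collapses to
estimation jitter and such a rule flags the source's own peak.

Flagged channels (plus any operator-supplied list) are replaced
sample-wise by the unweighted mean of their valid 4-connected
neighbors, computed from the original signals so bad channels never
feed each other and the repair is idempotent. A bad channel with no
valid neighbor is an error rather than a cascaded repair: the method
assumes isolated bad contacts (typically a handful per 128), and
silently chaining interpolations would hide a failed recording.

**Epoch.** Steadiest-force mode minimizes the SD of the force signal
over a sliding window (default 3 s) with a 1-sample step — an exact
search, implemented with cumulative sums and checked against the brute
force in tests. Ties resolve to the earliest window, with a ~1e-9
relative tolerance so exact ties are not broken by accumulated
rounding. Central mode takes the centered window; "auto" picks
steadiest when a force channel exists.

## Map segmentation and localization

The amplitude map is the per-channel RMS over the epoch. Equalization
is a rank transform: distinct values map to `(rank−1)/(n_distinct−1)`
on [0, 1], ties share a value. It is deterministic, parameter-free,
strictly monotone, and idempotent; a constant map degenerates to a
single cluster by contract. Watershed runs on the negated equalized
map, seeded from its regional maxima (8-connectivity default), with
excluded grid cells masked out of flooding; every valid cell receives
exactly one label. Regional maxima, labeling and flooding use
`scikit-image`.

Only the cluster containing the highest *raw* amplitude is analyzed
(exact ties break to the lowest label); relevant channels are those of
that cluster strictly above 0.70 of the cluster maximum (a config
switch rebases the threshold on the global maximum for sensitivity
analyses). The barycenter is the unweighted mean of the relevant
channels' positions; amplitude weighting is available but off by
default, since the 70% gate already restricts to near-peak channels.
Normalized coordinates divide x by the proximal forearm circumference
and y by the forearm length. No smoothing is applied before watershed
by default; a masked 3 × 3 mean filter sits behind a flag for very
noisy maps.

On noisy maps the rank transform amplifies noise-floor jitter into
spurious regional maxima, so over-segmentation of the background is
expected; it is harmless because primary-cluster selection and the 70%
threshold confine the analysis to the peak's catchment basin. The
number of clusters equals the number of regional maxima of the
equalized map — exactly 1 only in the noiseless limit.

## Statistics

One row per contraction (subject, task, %MVC, X, Y), duplicates
rejected. Both ANOVA layers are fixed-effects, main-effects-only OLS
fits (`statsmodels`, Type II sums of squares): with one observation per
cell the designs are otherwise saturated, and in balanced designs all
SS types coincide — Type II is only a tie-break for user-supplied
unbalanced tables. Treating *subject* as a fixed factor follows the
original analysis style for this design; a mixed model would be the
statistically ideal alternative and is out of scope. Task comparisons
use the lowest tested force level per task; the three-way layer
(subject + direction + level) uses the force-tracked directions at all
levels.

Holm–Šidák is implemented directly: sort the m p-values ascending,
adjust `p_(i) → 1 − (1 − p_(i))^(m−i+1)`, enforce monotonicity with a
running maximum, reject while adjusted ≤ α (default 0.05). The
`statsmodels` implementation serves as an independent cross-check in
the test suite only. Pairwise task discrimination tests each of the
C(k, 2) contrasts per axis with the pooled residual variance of the
two-way fit (standard post-hoc t), correcting the family of all pairs
on that axis.

## Pipeline and determinism

`run_pipeline` is a pure function of (config, seed) at the byte level
for all analysis artifacts — recordings (HDF5 written with
`track_times=False`), result JSONs, grid-aligned map/label CSVs, the
barycenter table and the reports; every result embeds the SHA-256 hash
of its producing config. The run log additionally records wall-clock
timings and is excluded from the byte-identity contract. Per-recording
failures are logged and skipped; the summary carries a nonzero-failure
flag for the CLI exit code.

## Problem sizes in tests and acceptance

The test suite and `scripts/acceptance.py` run the study at reduced
contraction durations (6 s / 4 s rather than 10 s / 5 s) and use 3 s
recordings for recovery sweeps: the analysis consumes a fixed 3 s
epoch, so duration beyond the epoch plus ramps only adds unused
samples. Recovery uses 100 seeded single-source runs at SNR 10
(median error ≈ 2 mm, bound 5 mm = half the pitch), 20 two-source runs,
and 1000 null tables for type-I calibration.

## What passing tests show — and what they do not

The synthetic generator matches the statistical structure the analysis
*assumes*: a single compact amplitude peak per task, independent
sources, spatially white noise, isolated bad channels. Passing
recovery and discrimination tests therefore validates the algorithmic
chain, not the physiological fidelity of the model. Real recordings
add volume-conduction anisotropy, innervation-zone geometry, common-
mode interference, correlated crosstalk and electrode-skin drift, none
of which are simulated; absolute error figures and F statistics from
the synthetic study do not transfer to real data. Known limitations:
planar grid geometry, no MUAP-level structure, no load-sharing analysis
across clusters (by design: only the primary cluster is interpreted),
and no power-line/motion-artifact handling.
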