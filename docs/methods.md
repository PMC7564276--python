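# Methods

`restconn` estimates resting-state functional connectivity between
region-of-interest (ROI) time series — here the 14 regions of the
default mode network (DMN) — with two complementary metrics, reduces
each recording to a thresholded adjacency matrix, and tests paired
pre/post contrasts with a cluster-based permutation test. A synthetic
generator with known phase-coupling ground truth closes the loop: every
stage of the chain can be validated against planted effects without any
real EEG.

## Connectivity metrics

**Magnitude-squared coherence.** For signals $x, y$,

$$\mathrm{Coh}_{x,y}(f) = \frac{|P_{x,y}(f)|^2}{P_x(f)\,P_y(f)} \in [0,1],$$

with auto- and cross-spectra $P$ estimated by Welch's method: 2-s Hann
windows, 50% overlap, over the full 60-s recording (frequency
resolution 0.5 Hz). The coherence spectrum is then averaged
arithmetically over the bins whose centers fall inside the band,
$[f_{low}, f_{high})$. Coherence measures linear frequency-domain
association and is inflated by any zero-lag common component.

A note on the estimator: coherence computed from a *single* averaged
segment is identically 1 whatever the data, so the implementation
refuses fewer than two Welch windows; averaging the spectra across
windows first and forming the ratio afterwards is the only
non-degenerate way to combine per-window information, and it is what
`msc`/`coherence_matrix` do.

**Phase lag index (PLI).** With instantaneous phases
$\varphi(t) = \arg\,\mathrm{analytic}(x)(t)$ from the Hilbert transform
of the *band-limited* signal,

$$\mathrm{PLI}_{x,y} = \left|\frac{1}{N}\sum_{t=1}^{N}
\operatorname{sign}\bigl[\sin(\varphi_x(t) - \varphi_y(t))\bigr]\right| \in [0,1].$$

PLI scores only the asymmetry of the phase-difference distribution.
A common source (volume conduction) contributes $\Delta\varphi \in
\{0, \pi\}$, whose sine's sign is zero or symmetrically distributed, so
PLI discards exactly the spurious coupling coherence picks up.
$\operatorname{sign}(0)$ contributes 0 (the mathematical convention),
which makes the PLI of two identical signals exactly 0.

PLI is computed per 4-s non-overlapping epoch of the band-split signal
and averaged across epochs (15 epochs for a 60-s recording). The first
and last 5% of samples of each epoch are excluded from the sum
(configurable `pli_edge_trim`): the Hilbert transform is circular and
distorts phase near segment edges.

**Bands.** alpha 7.5–12.5 Hz, beta 12.5–30 Hz, gamma 30–40 Hz. The
band split uses a 4th-order Butterworth band-pass applied
forward–backward (`sosfiltfilt`): zero net phase (the filter's group
delay would otherwise bias every phase difference), at the cost of a
doubled effective order. The broadband cleanup stage (1–45 Hz) is a
zero-phase FIR (Hamming design, applied with `filtfilt`); its edge
transients extend roughly one filter length into the recording and are
irrelevant at the 60-s scale.

**Sampling-rate convention.** All window and epoch sizes are specified
in seconds and converted at the recording's own rate; the synthetic
study uses 256 Hz (a 4-s epoch = 1024 samples), which keeps 60-s
recordings at desk scale without changing any estimator property that
matters here — every duration-based quantity (epoch counts, frequency
resolution, band edges) is rate-invariant.

## Thresholding

Each subject's matrix is truncated to its strongest 20% of edges:
$k = \lfloor 0.2 \cdot P \rfloor$ of the $P = \binom{14}{2} = 91$
unique pairs, so $k = 18$; all other entries are set to zero. Ties at
the cutoff break deterministically by lexicographic (row, column)
order. Because retained-edge sets vary by subject, a given edge's
paired sample can mix real values and zeros; edges retained by no
subject in either condition carry all-zero differences, get $t = 0$,
and can never enter a cluster — they are effectively excluded from
testing.

## Cluster-based permutation test

Per edge, the paired $t$ statistic of (post − pre) across subjects;
zero-variance differences give $t = 0$ (with a logged warning). Edges
with $|t|$ above the two-sided critical $t$ at the test's alpha
($n - 1$ df) are grouped, separately by sign, into clusters: two
supra-threshold edges are adjacent iff they share a node (the
network-based-statistic convention — the natural reading of spatial
adjacency for edge-level graphs). Each cluster is scored by its mass
$t_m = \sum_i t_i$ over its $b_n$ member edges.

The null is sampled by randomly swapping pre/post within subjects —
equivalently flipping the sign of each subject's difference vector,
which is exact under paired exchangeability. Per permutation the
maximum $|t_m|$ over clusters of *both* signs is recorded; an observed
cluster's p-value is

$$p = \frac{1 + \#\{\text{null max} \ge |t_m^{obs}|\}}{1 + n_{perm}},$$

significant iff $p < \alpha$. Using the common max-$|t_m|$ null for
both tails controls the familywise error of the two-sided test at
$\alpha$; the +1 correction counts the observed labelling and avoids
zero p-values (minimum attainable $p = 1/(1+n_{perm})$). When
$2^n \le n_{perm}$ the implementation switches to exhaustive
enumeration of all sign assignments, making the p-values exact. The
default budget is 5000 permutations at $\alpha = 0.05$; the
calibration simulations use 500 (at $n = 8$ subjects the exhaustive
256-assignment null kicks in regardless).

Permuted t-vectors are vectorised: under a sign flip the per-edge
second moment $\sum_i d_i^2$ is invariant, so each permuted $t$ follows
from the permuted mean alone.

**Effect size.** For edges of significant clusters, Cohen's
$d = (M_1 - M_2)/s_1$ with $M_1, s_1$ the mean and SD of the *post*
values and $M_2$ the pre mean; $s_1 = 0$ is flagged undefined and
rendered "-". Two caveats are deliberate: the convention assigning
$M_1$ to post is a choice (the formula's source leaves it open), and
published tables computed with this formula are not always internally
reproducible from their printed means/SDs — this implementation follows
the formula as written.

## Synthetic generator

Each ROI trace is a sum over bands of unit-variance band-limited noise
(zero-phase Butterworth-filtered white noise) plus independent Gaussian
broadband noise (`noise_sd`, default 0.5 — mild relative to the
unit-power band components). A planted coupling in band $b$ replaces
the target's band component by

$$\sqrt{1-c}\,\cdot\text{own} + \sqrt{c}\,\cdot\text{delay}(\text{source},\ \tau),
\qquad \tau = \frac{\varphi}{2\pi f_c},$$

a fractional-sample delay implemented as an FFT phase ramp; $c$ is
exactly the fraction of target band power that is a lagged source copy,
and $\varphi$ the planted phase difference at the band center $f_c$.
Zero-lag coupling ($\varphi = 0$) and an explicit instantaneous mixing
matrix are both available as volume-conduction surrogates: they inflate
coherence while PLI stays at its null floor.

The crossover study generates subjects × {Ctrl, SM} × {pre, post} with
per-cell seeds derived from (study seed, subject, session, phase), so
any recording is regenerable in isolation and restricting generation to
one session reproduces that session bit-exactly. Baseline couplings
apply everywhere; effect couplings only in (SM, post). The default
planted effect is the four parahippocampal↔posterior-cingulate
alpha-band edges at strength 0.35, lag $\pi/2$ — strong enough for a
clear positive cluster at $n = 24$ without saturating PLI. Coupling
strengths are jittered per subject by a multiplicative factor uniform
in ±20%, drawn once per subject and held constant across that
subject's four recordings: the jitter models between-subject effect
heterogeneity (no published between-subject PLI variance exists to
match, so this is a modeling choice), and holding it fixed within
subject keeps it out of the within-pair noise.

What the generator does *not* emulate: dipole-level cortical sources
and forward/inverse modeling, 1/f background spectra, EEG artifacts
(blinks, EMG), non-stationarity, or realistic cross-frequency
structure. Passing tests therefore demonstrate that the estimators and
the inference chain behave correctly on signals with known coupling —
not that any particular real-data effect is true.

## Null behaviour of narrowband PLI (why test bounds differ by context)

For iid phase differences the null PLI scales as
$\sqrt{2/(\pi N)}$. Band-limited signals violate the iid assumption:
phases decorrelate on the scale of the inverse bandwidth, so a 4-s
alpha epoch carries only $N_{eff} \approx BW \cdot T \approx 20{-}40$
independent phase samples, and averaging the *absolute* per-epoch PLI
across epochs converges to the positive floor
$E|\mathrm{PLI}| \approx \sqrt{2/(\pi N_{eff})} \approx 0.15$, not to
zero. Tests therefore use the strict $3/\sqrt{N}$ bound only for
broadband signals (near-iid phases) and an effective-bandwidth bound
(0.3, several null SEs above the floor and far below any planted
coupling) for narrowband epoch-averaged estimates. This floor is a
property of the estimator itself, cancels in paired contrasts, and is
the reason the inference is built on permutation rather than on
absolute PLI values.

## Calibration (computed by `analysis/05_calibration.py` and the test suite)

* Type-I error: 200 null crossover datasets (8 subjects, 14 ROIs, 60 s
  at 256 Hz, no couplings), alpha-band PLI pipeline, 500 permutations;
  the fraction of datasets with any significant cluster in the SM
  pre/post contrast is compared with $\alpha$ plus a one-sided binomial
  tolerance. One contrast is tested per dataset: the quantity being
  calibrated is the familywise error of a single cluster test.
* Power: at $n = 24$ with the default planted effect, the SM contrast
  recovers a significant positive alpha cluster containing at least 3
  of the 4 planted edges in the majority of seeded runs, with the Ctrl
  contrast staying null.

Problem sizes (200 datasets, 500 permutations, 5 power runs) are the
package's calibration defaults and run in a few minutes on one core.

## Degenerate inputs and numerical choices

* All-zero signal → instantaneous phase undefined (error); all-zero
  *epoch channel* inside a matrix computation contributes phase 0 and
  hence PLI 0 against any partner.
* Coherence with < 2 Welch windows → refused as degenerate.
* Proportional threshold retaining 0 edges → error.
* < 2 subjects → error before any statistics.
* Paired-sample label orders must match exactly; cluster edges are
  stored as label-sorted pairs so relabeling ROIs permutes results
  without changing any p-value.
* Recordings entering the pipeline are assumed artifact-free (sensor
  cleaning is out of scope); the quality gate enforces finite values
  and a 60-s minimum duration.

## Known limitations

* The generator's fractional delay is circular (FFT-based); for 60-s
  signals and sub-50-ms delays the wrap-around is negligible.
* A full-strength planted coupling yields epoch-averaged PLI ≈ 0.95–1,
  not exactly 1: instantaneous frequency occasionally slips outside the
  band at amplitude nulls, flipping the sine's sign for a few samples.
* Coherence matrices cost one cross-spectrum per pair; at 14 ROIs this
  is the slowest per-recording step.
* The test decides per contrast; no between-session
  (difference-of-differences) test is provided.
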