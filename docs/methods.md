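# Methods

This note documents the models, algorithms and numerical choices behind
`replitrack`: what is simulated, how foci are found and scored, how fork
pairs are classified, and where the open design decisions were settled.

## The biological picture

In slowly growing bacteria a single replication round starts at the origin
near midcell, where the two sister replication forks assemble. Labelling a
core replisome component (canonically the DnaN beta-clamp) produces one
diffraction-limited fluorescent focus per *co-localized* fork pair — the
"replication factory" configuration — which occasionally fissions into two
dim sister foci, fuses again, and disappears at termination. If the next
round initiates before division, two new factories appear near the
quarter-cell positions (the future midcells of the daughters) and persist
through division. The analysis quantifies how often sister forks are
co-localized versus resolved, using only cell masks, fluorescence images
and statistics — no manual curation.

## Synthetic-data generator

The generator (`replitrack.simulate` + `replitrack.render`) produces
populations of cells with known ("ground-truth") replisome dynamics and
renders them through a diffraction-limited PSF, so every pipeline stage is
testable without an external dataset.

**Growth and division.** Each cell elongates exponentially,
`L(t) = L0 * exp(t / t0)`, with the elongation constant `t0` drawn per cell
(default 260 ± 25 min, i.e. doubling time `tD = t0 ln 2 ≈ 3 h`). A cell
divides when it reaches a per-cell threshold, `2 * L0` with 10 % lognormal
noise, splitting at midcell with 2 % length asymmetry. Birth lengths are
3.5 ± 0.3 um. This sits at the long end of the 1–4 um birth-length window
the selection filter admits; the choice is deliberate: the focus score
divides by the intensity standard deviation over the *entire* cell mask,
which includes the focus signal itself, so small masks intrinsically cap
the attainable score (see *Focus scoring* below). Cells of 3.5–7 um at
110 nm/px sampling give mask areas where dim sister foci score comfortably
above the retention threshold while pure noise does not.

**Replication cycle.** Per cycle: initiation at birth + D (D ~ |N(12, 5)|
min, or inherited from a pre-division re-initiation), replication duration
~ N(135, 15) min, termination always at least two frames before division
(midcell foci are never allowed to persist through division).
Re-initiation is governed by a per-cell *re-initiation length*
(initiation-mass control): a lognormal threshold around the mean division
length whose offset is chosen so that `P(L_init < L_division) = p_preinit`
(default 0.45). The new round fires when the cell reaches that length (no
earlier than one frame after termination), so re-initiation precedes
division in exactly `p_preinit` of cycles on average *and* the longest
cells are precisely the ones that have re-initiated — which is what makes
two-focus patterns dominate the longest length bins and zero-focus
frequencies peak at intermediate lengths. A pre-division re-initiation
produces two new factories at relative positions 0.275/0.725 — slightly
inside the geometric quarter positions so that the mean measured
separation of quarter-cell focus pairs is 0.45 cell lengths, the reported
value (exact quarter positions would give 0.50). After division each
inherited factory continues as its daughter's midcell pair.  Within a
finite observation window, second-generation cycles that manage to
complete are biased toward fast cycles; event-frequency censuses therefore
use founder cycles, which the window covers completely.

**Fork-pair fission/fusion.** Each fork pair carries a two-state Markov
chain (co-localized/resolved) with stationary resolved probability
`p_resolved` and mean resolved-episode length of 3 frames. Episode
separations are drawn from N(0.20, 0.045) relative cell lengths, truncated
to [0.05, 0.32] so resolved sisters always respect the one-third-cell-length
bound. Factory centers execute a mean-reverting AR(1) walk (sd 0.02 cell
lengths, lag-1 correlation 0.7) around their home position. Quarter-cell
factories resolve more rarely (factor 0.25) — fission of re-initiated
factories is an occasional event, and with the mask-wide deltaI their dim
sisters are near the retention boundary anyway. Preset `p_resolved` values
(0.188 E. coli, 0.218 B. subtilis) are calibrated analytically so the
time-averaged ground-truth co-localized fraction of fork-pair observations
equals the published 82 % / 79 %, given the ~5 % share of quarter-factory
pair-frames: `coloc = 1 - p_resolved * (1 - 0.75 * w_quarter)`.

**Rendering.** Each founder lineage occupies one image lane; cells are
laid out end to end and push each other as they elongate. Masks are
stadium-shaped, 1.2 um wide, with labels equal to `cell_id + 1`; a division
retires the parent label and issues two new ones. Emitters are isotropic
2-D Gaussians of sigma 160 nm at 110 nm/px sampling: a co-localized pair is
one emitter at full amplitude (default 2000 photons peak over a 100-photon
background), a resolved pair two emitters at half amplitude ("two dim foci
which fuse back to the original intensity"). Noise is Poisson by default
(gaussian and noise-free modes exist for oracle tests). All randomness
derives from the config seed; identical configs give identical stacks.

**What the generator does *not* emulate.** Phase-contrast physics (masks
are emitted directly, i.e. segmentation is assumed perfect), photobleaching,
cytoplasmic autofluorescence gradients, B. subtilis chaining with shared
masks (emulated only as a longer D period and noisier division threshold),
chromosome structure, 3-D defocus, and camera artefacts (EM gain noise,
hot pixels). Passing recovery tests on this generator therefore
demonstrates that the *analysis* is correct and unbiased under the stated
optical model — not that segmentation or imaging of real data is solved.

## Cell tracking and growth

Tracks are built from the label masks: per frame, length is the maximal
Feret extent of the mask along its principal (inertia) axis, with a
one-pixel end-correction (`max - min + 1`); the axis sign is kept
pole-stable frame to frame. Lineage comes from label turnover with pixel
overlap. Tracks with frame gaps or >20 %/frame length jumps are flagged as
segmentation errors. Growth is fitted by unweighted least squares in
linear length space, `L(t) = L0 exp(t/t0)` (log-linear regression provides
the starting point), and `tD = t0 ln 2` exactly. Selection keeps tracks
with no error flag, doubling time 1.5–4.5 h, and birth length 1–4 um; in
snapshot mode the growth criterion cannot be evaluated and the length
window is widened to one doubling above the birth window (1–8 um observed
length), since a single frame cannot distinguish birth from division size.

## Focus detection and scoring

Per frame: a Gaussian blur (sigma 1.25 px) is applied; the conjugate
(inverted) blurred image is watershed-partitioned into intensity regions
around its regional maxima (plateau ties are broken by merging maxima
closer than 2 px); regions outside cell masks are discarded; each region
contributes one candidate at its maximum-intensity pixel. A 2-D Gaussian
`Ig exp(-|x-x0|^2 / 2b^2) + I0` is least-squares fitted to the **raw**
image over the 29-pixel disk of radius 3 around the candidate (bounds
`Ig >= 0`, `b` in [0.5, 5] px); the fitted `x0` is used for all
localization.

The significance score is `sigma = Ia / (deltaI * sqrt(A))` with
`Ia = (disk sum) - (min disk pixel) * A` measured on the **blurred** image
over the disk re-centered at the fitted position, and `deltaI` the raw
intensity standard deviation over the entire cell mask. Foci with
`sigma >= 4` are retained. Two numerical choices matter here:

* *Blurred disk photometry.* The min-pixel background estimator is biased
  by roughly two noise standard deviations on white-noise data; on the raw
  image this alone pushes pure-noise candidates to sigma ≈ 10, while on the
  blurred image (where neighbouring pixels are correlated) the bias nearly
  vanishes and pure noise scores ≈ 1. Measuring the disk on the image the
  watershed sees is the only self-consistent reading that both retains real
  foci and rejects noise at the stated threshold.
* *Blur width 1.25 px.* At sigma 1.0 px, ~18 % of pure-noise cell-frames
  still pass the threshold through the min-pixel bias; 1.25 px restores
  noise rejection (<0.5 % per cell-frame) without merging 0.2-cell-length
  sister pairs.
* *Mask-wide deltaI includes the focus.* Because the signal contributes to
  its own noise estimate, the score saturates at an amplitude-independent
  ceiling proportional to sqrt(mask area); resolved (half-intensity)
  sisters saturate a further sqrt(2) lower. This is intrinsic to the score
  definition and is why the simulated optical scale (110 nm/px, cells
  >= 3 um) was chosen such that the dim-sister ceiling sits near 5.

A cheap provisional score at the candidate pixel (cutoff 3.0, a full score
unit below retention) skips the Gaussian fit for candidates that cannot
reach the threshold; this is a pure speed-up and does not change retention.
Detection contains no randomness. Drift correction (integer-pixel phase
correlation against the previous frame) is available and tested; the
pipeline default is off because simulator masks are emitted pre-aligned.

## Pair statistics and classification

All unique within-cell-frame focus pairs contribute a relative separation
(long-axis component divided by cell length). A two-component Gaussian
mixture is fitted to the pooled separations by EM (median-split
initialization, convergence at |delta log-likelihood| < 1e-8, jittered
restarts on degenerate components, components ordered so mu_low < mu_high).
A pair whose posterior probability of the low-separation component exceeds
0.5 is a resolved-sister candidate; within a cell-frame, candidates are
accepted greedily in decreasing posterior under the constraint that each
focus belongs to at most one accepted pair (posterior exactly 0.5 goes to
the high population; ties are measure-zero). Counting follows the factory
bookkeeping: every focus not in an accepted pair is itself a co-localized
fork pair, `n_coloc = n_foci - 2 * n_resolved`, so a single-focus cell
contributes one co-localized pair and zero-focus cells contribute nothing.
The population co-localized fraction is `sum(n_coloc) / sum(n_coloc +
n_resolved)`. Conditional position densities use 0.02 relative-position by
0.25 um length bins, each length column normalized to 1.

Known, accepted biases: the low-component mean fit is pulled slightly
upward because sub-resolution separations (< ~450 nm) merge into single
foci and are lost from the low tail; the net effect on the recovered
co-localized fraction is about +1 percentage point on the default presets,
within the stated recovery tolerance.

## Problem sizes

Recovery runs use 200 founder lineages for 300 simulated minutes
(~14,000 retained foci, ~2,300 focus pairs) for the time-lapse presets,
2,000 independent cells for snapshot mode, 800 lineages (sim-only,
~2,200 complete cycles) for event-frequency counts, and 100 lineages for
growth-fit summaries. These sizes put the binomial standard error of the
co-localized fraction near 0.5 pp and of the pre-division re-initiation
frequency near 1 pp.

## Limitations

* The score's mask-wide deltaI makes retention of dim resolved sisters
  sensitive to cell size and fluorophore brightness; datasets with smaller
  cells or dimmer markers would undercount resolved pairs.
* The mixture is one-dimensional (separation only); the joint
  separation-versus-length structure is used for visualization, not
  classification.
* The greedy disjoint matching is exact for the focus configurations the
  model produces (verified against exhaustive matching for <= 4 foci) but
  is not a general maximum-weight matching.
* Snapshot mode infers a cell's cycle phase from length alone; mixed or
  non-steady-state populations would violate its age-distribution
  assumption.
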