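# Methods

## The analysis in one paragraph

Multi-channel 3D stacks (nuclear stain, CD90, CD19, CD3, CAR) are
segmented into per-cell masks on the nuclear channel (or imported from an
external segmenter). For each mask the total pixel intensity of each
marker channel is computed on the *raw* (unfiltered) channels, min–max
normalized and natural-log transformed with offset ε = 1e-6, pooling all
of a patient's stacks into one distribution per channel. Positivity
thresholds are anchored to an external modality: if flow cytometry says a
disease group's cultures contain f% marker-positive cells (mean over
replicates and over both experimental conditions, mock and CAR), the
threshold is placed at the (100 − f)th percentile (linear interpolation)
of the patient's pooled distribution, and a mask is positive iff its
value strictly exceeds the threshold. Masks positive for both CD19 and
CD3 are *co-localized*; the composition (stromal / B-only / T-only /
co-localized) and `coloc_of_b` = co-localized / all CD19⁺ masks are
summarized per stack, patient, region and group, and compared with
standard tests. Endpoint and kinetic cytotoxicity calculators complete
the readout set.

## Why a percentile anchor works (and when it does not)

Min–max normalization, the log transform, and percentile thresholds are
all rank-based, so the pipeline is invariant under any strictly monotone
rescaling of the intensities — the anchor calibration is exact up to
1/N: for a tie-free distribution of N masks and anchor f, the fraction
called positive is f/100 ± 1/N by construction. The threshold therefore
carries *no* information about where positive and negative populations
lie; it inherits its validity entirely from (a) the anchor fraction being
right for the imaged population and (b) positives ranking above negatives
in per-mask total intensity. The synthetic generator makes both
assumptions true and measurable; on real data, (a) is an explicit leap of
faith — thresholds are per patient but anchors are per group, so a
patient whose infiltration deviates from the group mean is mis-anchored.
This is reproduced as designed, not corrected.

## The synthetic phantom

The generator emulates the statistical structure the analysis assumes,
not optical realism.

**Geometry.** Stromal cells are spherocylinders (default radius 3,
length 16 voxels) placed preferentially attached to the growing network;
B and T cells are spheres (default radius 5 voxels, matching the
~10-pixel segmentation scale). B cells are placed touching the stromal
surface (scaffold adhesion); a configured fraction of B cells
(`coloc_fraction`, default 0.3) receives an *engaged* T cell whose mask
touches theirs (within one voxel), and every remaining T cell is placed
out of contact with all B cells, so the engaged count is exactly
`round(coloc_fraction × n_bcell)`. Placement uses rejection sampling on
distance-transform-derived candidate sets, capped at 1000 attempts per
cell with up to 8 deterministic whole-pass retries; an infeasible request
raises a placement error naming the limiting population. Default stack:
64 × 96 × 96 voxels (z step 1.04 µm, lateral 1.0 µm assumed isotropic)
with 18 stromal + 32 B + 32 T cells — an effector-to-target ratio of 1:1.

**Masks vs bodies.** The analysis mask is what a nuclear stain labels.
Lymphocytes have a high nuclear:cytoplasmic ratio, so B/T masks are the
whole sphere. Stromal cells keep a compact oval nucleus (a short capsule
at the body's center) as their mask and nuclear-channel signal, while the
elongated body carries the CD90 signal. This mirrors real morphology
(oval fibroblast nuclei inside spindle-shaped bodies) and is what makes
nuclear-channel segmentation well-posed; a phantom whose stromal
*nuclei* were themselves touching thin capsules would be unsegmentable
by any nuclear-stain method, ours or learned.

**Intensities.** Each cell draws one log-normal intensity per channel
(per-class location/scale; positive locations ~log 600, negative ~log 8)
painted uniformly over the cell, followed by linear channel crosstalk
(default 2%), Gaussian PSF blur (σ = 1 voxel) and additive Gaussian
noise (σ = 5), clipped at zero.

**The co-localization mechanism.** A double-positive mask needs genuine
CD3 signal inside a CD19⁺ mask. The generator models the immunological
synapse: for each engaged pair, T-cell-level CD3 intensity is painted
into the contact patch of the B mask (voxels within ~2.5 voxels of the
partner's mask). CD19 transfer in the other direction (trogocytosis) is
deliberately not modeled. Ground-truth marker semantics follow: CD19⁺ =
all B cells; CD3⁺ = all T cells plus engaged B cells. These are also the
fractions the matched anchor tables report, which is what lets the
end-to-end recovery test close exactly: with truth anchors, recovered
`coloc_of_b` equals `round(c·n_b)/n_b`. Had contamination been modeled
symmetrically, each engaged *T* cell would also go double-positive and
`coloc_of_b` would inflate to ≈ 2c/(1 + c) — a useful reminder that on
real data the denominator convention and the asymmetry of marker
transfer both matter.

**Regions.** Core = cells whose lateral centroid lies within
`core_radius_fraction` (default 0.5) of the lateral half-extent;
periphery = remainder. The study recovers regions by dissection, so this
is purely a simulation convention.

**Assay tables.** Viability tables satisfy
`car_live = target_alone × (1 − specified_lysis)` per group/region;
defaults specify ~27.9/19.9% (CLL periphery/core) and ~50.2/45.1% (ALL)
lysis on an 80%-viable target-alone baseline, the regime the calculators
are meant to operate in. Kinetic traces are per-object
(time, size, area) rows every 30 min: large objects carry a signal that
rises linearly to the maximal-lysis time (default 9 h) and then decays
(τ = 6 h), on top of a linear spontaneous (basal) component; small
objects (4–10 µm) are sub-threshold background the ≤ 10 µm size filter
must remove. The piecewise rise/decay shape makes the peak frame
well-defined under the 1% multiplicative noise.

## Segmentation baseline

Gaussian smoothing (σ = diameter/12) → global Otsu → Euclidean distance
transform → watershed seeded at the distance map's local maxima with
minimum separation diameter/2 → per-mask half-maximum trim: each mask
keeps voxels above half of its own peak smoothed intensity, then any
disconnected remnant becomes its own mask, and components below
`min_volume` (default 30 voxels, roughly a third of a 10-pixel cell's
mid-slice) are dropped. The trim is the step that matters in practice:
cells vary several-fold in brightness, so a single global threshold
yields fat masks around bright cells and thin ones around dim cells;
normalizing each mask to its own half-maximum equalizes extent and
detaches touching cells. Two design choices deviate from the more common
σ = diameter/6 smoothing and untrimmed watershed because both measurably
fuse or bloat masks at small diameters. Everything is deterministic for
fixed input (watershed flooding included); on the ~300-cell fixture the
baseline reaches F1 ≈ 0.90 at IoU 0.5 with perfect recall on isolated
zero-noise spheres. The intended production path for real data remains
importing masks from a trained segmenter via `load_labels`, which
relabels to consecutive ids and reports the id mapping; classification
downstream never depends on how masks were made.

## Numerical and convention choices

- **ε inside the log**: the minimum normalized value is 0, so the log
  needs an offset; ε = 1e-6. Rank order is unaffected, hence thresholds
  and calls are independent of ε.
- **Percentiles**: linear interpolation between order statistics
  (`numpy.percentile` default).
- **Strict inequality at the threshold**: a 0% anchor then yields zero
  positives — the only self-consistent boundary; a mask exactly at
  threshold is negative.
- **Degenerate distributions**: all-identical totals raise an error
  (thresholding undefined) rather than returning arbitrary calls.
- **coloc_of_b denominator**: all CD19⁺ masks (co-localized +
  B-only). With asymmetric contamination (above) this equals the engaged
  fraction of B cells.
- **Zero-variance paired differences**: reported as t = 0, p = 1 rather
  than NaN (no effect, not an undefined design).
- **Small-sample Mann–Whitney**: exact permutation enumeration (ties
  handled exactly; two identical samples give p = 1); asymptotic for
  larger groups.
- **Negative cytolysis**: reported and flagged, never clamped — clamping
  would hide target outgrowth. Kinetic corrected signal, by contrast, is
  floored at 0 before normalization because negative lysis *areas* are
  non-physical noise.
- **Region difference sign**: `core_minus_periphery`; a core deficit is
  negative.
- **Variance filter**: population variance over edge-clipped cubic
  neighborhoods, computed from zero-padded integral images after
  shifting by the global mean — constant inputs give exactly zero
  everywhere, including edges, and outputs are clamped at ≥ 0 against
  rounding residue. It is provided as the pre-segmentation texture
  transform; marker aggregation always uses unfiltered channels, since
  a variance transform would destroy total intensities.

## Problem sizes

The shipped simulation scales are chosen as desk-scale study stand-ins:
tiny fixture 32 × 48 × 48 with ~30 cells, small fixture 64 × 96 × 96
with ~300 cells, and the verification cohort 2 groups × 4 patients × 2
stacks of the default 64 × 96 × 96 geometry (~1300 masks). These sizes
exercise every code path, including touching-cell segmentation and
patient-pooled thresholding, while a full run of the test suite and the
acceptance script stays within a few minutes on one CPU.

## What passing tests do and do not show

The phantom's intensity distributions are well-separated, its anchors can
be made noise-free, and its cells are geometric primitives. Passing the
end-to-end recovery therefore shows the *machinery* is correct —
rank-based calibration, pooling, counting, and arithmetic — not that the
method is robust to overlapping intensity distributions, anchor bias,
segmentation errors propagating into counts, depth-dependent attenuation,
or irregular morphology, none of which the generator emulates. The
statistics power check simulates patient-level summaries directly and
says nothing about within-patient image-count imbalance. Known further
limitations: no spectral unmixing or bleaching model; no spatial
statistics beyond class counting; the CAR channel reuses the same
thresholding machinery but is not part of the four-class composition.
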