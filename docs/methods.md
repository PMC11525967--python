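# Methods

`lineagefish` implements the quantitative core of a *C. elegans* embryonic
cell-death study pipeline: absolute mRNA counting by single-molecule RNA FISH
(smFISH) integrated intensity, developmental staging by embryonic nuclei
count, concentration time-courses, and rule-based classification of
programmed-cell-death outcomes on timed lineage records. A synthetic-data
generator produces image stacks and lineage trees with known ground truth, so
every stage is tested against an oracle rather than against inaccessible raw
recordings.

## Copy-number estimation

The estimator is the integrated-intensity method, not per-spot counting. For
a cell modelled as a sphere (centre and diameter in µm):

- **SI_Total** — the stack's z-slices whose centres fall inside
  [z_c − r, z_c + r] are sum-projected, and the signal inside the disk of the
  cell's diameter is summed. Voxel indices are 0-based; a voxel belongs to
  the disk when its centre does.
- **SI_Bkgd** — eight candidate disks of the same size are placed at 1.5
  cell diameters from the centre (compass directions in-plane, same z-slab).
  Candidates containing any detected diffraction-limited spot are dropped
  ("no visible mRNA signal"); among the spot-free remainder the `n_regions`
  (default 3) whose mean is closest to the spot-free consensus median are
  averaged. Choosing the lowest-intensity regions instead would
  systematically pick the down-gradient side of any illumination tilt and
  bias the background low; the consensus rule is unbiased under a linear
  tilt (verified in the tests to a residual ≪ 5% of one spot). Each
  candidate integral is rescaled to the ROI's exact voxel count, because
  equal-diameter disks at different sub-voxel alignments cover slightly
  different numbers of voxel centres (ignoring this costs a consistent
  fraction of a spot). With fewer than `n_regions` spot-free candidates the
  lowest-median candidates fill in and a warning is logged.
- **SI_Spot** — single-molecule calibration. Difference-of-Gaussian (DoG)
  candidates at the diffraction-limited scale (σ_xy = 0.13 µm,
  σ_z = 0.30 µm) are deduplicated by a greedy anisotropic non-maximum
  suppression, then kept only if *isolated*: no other candidate within a
  per-axis box that covers the integration box plus its background shell
  plus one spot extent (≈ 1.3 µm laterally, ≈ 2.9 µm axially at the default
  voxel sizes). The axial reach is large because σ_z and the 0.5 µm slice
  spacing are coarse; consequently calibration needs sparse spots — dense
  cell interiors cannot supply clean singles and the function raises,
  directing the user to a manual `SI_Spot` via configuration, when fewer
  than five isolated spots exist. Each isolated spot is integrated over a
  ±3σ box above the mean of its surrounding shell, and the estimate is the
  **median** (robust to unresolved doublets) per image and channel.

Copies = max(0, (SI_Total − SI_Bkgd)/SI_Spot); negative differences are
clipped to zero and logged, since copy numbers are physical counts.
Volumes assume sphericality, V = (π/6)·d³, so a 6.0 µm cell is 113 µm³ and a
3.5 µm cell 22 µm³; concentration is copies/V (copies/µm³). Reported
precision mirrors field convention: volumes to the nearest µm³, copies and
concentrations to one decimal.

When the cell of interest is undetectable, the positional fallback averages
the copy numbers of exactly four cells at its expected location; outputs
using it carry a fallback flag.

## Nuclei staging

Embryos are staged by the total embryonic nuclei count. The DAPI channel is
filtered with a DoG at **half** the nominal nuclear sigma (1.0 µm): filtering
at the full scale merges neighbouring nuclei (≥ 2.5 µm apart) into single
maxima, while half-scale filtering keeps them separable and remains far above
noise. A global significance gate (median + 6·1.4826·MAD of the DoG
response) decides whether any detection is attempted — at high nucleus
density the blobs themselves inflate the MAD, so the robust level is used as
a gate rather than a per-voxel floor — after which maxima above 25% of the
peak response are counted, with greedy suppression at 0.8 × the minimum
separation. On well-separated synthetic nuclei this is exact for counts
10–400.

## Fate classification on 4D lineage records

A lineage record stores, per tracked cell, its birth time and at most one
terminal event (division or corpse — the refractile "erythrocyte"/button
stage under DIC) plus the last observation time, in float minutes. Frame
quantisation (35 s frame interval, 105 s daughter-marking lag) is carried as
metadata, not enforced.

For each programmed-death candidate, with `M` its mother:

1. `mother_dies` if M has a corpse; `mother_division_blocked` if M never
   divided.
2. Otherwise the deadline is the earlier of birth + 2 × M's cycle length
   (factor configurable) and the start of the next division round —
   operationalised as the earliest division among tracked cells of the
   candidate's generation (divisions counted from the zygote, so the 13
   AB-derived first-wave deaths are generation 9 and MSpaapp generation 8).
   The two criteria are combined whichever-first; either can be disabled.
3. `cell_death` if a corpse formed by the deadline; `cell_death_blocked` if
   no corpse and the cell was observed past the deadline; `lost` otherwise.

Percent blocked = 100 × blocked/(blocked + died); lost and mother-phenotype
candidates are excluded from the denominator and tabulated separately.
Sisters of candidates are classified as divided / division-blocked (followed
at least two mother cycles) / inappropriate death / lost, or not-applicable
when the mother already shows a phenotype.

## Time-courses

Cross-embryo measurements are ordered by increasing nuclei count (stable
sort), then both the stage axis and the measured value receive a centered
running average of order 5 (odd, configurable). Each smoothed point carries
the SEM of its window (sample SD/√order) — a per-window band, which is one
reasonable reading of "SEM of averaged data points"; gaps in the stage axis
are not interpolated. The division landmark (~180 nuclei, when MSpaap
divides) is annotated on every output row.

## Comparison statistics

Group comparisons use the field's conventional tests behind a thin module
surface: the unpaired two-tailed Welch t-test (Welch–Satterthwaite degrees
of freedom) for time-to-corpse distributions, and the two-tailed
Mann-Whitney U for per-cell copy numbers — exact by enumeration for
tie-free pooled samples of ≤ 12, otherwise a normal approximation with
mid-ranks, tie-corrected variance and continuity correction; the method used
is recorded in the result. Degenerate inputs are defined explicitly: zero
pooled standard error with equal means gives t = 0, p = 1; an all-tied
pooled sample gives U = n₁n₂/2, p = 1. Both implementations are validated in
the tests against independent oracles (a from-first-principles Welch formula;
full permutation enumeration) and a 1000-replicate null simulation of the
type-I error. Embryonic-lethality tables are summarised per adult
(100·dead/(dead + hatched), adults with zero scored eggs excluded with a
warning) and aggregated as mean ± SD per genotype; brood size is the eggs
laid.

## The synthetic generator

The generator defines the study conditions; its defaults are the regime
parameters the analyses are tested under, and they are not tuned per test.

**Images.** mRNAs are 3D Gaussians (σ_xy = 0.13 µm, σ_z = 0.30 µm) rendered
by per-voxel error-function integration (so each spot's voxel sum equals its
drawn integrated intensity to < 2% quadrature error), on a grid of
0.12 × 0.12 × 0.5 µm voxels (typical 63× confocal sampling; the axial
spacing is the 500 nm used for smFISH stacks). Spot integrated intensities
are Gamma-distributed with mean `unit_integrated_intensity` (500 a.u.) and
CV 0.2, emulating probe-labelling variability. Spots are placed uniformly
inside the cell sphere inset by 2.5σ per axis, so that the rendered
point-spread mass lies inside the cell — without the inset, boundary spots
leak ~3% of their signal outside the integration disk and the conservation
property cannot hold; physically this reflects that the cytoplasmic spot
positions, not the blurred photon distribution, are confined by the
membrane. Nuclei are isotropic 1.0 µm Gaussian blobs on a jittered grid
guaranteeing ≥ 2.5 µm centre separation (so a detector of that resolution
can succeed), with 10% intensity scatter. Noise: constant or linearly
tilted background (default 5 a.u./voxel), Poisson shot noise, Gaussian read
noise (SD 2 a.u.). Identical seeds give bit-identical stacks.

**Lineages.** A `Regime` bundles a genotype's statistics, calibrated to the
printed study values: wild-type mother cycles 42 ± 8 min and 23.6 min mean
time-to-corpse; helicase-mutant-like (`psf2_like`) cycles 108 min (mothers of
dying daughters) / 101 min (mothers of blocked daughters) ± 30 min, 49.7 min
time-to-corpse, death-block probabilities 0.63 (AB-derived), 0.67 (MSpaapp)
and 0.29 (postembryonic QL.pp), and sister/mother division-block probability
0.342; `tyms1_like` with 125 min cycles but intact deaths; `ced3_like` with
all deaths blocked. Cycle ramps along the reference path (ABarp →
ABarpppppp) run 22 → 40 min (wild type) and 39 → 144 min (mutant-like) via a
constant per-round lengthening factor. Where the source material prints only
means, spreads were chosen once as plausible biology: time-to-corpse SD is
30% of the mean (truncated normal), mother-cycle SDs are 8 min (wild type)
and 30 min (long-cycle regimes, whose printed range spans 42–168 min),
reference-path cycle SD is 15% of the round mean. Times-to-corpse are drawn
truncated to (0, 2 × mother cycle), and cohort next-round divisions are
scheduled strictly after the embryo's last corpse; both choices make the
generator's ground-truth labels exactly recoverable by the classifier, which
is the oracle property the tests rely on. Each embryo gets its own random
substream spawned from the master seed, so any embryo is reproducible
independently.

Only two of the 13 AB-derived first-wave candidate names are fixed by the
study (ABalaapapa, ABalaappaa); the remaining eleven defaults are synthetic
placeholder names (valid Sulston strings) and the list is configurable.

**What the generator does not emulate:** real point-spread functions
(Gaussians only), spectral bleed-through, cell-shape deformation, spatial
transcript localisation within a cell, DIC imagery, or observer tracking
error. Passing tests therefore demonstrate correctness of the estimators
and rules under the stated noise model, not robustness to every artefact of
real confocal data.

## Problem sizes and numerical choices

Test and demo workloads are sized for a laptop-class single core: single-cell
stacks of 16 × 120 × 120 voxels, calibration fields of 50 singleton spots,
nuclei stacks up to 36 × 220 × 220 voxels at 0.2 µm lateral sampling, 100
cells for recovery properties, 170–500 embryos for 3-SE recovery of regime
means and rates, 1000 replicates for the type-I-error check. The full demo
pipeline (simulate → quantify → classify → timecourse → report) runs in a
few seconds. Copy numbers are clipped at zero; ROI placement outside the
image raises with the offending bound; every output file records the master
seed and a configuration hash, and reruns are byte-identical (the OME-TIFF
UUID is derived from the pixel data).

## Known limitations

- Calibration requires sparse single molecules somewhere in the image; in
  their absence `SI_Spot` must be supplied manually.
- The axial isolation requirement is generous (~3 µm) because of the 0.5 µm
  slice spacing; extremely crowded fields yield few isolated spots.
- The background consensus rule assumes at least three spot-free neighbour
  regions fit in the image; tight fields fall back with a logged warning.
- Percent-blocked aggregates per cell, not per embryo; with few embryos a
  per-embryo average could differ.
- The exact Mann-Whitney path requires tie-free data; ties always route to
  the corrected normal approximation, which is approximate for tiny samples.
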