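# Methods

## The temporal program model

Neuronal identity is modeled as a deterministic function of birthdate: a
`TemporalProgram` maps each TF to a half-open window `[on, off)` in embryonic
days, and a neuron born at day *b* expresses the TF iff `on <= b < off`.
Defaults encode the qualitative sequence of the temporal code — Onecut2
[e9.0, e10.5), Zfhx3 [e9.0, e11.5), Pou2f2 [e10.5, e11.5), and Nfia, Nfib,
Neurod2 [e11.5, e13.5) — so that Zfhx3 marks neurons born before e11.5 and
Nfi/Neurod TFs neurons born after.  Windows are configuration, not
constants: any program satisfying the ordering invariants (Onecut2, Zfhx3,
Nfib midpoints increasing; Zfhx3 and Nfib windows disjoint) is accepted.
Cycling progenitors have no birthdate; late progenitor genes (Sox9 onset
e11.0; Nfia/Nfib onset e11.5) switch on in all progenitors once the
collection day reaches the onset.  Nfia and Nfib intentionally appear in
both maps: they are late-neuron markers *and* late-progenitor markers.

## Synthetic sections

Sections emulate transverse neural-tube cryosections in four 16-bit channels
(DAPI, class marker HuC or Sox2, one temporal TF, EdU).  Nuclei are ellipses
(major radius 5–9 px, axis ratio 0.7–1.0, random orientation) placed by
rejection sampling with minimum center spacing 1.5× the maximum radius; a
bounded retry budget converts overcrowded specs into an error that names the
achievable density.  The intensity profile is flat-top with a 1-px Gaussian
skirt that decays outward only, so the plateau is exact.  Noise is additive
Gaussian with sd = (signal unit)/snr; Poisson photon noise is deliberately
not modeled so the snr invariant stays analytic.  Stained nuclei are
rendered 15% above the nominal signal unit; this makes the stated snr a
strict lower bound on class separation (in noise-sd units) despite edge
softening, zero-clipping of the background noise, and 16-bit quantization.

EdU labeling does not model S-phase kinetics: a neuron is EdU-true iff its
birthdate lies within ±`edu_window_halfwidth` (default 0.25 day — a modeling
choice, exposed in `SectionSpec`) of the pulse; progenitors are labeled by an
independent Bernoulli (default 0.3) standing in for the fraction in S-phase
at the pulse.  Birthdates are drawn from a configurable mixture over a
0.25-day grid (default uniform on e9.0–e13.0).  Progenitor rows carry
birthdate NaN.

What passing tests show — and do not.  Recovery within ±5 percentage points
on these sections demonstrates that the measurement chain (segmentation,
normalization, trimming, classification, thresholding, counting) is
internally consistent and unbiased under the stated noise model.  It does
not certify performance on real cryosections, which add tissue autofluores-
cence, uneven illumination, anisotropic nuclei, true optical blur, and
segmentation-relevant crowding that the generator's spacing rule excludes.

## Image quantification

Segmentation thresholds the (optionally Gaussian-pre-smoothed, sigma 1 px)
DAPI channel at local mean + offset, computed over an odd square block
(default 51 px).  The offset defaults to 8% of the per-image dynamic range:
a pixelwise local-mean threshold needs an offset of roughly 3 noise sd to
keep the background speckle-free, and 2-3% offsets admit large fractions of
pure-noise pixels at any realistic snr.  Touching nuclei are split by a
watershed seeded at regional maxima of the smoothed distance transform with
a minimum seed separation (default 6 px ≈ 0.8× the expected radius).  All
parameters sit in `SegmentationConfig`, mirroring a protocol in which they
were tuned per image set.

Conventions, chosen where the protocol leaves room:

* normalization is min–max over **all** nuclei of a section per channel
  (progenitors and neurons), computed before trimming;
* trimming removes round-half-up(0.003·N) objects per tail, per channel
  independently; "0.3%" is read per tail;
* positivity and HuC classification are strict (`> 0.25`); Sox2-absence
  classification is the complement (`<= threshold` means neuron);
* pipeline order: normalize -> classify -> call;
* coordinates are 0-based row/col pixels, areas in px².

## Flow gating

The dynamic gate takes the (1 − f) empirical quantile (type-7, linear
interpolation) of the Sox2⁺ progenitor marker intensities with f = 1.5%, the
midpoint of the 1–2% calibration band.  With at least a few hundred
progenitor events the realized progenitor-positive fraction stays inside the
band.  Below 50 progenitor events the gate refuses and recommends global
mode.  The global threshold (for markers expressed in both compartments,
e.g. Nfia) defaults to the 97.5th percentile of pooled progenitor + neuron
intensities — a placeholder convention that presumes rare positives; when
positives are common, supply an explicit threshold.  Sox2/Tubb3 gates are
rectangles; real 2D polygon gates are not representable from a text
protocol.  Welch's t statistic and the Welch–Satterthwaite df are computed
from the textbook formulas (p from the t distribution); both-groups-constant
input degenerates to t = 0, p = 1 with a log message.

## Temporal marker discovery

Normalization rescales every cell to exactly 10,000 counts, then stores
log1p alongside.  For each domain and stage (one-vs-rest, stages with fewer
than 3 cells skipped with a warning): detection fractions are computed on
nonzero expression; genes pass if max(pct_in, pct_out) ≥ 0.25; the fold
change is the natural log of the ratio of group means of expm1(lognorm) with
pseudocount 1 (the convention of the popular single-cell toolkit, so results
are comparable); surviving genes get a two-sided Wilcoxon rank-sum p on
log-normalized values — exact enumeration over all label assignments
(mid-ranks, doubled smaller tail, capped at 1) when both groups have ≤ 8
cells, tie-corrected normal approximation otherwise — Bonferroni-adjusted
over the genes tested in that comparison.  "Detected in a domain" means
significant for **any** stage there; the cross-domain filter keeps genes
strictly above `min_domains` (default 7) eligible domains, dp6 excluded.

The count generator plants monotone geometric ramps (default 4× first-to-
last stage, up or down) in 9 of the 10 eligible domains, on a negative-
binomial background (var = mu + 0.5 mu², log-normal size factors, sd 0.3).
The default 50 cells per domain × stage group (2,750 cells, 525 genes, 25
planted) is the smallest configuration at which the full filter chain
recovers planted genes at ≥ 0.9 sensitivity with ≤ 0.1 false-discovery
proportion across seeds; detection must succeed in ≥ 8 of 9 planted domains
simultaneously, which demands high per-domain power.

## Correlation dynamics

Stage profiles are per-stage means of log-scaled expression, z-scored across
stages (population sd; rows constant to within 1e-12 relative tolerance
become zero rows, logged).  The in-vivo/in-vitro partition pairs stages
positionally (default e9.5→D5 … e13.5→D9), intersects gene universes, and
classifies by Pearson r with strict boundaries (> 0.5, < −0.5); r is
reported without a p-value — five stage points do not support one.
Undefined correlations (a constant profile) map to uncorrelated with a flag
rather than being dropped, so the three classes always partition the gene
universe.

The paired-profile generator plants three geometries: shared dynamics
(vitro = vivo + noise), sign-flipped (−vivo + noise), and *orthogonal*
dynamics for the uncorrelated class.  Orthogonality is deliberate: with only
five stage points, independently drawn profiles exceed |r| = 0.5 about 39%
of the time, so an "independent" label would not test what the partition
measures; orthogonalized planting makes the truth labels meaningful at the
default noise sd 0.2.

## Pseudotime

Lineage ordering is deliberately minimal: the unique start→end path in the
Euclidean minimum spanning tree of cluster centroids, with cells of on-path
clusters projected onto the piecewise-linear centroid path and arc length
rescaled to [0, 1].  This replaces iterative principal-curve fitting; the
binning/normalization protocol downstream is the quantity under test.
End cluster defaults to the centroid farthest from the start.  Curve
exclusion is by explicit user list, mirroring a manual-judgment step; an
advisory segment-intersection check warns about self-crossing centroid
paths but never auto-excludes.

Expression along pseudotime is LOESS-fitted (local linear, tricube weights,
span 0.75 — the common plotting default; no robustness iterations) and
evaluated at the midpoints of 30 equal bins; fits are floored at 0; each
gene is divided by its maximum over all stages' bins, so the global per-gene
maximum is exactly 1.  Fewer than 10 points is an error; a span window of
fewer than 4 points falls back to a global linear fit with a log message.
Note that a span of 0.75 on a [0, 1] trajectory is strongly smoothing:
expression peaks planted near the trajectory ends are pulled into the
terminal bins (argmax 0 or 29).  The wave-order statistic is unaffected — it
uses only the ordering of the per-group median argmax bins (strictly
increasing early < intermediate < late at every stage with at least one
expressed gene per group).

The trajectory generator places cells along a quarter-circle arc by a latent
maturation coordinate, with Gaussian-bump expression profiles (default peaks
at maturation 0.12 / 0.50 / 0.88 for the early / intermediate / late TF
groups, width 0.15).

## Determinism and orchestration

Every generator is a pure function of (spec, seed) using a dedicated
`numpy` Generator; identical inputs give bit-identical images and tables.
The CLI fans a single seed out to independent per-stage seeds through
`SeedSequence`, so stages can be re-run in isolation; the demo writes a
config echo with a hash, and its CSV/JSON outputs are byte-identical across
reruns with the same seed.  Demo problem sizes (2 sections per pulse day ×
3 TFs × 4 pulses; 160 genes × 1,650 cells with 8 planted TFs; 8,000 flow
events × 3 replicates × 2 conditions; 300 gene profiles; 3 trajectories of
600 cells) were chosen as the smallest configurations at which each stage's
recovery statistics are stable, keeping the full demo to a few seconds.

## Known limitations

* The image model omits optical blur beyond edge softening, illumination
  gradients, autofluorescence, and nuclear crowding; segmentation parameters
  will need retuning on real data.
* The EdU window model ignores cell-cycle kinetics; the ±0.25-day window is
  a stand-in for S-phase labeling dynamics.
* The rank-sum exact branch enumerates up to C(16, 8) label assignments;
  larger groups rely on the normal approximation with tie correction.
* The MST-path ordering handles single unbranched lineages only; branching
  trajectories and curve crossings require external curation via the
  exclusion list.
* The global flow threshold convention assumes rare positives and should be
  overridden when a marker is broadly expressed.
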