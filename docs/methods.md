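# Methods

This note documents the models, parameter choices and numerical decisions
behind `tetrace`, and what the synthetic study does and does not emulate.

## Coordinates and counting units

All internal coordinates are 0-based half-open; conversion to and from the
1-based inclusive conventions of RepeatMasker `.out` and GTF happens only in
`annotations_io`. The counting unit is the *fragment*: the two mates of a
proper pair are merged into one alignment hit, and multi-mapper multiplicity
is taken from the NH tag (falling back to counting records per query name).

## Fractional counting

For each hit of a fragment, the overlap with a feature is the number of
aligned bases inside the feature after merging the hit's blocks, so bases
covered by both mates count once — a 2×100 pair straddling a 30 nt feature
cannot clear the 30 nt minimum by double-counting. Every feature overlapped
by ≥ `min_overlap` (default 30) bases receives 1/(n_hits · |S|). The rule is
verified exactly against a per-base all-pairs enumerator in the tests. No
EM-style reassignment of multi-mappers is attempted; assignment is uniform
across hits, which is unbiased when homologous copies are expressed alike
(as the simulated ERV LTR pairs are) and dilutes family signal otherwise.

## The two FPKM statistics

Count-based FPKM uses the factor 10⁹ = 10³ (per kb) · 10⁶ (per million).
Coverage-based FPKM sums per-base depth C over the element and divides by
read length, element length and library size. One unit subtlety matters:
depth is accumulated per *read*, so a paired library deposits 2·L_read
bases per fragment. C/L_read is then in read units and the library-size
term must also be in read units (2 × fragments for paired data); otherwise
the coverage statistic is inflated 2× relative to the count statistic and
its sampling noise at a filter threshold doubles. With read-unit totals the
identity FPKM_cov = FPKM_count holds exactly for unique-mapping, fully
contained fragments, and this identity is asserted in the tests.

Coverage includes every reported hit of multi-mappers (as a pileup of all
alignment records would); a unique-only mode is available. Consequently the
coverage FPKM of an ERV LTR with a structurally homologous partner is
inflated by roughly the multi-mapping fraction — a sensitivity/specificity
trade-off inherent to the statistic, not corrected for.

## Filter cascades

The shared predicate is max(profile) ⋛ min_fpkm AND sd(profile) ⋛ min_sd.
Defaults: genes 20/20 and LTRs 5/5 on the 7 replicate-averaged timepoints
with "at least" (≥) semantics; TF candidates 5/5 likewise. For TEs two
published variants of the threshold exist (5/5 evaluated per library
across all 14 profiles, or >10/>5 on the 7 averages); both are provided as
presets (`TE_FILTER_RESULTS`, `TE_FILTER_METHODS`) and the per-library 5/5
variant is the default. They are not reconciled: the choice is recorded in
the `FilterConfig` so either cascade is reproducible. The standard
deviation uses the sample (n−1) denominator by default; `ddof` is
configurable. Gene-overlap exclusion removes any element sharing ≥ 1 base
with a *coding* gene body (half-open adjacency is not overlap).

Proximity classification measures the edge-to-edge gap in nt to the nearest
gene body: 0 = overlapping-gene, gap < 5000 = near-gene (strict
inequality), otherwise solo; an LTR on a chromosome without genes is solo
with infinite distance. `upstream_flag` is true when the LTR lies 5′ of
the nearest gene's TSS on that gene's strand.

## SOM clustering

Profiles are row z-scored (population variance; constant rows become zero
vectors with a warning). The map is a rectangular grid trained online:
prototypes are initialized from seeded random data rows; each step presents
one random profile and pulls the best-matching node and its neighbours by
α(t)·h(t)·(x−w), with α decaying linearly 0.1 → 0.005 and a Gaussian
neighbourhood whose radius decays linearly from max(grid dims)/2 to 0.5
over 20,000 iterations. Euclidean distance throughout; empty nodes are
reported with n = 0 rather than forcing reassignment. Training is performed
on rows sorted by feature id, making the result invariant to storage order,
and is deterministic given the seed.

Two robustness choices:

* **Restarts.** A single online run can land in a poor map — typically an
  empty node while two temporal programs share one prototype. `train_som`
  trains 5 independently initialized maps (sub-seeds derived from the main
  seed) and keeps the one with the lowest quantization error.
* **Grid sizing.** The class defaults (genes 4×4, TEs 2×3, LTRs 1×5) suit
  study-scale feature sets of hundreds to thousands of profiles. When a
  feature set cannot populate the grid (fewer than ~10 profiles per node),
  `choose_grid` falls back to a 1-row map with about n/10 nodes, so
  coherent programs are not shredded across near-empty nodes. On the
  default toy study this gives genes a 1×3 map.

A "transient" cluster (used to select the LTRs entering the TF correlation
stage) is a node whose prototype peaks at the 2nd or 3rd timepoint *and* is
below the profile mean both before activation and at every later timepoint
— i.e. activated early and then silenced, which distinguishes it from a
gradually decreasing program whose prototype can also peak near the start.

Because SOM hyperparameters for this kind of analysis are conventionally
unpublished, membership-level reproduction of any particular study is not a
goal; pattern-level structure (which programs exist, which elements follow
them) is the tested contract.

## Enrichment

`enrich` tests each GO term with ≥ 1 cluster gene using the hypergeometric
upper tail P(X ≥ k) for k successes among n cluster genes, K term genes and
N background genes, then applies Benjamini–Hochberg across all tested
terms; significance is p_adj < 0.05. The gene→term map is flat: no GO-graph
ancestor propagation (supply a pre-propagated map if wanted). The
background is the annotated universe intersected with the quantified genes.

## Correlation inference

TF–LTR association is Pearson's r over the 7 replicate-averaged timepoints
(n = 7, df = 5), two-sided p from the t transform. This df is the
internally consistent choice: at df = 5 the 5% boundary is r ≈ 0.7545 and
the 1% boundary ≈ 0.875, which matches the significance calls the method is
designed to reproduce, whereas df = 12 (14 libraries) would not.
Zero-variance profiles yield flagged pairs, excluded from clustering (or
imputed as r = 0 with a warning where the bicluster needs a complete
matrix). Biclustering is agglomerative with Euclidean distance on the raw
r rows/columns and average linkage; the "top" TF group is the root-split
branch with the higher mean r.

The analytic p-values are checked against a 10,000-draw permutation null.
Note that a permutation p conditions on the drawn sample: across random
datasets at n = 7 the per-dataset deviation from the t-based p has a
heavy tail (90th percentile ≈ 0.025), which is conditioning scatter, not
mis-calibration. The acceptance script therefore reports the mean
deviation over a 20-dataset grid of moderate-to-strong correlations (the
regime where the significance calls live), ≈ 0.005–0.015.

## Synthetic study

The generator emulates the study design: 7 timepoints × 2 replicates,
paired 2×100 nt fragments (insert 200 nt), a 1 Mb single-chromosome
genome carrying 60 coding genes (2 kb), 8 TF genes, 40 solo LTRs (800 nt,
6 of them planted 2 kb from a transient gene), 10 full ERVs
(600 nt LTR – 3 kb internal – 600 nt LTR) and 20 LINEs/SINEs. Five
temporal programs are planted: transient (high at timepoints 2–3, near
zero elsewhere), gradual up, gradual down, constant (flat but expressed —
must fail the sd filters) and low (must fail the peak filters). Planted
amplitudes sit well clear of the filter thresholds (e.g. transient LTRs
peak at 30 FPKM against the 5/5 filter) so that recovery measures the
pipeline, not threshold luck.

Counts are negative binomial with mean μ = FPKM · length(kb) ·
library_size(millions) and dispersion 100 (replicate CV ≈ 10%, i.e. highly
reproducible replicates); `dispersion=None` switches to deterministic
rounded counts. The default library size is 2 million fragments — a
deliberately scaled-down bulk library chosen so that one fragment
corresponds to ≲ 0.6 FPKM for the shortest elements, keeping count
granularity well below the 5-FPKM filter threshold. Fragments are placed
uniformly within their feature; 30% of ERV-LTR fragments are emitted with
n_hits = 2, the second hit at the same offset in the element's homologous
partner LTR, so multi-mapping is structural rather than random. A planted
GO term covers 80% of the transient gene cluster versus 10% of the rest,
among 15 decoy terms; three TF genes share the transient program (planted
activators), the rest are gradual or constant.

Not emulated: sequencing errors, GC/positional bias, introns and splicing,
fragment-length variation, genuinely divergent TE family copies, and
alignment itself (alignments are emitted directly, so aligner artefacts are
out of scope). Passing the recovery tests therefore demonstrates the
correctness of the pipeline's arithmetic and decision rules under a clean
generative model, not robustness to alignment noise on real genomes.

## Problem sizes

The default test suite and the acceptance script run the full synthetic
study (14 libraries × ~11k aligned fragments, ~160 annotated features) end
to end in well under a minute, with the counting/coverage/hypergeometric
oracle checks on instances of ≤ 100 fragments × ≤ 20 features and N ≤ 12
populations; these sizes exercise every code path while keeping the
enumeration oracles exact.
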