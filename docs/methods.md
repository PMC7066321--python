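# Methods

`vpcontact` analyzes viewpoint-based chromatin-interaction assays: 4C-seq
(all genomic contacts of one bait restriction site) and Capture-C (contacts
of a probe-captured viewpoint fragment, read out as ligation junctions in
paired-end reads). This note describes the models, the choices behind every
tunable parameter, what the synthetic libraries do and do not emulate, and
the known limitations.

## The 4C calling model

All coordinates live on the restriction map of the digestion enzyme
(HindIII by default for 4C): each chromosome is an ordered list of motif
sites; fragments are the intervals between them (0-based, half-open, cut
modeled at the motif start — sticky-end chemistry is irrelevant for
site/fragment identity).

Reads carrying the bait-specific primer as an exact prefix are trimmed and
assigned to the restriction site whose adjacent 40 bp fragment-end sequence
they match exactly (synthetic path), or imported as pre-mapped coordinates
(real-data path; read alignment itself is out of scope). Per-site counts
are then **binarized** (1 iff at least one ligation observed). Binarization
is the duplication defense: any PCR copy number maps to the same indicator,
so calls are provably invariant to amplification bias — a property the test
suite checks end to end.

For each site *i*, a foreground window *w* of `l_w` sites centered at *i*
is scored against a background window *W* of `L_W` sites (cis) or the whole
chromosome (trans):

    mu_W = S_W * l_w / L_W          (S_W = indicator sum in the background)
    z_i  = (C_i,w - mu_W) / sqrt(mu_W (1 - mu_W / l_w))

`C_i,w` is the foreground indicator sum; the variance is binomial with
success rate `mu_W / l_w`. The one-sided upper-tail Gaussian p-value is
compared against 0.05: the statistic detects *enrichment*, which is the
only biologically meaningful direction for a viewpoint assay. No
multiple-testing correction is applied by default (a BH option exists in
the differential module); the raw `p < 0.05` rule is the method's stated
convention.

Defaults: cis `l_w=100, L_W=3000`, trans `l_w=500` with whole-chromosome
background — sizes appropriate for mammalian chromosomes (tens of
thousands of sites). Design details the method itself leaves open were
fixed as follows:

* **Window centering and edges.** Half-width is floored (`l_w//2`), so the
  effective foreground is the next odd size; windows truncate at chromosome
  ends and the expectation rescales by the realized lengths, keeping it
  unbiased.
* **Degenerate windows.** `mu_W = 0` (no background evidence) or
  `mu_W = l_w` (zero variance, saturated background) return a
  non-significant sentinel (`z = NaN, p = 1`) and are excluded from the
  evaluated-site population: no finite test exists there.
* **Bait exclusion.** Cis sites within 10 sites of the bait are excluded
  from calling (configurable): self-ligation/religation makes the proximal
  zone uninformative.
* **Region merging.** Runs of flagged sites separated by at most 1
  unflagged site (configurable) merge into one region spanning from the
  first member site to the end of the last member's fragment, so region
  endpoints lie on restriction-site coordinates.
* **Replicate overlap.** High-confidence regions are the >= 1 bp pairwise
  intersections of two replicates' calls, trimmed to the intersection.

## The Capture-C chain

Read pairs are filtered (either mate < 20 bp or mean Phred < 20 discards
the pair — the quality rule is read-level by design; per-base trimming is
an upstream concern), merged when their ends share an exact overlap of
>= 10 bp, and digested in silico at internal motif occurrences (the motif
stays attached to the downstream piece, mirroring the genome convention).
Pairs that fail merging are analyzed as two independent mates, flagged as
such. Sub-fragments are mapped by unique exact match against the genome on
either strand (real data would come pre-mapped through the BED import
path) and classified: `capture` if intersecting the viewpoint fragment,
`proximity_exclusion` if intersecting the 1 kb flank on either side,
`reporter` otherwise. Reads with identical ordered sub-fragment
compositions (chrom, start, end, strand) are PCR duplicates; one survivor
is kept per class. Reporter sub-fragments of reads that retain a capture
sub-fragment increment the restriction fragment containing their midpoint
(midpoint assignment is robust to partial pieces at read ends); the
per-fragment counts are the bedGraph profile.

**Differential sites.** The comparison between two conditions is
deliberately minimal: replicates pooled per condition, per-fragment 2x2
tables (fragment vs rest-of-library) tested two-sided with Fisher's exact
test, BH-adjusted, reported at FDR 0.05 with the direction of the relative
change. Because profiles are compositional, a genuine gain at one locus
necessarily depresses every other fragment's relative frequency; in the
validation scenario those depletion-direction echoes appear alongside the
planted hub and are expected, while spurious *enriched* calls outside the
hub are not (and the tests assert none occur).

## The synthetic libraries

The generator exists to give every pipeline stage exact ground truth.

* **Genome.** Random sequence with the enzyme motif planted at a target
  spacing of 1000 bp, jittered uniformly +/-25%; spurious motif occurrences
  are patched out, so the restriction map is exactly the planted site list.
  Default genome: 2.5 Mb over four chromosomes (bait chromosome 1 Mb).
  These sizes keep every simulation seconds-fast while leaving hundreds of
  sites per chromosome for windowed statistics.
* **Partner mixture.** A cis site at distance `d` (in sites) from the bait
  has weight `(1+d)^-alpha` with `alpha = 2.0`; trans sites have uniform
  weight `1e-5`; planted regions multiply site weights by an enrichment
  factor >= 1; probabilities normalize to 1 with the bait at 0. The steep
  decay concentrates the bulk of ligations in the bait-proximal religation
  zone, as real 4C libraries do, and leaves per-site coverage of order one
  in far-cis — the regime where windowed detection actually operates. The
  trans baseline follows from typical 4C read allocation (roughly a third
  of reads in trans spread over ~7x10^5 genome-wide sites, versus a few
  percent on the single bait-adjacent fragment, a ~1e-5 ratio).
* **4C reads.** primer (the 25 bp immediately upstream of the bait site,
  checked unique in the genome) + the first 40 bp of the partner fragment;
  40 bp is shorter than any simulated fragment yet long enough for unique
  exact-match assignment.
* **Capture-C molecules.** A junction-anchored suffix of the viewpoint
  fragment joined to a prefix of the partner fragment (which begins with
  the motif), shear lengths uniform 40-110 bp for overlapping pairs (125 bp
  mates then always merge) or 126-150 bp for deliberately non-overlapping
  pairs. Shear lengths are rejection-sampled so **unique molecules never
  share a sub-fragment composition**, making composition dedup exact on
  error-free data. Real libraries violate this at high per-fragment
  coverage (two genuine molecules can shear identically), so real dedup
  slightly over-collapses; the simulator's guarantee isolates the
  bookkeeping property under test. Partner orientation is always forward;
  strand sensitivity of dedup is covered by constructed cases instead.
* **PCR duplication.** Each molecule is emitted `1 + Geometric(rate)`
  times from a dedicated random stream, so the molecule draws are
  invariant to the duplication rate — which is what makes the
  duplication-invariance test exact rather than statistical.
* **Not emulated.** Base-call errors (off by default; a uniform
  substitution option exists), realistic quality profiles, digestion
  inefficiency, chimeric artifacts beyond the modeled junction, mapping
  ambiguity of repetitive genomes. Passing tests therefore demonstrate the
  correctness of the analysis logic, not robustness to alignment noise.

## Validation scenarios and problem sizes

* **Null calibration**: 20 simulations, no planted regions, 50k molecules,
  1 Mb genome (400 + 3x200 kb) at 1 kb spacing. The flagged fraction is
  measured over evaluated (non-sentinel, non-excluded) sites.
* **Recovery**: 5 seeds, 100k molecules, default 2.5 Mb genome, 5 cis + 5
  trans planted regions of ~20 sites at weight 10. Cis hubs sit 260-450
  sites from the bait: with `alpha = 2` at this depth the expected
  molecules per site is ~7.7e4/d^2, so binarized occupancy saturates out
  to d ~ 250 and only beyond that does enrichment have dynamic range — the
  same reason real 4C calls exclude the viewpoint's shoulder.
* **Window scaling.** Chromosome-scale windows (100/3000, 500) do not fit
  chromosomes of a few hundred sites, so validation uses scaled analogs —
  cis 11/121, trans 25/whole-chromosome — preserving foreground <<
  background <= chromosome. Package defaults remain the full-scale values.
* **Capture-C exactness**: 1000 molecules at duplication 0.5;
  **differential detection**: 2 replicates x 4000 molecules per condition,
  one cis hub (weight 20 vs 1) 20-40 sites from the viewpoint, where
  baseline reporter coverage supports count-based testing at this depth.

### Calibration at desk scale

Two facts temper the null-calibration numbers. First, the statistic is a
one-sided test on an integer count thresholded at a continuous Gaussian
quantile: the achievable rejection probability rounds *down*, so the
realized type-I rate sits below the nominal 0.05 — negligibly at
`l_w = 100-500` (measured 0.048-0.057 on homogeneous 70k-site tracks), but
worth ~0.005 at `l_w <= 25`. Second, windows whose background is nearly
saturated (`mu_W` close to `l_w`) have an empty 0.05 rejection region
(the largest achievable z is `sqrt(l_w (l_w - mu_W) / mu_W)`), and at 50
molecules per site much of the cis chromosome is in that state. The
measured desk-scale null flagged fraction is therefore ~0.03 rather than
0.05. This is a property of the discrete statistic at these problem sizes,
not an implementation defect; the formula itself is verified against
independent arithmetic to 1e-12.

## Numerical and degenerate-input conventions

Ties and boundaries are half-open everywhere; a position equal to a
fragment end belongs to the next fragment. A chromosome with fewer sites
than the foreground window is skipped with a logged warning. Ambiguous
fragment-end sequences (shared by two sites) are excluded from assignment
and logged; ambiguous sub-fragment matches are left unmapped. Enrichment
thresholds are strict inequalities. qPCR technical replicates are averaged
on the Ct scale (geometric on the linear scale), with per-replicate values
available for dispersion checks.

## Known limitations

* Exact-match assignment is only valid for the error-free synthetic path;
  real libraries must come pre-mapped (BED import).
* The Fisher/BH differential test is a minimal count-based choice, not a
  dispersion-aware model; with many replicates a negative-binomial GLM
  would be preferable.
* The simulator's forward-only partner orientation and guaranteed-unique
  shear coordinates idealize real library anatomy (see above).
* Region merging and the replicate-overlap rule are parameterized
  conventions; no claim is made that they match any particular published
  merging rule.
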