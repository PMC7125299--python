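# Methods

`cyanoscreen` re-implements, as a tested library, the computational
workflow of a pooled inducible CRISPRi fitness and productivity screen in
a cyanobacterium: genome-wide sgRNA design, read counting, fitness and
growth-rate inference from turbidostat competitions, depletion-pattern
clustering, and hit selection for tolerance and droplet-sorted
productivity screens. A synthetic-data module generates every input with
recorded ground truth so that each stage can be validated end to end
without external sequencing data.

## sgRNA library design

Candidate protospacers are enumerated per gene so that the NGG PAM lies on
the gene's coding strand; equivalently, the template strand matches
5'-CCN[20–25 bases]T-3'. The terminal T on the template guarantees the
transcribed spacer starts with A, matching the +1 adenine preference of
the promoter driving sgRNA expression. When several spacer lengths match
at the same PAM, the site collapses to the shortest spacer, keeping
spacers in the standard 20–25 nt range.

Placement is anchored at the annotated TSS when present, else the start
codon. The PAM-proximal protospacer end must fall within
`min(max_tss_dist, ceil(max_gene_fraction × gene_length))` nt downstream
of the anchor (defaults 500 bp and 0.75). We read the published "within
500 bp of the TSS or within 75 % of gene length" rule as an intersection;
a union would admit sites 500 bp into short genes, where repression
efficiency drops steeply. Both bounds are configurable.

Composition filters: no run of six G, no run of four T (an internal
terminator for the U6-like polymerase context), and GC content within
[0.25, 0.75], boundaries inclusive.

Off-target counting follows the PAM-proximal seed model of dCas9
specificity: a genomic site counts when its 17 nt adjacent to an NGG or
NAG PAM (either strand, circular replicons wrap) are within one mismatch
of the spacer's PAM-proximal 17-mer. The guide's own site is excluded by
exact position. The production scanner vectorizes the exhaustive scan
with numpy sliding windows over pre-extracted PAM-adjacent 17-mers rather
than using a seed-and-extend index: at bacterial genome scale the
exhaustive comparison takes milliseconds per spacer, is trivially exact,
and is proven equivalent in the test suite to a per-position pure-Python
brute-force oracle, including planted 0/1/2-mismatch NGG/NAG sites on
both strands.

Selection takes, per gene, the candidate with the fewest off-targets,
breaking ties by anchor proximity and then leftmost coordinate, and then
the next-ranked candidate at least 10 nt away when one exists (falling
back to the next-ranked overall). Selection is invariant under permutation
of the candidate list.

## Read counting

Reads are assigned by exact dictionary matching: the bases after the 5'
flanking anchor of the expression cassette are matched against library
spacers, longest match first for nested spacers of mixed length; the 3'
flank, when found, truncates the window. No mismatch tolerance is applied
— library spacers are synthetic sequences, and the simulator emits
error-free reads, so round-trips are exact. Unassigned reads are tallied
and the conservation identity assigned + ambiguous + unassigned = total
holds per sample. The flanking anchors are configuration; the defaults are
the simulator's.

## Fitness scores

Counts are normalized by median-of-ratios size factors (geometric-mean
reference over guides detected in every sample; total-count fallback with
a warning otherwise). log2 fold-changes are computed within each replicate
against that replicate's induction (t = 0) sample with a +0.5 pseudocount,
then averaged across replicates. Time is converted to cell generations,
n_gen = μ_pop · t / ln 2, from the population growth rate recorded in the
sample metadata.

The fitness score of a trajectory is the trapezoid area under log2FC over
n_gen, normalized by the generation span:

    F = AUC(n_gen, log2FC) / max(n_gen)

so a constant trajectory has F equal to the constant, and F is linear in
the trajectory. max(n_gen) is taken per condition (each condition's own
span); differential fitness is ΔF = F_a − F_b, flagged at |ΔF| ≥ 3 by
default. Gene-level fitness is the mean of the (up to two) guide scores;
genes are eligible for condition-differential calls only when both guides
fall in the same depletion cluster.

Significance of count changes between two sample groups uses a
negative-binomial Wald test with per-guide method-of-moments dispersion
pooled across groups, a Student-t reference with n₁+n₂−2 degrees of
freedom (the plug-in standard error makes the statistic t-like at
screen-typical replicate numbers), and Benjamini–Hochberg adjustment
across guides. This is a documented approximation of the shrinkage-based
count-model packages usually applied to such data; it is calibrated by
simulation in the test suite (null p-values roughly uniform; 8-fold
depletions at ~100 reads/guide and 4 replicates detected at
p_adj < 0.005 with ≥ 95 % sensitivity and ≤ 1 % false positives) rather
than by matching any particular package's p-values.

## Growth-rate estimation

A clone's abundance fraction under competition is modeled as a discrete
per-hour decay,

    f(t) = f(0) · (1 − (μ_pop − μ_mut))^t,   t in hours, rates in h⁻¹,

inverted by least squares on log f(t) over points with f > 0:
μ_mut = μ_pop − (1 − e^slope). Flat trajectories return μ_mut = μ_pop
exactly, and noiseless model trajectories invert to machine precision.
Clones that vanish after t = 0 cannot constrain a slope; they are fitted
against a detection floor (half the smallest observed positive fraction)
and flagged as lower bounds.

Because observed fractions are renormalized over the population, the
shared normalizer adds a small common bias to every fitted slope (the
population-average depletion rate). Under the simulated study conditions
(10 % of clones depleted) this bias stays well under the sampling error;
the acceptance suite requires median |μ̂ − μ| < 5 % of μ_pop at depth 10⁶
and recovers ≈ 2 %.

## Depletion-pattern clustering

Guides are clustered on their concatenated log2FC vectors across
conditions and timepoints (missing values imputed as 0 with the mask
recorded) by Ward-linkage agglomerative clustering on Euclidean
distances. Mean silhouette widths are reported for k = 3..9; in this kind
of data the silhouette is typically flat over that range, so k is a
configuration choice, default 6. A merge rule then combines clusters
whose centroids stay within a near-zero band (max |centroid| < 0.5) into
a single "unchanged" cluster — the analogue of presenting two
indistinguishable no-change clusters as one. Final labels are ordered by
increasing centroid mean, most depleted first.

## Tolerance and droplet-screen hit selection

Stress-specific enrichment requires log2FC ≥ 2 and −log10 p ≥ 20 in the
stress condition and failure of at least one threshold in the control.
Stress-specific depletion ranks guides by dF = F_control − F_stress and
takes the top 200, reporting genes with both guides in the top set; ties
at the cutoff break by guide id.

The droplet pipeline floors each sample at 32 reads (per sample, not
globally), computes enrichment factors EF = relative abundance in the
sorted fraction / relative abundance in the unsorted library (relative
abundances on post-floor totals; absence in either fraction yields no EF,
never infinity), drops guides whose EFs differ ≥ 10-fold between paired
replicate runs, scores a run 1 when EF ≥ 3, and calls a clone a hit at
≥ 2 scores over the four runs. The EF threshold is exposed as `--ef-min`
because reasonable analyses have used 2 or 3; the default is 3. Raising
`ef_min` can only remove hits and lowering the read floor can only keep
more guides (monotonicity is tested).

Expression-variability binning computes a one-way ANOVA p-value per
protein across growth-rate levels and bins it into descending half-open
intervals (1–0.1, 0.1–0.05, 0.05–0.01, 0.01–0.001, < 0.001], upper bound
inclusive, so p = 0.05 falls in the 0.05–0.01 bin; constant proteins get
p = 1.

## Synthetic data: what it emulates and what it does not

`make_genome` draws a random circular replicon at a target GC content
with non-overlapping ORF/ncRNA features on both strands, each with a TSS
0–50 nt upstream of its start codon. `plant_site` edits in a spacer copy
with a chosen number of PAM-proximal mismatches and PAM variant,
re-randomizing (then failing loudly) if the edit would create additional
near-matches — the fixture for the off-target oracle.

`simulate_competition` evaluates the depletion model per clone,
renormalizes fractions per timepoint (a turbidostat holds total density
constant; both raw and renormalized fractions are recorded), and samples
reads multinomially at the configured depth — default 75 reads per clone
per sample, the midpoint of typical screen coverage — or
Dirichlet-multinomially with concentration 200 × n_clones for mild
replicate overdispersion (∞ gives exact multinomial). Sample sizes in the
bundled studies follow the screen proportions: four replicates, μ_pop
0.07 h⁻¹ or 0.03 h⁻¹ scale, ~32 generations.

`simulate_droplet_screen` gives each droplet Poisson(λ = 0.105) cells
(≈ 10 % occupancy), fluorescence equal to summed clone productivities
times a lognormal noise factor (mean 1, CV 0.3 by default), sorts the top
2 % most fluorescent cell-containing droplets, and read-samples sorted
cell counts and the input abundances. Defaults are proportional to a
full-scale sort (360 000 droplets for 2 000 clones ≈ 180 droplets per
clone). Empty droplets fluoresce at zero and are excluded from the
cell-containing denominator.

All randomness derives from one master seed; per-sample and per-run
substreams use fixed offsets (`default_rng([seed, stream, index])`), so
every simulator and the whole CLI pipeline are bit-reproducible.

The simulators deliberately omit: sequencing errors and quality variation
(counting is exact-match), PCR amplification bias, clone-specific guide
efficacy (each clone has a single true μ), induction kinetics, droplet
optics/fluidics, and cross-feeding between clones. Passing tests
therefore demonstrate correctness of the analysis arithmetic and
robustness to sampling noise at realistic depth — not robustness to
library-preparation artifacts in real data.

## Numerical choices and degenerate inputs

- Pseudocount +0.5 on normalized counts before logs (configurable).
- Trapezoid rule for the AUC; trajectories need ≥ 2 points and a positive
  generation span, otherwise an explicit error.
- Guides or proteins with undefined statistics fall back conservatively
  (Poisson dispersion flag, p = 1 for constant proteins, NA enrichment
  factors) rather than propagating infinities.
- Internal coordinates are 0-based half-open; GFF3 and output tables are
  1-based inclusive.

## Problem sizes in the bundled checks

The acceptance script and tests run at deliberately compact scale: 50-kb
genomes with 10–40 genes for design and oracle equivalence, 1 000 clones
at depth 10⁶ over 8 timepoints for growth-rate recovery, 600 trajectories
for cluster recovery, and 2 000 clones × 4 runs × 360 000 droplets for
the droplet screen. These sizes keep full runs in seconds while leaving
every statistical regime (sampling noise, overdispersion, sorting
stochasticity) active.

## Known limitations

- The NB-Wald test is less powerful than shrinkage-based count models at
  very low counts; its p-values are calibrated, not identical, to those
  of such packages.
- Growth-rate estimates inherit the renormalization bias described above;
  with a majority of strongly depleted clones the bias would grow, and an
  internal-reference correction would be needed.
- The off-target rule counts sites; it does not grade severity or model
  dCas9 binding energetics.
- Guide efficacy variation (weak guides) is not simulated, so gene-level
  false-negative patterns seen in real screens are out of scope here.
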