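# Methods

## The estimands

Both pipelines target the same quantity: the log2 change in a mutant's
relative abundance over one pooled growth competition, aggregated to genes.

**Barcoded pools.** A strain's measurement in a pool is the difference of
mean log2 tag intensities, END minus START, over whichever of its uptag and
downtag are present in both samples. (The intensity of a tag is treated as
proportional to strain abundance; the log of a ratio of intensities is
therefore the log fold change in abundance.) Gene fitness is the unweighted
mean over all included strain measurements carrying an insertion in the
gene, pools combined; strains mapping to intergenic regions are aggregated
under their intergenic label and flagged. Each pool is median-centred
separately before aggregation because the two pools are amplified and
hybridized independently.

**Insertion density.** For sequencing-based profiling of an uncatalogued
library, gene fitness is the log2 ratio of the gene's unique-insertion-site
density to the genome-wide density, both computed over the 5–85% coding
window. Only unique sites count; read depth never enters the statistic
(permuting reads across sites leaves every fitness unchanged). Read counts
matter only upstream, at site detection: a site is observed only if it
attracts at least one read, which is how strong selection reshapes the
observed site density.

## Coordinate and window conventions

Files (GFF3 and the 7-column TSV) are 1-based inclusive; all window
arithmetic is 0-based half-open, converted once at the I/O boundary. The
coding window keeps offsets `floor(0.05·L) ≤ o < floor(0.85·L)` measured
5'→3' on the coding strand (from `start` on + genes, from `end` on −
genes), so `win_len = floor(0.85L) − floor(0.05L)` and a uniform insertion
falls in-window with probability ~0.80. The window length is also the
denominator of the density ratio — numerator and normalizer must use the
same units; with a uniform window fraction the choice between window length
and full gene length shifts all fitness by a near-constant that cancels in
the log ratio up to per-gene rounding.

Genes with no in-window site would score −∞; they receive a pseudocount
(default 1) and an explicit `flagged_zero` marker, are excluded from
positive-fitness sets, and do not participate in the density-conservation
identity (the window-length-weighted mean of `2^fitness` equals 1 exactly
when no pseudocount fires).

Intergenic positions are labelled by the nearest gene they lie strand-aware
upstream of, with the distance to its 5' end; pseudogenes are retained and
scored like ordinary genes, with the flag carried through to reports.

## Normalizations

- **Low-START filter**: strains whose mean START log2 intensity falls below
  a threshold are excluded (kept in the table with `included = False`). No
  principled universal threshold exists; the default is the 5th percentile
  of all START intensities, overridable.
- **Median-zero**: per pool, the median of included strain fitness is
  subtracted; the post-condition (median exactly 0) is asserted in tests.
- **Position correction**: a running median of gene fitness over a centred
  window of 251 genes in chromosome order (truncated at edges) is
  subtracted. A running median tracks replication-associated and
  copy-number trends while being insensitive to isolated high-fitness
  outliers — a planted 10-gene jackpot shifts by < 0.05.
- **Mode-zero**: the mode is estimated as the argmax of a Gaussian KDE
  (Silverman bandwidth) on a fixed 512-point grid spanning the data and
  subtracted; determinism makes "mode within one grid step of 0" testable.
- Quality metrics use Pearson correlation; both are reported as undefined
  below 3 pairs.

## The simulator

**Growth.** Strain `i` has relative rate `ρ_i = true_rate + s`, where `s`
is the per-gene selection coefficient of the condition and `true_rate` is
1 plus optional strain-specific jitter (insertion-position effects: polar
disruption, partial knockouts). Two competition modes exist:

- *fixed per-strain doublings*: `a_i = x_i(0)·2^(ρ_i D)`, renormalized —
  the simplest model with closed-form oracles, and the default;
- *yield-limited*: the culture grows until total biomass has doubled `D`
  times (what an OD curve measures), i.e. the shared growth time `t`
  solves `Σ x_i(0)·2^(ρ_i t) = 2^D`. Under jackpot selection the fastest
  strains consume the yield quickly and everyone else receives far fewer
  effective doublings — the mechanism by which strong selection degrades
  pool-wide correlation metrics. The canonical nitrate scenario uses this
  mode for the pool cultures.

**Observation.** Array intensities are
`log2(scale·x + background) + ε`, `ε ~ N(0, σ)` independent per tag and
phase; the additive background floor compresses the signal of strains that
failed to grow and is what the low-START filter removes. With `σ = 0` and
`background = 0` the pipeline reproduces simulator truth exactly (the
oracle-equivalence tests). Noise streams are keyed by (seed, pool, phase)
only — conditions at the same master seed share noise draws (common random
numbers), which makes condition-versus-control comparisons low-variance and
deterministic; a side effect is that two conditions with identical planted
effects produce identical tables. Sequencing reads are multinomial over
sites with probabilities proportional to post-competition abundance; sites
with zero reads are not observed.

**The canonical nitrate scenario** (`nitrate_scenario`): 2400 genes of
length ~N(900, 100) bp (clipped to 600–1500) with 150 bp gaps; operons as
consecutive same-strand runs of geometric mean length 2; pools of
2300 + 2300 strains sharing 600 (4000 distinct); 5% intergenic insertions;
a contiguous 9-gene cluster with `s ~ U(2, 4)` plus a regulator with
`s = 4` under both nitrate salts and `s = −0.15` under the four control
conditions (losing a native transport/regulatory function is mildly
deleterious without the stress); 2% of genes as sick auxotroph analogues
(`s = −1` everywhere); background strains carry rate jitter of sd 0.5
while planted-gene strains carry none (their ground truth is the planted
effect exactly); σ = 0.3 in log2 units; D = 3.3 population doublings per
condition; and a sequencing arm of 5×10^5 unique sites and 2.5×10^6 reads
grown for 3.3 per-lineage doublings.

Two scenario sizes were set by feasibility analysis done at design time,
before any recovery run: (i) with unique-site fitness, planted genes can
only outrank neutral genes through read-detection dropout of neutral
sites, and keeping every neutral gene within |fitness| < 1 at the same
time requires on the order of 100 created in-window sites per gene —
hence hundreds of thousands of sites rather than tens of thousands, and a
read depth leaving roughly half the neutral sites detected; (ii) if all
non-planted genes had exactly equal true fitness, rank agreement between
true and estimated gene fitness would be destroyed by ties regardless of
pipeline quality — the strain-level rate jitter is what makes gene-level
truth continuous.

**What the simulator does not model**: array spatial artifacts, PCR and
GC bias, tag cross-hybridization, insertion hot/cold spots, plasmid loss,
nitrite chemistry, or growth-curve shapes. Passing recovery tests
therefore show that the pipelines invert this idealized generative model,
not that they are robust to every artifact of real arrays or libraries.

## Candidate selection and homologs

A gene is a candidate when fitness strictly exceeds 2 in every high
condition (both nitrate salts — anion consistency) and is strictly below
0.25 in every low condition (NaCl, KCl, nitrite, no stress). Genes with
any missing rule cell are excluded and listed separately — absence of
evidence is not resistance. Candidates are ranked by their minimum
high-condition fitness (the conservative anion-consistent score), ties
broken by gene id; plain top-k ranking in a single condition is also
provided. Homolog maps are supplied as TSV pairs (no orthology inference);
the join reports per-pair fitness side by side and the fraction of
evaluable pairs agreeing in fitness sign.

## Numerical choices and degenerate inputs

Competition is computed in log space (jackpot exponents would otherwise
overflow); abundance vectors are validated to sum to 1 within 1e-12. The
yield equation is solved by Brent's method to 1e-12 on a bracket
guaranteed by monotonicity. Median subtraction yields an exactly-zero
median; KDE mode re-centring is exact to one grid step. Fewer than 3 genes
skips position correction with a warning; an empty pool after the
low-START filter, a zero starting pool in the doublings estimate, and a
fitness table with no in-window insertions are errors, not silent NaNs.
Infinite candidate-rule thresholds are allowed (degenerate select-all
rules); finite ones must be ordered.

## Problem sizes

The recovery tests and the worked example use the full canonical scenario
(2400 genes, 4000 strains, six conditions, 5×10^5 sites), which runs in
roughly ten seconds; unit tests use scenarios of 50–300 strains. These
sizes were chosen to keep the whole suite fast while leaving the
jackpot/control contrast and the per-gene site counts at realistic
magnitudes.

## Known limitations

- The strain-fitness estimator assumes tag intensity proportional to
  abundance; saturation at the top of the array's dynamic range is not
  modelled or corrected.
- Operon correlation is computed from adjacent same-operon pairs only;
  non-adjacent co-operonic pairs are ignored.
- The intergenic labelling convention (nearest strand-aware downstream
  gene) is one of several used in the field; pooled analyses here treat
  intergenic strains as their own features rather than assigning them to
  neighbouring genes.
- The doublings estimator takes the positive-fitness gene set as the
  effective founding population; when selection is weak this set is large
  and the estimate approaches log2(final cells / all insertions), which is
  no longer a meaningful enrichment measure.
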