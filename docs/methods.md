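# Methods

This note records the statistical models, estimator conventions and design
choices behind `haplotrace`, at the level of detail a user needs to judge
whether the defaults fit their data.

## Data model and QC

The unit of analysis is an alignment of equal-length mtDNA sequences keyed
by specimen id, joined strictly to a metadata table
(`specimen_id, country, location, status, host, year`). Statuses partition
specimens into the analysis set (`native`, `introduced`) and auxiliary
records (`interception`, `outgroup`): interceptions have a country of
record but no confirmed field population, so they appear in haplotype
networks but never in abundance rankings, frequency tables, diversity
statistics or AMOVA; the outgroup is a different species and appears only
in the rooted tree.

QC follows the strictest interpretation of "no unconfirmed sites": under
`drop_ambiguous`, any specimen with a non-A/C/G/T character inside the
analysis window is removed entirely. Gaps count as ambiguous — the intended
target is a gap-free protein-coding region, so an alignment gap indicates a
data problem rather than a real indel. Coordinates are 0-based half-open
throughout; the trim window is a user input because only the final window
length is ever known in practice, not amplicon coordinates.

Because all ambiguity is removed before analysis, haplotype identity is
exact string equality; no fuzzy matching is defined or needed.

## Haplotype labels and classification

Haplotypes are ranked by descending carrier count among analysis specimens,
ties broken by first occurrence in input order (this makes labels
deterministic under re-runs and input permutations, up to the documented
ordering). Haplotypes that satisfy the invasive rule — found in ≥ 2
countries and carried by ≥ 1 introduced specimen — receive letter labels
`Hap-A`, `Hap-B`, …; everything else receives zero-padded numeric labels.
A haplotype found only in a single introduced country is *private*, not
invasive: it carries no information about geographic origin. A haplotype
with no analysis carriers at all (e.g. interception-only) is private by the
same logic.

## Diversity estimators

* Haplotype diversity uses the unbiased form
  `H = n/(n−1)·(1 − Σ p̂²)`. The correction matters: it is what reproduces
  published per-country values exactly from their printed count patterns
  (e.g. counts 7/1/1 → 0.4167; 37/4/1 → 0.2195; 9/1/1/1/1 → 0.5385;
  8/4/5 → 0.6765; 15/1/1 → 0.2279; 8/1 → 0.2222, all recomputed in the
  test suite), while the uncorrected form does not.
* Nucleotide diversity is the mean pairwise difference over all `C(n,2)`
  specimen pairs, per site, with no additional small-sample correction —
  consistent with published values to within last-digit rounding
  (8/1 carriers of haplotypes 3 steps apart at L=2181 → 0.000306 vs a
  printed 0.000305).
* Maximum pairwise divergence is `max d_ij / L × 100` in percent.
* For `n = 1` groups all three are reported as missing (NaN), never 0: a
  monomorphic group of `n ≥ 2` legitimately scores 0, a singleton defines
  no estimator. Report rounding is 4 dp for `H`, 6 for `π`, 3 for max PWD,
  1 for percentages.

## AMOVA

One level (among/within populations), from pairwise substitution counts
with the sequence-data convention that the number of differences plays the
role of the squared Euclidean distance (`δ²_ij = d_ij`):

```
SS_total  = (1/N) Σ_{i<j} δ²_ij          df_among = P − 1
SS_within = Σ_p (1/n_p) Σ_{i<j∈p} δ²_ij  df_within = N − P
σ²_w = SS_within/df_within
n̄    = (N − Σ n_p²/N)/(P − 1)
σ²_a = (SS_among/df_among − σ²_w)/n̄
Φ_ST = σ²_a/(σ²_a + σ²_w)
```

The permutation null shuffles individuals across populations with group
sizes fixed; `p = (1 + #{Φ_perm ≥ Φ_obs})/(1 + n_perm)` never returns an
exact zero, matching "p < 0.001"-style reporting at `n_perm = 999/1000`.
The seed is mandatory whenever permutations are requested. Default
`n_perm = 1000`. Degenerate input (all distances zero) reports `Φ = 0`
with an explicit `degenerate` flag rather than NaN, so downstream tables
stay well-formed. `σ²_a` (and hence `Φ`) may legitimately be negative on
unstructured data; values are not clipped.

Hierarchical (region/population) AMOVA is out of scope; when countries are
essentially disjoint in haplotype composition a pooled multi-country AMOVA
is not meaningful, so the pipeline runs one AMOVA per multi-site country
across its locations, plus one across groups at the configured grouping.

## Minimum spanning network

The MSN is defined as the union of all minimum spanning trees: an edge
`(u,v)` of weight `w` is included iff `u` and `v` are not connected using
only edges of weight `< w` (threshold `< w − ε` for the relaxed network).
All candidate edges of a given weight are tested against the same
connectivity snapshot, so the construction involves no tie-breaking and is
invariant to input order; the test suite verifies equality with exhaustive
spanning-tree enumeration on all instances up to 7 nodes. Default `ε = 0`.

Clusters are connected components after deleting edges of weight ≥ `cut`,
labeled 1, 2, … by descending total carrier count (ties by smallest node
label). "Long mutational branch" is inherently qualitative, so
`cut` is a configuration value (default 6 substitutions), not an inferred
quantity.

## Neighbor joining

Standard Q-criterion agglomeration; ties broken by the lowest (row,
column) index pair, so results are deterministic. On additive matrices NJ
is exact — topology and branch lengths — which the suite verifies on 100
random additive trees of up to 8 taxa. Negative branch-length estimates
(possible on non-additive input) are clamped to 0 with the raw estimate
kept as an annotation (`raw_length`). Distances default to uncorrected
p-distance, appropriate for the < 1% ingroup and ~6% outgroup divergences
this package targets; a Jukes–Cantor transform is available for deeper
divergences. Maximum-likelihood inference is deliberately out of scope:
for data of this divergence NJ and ML topologies coincide except for
placements among single-mutation variants.

Bootstrap support resamples the `L` alignment columns with replacement `B`
times (default 1000) and reports, for each internal edge of the reference
tree, the percentage of replicates whose NJ tree contains the same
bipartition. Zero-length internal edges are flagged: any "support" on an
edge of length zero reflects tie-breaking, not signal. Rooting places the
root at the midpoint of the outgroup's pendant edge and preserves all
bipartitions.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical signature* of a source-traceable
invasion:

* `n_regions` (3) native regions, each an independent mutation tree off a
  regional ancestor carrying `between_region_steps` (12) private
  substitutions, so regions are separated by long branches (≥ 24 steps
  between sampled haplotypes under the infinite-sites layout);
* within-region pools of 5–19 haplotypes with geometric frequencies
  (ratio 0.5) — one common haplotype plus progressively rarer ones;
* `n_invasive_haps` (4) haplotypes exported from one source region;
  introduced populations draw the top exported haplotype with probability
  `dominance` (0.9), the rest geometrically, and with probability
  `singleton_rate` (0.03) a specimen instead carries a brand-new one-step
  derivative — the "one mutational step from the dominant haplotype"
  pattern of real introductions;
* an optional outgroup record at `outgroup_divergence` (0.056) — the
  ~5.4–5.8% sister-species distance.

Two constructive guarantees make pipeline tests exact rather than
probabilistic. First, one carrier of each exported haplotype is seeded
into the source-region native population and into the first introduced
population (the field analog: every exported haplotype established at
least once), so "every exported haplotype classifies as invasive" holds by
construction. Second, each region's mutation-tree depth is capped at
`between_region_steps/2 − 1` and the regional ancestor is always sampled,
so a region can never be internally split by the default cluster cut of
`between_region_steps/2` even when rare intermediate haplotypes go
unsampled.

Mutations occupy globally unique sites (infinite sites): Hamming distance
equals the number of mutation events, making truth distances exact for
oracle tests. That is also the main idealization — no homoplasy, no
rate heterogeneity, no back-mutation, no recombination (reasonable for
clonal mtDNA), no migration between native regions, and per-population
sampling is independent rather than spatially autocorrelated. Passing the
simulation-recovery tests therefore demonstrates that the *pipeline*
correctly recovers structure that is present; it does not demonstrate
robustness to homoplasy or to weak, clinal structure in real data.

Default sizes (three native populations of 20; introduced populations of
30/20/10; L = 2181) keep one simulated dataset at ~91 specimens, small
enough that the 100-replicate end-to-end recovery test runs in seconds
while leaving per-population counts in the range typical of field
surveys. The end-to-end diversity contrast is evaluated as mean introduced
H < mean native H per replicate: single small introduced populations can
exceed a native population by sampling noise, and the scientific claim is
about the population sets.

## Known limitations

* Classification depends on sampling: an invasive haplotype not sampled in
  two countries will be called private. The generator's seeding sidesteps
  this for tests; real analyses cannot.
* The AMOVA permutes individuals, not populations; with very few
  populations the permutation distribution of Φ is coarse.
* Bootstrap support on near-identical haplotype sets is dominated by
  zero-length-edge noise; the flags should be honored when reading trees.
* Printed tables in the literature occasionally disagree with their own
  margins (rounded percentages, transcription slips); `haplotrace` always
  recomputes from counts and reports the recomputed value.
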