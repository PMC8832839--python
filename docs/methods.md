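# Methods

## Contact-map model and storage

A binned Hi-C map is treated as a sparse symmetric function over bin pairs:
`c(i, j) = c(j, i) ≥ 0`, with every unstored pair reading as 0.0. Storage
is a hash keyed by the canonicalised pair `(min(i,j), max(i,j))`, giving
O(1) lookup per bin pair; every query mode decomposes into such lookups.
Treating absent pairs as zero (rather than missing) is the convention of
sparse bin-pair distribution formats and keeps window means and domain
averages well defined; it does mean an unmappable (blacklisted) bin is
indistinguishable from a genuinely contact-free one — the tool does not
model mappability.

Coordinates are 0-based half-open everywhere (BED convention), including
bin intervals: position `p` belongs to bin `⌊p / bin_size⌋` of its
chromosome, and position `k·bin_size` belongs to bin `k`, not `k−1`. The
bin size is inferred from the bin table as the modal bin width, so terminal
chromosome bins may be shorter.

Values the input file holds are used as-is: no balancing, normalisation or
expected-value correction is applied. If a normalised map is wanted,
normalise upstream and feed the result in.

## Query-mode conventions

Decisions the mode definitions leave open, and how they were fixed:

* **Anchor resolution.** Bait viewpoints, loop ends and sites resolve to
  the bin containing the interval midpoint `⌊(start+end)/2⌋`. A BED
  interval wider than one bin has no canonical anchor bin; the midpoint is
  symmetric and deterministic, and matches viewpoint semantics where the
  interval marks a feature (a binding site, a promoter) rather than a
  range to aggregate.
* **Bait aggregation.** Bait averages the viewpoint bin against a window
  of `near_bin` bins on each side (a virtual-4C profile collapsed to its
  mean), not all pairs within the window. The window includes the bait's
  own diagonal entry and is clipped at chromosome ends rather than
  erroring; `n_pairs` records the effective window size so clipped queries
  are visible in the output.
* **Diagonal inclusion.** sites, local and TAD all include diagonal
  (self-pair) entries, for mutual consistency: the TAD sum equals the sum
  of the local listing over the same interval.
* **TAD average.** The intra-domain sum is divided by all `m(m+1)/2` bin
  pairs of the m-bin domain, not only the nonzero ones — zero pairs are
  data (absence of contact), and an all-pairs denominator makes domains of
  different sparsity comparable.
* **Pair headline.** `pair` reports both sum and mean; the mean is the
  headline frequency because it is invariant to region size, which is what
  the permutation null needs when region sizes vary across queries.
* **Loops are intra-chromosomal.** A BED line carries one chromosome, so
  loop mode rejects nothing it can express; inter-chromosomal contact is
  reachable through pair mode.
* **Submap output.** The submap keeps pairs with both bins inside the
  union of the query regions. The written bin table is the full table, not
  the union subset: bin tables are small, and a non-contiguous subset
  would not re-validate as a bin table. Because the returned submap keeps
  the full bin index, any query contained in the selected regions gives
  identical answers on the submap and the original map — the property the
  tests assert.

## Permutation null

The null asks: how large would this query's frequency be if the same
geometric object were dropped uniformly at random on the same chromosome?
Each of the `N` samples (default 100) applies one rigid shift: the start is
drawn uniformly from all in-range placements, preserving length,
chromosome, and — for a same-chromosome region pair — the offset between
the two regions (the envelope containing both regions is shifted as one).
Regions of an inter-chromosomal pair shift independently. Rigidity is what
makes the null meaningful for loop and pair queries: the distance between
anchors is part of the hypothesis, not a nuisance to randomise away,
because contact frequency decays strongly with distance.

Placements are not forced to avoid the original locus or one another; this
is the simplest exchangeable null, and self-collisions only make the
reported rank conservative.

Reported summaries:

* `ratio = observed / mean(samples)`; a zero sample mean yields NaN
  (rendered `NA`) rather than a crash. Display is fixed at two decimals.
* `rank = 100 · #{samples ≥ observed} / N`, displayed as `top X%` with X
  rounded to the nearest integer. Ties count toward the samples, the
  conservative one-sided choice, so a constant map ranks "top 100%", never
  "top 0%". The observed value itself is not pooled into the denominator;
  with N = 100 the achievable ranks are the 101 lattice points 0%..100%.

Determinism: each report is fully determined by the map, the query and the
integer seed; the CLI derives per-query seeds as `seed + k` (k = 1-based
query index) so multi-query runs are reproducible line by line.

## Synthetic maps

The generator emulates the text inputs of a binned map at desk scale. The
intra-chromosomal mean signal is a power-law distance decay

    μ(i, j) = C · (1 + |i − j|)^(−α)

with defaults C = 100 and α = 1, the canonical contact-probability decay
slope at sub-megabase scales. Domains are modelled as rectangular blocks:
pairs with both bins inside a block are multiplied by an enrichment factor
(≥ 1). Count noise is one Poisson draw per pair, `Poisson(μ)`; with noise
off the map equals its closed form exactly, which the unit tests exploit.
Inter-chromosomal pairs default to absent (0), with an optional constant
background for cross-chromosome tests. A fixed 5-bin toy map
(`c(i,j) = 10 − |i−j|` on one 50 bp chromosome) is shipped as a literal
value table so worked examples are stable.

What the generator does **not** emulate: restriction-fragment structure,
read-level noise, mappability gaps, compartment (A/B) checkerboards,
nested or boundary-sharing domains, and matrix balancing artefacts.
Passing tests therefore demonstrate correctness of the query arithmetic
and calibration of the permutation machinery on idealised decay+domain
maps, not robustness to every artefact of real Hi-C libraries.

### Problem sizes in the shipped checks

Test and acceptance runs use maps of 60–100 bins (oracle and binary-path
checks, 20 and 10 seeded replicates), a 400-bin chromosome with 200 domain
queries at 100 permutation samples each for null calibration, and 100
seeded 200-bin maps for enrichment recovery. These sizes make every
statistical property measurable in seconds while keeping the dense-matrix
reference (the independent oracle the query engine is compared against)
trivially enumerable.

The null-calibration fixture uses Poisson noise on the decay map
deliberately: on a noiseless translation-invariant map every placement of
a fixed-span query has the identical frequency, all samples tie the
observation, and the rank degenerates to 100%. Noise breaks ties while
leaving placements exchangeable, so ranks are uniform on the 1/N lattice —
which is what the Kolmogorov–Smirnov check measures.

## Numerical and degenerate-input choices

* Frequencies are double precision; no accumulation tricks are needed at
  the problem sizes the tool targets (sums over at most tens of thousands
  of doubles).
* Inconsistent symmetric duplicates in a contact file (both `(i,j,a)` and
  `(j,i,b)` with `a ≠ b`) abort the load; silent last-wins resolution
  would corrupt data invisibly. Exact duplicates are accepted.
* A query interval that overlaps no bin, an unknown chromosome, or a
  position past the last bin raise immediately, naming the query; a
  whole-chromosome query under permutation has exactly one placement and
  degenerates to the identity shuffle.
* The binary cache embeds a magic string and version; loading anything
  else fails with a format error. Round trips are bit-exact because values
  travel as raw IEEE-754 doubles.
* Rank display rounds half to even (Python `round`); full-precision ranks
  and samples are preserved in the per-query sample files.

## Known limitations

* One uniform resolution per map; no multi-resolution stores.
* No `.hic`/`.cool` readers; `hicquery.io.from_matrix` adapts any
  symmetric matrix an external reader produces.
* The permutation null randomises position only — it conditions on the
  query's span and the chromosome's global contact statistics, not on GC,
  mappability or compartment composition.
* Per-query ranks are not corrected for multiple testing across query
  files; downstream correction is the caller's responsibility.
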