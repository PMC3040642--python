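# Methods

## Distance model

Pairwise divergences use the Kimura 2-parameter model,
`d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)`, with the transition proportion
*P* and transversion proportion *Q* computed under **pairwise deletion**:
a site enters a pair's comparison only if both sequences carry an
unambiguous A/C/G/T there. Gaps, `N`, and partial IUPAC codes
(R, Y, S, W, K, M, B, D, H, V) are all treated as uninformative at that
site rather than probabilistically resolved — the simplest defensible
convention, and the one that lets full-length and >500 bp records mix in
one matrix. Pairwise (not complete) deletion is assumed throughout; with
complete deletion a single short record would shrink every comparison.

A pair is reported *missing* rather than numeric in two cases:

* **overlap** — fewer than `min_overlap` (default 300) jointly resolved
  sites. Short overlaps make zero distances meaningless, and barcode
  sharing is diagnosed from exact zeros, so such pairs are dropped
  instead of trusted.
* **saturation** — `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0`, where the
  correction diverges. Saturated pairs are missing, not `+inf`, and
  never enter min/max statistics; their count is carried on the matrix
  and logged.

Distances are proportions everywhere in memory. Only the report layer
renders percentages (half-up; 1 decimal in species-pair tables and
histograms, 2 decimals in the global stratum means), so rounding policy
lives in exactly one module.

## The audit

Intraspecific variation is summarized per species as the **maximum**
pairwise distance (MPD) among conspecific specimens; interspecific
separation as the **minimum** distance to the nearest heterospecific
specimen (NN). Using extremes rather than means is deliberate: the
barcode gap fails at the extremes, not at the averages.

Screens, all configurable:

* **sharing** — heterospecific specimen pairs at distance exactly 0,
  aggregated by species pair with the specimen-level evidence retained,
  so a regular pattern (several identical pairs) can be told from a
  one-off (a single stray specimen, e.g. introgression or a
  misidentification).
* **low divergence** — species pairs whose minimum distance lies in the
  half-open window `(lower, upper]`, default (1%, 4%]. The window is
  computed from the species-pair minimum matrix, not from the NN table:
  a species' second-closest neighbour can fall in the window even when
  its NN does not.
* **deep splits** — species with MPD strictly above the threshold
  (default 2%). Subclusters are connected components of single linkage
  at the threshold among conspecific specimens — the weakest clustering
  assumption consistent with "lineages more than the threshold apart".
  Each flagged species is labelled single-outlier (one specimen alone in
  a cluster of a two-cluster split) or multi-individual, since a split
  supported by several specimens per cluster is far stronger evidence of
  cryptic structure.
* **resolution** — the fraction of species (among those with a
  computable NN) whose minimum heterospecific distance is strictly
  positive. This is the strict criterion; a curator may still downgrade
  species on external evidence, which no distance rule can encode.

Global strata (interspecific, congeneric, intraspecific, intraspecific
excluding deep-split species) are means over unordered defined specimen
pairs. The SE is the sample SD divided by √n over those comparisons.
Comparisons sharing a specimen are not independent, so this SE is
**descriptive only** and understates the real uncertainty; it is kept
because it is the convention in which library audits quote their
numbers.

Histogram conventions: 0.5% classes, half-open `[k·0.5%, (k+1)·0.5%)`.
The MPD histogram excludes singletons (no intraspecific comparison
exists); the NN histogram excludes deep-split species, whose species
status is exactly what is in question.

## Neighbour joining

Saitou–Nei NJ, with two determinism rules: Q-criterion ties are broken
by the lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest specimen id), and negative branch-length
estimates are clamped to zero with the deficit moved to the sister
branch, preserving the joined pair's matrix distance. On additive
matrices NJ recovers the generating tree exactly; the tests verify this
against an exhaustive least-squares search over all topologies for ≤6
leaves. Missing matrix entries are never imputed: tree building demands
a complete matrix, and the CLI subsets greedily (dropping the specimen
with most missing pairs, ties by id) with a warning — silent imputation
would bias branch lengths invisibly.

## Synthetic libraries

The generator emulates the *distance structure* of a curated regional
library, not its genealogy. Topology is a star of genus ancestors, a
star of species centroids within each genus, and specimens evolved
independently from their centroid. Under K2P, distances are additive in
expectation along paths, so targets translate to branch lengths
directly: species branches are `congeneric/2`, genus branches
`(cross-genus − congeneric)/2`, specimen branches `intraspecific/2`.
Specimen-to-specimen expectations are therefore `target + intraspecific`
between species — at the defaults, 13.2% cross-genus and 10.2% between
congeners — and `intraspecific` within them.

Defaults (all configurable on `SimConfig`): 300 species × 3 specimens,
3 species per genus, 658 bp, cross-genus 13%, congeneric 10%,
intraspecific 0.2%, 20 deep-split species at 4.4%, 1 sharing pair,
κ = 4.0. The divergence and anomaly scales are those a European
geometrid survey reports; κ = 4 is a typical transition/transversion
rate ratio for insect mitochondrial COI (the estimator does not depend
on κ, only the simulator does). Sites evolve i.i.d. with the closed-form
K2P substitution probabilities `Q(d) = ½ − ½e^{−4βt}`,
`P(d) = ¼ − ½e^{−2(α+β)t} + ¼e^{−4βt}` with `αt = κd/(κ+2)`,
`βt = d/(κ+2)`, so the expected estimated distance equals the target.

Anomaly injection:

* **sharing** — a congeneric pair where the recipient species takes the
  donor's centroid and one recipient specimen is an exact copy of a
  donor specimen. Giving the recipient the donor's centroid mirrors the
  biology of sharing (incomplete lineage sorting between nearly
  identical barcodes) and keeps the injected event from mechanically
  creating a deep split in the recipient, so the sharing and deep-split
  truth sets stay disjoint.
* **deep splits** — a second centroid evolved `deep_split_d` from the
  first; specimens split with the smaller cluster holding ⌊k/2⌋ (so
  k = 3 yields the single-outlier pattern, k ≥ 4 multi-individual
  clusters); the two clusters carry different region tags, emulating
  geographically structured divergence.
* **low-divergence pairs** — a congener's centroid carries *exactly* the
  substitution counts implied by the nominal distance (rounded
  transition/transversion counts at distinct sites) rather than being
  evolved stochastically: at 658 bp, stochastic planting scatters the
  realized distance by ~0.7%, which would let a pair nominally outside a
  screening window drift inside it.
* **short records** — optionally truncate specimens (default to 450 bp)
  to exercise the length filter; anomaly-bearing specimens are never
  truncated.

What the generator does **not** emulate: coalescent genealogies and
shared polymorphism, rate variation across sites and lineages, indels,
sequencing error, uneven sampling, or realistic taxon names. Passing
tests therefore show that the audit recovers distance-level structure it
was pointed at — they say nothing about robustness to misalignment or to
non-neutral marker behaviour in real data.

## Numerical and scale choices

* The test-suite's full-scale recovery check runs one 300 × 3 library
  (404,550 pairs, ~2 s for the matrix, vectorized row-at-a-time) — the
  same species/specimen scale as the library the defaults emulate.
  Tolerances there are 3 library-level Monte-Carlo SEs, from the
  variance of a K2P estimate at 658 sites (SD ≈ 0.011–0.015 per pair,
  ≈ 0.002 for a 300-centroid library mean; ≈ 1 × 10⁻⁴ within species).
* Exact-zero comparison for sharing is intentional (no epsilon): the
  event of interest is an *identical* haplotype, and any positive
  distance at 658 sites is at least 1 bp ≈ 0.15%.
* Deep-split flagging is strict (`mpd > threshold`), so an MPD exactly
  at 2% is not flagged; the low-divergence window is left-open,
  right-closed, so a pair at exactly the upper bound is listed.
* Ties: NN ties resolve to the lexicographically smallest species; NJ
  ties as above; report rows sort by (distance, name). Re-rendering a
  report is byte-identical.
* Degenerate inputs: all-identical libraries give all-zero matrices and
  zero-length NJ branches; libraries whose pairs are all missing, empty
  length-filter results, and matrices with missing entries passed to NJ
  are hard errors, not silent repairs.

## Limitations

* K2P only — no JC/GTR or maximum-likelihood distances; the audit's
  comparability with the barcode literature rests on K2P, so other
  models are out of scope.
* The strict zero-distance resolution criterion can disagree with a
  curator's judgement that nearly-identical species "may share" on
  evidence from outside the library (other regions' populations);
  such narrative criteria are not encodable as a distance rule.
* SEs are descriptive (see above); no bootstrap on trees; no automated
  species delimitation (ABGD/ASAP/GMYC-style) — the screens implement
  fixed-threshold audit rules, not delimitation inference.
* Sequences are assumed aligned by position (no indels within the
  amplicon), the standard convention for COI-5′ barcodes.
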