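# Methods

This note documents the models, defaults and numerical choices behind
`mtoop`, and what the synthetic cohorts do and do not establish about
real data.

## The phylogeny model

The haplogroup tree is a rooted tree whose edges carry mutation events
expressed as differences from the rCRS coordinate frame (1-based,
`m.`-style labels). Rooting at the reference state — rather than at the
ancestral RSRS used by the full published phylogeny — removes a
re-basing step without changing any downstream behaviour, because
variant calls are made against the rCRS in the first place. The
expected variant set of a haplogroup is the union of forward events on
its root path; a back-mutation event (label suffixed `!`) deletes the
earlier event at its position from all descendants' expected sets.
Within one root path a position may host at most one surviving event;
recurrent mutation at a position on a single path must be declared with
a `#multiallelic=` header or the file is rejected, keeping expected-set
semantics unambiguous. Insertions (`m.{pos}ins{seq}`) and deletions
(`m.{pos}del{ref}`) participate in expected/defining lookups exactly
like substitutions but are never given a coding effect.

The packaged `toy_phylotree.tsv` (65 nodes) is a deliberately small
stand-in for the real maternal phylogeny. It preserves the relations the
worked examples need — X2p1 defined by m.11778G>A, Q3b by m.14484T>C,
U3a1a1 and H1q3 both by m.14258G>A, H4a by m.14582A>G, African L0–L6
branches, and a back-mutation on the HV stem — while every coordinate on
other edges is arbitrary. It is not a build of the real tree.

## Haplogroup assignment

Assignment scans every node and maximises

    q(h) = 0.5 * ( |E ∩ O| / |E|  +  |E ∩ O| / |O'| )

with E the node's expected set, O the sample's homoplasmic variant set
and O' = O minus hotspot-interval positions (in the standard pipeline O
is already hotspot-filtered, so O' = O). The first term is the fraction
of the haplogroup's signature found; the second, the fraction of the
sample's variation the haplogroup explains. The root state (E = ∅)
scores 1 on the first term, an empty O' scores 1 on the second. Ties are
broken toward greater depth, then lexicographically smaller label, so
results are deterministic. This two-term (Kulczynski-style) measure
reproduces, at toy scale, the behaviour of production haplogroup
callers — near-1 quality for a clean match, degraded symmetrically by
missing signature variants and by unexplained private variants — while
remaining fully specified; it does not reproduce any production tool's
weighted fluctuation ranks.

## Placement partition

Given the assigned haplogroup, each homoplasmic variant is classed

- `expected` — member of the assigned root-path expected set;
- `out_of_place` — otherwise, if it is a forward defining event of at
  least one other node (a "local private" variant);
- `global_private` — otherwise (absent from every edge).

The three classes are disjoint by construction and their union is the
analysis set, which the test suite asserts as an invariant.

## Filters and thresholds

All thresholds are strict on the retained side, i.e. "X% or below" is
excluded:

| parameter | default | meaning |
|---|---|---|
| heteroplasmy_annotation | 0.50 | calls at ≤ 50% are dropped before annotation |
| heteroplasmy_homoplasmic | 0.90 | analysis keeps only calls > 90% ("operationally homoplasmic") |
| min_quality | 0.90 | samples at quality ≤ 90% are excluded |
| hotspot intervals | 302–316, 513–526, 16180–16195 | mtDNA poly-C homopolymer tracts; overridable |
| alpha_family | 0.05 | four-way Bonferroni gives per-test alpha 0.0125 |

The homopolymer tract list is a documented default: upstream pipelines
exclude "homopolymer regions" without enumerating them, so the common
poly-C tracts are used and can be overridden per study. Doubt-flagged
heteroplasmies are taken from the input as called upstream; the flag is
not recomputed. Macro-lineage gating is table-driven with
longest-prefix-wins parsing (`L3` before `L`, and `HV`, an unlisted
clade, pre-empting `H`); anything unlisted maps to `other` and is
excludable. K, although a U subclade on the real phylogeny, is matched
by its own prefix because the allow-list enumerates it separately.

## Annotation

The gene map ships as a TSV transcribed from the standard rCRS
annotation: 37 genes plus the two control-region segments, with the 13
protein genes assigned to OXPHOS complexes I/III/IV/V. Effects are
computed by translating the affected codon before and after the
substitution under the vertebrate mitochondrial code (NCBI table 2:
TGA=Trp, AGA/AGG=stop, ATA=Met), with no start-codon special-casing for
internal codons. Light-strand genes are read in gene orientation after
reverse-complementing the codon and both alleles. Positions in the 1–2
trailing bases of an incomplete, polyadenylation-completed stop codon
have no defined codon context and are classed `other`, as are indels in
protein genes. A variant in an overlap (ATP8/ATP6, ND4L/ND4) is
evaluated in every covering frame; the overall effect is non-synonymous
if any frame is, and the per-frame calls are retained on the record.
The suite checks every possible substitution of a synthetic 3-gene
genome against a brute-force oracle that retranslates the whole gene.

No reference sequence is packaged: coding-effect computation in tests
and simulations uses seeded synthetic genomes, and real analyses supply
their own FASTA. Without a reference the annotator still performs the
gene/OXPHOS join but classes protein-gene substitutions `other`.

"Scored" (the fourth comparison category) means the variant's score
mapping is non-empty after joining the score table; no threshold is
applied, because scoring tools are treated as presence lookups here.
Scores attach only to non-synonymous substitutions — the tools predict
amino-acid-change impact. The packaged `synthetic_scores.tsv` is a
synthetic, illustrative stand-in for a MitImpact-style export.

## Fisher's exact test

The two-sided p-value uses the minimum-likelihood definition: with
margins fixed, the probabilities of all contingency tables whose
hypergeometric likelihood does not exceed the observed table's (with a
1e-7 relative round-off guard) are summed. Likelihoods are evaluated in
log-space via log-gamma binomial coefficients and combined with
`logsumexp`, so no normal approximation or continuity correction enters
at any table size; values within 1e-12 of 1 are snapped to exactly 1.
The implementation is validated against exact rational enumeration
(complete sweep of all tables with both group sizes ≤ 12) and
cross-checked against an independent library implementation.

The category battery always reports exactly four results at alpha
`alpha_family/4`; the lineage battery reuses the same 0.0125 level per
lineage rather than re-dividing by the number of lineages tested, which
matches how the printed threshold was applied in the motivating
analysis; a stricter per-lineage correction can be passed explicitly.
Point odds ratios are reported for description only (no confidence
intervals).

## The cohort simulator

`CohortSimConfig` defaults describe the scaled stand-in study the
acceptance suite exercises: 70 cases vs 53 controls, an African-style
lineage mix (L0 0.50, L1 0.15, L2 0.15, L3 0.20), out-of-place carrier
probabilities 0.6 (cases) vs 0.2 (controls) with all injected
out-of-place variants falling in OXPHOS genes (`oxphos_fraction = 1`),
one global-private variant per sample with probability 0.1, homoplasmic
heteroplasmy drawn uniformly on (0.95, 1.00) and decoy heteroplasmy on
(0.10, 0.90) so draws straddle both printed thresholds, plus occasional
hotspot-position and doubt-flagged decoys. One global seed drives an
independent per-sample substream (spawn key = sample index), so cohorts
are byte-reproducible and the first *n* samples are unchanged when the
cohort grows.

Two structural choices guarantee the exact-recovery property (pipeline
placements equal simulated truth):

- **Generating haplogroups carry ≥ 2 expected variants**, and the toy
  tree gives macro-lineage founding branches long defining-variant
  chains (10–14 events), as macrohaplogroup stems do on the real
  phylogeny. A correctly assigned sample then stays above the 90%
  quality gate even with two extra private variants, and no foreign
  defining variant can outscore the true node.
- **Out-of-place variants are drawn from branches diverging off the
  sample's maternal line** — excluding both the root path and the
  generating node's descendants. A variant on a descendant edge would
  legitimately extend the lineage (assignment rightly prefers the
  child), so it is not an unambiguous local-private event.

What the simulator does *not* emulate: sequencing error and strand
bias, read-level heteroplasmy calling, mutation-rate heterogeneity
along the genome, recurrent mutation, RSRS rooting, and realistic
haplogroup frequencies. Passing tests therefore demonstrate the
correctness of the analysis logic under its stated assumptions, not the
robustness of upstream variant calling on real sequencing data.

## Calibration and power checks

Type-I calibration and power are measured at the binomial carrier
level — per replicate, case and control carrier counts are drawn with
equal (null, p = 0.3) or unequal (0.6 vs 0.2) probabilities at
n = 70 vs 53 and tested at alpha 0.0125 — which is exactly the sampling
model of a single carrier-category comparison and keeps 1,000
replicates in seconds. The exact test's discreteness makes it
conservative: observed null rejection is ~1%, below the nominal 1.25%.
Power at the default effect size is ~98%, comfortably above the 80%
pilot threshold asserted in the suite. Whole-pipeline null behaviour is
additionally spot-checked on 25 fully simulated exchangeable cohorts.

Problem sizes used throughout (500-sample recovery cohort, 1,000 null
and 400 power replicates, margin-≤12 Fisher sweep) were chosen as the
smallest sizes at which the binomial/enumeration error bounds quoted in
the tests are meaningful.

## Known limitations

- The toy tree and simulator operate on tens of nodes; no attempt is
  made to parse the real published phylogeny distribution.
- Haplogroup quality is a two-term set-overlap score; samples whose
  true haplogroup has very few defining variants are legitimately
  filtered by the 90% quality gate when they carry several private
  variants, exactly as low-quality calls are in production pipelines.
- Heteroplasmy is treated as given; no read-level uncertainty model.
- The odds ratio is a point estimate; inference rests on the exact
  test only.
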