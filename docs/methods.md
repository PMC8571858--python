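# Methods

This note documents the models, conventions and numerical choices
behind `herbita`, and what the synthetic-data tests do and do not show
about real herbarium data.

## Specimen QC statistics

All dispersion statistics are sample standard deviations (denominator
n − 1); this is the convention spreadsheets use and the one that
reproduces the packaged tables' published summaries. Records missing a
value for the metric under summary (in practice: the one undated
specimen when summarising collection years) are excluded and counted.

Success rates are reported as three fractions — amplified/total,
complete-sequence/total and complete-sequence/amplified — because a
specimen can amplify yet yield only a partial read. In the packaged
transcription, complete-sequence status coincides with the presence of
a GenBank accession; the six specimens known to have produced only
partial ITS reads carry an explicit `partial_sequence` flag and count
as amplified but not complete.

**Age regression.** The concentration-on-age fit is ordinary least
squares of DNA yield (ng/µl) on specimen age in years,
`x = reference_year − collection_year`, with `reference_year = 2019`,
the year the fresh material was harvested and all extractions were
performed. Age at extraction is the physically meaningful axis: the
slope then measures yield change per year of storage and the intercept
estimates the expected yield of freshly collected tissue
(≈ 14.8 ng/µl on the packaged table). The choice of origin is a pure
affine shift: slope magnitude, r² and the slope test are invariant to
it (a property test asserts this), only the intercept moves. With a
constant response the correlation is undefined; we report r² = 0 and
p = 1 rather than NaN.

The year stratification compares mean ± SD collection year between
specimens whose ITS PCR failed versus succeeded (the ± column). On the
packaged table the failed stratum centres on 1915 ± 28 and the
successful one on 1953 ± 23 — old vouchers fail more, even though age
does not predict DNA yield.

## Alignment, annotation and masking

Inputs are pre-built multiple alignments (building MSAs is out of
scope; any external aligner works) with headers
`accession|species[|geography]`. Coordinates are 0-based half-open
internally and 1-based in every report.

ITS1/5.8S/ITS2 annotation is transferred from one annotated reference
by global pairwise alignment (Needleman–Wunsch, linear gaps, defaults
match +1 / mismatch −1 / gap −2 — the smallest scheme adequate for
near-identical rDNA; configurable). Traceback tie-breaking is fixed
(substitution, then gap in the second sequence) so results are
reproducible. Each region boundary maps to the number of target
residues consumed strictly before it; insertions in the target accrue
to the nearest left boundary. A region whose transferred interval is
empty (deleted in the target) is an error naming the region.

The 5.8S gene is conserved and carries no diagnostic signal, so its
columns are masked before site calling and distance computation: each
member's 5.8S interval is projected through its gaps onto a contiguous
column span and the union of spans over members is masked. Masking is
idempotent and monotone (more annotations never unmask a column).
Reference annotation intervals are user-supplied configuration — they
are properties of the chosen reference sequence, not constants of the
method.

## Diagnostic sites

A masked column yields a site for target set *S* when (i) every
determinate member of *S* carries the same state *s* ∈ {A, C, G, T,
DEL}, (ii) no determinate member outside *S* carries *s*, and (iii)
every species has at least `min_coverage` (default 1) determinate
members at the column — missing data may not manufacture diagnostics.
Gaps are the DEL state; `N` is always indeterminate. IUPAC ambiguity
codes are indeterminate under the default `strict` policy (a Sanger
ambiguity neither supports nor vetoes a site); the `expand` policy
instead counts an ambiguity as each constituent base, for both
fixation and exclusion. The reported `other_states` is the union of
determinate states outside the target.

Positions are 1-based over the masked (ITS1-then-ITS2) columns, the
convention used when such tables are printed. Codes are a per-target
letter prefix plus an ordinal in ascending column order; the prefixes
for this genus follow the published lettering (T, B-C, A, C, M, P, CA,
CR, AR), group targets join member letters with `-`, and arbitrary
species names fall back to epithet letters with collision lengthening
(prefixes stay all-letter so code strings parse unambiguously).

Default targets are all single species. Group (clade-shared) sites are
searched only for user-supplied sets: the one observed case is a
species pair, and scanning all subsets would invite spurious joint
sites. Indistinguishability is detected automatically for pairs: two
species are indistinguishable when no masked column shows a fixed
state difference between them (each species fixed, for different
states, both with coverage). This criterion is robust to
within-species polymorphism, which would break a naive
"state-identical everywhere" test.

Classification counts, per species targeted by the table, the sites
where a query is determinate (tested) and carries the target state
(matched). A query is `assigned` when a unique best species matched
every site it was tested on; ties — e.g. a member of an
indistinguishable pair matching only the shared group sites — are
`ambiguous`; no matches at all is `unassigned`.

## Distances, neighbor joining, bootstrap

Distances are computed over unmasked columns using only determinate
bases; gaps, Ns and ambiguity codes are removed pairwise
(`pairwise_deletion`, default) or column-wide (`complete_deletion`).
The default model is Jukes–Cantor, d = −¾ ln(1 − 4p/3), the
minimal-assumption correction; p-distance is available. p ≥ 0.75 (JC
undefined) and pairs with zero comparable sites are errors, not NaNs.

Neighbor joining is the classic Saitou–Nei agglomeration on
Q(i, j) = (n − 2)d(i, j) − Σd(i,·) − Σd(j,·), with exact ties resolved
to the lowest current index pair (reproducible by construction), and
the final three lineages attached to a trifurcating root by the
three-point formulas. NJ is exact on additive matrices; the tests
assert topology (split-set equality) and branch lengths to 1e−9 on
random 5–12 leaf trees, and the 3-taxon closed form to 1e−12. Negative
NJ branch lengths are retained internally and clamped to zero only for
display/Newick output. Trees are unrooted throughout; bipartitions are
represented as unordered pairs of leaf-name sets, so comparisons are
immune to rooting and input order.

The bootstrap resamples masked-in columns with replacement, rebuilds
the NJ tree per replicate, and annotates each internal edge of the
full-alignment tree with the percentage of successful replicates
containing its bipartition. A replicate whose resample leaves some
pair without comparable sites is dropped, counted and reported via a
warning; supports use the successful-replicate denominator. An
explicit seed is required — there is no silent default — and 100
replicates is the default, the figure standard for this kind of
analysis. Supports are rendered as integers 0–100 in Newick
internal-node labels.

## Misassignment flagging

A species with ≥ 2 leaves is monophyletic when some edge bipartition
isolates exactly its leaves; single-member species are untestable and
listed separately. For each non-monophyletic species *S* the repair is
computed in closed form: over every clade (edge side) *C*, flagging
the symmetric difference *C* Δ *S* isolates *S* ∩ *C* exactly, and the
smallest such difference equals the exhaustive minimal-leaf-removal
optimum for that species (every minimal removal set induces such an
edge). Among equal-cost repairs the one discarding fewest of the
species' own members wins, then the lexicographically lowest
accessions. Because one species' intruder is often another species'
stray, the per-species repairs are then jointly pruned: any flagged
leaf that the union of the others renders redundant is dropped,
approaching the global minimum removal set. On ground-truthed trees of
≤ 12 leaves the result matches an exhaustive global search; an earlier
one-leaf-at-a-time greedy was abandoned because it strips innocent
leaves whenever a species hosts two separated strays.

Flagged leaves are re-assigned to the majority species among their
k = 3 nearest leaves by patristic distance (ties: the nearest tied
neighbour's species). A species whose leaves were pruned while
repairing another species' clade is recorded as implicated in a
violation even if it passed its own test — this matters for
indistinguishable species pairs, whose intermingled zero-distance
members cannot be meaningfully separated by any tree method.

## Synthetic data generator

The generator emulates the structure of a multi-species ITS barcoding
study. Region lengths default to 220/160/220 nt (ITS1/5.8S/ITS2,
600 nt total, inside the genus's observed 588–602 nt span). Each
species descends from a common random root; planted diagnostic sites
(per-species or per-group, base or DEL) are written onto the templates
with a guaranteed non-conflicting background state; members then
receive i.i.d. within-species polymorphism (default 0.002/site) at
non-planted columns, optional uniform-random relabeling (the
mislabeling adversary), and optional N injection.

Inter-species divergence (default 0.03/site; study-structured runs use
0.04) is modelled as substitutions shared by at least two template
lineages on each side of a random lineage bipartition, and species
joined by a planted group target share a single lineage (they are
"sister species" that never diverge from each other). This is a
deliberate modelling choice with a strong payoff: no lineage ever
acquires a private fixed state by drift, so the planted sites are
provably the *only* diagnostic sites and precision/recall against the
recorded truth are exact quantities. The cost is realism — real
species do carry private substitutions beyond their diagnostic ones,
rate heterogeneity exists, and indels occur outside planted DEL
columns (there is no indel process at all). Passing the planted-site
recovery tests therefore demonstrates the correctness of the scanning
logic, not the expected yield of diagnostic sites in field data.
Likewise the misassignment tests (two planted intruders among
6 × 4 accessions at strong divergence) show the flagging procedure is
sound when species are well separated; they say nothing about species
whose clades genuinely interdigitate.

Metadata emulate the herbarium table: collection years uniform on
1882–2001, DNA concentration lognormal (µ = 2.7, σ = 0.9, i.e. median
≈ 15 ng/µl with a long right tail, matching the observed 2.5–88 range)
and independent of year, so the age regression has zero-slope truth;
amplification success logistic in collection year (intercept 1.0 at
the 1950 reference, slope 0.05/year) so that failures concentrate in
old specimens; purity ratios normal around 1.95. A calibration test
confirms the age regression rejects its zero-slope null at ≈ the
nominal 5% rate across 50 generator seeds.

All randomness flows from one explicit integer seed through a single
NumPy generator per call; identical configs are byte-identical on
regeneration, which the fixture-bundle round-trip test asserts.

## Problem sizes in the test suite

The suite runs the site-caller against a naive brute-force oracle on
100 random alignments up to 12 species × 20 members × 700 columns, NJ
against 50 random additive trees of 5–12 leaves, and the flagging
procedure against 20 seeded intruder scenarios plus exhaustive
minimal-removal search on 12-leaf trees; the whole suite completes in
well under a minute on a laptop-class machine. These sizes comfortably
bracket the study-scale data (≈ 70 sequences × 600 columns) while
keeping the oracles exhaustive.

## Known limitations

- The site caller assumes a trustworthy alignment; alignment error
  manifests as spurious DEL-state sites.
- Group-diagnostic search requires the user to name the group; there
  is no subset search.
- JC and p-distance are the only models; for deeper divergences a
  proper substitution model would be needed (out of scope — the genus
  sits well inside the JC-valid range).
- Misassignment flagging is topology-based; it cannot distinguish a
  mislabeled voucher from genuine introgression or incomplete lineage
  sorting, and for truly indistinguishable species pairs the flags
  within the joint clade are arbitrary.
- The packaged tables are transcriptions of printed values; one
  published summary (the herbarium OD260/230 SD) is not exactly
  derivable from the printed rows, and the package reports the value
  computed from the data rather than the printed one.
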