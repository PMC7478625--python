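# Methods

This note records the models, parameter choices and numerical
conventions behind each module, what the synthetic-data generator does
and does not emulate, and the design decisions taken where more than one
reasonable convention exists.

## Trusted-cutoff filtering

Profile-HMM hits (equivalog and domain tiers) are retained when the
bit score reaches the model's trusted cutoff, **inclusively**
(`score ≥ TC`), matching HMMER's own `--cut_tc` behaviour. The
comparison uses the full-sequence bit score by default; when one protein
carries several domains the per-target best-domain score can be selected
instead (`score_field="best_domain"`), since tabular outputs report
both and curation practice varies. Cutoffs are supplied as an
`{accession: cutoff}` mapping rather than an extra file column, because
the HMMER tabular format itself does not carry them — they live in the
HMM files.

Gene positions are 0-based ranks along a contig, not nucleotide
coordinates: all neighbourhood reasoning in this package is in "genes
away", the natural unit for operon arguments.

## The confidence scale

The scale is an ordered rule table (`ConfidenceScale`) over an evidence
profile; the default encodes:

| evidence | tier |
|---|---|
| equivalog HMM hit | HIGH |
| KO and FAMILY agreeing on one function | HIGH |
| KO alone | MODERATE |
| FAMILY alone, with genome context | MODERATE |
| FAMILY alone, no context | LOW |
| domain HMM alone ("hole filler") | LOW |
| nothing | NONE |

Equivalog models are expert-curated and function-specific, hence the top
tier; a family-level call is treated as corroborated when a same-pathway
gene sits within the context window, because operon-like co-localisation
is independent evidence that the call is functionally right. The scale
is plain data: a differently curated table can be substituted without
code changes.

Two conventions worth making explicit:

- **Conflicts.** When sources map a gene to different functions the
  highest-priority source (equivalog > KO > FAMILY > domain) names the
  function; every source that hit the gene stays in
  `supporting_sources` so the conflict is auditable. Only sources
  supporting the *chosen* function count toward the tier.
- **Two-pass context.** Tiers are first computed with context off;
  context-eligible genes are then re-scored against those first-pass
  tiers. This makes the output a fixed point in one extra pass and rules
  out circular rescue chains. Two adjacent family-only genes of one
  pathway do rescue each other — each sees the other's pass-1 LOW call,
  which is above NONE — and we consider that correct: the co-localised
  pair is jointly more believable than either gene alone. Context is
  evaluated per genome; whether corroboration in one strain should
  propagate to others is a curation question we deliberately do not
  automate.

The context window defaults to **±5 gene ranks**, strand-agnostic — the
span of a typical operon; the arguments this feature supports concern
immediately adjacent genes, so the results are insensitive to moderate
changes of the window.

## Orthologue groups and co-occurrence counting

The first-class input is a precomputed orthologue table (long-form TSV),
as produced by dedicated orthology tools. The built-in clusterer exists
so the pipeline runs end-to-end without external software: reciprocal
best hits between genome pairs by normalised global-alignment identity
(1 − edit distance / max length, via edlib), single-linkage components,
identity threshold 0.7 by default, ties broken lexicographically by gene
id. It is a stand-in, not a Markov-clustering reimplementation — the
analysis this package is about is the *counting* downstream.

Counting semantics: presence of a group in a genome means ≥1 member
(paralogues count once). Species-level presence defaults to
**all_strains** — every strain of the species must carry the group —
which is also the diagonal semantics of the pairwise matrix (per-species
core). `any_strain` is exposed as an option. Venn-exclusive region
counts are computed by exact per-group classification and therefore sum
to the pan-genome; the enumeration is limited to 7 taxa (128 subsets) to
keep output interpretable — aggregate strains into species beyond that.

## Pathway completeness and strategy calling

Requirements are AND/OR trees over function symbols. A leaf is satisfied
when any gene carries the function at tier ≥ `min_tier`
(default MODERATE: context-rescued family calls count as pathway
evidence, domain-only proposals do not). Completeness counts satisfied
**top-level AND children**, with an OR subtree as a single child — the
unit is "missing genes/steps", so a pathway lacking one of nine enzymes
is 8/9 complete, and an unsatisfied alternative route (e.g. serB|thrH)
counts as one missing step, reported in compact form. A leaf-weighted
completeness is available (`leaf_weighted=True`) for sensitivity
analyses. Statuses: complete (satisfied), absent (nothing satisfied),
partial (in between).

Strategy classification per vitamin is the 2×2 truth table of the
synthesis and salvage definitions' satisfied flags: synthesizer /
salvager / both / neither.

The shipped definitions are data (`src/panvita/data/pathways.yaml`),
intentionally compact: each route lists the diagnostic genes a curator
would check (e.g. thiamine de novo = (thiC|cytX) + thiD vs the ThiT ECF
transporter; pyridoxine pdxST vs pdxKYH or PdxU2), not every enzyme of
the KEGG map. Edit the YAML to refine routes; no code changes needed.

## Distances, neighbor joining, bootstrap

- **Poisson correction** (amino acids): p = mismatches / compared sites
  with **pairwise deletion** of gaps and X; d = −ln(1−p); p ≥ 1 is
  flagged saturated (infinite) rather than raised, and saturated pairs
  block tree building with an explicit error. Pairwise deletion is the
  default because complete deletion can discard most columns in sparse
  alignments; the choice matters only with many gaps, and synthetic
  alignments are gap-free.
- **Tamura–Nei 1993** (nucleotides): the published closed form with
  empirical base frequencies pooled over the two sequences, transition
  proportions P1 (A↔G) and P2 (C↔T) and transversion proportion Q.
  Degenerate frequency classes with observed divergence, or
  non-positive log arguments, are flagged saturated. In the symmetric
  limit — equal frequencies and equal rates over the 12 substitution
  types, i.e. P1 = P2 = Q/4 — the formula collapses exactly to the
  Jukes–Cantor distance, which the tests verify to 1e-9; the
  implementation is also checked against an independent line-by-line
  transcription of the formula (1e-12) and against `ape::dist.dna`
  during development.
- **Neighbor joining**: Saitou–Nei Q-criterion agglomeration, ties
  broken by the lexicographically smallest pair of subtree labels (each
  internal node is represented by its smallest leaf), so the result is
  independent of input taxon order. Negative branch lengths are clamped
  to 0 and the deficit logged at debug level — the standard convention;
  the clamping does not affect topology. NJ is used in place of a
  maximum-likelihood search: it is exactly consistent on additive
  matrices (property-tested on 100 random trees) and fully reproducible,
  at the cost of statistical efficiency on short alignments.
- **Bootstrap**: single-column resampling with replacement (not
  partition-aware; partition-aware resampling would be the natural
  extension), support = % of replicate NJ trees containing each internal
  bipartition of the point tree. Replicates whose resampled distance
  matrix saturates are skipped and contribute no support. All
  resampling flows from one integer seed.

Marker screening keeps a marker only when **every** genome has exactly
one above-cutoff hit; under the default `drop_marker` policy a violating
marker is removed genus-wide (logged), under `fail` it raises naming the
marker and genome. Neither policy is claimed to be what any particular
study did — published marker sets are typically already single-copy.

## The synthetic cohort

Defaults: 3 species × 2 strains, 40 genus-core families, 8 species-
accessory families, 3 strain-private genes, pathway gene content drawn
per genome (complete with probability 0.7, else partial or absent in
equal shares), proteins of 80–120 residues at 2 % within-family
divergence (between-family identity is that of unrelated random
sequences, far below the 0.7 clustering threshold), evidence noise off
(f_n = f_p = 0), true HMM scores above their cutoff by |N(25, 8)| bits
and spurious scores N(0, 8) around the cutoff, 18 markers × 120 residues
for tree building. These sizes keep a full end-to-end run in seconds
while leaving each statistic non-trivial (six genomes, ~100–130 genes
each, 25 pathways).

What the generator emulates: cohort structure (core/accessory/private),
operon-blocked pathway genes, four correlated-by-truth evidence streams
with calibrated dropout, gap-free marker evolution (Poisson/JC jump
process, or exact TN93 transition matrices via expm). What it does not:
indels and alignment error, paralogy and horizontal transfer, biased
annotation databases, genome incompleteness. Passing recovery tests
therefore demonstrates correctness of the counting, reconciliation and
tree machinery — not robustness to real-data artefacts upstream of it.

Sequences are generated by mutating per-family ancestors rather than by
forward evolution along a genealogy; within-family tree structure is
irrelevant to what the tests measure. All randomness flows from a single
integer seed through per-stage child streams (`default_rng([seed, k])`),
so each stage is reproducible in isolation and whole-cohort emission is
byte-identical under a fixed seed.

## Known limitations

- The RBH clusterer is quadratic in genes per genome pair; it is meant
  for cohort-scale inputs (tens of genomes), not metagenome catalogues.
- Completeness in "top-level step" units makes nested OR-of-AND routes
  count as one step; use leaf weighting when finer resolution matters.
- NJ on model-corrected distances underperforms ML on short or highly
  divergent alignments; saturated pairs are reported, not imputed.
- The shipped pathway YAML is a curation starting point, not a
  substitute for map-level inspection of a new clade.
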