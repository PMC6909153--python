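# Methods

## The screening model

A cnidarian neuropeptide preprohormone is modeled as

```
signal peptide · pro-region · [spacer · cassette · processing site] × n · tail
```

with n typically 3–32. A processing site is a maximal tract of 1–3 basic
residues (K/R), optionally preceded by a glycine amide donor. The screen
declares a protein a candidate precursor when it contains at least
`min_copies` (default 3) candidate peptides — the segments between
consecutive sites, length 3–30 by default — that are mutually similar.

**Site grammar.** Tracts are resolved greedily left-to-right with maximal
munch (`GKRR` is one site, tract `KRR`, with a G donor; a basic run longer
than three residues is chunked and the overflow is treated as convertase
remnant at the next segment's start). Monobasic tracts count only with a
glycine donor (`GR`, `GK`): the observed site inventory never contains a
bare single K or R, and accepting every lone arginine would cleave inside
peptides such as RPRSamide that carry internal basics.
`SiteGrammar(require_g_mono_r=False)` restores the permissive reading.

**Similarity.** Candidate peptides are compared C-terminally anchored:
right-align the two sequences and count matches over the length of the
shorter one (X matches nothing). This reflects the family structure of
these peptides — conserved C-termini stabilized by amidation, variable
N-termini — and is the same metric used later for family grouping. The
similarity threshold (default 0.5) is a declared free parameter: the
original annotation was curated by eye and no quantitative cutoff exists
to copy. Single-linkage clusters of size ≥ `min_copies` make a hit; a
site-count-only mode (≥ `min_copies` sites, no similarity requirement) is
available because the screening rule can be read either way.

## Signal peptides and curation

SignalP-class predictors are external services; the shipped heuristic
declares a signal peptide when, within the first 35 residues, there is a
hydrophobic window of ≥ 7 residues with mean Kyte–Doolittle hydropathy
≥ 1.6, preceded by an n-region of non-negative net charge (K/R = +1,
D/E = −1), and followed within 8 residues by a cleavage position whose −3
and −1 residues are small (A, G, S, C, T, V). The score is the mean of
three normalized margins and is monotone in each. Externally produced
calls can be injected bit-exactly from TSV (`protein_id`, `present`,
`cleavage_pos`, `score`) and are passed through verbatim.

Classification is a pure function: repeat hit + signal → **accepted**;
repeat hit without signal → **review** (assembled transcripts are often
5′-truncated, so a missing signal is weak negative evidence); no repeat
hit → **rejected**. The cluster-span/protein-length coverage is reported
but never gated on: "overall precursor structure" resists a crisp rule.

## Processing chemistry

Cleavage occurs C-terminal of each basic tract; tract residues are
removed, and a glycine immediately N-terminal of the tract is removed as
the amide donor (the segment becomes C-terminally amidated; otherwise it
is a free acid). N-terminal maturation is an unspecific aminopeptidase
that removes one residue at a time from the preferred set
{E, D, S, T, N, G, A, L, V, Y, F} and stops at:

1. glutamine — cyclized to pyroglutamate (`pQ`), blocking the N-terminus;
2. proline at position 1, or
3. proline at position 2 — the X-P bond is an imide and resists
   hydrolysis;
4. any residue outside the preferred set.

The rule order matters and is forced by the observed peptides: LPRSamide
survives only because the position-2 proline check runs before "L is
trimmable". K and R are never aminopeptidase substrates (otherwise
RPRSamide and KPRSamide could not exist); leading basics are removed only
as convertase remnants of over-long tracts. Trimming is idempotent, and
all 22 published mature peptide strings shipped as regression anchors are
fixed points of these rules, reproducing their printed pQ/proline/amide
states.

Two honest limitations. First, peptides printed with `pQ` but preceded in
their precursor by non-trimmable residues cannot be reached by these
rules; such cases surface as differently trimmed variants rather than
being forced to the printed product. Second, GRFamide-family cores contain
an internal G-R that the grammar legitimately reads as a monobasic
amidation site, so fully automatic processing yields pQWLRamide-style
products rather than the full pQWLRGRFamide; resolving that required the
original study's manual curation, and the module-level trimming (which is
what the published strings test) reproduces the full forms when given the
correct cassette boundaries.

Cystine-loop annotation: when a mature peptide contains exactly two
cysteines, the inclusive first-C-to-second-C span is reported (6 for both
the cubozoan CKGQMCWFRamide and the scyphozoan CTSPMCWFRPamide); no
oxidation chemistry is modeled.

## Families and consensus motifs

Mature peptides are bucketed by (last `anchor_len` = 3 core residues,
amide state), non-amidated variants join their amidated form when cores
are identical, and buckets merge single-linkage when any cross-pair
reaches right-anchored identity ≥ `merge_identity` (default 0.5). Two
guards refine the pure sequence rule, both taken from the biology:

- **pyroglutamate guard** — an all-pQ bucket never merges with a bucket
  containing no pQ member. N-terminal blockage is a family-level trait (a
  free, protonatable N-terminus versus a cyclized one), and it is what
  keeps pQLRGamide out of the never-pQ X1PRX2amide family, which it would
  otherwise reach at exactly 2/4 identity through GPRGamide.
- **architecture guard** — when the fraction of multi-basic sites in the
  source precursor is known, buckets with incompatible architectures do
  not merge. GPRRamide precursors carry exclusively monobasic R sites
  while X1PRX2amide precursors are dominated by dibasic KR; this keeps
  the two families apart despite 3/4 C-terminal identity.

Consensus motifs right-align all members; unanimous full-coverage columns
are emitted verbatim, all others as numbered wildcards annotated with the
observed residue set (`X1PRX2amide`, X2 ∈ {S, A, G}). Known limitation:
with 4-residue peptides, a single 2-residue coincidence already reaches
the 0.5 threshold, so single linkage can chain families that the original
tables keep apart using precursor context (which peptides share a gene) —
context a sequence-only grouping cannot see. The acceptance-level
groupings are stable; the full published partition is not forced by extra
ad-hoc rules because those would break the worked examples that define
the metric.

## Homology search

A full Smith–Waterman with affine gaps (BLOSUM62; a gap of length L costs
`gap_open + gap_extend·L`, defaults 11/1) over six-frame translations
stands in for a seeded translated-BLAST search: at desk scale exhaustive
DP is fast and bit-reproducible. Traceback ties break diagonal > up >
left; equal-scoring end cells resolve in row-major order. No E-value
statistics — a raw-score threshold (default 60) plus percent identity is
sufficient for the cross-annotation role, and an external tabular-hit
hook can substitute real BLAST output.

## Phylogenetics

The exact aligner/parsimony settings behind the published trees are not
recoverable, so both analyses are implemented and both must agree on the
biological claim. Progressive alignment uses a 3-mer-distance UPGMA guide
tree and profile–profile global alignment (affine gaps, leftmost-gap
tie-break). p-distance is mismatches over compared sites with pairwise
(default) or complete gap deletion; a pair with zero comparable sites is
an error naming the pair.

Parsimony uses the Fitch count with gaps as a 21st state by default (a
shared deletion is shared evidence; a `missing` mode treats gaps as
wildcards). Trees are unrooted binary topologies anchored at the smallest
taxon; children order by smallest descendant label, making the canonical
Newick byte-stable. For ≤ 8 taxa (10 395 topologies) the optimum is found
by exhaustive enumeration with subtree-level memoization of Fitch masks;
beyond that, stepwise addition followed by SPR descent with bounded
sideways moves (parsimony landscapes have large equal-score plateaus),
seeded random-order restarts, and a parsimony ratchet (a random quarter
of columns is upweighted ×3, the tree re-climbed under the perturbed
score, then re-climbed under the original) to escape basins plain
descent cannot leave — random protein landscapes at 7 taxa routinely
hide a unique optimum behind a +1 score barrier. SPR rather than NNI
because NNI-only descent stalls far more often; with these settings the
search matched the exhaustive minimum on every random 7-taxon alignment
tested (hundreds across independent seed families). Ties everywhere
resolve to the lexicographically
smallest canonical Newick so results are bit-stable. Neighbor joining is
delegated to scikit-bio and returns topology only (branch lengths are not
propagated into the canonical form). Rooting is the user's choice via
`--outgroup`; the class-level analyses root on Octocorallia.

## Synthetic data

The generator emits precursors with the architecture above: a sampled
signal template (three templates, all passing the heuristic), a 20-residue
acidic pro-region ending in `KR` (long enough that even a minimal 3-copy
precursor exceeds the 60-aa ORF floor), then cassettes whose cores come
from the published family archetypes with per-position variability,
spacers drawn from the trim-preferred pool plus K (1–4 residues), and
sites drawn from {GR, GKR, GRR, GKRR, RR, KR, RRR, RKR, RKK}. Structural
guards keep truth well-defined: spacers never start/end with K, never
contain KK or G-before-basic (either would forge a site), and cores
ending in K/R only receive G-prefixed sites (a bare basic site would fuse
with the core under maximal munch).

Ground truth for each cassette is computed by applying the package's own
site grammar and trimming rules to the cassette window at generation
time. This is deliberate: spacers may contain non-trimmable lysines and
cores may contain internal sites, so a structurally "intended" product
would provably disagree with any correct implementation of the stated
chemistry. Consequently the end-to-end recovery tests validate detection,
site parsing, cleavage coordinates, clustering and counting against
construction-time truth, while the trimming rules themselves are
validated independently against the 22 hand-traced published peptides.

Transcripts are back-translated with uniform synonymous codons, flanked
by stop codons (so the stop-to-stop ORF is exactly the designed protein)
and random UTRs. Decoys are i.i.d. draws from a Swiss-Prot-like residue
frequency table, rejection-sampled against the detector in all six
reading frames so the negative set is cassette-free by construction;
precursor transcripts are re-coded if an unintended reading frame happens
to screen positive. All outputs are pure functions of (spec, seed).

Divergence along the class tree
(((Cubozoa, Scyphozoa), Staurozoa), Octocorallia) mutates spacers at
per-branch rates (defaults 0.06–0.35 substitutions/site, outgroup branch
longest) and cores at 0.15× that rate with the C-terminal 3 anchor
residues frozen, so the family's diagnostic C-terminus survives in every
class. The topology-recovery analyses use 24-cassette precursors: with
shorter precursors (~8 cassettes) the stem branches leave only ~3
informative sites and recovery becomes luck-of-the-seed; at 24 cassettes
both parsimony and NJ recovered the generating topology across all seeds
probed. What passing these tests shows — and does not show — about real
data: the generator has no indels, no assembly error, no alternative
splicing and no compositional heterogeneity, so it validates the logic of
the pipeline, not its recall on real assemblies.

## Problem sizes and defaults

| parameter | default | why |
| --- | --- | --- |
| `min_orf_aa` | 60 | shortest plausible precursor (signal + pro + 3 cassettes) |
| `min_copies` | 3 | the screening rule's "at least three" |
| candidate length | 3–30 aa | shortest published peptide is 4 aa; longest families < 15 |
| `identity_threshold` / `merge_identity` | 0.5 | declared free parameter; reproduces the worked examples |
| `anchor_len` | 3 | C-terminal motif length of the published families |
| trimmable set | EDSTNGALVYF | the preferred aminopeptidase substrates |
| gap_open / gap_extend | 11 / 1 | standard BLOSUM62 pairing |
| score threshold | 60 | shuffle-null scores plateau near 40 for 150-aa proteins |
| exhaustive-search limit | 8 taxa | 10 395 topologies, sub-second with memoized Fitch |
| synthetic transcriptome | 200 decoys + 6 precursors | the recovery experiments' standard size |

The recovery experiment draws copy numbers uniformly from 3–32, matching
the published range.
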