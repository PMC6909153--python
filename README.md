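# cnidopep

Annotation of multi-copy neuropeptide preprohormones in cnidarian genomes
and transcriptomes.

Cnidarian nervous systems are strongly peptidergic, and their neuropeptide
genes have a distinctive architecture: a signal peptide followed by many
near-identical peptide "cassettes" separated by short spacers, each cassette
flanked by a prohormone-convertase processing site (a mono-, di- or tribasic
K/R tract such as `GKR`, `RR` or `RKK`, often with a glycine donor that
becomes a C-terminal amide). `cnidopep` implements the whole analysis a
peptide annotator performs on such data:

- **seqio** — FASTA I/O and six-frame, stop-to-stop ORF translation, so
  transcriptome and genome assemblies enter the pipeline as proteins.
- **detector** — the screening rule: flag proteins containing at least three
  mutually similar candidate peptides, each followed by a classical
  processing site. Similarity is C-terminally anchored (these families
  conserve their C-termini and vary at the N-terminus).
- **curation** — reproducible accept/review/reject classification from the
  repeat screen plus a signal-peptide call (a documented hydrophobicity
  heuristic, or externally produced calls injected verbatim from TSV).
- **maturation** — the processing chemistry: cleavage C-terminal of the
  basic tract, glycine-donated amidation, and N-terminal aminopeptidase
  trimming of preferred residues (E, D, S, T, N, G, A, L, V, Y, F) that
  stops at Q (cyclized to pyroglutamate, written `pQ`), at a position-1/2
  proline (the X-P imide resists hydrolysis), or at any other residue.
- **families** — cross-dataset grouping of mature peptides into families by
  shared C-terminal anchor, consensus motifs with numbered wildcards (e.g.
  `X1PRX2amide` with X2 ∈ {S,A,G}), presence/absence matrices across
  classes, and cystine-loop annotation for the cyclic FRamide peptides.
- **homology** — a deterministic Smith–Waterman/BLOSUM62 stand-in for
  translated-BLAST cross-dataset searches.
- **phylo** — progressive alignment, p-distance, Fitch maximum parsimony
  (exhaustive for ≤ 8 taxa, SPR hill-climbing beyond) and neighbor joining,
  with canonical Newick output.
- **simdata** — a synthetic-data generator producing transcriptomes with
  exact ground truth (precursor coordinates, intended mature peptides,
  class-structured divergence along the cnidarian class tree), so every
  stage is testable without downloading the public assemblies.
- **workbench** — YAML-configured end-to-end runs and a benchmark runner
  that compares locally fetched assemblies against published copy counts.

## Worked example

Generate a staurozoan-style precursor carrying eleven RPRSamide copies and
run the annotation stages over it:

```python
from cnidopep import detector, curation, maturation, simdata

spec = simdata.PrecursorSpec(core="RPRS", n_copies=11,
                             site_weights={"GKR": 1.0},
                             spacer_pool=tuple(sorted("EDSTNGALVYF")))
precursor, truth = simdata.generate_precursor(spec, seed=1)

result = detector.screen_protein(precursor)
signal = curation.predict_signal_peptide(precursor)
annotation = maturation.mature_all(curation.classify(result, signal))

print("sites:", len(result.sites), "| signal:", signal.present,
      "| status:", annotation.status)
print("mature peptides:", annotation.copy_counts)
```

prints

```
sites: 12 | signal: True | status: accepted
mature peptides: {'RPRSamide': 11}
```

Twelve processing sites are found (eleven `GKR` cassette sites plus the
`KR` closing the pro-region); the protein carries a signal peptide and a
cluster of ≥ 3 similar cassettes, so it is accepted as a preprohormone, and
cleavage + trimming yields exactly eleven copies of `RPRSamide` — the
N-terminal spacer residues are trimmed away and the peptide survives intact
because arginine is never an aminopeptidase substrate and the position-2
proline protects what remains.

The same stages are available from the shell:

```bash
cnidopep simulate -o simdir --n-decoys 200 --seed 1
cnidopep translate simdir/transcriptome.fna --min-orf 60 -o proteins.faa
cnidopep scan proteins.faa --min-copies 3 --identity 0.5 -o hits.tsv
cnidopep run -c config.yaml -o outdir     # full pipeline from a manifest
```

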