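# Public assemblies for the benchmark

Fetching is deliberately manual so the test suite and the acceptance
script stay network-free. To benchmark against the published copy
counts, download the nucleotide FASTA for the assemblies below (NCBI
TSA/WGS master records), place them anywhere on disk, and list them in a
manifest TSV with columns `path`, `dataset`, `class_label`, where
`dataset` is the species name exactly as written here.

| Species | Class | Type | Accession |
| --- | --- | --- | --- |
| Renilla reniformis | Octocorallia | WGS | FXAL00000000.1 |
| Eleutherobia rubra | Octocorallia | TSA | GHFI00000000.1 |
| Xenia sp. | Octocorallia | TSA | GHBC00000000.1 |
| Briareum asbestinum | Octocorallia | TSA | GHBD00000000.1 |
| Clavularia sp. | Octocorallia | TSA | GHAW00000000.1 |
| Heliopora coerulea | Octocorallia | TSA | GFVH00000000.1, IABP00000000.1 |
| Acanthogorgia aspera | Octocorallia | TSA | GETB00000000.1, GEXC00000000.1 |
| Rhopilema esculentum | Scyphozoa | TSA | GEMS00000000.1 |
| Nemopilema nomurai | Scyphozoa | TSA | GHAR00000000.1 |
| Aurelia aurita | Scyphozoa | TSA | GBRG00000000.1 |
| Aurelia aurita | Scyphozoa | WGS | REGM00000000.1 |
| Calvadosia cruxmelitensis | Staurozoa | TSA | HAHC00000000.1 |
| Calvadosia cruxmelitensis | Staurozoa | WGS | OFHS00000000.1 |
| Haliclystus sanjuanensis | Staurozoa | TSA | HAHB00000000.1 |
| Craterolophus convolvulus | Staurozoa | TSA | HAGZ00000000.1 |
| Lucernaria quadricornis | Staurozoa | TSA | HAHD00000000.1 |
| Haliclystus auricula | Staurozoa | TSA | HAHA00000000.1 |

Then run:

```bash
cnidopep benchmark manifest.tsv -o comparison.tsv
```

Missing files are skipped with a notice; the comparison table reports
observed versus published copy numbers per precursor peptide. Exact
agreement depends on the similarity threshold (the "similar peptides"
criterion was curated by eye in the original analysis), so the match
flag is informative, not a pass/fail gate.
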