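"""Pipeline orchestration: configuration, stage wiring, reports, benchmark.

``run_pipeline`` drives the full analysis over a manifest of datasets —
translate, screen, curate, mature, group into families, and build
preprohormone trees for families spanning several datasets — writing
every intermediate as TSV/Newick so each number in the final overview is
traceable.  ``benchmark`` compares locally available assemblies against
the published per-precursor copy counts.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import curation, detector, families, maturation, phylo, reference, seqio

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DatasetEntry:
    path: str
    dataset: str
    class_label: str
    alphabet: str = "auto"  # auto | nucleotide | protein


@dataclass(frozen=True)
class PipelineConfig:
    manifest: tuple[DatasetEntry, ...] = ()
    min_orf_aa: int = 60
    min_copies: int = 3
    identity_threshold: float = 0.5
    min_peptide_len: int = 3
    max_peptide_len: int = 30
    anchor_len: int = 3
    merge_identity: float = 0.5
    trimmable: str = "".join(sorted(maturation.TRIMMABLE_DEFAULT))
    tree_method: str = "both"  # parsimony | nj | both
    seed: int = 0
    signal_calls: str | None = None
    detector_mode: str = "cluster"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        manifest = tuple(
            DatasetEntry(**row) for row in raw.pop("manifest", [])
        )
        return cls(manifest=manifest, **raw)

    def detector_params(self) -> detector.DetectorParams:
        return detector.DetectorParams(
            min_len=self.min_peptide_len, max_len=self.max_peptide_len,
            identity_threshold=self.identity_threshold,
            min_copies=self.min_copies, mode=self.detector_mode,
        )

    def trim_policy(self) -> maturation.TrimPolicy:
        return maturation.TrimPolicy(trimmable=frozenset(self.trimmable))


@dataclass
class PipelineReport:
    annotations: list[curation.PreprohormoneAnnotation]
    overview: families.FamilyOverview | None
    trees: dict[str, str]
    stage_counts: dict[str, int]


def _sniff_alphabet(path: Path) -> str:
    sample = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                continue
            sample.append(line.strip().upper())
            if sum(len(s) for s in sample) > 2000:
                break
    text = "".join(sample)
    if not text:
        return seqio.PROTEIN
    nuc = sum(1 for c in text if c in "ACGTN")
    return seqio.NUCLEOTIDE if nuc / len(text) > 0.95 else seqio.PROTEIN


def _load_proteins(entry: DatasetEntry, config: PipelineConfig) -> list[seqio.SequenceRecord]:
    path = Path(entry.path)
    alphabet = entry.alphabet
    if alphabet == "auto":
        alphabet = _sniff_alphabet(path)
    records = seqio.read_fasta(path, alphabet=alphabet, source=entry.dataset)
    if alphabet == seqio.NUCLEOTIDE:
        return seqio.six_frame_translate_all(records, min_orf_aa=config.min_orf_aa)
    return records


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineReport:
    """Run every stage over the manifest and write intermediates to outdir."""
    if not config.manifest:
        raise ValueError("empty manifest: nothing to analyze")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.detector_params()
    policy = config.trim_policy()
    external_calls = (curation.read_signal_calls(config.signal_calls)
                      if config.signal_calls else {})

    stage_counts: dict[str, int] = {}
    all_annotations: list[curation.PreprohormoneAnnotation] = []
    members: list[families.FamilyMember] = []
    dataset_to_class: dict[str, str] = {}
    hit_rows, pep_rows = [], []
    precursor_seqs: dict[str, tuple[str, str]] = {}  # id -> (dataset, seq)

    for entry in config.manifest:
        dataset_to_class[entry.dataset] = entry.class_label
        try:
            proteins = _load_proteins(entry, config)
        except FileNotFoundError:
            raise ValueError(f"stage seqio failed for dataset {entry.dataset!r}: "
                             f"missing file {entry.path}")
        stage_counts[f"{entry.dataset}:proteins"] = len(proteins)
        for prot in proteins:
            det = detector.screen_protein(prot, params)
            if not det.is_hit and not det.sites:
                continue
            sig = external_calls.get(prot.id) or curation.predict_signal_peptide(prot)
            ann = curation.classify(det, sig)
            best = max((len(c.members) for c in det.clusters), default=0)
            hit_rows.append({
                "protein_id": prot.id, "dataset": entry.dataset,
                "n_sites": len(det.sites), "best_cluster_size": best,
                "medoid_seq": det.clusters[0].medoid.seq if det.clusters else "",
                "is_hit": int(det.is_hit), "status": ann.status,
            })
            if ann.status in ("accepted", "review"):
                ann = maturation.mature_all(ann, policy, config.min_copies)
                all_annotations.append(ann)
                arch = _multibasic_fraction(det)
                precursor_seqs[prot.id] = (entry.dataset, prot.seq)
                for pep in ann.mature_peptides:
                    members.append(families.FamilyMember(
                        peptide=pep, dataset=entry.dataset,
                        class_label=entry.class_label,
                        arch_multibasic_fraction=arch,
                    ))
                    pep_rows.append({
                        "precursor_id": prot.id, "dataset": entry.dataset,
                        "display": pep.display, "n_state": pep.n_state,
                        "c_state": pep.c_state, "start": pep.start,
                        "end": pep.end,
                    })
        stage_counts[f"{entry.dataset}:annotations"] = sum(
            1 for a in all_annotations
            if precursor_seqs.get(a.protein_id, ("",))[0] == entry.dataset
        )

    pd.DataFrame(hit_rows).to_csv(outdir / "hits.tsv", sep="\t", index=False)
    pd.DataFrame(pep_rows).to_csv(outdir / "peptides.tsv", sep="\t", index=False)

    overview = None
    if members:
        fams = families.group_families(
            members, anchor_len=config.anchor_len,
            merge_identity=config.merge_identity,
        )
        overview = families.presence_matrix(fams, dataset_to_class)
        fam_rows = [{
            "family_id": f.id, "consensus": f.consensus,
            "breadth": f.breadth, "size": f.size,
            "classes_present": ";".join(c for c, v in sorted(f.presence.items()) if v),
        } for f in overview.families]
        pd.DataFrame(fam_rows).to_csv(outdir / "families.tsv", sep="\t", index=False)
        overview.matrix.to_csv(outdir / "presence.tsv", sep="\t")

    trees = _family_trees(overview, precursor_seqs, members, config, outdir)

    run_log = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stage_counts": stage_counts,
        "n_annotations": len(all_annotations),
        "n_peptides": len(members),
        "n_families": len(overview.families) if overview else 0,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)
    return PipelineReport(annotations=all_annotations, overview=overview,
                          trees=trees, stage_counts=stage_counts)


def _multibasic_fraction(det: detector.DetectorResult) -> float | None:
    if not det.sites:
        return None
    multi = sum(1 for s in det.sites if len(s.basic_tract) >= 2)
    return multi / len(det.sites)


def _family_trees(overview, precursor_seqs, members, config, outdir) -> dict[str, str]:
    """Tree(s) for each family whose precursors span >= 4 datasets."""
    trees: dict[str, str] = {}
    if overview is None:
        return trees
    for fam in overview.families:
        pids = sorted({m.peptide.precursor_id for m in fam.members
                       if m.peptide.precursor_id in precursor_seqs})
        if len(pids) < 4:
            continue
        seqs = [(pid, precursor_seqs[pid][1]) for pid in pids]
        aln = phylo.progressive_align(seqs)
        methods = (["parsimony", "nj"] if config.tree_method == "both"
                   else [config.tree_method])
        for method in methods:
            tree = phylo.best_tree(aln, method=method, seed=config.seed)
            key = f"{fam.id}:{method}"
            trees[key] = tree.newick()
            safe = fam.id.replace("/", "_")
            with open(outdir / f"tree_{safe}_{method}.nwk", "w") as fh:
                fh.write(trees[key] + "\n")
    return trees


def benchmark(
    manifest: list[DatasetEntry] | str | Path,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Compare observed copy counts on locally fetched assemblies with the
    published per-precursor numbers.  Missing files are skipped with a
    notice; with nothing available an empty comparison is returned.
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, list):
        df = pd.read_csv(manifest, sep="\t")
        entries = []
        for row in df.itertuples(index=False):
            try:
                entries.append(DatasetEntry(
                    path=str(row.path), dataset=str(row.dataset),
                    class_label=str(row.class_label),
                ))
            except (AttributeError, TypeError) as exc:
                log.error("malformed manifest row %r: %s", row, exc)
        manifest = entries

    rows = []
    for entry in manifest:
        if entry.dataset not in reference.PRINTED_COPY_COUNTS:
            continue
        if not Path(entry.path).exists():
            log.warning("benchmark: %s not fetched; skipping %s",
                        entry.path, entry.dataset)
            continue
        _, printed = reference.PRINTED_COPY_COUNTS[entry.dataset]
        sub = dataclasses.replace(config, manifest=(entry,))
        import tempfile
        with tempfile.TemporaryDirectory() as tmp:
            report = run_pipeline(sub, tmp)
        observed = {}
        for ann in report.annotations:
            for display, n in ann.copy_counts.items():
                observed[display] = observed.get(display, 0) + n
        for display, expected in printed.items():
            got = observed.get(display, 0)
            rows.append({
                "dataset": entry.dataset, "peptide": display,
                "printed": expected, "observed": got,
                "match": int(got == expected),
            })
    return pd.DataFrame(rows, columns=["dataset", "peptide", "printed",
                                       "observed", "match"])
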