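"""Synthetic transcriptomes with known neuropeptide content.

The generator emulates the architecture the screen assumes: a signal
peptide, an acidic pro-region ending in a convertase site, then 3-32
near-identical peptide cassettes separated by spacers of
trim-preferred residues and flanked by G/basic processing sites,
back-translated into transcripts and embedded among decoy proteins
drawn from a background amino-acid frequency model.  Every output is a
pure function of (spec, seed).

Ground truth records, per generated transcript, whether it is a
precursor, where its cassettes lie and which mature display strings
(with multiplicities) the processing chemistry yields.  The intended
mature products are computed by applying the documented trimming rules
to each generated segment, so truth stays exact even when a sampled
spacer contains a non-trimmable lysine.

Structural constraints keep the truth well-defined: spacers never
start or end with K and never contain a KK doublet (either would forge
a processing site), cores ending in K/R only receive G-prefixed sites
(a bare basic site would fuse with the core under maximal munch), and
back-translated coding sequences are flanked by stop codons so the
stop-to-stop ORF is exactly the designed protein.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from . import reference
from .detector import DetectorParams, find_processing_sites, screen_protein
from .maturation import TrimPolicy, cleave, trim_n_terminus
from .seqio import NUCLEOTIDE, PROTEIN, SequenceRecord

# Swiss-Prot-like background amino-acid frequencies for decoy proteins.
AA_BACKGROUND = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

SIGNAL_TEMPLATES = (
    "MKTLVLLALLAVALA",
    "MRALLLVALVALAASA",
    "MKALIVLSLLVIGSVFA",
)

# Acidic N-terminal pro-region between the signal peptide and the first
# cassette, ending in its own convertase site.  Long enough that even a
# minimal precursor (signal + 3 single-spacer cassettes) exceeds the
# 60-residue ORF floor used for screening.
PRO_REGION = "EESSEDELSENDAEESSADE"
PRO_SITE = "KR"

DEFAULT_SITE_WEIGHTS = {
    "GR": 0.15, "GKR": 0.30, "GRR": 0.10, "GKRR": 0.05,
    "RR": 0.10, "KR": 0.20, "RRR": 0.05, "RKR": 0.025, "RKK": 0.025,
}

SPACER_POOL_DEFAULT = tuple(sorted(set("EDSTNGALVYF") | {"K"}))

DEFAULT_CLASS_TREE = (
    ((reference.CUBOZOA, reference.SCYPHOZOA), reference.STAUROZOA),
    reference.OCTOCORALLIA,
)


@dataclass(frozen=True)
class PrecursorSpec:
    core: str
    n_copies: int
    variable_positions: dict[int, str] = field(default_factory=dict)
    site_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SITE_WEIGHTS))
    spacer_len_range: tuple[int, int] = (1, 4)
    spacer_pool: tuple[str, ...] = SPACER_POOL_DEFAULT
    signal_template: str | None = None
    family: str = ""
    class_label: str = ""
    # per-copy, per-position substitution probability (any amino acid)
    copy_substitution_rate: float = 0.0

    def __post_init__(self):
        if not self.core:
            raise ValueError("precursor spec needs a non-empty core motif")
        if self.n_copies < 0:
            raise ValueError("n_copies must be >= 0")
        forbidden = set(self.spacer_pool) & {"C", "W"}
        if forbidden:
            raise ValueError(f"spacer pool may not contain {sorted(forbidden)}")


@dataclass
class GroundTruth:
    transcript_id: str
    is_precursor: bool
    class_label: str = ""
    family: str = ""
    n_copies: int = 0
    cassette_spans: list[tuple[int, int]] = field(default_factory=list)
    mature_counts: Counter = field(default_factory=Counter)
    protein: str = ""


def _sample_spacer(rng: np.random.Generator, spec: PrecursorSpec,
                   next_residue: str = "") -> str:
    """Spacer residues that cannot forge a processing site: no K at the
    edges or after a G/K, and no G immediately before a basic residue
    (which would read as a G-donor site)."""
    lo, hi = spec.spacer_len_range
    length = int(rng.integers(lo, hi + 1))
    pool = list(spec.spacer_pool)
    chars: list[str] = []
    for k in range(length):
        while True:
            c = str(rng.choice(pool))
            prev = chars[-1] if chars else ""
            if c == "K" and (k == 0 or k == length - 1 or prev in "GK"):
                continue
            if c == "G" and k == length - 1 and next_residue in "KR":
                continue
            break
        chars.append(c)
    return "".join(chars)


def _sample_site(rng: np.random.Generator, spec: PrecursorSpec) -> str:
    weights = spec.site_weights
    if spec.core[-1] in "KR":
        weights = {s: w for s, w in weights.items() if s.startswith("G")}
    names = sorted(weights)
    probs = np.array([weights[s] for s in names], dtype=float)
    probs /= probs.sum()
    return str(names[int(rng.choice(len(names), p=probs))])


_AA20 = sorted(AA_BACKGROUND)


def _sample_core(rng: np.random.Generator, spec: PrecursorSpec) -> str:
    chars = list(spec.core)
    for pos, alphabet in spec.variable_positions.items():
        chars[pos] = str(rng.choice(list(alphabet)))
    if spec.copy_substitution_rate > 0:
        for i in range(len(chars)):
            if rng.random() < spec.copy_substitution_rate:
                chars[i] = _AA20[int(rng.integers(20))]
    return "".join(chars)


def _cassette_products(spacer: str, core: str, site: str,
                       policy: TrimPolicy) -> list[str]:
    """Mature display strings one cassette yields under the chemistry.

    The cassette window (spacer + core + its processing site) is
    segmented with the same site grammar the detector uses, so cores
    that legitimately contain an internal site (e.g. the G-R inside a
    GRFamide core) produce the same products the pipeline will report.
    """
    window = spacer + core + site
    sites = find_processing_sites(window)
    out = []
    for prod in cleave(window, sites, policy):
        mp = trim_n_terminus(prod.seq, prod.amide, policy)
        if mp is not None:
            out.append(mp.display)
    return out


def generate_precursor(
    spec: PrecursorSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    record_id: str = "precursor",
    policy: TrimPolicy | None = None,
) -> tuple[SequenceRecord, GroundTruth]:
    """Assemble one precursor protein and its ground truth."""
    if rng is None:
        rng = np.random.default_rng(seed)
    policy = policy or TrimPolicy()
    signal = spec.signal_template or str(rng.choice(SIGNAL_TEMPLATES))
    parts = [signal, PRO_REGION, PRO_SITE]
    truth = GroundTruth(
        transcript_id=record_id, is_precursor=spec.n_copies > 0,
        class_label=spec.class_label, family=spec.family,
        n_copies=spec.n_copies,
    )
    pos = sum(len(p) for p in parts)
    for _ in range(spec.n_copies):
        core = _sample_core(rng, spec)
        spacer = _sample_spacer(rng, spec, next_residue=core[0])
        site = _sample_site(rng, spec)
        amide = site.startswith("G")
        parts.extend([spacer, core, site])
        truth.cassette_spans.append((pos + len(spacer), pos + len(spacer) + len(core)))
        for display in _cassette_products(spacer, core, site, policy):
            truth.mature_counts[display] += 1
        pos += len(spacer) + len(core) + len(site)
    tail = _sample_spacer(rng, spec) + "DE"
    parts.append(tail)
    protein = "".join(parts)
    truth.protein = protein
    rec = SequenceRecord(id=record_id, seq=protein, alphabet=PROTEIN,
                         source="simdata")
    return rec, truth


# ------------------------------------------------------------- nucleotide

_CODON_TABLE = unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for aa in _AA_TO_CODONS:
    _AA_TO_CODONS[aa].sort()


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform synonymous codon choice."""
    return "".join(
        _AA_TO_CODONS[aa][int(rng.integers(len(_AA_TO_CODONS[aa])))]
        for aa in protein
    )


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=length))


def _wrap_transcript(protein: str, rng: np.random.Generator) -> str:
    utr5 = _random_nt(rng, int(rng.integers(15, 41)))
    utr3 = _random_nt(rng, int(rng.integers(15, 41)))
    return utr5 + "TAA" + back_translate(protein, rng) + "TAA" + utr3


def _sample_decoy_protein(rng: np.random.Generator,
                          length_range=(80, 300)) -> str:
    aas = sorted(AA_BACKGROUND)
    probs = np.array([AA_BACKGROUND[a] for a in aas])
    probs /= probs.sum()
    length = int(rng.integers(*length_range))
    idx = rng.choice(len(aas), size=length, p=probs)
    return "".join(aas[int(i)] for i in idx)


def generate_transcriptome(
    n_decoys: int,
    precursor_specs: list[PrecursorSpec],
    seed: int = 0,
    detector_params: DetectorParams | None = None,
    min_orf_aa: int = 60,
    max_resample: int = 50,
) -> tuple[list[SequenceRecord], list[GroundTruth]]:
    """Decoys plus precursors as nucleotide transcripts with ground truth.

    Decoy proteins are rejection-sampled against the detector so the
    negative set is cassette-free by construction; precursor transcripts
    are re-coded if any unintended reading frame of the back-translated
    sequence happens to screen positive.
    """
    rng = np.random.default_rng(seed)
    params = detector_params or DetectorParams()
    entries: list[tuple[str, GroundTruth]] = []

    from .seqio import six_frame_translate  # local import avoids cycle at load

    for k, spec in enumerate(precursor_specs):
        rec, truth = generate_precursor(spec, rng=rng, record_id=f"pre{k}")
        for _ in range(max_resample):
            nt = _wrap_transcript(rec.seq, rng)
            nt_rec = SequenceRecord(id="tmp", seq=nt, alphabet=NUCLEOTIDE)
            orfs = six_frame_translate(nt_rec, min_orf_aa=min(min_orf_aa, len(rec.seq)))
            hits = [o for o in orfs if screen_protein(o, params).is_hit]
            if len(hits) == (1 if truth.is_precursor else 0) and \
                    all(h.seq == rec.seq for h in hits):
                break
        entries.append((nt, truth))

    for k in range(n_decoys):
        for _ in range(max_resample):
            protein = _sample_decoy_protein(rng)
            rec = SequenceRecord(id=f"dec{k}", seq=protein, alphabet=PROTEIN)
            if screen_protein(rec, params).is_hit:
                continue
            nt = _wrap_transcript(protein, rng)
            nt_rec = SequenceRecord(id="tmp", seq=nt, alphabet=NUCLEOTIDE)
            orfs = six_frame_translate(nt_rec, min_orf_aa=min_orf_aa)
            if not any(screen_protein(o, params).is_hit for o in orfs):
                break
        truth = GroundTruth(transcript_id=f"dec{k}", is_precursor=False,
                            protein=protein)
        entries.append((nt, truth))

    # neutral, order-shuffled transcript ids
    order = rng.permutation(len(entries))
    records: list[SequenceRecord] = []
    truths: list[GroundTruth] = []
    for rank, idx in enumerate(order):
        nt, truth = entries[int(idx)]
        tid = f"tx{rank:05d}"
        truth.transcript_id = tid
        records.append(SequenceRecord(id=tid, seq=nt, alphabet=NUCLEOTIDE,
                                      source="simdata"))
        truths.append(truth)
    return records, truths


# --------------------------------------------------------------- divergence

CORE_SUB_ALPHABET = "ASTNDELVIFYMH"  # avoids K/R/G/P/Q/C/W: keeps processing intact

DEFAULT_BRANCH_RATES = {
    reference.OCTOCORALLIA: 0.35,
    "medusozoa_stem": 0.15,
    reference.STAUROZOA: 0.15,
    "cubo_scypho_stem": 0.12,
    reference.CUBOZOA: 0.06,
    reference.SCYPHOZOA: 0.06,
}


@dataclass(frozen=True)
class _Regions:
    """A precursor decomposed into mutable and frozen regions."""
    parts: tuple[tuple[str, str], ...]  # (kind, residues)

    def assemble(self) -> str:
        return "".join(s for _, s in self.parts)


def _build_regions(spec: PrecursorSpec, rng: np.random.Generator) -> _Regions:
    signal = spec.signal_template or str(rng.choice(SIGNAL_TEMPLATES))
    parts: list[tuple[str, str]] = [
        ("signal", signal), ("pro", PRO_REGION), ("site", PRO_SITE),
    ]
    for _ in range(spec.n_copies):
        core = _sample_core(rng, spec)
        parts.append(("spacer", _sample_spacer(rng, spec, next_residue=core[0])))
        parts.append(("core", core))
        parts.append(("site", _sample_site(rng, spec)))
    parts.append(("spacer", _sample_spacer(rng, spec) + "DE"))
    return _Regions(parts=tuple(parts))


def _mutate_regions(
    regions: _Regions, rate: float, core_rate_factor: float,
    anchor_len: int, spacer_sub_pool: str, rng: np.random.Generator,
) -> _Regions:
    new_parts = []
    for idx, (kind, residues) in enumerate(regions.parts):
        if kind == "spacer":
            nxt = regions.parts[idx + 1][1] if idx + 1 < len(regions.parts) else ""
            chars = list(residues)
            for i, c in enumerate(chars):
                if c == "K":
                    continue  # keep the no-KK/no-edge-K guarantees intact
                if rng.random() < rate:
                    sub = str(rng.choice(list(spacer_sub_pool)))
                    # never forge a G-donor site against a basic neighbor
                    after = chars[i + 1] if i + 1 < len(chars) else nxt[:1]
                    if sub == "G" and after in "KR":
                        continue
                    chars[i] = sub
            residues = "".join(chars)
        elif kind == "core":
            chars = list(residues)
            for i in range(max(0, len(chars) - anchor_len)):
                if rng.random() < rate * core_rate_factor:
                    chars[i] = str(rng.choice(list(CORE_SUB_ALPHABET)))
            residues = "".join(chars)
        new_parts.append((kind, residues))
    return _Regions(parts=tuple(new_parts))


def diverge(
    spec: PrecursorSpec,
    class_tree=DEFAULT_CLASS_TREE,
    branch_rates: dict[str, float] | None = None,
    core_rate_factor: float = 0.15,
    anchor_len: int = 3,
    seed: int = 0,
    policy: TrimPolicy | None = None,
) -> dict[str, tuple[SequenceRecord, GroundTruth]]:
    """Evolve one ancestral precursor along the class tree.

    Spacer residues substitute at the branch rate, core residues at a
    reduced rate with the C-terminal ``anchor_len`` positions held fixed,
    so the sequences' true history matches the class tree while the
    family's diagnostic C-terminus survives in every class.
    """
    rng = np.random.default_rng(seed)
    rates = dict(DEFAULT_BRANCH_RATES)
    if branch_rates:
        rates.update(branch_rates)
    policy = policy or TrimPolicy()
    spacer_sub_pool = "".join(sorted(set("EDSTNGALVYF")))
    root = _build_regions(spec, rng)
    out: dict[str, tuple[SequenceRecord, GroundTruth]] = {}

    internal_names = {
        frozenset({reference.CUBOZOA, reference.SCYPHOZOA}): "cubo_scypho_stem",
        frozenset({reference.CUBOZOA, reference.SCYPHOZOA,
                   reference.STAUROZOA}): "medusozoa_stem",
    }

    def branch_name(node) -> str:
        if isinstance(node, str):
            return node
        leaves = frozenset(_tree_leaves(node))
        return internal_names.get(leaves, "stem")

    def walk(node, regions: _Regions):
        if isinstance(node, str):
            out[node] = _finalize(node, regions)
            return
        for child in node:
            rate = rates.get(branch_name(child), 0.1)
            walk(child, _mutate_regions(regions, rate, core_rate_factor,
                                        anchor_len, spacer_sub_pool, rng))

    def _finalize(label: str, regions: _Regions):
        protein = regions.assemble()
        truth = GroundTruth(
            transcript_id=label, is_precursor=spec.n_copies > 0,
            class_label=label, family=spec.family, n_copies=spec.n_copies,
            protein=protein,
        )
        parts = list(regions.parts)
        pos = 0
        for i, (kind, residues) in enumerate(parts):
            if kind == "core":
                truth.cassette_spans.append((pos, pos + len(residues)))
                spacer = parts[i - 1][1] if parts[i - 1][0] == "spacer" else ""
                site = parts[i + 1][1] if i + 1 < len(parts) else ""
                for display in _cassette_products(spacer, residues, site, policy):
                    truth.mature_counts[display] += 1
            pos += len(residues)
        rec = SequenceRecord(id=label, seq=protein, alphabet=PROTEIN,
                             source=f"simdata:{label}")
        return rec, truth

    # root: no mutation on the edge into the root itself
    walk(class_tree, root)
    return out


def _tree_leaves(node):
    if isinstance(node, str):
        yield node
    else:
        for child in node:
            yield from _tree_leaves(child)


# --------------------------------------------------------- default study set

def default_precursor_specs(rng: np.random.Generator | None = None,
                            copy_numbers: list[int] | None = None) -> list[PrecursorSpec]:
    """Six precursor specs, one per published family archetype."""
    base = [
        PrecursorSpec(core="RPRS", n_copies=11,
                      variable_positions={0: "RLKG"},
                      family="XPRXamide", class_label=reference.STAUROZOA),
        PrecursorSpec(core="QWLRGRF", n_copies=8,
                      family="GRFamide", class_label=reference.SCYPHOZOA),
        PrecursorSpec(core="QPPGVW", n_copies=6,
                      variable_positions={4: "VTA"},
                      family="PPGxWamide", class_label=reference.CUBOZOA),
        PrecursorSpec(core="CKGQMCWFR", n_copies=4,
                      family="cyclic-FRamide", class_label=reference.CUBOZOA),
        PrecursorSpec(core="QHLRY", n_copies=6,
                      variable_positions={2: "LV"},
                      family="RYamide", class_label=reference.SCYPHOZOA),
        PrecursorSpec(core="PPFH", n_copies=5,
                      family="PFHamide", class_label=reference.OCTOCORALLIA),
    ]
    if copy_numbers is not None:
        base = [replace(s, n_copies=c) for s, c in zip(base, copy_numbers)]
    return base
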