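"""Cross-dataset grouping of mature peptides into neuropeptide families.

Families are seeded by the C-terminal anchor (last ``anchor_len`` core
residues plus the amide state) and then merged single-linkage whenever
two members reach ``merge_identity`` right-anchored identity.  Two
biology-derived guards refine the pure sequence rule:

* pyroglutamate guard — a bucket whose members are all pQ-protected is
  never merged with a bucket containing no pQ member.  N-terminal
  blockage is a family-level trait (a free, protonatable N-terminus
  versus a cyclized one changes receptor pharmacology), and it is what
  separates e.g. pQLRGamide from the never-pQ X1PRX2amide peptides.
* architecture guard — when precursor architecture is known (fraction of
  multi-basic processing sites), buckets with incompatible architectures
  are not merged.  GPRRamide precursors use exclusively monobasic R
  sites while X1PRX2amide precursors are dominated by dibasic KR, which
  keeps those families apart despite 3/4 C-terminal identity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .detector import right_anchored_identity
from .maturation import AMIDE, PYROGLUTAMATE, MaturePeptide

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FamilyMember:
    peptide: MaturePeptide
    dataset: str = ""
    class_label: str = ""
    # fraction of the source precursor's processing sites that are
    # multi-basic; None when unknown
    arch_multibasic_fraction: float | None = None


@dataclass(frozen=True)
class PeptideFamily:
    id: str
    members: tuple[FamilyMember, ...]
    anchor: str
    consensus: str
    wildcard_sets: dict[str, frozenset]
    presence: dict[str, bool] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def breadth(self) -> int:
        return sum(self.presence.values()) if self.presence else 0


@dataclass(frozen=True)
class FamilyOverview:
    families: tuple[PeptideFamily, ...]
    matrix: pd.DataFrame  # families x classes, boolean

    def class_specific(self) -> list[str]:
        return [f.id for f in self.families if f.breadth == 1]


def _bucket_all_pq(members: list[FamilyMember]) -> bool:
    return all(m.peptide.n_state == PYROGLUTAMATE for m in members)


def _bucket_any_pq(members: list[FamilyMember]) -> bool:
    return any(m.peptide.n_state == PYROGLUTAMATE for m in members)


def _arch_values(members: list[FamilyMember]) -> list[float]:
    return [m.arch_multibasic_fraction for m in members
            if m.arch_multibasic_fraction is not None]


def _mergeable(
    a: list[FamilyMember], b: list[FamilyMember],
    merge_identity: float, pq_guard: bool, arch_guard: bool, arch_gap: float,
) -> bool:
    if a[0].peptide.c_state != b[0].peptide.c_state:
        return False
    if pq_guard:
        if _bucket_all_pq(a) and not _bucket_any_pq(b):
            return False
        if _bucket_all_pq(b) and not _bucket_any_pq(a):
            return False
    if arch_guard:
        va, vb = _arch_values(a), _arch_values(b)
        if va and vb and abs(sum(va) / len(va) - sum(vb) / len(vb)) > arch_gap:
            return False
    best = max(
        right_anchored_identity(ma.peptide.core, mb.peptide.core)
        for ma in a for mb in b
    )
    return best >= merge_identity


def group_families(
    members: list[FamilyMember],
    anchor_len: int = 3,
    merge_identity: float = 0.5,
    pq_guard: bool = True,
    arch_guard: bool = True,
    arch_gap: float = 0.5,
) -> list[PeptideFamily]:
    """Partition mature peptides into C-terminally anchored families."""
    if anchor_len < 2:
        raise ValueError("anchor_len must be >= 2")

    # initial buckets: (C-terminal anchor, amide state)
    buckets: dict[tuple[str, str], list[FamilyMember]] = {}
    for m in members:
        key = (m.peptide.core[-anchor_len:], m.peptide.c_state)
        buckets.setdefault(key, []).append(m)
    keys = sorted(buckets)

    # non-amidated variants join their amidated form when cores are identical
    merged_into: dict[tuple[str, str], tuple[str, str]] = {}
    for key in keys:
        anchor, cstate = key
        if cstate == AMIDE:
            continue
        partner = (anchor, AMIDE)
        if partner in buckets:
            cores_a = {m.peptide.core for m in buckets[key]}
            cores_b = {m.peptide.core for m in buckets[partner]}
            if cores_a & cores_b:
                merged_into[key] = partner
    for src, dst in merged_into.items():
        buckets[dst].extend(buckets.pop(src))
    keys = sorted(buckets)

    # single-linkage merge of buckets
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            if find(ka) == find(kb):
                continue
            if _mergeable(buckets[ka], buckets[kb], merge_identity,
                          pq_guard, arch_guard, arch_gap):
                parent[find(ka)] = find(kb)

    groups: dict[tuple[str, str], list[FamilyMember]] = {}
    for k in keys:
        groups.setdefault(find(k), []).extend(buckets[k])

    families = []
    for mem in groups.values():
        mem.sort(key=lambda m: (m.peptide.display, m.dataset))
        medoid = _medoid_display(mem)
        pattern, wsets = consensus_pattern([m.peptide for m in mem])
        families.append(PeptideFamily(
            id=f"FAM_{medoid}",
            members=tuple(mem),
            anchor=mem[0].peptide.core[-anchor_len:]
                   + ("amide" if mem[0].peptide.c_state == AMIDE else ""),
            consensus=pattern,
            wildcard_sets=wsets,
        ))
    families.sort(key=lambda f: f.id)
    return families


def _medoid_display(members: list[FamilyMember]) -> str:
    """Member maximizing summed right-anchored identity; ties lexicographic."""
    cores = [m.peptide.core for m in members]
    best = None
    for m in members:
        s = sum(right_anchored_identity(m.peptide.core, c) for c in cores)
        key = (-s, m.peptide.display)
        if best is None or key < best[0]:
            best = (key, m.peptide.display)
    return best[1]


def consensus_pattern(peptides: list[MaturePeptide]) -> tuple[str, dict[str, frozenset]]:
    """C-terminally aligned consensus with numbered wildcards.

    Members are right-aligned; a column is emitted verbatim when every
    member reaches it and all agree, otherwise as a fresh numbered
    wildcard annotated with the observed residue set.  The amide suffix
    is appended when shared by all members.
    """
    if not peptides:
        raise ValueError("empty family")
    cores = [p.core for p in peptides]
    width = max(len(c) for c in cores)
    parts: list[str] = []
    wsets: dict[str, frozenset] = {}
    n_wild = 0
    for col in range(width):
        observed = set()
        full = True
        for c in cores:
            j = col - (width - len(c))
            if j < 0:
                full = False
            else:
                observed.add(c[j])
        if full and len(observed) == 1:
            parts.append(next(iter(observed)))
        else:
            n_wild += 1
            name = f"X{n_wild}"
            parts.append(name)
            wsets[name] = frozenset(observed)
    pattern = "".join(parts)
    if all(p.c_state == AMIDE for p in peptides):
        pattern += "amide"
    return pattern, wsets


def matches_consensus(peptide: MaturePeptide, family: PeptideFamily) -> bool:
    """Check that a member is consistent with its family consensus."""
    import re
    tokens = re.findall(r"X\d+|[A-Z]", family.consensus.removesuffix("amide"))
    core = peptide.core
    offset = len(tokens) - len(core)
    if offset < 0:
        return False
    for idx, ch in enumerate(core):
        tok = tokens[offset + idx]
        if tok.startswith("X"):
            if ch not in family.wildcard_sets[tok]:
                return False
        elif tok != ch:
            return False
    return True


def presence_matrix(
    families: list[PeptideFamily], dataset_to_class: dict[str, str]
) -> FamilyOverview:
    """Boolean family x class matrix, families sorted by breadth then size."""
    classes = sorted(set(dataset_to_class.values()))
    out_families = []
    rows = {}
    for fam in families:
        presence = {c: False for c in classes}
        for m in fam.members:
            label = m.class_label
            if not label:
                if m.dataset not in dataset_to_class:
                    raise KeyError(
                        f"dataset {m.dataset!r} has no class mapping"
                    )
                label = dataset_to_class[m.dataset]
            if label not in presence:
                presence[label] = True
                classes.append(label)
            presence[label] = True
        fam2 = PeptideFamily(
            id=fam.id, members=fam.members, anchor=fam.anchor,
            consensus=fam.consensus, wildcard_sets=fam.wildcard_sets,
            presence=presence,
        )
        out_families.append(fam2)
        rows[fam.id] = presence
    out_families.sort(key=lambda f: (-f.breadth, -f.size, f.id))
    matrix = pd.DataFrame(
        [rows[f.id] for f in out_families],
        index=[f.id for f in out_families],
    ).fillna(False)
    return FamilyOverview(families=tuple(out_families), matrix=matrix)


def cystine_loop_size(peptide: MaturePeptide | str) -> int | None:
    """Inclusive span between a peptide's two cysteines, if exactly two.

    The cyclic FRamide peptides form a cystine bridge between their two
    cysteines; the ring size (first C through second C, inclusive) is a
    conserved feature of the family.
    """
    core = peptide if isinstance(peptide, str) else peptide.core
    if core.endswith("amide"):
        core = MaturePeptide.from_display(core).core
    positions = [i for i, c in enumerate(core) if c == "C"]
    if len(positions) != 2:
        if len(positions) > 2:
            log.warning("peptide %r has >2 cysteines; loop undefined", core)
        return None
    return positions[1] - positions[0] + 1
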