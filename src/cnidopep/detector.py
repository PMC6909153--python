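"""Screening for multi-copy neuropeptide precursors.

A neuropeptide preprohormone carries several near-identical peptide
cassettes, each followed by a prohormone-convertase processing site: a
mono-, di- or tribasic tract of K/R, optionally preceded by a glycine
that is consumed during C-terminal amidation (GR, GKR, GRR, RR, KR, RRR,
RKR, RKK ...).  The screen flags any protein containing at least
``min_copies`` mutually similar candidate peptides each followed by such
a site.

Similarity between candidate peptides is computed *C-terminally
anchored*: cnidarian peptide families conserve their C-termini (the
receptor-binding end, protected by amidation) while N-termini vary, so
two candidates are right-aligned and identity is counted over the length
of the shorter one.  X never matches anything, including another X.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import SequenceRecord

BASIC = frozenset("KR")


@dataclass(frozen=True)
class SiteGrammar:
    """Which basic tracts count as convertase processing sites.

    Monobasic tracts are only accepted with a glycine donor (GR / GK) by
    default: the observed site inventory lists bare single basics never,
    and treating every lone R as a cleavage point would shred peptides
    such as RPRSamide that carry internal arginines.
    """

    max_tract: int = 3
    require_g_mono_r: bool = True
    require_g_mono_k: bool = True


@dataclass(frozen=True)
class ProcessingSite:
    start: int
    end: int
    basic_tract: str
    g_preceded: bool
    site_string: str

    def __post_init__(self):
        if not 1 <= len(self.basic_tract) <= 3:
            raise ValueError("basic tract length must be 1-3")
        if self.end - self.start != len(self.basic_tract):
            raise ValueError("tract coordinates inconsistent")


@dataclass(frozen=True)
class CandidatePeptide:
    start: int
    end: int
    seq: str
    amidation_flag: bool


@dataclass(frozen=True)
class RepeatCluster:
    members: tuple[CandidatePeptide, ...]
    medoid: CandidatePeptide
    mean_pairwise_identity: float


@dataclass(frozen=True)
class DetectorParams:
    grammar: SiteGrammar = field(default_factory=SiteGrammar)
    min_len: int = 3
    max_len: int = 30
    identity_threshold: float = 0.5
    min_copies: int = 3
    mode: str = "cluster"  # or "site_count": >=min_copies sites suffices


@dataclass(frozen=True)
class DetectorResult:
    protein_id: str
    sites: tuple[ProcessingSite, ...]
    clusters: tuple[RepeatCluster, ...]
    is_hit: bool


def find_processing_sites(
    protein: SequenceRecord | str, grammar: SiteGrammar | None = None
) -> list[ProcessingSite]:
    """Locate all maximal K/R tracts that qualify as processing sites.

    Tracts are resolved greedily left-to-right with maximal munch: a run of
    basic residues is consumed in chunks of up to ``grammar.max_tract``
    (e.g. GKRR yields the single tract KRR with a G donor).
    """
    grammar = grammar or SiteGrammar()
    seq = protein.seq if isinstance(protein, SequenceRecord) else protein
    sites: list[ProcessingSite] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] not in BASIC:
            i += 1
            continue
        j = i
        while j < n and seq[j] in BASIC:
            j += 1
        # chunk the run greedily left-to-right
        s = i
        while s < j:
            e = min(s + grammar.max_tract, j)
            tract = seq[s:e]
            g = s > 0 and seq[s - 1] == "G"
            keep = True
            if len(tract) == 1:
                if tract == "R" and grammar.require_g_mono_r and not g:
                    keep = False
                if tract == "K" and grammar.require_g_mono_k and not g:
                    keep = False
            if keep:
                sites.append(ProcessingSite(
                    start=s, end=e, basic_tract=tract, g_preceded=g,
                    site_string=("G" if g else "") + tract,
                ))
            s = e
        i = j
    return sites


def extract_candidates(
    protein: SequenceRecord | str,
    sites: list[ProcessingSite],
    min_len: int = 3,
    max_len: int = 30,
) -> list[CandidatePeptide]:
    """Slice out the raw segment preceding each processing site.

    Each segment runs from the previous site's tract end (or the protein
    start) up to the site's glycine donor if present, otherwise to the
    tract start.  Segments outside ``[min_len, max_len]`` are dropped.
    """
    seq = protein.seq if isinstance(protein, SequenceRecord) else protein
    out: list[CandidatePeptide] = []
    prev_end = 0
    for site in sites:
        seg_end = site.start - 1 if site.g_preceded else site.start
        if seg_end > prev_end:
            segment = seq[prev_end:seg_end]
            if min_len <= len(segment) <= max_len:
                out.append(CandidatePeptide(
                    start=prev_end, end=seg_end, seq=segment,
                    amidation_flag=site.g_preceded,
                ))
        prev_end = site.end
    return out


def right_anchored_identity(a: str, b: str) -> float:
    """Fraction of matching residues after right-aligning, over the shorter
    sequence.  X is treated as unknown and never matches."""
    m = min(len(a), len(b))
    if m == 0:
        return 0.0
    matches = sum(
        1 for k in range(1, m + 1)
        if a[-k] == b[-k] and a[-k] != "X"
    )
    return matches / m


def cluster_candidates(
    cands: list[CandidatePeptide], identity_threshold: float = 0.5
) -> list[RepeatCluster]:
    """Single-linkage clustering of candidates under right-anchored identity.

    Clusters of size 1 are discarded (a lone peptide is not a repeat).  The
    medoid is the member maximizing summed identity to the others, ties
    resolved by precursor coordinate.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    n = len(cands)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ident = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = right_anchored_identity(cands[i].seq, cands[j].seq)
            ident[i][j] = ident[j][i] = d
            if d >= identity_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters: list[RepeatCluster] = []
    for idxs in groups.values():
        if len(idxs) < 2:
            continue
        idxs.sort(key=lambda i: cands[i].start)
        sums = {i: sum(ident[i][j] for j in idxs if j != i) for i in idxs}
        medoid_idx = max(idxs, key=lambda i: (sums[i], -cands[i].start))
        pairs = [(i, j) for i in idxs for j in idxs if i < j]
        mpi = sum(ident[i][j] for i, j in pairs) / len(pairs)
        clusters.append(RepeatCluster(
            members=tuple(cands[i] for i in idxs),
            medoid=cands[medoid_idx],
            mean_pairwise_identity=mpi,
        ))
    clusters.sort(key=lambda c: c.members[0].start)
    return clusters


def screen_protein(
    protein: SequenceRecord, params: DetectorParams | None = None
) -> DetectorResult:
    """Full screen of one protein: sites -> candidates -> clusters -> verdict."""
    params = params or DetectorParams()
    sites = find_processing_sites(protein, params.grammar)
    cands = extract_candidates(protein, sites, params.min_len, params.max_len)
    clusters = cluster_candidates(cands, params.identity_threshold)
    if params.mode == "site_count":
        is_hit = len(sites) >= params.min_copies
    elif params.mode == "cluster":
        is_hit = any(len(c.members) >= params.min_copies for c in clusters)
    else:
        raise ValueError(f"unknown detector mode {params.mode!r}")
    return DetectorResult(
        protein_id=protein.id, sites=tuple(sites),
        clusters=tuple(clusters), is_hit=is_hit,
    )
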