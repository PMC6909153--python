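"""Preprohormone phylogenetics: alignment, p-distance, parsimony, NJ.

Trees here are unrooted binary topologies over taxon labels.  The
internal representation anchors the tree at the lexicographically
smallest taxon: an unrooted binary tree over n taxa is stored as that
leaf plus a rooted binary subtree (nested tuples) over the remaining
n-1 taxa.  This makes canonicalization, exhaustive enumeration and
Newick round-tripping straightforward and byte-stable: children are
ordered by their smallest descendant label, and the serialized form of
a topology is unique.

Parsimony uses the Fitch small-parsimony count with alignment gaps
scored as a 21st character state (a shared deletion is shared evidence;
a "missing data" mode is available).  For eight or fewer taxa the
maximum-parsimony tree is found by exhaustive enumeration of all
unrooted topologies; beyond that, stepwise addition with NNI
hill-climbing and seeded random restarts is used.  Neighbor joining is
delegated to scikit-bio and operates on the p-distance matrix.
"""
from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP_STATE = 20
N_STATES = 21
FULL_MASK = (1 << 20) - 1  # X / unknown: any amino acid, not a gap

Topo = tuple | str  # nested tuples of taxon labels; a str is a leaf


class PhyloError(ValueError):
    pass


@dataclass(frozen=True)
class Alignment:
    rows: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise PhyloError("an alignment needs at least 2 rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise PhyloError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def taxa(self) -> list[str]:
        return [t for t, _ in self.rows]

    def row(self, taxon: str) -> str:
        for t, seq in self.rows:
            if t == taxon:
                return seq
        raise KeyError(taxon)


@dataclass(frozen=True)
class PhyloTree:
    """Unrooted binary topology, anchored at its smallest taxon."""

    anchor: str
    subtree: Topo
    parsimony_score: int | None = None

    @property
    def taxa(self) -> list[str]:
        return sorted([self.anchor] + list(_leaves(self.subtree)))

    def newick(self) -> str:
        return f"({self.anchor},{_render(canonicalize(self.subtree))});"

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each given as the side not containing
        the anchor."""
        out: set[frozenset] = set()

        def walk(node: Topo):
            if isinstance(node, str):
                return {node}
            below = set()
            for child in node:
                below |= walk(child)
            if 1 < len(below) < len(self.taxa) - 1:
                out.add(frozenset(below))
            return below

        walk(self.subtree)
        return out


def _leaves(node: Topo):
    if isinstance(node, str):
        yield node
    else:
        for child in node:
            yield from _leaves(child)


def _min_leaf(node: Topo) -> str:
    return node if isinstance(node, str) else min(_min_leaf(c) for c in node)


def canonicalize(node: Topo) -> Topo:
    if isinstance(node, str):
        return node
    children = tuple(sorted((canonicalize(c) for c in node), key=_min_leaf))
    return children


def _render(node: Topo) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(_render(c) for c in node) + ")"


def make_tree(structure: Topo, score: int | None = None) -> PhyloTree:
    """Build a canonical :class:`PhyloTree` from any nested-tuple topology.

    The structure is read as an unrooted tree (its outermost node is an
    arbitrary root) and re-anchored at the smallest taxon.
    """
    graph, leaves = _to_graph(structure)
    anchor = min(leaves)
    sub = _from_graph(graph, anchor)
    return PhyloTree(anchor=anchor, subtree=canonicalize(sub), parsimony_score=score)


def _to_graph(structure: Topo):
    graph: dict[int | str, list] = {}
    leaves: list[str] = []
    counter = itertools.count()

    def add_edge(a, b):
        graph.setdefault(a, []).append(b)
        graph.setdefault(b, []).append(a)

    def build(node: Topo):
        if isinstance(node, str):
            leaves.append(node)
            return node
        nid = next(counter)
        for child in node:
            add_edge(nid, build(child))
        return nid

    root = build(structure)
    # suppress degree-2 internal nodes (e.g. the artificial root)
    changed = True
    while changed:
        changed = False
        for node in list(graph):
            if not isinstance(node, str) and len(graph[node]) == 2:
                a, b = graph.pop(node)
                graph[a] = [x for x in graph[a] if x != node] + [b]
                graph[b] = [x for x in graph[b] if x != node] + [a]
                changed = True
    return graph, leaves


def _from_graph(graph, anchor: str) -> Topo:
    def descend(node, parent) -> Topo:
        if isinstance(node, str):
            return node
        children = [n for n in graph[node] if n != parent]
        return tuple(descend(c, node) for c in children)

    (start,) = graph[anchor]
    return descend(start, anchor)


# ---------------------------------------------------------------- newick

_TOKEN = re.compile(r"\(|\)|,|;|[^(),;]+")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths and support values ignored)
    into the canonical anchored form."""
    tokens = [t for t in _TOKEN.findall(text.strip()) if t != ";"]
    pos = 0

    def parse() -> Topo:
        nonlocal pos
        if tokens[pos] == "(":
            pos += 1
            children = [parse()]
            while tokens[pos] == ",":
                pos += 1
                children.append(parse())
            if tokens[pos] != ")":
                raise PhyloError("unbalanced parentheses in newick")
            pos += 1
            if pos < len(tokens) and tokens[pos] not in "(),":
                pos += 1  # internal label / support
            return tuple(children)
        label = tokens[pos]
        pos += 1
        return label.split(":")[0].strip("'\"")

    structure = parse()

    def strip_lengths(node: Topo) -> Topo:
        if isinstance(node, str):
            return node.split(":")[0]
        return tuple(strip_lengths(c) for c in node)

    return make_tree(strip_lengths(structure))


# ----------------------------------------------------- progressive alignment

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    k = min(k, len(a), len(b))
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile_col_score(cols_a, cols_b, sub) -> float:
    total = 0.0
    n = 0
    for x in cols_a:
        for y in cols_b:
            n += 1
            if x != "-" and y != "-":
                total += sub.get((x, y), -4.0)
    return total / n


def _align_profiles(prof_a: list[str], prof_b: list[str], sub,
                    gap_open: float, gap_extend: float) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment with affine gaps (NW), tie-break
    diagonal > up > left so gaps land leftmost."""
    la, lb = len(prof_a[0]), len(prof_b[0])
    cols_a = ["".join(r[i] for r in prof_a) for i in range(la)]
    cols_b = ["".join(r[j] for r in prof_b) for j in range(lb)]
    open_cost = gap_open + gap_extend
    NEG = float("-inf")
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # consumes A (gap in B)
    Y = np.full((la + 1, lb + 1), NEG)
    ptr = {}
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -open_cost - gap_extend * (i - 1)
        ptr[("X", i, 0)] = "M" if i == 1 else "X"
    for j in range(1, lb + 1):
        Y[0][j] = -open_cost - gap_extend * (j - 1)
        ptr[("Y", 0, j)] = "M" if j == 1 else "Y"
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sc = _profile_col_score(cols_a[i - 1], cols_b[j - 1], sub)
            cand = [(M[i - 1][j - 1], "M"), (X[i - 1][j - 1], "X"), (Y[i - 1][j - 1], "Y")]
            v, p = max(cand, key=lambda t: t[0])
            # preference on ties: M > X > Y (cand order is stable via explicit scan)
            for cv, cp in cand:
                if cv == v:
                    p = cp
                    break
            M[i][j] = v + sc
            ptr[("M", i, j)] = p
            xo, xe = M[i - 1][j] - open_cost, X[i - 1][j] - gap_extend
            if xo >= xe:
                X[i][j], ptr[("X", i, j)] = xo, "M"
            else:
                X[i][j], ptr[("X", i, j)] = xe, "X"
            yo, ye = M[i][j - 1] - open_cost, Y[i][j - 1] - gap_extend
            if yo >= ye:
                Y[i][j], ptr[("Y", i, j)] = yo, "M"
            else:
                Y[i][j], ptr[("Y", i, j)] = ye, "Y"
    end = max([(M[la][lb], "M"), (X[la][lb], "X"), (Y[la][lb], "Y")],
              key=lambda t: t[0])
    state = end[1]
    for cv, cp in [(M[la][lb], "M"), (X[la][lb], "X"), (Y[la][lb], "Y")]:
        if cv == end[0]:
            state = cp
            break
    i, j = la, lb
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ops.append("M")
            state = ptr[("M", i, j)]
            i, j = i - 1, j - 1
        elif state == "X":
            ops.append("X")
            state = ptr[("X", i, j)]
            i -= 1
        else:
            ops.append("Y")
            state = ptr[("Y", i, j)]
            j -= 1
    ops.reverse()
    new_a = [[] for _ in prof_a]
    new_b = [[] for _ in prof_b]
    ai = bi = 0
    for op in ops:
        if op == "M":
            for r, row in enumerate(prof_a):
                new_a[r].append(row[ai])
            for r, row in enumerate(prof_b):
                new_b[r].append(row[bi])
            ai += 1
            bi += 1
        elif op == "X":
            for r, row in enumerate(prof_a):
                new_a[r].append(row[ai])
            for r in range(len(prof_b)):
                new_b[r].append("-")
            ai += 1
        else:
            for r in range(len(prof_a)):
                new_a[r].append("-")
            for r, row in enumerate(prof_b):
                new_b[r].append(row[bi])
            bi += 1
    return ["".join(r) for r in new_a], ["".join(r) for r in new_b]


def progressive_align(
    seqs: list[tuple[str, str]],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    pre_aligned: bool = False,
) -> Alignment:
    """Progressive multiple alignment: k-mer distance guide tree (UPGMA)
    followed by profile-profile global alignment.  Deterministic for a
    fixed input order and parameters.
    """
    if len(seqs) < 2:
        raise PhyloError("progressive_align needs at least 2 sequences")
    if pre_aligned:
        return Alignment(rows=tuple(seqs))
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    from .homology import load_matrix

    sub = load_matrix(matrix)
    names = [n for n, _ in seqs]
    raw = [s for _, s in seqs]
    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i][j] = dm[j][i] = _kmer_distance(raw[i], raw[j])
    Z = linkage(squareform(dm, checks=False), method="average")
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [raw[i]]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        idx_a, prof_a = profiles.pop(ia)
        idx_b, prof_b = profiles.pop(ib)
        na, nb = _align_profiles(prof_a, prof_b, sub, gap_open, gap_extend)
        profiles[n + step] = (idx_a + idx_b, na + nb)
    (final_idx, final_prof), = profiles.values()
    order = sorted(range(len(final_idx)), key=lambda k: final_idx[k])
    rows = tuple((names[final_idx[k]], final_prof[k]) for k in order)
    return Alignment(rows=rows)


# ---------------------------------------------------------------- p-distance

def p_distance(alignment: Alignment, deletion_mode: str = "pairwise"):
    """Proportion of differing residues over compared (non-gap) sites.

    Returns ``(taxa, matrix)``.  Under pairwise deletion, each pair skips
    only the columns where either row is gapped; under complete deletion,
    any column containing a gap is discarded for all pairs.
    """
    if deletion_mode not in ("pairwise", "complete"):
        raise PhyloError(f"unknown deletion mode {deletion_mode!r}")
    rows = alignment.rows
    if deletion_mode == "complete":
        keep = [
            k for k in range(alignment.length)
            if all(seq[k] != "-" for _, seq in rows)
        ]
        rows = tuple((t, "".join(seq[k] for k in keep)) for t, seq in rows)
    n = len(rows)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i][1], rows[j][1]
            comp = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not comp:
                raise PhyloError(
                    f"no comparable sites between {rows[i][0]!r} and {rows[j][0]!r}"
                )
            diff = sum(1 for x, y in comp if x != y)
            mat[i][j] = mat[j][i] = diff / len(comp)
    return [t for t, _ in rows], mat


# ------------------------------------------------------------------- Fitch

def _encode_masks(alignment: Alignment, gap_mode: str = "state") -> dict[str, np.ndarray]:
    """Per-taxon uint32 state masks per column.  gap_mode 'state' scores a
    gap as a 21st character; 'missing' treats it like X (any residue)."""
    index = {aa: i for i, aa in enumerate(AA20)}
    masks = {}
    for taxon, seq in alignment.rows:
        arr = np.empty(len(seq), dtype=np.uint32)
        for k, ch in enumerate(seq):
            if ch in index:
                arr[k] = 1 << index[ch]
            elif ch == "-":
                arr[k] = (1 << GAP_STATE) if gap_mode == "state" else FULL_MASK
            else:  # X or anything unknown
                arr[k] = FULL_MASK
        masks[taxon] = arr
    return masks


def _fitch_node(node: Topo, masks, cache) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(node, str):
        return masks[node], np.zeros(len(masks[node]), dtype=np.int64)
    if node in cache:
        return cache[node]
    (m, c), rest = _fitch_node(node[0], masks, cache), node[1:]
    for child in rest:
        m2, c2 = _fitch_node(child, masks, cache)
        inter = m & m2
        union = m | m2
        changed = inter == 0
        m = np.where(changed, union, inter)
        c = c + c2 + changed
    cache[node] = (m, c)
    return cache[node]


def parsimony_score(tree: PhyloTree, alignment: Alignment,
                    gap_mode: str = "state",
                    masks: dict[str, np.ndarray] | None = None,
                    cache: dict | None = None) -> int:
    """Fitch small-parsimony count summed over columns."""
    if set(tree.taxa) != set(alignment.taxa):
        raise PhyloError("tree taxa do not match alignment taxa")
    if masks is None:
        masks = _encode_masks(alignment, gap_mode)
    if cache is None:
        cache = {}
    m, c = _fitch_node(tree.subtree, masks, cache)
    m2, c2 = masks[tree.anchor], np.zeros(len(m), dtype=np.int64)
    inter = m & m2
    changed = inter == 0
    total = c + c2 + changed
    return int(total.sum())


# ------------------------------------------------------------ tree search

def enumerate_subtrees(taxa: list[str]):
    """All rooted binary subtree shapes over ``taxa`` (each corresponds to
    one unrooted topology once the anchor leaf is attached)."""
    if len(taxa) == 1:
        yield taxa[0]
        return
    if len(taxa) == 2:
        yield (taxa[0], taxa[1])
        return
    head, rest = taxa[-1], taxa[:-1]
    for t in enumerate_subtrees(rest):
        yield from _insert_everywhere(t, head)


def _insert_everywhere(node: Topo, leaf: str):
    yield (node, leaf)
    if not isinstance(node, str):
        a, b = node
        for a2 in _insert_everywhere(a, leaf):
            yield (a2, b)
        for b2 in _insert_everywhere(b, leaf):
            yield (a, b2)


def _nni_neighbors(node: Topo):
    """All NNI rearrangements of a rooted binary subtree (covers every
    internal edge of the corresponding unrooted tree)."""
    if isinstance(node, str):
        return
    a, b = node
    if not isinstance(a, str):
        x, y = a
        yield ((x, b), y)
        yield ((y, b), x)
    if not isinstance(b, str):
        x, y = b
        yield ((x, a), y)
        yield ((y, a), x)
    for a2 in _nni_neighbors(a):
        yield (a2, b)
    for b2 in _nni_neighbors(b):
        yield (a, b2)


def _prunings(node: Topo):
    """Every (pruned proper subtree, remaining tree) pair of a rooted
    binary subtree."""
    if isinstance(node, str):
        return
    a, b = node
    yield (a, b)
    yield (b, a)
    for pa, rest in _prunings(a):
        yield (pa, (rest, b))
    for pb, rest in _prunings(b):
        yield (pb, (a, rest))


def _spr_neighbors(node: Topo):
    """Subtree prune-and-regraft neighborhood (strictly contains NNI)."""
    seen = set()
    for pruned, rest in _prunings(node):
        for cand in _insert_everywhere(rest, pruned):
            key = canonicalize(cand)
            if key not in seen:
                seen.add(key)
                yield cand


def best_tree(
    alignment: Alignment,
    method: str = "parsimony",
    gap_mode: str = "state",
    seed: int = 0,
    max_exhaustive: int = 8,
    n_restarts: int = 4,
    n_ratchet: int = 6,
) -> PhyloTree:
    """Find the best tree for an alignment.

    parsimony: exhaustive enumeration of unrooted topologies up to
    ``max_exhaustive`` taxa, otherwise stepwise addition plus NNI
    hill-climbing with seeded random restarts.  Ties are broken by the
    lexicographically smallest canonical Newick string.  nj: neighbor
    joining on the p-distance matrix.
    """
    taxa = sorted(alignment.taxa)
    if len(taxa) < 3:
        raise PhyloError("need at least 3 taxa")
    if method == "nj":
        return neighbor_joining(alignment)
    if method != "parsimony":
        raise PhyloError(f"unknown method {method!r}")

    masks = _encode_masks(alignment, gap_mode)
    cache: dict = {}
    anchor, rest = taxa[0], taxa[1:]

    def score_sub(sub: Topo) -> int:
        # direct Fitch kernel: also valid for partial trees during
        # stepwise addition
        m, c = _fitch_node(sub, masks, cache)
        changed = (m & masks[anchor]) == 0
        return int((c + changed).sum())

    if len(taxa) <= max_exhaustive:
        best_score, best_sub = None, None
        for sub in enumerate_subtrees(rest):
            s = score_sub(sub)
            if best_score is None or s < best_score:
                best_score, best_sub = s, [sub]
            elif s == best_score:
                best_sub.append(sub)
        chosen = min(best_sub, key=lambda t: _render(canonicalize(t)))
        return PhyloTree(anchor=anchor, subtree=canonicalize(chosen),
                         parsimony_score=best_score)

    rng = np.random.default_rng(seed)
    n_cols = alignment.length

    def weighted_score(weights):
        def score(sub: Topo) -> int:
            m, c = _fitch_node(sub, masks, cache)
            changed = (m & masks[anchor]) == 0
            return int(((c + changed) * weights).sum())
        return score

    overall: tuple[int, str, Topo] | None = None
    for restart in range(n_restarts):
        order = list(rest)
        if restart > 0:
            rng.shuffle(order)
        sub: Topo = (order[0], order[1])
        for leaf in order[2:]:
            cands = list(_insert_everywhere(sub, leaf))
            scored = [(score_sub(c), _render(canonicalize(c)), c) for c in cands]
            scored.sort(key=lambda t: (t[0], t[1]))
            sub = scored[0][2]
        cur = _spr_descend(sub, score_sub)
        # parsimony ratchet: upweight a random quarter of the columns,
        # re-climb under the perturbed score, then re-climb under the
        # original one — escapes basins plain descent cannot leave
        for _ in range(n_ratchet):
            w = np.ones(n_cols, dtype=np.int64)
            w[rng.random(n_cols) < 0.25] = 3
            perturbed = _spr_descend(cur[2], weighted_score(w))
            candidate = _spr_descend(perturbed[2], score_sub)
            if candidate[:2] < cur[:2]:
                cur = candidate
        if overall is None or cur[:2] < overall[:2]:
            overall = cur
    return PhyloTree(anchor=anchor, subtree=canonicalize(overall[2]),
                     parsimony_score=overall[0])


def _spr_descend(sub: Topo, score_sub, max_sideways: int = 30):
    """SPR descent with bounded sideways moves.

    Parsimony landscapes contain large plateaus of equal-scoring trees;
    pure descent stalls on them, so equal-score moves to unvisited trees
    are allowed up to ``max_sideways`` steps.  Returns the best
    (score, canonical newick, subtree) visited.
    """
    cur = (score_sub(sub), _render(canonicalize(sub)), sub)
    best = cur
    visited = {cur[1]}
    sideways_left = max_sideways
    while True:
        downhill = None
        sideways = None
        for nb in _spr_neighbors(cur[2]):
            cand = (score_sub(nb), _render(canonicalize(nb)), nb)
            if cand[:2] < cur[:2] and (downhill is None or cand[:2] < downhill[:2]):
                downhill = cand
            elif cand[0] == cur[0] and cand[1] not in visited and \
                    (sideways is None or cand[1] < sideways[1]):
                sideways = cand
        if downhill is not None:
            cur = downhill
        elif sideways is not None and sideways_left > 0:
            cur = sideways
            sideways_left -= 1
        else:
            break
        visited.add(cur[1])
        if cur[:2] < best[:2]:
            best = cur
    return best


def neighbor_joining(alignment: Alignment, deletion_mode: str = "pairwise") -> PhyloTree:
    """Neighbor joining on the p-distance matrix (scikit-bio)."""
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    taxa, mat = p_distance(alignment, deletion_mode)
    return nj_from_matrix(taxa, mat)


def nj_from_matrix(taxa: list[str], mat: np.ndarray) -> PhyloTree:
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    if len(taxa) < 3:
        raise PhyloError("need at least 3 taxa")
    sk_tree = sk_nj(SkDM(mat, ids=taxa))
    return parse_newick(str(sk_tree))


def reroot_newick(tree: PhyloTree, outgroup: str) -> str:
    """Newick string with the tree rooted on the outgroup's pendant edge."""
    if outgroup not in tree.taxa:
        raise PhyloError(f"outgroup {outgroup!r} not in tree")
    graph, _ = _to_graph((tree.anchor, tree.subtree))
    sub = _from_graph(graph, outgroup)
    return f"({_render(canonicalize(sub))},{outgroup});"
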