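"""From candidate cassettes to predicted mature neuropeptides.

Processing chemistry applied:

* Cleavage occurs C-terminally of each basic tract; the tract residues
  are removed.  A glycine immediately preceding the tract is the amide
  donor: it is removed and the peptide becomes C-terminally amidated.
* The N-terminus is shortened by an unspecific aminopeptidase that
  removes the preferred residues E, D, S, T, N, G, A, L, V, Y, F one at
  a time.  Trimming stops at a glutamine (which cyclizes to N-terminal
  pyroglutamate, written pQ), at a proline in position 1 or 2 (the X-P
  imide bond resists hydrolysis), or at any residue outside the
  preferred set.
* K and R are never aminopeptidase substrates; leading basics are only
  removed when they are convertase remnants, i.e. contiguous with an
  upstream basic tract too long for a single site.

Rule order matters and is forced by the observed peptides: LPRSamide
survives only because the position-2 proline check precedes the
"L is trimmable" step.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace

from .curation import PreprohormoneAnnotation
from .detector import BASIC, CandidatePeptide, ProcessingSite

log = logging.getLogger(__name__)

TRIMMABLE_DEFAULT = frozenset("EDSTNGALVYF")

FREE = "free"
PYROGLUTAMATE = "pyroglutamate"
PROLINE_PROTECTED = "proline_protected"
AMIDE = "amide"
FREE_ACID = "free_acid"


@dataclass(frozen=True)
class TrimPolicy:
    trimmable: frozenset = TRIMMABLE_DEFAULT
    stop_on_Q: bool = True
    stop_on_P_pos1: bool = True
    stop_on_P_pos2: bool = True
    min_len: int = 3
    strip_convertase_remnants: bool = True

    def __post_init__(self):
        clash = self.trimmable & frozenset("QPKR")
        if clash:
            raise ValueError(f"trimmable set may not contain {sorted(clash)}")


@dataclass(frozen=True)
class MaturePeptide:
    core: str
    n_state: str
    c_state: str
    precursor_id: str = ""
    start: int = -1
    end: int = -1

    def __post_init__(self):
        if self.n_state == PYROGLUTAMATE and not self.core.startswith("Q"):
            raise ValueError("pyroglutamate peptide must start with Q")
        if self.n_state == PROLINE_PROTECTED and "P" not in self.core[:2]:
            raise ValueError("proline-protected peptide needs P at position 1 or 2")

    @property
    def display(self) -> str:
        """Canonical string, e.g. ``pQWLRGRFamide`` or ``pQPPGVW``."""
        body = "p" + self.core if self.n_state == PYROGLUTAMATE else self.core
        return body + ("amide" if self.c_state == AMIDE else "")

    @classmethod
    def from_display(cls, display: str, precursor_id: str = "") -> "MaturePeptide":
        """Parse a canonical display string back into a peptide."""
        c_state = FREE_ACID
        body = display
        if body.endswith("amide"):
            c_state = AMIDE
            body = body[: -len("amide")]
        if body.startswith("pQ"):
            return cls(core=body[1:], n_state=PYROGLUTAMATE, c_state=c_state,
                       precursor_id=precursor_id)
        if body[:1] == "P" or body[1:2] == "P":
            n_state = PROLINE_PROTECTED
        else:
            n_state = FREE
        return cls(core=body, n_state=n_state, c_state=c_state,
                   precursor_id=precursor_id)


@dataclass(frozen=True)
class CleavageProduct:
    seq: str
    start: int
    end: int
    amide: bool


def cleave(
    precursor_seq: str,
    sites: list[ProcessingSite],
    policy: TrimPolicy | None = None,
) -> list[CleavageProduct]:
    """Cut a precursor at its processing sites.

    Cleavage is C-terminal of each basic tract; tract residues and the
    glycine amide donor are removed.  Basic residues left at a segment's
    N-terminus (overflow from a >3-residue basic run) are attributed to
    the upstream convertase site and stripped.
    """
    policy = policy or TrimPolicy()
    out: list[CleavageProduct] = []
    prev_end = 0
    for site in sites:
        seg_end = site.start - 1 if site.g_preceded else site.start
        start = prev_end
        if policy.strip_convertase_remnants and start > 0:
            while start < seg_end and precursor_seq[start] in BASIC \
                    and precursor_seq[start - 1] in BASIC:
                start += 1
        if seg_end > start:
            out.append(CleavageProduct(
                seq=precursor_seq[start:seg_end], start=start, end=seg_end,
                amide=site.g_preceded,
            ))
        prev_end = site.end
    return out


def trim_n_terminus(
    segment: str,
    amide: bool,
    policy: TrimPolicy | None = None,
    precursor_id: str = "",
    start: int = -1,
) -> MaturePeptide | None:
    """Apply aminopeptidase trimming to one cleaved segment.

    Returns the mature peptide, or None when fewer than ``policy.min_len``
    residues survive (a logged rejection, not an error).
    """
    policy = policy or TrimPolicy()
    if not segment:
        return None
    i = 0
    n = len(segment)
    n_state = FREE
    while i < n:
        c = segment[i]
        if policy.stop_on_Q and c == "Q":
            n_state = PYROGLUTAMATE
            break
        if policy.stop_on_P_pos1 and c == "P":
            n_state = PROLINE_PROTECTED
            break
        if policy.stop_on_P_pos2 and i + 1 < n and segment[i + 1] == "P":
            n_state = PROLINE_PROTECTED
            break
        if c in policy.trimmable:
            i += 1
            continue
        n_state = FREE
        break
    core = segment[i:]
    if len(core) < policy.min_len:
        log.debug("segment %r trimmed below min_len; rejected", segment)
        return None
    return MaturePeptide(
        core=core, n_state=n_state,
        c_state=AMIDE if amide else FREE_ACID,
        precursor_id=precursor_id,
        start=start + i if start >= 0 else -1,
        end=start + len(segment) if start >= 0 else -1,
    )


def mature_all(
    annotation: PreprohormoneAnnotation,
    policy: TrimPolicy | None = None,
    min_copies: int = 3,
) -> PreprohormoneAnnotation:
    """Cleave and trim every cassette in the annotation's hit clusters.

    Clusters below ``min_copies`` members are spacer-level noise and are
    skipped.  Returns a copy of the annotation with ``mature_peptides``
    filled and ``copy_counts`` holding the multiset of display strings.
    """
    policy = policy or TrimPolicy()
    peptides: list[MaturePeptide] = []
    for cluster in annotation.detector.clusters:
        if len(cluster.members) < min_copies:
            continue
        for cand in cluster.members:
            seq, start = cand.seq, cand.start
            # A candidate starting after position 0 begins immediately after
            # an upstream basic tract, so leading K/R are tract overflow
            # (convertase remnants), not part of the peptide.
            if policy.strip_convertase_remnants and start > 0:
                while seq and seq[0] in BASIC:
                    seq = seq[1:]
                    start += 1
            mp = trim_n_terminus(
                seq, cand.amidation_flag, policy,
                precursor_id=annotation.protein_id, start=start,
            )
            if mp is not None:
                peptides.append(mp)
    counts = Counter(p.display for p in peptides)
    return replace(annotation, mature_peptides=tuple(peptides),
                   copy_counts=dict(counts))
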