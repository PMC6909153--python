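"""Reproducible curation of detector hits into precursor annotations.

The manual criteria — a signal peptide, at least three potential
neuropeptides, sensible precursor architecture — are codified as a pure
accept/review/reject classification.  Signal peptides are called either
by a documented three-criterion heuristic (hydrophobic h-region,
non-negative n-region charge, small residues at the -3/-1 cleavage
positions) or injected verbatim from an external predictor via a TSV
hook, so published SignalP calls can be reproduced bit-exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .detector import DetectorResult
from .seqio import SequenceRecord

log = logging.getLogger(__name__)

SMALL_CLEAVAGE_RESIDUES = frozenset("AGSCTV")
CANONICAL_SMALL = frozenset("AGS")
POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")


@dataclass(frozen=True)
class SignalPeptideCall:
    present: bool
    cleavage_pos: int | None  # 0-based position after the signal
    score: float
    method: str = "heuristic"

    def __post_init__(self):
        if self.present and (self.cleavage_pos is None or self.cleavage_pos > 45):
            raise ValueError("present signal requires cleavage_pos <= 45")


@dataclass(frozen=True)
class PreprohormoneAnnotation:
    protein_id: str
    signal: SignalPeptideCall
    detector: DetectorResult
    status: str  # accepted | review | rejected
    mature_peptides: tuple = ()
    copy_counts: dict = field(default_factory=dict)


def _net_charge(seq: str) -> int:
    return sum(1 for c in seq if c in POSITIVE) - sum(1 for c in seq if c in NEGATIVE)


def predict_signal_peptide(
    protein: SequenceRecord | str,
    max_start: int = 35,
    min_window: int = 7,
    max_window: int = 20,
    kd_threshold: float = 1.6,
    max_cleavage: int = 45,
) -> SignalPeptideCall:
    """Heuristic signal-peptide call.

    Present iff, within the first ``max_start`` residues, there is a
    hydrophobic window of >= ``min_window`` residues with mean
    Kyte-Doolittle hydropathy >= ``kd_threshold``, preceded by an n-region
    of net charge >= 0, and followed within 8 residues by a cleavage
    position whose -3 and -1 residues are small (A,G,S,C,T,V).  The score
    is the mean of three normalized sub-criterion margins and is monotone
    in each of them.
    """
    seq = protein.seq if isinstance(protein, SequenceRecord) else protein
    if len(seq) < 20:
        log.warning("protein shorter than 20 aa; no signal peptide called")
        return SignalPeptideCall(present=False, cleavage_pos=None, score=0.0)

    best: tuple[float, int] | None = None  # (score, cleavage_pos)
    for start in range(0, min(max_start, len(seq)) + 1):
        for wlen in range(min_window, max_window + 1):
            end = start + wlen
            if end > len(seq):
                break
            window = seq[start:end]
            mean_kd = sum(KYTE_DOOLITTLE.get(c, 0.0) for c in window) / wlen
            if mean_kd < kd_threshold:
                continue
            charge = _net_charge(seq[:start])
            if charge < 0:
                continue
            for cpos in range(end + 1, min(end + 9, len(seq), max_cleavage + 1)):
                if cpos < 3:
                    continue
                if seq[cpos - 3] in SMALL_CLEAVAGE_RESIDUES and seq[cpos - 1] in SMALL_CLEAVAGE_RESIDUES:
                    h = min(max((mean_kd - kd_threshold) / 2.0, 0.0), 1.0)
                    q = min(charge, 4) / 4.0
                    s = 1.0 if (seq[cpos - 3] in CANONICAL_SMALL and seq[cpos - 1] in CANONICAL_SMALL) else 0.5
                    score = (h + q + s) / 3.0
                    if best is None or (score, -cpos) > (best[0], -best[1]):
                        best = (score, cpos)
    if best is None:
        return SignalPeptideCall(present=False, cleavage_pos=None, score=0.0)
    return SignalPeptideCall(present=True, cleavage_pos=best[1], score=round(best[0], 4))


def classify(
    detector_result: DetectorResult, signal_call: SignalPeptideCall
) -> PreprohormoneAnnotation:
    """Combine the repeat screen and the signal call into a verdict.

    accepted: repeat hit AND signal present.
    review:   repeat hit without a signal — plausibly a 5'-truncated
              transcript whose signal peptide is missing from the assembly.
    rejected: no repeat hit.
    """
    if detector_result.is_hit and signal_call.present:
        status = "accepted"
    elif detector_result.is_hit:
        status = "review"
    else:
        status = "rejected"
    return PreprohormoneAnnotation(
        protein_id=detector_result.protein_id,
        signal=signal_call,
        detector=detector_result,
        status=status,
    )


def read_signal_calls(path: str | Path) -> dict[str, SignalPeptideCall]:
    """Load externally produced signal-peptide calls from TSV.

    Columns: protein_id, present (0/1), cleavage_pos, score.  Calls are
    passed through verbatim with method="external".
    """
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "present", "cleavage_pos", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"signal-call file missing columns: {sorted(missing)}")
    calls: dict[str, SignalPeptideCall] = {}
    for row in df.itertuples(index=False):
        present = bool(int(row.present))
        cpos = int(row.cleavage_pos) if present and pd.notna(row.cleavage_pos) else None
        calls[str(row.protein_id)] = SignalPeptideCall(
            present=present, cleavage_pos=cpos,
            score=float(row.score), method="external",
        )
    return calls


def write_signal_calls(calls: dict[str, SignalPeptideCall], path: str | Path) -> None:
    rows = [
        {"protein_id": pid, "present": int(c.present),
         "cleavage_pos": c.cleavage_pos if c.cleavage_pos is not None else -1,
         "score": c.score}
        for pid, c in calls.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
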