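"""Published mature-peptide strings and copy counts used as regression anchors.

``REFERENCE_PEPTIDES`` lists the mature neuropeptide display strings
reported across the four surveyed cnidarian classes/subclasses, with the
family each belongs to and the classes it was observed in.  They anchor
two regression suites: every string must be a fixed point of the
trimming chemistry (the printed pQ/proline/amide states are exactly what
the rules produce), and the default family-grouping parameters must keep
the published families coherent.

``PRINTED_COPY_COUNTS`` holds per-precursor copy numbers stated for the
staurozoan RPRSamide family and the octocoral GPRRamide family; the
benchmark runner compares a user's locally fetched assemblies against
them.
"""
from __future__ import annotations

SCYPHOZOA = "Scyphozoa"
STAUROZOA = "Staurozoa"
CUBOZOA = "Cubozoa"
OCTOCORALLIA = "Octocorallia"

ALL_CLASSES = (CUBOZOA, SCYPHOZOA, STAUROZOA, OCTOCORALLIA)

# display string, family key, classes observed in
REFERENCE_PEPTIDES: list[tuple[str, str, tuple[str, ...]]] = [
    # X1PRX2amide family (X2 in {S, A, G}) — present in every class
    ("RPRSamide", "XPRXamide", (STAUROZOA,)),
    ("LPRSamide", "XPRXamide", (SCYPHOZOA,)),
    ("RPRAamide", "XPRXamide", (CUBOZOA,)),
    ("GPRGamide", "XPRXamide", (OCTOCORALLIA,)),
    ("KPRSamide", "XPRXamide", (STAUROZOA,)),
    # GRFamide family — present in every class
    ("pQGRFamide", "GRFamide", (OCTOCORALLIA,)),
    ("pQWLRGRFamide", "GRFamide", (CUBOZOA, SCYPHOZOA)),
    ("pQFLRGRFamide", "GRFamide", (STAUROZOA,)),
    # pQPPGVWamide family — medusozoan, absent in Octocorallia
    ("pQPPGVWamide", "PPGxWamide", (CUBOZOA, SCYPHOZOA, STAUROZOA)),
    ("pQPPGTWamide", "PPGxWamide", (SCYPHOZOA,)),
    # cyclic cystine-loop FRamides — Scyphozoa and Cubozoa only
    ("CKGQMCWFRamide", "cyclic-FRamide", (CUBOZOA,)),
    # scyphozoan-specific RYamides
    ("pQHLRYamide", "RYamide", (SCYPHOZOA,)),
    ("pQHVRYamide", "RYamide", (SCYPHOZOA,)),
    ("PHVRYamide", "RYamide", (SCYPHOZOA,)),
    ("PHLRYamide", "RYamide", (SCYPHOZOA,)),
    # scyphozoan-specific WSARFamide group
    ("pQPLWSARFamide", "WSARFamide", (SCYPHOZOA,)),
    ("pQLRPamide", "LRPamide", (SCYPHOZOA,)),
    # octocoral-specific families
    ("pQLRGamide", "LRGamide", (OCTOCORALLIA,)),
    ("PPFHamide", "PFHamide", (OCTOCORALLIA,)),
    ("pQPFHamide", "PFHamide", (OCTOCORALLIA,)),
    ("RPFLamide", "PFHamide", (OCTOCORALLIA,)),
    ("GPRRamide", "GPRRamide", (OCTOCORALLIA,)),
]

# Scyphozoan member of the cyclic family, used in the cystine-loop worked
# example alongside the cubozoan CKGQMCWFRamide.
CYCLIC_SCYPHOZOAN_PEPTIDE = "CTSPMCWFRPamide"

# Precursor architecture hint: fraction of multi-basic processing sites.
# GPRRamide precursors carry exclusively monobasic (R) sites, which is the
# published argument for keeping them outside the X1PRX2amide family.
ARCHITECTURE_HINTS: dict[str, float] = {
    "GPRRamide": 0.0,
    "RPRSamide": 1.0, "LPRSamide": 1.0, "RPRAamide": 1.0,
    "GPRGamide": 1.0, "KPRSamide": 1.0,
}

# species -> (class, {display: printed copy number})
PRINTED_COPY_COUNTS: dict[str, tuple[str, dict[str, int]]] = {
    "Calvadosia cruxmelitensis": (STAUROZOA, {"RPRSamide": 11}),
    "Haliclystus auricula": (STAUROZOA, {"RPRSamide": 15}),
    "Haliclystus sanjuanensis": (STAUROZOA, {"RPRSamide": 16}),
    "Craterolophus convolvulus": (STAUROZOA, {"RPRSamide": 8}),
    "Lucernaria quadricornis": (STAUROZOA, {"RPRSamide": 3, "KPRSamide": 6}),
    "Renilla reniformis": (OCTOCORALLIA, {"GPRRamide": 2}),
    "Eleutherobia rubra": (OCTOCORALLIA, {"GPRRamide": 8}),
    "Xenia sp.": (OCTOCORALLIA, {"GPRRamide": 15}),
    "Briareum asbestinum": (OCTOCORALLIA, {"GPRRamide": 22}),
    "Clavularia sp.": (OCTOCORALLIA, {"GPRRamide": 5}),
    "Heliopora coerulea": (OCTOCORALLIA, {"GPRRamide": 4}),
}
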