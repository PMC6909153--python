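"""Peptide family grouping, consensus motifs and the presence matrix."""
import numpy as np
import pytest

from cnidopep import families as fam
from cnidopep.families import FamilyMember, consensus_pattern, cystine_loop_size
from cnidopep.maturation import MaturePeptide
from cnidopep.reference import (ARCHITECTURE_HINTS, CYCLIC_SCYPHOZOAN_PEPTIDE,
                                REFERENCE_PEPTIDES)

FIVE_XPRX = ["RPRSamide", "LPRSamide", "RPRAamide", "GPRGamide", "KPRSamide"]


def _members(displays, arch=None, dataset="ds", class_label="C"):
    return [FamilyMember(MaturePeptide.from_display(d), dataset=dataset,
                         class_label=class_label,
                         arch_multibasic_fraction=arch)
            for d in displays]


def _fixture_members():
    out = []
    for d, key, classes in REFERENCE_PEPTIDES:
        for c in classes:
            out.append(FamilyMember(
                MaturePeptide.from_display(d), dataset=c, class_label=c,
                arch_multibasic_fraction=ARCHITECTURE_HINTS.get(d)))
    return out


class TestGrouping:
    def test_xprx_five_form_one_family(self):
        fams = fam.group_families(_members(FIVE_XPRX, arch=1.0))
        assert len(fams) == 1 and fams[0].size == 5

    def test_grf_trio_share_c_terminus(self):
        fams = fam.group_families(
            _members(["pQGRFamide", "pQWLRGRFamide", "pQFLRGRFamide"]))
        assert len(fams) == 1

    def test_singleton_family_is_itself(self):
        (f,) = fam.group_families(_members(["pQGRFamide"]))
        assert f.size == 1 and f.consensus == "QGRFamide"

    def test_published_family_structure_on_fixture_list(self):
        fams = fam.group_families(_fixture_members())
        by_display = {}
        for f in fams:
            for m in f.members:
                by_display[m.peptide.display] = f.id
        # the five XPRXamide peptides group together
        assert len({by_display[d] for d in FIVE_XPRX}) == 1
        # GRFamide trio together
        assert len({by_display[d] for d in
                    ["pQGRFamide", "pQWLRGRFamide", "pQFLRGRFamide"]}) == 1
        # PPGxW pair together
        assert by_display["pQPPGVWamide"] == by_display["pQPPGTWamide"]
        # architecture guard keeps GPRRamide out of the XPRXamide family
        assert by_display["GPRRamide"] != by_display["RPRSamide"]
        # pyroglutamate guard keeps pQLRGamide out of the XPRXamide family
        assert by_display["pQLRGamide"] != by_display["RPRSamide"]
        # the cyclic cystine peptide stands alone
        assert by_display["CKGQMCWFRamide"] != by_display["pQGRFamide"]
        # PFHamide group coheres, including the 50%-identical RPFLamide
        assert len({by_display[d] for d in
                    ["PPFHamide", "pQPFHamide", "RPFLamide"]}) == 1

    def test_partition_property(self):
        members = _fixture_members()
        fams = fam.group_families(members)
        assert sum(f.size for f in fams) == len(members)

    def test_permutation_invariance(self, rng):
        members = _fixture_members()
        ref = {f.id: f.size for f in fam.group_families(members)}
        perm = [members[i] for i in rng.permutation(len(members))]
        got = {f.id: f.size for f in fam.group_families(perm)}
        assert ref == got

    def test_amide_and_free_acid_variants_grouped_when_core_identical(self):
        fams = fam.group_families(_members(["pQPPGVWamide", "pQPPGVW"]))
        assert len(fams) == 1


class TestConsensus:
    def test_two_member_wildcard(self):
        pattern, wsets = consensus_pattern(
            [MaturePeptide.from_display(d) for d in ["RPRSamide", "LPRSamide"]])
        assert pattern == "X1PRSamide"
        assert wsets["X1"] == frozenset("RL")

    def test_xprx_wildcard_sets(self):
        pattern, wsets = consensus_pattern(
            [MaturePeptide.from_display(d) for d in FIVE_XPRX])
        assert pattern == "X1PRX2amide"
        assert wsets["X2"] == frozenset("SAG")

    def test_identical_members_literal_pattern(self):
        pattern, wsets = consensus_pattern(
            [MaturePeptide.from_display("RPRSamide")] * 3)
        assert pattern == "RPRSamide" and wsets == {}

    def test_members_match_their_consensus(self):
        for f in fam.group_families(_fixture_members()):
            for m in f.members:
                assert fam.matches_consensus(m.peptide, f)


class TestPresenceMatrix:
    def test_breadth_and_class_specific_flags(self):
        members = _fixture_members()
        fams = fam.group_families(members)
        overview = fam.presence_matrix(
            fams, {c: c for f in fams for m in f.members for c in [m.dataset]})
        widest = overview.families[0]
        assert widest.breadth == 4  # the XPRXamide-bearing family
        specific = overview.class_specific()
        assert any("CKGQMCWFR" in fid for fid in specific)

    def test_absent_class_stays_false(self):
        members = _members(["pQPPGVWamide"], dataset="scy", class_label="") + \
                  _members(["pQPPGTWamide"], dataset="sta", class_label="")
        fams = fam.group_families(members)
        overview = fam.presence_matrix(
            fams, {"scy": "Scyphozoa", "sta": "Staurozoa", "oct": "Octocorallia"})
        (f,) = overview.families
        assert f.presence["Octocorallia"] is False

    def test_unmapped_dataset_errors(self):
        members = _members(["RPRSamide"], dataset="mystery", class_label="")
        fams = fam.group_families(members)
        with pytest.raises(KeyError):
            fam.presence_matrix(fams, {"known": "Scyphozoa"})


class TestCystineLoop:
    @pytest.mark.parametrize("display,size", [
        ("CKGQMCWFRamide", 6),
        (CYCLIC_SCYPHOZOAN_PEPTIDE, 6),
        ("ACA", None),
        ("AAA", None),
        ("CACACA", None),  # more than two cysteines
    ])
    def test_loop_sizes(self, display, size):
        assert cystine_loop_size(display) == size
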