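"""Generator determinism, round trips and conservation of cassette counts."""
from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from cnidopep import curation, detector, maturation, seqio, simdata as sd
from cnidopep.reference import CUBOZOA, OCTOCORALLIA, SCYPHOZOA, STAUROZOA


class TestGeneratePrecursor:
    def test_deterministic_under_seed(self):
        spec = sd.default_precursor_specs()[0]
        r1, t1 = sd.generate_precursor(spec, seed=9)
        r2, t2 = sd.generate_precursor(spec, seed=9)
        assert r1.seq == r2.seq and t1.mature_counts == t2.mature_counts

    def test_clean_eleven_copy_rprs(self):
        spec = sd.PrecursorSpec(core="RPRS", n_copies=11,
                                site_weights={"GKR": 1.0},
                                spacer_pool=tuple(sorted("EDSTNGALVYF")))
        rec, truth = sd.generate_precursor(spec, seed=0)
        assert truth.mature_counts == Counter({"RPRSamide": 11})

    def test_zero_copies_is_detector_negative(self):
        spec = sd.PrecursorSpec(core="RPRS", n_copies=0)
        rec, truth = sd.generate_precursor(spec, seed=0)
        assert not truth.is_precursor
        assert not detector.screen_protein(rec).is_hit

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            sd.PrecursorSpec(core="", n_copies=3)

    def test_cassette_spans_slice_cores(self):
        spec = sd.PrecursorSpec(core="QPPGVW", n_copies=5)
        rec, truth = sd.generate_precursor(spec, seed=3)
        assert len(truth.cassette_spans) == 5
        for start, end in truth.cassette_spans:
            assert rec.seq[start:end] == "QPPGVW"


class TestBackTranslation:
    def test_roundtrip_translation(self, rng):
        protein = "MKTLVLLALLAVALAEESSEDEKRDVRPRSGKRDE"
        nt = sd.back_translate(protein, rng)
        assert seqio.translate_frame(nt, 1) == protein


class TestGenerateTranscriptome:
    def test_conservation_and_specificity(self, small_transcriptome):
        records, truths = small_transcriptome
        truth_by_protein = {t.protein: t for t in truths if t.is_precursor}
        n_precursors = len(truth_by_protein)
        orfs = seqio.six_frame_translate_all(records, min_orf_aa=60)
        tp = fp = exact = 0
        for orf in orfs:
            det = detector.screen_protein(orf)
            if not det.is_hit:
                continue
            truth = truth_by_protein.get(orf.seq)
            if truth is None:
                fp += 1
                continue
            tp += 1
            sig = curation.predict_signal_peptide(orf)
            ann = maturation.mature_all(curation.classify(det, sig))
            exact += Counter(ann.copy_counts) == truth.mature_counts
        assert tp == n_precursors
        assert fp == 0
        assert exact == n_precursors

    def test_decoys_only_yield_nothing(self):
        records, truths = sd.generate_transcriptome(10, [], seed=1)
        assert all(not t.is_precursor for t in truths)
        for orf in seqio.six_frame_translate_all(records, min_orf_aa=60):
            assert not detector.screen_protein(orf).is_hit

    def test_determinism(self):
        specs = sd.default_precursor_specs()[:2]
        r1, _ = sd.generate_transcriptome(5, specs, seed=7)
        r2, _ = sd.generate_transcriptome(5, specs, seed=7)
        assert [(r.id, r.seq) for r in r1] == [(r.id, r.seq) for r in r2]


class TestDiverge:
    def test_zero_rate_gives_identical_classes(self):
        spec = sd.PrecursorSpec(core="QWLRGRF", n_copies=6)
        rates = {k: 0.0 for k in sd.DEFAULT_BRANCH_RATES}
        variants = sd.diverge(spec, branch_rates=rates, seed=0)
        seqs = {rec.seq for rec, _ in variants.values()}
        assert len(seqs) == 1

    def test_all_four_classes_produced(self):
        spec = sd.PrecursorSpec(core="QWLRGRF", n_copies=6)
        variants = sd.diverge(spec, seed=0)
        assert set(variants) == {CUBOZOA, SCYPHOZOA, STAUROZOA, OCTOCORALLIA}

    def test_spacer_rate_increases_interclass_distance(self):
        from cnidopep import phylo
        spec = sd.PrecursorSpec(core="QWLRGRF", n_copies=10)
        means = []
        for scale in (0.3, 1.0):
            rates = {k: v * scale for k, v in sd.DEFAULT_BRANCH_RATES.items()}
            dists = []
            for seed in range(10):
                variants = sd.diverge(spec, branch_rates=rates, seed=seed)
                seqs = [(k, rec.seq) for k, (rec, _) in sorted(variants.items())]
                aln = phylo.progressive_align(seqs)
                _, m = phylo.p_distance(aln)
                dists.append(m[np.triu_indices(4, k=1)].mean())
            means.append(np.mean(dists))
        assert means[1] > means[0]

    def test_anchor_held_fixed(self):
        spec = sd.PrecursorSpec(core="QWLRGRF", n_copies=8)
        variants = sd.diverge(spec, seed=2)
        for cls, (rec, truth) in variants.items():
            for start, end in truth.cassette_spans:
                assert rec.seq[end - 3:end] == "GRF"


class TestNoise:
    def test_sensitivity_under_substitution_noise(self):
        rng = np.random.default_rng(11)
        base = sd.default_precursor_specs()
        hits = 0
        n = 200
        for k in range(n):
            spec = replace(base[k % len(base)],
                           n_copies=int(rng.integers(3, 33)),
                           copy_substitution_rate=0.10)
            rec, _ = sd.generate_precursor(spec, rng=rng)
            hits += detector.screen_protein(rec).is_hit
        assert hits / n >= 0.95
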