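"""Masking, candidate enumeration, scoring and per-gene probe selection."""

import pytest

from carpoligo.probe_design import (
    DesignAccounting,
    ProbeCandidate,
    ScoringParams,
    design_accounting,
    design_probes,
    enumerate_candidates,
    mask_sequence,
    score_candidate,
)
from carpoligo.transcriptome import GeneModel, TranscriptRecord
from .conftest import random_dna


def _dust_score_brute(window: str) -> float:
    """Independent DUST scorer: triplet pair count over one window."""
    counts = {}
    for i in range(len(window) - 2):
        t = window[i : i + 3]
        counts[t] = counts.get(t, 0) + 1
    n = len(window) - 2
    return sum(c * (c - 1) / 2 for c in counts.values()) / (n - 1)


class TestMasking:
    def test_polya_fully_masked(self):
        ms = mask_sequence("A" * 100)
        assert len(ms.intervals) == 1
        s, e, tag = ms.intervals[0]
        assert (s, e, tag) == (0, 100, "low_complexity")

    def test_random_sequence_unmasked_matches_brute_force(self, rng):
        seq = random_dna(rng, 200)
        # independent check: no 64-nt window exceeds the threshold
        brute_hot = [
            i for i in range(200 - 64 + 1) if _dust_score_brute(seq[i : i + 64]) > 2.0
        ]
        ms = mask_sequence(seq)
        low = [iv for iv in ms.intervals if iv[2] == "low_complexity"]
        assert brute_hot == []
        assert low == []

    def test_dust_agrees_with_brute_force_on_mixed_sequence(self, rng):
        seq = random_dna(rng, 100) + "AT" * 40 + random_dna(rng, 100)
        ms = mask_sequence(seq)
        covered = set()
        for s, e, tag in ms.intervals:
            if tag == "low_complexity":
                covered.update(range(s, e))
        brute = set()
        for i in range(len(seq) - 64 + 1):
            if _dust_score_brute(seq[i : i + 64]) > 2.0:
                brute.update(range(i, i + 64))
        assert covered == brute

    def test_vector_substring_masked_exactly(self, rng):
        vec = random_dna(rng, 30)
        seq = random_dna(rng, 80) + vec + random_dna(rng, 80)
        ms = mask_sequence(seq, vectors=[vec])
        vints = [iv for iv in ms.intervals if iv[2] == "vector"]
        assert vints == [(80, 110, "vector")]

    def test_vector_reverse_complement_detected(self, rng):
        from carpoligo.transcriptome import reverse_complement

        vec = random_dna(rng, 40)
        seq = random_dna(rng, 50) + reverse_complement(vec) + random_dna(rng, 50)
        ms = mask_sequence(seq, vectors=[vec])
        assert any(tag == "vector" for _, _, tag in ms.intervals)

    def test_n_positions_masked_ambiguous(self, rng):
        seq = random_dna(rng, 40) + "N" + random_dna(rng, 40)
        ms = mask_sequence(seq)
        assert (40, 41, "ambiguous") in ms.intervals

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mask_sequence("")


class TestEnumeration:
    def test_short_transcript_window_covers_everything(self, rng):
        ms = mask_sequence(random_dna(rng, 500))
        assert ms.intervals == ()
        cands = enumerate_candidates(ms)
        assert len(cands) == 441  # 500 - 60 + 1

    def test_long_transcript_restricted_to_3prime_window(self, rng):
        ms = mask_sequence(random_dna(rng, 5000))
        cands = enumerate_candidates(ms)
        assert len(cands) == 941  # 1000 - 60 + 1
        assert all(c.start >= 4000 for c in cands)
        assert all(c.distance_to_3prime < 1000 for c in cands)

    def test_fully_masked_transcript_has_no_candidates(self):
        ms = mask_sequence("A" * 300)
        assert enumerate_candidates(ms) == []

    def test_masked_overlap_excluded(self, rng):
        seq = random_dna(rng, 200)
        ms = mask_sequence(seq, vectors=[seq[100:130]])
        for c in enumerate_candidates(ms):
            assert c.start + 60 <= 100 or c.start >= 130


class TestScoring:
    def _cand(self, seq, dist):
        return ProbeCandidate("g", 0, seq, dist)

    def test_ideal_candidate_scores_zero(self):
        # GC exactly at target 0.45 (27/60), no long runs, flush with 3' end
        seq = "GC" * 13 + "G" + "AT" * 16 + "A"  # 27 GC / 60
        assert len(seq) == 60
        gc = (seq.count("G") + seq.count("C")) / 60
        assert gc == pytest.approx(0.45)
        assert score_candidate(self._cand(seq, 0), ScoringParams()) == pytest.approx(0.0)

    def test_distance_penalty_is_monotone(self):
        seq = "GC" * 13 + "G" + "AT" * 16 + "A"
        p = ScoringParams()
        near = score_candidate(self._cand(seq, 0), p)
        far = score_candidate(self._cand(seq, 500), p)
        assert near > far

    def test_homopolymer_penalty_linear(self):
        p = ScoringParams()
        base = "ACGT" * 15
        run10 = "A" * 10 + base[10:]
        run6 = "A" * 6 + base[6:]
        # same length; compare homopolymer terms after removing GC differences
        def homopoly_part(seq):
            gc = (seq.count("G") + seq.count("C")) / 60
            s = score_candidate(self._cand(seq, 0), p)
            return s + p.gc_weight * abs(gc - p.gc_target)

        assert homopoly_part(run6) - homopoly_part(run10) == pytest.approx(
            4 * p.homopolymer_weight
        )


def _gene(gid, seq):
    return GeneModel(gid, TranscriptRecord(f"{gid}.t1", gid, seq), 1)


class TestDesign:
    def test_too_short_status(self, rng):
        probes, acct = design_probes([_gene("g1", random_dna(rng, 40))])
        assert probes[0].status == "too_short"
        assert acct.too_short == 1 and acct.designed == 0

    def test_identical_representatives_yield_duplicate(self, rng):
        seq = random_dna(rng, 300)
        probes, acct = design_probes([_gene("g1", seq), _gene("g2", seq)])
        by_gene = {p.gene_id: p for p in probes}
        assert by_gene["g1"].status == "designed"
        assert by_gene["g2"].status == "duplicate"
        assert acct.duplicate == 1

    def test_engineered_ten_gene_fixture(self, rng):
        # 7 designable + 1 too-short + 1 fully-masked + 1 duplicate
        genes = [_gene(f"g{i}", random_dna(rng, 400 + 13 * i)) for i in range(7)]
        genes.append(_gene("g_short", random_dna(rng, 59)))
        genes.append(_gene("g_masked", "A" * 400))
        genes.append(_gene("g_dup", genes[0].representative.sequence))
        probes, acct = design_probes(genes)
        assert acct.submitted == 10
        assert acct.designed == 7
        assert (acct.too_short, acct.duplicate, acct.masked, acct.design_fail) == (1, 1, 1, 0)

    def test_designed_probes_unmasked_and_in_window(self, rng):
        from carpoligo.probe_design import mask_sequence

        genes = [_gene(f"g{i}", random_dna(rng, 2500)) for i in range(5)]
        probes, _ = design_probes(genes)
        reps = {g.gene_id: g.representative.sequence for g in genes}
        for p in probes:
            assert p.status == "designed"
            seq = reps[p.gene_id]
            assert p.start >= len(seq) - 1000
            assert seq[p.start : p.start + 60] == p.sequence
            assert not mask_sequence(seq).is_masked(p.start, p.start + 60)

    def test_selection_deterministic(self, rng):
        genes = [_gene(f"g{i}", random_dna(rng, 800)) for i in range(6)]
        a, _ = design_probes(genes)
        b, _ = design_probes(list(reversed(genes)))
        assert [(p.probe_id, p.sequence) for p in a] == [(p.probe_id, p.sequence) for p in b]

    def test_empty_input(self):
        probes, acct = design_probes([])
        assert probes == [] and acct.submitted == 0

    def test_designed_sequences_unique(self, rng):
        genes = [_gene(f"g{i}", random_dna(rng, 600)) for i in range(10)]
        probes, _ = design_probes(genes)
        seqs = [p.sequence for p in probes if p.status == "designed"]
        assert len(seqs) == len(set(seqs))


class TestAccounting:
    def test_identity_enforced(self):
        with pytest.raises(ValueError, match="identity"):
            DesignAccounting(10, 8, 1, 1, 1, 1)

    def test_no_exclusions_means_designed_equals_submitted(self):
        acct = DesignAccounting.from_exclusions(100, 0, 0, 0, 0)
        assert acct.designed == 100

    def test_empty_counts(self):
        acct = design_accounting([])
        assert acct.submitted == 0 and acct.designed == 0

    def test_unknown_status_rejected(self):
        class Fake:
            status = "bogus"

        with pytest.raises(ValueError, match="unknown status"):
            design_accounting([Fake()])
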