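import numpy as np
import pandas as pd
import pytest

from viromescope import (
    CrisprArray,
    ProteinHit,
    assign_family,
    detect_crispr_arrays,
    generate_genomes,
    host_census,
    match_spacers,
    predict_host_prophage,
)
from viromescope.annotate import UNCLASSIFIED, HostAssignment

from conftest import random_sequence


def _hit(protein, family, bit=100.0, ident=60.0, qcov=80.0, scov=80.0):
    return ProteinHit("v1", protein, family, ident, qcov, scov, bit)


TAX = pd.DataFrame(
    {"genus": ["Bacteroides", "Prevotella"], "phylum": ["Bacteroidota", "Bacteroidota"]},
    index=pd.Index(["h1", "h2"], name="host_id"),
)


class TestAssignFamily:
    def test_plurality_above_quarter_wins(self):
        hits = [_hit(f"p{i}", "Siphoviridae") for i in range(3)]
        assert assign_family(hits, 10) == "Siphoviridae"  # 0.30 > 0.25

    def test_exactly_one_quarter_is_unclassified(self):
        hits = [_hit(f"p{i}", "Siphoviridae") for i in range(2)]
        assert assign_family(hits, 8) == UNCLASSIFIED  # 0.25 not > 0.25

    def test_plurality_tie_is_unclassified(self):
        hits = [_hit(f"p{i}", "Siphoviridae") for i in range(4)]
        hits += [_hit(f"q{i}", "Myoviridae") for i in range(4)]
        assert assign_family(hits, 12) == UNCLASSIFIED

    def test_sub_threshold_hits_do_not_vote(self):
        good = [_hit(f"p{i}", "Siphoviridae") for i in range(3)]
        junk = [
            _hit(f"x{i}", "Myoviridae", bit=20.0) for i in range(6)
        ] + [
            _hit(f"y{i}", "Myoviridae", qcov=30.0) for i in range(6)
        ] + [
            _hit(f"z{i}", "Myoviridae", ident=10.0) for i in range(6)
        ]
        assert assign_family(good + junk, 10) == "Siphoviridae"
        assert assign_family(good, 10) == "Siphoviridae"  # removal changes nothing

    def test_hit_order_is_irrelevant_and_one_vote_per_protein(self):
        hits = [_hit(f"p{i}", "Siphoviridae") for i in range(3)]
        # ten redundant hits on one protein still count as one vote
        hits += [_hit("q0", "Myoviridae", bit=60 + i) for i in range(10)]
        forward = assign_family(hits, 10)
        assert forward == assign_family(list(reversed(hits)), 10)
        assert forward == "Siphoviridae"

    def test_zero_proteins_is_an_error(self):
        with pytest.raises(ValueError, match="n_proteins"):
            assign_family([], 0)


class TestCrisprDetection:
    def _array_genome(self, rng, n_repeats=3):
        repeat = random_sequence(rng, 30)
        spacers = []
        firsts = "ACG"
        for k in range(n_repeats - 1):
            sp = firsts[k] + random_sequence(rng, 30) + firsts[k]
            spacers.append(sp)
        text = repeat + "".join(sp + repeat for sp in spacers)
        left = random_sequence(rng, 400)
        if left[-1] == spacers[0][-1]:
            left = left[:-1] + ("T" if spacers[0][-1] != "T" else "A")
        genome = left + text + random_sequence(rng, 400)
        return genome, repeat, spacers

    def test_planted_array_recovered_byte_identical(self, make_rng):
        genome, repeat, spacers = self._array_genome(make_rng(4))
        arrays = detect_crispr_arrays(genome)
        assert len(arrays) == 1
        assert arrays[0].repeat_sequence == repeat
        assert list(arrays[0].spacers) == spacers
        assert arrays[0].n_repeats == 3

    def test_single_repeat_not_reported(self, make_rng):
        r = make_rng(8)
        genome = random_sequence(r, 300) + random_sequence(r, 30) + random_sequence(r, 300)
        assert detect_crispr_arrays(genome) == []

    def test_random_genomes_have_no_spurious_arrays(self, make_rng):
        for seed in range(10):
            genome = random_sequence(make_rng(seed), 10000)
            assert detect_crispr_arrays(genome) == []

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError, match="100"):
            detect_crispr_arrays("ACGT" * 10)

    def test_one_mismatch_tolerance_knob(self, make_rng):
        rng = make_rng(13)
        genome, repeat, spacers = self._array_genome(rng)
        # corrupt a central base of the second repeat copy (every 23-mer
        # window of that copy is then dirty, so exact chaining must fail)
        pos = genome.index(repeat, genome.index(repeat) + 1) + 15
        mutated = genome[:pos] + ("A" if genome[pos] != "A" else "C") + genome[pos + 1:]
        exact = detect_crispr_arrays(mutated)
        tolerant = detect_crispr_arrays(mutated, max_mismatches=1)
        assert all(a.n_repeats < 3 for a in exact)
        assert any(a.n_repeats == 3 for a in tolerant)


class TestSpacerMatching:
    def test_perfect_30mer_assigns_and_20mer_does_not(self, make_rng):
        r = make_rng(1)
        virus = random_sequence(r, 4000)
        spacer30 = virus[500:530]
        arr30 = CrisprArray("h1", "G" * 25, (spacer30,), ((0, 25), (55, 80)))
        out = match_spacers([arr30], "v", virus, TAX)
        assert len(out) == 1 and out[0].score == pytest.approx(55.39, abs=0.01)
        # spacer sharing only a 20-mer with the virus: raw 40 -> 37.4 bits < 45
        spacer_partial = virus[600:620] + "".join(
            c for c in random_sequence(r, 10)
        )
        arr20 = CrisprArray("h2", "G" * 25, (spacer_partial,), ((0, 25), (55, 80)))
        assert match_spacers([arr20], "v", virus, TAX) == []

    def test_unrelated_spacer_is_a_negative_control(self, make_rng):
        virus = random_sequence(make_rng(2), 4000)
        spacer = random_sequence(make_rng(3), 30)
        arr = CrisprArray("h1", "G" * 25, (spacer,), ((0, 25), (55, 80)))
        assert match_spacers([arr], "v", virus, TAX) == []

    def test_duplicate_pairs_collapse_to_max_score(self, make_rng):
        r = make_rng(5)
        virus = random_sequence(r, 4000)
        arr = CrisprArray(
            "h1", "G" * 25, (virus[100:130], virus[700:740]), ((0, 25), (55, 80))
        )
        out = match_spacers([arr], "v", virus, TAX)
        assert len(out) == 1
        assert out[0].score == pytest.approx(
            max((0.625 * 2 * 30 + 0.8916) / 0.6931,
                (0.625 * 2 * 40 + 0.8916) / 0.6931), abs=0.01,
        )


class TestProphagePrediction:
    class _Host:
        def __init__(self, hid, seq):
            self.id, self.sequence = hid, seq

    def test_planted_full_copy_is_assigned(self, make_rng):
        r = make_rng(6)
        virus = random_sequence(r, 3000)
        host = self._Host("h1", random_sequence(r, 4000) + virus + random_sequence(r, 4000))
        out = predict_host_prophage("v", virus, [host], TAX)
        assert len(out) == 1
        assert out[0].score == pytest.approx(100.0, abs=0.5)

    def test_low_coverage_fails_the_gate(self, make_rng):
        r = make_rng(7)
        virus = random_sequence(r, 3000)
        host = self._Host("h1", random_sequence(r, 5000) + virus[:600] + random_sequence(r, 5000))
        assert predict_host_prophage("v", virus, [host], TAX) == []  # 20% < 30%

    def test_unrelated_host_not_assigned(self, make_rng):
        virus = random_sequence(make_rng(8), 3000)
        host = self._Host("h1", random_sequence(make_rng(9), 10000))
        assert predict_host_prophage("v", virus, [host], TAX) == []


class TestHostCensusAndRecovery:
    def _assign(self, virus, host, genus, phylum="Bacteroidota", ev="crispr"):
        return HostAssignment(virus, host, genus, phylum, ev, 50.0)

    def test_multi_host_versus_single_host(self):
        multi = [
            self._assign("v1", "h1", "Bacteroides", ev="prophage"),
            self._assign("v1", "h2", "Prevotella"),
        ]
        single = [
            self._assign("v2", "h1", "Bacteroides"),
            self._assign("v2", "h1", "Bacteroides", ev="prophage"),
        ]
        census = host_census(multi + single, TAX)
        assert census == {"multi-host": 1, "Bacteroidota": 1}

    def test_unknown_host_rejected(self):
        with pytest.raises(ValueError, match="unknown host"):
            host_census([self._assign("v1", "nope", "X")], TAX)

    def test_fixture_census_equals_hand_count(self):
        assignments = []
        for i in range(6):  # 6 single-host Bacteroidota viruses
            assignments.append(self._assign(f"s{i}", "h1", "Bacteroides"))
        for i in range(4):  # 4 multi-host viruses
            assignments.append(self._assign(f"m{i}", "h1", "Bacteroides"))
            assignments.append(self._assign(f"m{i}", "h2", "Prevotella"))
        assert host_census(assignments, TAX) == {
            "Bacteroidota": 6, "multi-host": 4,
        }

    def test_planted_links_recovered_without_false_pairs(self, make_rng):
        # spacer-based host recovery on synthetic genome sets (10-seed sweep
        # here; the 50-seed sweep runs in the acceptance suite)
        from viromescope import detect_crispr_arrays, match_spacers

        for seed in range(10):
            gs = generate_genomes(3, 3, spacer_count=3, seed=seed)
            tax = gs.host_taxonomy()
            arrays = []
            for h in gs.host_genomes:
                arrays.extend(detect_crispr_arrays(h.sequence, genome_id=h.id))
            planted = {
                (vid, h.id)
                for h in gs.host_genomes
                for arr in h.crispr_arrays
                for vid, _, _ in arr.spacer_sources
            }
            found = set()
            for v in gs.viral_genomes:
                for a in match_spacers(arrays, v.id, v.sequence, tax):
                    found.add((a.virus_id, a.host_id))
            assert found == planted
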