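"""Candidate enumeration, mismatch scoring, ranking and blocking primers."""

import random

import pytest

from clampforge import wheat_panel
from clampforge.alignment_profile import (
    MultipleAlignment,
    build_profile,
    host_conserved_blocks,
)
from clampforge.clamp_design import (
    ClampCandidate,
    DesignConstraints,
    PrimerPair,
    count_clamp_microbe_mismatches,
    design_blocking_primers,
    design_pna,
    enumerate_pna_candidates,
    rank_candidates,
    score_candidates,
)
from clampforge.fixtures import FixtureSpec, simulate_panel
from clampforge.seq_core import (
    GAP,
    Role,
    SequenceRecord,
    iupac_match,
    max_purine_run,
    purine_fraction,
    reverse_complement,
    self_complementary_stretch,
)
from clampforge.thermo import ThermoConfig, tm_dna_nn, tm_pna


def aln_of(hosts, microbes):
    recs = [SequenceRecord(f"h{i}", s, Role.HOST, aligned=True)
            for i, s in enumerate(hosts)]
    recs += [SequenceRecord(f"m{i}", s, Role.MICROBE, aligned=True)
             for i, s in enumerate(microbes)]
    return MultipleAlignment(tuple(recs))


class TestEnumerate:
    def test_unconserved_alignment_yields_nothing(self):
        rng = random.Random(0)
        hosts = ["".join(rng.choice("ACGT") for _ in range(60)) for _ in range(3)]
        prof = build_profile(aln_of(hosts, ["A" * 60]))
        out = enumerate_pna_candidates(
            prof, DesignConstraints(constraint_mode="hard"))
        assert out == []

    def test_matches_brute_force_on_toy_alignment(self):
        rng = random.Random(7)
        host = "".join(rng.choice("ACGT") for _ in range(60))
        hosts = [host] * 3
        microbes = ["".join(rng.choice("ACGT") for _ in range(60))
                    for _ in range(2)]
        prof = build_profile(aln_of(hosts, microbes))
        cons = DesignConstraints()
        got = {(c.alignment_interval, c.strand)
               for c in enumerate_pna_candidates(prof, cons)}
        expected = set()
        blocks = host_conserved_blocks(prof, 1.0, cons.min_len)
        for bs, be in blocks:
            for start in range(bs, be):
                for n in range(cons.min_len, cons.max_len + 1):
                    if start + n > be:
                        continue
                    for strand in ("same_as_host_reference", "reverse_complement"):
                        expected.add(((start, start + n), strand))
        assert got == expected

    def test_hard_mode_candidates_pass_all_criteria(self, recovery_panel_seed1,
                                                    v5v7_pair):
        records, _ = recovery_panel_seed1
        prof = build_profile(MultipleAlignment(tuple(records)))
        thermo = ThermoConfig()
        cons = DesignConstraints(constraint_mode="hard",
                                 require_tm_above_extension=False,
                                 min_tm_margin_over_primers=-100.0)
        primer_tm = max(tm_dna_nn(v5v7_pair.forward.sequence, thermo),
                        tm_dna_nn(v5v7_pair.reverse.sequence, thermo))
        for c in enumerate_pna_candidates(prof, cons, thermo, v5v7_pair):
            assert cons.min_len <= len(c.sequence) <= cons.max_len
            assert purine_fraction(c.sequence) < cons.max_purine_fraction
            assert max_purine_run(c.sequence) <= cons.max_purine_run
            assert not self_complementary_stretch(c.sequence, cons.self_comp_k)[1]
            assert c.violations == []

    def test_soft_mode_reports_violations(self):
        # a pure-purine conserved host block must come back flagged, not dropped
        host = "G" * 30
        prof = build_profile(aln_of([host] * 2, ["C" * 30]))
        cands = enumerate_pna_candidates(prof, DesignConstraints())
        same = [c for c in cands if c.strand == "same_as_host_reference"]
        assert same
        assert all("purine_fraction" in c.violations for c in same)
        assert all("purine_run" in c.violations for c in same)


class TestScoring:
    def test_identical_microbe_scores_zero(self):
        host = "ACGTACGTACGTACGT"
        prof = build_profile(aln_of([host], [host]))
        cands = enumerate_pna_candidates(prof, DesignConstraints(min_len=12, max_len=12))
        scored = score_candidates(cands, prof.alignment.by_role(Role.MICROBE), prof)
        assert all(c.min_microbe_mismatches == 0 for c in scored)

    def test_all_gap_microbe_counts_full_length(self):
        # clamp over a host-specific insertion: every position is a mismatch
        host = "ACGTACGTACGTACGT"
        prof = build_profile(aln_of([host], ["-" * 16]))
        cands = enumerate_pna_candidates(prof, DesignConstraints(min_len=12, max_len=12))
        scored = score_candidates(cands, prof.alignment.by_role(Role.MICROBE), prof)
        assert all(c.per_microbe_mismatches["m0"] == 12 for c in scored)

    def test_counts_match_position_by_position_brute_force(self, profile_seed1):
        prof = profile_seed1
        microbes = prof.alignment.by_role(Role.MICROBE)
        cands = enumerate_pna_candidates(prof, DesignConstraints(max_len=14))
        scored = score_candidates(cands[:300], microbes, prof)
        for c in scored:
            s, e = c.alignment_interval
            for m in microbes:
                n = 0
                for j in range(s, e):
                    a, b = prof.host_consensus[j], m.residues[j]
                    if b == GAP or not iupac_match(a, b):
                        n += 1
                assert c.per_microbe_mismatches[m.id] == n
            assert c.min_microbe_mismatches == min(c.per_microbe_mismatches.values())

    def test_column_space_mismatch_rejected(self, profile_seed1):
        bad = SequenceRecord("bad", "ACGT", Role.MICROBE)
        with pytest.raises(ValueError, match="alignment width"):
            score_candidates([], [bad], profile_seed1)

    def test_adding_a_microbe_never_raises_min_mismatches(self, profile_seed1):
        prof = profile_seed1
        microbes = prof.alignment.by_role(Role.MICROBE)
        cands = enumerate_pna_candidates(prof, DesignConstraints(max_len=13))[:100]
        before = [c.min_microbe_mismatches for c in
                  score_candidates(cands, microbes[:3], prof)]
        after = [c.min_microbe_mismatches for c in
                 score_candidates(cands, microbes, prof)]
        assert all(a <= b for a, b in zip(after, before))


def make_candidate(start, mm, tm, violations=()):
    c = ClampCandidate(
        sequence="ACCTCCTACCTC", alignment_interval=(start, start + 12),
        strand="same_as_host_reference", tm_pna=tm, purine_fraction=0.25,
        max_purine_run=1, self_comp_len=0, violations=list(violations),
    )
    c.min_microbe_mismatches = mm
    c.mismatch_score = float(mm)
    return c


class TestRanking:
    def test_more_mismatches_first(self):
        a, b = make_candidate(0, 7, 75.0), make_candidate(5, 5, 80.0)
        assert rank_candidates([b, a])[0] is a

    def test_tie_break_toward_target_tm(self):
        a, b = make_candidate(0, 5, 79.0), make_candidate(5, 5, 70.0)
        assert rank_candidates([b, a])[0] is a

    def test_tie_break_fewer_violations_then_position(self):
        a = make_candidate(3, 5, 75.0)
        b = make_candidate(3, 5, 75.0, violations=["length"])
        assert rank_candidates([b, a])[0] is a
        c, d = make_candidate(2, 5, 75.0), make_candidate(9, 5, 75.0)
        assert rank_candidates([d, c])[0] is c

    def test_equals_brute_force_sort(self, profile_seed1, v5v7_pair):
        ranked = design_pna(profile_seed1, DesignConstraints(max_len=13),
                            primer_pair=v5v7_pair)
        target = ThermoConfig().pna_target_tm
        order = {"same_as_host_reference": 0, "reverse_complement": 1}
        keys = [(-c.mismatch_score, abs(c.tm_pna - target), len(c.violations),
                 c.alignment_interval[0], order[c.strand], c.alignment_interval[1])
                for c in ranked]
        assert keys == sorted(keys)


class TestPlantedSiteRecovery:
    @pytest.mark.parametrize("seed", range(1, 21))
    def test_top_candidate_overlaps_planted_window(self, seed, v5v7_pair):
        length = 120 + (seed * 37) % 680
        spec = FixtureSpec(seed=seed, locus_length=length, insertion_length=0)
        records, truth = simulate_panel(spec)
        prof = build_profile(MultipleAlignment(tuple(records)))
        ranked = design_pna(prof, DesignConstraints(), primer_pair=v5v7_pair)
        assert ranked, "no candidates emitted"
        s, e = ranked[0].alignment_interval
        ps, pe = truth.planted_columns
        assert s < pe and e > ps, f"top candidate {s, e} misses planted {ps, pe}"
        assert ranked[0].min_microbe_mismatches >= truth.min_mismatches_to_microbes


class TestPublishedPanelCompliance:
    """The toolkit's criteria screen applied to the published wheat PNAs."""

    def screen(self, seq):
        cons = DesignConstraints()
        v = []
        if not (cons.min_len <= len(seq) <= cons.max_len):
            v.append("length")
        if purine_fraction(seq) >= cons.max_purine_fraction:
            v.append("purine_fraction")
        if max_purine_run(seq) > cons.max_purine_run:
            v.append("purine_run")
        if self_complementary_stretch(seq, cons.self_comp_k)[1]:
            v.append("self_complementary")
        return v

    def test_max_purine_fraction_at_most_half(self):
        worst = max(purine_fraction(o.sequence) for o in wheat_panel.PNAS.values())
        assert worst <= 0.50

    def test_its1_pna_flagged_for_length(self):
        assert len(wheat_panel.PNAS["PNA_ITS1"].sequence) == 24
        assert "length" in self.screen(wheat_panel.PNAS["PNA_ITS1"].sequence)

    def test_v5v7_pna_flagged_for_purine_run(self):
        assert max_purine_run(wheat_panel.PNAS["PNA_V5V7"].sequence) == 5
        assert "purine_run" in self.screen(wheat_panel.PNAS["PNA_V5V7"].sequence)


class TestBlockingPrimers:
    def test_competitive_overlaps_reverse_primer(self, v5v7_pair):
        # geometry: only the reverse-primer site sits in a conserved block
        spec = FixtureSpec(seed=2, insertion_length=0, locus_length=300,
                           host_divergence=0.0)
        records, truth = simulate_panel(spec)
        prof = build_profile(MultipleAlignment(tuple(records)))
        pair = PrimerPair(v5v7_pair.forward, v5v7_pair.reverse)
        res = design_blocking_primers(prof, pair, "competitive", "short")
        assert res.ok
        d = res.design
        assert d.overlapped_primer in (pair.forward.name, pair.reverse.name)
        iv = (truth.reverse_primer_columns
              if d.overlapped_primer == pair.reverse.name
              else truth.forward_primer_columns)
        s, e = d.alignment_interval
        assert s < iv[1] and e > iv[0], "design does not overlap the primer site"
        assert d.oligo.three_prime_block

    def test_elongation_arrest_strictly_between_primers(self, profile_seed1,
                                                        v5v7_pair, panel_seed1):
        _, truth = panel_seed1
        res = design_blocking_primers(profile_seed1, v5v7_pair,
                                      "elongation_arrest", "short")
        assert res.ok
        s, e = res.design.alignment_interval
        assert s >= truth.forward_primer_columns[1]
        assert e <= truth.reverse_primer_columns[0]
        assert res.design.overlapped_primer is None

    @pytest.mark.parametrize("strategy", ["competitive", "elongation_arrest"])
    def test_long_extends_short_at_same_locus(self, profile_seed1, v5v7_pair,
                                              strategy):
        short = design_blocking_primers(profile_seed1, v5v7_pair, strategy, "short")
        long_ = design_blocking_primers(profile_seed1, v5v7_pair, strategy, "long")
        assert short.ok and long_.ok
        ss, se = short.design.alignment_interval
        ls, le = long_.design.alignment_interval
        assert ls <= ss and le >= se
        assert long_.design.achieved_tm >= short.design.achieved_tm

    def test_no_geometry_gives_explicit_reason(self, v5v7_pair):
        # conserved host but primers absent from the consensus entirely
        host = "ACGTTGCA" * 10
        prof = build_profile(aln_of([host] * 2, ["TTTTACGT" * 10]))
        res = design_blocking_primers(prof, v5v7_pair, "elongation_arrest")
        assert not res.ok
        assert res.reason
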