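"""Tests for TTS scanning, placement classification and TFO design."""

import pytest

from triplexion.sequence_screen import (
    GEOMETRY_MAP,
    PromoterRecord,
    ScanParams,
    SequenceInputError,
    TTSCandidate,
    TUScaffold,
    build_tu,
    classify_placement,
    design_tfo,
    enumerate_designs,
    mutate_tfo,
    purine_strand_from_tfo,
    reverse_complement,
    scan_tts,
)

PURINES = set("AG")


def brute_force_qualifying_windows(seq: str, params: ScanParams) -> set[tuple[int, int]]:
    """Independent oracle: every >=min_length window satisfying the purine
    thresholds, by direct substring enumeration."""
    out = set()
    n = len(seq)
    for s in range(n):
        for e in range(s + params.min_length, n + 1):
            sub = seq[s:e]
            if sub[0] not in PURINES or sub[-1] not in PURINES:
                continue
            n_pyr = sum(c not in PURINES for c in sub)
            if n_pyr > params.max_pyrimidine_fraction * len(sub):
                continue
            run = best = 0
            for c in sub:
                run = 0 if c in PURINES else run + 1
                best = max(best, run)
            if best > params.max_consecutive_interruptions:
                continue
            out.add((s, e))
    return out


def make_promoter(pre: str, run: str, post: str, m35: int, m10: int, p1: int,
                  pid: str = "p") -> PromoterRecord:
    return PromoterRecord(id=pid, sequence=pre + run + post,
                          minus35_start=m35, minus10_start=m10, plus1_index=p1)


def blocked_background(n: int) -> list[str]:
    """'CCAA' repeats: every 15-nt window carries a CC on the sense strand
    and a TT on the template strand, so no background window can satisfy
    the <=1-consecutive-interruption rule on either strand."""
    return list(("CCAA" * (n // 4 + 1))[:n])


@pytest.fixture
def promoter_81nt() -> PromoterRecord:
    """81-nt promoter: -35 at 10, -10 at 33, +1 at 45, a 16-nt pure-purine
    run at [42, 58) (3 nt after the -10 box) flanked by CC so it cannot
    extend."""
    seq = blocked_background(81)
    seq[10:16] = "TTGACA"
    seq[33:39] = "TATAAT"
    seq[40:42] = "CC"
    seq[42:58] = "GA" * 8
    seq[58:60] = "CC"
    return PromoterRecord(id="p81", sequence="".join(seq),
                          minus35_start=10, minus10_start=33, plus1_index=45)


class TestScanTTS:
    def test_single_pure_purine_run_found(self, promoter_81nt):
        cands = scan_tts(promoter_81nt)
        sense = [c for c in cands if c.purine_strand == "sense"]
        assert len(sense) == 1
        c = sense[0]
        assert (c.start, c.end) == (42, 58)
        assert c.length == 16
        assert c.purine_fraction == 1.0
        assert c.purine_sequence == "GA" * 8

    def test_reported_tracts_match_brute_force(self, promoter_81nt):
        """Every reported interval is a qualifying window and every
        qualifying window is covered by a reported candidate."""
        params = ScanParams()
        cands = scan_tts(promoter_81nt, params)
        for strand_seq, strand in ((promoter_81nt.sequence, "sense"),
                                   (reverse_complement(promoter_81nt.sequence), "template")):
            wins = brute_force_qualifying_windows(strand_seq, params)
            n = len(strand_seq)
            if strand == "template":
                wins = {(n - e, n - s) for s, e in wins}
            reported = {(c.start, c.end) for c in cands if c.purine_strand == strand}
            for s, e in reported:
                assert any(ws <= s and e <= we for ws, we in wins | reported)
            for ws, we in wins:
                assert any(s <= ws and we <= e for s, e in reported), (
                    f"qualifying window ({ws},{we}) on {strand} not covered"
                )

    def test_run_truncated_below_min_length(self, promoter_81nt):
        seq = list(promoter_81nt.sequence)
        seq[56:58] = "CC"  # 16-nt run -> 14-nt run
        p = PromoterRecord(id="p", sequence="".join(seq), minus35_start=10,
                           minus10_start=33, plus1_index=45)
        assert scan_tts(p) == []

    def test_template_strand_run(self, promoter_81nt):
        """A pyrimidine run on the sense strand is a purine tract on the
        template; purine_sequence is the reverse complement."""
        seq = list(promoter_81nt.sequence)
        seq[40:42] = "AA"   # template-strand TT blocks extension there
        seq[42:58] = reverse_complement("GA" * 8)  # 'TC'*8 on sense
        seq[58:60] = "AA"
        p = PromoterRecord(id="p", sequence="".join(seq), minus35_start=10,
                           minus10_start=33, plus1_index=45)
        cands = [c for c in scan_tts(p) if c.purine_strand == "template"]
        assert len(cands) == 1
        assert cands[0].purine_sequence == reverse_complement(p.sequence[42:58])
        assert set(cands[0].purine_sequence) <= PURINES

    def test_tract_outside_proximity_window_ignored(self):
        seq = blocked_background(120)
        seq[5:11] = "TTGACA"
        seq[22:28] = "TATAAT"
        seq[98:100] = "CC"
        seq[100:116] = "GA" * 8
        seq[116:118] = "CC"
        p = PromoterRecord(id="p", sequence="".join(seq), minus35_start=5,
                           minus10_start=22, plus1_index=30)
        assert scan_tts(p, ScanParams(proximity_margin=20)) == []
        assert len(scan_tts(p, ScanParams(proximity_margin=80))) == 1

    def test_strand_symmetry(self, promoter_81nt):
        """Scanning the reverse complement yields the same intervals with
        sense/template swapped (windows made all-covering)."""
        n = len(promoter_81nt.sequence)
        params = ScanParams(proximity_margin=n)
        fwd = scan_tts(promoter_81nt, params)
        rc = PromoterRecord(id="rc", sequence=reverse_complement(promoter_81nt.sequence),
                            minus35_start=10, minus10_start=33, plus1_index=45)
        rev = scan_tts(rc, params)
        flip = {"sense": "template", "template": "sense"}
        fwd_set = {(c.start, c.end, c.purine_strand) for c in fwd}
        rev_set = {(n - c.end, n - c.start, flip[c.purine_strand]) for c in rev}
        assert fwd_set == rev_set

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(SequenceInputError):
            PromoterRecord(id="x", sequence="ACGTN" * 10, minus35_start=1,
                           minus10_start=10, plus1_index=20)


class TestClassifyPlacement:
    @pytest.fixture
    def promoter(self, promoter_81nt):
        return promoter_81nt

    def _tts(self, start, end, promoter):
        return TTSCandidate(promoter_id=promoter.id, start=start, end=end,
                            purine_strand="sense", purine_fraction=1.0,
                            placement="", purine_sequence=promoter.sequence[start:end])

    def test_spacer_between_boxes_is_within(self, promoter):
        # spacer: [-35 end, -10 start) = [16, 33)
        assert classify_placement(self._tts(16, 33, promoter), promoter) == "within_consensus"

    def test_first_base_after_minus10_is_downstream(self, promoter):
        # -10 box ends at 33 + 6 = 39 (half-open)
        assert classify_placement(self._tts(39, 60, promoter), promoter) == "downstream"

    def test_straddling_minus10_edge_is_spanning(self, promoter):
        assert classify_placement(self._tts(36, 50, promoter), promoter) == "spanning"

    def test_upstream(self, promoter):
        assert classify_placement(self._tts(0, 10, promoter), promoter) == "upstream"

    def test_outside_sequence_is_error(self, promoter):
        tts = TTSCandidate(promoter_id="p", start=70, end=100, purine_strand="sense",
                           purine_fraction=1.0, placement="", purine_sequence="A" * 30)
        with pytest.raises(SequenceInputError):
            classify_placement(tts, promoter)


def _tts_for(purine_seq: str) -> TTSCandidate:
    return TTSCandidate(promoter_id="t", start=0, end=len(purine_seq),
                        purine_strand="sense", purine_fraction=1.0,
                        placement="downstream", purine_sequence=purine_seq)


class TestDesignTFO:
    def test_pyrimidine_motif(self):
        tfo = design_tfo(_tts_for("GAAGGAGGAGAAGGA"), "pyrimidine")
        assert tfo.rna_sequence == "CUUCCUCCUCUUCCU"
        assert tfo.orientation == "parallel"
        assert tfo.mismatch_positions == ()

    def test_purine_motif_is_reversed(self):
        tfo = design_tfo(_tts_for("GAAGGAGGAGAAGGA"), "purine")
        assert tfo.rna_sequence == "AGGAAGAGGAGGAAG"
        assert tfo.orientation == "antiparallel"

    def test_homopolymer_flagged_low_complexity(self):
        tfo = design_tfo(_tts_for("A" * 15), "pyrimidine")
        assert tfo.rna_sequence == "U" * 15
        assert tfo.low_complexity

    def test_interruption_uses_complement_partner(self):
        """A pyrimidine interruption in the purine strand gets the
        Hoogsteen partner of the purine on the opposite strand."""
        tfo = design_tfo(_tts_for("GAAGGAGGAGAAGGT"), "pyrimidine")
        assert tfo.rna_sequence == "CUUCCUCCUCUUCCU"  # T -> (A on other strand) -> U
        assert tfo.mismatch_positions == (14,)
        pu = design_tfo(_tts_for("GAAGGAGGAGAAGGT"), "purine")
        assert pu.mismatch_positions == (0,)  # reversed frame

    def test_inverse_recovers_purine_strand(self):
        for motif in ("pyrimidine", "purine"):
            tfo = design_tfo(_tts_for("GAAGGAGGAGAAGGA"), motif)
            assert purine_strand_from_tfo(tfo) == "GAAGGAGGAGAAGGA"


class TestMutateTFO:
    @pytest.fixture
    def tfo(self):
        return design_tfo(_tts_for("GAAGG"), "pyrimidine")  # CUUCC

    def test_single_mutation(self, tfo):
        mut = mutate_tfo(tfo, 0)
        assert mut.rna_sequence == "UUUCC"
        assert mut.mismatch_positions == (0,)

    def test_mutate_back_restores_perfect_design(self, tfo):
        back = mutate_tfo(mutate_tfo(tfo, 2), 2)
        assert back.rna_sequence == tfo.rna_sequence
        assert back.mismatch_positions == ()

    def test_out_of_range_is_error(self, tfo):
        with pytest.raises(SequenceInputError):
            mutate_tfo(tfo, 99)


class TestEnumerateDesigns:
    def test_eight_combinations_per_tts(self):
        pairs = enumerate_designs([_tts_for("GA" * 8)],
                                  domains=["TTS1_within_consensus", "TTS2_downstream"],
                                  placements=["sense", "template"],
                                  motifs=["purine", "pyrimidine"])
        assert len(pairs) == 8
        assert {tu.geometry for tu, _ in pairs} == {"A", "B", "C", "D"}

    def test_24_measurements_for_three_tts(self):
        tts = [_tts_for(s) for s in ("GA" * 8, "AG" * 8, "GGA" * 5)]
        pairs = enumerate_designs(tts,
                                  domains=["TTS1_within_consensus", "TTS2_downstream"],
                                  placements=["sense", "template"],
                                  motifs=["purine", "pyrimidine"])
        assert len(pairs) == 24

    def test_cardinality_is_product_of_factors(self):
        pairs = enumerate_designs([_tts_for("GA" * 8)], ["TTS2_downstream"],
                                  ["sense"], ["purine"])
        assert len(pairs) == 1
        assert pairs[0][0].geometry == "B"

    def test_geometry_mapping_is_bijective(self):
        assert len(set(GEOMETRY_MAP.values())) == 4

    def test_empty_factor_list_is_error(self):
        with pytest.raises(SequenceInputError):
            enumerate_designs([], ["TTS2_downstream"], ["sense"], ["purine"])


class TestBuildTU:
    @pytest.fixture
    def scaffold(self):
        bg = "AC" * 60
        seq = list(bg[:100])
        seq[10:16] = "TTGACA"
        seq[33:39] = "TATAAT"
        return TUScaffold(sequence="".join(seq), tts1_slot=(16, 31), tts2_slot=(45, 60),
                          reporter_slot=(70, 95), minus35_start=10, minus10_start=33)

    def test_geometry_a_preserves_length_and_boxes(self, scaffold):
        tu = build_tu(_tts_for("GA" * 7 + "G"), "A", scaffold)
        assert len(tu.assembled_sequence) == len(scaffold.sequence)
        assert tu.assembled_sequence[10:16] == "TTGACA"
        assert tu.assembled_sequence[33:39] == "TATAAT"

    def test_geometry_b_sense_placement_verbatim(self, scaffold):
        tts = _tts_for("GA" * 7 + "G")
        tu = build_tu(tts, "B", scaffold)
        assert tu.assembled_sequence[45:60] == tts.purine_sequence

    def test_geometry_c_differs_only_inside_slot(self, scaffold):
        tu = build_tu(_tts_for("GA" * 7 + "G"), "C", scaffold)
        s, e = scaffold.tts1_slot
        assert tu.assembled_sequence[:s] == scaffold.sequence[:s]
        assert tu.assembled_sequence[e:] == scaffold.sequence[e:]

    def test_length_mismatch_is_error(self, scaffold):
        with pytest.raises(SequenceInputError, match="15"):
            build_tu(_tts_for("GA" * 8), "A", scaffold)
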