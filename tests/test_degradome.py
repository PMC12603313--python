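import random

import pytest

from auxinmir.config import PipelineConfig
from auxinmir.degradome import (DegradomeProfile, build_module_table,
                                categorise, export_tplot, import_tplot,
                                scan_targets, score_site)
from auxinmir.sequence_core import Transcript, reverse_complement

from oracles import degradome_category, site_penalty_recursion


def rc(mirna):
    return reverse_complement(mirna.replace("U", "T"))


# ---------------------------------------------------------------------------
# complementarity scoring
# ---------------------------------------------------------------------------

class TestScoreSite:
    def test_perfect_complement_is_zero(self):
        mirna = "UGGAGCUCCCUUCAUUCCAAU"
        penalty, states = score_site(mirna, rc(mirna))
        assert penalty == 0.0
        assert set(states) == {"match"}

    def test_seed_mismatch_costs_double(self):
        mirna = "AAGGCUCCAAUGGAAGGCAAA"
        window = list(rc(mirna))
        # window is reversed relative to the miRNA: position p (1-based)
        # of the miRNA pairs window index len-p
        for pos, expected in ((15, 1.0), (5, 2.0)):
            w = list(window)
            idx = len(w) - pos
            w[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[w[idx]]
            penalty, _ = score_site(mirna, "".join(w))
            assert penalty == expected, pos

    def test_gu_wobble_half_cost(self):
        mirna = "AAAAAAAAAAAAAAAAAAGAA"       # G at position 19 (tail)
        window = list(rc(mirna))
        window[len(window) - 19] = "T"        # G:U opposite position 19
        penalty, states = score_site(mirna, "".join(window))
        assert penalty == 0.5 and states[18] == "GU"

    def test_matches_exhaustive_recursion(self):
        rng = random.Random(16)
        for _ in range(200):
            m = "".join(rng.choice("ACGU") for _ in range(rng.randint(3, 12)))
            w = "".join(rng.choice("ACGU") for _ in range(rng.randint(3, 12)))
            penalty, _ = score_site(m, w)
            assert penalty == site_penalty_recursion(m, w)

    def test_state_degradation_monotonicity(self):
        # match -> GU -> mismatch at one position never decreases the penalty
        mirna = "ACGGCUCCAAUGGAAGGCGAA"
        base = list(rc(mirna))
        p0, _ = score_site(mirna, "".join(base))
        idx = len(base) - 16                  # miRNA position 16, unweighted
        assert mirna[15] == "G" and base[idx] == "C"
        gu = list(base)
        gu[idx] = "T"
        p_gu, _ = score_site(mirna, "".join(gu))
        mm = list(base)
        mm[idx] = "A"
        p_mm, _ = score_site(mirna, "".join(mm))
        assert p0 <= p_gu <= p_mm

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError, match="non-RNA"):
            score_site("ACGX", "ACGU")


# ---------------------------------------------------------------------------
# target scanning
# ---------------------------------------------------------------------------

class TestScanTargets:
    def test_planted_perfect_site_found_once(self, cfg):
        rng = random.Random(17)
        mirna = "".join(rng.choice("ACGU") for _ in range(21))
        flank5 = "".join(rng.choice("ACGT") for _ in range(100))
        flank3 = "".join(rng.choice("ACGT") for _ in range(100))
        t = Transcript("t", flank5 + rc(mirna) + flank3)
        sites = scan_targets("m", mirna, [t], cfg)
        perfect = [s for s in sites if s.penalty == 0.0]
        assert len(perfect) == 1
        s = perfect[0]
        assert (s.site_start, s.site_end) == (100, 121)
        # cleavage opposite miRNA position 10, 1-based
        assert s.cleavage_pos == s.site_end - 9

    def test_site_above_threshold_not_reported(self, cfg):
        rng = random.Random(18)
        mirna = "".join(rng.choice("ACGU") for _ in range(21))
        window = list(rc(mirna))
        # five seed-region mismatches: gapless penalty 10
        for pos in (3, 5, 7, 9, 11):
            idx = len(window) - pos
            window[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[window[idx]]
        t = Transcript("t", "".join(window))
        assert scan_targets("m", mirna, [t], cfg) == []

    def test_overlapping_hits_keep_minimal_penalty(self, cfg):
        mirna = "UGGAGCUCCCUUCAUUCCAAU"
        t = Transcript("t", "AAAA" + rc(mirna) + "AAAA")
        sites = scan_targets("m", mirna, [t], cfg)
        assert len(sites) == 1 and sites[0].penalty == 0.0


# ---------------------------------------------------------------------------
# degradome categories
# ---------------------------------------------------------------------------

class TestCategorise:
    def test_unique_maximum_is_category_0(self):
        prof = DegradomeProfile("t", {100: 50, 200: 3, 300: 2})
        assert categorise(prof, 100).category == 0

    def test_shared_maximum_is_category_1(self):
        prof = DegradomeProfile("t", {100: 5, 200: 5})
        assert categorise(prof, 100).category == 1

    def test_single_read_is_category_4_and_absent_is_none(self):
        prof = DegradomeProfile("t", {100: 1, 200: 9})
        assert categorise(prof, 100).category == 4
        assert categorise(prof, 150).category is None

    def test_matches_literal_definition_on_random_profiles(self):
        rng = random.Random(19)
        for _ in range(500):
            npos = rng.randint(1, 12)
            counts = {rng.randint(1, 300): rng.randint(1, 30) for _ in range(npos)}
            pos = (rng.choice(list(counts)) if rng.random() < 0.7
                   else rng.randint(1, 300))
            prof = DegradomeProfile("t", counts)
            assert categorise(prof, pos).category == degradome_category(counts, pos)

    def test_scaling_invariance_for_order_statistic_categories(self):
        counts = {10: 8, 20: 3, 30: 3, 40: 2}
        for pos in counts:
            base = categorise(DegradomeProfile("t", counts), pos).category
            scaled = {p: c * 7 for p, c in counts.items()}
            assert categorise(DegradomeProfile("t", scaled), pos).category == base

    def test_adding_reads_at_site_never_worsens_category(self):
        rng = random.Random(20)
        for _ in range(100):
            counts = {rng.randint(1, 50): rng.randint(2, 20) for _ in range(6)}
            pos = rng.choice(list(counts))
            before = categorise(DegradomeProfile("t", counts), pos).category
            boosted = dict(counts)
            boosted[pos] += rng.randint(1, 30)
            after = categorise(DegradomeProfile("t", boosted), pos).category
            assert after <= before

    def test_counts_below_one_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            DegradomeProfile("t", {5: 0})


# ---------------------------------------------------------------------------
# T-plots and the module table
# ---------------------------------------------------------------------------

class TestTplot:
    def test_empty_profile_header_only(self, tmp_path):
        prof = DegradomeProfile("t", {})
        path = tmp_path / "tp.tsv"
        export_tplot(prof, 10, path)
        assert path.read_text() == "position\tcount\tis_cleavage_site\n"

    def test_rows_sorted_and_flagged(self, tmp_path):
        prof = DegradomeProfile("t", {30: 2, 10: 5, 20: 1})
        path = tmp_path / "tp.tsv"
        export_tplot(prof, 20, path)
        lines = path.read_text().strip().split("\n")[1:]
        assert [l.split("\t")[0] for l in lines] == ["10", "20", "30"]
        assert lines[1].endswith("\t1")

    def test_roundtrip_identity(self, tmp_path):
        prof = DegradomeProfile("t", {7: 3, 99: 12, 15: 1})
        path = tmp_path / "tp.tsv"
        export_tplot(prof, 99, path)
        back = import_tplot(path, "t")
        assert back.counts == prof.counts and back.total == prof.total


class TestModuleTable:
    def _evidence(self, mirna, tid, category):
        from auxinmir.degradome import CleavageEvidence, TargetSite
        site = TargetSite(mirna_id=mirna, transcript_id=tid, site_start=0,
                          site_end=21, penalty=0.0, alignment=[], cleavage_pos=12)
        return CleavageEvidence(site=site, reads_at_site=5, category=category)

    def test_one_mirna_two_targets(self):
        ev = [self._evidence("m1", "t1", 0), self._evidence("m1", "t2", 2)]
        rows = build_module_table(ev, {"t1": "ARF:full_arf", "t2": "TIR1/AFB:receptor"})
        assert len(rows) == 2 and not any(r.warning for r in rows)

    def test_missing_annotation_warns_not_drops(self):
        rows = build_module_table([self._evidence("m1", "tX", 1)], {})
        assert len(rows) == 1
        assert rows[0].annotation == "unclassified" and rows[0].warning

    def test_category_filter_and_no_evidence_excluded(self):
        ev = [self._evidence("m1", "t1", 0), self._evidence("m1", "t2", None),
              self._evidence("m1", "t3", 4)]
        rows = build_module_table(ev, {}, max_category=2)
        assert [r.transcript_id for r in rows] == ["t1"]
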