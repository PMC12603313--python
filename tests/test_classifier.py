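import random

import numpy as np
import pytest

from auxinmir.classifier import (ReferenceConfigError, anchor_residues,
                                 assign_architecture, classify_arf, classify_md,
                                 classify_tir_afb, scan_dbd_motif, type_pb1)
from auxinmir.config import PipelineConfig
from auxinmir.sequence_core import OrfProtein

AA = "ACDEFGHIKLMNPQRSTVWY"


def as_orf(aa_seq, tid="q"):
    return OrfProtein(transcript_id=tid, frame=0, strand="+", cds_start=0,
                      cds_end=(len(aa_seq) + 1) * 3, aa_seq=aa_seq, complete=True)


# ---------------------------------------------------------------------------
# residue anchoring
# ---------------------------------------------------------------------------

class TestAnchorResidues:
    def test_reference_against_itself_all_conserved(self, refs):
        tir1, _, _ = refs
        pos = [(p, a, "orientation") for p, a in tir1.pocket_orientation]
        checks = anchor_residues(tir1.seq, tir1.seq, pos)
        assert all(c.conserved for c in checks)

    def test_single_substitution_flips_exactly_that_check(self, refs):
        tir1, _, _ = refs
        pos = ([(p, a, "orientation") for p, a in tir1.pocket_orientation]
               + [(p, a, "selectivity") for p, a in tir1.pocket_selectivity])
        p410 = 410
        edited = list(tir1.seq)
        edited[p410 - 1] = "R"                      # Lys-410 -> Arg
        checks = anchor_residues("".join(edited), tir1.seq, pos)
        flipped = {c.ref_pos for c in checks if not c.conserved}
        assert flipped == {p410}

    def test_gap_reported_as_nonconserved(self, refs):
        tir1, _, _ = refs
        query = tir1.seq[:430] + tir1.seq[445:]      # delete residues 431-445
        pos = [(440, "S", "selectivity"), (441, "G", "orientation")]
        checks = anchor_residues(query, tir1.seq, pos)
        assert all(not c.conserved and c.query_aa == "-" for c in checks)

    def test_nterminal_padding_does_not_move_anchors(self, refs):
        tir1, _, _ = refs
        pos = [(p, a, "orientation") for p, a in tir1.pocket_orientation]
        padded = "GGSGG" + tir1.seq
        checks = anchor_residues(padded, tir1.seq, pos)
        assert all(c.conserved for c in checks)

    def test_metadata_drift_is_a_configuration_error(self, refs):
        tir1, _, _ = refs
        with pytest.raises(ReferenceConfigError, match="metadata"):
            anchor_residues(tir1.seq, tir1.seq, [(410, "W", "orientation")])
        with pytest.raises(ReferenceConfigError, match="outside"):
            anchor_residues(tir1.seq, tir1.seq, [(9999, "K", "orientation")])


# ---------------------------------------------------------------------------
# TIR1/AFB curation
# ---------------------------------------------------------------------------

class TestTirAfb:
    def test_reference_self_classifies_as_receptor(self, refs, cfg):
        tir1, _, _ = refs
        rep = classify_tir_afb(as_orf(tir1.seq), tir1, cfg)
        assert rep.verdict == "receptor"
        assert rep.n_pocket_conserved == len(rep.pocket_checks) == 11

    def test_cterminal_truncation_gives_incomplete(self, refs, cfg):
        tir1, _, _ = refs
        short = tir1.seq[: int(len(tir1.seq) * 0.6)]
        rep = classify_tir_afb(as_orf(short), tir1, cfg)
        assert rep.verdict == "incomplete"
        assert rep.lrr_coverage < cfg.lrr_coverage_threshold
        # coverage arithmetic: aligned LRR columns cannot exceed kept length
        lo, hi = tir1.lrr_span
        assert rep.lrr_coverage <= (len(short) - lo + 1) / (hi - lo + 1) + 1e-9

    def test_ac_substitution_reported_but_verdict_unchanged(self, refs, cfg):
        # an Asn->Asp swap at the first AC-critical position marks the check
        # non-conserved without revoking receptor status
        tir1, _, _ = refs
        pos, _ = tir1.ac_positions[0]
        edited = list(tir1.seq)
        edited[pos - 1] = "D"
        rep = classify_tir_afb(as_orf("".join(edited)), tir1, cfg)
        assert rep.verdict == "receptor"
        assert [c.conserved for c in rep.ac_checks] == [False, True, True]

    def test_incomplete_orf_rejected(self, refs, cfg):
        tir1, _, _ = refs
        orf = as_orf(tir1.seq)
        orf.complete = False
        rep = classify_tir_afb(orf, tir1, cfg)
        assert rep.verdict == "rejected" and "incomplete" in rep.reason


# ---------------------------------------------------------------------------
# ARF domain grammar
# ---------------------------------------------------------------------------

class TestDbdMotif:
    def test_exact_match(self):
        m = scan_dbd_motif("MKE" + "SACDEHGKLSQWR" + "VV")
        assert m.start == 4 and m.n_mismatch == 0 and m.substitutions == []

    def test_histidine_to_glycine_variant_recorded(self):
        m = scan_dbd_motif("MKE" + "SACDEGGKLSQWR" + "VV")
        assert m.n_mismatch == 1
        assert m.substitutions == [("H", 6, "G")]

    def test_absent_matches_window_scan_oracle(self):
        rng = random.Random(5)
        literals = ((0, "S"), (5, "H"), (6, "G"), (9, "S"), (12, "R"))
        for _ in range(40):
            seq = "".join(rng.choice(AA) for _ in range(200))
            best = min(
                (sum(seq[i + off] != exp for off, exp in literals)
                 for i in range(len(seq) - 12)), default=99)
            got = scan_dbd_motif(seq, max_mismatch=1)
            assert (got is None) == (best > 1)


class TestPb1:
    def test_reference_types_full(self, refs, cfg):
        _, _, pb1 = refs
        ev = type_pb1(pb1.seq, pb1, cfg)
        assert ev.pb1_type == "full" and ev.motif_i_lysine and ev.motif_ii_opca

    def test_lysine_edit_gives_type_i(self, refs, cfg):
        _, _, pb1 = refs
        edited = list(pb1.seq)
        edited[pb1.canonical_k_pos - 1] = "A"
        ev = type_pb1("".join(edited), pb1, cfg)
        assert ev.pb1_type == "typeI_OPCA_only"

    def test_unrelated_sequence_absent(self, refs, cfg):
        _, _, pb1 = refs
        rng = random.Random(6)
        seq = "".join(rng.choice(AA) for _ in range(90))
        ev = type_pb1(seq, pb1, cfg)
        assert not ev.present and ev.pb1_type == "absent"


class TestMdClassifier:
    def test_qsl_rich_is_activator(self):
        call, comp = classify_md("QQQSSSLLL" * 5, (0, 45))
        assert call == "activator"
        assert abs(sum(comp.values()) - 1.0) < 1e-9

    def test_pg_rich_without_q_is_repressor(self):
        call, _ = classify_md("SSLLPPGG" * 5, (0, 40))
        assert call == "repressor"

    def test_short_span_is_none(self):
        assert classify_md("QQQSSSLLL", (0, 9)) == ("none", None)

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            classify_md("QSL" * 20, (40, 10))

    def test_dirichlet_families_fully_separated(self):
        # planted compositions from a Q/S/L-concentrated and a P/G/S/L-
        # concentrated Dirichlet; the verbal composition rule must recover
        # every label at default thresholds
        rng = np.random.default_rng(7)
        idx = {a: i for i, a in enumerate(AA)}
        act_alpha = np.full(20, 0.2)
        for a in "QSL":
            act_alpha[idx[a]] = 30.0
        rep_alpha = np.full(20, 0.2)
        for a in "SLPG":
            rep_alpha[idx[a]] = 20.0
        rep_alpha[idx["Q"]] = 0.05
        for alpha, expected in ((act_alpha, "activator"), (rep_alpha, "repressor")):
            for _ in range(100):
                comp = rng.dirichlet(alpha)
                counts = rng.multinomial(120, comp)
                span = "".join(a * c for a, c in zip(AA, counts))
                call, _ = classify_md(span, (0, len(span)))
                assert call == expected

    def test_scale_invariance(self):
        span = "QQQSSSLLLAAC" * 4
        assert classify_md(span, (0, len(span)))[0] == classify_md(span * 3, (0, len(span) * 3))[0]


class TestArchitecture:
    @pytest.mark.parametrize("dbd,md,pb1,expected", [
        (True, True, True, "full_arf"),
        (True, False, False, "dbd_only"),
        (False, False, True, "pb1_only"),
        (True, True, False, "no_pb1"),
        (False, True, True, "no_dbd"),
    ])
    def test_mapping_table(self, dbd, md, pb1, expected):
        arch, role = assign_architecture(dbd, md, pb1)
        assert arch == expected and role

    def test_full_reference_is_full_arf(self, refs, cfg):
        _, arf, pb1 = refs
        rep = classify_arf(as_orf(arf.seq), arf, pb1, cfg)
        assert rep.architecture == "full_arf"
        assert rep.has_dbd and rep.has_dd and rep.pb1.pb1_type == "full"
        assert rep.dbd_motif is not None and rep.dbd_motif.n_mismatch == 0

    def test_pb1_fragment_is_pb1_only(self, refs, cfg):
        _, arf, pb1 = refs
        frag = arf.seq[arf.pb1_span[0] - 1:]
        rep = classify_arf(as_orf(frag), arf, pb1, cfg)
        assert rep.architecture == "pb1_only"
        assert "polymerisation" in rep.role_note
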