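"""TF/GO switch set algebra, the filter cascade, and patient profiles."""

import pytest

from conftest import make_ontology
from regswitch.formats import PatientGenotype
from regswitch.motifs import PerturbationCall
from regswitch.switches import (
    GOSwitch, SNPSwitchRecord, apply_filter_cascade, filter_by_enrichment,
    filter_contrast, filter_curated, go_switch_pairs, patient_profile,
    tf_switch,
)


def calls(rsid, status_by_tf):
    return [PerturbationCall(rsid=rsid, tf_name=tf, status=s)
            for tf, s in status_by_tf.items()]


class TestTFSwitch:
    def test_single_loss_with_multiple_gains(self):
        """An IRF-family loss accompanied by EGR1/TBX gains at one SNP."""
        sw = tf_switch("rs1", calls("rs1", {
            "IRF1": "lost", "EGR1": "gained", "TBX2": "gained",
            "TBX21": "gained",
        }))
        assert sw.lost == {"IRF1"}
        assert sw.gained == {"EGR1", "TBX2", "TBX21"}
        assert sw.shared == set()

    def test_loss_with_alternative_tfs(self):
        sw = tf_switch("rs2", calls("rs2", {
            "GFI1": "lost", "ATF2": "gained", "FOSB": "gained",
        }))
        assert sw.lost == {"GFI1"} and sw.gained == {"ATF2", "FOSB"}

    def test_unchanged_binding_is_shared_not_switched(self):
        sw = tf_switch("rs1", calls("rs1", {"X": "unchanged_bound"}))
        assert sw.gained == set() and sw.lost == set()
        assert sw.shared == {"X"}

    def test_set_algebra_invariant(self):
        sw = tf_switch("rs1", calls("rs1", {
            "A": "lost", "B": "gained", "C": "unchanged_bound", "D": "unbound",
        }))
        assert len(sw.healthy_tfs) == len(sw.lost) + len(sw.shared)
        assert len(sw.disease_tfs) == len(sw.gained) + len(sw.shared)

    def test_conflicting_duplicate_call_is_error(self):
        bad = calls("rs1", {"A": "lost"}) + calls("rs1", {"A": "gained"})
        with pytest.raises(ValueError, match="conflicting"):
            tf_switch("rs1", bad)

    def test_wrong_rsid_rejected(self):
        with pytest.raises(ValueError):
            tf_switch("rs1", calls("rs2", {"A": "lost"}))


class TestGOSwitchPairs:
    def test_single_pair(self):
        sw = tf_switch("rs1", calls("rs1", {"A": "lost", "C": "gained"}))
        pairs, shared = go_switch_pairs(sw, {"A": {"t1"}, "C": {"t2"}})
        assert [(p.healthy_term, p.disease_term) for p in pairs] == [("t1", "t2")]
        assert pairs[0].supporting_pairs == {("A", "C")}

    def test_same_term_both_sides_is_shared_not_switched(self):
        sw = tf_switch("rs1", calls("rs1", {"A": "lost", "C": "gained"}))
        pairs, shared = go_switch_pairs(sw, {"A": {"t1"}, "C": {"t1"}})
        assert pairs == [] and shared == {"t1"}

    def test_cross_product_counts_multiply(self):
        sw = tf_switch("rs1", calls("rs1", {
            "A": "lost", "B": "lost", "C": "gained", "D": "gained",
        }))
        pairs, _ = go_switch_pairs(sw, {
            "A": {"t1"}, "B": {"t2"}, "C": {"t3"}, "D": {"t4"},
        })
        got = {(p.healthy_term, p.disease_term) for p in pairs}
        assert got == {(h, d) for h in ("t1", "t2") for d in ("t3", "t4")}

    def test_shared_tf_terms_block_pairing(self):
        sw = tf_switch("rs1", calls("rs1", {
            "A": "lost", "C": "gained", "S": "unchanged_bound",
        }))
        pairs, shared = go_switch_pairs(
            sw, {"A": {"t1", "t9"}, "C": {"t2", "t9"}, "S": {"t1"}})
        # t9 in H∩D, t1 annotated to a shared TF: both excluded
        assert [(p.healthy_term, p.disease_term) for p in pairs] == []
        assert shared == {"t1", "t9"}

    def test_reduction_map_applied_before_pairing(self):
        sw = tf_switch("rs1", calls("rs1", {"A": "lost", "C": "gained"}))
        pairs, _ = go_switch_pairs(sw, {"A": {"t1"}, "C": {"t2"}},
                                   term_map={"t2": "t1"})
        assert pairs == []  # both sides collapse onto t1 -> shared

    def test_switch_to_itself_impossible(self):
        with pytest.raises(ValueError, match="itself"):
            GOSwitch("rs1", "t1", "t1", frozenset())


def mkswitch(h, d, rsid="rs1"):
    return GOSwitch(rsid=rsid, healthy_term=h, disease_term=d,
                    supporting_pairs=frozenset())


class TestFilters:
    def test_curated_keeps_either_side(self):
        sws = [mkswitch("t1", "t2"), mkswitch("t1", "t9")]
        kept = filter_curated(sws, {"t2"})
        assert [(s.healthy_term, s.disease_term) for s in kept] == [("t1", "t2")]
        assert filter_curated(sws, {"t1"}) == sws  # healthy side also counts

    def test_curated_disabled_is_identity(self):
        sws = [mkswitch("t1", "t2")]
        assert filter_curated(sws, set(), enabled=False) == sws

    def test_curated_enabled_with_empty_list_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            filter_curated([mkswitch("t1", "t2")], set())

    def _contrast_onto(self):
        anns = {"g1": ["child"], "g2": ["child"], "g3": ["parent"],
                "g4": ["other"],
                **{f"h{i}": ["far"] for i in range(16)}}
        return make_ontology({"child": ["parent"], "parent": ["root"],
                              "other": ["root"], "far": ["root"]}, anns)

    def test_contrast_keeps_disjoint_drops_similar(self):
        onto = self._contrast_onto()
        disjoint = mkswitch("child", "far")
        similar = mkswitch("child", "parent")
        kept = filter_contrast([disjoint, similar], onto, cutoff=0.5)
        assert [(s.healthy_term, s.disease_term) for s in kept] == \
            [("child", "far")]
        assert kept[0].similarity is not None and kept[0].similarity < 0.5

    def test_contrast_drops_unknown_terms_with_warning(self, caplog):
        onto = self._contrast_onto()
        kept = filter_contrast([mkswitch("child", "GO:404")], onto)
        assert kept == [] and "missing from ontology" in caplog.text

    def test_enrichment_disease_side_governs(self):
        sws = [mkswitch("t1", "t2")]
        assert filter_by_enrichment(sws, {"t2"}) == sws
        assert filter_by_enrichment(sws, {"t1"}) == []
        assert filter_by_enrichment(sws, {"t1"}, side="healthy") == sws
        assert filter_by_enrichment(sws, {"t1"}, side="either") == sws

    def test_enrichment_with_all_terms_is_identity(self):
        sws = [mkswitch("t1", "t2"), mkswitch("t3", "t4")]
        assert filter_by_enrichment(sws, {"t1", "t2", "t3", "t4"}) == sws

    def test_cascade_idempotent_and_shrinking(self):
        onto = self._contrast_onto()
        sws = [mkswitch("child", "far"), mkswitch("child", "parent"),
               mkswitch("far", "other")]
        args = dict(curated_terms={"far", "other"},
                    enriched_terms={"far", "other"})
        once = apply_filter_cascade(sws, onto, **args)
        twice = apply_filter_cascade(once, onto, **args)
        assert [(s.healthy_term, s.disease_term) for s in once] == \
            [(s.healthy_term, s.disease_term) for s in twice]
        assert set((s.healthy_term, s.disease_term) for s in once) <= \
            set((s.healthy_term, s.disease_term) for s in sws)


class TestPatientProfile:
    def _records(self):
        swA = tf_switch("rs1", calls("rs1", {"A": "lost", "B": "gained"}))
        swB = tf_switch("rs2", calls("rs2", {"B": "lost", "A": "gained"}))
        return {
            "rs1": SNPSwitchRecord("rs1", swA,
                                   [mkswitch("t1", "t2", "rs1")], frozenset()),
            "rs2": SNPSwitchRecord("rs2", swB,
                                   [mkswitch("t2", "t3", "rs2")], frozenset({"t9"})),
        }

    def test_non_carrier_has_empty_profile(self):
        patient = PatientGenotype("P1", "UC", {"rs1": 0, "rs2": 0})
        prof = patient_profile(patient, self._records())
        assert prof.active_rsids == frozenset()
        assert prof.term_states == {}

    def test_single_snp_gain_and_loss(self):
        patient = PatientGenotype("P1", "UC", {"rs1": 1, "rs2": 0})
        prof = patient_profile(patient, self._records())
        assert prof.term_states == {"t1": "lost", "t2": "gained"}

    def test_term_in_both_directions_across_snps(self):
        patient = PatientGenotype("P1", "UC", {"rs1": 2, "rs2": 1})
        prof = patient_profile(patient, self._records())
        assert prof.term_states["t2"] == "both"
        assert prof.term_states["t9"] == "shared"

    def test_dominant_vs_recessive_carrier_rule(self):
        patient = PatientGenotype("P1", "UC", {"rs1": 1, "rs2": 2})
        dominant = patient_profile(patient, self._records(), min_dosage=1)
        recessive = patient_profile(patient, self._records(), min_dosage=2)
        assert dominant.active_rsids == {"rs1", "rs2"}
        assert recessive.active_rsids == {"rs2"}
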