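"""DDE/D triad location, spacing labels, family assignment, signatures."""
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tesurvey import seqs
from tesurvey import synthetic as syn
from tesurvey.classify import (assign_family, check_signature,
                               classify_protein, is_intact,
                               locate_catalytic_triad, spacing_label)
from tesurvey.elements import ElementModel, Orf, TirPair, find_orf
from tesurvey.references import PLANTABLE


def _protein_with_triad(p1, p2, p3, third="D", length=400, seed=0):
    rng = np.random.default_rng(seed)
    prot = list(seqs.random_protein(length, rng).replace("D", "A")
                .replace("E", "A"))
    prot[p1], prot[p2], prot[p3] = "D", "D", third
    return "".join(prot)


class TestTriadLocation:
    def test_reference_recovers_its_own_triad(self, references):
        for ref in references:
            res = locate_catalytic_triad(ref.protein, references)
            assert res.ok
            assert res.positions == ref.triad
            assert res.reference.family == ref.family

    def test_mutated_transposase_keeps_triad(self, references):
        ref = next(r for r in references if r.family == "maT")
        rng = np.random.default_rng(2)
        prot = list(ref.protein)
        # 10% substitutions away from the triad
        triad = set(ref.triad)
        sites = [i for i in range(len(prot)) if i not in triad]
        for i in rng.choice(sites, size=len(prot) // 10, replace=False):
            prot[i] = "ACFGHIKLMNPQRSTVWY"[rng.integers(18)]
        res = locate_catalytic_triad("".join(prot), references)
        assert res.ok and res.positions == ref.triad
        assert res.reference.family == "maT"

    def test_mutated_triad_residue_is_unclassifiable(self, references):
        ref = next(r for r in references if r.family == "Tc1")
        prot = list(ref.protein)
        prot[ref.triad[0]] = "A"
        res = locate_catalytic_triad("".join(prot), references)
        assert not res.ok
        assert "not D/E" in res.reason

    def test_score_floor_failure_reported_not_fatal(self, references):
        rng = np.random.default_rng(3)
        junk = seqs.random_protein(150, rng)
        res = locate_catalytic_triad(junk, references, score_floor=500.0)
        assert not res.ok

    def test_short_protein_rejected(self, references):
        with pytest.raises(ValueError):
            locate_catalytic_triad("MKV" * 10, references)


class TestSpacingLabel:
    def test_dd34d_convention(self):
        prot = _protein_with_triad(150, 250, 284)
        lab = spacing_label((150, 250, 284), prot)
        assert lab.label == "DD34D" and lab.n == 34 and lab.third == "D"

    @pytest.mark.parametrize("third,n,expect", [
        ("E", 34, "DD34E"), ("E", 33, "DD33E"), ("D", 41, "DD41D")])
    def test_letter_and_spacing_combinations(self, third, n, expect):
        prot = _protein_with_triad(100, 200, 200 + n, third=third)
        assert spacing_label((100, 200, 200 + n), prot).label == expect

    def test_invalid_first_residues_raise(self):
        prot = _protein_with_triad(100, 200, 234)
        bad = "A" + prot[1:]
        bad = bad[:100] + "A" + bad[101:]
        with pytest.raises(ValueError):
            spacing_label((100, 200, 234), bad)

    @given(st.integers(min_value=20, max_value=60),
           st.sampled_from("DE"))
    def test_label_roundtrip(self, n, letter):
        prot = _protein_with_triad(100, 200, 200 + n, third=letter, seed=n)
        lab = spacing_label((100, 200, 200 + n), prot)
        assert lab.label == f"DD{lab.n}{lab.third}"
        assert (lab.n, lab.third) == (n, letter)


class TestAssignFamily:
    def test_known_labels_map_to_families(self, references):
        ref_by = {r.family: r for r in references}
        cases = [(34, "D", "mariner", ref_by["mariner"]),
                 (37, "D", "maT", ref_by["maT"]),
                 (34, "E", "Tc1", ref_by["Tc1"]),
                 (38, "E", "IT", ref_by["IT"]),
                 (39, "D", "GT", ref_by["GT"])]
        for n, letter, family, ref in cases:
            prot = _protein_with_triad(100, 200, 200 + n, third=letter)
            lab = assign_family(spacing_label((100, 200, 200 + n), prot), ref)
            assert lab.family == family

    def test_drifted_dd40d_maps_to_vs(self, references):
        vs = next(r for r in references if r.family == "VS")
        prot = _protein_with_triad(100, 200, 240)
        lab = assign_family(spacing_label((100, 200, 240), prot), vs)
        assert lab.family == "VS" and "drifted" in lab.notes

    def test_drifted_dd33e_maps_to_best_reference(self, references):
        tig = next(r for r in references if r.family == "Tigger")
        prot = _protein_with_triad(100, 200, 233, third="E")
        lab = assign_family(spacing_label((100, 200, 233), prot), tig)
        assert lab.family == "Tigger" and "drifted" in lab.notes

    def test_out_of_table_label_is_novel(self):
        prot = _protein_with_triad(100, 200, 252)
        lab = assign_family(spacing_label((100, 200, 252), prot), None)
        assert lab.family == "novel:DD52D"

    def test_reference_order_never_changes_assignment(self, references):
        prog = syn.build_progenitor(syn.default_spec("Fot"))
        rng = np.random.default_rng(4)
        codes = seqs.mutate_k2p_exact(prog.codes, 0.08, rng,
                                      protected=prog.protected,
                                      orf=prog.orf)
        protein = find_orf(seqs.codes_to_seq(codes)).protein
        families = set()
        shuffled = list(references)
        for s in range(5):
            random.Random(s).shuffle(shuffled)
            label, _ = classify_protein(protein, shuffled)
            families.add(label.family)
        assert families == {"Fot"}


class TestPlantedAccuracy:
    @pytest.mark.parametrize("family", PLANTABLE)
    def test_all_families_classified_correctly(self, family, references):
        prog = syn.build_progenitor(syn.default_spec(family))
        rng = np.random.default_rng(hash(family) % 2**31)
        for _ in range(3):
            codes = seqs.mutate_k2p_exact(prog.codes, 0.10, rng,
                                          protected=prog.protected,
                                          orf=prog.orf)
            protein = find_orf(seqs.codes_to_seq(codes)).protein
            label, _ = classify_protein(protein, references)
            assert label is not None and label.family == family


class TestSignature:
    def test_maT_progenitor_passes(self):
        prog = syn.build_progenitor(syn.default_spec("maT"))
        assert check_signature(prog.seq, "maT") == "pass"

    def test_gt_progenitor_passes(self):
        prog = syn.build_progenitor(syn.default_spec("GT"))
        assert prog.seq.startswith("CTCCC")
        assert check_signature(prog.seq, "GT") == "pass"

    def test_it_accepts_both_pentanucleotides(self):
        assert check_signature("CACTA" + "G" * 100, "IT") == "pass"
        assert check_signature("CACTG" + "G" * 100, "IT") == "pass"
        assert check_signature("CACTT" + "G" * 100, "IT") == "fail"

    def test_mariner_has_no_signature(self):
        assert check_signature("AAAAA" + "G" * 100, "mariner") \
            == "not-applicable"

    def test_boundaryless_model_not_applicable(self):
        model = ElementModel("e", "sp", "c1", None, None, "+", None, None,
                             None)
        assert check_signature(model, "maT") == "not-applicable"


class TestIntactRule:
    def _model(self, orf_aa, with_tirs, frameshift_free=True):
        orf = Orf(0, orf_aa * 3, "+", 0, "M" * orf_aa,
                  frameshift_free=frameshift_free) if orf_aa else None
        tir = TirPair((0, 30), (1370, 1400), "A" * 30, "T" * 30, 30,
                      100.0, 60.0) if with_tirs else None
        return ElementModel("e", "sp", "c1", 0, 1400, "+", tir, None, orf)

    def test_long_orf_with_tirs_is_intact(self):
        assert is_intact(self._model(340, True))

    def test_orf_only_is_not_intact(self):
        assert not is_intact(self._model(340, False))

    def test_short_orf_is_not_intact(self):
        assert not is_intact(self._model(250, True))

    def test_frameshifted_orf_is_not_intact(self):
        assert not is_intact(self._model(340, True, frameshift_free=False))
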