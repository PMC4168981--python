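"""Fingerprints, Tanimoto metrics, reaction operators and GoF calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncoflux.gof_chem import (
    ALPHA_KG_SMILES,
    HYDROXYGLUTARATE_SMILES,
    ISOCITRATE_SMILES,
    Fingerprint,
    SmilesError,
    apply_operator,
    call_gof_pairs,
    canonical_smiles,
    compound_fingerprint,
    default_reaction_cutoff,
    dominant_substructure,
    enumerate_synthetic_reactions,
    load_cofactor_formulas,
    load_operators,
    mass_balanced,
    molecular_formula,
    reaction_fingerprint,
    reaction_tanimoto,
    select_candidates,
    tanimoto,
)
from oracles import bit_loop_tanimoto, explicit_atom_counts


@pytest.fixture(scope="module")
def operators():
    return {op.name: op for op in load_operators()}


@pytest.fixture(scope="module")
def cofactors():
    return load_cofactor_formulas()


class TestCompoundFingerprint:
    def test_canonicalization_invariance(self):
        a = compound_fingerprint("CCO")
        b = compound_fingerprint("OCC")
        assert np.array_equal(a.bits, b.bits)

    def test_methane_sparse_but_nonzero(self):
        fp = compound_fingerprint("C")
        assert 0 < fp.popcount <= 1024

    def test_popcount_bounded(self, compound_library):
        for smiles in compound_library["smiles"]:
            fp = compound_fingerprint(smiles)
            assert len(fp) == 1024 and fp.popcount <= 1024

    def test_invalid_smiles_rejected(self):
        with pytest.raises(SmilesError):
            compound_fingerprint("not-a-molecule(((")


class TestTanimoto:
    def test_identity_dissimilarity_zero(self, compound_library):
        for smiles in compound_library["smiles"]:
            fp = compound_fingerprint(smiles)
            sim, diss = tanimoto(fp, fp)
            assert sim == 1.0 and diss == 0.0

    def test_bit_arithmetic_example(self):
        a = Fingerprint(bits=np.array([1, 1, 0, 0], dtype=bool))
        b = Fingerprint(bits=np.array([1, 0, 1, 0], dtype=bool))
        sim, diss = tanimoto(a, b)
        assert sim == pytest.approx(1 / 3) and diss == pytest.approx(2 / 3)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.lists(st.booleans(), min_size=16, max_size=16),
        b=st.lists(st.booleans(), min_size=16, max_size=16),
    )
    def test_matches_bit_loop_oracle_and_invariants(self, a, b):
        fa = Fingerprint(bits=np.array(a, dtype=bool))
        fb = Fingerprint(bits=np.array(b, dtype=bool))
        sim, diss = tanimoto(fa, fb)
        assert (sim, diss) == bit_loop_tanimoto(np.array(a), np.array(b))
        assert sim + diss == pytest.approx(1.0)
        assert tanimoto(fb, fa) == (sim, diss)

    def test_length_mismatch_rejected(self):
        a = Fingerprint(bits=np.zeros(8, dtype=bool))
        b = Fingerprint(bits=np.zeros(4, dtype=bool))
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto(a, b)


class TestReactionFingerprint:
    def test_order_invariance(self):
        a = reaction_fingerprint(["CCO", "CC(=O)O"], ["CCOC(C)=O"])
        b = reaction_fingerprint(["CC(=O)O", "OCC"], ["CCOC(C)=O"])
        assert np.array_equal(a.concatenated.bits, b.concatenated.bits)

    def test_product_difference_localised_to_product_slots(self):
        a = reaction_fingerprint(["CCO"], ["CC=O"])
        b = reaction_fingerprint(["CCO"], ["CCC=O"])  # extra methyl on product
        for i in range(4):  # substrate slots identical
            assert np.array_equal(a.segments[i].bits, b.segments[i].bits)
        _, diss = reaction_tanimoto(a, b)
        assert diss > 0

    def test_empty_product_side_is_zero(self):
        fp = reaction_fingerprint(["CCO"], [])
        assert all(s.popcount == 0 for s in fp.segments[4:])

    def test_more_than_four_compounds_rejected(self):
        with pytest.raises(ValueError, match="cofactors"):
            reaction_fingerprint(["C", "CC", "CCC", "CCCC", "CCCCC"], ["C"])


class TestOperators:
    def test_alcohol_oxidation_of_2_propanol_gives_acetone(self, operators, cofactors):
        out = apply_operator(operators["alcohol_oxidation"], "CC(O)C", cofactors)
        assert [r.product for r in out] == [canonical_smiles("CC(C)=O")]
        assert out[0].balanced

    def test_no_match_on_alkane(self, operators, cofactors):
        assert apply_operator(operators["alcohol_oxidation"], "CCCC", cofactors) == []

    def test_two_distinct_sites_give_two_products(self, operators, cofactors):
        # glycerol: primary and secondary alcohols oxidise to distinct products
        out = apply_operator(operators["alcohol_oxidation"], "OCC(O)CO", cofactors)
        assert len({r.product for r in out}) == 2

    def test_balanced_flag_matches_independent_audit(self, operators, cofactors, compound_library):
        from collections import Counter

        checked = 0
        for op in operators.values():
            for smiles in compound_library["smiles"]:
                for rxn in apply_operator(op, smiles, cofactors, balance_filter=False):
                    left = explicit_atom_counts(rxn.substrate)
                    right = explicit_atom_counts(rxn.product)
                    for cid in op.cofactor_reactants:
                        left = left + Counter(cofactors[cid])
                    for cid in op.cofactor_products:
                        right = right + Counter(cofactors[cid])
                    assert rxn.balanced == (left == right), (op.id, rxn.product)
                    checked += 1
        assert checked > 50

    def test_unbalanced_reactions_dropped_by_filter(self, operators, cofactors):
        from dataclasses import replace

        broken = replace(operators["alcohol_oxidation"], cofactor_products=())
        assert apply_operator(broken, "CC(O)C", cofactors, balance_filter=True) == []
        kept = apply_operator(broken, "CC(O)C", cofactors, balance_filter=False)
        assert kept and not kept[0].balanced


class TestCandidateSelection:
    def test_cutoff_zero_only_exact_matches(self, compound_library):
        out = select_candidates(ALPHA_KG_SMILES, compound_library, tc_cutoff=0.0)
        assert out.empty  # the native structure itself is excluded

    def test_cutoff_one_returns_whole_library_minus_exclusions(self, compound_library):
        out = select_candidates(ALPHA_KG_SMILES, compound_library, tc_cutoff=1.0)
        assert len(out) == len(compound_library) - 1  # minus the native itself

    def test_analog_retained_decoys_excluded_at_default_cutoff(self, compound_library):
        out = select_candidates(ALPHA_KG_SMILES, compound_library, tc_cutoff=0.6)
        ids = set(out["compound_id"])
        assert "2_hydroxyglutarate" in ids
        decoys = set(compound_library.loc[compound_library["role"] == "decoy", "compound_id"])
        assert not ids & decoys

    def test_empty_library_rejected(self, compound_library):
        with pytest.raises(ValueError, match="empty"):
            select_candidates(ALPHA_KG_SMILES, compound_library.iloc[:0], 0.5)


class TestEnumeration:
    def test_counting_bound(self, compound_library, operators):
        cands = select_candidates(ALPHA_KG_SMILES, compound_library, 0.6)
        res = enumerate_synthetic_reactions(cands, [operators["alcohol_oxidation"]])
        assert len(res.reactions) <= len(cands)

    def test_duplicates_collapsed_on_substrate_product_ec3(self, compound_library, operators):
        cands = select_candidates(ALPHA_KG_SMILES, compound_library, 0.6)
        doubled = [operators["alcohol_oxidation"], operators["alcohol_oxidation"]]
        once = enumerate_synthetic_reactions(cands, doubled[:1])
        twice = enumerate_synthetic_reactions(cands, doubled)
        assert len(once.reactions) == len(twice.reactions)

    def test_cap_excludes_native_reaction(self, compound_library, operators):
        cands = select_candidates(ALPHA_KG_SMILES, compound_library, 1.0)
        res = enumerate_synthetic_reactions(
            cands, list(operators.values()), max_activities=3
        )
        assert res.capped and res.reactions == [] and res.n_raw > 3


class TestGofCalling:
    def test_native_reaction_has_zero_dissimilarity_and_is_saved(self, operators, cofactors):
        synthetic = apply_operator(
            operators["alcohol_oxidation"], HYDROXYGLUTARATE_SMILES, cofactors
        )
        akg = canonical_smiles(ALPHA_KG_SMILES)
        pairs = call_gof_pairs(
            [HYDROXYGLUTARATE_SMILES], [akg],
            [r for r in synthetic if r.product == akg],
        )
        assert pairs[0].reaction_tcdiss == 0.0 and pairs[0].saved

    def test_calibration_pair_saved_at_default_cutoff(self, operators, cofactors):
        synthetic = apply_operator(
            operators["alcohol_oxidation"], HYDROXYGLUTARATE_SMILES, cofactors
        )
        pairs = call_gof_pairs([ISOCITRATE_SMILES], [ALPHA_KG_SMILES], synthetic)
        akg = canonical_smiles(ALPHA_KG_SMILES)
        planted = [p for p in pairs if p.synthetic.product == akg]
        assert planted and planted[0].saved
        assert planted[0].reaction_tcdiss <= default_reaction_cutoff()

    def test_dissimilar_reaction_not_saved(self, operators, cofactors):
        synthetic = apply_operator(operators["alcohol_oxidation"], "CCCCCCCCO", cofactors)
        pairs = call_gof_pairs([ISOCITRATE_SMILES], [ALPHA_KG_SMILES], synthetic)
        assert pairs and not any(p.saved for p in pairs)

    def test_degenerate_native_fingerprint_rejected(self):
        # an empty structure has an all-zero fingerprint
        with pytest.raises(ValueError, match="degenerate"):
            call_gof_pairs([""], [""], [])


class TestDominantSubstructure:
    def test_alkanols_share_hydroxyl_chain(self):
        out = dominant_substructure(
            ["CCCO", "CCCCO", "CCCCCO", "CCCCCCO"], support_threshold=1.0
        )
        assert out.support == 1.0 and out.dominant
        assert "#8" in out.mcs_smarts or "O" in out.mcs_smarts

    def test_disjoint_chemotypes_no_dominant_pattern(self):
        out = dominant_substructure(
            ["CCCCCC", "OCC1OC(O)C(O)C(O)C1O", "c1ccccc1"], support_threshold=0.9
        )
        assert not out.dominant

    def test_identical_compounds_mcs_is_the_compound(self):
        out = dominant_substructure(["CCO", "CCO", "OCC"])
        assert out.support == 1.0 and out.n_atoms == 3

    def test_single_compound_degenerate(self):
        out = dominant_substructure(["CCO"])
        assert out.degenerate and out.support == 1.0


def test_formula_parsing_agrees_with_explicit_atoms(compound_library):
    for smiles in compound_library["smiles"]:
        assert molecular_formula(smiles) == explicit_atom_counts(smiles)
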