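"""Flux-space-shift statistics, LoF calling, and the validation analyses."""

import numpy as np
import pandas as pd
import pytest
from cobra import Metabolite, Model, Reaction

from oncoflux.flux_sampling import (
    FluxSampleSet,
    filter_zero_and_loop_reactions,
    normalize_fluxes,
)
from oncoflux.fss_lof import (
    AccuracyResult,
    build_deficient_model,
    call_lof_oncometabolites,
    essentiality_enrichment,
    flux_change,
    flux_expression_accuracy,
    significant_changes,
)
from oracles import brute_overlap_p, exact_hypergeom_upper_tail


def norm_set(points, reactions=None):
    points = np.asarray(points, dtype=float)
    reactions = tuple(reactions or (f"r{i}" for i in range(points.shape[1])))
    return FluxSampleSet(points=points, reactions=reactions, normalized=True)


@pytest.fixture(scope="module")
def filtered_pair(toy_model, toy_samples, sdh_deficient_samples):
    retained = filter_zero_and_loop_reactions(
        sdh_deficient_samples, toy_samples, toy_model
    )
    a = normalize_fluxes(sdh_deficient_samples.subset(retained))
    b = normalize_fluxes(toy_samples.subset(retained))
    return a, b


@pytest.fixture(scope="module")
def sdh_changes(filtered_pair):
    a, b = filtered_pair
    return flux_change(a, b, min_points=500)


class TestFluxChange:
    def test_identical_sets_give_p_one(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(300, 3))
        out = flux_change(norm_set(pts), norm_set(pts.copy()), min_points=100)
        assert (out["p_value"] == 1.0).all()

    def test_disjoint_supports_significant_and_down(self):
        rng = np.random.default_rng(1)
        a = norm_set(rng.uniform(1, 2, size=(400, 1)))
        b = norm_set(rng.uniform(3, 4, size=(400, 1)))
        out = flux_change(a, b, min_points=100)
        assert out.loc[0, "p_value"] == pytest.approx(1 / 400**2)
        assert out.loc[0, "direction"] == "down"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, size=500)
        b = rng.normal(1.0, 1.0, size=500)  # 1-sigma shift
        out = flux_change(norm_set(a[:, None]), norm_set(b[:, None]), min_points=100)
        assert out.loc[0, "p_value"] == pytest.approx(brute_overlap_p(a, b), abs=0.005)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a = norm_set(rng.normal(0, 1, size=(300, 2)))
        b = norm_set(rng.normal(0.5, 1, size=(300, 2)))
        ab = flux_change(a, b, min_points=100)
        ba = flux_change(b, a, min_points=100)
        assert np.allclose(ab["p_value"], ba["p_value"])
        assert (ab["direction"] != ba["direction"]).all() or (
            ab["fold_change"] == 1.0
        ).all()

    def test_constant_equal_columns_give_p_one(self):
        a = norm_set(np.full((200, 1), 0.25))
        b = norm_set(np.full((200, 1), 0.25))
        out = flux_change(a, b, min_points=100)
        assert out.loc[0, "p_value"] == 1.0

    def test_q_values_monotone_in_p(self, sdh_changes):
        ordered = sdh_changes.sort_values("p_value")
        assert ordered["q_value"].is_monotonic_increasing
        assert (sdh_changes["q_value"] >= sdh_changes["p_value"] - 1e-12).all()
        alpha = 0.01
        assert (sdh_changes["q_value"] <= alpha).sum() <= (
            sdh_changes["p_value"] <= alpha
        ).sum()

    def test_unnormalized_inputs_rejected(self, toy_samples):
        with pytest.raises(ValueError, match="normalized"):
            flux_change(toy_samples, toy_samples)

    def test_low_point_count_warns(self):
        rng = np.random.default_rng(4)
        a = norm_set(rng.normal(size=(50, 1)))
        with pytest.warns(UserWarning, match="sample points"):
            flux_change(a, a, min_points=1000)


class TestDeficientModels:
    def test_redundant_gene_stays_feasible(self, toy_model):
        verdict = build_deficient_model(toy_model, "g_glyc1")
        assert verdict.feasible
        assert verdict.deficient_objective == pytest.approx(
            verdict.wild_type_objective
        )

    def test_essential_gene_gets_infeasible_verdict(self, toy_model):
        verdict = build_deficient_model(toy_model, "g_cs", optimality_fraction=0.9)
        assert not verdict.feasible

    def test_planted_gene_feasible_at_sampling_bound(self, toy_model):
        for gene in ("g_sdh", "g_fh"):
            verdict = build_deficient_model(toy_model, gene)
            assert verdict.feasible
            assert verdict.deficient_objective >= 0.9 * verdict.wild_type_objective


class TestLofCalling:
    def test_planted_sdh_metabolites_called(self, sdh_changes, toy_model):
        calls = call_lof_oncometabolites(sdh_changes, "g_sdh", toy_model)
        assert {"succ", "fum"} <= set(calls["base_metabolite"])

    def test_currency_metabolites_excluded(self, sdh_changes, toy_model):
        calls = call_lof_oncometabolites(sdh_changes, "g_sdh", toy_model)
        assert not {"nadh", "co2", "atp", "adp", "o2"} & set(calls["base_metabolite"])

    def test_compartment_tags_present(self, sdh_changes, toy_model):
        calls = call_lof_oncometabolites(sdh_changes, "g_sdh", toy_model)
        assert set(calls["compartment"]) <= {"c", "m", "e"}

    def test_no_significant_neighbors_empty_calls(self, sdh_changes, toy_model):
        relaxed = sdh_changes.copy()
        relaxed["p_value"] = 1.0
        calls = call_lof_oncometabolites(relaxed, "g_sdh", toy_model)
        assert calls.empty

    def test_gene_without_reactions_rejected(self, sdh_changes, toy_model):
        with pytest.raises(KeyError):
            call_lof_oncometabolites(sdh_changes, "missing_gene", toy_model)


def accuracy_fixture():
    """10 one-gene reactions with known up/down shifts and expression deltas."""
    model = Model("acc")
    mets = [Metabolite(f"m{i}_c", compartment="c") for i in range(10)]
    rxns = []
    for i, met in enumerate(mets):
        r = Reaction(f"R{i}"); r.add_metabolites({met: -1}); r.bounds = (0, 10)
        r.gene_reaction_rule = f"g{i}"
        rxns.append(r)
    model.add_reactions(rxns)
    changes = pd.DataFrame(
        {
            "reaction": [f"R{i}" for i in range(10)],
            "p_value": [1e-6] * 10,
            "q_value": [1e-5] * 10,
            "fold_change": [4.0 if i < 5 else 0.25 for i in range(10)],
            "direction": ["up" if i < 5 else "down" for i in range(10)],
        }
    )
    # 8 of 10 deltas agree with the predicted direction
    delta = pd.Series(
        {f"g{i}": (1.0 if i < 5 else -1.0) * (-1 if i in (0, 9) else 1) for i in range(10)}
    )
    return model, changes, delta


class TestAccuracy:
    def test_eight_of_ten_concordant(self):
        model, changes, delta = accuracy_fixture()
        res = flux_expression_accuracy(changes, delta, model, n_permutations=2000, seed=0)
        assert res.accuracy == pytest.approx(0.8)
        assert res.tp + res.tn + res.fp + res.fn == 10

    def test_perfect_concordance_has_tiny_permutation_p(self):
        model, changes, delta = accuracy_fixture()
        aligned = delta.abs() * np.where(
            [changes.set_index("reaction").loc[f"R{i}", "direction"] == "up" for i in range(10)],
            1.0, -1.0,
        )
        res = flux_expression_accuracy(
            changes, pd.Series(aligned.values, index=delta.index), model,
            n_permutations=5000, seed=1,
        )
        assert res.accuracy == 1.0
        assert res.permutation_p < 0.01

    def test_ambiguous_gene_excluded(self):
        model, changes, delta = accuracy_fixture()
        model.reactions.R1.gene_reaction_rule = "g0"  # g0 now up (R0) and ... R1 up too
        changes.loc[1, "direction"] = "down"
        changes.loc[1, "fold_change"] = 0.25
        res = flux_expression_accuracy(changes, delta, model, n_permutations=100, seed=0)
        assert res.tp + res.tn + res.fp + res.fn == 8  # g0 and g1's reaction dropped

    def test_isoenzyme_reaction_excluded(self):
        model, changes, delta = accuracy_fixture()
        model.reactions.R0.gene_reaction_rule = "g0 or g99"
        res = flux_expression_accuracy(changes, delta, model, n_permutations=100, seed=0)
        assert res.tp + res.tn + res.fp + res.fn == 9

    def test_empty_predictions_rejected(self):
        model, changes, delta = accuracy_fixture()
        changes["p_value"] = 1.0
        with pytest.raises(ValueError, match="accuracy undefined"):
            flux_expression_accuracy(changes, delta, model, n_permutations=10)


class TestEssentialityEnrichment:
    def test_matches_exact_combinatorial_sum(self):
        universe = {f"g{i}" for i in range(20)}
        in_vivo = {f"g{i}" for i in range(5)}
        in_silico = {"g0", "g1", "g2", "g10"}
        res = essentiality_enrichment(in_silico, in_vivo, universe)
        expected = exact_hypergeom_upper_tail(3, 20, 5, 4)
        assert res.p_value == pytest.approx(expected, rel=1e-12)
        from scipy.stats import norm

        assert res.z_score == pytest.approx(norm.isf(expected))

    def test_zero_overlap_gives_nonpositive_z(self):
        universe = {f"g{i}" for i in range(20)}
        res = essentiality_enrichment({"g10", "g11"}, {"g0", "g1", "g2"}, universe)
        assert res.z_score <= 0

    def test_saturation_p_is_one(self):
        universe = {f"g{i}" for i in range(10)}
        res = essentiality_enrichment(universe, universe, universe)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_in_silico_set(self):
        universe = {"a", "b", "c"}
        res = essentiality_enrichment(set(), {"a"}, universe)
        assert res.p_value == 1.0 and res.overlap == 0

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            essentiality_enrichment({"x"}, set(), {"a"})
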