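"""End-to-end orchestration of the LoF and GoF oncometabolite arms.

``run_lof_arm`` chains: synthetic inputs -> mutation screen -> presence
calls -> GIMME cancer/normal context models (biomass objective for cancer,
scaled biomass+ATP objective for normal) -> enzyme-deficient cancer models
-> ACHR sampling -> loop/zero filtering -> normalisation -> flux-space
shift statistics -> metabolite calls.

``run_gof_arm`` chains: mutation screen -> native reactions of GoF genes
-> analog candidate selection from the compound library -> operator
enumeration with mass balance -> promiscuity-pair calling -> dominant
substructure summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import pandas as pd

from oncoflux import synthetic_data
from oncoflux.context_models import (
    PresenceCallVector,
    apply_medium,
    gimme_extract,
    presence_calls,
    scale_objective,
    toy_medium,
)
from oncoflux.flux_sampling import (
    FluxSampleSet,
    achr_sample,
    filter_zero_and_loop_reactions,
    mixed_fraction,
    normalize_fluxes,
)
from oncoflux.fss_lof import (
    DeficiencyVerdict,
    build_deficient_model,
    call_lof_oncometabolites,
    flux_change,
)
from oncoflux.gof_chem import (
    PromiscuityPair,
    SubstructureSummary,
    call_gof_pairs,
    canonical_smiles,
    dominant_substructure,
    enumerate_synthetic_reactions,
    load_cofactor_formulas,
    load_operators,
    select_candidates,
)
from oncoflux.mutation_screen import run_screen
from oncoflux.synthetic_data import SyntheticScenario

#: currency bases never used as GoF query compounds
_GOF_CURRENCY_BASES = frozenset({"atp", "adp", "nad", "nadh", "h", "h2o", "co2", "o2", "pi"})


@dataclass
class LofGeneResult:
    gene: str
    verdict: DeficiencyVerdict
    changes: pd.DataFrame | None
    predictions: pd.DataFrame | None

    @property
    def called_bases(self) -> set[str]:
        if self.predictions is None or self.predictions.empty:
            return set()
        return set(self.predictions["base_metabolite"])


@dataclass
class LofArmResult:
    scenario: SyntheticScenario
    screen: pd.DataFrame
    cancer_model: cobra.Model
    normal_model: cobra.Model
    normal_samples: FluxSampleSet
    per_gene: dict[str, LofGeneResult] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def _context_models(
    scenario: SyntheticScenario, model: cobra.Model
) -> tuple[cobra.Model, cobra.Model, PresenceCallVector, PresenceCallVector]:
    cancer_expr, normal_expr = synthetic_data.generate_expression(scenario, model)
    calls_cancer = presence_calls(cancer_expr, scenario.detection_threshold)
    calls_normal = presence_calls(normal_expr, scenario.detection_threshold)
    cancer_ctx = gimme_extract(model, calls_cancer).model  # biomass objective
    normal_objective = scale_objective(model)  # biomass + ATP demand, a = b = 1
    normal_ctx = gimme_extract(model, calls_normal, objective=normal_objective).model
    return cancer_ctx, normal_ctx, calls_cancer, calls_normal


def run_lof_arm(
    scenario: SyntheticScenario,
    n_points: int = 1000,
    thinning: int = 25,
    optimality_fraction: float = 0.9,
    p_cut: float = 1e-3,
    fold_cut: float = 2.0,
) -> LofArmResult:
    """Run the complete loss-of-function arm on a synthetic scenario."""
    scenario.validate()
    base = synthetic_data.generate_toy_model(scenario)
    base = apply_medium(base, toy_medium())
    mutations = synthetic_data.generate_mutations(scenario, base)
    screen = run_screen(mutations, base, scenario.n_samples_cancer)
    lof_genes = sorted(screen.loc[screen["selected"] & screen["arm_lof"], "gene"])

    cancer_ctx, normal_ctx, _, _ = _context_models(scenario, base)
    normal_samples = achr_sample(
        normal_ctx,
        n_points=n_points,
        thinning=thinning,
        optimality_fraction=optimality_fraction,
        seed=scenario.rng(41).integers(2**31),
    )

    result = LofArmResult(
        scenario=scenario,
        screen=screen,
        cancer_model=cancer_ctx,
        normal_model=normal_ctx,
        normal_samples=normal_samples,
        diagnostics={"normal_mixed_fraction": mixed_fraction(normal_samples)},
    )

    for offset, gene in enumerate(lof_genes):
        verdict = build_deficient_model(cancer_ctx, gene, optimality_fraction)
        if not verdict.feasible:
            result.per_gene[gene] = LofGeneResult(gene, verdict, None, None)
            continue
        deficient_samples = achr_sample(
            verdict.model,
            n_points=n_points,
            thinning=thinning,
            optimality_fraction=optimality_fraction,
            seed=scenario.rng(50 + offset).integers(2**31),
        )
        retained = filter_zero_and_loop_reactions(
            deficient_samples, normal_samples, cancer_ctx
        )
        a = normalize_fluxes(deficient_samples.subset(retained))
        b = normalize_fluxes(normal_samples.subset(retained))
        changes = flux_change(a, b, min_points=min(1000, n_points))
        predictions = call_lof_oncometabolites(
            changes, gene, cancer_ctx, p_cut=p_cut, fold_cut=fold_cut
        )
        result.per_gene[gene] = LofGeneResult(gene, verdict, changes, predictions)
    return result


@dataclass
class GofGeneResult:
    gene: str
    native_reaction: str
    native_substrates: tuple[str, ...]
    native_products: tuple[str, ...]
    pairs: list[PromiscuityPair]
    capped: bool
    substrate_summary: SubstructureSummary | None
    product_summary: SubstructureSummary | None

    @property
    def saved_pairs(self) -> list[PromiscuityPair]:
        return [p for p in self.pairs if p.saved]


@dataclass
class GofArmResult:
    scenario: SyntheticScenario
    screen: pd.DataFrame
    per_reaction: list[GofGeneResult] = field(default_factory=list)


def _native_participants(
    rxn: cobra.Reaction, smiles_by_base: dict[str, str]
) -> tuple[list[str], list[str]]:
    def side(mets) -> list[str]:
        out = []
        for met in mets:
            base = met.id.rsplit("_", 1)[0]
            if base in _GOF_CURRENCY_BASES:
                continue
            if base in smiles_by_base:
                out.append(smiles_by_base[base])
        return out

    return side(rxn.reactants), side(rxn.products)


def run_gof_arm(
    scenario: SyntheticScenario,
    substrate_cutoff: float = 0.6,
    reaction_tc_cutoff: float | None = None,
    max_activities: int = 30_000,
) -> GofArmResult:
    """Run the complete gain-of-function arm on a synthetic scenario."""
    scenario.validate()
    base = synthetic_data.generate_toy_model(scenario)
    mutations = synthetic_data.generate_mutations(scenario, base)
    screen = run_screen(mutations, base, scenario.n_samples_cancer)
    gof_genes = sorted(screen.loc[screen["selected"] & screen["arm_gof"], "gene"])

    library = synthetic_data.generate_compound_library(scenario)
    smiles_by_base = {
        row.metabolite: row.smiles for row in library.itertuples() if row.metabolite
    }
    operators = load_operators()
    cofactor_ids = set(load_cofactor_formulas())

    result = GofArmResult(scenario=scenario, screen=screen)
    for gene in gof_genes:
        for rxn in sorted(base.genes.get_by_id(gene).reactions, key=lambda r: r.id):
            substrates, products = _native_participants(rxn, smiles_by_base)
            if not substrates or not products:
                continue
            candidates = pd.concat(
                [
                    select_candidates(q, library, substrate_cutoff, cofactor_ids)
                    for q in substrates + products
                ]
            ).drop_duplicates(subset=["compound_id"]).reset_index(drop=True)
            enumeration = enumerate_synthetic_reactions(
                candidates, operators, max_activities=max_activities
            )
            if enumeration.capped:
                result.per_reaction.append(
                    GofGeneResult(gene, rxn.id, tuple(substrates), tuple(products),
                                  [], True, None, None)
                )
                continue
            pairs = call_gof_pairs(
                substrates, products, enumeration.reactions, reaction_tc_cutoff
            )
            saved = [p for p in pairs if p.saved]
            sub_summary = prod_summary = None
            if len(saved) >= 2:
                sub_summary = dominant_substructure(
                    sorted({p.synthetic.substrate for p in saved})
                )
                prod_summary = dominant_substructure(
                    sorted({p.synthetic.product for p in saved})
                )
            result.per_reaction.append(
                GofGeneResult(
                    gene, rxn.id, tuple(substrates), tuple(products),
                    pairs, False, sub_summary, prod_summary,
                )
            )
    return result


def planted_pair_recovered(result: GofArmResult) -> bool:
    """Was every planted analog reaction saved as a promiscuity pair?"""
    library = synthetic_data.generate_compound_library(result.scenario)
    smiles = dict(zip(library["compound_id"], library["smiles"]))
    for _, _, analog_id in result.scenario.planted_gof:
        analog = canonical_smiles(smiles[analog_id])
        hit = any(
            p.synthetic.substrate == analog
            for gr in result.per_reaction
            for p in gr.saved_pairs
        )
        if not hit:
            return False
    return True
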