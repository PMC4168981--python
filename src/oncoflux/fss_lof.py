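"""Flux-space-shift statistics and loss-of-function oncometabolite calling.

Differential reaction activity between two sampled conditions is scored by
an empirical overlap probability: for each reaction, how likely is it to
find a flux value in one condition at least as extreme -- relative to the
other condition's median -- as a value drawn from the other condition.
The statistic is symmetrised over both orderings and floored at
``1/(n_A * n_B)``; identical distributions give p = 1, disjoint supports
give the floor.  Benjamini-Hochberg q-values are reported alongside.

A candidate oncometabolite of a loss-of-function mutation is a substrate
or product of the mutant enzyme's (now closed) reactions, or of reactions
sharing a metabolite with them, whenever those reactions shift
significantly between the enzyme-deficient cancer model and the matched
normal model.  Ubiquitous currency metabolites are excluded throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import cobra
import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm
from statsmodels.stats.multitest import multipletests

from oncoflux.core_model import delete_genes, fba
from oncoflux.flux_sampling import FluxSampleSet

P_CUT = 1e-3
FOLD_CUT = 2.0
FDR_CUT = 0.01
_FOLD_FLOOR = 1e-9
MIN_POINTS = 1000

#: base ids of ubiquitous cofactors excluded from metabolite-level calls
CURRENCY_METABOLITES = frozenset(
    {"atp", "adp", "nad", "nadh", "h", "h2o", "co2", "o2", "pi", "coa"}
)


def _overlap_p(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetrised empirical overlap probability of two flux samples."""

    def one_sided(x: np.ndarray, y: np.ndarray) -> float:
        med = np.median(y)
        dist = np.sort(np.abs(y - med))
        extreme = np.abs(x - med)
        # number of y at least as extreme as each x, relative to y's median
        count = len(y) - np.searchsorted(dist, extreme, side="left")
        return float(count.mean()) / len(y)

    p = one_sided(a, b) + one_sided(b, a)
    return min(1.0, max(p, 1.0 / (len(a) * len(b))))


def flux_change(
    samples_a: FluxSampleSet,
    samples_b: FluxSampleSet,
    min_points: int = MIN_POINTS,
) -> pd.DataFrame:
    """Per-reaction flux-shift statistics, condition A versus condition B.

    Both sample sets must be normalised and restricted to the shared,
    filtered reaction set.  Returns columns ``reaction, p_value, q_value,
    fold_change, direction`` where the fold change is the ratio of mean
    flux magnitudes A/B and the direction is A relative to B.
    """
    if not (samples_a.normalized and samples_b.normalized):
        raise ValueError("flux_change expects normalized sample sets")
    if samples_a.reactions != samples_b.reactions:
        raise ValueError("sample sets must share an identical reaction order")
    if min(samples_a.n_points, samples_b.n_points) < min_points:
        warnings.warn(
            f"fewer than {min_points} sample points; p-value resolution is limited",
            stacklevel=2,
        )
    rows = []
    for i, rid in enumerate(samples_a.reactions):
        a, b = samples_a.points[:, i], samples_b.points[:, i]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            p = 1.0
        else:
            p = _overlap_p(a, b)
        mean_a, mean_b = np.abs(a).mean(), np.abs(b).mean()
        fold = (mean_a + _FOLD_FLOOR) / (mean_b + _FOLD_FLOOR)
        rows.append((rid, p, fold, "up" if fold >= 1.0 else "down"))
    out = pd.DataFrame(rows, columns=["reaction", "p_value", "fold_change", "direction"])
    out.insert(2, "q_value", multipletests(out["p_value"], method="fdr_bh")[1])
    return out


def significant_changes(
    changes: pd.DataFrame,
    p_cut: float = P_CUT,
    fold_cut: float = FOLD_CUT,
    q_cut: float | None = None,
) -> pd.DataFrame:
    """Rows passing p < ``p_cut`` with at least ``fold_cut``-fold shift.

    The fold criterion applies in either direction (ratio or its inverse).
    ``q_cut`` optionally adds an FDR condition on the BH q-values.
    """
    fold = changes["fold_change"]
    mask = (changes["p_value"] < p_cut) & (
        np.maximum(fold, 1.0 / fold) >= fold_cut
    )
    if q_cut is not None:
        mask &= changes["q_value"] <= q_cut
    return changes[mask].reset_index(drop=True)


@dataclass
class DeficiencyVerdict:
    """An enzyme-deficient model and whether it supports sampling."""

    gene: str
    model: cobra.Model
    feasible: bool
    wild_type_objective: float
    deficient_objective: float


def build_deficient_model(
    model: cobra.Model,
    gene: str,
    optimality_fraction: float = 0.9,
) -> DeficiencyVerdict:
    """Knock out ``gene`` and check viability at the sampling bound.

    The verdict is infeasible when the deficient optimum falls below
    ``optimality_fraction`` of the wild-type optimum (or the LP becomes
    infeasible outright); such models are excluded from the LoF arm.
    """
    wild_type = fba(model).objective_value
    deficient = delete_genes(model, [gene])
    value = deficient.slim_optimize()
    deficient_objective = 0.0 if np.isnan(value) else float(value)
    feasible = deficient_objective >= optimality_fraction * wild_type - 1e-9
    return DeficiencyVerdict(
        gene=gene,
        model=deficient,
        feasible=feasible,
        wild_type_objective=wild_type,
        deficient_objective=deficient_objective,
    )


def _base(met: cobra.Metabolite) -> str:
    return met.id.rsplit("_", 1)[0]


def call_lof_oncometabolites(
    changes: pd.DataFrame,
    gene: str,
    model: cobra.Model,
    p_cut: float = P_CUT,
    fold_cut: float = FOLD_CUT,
    currency: frozenset[str] = CURRENCY_METABOLITES,
    neighbor_steps: int = 1,
) -> pd.DataFrame:
    """Metabolites surrounded by significantly shifted flux near ``gene``.

    Candidate reactions are those catalysed by the mutant gene plus the
    reactions within ``neighbor_steps`` shared (non-currency) metabolites
    of them.  Substrates and products of candidates passing the
    significance rule are emitted, tagged by compartment, with currency
    metabolites removed.
    """
    gene_obj = model.genes.get_by_id(gene)
    seed_rxns = set(gene_obj.reactions)
    if not seed_rxns:
        raise ValueError(f"gene {gene} catalyses no reaction in the model")

    candidates = set(seed_rxns)
    frontier = set(seed_rxns)
    for _ in range(neighbor_steps):
        shared_mets = {
            m for r in frontier for m in r.metabolites if _base(m) not in currency
        }
        frontier = {
            r for m in shared_mets for r in m.reactions
        } - candidates
        candidates |= frontier

    sig = significant_changes(changes, p_cut=p_cut, fold_cut=fold_cut)
    sig = sig[sig["reaction"].isin({r.id for r in candidates})]

    rows = []
    for _, rec in sig.iterrows():
        rxn = model.reactions.get_by_id(rec["reaction"])
        for met in rxn.metabolites:
            if _base(met) in currency:
                continue
            rows.append(
                {
                    "metabolite": met.id,
                    "base_metabolite": _base(met),
                    "compartment": met.compartment,
                    "gene": gene,
                    "reaction": rxn.id,
                    "p_value": rec["p_value"],
                    "q_value": rec["q_value"],
                    "fold_change": rec["fold_change"],
                    "direction": rec["direction"],
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "metabolite", "base_metabolite", "compartment", "gene", "reaction",
            "p_value", "q_value", "fold_change", "direction",
        ],
    )
    return out.drop_duplicates(subset=["metabolite", "reaction"]).reset_index(drop=True)


@dataclass(frozen=True)
class AccuracyResult:
    """Confusion counts of flux-predicted versus observed expression change."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    permutation_p: float
    n_permutations: int


def _isoenzymatic(rxn: cobra.Reaction) -> bool:
    """True when any single catalysing gene is dispensable (OR redundancy)."""
    genes = list(rxn.genes)
    if len(genes) < 2:
        return False
    return any(rxn.gpr.eval(knockouts={g.id}) for g in genes)


def flux_expression_accuracy(
    changes: pd.DataFrame,
    expression_delta: pd.Series,
    model: cobra.Model,
    p_cut: float = P_CUT,
    fold_cut: float = FOLD_CUT,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> AccuracyResult:
    """Fraction of genes whose flux-predicted direction matches expression.

    Significant reactions are decomposed into genes through the GPRs;
    isoenzyme-catalysed reactions and genes mapped to both directions are
    discarded as ambiguous.  The accuracy (correct / total predictions) is
    compared with a null of ``n_permutations`` random direction
    assignments.
    """
    sig = significant_changes(changes, p_cut=p_cut, fold_cut=fold_cut)
    directions: dict[str, set[str]] = {}
    for _, rec in sig.iterrows():
        rxn = model.reactions.get_by_id(rec["reaction"])
        if _isoenzymatic(rxn):
            continue
        for g in rxn.genes:
            directions.setdefault(g.id, set()).add(rec["direction"])
    predictions = {
        g: next(iter(d)) for g, d in directions.items() if len(d) == 1
    }
    predictions = {
        g: d for g, d in predictions.items()
        if g in expression_delta.index and expression_delta[g] != 0
    }
    if not predictions:
        raise ValueError("no unambiguous predictions; accuracy undefined")

    genes = sorted(predictions)
    pred_up = np.array([predictions[g] == "up" for g in genes])
    obs_up = np.array([expression_delta[g] > 0 for g in genes])
    tp = int(np.sum(pred_up & obs_up))
    tn = int(np.sum(~pred_up & ~obs_up))
    fp = int(np.sum(pred_up & ~obs_up))
    fn = int(np.sum(~pred_up & obs_up))
    accuracy = (tp + tn) / len(genes)

    rng = np.random.default_rng(seed)
    null = (
        rng.random((n_permutations, len(genes))) < 0.5
    ) == obs_up[None, :]
    exceed = int(np.sum(null.mean(axis=1) >= accuracy))
    permutation_p = (1 + exceed) / (n_permutations + 1)
    return AccuracyResult(tp, tn, fp, fn, accuracy, permutation_p, n_permutations)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment with its probit z-score."""

    overlap: int
    p_value: float
    z_score: float


def essentiality_enrichment(
    in_silico: set[str], in_vivo: set[str], universe: set[str]
) -> EnrichmentResult:
    """Enrichment of experimentally essential genes among predicted ones.

    Upper-tail hypergeometric P of the overlap, converted to a z-score by
    the probit transform ``z = Phi^-1(1 - P)``; higher z means stronger
    enrichment.
    """
    if not in_silico <= universe or not in_vivo <= universe:
        raise ValueError("essential gene sets must be subsets of the universe")
    if not in_silico:
        return EnrichmentResult(overlap=0, p_value=1.0, z_score=float(norm.isf(1 - 1e-16)))
    overlap = len(in_silico & in_vivo)
    p = float(hypergeom.sf(overlap - 1, len(universe), len(in_vivo), len(in_silico)))
    p = min(max(p, 1e-300), 1.0)
    z = float(norm.isf(max(p, 1e-16) if p < 1 else 1 - 1e-16))
    return EnrichmentResult(overlap=overlap, p_value=p, z_score=z)
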