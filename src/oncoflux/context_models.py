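"""Presence/absence expression calls and GIMME context-specific extraction.

A gene is called *present* when it is detected in more than a consensus
fraction (default 99%) of samples.  The calls condition a genome-scale
model through the GIMME program: minimise total flux through reactions
whose GPR is unsatisfied by the present genes, subject to retaining a
required fraction of the optimal objective.  Reactions that are both
unsupported by expression and idle in the penalty optimum are removed from
the context model; the minimised penalty sum is reported as the
inconsistency score.

Cancer models maximise biomass; normal models use a two-term objective,
biomass plus ATP maintenance, each term scaled by its maximum achievable
flux so the weights are dimensionless:

    max  a * v_biomass / v_biomass_max  +  b * v_atp / v_atp_max,  a = b = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
import yaml
from cobra.util.solver import set_objective

from oncoflux.core_model import InfeasibleModelError, fba, gpr_satisfied

CONSENSUS_FRACTION = 0.99
REQUIRED_FRACTION = 0.9
_ZERO_FLUX = 1e-6


@dataclass(frozen=True)
class PresenceCallVector:
    """Present/absent call per gene plus its provenance."""

    calls: pd.Series  # bool, indexed by gene id
    platform: str
    detection_threshold: float
    consensus: float

    @property
    def present(self) -> set[str]:
        return set(self.calls.index[self.calls])

    @property
    def absent(self) -> set[str]:
        return set(self.calls.index[~self.calls])


def presence_calls(
    expression: pd.DataFrame,
    detection_threshold: float = 10.0,
    consensus: float = CONSENSUS_FRACTION,
    platform: str = "generic",
) -> PresenceCallVector:
    """Call genes present when detected in more than ``consensus`` of samples.

    ``expression`` is genes x samples.  Detection in a sample means the
    value reaches ``detection_threshold``; the consensus rule is strict
    ("more than"), so a gene detected in exactly 99 of 100 samples is
    absent at the default consensus of 0.99.
    """
    if not 0.0 < consensus <= 1.0:
        raise ValueError(f"consensus outside (0, 1]: {consensus}")
    if expression.index.duplicated().any():
        dupes = sorted(expression.index[expression.index.duplicated()].unique())
        raise ValueError(f"duplicated genes in expression matrix: {dupes}")
    detected = (expression >= detection_threshold).sum(axis=1)
    present = detected > consensus * expression.shape[1]
    return PresenceCallVector(
        calls=present.astype(bool),
        platform=platform,
        detection_threshold=detection_threshold,
        consensus=consensus,
    )


@dataclass(frozen=True)
class ObjectiveSpec:
    """Linear objective with per-term max-flux scaling."""

    terms: tuple[tuple[str, float, float], ...]  # (reaction, weight, scale)

    def coefficients(self) -> dict[str, float]:
        return {rid: w / s for rid, w, s in self.terms}


def scale_objective(
    model: cobra.Model,
    terms: Sequence[tuple[str, float]] = (("BIOMASS", 1.0), ("ATPM", 1.0)),
) -> ObjectiveSpec:
    """Scale each objective term by its maximum achievable flux.

    With terms biomass and ATP demand at weights ``a = b = 1`` this is the
    normal-cell objective; a single biomass term at weight 1 degenerates to
    plain biomass maximisation.
    """
    scaled = []
    for rid, weight in terms:
        if weight == 0:
            continue
        rxn = model.reactions.get_by_id(rid)
        with model:
            set_objective(model, {rxn: 1.0})
            vmax = model.slim_optimize()
        if not np.isfinite(vmax) or vmax <= 0:
            raise ValueError(f"objective term {rid} has non-positive maximum flux")
        scaled.append((rid, float(weight), float(vmax)))
    if not scaled:
        raise ValueError("objective has no non-zero terms")
    return ObjectiveSpec(terms=tuple(scaled))


def apply_objective(model: cobra.Model, spec: ObjectiveSpec) -> None:
    """Install ``spec`` as the model objective (in place)."""
    coeffs = spec.coefficients()
    set_objective(
        model, {model.reactions.get_by_id(rid): c for rid, c in coeffs.items()}
    )


@dataclass(frozen=True)
class MediumSpec:
    """Exchange uptake bounds plus forced minimum fluxes."""

    uptakes: Mapping[str, float] = field(default_factory=dict)
    forced: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "MediumSpec":
        data = yaml.safe_load(open(path)) or {}
        return cls(uptakes=dict(data.get("uptakes", {})), forced=dict(data.get("forced", {})))


def toy_medium() -> MediumSpec:
    """The packaged medium for the toy network."""
    ref = resources.files("oncoflux.data") / "toy_medium.yml"
    with resources.as_file(ref) as path:
        return MediumSpec.from_yaml(path)


def apply_medium(model: cobra.Model, medium: MediumSpec, inplace: bool = False) -> cobra.Model:
    """Constrain exchanges to the medium; idempotent.

    All exchange uptakes are first closed, then the medium's uptakes are
    opened to their maximal magnitude; forced fluxes become lower bounds on
    the named reactions (secretion or maintenance demands).
    """
    target = model if inplace else model.copy()
    known = {r.id for r in target.reactions}
    unknown = sorted((set(medium.uptakes) | set(medium.forced)) - known)
    if unknown:
        raise KeyError(f"medium references unknown reactions: {unknown}")
    for rxn in target.exchanges:
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
    for rid, magnitude in medium.uptakes.items():
        target.reactions.get_by_id(rid).lower_bound = -abs(magnitude)
    for rid, minimum in medium.forced.items():
        target.reactions.get_by_id(rid).lower_bound = float(minimum)
    return target


@dataclass
class GimmeResult:
    """Outcome of a GIMME extraction."""

    model: cobra.Model
    inconsistency: float
    penalized_reactions: list[str]
    removed_reactions: list[str]
    fluxes: pd.Series
    required_fraction: float


def gimme_extract(
    model: cobra.Model,
    calls: PresenceCallVector,
    objective: ObjectiveSpec | None = None,
    required_fraction: float = REQUIRED_FRACTION,
    penalty: float = 1.0,
    zero_tolerance: float = _ZERO_FLUX,
) -> GimmeResult:
    """Extract a context-specific sub-model from presence/absence calls.

    Solves ``min sum penalty * |v_r|`` over reactions whose GPR is not
    satisfied by the present genes, subject to steady state and to the
    model objective reaching ``required_fraction`` of its optimum.  The
    context model retains every present-GPR reaction plus any penalised
    reaction that still carries flux in the penalty optimum.
    """
    if not 0.0 < required_fraction <= 1.0:
        raise ValueError(f"required_fraction outside (0, 1]: {required_fraction}")
    absent = calls.absent & {g.id for g in model.genes}

    work = model.copy()
    if objective is not None:
        apply_objective(work, objective)
    optimum = work.slim_optimize()
    if np.isnan(optimum):
        raise InfeasibleModelError("model infeasible before GIMME extraction")

    penalized = [
        r.id
        for r in work.reactions
        if r.gene_reaction_rule and not gpr_satisfied(r, absent)
    ]

    prob = work.problem
    floor = prob.Constraint(
        work.objective.expression, lb=required_fraction * optimum, name="gimme_floor"
    )
    aux, couplings = [], []
    for rid in penalized:
        rxn = work.reactions.get_by_id(rid)
        t = prob.Variable(f"gimme_abs_{rid}", lb=0.0)
        couplings.append(prob.Constraint(t - rxn.flux_expression, lb=0.0))
        couplings.append(prob.Constraint(t + rxn.flux_expression, lb=0.0))
        aux.append(t)
    work.add_cons_vars([floor, *aux, *couplings])
    work.objective = prob.Objective(
        sum(penalty * t for t in aux) if aux else 0, direction="min"
    )
    solution = work.optimize()
    if solution.status != "optimal":
        raise InfeasibleModelError(
            f"GIMME program infeasible at required_fraction={required_fraction}; "
            "consider a lower fraction"
        )
    inconsistency = float(solution.objective_value) if aux else 0.0
    fluxes = solution.fluxes

    removed = [rid for rid in penalized if abs(fluxes[rid]) < zero_tolerance]
    context = model.copy()
    if objective is not None:
        apply_objective(context, objective)
    context.remove_reactions(
        [context.reactions.get_by_id(rid) for rid in removed], remove_orphans=True
    )
    return GimmeResult(
        model=context,
        inconsistency=inconsistency,
        penalized_reactions=penalized,
        removed_reactions=removed,
        fluxes=fluxes,
        required_fraction=required_fraction,
    )


def reaction_presence(context: cobra.Model, reference: cobra.Model) -> pd.Series:
    """Boolean vector over the reference reactions: kept in the context model?"""
    kept = {r.id for r in context.reactions}
    return pd.Series(
        {r.id: r.id in kept for r in reference.reactions}, dtype=bool
    )


def structure_expression_correlation(
    gene_calls: Mapping[str, pd.Series],
    reaction_presence_by_condition: Mapping[str, pd.Series],
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlation-of-correlations between expression calls and model structure.

    Step 1: pairwise Pearson correlations between conditions of the binary
    gene-call vectors, and likewise of the binary reaction-presence
    vectors.  Step 2: for each condition, the final value is the Pearson
    correlation between its (off-diagonal) row of gene-level correlations
    and its row of reaction-level correlations.  Significance comes from
    permuting each condition's reaction-presence entries independently.
    """
    conditions = list(gene_calls)
    if len(conditions) < 3:
        raise ValueError("need at least 3 conditions for a correlation of correlations")
    if set(conditions) != set(reaction_presence_by_condition):
        raise ValueError("condition labels differ between calls and structures")

    genes = gene_calls[conditions[0]].index
    G = np.column_stack([gene_calls[c].reindex(genes).to_numpy(float) for c in conditions])
    rxns = reaction_presence_by_condition[conditions[0]].index
    R = np.column_stack(
        [reaction_presence_by_condition[c].reindex(rxns).to_numpy(float) for c in conditions]
    )

    def pairwise_pcc(M: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(M.T)
        return np.nan_to_num(C, nan=1.0)  # constant vectors: treated as identical

    def final_values(C_gene: np.ndarray, C_rxn: np.ndarray) -> tuple[np.ndarray, list[bool]]:
        k = len(conditions)
        out, flat = np.empty(k), []
        for i in range(k):
            mask = np.arange(k) != i
            x, y = C_gene[i, mask], C_rxn[i, mask]
            degenerate = np.std(x) == 0 or np.std(y) == 0
            flat.append(bool(degenerate))
            if degenerate:
                # constant correlation rows (e.g. identical conditions):
                # perfect agreement by convention when the rows coincide
                out[i] = 1.0 if np.allclose(x, y) else 0.0
            else:
                out[i] = np.corrcoef(x, y)[0, 1]
        return out, flat

    C_gene = pairwise_pcc(G)
    observed, degenerate = final_values(C_gene, pairwise_pcc(R))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(conditions))
    for _ in range(n_permutations):
        Rp = np.column_stack([rng.permutation(R[:, j]) for j in range(R.shape[1])])
        exceed += final_values(C_gene, pairwise_pcc(Rp))[0] >= observed
    p = (1.0 + exceed) / (n_permutations + 1.0)

    return pd.DataFrame(
        {
            "condition": conditions,
            "correlation": observed,
            "p_value": p,
            "degenerate": degenerate,
        }
    )
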