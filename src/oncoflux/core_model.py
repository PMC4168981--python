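"""Metabolic-model plumbing: SBML I/O, FBA, gene deletions, essentiality.

A model is represented by a :class:`cobra.Model` carrying stoichiometry,
flux bounds and gene-protein-reaction (GPR) boolean rules.  The functions
here are thin, strict wrappers: infeasibility is always raised as an
exception rather than returned as a zero flux vector, and gene-deletion
semantics follow the usual GPR evaluation (AND = all subunits required,
OR = isoenzymes substitute).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import cobra
import numpy as np
import pandas as pd
from cobra.util.array import create_stoichiometric_matrix

#: LP feasibility tolerance handed to the solver.
SOLVER_TOLERANCE = 1e-9
#: Tolerance used when reporting/auditing steady state and bounds.
REPORT_TOLERANCE = 1e-6
#: Magnitude used to encode an unbounded flux.
BIG_BOUND = 1000.0

#: Knockout growth-ratio below which a gene is called essential
#: (strictly "more than 10%" growth reduction).
ESSENTIAL_RATIO = 0.90
#: Growth-ratio at or above which a knockout is called "no change".
NO_CHANGE_RATIO = 0.99

DELETION_CATEGORIES = ("essential", "reduced_1_10", "no_change")


class InfeasibleModelError(Exception):
    """Raised when an LP over the model has no feasible solution."""


class UnknownGeneError(KeyError):
    """Raised when a gene id is not part of the model."""


@dataclass(frozen=True)
class FluxVector:
    """One steady-state flux distribution and its objective value."""

    fluxes: pd.Series
    objective_value: float

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.fluxes[reaction_id])


def read_sbml(path) -> cobra.Model:
    """Read an SBML (Level 2/3, fbc) model from ``path``.

    Reactions missing explicit bounds are given the COBRA defaults
    (+-``BIG_BOUND``) with a warning.
    """
    model = cobra.io.read_sbml_model(str(path))
    patched = []
    for rxn in model.reactions:
        lb, ub = rxn.bounds
        if not np.isfinite(lb) or not np.isfinite(ub):
            rxn.bounds = (max(lb, -BIG_BOUND), min(ub, BIG_BOUND))
            patched.append(rxn.id)
    if patched:
        warnings.warn(
            f"bounds missing/infinite for {len(patched)} reactions; "
            f"defaulted to +-{BIG_BOUND}: {patched[:5]}...",
            stacklevel=2,
        )
    model.solver.configuration.tolerances.feasibility = SOLVER_TOLERANCE
    return model


def write_sbml(model: cobra.Model, path) -> None:
    """Write ``model`` as SBML Level 3 + fbc."""
    cobra.io.write_sbml_model(model, str(path))


def fba(model: cobra.Model) -> FluxVector:
    """Maximise the model objective: ``max c'v  s.t.  S v = 0, lb <= v <= ub``.

    Raises
    ------
    InfeasibleModelError
        If the LP is infeasible or has no objective.
    """
    if not model.objective.expression.free_symbols:
        raise InfeasibleModelError("model has an empty objective")
    solution = model.optimize()
    if solution.status != "optimal":
        raise InfeasibleModelError(
            f"FBA did not reach an optimum (status={solution.status!r})"
        )
    return FluxVector(fluxes=solution.fluxes, objective_value=float(solution.objective_value))


def _require_genes(model: cobra.Model, genes: Iterable[str]) -> list[str]:
    genes = list(genes)
    known = {g.id for g in model.genes}
    missing = sorted(set(genes) - known)
    if missing:
        raise UnknownGeneError(f"gene ids not in model: {missing}")
    return genes


def delete_genes(model: cobra.Model, genes: Iterable[str]) -> cobra.Model:
    """Return a copy of ``model`` with ``genes`` knocked out.

    Every reaction whose GPR evaluates to false once the deleted genes are
    set to false gets bounds (0, 0); all other reactions are untouched.
    Idempotent and order-independent over gene sets.
    """
    genes = _require_genes(model, genes)
    knocked = model.copy()
    for gid in genes:
        knocked.genes.get_by_id(gid).knock_out()
    return knocked


def gpr_satisfied(reaction: cobra.Reaction, inactive_genes: Iterable[str]) -> bool:
    """Evaluate a reaction's GPR with ``inactive_genes`` set to false.

    Reactions without a GPR (spontaneous, exchange) count as satisfied.
    """
    if not reaction.gene_reaction_rule:
        return True
    return bool(reaction.gpr.eval(knockouts=set(inactive_genes)))


def categorize_growth_ratio(ratio: float) -> str:
    """Map a knockout/wild-type growth ratio to its essentiality category."""
    if ratio < ESSENTIAL_RATIO:
        return "essential"
    if ratio < NO_CHANGE_RATIO:
        return "reduced_1_10"
    return "no_change"


def single_gene_deletion_screen(model: cobra.Model) -> pd.DataFrame:
    """Knock out every gene in turn and categorise the growth effect.

    Categories: ``essential`` (growth reduced by more than 10%),
    ``reduced_1_10`` (1-10% reduction) and ``no_change``.

    Returns a DataFrame with columns ``gene``, ``growth_ratio`` and
    ``category``; the three categories partition the gene set.
    """
    wild_type = fba(model).objective_value
    if not wild_type > 0:
        raise InfeasibleModelError(
            "wild-type objective is zero; essentiality screen is undefined"
        )
    rows = []
    for gene in model.genes:
        with model:
            gene.knock_out()
            value = model.slim_optimize()
        ratio = 0.0 if np.isnan(value) else max(float(value), 0.0) / wild_type
        rows.append((gene.id, ratio, categorize_growth_ratio(ratio)))
    return pd.DataFrame(rows, columns=["gene", "growth_ratio", "category"])


def write_deletion_screen(screen: pd.DataFrame, path) -> None:
    screen.to_csv(path, sep="\t", index=False)


def check_steady_state(
    model: cobra.Model, fluxes: pd.Series, tolerance: float = REPORT_TOLERANCE
) -> float:
    """Return ``max |S v|`` for a flux vector; raise if above ``tolerance``."""
    S = create_stoichiometric_matrix(model)
    v = fluxes.reindex([r.id for r in model.reactions]).to_numpy()
    residual = float(np.max(np.abs(S @ v))) if len(v) else 0.0
    if residual > tolerance:
        raise ValueError(f"steady-state violated: max |S v| = {residual:.3g}")
    return residual
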