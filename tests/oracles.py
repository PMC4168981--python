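"""Independent oracles used to cross-check the package's computations.

Each routine here recomputes a quantity by a different route than the
implementation: scipy's LP solver for FBA, a brute-force double loop for
the flux-shift p-value, explicit bit loops for Tanimoto, exact rational
combinatorics for the hypergeometric tail, and explicit-hydrogen atom
counting for mass balance.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction
from math import comb

import numpy as np
from cobra.util.array import create_stoichiometric_matrix
from scipy.optimize import linprog


def linprog_fba(model) -> float:
    """FBA optimum from an independent scipy/HiGHS formulation."""
    S = create_stoichiometric_matrix(model)
    reactions = list(model.reactions)
    c = np.array([r.objective_coefficient for r in reactions], dtype=float)
    bounds = [(r.lower_bound, r.upper_bound) for r in reactions]
    res = linprog(
        -c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs"
    )
    if not res.success:
        raise RuntimeError(f"oracle LP failed: {res.message}")
    return -res.fun


def brute_overlap_p(a: np.ndarray, b: np.ndarray) -> float:
    """O(n^2) double-loop version of the symmetrised overlap probability."""

    def one_sided(x, y):
        med = np.median(y)
        total = 0
        for xi in x:
            total += sum(abs(yj - med) >= abs(xi - med) for yj in y)
        return total / (len(x) * len(y))

    p = one_sided(a, b) + one_sided(b, a)
    return min(1.0, max(p, 1.0 / (len(a) * len(b))))


def bit_loop_tanimoto(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Naive per-bit Tanimoto similarity/dissimilarity."""
    inter = union = 0
    for bit_a, bit_b in zip(a, b, strict=True):
        if bit_a and bit_b:
            inter += 1
        if bit_a or bit_b:
            union += 1
    sim = 1.0 if union == 0 else inter / union
    return sim, 1.0 - sim


def exact_hypergeom_upper_tail(overlap: int, universe: int, members: int, drawn: int) -> float:
    """Exact P(X >= overlap) as a rational combinatorial sum."""
    total = Fraction(0)
    for k in range(overlap, min(members, drawn) + 1):
        total += Fraction(comb(members, k) * comb(universe - members, drawn - k),
                          comb(universe, drawn))
    return float(total)


def explicit_atom_counts(smiles: str) -> Counter:
    """Elemental composition by explicit-hydrogen atom enumeration."""
    from rdkit import Chem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    counts: Counter = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
    return counts


def gimme_penalty_oracle(model, penalized: list[str], required_fraction: float) -> float:
    """Minimal penalised |flux| sum via an independent split-variable LP."""
    S = create_stoichiometric_matrix(model)
    reactions = [r.id for r in model.reactions]
    n = len(reactions)
    c_obj = np.array([r.objective_coefficient for r in model.reactions])
    opt = linprog(
        -c_obj, A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=[(r.lower_bound, r.upper_bound) for r in model.reactions],
        method="highs",
    )
    assert opt.success
    optimum = -opt.fun

    # variables: v (free within bounds) plus t_r >= |v_r| for penalised r
    pen_idx = [reactions.index(r) for r in penalized]
    m = len(pen_idx)
    cost = np.concatenate([np.zeros(n), np.ones(m)])
    A_ub, b_ub = [], []
    for j, i in enumerate(pen_idx):
        row = np.zeros(n + m); row[i] = 1.0; row[n + j] = -1.0
        A_ub.append(row); b_ub.append(0.0)       # v_i - t_j <= 0
        row = np.zeros(n + m); row[i] = -1.0; row[n + j] = -1.0
        A_ub.append(row); b_ub.append(0.0)       # -v_i - t_j <= 0
    row = np.zeros(n + m); row[:n] = -c_obj
    A_ub.append(row); b_ub.append(-required_fraction * optimum)
    A_eq = np.hstack([S, np.zeros((S.shape[0], m))])
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    bounds += [(0, None)] * m
    res = linprog(
        cost, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
        A_eq=A_eq, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs",
    )
    assert res.success, res.message
    return float(res.fun)
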