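"""Hit-and-run sampling of the sub-optimal flux space and its diagnostics.

The feasible flux polytope, with the objective constrained to at least a
fraction (default 90%) of its FBA optimum, is sampled with the
artificially-centered hit-and-run (ACHR) chain: directions are drawn as
(random warmup corner - running center) and the step length is uniform on
the feasible chord.  Convergence is summarised by the *mixed fraction*: the
fraction of (point, reaction) pairs that lie on different sides of the
per-reaction median between the half-way and final snapshots of the chain;
a well-mixed sampler gives about 0.5, a frozen chain gives 0.

Before differential statistics, reactions that carry no flux in either
condition and reactions that can carry flux with every exchange closed
(thermodynamically infeasible loops) are removed, and each sample point is
normalised to unit total flux magnitude:

    v_r  <-  v_r / sum_r |v_r|        (per sample point)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import cobra
import numpy as np
import pandas as pd
from cobra.flux_analysis import flux_variability_analysis
from cobra.sampling import ACHRSampler
from cobra.util import fix_objective_as_constraint

from oncoflux.core_model import InfeasibleModelError

DEFAULT_N_POINTS = 5000
DEFAULT_THINNING = 100
OPTIMALITY_FRACTION = 0.9
ZERO_FLUX_TOL = 1e-9
#: fraction of points that must be at zero for a reaction to count as idle
ZERO_POINT_FRACTION = 0.99


@dataclass(frozen=True)
class FluxSampleSet:
    """Points x reactions matrix of sampled steady-state fluxes."""

    points: np.ndarray
    reactions: tuple[str, ...]
    config: dict = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self):
        if self.points.ndim != 2 or self.points.shape[1] != len(self.reactions):
            raise ValueError("points must be (n_points, n_reactions)")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=list(self.reactions))

    def column(self, reaction_id: str) -> np.ndarray:
        return self.points[:, self.reactions.index(reaction_id)]

    def subset(self, reaction_ids) -> "FluxSampleSet":
        idx = [self.reactions.index(r) for r in reaction_ids]
        return replace(
            self, points=self.points[:, idx], reactions=tuple(reaction_ids)
        )

    def save(self, prefix) -> tuple[Path, Path]:
        """Persist as TSV matrix plus JSON sidecar (order, config, flags)."""
        prefix = Path(prefix)
        matrix = prefix.with_suffix(".tsv")
        sidecar = prefix.with_suffix(".json")
        self.to_frame().to_csv(matrix, sep="\t", index=False)
        sidecar.write_text(
            json.dumps(
                {
                    "reactions": list(self.reactions),
                    "config": self.config,
                    "normalized": self.normalized,
                },
                indent=1,
            )
        )
        return matrix, sidecar

    @classmethod
    def load(cls, prefix) -> "FluxSampleSet":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        frame = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
        return cls(
            points=frame[meta["reactions"]].to_numpy(float),
            reactions=tuple(meta["reactions"]),
            config=meta["config"],
            normalized=meta["normalized"],
        )


def achr_sample(
    model: cobra.Model,
    n_points: int = DEFAULT_N_POINTS,
    thinning: int = DEFAULT_THINNING,
    optimality_fraction: float = OPTIMALITY_FRACTION,
    seed: int = 0,
) -> FluxSampleSet:
    """Sample the flux polytope at >= ``optimality_fraction`` of the optimum.

    Records every ``thinning``-th state of a single ACHR chain; the chain
    variant (warmup corners, centered directions, uniform chord step) is
    recorded in the sample-set config.  Deterministic for a fixed seed.
    """
    if not 0.0 <= optimality_fraction <= 1.0:
        raise ValueError(f"optimality_fraction outside [0, 1]: {optimality_fraction}")
    if np.isnan(model.slim_optimize()):
        raise InfeasibleModelError("model infeasible; cannot sample")
    with model:
        if optimality_fraction > 0:
            fix_objective_as_constraint(model, fraction=optimality_fraction)
        # map into [1, 2^31-1]: cobra treats seed 0/None as "use the clock"
        sampler = ACHRSampler(model, thinning=thinning, seed=int(seed) % (2**31 - 1) + 1)
        frame = sampler.sample(n_points)
    return FluxSampleSet(
        points=frame.to_numpy(float),
        reactions=tuple(frame.columns),
        config={
            "n_points": int(n_points),
            "thinning": int(thinning),
            "optimality_fraction": float(optimality_fraction),
            "seed": int(seed),
            "variant": "achr/centered-directions/uniform-chord/warmup-corners",
        },
    )


def mixed_fraction(samples: FluxSampleSet, tol: float = ZERO_FLUX_TOL) -> float:
    """Convergence diagnostic comparing half-way and final chain snapshots.

    The recorded chain is split in two halves; for each reaction the median
    of the final half defines the "side" of every point.  The mixed
    fraction is the fraction of (point index, reaction) pairs whose side
    differs between the two halves, over non-constant reactions.  Values
    near 0.5 indicate uniform mixing; a frozen chain yields 0.
    """
    n = samples.n_points
    if n < 4:
        raise ValueError("need at least 4 points for the mixed-fraction diagnostic")
    half = n // 2
    first, final = samples.points[:half], samples.points[half : 2 * half]
    keep = np.ptp(samples.points, axis=0) > tol
    if not keep.any():
        raise ValueError("all reaction columns are constant")
    median = np.median(final, axis=0)
    differs = (first > median) != (final > median)
    return float(differs[:, keep].mean())


def find_loop_reactions(model: cobra.Model, tol: float = 1e-6) -> set[str]:
    """Reactions able to carry flux with every exchange closed.

    Flux variability on the exchange-closed model: any reaction with a
    non-zero feasible range belongs to an internal (thermodynamically
    infeasible) cycle.
    """
    closed = model.copy()
    for rxn in closed.reactions:
        # relax forced fluxes so the zero vector is feasible; loop capacity
        # is a property of the internal cycle space, not of demands
        rxn.bounds = (min(rxn.lower_bound, 0.0), max(rxn.upper_bound, 0.0))
    for rxn in closed.boundary:
        rxn.bounds = (0.0, 0.0)
    closed.objective = closed.problem.Objective(0)
    fva = flux_variability_analysis(
        closed, fraction_of_optimum=0.0, processes=1
    )
    loops = fva.index[(fva["maximum"].abs() > tol) | (fva["minimum"].abs() > tol)]
    return set(loops)


def filter_zero_and_loop_reactions(
    samples_a: FluxSampleSet,
    samples_b: FluxSampleSet,
    model: cobra.Model,
    zero_tol: float = ZERO_FLUX_TOL,
    zero_fraction: float = ZERO_POINT_FRACTION,
) -> list[str]:
    """Reactions retained for differential analysis.

    Drops reactions at zero flux in at least ``zero_fraction`` of points in
    *both* sample sets, and reactions on closed-exchange loops.  Returns
    the retained reaction ids in the order shared by both sets.
    """
    shared = [r for r in samples_a.reactions if r in set(samples_b.reactions)]
    loops = find_loop_reactions(model)

    def idle(samples: FluxSampleSet, rid: str) -> bool:
        v = samples.column(rid)
        return float((np.abs(v) < zero_tol).mean()) >= zero_fraction

    retained = []
    for rid in shared:
        if rid in loops:
            continue
        if idle(samples_a, rid) and idle(samples_b, rid):
            continue
        retained.append(rid)
    return retained


def normalize_fluxes(samples: FluxSampleSet, zero_tol: float = 1e-12) -> FluxSampleSet:
    """Divide each sample point by its total flux magnitude.

    Signs are preserved and every normalised row satisfies
    ``sum_r |v_r| = 1``.  Apply after filtering, so removed loop fluxes do
    not distort the denominators.
    """
    if samples.normalized:
        raise ValueError("sample set is already normalized")
    totals = np.abs(samples.points).sum(axis=1)
    if (totals <= zero_tol).any():
        raise ValueError("cannot normalize: some sample points have zero total flux")
    return replace(
        samples,
        points=samples.points / totals[:, None],
        normalized=True,
    )
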