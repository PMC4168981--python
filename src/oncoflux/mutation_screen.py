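"""Gene-selection funnel: recurrence, mutation-class arms, redundancy filters.

Starting from a per-sample somatic mutation table, candidate driver enzymes
are selected in stages: (1) recurrence in at least 5% of samples, computed
per mutation-class arm on distinct samples, with transporter-only genes
excluded; (2) assignment to the loss-of-function arm (nonsense, frameshift
and splice-site mutations) and/or the gain-of-function arm (missense);
(3) removal of fully redundant isoenzymes, whose loss would be masked by a
duplicate activity; (4) a functional-impact-score (FIS) cut.  Pathway
enrichment of the selected genes is assessed with a one-sided
hypergeometric test.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence
import warnings

import cobra
import pandas as pd
from scipy.stats import hypergeom

from oncoflux.core_model import gpr_satisfied

MUTATION_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel", "silent", "splice_site"}
)
LOF_CLASSES = frozenset({"nonsense", "frameshift_indel", "splice_site"})
GOF_CLASSES = frozenset({"missense"})

RECURRENCE_THRESHOLD = 0.05
MIN_FIS = 1.9  # "medium impact" convention of conservation-based scorers


def _check_classes(table: pd.DataFrame) -> None:
    unknown = set(table["mclass"]) - MUTATION_CLASSES
    if unknown:
        raise ValueError(f"unknown mutation classes: {sorted(unknown)}")


def mutation_summary(table: pd.DataFrame) -> dict:
    """Per-sample mutated-gene counts and per-class percentages."""
    if table.empty:
        warnings.warn("empty mutation table; summary is empty", stacklevel=2)
        return {
            "genes_per_sample": pd.Series(dtype=int),
            "median_genes_per_sample": float("nan"),
            "mean_genes_per_sample": float("nan"),
            "class_percent": pd.Series(dtype=float),
        }
    _check_classes(table)
    per_sample = table.groupby("sample")["gene"].nunique()
    class_pct = table["mclass"].value_counts(normalize=True) * 100.0
    return {
        "genes_per_sample": per_sample,
        "median_genes_per_sample": float(per_sample.median()),
        "mean_genes_per_sample": float(per_sample.mean()),
        "class_percent": class_pct,
    }


def transporter_genes(model: cobra.Model) -> set[str]:
    """Genes whose every reaction only moves species between compartments.

    A transport reaction carries the same base metabolite species (id minus
    compartment tag) on both sides, in different compartments, with no
    chemical transformation.
    """

    def base(met: cobra.Metabolite) -> str:
        return met.id.rsplit("_", 1)[0]

    def is_transport(rxn: cobra.Reaction) -> bool:
        subs = {base(m) for m in rxn.reactants}
        prods = {base(m) for m in rxn.products}
        if not subs or subs != prods:
            return False
        return len({m.compartment for m in rxn.metabolites}) > 1

    out = set()
    for gene in model.genes:
        if gene.reactions and all(is_transport(r) for r in gene.reactions):
            out.add(gene.id)
    return out


def _recurrence(table: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    counts = table.groupby("gene")["sample"].nunique()
    return pd.DataFrame(
        {"n_mutated_samples": counts, "recurrence": counts / n_samples}
    ).reset_index()


def recurrence_filter(
    table: pd.DataFrame,
    n_samples: int,
    threshold: float = RECURRENCE_THRESHOLD,
    model: cobra.Model | None = None,
    classes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Genes mutated in at least ``threshold`` of samples (distinct samples).

    ``classes`` restricts the records considered (used for per-arm
    recurrence).  When ``model`` is given, transporter-only genes are
    dropped.  Returns columns ``gene, n_mutated_samples, recurrence``.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold outside (0, 1]: {threshold}")
    _check_classes(table)
    if classes is not None:
        table = table[table["mclass"].isin(set(classes))]
    rec = _recurrence(table, n_samples)
    rec = rec[rec["recurrence"] >= threshold]
    if model is not None:
        rec = rec[~rec["gene"].isin(transporter_genes(model))]
    return rec.reset_index(drop=True)


def classify_arms(
    table: pd.DataFrame,
    n_samples: int,
    threshold: float = RECURRENCE_THRESHOLD,
) -> dict[str, set[str]]:
    """Assign genes to the LoF/GoF arms by per-arm recurrence.

    A gene enters the LoF arm iff its truncating-class records alone meet
    the recurrence threshold, the GoF arm iff its missense records do; both
    arms are possible, silent and in-frame-indel records count to neither.
    """
    _check_classes(table)
    arms: dict[str, set[str]] = {}
    for arm, classes in (("LoF", LOF_CLASSES), ("GoF", GOF_CLASSES)):
        passed = recurrence_filter(table, n_samples, threshold, classes=classes)
        for gene in passed["gene"]:
            arms.setdefault(gene, set()).add(arm)
    return arms


def isoenzyme_filter(genes: Iterable[str], model: cobra.Model) -> list[str]:
    """Drop genes that are fully redundant in every reaction they catalyse.

    A gene is removed iff each of its reactions' GPRs stays satisfiable with
    that gene knocked out (pure isoenzyme), or if it appears in no GPR.
    """
    retained = []
    model_genes = {g.id: g for g in model.genes}
    for gid in genes:
        gene = model_genes.get(gid)
        if gene is None or not gene.reactions:
            continue  # absent from all GPRs: removed with a note in results
        if any(not gpr_satisfied(r, {gid}) for r in gene.reactions):
            retained.append(gid)
    return retained


def fis_filter(
    genes: Iterable[str],
    table: pd.DataFrame,
    min_fis: float = MIN_FIS,
    enabled: bool = True,
) -> list[str]:
    """Keep genes whose maximal mutation FIS reaches ``min_fis``."""
    genes = list(genes)
    if not enabled:
        return genes
    sub = table[table["gene"].isin(genes)]
    missing = sorted(set(genes) & set(sub.loc[sub["fis"].isna(), "gene"]))
    if missing:
        raise ValueError(f"FIS filter enabled but FIS missing for genes: {missing}")
    max_fis = sub.groupby("gene")["fis"].max()
    return [g for g in genes if max_fis.get(g, float("-inf")) >= min_fis]


def run_screen(
    table: pd.DataFrame,
    model: cobra.Model,
    n_samples: int,
    threshold: float = RECURRENCE_THRESHOLD,
    min_fis: float = MIN_FIS,
    fis_enabled: bool = True,
) -> pd.DataFrame:
    """Run the full funnel; one row per mutated gene with filter outcomes.

    ``selected`` is true iff the gene passes recurrence (in at least one
    arm, transporters excluded), the isoenzyme filter and the FIS filter.
    """
    _check_classes(table)
    rec_all = _recurrence(table, n_samples).set_index("gene")
    arms = classify_arms(table, n_samples, threshold)
    transporters = transporter_genes(model)
    arm_genes = [g for g in arms if g not in transporters]
    iso_ok = set(isoenzyme_filter(arm_genes, model))
    fis_ok = set(fis_filter(sorted(iso_ok), table, min_fis, enabled=fis_enabled))

    rows = []
    for gene in sorted(rec_all.index):
        gene_arms = arms.get(gene, set()) if gene not in transporters else set()
        passed_iso = gene in iso_ok
        passed_fis = gene in fis_ok
        rows.append(
            {
                "gene": gene,
                "n_mutated_samples": int(rec_all.loc[gene, "n_mutated_samples"]),
                "recurrence": float(rec_all.loc[gene, "recurrence"]),
                "arm_lof": "LoF" in gene_arms,
                "arm_gof": "GoF" in gene_arms,
                "passed_isoenzyme": passed_iso,
                "passed_fis": passed_fis,
                "selected": bool(gene_arms) and passed_iso and passed_fis,
            }
        )
    return pd.DataFrame(rows)


def pathway_enrichment(
    selected: Sequence[str],
    model: cobra.Model,
    universe: Sequence[str] | None = None,
    p_cut: float = 1e-3,
    subsystem_map: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric subsystem enrichment of ``selected`` genes.

    Gene-to-subsystem membership follows the subsystems of the reactions a
    gene catalyses.  ``universe`` defaults to all GPR-bearing model genes.
    """
    if subsystem_map is None:
        subsystem_map = {}
        for gene in model.genes:
            subsystem_map[gene.id] = {r.subsystem for r in gene.reactions if r.subsystem}
    if universe is None:
        universe = sorted(subsystem_map)
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty gene universe")
    selected = [g for g in dict.fromkeys(selected) if g in set(universe)]

    subsystems = sorted({s for g in universe for s in subsystem_map.get(g, ())})
    M, n_draw = len(universe), len(selected)
    rows = []
    for subsystem in subsystems:
        members = {g for g in universe if subsystem in subsystem_map.get(g, ())}
        overlap = len(members & set(selected))
        # P(X >= overlap) for X ~ Hypergeom(M, |members|, n_draw)
        p = float(hypergeom.sf(overlap - 1, M, len(members), n_draw))
        rows.append(
            {
                "subsystem": subsystem,
                "n_universe": len(members),
                "n_selected": n_draw,
                "overlap": overlap,
                "p_value": min(p, 1.0),
                "enriched": p < p_cut,
            }
        )
    return pd.DataFrame(rows)
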