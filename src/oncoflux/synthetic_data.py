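"""Synthetic study inputs with planted, recoverable ground truth.

The generators emulate everything the oncometabolite pipeline consumes:

* a small three-compartment metabolic network whose topology mirrors the
  canonical oncometabolite lesions -- a succinate-dehydrogenase-like and a
  fumarate-hydratase-like step whose loss reroutes TCA flux into succinate
  or fumarate overflow, and an isocitrate-dehydrogenase-like enzyme whose
  gain of function is emulated chemically;
* paired cancer/normal expression matrices whose presence/absence structure
  encodes planted reaction removals;
* per-sample somatic mutation tables with controlled recurrence, mutation
  class mixture and functional-impact scores;
* a compound library of native substrates, one close structural analog
  (2-hydroxyglutarate) and clearly dissimilar decoys.

Everything is a pure function of ``(scenario, scenario.seed)``; independent
RNG streams are split off the scenario seed with fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
import yaml
from cobra import Metabolite, Model, Reaction

from oncoflux.core_model import SOLVER_TOLERANCE, write_sbml

LOF_CLASSES = ("nonsense", "frameshift_indel", "splice_site")
GOF_CLASS = "missense"

# -- network blueprint -------------------------------------------------------
# (id, compartment) pairs; compartments: e extracellular, c cytosol,
# m mitochondria.
_METABOLITES = [
    ("glc", "e"), ("glc", "c"), ("o2", "e"), ("o2", "m"), ("co2", "m"),
    ("co2", "e"), ("pyr", "c"), ("pyr", "m"), ("lac", "c"), ("lac", "e"),
    ("accoa", "m"), ("oaa", "m"), ("icit", "m"), ("akg", "m"),
    ("succ", "m"), ("succ", "e"), ("fum", "m"), ("mal", "m"),
    ("nadh", "m"), ("atp", "c"), ("adp", "c"),
    ("cyc1", "c"), ("cyc2", "c"), ("cyc3", "c"),
]

# (id, stoichiometry, lb, ub, gpr, subsystem).  TCA dehydrogenase steps get
# a finite Vmax-like capacity so that, at 90% optimality, the energy balance
# pins their feasible flux well away from zero -- losing one of them then
# moves the whole local flux distribution instead of merely widening it.
_REACTIONS = [
    ("EX_glc_e", {"glc_e": -1}, -10, 0, "", "Exchange"),
    ("EX_o2_e", {"o2_e": -1}, -25, 0, "", "Exchange"),
    ("EX_co2_e", {"co2_e": -1}, 0, 1000, "", "Exchange"),
    ("EX_lac_e", {"lac_e": -1}, 0, 1000, "", "Exchange"),
    ("EX_succ_e", {"succ_e": -1}, 0, 1000, "", "Exchange"),
    ("GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000, "g_glct", "Transport"),
    ("O2t", {"o2_e": -1, "o2_m": 1}, 0, 1000, "", "Transport"),
    ("CO2t", {"co2_m": -1, "co2_e": 1}, -1000, 1000, "", "Transport"),
    ("LACt", {"lac_c": -1, "lac_e": 1}, 0, 1000, "g_lact", "Transport"),
    ("SUCCt", {"succ_m": -1, "succ_e": 1}, 0, 1000, "g_succt", "Transport"),
    ("PYRt", {"pyr_c": -1, "pyr_m": 1}, 0, 1000, "g_pyrt", "Transport"),
    ("GLYC", {"glc_c": -1, "adp_c": -2, "pyr_c": 2, "atp_c": 2}, 0, 1000,
     "g_glyc1 or g_glyc2", "Glycolysis"),
    ("LDH", {"pyr_c": -1, "lac_c": 1}, 0, 1000, "g_ldh", "Fermentation"),
    ("PDH", {"pyr_m": -1, "accoa_m": 1, "co2_m": 1, "nadh_m": 1}, 0, 1000,
     "g_pdh", "TCA cycle"),
    ("PC", {"pyr_m": -1, "co2_m": -1, "oaa_m": 1}, 0, 1000,
     "g_pc", "Anaplerosis"),
    ("CS", {"accoa_m": -1, "oaa_m": -1, "icit_m": 1}, 0, 1000,
     "g_cs", "TCA cycle"),
    ("IDH", {"icit_m": -1, "akg_m": 1, "co2_m": 1, "nadh_m": 1}, 0, 1000,
     "g_idh", "TCA cycle"),
    ("AKGDH", {"akg_m": -1, "succ_m": 1, "co2_m": 1, "nadh_m": 1}, 0, 1000,
     "g_akgdh", "TCA cycle"),
    ("SDH", {"succ_m": -1, "fum_m": 1, "nadh_m": 1}, 0, 1.5,
     "g_sdh", "TCA cycle"),
    ("FUM", {"fum_m": -1, "mal_m": 1}, 0, 1.5, "g_fh", "TCA cycle"),
    ("MDH", {"mal_m": -1, "oaa_m": 1, "nadh_m": 1}, 0, 1.5,
     "g_mdh", "TCA cycle"),
    ("OXPHOS", {"nadh_m": -1, "o2_m": -0.5, "adp_c": -2, "atp_c": 2}, 0, 1000,
     "g_oxphos", "Oxidative phosphorylation"),
    ("ATPM", {"atp_c": -1, "adp_c": 1}, 38.0, 1000, "", "Maintenance"),
    ("BIOMASS", {"akg_m": -1, "pyr_c": -1, "atp_c": -2, "adp_c": 2}, 0, 1000,
     "", "Biomass"),
    # Thermodynamically infeasible 3-cycle: exercised by the loop filter.
    ("CYC1", {"cyc1_c": -1, "cyc2_c": 1}, -1000, 1000, "g_cyc1", "Futile cycle"),
    ("CYC2", {"cyc2_c": -1, "cyc3_c": 1}, -1000, 1000, "g_cyc2", "Futile cycle"),
    ("CYC3", {"cyc3_c": -1, "cyc1_c": 1}, -1000, 1000, "g_cyc3", "Futile cycle"),
]

_MODEL_GENES = sorted(
    {g for _, _, _, _, gpr, _ in _REACTIONS for g in
     gpr.replace("(", " ").replace(")", " ").replace(" or ", " ").replace(" and ", " ").split()
     if g}
)

# Compound library template: native substrates of the toy network, the
# 2-hydroxyglutarate analog, and structurally unrelated decoys.
_COMPOUNDS = [
    # compound_id, smiles, model metabolite (base id) or "", role
    ("isocitrate", "OC(C(CC(=O)O)C(=O)O)C(=O)O", "icit", "native"),
    ("alpha_ketoglutarate", "OC(=O)CCC(=O)C(=O)O", "akg", "native"),
    ("2_hydroxyglutarate", "OC(CCC(=O)O)C(=O)O", "", "analog"),
    ("succinate", "OC(=O)CCC(=O)O", "succ", "native"),
    ("fumarate", "OC(=O)/C=C/C(=O)O", "fum", "native"),
    ("malate", "OC(CC(=O)O)C(=O)O", "mal", "native"),
    ("oxaloacetate", "OC(=O)CC(=O)C(=O)O", "oaa", "native"),
    ("pyruvate", "CC(=O)C(=O)O", "pyr", "native"),
    ("lactate", "CC(O)C(=O)O", "lac", "native"),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O", "glc", "native"),
    ("benzoate", "OC(=O)c1ccccc1", "", "decoy"),
    ("octanol", "CCCCCCCCO", "", "decoy"),
    ("urea", "NC(N)=O", "", "decoy"),
    ("glycerol", "OCC(O)CO", "", "decoy"),
    ("indole", "c1ccc2c(c1)cc[nH]2", "", "decoy"),
    ("toluene", "Cc1ccccc1", "", "decoy"),
]


def _default_recurrence() -> dict[str, float]:
    return {
        # planted drivers
        "g_sdh": 0.12, "g_fh": 0.12, "g_idh": 0.12,
        # decoys: recurrent but removed by one filter each
        "g_ldh": 0.08,    # low functional-impact score
        "g_glyc1": 0.10,  # redundant isoenzyme
        "g_pyrt": 0.10,   # transporter
        "g_cs": 0.08,     # silent mutations only
        # below the recurrence threshold
        "g_mdh": 0.02,
    }


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study.

    The defaults are the package's reference conditions: sample sizes in the
    range of the site-matched expression series the pipeline is meant for,
    planted driver genes mutated in 12% of tumours (comfortably above the 5%
    recurrence screen), decoy genes that each trip exactly one filter, and
    one gene whose expression presence/absence differs between conditions.
    """

    seed: int = 1
    n_genes: int = len(_MODEL_GENES)
    n_samples_cancer: int = 60
    n_samples_normal: int = 60
    #: gene -> metabolites (base ids) expected to surround the flux lesion
    planted_lof: Sequence[tuple[str, tuple[str, ...]]] = (
        ("g_sdh", ("succ", "fum")),
        ("g_fh", ("fum", "mal")),
    )
    #: (gene, native substrate compound id, analog compound id)
    planted_gof: Sequence[tuple[str, str, str]] = (
        ("g_idh", "isocitrate", "2_hydroxyglutarate"),
    )
    recurrence_map: Mapping[str, float] = field(default_factory=_default_recurrence)
    #: (gene, condition in which the gene is absent): "cancer" or "normal"
    pa_shift: Sequence[tuple[str, str]] = (("g_ldh", "normal"),)
    detection_threshold: float = 10.0

    def validate(self) -> None:
        genes = set(_MODEL_GENES)
        planted = {g for g, _ in self.planted_lof}
        planted |= {g for g, _, _ in self.planted_gof}
        missing = sorted(planted - genes)
        if missing:
            raise ValueError(f"planted genes not hosted by the toy network: {missing}")
        for gene, frac in self.recurrence_map.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"recurrence fraction for {gene} outside [0, 1]: {frac}")
        if self.n_samples_cancer <= 0 or self.n_samples_normal <= 0:
            raise ValueError("sample counts must be positive")
        if self.n_genes < len(_MODEL_GENES):
            raise ValueError(
                f"scenario too small to host the planted structures: "
                f"n_genes={self.n_genes} < {len(_MODEL_GENES)}"
            )

    def rng(self, stream: int) -> np.random.Generator:
        """Independent RNG stream ``stream`` for this scenario."""
        return np.random.default_rng((int(self.seed) * 1_000_003 + stream) % 2**31)


def generate_toy_model(scenario: SyntheticScenario) -> Model:
    """Build the toy genome-scale model hosting the planted lesions.

    The network takes up a glucose-like carbon source and oxygen, secretes
    CO2, lactate and succinate, runs a lumped glycolysis (with an isoenzyme
    pair), a TCA-like cycle with anaplerosis, oxidative phosphorylation, an
    ATP maintenance demand and a biomass drain.  Deleting a planted LoF gene
    provably reroutes flux around the listed metabolites while the model
    stays viable.  Deterministic: topology does not depend on the seed.
    """
    scenario.validate()
    model = Model("oncoflux_toy")
    mets = {
        f"{base}_{comp}": Metabolite(f"{base}_{comp}", name=base, compartment=comp)
        for base, comp in _METABOLITES
    }
    reactions = []
    for rid, stoich, lb, ub, gpr, subsystem in _REACTIONS:
        rxn = Reaction(rid)
        rxn.add_metabolites({mets[k]: v for k, v in stoich.items()})
        rxn.bounds = (lb, ub)
        rxn.gene_reaction_rule = gpr
        rxn.subsystem = subsystem
        reactions.append(rxn)
    model.add_reactions(reactions)
    model.objective = "BIOMASS"
    model.compartments = {"e": "extracellular", "c": "cytosol", "m": "mitochondria"}
    model.solver.configuration.tolerances.feasibility = SOLVER_TOLERANCE
    return model


def generate_expression(
    scenario: SyntheticScenario, model: Model
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired cancer/normal expression matrices (genes x samples).

    Genes listed in ``scenario.pa_shift`` fall below the detection threshold
    in every sample of the designated condition; all other model genes are
    detected in every sample of both conditions, with multiplicative
    lognormal noise on the expressed values.
    """
    scenario.validate()
    rng = scenario.rng(11)
    genes = sorted(g.id for g in model.genes)
    absent_in = {gene: cond for gene, cond in scenario.pa_shift}
    thr = scenario.detection_threshold

    def matrix(condition: str, n_samples: int, prefix: str) -> pd.DataFrame:
        if n_samples <= 0:
            raise ValueError(f"{condition}: number of samples must be positive")
        cols = [f"{prefix}{i + 1:03d}" for i in range(n_samples)]
        values = np.empty((len(genes), n_samples))
        for i, gene in enumerate(genes):
            if absent_in.get(gene) == condition:
                values[i] = rng.uniform(0.0, 0.01 * thr, size=n_samples)
            else:
                values[i] = thr * (1.0 + rng.lognormal(mean=1.0, sigma=0.5, size=n_samples))
        return pd.DataFrame(values, index=genes, columns=cols)

    cancer = matrix("cancer", scenario.n_samples_cancer, "C")
    normal = matrix("normal", scenario.n_samples_normal, "N")
    return cancer, normal


def generate_mutations(scenario: SyntheticScenario, model: Model) -> pd.DataFrame:
    """Somatic mutation table: columns ``gene, sample, mclass, fis``.

    Recurrence per gene follows ``scenario.recurrence_map`` to within one
    sample.  Planted LoF genes receive truncating classes, planted GoF genes
    missense; planted genes get high functional-impact scores, decoys low.
    """
    scenario.validate()
    rng = scenario.rng(23)
    n = scenario.n_samples_cancer
    samples = np.array([f"C{i + 1:03d}" for i in range(n)])
    lof_genes = {g for g, _ in scenario.planted_lof}
    gof_genes = {g for g, _, _ in scenario.planted_gof}
    model_genes = {g.id for g in model.genes}

    rows = []
    for gene in sorted(scenario.recurrence_map):
        if gene not in model_genes:
            raise ValueError(f"recurrence_map gene not in model: {gene}")
        frac = scenario.recurrence_map[gene]
        k = int(round(frac * n))
        if k == 0:
            continue
        mutated = rng.choice(samples, size=k, replace=False)
        for sample in mutated:
            if gene in lof_genes:
                mclass = rng.choice(LOF_CLASSES)
            elif gene == "g_cs":
                mclass = "silent"
            else:
                mclass = GOF_CLASS
            planted = gene in lof_genes or gene in gof_genes
            decoy_high_fis = gene in {"g_glyc1", "g_pyrt"}
            if planted or decoy_high_fis:
                fis = 3.5 + abs(rng.normal(0.0, 0.5))
            else:
                fis = rng.uniform(0.0, 1.5)
            rows.append((gene, sample, mclass, round(float(fis), 3)))
    return pd.DataFrame(rows, columns=["gene", "sample", "mclass", "fis"])


def generate_compound_library(scenario: SyntheticScenario) -> pd.DataFrame:
    """Compound library: ``compound_id, smiles, metabolite, role``.

    Contains every native substrate of the toy network, the close structural
    analog of the planted gain-of-function pair, and >= 5 dissimilar decoys.
    All SMILES are validated with RDKit.
    """
    from rdkit import Chem

    scenario.validate()
    rows = []
    for cid, smiles, met, role in _COMPOUNDS:
        if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover - template guard
            raise ValueError(f"invalid SMILES in compound template: {cid}={smiles!r}")
        rows.append((cid, smiles, met, role))
    return pd.DataFrame(rows, columns=["compound_id", "smiles", "metabolite", "role"])


def write_scenario_bundle(scenario: SyntheticScenario, outdir) -> dict[str, Path]:
    """Materialise all generator outputs under ``outdir``.

    Writes the SBML model, expression and mutation TSVs, the SMILES table
    and a YAML manifest; returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = generate_toy_model(scenario)
    cancer, normal = generate_expression(scenario, model)
    mutations = generate_mutations(scenario, model)
    library = generate_compound_library(scenario)

    paths = {
        "model": outdir / "toy_model.xml",
        "expression_cancer": outdir / "expression_cancer.tsv",
        "expression_normal": outdir / "expression_normal.tsv",
        "mutations": outdir / "mutations.tsv",
        "compounds": outdir / "compound_library.tsv",
        "manifest": outdir / "scenario.yml",
    }
    write_sbml(model, paths["model"])
    cancer.to_csv(paths["expression_cancer"], sep="\t")
    normal.to_csv(paths["expression_normal"], sep="\t")
    mutations.to_csv(paths["mutations"], sep="\t", index=False)
    library.to_csv(paths["compounds"], sep="\t", index=False)
    manifest = {
        "seed": scenario.seed,
        "n_samples_cancer": scenario.n_samples_cancer,
        "n_samples_normal": scenario.n_samples_normal,
        "planted_lof": [[g, list(m)] for g, m in scenario.planted_lof],
        "planted_gof": [list(t) for t in scenario.planted_gof],
        "recurrence_map": dict(scenario.recurrence_map),
        "pa_shift": [list(t) for t in scenario.pa_shift],
        "detection_threshold": scenario.detection_threshold,
    }
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True))
    return paths
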