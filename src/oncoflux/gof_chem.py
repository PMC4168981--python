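"""Gain-of-function arm: fingerprints, reaction operators, promiscuity calls.

The neomorphic-activity model follows the IDH paradigm: a missense-mutated
enzyme may catalyse a reaction on a substrate structurally close to a
native participant, through a generic transformation.  The machinery:

* **Chemical fingerprints** -- hashed linear-path fingerprints (1024 bits,
  fragments up to 6 bonds, 2 bits per pattern) over canonicalised
  structures.
* **Tanimoto metrics** -- similarity ``B(a & b) / B(a | b)`` over the set
  bits, dissimilarity ``TCdiss = 1 - TCsim``; zero dissimilarity means
  identical fingerprints.
* **Reaction fingerprints** -- 8 concatenated compound sections (up to 4
  substrates + 4 products after cofactor removal, each side sorted by
  canonical SMILES).
* **Biochemical reaction operators (BROs)** -- irreversible SMIRKS
  transforms tagged with a third-level EC number and their cofactor pair;
  a small curated library ships with the package and user libraries in the
  same tab-separated format are accepted.
* **Promiscuity calling** -- synthetic reactions are enumerated over
  operator x analog-substrate combinations, mass-balance filtered
  (substrate + cofactor reactants versus product + cofactor products,
  heavy atoms and hydrogens), capped per native reaction, and saved as
  gain-of-function pairs when the reaction-level TCdiss to the native
  reaction does not exceed a cutoff calibrated on the packaged
  isocitrate/2-hydroxyglutarate pair.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdChemReactions, rdFMCS
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

RDLogger.DisableLog("rdApp.*")

FP_SIZE = 1024
FP_MAX_PATH = 6  # bonds
FP_BITS_PER_PATTERN = 2
REACTION_SLOTS_PER_SIDE = 4

MAX_ACTIVITIES = 30_000
SUBSTRATE_TC_CUTOFF = 0.6
REACTION_CUTOFF_MARGIN = 0.05

#: the packaged IDH-analog calibration pair: the native oxidative
#: decarboxylation substrate/product and the neomorphic reduction product.
ISOCITRATE_SMILES = "OC(C(CC(=O)O)C(=O)O)C(=O)O"
ALPHA_KG_SMILES = "OC(=O)CCC(=O)C(=O)O"
HYDROXYGLUTARATE_SMILES = "OC(CCC(=O)O)C(=O)O"


class SmilesError(ValueError):
    """Raised when a structure cannot be parsed."""


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"invalid SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    return Chem.MolToSmiles(_mol(smiles))


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length hashed path fingerprint of one structure."""

    bits: np.ndarray  # bool, length FP_SIZE (or a multiple for reactions)

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    def __len__(self) -> int:
        return self.bits.size

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def compound_fingerprint(smiles: str) -> Fingerprint:
    """Hashed linear-path fingerprint of a canonicalised structure."""
    mol = _mol(canonical_smiles(smiles))
    if mol.GetNumBonds() == 0:
        # single-heavy-atom molecules have no heavy-atom paths; use the
        # explicit-hydrogen bonds so the fingerprint is sparse but non-zero
        mol = Chem.AddHs(mol)
    bv = Chem.RDKFingerprint(
        mol,
        minPath=1,
        maxPath=FP_MAX_PATH,
        fpSize=FP_SIZE,
        nBitsPerHash=FP_BITS_PER_PATTERN,
    )
    return Fingerprint(bits=np.array(bv, dtype=bool))


def tanimoto(a: Fingerprint, b: Fingerprint) -> tuple[float, float]:
    """Tanimoto similarity and dissimilarity of two equal-length fingerprints.

    Two all-zero fingerprints count as identical (similarity 1).
    """
    if len(a) != len(b):
        raise ValueError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    union = int(np.logical_or(a.bits, b.bits).sum())
    sim = 1.0 if union == 0 else int(np.logical_and(a.bits, b.bits).sum()) / union
    return sim, 1.0 - sim


@dataclass(frozen=True)
class ReactionFingerprint:
    """Segmented fingerprint: 4 substrate + 4 product compound sections."""

    segments: tuple[Fingerprint, ...]

    def __post_init__(self):
        if len(self.segments) != 2 * REACTION_SLOTS_PER_SIDE:
            raise ValueError("reaction fingerprint needs exactly 8 segments")

    @property
    def concatenated(self) -> Fingerprint:
        return Fingerprint(bits=np.concatenate([s.bits for s in self.segments]))


def reaction_fingerprint(
    substrates: Sequence[str], products: Sequence[str]
) -> ReactionFingerprint:
    """Segmented reaction fingerprint from substrate/product SMILES.

    Each side is sorted by canonical SMILES so the representation does not
    depend on input order; empty slots are zero sections.  More than four
    compounds on a side is an error -- exclude cofactors first.
    """

    def side(smiles_list: Sequence[str]) -> list[Fingerprint]:
        if len(smiles_list) > REACTION_SLOTS_PER_SIDE:
            raise ValueError(
                f"more than {REACTION_SLOTS_PER_SIDE} compounds on one side; "
                "remove cofactors before fingerprinting"
            )
        ordered = sorted(canonical_smiles(s) for s in smiles_list)
        fps = [compound_fingerprint(s) for s in ordered]
        fps += [Fingerprint(bits=np.zeros(FP_SIZE, dtype=bool))] * (
            REACTION_SLOTS_PER_SIDE - len(fps)
        )
        return fps

    return ReactionFingerprint(segments=tuple(side(substrates) + side(products)))


def reaction_tanimoto(
    a: ReactionFingerprint, b: ReactionFingerprint
) -> tuple[float, float]:
    return tanimoto(a.concatenated, b.concatenated)


# -- elemental bookkeeping ---------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Counter:
    """Elemental composition of a Hill-notation formula (charge ignored)."""
    counts: Counter = Counter()
    for element, number in _FORMULA_TOKEN.findall(formula.split("+")[0].split("-")[0]):
        if element:
            counts[element] += int(number) if number else 1
    return counts


def molecular_formula(smiles: str) -> Counter:
    return parse_formula(CalcMolFormula(_mol(smiles)))


@dataclass(frozen=True)
class ReactionOperator:
    """Generic irreversible transformation with EC tag and cofactor pair."""

    id: str
    name: str
    smirks: str
    ec3: str
    cofactor_reactants: tuple[str, ...] = ()
    cofactor_products: tuple[str, ...] = ()

    def reaction(self) -> rdChemReactions.ChemicalReaction:
        rxn = rdChemReactions.ReactionFromSmarts(self.smirks)
        if rxn is None:
            raise ValueError(f"operator {self.id}: SMIRKS does not parse")
        return rxn


def _packaged(name: str):
    return resources.files("oncoflux.data") / name


def load_cofactor_formulas(path=None) -> dict[str, Counter]:
    """Cofactor id -> elemental composition, from the packaged table."""
    with resources.as_file(_packaged("cofactors.tsv")) if path is None else _nullctx(path) as p:
        table = pd.read_csv(p, sep="\t")
    return {row.cofactor_id: parse_formula(row.formula) for row in table.itertuples()}


class _nullctx:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def load_operators(path=None) -> list[ReactionOperator]:
    """Load a SMIRKS operator library (the packaged one by default)."""
    with resources.as_file(_packaged("operators.tsv")) if path is None else _nullctx(path) as p:
        table = pd.read_csv(p, sep="\t", keep_default_na=False)
    ops = []
    for row in table.itertuples():
        op = ReactionOperator(
            id=row.operator_id,
            name=row.name,
            smirks=row.smirks,
            ec3=row.ec3,
            cofactor_reactants=tuple(c for c in row.cofactor_reactants.split(";") if c),
            cofactor_products=tuple(c for c in row.cofactor_products.split(";") if c),
        )
        op.reaction()  # validate eagerly
        ops.append(op)
    return ops


@dataclass(frozen=True)
class SyntheticReaction:
    """One enumerated promiscuous activity."""

    substrate: str  # canonical SMILES
    product: str
    operator_id: str
    ec3: str
    balanced: bool
    substrate_id: str = ""


def mass_balanced(
    op: ReactionOperator,
    substrate: str,
    product: str,
    cofactor_formulas: Mapping[str, Counter],
) -> bool:
    """Elemental balance of substrate + cofactors -> product + cofactors."""
    left = molecular_formula(substrate).copy()
    right = molecular_formula(product).copy()
    for cid in op.cofactor_reactants:
        left += cofactor_formulas[cid]
    for cid in op.cofactor_products:
        right += cofactor_formulas[cid]
    return left == right


def apply_operator(
    op: ReactionOperator,
    substrate: str,
    cofactor_formulas: Mapping[str, Counter] | None = None,
    balance_filter: bool = True,
    substrate_id: str = "",
) -> list[SyntheticReaction]:
    """All distinct products of applying ``op`` at every matching site.

    Products failing valence sanitisation are discarded; when the mass
    balance filter is on, unbalanced reactions are dropped as well.  A
    pattern that matches nowhere yields an empty list.
    """
    if cofactor_formulas is None:
        cofactor_formulas = load_cofactor_formulas()
    sub_canonical = canonical_smiles(substrate)
    mol = _mol(sub_canonical)
    out, seen = [], set()
    for products in op.reaction().RunReactants((mol,)):
        product = products[0]
        try:
            Chem.SanitizeMol(product)
        except Exception:
            continue
        psmiles = Chem.MolToSmiles(product)
        if psmiles in seen or psmiles == sub_canonical:
            continue
        seen.add(psmiles)
        balanced = mass_balanced(op, sub_canonical, psmiles, cofactor_formulas)
        if balance_filter and not balanced:
            continue
        out.append(
            SyntheticReaction(
                substrate=sub_canonical,
                product=psmiles,
                operator_id=op.id,
                ec3=op.ec3,
                balanced=balanced,
                substrate_id=substrate_id,
            )
        )
    return out


def select_candidates(
    native_substrate: str,
    library: pd.DataFrame,
    tc_cutoff: float = SUBSTRATE_TC_CUTOFF,
    cofactor_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Library compounds within ``tc_cutoff`` TCdiss of the native substrate.

    The native structure itself and configured cofactor compounds are
    excluded.  ``library`` needs columns ``compound_id`` and ``smiles``.
    Returns the selected rows with an extra ``substrate_tcdiss`` column.
    """
    if library.empty:
        raise ValueError("empty compound library")
    native_fp = compound_fingerprint(native_substrate)
    native_canonical = canonical_smiles(native_substrate)
    excluded = set(cofactor_ids)
    rows = []
    for row in library.itertuples():
        if row.compound_id in excluded:
            continue
        if canonical_smiles(row.smiles) == native_canonical:
            continue
        _, diss = tanimoto(native_fp, compound_fingerprint(row.smiles))
        if diss <= tc_cutoff:
            rows.append((row.Index, diss))
    out = library.loc[[i for i, _ in rows]].copy()
    out["substrate_tcdiss"] = [d for _, d in rows]
    return out.reset_index(drop=True)


@dataclass
class EnumerationResult:
    reactions: list[SyntheticReaction]
    capped: bool
    n_raw: int


def enumerate_synthetic_reactions(
    candidates: pd.DataFrame,
    operators: Sequence[ReactionOperator],
    max_activities: int = MAX_ACTIVITIES,
    balance_filter: bool = True,
) -> EnumerationResult:
    """Cross product of candidate substrates and operators, deduplicated.

    Duplicates are collapsed on (canonical substrate, canonical product,
    EC level-3).  If the raw activity count for the native reaction
    exceeds ``max_activities`` the enumeration is reported as capped and
    no reactions are returned, mirroring the exclusion of overly complex
    substrates.
    """
    if candidates.empty:
        raise ValueError("no candidate substrates to enumerate over")
    cofactors = load_cofactor_formulas()
    reactions: dict[tuple[str, str, str], SyntheticReaction] = {}
    n_raw = 0
    for row in candidates.itertuples():
        for op in operators:
            for rxn in apply_operator(
                op, row.smiles, cofactors, balance_filter, substrate_id=row.compound_id
            ):
                n_raw += 1
                reactions.setdefault((rxn.substrate, rxn.product, rxn.ec3), rxn)
    if n_raw > max_activities:
        return EnumerationResult(reactions=[], capped=True, n_raw=n_raw)
    return EnumerationResult(reactions=list(reactions.values()), capped=False, n_raw=n_raw)


@dataclass(frozen=True)
class PromiscuityPair:
    """A synthetic reaction judged against the native reaction."""

    native_substrates: tuple[str, ...]
    native_products: tuple[str, ...]
    synthetic: SyntheticReaction
    substrate_tcdiss: float
    reaction_tcdiss: float
    saved: bool


def default_reaction_cutoff(margin: float = REACTION_CUTOFF_MARGIN) -> float:
    """Reaction-level TCdiss cutoff calibrated on the IDH-analog pair.

    The dissimilarity between the packaged native oxidative step
    (isocitrate -> alpha-ketoglutarate) and its neomorphic counterpart
    (alpha-ketoglutarate -> 2-hydroxyglutarate), plus a margin.
    """
    native = reaction_fingerprint([ISOCITRATE_SMILES], [ALPHA_KG_SMILES])
    neomorphic = reaction_fingerprint([ALPHA_KG_SMILES], [HYDROXYGLUTARATE_SMILES])
    _, diss = reaction_tanimoto(native, neomorphic)
    return diss + margin


def call_gof_pairs(
    native_substrates: Sequence[str],
    native_products: Sequence[str],
    synthetic_reactions: Sequence[SyntheticReaction],
    reaction_tc_cutoff: float | None = None,
) -> list[PromiscuityPair]:
    """Score synthetic reactions against the native reaction fingerprint.

    A pair is saved when its reaction-level TCdiss is at or below the
    cutoff (default: the IDH-calibrated value).  The native fingerprint
    must not be degenerate (all-zero).
    """
    if reaction_tc_cutoff is None:
        reaction_tc_cutoff = default_reaction_cutoff()
    native_fp = reaction_fingerprint(native_substrates, native_products)
    if native_fp.concatenated.popcount == 0:
        raise ValueError("native reaction fingerprint is degenerate (all zero)")
    native_sub_fp = compound_fingerprint(native_substrates[0])
    pairs = []
    for rxn in synthetic_reactions:
        _, sub_diss = tanimoto(native_sub_fp, compound_fingerprint(rxn.substrate))
        _, rxn_diss = reaction_tanimoto(
            native_fp, reaction_fingerprint([rxn.substrate], [rxn.product])
        )
        pairs.append(
            PromiscuityPair(
                native_substrates=tuple(native_substrates),
                native_products=tuple(native_products),
                synthetic=rxn,
                substrate_tcdiss=sub_diss,
                reaction_tcdiss=rxn_diss,
                saved=rxn_diss <= reaction_tc_cutoff,
            )
        )
    return pairs


@dataclass(frozen=True)
class SubstructureSummary:
    """Most common substructure of a compound set."""

    mcs_smarts: str
    support: float
    n_atoms: int
    dominant: bool
    degenerate: bool = False


def dominant_substructure(
    smiles_list: Sequence[str],
    support_threshold: float = 0.5,
    min_atoms: int = 3,
    timeout_s: int = 10,
) -> SubstructureSummary:
    """Maximum common substructure supported by most of the compound set.

    Searches for the largest substructure present in at least
    ``support_threshold`` of the compounds; the summary is *dominant* when
    the verified support reaches the threshold and the pattern has at
    least ``min_atoms`` heavy atoms.  A single compound yields its own
    scaffold, flagged degenerate.
    """
    mols = [_mol(s) for s in smiles_list]
    if not mols:
        raise ValueError("empty compound set")
    if len(mols) == 1:
        return SubstructureSummary(
            mcs_smarts=Chem.MolToSmarts(mols[0]),
            support=1.0,
            n_atoms=mols[0].GetNumAtoms(),
            dominant=True,
            degenerate=True,
        )
    mcs = rdFMCS.FindMCS(
        mols,
        threshold=support_threshold,
        timeout=timeout_s,
        completeRingsOnly=False,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
    )
    if mcs.canceled or not mcs.smartsString or mcs.numAtoms < 1:
        return SubstructureSummary("", 0.0, 0, dominant=False)
    pattern = Chem.MolFromSmarts(mcs.smartsString)
    support = float(np.mean([m.HasSubstructMatch(pattern) for m in mols]))
    return SubstructureSummary(
        mcs_smarts=mcs.smartsString,
        support=support,
        n_atoms=mcs.numAtoms,
        dominant=support >= support_threshold and mcs.numAtoms >= min_atoms,
    )
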