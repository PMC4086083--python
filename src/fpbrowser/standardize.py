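"""Molecule standardization and annotation.

Every library molecule passes through the same three-step pipeline exactly
once, at library-build time:

1. counter-ion removal — keep the largest fragment of a multi-fragment
   structure;
2. pH 7.4 ionization — a fixed, deterministic rule table (deprotonate
   carboxylic / sulfonic / phosphonic acids; protonate aliphatic amines,
   amidines and guanidines; anilines, amides, alcohols and phenols stay
   neutral);
3. annotation — molecular formula, hydrogen-bond acceptor and donor counts,
   and the numbers of oxygen and nitrogen atoms, which back the query-time
   property filters.

The pipeline is idempotent: standardizing an already-standardized structure
is a no-op.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors
from rdkit.Chem.Lipinski import NHOHCount, NOCount

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Nine supplier bits; a record's vendor mask is an integer in [1, 511].
N_VENDOR_BITS = 9
VENDOR_MASK_MAX = (1 << N_VENDOR_BITS) - 1  # 511, "all vendors"


class ParseError(ValueError):
    """Raised when an input structure string cannot be parsed."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized, annotated library molecule.

    Attributes
    ----------
    id : str
        Unique identifier (duplicate structures with distinct ids are kept).
    smiles : str
        Canonical SMILES of the single retained fragment.
    formula : str
        Hill-order molecular formula (charged species carry their charge,
        e.g. ``C9H14NO3+``).
    hba, hbd : int
        Hydrogen-bond acceptor count (N + O atoms) and donor count
        (hydrogens on N or O), Lipinski-style.
    n_oxygen, n_nitrogen : int
        Element counts used by the exact-composition query filters.
    vendor_mask : int
        9-bit supplier availability mask in [1, 511].
    """

    id: str
    smiles: str
    formula: str
    hba: int
    hbd: int
    n_oxygen: int
    n_nitrogen: int
    vendor_mask: int


def _mol_from_smiles(smiles: str, context: str = "") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        where = f" ({context})" if context else ""
        raise ParseError(f"unparseable SMILES {smiles!r}{where}")
    return mol


def strip_counter_ions(raw_smiles: str) -> str:
    """Return the canonical SMILES of the retained fragment.

    The fragment with the most heavy atoms is kept; ties go to the fragment
    with more carbons, then to the lexicographically smallest canonical
    SMILES.
    """
    mol = _mol_from_smiles(raw_smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return Chem.MolToSmiles(frags[0])

    def key(frag: Chem.Mol) -> tuple[int, int, str]:
        n_carbon = sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() == 6)
        return (-frag.GetNumHeavyAtoms(), -n_carbon, Chem.MolToSmiles(frag))

    best = min(frags, key=key)
    return Chem.MolToSmiles(best)


# Rule table for pH 7.4. Each entry: (SMARTS, index of the atom to modify
# within the match, charge delta). Acid rules remove one H from a neutral
# O-H; base rules add one H. Patterns are written so that an already
# transformed site no longer matches, which makes the table idempotent.
_ACID_RULES = (
    # carboxylic acid -> carboxylate
    ("[CX3](=O)[OX2H1]", 2, -1),
    # sulfonic acid -> sulfonate
    ("[SX4](=O)(=O)[OX2H1]", 3, -1),
    # phosphonic/phosphoric acid O-H -> phosphonate (every acidic O-H)
    ("[PX4](=O)[OX2H1]", 2, -1),
)
_BASE_RULES = (
    # aliphatic primary/secondary/tertiary amine -> ammonium. Excludes
    # anilines, amides/sulfonamides, N-N/N-O linked and unsaturated N.
    ("[NX3;v3;!$(N[a]);!$(NC=[O,S,N]);!$(N[#7,#8,#15,#16]);!$(N=*)]", 0, +1),
    # amidine / guanidine sp2 nitrogen -> amidinium/guanidinium
    ("[NX2;v3;!$(N[a])]=[CX3][NX3]", 0, +1),
)


def adjust_ionization_ph74(smiles: str) -> str:
    """Apply the fixed pH 7.4 protonation rule table and re-canonicalize.

    This is a deterministic stand-in for pKa-based microspecies prediction:
    it covers the dominant drug-like ionizable groups and nothing else.
    """
    mol = _mol_from_smiles(smiles)
    rw = Chem.RWMol(mol)
    modified: set[int] = set()  # symmetric matches must not fire twice
    for smarts, pos, delta in _ACID_RULES + _BASE_RULES:
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetSubstructMatches(patt):
            if match[pos] in modified:
                continue
            atom = rw.GetAtomWithIdx(match[pos])
            if delta < 0 and atom.GetTotalNumHs() < 1:
                continue
            modified.add(match[pos])
            atom.SetFormalCharge(atom.GetFormalCharge() + delta)
            atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() + delta))
            atom.SetNoImplicit(True)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def annotate(smiles: str, id: str, vendor_mask: int = VENDOR_MASK_MAX) -> MoleculeRecord:
    """Build a :class:`MoleculeRecord` from a standardized structure.

    HBA is the count of N + O atoms and HBD the count of hydrogens bonded
    to N or O (the Lipinski rule-of-five definitions).
    """
    if not 1 <= vendor_mask <= VENDOR_MASK_MAX:
        raise ValueError(
            f"vendor_mask must be in [1, {VENDOR_MASK_MAX}], got {vendor_mask}"
        )
    mol = _mol_from_smiles(smiles)
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError(f"expected a single-fragment structure, got {smiles!r}")
    return MoleculeRecord(
        id=id,
        smiles=Chem.MolToSmiles(mol),
        formula=rdMolDescriptors.CalcMolFormula(mol),
        hba=NOCount(mol),
        hbd=NHOHCount(mol),
        n_oxygen=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 8),
        n_nitrogen=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7),
        vendor_mask=vendor_mask,
    )


def standardize_smiles(raw_smiles: str) -> str:
    """Full strip -> ionize pipeline, returning the canonical SMILES."""
    return adjust_ionization_ph74(strip_counter_ions(raw_smiles))


def load_library(path: str | Path) -> list[MoleculeRecord]:
    """Read a ``.smi`` library file and standardize every molecule.

    Dialect: one record per line, whitespace-separated
    ``SMILES id [vendor_mask]``; ``#`` lines are comments; a missing vendor
    mask defaults to 511 (all vendors). Malformed lines are skipped with a
    logged warning; an input yielding zero valid records is an error.
    """
    path = Path(path)
    records: list[MoleculeRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if len(parts) == 2:
                    raw, mol_id = parts
                    mask = VENDOR_MASK_MAX
                elif len(parts) == 3:
                    raw, mol_id = parts[:2]
                    mask = int(parts[2])
                else:
                    raise ValueError(f"expected 2 or 3 fields, got {len(parts)}")
                records.append(annotate(standardize_smiles(raw), mol_id, mask))
            except (ValueError, ParseError) as exc:
                logger.warning("%s:%d: skipping line (%s)", path, lineno, exc)
    if not records:
        raise ValueError(f"no valid records in {path}")
    return records
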