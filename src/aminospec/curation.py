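"""Amino-acid library curation: scaffold classification, derivatization
detection, cross-library deduplication and property annotation.

The central gate is :func:`classify_type1a`, a substructure predicate for
"Type Ia" monosubstituted alpha-amino acids: one carbon bearing a primary,
acyclic, non-amide amine, a carboxylic acid, and at most one non-hydrogen
side chain.  Glycine (side chain = H) is the degenerate member and is
accepted.  Derivatized molecules are classified on their parent scaffold:
tert-butyldimethylsilyl (TBDMS) groups — the product of MTBSTFA
derivatization, which replaces active hydrogens on O, N and S — are stripped
before core matching, so free and derivatized forms of the same amino acid
classify identically.

Compound identity for deduplication uses the first (skeleton) block of the
InChIKey, deliberately ignoring stereochemistry: EI spectra of enantiomers
are identical, so stricter matching would under-deduplicate D/L pairs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors

from .spectra import Spectrum

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "MoleculeRecord",
    "classify_type1a",
    "detect_tbdms",
    "dedup_against",
    "filter_instrument",
    "annotate_properties",
    "strip_tbdms_smiles",
]


@dataclass
class MoleculeRecord:
    """A compound's structure key, physicochemical properties and class flags."""

    compound_id: str
    smiles: str
    structure_key: str = ""
    molecular_weight: float = 0.0
    logp: float = 0.0
    is_type1a_alpha_aa: bool = False
    derivatized: bool = False
    tbdms_count: int = 0
    source_library: str = ""


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


# Si bearing two methyls and one tert-butyl, attached to O, N or S.
_TBDMS = Chem.MolFromSmarts("[#7,#8,#16][Si]([CH3])([CH3])[CX4]([CH3])([CH3])[CH3]")

# Strip one TBDMS group off its heteroatom (implicit H restores the parent).
_STRIP_TBDMS = AllChem.ReactionFromSmarts(
    "[#7,#8,#16:1][Si]([CH3])([CH3])[CX4]([CH3])([CH3])[CH3]>>[*:1]"
)

# Alpha carbon: primary acyclic non-amide amine + carboxylic acid + at most
# one non-H substituent (H1 -> one side chain, H2 -> glycine).
_ALPHA_CORE = Chem.MolFromSmarts(
    "[CX4;H1,H2]([NX3;H2;!R;!$(N[CX3]=[OX1])])[CX3](=[OX1])[OX2H1]"
)


def detect_tbdms(smiles: str) -> int:
    """Count TBDMS groups (Si with two methyls + tert-butyl on O/N/S)."""
    mol = _mol(smiles)
    matches = mol.GetSubstructMatches(_TBDMS)
    return len({m[1] for m in matches})  # unique silicon atoms


def _strip_tbdms(mol: Chem.Mol) -> Chem.Mol:
    """Remove all TBDMS groups, returning the underivatized parent scaffold."""
    while True:
        products = _STRIP_TBDMS.RunReactants((mol,))
        if not products:
            return mol
        mol = products[0][0]
        Chem.SanitizeMol(mol)


def strip_tbdms_smiles(smiles: str) -> str:
    """SMILES of the parent scaffold with every TBDMS group removed."""
    return Chem.MolToSmiles(_strip_tbdms(_mol(smiles)))


def classify_type1a(smiles: str) -> bool:
    """True iff the molecule is a Type Ia monosubstituted alpha-amino acid.

    The predicate requires exactly one alpha-amino-acid core in the parent
    scaffold (TBDMS groups ignored): a tetrahedral carbon bearing a primary
    amine (two hydrogens, acyclic, not an amide nitrogen — excluding
    proline-like and peptide nitrogens), a carboxylic acid, and at most one
    non-hydrogen side-chain substituent.  Glycine is accepted.
    """
    parent = _strip_tbdms(_mol(smiles))
    alpha_carbons = {m[0] for m in parent.GetSubstructMatches(_ALPHA_CORE)}
    return len(alpha_carbons) == 1


def dedup_against(
    candidates: Sequence[MoleculeRecord],
    reference: Sequence[MoleculeRecord],
) -> list[MoleculeRecord]:
    """Keep candidates whose InChIKey skeleton block is absent from reference.

    Order is preserved.  Raises if any record lacks a structure key.
    """
    for rec in list(candidates) + list(reference):
        if not rec.structure_key:
            raise ValueError(f"record {rec.compound_id!r} has no structure key")
    ref_keys = {rec.structure_key[:14] for rec in reference}
    return [rec for rec in candidates if rec.structure_key[:14] not in ref_keys]


def filter_instrument(spectra: Iterable[Spectrum], instrument_pattern: str) -> list[Spectrum]:
    """Spectra whose instrument metadata matches the pattern (case-insensitive).

    Spectra without instrument metadata are excluded and counted in the log.
    """
    pattern = re.compile(instrument_pattern, re.IGNORECASE)
    kept: list[Spectrum] = []
    missing = 0
    for s in spectra:
        if not s.instrument:
            missing += 1
        elif pattern.search(s.instrument):
            kept.append(s)
    if missing:
        logger.warning(
            "filter_instrument: %d spectra lacked instrument metadata and were excluded",
            missing,
        )
    return kept


def load_curation_fixture():
    """The packaged 30-molecule labelled set used to pin down the Type Ia gate.

    Columns: compound_id, smiles, is_type1a (designated label), tbdms_count.
    Contains 20 genuine Type Ia amino acids, six excluded scaffolds
    (proline, beta-alanine, sarcosine, glycine betaine, an N-methyl amino
    acid, a dipeptide) and four TBDMS derivatives of Type Ia parents.
    """
    import pandas as pd
    from importlib.resources import files

    path = files("aminospec.data").joinpath("curation_fixture.csv")
    with path.open() as fh:
        return pd.read_csv(fh)


def annotate_properties(record: MoleculeRecord) -> MoleculeRecord:
    """Fill molecular weight (average, Da), atom-contribution logP,
    InChIKey, TBDMS count, derivatization state and the Type Ia flag.

    The logP estimate is Crippen's atom-contribution method; absolute values
    differ from proprietary predictors, so only correlations with it are
    meaningful across toolkits.  Idempotent.
    """
    mol = _mol(record.smiles)
    tbdms = detect_tbdms(record.smiles)
    return replace(
        record,
        molecular_weight=float(Descriptors.MolWt(mol)),
        logp=float(Crippen.MolLogP(mol)),
        structure_key=Chem.MolToInchiKey(mol),
        tbdms_count=tbdms,
        derivatized=tbdms > 0,
        is_type1a_alpha_aa=classify_type1a(record.smiles),
    )
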