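"""Structural similarity between compounds.

Compounds (microbial secondary metabolites and approved drugs) are compared
on binary substructure fingerprints with the Tanimoto coefficient
``|A ∩ B| / |A ∪ B|``.  Structure *identity* is decided on canonical-SMILES
string equality, never on fingerprint equality, because folded fingerprints
can collide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

log = logging.getLogger(__name__)

# RDKit prints parse errors to stderr by default; invalid structures are an
# expected, handled input class here, so route diagnostics through `log`.
RDLogger.DisableLog("rdApp.error")


class CompoundSource(str, Enum):
    METABOLITE = "metabolite"
    DRUG = "drug"


@dataclass(frozen=True)
class CompoundRecord:
    """One metabolite or drug: identity, structure, provenance."""

    compound_id: str
    name: str
    smiles: str
    source: CompoundSource

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be a nonempty token")


@dataclass(frozen=True)
class Fingerprint:
    """Binary fingerprint as the set of on-bit positions."""

    bits: frozenset[int]
    n_bits: int
    kind: str = "morgan"
    radius: int = 2

    def __post_init__(self) -> None:
        if self.bits and max(self.bits) >= self.n_bits:
            raise ValueError("bit position out of range")


def canonicalize(smiles: str) -> Optional[str]:
    """Return the canonical SMILES for *smiles*, or ``None`` if unparseable.

    Two strings describing the same molecule map to the same output, so
    structure identity is decidable as string equality.  Never raises on bad
    input: a ``None`` marker is returned and the reason logged, so a single
    malformed record cannot abort a pipeline run.
    """
    if not smiles:
        log.warning("empty SMILES string; marking invalid")
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        log.warning("unparseable SMILES %r; marking invalid", smiles)
        return None
    return Chem.MolToSmiles(mol)


def fingerprint(
    record: CompoundRecord | str,
    kind: str = "morgan",
    radius: int = 2,
    n_bits: int = 2048,
) -> Fingerprint:
    """Compute a binary fingerprint for a compound.

    Parameters
    ----------
    record
        A :class:`CompoundRecord` or a bare SMILES string.
    kind
        ``"morgan"`` (circular, ECFP-like; the default used for
        drug-likeness comparison) or ``"rdkit"`` (topological path-based).
    radius
        Neighbourhood radius for circular fingerprints (ignored for
        ``"rdkit"``).
    n_bits
        Folded length.

    Raises
    ------
    ValueError
        If the structure is invalid; the message names the compound.
    """
    if isinstance(record, CompoundRecord):
        smiles, ident = record.smiles, record.compound_id
    else:
        smiles, ident = record, "<anonymous>"
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        raise ValueError(f"invalid structure for compound {ident!r}")
    if kind == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    elif kind == "rdkit":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    bv = gen.GetFingerprint(mol)
    bits = frozenset(bv.GetOnBits())
    if not bits:
        log.warning("degenerate molecule %s: empty fingerprint", ident)
    return Fingerprint(bits=bits, n_bits=n_bits, kind=kind, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient ``|A ∩ B| / |A ∪ B|`` between two fingerprints.

    Symmetric; 1.0 iff the bit sets are equal and nonempty.  Two empty bit
    sets score 0.0 (structureless entities are treated as dissimilar, not
    identical) and the event is logged.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint lengths differ: {a.n_bits} != {b.n_bits}")
    if not a.bits and not b.bits:
        log.warning("tanimoto of two empty fingerprints; returning 0.0")
        return 0.0
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union
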