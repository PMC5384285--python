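"""Tanimoto analog shortlisting over 2-D fingerprints.

Fingerprints computed by any cheminformatics toolkit can be supplied from a
CSV file (compound_id, hex-encoded bit string, n_bits). A deterministic
hashed character-n-gram fingerprint of the SMILES string is built in as an
explicitly labeled fallback so the module works with no chemistry toolkit;
when RDKit is available, :func:`rdkit_morgan_fingerprint` produces real
circular fingerprints.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ComputationError, ValidationError

__all__ = [
    "Fingerprint",
    "AnalogHit",
    "tanimoto",
    "smiles_ngram_fingerprint",
    "rdkit_morgan_fingerprint",
    "analog_shortlist",
    "read_fingerprint_table",
    "write_fingerprint_table",
]


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length molecular bit set (stored as the set of on-bit indices)."""

    bits: frozenset[int]
    n_bits: int = 2048
    origin: str = "external_file"

    def __post_init__(self) -> None:
        if self.n_bits < 1:
            raise ValidationError("n_bits must be >= 1")
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValidationError("bit index out of range")


@dataclass(frozen=True)
class AnalogHit:
    compound_id: str
    similarity: float


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a & b| / |a | b|; 0 (with a warning) when both
    fingerprints are empty."""
    if a.n_bits != b.n_bits:
        raise ComputationError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0", stacklevel=2)
        return 0.0
    return len(a.bits & b.bits) / union


def smiles_ngram_fingerprint(smiles: str, n: int = 4, n_bits: int = 2048) -> Fingerprint:
    """Deterministic hashed character n-gram fingerprint of a SMILES string.

    This is a structure-agnostic stand-in, not a chemical fingerprint: it
    captures string similarity of the SMILES encoding only. Hashing uses
    SHA-1, so the same input always yields the same bits across processes.
    """
    if not smiles:
        raise ValidationError("empty SMILES string")
    if n < 1:
        raise ValidationError("n must be >= 1")
    grams = (
        [smiles[i : i + n] for i in range(len(smiles) - n + 1)]
        if len(smiles) >= n
        else [smiles]
    )
    bits = frozenset(
        int.from_bytes(hashlib.sha1(g.encode()).digest()[:8], "big") % n_bits for g in grams
    )
    return Fingerprint(bits=bits, n_bits=n_bits, origin="smiles_ngram")


def rdkit_morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Morgan (circular) fingerprint via RDKit, when installed."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"RDKit could not parse SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), n_bits=n_bits, origin="external_file")


def analog_shortlist(
    query: Fingerprint,
    library: Sequence[tuple[str, Fingerprint]],
    min_similarity: float = 0.0,
) -> list[AnalogHit]:
    """Library entries with Tanimoto >= ``min_similarity`` against the query,
    sorted by descending similarity then id."""
    hits = []
    for cid, fp in library:
        if fp.n_bits != query.n_bits:
            raise ComputationError(f"library entry {cid}: n_bits mismatch")
        sim = tanimoto(query, fp)
        if sim >= min_similarity:
            hits.append(AnalogHit(cid, sim))
    hits.sort(key=lambda h: (-h.similarity, h.compound_id))
    return hits


def _to_hex(fp: Fingerprint) -> str:
    value = 0
    for b in fp.bits:
        value |= 1 << b
    width = (fp.n_bits + 3) // 4
    return format(value, f"0{width}x")


def _from_hex(hexstring: str, n_bits: int) -> Fingerprint:
    value = int(hexstring, 16)
    bits = frozenset(i for i in range(n_bits) if value >> i & 1)
    return Fingerprint(bits=bits, n_bits=n_bits)


def write_fingerprint_table(entries: Iterable[tuple[str, Fingerprint]], path) -> None:
    pd.DataFrame(
        [
            {"compound_id": cid, "fingerprint_hex": _to_hex(fp), "n_bits": fp.n_bits}
            for cid, fp in entries
        ],
        columns=["compound_id", "fingerprint_hex", "n_bits"],
    ).to_csv(path, index=False)


def read_fingerprint_table(path) -> list[tuple[str, Fingerprint]]:
    df = pd.read_csv(path, dtype={"compound_id": str, "fingerprint_hex": str, "n_bits": int})
    return [
        (row["compound_id"], _from_hex(row["fingerprint_hex"], int(row["n_bits"])))
        for _, row in df.iterrows()
    ]
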