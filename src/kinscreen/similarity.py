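"""Fingerprint Tanimoto similarity and analog retrieval for hit expansion.

Fingerprints are abstract feature sets (non-negative integer feature ids,
set semantics), so the core stays independent of any particular
fingerprinting scheme; a thin adapter builds Morgan feature sets from
SMILES when RDKit is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

__all__ = [
    "Fingerprint",
    "tanimoto",
    "analog_search",
    "load_fingerprints",
    "save_fingerprints",
    "fingerprint_from_smiles",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fingerprint:
    compound_id: str
    bits: frozenset[int]

    def __post_init__(self) -> None:
        bits = frozenset(int(b) for b in self.bits)
        if any(b < 0 for b in bits):
            raise ValueError("feature ids must be non-negative")
        object.__setattr__(self, "bits", bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tc = |A n B| / |A u B|; 1.0 for two empty sets (degenerate, logged)."""
    union = len(a.bits | b.bits)
    if union == 0:
        log.info("tanimoto of two empty fingerprints (%s, %s): defined as 1.0",
                 a.compound_id, b.compound_id)
        return 1.0
    return len(a.bits & b.bits) / union


def analog_search(
    query: Fingerprint,
    library: Sequence[Fingerprint],
    threshold: float = 0.70,
) -> list[tuple[Fingerprint, float]]:
    """Library members with Tc strictly above ``threshold``, best first.

    Sorted by descending Tc, ties by compound id; the query itself is
    excluded when present in the library (matched by id).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    matches = [
        (fp, tanimoto(query, fp))
        for fp in library
        if fp.compound_id != query.compound_id
    ]
    matches = [(fp, tc) for fp, tc in matches if tc > threshold]
    matches.sort(key=lambda m: (-m[1], m[0].compound_id))
    return matches


def load_fingerprints(source: str | Path | IO[str]) -> list[Fingerprint]:
    """Read ``compound_id,f1;f2;f3`` lines (empty feature list allowed)."""
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    fps = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cid, _, feats = line.partition(",")
        bits = frozenset(int(f) for f in feats.split(";") if f.strip())
        fps.append(Fingerprint(compound_id=cid.strip(), bits=bits))
    return fps


def save_fingerprints(fps: Sequence[Fingerprint], dest: str | Path | IO[str]) -> None:
    lines = [f"{fp.compound_id},{';'.join(str(b) for b in sorted(fp.bits))}" for fp in fps]
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def fingerprint_from_smiles(smiles: str, compound_id: str, radius: int = 2) -> Fingerprint:
    """Morgan feature set from a SMILES string (requires RDKit)."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {compound_id!r}: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    fp = gen.GetSparseCountFingerprint(mol)
    return Fingerprint(compound_id=compound_id, bits=frozenset(fp.GetNonzeroElements()))
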