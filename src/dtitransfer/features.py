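"""Compound featurization: ECFP4 fingerprints, Tanimoto similarity, classifier vectors.

Two distinct representations are used downstream, mirroring how they serve
different jobs: 2048-bit ECFP4 fingerprints feed the Butina clustering that
guards against chemical-series bias, while the classifiers consume 300-d
real vectors — either imported learned embeddings (e.g. from a message-passing
network trained externally) or, as a self-contained default, the ECFP4
fingerprint hashed directly to 300 bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .errors import DimensionError, FeaturizationError

if TYPE_CHECKING:  # pragma: no cover
    from .curation import LabeledCompound
    from .io import EmbeddingTable

DEFAULT_NBITS = 2048
CLASSIFIER_DIM = 300

SCHEME_IMPORTED = "imported_embedding"
SCHEME_FOLDED = "folded_fingerprint"


@dataclass(frozen=True)
class Fingerprint:
    """A hashed circular fingerprint stored as its set of on-bit indices."""

    bits: frozenset[int]
    nbits: int = DEFAULT_NBITS
    radius: int = 2

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.nbits):
            raise ValueError("bit index outside [0, nbits)")


@dataclass(frozen=True)
class CompoundVector:
    """Fixed-length real-valued compound representation fed to classifiers."""

    values: np.ndarray
    scheme: str
    dimension: int = CLASSIFIER_DIM

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float32))
        if self.values.shape != (self.dimension,):
            raise DimensionError(
                f"vector of length {self.values.shape} does not match dimension {self.dimension}"
            )


def _parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return mol


def ecfp4(smiles: str, nbits: int = DEFAULT_NBITS) -> Fingerprint:
    """ECFP4 (Morgan radius-2) fingerprint hashed to ``nbits`` bits."""
    mol = _parse_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), nbits=nbits, radius=2)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B|/|A∪B|; defined as 1.0 when both sets are empty."""
    if a.nbits != b.nbits:
        raise DimensionError(f"fingerprint sizes differ: {a.nbits} vs {b.nbits}")
    if not a.bits and not b.bits:
        return 1.0
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


def featurize(
    compound: "LabeledCompound",
    scheme: str = SCHEME_FOLDED,
    embeddings: "EmbeddingTable | None" = None,
    dimension: int = CLASSIFIER_DIM,
) -> CompoundVector:
    """Turn a curated compound into the classifier's input vector.

    ``imported_embedding`` returns the stored vector verbatim (the compound id
    must be present in the table); ``folded_fingerprint`` hashes the ECFP4
    fingerprint down to ``dimension`` 0/1 entries.
    """
    if scheme == SCHEME_IMPORTED:
        if embeddings is None:
            raise ValueError("imported_embedding scheme requires an embedding table")
        try:
            vec = embeddings.vectors[compound.compound_id]
        except KeyError:
            raise FeaturizationError(
                f"compound id {compound.compound_id!r} absent from embedding table"
            ) from None
        return CompoundVector(values=vec, scheme=scheme, dimension=embeddings.dimension)
    if scheme == SCHEME_FOLDED:
        fp = ecfp4(compound.smiles, nbits=dimension)
        values = np.zeros(dimension, dtype=np.float32)
        values[sorted(fp.bits)] = 1.0
        return CompoundVector(values=values, scheme=scheme, dimension=dimension)
    raise ValueError(f"unknown featurization scheme: {scheme!r}")


def featurize_all(
    compounds,
    scheme: str = SCHEME_FOLDED,
    embeddings: "EmbeddingTable | None" = None,
    dimension: int = CLASSIFIER_DIM,
) -> np.ndarray:
    """Stack ``featurize`` over a compound sequence into an (n, d) matrix."""
    return np.stack(
        [featurize(c, scheme=scheme, embeddings=embeddings, dimension=dimension).values
         for c in compounds]
    )
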