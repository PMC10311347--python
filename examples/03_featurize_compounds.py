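"""Compound featurization: fingerprints, similarity, classifier vectors.

Computes ECFP4 fingerprints and Tanimoto similarities for a few molecules,
then turns a curated compound into the 300-d vector the classifiers consume,
via both supported schemes.
"""

import numpy as np

from dtitransfer import EmbeddingTable, ecfp4, featurize, tanimoto
from dtitransfer.curation import LabeledCompound
from dtitransfer.features import SCHEME_FOLDED, SCHEME_IMPORTED

ethanol, propanol, benzene = "CCO", "CCCO", "c1ccccc1"
fp = {s: ecfp4(s) for s in (ethanol, propanol, benzene)}
print("pairwise ECFP4 Tanimoto similarities (2048 bits):")
print(f"  ethanol vs propanol: {tanimoto(fp[ethanol], fp[propanol]):.3f}")
print(f"  ethanol vs benzene:  {tanimoto(fp[ethanol], fp[benzene]):.3f}")

compound = LabeledCompound("C1", "CCO", "kinase", 7.5, "active")

folded = featurize(compound, scheme=SCHEME_FOLDED)
print(f"\nfolded fingerprint vector: length {folded.dimension}, "
      f"{int(folded.values.sum())} bits set")

table = EmbeddingTable(dimension=300,
                       vectors={"C1": np.linspace(-1, 1, 300).astype(np.float32)})
imported = featurize(compound, scheme=SCHEME_IMPORTED, embeddings=table)
print(f"imported embedding vector: length {imported.dimension}, "
      f"first values {imported.values[:3].round(3).tolist()}")
# Imported embeddings are returned verbatim, so any externally learned
# 300-d representation can stand behind the same classifier interface.
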