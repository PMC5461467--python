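"""Optional SMILES -> fingerprint adapter.

The analysis core treats fingerprints as opaque fixed-length bit
vectors supplied with the data.  This adapter is the only place a
cheminformatics toolkit is touched: it derives a substructure-style
fingerprint from a SMILES string with RDKit, folded to the collection's
bit length (881 by default, matching the PubChem 2D key length; note
the folded pattern fingerprint is not bit-for-bit the PubChem key
definition, but is interchangeable for Tanimoto-based read-across).
RDKit is imported lazily so the core has no hard dependency on it.
"""

from __future__ import annotations

import numpy as np

from .model import Fingerprint

__all__ = ["fingerprint_from_smiles"]


def fingerprint_from_smiles(smiles: str, length: int = 881) -> Fingerprint:
    """Substructure fingerprint of a molecule, folded to ``length`` bits.

    Raises ``ImportError`` when RDKit is not installed and ``ValueError``
    for an unparsable SMILES.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "fingerprint_from_smiles requires the optional rdkit dependency"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    bv = Chem.rdmolops.PatternFingerprint(mol, fpSize=length)
    bits = np.zeros(length, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits)
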