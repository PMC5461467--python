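import numpy as np
import pytest

from draize_miner.model import (
    DraizeStudy,
    Fingerprint,
    Guideline,
    HazardStatus,
    IrritationCategory,
    SubstanceRecord,
)


def study(num, cornea=None, iris=None, conj=None, chem=None, rev=None,
          verdict="", reliability=1, guideline=Guideline.TG405_INVIVO):
    return DraizeStudy(
        study_num=num, cornea=cornea, iris=iris, conjunctivae=conj,
        chemosis=chem, reversibility_days=rev or {}, verdict_text=verdict,
        reliability=reliability, guideline=guideline)


@pytest.fixture
def tiny_records():
    """Three hand-built substances covering studies, hazards, fingerprints."""
    fp1 = Fingerprint(np.array([1, 0, 1, 1, 0, 0, 0, 1], dtype=np.uint8))
    fp2 = Fingerprint(np.array([1, 0, 1, 0, 0, 0, 0, 1], dtype=np.uint8))
    return [
        SubstanceRecord(
            id="200-001-8",
            studies=[
                study(1, cornea=3.0, iris=1.0, conj=2.5, chem=3.0,
                      rev={"cornea": "NOT_REVERSED"}, verdict="category 1"),
                study(2, cornea=3.5, iris=1.5, conj=3.0, chem=3.5,
                      rev={"cornea": 25}, verdict="corrosive"),
            ],
            hazards={"H318": HazardStatus.POSITIVE,
                     "H315": HazardStatus.POSITIVE},
            fingerprint=fp1,
            dossier_category=IrritationCategory.TYPE1,
        ),
        SubstanceRecord(
            id="200-002-3",
            studies=[
                study(1, cornea=0.0, iris=0.0, conj=0.5, chem=0.0,
                      rev={"conjunctivae": 3}, verdict="not irritating"),
            ],
            hazards={"H318": HazardStatus.NEGATIVE,
                     "H319": HazardStatus.NEGATIVE,
                     "H320": HazardStatus.NEGATIVE},
            fingerprint=fp2,
            dossier_category=IrritationCategory.NON_IRRITANT,
        ),
        SubstanceRecord(
            id="200-003-9",
            studies=[
                study(1, cornea=1.0, iris=0.5, conj=2.0, chem=2.0,
                      rev={"conjunctivae": 14}, verdict="irritating"),
            ],
            hazards={"H319": HazardStatus.POSITIVE},
        ),
    ]
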