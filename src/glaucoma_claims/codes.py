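"""Diagnosis and procedure coding used across the pipeline."""

from __future__ import annotations

import enum

#: ICD-10 codes defining the glaucoma population: H401 (normal-tension,
#: primary open-angle and open-angle glaucoma) and H409 (unspecified).
GLAUCOMA_ICD10 = frozenset({"H401", "H409"})


class ProcedureCategory(str, enum.Enum):
    """Claim-level procedure groups: the three exam categories plus surgery
    (including laser treatment)."""

    OPHTHALMOSCOPY_TONOMETRY = "OPHTHALMOSCOPY_TONOMETRY"
    PERIMETRY = "PERIMETRY"
    OCT = "OCT"
    SURGERY = "SURGERY"


EXAM_CATEGORIES = (
    ProcedureCategory.OPHTHALMOSCOPY_TONOMETRY,
    ProcedureCategory.PERIMETRY,
    ProcedureCategory.OCT,
)
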