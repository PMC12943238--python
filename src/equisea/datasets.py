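"""Bundled study inputs.

The enrollment cytology of the 12-horse cohort (BALF differential
percentages for eight healthy horses and four horses with severe
neutrophilic asthma) is shipped as data: it is the input the
phenotyping stage classifies. Clinical-sign flags follow the enrollment
narrative — SEA horses presented respiratory signs at the exam, healthy
horses showed no signs of illness.
"""

from __future__ import annotations

from .phenotyping import CytologyProfile

# animal_id, neutrophil %, eosinophil %, mast cell %
_COHORT_CYTOLOGY: tuple[tuple[str, float, float, float], ...] = (
    ("H1", 1, 1, 1),
    ("H2", 1, 0, 2),
    ("H3", 1, 0, 1),
    ("H4", 2, 1, 1),
    ("H5", 1, 1, 1),
    ("H6", 5, 0, 1),
    ("H7", 1, 1, 1),
    ("H8", 2, 1, 1),
    ("S1", 27, 0, 2),
    ("S2", 23, 3, 0),
    ("S3", 26, 0, 1),
    ("S4", 47, 0, 1),
)


def study_cohort_cytology() -> list[CytologyProfile]:
    """The 12-horse enrollment cytology table as profiles."""
    return [
        CytologyProfile(
            animal_id=aid,
            neutrophil_pct=neut,
            eosinophil_pct=eos,
            mastcell_pct=mast,
            respiratory_signs=aid.startswith("S"),
            illness_signs=aid.startswith("S"),
        )
        for aid, neut, eos, mast in _COHORT_CYTOLOGY
    ]
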