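"""Feature metadata for the glioma-grading problem.

The feature panel mirrors what a multimodal MR workup yields per patient:

* ``t1wc`` — a three-state contrast-enhancement category read from
  contrast-enhanced T1-weighted images (negative / slight / apparent).
* five perfusion parameters from PWI, each normalized by a contralateral
  normal-appearing region (``nrCBV``, ``nMTT``, ``nrCBF``, ``nT0``, ``nTTP``).
* four metabolite ratios from MR spectroscopic imaging
  (``Cho/Cr``, ``NAA/Cr``, ``Lac/Cr``, ``Lip13/Cr``).

Perfusion and MRSI features are acquired as whole modalities, so they are
missing as whole blocks per patient (block missingness).
"""

from __future__ import annotations

GRADE_COL = "grade"
T1WC_COL = "t1wc"
ID_COL = "patient_id"

GRADE_STATES = ("low", "high")
T1WC_STATES = ("negative", "slight", "apparent")

PERFUSION_FEATURES = ("nrCBV", "nMTT", "nrCBF", "nT0", "nTTP")
MRSI_FEATURES = ("Cho/Cr", "NAA/Cr", "Lac/Cr", "Lip13/Cr")
CONTINUOUS_FEATURES = PERFUSION_FEATURES + MRSI_FEATURES

#: modality name -> tuple of member features; used for block-missingness
MODALITY_GROUPS = {
    "T1WC": (T1WC_COL,),
    "perfusion": PERFUSION_FEATURES,
    "MRSI": MRSI_FEATURES,
}

#: fixed column order of the cohort CSV
TABLE_COLUMNS = (ID_COL, GRADE_COL, T1WC_COL) + CONTINUOUS_FEATURES


def modality_of(feature: str) -> str:
    """Return the modality ("T1WC", "perfusion" or "MRSI") owning *feature*."""
    for modality, members in MODALITY_GROUPS.items():
        if feature in members:
            return modality
    raise KeyError(f"unknown feature: {feature!r}")
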