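"""Anatomical dimension containers and ML-normalization.

Five femoral/tibiofemoral length measurements characterize a knee for
template matching: the maximum medial-lateral length (ML, the clinical
transepicondylar axis), the maximum anterior-posterior lengths of the
medial and lateral condyles (AP medial/lateral), and the tibiofemoral
joint space widths of both compartments (JSW medial/lateral, taken as
the combined femoral+tibial cartilage thickness). All lengths are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "AnatomicalDimensions",
    "NormalizedDimensions",
    "normalize_dimensions",
    "read_subject_table",
]

_FIELDS = ("ml", "ap_medial", "ap_lateral", "jsw_medial", "jsw_lateral")


@dataclass(frozen=True)
class AnatomicalDimensions:
    """The five knee length measurements of one subject or template, mm."""

    ml: float
    ap_medial: float
    ap_lateral: float
    jsw_medial: float
    jsw_lateral: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(
                    f"dimension {f.name!r} must be finite and > 0, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _FIELDS], dtype=float)

    def scaled(self, c: float) -> "AnatomicalDimensions":
        return AnatomicalDimensions(*(self.as_array() * c))


@dataclass(frozen=True)
class NormalizedDimensions:
    """Dimensions divided by ML; the ml field is identically 1."""

    ml: float
    ap_medial: float
    ap_lateral: float
    jsw_medial: float
    jsw_lateral: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _FIELDS], dtype=float)


def normalize_dimensions(dims: AnatomicalDimensions) -> NormalizedDimensions:
    """Normalize all five dimensions by the subject's ML length.

    Normalization makes knees of different overall size comparable in
    shape; ML itself maps to exactly 1.0.
    """
    if dims.ml <= 0:
        raise ValueError("ml must be > 0")
    a = dims.as_array() / dims.ml
    a[0] = 1.0  # exact, avoids x/x rounding
    return NormalizedDimensions(*a)


def read_subject_table(path) -> pd.DataFrame:
    """Read a subject dimension CSV.

    Expected header: ``subject_id,ml,ap_medial,ap_lateral,jsw_medial,
    jsw_lateral,body_mass_kg``.
    """
    df = pd.read_csv(path)
    required = {"subject_id", *_FIELDS, "body_mass_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject CSV missing columns: {sorted(missing)}")
    return df


def dims_from_row(row) -> AnatomicalDimensions:
    return AnatomicalDimensions(*(float(row[f]) for f in _FIELDS))
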