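"""Deterministic trauma scores: TRISS probability of survival.

TRISS combines the Revised Trauma Score (RTS), the Injury Severity Score
(ISS) and an age indicator in a mechanism-specific logistic equation:

    Ps = 1 / (1 + exp(-b))
    blunt:        b = -0.4499 + 0.8085*RTS - 0.0835*ISS - 1.7430*AgeIndex
    penetrating:  b = -2.5355 + 0.9934*RTS - 0.0651*ISS - 1.1360*AgeIndex

with AgeIndex = 0 for age < 55 and 1 for age >= 55.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dditraj.errors import ValidationError

RTS_MAX = 7.8408

_TRISS_COEF = {
    "blunt": (-0.4499, 0.8085, -0.0835, -1.7430),
    "penetrating": (-2.5355, 0.9934, -0.0651, -1.1360),
}


@dataclass(frozen=True)
class TrissInput:
    rts: float
    iss: float
    age: float
    mechanism: str

    def __post_init__(self):
        if not 0 <= self.iss <= 75:
            raise ValidationError("ISS must be within 0..75")
        if not 0 <= self.rts <= RTS_MAX:
            raise ValidationError(f"RTS must be within 0..{RTS_MAX}")
        if self.age < 0:
            raise ValidationError("age must be non-negative")
        if self.mechanism not in _TRISS_COEF:
            raise ValidationError(
                f"mechanism must be 'blunt' or 'penetrating', got {self.mechanism!r}")


def age_index(age: float) -> int:
    """TRISS age indicator: 0 below 55 years, 1 at 55 and over."""
    if age < 0:
        raise ValidationError("age must be non-negative")
    return int(age >= 55)


def triss_ps(inp: TrissInput) -> float:
    """Probability of survival from the mechanism-specific TRISS logit."""
    c0, c_rts, c_iss, c_age = _TRISS_COEF[inp.mechanism]
    b = c0 + c_rts * inp.rts + c_iss * inp.iss + c_age * age_index(inp.age)
    return float(1.0 / (1.0 + np.exp(-b)))


def triss_ps_table(covariates) -> np.ndarray:
    """Vectorised TRISS Ps over a covariate table (rts, iss, age, mechanism)."""
    return np.array([
        triss_ps(TrissInput(rts=float(r.rts), iss=float(r.iss),
                            age=float(r.age), mechanism=str(r.mechanism)))
        for r in covariates.itertuples()
    ])


def rts_from_coded(gcs_code: int, sbp_code: int, rr_code: int) -> float:
    """Weighted RTS from coded GCS / systolic BP / respiratory-rate values.

    Standard triage weights 0.9368, 0.7326 and 0.2908 on codes 0-4.  This
    helper exists only so the synthetic covariate generator can produce a
    physiologically plausible RTS; the analysis treats RTS as an input.
    """
    for code in (gcs_code, sbp_code, rr_code):
        if code not in (0, 1, 2, 3, 4):
            raise ValidationError("coded components must be integers 0..4")
    return 0.9368 * gcs_code + 0.7326 * sbp_code + 0.2908 * rr_code
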