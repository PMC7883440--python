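"""Session calibration of NanoSIMS isotope ratios against a bulk-analysed standard.

NanoSIMS count ratios carry an instrument mass-fractionation bias, and carbon is
measured on the diatomic C2- species whose minor/major count ratio is twice the
atomic ratio at trace abundance.  Both effects are absorbed by a multiplicative
session correction factor

    CF = R_standard(IRMS) / mean(R_standard(NanoSIMS))

derived from repeated scans of a yeast standard whose bulk isotope ratio is
known from IRMS.  Corrected ratios are converted to heavy-isotope atom
fractions

    F = (R / (R + 1)) * CF,     Atom% = 100 * F

with CF applied after the ratio-to-fraction transform.  For the CN- species
this recovers the true nitrogen atom fraction exactly; for C2- it is a
small-enrichment approximation (relative error <= f for f <= 0.05), so the
exact algebraic inversion of the C2 isotopologue ratio is provided alongside
as an internal oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# Reference isotope ratios of the international standards (heavy/light).
R_VPDB_C = 0.0111802  # 13C/12C, Vienna Pee Dee Belemnite
R_AIR_N = 0.0036765  # 15N/14N, atmospheric N2

#: Natural-abundance atom fractions implied by the standards.
F_NAT_C = R_VPDB_C / (1.0 + R_VPDB_C)
F_NAT_N = R_AIR_N / (1.0 + R_AIR_N)

#: Coefficient of variation above which repeated standard scans are flagged.
CV_WARN_THRESHOLD = 0.10


@dataclass
class SessionCalibration:
    """Correction factor for one isotope in one measurement session.

    Attributes
    ----------
    isotope:
        ``"13C"`` or ``"15N"``.
    r_irms_standard:
        Bulk (IRMS) isotope ratio of the shared standard.
    measured_standard_ratios:
        NanoSIMS count ratios of the standard from that session's scans.
    cf:
        ``r_irms_standard / mean(measured_standard_ratios)``.
    cv:
        Coefficient of variation of the measured ratios (0 for one scan).
    unstable:
        True when ``cv`` exceeds :data:`CV_WARN_THRESHOLD`.
    """

    isotope: str
    r_irms_standard: float
    measured_standard_ratios: list[float] = field(default_factory=list)
    cf: float = 1.0
    cv: float = 0.0
    unstable: bool = False
    session_id: str = ""


def session_cf(
    r_irms_standard: float,
    measured: Sequence[float],
    *,
    isotope: str = "15N",
    session_id: str = "",
) -> SessionCalibration:
    """Derive the session correction factor from standard scans.

    Raises
    ------
    ValueError
        If ``measured`` is empty or contains a nonpositive ratio, or if
        ``r_irms_standard`` is not positive.
    """
    measured = [float(m) for m in measured]
    if not measured:
        raise ValueError("at least one measured standard ratio is required")
    if any(m <= 0 for m in measured):
        raise ValueError("measured standard ratios must be positive")
    if r_irms_standard <= 0:
        raise ValueError("standard reference ratio must be positive")

    mean = float(np.mean(measured))
    cf = r_irms_standard / mean
    cv = float(np.std(measured, ddof=1) / mean) if len(measured) > 1 else 0.0
    unstable = cv > CV_WARN_THRESHOLD
    if unstable:
        warnings.warn(
            f"standard-scan CV {cv:.1%} exceeds {CV_WARN_THRESHOLD:.0%} "
            f"for session {session_id or '<unnamed>'}",
            stacklevel=2,
        )
    return SessionCalibration(
        isotope=isotope,
        r_irms_standard=r_irms_standard,
        measured_standard_ratios=measured,
        cf=cf,
        cv=cv,
        unstable=unstable,
        session_id=session_id,
    )


def atom_fraction(r_measured, cf: float):
    """Convert a measured count ratio to a calibrated atom fraction.

    Returns ``(F, Atom%)`` where ``F = (r/(r+1))*cf`` and ``Atom% = 100*F``.
    Accepts scalars or arrays.
    """
    r = np.asarray(r_measured, dtype=float)
    if np.any(r < 0):
        raise ValueError("measured ratio must be nonnegative")
    if cf <= 0:
        raise ValueError("correction factor must be positive")
    f = (r / (r + 1.0)) * cf
    if np.ndim(r_measured) == 0:
        f = float(f)
        return f, 100.0 * f
    return f, 100.0 * f


def exact_atom_fraction_c2(r_c2, bias: float = 1.0):
    """Exact atom fraction from a C2- isotopologue count ratio.

    The 13C12C/12C12C count ratio of a sample with atom fraction ``f`` is
    ``2 f (1-f) / (1-f)^2 = 2f/(1-f)`` (times an instrument bias).  This
    inverts that relation: with ``r' = r_c2 / bias``, ``f = r' / (2 + r')``.
    Serves as the oracle against which the Eq.-style approximation is judged.
    """
    if bias <= 0:
        raise ValueError("bias must be positive")
    r = np.asarray(r_c2, dtype=float)
    if np.any(r < 0):
        raise ValueError("count ratio must be nonnegative")
    rp = r / bias
    f = rp / (2.0 + rp)
    return float(f) if np.ndim(r_c2) == 0 else f


def c2_ratio_from_fraction(f, bias: float = 1.0):
    """Forward C2- isotopologue model: count ratio ``2f/(1-f) * bias``."""
    f = np.asarray(f, dtype=float)
    r = 2.0 * f / (1.0 - f) * bias
    return float(r) if r.ndim == 0 else r


def cn_ratio_from_fraction(f, bias: float = 1.0):
    """Forward CN- model: count ratio ``f/(1-f) * bias``."""
    f = np.asarray(f, dtype=float)
    r = f / (1.0 - f) * bias
    return float(r) if r.ndim == 0 else r
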