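"""Reference gestational-age computations.

Two clinical reference scales:

* Biometry dating — the standard second/third-trimester regression on
  biparietal diameter (BPD), head circumference (HC), abdominal
  circumference (AC) and femur length (FL), all in millimetres:

      GA_days = 7 * (10.85 + 0.0006*HC*FL + 0.067*BPD + 0.0168*AC)

* CRL dating — the gold standard: a first-trimester crown-rump length
  measurement (taken between 9+0 and 13+6 weeks) converted to GA by a
  dating curve, then propagated to the examination date by adding the days
  elapsed since the dating scan.  The dating curve is pluggable; the
  default is the Robinson-Fleming form GA_days = 8.052*sqrt(CRL_mm) + 23.73.

Before 14 weeks, CRL-based GA is the definition of truth, so model-vs-
biometry comparison is replaced by a literature benchmark in that band
(see :func:`comparison_mode`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

#: Gold-standard dating-scan eligibility window, days (9+0 to 13+6 weeks).
DATING_WINDOW_DAYS = (63.0, 97.0)

#: Below 14 completed weeks (98 days), CRL is definitionally correct.
CRL_DEFINITIVE_BEFORE_DAYS = 98.0

CRL_PLAUSIBLE_MM = (2.0, 95.0)


@dataclass(frozen=True)
class BiometrySet:
    """BPD/HC/AC/FL measurements in millimetres."""

    bpd_mm: float
    hc_mm: float
    ac_mm: float
    fl_mm: float

    def __post_init__(self) -> None:
        for name in ("bpd_mm", "hc_mm", "ac_mm", "fl_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass(frozen=True)
class DatingRecord:
    """A first-trimester dating measurement and the elapsed time to exam."""

    crl_mm: float
    days_elapsed_to_exam: int = 0

    def __post_init__(self) -> None:
        if self.days_elapsed_to_exam < 0:
            raise ValueError("days_elapsed_to_exam must be non-negative")
        if self.crl_mm <= 0:
            raise ValueError("crl_mm must be positive")


def biometry_ga(biometry: BiometrySet) -> float:
    """Evaluate the biometry dating formula (inputs in mm, output in days)."""
    return 7.0 * (
        10.85
        + 0.0006 * biometry.hc_mm * biometry.fl_mm
        + 0.067 * biometry.bpd_mm
        + 0.0168 * biometry.ac_mm
    )


def robinson_fleming(crl_mm: float) -> float:
    """Default CRL dating curve: GA_days = 8.052*sqrt(CRL) + 23.73."""
    return 8.052 * float(np.sqrt(crl_mm)) + 23.73


def crl_to_ga(
    crl_mm: float, formula: Optional[Callable[[float], float]] = None
) -> float:
    """Convert a CRL measurement (mm) to GA (days) via a dating curve.

    A CRL outside the plausible 2-95 mm range triggers a warning but the
    curve value is still returned.
    """
    if crl_mm <= 0:
        raise ValueError("crl_mm must be positive")
    if not (CRL_PLAUSIBLE_MM[0] <= crl_mm <= CRL_PLAUSIBLE_MM[1]):
        warnings.warn(
            f"CRL {crl_mm} mm outside plausible range {CRL_PLAUSIBLE_MM}",
            stacklevel=2,
        )
    return (formula or robinson_fleming)(crl_mm)


def propagate_gold_standard(
    record: DatingRecord, formula: Optional[Callable[[float], float]] = None
) -> float:
    """Gold-standard GA at the examination date.

    The dating-scan GA (from CRL) must fall inside the 9+0 to 13+6 week
    eligibility window; the elapsed days since the dating scan are added.
    """
    dating_ga = crl_to_ga(record.crl_mm, formula)
    lo, hi = DATING_WINDOW_DAYS
    if not (lo <= dating_ga <= hi):
        raise ValueError(
            f"dating-scan GA {dating_ga:.1f} d outside the gold-standard "
            f"eligibility window [{lo:.0f}, {hi:.0f}] days"
        )
    return dating_ga + record.days_elapsed_to_exam


def comparison_mode(reference_ga_days: float) -> str:
    """Which comparator applies at this GA.

    'crl_benchmark' before 14 weeks (CRL is definitionally correct there, so
    the comparison is to a literature accuracy benchmark), 'biometry' from
    14 weeks on.
    """
    return (
        "crl_benchmark"
        if reference_ga_days < CRL_DEFINITIVE_BEFORE_DAYS
        else "biometry"
    )
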