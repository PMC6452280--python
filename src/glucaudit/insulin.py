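"""Sliding-scale insulin protocol and dose-discrepancy assessment.

A transcription error matters clinically when the wrong glucose value
crosses a dosing band of the unit's sliding-scale protocol, so the nurse
gives a different subcutaneous dose than the true value prescribes — or
withholds a due dose. An *insulin error* is any nonzero difference
between the dose the protocol assigns to the transcribed value and the
dose it assigns to the meter's (true) value, regardless of magnitude.

Hospitals do not publish a universal sliding scale, so the protocol is
configuration: an ordered list of half-open glucose bands ``[lo, hi)``
each mapped to a dose in whole units, optionally with a hold-and-notify
hypoglycemia threshold. A documented default scale ships with the
package; any real audit should supply the unit's own protocol.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ConfigError
from .records import REPORTABLE_RANGE


@dataclass(frozen=True)
class InsulinProtocol:
    """Ordered, non-overlapping, exhaustive glucose bands mapped to doses.

    Parameters
    ----------
    bands : sequence of (lo, hi, dose_units)
        Half-open intervals ``[lo, hi)`` in mg/dL covering the reportable
        range with no gaps or overlaps; doses are non-negative units and
        must be non-decreasing in glucose above the hold band.
    hold_below : int, optional
        Hypoglycemia threshold; values below it are "hold and notify"
        (dose 0 plus an alert), e.g. 70 mg/dL.
    """

    bands: tuple = ()
    hold_below: Optional[int] = None
    domain: tuple[int, int] = REPORTABLE_RANGE

    def __post_init__(self):
        bands = tuple(tuple(b) for b in self.bands)
        object.__setattr__(self, "bands", bands)
        if not bands:
            raise ConfigError("protocol needs at least one band")
        lo0, hi_prev, _ = bands[0]
        if lo0 > self.domain[0]:
            raise ConfigError(f"first band starts at {lo0}, above domain min {self.domain[0]}")
        prev_dose = None
        for lo, hi, dose in bands:
            if hi <= lo:
                raise ConfigError(f"band [{lo}, {hi}) is empty or inverted")
            if dose < 0:
                raise ConfigError(f"negative dose {dose} in band [{lo}, {hi})")
        for (lo_a, hi_a, dose_a), (lo_b, hi_b, dose_b) in zip(bands, bands[1:]):
            if lo_b != hi_a:
                raise ConfigError(f"gap or overlap between [{lo_a},{hi_a}) and [{lo_b},{hi_b})")
            above_hold = self.hold_below is None or lo_a >= self.hold_below
            if above_hold and dose_b < dose_a:
                raise ConfigError("doses must be non-decreasing in glucose above the hold band")
        if bands[-1][1] < self.domain[1] + 1:
            raise ConfigError(
                f"bands end at {bands[-1][1]}, below domain max {self.domain[1]}"
            )

    def dose(self, glucose: int) -> int:
        """Dose in units of the unique band containing ``glucose``."""
        lo, hi = self.domain
        if not lo <= glucose <= hi:
            raise ValueError(f"glucose {glucose} outside protocol domain [{lo}, {hi}]")
        los = [b[0] for b in self.bands]
        i = bisect.bisect_right(los, glucose) - 1
        return self.bands[i][2]

    def is_hold(self, glucose: int) -> bool:
        return self.hold_below is not None and glucose < self.hold_below


#: Default sliding scale: no insulin below 150 mg/dL, 2 U per 50 mg/dL band
#: up to 10 U at >=350, hold-and-notify below 70.
DEFAULT_PROTOCOL = InsulinProtocol(
    bands=(
        (10, 150, 0),
        (150, 200, 2),
        (200, 250, 4),
        (250, 300, 6),
        (300, 350, 8),
        (350, 601, 10),
    ),
    hold_below=70,
)


def protocol_dose(protocol: InsulinProtocol, glucose: int) -> int:
    """Look up the protocol dose for a glucose value (half-open bands)."""
    return protocol.dose(glucose)


@dataclass(frozen=True)
class InsulinAssessment:
    """Dose under the true value vs under the transcribed value."""

    dose_true: int
    dose_transcribed: int
    discrepancy: int  # dose_transcribed - dose_true, units
    is_error: bool


def assess_insulin(
    meter_value: int, transcribed_value: int, protocol: InsulinProtocol = DEFAULT_PROTOCOL
) -> InsulinAssessment:
    """Assess whether dosing off the transcribed value is an insulin error.

    An error is any nonzero dose discrepancy, which subsumes "not giving
    insulin when it should be administered" (a due dose of d>0 read as a
    no-dose value gives discrepancy -d).
    """
    dose_true = protocol.dose(meter_value)
    dose_tr = protocol.dose(transcribed_value)
    disc = dose_tr - dose_true
    is_error = disc != 0 or (dose_true > 0 and dose_tr == 0)
    return InsulinAssessment(dose_true, dose_tr, disc, is_error)


def summarize_insulin_errors(assessments, vins=None) -> dict:
    """Tally insulin errors over a collection of assessments.

    Parameters
    ----------
    assessments : sequence of InsulinAssessment
        Assessments of the transcription-error cases only.
    vins : sequence of str, optional
        Episode identifier aligned with ``assessments``, to count
        distinct patients affected.

    Returns
    -------
    dict with n_errors, discrepancy min/max over the errors (None when
    there are none), and n_patients when vins given.
    """
    assessments = list(assessments)
    errs = [a for a in assessments if a.is_error]
    out = {
        "n_assessed": len(assessments),
        "n_errors": len(errs),
        "min_discrepancy": min((a.discrepancy for a in errs), default=None),
        "max_discrepancy": max((a.discrepancy for a in errs), default=None),
    }
    if vins is not None:
        vins = list(vins)
        if len(vins) != len(assessments):
            raise ValueError("vins must align with assessments")
        out["n_patients"] = len({v for v, a in zip(vins, assessments) if a.is_error})
    return out


def load_protocol(spec: dict) -> InsulinProtocol:
    """Build a protocol from a config mapping (e.g. parsed YAML).

    Expected keys: ``bands`` (list of [lo, hi, dose_units]) and optional
    ``hold_below``.
    """
    try:
        bands = tuple(tuple(int(x) for x in b) for b in spec["bands"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed protocol config: {exc}") from exc
    hold = spec.get("hold_below")
    return InsulinProtocol(bands=bands, hold_below=None if hold is None else int(hold))
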