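"""Rule-based drug-likeness profiling.

Implements the oral drug-likeness rule counters used in CNS screening
campaigns:

* Lipinski rule of five (VRF): MW < 500, logP < 5, DHB <= 5, AHB <= 10,
  PSA > 0 — the violation count over these five conditions.
* Jorgensen rule of three (VRT): logS > -5.7, PCaco > 22 nm/s, PM < 7.
* Blood–brain-barrier range check: predicted QPlogBB within [-3, 1.2],
  the range covering 95% of CNS drugs.
* CNS MPO: the multiparameter-optimization score of Wager et al., a sum of
  six piecewise-linear desirability functions (clogP, clogD, MW, TPSA,
  HBD, most-basic pKa), each in [0, 1], total in [0, 6].

Inequality strictness follows the published footnote verbatim (MW strictly
below 500, DHB up to and including 5, ...).  Fractional donor/acceptor
counts are compared as real numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .chem_io import PropertyRow

__all__ = [
    "RuleReport",
    "lipinski_violations",
    "jorgensen_violations",
    "check_bbb_range",
    "cns_mpo_score",
    "druglikeness_report",
]


@dataclass
class RuleReport:
    """Per-compound rule outcome: violation counts + failed-rule names."""

    id: str
    vrf: int
    vrt: int
    vrf_reasons: list[str] = field(default_factory=list)
    vrt_reasons: list[str] = field(default_factory=list)
    bbb_in_range: Optional[bool] = None
    cns_mpo: Optional[float] = None

    def __post_init__(self) -> None:
        assert self.vrf == len(self.vrf_reasons)
        assert self.vrt == len(self.vrt_reasons)


def _require(row: PropertyRow, fields: list[str]) -> None:
    for f in fields:
        if getattr(row, f, None) is None:
            raise ValueError(f"missing field {f} for compound {row.id}")


def lipinski_violations(row: PropertyRow) -> tuple[int, list[str]]:
    """Count rule-of-five violations: MW<500, logP<5, DHB<=5, AHB<=10, PSA>0."""
    _require(row, ["MW", "logP", "DHB", "AHB", "PSA"])
    reasons = []
    if not row.MW < 500:
        reasons.append("MW")
    if not row.logP < 5:
        reasons.append("logP")
    if not row.DHB <= 5:
        reasons.append("DHB")
    if not row.AHB <= 10:
        reasons.append("AHB")
    if not row.PSA > 0:
        reasons.append("PSA")
    return len(reasons), reasons


def jorgensen_violations(row: PropertyRow) -> tuple[int, list[str]]:
    """Count rule-of-three violations: logS>-5.7, PCaco>22 nm/s, PM<7."""
    _require(row, ["logS", "PCaco", "PM"])
    reasons = []
    if not row.logS > -5.7:
        reasons.append("logS")
    if not row.PCaco > 22:
        reasons.append("PCaco")
    if not row.PM < 7:
        reasons.append("PM")
    return len(reasons), reasons


def check_bbb_range(qplogbb: float) -> bool:
    """True iff the predicted brain/blood log ratio is within [-3, 1.2]."""
    import math

    if not math.isfinite(qplogbb):
        raise ValueError("QPlogBB must be finite")
    return -3.0 <= qplogbb <= 1.2


def _monotone_desirability(x: float, lo: float, hi: float) -> float:
    """1 below ``lo``, 0 above ``hi``, linear in between."""
    if x <= lo:
        return 1.0
    if x >= hi:
        return 0.0
    return (hi - x) / (hi - lo)


def _hump_desirability(x: float, lo0: float, lo1: float, hi1: float, hi0: float) -> float:
    """0 outside [lo0, hi0], 1 inside [lo1, hi1], linear ramps between."""
    if x <= lo0 or x >= hi0:
        return 0.0
    if lo1 <= x <= hi1:
        return 1.0
    if x < lo1:
        return (x - lo0) / (lo1 - lo0)
    return (hi0 - x) / (hi0 - hi1)


def cns_mpo_score(
    clogp: float, clogd: float, mw: float, tpsa: float, hbd: float, pka: float
) -> float:
    """CNS MPO desirability score in [0, 6].

    Component transforms (Wager et al.): clogP monotone 3→5, clogD 2→4,
    MW 360→500, HBD 0.5→3.5, pKa 8→10; TPSA is a hump — undesirable below
    20 or above 120, fully desirable between 40 and 90.
    """
    import math

    parts = [clogp, clogd, mw, tpsa, hbd, pka]
    if not all(math.isfinite(p) for p in parts):
        raise ValueError("all six CNS MPO inputs must be finite")
    return (
        _monotone_desirability(clogp, 3.0, 5.0)
        + _monotone_desirability(clogd, 2.0, 4.0)
        + _monotone_desirability(mw, 360.0, 500.0)
        + _hump_desirability(tpsa, 20.0, 40.0, 90.0, 120.0)
        + _monotone_desirability(hbd, 0.5, 3.5)
        + _monotone_desirability(pka, 8.0, 10.0)
    )


def druglikeness_report(
    rows: Iterable[PropertyRow],
) -> tuple[list[RuleReport], Optional[int]]:
    """Per-row rule reports + the set-level maximum violation count.

    The summary is ``max over rows of max(vrf, vrt)`` — the statistic used
    to state that a candidate set "causes no more than one violation".
    ``None`` when the input is empty.
    """
    reports = []
    for row in rows:
        vrf, vrf_reasons = lipinski_violations(row)
        vrt, vrt_reasons = jorgensen_violations(row)
        reports.append(
            RuleReport(
                id=row.id,
                vrf=vrf,
                vrt=vrt,
                vrf_reasons=vrf_reasons,
                vrt_reasons=vrt_reasons,
                bbb_in_range=(
                    check_bbb_range(row.QPlogBB) if row.QPlogBB is not None else None
                ),
                cns_mpo=row.CNSMPO,
            )
        )
    summary = max((max(r.vrf, r.vrt) for r in reports), default=None)
    return reports, summary
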