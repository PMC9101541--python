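"""Electron–ion interaction potential (EIIP) and AQVN descriptors.

The average quasi-valence number (AQVN, written Z*) of a molecule is the
atom-count-weighted mean of valence-electron numbers over *all* atoms,
hydrogens included:

    Z* = sum_i(n_i * Z_i) / N

where ``Z_i`` is the number of valence electrons of element i, ``n_i`` the
number of atoms of that element, and ``N`` the total atom count.  The EIIP
descriptor, in Rydberg units, follows from a general model pseudopotential:

    EIIP = 0.25 * Z* * sin(1.04 * pi * Z*) / (2 * pi)

The division by 2*pi applies to the whole product; published tables report
the magnitude of this quantity.  Small molecules targeting a common receptor
cluster in narrow EIIP/AQVN windows, which makes the pair a cheap first-pass
virtual-screening filter: serotonin sits at AQVN 2.72 / EIIP 0.055, and the
active domain for 5HT6 antagonists spans AQVN 2.51-2.90, EIIP 0.009-0.09.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "DEFAULT_VALENCE",
    "ValenceTable",
    "MolecularComposition",
    "EIIPDescriptor",
    "DomainWindow",
    "PAPER_WINDOWS",
    "compute_aqvn",
    "compute_eiip",
    "classify_domain",
    "screen_library",
    "ScreenResult",
]

#: Valence-electron counts for neutral main-group atoms.  Formal charges do
#: not alter these: AQVN is defined per element.
DEFAULT_VALENCE: dict[str, int] = {
    "H": 1,
    "C": 4,
    "N": 5,
    "O": 6,
    "S": 6,
    "P": 5,
    "F": 7,
    "Cl": 7,
    "Br": 7,
    "I": 7,
}


@dataclass(frozen=True)
class ValenceTable:
    """Element symbol -> valence-electron count.

    The default table must reproduce AQVN(C10H12N2O) = 2.72 exactly; this
    calibration invariant pins the serotonin anchor value.
    """

    values: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_VALENCE))

    def __post_init__(self) -> None:
        for el, z in self.values.items():
            if not (isinstance(z, int) and 1 <= z <= 8):
                raise ValueError(f"valence for {el} must be an integer in [1, 8], got {z!r}")

    def __getitem__(self, element: str) -> int:
        try:
            return self.values[element]
        except KeyError:
            raise KeyError(f"no valence-electron count for element {element!r}") from None

    def __contains__(self, element: str) -> bool:
        return element in self.values


@dataclass(frozen=True)
class MolecularComposition:
    """Per-element atom counts, explicit hydrogens included."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("composition must contain at least one atom")
        for el, n in self.counts.items():
            if n < 1:
                raise ValueError(f"atom count for {el} must be >= 1, got {n}")

    @property
    def n_atoms(self) -> int:
        """Total atom count N."""
        return sum(self.counts.values())

    @property
    def n_elements(self) -> int:
        """Number of distinct atomic components m."""
        return len(self.counts)

    @classmethod
    def from_formula(cls, formula: str) -> "MolecularComposition":
        """Parse a Hill-style formula such as ``C10H12N2O``."""
        import re

        counts: dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
            if m.start() != pos or not m.group(0):
                break
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse molecular formula {formula!r}")
        return cls(counts)


@dataclass(frozen=True)
class EIIPDescriptor:
    """AQVN plus signed and magnitude EIIP (Ry) for one molecule."""

    aqvn: float
    eiip_signed: float

    @property
    def eiip(self) -> float:
        """EIIP magnitude — the value published tables print."""
        return abs(self.eiip_signed)


@dataclass(frozen=True)
class DomainWindow:
    """An AQVN interval (center ± halfwidth) with optional EIIP bounds."""

    label: str
    aqvn_center: float
    aqvn_halfwidth: float = 0.005
    eiip_min: Optional[float] = None
    eiip_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.aqvn_halfwidth <= 0:
            raise ValueError("aqvn_halfwidth must be > 0")
        if self.eiip_min is not None and self.eiip_max is not None and self.eiip_min > self.eiip_max:
            raise ValueError("eiip_min must be <= eiip_max")

    def contains(self, desc: EIIPDescriptor) -> bool:
        if abs(desc.aqvn - self.aqvn_center) > self.aqvn_halfwidth:
            return False
        if self.eiip_min is not None and desc.eiip < self.eiip_min:
            return False
        if self.eiip_max is not None and desc.eiip > self.eiip_max:
            return False
        return True

    @property
    def aqvn_lo(self) -> float:
        return self.aqvn_center - self.aqvn_halfwidth

    @property
    def aqvn_hi(self) -> float:
        return self.aqvn_center + self.aqvn_halfwidth


#: The three screening subdomains used in the 5HT6 campaign.  Both the
#: printed "2.99" center and the intepirdine AQVN 2.909 are shipped as
#: presets; window bounds are configuration, not hard-coded truth.
PAPER_WINDOWS: tuple[DomainWindow, ...] = (
    DomainWindow("2.55", 2.55),
    DomainWindow("2.72", 2.72),
    DomainWindow("2.99", 2.99),
)

#: Alternative third window centered on intepirdine's AQVN.
INTEPIRDINE_WINDOW = DomainWindow("2.909", 2.909)

#: The wide active domain for 5HT6 antagonists.
ACTIVE_DOMAIN = DomainWindow(
    "active", (2.51 + 2.90) / 2, (2.90 - 2.51) / 2, eiip_min=0.009, eiip_max=0.09
)


def compute_aqvn(comp: MolecularComposition, table: ValenceTable | None = None) -> float:
    """Average quasi-valence number Z* = sum(n_i * Z_i) / N."""
    table = table or ValenceTable()
    unknown = [el for el in comp.counts if el not in table]
    if unknown:
        raise KeyError(f"no valence-electron count for element(s): {', '.join(sorted(unknown))}")
    total = sum(n * table[el] for el, n in comp.counts.items())
    return total / comp.n_atoms


def compute_eiip(aqvn: float) -> EIIPDescriptor:
    """EIIP = 0.25 * Z* * sin(1.04 * pi * Z*) / (2 * pi), in Ry.

    The signed value is retained; the magnitude is what gets tabulated.
    Zeros fall exactly at Z* = k / 1.04 for integer k.
    """
    if aqvn <= 0:
        raise ValueError(f"AQVN must be positive, got {aqvn}")
    signed = 0.25 * aqvn * math.sin(1.04 * math.pi * aqvn) / (2.0 * math.pi)
    return EIIPDescriptor(aqvn=aqvn, eiip_signed=signed)


def _validate_windows(windows: Sequence[DomainWindow]) -> None:
    for i, a in enumerate(windows):
        for b in windows[i + 1 :]:
            if a.aqvn_lo <= b.aqvn_hi and b.aqvn_lo <= a.aqvn_hi:
                raise ValueError(
                    f"overlapping AQVN windows: {a.label!r} [{a.aqvn_lo:.4f}, {a.aqvn_hi:.4f}] "
                    f"and {b.label!r} [{b.aqvn_lo:.4f}, {b.aqvn_hi:.4f}]"
                )


def classify_domain(
    desc: EIIPDescriptor, windows: Sequence[DomainWindow]
) -> Optional[str]:
    """Label of the unique window containing ``desc``, or None.

    Windows must be non-overlapping in AQVN; overlap is a configuration
    error, raised eagerly.
    """
    _validate_windows(windows)
    for w in windows:
        if w.contains(desc):
            return w.label
    return None


@dataclass
class ScreenResult:
    """Outcome of screening a library against a set of AQVN/EIIP windows."""

    survivors: dict[str, list]  # window label -> list of (record, EIIPDescriptor)
    n_input: int = 0
    n_survivors: int = 0
    n_errors: int = 0
    errors: list = field(default_factory=list)  # (record id, message)

    def summary(self) -> dict[str, int]:
        out = {"input": self.n_input, "survivors": self.n_survivors, "errors": self.n_errors}
        for label, recs in self.survivors.items():
            out[f"window:{label}"] = len(recs)
        return out


def screen_library(
    records: Iterable,
    windows: Sequence[DomainWindow] = PAPER_WINDOWS,
    table: ValenceTable | None = None,
) -> ScreenResult:
    """Filter molecule records by EIIP/AQVN window membership.

    Each record needs a ``composition`` attribute (MolecularComposition) and
    an ``id``.  Per-record failures (unknown elements) are collected, never
    abort the batch.  Input order is preserved within each window.
    """
    _validate_windows(windows)
    table = table or ValenceTable()
    result = ScreenResult(survivors={w.label: [] for w in windows})
    for rec in records:
        result.n_input += 1
        try:
            desc = compute_eiip(compute_aqvn(rec.composition, table))
        except (KeyError, ValueError) as exc:
            result.n_errors += 1
            result.errors.append((getattr(rec, "id", "?"), str(exc)))
            continue
        for w in windows:
            if w.contains(desc):
                result.survivors[w.label].append((rec, desc))
                result.n_survivors += 1
                break
    return result
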