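"""Thermodynamic-cycle assembly for sterol transport legs.

A transport pathway is a chain of directed free-energy legs (for example
SSD → membrane → solvent → SBD for the indirect cholesterol-export path).
Legs are statistically independent estimates, so the pathway total carries
a quadrature error, e_T = sqrt(sum_i e_i**2).  Reported values are rounded
to integer kJ·mol⁻¹ (half-up) only at presentation time; raw floats are
preserved on every object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FreeEnergyValue",
    "TransportLeg",
    "TransportPathResult",
    "CycleClosureReport",
    "DEFAULT_SITES",
    "quadrature_error",
    "compose_path",
    "cycle_closure",
    "round_half_up",
]

#: Site vocabulary for the PTCH1/DISP1 transport network.  Extensible via the
#: ``sites`` argument of :func:`compose_path`.
DEFAULT_SITES = ("SSD", "membrane", "solvent", "SBD", "ECD_base")


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (reporting rule)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def quadrature_error(errors: Iterable[float]) -> float:
    """Combine independent errors in quadrature: sqrt(sum e_i^2).

    Raises ``ValueError`` on any negative input.
    """
    arr = np.asarray(list(errors), dtype=float)
    if arr.size and (arr < 0).any():
        raise ValueError("errors must be nonnegative")
    return float(np.sqrt(np.sum(arr**2)))


@dataclass(frozen=True)
class FreeEnergyValue:
    """A directed free-energy difference with uncertainty (kJ·mol⁻¹).

    ``direction`` is an ordered (from_state, to_state) pair; reversing the
    direction negates the value and preserves the error.
    """

    value: float
    error: float = 0.0
    label: str = ""
    direction: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("error must be nonnegative")

    def reversed(self) -> "FreeEnergyValue":
        direction = None if self.direction is None else (self.direction[1], self.direction[0])
        return replace(self, value=-self.value, direction=direction)

    def __neg__(self) -> "FreeEnergyValue":
        return self.reversed()

    def reported(self) -> tuple[int, int]:
        """(value, error) rounded half-up to integer kJ·mol⁻¹."""
        return round_half_up(self.value), round_half_up(self.error)

    def __str__(self) -> str:
        v, e = self.reported()
        tag = f" {self.label}" if self.label else ""
        return f"{v:+d} ± {e:d} kJ/mol{tag}"


@dataclass(frozen=True)
class TransportLeg:
    """A directed edge of the transport network with its ΔG estimate.

    ``provenance`` records where the estimate came from (a PMF id, an ABFE
    cycle id, or literature).  ``physiological`` marks legs that belong to
    the canonical export pathway; alternatives (the OH-down SSD orientation,
    the solvent-exposed ECD egress) are representable but are never composed
    automatically.
    """

    from_site: str
    to_site: str
    dg: FreeEnergyValue
    provenance: str = ""
    physiological: bool = True

    def __post_init__(self) -> None:
        if self.from_site == self.to_site:
            raise ValueError("a transport leg must connect two distinct sites")

    def reversed(self) -> "TransportLeg":
        return TransportLeg(
            from_site=self.to_site,
            to_site=self.from_site,
            dg=self.dg.reversed(),
            provenance=self.provenance,
            physiological=self.physiological,
        )


@dataclass(frozen=True)
class TransportPathResult:
    """An end-to-end pathway: ordered legs, total ΔG, quadrature error."""

    legs: tuple[TransportLeg, ...]
    total: FreeEnergyValue

    @property
    def path(self) -> str:
        if not self.legs:
            return ""
        return " -> ".join([self.legs[0].from_site] + [leg.to_site for leg in self.legs])

    def summary(self) -> str:
        lines = [f"Transport path: {self.path}"]
        for leg in self.legs:
            v, e = leg.dg.reported()
            lines.append(
                f"  {leg.from_site:>9s} -> {leg.to_site:<9s} {v:+4d} ± {e:d} kJ/mol"
                + (f"  [{leg.provenance}]" if leg.provenance else "")
            )
        v, e = self.total.reported()
        lines.append(f"  total: {v:+d} ± {e:d} kJ/mol (raw {self.total.value:+.3f} ± {self.total.error:.3f})")
        return "\n".join(lines)


class BrokenPathError(ValueError):
    """No leg continues the chain from the named site."""


class AmbiguousPathError(ValueError):
    """More than one distinct leg could continue the chain."""


def compose_path(
    legs: Sequence[TransportLeg],
    start: str,
    end: str,
    sites: Sequence[str] = DEFAULT_SITES,
    allow_nonphysiological: bool = False,
) -> TransportPathResult:
    """Chain directed legs from ``start`` to ``end`` and sum their ΔG values.

    Legs are reversed automatically when needed.  The total error is the
    quadrature combination of the leg errors (the legs are independent
    estimates).  A gap raises :class:`BrokenPathError`; two distinct legs
    leaving the current site raise :class:`AmbiguousPathError`.
    """
    known = set(sites)
    for leg in legs:
        for s in (leg.from_site, leg.to_site):
            if s not in known:
                raise ValueError(f"unknown site {s!r}; extend `sites` to accept it")
    if start not in known or end not in known:
        raise ValueError(f"unknown endpoint: {start!r} or {end!r}")

    pool = [leg for leg in legs if leg.physiological or allow_nonphysiological]
    ordered: list[TransportLeg] = []
    current = start
    remaining = list(pool)
    first_step = current == end and bool(remaining)  # closed loop: force one step
    while current != end or first_step:
        first_step = False
        candidates = []
        for leg in remaining:
            if leg.from_site == current:
                candidates.append(leg)
            elif leg.to_site == current:
                candidates.append(leg.reversed())
        if not candidates:
            raise BrokenPathError(
                f"no leg continues the path from {current!r} (reached via {ordered and ordered[-1].from_site})"
            )
        targets = {leg.to_site for leg in candidates}
        if len(targets) > 1:
            raise AmbiguousPathError(
                f"multiple legs leave {current!r} (to {sorted(targets)}); supply an unambiguous chain"
            )
        # duplicates with identical estimates are interchangeable; conflicting
        # duplicates are a data error
        estimates = {(leg.to_site, leg.dg.value, leg.dg.error) for leg in candidates}
        if len(estimates) > 1:
            raise AmbiguousPathError(
                f"conflicting duplicate legs between {current!r} and {candidates[0].to_site!r}"
            )
        chosen = candidates[0]
        ordered.append(chosen)
        # remove the consumed leg from the pool (match by endpoints either way)
        for i, leg in enumerate(remaining):
            if {leg.from_site, leg.to_site} == {chosen.from_site, chosen.to_site}:
                del remaining[i]
                break
        current = chosen.to_site

    total = FreeEnergyValue(
        value=float(sum(leg.dg.value for leg in ordered)),
        error=quadrature_error(leg.dg.error for leg in ordered),
        label=f"{start}->{end}",
        direction=(start, end),
    )
    return TransportPathResult(legs=tuple(ordered), total=total)


@dataclass(frozen=True)
class CycleClosureReport:
    """Direct-vs-indirect consistency of two estimates of the same ΔG."""

    direct: FreeEnergyValue
    indirect: FreeEnergyValue
    discrepancy: FreeEnergyValue
    zero_within_error: bool
    same_sign: bool

    def summary(self) -> str:
        dv, de = self.discrepancy.reported()
        return (
            f"cycle closure: direct {self.direct} vs indirect {self.indirect}\n"
            f"  discrepancy (direct - indirect): {dv:+d} ± {de:d} kJ/mol\n"
            f"  zero within combined 1-sigma interval: {self.zero_within_error}\n"
            f"  estimates share sign: {self.same_sign}"
        )


def cycle_closure(direct: FreeEnergyValue, indirect: FreeEnergyValue) -> CycleClosureReport:
    """Compare two independent estimates of one free-energy difference.

    Both values must describe the same endpoints in the same direction when
    directions are declared.  The discrepancy is direct − indirect with
    quadrature error; the report flags whether zero lies within the combined
    1σ interval and whether both estimates share a sign.
    """
    if direct.direction is not None and indirect.direction is not None:
        if direct.direction != indirect.direction:
            raise ValueError(
                f"direction mismatch: {direct.direction} vs {indirect.direction}"
            )
    disc_val = direct.value - indirect.value
    disc_err = quadrature_error([direct.error, indirect.error])
    discrepancy = FreeEnergyValue(disc_val, disc_err, label="direct-indirect")
    return CycleClosureReport(
        direct=direct,
        indirect=indirect,
        discrepancy=discrepancy,
        zero_within_error=bool(abs(disc_val) <= disc_err),
        same_sign=bool(math.copysign(1.0, direct.value) == math.copysign(1.0, indirect.value)),
    )
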