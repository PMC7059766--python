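"""In-silico fragment size selection and MAF enrichment.

Computational analogue of gel-band size selection: restrict analysis to
fragments whose length falls in a band and recompute the mutant allele
frequency on the gated subset.  When mutant fragments run longer than
wild-type ones, an upper band enriches the mutant fraction; when they run
shorter, it depletes it.

Gate convention: bands in a gate set partition the length axis — every
interior gate is lower-closed, upper-open ``[lo, hi)`` and the terminal
(highest) gate is closed on both ends ``[lo, hi]``, so a fragment on a
shared boundary (e.g. 160 bp with the default 130-160 / 160-230 bands)
belongs to exactly one band.  The default gate set mirrors the two gel
bands used in ddPCR validation: 130-160 bp and 160-230 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .extract import TypedFragment
from .fragstats import compute_maf


class GateError(ValueError):
    pass


@dataclass(frozen=True)
class SizeGate:
    """A fragment-length band [lo, hi) — or [lo, hi] when terminal."""

    lo: int
    hi: int
    upper_closed: bool = False

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise GateError(f"gate lo must be < hi, got [{self.lo}, {self.hi}]")

    def __contains__(self, length: int) -> bool:
        if self.upper_closed:
            return self.lo <= length <= self.hi
        return self.lo <= length < self.hi

    @property
    def label(self) -> str:
        return f"{self.lo}-{self.hi}"


def default_gates() -> tuple[SizeGate, SizeGate]:
    """The two gel bands: [130, 160) and [160, 230]."""
    return (SizeGate(130, 160), SizeGate(160, 230, upper_closed=True))


def make_gates(bounds: Sequence[tuple[int, int]]) -> tuple[SizeGate, ...]:
    """Build a non-overlapping gate set; the last gate is upper-closed."""
    gates = tuple(
        SizeGate(lo, hi, upper_closed=(i == len(bounds) - 1))
        for i, (lo, hi) in enumerate(bounds)
    )
    for a, b in zip(gates, gates[1:]):
        if b.lo < a.hi:
            raise GateError(f"gates {a.label} and {b.label} overlap")
    return gates


def parse_gates(text: str) -> tuple[SizeGate, ...]:
    """Parse a CLI gate string like ``"130-160,160-230"``."""
    bounds = []
    for part in text.split(","):
        try:
            lo, hi = part.strip().split("-")
            bounds.append((int(lo), int(hi)))
        except ValueError as exc:
            raise GateError(f"cannot parse gate {part!r}; expected LO-HI") from exc
    if not bounds:
        raise GateError("no gates given")
    return make_gates(bounds)


def apply_gate(fragments: Sequence[TypedFragment],
               gate: SizeGate) -> list[TypedFragment]:
    """Fragments whose length falls inside the gate.  Unresolved fragments
    pass gating like any other but stay excluded from MAF downstream."""
    return [f for f in fragments if f.length in gate]


@dataclass(frozen=True)
class GateResult:
    """MAF recomputed inside one size gate.

    ``maf_gated`` is None when the gate captures no typed (mutant or wild)
    fragment — undefined, not zero.  ``enrichment`` is the ratio of gated
    to ungated MAF, None when either is undefined or the ungated MAF is 0.
    """

    gate: SizeGate
    n_mut: int
    n_wt: int
    n_unresolved: int
    maf_gated: float | None
    enrichment: float | None


def gate_report(fragments: Sequence[TypedFragment],
                gates: Sequence[SizeGate] | None = None) -> list[GateResult]:
    """Per-gate counts, MAF and enrichment relative to the ungated MAF."""
    if not fragments:
        raise GateError("no fragments to gate")
    if gates is None:
        gates = default_gates()
    n_mut_all = sum(1 for f in fragments if f.allele == "mutant")
    n_wt_all = sum(1 for f in fragments if f.allele == "wild")
    maf_ungated = (compute_maf(n_mut_all, n_wt_all)
                   if n_mut_all + n_wt_all else None)
    results = []
    for gate in gates:
        sub = apply_gate(fragments, gate)
        n_mut = sum(1 for f in sub if f.allele == "mutant")
        n_wt = sum(1 for f in sub if f.allele == "wild")
        n_unres = len(sub) - n_mut - n_wt
        maf = compute_maf(n_mut, n_wt) if n_mut + n_wt else None
        enrich = (maf / maf_ungated
                  if maf is not None and maf_ungated else None)
        results.append(GateResult(gate=gate, n_mut=n_mut, n_wt=n_wt,
                                  n_unresolved=n_unres, maf_gated=maf,
                                  enrichment=enrich))
    return results
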