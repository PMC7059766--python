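"""Hotspot panel definition and TSV I/O.

A *hotspot* is a recurrent single-base somatic substitution (for example
``EGFR-T790M``) targeted by a capture panel.  Positions are 1-based on the
forward reference strand, following the variant-centric (VCF) convention;
all internal interval arithmetic elsewhere in the package is 0-based
half-open, and the conversion happens only at I/O boundaries like this
module.

Only SNVs are supported: multi-nucleotide variants and indels are rejected
at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

_BASES = frozenset("ACGT")


class PanelError(ValueError):
    """Raised for malformed panel files or invalid hotspot definitions."""


@dataclass(frozen=True)
class Hotspot:
    """A single-base substitution locus on the forward reference strand.

    Parameters
    ----------
    name
        Unique variant label, e.g. ``"EGFR-T790M"``.
    gene
        Gene symbol the variant falls in.
    chrom
        Reference sequence name.
    pos
        1-based position of the variant base.
    ref_base, alt_base
        Single upper-case bases; must differ.
    """

    name: str
    gene: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise PanelError(f"hotspot {self.name!r}: pos must be >= 1, got {self.pos}")
        for label, base in (("ref", self.ref_base), ("alt", self.alt_base)):
            if base not in _BASES:
                raise PanelError(
                    f"hotspot {self.name!r}: {label} base must be one of A/C/G/T, "
                    f"got {base!r} (indels and MNVs are not supported)"
                )
        if self.ref_base == self.alt_base:
            raise PanelError(f"hotspot {self.name!r}: ref and alt base are both {self.ref_base!r}")

    @property
    def pos0(self) -> int:
        """0-based position of the variant base."""
        return self.pos - 1


@dataclass(frozen=True)
class Panel:
    """An ordered, non-empty collection of hotspots.

    Names are unique and no two entries share a (chrom, pos, alt) triple.
    """

    hotspots: tuple[Hotspot, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "hotspots", tuple(self.hotspots))
        if not self.hotspots:
            raise PanelError("empty panel")
        seen_names: set[str] = set()
        seen_triples: set[tuple[str, int, str]] = set()
        for hs in self.hotspots:
            if hs.name in seen_names:
                raise PanelError(f"duplicate hotspot name {hs.name!r}")
            triple = (hs.chrom, hs.pos, hs.alt_base)
            if triple in seen_triples:
                raise PanelError(f"duplicate hotspot site {hs.chrom}:{hs.pos} {hs.alt_base}")
            seen_names.add(hs.name)
            seen_triples.add(triple)

    def __iter__(self) -> Iterator[Hotspot]:
        return iter(self.hotspots)

    def __len__(self) -> int:
        return len(self.hotspots)

    def __getitem__(self, key: int | str) -> Hotspot:
        if isinstance(key, str):
            for hs in self.hotspots:
                if hs.name == key:
                    return hs
            raise KeyError(key)
        return self.hotspots[key]


_COLUMNS = ("name", "gene", "chrom", "pos", "ref", "alt")


def read_panel(path: str | Path) -> Panel:
    """Read a hotspot panel from a 6-column TSV.

    Columns are ``name, gene, chrom, pos, ref, alt`` (tab-separated, UTF-8).
    A header line is optional and detected by a non-numeric ``pos`` field;
    ``#``-prefixed comment lines and blank lines are ignored.

    Raises
    ------
    PanelError
        On malformed lines (with the line number), duplicate sites, or an
        empty panel.
    """
    path = Path(path)
    hotspots: list[Hotspot] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise PanelError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
                )
            name, gene, chrom, pos_s, ref, alt = (f.strip() for f in fields)
            if not pos_s.lstrip("-").isdigit():
                if not hotspots and lineno <= _first_data_lineno(path):
                    continue  # header line
                raise PanelError(f"{path}:{lineno}: non-numeric pos field {pos_s!r}")
            try:
                hotspots.append(
                    Hotspot(name=name, gene=gene, chrom=chrom, pos=int(pos_s),
                            ref_base=ref.upper(), alt_base=alt.upper())
                )
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
    if not hotspots:
        raise PanelError(f"{path}: empty panel")
    try:
        return Panel(tuple(hotspots))
    except PanelError as exc:
        raise PanelError(f"{path}: {exc}") from exc


def _first_data_lineno(path: Path) -> int:
    """Line number of the first non-comment, non-blank line."""
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.strip() and not raw.startswith("#"):
                return lineno
    return 0


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel as TSV with a commented header; inverse of :func:`read_panel`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for hs in panel:
            fh.write(
                f"{hs.name}\t{hs.gene}\t{hs.chrom}\t{hs.pos}\t{hs.ref_base}\t{hs.alt_base}\n"
            )
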