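"""Fragment extraction and allele typing from paired-end alignments.

For each hotspot, read pairs overlapping the variant base are collected
from a SAM/BAM, the template (fragment) length is recovered from the
alignment's TLEN field (SAM column 9, the outermost-coordinate span of the
proper pair), and each fragment is typed mutant / wild / unresolved from
the base its mates report at the hotspot position.

The base at the hotspot is located by CIGAR-aware coordinate walking on
each covering mate: M/=/X consume both query and reference, I/S consume
query only, D/N consume reference only.  If every covering mate reports
the alt base the fragment is mutant; the ref base, wild; any other base,
a disagreement between mates, or a deletion spanning the hotspot makes it
unresolved.  Unresolved fragments are labeled, never dropped silently.

Filtering defaults are min_mapq=20 and require_proper_pair=True; secondary
and supplementary records, unmapped reads or mates, and TLEN=0 singletons
are always excluded.  A template whose name appears more than twice among
primary records is typed unresolved (ambiguous pairing).  Base quality is
ignored unless ``min_baseq`` is set.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .panel import Hotspot

#: sentinel returned by the CIGAR walk when a deletion spans the position
DELETED = "-"


class ExtractionError(ValueError):
    pass


@dataclass
class FilterTally:
    """Per-filter exclusion counts for one hotspot extraction."""

    n_records: int = 0
    secondary_or_supplementary: int = 0
    unmapped: int = 0
    mate_unmapped: int = 0
    low_mapq: int = 0
    not_proper_pair: int = 0
    zero_tlen: int = 0
    low_baseq: int = 0
    not_covering: int = 0
    ambiguous_pairing: int = 0
    n_templates: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class ReadPairObservation:
    """One sequenced template at a hotspot.

    ``base_calls`` holds the base each covering mate reports at the hotspot
    position (:data:`DELETED` when a deletion spans it); ``ambiguous`` marks
    templates with more than two primary records.
    """

    template_name: str
    chrom: str
    leftmost_start: int
    tlen_abs: int
    base_calls: tuple[str, ...]
    ambiguous: bool = False


@dataclass(frozen=True)
class TypedFragment:
    """A fragment assigned to an allele class, with its length in bp."""

    hotspot_name: str
    allele: str  # mutant | wild | unresolved
    length: int


def base_at_reference_position(read: pysam.AlignedSegment, pos0: int,
                               min_baseq: int = 0) -> str | None:
    """Base the read reports at 0-based reference position ``pos0``.

    Returns None when the read's alignment does not cover the position,
    :data:`DELETED` when a deletion or reference skip spans it, and the
    query base otherwise (None if the base fails ``min_baseq``).
    """
    if read.cigartuples is None:
        return None
    qpos = 0
    rpos = read.reference_start
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            if rpos <= pos0 < rpos + ln:
                qi = qpos + (pos0 - rpos)
                if min_baseq and read.query_qualities is not None \
                        and read.query_qualities[qi] < min_baseq:
                    return None
                return read.query_sequence[qi].upper()
            qpos += ln
            rpos += ln
        elif op in (1, 4):  # I, S
            qpos += ln
        elif op in (2, 3):  # D, N
            if rpos <= pos0 < rpos + ln:
                return DELETED
            rpos += ln
        # H (5) and P (6) consume neither
    return None


def extract_pairs_at_hotspot(
    alignments: str | Path | pysam.AlignmentFile,
    hotspot: Hotspot,
    min_mapq: int = 20,
    require_proper_pair: bool = True,
    min_baseq: int = 0,
    tally: FilterTally | None = None,
) -> list[ReadPairObservation]:
    """Collect one observation per template whose pair covers the hotspot.

    A template is kept when at least one of its primary mates' aligned
    spans covers the hotspot position after filtering.  The two records of
    a pair are deduplicated by template name; ``tlen_abs`` is taken from
    the record with positive TLEN.

    Raises :class:`ExtractionError` if the hotspot's chromosome is absent
    from the header.
    """
    own = not isinstance(alignments, pysam.AlignmentFile)
    af = pysam.AlignmentFile(str(alignments)) if own else alignments
    try:
        if hotspot.chrom not in af.references:
            raise ExtractionError(
                f"chromosome {hotspot.chrom!r} not in alignment header "
                f"(has {list(af.references)[:5]}...)"
            )
        tally = tally if tally is not None else FilterTally()
        pos0 = hotspot.pos0

        by_template: dict[str, list[pysam.AlignedSegment]] = defaultdict(list)
        n_primary: dict[str, int] = defaultdict(int)
        for rec in _iter_near(af, hotspot):
            tally.n_records += 1
            if rec.is_secondary or rec.is_supplementary:
                tally.secondary_or_supplementary += 1
                continue
            n_primary[rec.query_name] += 1
            if rec.is_unmapped:
                tally.unmapped += 1
                continue
            if rec.mate_is_unmapped:
                tally.mate_unmapped += 1
                continue
            if rec.mapping_quality < min_mapq:
                tally.low_mapq += 1
                continue
            if require_proper_pair and not rec.is_proper_pair:
                tally.not_proper_pair += 1
                continue
            if rec.template_length == 0:
                tally.zero_tlen += 1
                continue
            by_template[rec.query_name].append(rec)

        observations: list[ReadPairObservation] = []
        for name, recs in by_template.items():
            covering = [r for r in recs
                        if r.reference_start <= pos0 < r.reference_end]
            if not covering:
                tally.not_covering += 1
                continue
            ambiguous = n_primary[name] > 2
            if ambiguous:
                tally.ambiguous_pairing += 1
            canonical = next((r for r in recs if r.template_length > 0), recs[0])
            calls = []
            for r in covering:
                base = base_at_reference_position(r, pos0, min_baseq=min_baseq)
                if base is None and min_baseq:
                    tally.low_baseq += 1
                if base is not None:
                    calls.append(base)
            observations.append(ReadPairObservation(
                template_name=name,
                chrom=hotspot.chrom,
                leftmost_start=min(r.reference_start for r in recs),
                tlen_abs=abs(canonical.template_length),
                base_calls=tuple(calls),
                ambiguous=ambiguous,
            ))
        tally.n_templates = len(observations)
        observations.sort(key=lambda o: o.template_name)
        return observations
    finally:
        if own:
            af.close()


def _iter_near(af: pysam.AlignmentFile, hotspot: Hotspot,
               window: int = 5000) -> Iterable[pysam.AlignedSegment]:
    """Records on the hotspot's chromosome near its position.

    Uses the index when available, otherwise streams the whole file.  The
    window bounds memory without losing pairs: any mate of a covering
    template starts within one template span of the hotspot.
    """
    if af.has_index():
        lo = max(0, hotspot.pos0 - window)
        yield from af.fetch(hotspot.chrom, lo, hotspot.pos0 + window)
        return
    for rec in af.fetch(until_eof=True):
        if rec.reference_name != hotspot.chrom:
            continue
        if rec.reference_start is None or rec.reference_start < 0:
            continue
        if abs(rec.reference_start - hotspot.pos0) <= window:
            yield rec


def type_allele(obs: ReadPairObservation, hotspot: Hotspot) -> TypedFragment:
    """Assign an allele class to one observation.

    All covering mates must agree: alt base => mutant, ref base => wild;
    any third base, a mate disagreement, a spanning deletion, no usable
    base call, or ambiguous pairing => unresolved.
    """
    if obs.ambiguous or not obs.base_calls:
        allele = "unresolved"
    elif len(set(obs.base_calls)) != 1:
        allele = "unresolved"
    else:
        base = obs.base_calls[0]
        if base == hotspot.alt_base:
            allele = "mutant"
        elif base == hotspot.ref_base:
            allele = "wild"
        else:
            allele = "unresolved"  # third base or spanning deletion
    return TypedFragment(hotspot_name=hotspot.name, allele=allele,
                         length=obs.tlen_abs)


def extract_typed_fragments(
    alignments: str | Path | pysam.AlignmentFile,
    hotspot: Hotspot,
    min_mapq: int = 20,
    require_proper_pair: bool = True,
    min_baseq: int = 0,
    tally: FilterTally | None = None,
) -> list[TypedFragment]:
    """Extraction and typing in one call; one TypedFragment per observation."""
    obs = extract_pairs_at_hotspot(
        alignments, hotspot, min_mapq=min_mapq,
        require_proper_pair=require_proper_pair, min_baseq=min_baseq,
        tally=tally,
    )
    return [type_allele(o, hotspot) for o in obs]


def write_typed_fragments_tsv(fragments: Sequence[TypedFragment],
                              path: str | Path,
                              header_lines: Sequence[str] = ()) -> None:
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("hotspot\tallele\tlength\n")
        for frag in fragments:
            fh.write(f"{frag.hotspot_name}\t{frag.allele}\t{frag.length}\n")


def read_typed_fragments_tsv(path: str | Path) -> list[TypedFragment]:
    fragments: list[TypedFragment] = []
    with Path(path).open() as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            name, allele, length = raw.rstrip("\n").split("\t")
            if name == "hotspot":
                continue
            fragments.append(TypedFragment(name, allele, int(length)))
    return fragments
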