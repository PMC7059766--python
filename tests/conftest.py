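from __future__ import annotations

from pathlib import Path

import pytest

from ctfrag.panel import Hotspot
from ctfrag.simulate import LocusSimSpec, fragments_to_sam, simulate_fragments


@pytest.fixture
def hotspot() -> Hotspot:
    # synthetic fixture coordinates, not the true genomic locus
    return Hotspot(name="EGFR-T790M", gene="EGFR", chrom="chrS",
                   pos=600, ref_base="C", alt_base="T")


@pytest.fixture
def simulate_to_sam(tmp_path: Path):
    """Run the generator and write its output as SAM; returns (sam, truth)."""

    def _run(spec: LocusSimSpec, name: str = "sim"):
        frags = simulate_fragments(spec)
        sam = tmp_path / f"{name}.sam"
        fragments_to_sam(frags, spec.hotspot, sam_path=sam,
                         read_length=spec.read_length, ref_seed=spec.seed)
        return sam, frags

    return _run


def sam_text(records: list[str], chrom: str = "chrS", length: int = 2000) -> str:
    """Minimal SAM document from raw record lines (for hand-built fixtures)."""
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{chrom}\tLN:{length}"]
    return "\n".join(lines + records) + "\n"


def sam_record(name: str, flag: int, pos1: int, cigar: str, tlen: int,
               seq: str, chrom: str = "chrS", mapq: int = 60,
               mate_pos1: int | None = None) -> str:
    mate_pos1 = mate_pos1 if mate_pos1 is not None else pos1
    qual = "I" * len(seq)
    return (f"{name}\t{flag}\t{chrom}\t{pos1}\t{mapq}\t{cigar}\t=\t"
            f"{mate_pos1}\t{tlen}\t{seq}\t{qual}")
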