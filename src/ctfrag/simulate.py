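"""Synthetic cfDNA fragment populations and ddPCR droplet occupancy.

This module is the stand-in for plasma sequencing data: it draws fragment
lengths per allele from configurable length models, places each fragment so
it spans a hotspot, and writes the result as an already-aligned paired-end
SAM (plus reference FASTA) whose TLEN field encodes the exact fragment
length.  Writing aligned SAM directly keeps the pipeline alignment-free;
a FASTQ export is provided for completeness but is not validated against
external aligners.

Length models
-------------
Circulating cell-free DNA is dominated by mono-nucleosomal fragments
peaking near 167-168 bp; tumor-derived fragments can run shorter (high
mutant allele frequency) or longer (low frequency).  Three model families
cover these regimes:

``point``
    All fragments have one exact length — used for exact round-trip checks.
``discrete_normal``
    Integer-rounded normal, truncated to [70, 500] bp by rejection.  The
    wild-type default is ``discrete_normal(mu=168, sd=10)``.
``mixture``
    Weighted mixture of other models, for bimodal mutant populations.

Droplet simulation follows the standard digital-PCR occupancy model:
template counts per droplet are independent Poisson draws per channel and
a droplet is channel-positive iff it holds at least one template of that
channel.  Default droplet volume is 1 nL.

All generators are pure functions of their spec (seed included): the same
spec always yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import pysam

from .panel import Hotspot

MIN_FRAG_LEN = 70
MAX_FRAG_LEN = 500

#: largest hotspot coordinate for which a reference contig is auto-generated
MAX_AUTO_REF_POS = 1_000_000

DEFAULT_READ_LENGTH = 151
DEFAULT_DROPLET_VOLUME_NL = 1.0

_REF_FLANK = 50  # bases kept beyond the outermost fragment end


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class LengthModel:
    """A distribution over integer fragment lengths on [70, 500] bp."""

    kind: Literal["point", "discrete_normal", "mixture"]
    length: int | None = None
    mean: float | None = None
    sd: float | None = None
    components: tuple["LengthModel", ...] = ()
    weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "point":
            if self.length is None or not (MIN_FRAG_LEN <= self.length <= MAX_FRAG_LEN):
                raise SimulationError(
                    f"point length must be in [{MIN_FRAG_LEN}, {MAX_FRAG_LEN}], got {self.length}"
                )
        elif self.kind == "discrete_normal":
            if self.mean is None or self.sd is None or self.sd < 0:
                raise SimulationError("discrete_normal requires mean and sd >= 0")
        elif self.kind == "mixture":
            if not self.components or len(self.components) != len(self.weights):
                raise SimulationError("mixture requires matching components and weights")
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise SimulationError("mixture weights must be >= 0 and sum to 1")
        else:
            raise SimulationError(f"unknown length model kind {self.kind!r}")

    @classmethod
    def point(cls, length: int) -> "LengthModel":
        return cls(kind="point", length=int(length))

    @classmethod
    def discrete_normal(cls, mean: float, sd: float) -> "LengthModel":
        return cls(kind="discrete_normal", mean=float(mean), sd=float(sd))

    @classmethod
    def mixture(cls, components: Sequence["LengthModel"],
                weights: Sequence[float]) -> "LengthModel":
        return cls(kind="mixture", components=tuple(components), weights=tuple(weights))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` integer lengths in [70, 500]."""
        if self.kind == "point":
            return np.full(n, self.length, dtype=np.int64)
        if self.kind == "discrete_normal":
            out = np.empty(n, dtype=np.int64)
            filled = 0
            while filled < n:  # rejection keeps the truncated shape unbiased
                draw = np.rint(rng.normal(self.mean, self.sd, size=n - filled)).astype(np.int64)
                keep = draw[(draw >= MIN_FRAG_LEN) & (draw <= MAX_FRAG_LEN)]
                out[filled:filled + keep.size] = keep
                filled += keep.size
            return out
        # mixture
        choice = rng.choice(len(self.components), size=n, p=np.asarray(self.weights))
        out = np.empty(n, dtype=np.int64)
        for i, comp in enumerate(self.components):
            mask = choice == i
            out[mask] = comp.sample(int(mask.sum()), rng)
        return out

    @classmethod
    def from_config(cls, cfg: dict) -> "LengthModel":
        """Build a model from a plain dict (as parsed from YAML)."""
        kind = cfg.get("kind")
        if kind == "point":
            return cls.point(cfg["length"])
        if kind == "discrete_normal":
            return cls.discrete_normal(cfg["mean"], cfg["sd"])
        if kind == "mixture":
            comps = [cls.from_config(c) for c in cfg["components"]]
            return cls.mixture(comps, cfg["weights"])
        raise SimulationError(f"unknown length model kind {kind!r}")


def default_wild_model() -> LengthModel:
    """Mono-nucleosomal wild-type default: discrete normal, 168 +/- 10 bp."""
    return LengthModel.discrete_normal(168.0, 10.0)


@dataclass(frozen=True)
class LocusSimSpec:
    """Everything needed to simulate one hotspot locus.

    ``allele_assignment='deterministic'`` fixes the mutant template count at
    ``round(true_maf * n_templates)``; ``'binomial'`` draws it per template.
    """

    hotspot: Hotspot
    true_maf: float
    n_templates: int
    wild_model: LengthModel = field(default_factory=default_wild_model)
    mutant_model: LengthModel | None = None
    read_length: int = DEFAULT_READ_LENGTH
    allele_assignment: Literal["deterministic", "binomial"] = "deterministic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_maf <= 1.0):
            raise SimulationError(f"true_maf must be in [0, 1], got {self.true_maf}")
        if self.n_templates < 1:
            raise SimulationError("n_templates must be positive")
        if self.read_length < 20:
            raise SimulationError("read_length must be >= 20")
        if self.true_maf > 0 and self.mutant_model is None:
            raise SimulationError("mutant_model required when true_maf > 0")


def simulate_fragments(spec: LocusSimSpec) -> pd.DataFrame:
    """Simulate one locus; returns a table with columns allele, length, start.

    ``start`` is the 0-based leftmost reference position of the fragment,
    drawn uniformly over all placements whose span [start, start+length)
    contains the hotspot base.  Row order is deterministic given the spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_templates
    if spec.allele_assignment == "deterministic":
        n_mut = int(round(spec.true_maf * n))
        is_mut = np.zeros(n, dtype=bool)
        if n_mut:
            is_mut[rng.choice(n, size=n_mut, replace=False)] = True
    else:
        is_mut = rng.random(n) < spec.true_maf

    lengths = np.empty(n, dtype=np.int64)
    n_mut_total = int(is_mut.sum())
    if n_mut_total:
        lengths[is_mut] = spec.mutant_model.sample(n_mut_total, rng)
    if n_mut_total < n:
        lengths[~is_mut] = spec.wild_model.sample(n - n_mut_total, rng)

    # uniform start over [pos0 - length + 1, pos0], clipped at 0
    pos0 = spec.hotspot.pos0
    lo = np.maximum(pos0 - lengths + 1, 0)
    starts = lo + rng.integers(0, pos0 - lo + 1)

    return pd.DataFrame({
        "allele": np.where(is_mut, "mutant", "wild"),
        "length": lengths,
        "start": starts,
    })


def make_reference(hotspot: Hotspot, span_end: int, seed: int = 0) -> str:
    """Fabricate a seeded random reference covering [0, span_end) with the
    hotspot's ref base placed at its position."""
    if hotspot.pos > MAX_AUTO_REF_POS:
        raise SimulationError(
            f"hotspot position {hotspot.pos} too large for an auto-generated "
            f"reference (limit {MAX_AUTO_REF_POS}); supply a FASTA"
        )
    rng = np.random.default_rng(seed)
    length = span_end + _REF_FLANK
    seq = rng.choice(np.array(list("ACGT")), size=length)
    seq[hotspot.pos0] = hotspot.ref_base
    return "".join(seq)


def write_fasta(chrom: str, sequence: str, path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


def _mate_record(name: str, hotspot: Hotspot, ref_seq: str, start: int, length: int,
                 read_length: int, is_mutant: bool, is_left: bool,
                 ref_id: int) -> pysam.AlignedSegment:
    eff = min(read_length, length)
    mstart = start if is_left else start + length - eff
    other = start + length - eff if is_left else start
    seq = list(ref_seq[mstart:mstart + eff])
    pos0 = hotspot.pos0
    nm = 0
    md = str(eff)
    if is_mutant and mstart <= pos0 < mstart + eff:
        off = pos0 - mstart
        seq[off] = hotspot.alt_base
        nm = 1
        md = f"{off}{hotspot.ref_base}{eff - off - 1}"
    rec = pysam.AlignedSegment()
    rec.query_name = name
    # proper pair, leftmost mate forward / rightmost reverse
    rec.flag = 0x1 | 0x2 | (0x20 | 0x40 if is_left else 0x10 | 0x80)
    rec.reference_id = ref_id
    rec.reference_start = mstart
    rec.mapping_quality = 60
    rec.cigartuples = [(0, eff)]
    rec.next_reference_id = ref_id
    rec.next_reference_start = other
    rec.template_length = length if is_left else -length
    rec.query_sequence = "".join(seq)
    rec.query_qualities = pysam.qualitystring_to_array("I" * eff)
    rec.set_tag("MD", md)
    rec.set_tag("NM", nm)
    return rec


def fragments_to_sam(
    fragments: pd.DataFrame,
    hotspot: Hotspot,
    sam_path: str | Path,
    reference: str | None = None,
    fasta_path: str | Path | None = None,
    read_length: int = DEFAULT_READ_LENGTH,
    ref_seed: int = 0,
) -> str:
    """Write simulated fragments as aligned paired-end SAM.

    Each fragment becomes two primary proper-pair records whose |TLEN|
    equals the fragment length (positive on the leftmost mate).  Mutant
    fragments carry the alt base at the hotspot position in every mate base
    covering it; CIGAR is all-match and MD/NM are written consistently.

    If ``reference`` is None a seeded random contig is fabricated (and
    written to ``fasta_path`` when given).  Returns the reference sequence.
    """
    span_end = int((fragments["start"] + fragments["length"]).max())
    if reference is None:
        reference = make_reference(hotspot, span_end, seed=ref_seed)
    elif span_end > len(reference):
        raise SimulationError(
            f"fragment end {span_end} outside reference of length {len(reference)}"
        )
    if fasta_path is not None:
        write_fasta(hotspot.chrom, reference, fasta_path)

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": hotspot.chrom, "LN": len(reference)}],
    }
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for i, row in enumerate(fragments.itertuples(index=False)):
            name = f"frag{i:07d}"
            is_mut = row.allele == "mutant"
            for is_left in (True, False):
                out.write(_mate_record(name, hotspot, reference, int(row.start),
                                       int(row.length), read_length, is_mut,
                                       is_left, ref_id=0))
    return reference


def fragments_to_fastq(
    fragments: pd.DataFrame,
    hotspot: Hotspot,
    reference: str,
    r1_path: str | Path,
    r2_path: str | Path,
    read_length: int = DEFAULT_READ_LENGTH,
) -> None:
    """Export simulated read pairs as FASTQ (R2 reverse-complemented)."""
    comp = str.maketrans("ACGT", "TGCA")
    with Path(r1_path).open("w") as r1, Path(r2_path).open("w") as r2:
        for i, row in enumerate(fragments.itertuples(index=False)):
            name = f"frag{i:07d}"
            is_mut = row.allele == "mutant"
            for fh, is_left in ((r1, True), (r2, False)):
                rec = _mate_record(name, hotspot, reference, int(row.start),
                                   int(row.length), read_length, is_mut, is_left, 0)
                seq = rec.query_sequence
                if not is_left:
                    seq = seq.translate(comp)[::-1]
                fh.write(f"@{name}/{1 if is_left else 2}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fragments_tsv(fragments: pd.DataFrame, path: str | Path,
                        header_lines: Sequence[str] = ()) -> None:
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fragments.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ddPCR droplet simulation


@dataclass(frozen=True)
class DropletSimSpec:
    """Poisson occupancy simulation for a droplet digital PCR reaction."""

    n_droplets: int
    lambda_mut: float
    lambda_wt: float
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_NL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise SimulationError("n_droplets must be positive")
        for lam in (self.lambda_mut, self.lambda_wt):
            if not np.isfinite(lam) or lam < 0:
                raise SimulationError(f"rates must be finite and >= 0, got {lam}")
        if self.droplet_volume <= 0:
            raise SimulationError("droplet_volume must be positive")


def simulate_droplets(spec: DropletSimSpec) -> "DropletCounts":
    """Draw per-droplet template counts and return channel-positive totals.

    Mutant and wild template counts per droplet are independent
    Poisson(lambda_mut) and Poisson(lambda_wt); a droplet is positive in a
    channel iff it holds >= 1 template of that channel.
    """
    from .ddpcr import DropletCounts  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    n_mut_pos = int((rng.poisson(spec.lambda_mut, spec.n_droplets) > 0).sum())
    n_wt_pos = int((rng.poisson(spec.lambda_wt, spec.n_droplets) > 0).sum())
    return DropletCounts(
        n_total=spec.n_droplets,
        n_mut_pos=n_mut_pos,
        n_wt_pos=n_wt_pos,
        droplet_volume=spec.droplet_volume,
    )


def synthetic_panel(n: int = 38, seed: int = 0) -> "Panel":
    """A seeded synthetic hotspot panel of ``n`` SNVs for fixtures and demos.

    The first six entries reuse the names of well-known driver hotspots
    (EGFR-T790M, EGFR-L858R, BRAF-V600E, PIK3CA-E545K, KRAS-G12C,
    KRAS-G12V); all coordinates are synthetic fixture values, not the true
    genomic loci.
    """
    from .panel import Panel

    rng = np.random.default_rng(seed)
    known = [("EGFR-T790M", "EGFR"), ("EGFR-L858R", "EGFR"), ("BRAF-V600E", "BRAF"),
             ("PIK3CA-E545K", "PIK3CA"), ("KRAS-G12C", "KRAS"), ("KRAS-G12V", "KRAS")]
    bases = "ACGT"
    hotspots = []
    for i in range(n):
        name, gene = known[i] if i < len(known) else (f"GENE{i:02d}-X{i}", f"GENE{i:02d}")
        ref = bases[rng.integers(4)]
        alt = rng.choice([b for b in bases if b != ref])
        pos = 1000 + 2000 * i + int(rng.integers(0, 500))
        hotspots.append(Hotspot(name=name, gene=gene, chrom=f"chrS{i % 4}",
                                pos=pos, ref_base=ref, alt_base=str(alt)))
    return Panel(tuple(hotspots))


def spec_to_dict(spec: LocusSimSpec) -> dict:
    """Serialize a LocusSimSpec for provenance headers."""
    d = dataclasses.asdict(spec)
    d["hotspot"] = dataclasses.asdict(spec.hotspot)
    return d
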