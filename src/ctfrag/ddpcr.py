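"""Poisson quantification of droplet digital PCR counts.

Templates partitioned into ~1 nL droplets occupy them as a Poisson
process, so the per-channel positive-droplet fraction p converts to a mean
template load per droplet by the occupancy inversion

    lambda = -ln(1 - p)

and to a concentration by dividing by the droplet volume.  The mutant
allele fraction is lambda_mut / (lambda_mut + lambda_wt) — invariant to
droplet volume.  The correction matters: at lambda = 1 only 1 - e^-1 ~ 63%
of droplets are positive, so the naive positive fraction understates the
load.

Channels are treated as independent single-plex counts; a saturated
channel (every droplet positive) has no finite estimate and is an error,
not a clamp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

DEFAULT_DROPLET_VOLUME_NL = 1.0


class DdpcrError(ValueError):
    pass


@dataclass(frozen=True)
class DropletCounts:
    """Observed droplet totals for one reaction (volume in nL)."""

    n_total: int
    n_mut_pos: int
    n_wt_pos: int
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise DdpcrError("n_total must be positive")
        for label, n in (("mutant", self.n_mut_pos), ("wild", self.n_wt_pos)):
            if not (0 <= n <= self.n_total):
                raise DdpcrError(
                    f"{label}-positive count {n} outside [0, {self.n_total}]"
                )
        if self.droplet_volume <= 0:
            raise DdpcrError("droplet_volume must be positive")


@dataclass(frozen=True)
class DdpcrEstimate:
    """Per-channel loads, concentrations (copies per nL) and mutant fraction."""

    lambda_mut: float
    lambda_wt: float
    conc_mut: float
    conc_wt: float
    maf_ddpcr: float


def poisson_lambda(n_pos: int, n_total: int) -> float:
    """Mean templates per droplet from a positive-droplet count.

    lambda = -ln(1 - n_pos/n_total); 0 when no droplet is positive.
    Raises :class:`DdpcrError` on a saturated channel (n_pos == n_total).
    """
    if n_total <= 0 or not (0 <= n_pos <= n_total):
        raise DdpcrError(f"invalid counts n_pos={n_pos}, n_total={n_total}")
    if n_pos == n_total:
        raise DdpcrError("saturated channel: every droplet positive, "
                         "lambda is unbounded")
    return -math.log1p(-n_pos / n_total)


def ddpcr_maf(counts: DropletCounts) -> DdpcrEstimate:
    """Estimate per-channel loads and the mutant allele fraction.

    maf = lambda_mut / (lambda_mut + lambda_wt).  Raises
    :class:`DdpcrError` when a channel is saturated or no template was
    detected in either channel.
    """
    lam_mut = poisson_lambda(counts.n_mut_pos, counts.n_total)
    lam_wt = poisson_lambda(counts.n_wt_pos, counts.n_total)
    if lam_mut + lam_wt == 0.0:
        raise DdpcrError("no template detected in either channel")
    return DdpcrEstimate(
        lambda_mut=lam_mut,
        lambda_wt=lam_wt,
        conc_mut=lam_mut / counts.droplet_volume,
        conc_wt=lam_wt / counts.droplet_volume,
        maf_ddpcr=lam_mut / (lam_mut + lam_wt),
    )


def read_droplet_counts_tsv(path: str | Path) -> list[tuple[str, DropletCounts]]:
    """Read (sample, n_total, n_mut_pos, n_wt_pos[, droplet_volume]) rows."""
    rows: list[tuple[str, DropletCounts]] = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if fields[0] == "sample":
                continue
            if len(fields) not in (4, 5):
                raise DdpcrError(f"{path}:{lineno}: expected 4 or 5 columns")
            vol = float(fields[4]) if len(fields) == 5 else DEFAULT_DROPLET_VOLUME_NL
            rows.append((fields[0], DropletCounts(
                n_total=int(fields[1]), n_mut_pos=int(fields[2]),
                n_wt_pos=int(fields[3]), droplet_volume=vol,
            )))
    if not rows:
        raise DdpcrError(f"{path}: no droplet count rows")
    return rows


def write_estimates_tsv(rows: Sequence[tuple[str, DdpcrEstimate | str]],
                        path: str | Path,
                        header_lines: Sequence[str] = ()) -> None:
    """Write estimates; a string in place of an estimate records a row-level
    error (e.g. saturation) without aborting the run."""
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("sample\tlambda_mut\tlambda_wt\tconc_mut\tconc_wt\tmaf_pct\terror\n")
        for sample, est in rows:
            if isinstance(est, str):
                fh.write(f"{sample}\tNA\tNA\tNA\tNA\tNA\t{est}\n")
            else:
                fh.write(
                    f"{sample}\t{est.lambda_mut:.6g}\t{est.lambda_wt:.6g}\t"
                    f"{est.conc_mut:.6g}\t{est.conc_wt:.6g}\t"
                    f"{100.0 * est.maf_ddpcr:.2f}\t\n"
                )
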