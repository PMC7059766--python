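"""Per-allele fragment-length statistics and sample-level summaries.

Turns typed fragments into the quantities a fragmentomics report needs:
per-allele length histograms with modal peak(s) and median, the NGS mutant
allele frequency (MAF), a frequency stratum, and a descriptive class
comparing the mutant length profile to the wild-type profile of the same
sample.

Conventions
-----------
* Median of an even-sized sample is the mean of the two central order
  statistics, so half-integer medians (e.g. 169.5 bp) are representable.
* Peaks are local maxima of the raw integer histogram whose count is at
  least ``peak_fraction`` (default 0.8) of the global maximum, reported in
  ascending length order — mutant populations can be bimodal, so more than
  one peak may be returned.  An optional moving-average window can smooth
  the histogram before peak calling.
* MAF = n_mut / (n_mut + n_wt); unresolved fragments are reported but
  excluded from both the MAF denominator and the profiles.
* Frequency strata are half-open below and closed at 1: below_lod
  (< 0.1%), low (0.1-1%), medium (1-10%), high (10-100%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .extract import TypedFragment

FREQ_BINS = ("below_lod", "low", "medium", "high")
DESCRIPTIONS = ("Short", "Long", "Normal", "Other", "Insufficient")

DEFAULT_PEAK_FRACTION = 0.8
DEFAULT_MIN_SUPPORT = 5
DEFAULT_DELTA_BP = 3.0


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class LengthProfile:
    """Histogram of integer fragment lengths with median and modal peaks."""

    histogram: dict[int, int]
    n: int
    median: float
    modes: tuple[int, ...]


def profile(lengths: Iterable[int],
            peak_fraction: float = DEFAULT_PEAK_FRACTION,
            smooth_window: int = 0) -> LengthProfile:
    """Build a :class:`LengthProfile` from raw fragment lengths.

    ``smooth_window`` (odd, in bins) applies a moving average to the dense
    histogram before peak calling; 0 disables smoothing.  Peaks are local
    maxima (ties included) of the (smoothed) histogram with count >=
    peak_fraction * global max, in ascending length order.
    """
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ProfileError("no fragments")
    values, counts = np.unique(arr, return_counts=True)
    histogram = {int(v): int(c) for v, c in zip(values, counts)}

    median = float(np.median(arr))

    lo, hi = int(values[0]), int(values[-1])
    dense = np.zeros(hi - lo + 1, dtype=float)
    dense[values - lo] = counts
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        dense = np.convolve(dense, kernel, mode="same")
    padded = np.concatenate(([0.0], dense, [0.0]))
    is_peak = (padded[1:-1] >= padded[:-2]) & (padded[1:-1] >= padded[2:]) & (padded[1:-1] > 0)
    threshold = peak_fraction * dense.max()
    modes = tuple(int(lo + i) for i in np.nonzero(is_peak & (dense >= threshold))[0])

    return LengthProfile(histogram=histogram, n=int(arr.size),
                         median=median, modes=modes)


def compute_maf(n_mut: int, n_wt: int) -> float:
    """Mutant allele frequency n_mut / (n_mut + n_wt), in [0, 1]."""
    if n_mut < 0 or n_wt < 0:
        raise ProfileError("counts must be non-negative")
    total = n_mut + n_wt
    if total == 0:
        raise ProfileError("no typed fragments")
    return n_mut / total


def bin_frequency(maf: float) -> str:
    """Stratify a MAF: below_lod (<0.1%), low (0.1-1%), medium (1-10%),
    high (10-100%).  Bins are half-open below and closed at 1."""
    if not (0.0 <= maf <= 1.0):
        raise ProfileError(f"maf must be in [0, 1], got {maf}")
    if maf < 0.001:
        return "below_lod"
    if maf < 0.01:
        return "low"
    if maf < 0.10:
        return "medium"
    return "high"


def classify_sample(mut_profile: LengthProfile, wt_profile: LengthProfile,
                    min_support: int = DEFAULT_MIN_SUPPORT,
                    delta: float = DEFAULT_DELTA_BP) -> str:
    """Describe the mutant length profile relative to the wild-type one.

    With d = mutant median - wild median: ``Short`` when d <= -delta,
    ``Long`` when d >= +delta; otherwise ``Other`` when the mutant profile
    has multiple modes straddling the wild median, else ``Normal``.
    Fewer than ``min_support`` mutant fragments gives ``Insufficient``.

    The rule is a reconstruction from reported medians and peaks — no
    published threshold exists; delta defaults to 3 bp.
    """
    if mut_profile.n < min_support:
        return "Insufficient"
    d = mut_profile.median - wt_profile.median
    if d <= -delta:
        return "Short"
    if d >= delta:
        return "Long"
    if len(mut_profile.modes) > 1 and (
            min(mut_profile.modes) < wt_profile.median < max(mut_profile.modes)):
        return "Other"
    return "Normal"


@dataclass(frozen=True)
class LocusSummary:
    """Per-hotspot result row: counts, MAF, profiles, stratum and class."""

    hotspot_name: str
    n_mut: int
    n_wt: int
    n_unresolved: int
    maf: float
    mut_profile: LengthProfile | None
    wt_profile: LengthProfile | None
    freq_bin: str
    description: str


def summarize_locus(fragments: Sequence[TypedFragment], hotspot_name: str,
                    min_support: int = DEFAULT_MIN_SUPPORT,
                    delta: float = DEFAULT_DELTA_BP,
                    peak_fraction: float = DEFAULT_PEAK_FRACTION,
                    smooth_window: int = 0) -> LocusSummary:
    """Aggregate one hotspot's typed fragments into a :class:`LocusSummary`."""
    mut = [f.length for f in fragments
           if f.hotspot_name == hotspot_name and f.allele == "mutant"]
    wt = [f.length for f in fragments
          if f.hotspot_name == hotspot_name and f.allele == "wild"]
    unres = sum(1 for f in fragments
                if f.hotspot_name == hotspot_name and f.allele == "unresolved")
    maf = compute_maf(len(mut), len(wt))
    mut_profile = (profile(mut, peak_fraction=peak_fraction, smooth_window=smooth_window)
                   if mut else None)
    wt_profile = (profile(wt, peak_fraction=peak_fraction, smooth_window=smooth_window)
                  if wt else None)
    if mut_profile is not None and wt_profile is not None:
        description = classify_sample(mut_profile, wt_profile,
                                      min_support=min_support, delta=delta)
    else:
        description = "Insufficient"
    return LocusSummary(
        hotspot_name=hotspot_name, n_mut=len(mut), n_wt=len(wt),
        n_unresolved=unres, maf=maf, mut_profile=mut_profile,
        wt_profile=wt_profile, freq_bin=bin_frequency(maf),
        description=description,
    )


SUMMARY_COLUMNS = (
    "mutation_type", "ngs_pct", "ddpcr_pct", "description",
    "mutation_peak", "wild_peak", "mutation_median", "wild_median",
)


def summary_row(summary: LocusSummary, ddpcr_pct: float | None = None) -> dict:
    """Flatten a LocusSummary into the 8-column report row (percent values
    to 2 decimals; dual peaks joined as '158/191')."""

    def fmt_modes(p: LengthProfile | None) -> str:
        return "/".join(str(m) for m in p.modes) if p else "NA"

    def fmt_median(p: LengthProfile | None) -> str:
        if p is None:
            return "NA"
        return f"{p.median:g}"

    return {
        "mutation_type": summary.hotspot_name,
        "ngs_pct": f"{100.0 * summary.maf:.2f}",
        "ddpcr_pct": "NA" if ddpcr_pct is None else f"{ddpcr_pct:.2f}",
        "description": summary.description,
        "mutation_peak": fmt_modes(summary.mut_profile),
        "wild_peak": fmt_modes(summary.wt_profile),
        "mutation_median": fmt_median(summary.mut_profile),
        "wild_median": fmt_median(summary.wt_profile),
    }
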