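# Methods

## Scope and data model

`ctfrag` analyzes per-allele fragment-length structure of cell-free DNA
(cfDNA) at single-base cancer hotspots. Its unit of observation is the
*template* (the original DNA fragment), not the read: a paired-end
alignment carries the template span in the TLEN field (SAM column 9), so
each sequenced fragment's length is `|TLEN|` of its proper pair. The
pipeline stages are

1. **panel** — hotspots as (name, gene, chrom, pos, ref, alt); positions
   are 1-based on the forward strand at I/O boundaries and converted to
   0-based half-open internally. Only SNVs are supported.
2. **extraction** — templates whose primary mates' aligned spans cover
   the hotspot position, deduplicated by template name, with `|TLEN|`
   taken from the positive-TLEN record.
3. **typing** — the base each covering mate reports at the hotspot,
   located by a CIGAR walk (M/=/X consume query and reference, I/S query
   only, D/N reference only). Agreement on the alt base types the
   fragment mutant; on the ref base, wild; anything else (third base,
   mate disagreement, spanning deletion, ambiguous pairing, no usable
   call) is *unresolved* — labeled, never silently dropped.
4. **statistics** — per-allele length profiles, MAF, frequency strata,
   Short/Long/Normal/Other description.
5. **size gating** — MAF recomputed inside fragment-length bands.
6. **ddPCR** — Poisson occupancy quantification of droplet counts.

Historically this kind of typing was done by re-aligning extracted pairs
with a second aligner and parsing its mismatch field; the direct
CIGAR/MD-based base lookup used here is the modern equivalent for SNV
typing and avoids any dependence on an obsolete aligner's private format.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_mapq` | 20 | minimum mapping quality per record |
| `require_proper_pair` | true | drop non-proper pairs |
| `min_baseq` | 0 (off) | minimum base quality at the hotspot |
| `peak_fraction` | 0.8 | local maxima ≥ this fraction of the global maximum are peaks |
| `smooth_window` | 0 (off) | odd moving-average window (bins) before peak calling |
| `min_support` | 5 | mutant fragments needed for a length-class call |
| `delta` | 3 bp | median difference for Short/Long |
| gates | 130–160, 160–230 bp | default size-selection bands |
| `droplet_volume` | 1 nL | converts λ to concentration |
| `read_length` | 151 bp | simulated mate length |

Filtering thresholds have no published values in this setting; 20 is the
conventional mapping-quality floor and both are config-exposed.

## Length statistics

* **Median**: for even *n*, the mean of the two central order statistics,
  so half-integer medians (169.5 bp) are representable.
* **Peaks**: all local maxima (plateau ties included) of the raw integer
  histogram whose count is ≥ `peak_fraction` × the global maximum,
  ascending. Multi-peak output is deliberate — mutant populations can be
  bimodal (e.g. 158/191 bp) — but on large noisy samples the raw rule
  reports jittery near-tied maxima; the optional moving-average window
  trades that resolution for stability. No published peak-calling rule
  exists; this reconstruction is the package's own.
* **Classification**: with d = mutant median − wild median, d ≤ −delta is
  Short, d ≥ +delta Long; otherwise Other if the mutant profile has
  multiple modes straddling the wild median, else Normal. Fewer than
  `min_support` mutant fragments yields Insufficient. The 3 bp delta is a
  design choice: it separates clearly shifted samples from median noise
  at these depths, but it is a reconstruction — reported length-class
  labels in the motivating data are not always consistent with a pure
  median rule (a sample with medians 169.5 vs 169 has been described as
  Long), so borderline calls should be read as descriptive.
* **MAF strata**: below_lod < 0.1 % ≤ low < 1 % ≤ medium < 10 % ≤ high
  ≤ 100 %. Published bin edges overlap ("0.1–1 %", "1–10 %"); bins here
  are half-open below and closed at 1 so the function is total and
  monotone.

## Size selection

Gates partition the length axis: interior gates are `[lo, hi)` and the
terminal gate `[lo, hi]`, so a fragment at a shared boundary (160 bp with
the default bands) belongs to exactly one band — in a physical gel
extraction its fate would be unknowable, so a convention is required.
Enrichment is the ratio of gated to ungated MAF. Unresolved fragments
pass gates like any others but never enter a MAF. A gate capturing no
typed fragment reports an undefined MAF, not zero. When the mutant length
distribution stochastically dominates the wild one, every upper-tail
gate's expected MAF is ≥ the ungated MAF (and conversely); the test suite
verifies this by exact enumeration on small discrete distributions.

## ddPCR model

Channels are independent single-plex Poisson counts: with positive
fraction *p*, λ = −ln(1 − *p*) templates per droplet, concentration
λ / volume, and MAF λ_mut / (λ_mut + λ_wt) (volume-invariant). The
correction matters — at λ = 1 only ≈ 63.2 % of droplets are positive. A
saturated channel (every droplet positive) is an error, not a clamp:
λ is unbounded and no workaround is attempted. Cross-channel probe
competition in duplex assays is not modeled; there is no data to
parameterize it.

## Synthetic data generator

The generator emulates deep hotspot sequencing of plasma cfDNA: 151 bp
paired-end reads, per-allele integer length models on [70, 500] bp
(point masses, truncated discrete normals via rejection sampling, and
mixtures), fragment placement uniform over starts spanning the hotspot,
and direct output of aligned SAM — two primary proper-pair records per
fragment with |TLEN| equal to the fragment length, all-match CIGAR, and
consistent MD/NM tags. The wild-type default is discrete_normal(168, 10),
the canonical mono-nucleosomal peak. Deterministic allele assignment
fixes the mutant count at `round(maf × n)`, making end-to-end recovery
exact; binomial assignment models sampling noise. Droplet simulation
draws per-droplet Poisson template counts per channel.

What it does **not** emulate: sequencing errors (an error-free read model;
no per-base error process is published for this setting), PCR/optical
duplicates and UMIs, capture bias across fragment lengths, soft-clipping
and indel alignment artifacts, quality-score structure, multi-peak
sub-nucleosomal ladders. Passing recovery tests therefore demonstrates
the bookkeeping and estimators are exact on clean input, not robustness
to real-data artifacts; the typing rules for disagreement, deletions and
third bases are exercised by hand-built fixtures instead.

Auto-generated references are seeded random contigs with the ref base
planted at the hotspot, capped at positions ≤ 1e6 (the contig is
materialized in memory); larger coordinates need a user FASTA. A FASTQ
export exists for completeness but is untested against external aligners.

## Problem sizes and numerics

Recovery tests use 10^3–10^4 templates per locus and 10^4–10^6 droplets —
sizes at which deterministic checks are exact and stochastic checks sit
comfortably inside 3–4 standard errors (the binomial/delta-method SEs are
computed in the tests). Mixture weights must sum to 1 within 1e-9.
Deterministic mutant counts round half to even via Python's `round`.
Every generator output is a pure function of its spec including the seed
(numpy PCG64); CLI outputs carry version, seed and config-hash headers.

## Known limitations

* Fragment length is |TLEN|, i.e. the outermost span of the mate pair;
  chimeric or split alignments are not reconstructed (templates with more
  than two primary records are typed unresolved).
* Indels and MNVs at the hotspot are out of scope; a deletion spanning
  the hotspot is unresolved by design.
* The Short/Long/Normal/Other rule and the peak-calling rule are
  reconstructions (see above); both are parameterized so alternative
  conventions can be explored.
* No statistical test of length-distribution differences is performed —
  outputs are descriptive, matching the intended use.
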