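# Methods

This note documents the statistical content of each metric, the defaults
and why they were chosen, what the simulators do and do not emulate, and
the numerical decisions a maintainer would want written down.

## Pair and read bookkeeping

All coordinates are 0-based half-open internally; SAM/BAM and pairs text
(both 1-based) are converted at the I/O boundary and converted back on
write. Hi-C pairs are canonicalized to upper-triangle order by
(chromosome rank, position) — rank from the supplied genome layout, or
natural name order (chr2 < chr10) without one — so positional duplicate
detection is insensitive to mate order. Secondary and supplementary
alignments are dropped on read so each sequenced fragment counts once.

Pair classification uses the precedence **unmapped > duplicate > inter >
intra**; a pair is unmapped when either end is unmapped or when the
smaller of the two mapping qualities is below `mapq_min` (default 10, a
conventional multi-mapper cutoff; the choice only moves reads between
the unmapped and usable classes and is recorded in every report).
Duplicates are positional: both ends' (chromosome, position, strand)
identical; optical duplicates and UMIs are out of scope. For barcoded
Linked Reads deduplication is per tagged read, keyed on (barcode,
chromosome, start, strand), since those libraries amplify per fragment,
not per pair.

## Accessibility

A = 1 − D − C − U. All three rates share the single denominator *total
read pairs*, which makes the identity exact and lets the four class
counts partition the dataset; this matches the additive structure of the
published tables, whose rate columns and accessibility sum to 1 within
rounding. Two ICI-style rates are therefore reported:

- `ici_rate` = inter / total pairs — the term entering A;
- `ici_conditional_rate` = inter / (inter + intra), i.e. among usable
  pairs — the quantity the 30 % QC threshold applies to (a dataset fails
  only when it is strictly above 0.30).

Both appear in the JSON report together with the denominator convention,
because published QC tables are not always explicit about which was
used. Linked Reads have no inter-chromosomal term: A = 1 − D − U.

## Association (Hi-C)

Link-separation distances |i − j| of intra-chromosomal pairs (leftmost
mapped positions; a deterministic choice in preference to 5′-end or
midpoint conventions) are binned at 100 bp. For the tail fit the raw
bins are aggregated onto 32 log-spaced bins per decade over
[10⁴, 10⁷] bp: each log bin's frequency is the mean count per raw bin it
covers (preserving the per-100-bp frequency scale) at the geometric mean
of the occupied raw-bin centers. A straight line through (log₁₀ d,
log₁₀ f) by least squares gives the exponent b = −slope and R². The
re-binning stabilizes the sparse far tail, where individual 100-bp bins
hold 0 or 1 pairs; at least 10 non-empty log bins are required, and R²
below 0.8 marks the fit as unreliable (power-law breakdown). An optional
exclusion window can mask a known artefact peak (alignment artefacts
near ~1.1 × 10⁷ bp appear in some real libraries); it is off by default.
Log bins straddling the window edges keep only part of their raw bins,
so exclusion can leave a residual tilt of order 10⁻² in b.

The fit is intentionally ordinary least squares on binned log-log
frequencies — the visual, field-standard diagnostic — not a maximum-
likelihood power-law estimator: the exponent is a comparative quality
score, not an inference target.

## Association (Linked Reads)

Molecules are reconstructed per (barcode, chromosome): reads sorted by
start, split where the gap between consecutive read intervals exceeds
`max_gap` = 50 kb (about the mean molecule length, and large relative to
within-molecule read spacing at typical densities), and filtered to
`min_reads` = 2 (a single read carries no linking evidence). Both knobs
are mandatory report metadata. Discarded (sub-threshold) molecules stay
in the bookkeeping: they count toward the barcode-collision rate (the
fraction of barcodes attached to ≥ 2 molecules) and the clustered-read
percentage (100 × reads in retained molecules / mapped non-duplicate
barcoded reads — the exact formula is embedded in the report since the
phrase "clustered reads" is used loosely in the literature). Molecule
N50 and the reads-per-molecule N50 (at ≥ 3 and ≥ 5 reads, computed per
molecule) use the same weighted-Nx rule as assembly statistics.

## Evenness

U = (Var − mean) / mean over the *non-zero* per-base depth distribution,
i.e. the index of dispersion minus one: 0 for Poisson sampling, m/k in
the Gamma(k)–Poisson limit, −1 in the degenerate single-depth case
(flagged). Zero-depth sites are excluded because unsequenced and
unmappable bases are uninformative about sampling noise; an
include-zeros variant exists for diagnostics only. The variance is the
population variance — immaterial at genomic site counts, fixed for
determinism. Coverage is per-base (difference-array pileup of mapped,
non-duplicate reads); published table values are reproduced from their
printed moments by the same formula. A printed form of this statistic
with the variance in the denominator circulates in the literature; it is
inconsistent with all published table values this package reproduces,
which follow the mean-denominator dispersion index throughout
(erratum note).

Downsampling is binomial thinning with p = target/current, seeded and
mandatory-seeded: thinning a Poisson track yields a Poisson track, so
comparisons at a common ~30× depth do not distort U.

## Capability

Nx = the length of the shortest sequence such that sequences at least
that long cumulatively reach ≥ x % of total assembly length (ties
resolved by ≥, the standard convention; "more than" phrasings differ
only at exact-tie boundaries). Before/after scaffolding comparisons
report per-level deltas and warn when the scaffolded maximum exceeds a
supplied expected chromosome length — scaffolds longer than any
chromosome indicate joins that should not exist.

## Simulators

- `simulate_hic` draws pair classes from configured unmapped/duplicate/
  ICI fractions (duplicates are re-emitted copies of already-generated
  pairs, so deduplication is exercised, not bypassed); intra separations
  come from the truncated power law d^−b on [d_min, d_max] via the
  closed-form inverse CDF (exact, no rejection); positions are uniform
  on length-weighted chromosomes.
- `simulate_linked` gives each barcode a molecule count (fixed, or drawn
  from a probability vector — (0.99, 0.01) yields a 1 % collision rate),
  exponential molecule lengths (default mean 50 kb, the scale of real
  HMW-DNA fragments), uniform placement, and Poisson read pairs at
  `reads_per_kb` = 0.8 — chosen to match the reported per-molecule read
  densities of real bead libraries (~80 reads on a ~100 kb molecule).
  Reads are proper pairs of fixed length (150 bp default; 100 bp mirrors
  2 × 100 bp chemistries) with fixed insert; no base content is
  simulated, since no metric reads bases.
- `simulate_coverage` draws Poisson(m) depths, or Gamma(k)–Poisson for
  an overdispersed track with known limiting unevenness m/k.

All generators are driven by a single integer seed and are byte-identical
across reruns; every parameter is serialized in a truth sidecar.

What the simulators deliberately do **not** emulate: restriction-site
structure, chimeric/re-ligation artefacts and the short-range insert
peak of real Hi-C; barcode sequencing errors and whitelists; GC and
mappability bias in coverage. Passing recovery tests therefore shows the
estimators are correct under each metric's own statistical model, not
that real libraries satisfy those models — detecting when they do not
(low R², high U) is precisely the tool's purpose.

## Problem sizes and tolerances in the test suite

Recovery tests run at 10⁶ Hi-C pairs (exponent within ±0.05 of b ∈
{0.8, 1.2, 1.5}), 10⁵ pairs for ICI-fraction recovery (3 binomial SEs),
10⁴ molecules for molecule-N50 (±10 %) and collision-rate (3 SEs)
recovery, and 10⁶ sites for the evenness limits (|U| < 0.02 Poisson;
U = 10 ± 0.2 at m = 30, k = 3). These sizes keep the full suite around
half a minute while leaving the sampling error well inside each
tolerance. Exhaustive Nx oracle checks cover every multiset of size ≤ 6
with values ≤ 10 at every decile.

## Known limitations

- BAM pair loading in the CLI trusts mate fields of a name-consistent
  BAM rather than re-pairing by read name; pre-processed pairs text is
  the first-class Hi-C input.
- The contact matrix is raw counts (upper triangle); normalization
  (ICE/KR) and downstream 3D-genomics analyses are out of scope.
- Barcode whitelisting/error correction is not performed; a corrupted
  barcode becomes a new (singleton) barcode and slightly deflates the
  clustered-read percentage.
- Per-chromosome ICI rates attribute an inter pair to both chromosomes
  it touches; rates across chromosomes therefore do not average to the
  global rate.
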