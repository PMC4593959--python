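# Methods

## Exact isotopic envelopes

Theoretical envelopes are computed from each ion's elemental composition by
convolving the natural isotope distributions of its atoms (C, H, N, O, S, P;
fixed IUPAC/CIAAW masses and abundances, table version `NIST-2013`, embedded
so results are bit-stable). Isotopologues are aggregated by nucleon-number
offset from the monoisotopic species (A+0, A+1, …): high-resolution
centroided spectra show one peak per nucleon offset, and fine structure
(e.g. ¹³C vs ¹⁵N at the same offset) is deliberately not resolved. Each
aggregate's centroid mass is the abundance-weighted mean of its
isotopologue masses; m/z uses the [M + zH]^z+ convention with
m(proton) = 1.007276466 Da and the electron mass neglected (≈0.5 ppm,
far inside the 15 ppm matching tolerance).

Per element the n-atom distribution is built by repeated squaring of the
single-atom distribution; probability and probability-weighted-mass arrays
are convolved with `numpy.convolve`. Intermediate states below 1e-14 of the
running maximum are dropped — this keeps protein-sized compositions at a few
dozen bins while leaving even far-tail aggregate centroids accurate to
~1e-11 Da (verified against exhaustive isotopologue enumeration, which the
test suite keeps as an independent oracle for ≤65-atom compositions).
Envelopes are normalized so the most abundant aggregate is exactly 100%,
then truncated at the abundance cutoff IPACO.

## Fragment generation

b ions are prefix residue sums, y ions suffix sums plus water, a ions
b − CO; PTM deltas (supplied as elemental-composition differences, never
average masses) are added to the residues that carry them, so a PTM is
counted exactly once across any complementary b/y pair (checked by the mass
complementarity self-test). Neutral losses NH₃, H₂O, NH₃+H₂O, 2NH₃ and 2H₂O
are generated only when the fragment contains an eligible residue: D/E/S/T
for any water-containing loss, K/N/Q/R for any ammonia-containing loss,
both classes for the combined loss. 2H₂O requires ≥1 (not ≥2) eligible
residue — the eligibility rule is per loss class, not per loss count; this
is a deliberate reading and sits behind the single eligibility predicate
should it need changing. Proteoform expansion turns k annotated PTM sites
into all 2^k on/off combinations (guarded by `k_max`, default 10).
Internal ions and c/z (ETD) series are out of scope.

## Envelope fingerprinting

An ion is fished from a spectrum only if its 100% theoretical peak finds an
experimental peak within the IPMD tolerance (ppm). Remaining theoretical
peaks link to their nearest experimental peak within tolerance (ties:
smaller |Δm/z|, then lower m/z); one experimental peak may be linked by many
ions — that is precisely how OIPs arise — but one ion links each theoretical
peak at most once. Degenerate spectra (empty, or no peak in range) yield no
match rather than an error.

IPAD is a **percentage-point difference** (experimental minus theoretical
relative abundance), not a ratio. This is fixed by the worked example the
package reproduces: 480992.3125 × 63.64 / 128926.921875 − 23.01 ≈ 214.4
matches the printed 214, whereas a ratio form would give ≈932. IPMD/IPAD
are printed as nearest integers (halves away from zero) but every tolerance
check uses the unrounded value.

**Reference peak.** Relative experimental abundances are normalized through
one reference isotopic peak per ion (IPAD ≡ 0 there). The selection rule:
the linked peak of highest theoretical abundance whose experimental peak is
*not* shared with another ion; tie → lower m/z. If every linked peak is
shared, the match is flagged `reference_degenerate`, normalized provisionally
on its most abundant linked peak, and excluded from partitioning. The rule
reproduces the reference choices of the packaged worked example (y10-1+
normalizes on its 63.64% peak because its most abundant listed peak is
itself shared; y20-2+ on 67.65%; y72-7+ on its clean 100% peak).

An ion is **matching** iff every IPACO-surviving theoretical peak is linked
and all |IPMD| and |IPAD| are within tolerance, evaluated on the current
(possibly partitioned) abundances; otherwise non-matching. Enlarging
tolerances can only convert non-matching → matching, and resolution never
changes the set of fished ions — only verdicts.

## OIP partitioning

Per shared peak, independently of every other shared peak:
DEA_i = TA_i·EA_r/TA_r, RD = (EA_OIP − ΣDEA)/ΣDEA,
final_i = DEA_i·(1 + RD). RD is carried at full precision; the two-decimal
RD in reports is display-only (46615.469396 × (1 − 0.09) does **not**
reproduce the correct 42330.617979). The pipeline is algebraically the
proportional allocation EA_OIP·DEA_i/ΣDEA, so Σfinal = EA_OIP exactly (to
floating point) and the per-group cost is Θ(n) in claimant count — the
implementation counts its scalar operations and the tests assert linearity.

Partitioning runs as a single pass (no fixed-point iteration after verdicts
change). By default a group is only partitioned when at least one claimant
sees the shared peak with a provisional IPAD ≥ 0 — a peak that everyone
observes *below* its ideal value is not an abundance-sharing situation;
`gate_nonneg=False` partitions unconditionally. If the same experimental
peak is claimed twice by one ion's different neutral-loss variants, the
variants are distinct claimants (their labels differ).

## Scoring and FDR

Identification uses matching b/y ions only, charge-collapsed on the
(series, index) backbone key; neutral-loss variants are excluded from the
counts (they corroborate interpretation, not identification). Sequence
coverage is 100% when the largest matching b_j and y_k satisfy j + k ≥ n,
else (j + k)·100/n; bond i (between residues i and i+1) is covered by b_i
or y_{n−i}; PMP is the matched fraction of theoretical b/y backbone pairs,
thresholded at ≥5% for reporting. The PTM localization score counts
charge-collapsed matching b/y ions whose residue span contains the annotated
site while excluding at least one alternative candidate site (with a single
candidate, containing the site suffices). The ranking score is the matching
b/y ion count with a bond-coverage tie-break; it is a deliberately simple
stand-in ranking statistic, not the original engine's P Score, and is
labelled `rank_score` in every report.

Decoys are reversed or seed-shuffled sequences (`DECOY_` accessions). The
FDR estimate at score cutoff c is (#decoys ≥ c)/(#targets ≥ c); the loosest
cutoff with estimate strictly below α is used (equality steps to the
stricter cutoff, so an estimate exactly at α never passes). Calibration is
exercised in simulation: under a shared null score distribution essentially
nothing is accepted at α = 1%, and with shifted target scores the empirical
FDR stays within binomial error of α over hundreds of replicates.

## Synthetic spectra

The generator emulates the study conditions the engine is meant for:
centroided HCD fragments of an intact protein. Its default scenario is the
embedded 153-residue mature horse-myoglobin chain, whose y10-1+, y20-2+ and
y72-7+ envelopes genuinely collide within ~4 ppm near m/z 1142.61 — overlaps
are engineered by *choosing* ions whose exact envelopes already collide,
never by editing m/z values, so the theoretical side stays honest. Envelope
peaks from different ions closer than the merge tolerance (default 15 ppm,
matching the search IPMD) are summed into one centroid, and those merged
peaks are recorded as true OIPs with each ion's noiseless contribution.

Noise model: multiplicative log-normal abundance noise with coefficient of
variation `noise_cv` (default 0.05, a typical peak-area CV for replicate
Orbitrap HCD measurements; the log-normal is mean-one so truth is unbiased),
uniform m/z jitter within `ppm_jitter` (default 3 ppm, well inside the
15 ppm tolerance, as expected of an externally calibrated instrument), and
uniform-random chemical-noise peaks at 0.1–2% of the base peak. Default ion
abundances (2×10⁵/4×10⁵/1.2×10⁵ for the trio) mirror the worked example's
order of magnitude and its ~1:10 dynamic range between claimant ions.

What the generator does not emulate: centroiding artifacts on truly overlapping
profiles (peaks are merged exactly, never split or skewed), detector
saturation, harmonics, co-isolated precursors, and LC elution structure.
Passing the recovery tests therefore shows the partitioning arithmetic and
matching machinery are correct under realistic abundance noise — not that
real centroiding never merges peaks the tolerance model would keep apart.

## Problem sizes and numerical conventions

The tests run the partitioning identity on 1000 random groups, recovery on
100 simulation seeds at 5% noise (median relative error bound 0.15), FDR
calibration on 250 replicates of 100 targets/decoys, and the
convolution-vs-enumeration oracle on ≤65-atom compositions — sizes chosen so
the whole suite completes in seconds while the statistical assertions keep
useful power. Reports print absolute abundances to 6 decimals, relative
abundances to 2, IPMD/IPAD as nearest integers; all comparisons happen on
unrounded values. Coordinates are 1-based; bond i lies between residues i
and i+1.

## Known limitations

- The worked-example fixture stores envelope *excerpts* (only the shared and
  reference peaks are printed), so it is fished with the 100%-peak gate
  disabled; full-envelope searches always apply the gate.
- Reference selection is greedy per ion; a spectrum where every high-
  abundance peak of every ion overlaps leaves matches degenerate and their
  groups unpartitioned rather than attempting a joint fit.
- No profile-mode centroiding, no charge deconvolution of unassigned peaks,
  no protein-level FDR, no quantification.
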