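# Methods

## ORF model and coordinate conventions

Coordinates are 1-based inclusive throughout. A coding span includes its
stop codon; the reported amino-acid length excludes it:
`aa = (end − start + 1)/3 − 1`. This convention is validated against all
79 printed (start, end, size) triples of the bundled reference table.
Genomes are treated as linear; origin-spanning ORFs are not modelled.
N bases are accepted in input sequences, but ORFs whose span contains an N
are flagged and excluded from translation-dependent features.

The caller reports, per stop codon per frame, the span from the most
upstream in-frame ATG/GTG/TTG with no intervening stop ("longest ORF per
stop"), matching the one-gene-per-row structure of published feature
tables; `longest_only=False` exposes nested starts. Reverse-strand ORFs
are reported in forward coordinates with strand "−". The caller is tested
for exact equality against an independent brute-force six-frame enumerator.

## Shine–Dalgarno detection

The 7-nt consensus AGGAGGT slides over the upstream window at spacer
distances `min_spacer..max_spacer` (spacer = nt between the motif's 3′ end
and the start codon). Score = number of position-wise matches; ties prefer
the spacer closest to 7 nt (canonical placement), then the smaller spacer;
windows truncated at the sequence start are allowed, with missing positions
counting as mismatches. All tie-breaking is deterministic.

Defaults — spacers 0–15, acceptance at ≥3 matching positions with no
consecutiveness requirement — are **calibrated on the 79 published SD
contexts** of the reference phage. Several printed contexts are weak (best
placement 3 scattered matches at spacer 0, e.g. TGTAACT directly abutting
a GTG start), which rules out stricter settings; the threshold, spacer
range and required consecutive run are all exposed as configuration. The
permissive default means the SD filter alone is a weak decoy screen;
specificity in the synthetic benchmark comes from the generator's
ground-truth repair (below). Candidates additionally need ≥45 encoded
residues and an allowed start codon.

## Protein features

Translation uses the standard bacterial code (table 11); an initial
GTG/TTG is read as methionine (start-codon semantics), the initial Met is
retained, and a single trailing stop is stripped. Internal stops and
N-containing codons raise errors.

Molecular weight sums average (not monoisotopic) residue masses plus one
water, reported in kDa to 1 decimal. The isoelectric point bisects the net
charge

    Z(pH) = Σ_b 1/(1 + 10^(pH − pKa_b)) − Σ_a 1/(1 + 10^(pKa_a − pH))

over pH ∈ [0, 14] with the Bjellqvist pKa set (N-terminus 7.5 with
residue-specific values for A/M/S/P/T/V/E, C-terminus 3.55; side chains
D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0 — the table in
`phagekit.proteins.BJELLQVIST_PKA`). Z is strictly decreasing in pH, so
the root is unique; the result is reported to 2 decimals. Tests
cross-check against an independent implementation of the same pKa model
rather than asserting exact equality, since reporting-grain rounding at
0.05 boundaries is tool-specific.

## Comparative proteomics

The identity statistic divides identical aligned residues by the length of
the **smaller unaligned protein** and rounds half-up to an integer percent.
Published hit tables sometimes print a percentage computed with a different
denominator (an aligner's own alignment length); transcribed rows therefore
carry the printed value (`HomologyHit.reported_identity`), which takes
precedence when counting shared sets, while `percent_identity()` always
implements the smallest-protein definition.

Alignment is global with affine gaps (Gotoh), BLOSUM62, gap open 10 /
extend 1 (a gap of length k costs 10 + k). Among equal-score alignments
the one with the most identical columns is selected, which makes the
identical-residue count well defined; the dynamic program tracks
(score, identities) lexicographically through a scaled integer. This is a
deterministic desk-scale stand-in for a database search: E-values and
bitscores are out of scope, and a minimum-identity floor replaces the
E-value validity screen. Best hits are unidirectional per query (tie →
lowest subject index); a reciprocal-best-hit mode is available. Shared
sets at a cutoff support both ≥ ("cut-off of 80%") and strict >
("more than 90%") semantics via the `strict` flag.

## Spot tests and host range

Dilution ladder 10⁰, 10⁻², 10⁻⁴, 10⁻⁶; the symbol is set by the deepest
dilution with lysis (−, +, ++, +++, ++++). Non-contiguous patterns (lysis
at a deep dilution but not a shallow one) are biologically inconsistent:
they are scored by the deepest lysed dilution and flagged with a warning,
never an abort. Infection counts exclude "+" by default because a single
lysis zone at 10⁰ is compatible with lysis from without; this rule is what
reproduces the reference count of 10 infected strains (4 pathogenic, 6
non-pathogenic) out of 73.

## One-step growth curves

A 4-parameter logistic `y(t) = a + c/(1 + e^{−(t−m)/s})` is fitted to
log₁₀ titer versus time (scipy least squares, data-driven initial values,
bounded parameters). The latent period is the inflection time `m` — the
middle of the exponential phase on the conventional log plot; a
first-departure estimator (first sampling time with fitted lysed fraction
above 5%) is available behind a flag. Burst size is
`(final − initial)/initial`; by default initial and final are means of the
observed titers at times where the *fitted* curve sits within 5% of the
lower/upper plateau (classified in titer space — a lysed-fraction
threshold would admit pre-rise points already inflated ~16-fold at burst
sizes near 600), with a `single`-endpoint mode (first/last point) also
exposed. Curves rising less than 0.3 log₁₀ (< 2-fold) raise a no-rise
error rather than returning a meaningless fit.

Replicate-level burst sizes feed a classical one-way ANOVA; pairwise
temperature comparisons use Tukey's HSD (Tukey–Kramer standard error at
unequal group sizes) at α = 0.01, with studentized-range critical values
verified against a direct numerical integration of the range CDF. The
degenerate all-constant input returns F = 0; zero within-group variance
with distinct means is an error.

## Synthetic data

`simulate_genome` emulates a small lytic myophage genome: by default 80
unidirectional genes, log-uniform lengths 45–650 aa, GC target 44%, start
codon probabilities 0.81/0.114/0.076 (ATG/GTG/TTG), an exact SD core
planted at a spacer of 4–9 nt upstream of every gene, and 30–120 nt
intergenic spacers. Defaults mirror the reference phage's published
genome-scale statistics. Ground truth is exact by construction: after
assembly the genome is annotated with the same default filter, and every
unplanned filter-passing candidate (decoys arise readily in alternate
frames and on the reverse strand of random coding sequence) is disrupted —
by a base edit in free intergenic sequence, or by a codon substitution
inside a planted gene (synonymous preferred, any sense codon as fallback;
planted coordinates, frames, starts, stops and SD cores are never
touched). A per-position memory forbids reverting a base to an abandoned
value, so repairs cannot cycle; the loop re-annotates until the called set
equals the planted truth. Full-scale genomes converge in a few rounds
(~1–2 s).

`diverge_proteome` plants a target identity by substituting
`round((1 − t/100)·L)` interior residues per protein with different amino
acids via whole-codon changes, so nucleotide and protein views stay
consistent and realized identities are returned exactly.

`simulate_growth_curve` models a synchronized single cycle: expected titer
`N0(1 + burst·F(t))` with F the 0-truncated Gaussian CDF of per-cell lysis
times, then Poisson plate-count noise at a dilution targeting ~200
plaques, rescaled — mimicking double-layer titration. The planted
`latent_min` is defined as the **log-scale mid-rise time** (the quantity
the estimator reads off); because the log midpoint precedes the median
lysis time by `spread·z_p` with `p = (√(1+burst) − 1)/burst`, the
lysis-time centre is shifted by that analytic offset. Three presets carry
the reference phage's temperature regimes: burst 2/64/602 and latent
55/54/102 min at 37/30/20 °C (lysis spread 6 min, 10 min at 20 °C;
initial free phage 2×10⁵ PFU/mL; triplicates; 10-min sampling to 120 min,
200 min at 20 °C). Recovery tests use 100 seeded simulations per preset.

`simulate_spot_matrix` assigns score symbols from a count profile,
shuffles strain order and pathogenicity deterministically, and emits
prefix-monotone infectivity patterns.

What the generators do **not** emulate: realistic gene content or order,
operon structure, codon usage bias, selection, adsorption kinetics,
multi-cycle growth, or strain-specific resistance mechanisms. Passing the
synthetic benchmarks therefore demonstrates the correctness of the
*computations* (calling, scoring, fitting, counting) under the stated
noise models, not predictive accuracy on real genomes or assays.

## Problem sizes and numerical choices

The test suite runs the ORF-caller/brute-force equivalence on 20 random
genomes of 3–5 kb, full-scale (80-gene) planted-recovery on two seeds,
alignment/DP-oracle equivalence on 30 random pairs of ≤30 aa, and 100
growth simulations per temperature preset — sizes chosen to exercise each
guarantee thoroughly at desk scale. Rounding of reported values is
half-up everywhere (GC to 2 dp, usage percentages to 1 dp, MW to 0.1 kDa,
pI to 2 dp, identity to integer percent). Checks against the deposited
genome sequence itself (length 53,092 bp, GC 44.14%, per-ORF MW/pI) run
only when a locally supplied FASTA is present, as the sequence is not
bundled.

## Known limitations

- The SD detector reproduces the published candidate set by calibration,
  not by re-deriving the original prediction tools' internals; it should
  not be expected to match HMM-based gene finders on real genomes.
- The identity statistic is sensitive to the alignment parameters when
  proteins differ greatly in length; the smallest-protein denominator can
  exceed 100·identical/alignment-length conventions by several points.
- Whole-genome nucleotide identity between phages and phylogenetic tree
  construction are out of scope.
- Burst-size estimates assume the curve reaches both plateaus within the
  sampling window; severely truncated curves fall back to first/last
  points and inherit their noise.
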