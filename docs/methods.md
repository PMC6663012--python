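# Methods

`circaprot` analyzes untargeted label-free proteomics time courses from
mosquito whole-body samples and audits a target genome annotation with the
peptides such an experiment detects.  Because raw LC-MS data of this kind are
rarely redistributable, the package pairs every analysis stage with a
synthetic-data generator that reproduces the study conditions with known
ground truth; all tests and the acceptance script run on those generators.

## Sampling design

Samples are pooled mosquito bodies (default pool of 10) collected every 4 h
from several staggered time courses under a 12:12 light:dark cycle (ZT0 =
lights on, ZT12 = lights off).  The default design is three courses of 44,
36 and 28 h.  Start offsets are not uniquely determined by a course-length
trio; `make_design` picks them by a deterministic grid search that balances
per-ZT-bin replicate counts, which for the default trio gives starts ZT0 /
ZT0 / ZT16 and exactly five biological replicates in each of the six 4-h
bins (30 samples).  A single course is counted inclusively (a 44-h course
sampled every 4 h has 12 samples), so a lone 24-h course yields seven
samples with its starting bin covered twice — full ZT coverage is the
guaranteed property, not equal replication.

## Abundance model

Protein *p* at zeitgeber time *t* has true intensity

    I_p(t) = B_p * (1 + A_p * cos(2*pi*(t - phi_p)/24)) * exp(eps),   eps ~ N(0, sigma^2)

with baseline `B_p` lognormal (median ~3000 intensity units, log-sd 1.5),
amplitude `A_p` uniform on [0.1, 0.6] for the rhythmic fraction (default
20%, the order reported for mosquito transcriptomes) and zero otherwise, and
phase `phi_p` drawn from the 2-h grid.  Multiplicative lognormal noise
(default sigma = 0.2, a typical label-free CV) acts on the mean.  Detection
dropout is missing-not-at-random: a measurement is lost with probability
`1/(1 + exp(slope*(ln I - ln midpoint)))`, i.e. a decreasing logistic in log
intensity, applied to the raw intensity because detection happens at
acquisition, before any normalization.  The defaults (midpoint 2.0e4, slope
1.2) were chosen so that, at study scale (1,525 proteins), the number of
proteins detectable per time-of-day falls in the 583–733 band the real
experiment reported.  The resulting breadth distribution is less bimodal
than the real one (the real data had more always-detected and more
once-detected proteins than a single lognormal baseline family produces);
conclusions that depend on the exact breadth histogram should not lean on
the simulation.  Abundances are fanned out to spectrum-level feature rows
(2–5 peptides per protein, 1–7 spectra per feature, charges 1+–5+) with
per-feature fractions drawn once and reused across samples, so a protein's
temporal profile survives the quantitation chain intact.

## Quantitation

Following standard label-free practice: only 2+/3+/4+ features are kept and
only the five most intense spectra per feature; per-sample median
normalization rescales every sample to the grand median of per-sample median
*detected* feature intensities (zeros carry no scale information — with
realistic dropout a median over all features would be 0 and normalization
would silently turn off); protein abundance is the ArcSinH-transformed sum
of the ion intensities of peptides unique to that protein.  ArcSinH rather
than a log transform because the data contain many near-zero measurements;
undetected values are stored as raw 0 with an explicit mask and are never
imputed.  Proteins with fewer than two distinct component peptides are not
quantifiable and are dropped.  Target-decoy FDR is reported as
100 * decoys / targets, rounded half-up to two decimals.

A property worth knowing: when a large fraction of total signal is rhythmic
and measurement noise is very low, the per-sample median itself oscillates,
and normalization imprints a shared time-of-day pattern on genuinely flat
proteins.  At realistic noise and at the ~2% rhythmic fraction seen in real
data the effect is negligible, but in the exact noise-free limit it makes
every flat protein formally "rhythmic".  The noise-free truth tests
therefore disable normalization (noise-free synthetic data have no
between-sample scale offsets, so skipping it is exact); `QuantConfig.normalize`
exposes the switch.

## Detectability profiling

A protein is detectable at a time-of-day if at least one replicate at that
ZT bin is above zero (a stricter minimum-replicate rule is a parameter).
The module reports per-ZT detectable counts, per-protein detection breadth
(number of ZT bins ever detected), abundance stratified by breadth (means
over detected samples only — zeros never enter a mean), and the ZT bin of
peak mean abundance (ties resolved to the earliest bin and flagged).

## Rhythm calling

Two-stage funnel. Eligibility: detected at every ZT bin with at least two
replicates per bin and, by default, quantified from more than one peptide in
each detected sample.  Stage one is a one-way fixed-effects ANOVA with ZT
bin as the factor on the transformed values (retain p < 0.1); proteins whose
groups are all identical constants have no variance to test and are excluded
with a logged reason, while zero within-group variance with nonzero
between-group variance is reported as p = 0.

Stage two is JTK_CYCLE at a fixed 24-h period.  For each lag on a 2-h grid
(2 h rather than the 4-h sampling interval, because observed peak phases
fall on odd multiples of two), the reference is the cosine at the sample
times converted to dense ranks; replicates share a rank.  The statistic S
counts concordant minus discordant pairs over reference-untied pairs;
data ties contribute zero.  Under a random permutation of the data, S =
2J − max(S) where J is a Jonckheere–Terpstra sum of Mann–Whitney counts
between reference tie groups, so its exact pmf is the convolution of
Mann–Whitney pmfs, each built from the Gaussian-binomial polynomial
recurrence.  The exact null is used up to 60 observations (the default
design needs 30); beyond that a tie-matched normal approximation with
continuity correction takes over.  The reported p is the minimum over lags
of the exact two-sided tail P(|S*| >= |S|), multiplied by the number of
distinct reference orderings counted up to reversal — a two-sided tail
cannot distinguish a reference from its mirror image, so lag L and L+12 are
one test, and counting both would double-penalize — and capped at 1.  The
phase estimate is the lag of the most concordant reference; tau = S/max(S)
at that lag.  The null assumes continuous data while tied data contribute
zero to S, which only loses score mass: the test stays conservative, and
calibration under i.i.d. nulls (P(p < alpha) <= alpha) is verified by
simulation in the test suite.  Because only ranks are used, p is invariant
under any strictly monotone transform of the abundances.

Rhythmic calls are jtk_p < 0.1 among ANOVA-passing proteins;
Benjamini–Hochberg q-values are attached across the tested set (the
standard choice where the reporting convention is unstated).

## Proteogenomics

The procedure consumes identification-level PSM tables (peptide, database,
accession, Mascot-like score, identity threshold, rank) — spectra and
search-engine scoring are upstream and out of scope.  A peptide is
*missing* when it has a rank-1, above-identity match in the reference
collection but no credible target-proteome explanation.  Filters, in order:
drop hits to excluded databases (e.g. a conspecific strain, which would
trivially "explain" every peptide); drop peptides with a confident target
match at an identical score (same spectrum explained by both databases;
exact equality by default since Mascot scores are discrete, with a
configurable tolerance); drop peptides with an I/L-equivalent target match
(isoleucine and leucine are isobaric and indistinguishable by MS — all
sequence comparisons in this module use I/L-collapsed strings).  Survivors
are collapsed into containment groups (one peptide an I/L-equivalent
substring of another, closed transitively via union–find; representative =
longest member, lexicographic on ties, flagged).  Taxon support counts each
group once per taxonomic group.

Each group's representative is then located on the genome by a six-frame
translated scan: exact and 1-mismatch full-length window matches (windows
containing a stop codon are invalid), plus split matches where a prefix and
suffix are encoded at adjacent positions offset by +-1 nt (a 1-nt
frameshift; total span = 3L +- 1).  For peptide-length queries at <= 1
mismatch this scan is equivalent to a tblastn full-query-length search while
being deterministic and dependency-free; it is verified against a naive
translate-every-window oracle in the tests.  Categories, in precedence
order: perfect hit inside an annotated transcript in a *different*
frame/strand (overlapping gene model); perfect hit outside every transcript
(uncalled gene); 1-mismatch or frameshift hit (wobbly: SNP, sequencing
error, or 1-nt indel — both sub-types are detected and reported); no hit
(suspected assembly gap).  A perfect hit in the *annotated* frame of a
transcript means the peptide should never have been flagged missing; the
classifier returns an explicit `annotated` category with a warning rather
than forcing it into an error class.  Coordinates are 0-based half-open on
the forward strand; minus-strand hits report the forward interval with
strand "−".

The synthetic side plants each defect class in a toy genome (proteome
reverse-translated onto scaffolds with transcript models; ~30% of genes on
the minus strand).  Wobbly substitutions change one nucleotide so the
encoded residue changes to a different, non-stop, non-I/L-equivalent one;
wobbly indels either insert one nucleotide at a codon boundary or encode the
prefix and suffix sharing one boundary nucleotide (span 3L−1).  Every
planted segment is re-scanned locally before acceptance so junction codons
cannot accidentally restore a perfect full-length match.  Planted peptides
are generated mutually non-contained and absent from the target proteome
under I/L collapse, so group counts equal plant counts by construction.
Simulated PSM scores are drawn once per peptide (N(60, 8) by default, vs
identity thresholds 35.6 for the collection and 19 for the target, the
averages reported for such searches), so the same evidence scores
identically in every database containing it; this is what makes the
identical-score filter meaningful.

## Numerical and design choices

* One master seed; every generator derives independent streams via
  seed-sequence spawning, so identical configuration + seed reproduces
  byte-identical outputs (asserted in the tests).
* Cosine reference values are rounded to 9 decimals before ranking so that
  analytically tied values (cos symmetric about the lag) tie exactly.
* ANOVA degeneracy uses a relative tolerance of 1e-12 on the total sum of
  squares; peak-time ties use an absolute 1e-12 band.
* Exact-null polynomials are convolved in float64 after per-factor
  normalization; at n = 30 the multinomial normalizer (~9e19) would overflow
  int64, so counts are never held as integers.
* The analysis drivers and acceptance script run at the study scale (1,525
  proteins, 30 samples, 39 reference proteomes, 241 planted defects), which
  completes in well under a minute per stage; the null-calibration
  experiment uses 10,000 proteins.

## What passing tests do and do not show

The generators produce cosine rhythms with lognormal noise, logistic
missing-not-at-random dropout, i.i.d. residue divergence between proteomes,
and annotation defects planted one per locus.  Passing tests show the
statistics are calibrated and the procedures recover planted truth under
those mechanisms.  Real data add peak-shape distortion, correlated noise
across samples, shared peptides between paralogs, non-uniform codon usage,
repeat-rich genomes, and search-engine score miscalibration — none of which
are modelled; headline counts from the real study (e.g. its 489/134
detectability split or its 31 rhythmic proteins) are emergent properties of
real biology that the simulation only approximates in regime, not in value.
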