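# Methods

## The problem

In intensively selected livestock breeds (the motivating case is Japanese
Black beef cattle, bred in a closed system around a few elite AI sires), a
recessive allele that kills embryos or juveniles can drift to an
appreciable frequency while remaining invisible: carriers are healthy, and
homozygotes never appear in the adult population. The allele's footprint
in SNP-array data is a *haplotype with missing homozygosity* — an allele
string over a marker window that segregates at frequency `q` among adult
survivors yet shows far fewer than the `N·q²` homozygotes random mating
predicts. `recscan` implements the full desk-side arm of that study
design: the genome-wide deficiency scan, the AI return-interval
(embryonic-mortality) contrast, the single-locus genotype statistics used
in follow-up cohorts, the four-criterion candidate-variant filter with
haplotype–variant LD, and the splice-boundary sequence-logo construction,
together with a synthetic-data generator that provides every input with
known ground truth.

## Deficiency scan

Phase is consumed as given (external phasing, e.g. BEAGLE, is out of
scope). For each chromosome, windows of `k_min=2` to `k_max=100` SNPs
slide one marker at a time. For every haplotype `h` in a window with
estimated frequency `q̂ = copies/2N`:

- expected homozygotes `E = N·q̂²` (random mating);
- deficit p-value = lower-tail binomial `P(X ≤ obs)` with
  `X ~ Binomial(N, q̂²)`;
- homozygosity is exact string identity over the window; a carrier is a
  sample with ≥ 1 copy.

Significance uses two nested rules. The raw threshold is `p < 1e-4`
(`alpha`). Because the number of window tests depends strongly on marker
density and haplotype diversity, the pipeline additionally requires a
Benjamini–Hochberg `q ≤ 0.05` computed over all performed tests
(`fdr=0.05`), which is the rule that stays calibrated when panel sizes
change; in the original study design the two thresholds coincided.

**Power screen (independent filtering).** At a census of `N`, a haplotype
with frequency below `q_floor = sqrt(1 − alpha^(1/N))` (≈ 0.0436 at
`N = 4843`, `alpha = 1e-4`) cannot reach `p < alpha` under any outcome —
even zero observed homozygotes gives `p = (1−q²)^N ≥ alpha`. The scan
therefore excludes such haplotypes from the testing family by default
(`power_screen=True`). This never changes which windows clear the raw
threshold; it only stops zero-power tests from inflating the BH
denominator. `min_q` (default 0.01) remains as a hard floor below which
haplotypes are not even counted.

Windows significant under both rules are merged per chromosome by
transitive genomic overlap into risk regions; a region reports the
statistics of its most significant constituent window, its bp extent
(length = end − start), and the number of panel markers it spans. Regions
are named `<prefix>_<chrom>`, with `_1`, `_2`, … suffixes when one
chromosome carries several.

A consequence of FDR control worth knowing: when a strong signal
contributes hundreds of true discoveries, the BH step-up threshold rises
and one or two borderline null windows (chance zero-homozygote haplotypes
near the power floor) may enter as small additional regions. That is the
designed 5% false-discovery share, not a defect; on signal-free panels
the procedure returns zero discoveries in ≈ 95% of runs.

The window enumeration is exhaustive but cheap: within a start position,
the haplotype partition for size `k` refines the size-`k−1` partition
with one more marker column, and a start is abandoned as soon as its most
frequent haplotype falls below the testable floor (frequencies are
non-increasing in `k`). Two equivalent implementations exist — a
vectorized numpy path and a numba kernel used for genome-scale panels —
cross-checked against each other and against exhaustive string
enumeration in the test suite.

## Mortality from AI return intervals

A cow with no second insemination after the first (non-return) is taken
as having conceived; a second AI marks conception failure, binned by the
interval since the first AI: 18–29, 30–60, 61–90, 91–140, ≥141 days
(returns under 18 days are excluded — too early to reflect conception
failure; their handling is a package decision). Matings are classified
`risk` iff both sire and cow carry the haplotype; everything else
(including carrier × non-carrier) is `other`. For one bin the 2×2 table
(risk/other × non-return/second-AI-in-bin) is tested by chi-square
without continuity correction (df=1; Fisher's exact offered); records
returning in *other* bins are excluded from that bin's contrast, so each
bin contrasts "returned in this bin" against "never returned". Mortality
% = 100·secondAI/(non-return + secondAI), rounded to integer (half away
from zero, as everywhere a printed value is matched).

## Single-locus statistics

From a genotype triple (rr, rv, vv) with `N` genotyped animals and
unrounded risk-allele frequency `p = (rv + 2vv)/2N`:

- HWE expectations `N(1−p)², 2Np(1−p), Np²`; printed triples use
  half-away-from-zero rounding of each class;
- deficit chi-square `Σ(obs−exp)²/exp` with **df = 1 by default**: one
  parameter (the allele frequency) is estimated from two free genotype
  classes, and df=1 uniquely reproduces the published follow-up P values
  (0.002 for the local cow cohort; 0.0001 for the embryo segregation
  test). df is exposed because conventions differ;
- homozygote-absence binomial `(1−p²)^N` for the case where the expected
  homozygote class is too small for a chi-square;
- segregation test against 1:2:1 for embryos of het × het matings.

Known irreproducibilities of printed values (documented, not asserted):
the central-slaughterhouse deficit P prints 0.024 where the df=1/df=2
chi-squares give 0.0046/0.018; two expected-genotype cells (one het cell
at 75.50 printing 76, one homozygote cell at 2.47 printing 3) are not
reached by any single rounding rule; the two published mortality P values
(0.035/0.012) sit slightly above the plain 2×2 chi-square (0.033/0.011),
suggesting an uncorrected difference in record filtering or correction.

## Candidate-variant prioritization

Within a risk region ± 6 Mb flank (causal variants are known to sit
megabases outside the haplotype while in LD with it), each annotated
variant is scored on four criteria: (1) no homozygotes among genotyped
animals; (2) |variant allele frequency − haplotype frequency| ≤
`freq_tol` (default 0.05 absolute — deliberately loose, since published
causal variants can be nearly twice as common as the within-cohort
haplotype when the variant predates the haplotype); (3) annotated
deleterious — nonsense/frameshift/stop-lost/splice-donor/
splice-acceptor/inframe indels unconditionally, missense only with a
damaging prediction; *splice-region* labels deliberately do **not**
qualify, and a variant passing (1), (2), (4) but failing (3) is flagged a
*near-miss*, because a real splice-donor-adjacent causal variant was
annotated benign in the motivating study; (4) present in ≥
`min_carrier_fraction` (default 1.0) of the haplotype carriers.
Genotyped-but-missing calls reduce the per-variant `N`. A candidate is
vetoed outright if an independent healthy-adult validation cohort
contains any risk-allele homozygote (complete recessive lethality is
disproved, or penetrance is incomplete). CNV deletions enter as
pseudo-biallelic carrier-coded markers.

LD `r²`: phased mode `D²/(p_A(1−p_A)p_B(1−p_B))` from haplotype
frequencies; genotype mode squared Pearson correlation of dosages;
haplotype-versus-variant LD codes haplotype carriage (0/1/2 copies) as a
pseudo-marker. The two modes agree within 0.02 on random-mating panels of
several thousand.

## Splice-boundary logos

From a GTF + FASTA, every internal exon boundary yields a donor window
(last 6 exonic + first 6 intronic bases) and an acceptor window (last 50
intronic + 2 exonic bases), read 5′→3′ in transcript orientation
(minus-strand windows reverse-complemented); duplicate boundaries shared
by transcripts are counted once, windows running off a contig are skipped
and counted. The GT/AG rule keeps donors whose intron opens `GT` and
acceptors whose intron closes `AG`. The position-frequency matrix
excludes `N` bases per position; information content is
`IC_j = 2 + Σ_b p_bj log₂ p_bj` bits (0·log 0 = 0, no small-sample
correction — exposed as an option would be trivial but the reference
behavior is unspecified, so none is applied). `variant_splice_offset`
labels a variant by its transcript-oriented distance to the nearest
junction (`donor+5` = fifth intronic base after the exon).

## Synthetic data generator

The generator's defaults are the study conditions:

- **Census panel**: `N = 4843` survivors, 5 chromosomes × 2,000 markers
  at 80 kb spacing (a 32k-SNP-array density), per-marker alternate-allele
  frequencies uniform on (0.05, 0.95) (array QC keeps MAF > 0.05),
  markers drawn independently — **no background LD, recombination maps,
  pedigree structure or genotyping error** (explicit non-goals, keeping
  the null interpretable). Each individual receives two independent
  founder haplotypes (random mating). A planted risk haplotype occupies a
  30-marker (≈ 2.3 Mb) span at founder frequency 0.05; background
  haplotypes that would coincide with the planted string are redrawn so
  carriage flags are exact. Individuals homozygous for a lethal planted
  haplotype are rejected with probability `penetrance` (default 1.0) and
  redrawn, holding the census at `N` — the panel is a census of
  survivors, so its planted-haplotype frequency settles near
  `q/(1+q) ≈ 0.0476`, inside the 0.045–0.052 band of reported risk
  haplotypes. One `SeedSequence` seed determines everything.
- **Mating records**: finite sire/cow pools with carrier flags at
  `2q(1−q) ≈ 0.095`; per-service return-bin probabilities (0.10, 0.08,
  0.05, 0.03, 0.02 for the five bins) with `excess_early_loss = 0.07`
  added to the 30–60 d bin for carrier × carrier matings. The study-scale
  record count (≈ 786k) is emulated at 20k–100k records.
- **Embryos**: genotypes 1:2:1 from het × het; risk homozygotes removed
  before observation with the stated probability.
- **Variant tables**: the causal variant makes every risk-haplotype
  carrier heterozygous; decoys violate exactly one criterion each —
  homozygotes present, frequency ≈ `q + 0.15`, benign annotation, or
  carriage in only half the carriers — with the violated criterion
  recorded in the truth object. An option plants extra non-carrier
  heterozygotes for the variant-older-than-haplotype case; how common
  that configuration is in real data is unknown, so it is off by default.
- **Toy genome**: genes on both strands; introns open `GT`/close `AG`
  with probability `donor_consensus_strength`, consensus donors carry a
  cattle-like +3..+6 profile; non-consensus intron ends explicitly avoid
  GT/AG so the retained fraction estimates the strength directly.

What passing tests on this generator do *not* show: behavior under
background LD (real window tests are far more correlated, so the raw
`p < 1e-4` threshold and the 5% FDR coincide in real array data but not
here — the pipeline therefore applies the FDR rule explicitly), under
phasing error, genotyping error or pedigree structure, and the published
genome-wide values that depend on the restricted raw data (the specific
seven regions, exact Table-level expected/P values at unrounded
frequencies, boundary counts of a particular annotation release).

## Problem sizes

The full-scale runs (recovery and 20-seed null calibration) use
`N = 4843` × 10k markers, the package's standard demonstration scale;
unit-level recovery replicates run at 1 chromosome × 1,000–2,000 markers,
and the power/type-I Monte-Carlo checks use 4k–50k mating records with
100–400 replicates. These sizes are the package's own choices for a
reproducible desk-scale analysis.

## Numerical conventions

1-based inclusive coordinates at every file interface (VCF/GTF); marker
indices half-open internally. Region length = end − start (matches the
published region table). Rounding half away from zero wherever a printed
integer or 3-dp value is matched. Binomial CDF p-values clipped to (0,1].
Ties in `variant_splice_offset` resolve to the donor side. The deficit
test treats `q̂` as known; for common haplotypes the coupling between
`q̂` and the homozygote count makes the test mildly conservative, which
the null-calibration tests verify empirically.

## Known limitations

- No pedigree-aware expected-homozygote correction (carrier-mating
  enumeration); expected counts assume random mating, as published.
- The deficit test's p-values are discrete; near the power floor they
  jump, and FDR calibration is asymptotic in the number of tests.
- The mortality contrast ignores seasonality, parity and repeated
  services per cow beyond the finite-pool structure.
- The splice module extracts and summarizes boundaries; it does not score
  splice strength (MaxEnt-style) or model the wet-lab assays.
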