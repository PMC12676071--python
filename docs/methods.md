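# Methods

## Data model

The analysis takes four inputs: a haploid genotype matrix (pollen nuclei ×
array markers, calls A/B/missing), the diploid sporophyte genotypes of the
same individuals (to identify heterozygous, i.e. informative, markers), a
marker map with per-chromosome lengths, and sample metadata (subpopulation,
treatment). All tables are plain delimited text. Calls are integer-coded
internally (A=0, B=1, heterozygous=2, missing=−1); marker positions are
1-based bp and carried as fractions of chromosome length throughout.

## Quality control

Three filters, applied in order: per-nucleus allele call rate over all
assayed markers (< 10% removed), minimum of three nuclei per individual, and
joint missing-data fraction of the retained nuclei at the individual's
informative markers (> 50% removed). Thresholds are strict inequalities;
values exactly at a threshold are retained. The call rate is computed
against all assayed markers, not the informative subset, because QC precedes
phasing; both the informative-subset restriction and the thresholds are
arguments of `qc_filter`. QC is idempotent, and every removal is reported
with its reason.

## Haplotype phasing

At heterozygous markers the parent's two haplotypes are complementary, and
each gamete is a mosaic of the two with ~2 crossovers per chromosome, so for
any two nearby markers most gametes preserve the parental phase. Each
chromosome is phased greedily left to right: marker *m* is oriented by the
signed cis-minus-trans vote counts of the marker pairs joining it to the
last two well-oriented markers (pair lags up to 3), each vote being one
gamete with non-missing calls at both markers. Evidence that cancels exactly
falls back to the nearest-anchor vote alone. A marker whose evidence
collapses entirely — typically one with several coincident bad calls — is
left unphased as a singleton block and bridged, so it costs one masked
marker instead of a phase break; a fresh, independently anchored block
starts only when no anchor is within reach. The `link_window` parameter
restricts voting to adjacent pairs (1) or enables the anchor-bridging
scheme (2, default).

Two design points deserve emphasis:

* **Ties are never guessed.** When no evidence orients a marker, guessing
  would create phantom crossovers in half the gametes; splitting into
  independently anchored blocks localises the ambiguity. At the window
  aggregation stage, blocks spanning less than one window are masked
  (markers set to missing) so unanchored fragments cannot inject spurious
  switches.
* **Identifiability has a hard limit.** If half or more of the gametes carry
  an odd number of crossovers inside the same inter-marker interval, the two
  phase orientations of the flanking arms explain the data with identical
  total agreement — the crossovers simply move to the complementary gametes.
  No gamete-based method can resolve these (they are rare: ~0.3% of
  individual × chromosome cells at study marker density). The simulator's
  `phase_identifiable` flags them from the truth, and exact-recovery
  comparisons censor them; per-individual event counts and positions are
  invariant under the flip, so cohort-level statistics are unaffected.

Phasing accuracy, measured against simulated truth up to the arbitrary
per-chromosome A/B labelling, exceeds 99% of informative markers at 6
gametes, 1% genotyping error and 5% missing calls (computed on 50-parent
cohorts by the test suite and the acceptance script).

## Crossover calling

Haplotype-origin labels are aggregated into ten non-overlapping windows of
10% relative chromosome length by majority vote (ties and empty windows are
missing). Crossovers are label changes between consecutive informative
windows; an event is kept only if the flanking window midpoints are at most
30% of the chromosome apart (at most two intervening missing windows). The
boundary case of exactly 30% is included by default (`inclusive_gap=False`
gives the strict reading). Event positions are the mean of the two flanking
midpoints; resolution is the number of intervening missing windows.

Consequences of this resolution, quantified exactly by the simulator's
detectability oracle rather than corrected for: crossovers beyond the
outermost window midpoints are invisible; double crossovers within one
window cancel; gene conversions and other small events are far below window
size. At the default conditions (true 2.2 crossovers per chromatid) the
called mean is ≈ 1.8 per chromatid, ~83% of simulated events.

## Traits

* **CC per chromatid** — genome-wide event count of a nucleus divided by the
  number of chromosomes; per individual, the mean over its nuclei.
* **ICD** — successive inter-crossover distances within (nucleus,
  chromosome), pooled over all of an individual's nuclei and chromosomes
  before averaging (unweighted); individuals without any multi-crossover
  chromatid have a null ICD and are excluded from group statistics.
  Observable ICD is bounded below by one window (0.10) and above by 0.80.
* **ICS** — r̄ᵢₙₜᵣₐ = Σₖ 2pₖ(1−pₖ)Lₖ², with pₖ computed over informative
  windows (the unit at which origin is defined after aggregation; a
  marker-level option would weight dense regions more) and Lₖ =
  chromosome length / genome length. The statistic equals the probability
  that two uniformly drawn genome positions lie on the same chromosome and
  carry different haplotype origins; a Monte-Carlo pair-sampling check
  agrees to < 0.01. Its maximum Σₖ Lₖ²/2 is attained only at pₖ = ½.

## Group statistics

ANOVA and Tukey's HSD run over the crossed subpopulation × treatment cells
(statsmodels); estimates are differences of group means. Landscapes are
per-(chromosome, window) event frequencies (events per gamete); cM/Mb =
frequency × 100 / window Mb, so the genome-wide rate equals mean crossovers
per nucleus × 100 / genome Mb by construction. Two landscapes are compared
by Pearson correlation of window frequencies and per-window 2×2 chi-square
tests on recombinant vs non-recombinant gamete counts (without continuity
correction), Benjamini–Hochberg adjusted across all windows. Allele stacking
orders beneficial-allele indicators by decreasing frequency, averages the
trait over carriers of the first *m* alleles, and reports the Spearman
correlation between per-individual allele count and trait.

## The simulator

`synthetic_data` emulates the full data-generating process with recorded
truth. Crossovers per chromatid follow a stationary gamma renewal process
along relative chromosome length: inter-crossover gaps are Gamma(ν,
1/(λν)) and the first point is an equilibrium draw (uniform fraction of a
length-biased gap), so ν = 1 is exactly Poisson with rate λ and larger ν
yields the underdispersed, evenly spaced counts characteristic of crossover
interference. An optional rejection step enforces an obligate crossover.

Defaults are the study conditions: 7 chromosomes of 730–960 Mb (10% windows
of 73–96 Mb), 875 markers per chromosome placed uniformly, heterozygosity
0.7 (≈ 4290 informative markers per individual), 584 individuals in two
subpopulations (diversity panel : population variety ≈ 310:365) × two
treatments, 6 nuclei per individual, λ = 2.2, ν = 5, symmetric allele-flip
error 0.003 (a 99.4% technical-replicate concordance implies ~0.3% per-call
error), missingness 0.05, nucleus amplification-failure rate 0.15 (failed
nuclei are 95% missing and are removed by QC, reproducing ~77–85% nucleus
retention), and a multiplicative crossover reduction of 0.08 under nutrient
deficiency. Optional beneficial-allele effects add a per-allele increment to
λ for carriers.

What the simulator does **not** emulate: segregation distortion, selection
on gametes (survivorship bias between gametophyte and sporophyte maps),
centromere-suppressed recombination or SNP-density troughs (uniform marker
placement and a homogeneous renewal rate along the chromosome), linkage
disequilibrium between parents (haplotypes are iid random), and
array-specific artefacts (cluster-calling errors are modelled as symmetric
iid flips). Passing tests therefore demonstrate the correctness and
calibration of the pipeline under these assumptions, not robustness to every
feature of real array data.

## Numerical and design choices

* Windows are half-open except the last ([0.9, 1.0] closed); a marker
  exactly on a boundary belongs to the right window.
* Window-majority ties and marker-vote ties are treated as missing/splits,
  never guessed.
* Relabelling haplotypes A↔B leaves every downstream quantity unchanged
  (verified by test).
* The per-window chi-square uses recombinant-gamete counts rather than raw
  event counts so the 2×2 table has a clean binomial interpretation; both
  counts are carried in the landscape table.
* Problem sizes in the validation suite: exact recovery and phasing accuracy
  run at full marker density (100 and 50 individuals); the treatment-effect
  power study and the null calibration use 150 markers per chromosome
  (≈ 105 informative, ~10 per window) over 100 replicate cohorts each —
  window-level detection saturates well below full density, so this choice
  trades no statistical fidelity.
* The estimated treatment-group reduction in called CC slightly
  underestimates the simulated reduction in λ (≈ −7.6% called vs −8%
  simulated) because window-level censoring is mildly concave in λ; the
  bias is well within one experiment's sampling uncertainty and applies
  equally to both groups.

## Known limitations

* Phase-unidentifiable configurations (above) are censored, not resolved;
  with more nuclei per individual they become vanishingly rare.
* ICD is truncated below at one window length, so interference strength is
  compressed for tightly spaced double crossovers.
* The cM conversion treats each called event in a sampled chromatid as
  100/n cM; it is a gamete-frequency map, not a meiotic bivalent map.
* With fewer than ~5 informative markers per window, window majorities rest
  on one or two calls and the missing-window rate rises; the gap rule then
  discards more events.
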