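# Methods

This note documents the models, rules and numerical choices behind
`rohscan`, and what the synthetic-data studies do and do not demonstrate.

## Data model and coordinates

Genotypes are allele-B dosages (0/1/2) with −1 for missing, in an
`int8` samples × markers matrix; sample and marker registries are pandas
DataFrames. All coordinates are 1-based inclusive internally; BED gene input
(0-based half-open) is shifted on read, GFF3 is taken as-is. Markers are
re-sorted by (chromosome, position) on construction and the permutation is
applied to the call columns, so every downstream stage can assume a sorted
map. Non-autosomal and unmapped markers (chromosome 0, X, Y, MT) are dropped
at load with a logged count. Within a genotype, allele order is
meaningless (`A T` ≡ `T A`), and PLINK's `0` codes a missing allele.

## Quality control

Filters never edit genotype values; they only change membership, and each
stage logs before/after counts into a `QcReport`. The cascade order is
call rate → MAF → HWE → relatedness → (optional) LD pruning. Whether the
call-rate pass runs markers-first or samples-first is configurable
(`markers_first`, default true); the two differ when a low-call sample drags
marker call rates down.

* **Call rate** — default 0.90 for samples and markers; the ROH profile
  tightens markers to 0.95.
* **MAF** — min(p, 1−p) over non-missing calls; monomorphic markers are
  removed whenever the threshold is positive. Disabled (`None`) in the ROH
  and FST profiles: MAF pruning preferentially deletes the homozygous and
  differentiated markers those analyses are about.
* **Hardy–Weinberg** — the standard (non-mid-p) exact test: the two-sided
  p-value sums the probabilities of all heterozygote counts no likelier than
  the observed one under the conditional distribution given allele counts.
  Implemented with log-gamma weights and a 1e-10 relative tie tolerance;
  verified against exact-rational enumeration for 2N ≤ 200. A practical
  resolution limit worth knowing: with 20 diploids the smallest attainable
  p over all genotype tables is 1.34e-6, so a 1e-6 screen cannot remove
  anything below ~22 samples; typical per-breed cohorts (23–30) sit just
  above the limit.
* **Relatedness** — VanRaden method-1 GRM, `G = ZZ' / (2 Σ p q)` with
  frequency-centred dosages, computed pairwise-complete over markers
  non-missing for both samples. Pairs above the threshold (default 0.95) are
  broken greedily from the strongest pair down, dropping the lower-call-rate
  member (tie → later sample). Because allele frequencies are estimated from
  the sample itself, rows of Z sum to ≈ 0 and the off-diagonal expectation
  for unrelated animals is −mean(diag)/(n−1), not 0; it vanishes as n grows.
  For the same reason a literal duplicate pair only clears 0.95 once n is
  a few dozen; a homozygous (inbred) duplicate clears it at any n.
* **LD pruning** — PLINK-style `indep-pairwise` semantics: within a
  50-SNP window, r² (squared Pearson correlation of dosages over
  pairwise-complete samples) above 0.5 removes the lower-MAF member of the
  pair (tie → later position), iterated to a fixpoint before the window
  advances 25 SNPs. Zero-variance markers get r² = 0.

Three named profiles bundle these: `structure` (90%, MAF 0.05, HWE 1e-6,
LD 50/25/0.5), `roh` (95% marker call rate, no MAF/HWE, applied per breed)
and `fst` (no MAF). In the pipeline the ROH branch runs per breed; the FST
branch runs pooled because the comparison needs one common marker set.

## ROH calling

The window length L is computed from the data:
`L = ceil( ln(α / (n_SNPs · n_samples)) / ln(1 − mean_het) )`, α = 0.05,
floored at 20 SNPs, with mean_het the cohort mean of per-individual
heterozygous-call fractions. At chip density (≈ 60 kb spacing) and
Ho ≈ 0.26–0.35 this gives L ≈ 40–55, which is why no segment shorter than
~2.5 Mb can ever be emitted on such data.

A window is homozygous iff its heterozygote count is 0 and its missing
count ≤ 1. A SNP is in-run when ≥ 5% of the windows covering it are
homozygous (the hit-ratio default of the standard tooling; edge SNPs are
covered by fewer windows and the ratio uses the actual covering count).
Maximal flagged stretches are split at inter-SNP gaps > 1 Mb; each piece
must hold ≥ L SNPs at an average density ≤ 150 kb/SNP (run-average
semantics: length / n_SNPs). Segment length is `end − start` and length
classes are half-open `[1,2), [2,4), [4,8), [8,16), [16,∞)` Mb; a `<1` Mb
bucket exists so per-class F_ROH sums exactly to the total on dense maps.
The production scan is a vectorised cumulative-sum implementation; tests
hold it equal to a brute-force per-window enumerator on hundreds of random
instances.

F_ROH divides summed segment length by the SNP-covered genome (sum over
chromosomes of last − first SNP position on the post-QC map), so it is a
statement about the genome the chip sees, not the physical assembly.

## ROH islands

Incidence is the percentage of a breed's individuals whose segments cover a
SNP (closed interval containment). z-scores use the breed's whole track
(mean, sd with ddof = 1) and p = Φ(z); the normal approximation to a bounded,
spatially correlated quantity is a known simplification and is kept because
it is the field's convention for this scan. Members need p > 0.999 and
incidence ≥ 30% of the breed; adjacent members merge into intervals with a
1 Mb gap tolerance. If nothing clears 0.999 — the situation in a uniformly
very inbred breed, where the whole track shifts up — a fallback p ≥ 0.998
rule is applied and flagged in the output. A flat track (sd = 0) yields no
islands, with a warning. The island's peak SNP is the median-position member
among those at maximal incidence: a plateau centre, chosen so that ties at
the plateau edge cannot displace the peak into the flank.

## FST

Per-SNP Weir & Cockerham (1984) components a (among populations), b (among
individuals within) and c (within individuals) are computed from
per-population sample sizes, allele frequencies and observed heterozygote
frequencies, with populations lacking calls at a SNP dropped from that SNP's
comparison (r varies per SNP; SNPs informative in < 2 populations are
skipped, as are monomorphic SNPs with a+b+c = 0). Negative per-SNP estimates
are retained for the mean — the genome-wide mean is the ratio of sums
Σa / Σ(a+b+c) — and floored at 0 only in the Manhattan export. Empirical
p-values are Φ((θ̂ − mean)/sd) over the track; outlier calls take the
⌈0.001 n⌉ highest-θ̂ SNPs with p > 0.999, ties broken by genome order,
per comparison (multi-way and each pair are scanned from the same genotype
object).

## Synthetic cohorts

The generator emulates a conservation-genetics chip study: 18 autosomes of
100 Mb, 1,700 SNPs each (jittered ±30% around a regular 60 kb grid,
strictly increasing), ancestral MAF uniform on [0.05, 0.5], three breeds of
23/24/30 animals, 1% missingness, no genotype error by default.

* **Divergence** follows the Balding–Nichols model: per-breed frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F), so breeds i and j have expected pairwise
  Weir–Cockerham FST ≈ (F_i + F_j)/2. Defaults (0.03, 0.03, 0.16) place one
  close pair (~0.03) against a distant third (~0.095), the structure such
  three-breed studies report.
* **Autozygosity** is planted as per-individual tracts (uniform 4–16 Mb,
  non-overlapping, random placement) in which both chromosomes carry one
  haplotype sampled from the breed's frequencies — zero heterozygotes, exact
  per-individual truth. Breed targets default to (0.24, 0.16, 0.21) with a
  ±0.08 per-individual spread, mirroring the wide individual variation real
  cohorts show. Tracts below ~L SNPs would be undetectable by construction,
  which is why the planted-length floor sits at 4 Mb.
* **Islands** are a shared autozygous core: ⌈carrier_fraction · n⌉ carriers
  are homozygous for one breed-shared haplotype across the core and for
  private haplotypes over Exponential(mean 3 Mb) flanking extensions per
  side. The extensions are the point: a bare 2 Mb core holds ~34 SNPs,
  fewer than L, and could never be called as ROH; biologically, a shared IBD
  core sits inside longer individual ROH, and the incidence plateau decays
  over the flanks exactly as real island tracks do.
* **Divergent selection loci** are near-fixed frequency contrasts: the
  favoured allele at ~U[0.80, 0.98] in one breed group and ~U[0.02, 0.20] in
  the other. An unconstrained Balding–Nichols draw at high F models drift,
  which as often as not leaves both breeds near the same boundary — a locus
  planted that way is not divergent and cannot honestly be labelled truth.
  The near-fixed contrast reproduces the θ̂ ≈ 0.6–0.9 range that detected
  signatures actually occupy.

Everything is deterministic under the seed, including file bytes.

What the synthetic studies do **not** show: the generator has no LD beyond
the planted tracts, no allele-frequency spectrum realism beyond the uniform
ancestral draw, no genotyping batch structure, and islands/tracts are placed
independently of recombination or gene density. Passing recovery tests
therefore demonstrates that the estimators and rules are implemented
correctly and are calibrated under their own model assumptions — not that
real-data islands or outliers at these thresholds are true positives.

## Study sizes used in the shipped checks

The statistical acceptance tests run: ROH oracle equivalence on 200 random
instances (≤ 500 SNPs, ≤ 10 samples); F_ROH recovery at planted fractions
{0.05, 0.15, 0.25} over 20 seeds × 6 individuals on the 30.6k-SNP map
(mean |error| ≤ 0.02); island recovery and no-sharing nulls over 100 seeds
each (≥ 95/100); per-SNP FST against a rational-arithmetic oracle on 100
random count tables (1e-12) and mean-FST calibration at F ∈ {0.03, 0.10}
over 20 seeds (±0.02); outlier recovery over 100 seeds (≥ 90%); HWE against
enumeration on 500 tables with 2N ≤ 200 (1e-12); the Ho–F_ROH gradient over
50 seeds (mean r < −0.8); the 24-sample QC toy; and the ±100 kb annotation
boundary. `scripts/acceptance.py` re-runs the same studies at 5–10 seeds
each plus the full demo-cohort pipeline.

## Known limitations

* The ROH caller is sliding-window only; consecutive-runs (window-free)
  calling and heterozygosity-rich runs are out of scope.
* The island null model is the normal approximation, not permutation; on
  tracks with heavy baseline autozygosity the 0.999 quantile is exceeded by
  chance at a non-negligible rate, which is intrinsic to the thresholding
  rule rather than to this implementation.
* The relatedness screen targets duplicates/clones (coefficient > 0.95);
  it is not a pedigree-relationship classifier.
* Half-missing PED genotypes (`A 0`) are treated as fully missing.
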