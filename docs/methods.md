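# Methods

## Allele encoding

A gene's allele, for this scan, is the tuple of an accession's states at the
gene's *allele-defining* variant positions: exonic indels (inframe and
frameshift), nonsense, splice-site, start/stop gain-or-loss, and
non-conservative missense changes on the primary transcript. A missense
change is non-conservative when its two residues fall in different
physicochemical groups. The default grouping is aliphatic {A,V,L,I,M},
aromatic {F,W,Y}, polar {S,T,N,Q,C}, positive {K,R,H}, negative {D,E},
special {G,P}; it is supplied as data (a two-column TSV can replace it) so an
alternative classification can be dropped in verbatim. Under this default,
I↔V is conservative (both aliphatic) and M↔T non-conservative — the calls the
scan's motivating examples require. Heterozygous calls, when enabled, are
treated as carrying the alternate state (maximizing sensitivity; panels of
inbred lines are homozygous, the default). Each ALT allele of a multiallelic
site is an independent tuple state. A per-site exclusion list supports manual
removal of indel calls judged to be alignment artifacts (e.g. frameshifts
inside homopolymer runs). Distinct tuples are distinct alleles; the
all-reference tuple is `Ref` and the others `Alt1, Alt2, …` by descending
carrier count with ties broken by tuple lexicographic order, making catalogs
independent of input site order.

Genes enter the scan when they have at least one qualifying variant and at
least one non-reference allele carried by `min_carriers` (default 10) lines.
Inside a test, alleles below the same threshold are dropped and their
carriers omitted, so a gene's effective sample can be slightly smaller than
the stratum.

## Latitude as a flowering-time proxy

Within a (state, program) group with at least two distinct maturity scores,
latitudes are a linear rescaling of the scores onto the state span: minimum
score (earliest maturity) → northern border, maximum → southern border. RM
scores and days-to-maturity are handled identically (fewest days → north);
a group must use a single score kind. Tied scores map to the same latitude.
Degenerate groups (one scored line, zero score range) and unscored lines
receive the state centroid, flagged `centroidal latitude`. Assigned latitudes
can never escape the state span. Note the rescaling stretches a program's
lines across the whole state span regardless of how tightly they cluster, so
disparities measured on assigned latitudes are mildly inflated relative to
the underlying adaptation gradient; this is a property of the assignment
method itself and is visible in the synthetic round-trips.

## Stratification

E1/E2 genotypes are called from two diagnostic positions (configuration, not
hard-code; defaults are the Wm82.a2.v1 coordinates of the E1 T75R missense,
06:20207322, and the E2 K528\* nonsense, 10:45310798). Any alternate dosage
gives the recessive call. The scan runs inside one genotype class (default
*e1-as/E2*, the largest) to remove the dominant confounding of these loci;
the rare *E1/e2* class is reported as excluded.

## Disparity test

Two-allele genes use the pooled-variance two-sample t (the classical equal-
variance form; a Welch toggle is not provided because group variances within
a stratum band are comparable by construction), taken in absolute value for
two-sided testing — disparities occur in both directions. Multi-allele genes
use one-way ANOVA F. Significance is calibrated by randomization: latitudes
are permuted against fixed labels `n_perm = 1000` times; the critical value
is the empirical 95th percentile (linear/type-7 interpolation) and the
empirical p-value uses the add-one rule `p = (1 + #{perm ≥ obs})/(n_perm+1)`,
so p is never zero and the test is exact-in-expectation under
exchangeability. Permuting latitudes, labels or residuals is equivalent for
these statistics. Per-gene random streams derive from the master seed and a
CRC-32 of the gene id, so results are reproducible regardless of scan order.
No multiple-testing correction is applied to the significance calls (the
scan reports per-gene p < α, matching its exploratory purpose); a
Benjamini–Hochberg column is emitted alongside for users who want it.

For multi-allele genes, compact letters come from Fisher's LSD on the ANOVA
mean square error, with the insert-and-absorb procedure on means sorted
descending; groups sharing a letter never differ at α.

## Conservation windows

One representative ortholog per genus (highest percent identity, ties by
sequence id) forms the alignment input; alignment construction itself is
upstream. The variant's peptide position is mapped to its alignment column
through the reference row's non-gap count, and the window clipped to ten
columns either side, truncated at alignment ends. Per column, residue
frequencies exclude gaps and information content is `IC = log2(20) − H` in
bits (no small-sample correction — the convention of sequence logos, whose
letter heights `p·IC` the logo-matrix export reproduces). A variant column is
a conserved site when IC ≥ 2.0 bits and the modal residue frequency is
≥ 0.8; columns with gap fraction > 0.5 are never called conserved. The
thresholds formalize what is otherwise a visual judgement of a logo and are
configurable. The conserved residue is the modal one; the reference and
alternate residues are classified by matching it, which distinguishes
"reference line carries the non-conserved state" candidates from the
opposite pattern.

## Synthetic panel

The generator emulates the study conditions rather than any particular
dataset: 264 lines, eight contributing states spanning 25.8–49.4°N with the
Illinois borders exact, an *E*-class census of 187/41/31/5, and roughly half
of lines carrying breeder maturity scores.

Its structural model is hierarchical, mirroring maturity-group adaptation:
the E-genotype class is drawn first (exact counts) and places a line in a
latitude band — the analysis stratum at the configured center (40.5°N,
SD 1.5°), the *e1-as/e2* band one planted E2 effect (2.5°N) above it, the
old-*E1* bands one planted E1 effect (4.6°N) below the e1-as carrier mean,
with wider tails (SD 2.0–2.5°) so the panel reaches its full span. State of
origin is then any state whose borders cover the line's latitude, and RM is
affine in latitude plus Gaussian noise (SD 0.15 RM units). This makes the
within-stratum latitude SD ≈ 1.5–1.8°N, the regime in which sub-degree
disparities are detectable at realistic carrier counts — the regime the
method is designed for. A flat geography was considered and rejected: it
yields stratum SDs of ~5°N, under which no minor gene is detectable and the
generator would not emulate the system under study.

Minor genes get a logistic allele-frequency cline,
`P(carrier) = expit(a + b·(lat − mean))`, with the intercept solved for a
carrier fraction drawn from (0.06, 0.6) and the slope solved numerically so
the *expected* carrier/noncarrier mean-latitude gap equals the planted
disparity **within the analysis stratum**, where the scan measures it; the
fitted cline extends over the whole panel. Planted disparities default to
the 0.4–0.9°N range of minor candidate genes, plus twelve null genes.
Each gene carries 1–2 qualifying variants (non-conservative missense drawn
from cross-group residue pairs, or nonsense/splice/indel/frameshift) in
perfect within-gene linkage, and, half the time, a decoy variant
(synonymous or conservative missense) that must not survive filtering.
Genotypes are emitted homozygous (0/2) unless heterozygotes are enabled.

Synthetic ortholog alignments hold one sequence per genus (default 100,
length 80): conserved columns carry a modal residue at frequency
≥ 0.95 (deviant fraction `min(1/(1+concentration), 0.05)`), other columns
are near-uniform. Missense variant columns are planted conserved with
probability ½, the modal residue being the alternate or reference residue
with equal probability, and the reference row always shows the annotated
reference residue — reproducing both the "alternate conserved" and
"reference conserved" candidate patterns.

What the generator does *not* emulate: linkage disequilibrium between genes,
pedigree/population structure, heterozygosity, genotyping error, phylogenetic
correlation among ortholog sequences, or gapped alignments. Tests passing on
synthetic panels therefore demonstrate the correctness and calibration of the
machinery under exchangeability, not robustness to relatedness-driven
confounding in real panels — the scan deliberately has no kinship
correction, as linked-selection signals are part of what it reports.

## Numerical choices and degenerate inputs

- Cline slope and intercept are solved with Brent's method; an unreachable
  disparity saturates the slope (bracket ±8 per °N) rather than failing.
- Exact carrier counts (the E census) are realized by Bernoulli draws
  repaired to the target count by uniform promotion/demotion, preserving the
  expected gap to O(√n).
- Permutation matrices are generated row-wise with `numpy` Generator
  `permuted`; statistics are computed by blocked matrix products, so a
  1000-permutation test on 187 lines costs ~1 ms.
- Groups with fewer than two members abort a gene's test with a logged skip
  reason; all-gap alignment columns are flagged undefined and never called
  conserved; degenerate latitude programs fall back to centroids.

## Problem sizes

Default analyses and the test suite run on the generator's native scale
(264 lines, 20 genes, 1,000 permutations). Calibration checks use 500 null
genes and power estimation 100 replicates per carrier count — sizes chosen so
the Monte-Carlo error on a 5% rejection rate (±1 percentage point) is well
inside the tolerance being asserted.

## Known limitations

- The physicochemical grouping is a stated default, not a universal truth;
  borderline substitutions can flip qualification under other schemes.
- The published per-line supplementary table is not redistributable here, so
  the comparison against the printed real-data disparities requires the user
  to supply that table (`latscan.pipeline.published_scan`).
- Assigned latitudes inherit the state-span stretching described above;
  cross-state comparability rests on the assumption that breeding programs
  target their own state's span.
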