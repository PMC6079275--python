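# Methods

This note documents the models, conventions and numerical choices behind
`hspkit`, and what the synthetic fixtures do and do not establish.

## Family identification

**Evidence model.** A gene is a family candidate when one of six profile
models (Hsp20/PF00011, Hsp40/PF01556, Hsp60/PF00118, Hsp70/PF00012,
Hsp90/PF00183, Hsf/PF00447) hits its protein with full-sequence
`E < 1e-6` (strict). Multiple hits of one model on a protein collapse to
the best-E hit; a protein hit by several models keeps the best-E model,
with ties broken by higher bit score and then lexicographic model name.
The filter is idempotent by construction.

**Hsp100 reassignment.** The Hsp100/ClpB class shares enough sequence with
Hsp70 that it is recovered by the Hsp70 profile rather than a dedicated
one. Proteins assigned by the Hsp70 model are therefore reassigned to
Hsp100 when their theoretical molecular weight reaches the 100 kD class.
The default threshold is 95,000 Da (configurable): it sits clearly above
the heaviest genuine Hsp70 in the packaged reference complement (~87 kD)
and clearly below the reassigned 100.3 kD protein, so the decision is
insensitive to small mass-table differences.

**Molecular weight.** Sum of average isotopic residue masses (the Expasy
convention) plus one water (18.01524 Da). `X` contributes the mean of the
20 standard residue masses; any other letter is an error naming the
residue. The mass table is coded directly rather than derived from
free-amino-acid weights, whose subtraction convention differs in the third
decimal.

**Isoelectric point.** The pH at which the net charge — Henderson–
Hasselbalch over the charged side chains (D, E, C, Y, H, K, R) and both
termini with the Bjellqvist pK set, as implemented in Biopython's
`IsoelectricPoint` — equals zero. The root is located by bisection on
[0, 14] to `|charge| < 1e-4`. Net charge is strictly decreasing in pH and
positive at pH 0 / negative at pH 14 for every sequence, so the bracket is
guaranteed.

**Naming.** `<prefix><family>-<ordinal>` (prefix `Cs` or `Cr` for the two
*Ciona* species), ordinals assigned deterministically in input order;
a single-member family carries no ordinal (`CsHsf`, `CsHsp100`).
Deterministic ordering was chosen over any randomized numbering for
reproducibility.

**PSSM fallback scanner.** So fixtures can exercise the identical
downstream path without profile-HMM software, a position-specific scoring
model is built per family from a consensus motif: each column gives
probability 0.6 to the consensus residue, spreads 0.4 uniformly over the
rest, and is scored as natural-log odds against a uniform background.
E-values use the Karlin–Altschul form `E = K·m·n·exp(−λS)` with (K, λ)
obtained from a Gumbel fit to best-window scores on 1,000 random background
sequences of length 400 at model build time, seed-fixed. This is a real
ungapped motif search with calibrated statistics, not a profile HMM;
sensitivity to degenerate family members is accordingly lower, which is
irrelevant for planted-motif fixtures and is why the `domtblout` reader is
the intended production input.

**Gene structure.** Exon intervals (1-based, sorted, non-overlapping) give
`introns = exons − 1` for a transcribed model; overlapping exons are a
model error.

## HSE scanner

**Grammar.** An HSE is a maximal run of contiguous 5-bp units on one of the
five phase lattices, each unit carrying an exact `GAA` or `TTC` core at
positions 2–4, with strict alternation between adjacent units. The minimum
reported size is 3 units — the printed minimal consensus
`nnGAAnnTTCnnGAAnn` — and is configurable. `N` never matches a core
position; flanking (`n`) positions are unconstrained. Maximal munch: a
five-unit array is one match, never also its sub-arrays; maximal runs on
different phases may overlap and are all reported.

**Degenerate modes (off by default).** `mismatch_tolerance=1` admits one
unit per array whose core is one base off the expected core (the first unit
must be exact); `allow_gap_units=g` admits up to `g` skipped 5-bp slots of
arbitrary sequence, each consuming one alternation step without counting
toward the unit total, with greedy extension. Both default to 0 because
the strict grammar is the defensible reading of the consensus; the options
exist for sensitivity analyses only.

**Coordinates and strand.** Promoters cover 1,000 bp upstream and 1,000 bp
downstream of the TSS (gene start on `+`, gene end on `−`, 1-based GFF);
minus-strand windows are reverse-complemented so head/tail labels are
defined in transcription orientation. TSS = position 0; the first upstream
base is −1; windows truncated at contig edges are flagged, never padded.
Internally 0-based half-open; BED export is genomic 0-based half-open per
the standard, the companion TSV reports TSS-relative positions.

**Strand antisymmetry.** The reverse complement of a `k`-unit array is a
`k`-unit array; the head/tail label swaps for odd `k` and is preserved for
even `k` (the complement of the last unit becomes the first, and the last
unit's core is opposite to the first's exactly when `k` is even). The
property tests assert this parity-exact bijection.

**Summaries.** Totals, head/tail split, per-gene counts and maximum array
size, per-family counts and median |distance to TSS| (distance of the
array's first base). Matches starting at or downstream of the TSS are
tallied separately from upstream ones, since the upstream set is the
canonical promoter complement and the downstream set is reported as a
supplementary signal.

## Expression profiling

**Fold change.** `FC = (mean FPKM_treat + ε)/(mean FPKM_ctrl + ε)` against
the time-matched control, `ε = 0.01` FPKM on both means. The symmetric
pseudocount keeps log2FC antisymmetric under label swap and bounds the
ratio when control expression is near zero — unavoidable when inductions
reach ~10³–10⁴-fold. `ε = 0` is allowed and raises on a zero denominator.

**Significance.** Ordinary least squares of `log2(FPKM + 1)` on a
two-group indicator over the six samples of a (treatment, control) pair —
computed as the algebraically identical pooled-variance t test, with the
OLS route kept as an independent cross-check in the tests. No
multiple-testing correction by default (α = 0.05 on raw p); a
Benjamini–Hochberg option can be applied downstream of the returned
p-values. Degenerate zero-variance pairs give p = 1 (equal means) or p = 0
(unequal), flagged in the log. Under the generator's lognormal noise at
n = 3 + 3 the test's empirical type-I error is within [0.04, 0.06]
(verified on 10,000 null genes).

**PCA.** Per time point, samples are observations and genes variables;
data are centered but not unit-scaled, so high-expression genes dominate
the axes as intended for a small chaperone gene set (a scaling flag
exists). Variance fractions are the normalized covariance eigenvalues and
sum to 1; component signs are fixed by making each component's
largest-magnitude gene loading positive.

**DEG overlap.** A gene is a DEG under a condition if significant at ≥ 1
time point under that condition; the four condition sets are decomposed
into all 2⁴ − 1 exclusive Venn regions, which partition the union.

## Temporal clustering

Model profiles are all unit-step vectors in {−c..+c}^(T−1) anchored at 0 —
27 profiles for the default c = 1 over (0, 1, 24, 48) h — in lexicographic
order. Exhaustive enumeration replaces any "m maximally distinct profiles"
selection because the exhaustive set is already small; a greedy
farthest-first selection kicks in only above a cap of 200 profiles.

Genes are assigned to the profile maximizing Pearson correlation between
the 0-prepended log2FC series and the profile's value track. A constant
series correlates 0 with every changing profile and 1 with the flat
profile (two constant vectors have identical shape), so flat genes land on
the flat profile; remaining ties break to the lowest profile id.

Enrichment uses the exhaustive null for three post-baseline time points:
all 6 permutations of the time labels (baseline fixed, identity included),
re-assigning every gene under each and averaging per-profile counts into
the expected count. Significance of an excess is the binomial tail
probability of the observed count at the permutation-derived expected
rate, Bonferroni-corrected across profiles. The raw permutation exceedance
fraction `(#perms with count ≥ observed + 1)/(N + 1)` is reported
alongside, but with N = 6 exhaustive permutations (identity always
matching) its floor is 2/7, so it cannot grade significance on its own —
hence the binomial form, which is also how STEM-style tools test profile
enrichment. Everything is deterministic in exhaustive mode.

## Synthetic data

The generators encode the study design the pipeline targets: five groups
(control, 5 °C, 25 °C, 20 ‰, 40 ‰ against a 15 °C / 30 ‰ control) × three
exposure durations (1, 24, 48 h) × three biological replicates.

* **Proteome** — planted family sizes 3/6/10/9/3/1 for
  Hsp20/40/60/70/90/Hsf, the ninth Hsp70-motif member pinned at 879
  residues so its ~104 kD weight exercises the Hsp100 reassignment
  (total complement 32), plus 150 random decoys of 80–600 residues.
  The real search space (a ~20,000-protein proteome) is represented at
  this reduced decoy count as the package's fixture scale; each member
  carries exactly one copy of its 14–15-residue consensus, and decoys are
  resampled until motif-free. Residue composition is uniform over the 20
  standard amino acids.
* **Promoters** — 58 arrays (36 tail, 22 head; 3–5 units, maximum five)
  across 29 gene promoters by default, matching the published survey's
  scale; one contig per gene, random strand, uniform 25 %-per-base
  background. Background purity is enforced by rejection sampling: the
  window is resampled until an independent enumeration finds exactly the
  planted arrays, so a zero-plant fixture scans clean and recovery can be
  asserted exactly. Planted arrays may not overlap and must fit the
  window. Gene models carry planted exon chains for structure summaries.
* **Expression** — per-replicate `FPKM = baseline · 2^(log2FC + N(0, σ))`
  with σ = 0.2 on the log2 scale and log2FC = 0 in controls and unplanted
  cells. The replicate dispersion of the original FPKM data is unreported,
  so σ is a free parameter chosen to give realistic power at n = 3, not an
  estimate. Default plants: one extreme heat-induced gene
  (log2FC = log2(4734) at 1 h high temperature, then decaying), a 12-gene
  cold cluster peaking at 24 h, a 10-gene heat cluster induced at 1 h and
  holding to 24 h, a 3-gene low-salinity down-then-up cluster, a 4-gene
  high-salinity gradual-induction cluster, and 70 null genes with
  log-uniform baselines in 5–200 FPKM.

**What passing fixtures do not show.** The generators share the
pipeline's coordinate conventions but not real-genome structure: no
repeats, GC bias, alternative TSSs or annotation error for the scanner;
no count-based mean–variance relationship, library-size effects or
outlier replicates for the expression model; motif-planted proteins are
far easier than remote homologs for the PSSM search. Recovery results on
fixtures certify implementation correctness, not performance on real
*Ciona* data, and RNA-seq-derived quantities from the original experiment
(PCA percentages, induced-gene counts, cluster counts) are not
reproducible without reprocessing the raw reads.

## Packaged reference table

`data/cs_hsp_families.tsv` is a curated summary of the 32 validated
*C. savignyi* genes (name, gene id, originating profile model, protein
length, MW in kD, pI where reported, locus, predicted subcellular
localization). The Hsp100 entry's originating model is the Hsp70 profile
and its pI is not reported in the source summary (left blank). Replaying
this table through the classifier — using only each entry's model and
molecular weight — reproduces the family sizes 3/6/10/8/3/1/1 with exactly
one reassignment, which anchors the classification logic to the published
complement without any downloads.

## Problem sizes and determinism

Test-suite and acceptance-script problem sizes (150 decoys, 29 promoters,
~100-gene expression matrices, 1,000 oracle sequences, 10,000 null genes)
are the package's chosen desk-scale defaults; the whole suite runs in well
under a minute. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configuration and seed reproduce all
generator outputs byte-for-byte, and the enrichment computation is fully
deterministic in exhaustive mode.
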