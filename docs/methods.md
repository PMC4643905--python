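# Methods

This note documents the models, defaults and numerical choices behind
`shotmapbench`, and what its synthetic benchmarks do and do not demonstrate.

## Mock communities and expected profiles

A mock community assigns each reference genome a non-negative coverage
`A_j`. The expected abundance of protein family *i* is the coverage-weighted
copy number `A_i = Σ_j C_ij·A_j`, normalized so `Σ_i R_i = 1`. Copy numbers
`C_ij` are always *counted* from the gene records of the reference set — they
cannot be supplied directly — so the simulation truth and the classification
database share one source of truth. Families with zero total abundance are
omitted from profiles rather than stored as zeros; the family universe of a
reference set is available separately where a test needs it (prevalence
filtering, enrichment universes).

Genome "relative abundance" here is coverage, not cell count, and expected
profiles deliberately do not weight by genome length: reads are allocated to
genomes proportional to `A_j` alone. For workflows that want per-base
coverage realized exactly, `simulate_reads(..., weight_by_length=True)`
allocates proportional to `A_j × genome length` instead; both conventions
are exposed because either can be meant by "abundance" in practice.

## Read simulation

Reads are single-end, with multinomial allocation across genomes, uniform
start positions, uniform strand, and a per-position error process. Given an
error, the event is a substitution with probability 4/5 and an insertion or
deletion with probability 1/10 each (a 4:1 substitution:indel ratio,
approximately matching raw Illumina base-calling error). Error models:

| model | per-position probability | default |
|---|---|---|
| `error_free` | 0 | — |
| `uniform` | constant `rate` | 1% |
| `linear` | interpolates `rate_start → rate_end` | 1% → 2% (Sanger-style) |
| `poly4` | `(a + b·i⁴)/100`, `i` 1-based | `a=3e-3`, `b=3.3e-8` |
| `homopolymer` | run-length resampling (454-style) | `N(n, 0.03+0.15n)` |

**`poly4` percent convention.** The polynomial is evaluated in percent and
divided by 100; with the default parameters the error probability at
position 100 is `(3e-3 + 3.3e-8·10⁸)/100 = 0.033`. Without the percent
convention the value would exceed 1 just past position 100, which is not a
probability; model construction rejects any parameterization whose
probability exceeds 1 within `poly4_max_len` (default 150, the longest read
the default polynomial remains valid for).

The homopolymer model resamples each run of identical bases from a normal
with mean `n` and sd `0.03 + 0.15·n`, rounded and clamped at zero. It is a
deliberately simple approximation of 454-style length miscalls and is
marked approximate; no quality-score modelling is attempted anywhere.

`shuffle_reads` permutes each read's bases uniformly, preserving length and
composition while destroying all homology — the synthetic negatives used for
empirical false-positive rates.

## ORF prediction

Six-frame translation uses the standard genetic code (table 1, identical in
its amino-acid assignments to the bacterial table for the purposes of this
package; organisms with alternative codes are out of scope). Codons
containing ambiguity codes translate to `X`; trailing partial codons are
dropped. Each frame is split on stop codons into maximal stop-free runs;
ORFs are not required to start with Met because reads are genome fragments.
The length filter is strict: peptides shorter than `min_len` (default 15 aa)
are discarded, and a 15-aa peptide is kept. External gene-finder output can
be imported in place of the naive translation; imported peptides may not
contain internal stops.

## Built-in translated search

The package bundles a self-contained translated search so benchmarks run
without external binaries: Smith–Waterman local alignment (BLOSUM62, gap
open 11, extend 1) of each query peptide against candidate reference
proteins, with raw scores converted to bits via the Karlin–Altschul
transform `S′ = (λS − ln K)/ln 2` using fixed gapped-BLOSUM62 constants
λ = 0.267, K = 0.041, and `E = db_residues · query_len · 2^(−S′)`. These
constants need only be internally consistent: thresholds in this package are
swept or calibrated against this aligner, never transplanted from another
tool.

An exact-match k-mer prefilter (default k = 5) restricts the all-vs-all scan
to targets sharing at least one 5-mer with the query. Peptide pairs without
a shared 5-mer essentially never score anywhere near the classification
thresholds in use, so the prefilter changes practical results only by
omitting deeply sub-threshold hits; `seed_k=None` recovers the exhaustive
scan, and the test suite verifies the top hits agree between the two modes.
The best local alignment per (query, target) pair is emitted; raw scores
≤ 0 are suppressed, and pipeline callers additionally set an emission floor
below their classification threshold to bound memory.

## Classification

Hits survive a threshold if `bit_score ≥ min_bits` (inclusive) or
`e_value ≤ max_evalue`; exactly one threshold kind is active at a time.
Within each unit — the read in per-read mode, the ORF in per-ORF mode — the
winner is chosen by highest bit score, then lowest E-value, then
lexicographically smallest target gene id. The second and third tie-break
levels are this package's own determinism convention; any tie-break would
do statistically, but reproducible tests require a total order.

The read-length-dependent default threshold interpolates linearly between
two calibrated anchors — 31 bits at 100 bp and 35 bits at 250 bp — and
clamps (with a warning) outside that range, where the defaults are
extrapolations and a sweep is recommended instead.

Clade exclusion removes hits whose target genome shares the read's
source-genome taxon at a chosen rank of the seven-rank lineage
(strain … phylum), emulating communities novel at that rank; exclusion sets
are nested across ranks by construction.

## Abundance estimation

Count-based abundance adds `1/L_k` per classified hit and coverage-based
abundance adds `X_k/L_k`, where `L_k` is the *winning hit's own* target gene
length and `X_k = send − sstart + 1` counts aligned target residues —
deliberately not alignment columns, so gaps in the target cannot inflate
coverage. Both `L_k` and `X_k` are in amino acids; only their ratio enters
the profile. Note that when every hit covers its full target the two metrics
coincide only if all target lengths are equal (coverage contributes 1 per
hit, count contributes `1/L_k`). Unclassified reads contribute nothing and
are reported separately as a classification rate.

AGS normalization divides unnormalized abundances by the community's average
genome size in Mb. It matters only for cross-sample comparison of
non-relative abundances; within-sample relative profiles are invariant to
it, so it must be applied before relative normalization. AGS itself is an
input (estimated upstream by tools built for that purpose), never computed
here.

## Evaluation

The accuracy metric is `D = ½ Σ_i |R_i − R̂_i|` over the union of family
ids, bounded on [0, 1]; on normalized profiles it equals the Bray–Curtis
dissimilarity exactly, and the suite asserts this identity on random
profiles. Threshold sweeps score `D` at each grid value, report the
argmin, and report the band of thresholds whose error is within 1% of the
optimum; thresholds at which nothing classifies score the maximum error 1.

Rarefaction subsamples *reads* (a drawn read keeps all its classifications)
without replacement; bootstrap resampling is with replacement — the two
sampling modes mirror the distinct purposes of depth curves and variance
estimation. The per-family bootstrap CV table models counts as Poisson
(variance equal to the mean, appropriate in the absence of biological
variation), so CV ≈ 1/√mean: ~0.10 at 100 expected reads. The closed-form
depth calculator inverts this: a gene occupying fraction `gene_len/AGS` of
the average genome needs `N = ⌈(1/cv²)·AGS/gene_len⌉` total reads for a
target CV — 300,000 reads for a 1-kb single-copy gene at 3 Mb AGS and
CV ≤ 0.10.

Alpha diversity reports family richness, Shannon entropy in **nats**
(the unit is a documented choice), and Good's coverage `1 − F₁/N` with `F₁`
the number of singleton families — the classical estimator of the fraction
of classified reads drawn from already-seen families.

## Group comparison

Families are tested one at a time: Kruskal–Wallis for categorical
covariates, Kendall's τ for continuous ones. With ≤ 10 samples, exact
p-values are used — full enumeration of distinct group-label assignments for
Kruskal–Wallis, and the exact τ null distribution when there are no ties
(full permutation enumeration up to n = 7 with ties) — because cohort sizes
as small as 4 per group make asymptotics unreliable. Constant families are
assigned p = 1 by convention.

Storey q-values use the smoother estimate of π₀ (cubic fit to
`π₀(λ) = #{p > λ}/(m(1−λ))` over λ ∈ {0.05, …, 0.95}, evaluated at the
largest λ, clipped to (0, 1]); with fewer than 20 p-values π₀ defaults to 1.
Fixing `pi0=1` reproduces Benjamini–Hochberg adjusted p-values exactly,
which the suite asserts against an independent implementation. Default
significance conventions: families at q ≤ 0.10, pathways at q ≤ 0.25.
Pathway enrichment is a one-sided (greater) Fisher exact test per pathway
on the significant/member 2×2 table, restricted to pathway members present
in the tested universe.

PERMANOVA computes Anderson's pseudo-F from squared dissimilarities with a
seeded permutation p-value `(1 + #{F_perm ≥ F_obs})/(1 + n_perm)`
(default 10,000 permutations); it is implemented in-package so the seed
contract is explicit, and its statistic is cross-checked against an
independent implementation in the tests. PCA treats samples as observations
and families as variables, drops zero-variance families, and scales to zero
mean and unit variance by default.

## Synthetic data

`make_reference_set` defaults: 10 genomes × 50 genes from a pool of 120
family ancestors of 100–200 aa, 5% within-family amino-acid divergence,
20–50 nt intergenic spacers (≈ 90% coding density, bacteria-like), random
strands, random synonymous codons, stop codon appended to each CDS.
Communities default to log-normal coverages (σ = 1), a standard rough model
of microbial abundance distributions. Sample matrices are log-normal with an
optional multiplicative group effect on a chosen number of families.

What passing benchmarks on these fixtures shows: the statistical machinery
of the pipeline — allocation, translation, thresholding, length
normalization, depth scaling — behaves as designed. What it does not show:
performance on real data, which additionally depends on database
completeness and phylogenetic representativeness, real codon usage and GC
structure, repeats and mobile elements, and biological (super-Poisson)
variance between samples. The fixtures' i.i.d. random ancestral proteins
make families more separable than deep homology in real databases; absolute
error levels here are therefore optimistic, while *orderings* (e.g. per-ORF
+ coverage beating per-read + count on multi-gene long reads, and the
reverse tie on short reads) are the meaningful outputs.

## Problem sizes

The standard end-to-end benchmark in the test suite uses the 10-genome
reference with 50,000 101-bp reads at 1% uniform error (L1 < 0.05,
rarefaction depths 10³/10⁴/5×10⁴), 300 3-kb reads for the long-read regime,
and 2,000 error-free reads plus their shuffles for the negative control —
sizes chosen to make the Monte-Carlo assertions stable while keeping a full
suite run to a few minutes on one core.

## Known limitations

- The built-in aligner's λ/K are not re-estimated per scoring system; bit
  scores are internally consistent but not interchangeable with BLAST's.
- Paired-end reads, quality-score error profiles, and per-base quality
  trimming are not modelled.
- Per-read mode assigns exactly one winning hit per read by construction;
  multi-HSP accounting within one read is not attempted.
- The homopolymer model is a coarse approximation; it applies no
  substitution errors.
- `bootstrap_family_cv` treats families independently (Poisson), ignoring
  the multinomial constraint across families; at realistic family counts
  the difference is negligible.
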