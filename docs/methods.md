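# Methods

## Data model

The universal input is a table of replicate-level quantification cycles
(Ct): one row per (sample, gene, replicate). Ct is on a log2 expression
scale — at 100 % amplification efficiency one cycle is a twofold change in
template — so all of the statistics below work in cycles or log2 units
interchangeably. Validation enforces unique (sample, gene, replicate)
triples and finite Ct in (0, 45] (a few-dozen-cycle thermal program plus
margin; values outside the window raise in strict mode and are flagged,
never silently dropped, otherwise).

Technical replicates are averaged (mean by default, median optionally)
into one value per biological replicate, and biological replicates enter
the analysis as separate samples. This is deliberate: collapsing
biological replicates into per-condition means would hide exactly the
variance the stability statistics are meant to measure. A one-step
per-condition pooling helper exists but is not the default route.

The geNorm-style transform to relative quantities is
q_i(s) = E_i^(Ct_min,i − Ct_i(s)) with E the per-cycle fold amplification
(default 2.0, i.e. perfect doubling). The per-gene anchor at the
within-subset minimum Ct makes max_s q = 1 by construction; it cancels out
of every ratio statistic, so the choice of anchor is cosmetic. Stability
scoring uses E = 2.0 throughout unless per-gene efficiencies are supplied;
efficiencies outside [1.6, 2.2] trigger a warning because they usually
indicate a unit mistake (percent vs fold).

## Stability algorithms

All four algorithms consume the genes × samples Ct matrix; lower scores
mean more stable; ties receive average (fractional) ranks everywhere, and
downstream consumers accept fractional ranks unchanged.

**Comparative ΔCt.** For each ordered gene pair, ΔCt_ij(s) = Ct_i − Ct_j
per sample; the pair's disagreement is the sample SD (n−1 denominator) of
that difference, and a gene's score is the mean SD over all partners.
Sample-wide loading shifts add the same constant to both genes of a pair
and cancel exactly.

**geNorm.** M_j is the mean over partners k of SD_s[log2(q_j/q_k)]. With
E = 2 this is algebraically identical to the ΔCt score (log2 q ratios are
Ct differences up to per-gene constants), a property the test suite
asserts to 1e−12. The reported ranking uses canonical stepwise exclusion:
recompute M within the surviving set, drop the arg-max gene, repeat until
two remain; the final pair is ordered by full-set M, then lexicographically
(the pair shares a single stepwise M, so some tie-break is required).
Both the full-set and the at-exclusion M values are exposed, since
published tables rarely say which variant they print. The pairwise
variation series V_n = SD_s[log2(NF_n/NF_{n+1})], with NF_n the per-sample
geometric mean of the top-n quantities, is computed for n = 2..k−1 along
the stepwise ordering.

**NormFinder.** Work on y = −Ct. Each sample is centred across genes
first, removing loading/template effects. Ungrouped mode fits the additive
model y_ij = α_i + β_j + ε_ij with gene-specific Var(ε_ij) = σ²_i and
reports σ̂_i. The per-gene residual mean square after joint two-way
centering is biased — every gene's noise leaks into every row through the
per-sample means — with expectation (1 − 2/k)σ²_i + S/k², S = Σσ²_l.
Summing over genes gives Ŝ = Σ ms_i / (1 − 1/k), after which each σ²_i is
solved linearly and floored at 0 before the square root (k ≥ 3 genes
required; ungrouped mode needs ≥ 4 samples). Grouped mode computes, per
gene and group, the systematic deviation d_ig = (group mean) − (gene
mean) — which sums to zero over genes within each group, a consequence of
the sample centering that the tests assert — and the within-group
residual variance σ̂²_ig by the same de-biased estimator applied within
the group; the stability value is mean_g(|d_ig| + √(σ̂²_ig/n_g)). This is
a deliberate plain moment-estimator formulation without empirical-Bayes
shrinkage of d_ig; correctness is defined by model recovery (bias < 5 %
at n = 500, agreement with a direct maximum-likelihood variance-components
fit within 10 % on small instances), not bit-equality with legacy tools.

**BestKeeper.** Descriptive statistics on raw Ct per gene: arithmetic and
geometric means, min/max, the classical "SD" (mean absolute deviation from
the arithmetic mean), the n−1 sample SD alongside, and CV% = SD/mean·100.
The default ranking key is the mean absolute deviation; CV% is available
as an alternative key because published tables are often ambiguous about
which of the two ordered their columns. Unlike the ratio-based methods,
BestKeeper is sensitive to per-sample loading shifts — the tests assert
this asymmetry explicitly. The optional BestKeeper index is the per-sample
geometric mean of Ct across genes, with per-gene Pearson correlations
against it.

## Consensus and the number of reference genes

The comprehensive ranking is the per-gene geometric mean of the rank
numbers from the contributing algorithms, re-ranked ascending. It is
order-invariant in the inputs and monotone: improving one contributing
rank can never worsen the geometric mean. The optimal-number rule scans
the V series for the smallest n with V_n below a threshold (0.15 by
convention); if none qualifies the recommendation is max(n)+1 with a
`satisfied=False` flag, i.e. even the full panel did not stabilise the
normalization factor.

A useful piece of algebra for interpreting V2: if the two top genes have
noise SDs σ1, σ2 and the third-ranked gene σ3 (all in cycles, independent
noise), then V2 ≈ √((σ1² + σ2²)/36 + σ3²/9) ≈ σ3/3 when σ3 dominates.
The V2 < 0.15 outcome of a real screen therefore presupposes a panel
whose third-best candidate is reasonably quiet (σ3 ≲ 0.45); in a panel
where every non-planted gene has σ ≥ 0.8 the rule deterministically
refuses a two-gene set (V2 ≈ 0.27), which the test suite asserts as the
correct behaviour of the rule rather than a failure of recovery.

## Quantification

Standard curves are ordinary least-squares fits of Ct on log10 dilution
(≥ 3 distinct levels; a non-negative slope is rejected as degenerate).
Efficiency E(%) = (10^(−1/slope) − 1) × 100, so slope −3.3219 ↔ 100 %;
the reliability flag covers the closed interval [90, 115] % with a 1e−9
numeric guard at the boundaries. R² is the squared Pearson correlation of
the fit.

Relative expression uses 2^−ΔΔCt. Multi-RG normalization summarises the
reference genes by their arithmetic-mean Ct per sample — equivalent, at
perfect doubling, to the geometric mean of their relative quantities.
ΔCt = Ct_target − Ct_refmean; ΔΔCt subtracts the calibrator's ΔCt; the
calibrator's fold change is exactly 1. An efficiency-corrected
(Pfaffl-style) mode is out of scope by design.

## Duplicated-gene sequence handling

Near-identical gene copies in polyploids can diverge in expression, so
primers for a duplicated candidate are placed in regions *identical*
across all copies, measuring the aggregate pool. "Identical" is taken
literally: the window search reports all maximal substrings (length ≥
min_len, default 20 nt; below 15 warns) occurring exactly in every input
sequence, found by extending shared substrings with a two-pointer scan and
verified against a brute-force common-substring oracle in the tests. This
is intentionally not an MSA-based notion — exact identity avoids
aligner-dependent results.

In-silico PCR matches the forward primer on the sense strand and the
reverse primer as its reverse complement downstream; every site pairing
yields a product with 1-based inclusive coordinates, length = end − start
+ 1, and the invariant that the product begins with the forward primer
and ends with the reverse complement of the reverse primer. Exact matching
is the default (two or more mismatches are what distinguish near-identical
copies); a Hamming-tolerant mode is opt-in. Pairwise identity uses a
global alignment with match +1, mismatch 0 and a linear gap penalty (−1
default), reported as identical columns over alignment length; the
parameters always travel with the result since "percent similarity" is
meaningless without them. Primer Tm uses the SantaLucia 1998
nearest-neighbor parameters (Biopython's `Tm_NN` defaults), recorded by
name in every report, and no attempt is made to reproduce the Tm column
of any particular primer-design program.

Because the original transcript sequences of the packaged oat panel are
not redistributable, the in-silico PCR checks run on *synthetic* templates
(`synthetic_template`, `synthetic_homeolog_templates`) that embed the
published primer pairs at the published product spacing, with random
flanks and, for homeolog sets, a shared amplicon region inside partially
diverged copies. These verify the PCR engine's site pairing, strand
conventions and length accounting — not the biological sequences.

## Synthetic Ct generator

Ct(sample s, bio rep b, gene i, tech rep t) =
μ_i + λ_{s,b} + δ_{i,group(s)} + ε_{i,s,b} + τ_t, with
λ ~ N(0, σ_load) shared by all genes of a biological sample (the loading
effect the ratio methods cancel), δ systematic group/tissue shifts,
ε ~ N(0, σ_bio,i) gene-specific biological noise, τ ~ N(0, σ_tech)
technical noise. All noise is Normal on the Ct (log2) scale, matching the
scale every algorithm works on. Ground-truth instability is
√(Var_g(δ_ig, group-size weighted) + σ²_bio,i), zero only for a gene with
no shifts and no biological noise.

Determinism: one seed yields a bit-identical table; the loading,
biological and technical streams are drawn from independent child seeds
and stored as standard-normal draws scaled by their SDs, so rescaling one
SD (e.g. σ_load × 10) reuses the same underlying draws — loading-
cancellation claims become exact assertions, not statistical ones.

Two packaged scenarios define the benchmark conditions:

* `planted_pair_scenario`: 8 genes, two planted stable (σ_bio = 0.05
  cycles) among six noisy (σ_bio ≥ 0.8), 100 independent samples,
  σ_load = 0.3, σ_tech = 0.1 — the recovery regime in which all four
  algorithms should put the planted pair on top.
* `benchmark_scenario`: 10 genes over four tissue/stage groups (shoot and
  root at two seedling stages, 3 biological × 3 technical replicates,
  12 biological samples), two planted stable genes (σ 0.05), a moderate
  mid-panel (σ 0.3–0.6 — pairwise ΔCt SDs of ~0.4–0.9 cycles, the range
  typical of published screens), and three unstable genes combining large
  σ with tissue/stage shifts, one of them an extremely highly expressed
  rRNA-like gene (baseline Ct 8). σ_load = 0.15 reflects carefully
  equalised template input; σ_tech = 0.1. The mid-panel σ was chosen from
  the V2 algebra above so that a two-gene set is genuinely sufficient
  (expected V2 ≈ 0.10), making the scenario a faithful analogue of a
  screen whose pairwise variation analysis settles at n = 2.

What the generator does *not* emulate: amplification-curve artefacts
(inputs are called Ct values), primer-dimer or multi-peak melting
behaviour, inhibition-driven efficiency differences between samples,
count-based noise at very high Ct, and correlated regulation between
candidate genes (noise is independent across genes given the loading
shift). Passing the recovery benchmarks therefore shows the algorithms
are correct under their own model assumptions — not that any particular
wet-lab panel satisfies those assumptions.

## Numerical conventions

* All logarithms base 2; scores are in cycles / log2 units.
* All sample SDs use the n−1 denominator.
* Ranks ascending by score; ties get average ranks; consensus consumes
  fractional ranks unchanged.
* Negative variance estimates are floored at 0 before square roots.
* Sequence coordinates are 1-based inclusive on the sense strand; the BED
  export converts to 0-based half-open.
* Aggregation problem sizes in the packaged benchmarks (100 runs × 8×100
  recovery panels; 200 seeds × 10×500 estimator panels) keep the full
  validation suite and the reproduction script in the seconds-to-a-minute
  range on one core.

## Known limitations

* The ΔCt/geNorm equivalence holds exactly only at uniform E = 2;
  per-gene efficiencies break it by design.
* BestKeeper's dispersion confounds biological instability with loading
  variation; this is a property of the method, reproduced faithfully.
* The grouped NormFinder stability value is a plain moment combination;
  with very small groups (n_g = 2–3) the √(σ̂²/n_g) term is noisy and the
  ungrouped mode may rank more reliably.
* The identical-window search reports the first occurrence of a window in
  each non-anchor sequence; repeated windows within one sequence are not
  enumerated per occurrence.
* Published "percent similarity" figures for gene copies are generally
  not reproducible without the original aligner settings; the identity
  function is parameter-tagged instead of chasing any specific value.
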