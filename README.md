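# refstab

Reference-gene stability evaluation for quantitative real-time PCR (qPCR).

Relative qPCR quantification stands or falls with the reference genes (RGs)
used for normalization: a "housekeeping" gene that drifts across tissues or
developmental stages silently distorts every fold change computed against
it. This package implements the standard workflow for screening candidate
RGs from replicate-level Ct data — as applied, for example, to candidate
panels in polyploid crops where many candidates are duplicated genes
(homeologs) that must be primed in regions identical across all copies:

* **Four stability algorithms** over a genes × samples Ct matrix:
  * *comparative ΔCt*: score_i = mean over partners j of
    SD_s[Ct_i(s) − Ct_j(s)];
  * *geNorm*: M_j = mean over partners k of SD_s[log2(q_j/q_k)] with
    q = E^(Ct_min − Ct), stepwise worst-gene exclusion, and the pairwise
    variation series V_n = SD_s[log2(NF_n/NF_{n+1})], NF_n the geometric
    mean of the top-n quantities;
  * *NormFinder*: model-based decomposition of y = −Ct into sample
    (loading), gene, and gene-specific noise effects, with inter-group
    deviations d_ig when group labels are supplied; stability =
    mean_g(|d_ig| + √(σ̂²_ig/n_g)) (grouped) or σ̂_i (ungrouped);
  * *BestKeeper*: dispersion of raw Ct per gene — the classical "SD" is
    the mean absolute deviation from the arithmetic mean — plus CV% and
    the per-sample geometric-mean index correlation.
* **Consensus ranking**: per-gene geometric mean of the four rank numbers
  (lower = more stable), and the V_n < 0.15 rule for how many RGs to
  combine.
* **Quantification**: standard-curve fitting with
  E(%) = (10^(−1/slope) − 1) × 100 and a 90–115 % reliability window, and
  2^−ΔΔCt relative expression against one or several RGs.
* **Duplicated-gene sequence tools**: global pairwise identity, discovery
  of maximal windows exactly shared by all gene copies (candidate priming
  regions), exact-match in-silico PCR, and primer-constraint checking
  (length 20–24 bp, Tm 55–65 °C, GC 45–60 %, product 80–200 bp).
* **Synthetic Ct generator**: a seeded additive model (gene baseline +
  per-sample loading + group shifts + biological + technical noise) with
  known ground truth, used to validate every algorithm end to end.

The package also ships the published per-algorithm rank orders and primer
pairs of a ten-gene candidate panel in hexaploid oat (*Avena sativa*),
so the consensus step can be exercised against published designations
offline.

## Worked example

Screen a simulated ten-gene candidate panel over four tissue/stage groups
(three biological × three technical replicates each; two genes planted as
stable, three as tissue-shifted or noisy):

```python
from refstab import (aggregate_replicates, bestkeeper, consensus_rank,
                     delta_ct_method, genorm, normfinder, optimal_rg_number)
from refstab.synthetic_data import benchmark_scenario, simulate_ct_table

table, truth = simulate_ct_table(benchmark_scenario())
m = aggregate_replicates(table)          # 10 genes x 12 biological samples

gn = genorm(m)
ranks = {
    "deltact": delta_ct_method(m).rank,
    "genorm": gn.rank,
    "normfinder": normfinder(m, mode="ungrouped").rank,
    "bestkeeper": bestkeeper(m).rank,
}
cons = consensus_rank(ranks)
print("consensus ordering:", cons.ordering())
print("most stable pair:", cons.most_stable_pair)
print("least stable:", cons.least_stable)
n = optimal_rg_number(gn.v_series)
print("V series:", [(k, round(v, 3)) for k, v in gn.v_series])
print("optimal number of reference genes:", n.n_optimal)
```

prints

```
consensus ordering: ['REF2', 'REF1', 'MID4', 'MID1', 'MID2', 'MID5', 'MID3', 'VAR1', 'VAR2', 'RRNA']
most stable pair: ('REF2', 'REF1')
least stable: RRNA
V series: [(2, 0.12), (3, 0.092), (4, 0.086), (5, 0.081), (6, 0.074), (7, 0.1), (8, 0.093), (9, 0.115)]
optimal number of reference genes: 2
```

The two planted stable genes head the consensus ordering, the very
highly expressed but tissue-shifted rRNA-like gene comes last, and
V2 = 0.12 < 0.15 says two reference genes suffice for normalization —
exactly the read-out a practitioner wants from a screen.

The same pipeline is available from the shell:

```
refstab simulate --config sim.yaml --out ct.csv --truth truth.tsv
refstab stability --ct ct.csv --sets sets.yaml --out report.tsv --v-series-out v.tsv
refstab consensus --ranks report.tsv --v-series v.tsv --out consensus.tsv
refstab efficiency --points dilutions.csv --out curve.json
refstab ddct --ct ct.csv --target PKP1 --refs EP,EF1A --calibrator stageB --out fold.tsv
refstab insilico-pcr --fasta transcripts.fa --primers primers.tsv --out amplicons.tsv
refstab identical-regions --fasta copies.fa --min-len 20 --out windows.tsv
```

Ct input is long CSV/TSV with columns `sample,gene,replicate,ct` (a wide
dialect with one column per gene is also read); sample sets are YAML/JSON
with `name`, ordered `samples`, and an optional `groups` map.

## Documentation

`docs/methods.md` describes the statistical model behind each algorithm,
the synthetic-data generator and what it does and does not emulate, the
numerical conventions (log base 2 throughout, n−1 SDs, average ranks on
ties, variance floors), and known limitations.
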