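# readnet

Graph-theoretic analysis of task-based functional connectivity in the
left-hemisphere reading network, and its relationship to reading skill in
children with reading difficulty.

The package is for researchers who have per-run node time series (regional
fMRI activity extracted from a reading-network parcellation) plus a
participant table, and who want to reproduce — or stress-test on synthetic
cohorts — the full analysis chain:

1. **Connectivity.** For each run, zero-lag Pearson correlations between
   all node pairs form a weighted adjacency matrix.
2. **Binarization**, under two deliberately different schemes:
   *significance* — keep edge (i, j) iff the two-sided exact t test of
   r_ij rejects at α = .05 (uncorrected), with
   t = r·√((n−2)/(1−r²)) on n−2 df; and *minimum connected component
   (MCC)* — insert edges in descending weight order, stopping as soon as
   the graph spans all nodes in one component (ties with the stopping
   weight are all included, so the result is order-independent).
3. **Network measures** per binary network: segregation via maximised
   Newman modularity
   Q = (1/2m) Σ_ij [a_ij − γ k_i k_j / 2m] δ(c_i, c_j) (γ = 1, seeded
   multi-level community search with restarts) and transitivity
   T = Σ_i 2t_i / Σ_i k_i(k_i − 1); integration via global efficiency
   E = (1/(n(n−1))) Σ_{i≠j} 1/d_ij with 1/d = 0 for disconnected pairs.
4. **Aggregation.** Metrics are averaged over the two runs within each
   subject × modality, then values beyond mean ± 2 SD of each
   metric × modality × scheme column are replaced by the boundary
   (winsorization with pre-replacement statistics, sample SD).
5. **Inference.** Hierarchical OLS predicting pseudo-word decoding
   efficiency (PDE): step 1 = age, task accuracy, response latency;
   step 2 adds the nine connectivity predictors (3 metrics × 3
   presentation modalities VV/AV/AA). The increment is tested with the
   nested F statistic, and predictor importance is decomposed exactly with
   the LMG method (average sequential R² contribution over all predictor
   orderings, computed by 2^p subset enumeration), with percentile
   bootstrap CIs for pairwise share differences.

A synthetic-cohort generator (`readnet.simulate`) plants block-modular
correlation structure with per-subject strength and a linear
metric → outcome model, so every stage is testable end to end and
parameter recovery can be checked against ground truth without any data
download.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_build_networks.py
python analysis/03_network_metrics.py --seed 1
python analysis/04_aggregate_metrics.py
python analysis/05_hierarchical_regression.py --seed 1
python analysis/06_outside_network_null.py --seed 1
```

With seed 1 this prints (abridged):

```
significance: mean 681 edges of 903 possible (density 0.75)
mcc: mean 121 edges of 903 possible (density 0.13)
              modularity  transitivity  global_efficiency
mcc                0.506         0.358              0.440
significance       0.075         0.783              0.877
[significance] step 1 (nuisance): F(3,20)=0.27, p=0.85, adjR2=-0.105
[significance] step 2 (+9 metrics): F(12,11)=1.68, p=0.200, adjR2=0.261
[significance] increment: F(9,11)=2.10, p=0.123; 0 significant importance contrast(s)
[mcc] step 2 (+9 metrics): F(12,11)=1.72, p=0.188, adjR2=0.274
[significance] 154-node null network: increment F(9,11)=1.49, p=0.26 (non-significant)
```

Reading this: the significance scheme produces dense networks (weak
modularity ~.08, high efficiency ~.88) while the MCC keeps only the
strongest ~13% of edges (modular, Q ~.51, efficiency ~.44). The nuisance
variables alone explain nothing (adjusted R² ≈ −.11). This particular
24-subject cohort carries a planted positive link from crossmodal (AV)
modularity to PDE; the step-2 model recovers a positive adjusted R²
(~.26–.27) whose nested-F increment at n = 24 is suggestive but not
significant — single small cohorts are noisy, which is exactly what the
seeded multi-cohort tests quantify. The 154-node control cohort, which
has no planted link, shows a clearly non-significant increment.

The same stages are available as a CLI (`readnet simulate | connect |
metrics | regress | run`) and as library functions; `readnet run --config
config.yaml` executes everything reproducibly from one YAML file.

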