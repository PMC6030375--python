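# fanet — FA-weighted structural brain-network analysis

`fanet` is a pipeline for group comparison of **structural connectomes**:
90-node brain networks (AAL parcellation) whose nodes are cortical and
subcortical regions and whose edge weights are the mean fractional
anisotropy (FA) of the white-matter fiber bundles connecting them.  It
was built around a preschool autism (ASD) vs typically-developing (HC)
study design — 39 ASD, 19 control subjects — and covers the full chain
from fiber-level records to a statistical report:

1. **Construction** — two regions are connected if at least one
   tractography fiber links them; the edge weight is the mean per-fiber
   FA (`fanet.construction`).
2. **Weighted graph metrics** (`fanet.metrics`), with edge length
   defined as the reciprocal weight 1/w:
   * characteristic path length, the harmonic mean
     `L^w = N(N-1) / Σ_{i≠j} 1/L_ij` (disconnected pairs contribute 0);
   * global efficiency `E_global = 1/L^w`, nodal efficiency
     `e_i^w = (1/(N-1)) Σ_j 1/L_ij`, local efficiency `E_local`
     (mean efficiency of neighbor-induced subgraphs);
   * weighted clustering
     `C_i^w = (1/(k_i(k_i−1))) Σ_{j,h} (w_ij w_ih w_jh)^{1/3}`;
   * strength `k_i^w`, betweenness `B_i^w` and its network-normalized
     form `b_i^w = B_i^w / ⟨B^w⟩`.
3. **Null models** (`fanet.nullmodels`) — matched random networks
   preserving the exact degree sequence (double edge swaps) and the
   exact edge-weight multiset, yielding the small-world indices
   `γ = C^w/C^w_rand`, `λ = L^w/L^w_rand`, `σ = γ/λ`.
4. **Group inference** (`fanet.inference`, `fanet.model`) — 10,000-fold
   permutation tests on group mean differences (uncorrected α = 0.05 for
   the 8 whole-network metrics), Benjamini–Hochberg FDR at Q < 0.05
   across the 90 regions for each nodal family, and Pearson correlation
   of metrics with CARS autism-severity scores in the ASD group.
5. **Synthetic cohorts** (`fanet.synthetic`) — a calibrated generator of
   FA-weighted small-world cohorts (shared rewired-ring substrate,
   per-subject Beta weights, lognormal subject and regional factors, an
   ASD effect injected at left precuneus, left thalamus and bilateral
   superior parietal cortex, and CARS scores linearly linked to
   left-precuneus nodal efficiency), so the whole pipeline is testable
   without MRI data.

## Worked example

```python
from fanet import ConnectomeGroupModel

model = ConnectomeGroupModel.from_cohort()   # packaged calibrated cohort
res = model.fit(n_perm=10000, n_random=100, seed=0)
print(res.summary())
```

prints (abridged; full run ≈ 2 minutes, dominated by the 58 × 100
random-network ensembles):

```
Connectome group comparison (ASD vs HC)
  subjects: 39 ASD, 19 HC; nodes: 90
  permutations: 10000; random networks/subject: 100; alpha=0.05, Q=0.05

Global metrics (permutation test, uncorrected):
  metric        ASD mean±SD       HC mean±SD      diff        p
  Cw          0.233±0.015     0.225±0.009     0.0073   0.0655
  Lw          4.181±0.276     4.358±0.266    -0.1767   0.0239 *
  gamma       5.350±0.069     5.326±0.074     0.0235   0.2385
  lambda      1.171±0.041     1.173±0.038    -0.0020   0.8578
  sigma       4.574±0.149     4.545±0.108     0.0294   0.4526
  Sw          5.169±0.316     5.000±0.214     0.1682   0.0408 *
  Eglobal     0.240±0.016     0.230±0.014     0.0099   0.0235 *
  Elocal      0.366±0.021     0.352±0.017     0.0148   0.0118 *

Nodal metrics surviving FDR (Q < 0.05): 14
  ...
  nodal_efficiency  node 60 (Parietal_Sup_R): diff=+0.0799, p=0.0001, q=0.0045
  nodal_efficiency  node 67 (Precuneus_L): diff=+0.0783, p=0.0001, q=0.0045
  nodal_efficiency  node 77 (Thalamus_L): diff=+0.0452, p=0.0008, q=0.0240

CARS correlations (ASD group, metrics with group differences):
  ...
  nodal_efficiency node 67 (Precuneus_L): r=+0.467, p=0.0028 *
```

Reading it: the ASD group has a shorter harmonic path length (L^w 4.18
vs 4.36, p = 0.024) and higher global and local efficiency — the
"over-connected young ASD brain" pattern — while both groups are
small-world (γ ≈ 5.3, λ ≈ 1.17, so σ ≈ 4.6 » 1).  FDR-corrected nodal
efficiency recovers the four regions where the generator injects the
effect (nodes 59, 60, 67, 77), here alongside a few of their graph
neighbors that genuinely inherit part of the elevation through shortcut
paths; and left-precuneus nodal efficiency correlates with CARS severity
(r = 0.47) — the generator's built-in severity linkage.

Artifacts: `res.save("outdir/")` writes tidy CSVs plus `summary.txt`;
`res.plot_global_metrics()` draws the group comparison.

The same pipeline runs from the shell:

```bash
fanet run-all --seed 2018 --outdir study_run      # generate → analyze
fanet generate --outdir cohort                    # matrices + metadata
fanet build fibers.csv --n-nodes 90               # fiber CSV → matrices
fanet metrics cohort/matrices/asd001.tsv
fanet nulls cohort/matrices/asd001.tsv --n-random 100
fanet analyze --matrix-dir cohort/matrices --meta cohort/cohort.csv
```

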