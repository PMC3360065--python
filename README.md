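# sirnarank

Cross-platform feature selection for siRNA silencing efficacy.

Short interfering RNAs (siRNAs) silence genes with efficacies that depend
strongly on the guide-strand sequence, but the public efficacy datasets were
produced on incompatible platforms (different cell lines, assays, delivery
methods, concentrations), so naively pooling them is unreliable and any
single dataset is small. `sirnarank` addresses this by treating each
platform as a separate regression **task** that shares one feature space,
and selecting the features that matter *jointly across platforms*:

1. **Encoding** — every 19-nt antisense guide strand (5′→3′, product-level
   efficacy in [0, 1], lower = more potent) is encoded into an ordered
   **497-feature** vector: position-dependent nucleotide identity, 2-/3-/4-mer
   motif flags, GC-content threshold flags, nearest-neighbor duplex
   thermodynamics (Xia-1998 ΔG°37 stacks), immune-stimulatory motifs,
   palindromes, homopolymer stretches and intramolecular secondary structure.
2. **Joint sparse regression** — with per-task design `X_j` (n_j × d) and
   responses `y_j`, one weight matrix `W ∈ ℝ^{d×M}` is fitted by

   ```
   min_W  Σ_j 1/(2 n_j) ‖X_j w_j − y_j‖²  +  λ Ω(W)
   ```

   under three penalties: the ℓ2,1 norm `Σ_i ‖W_i‖₂`, the ℓ1,∞ norm
   `Σ_i ‖W_i‖_∞` (both zero whole feature rows, i.e. drop a feature from
   every platform at once) and the trace norm `Σ_k σ_k(W)` (low-rank
   coupling). The solver is monotone FISTA with closed-form proximal
   operators; λ is chosen on a 20-point log grid by 10-fold CV.
3. **Ranking and stability** — the cross-task weight `w_i = Σ_j |W_ij|` is
   zero exactly when feature *i* is useless in every task; features kept in
   **all** CV folds form a per-norm ranked list.
4. **Rank aggregation** — the three per-norm lists are integrated into one
   consensus ordering δ* minimising `Σ_i w_i · d_K(δ, L_i)` (Kendall
   distance) with a Cross-Entropy Monte Carlo search, verified against an
   exhaustive oracle at small sizes.
5. **Validation** — one-tailed Welch t-tests and Pearson correlations per
   feature, a GC-content window scan for the potency-enriched GC range,
   position-specific motif profiles, and repeated 2-fold ridge-regression
   RMSE comparison of competing feature sets.

A synthetic multi-platform generator (`sirnarank.synthetic_data`) plants a
shared sparse support with task-specific coefficient magnitudes, noise
levels and offsets, so the whole pipeline is testable end to end without
any external download.

## Worked example

```bash
python examples/02_fit_multitask.py
```

```
tasks: [500, 200, 200, 100, 40, 40, 10, 40, 40, 100]
planted features: ['U @ PS1', 'A @ PS3', 'G @ PS5', 'C @ PS7', 'A @ PS9',
                   'U @ PS11', 'G @ PS13', 'C @ PS15', 'A @ PS17', 'U @ PS19']

chosen lambda = 0.05487
CV-stable features: 14; after gap cut: 10
per-task held-out RMSE: [0.091 0.098 0.111 0.12  0.146 0.172 0.289 0.192 0.163 0.184]
planted noise sigma:    [0.05  0.067 0.083 0.1   0.117 0.133 0.15  0.167 0.183 0.2 ]

selected-feature F1 vs planted support: 1.000
```

Ten heterogeneous tasks (sizes mirroring the real ten-platform collection)
are generated with ten planted positional features; the ℓ2,1 joint fit with
CV-chosen λ keeps 14 stable features, the weight-gap cut trims them to
exactly the planted ten (F1 = 1.0), and the held-out RMSE per task sits
near the injected noise level σ. The other examples cover encoding
(`01_encode_features.py`), consensus ranking with the brute-force check
(`03_aggregate_rankings.py`) and the validation statistics
(`04_validate_features.py`).

The same steps are available as a thin CLI:

```bash
sirna simulate --seed 17 --out-dir sim/
sirna encode --in sim/task01.tsv --out enc01.tsv
sirna fit --in enc01.tsv ... --norm l21 --lambda auto --folds 10 --seed 17 --out list_l21.tsv
sirna aggregate --lists list_l21.tsv --lists list_l1inf.tsv --lists list_trace.tsv --seed 17 --out consensus.tsv
sirna gc-scan --in sim/task01.tsv
```

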