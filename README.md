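# epidomain

Detection of **multi-gene epigenetic domains** from multi-mark
histone-modification ChIP-seq data with a hidden Markov model.

Many regulatory phenomena act on regions far larger than a single gene:
Polycomb-repressed *Hox* clusters, olfactory-receptor gene deserts,
broad active neighbourhoods.  `epidomain` finds such regions by treating each
gene as one observation in a chain along its chromosome.  Every gene is
reduced to an m-dimensional vector of **summary scores** (average ChIP-seq
tag counts per 100-bp bin over the ±2 kb promoter window, or over the 3′ end
of the coding region for H3K36me3), and a hidden Markov model with
diagonal-covariance multivariate Gaussian emissions

x_i | state s ~ N(μ_s, Σ_s),  Σ_s diagonal

is fitted by EM and decoded by Viterbi.  Maximal runs of genes in one state
are **domains**; with five marks (H3K4me2, H3K4me3, H3K27me3, H3K9me3,
H3K36me3) and three states they separate into *active* (high H3K4me2/3),
*non-active* (high H3K27me3) and *null* (uniformly low signal) types.

The toolkit covers the full workflow:

- **Scoring** (`epidomain.scores`) — strand-aware promoter / 3′-coding
  windows, repeat-content filtering (genes >50% repeat-masked in either
  window are dropped).
- **Model selection** (`epidomain.cluster`) — k-means plus the gap statistic
  Gap(K) = E[log W_K] − log W\*_K over a uniform bootstrap reference.
- **HMM** (`epidomain.hmm`) — EM with cluster-based or semi-conjugate-prior
  initialisation; Viterbi and scaled forward–backward decoding.
- **Significance** (`epidomain.domains`) — per-domain likelihood-ratio
  statistic λ_j = −2 Σ_i [log N(x_i; μ_0, Σ_0) − log N(x_i; μ_s, Σ_s)]
  against the global model, referred to χ² with df = 2·S·m − 2·m, with
  Benjamini–Hochberg FDR control (default q ≤ 0.01).
- **Validation** (`epidomain.validate`) — permutation tests against
  contiguous, size-matched random gene neighbourhoods (within-domain score
  and expression variance; Fleiss' kappa of GO membership).
- **Simulation** (`epidomain.simulate`) — synthetic domain-structured data
  from the reference emission parameters and the state-recovery accuracy
  study.
- **Differential** (`epidomain.differential`) — second-condition
  normalisation, fixed-parameter transfer decoding and the domain-change
  rule (changed iff ≥1 gene changes state).

## Worked example

```sh
python examples/simulation_accuracy.py
```

```
variance x1: mean accuracy 0.993 (per replicate: [0.992, 0.992, 0.994])
  confusion (true x inferred):
[[3005   20]
 [  24 2951]]
variance x2: mean accuracy 0.986 (per replicate: [0.985, 0.984, 0.987])
```

Each replicate simulates 2,000 genes whose hidden states follow a 2-state
Markov chain (mean domain length 10) with the reference five-mark Gaussian
emissions, then re-infers the states blind to the truth (k-means → EM →
Viterbi) and label-matches.  An accuracy of 0.993 means 99.3% of genes were
assigned their true domain state; the doubled-variance row shows the
degradation under twice the emission noise is under one percentage point.

Other examples: `examples/end_to_end_pipeline.py` (tag BEDs → scored matrix
→ fitted model → significant-domain summary → permutation validation),
`examples/model_selection_gap.py` (gap statistic picking K = 3),
`examples/two_condition_changes.py` (transfer decoding and the change rule).

The same stages are available as a CLI for file-based workflows:

```sh
epidomain score --genes genes.bed --mark H3K4me3=k4me3.bed ... -o scores.tsv
epidomain fit --scores scores.tsv --states 3 -o model.json
epidomain decode --model model.json --scores scores.tsv -o states.tsv
epidomain call --scores scores.tsv --model model.json --states states.tsv -o domains.tsv
epidomain run --config run.yaml -o outdir/     # everything, with a manifest
```

## Documentation

`docs/methods.md` describes the model, estimation and testing procedures,
the synthetic-data generator, numerical choices and known limitations.
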