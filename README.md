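# enrichfit

Statistical detection of nucleotide positions significantly enriched in a
feature-enriched RNA-seq library relative to an unenriched control.

Protocols such as Cappable-seq and dRNA-seq enrich RNA fragments carrying a
structural feature of interest — most prominently the triphosphorylated 5′
end that marks a prokaryotic transcription start site (TSS) — and are
sequenced alongside an unenriched control library. The analysis question is
which individual genome positions carry significantly more reads in the
enriched library than the control predicts. `enrichfit` answers it with a
single *global* model of the enrichment-score distribution, rather than
local windowed models, so every covered position receives a statistic — no
region is left unmodeled. The same machinery applies to internal-feature
enrichment (e.g. m6A-seq) by counting all read positions instead of read
starts.

## Model

For each genome position *i* (strand-aware; 1-based), let D₁ᵢ and D₂ᵢ be
read depths in the enriched and control libraries under the chosen counting
mode (read 5′ starts, 3′ ends, or all aligned bases). With the default unit
pseudo-count applied at every analyzed position (all positions with at
least one read in either library), the enrichment score is the
total-depth-normalized ratio

```
E_i = (D1_i / D2_i) · (Σ_j D2_j / Σ_j D1_j)
```

Under the null of no enrichment the scores are assumed normal after a
Box-Cox power transform `t = (E^λ − 1)/λ` (log at λ = 0), with λ chosen by
profile-likelihood maximization. The fit is accepted only if the squared
Pearson correlation of the normal Q-Q point set satisfies R² ≥ 0.90
(configurable); positions with `t_i ≥ μ + σ·z₁₋α` (default α = 0.05,
one-sided upper tail) are called significantly enriched, each with the
p-value `1 − Φ((t_i − μ)/σ)`. If the normality gate fails, a 95th-percentile
rank cutoff is used instead (no p-values). Across replicates, per-position
p-values are pooled with Fisher's combined probability test
(−2Σln pᵢ ~ χ²₂ₖ), or a consensus rule (significant in ≥ m replicates).

## Worked example

`examples/01_simulate_and_call.py` simulates a 5 kb genome with 20 planted
sites at 50× background start probability (~200,000 reads per library,
background depth ≈ 20), writes SAM, converts to indexed BAM, and runs the
pipeline:

```
positions analyzed : 10000
Box-Cox lambda     : -0.4512
Q-Q R^2            : 0.9766  (gate: >= 0.9)
critical raw score : 1.676
positions called   : 281
planted recovered  : 20/20
```

The transformed scores pass the normality gate (R² = 0.977 ≥ 0.90), the
fitted model puts the α = 0.05 critical value at a raw score of 1.68, and
all 20 planted sites score far above it. `examples/02_replicate_meta_analysis.py`
shows the power gain of Fisher combination on weak (1.7×) signal — single
replicates recall 55% and 42.5% of planted sites, the combined test 72.5% —
and `examples/03_annotate_and_recall.py` demonstrates strand-aware gene
annotation and the ±5 nt known-site recall rule.

A thin CLI wraps the same pipeline:

```bash
enrichfit simulate --out fixtures --seed 3
enrichfit run --enriched rep1.bam --enriched rep2.bam --control ctrl.bam \
    --mode start --alpha 0.05 --combine fisher --gff genes.gff3 \
    --known-sites tss.tsv --out results/
```

Outputs per replicate: significant-positions TSV, GFF3 of called sites,
summary statistics, and Q-Q / depth-summary PNGs; plus a meta-analysis TSV
when replicates are combined.

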