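# idrsig

Evolutionary signatures of molecular features in intrinsically disordered
protein regions (IDRs).

Highly diverged IDRs rarely align residue-by-residue, yet they often
preserve bulk molecular features — charge patterning, composition, motif
content — under selection. `idrsig` detects this: for each orthologous IDR
set it simulates a phylogenetic null ensemble (disorder-specific
substitution model, power-law indels, conserved-segment protection),
compares the observed across-ortholog mean and log-variance of each
molecular feature against the simulated null via empirical p-values and
Z-scores, clusters the resulting 164-dimensional "evolutionary signatures",
and tests clusters for annotation enrichment with hypergeometric +
permutation controls. A synthetic-data generator makes the entire pipeline
testable without any external downloads.

## Layout

| module | role |
| --- | --- |
| `idrsig.io` | FASTA/Newick/TSV readers and writers, region slicing, region and ortholog-set filters (≥30 aa, ≥10 species × ≥10 aa) |
| `idrsig.features` | the 82-feature default catalog (config-defined, swappable) and the per-sequence feature engine |
| `idrsig.rates` | per-column ML evolutionary rates, 31-column local rates, two-state HMM conservation mask |
| `idrsig.simulate` | reversible substitution model, truncated-Zipf indels, mask-protected simulation along a tree, ensemble generation and the 950-non-empty filter, distance-scaling calibration |
| `idrsig.signatures` | feature summaries, empirical p-values, Z-scores, signature vectors, significance counting and the chance expectation |
| `idrsig.cluster` | weighted uncentered-correlation distance, average linkage, cluster extraction, composition k-means control, BLOSUM62 similarity control, query annotation transfer |
| `idrsig.enrich` | hypergeometric enrichment, BH FDR, uniform and composition-matched permutation Z (sum of top ten −log10 Q) |
| `idrsig.synth` | synthetic trees, root IDRs, null and constraint-carrying ortholog sets, planted-annotation benchmarks |
| `idrsig.pipeline` | null-calibration pools and end-to-end benchmark recovery |
| `idrsig.cli` | `idrsig <stage>` orchestration |

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (null p-value
calibration, chance expectation, calibration identity, structural
constants, oracle equivalences, planted-benchmark parameter recovery,
simulator physics). The full suite takes ~15–20 minutes on one CPU; the
heavy fixtures are a 50-IDR × 500-replicate null pool and a 3-class
planted benchmark.

## CLI

Stages read and write plain-text artifacts in one working directory:

```sh
idrsig synth     --workdir run/ --seed 1      # synthetic benchmark dataset
idrsig rates     --workdir run/               # column/local rates + masks
idrsig simulate  --workdir run/               # null ensembles -> summaries
idrsig features  --workdir run/               # real-set feature summaries
idrsig signatures --workdir run/              # Z-score signature matrix
idrsig cluster   --workdir run/               # uncentered-corr UPGMA clusters
idrsig enrich    --workdir run/               # enrichment + permutation Z
idrsig annotate  --workdir run/ --idr idr_class1_001
```

All parameters (replicates = 1000, non-empty threshold = 950, α = 0.01,
|Z| ≥ 3, 95% presence, FDR 5%, GO term cap 5000, ...) live in a YAML config
passed with `--config`; every stage writes a resolved-config snapshot and
is byte-reproducible given the same config and seed.

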