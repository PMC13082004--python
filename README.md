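# pvep

Personalized variant effect prediction at desk scale: inject focal
clinical variants into population-derived personalized haplotypes, compute
per-haplotype delta scores through a pluggable scorer interface, and run
the downstream statistics — score-distribution characterization, variant
sensitization maps, non-additive interaction tests, structural contact
enrichment, and population-averaged benchmarking.

The package never runs a deep learning model. Scoring goes through a
`ScorerAdapter` contract (protein log-probabilities, splice acceptor/donor
probabilities, or per-track coverage); deterministic toy scorers
(position-specific score table, planted-epistasis scorer, AG/GT motif
splice scorer, motif coverage scorer) make every pipeline stage fully
testable offline, and a synthetic phased-cohort generator provides all
fixtures (reference FASTA + GFF3 transcripts, phased VCF with
superpopulation labels and INFO scores, focal variant tables, planted
ground-truth effects, toy residue distance maps).

## Layout

| module | role |
|---|---|
| `pvep.synthetic` | reference/cohort/focal-variant/ground-truth/distance-map generators |
| `pvep.haplotypes` | personalized DNA windows, protein haplotypes, indel-aware residue maps, focal injection |
| `pvep.scoring` | scorer adapters, delta metrics (masked/wt marginals, pseudo-perplexity; splice deltas; COVR), the pVEP loop, result store |
| `pvep.distributions` | representativeness percentiles, normality/modality (VB-GMM), pathogenic boundary, effect-class entropy, MAD, group tests, BH-FDR |
| `pvep.sensitization` | ridge sensitization maps, marginal effects, ±5 kb local surrogates, non-additive interaction F-tests |
| `pvep.structure` | contact binarization (<8 Å), contact diffs, interaction-at-contact enrichment, population-weighted contact maps |
| `pvep.benchmark` | Spearman annotation correlations, win rate, 3-parameter logistic allele-frequency fit |
| `pvep.io`, `pvep.cli` | file contracts (FASTA/GFF3/VCF/TSV/zarr/parquet), run config, CLI |

## CLI

All stages operate on one run directory and are deterministic for a fixed
seed:

```bash
pvep simulate --seed 1 --out run/        # synthetic cohort + fixtures
pvep score --run run/                    # pVEP loop with toy scorers
pvep distributions --run run/            # per-variant distribution summaries
pvep sensitize --run run/                # sensitization maps + local surrogates
pvep epistasis --run run/                # non-additive interaction scan
pvep structure --run run/                # contact enrichment
pvep benchmark --run run/                # ref vs population-average benchmark
pvep report --run run/                   # accounting / provenance aggregate
```

DNA results are stored one zarr per contig with dims
site × sample × ploid × metric (plus a plain-TSV export); protein results
are parquet tables under
`{cohort}/vep/{model}/{protein}/{haplotype}/{variant_source}/{strategy}.parquet`.

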