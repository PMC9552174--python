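# panelsieve

Discover a stable predictive gene panel from a binary patient × gene somatic
mutation matrix, score patients by the number of mutated panel genes, pick the
benefit/non-benefit score threshold from the survival data, and evaluate the
resulting stratification head-to-head against tumor mutational burden (TMB).

The pipeline has five stages:

1. **synthetic cohort** (`panelsieve.simulate`) — a randomized two-arm trial
   generator with a planted benefit-gene panel: exponential PFS/OS whose
   hazard is modulated per mutated planted gene (opposite sign per arm),
   uniform administrative censoring, and a logistic responder model with a
   treatment × score interaction. Everything downstream is testable offline.
2. **cohort I/O** (`panelsieve.io`) — MAF or long-format TSV mutation calls plus
   a clinical TSV (`sample_id, arm, pfs_time, pfs_event, os_time, os_event
   [, response, sld, tmb]`) assembled into a validated `CohortDataset`,
   optionally restricted to a gene universe (e.g. a 391-gene assay panel).
3. **panel selection** (`panelsieve.selection`) — repeated gradient-boosted-tree
   modeling (default 350 repetitions, stratified 8/2 train/validation splits)
   on the treated arm; genes ranked per repetition by held-out permutation
   importance (AUC drop; native split gain available); the panel is the
   intersection of the per-repetition top-k gene sets (or an
   inclusion-frequency threshold, which is far more robust), with a stability
   trace of the running intersection.
4. **scoring & cutpoint** (`panelsieve.scoring`, `panelsieve.cutpoint`) — the
   benefit score is the count of mutated panel genes; the threshold is chosen
   by scanning Cox PFS hazard ratios of `score >= c` vs `score < c` over all
   cutoffs in the treated arm, LOESS-smoothing the Wald-statistic curve
   (span 0.80), and locating the structural break with the Chow test.
5. **evaluation** (`panelsieve.evaluation`) — Cox contrasts (continuous and
   dichotomized score per arm and endpoint, treated-vs-control within strata),
   Kaplan–Meier curves with log-rank tests, ORR tables, responder AUC with
   bootstrap CI, and Spearman correlations — each computed for the panel
   score and for TMB side by side.

Note: the classification label used during panel selection defaults to RECIST
objective response (CR/PR vs SD/PD); `pfs_ge_<months>` is available as an
alternative (`SelectionConfig.label_spec`).

## CLI

```bash
# synthetic demo cohort
panelsieve simulate --n-patients 800 --n-genes 400 --seed 1 --out-dir demo/

# stability panel selection
panelsieve select --mutations demo/mutations.tsv --clinical demo/clinical.tsv \
    --label responder --reps 350 --top-k 150 --seed 1 --out demo/panel.txt

# score + stratify
panelsieve score --mutations demo/mutations.tsv --clinical demo/clinical.tsv \
    --panel demo/panel.txt --out demo/scored.tsv

# survival-driven score threshold
panelsieve cutpoint --scored demo/scored.tsv --endpoint pfs --span 0.8 \
    --out demo/cutpoint.json

# full evaluation vs TMB
panelsieve evaluate --mutations demo/mutations.tsv --clinical demo/clinical.tsv \
    --panel demo/panel.txt --cutoff 2 --out demo/report.json

# everything from one YAML config
panelsieve run --config run.yaml
```

A run config contains either a `simulation:` block or
`mutations_path`/`clinical_path`, plus optional `selection:`, `scoring:`,
`cutpoint:` and `evaluation:` blocks, an `output_dir` and a global `seed`
from which all stage seeds are derived deterministically (see
`tests/test_pipeline.py` for a complete example).

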