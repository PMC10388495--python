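# mrkit

Summary-statistics Mendelian randomization in Python: instrument selection
and harmonization, five two-sample MR estimators, sensitivity diagnostics
(Cochran's Q, Egger intercept, simulation-based outlier detection,
leave-one-out), multivariable MR with mutual adjustment, a
product-of-coefficients mediation decomposition, and a ground-truth
synthetic GWAS summary-data generator for testing every stage offline.

## Layout

| module | contents |
| --- | --- |
| `mrkit.gwas_io` | delimited summary-statistics and LD-matrix I/O, result tables |
| `mrkit.instruments` | p-value selection with threshold relaxation, greedy LD clumping, allele harmonization, F statistics |
| `mrkit.estimators` | Wald ratio, fixed/random-effects IVW, Egger, weighted median, simple/weighted mode |
| `mrkit.sensitivity` | Cochran's Q, Egger intercept test, simulation-based outlier/global/distortion tests, leave-one-out, plot tables |
| `mrkit.mvmr` | multivariable IVW/Egger and the mediation decomposition |
| `mrkit.simulate` | synthetic exposure/mediator/outcome triplets with known truth |
| `mrkit.pipeline` | config-driven orchestration (forward, MVMR, mediation, reverse) |

## Quick start

```python
import numpy as np
from mrkit import (harmonize, ivw, mediate, paper_shaped_scenario,
                   run_pipeline, PipelineConfig, simulate_triplet)

# synthetic data with known truth
x, z, y, ld, truth = simulate_triplet(paper_shaped_scenario(seed=1))

# a single univariable analysis
h = harmonize(x, y)
print(ivw(h, effects="random"))

# the full pipeline (forward MR, MVMR, mediation, reverse MR)
cfg = PipelineConfig(mode="all", seed=1, n_boot=500, presso_n_sim=500)
report = run_pipeline(cfg, exposure=x, mediator=z, outcome=y, ld=ld)
print(report.blocks["mediation"])

# the mediation decomposition on explicit effects
print(mediate(np.log(0.703), np.log(2.103), -0.277).printed())
```

## CLI

```bash
mrkit simulate --seed 1 --n-snps 100 --out-dir scratch/sim
mrkit run --config pipeline.yaml --out report.json
mrkit mr --exposure exp.tsv --outcome out.tsv --seed 1 --out mr.tsv
mrkit mediate --total -0.352 --bxz 0.743 --bzy -0.277
mrkit report --report report.json --block forward
```

`mrkit run` takes a YAML config mirroring `PipelineConfig` (paths, column
maps, thresholds, estimator settings, mode). Exit code 2 marks config
errors, 3 statistical hard errors (e.g. no instruments at any threshold).

## Tests

```bash
python -m pytest tests/            # full suite incl. acceptance (~3 min)
python -m pytest tests/ --ignore=tests/test_acceptance.py   # fast subset
```

`tests/test_acceptance.py` holds the calibration (type-I error over 1000
null replicates), robustness (invalid instruments, planted outliers), and
end-to-end parameter-recovery checks.

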