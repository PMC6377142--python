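# dyde

Dynamical differential expression analysis of gene regulatory networks.

`dyde` localizes the entry point of a chemical perturbation in a gene
regulatory network from short, two-condition expression time courses
(e.g. 12 samples at 4 h, 2 replicates). Instead of asking which genes
change in *level*, it asks which regulatory *links* change in *dynamics*:

1. **Rhythmicity screen** — each transcript is fitted with a
   pseudo-sinusoid (two joined half-cycles with periods `p1`, `p2`,
   overall period `(p1+p2)/2`, searched over 12–36 h) and classified
   rhythmic/arrhythmic by a logistic regression over 8 spectral and fit
   features computed from the replicate mean and the best single
   replicate.
2. **Link identification** — for every ordered gene pair, a first-order
   LTI model `dy/dt = a·u − b·y + c` is fitted per condition by
   simulation-error minimization; links are validated by an NRMSE fitness
   threshold (default 46 %).
3. **Differential network analysis** — validated networks from the two
   conditions are diffed into *common*, *lost* (regulation-loss) and
   *gained* links; every common link's dynamics are compared with the
   **nu-gap** metric restricted to the oscillation band (periods 18–32 h
   by default), and genes are ranked by per-gene connectivity loss.
   Values above ~0.2 flag meaningfully altered links; the top nu-gap link
   is the prime candidate for the perturbation's entry point.

A first-class synthetic-data module generates two-condition datasets with
known link kinetics and a known perturbed link, plus labeled
rhythmic/arrhythmic series, so the whole pipeline is testable without any
external data. An AUROC/AUPR harness scores link recovery against a
ground-truth edge list.

## Test

```sh
python -m pytest -q tests/
```

Note: `tests/test_acceptance.py::TestCriterion2DataAnchored` reproduces
published numbers from a supplementary dataset that is not
redistributable here; it fails with an explanatory message unless you
provide the data (set `DYDE_S1_DIR` to a directory containing
`untreated.tsv` and `nam.tsv` in the wide dialect below). Everything else
runs on generated data.

## Data format

Wide dialect (TSV/CSV), one row per gene, header cells
`<condition>:<replicate>:<time_h>`:

```
gene	untreated:1:0	untreated:1:4	...	untreated:2:44
CCA1	10.61	9.34	...	8.02
```

A long dialect with columns `gene, condition, replicate, time_h, value`
is also accepted. Times are hours on a uniform grid; values are used
as-is (typically log-scale normalized intensities).

## CLI

```sh
dyde simulate --spec spec.json --out-prefix sim_      # synthetic pair
dyde rhythm   --input expr.tsv --out calls.tsv        # rhythmicity screen
dyde fit      --input expr.tsv --threshold 46 --out netA.json
dyde compare  netA.json netB.json --band 18:32 --out diff.json
dyde nugap    model1.json model2.json --band 18:32
dyde scan     --mode perturbed --input-a a.tsv --input-b b.tsv --genes g.txt --out scan.json
dyde bench    --input expr.tsv --truth edges.tsv --out metrics.json
dyde run      --input-a a.tsv --input-b b.tsv --threshold 46 --outdir out/
```

`dyde run` executes the full pipeline (fit both conditions → validate →
compare → rank nu-gaps → connectivity-loss sensitivity) and writes
`report.json` embedding the exact config and seed; reruns with the same
seed are byte-identical.

## Library use

```python
import numpy as np
from dyde import (AnalysisConfig, fit_first_order, nu_gap, simulate_pair,
                  SyntheticSpec)
from dyde.synthetic import DriverSpec

spec = SyntheticSpec(
    drivers={"G0": DriverSpec(A=1.5, p1=31.6, p2=16.4, mean=6.0)},
    adjacency={("G0", "G1"): (1.0, 0.4, 0.5)},
    perturbed_link=("G0", "G1"), perturbed_params=(-1.0, 1.6, 8.0),
    noise_sd=0.03, seed=0, duration_h=44.0,
)
ds_a, ds_b, truth = simulate_pair(spec)
cfg = AnalysisConfig(rng_seed=0)
m_a = fit_first_order(ds_a.values[0, 0], ds_a.values[1, 0], ds_a.times, cfg)
m_b = fit_first_order(ds_b.values[0, 0], ds_b.values[1, 0], ds_b.times, cfg)
print(nu_gap(m_a, m_b, cfg=cfg).value)
```
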