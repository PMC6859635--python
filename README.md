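# pearmedia

Surrogate modelling and evolutionary optimization of in vitro tissue-culture
media for two pear rootstocks, **Pyrodwarf** and **OHF** (*Pyrus communis*
dwarfing stocks used in high-density orchards).

Micropropagation performance depends strongly on the mineral and hormone
make-up of the culture medium.  This package models how six components of
Murashige–Skoog (MS) medium — KNO₃, NH₄NO₃, the *mesos* salt group (CaCl₂,
KH₂PO₄, MgSO₄), the micronutrient group, and the hormones BAP and IBA —
shape five growth responses of proliferating explants:

| symbol | response | units |
|---|---|---|
| PR | proliferation rate | shoots per explant |
| SL | mean shoot length | cm |
| STN | shoot-tip necrosis incidence | % |
| Vitri | vitrification (hyperhydricity) incidence | % |
| QI | explant quality index | 1–5 score |

and then searches the factor box for media that maximize PR, SL and QI and
minimize STN and Vitri.

## What is inside

* **`pearmedia.bbd`** — the 6-factor, 3-level, 48-run Box–Behnken design the
  experiments used (both a generator and the literal printed design; they
  coincide run-for-run).
* **`pearmedia.datasets`** — the per-medium mean responses of all 51 media
  (48 designed + MS/WPM/QL controls) for both rootstocks, as packaged,
  checksummed CSV fixtures.
* **`pearmedia.expressions` / `pearmedia.published`** — expression trees
  with *protected* (total) operators, and the ten published
  symbolic-regression media models (one per rootstock × response), each the
  sum of three gene sub-expressions over terminals A–F.
* **`pearmedia.gep`** — a from-scratch gene-expression-programming engine:
  fixed-length multigenic Karva genomes, head/tail structure
  (t = h(a−1)+1), roulette selection with elitism, the classical operator
  suite at the published rates, RRSE fitness.
* **`pearmedia.rbf`**, **`pearmedia.mlr`** — RBF-network and
  ordinary-least-squares baselines with the same predict contract.
* **`pearmedia.metrics`** — RMSE, MARE, MBE and the Pearson r / r²
  comparison statistics.
* **`pearmedia.ga`** — a real-coded, bound-constrained genetic algorithm
  (uniform crossover, Gaussian mutation, rank-based roulette, elitism,
  restarts) for optimizing any fitted model over the factor ranges.
* **`pearmedia.simulate`** — replicate-level synthetic data (51 media × 10
  jars = 510 records) over the published response surfaces, for testing the
  whole pipeline without wet-lab data.
* **`pearmedia.pipeline` / CLI `pearmedia`** — the full workflow:
  load → split 70/30 → fit GEP/RBFNN/MLR → score → rank → GA-optimize →
  report, with every table written as CSV next to the run's YAML config.

## Worked example

Evaluate a published model at a candidate medium — here the reported
Vitri-minimal Pyrodwarf medium (0.5× KNO₃, 0.5× NH₄NO₃, 2.5× mesos,
2.76× minors, 0.5 mg/l BAP, 0.05 mg/l IBA):

```python
>>> from pearmedia import FactorVector, predict
>>> x = FactorVector(KNO3=0.50, NH4NO3=0.50, mesos=2.50,
...                  minors=2.76, BAP=0.50, IBA=0.05)
>>> round(predict("Pyrodwarf", "Vitri", x), 2)
4.0
```

i.e. the model predicts a 4.0 % vitrification incidence at that
composition, matching the reported optimum for this response.

Compare the three model families on a held-out split of the Pyrodwarf
dataset (the published equations stand in for the GEP column):

```sh
$ pearmedia --seed 1 evaluate --rootstock Pyrodwarf --outdir run_ex
response  rank model     rmse     mare       mbe         r  r_squared ...
     STN     1   GEP 1.827125 0.082769 -0.970386  0.995953   0.991922
     STN     2 RBFNN 5.131584 0.164464 -1.311303  0.945785   0.894508
     STN     3   MLR 5.880204 0.169589 -1.311751  0.911848   0.831466
   Vitri     1   GEP 2.093178 0.075244  0.349456  0.984140   0.968531
   ...
```

For STN the symbolic model explains 99 % of the held-out variance
(RMSE 1.8 percentage points) against 83 % for the linear baseline —
the qualitative ordering the study reports.  `pearmedia optimize` then
searches the factor box for optimal media; `pearmedia simulate` emits
replicate-level synthetic data; `pearmedia run-all` chains everything.

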