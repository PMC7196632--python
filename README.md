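# nadhub

Quantitative models of the **PII–NadE2 regulatory hub**: how bacterial
glutamine-dependent NAD synthetase (NadE2) is feedback-inhibited by its
product NAD⁺, and how the trimeric signal-transduction protein PII
(GlnB/GlnZ/GlnK) acts as a dissociable regulatory subunit that reshapes that
inhibition in response to the cell's nitrogen and energy state.

The package is aimed at enzymologists and systems biologists who want to
refit, simulate or stress-test the regulatory circuit without wet-lab data:
every analysis runs on synthetic data with known ground truth.

## What it models

**Feedback-inhibition kinetics** (`nadhub.kinetics`). Dose–response rate
laws fitted by seeded multi-start nonlinear least squares, in a
statsmodels-style Model/Results idiom:

- free enzyme: hyperbolic inhibition, v = v₀·(1 − I_max·[NAD⁺]/(K_i + [NAD⁺])), with K_i ≈ 1 mM;
- PII-bound enzyme: cooperative sigmoid, v = v₀·(1 − I_max·[NAD⁺]ⁿ/(IC₅₀ⁿ + [NAD⁺]ⁿ)), IC₅₀ ≈ 2.5 mM, n ≈ 2.2;
- hyperbolic activation by PII (half-maximal relief K_act ≈ 640 nM trimer),
  Michaelis–Menten ± noncompetitive inhibition, and 2-OG effector curves.

Also: initial-velocity extraction from assay traces (discontinuous PPi and
coupled A₃₄₀ via Beer–Lambert), AICc/F-test model discrimination, and
inhibition-mode classification (V_max down at constant K_m ⇒ allosteric).

**Biolayer interferometry** (`nadhub.bli`). Langmuir 1:1 and 2:1
heterogeneous-ligand sensorgram simulation, reference subtraction +
Savitzky–Golay smoothing, and global multi-concentration fits sharing
(k_ON, k_OFF, R_max), with K_d = k_OFF/k_ON.

**Regulatory switch** (`nadhub.switch`). Integrates the constants into a
predictive model: uridylylated PII cannot bind; 2-OG raises the effective
complex K_d competitively, with a history-dependent half-effect constant
(15.5 μM for forming complexes, 1 mM for pre-formed ones — the "memory
effect"); the bound fraction follows the exact tight-binding quadratic; and
activity is the bound/free mixture of the two inhibition curves. The sweep
`hysteresis_scan` exhibits the resulting hysteresis loop.

**Genomic islands** (`nadhub.islands`). Detection of PII–nadE gene
neighbourhoods from homology hit tables: one genome per species, 10-kb-flank
PII islands (e-value ≤ 1e-5), nadE pairing at gene-midpoint distance
< 2000 bp, dereplication and taxonomy rollup.

**Similarity clustering** (`nadhub.clustering`), **ligand-fishing
enrichment** (`nadhub.enrichment`), and **synthetic-data generators with
ground truth** (`nadhub.simulate`) complete the pipeline.

## Worked example

Simulate a triplicate NAD⁺ dose–response of the PII-bound enzyme at the
measured constants (IC₅₀ 2.5 mM, n 2.2, 3% CV noise) and refit it:

```python
from nadhub import DoseResponseModel, HubState, predicted_activity
from nadhub import simulate as sim

data, truth = sim.gen_dose_response(
    "hill_inhibition",
    {"v0": 100.0, "Imax": 1.0, "IC50": 2.5, "n": 2.2},
    [0.0, 0.25, 0.5, 1.0, 2.0, 3.5, 5.0, 10.0],
    noise_cv=0.03, replicates=3, seed=7)

fit = DoseResponseModel(data, model="hill_inhibition").fit(n_starts=20, seed=7)
print(fit.summary())
```

```
Model: hill_inhibition
Observations: 24   RSS: 161.353   converged: True   starts: 21   seed: 7
parameter         estimate       std err
v0                 99.8827       1.02941
Imax                     1             0  (fixed)
IC50                2.4669     0.0614478
n                  2.13029     0.0974286
```

The fit recovers the generating IC₅₀ (2.47 vs 2.5 mM) and Hill coefficient
(2.13 vs 2.2) within their standard errors. The switch model then predicts
how much PII relieves inhibition at physiological NAD⁺:

```python
for pii in (0.0, 2.0):
    act = predicted_activity(HubState(NAD=2.5, PII_total=pii, NadE_total=0.1))
    print(f"PII {pii:>4.1f} uM trimer -> activity {act:5.1f} % at 2.5 mM NAD+")
```

```
PII  0.0 uM trimer -> activity  28.6 % at 2.5 mM NAD+
PII  2.0 uM trimer -> activity  47.1 % at 2.5 mM NAD+
```

Free enzyme sits on the hyperbola (28.6% activity at 2.5 mM NAD⁺); with
2 μM PII trimer, 86% of the enzyme is complexed and activity rises to 47%.

A thin CLI wraps the same library calls, e.g.

```bash
nadhub switch --nad 2.5 --pii 2 --nade 0.1 --og 50 --history preformed
# {"activity_percent": 46.972}
nadhub simulate genomes --seed 7 --out synthetic/
nadhub islands --meta synthetic/meta.tsv --contigs synthetic/contigs.tsv \
  --pii-hits synthetic/pii_hits.tsv --nade-hits synthetic/nade_hits.tsv
```

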