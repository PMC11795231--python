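# dentasym

Early-life developmental stress leaves a permanent record in the first
permanent molar (M1): its crown geometry is fixed by the end of the first
postnatal year and never remodels. Random left–right differences in crown
shape — *fluctuating asymmetry* (FA) — index developmental instability, so M1
FA can proxy early-life stress in both juvenile and adult skeletons.
`dentasym` is a Python toolkit for bioarchaeologists and biostatisticians who
want to measure that signal from 2D landmark data and relate it to later-life
skeletal inflammation (periosteal new bone formation, periodontal disease)
and mortality risk (age-at-death models).

## What it computes

**Shape and asymmetry.** Paired antimere digitizations (fixed anatomical
landmarks + 20 occlusal-outline semilandmarks, 3 replicates per tooth) are
read from TPS or delimited tables. Right antimeres are reflected, outline
semilandmarks slide along neighbour-chord tangents to minimise thin-plate-
spline bending energy, and all configurations enter one Generalized
Procrustes Analysis, then project to the tangent space at the mean. A
two-way mixed-model Procrustes ANOVA decomposes the tangent coordinates:

| effect           | meaning                | df          |
|------------------|------------------------|-------------|
| individual       | between-individual shape | I − 1     |
| side             | directional asymmetry  | 1           |
| individual × side| fluctuating asymmetry  | I − 1       |
| error            | digitizing error       | 2I(R − 1)   |

with F(FA) = MS(FA)/MS(error) and significance from residual-randomization
permutation (reduced-model residuals permuted across observations,
p = (1 + #{F\* ≥ F})/(n_perm + 1)). Per individual, replicates are averaged
and the FA score is ‖(L − R) − DA‖, where DA is the sample-mean left−right
difference; isomere scores average into a composite that is log-transformed
and z-standardised for modelling.

**Records and prevalence.** Skeletal records carry explicit observability for
every long bone and alveolar socket. Crude prevalence = affected /
assessable individuals; true prevalence = affected / observable elements.
PD grades (0–3) collapse to a moderate-severe class; PNBF classifies into
presence, activity (active dominates mixed cases) and laterality.

**Outcome models.** OLS on ln(age-at-death) and binary logistic models of
lesion classes, with bidirectional stepwise AIC selection, Wald intervals,
adjusted R² / McFadden pseudo-R², and effect transforms: a log-scale
coefficient b is a 100·(e^b − 1) percent change in age-at-death; a logit
coefficient is an odds ratio e^b.

**Synthetic data.** `simulate_landmarks` / `simulate_cohort` /
`simulate_study` generate the whole study with known ground truth —
individual, side, FA and error variance components in the landmark data; a
latent stress variable linking FA to cohort membership; lesion and age
models with the coefficient structure above. Every downstream stage can be
checked against planted parameters.

## Worked example

```python
from dentasym import LandmarkScheme, analyze_tooth_class, simulate_landmarks
from dentasym.synthetic_data import ShapeSimParams

scheme = LandmarkScheme.for_tooth("UM1")
config_set, truth = simulate_landmarks(
    ShapeSimParams(scheme=scheme, n_individuals=40, seed=7))
analysis = analyze_tooth_class(config_set, n_perm=499, seed=7)
print(analysis.anova.to_frame())
```

prints (see `examples/01_landmark_fa_analysis.py`):

```
        Effects  df     SS     MS     R2       F      p
            ind  39 1.3092 0.0336 0.8245  5.6829 0.0020
           side   1 0.0079 0.0079 0.0050  1.3322 0.1820
ind x side (FA)  39 0.2304 0.0059 0.1451 23.3609 0.0020
          error 160 0.0405 0.0003 0.0255     NaN    NaN
          total 239 1.5879    NaN    NaN     NaN    NaN
```

Read: individuals differ far more than sides (82% vs 0.5% of shape
variation); the FA interaction carries 14.5% and stands 23× above
digitizing error (2.6%), with permutation p = 0.002 — a significant,
measurable asymmetry signal. `analysis.scores` then holds the
per-individual FA scores that feed the outcome models
(`examples/03_outcome_models.py` shows the regression side: e.g. one SD of
FA predicting a +11.3% change in immature age-at-death, odds of bilateral
periosteal lesions ×2.85 per SD of FA in that simulated cohort).

The other examples cover prevalence arithmetic
(`02_prevalence_tables.py`) and the one-call reproducible pipeline with a
hashed run manifest (`04_full_pipeline.py`, or `dentasym run config.yaml`
from the shell).

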