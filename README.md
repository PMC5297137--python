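# linkvar

Probabilistic record linkage that exploits *variation* in identifier error
rates — across individuals and across the organisations that record the
data — instead of assuming errors strike uniformly at random.

`linkvar` is aimed at researchers linking administrative health records
(hospital admissions, demographic registers) on quasi-identifiers such as
date of birth, sex and postcode, and at methodologists studying how linkage
error biases downstream estimates such as hospital readmission rates.

## The method

A candidate record pair is summarised by its agreement pattern
φ ∈ {0,1}^k over k identifiers.  With m<sub>k</sub> = P(agree on k | match)
and u<sub>k</sub> = P(agree on k | non-match), the package computes four
match-weight families:

* **traditional** (Fellegi–Sunter, independence across identifiers):
  W = Σ<sub>k</sub> [ bit<sub>k</sub>·log₂(m<sub>k</sub>/u<sub>k</sub>) +
  (1−bit<sub>k</sub>)·log₂((1−m<sub>k</sub>)/(1−u<sub>k</sub>)) ]
* **joint**: probabilities estimated per full pattern,
  W = log₂(m<sub>φ</sub>/u<sub>φ</sub>), dropping the independence
  assumption;
* **attribute-specific**: traditional-form weights with m/u estimated
  separately in each (age cohort × sex × ethnic group) stratum — including
  attributes *not* used for matching;
* **organisation-specific**: m/u estimated per hospital, with a global
  fallback for thin strata.

Around the weights sit: a multilevel logistic model of identifier-error
risk (hospital random intercept, fitted by adaptive Gauss–Hermite
quadrature), pairwise error-dependence tests, funnel-plot control limits
for between-hospital comparison, threshold calibration at a target
false-match rate, and a simulation study that measures the readmission-rate
bias each weighting scheme incurs under non-random unique-identifier error.

## Worked example

Calibrating a cut-off at a 1% false-match rate and linking a synthetic
population of 20,000 individuals (`python examples/calibrate_and_link.py`):

```
traditional  cutoff   3.98  accepted   850  sensitivity 0.482  false-match rate 0.0000
attribute    cutoff   0.31  accepted  1657  sensitivity 0.930  false-match rate 0.0097
```

Both schemes keep the false-match rate at or below 1%, but the
attribute-specific weights nearly double sensitivity: they know that an
infant's postcode is usually missing, so a pair agreeing only on date of
birth and sex is still strong evidence *for that stratum*, while a single
global weight table has to reject the whole pattern class.

The downstream consequence (`python examples/bias_study.py`, scenario A =
30% of unique identifiers missing at random, 20 replicates):

```
      method scenario  pct_readmitted     se  pct_bias  sensitivity
 traditional        A           7.273  0.032   -16.817        0.843
       joint        A           7.274  0.032   -16.808        0.843
   attribute        A           7.628  0.049   -12.756        0.881
organisation        A           7.506  0.062   -14.157        0.867
```

The true readmission rate is 8.74%: missed matches split readmitted
patients into apparent single-admission patients, biasing every estimate
downward, but attribute- and organisation-specific weights recover a
substantial part of the loss.  Other examples cover m/u estimation and
weight tables (`estimate_weights.py`) and the multilevel error-risk model
with funnel limits (`error_model_fit.py`).

A thin CLI mirrors the library: `linkvar generate | estimate | link |
error-model | simulate` (see `linkvar --help`).

## Layout

```
src/linkvar/     core.py        schemas, agreement patterns, pair filtering
                 estimation.py  m/u probabilities, four weight families
                 error_model.py multilevel error-risk model, funnel limits
                 linkage.py     scoring, threshold calibration, metrics
                 simulate.py    synthetic data generator, bias study
                 io.py, cli.py  CSV/JSON/YAML I/O and the CLI
examples/        narrative scripts, one per capability
docs/methods.md  model assumptions, parameter defaults, design notes
```
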