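# imksurv

Cell-survival modelling for combined drug + radiation treatment, built
around the integrated microdosimetric-kinetic (IMK) description of
clonogenic survival with non-targeted (bystander) effects, extended with
a pharmacological term for the hyaluronan-synthesis inhibitor
4-methylumbelliferone (4-MU) acting as a radiosensitizer of HT1080
fibrosarcoma cells.

It is written for radiobiologists and medical physicists who want to
(i) fit the model to clonogenic survival tables, (ii) predict survival
under combinations of drug concentration, dose, dose rate and
fractionation, and (iii) compare fractionated regimens at an isoeffect
survival level.

## The model

The overall surviving fraction after one exposure at dose *D* (Gy) under
drug concentration *D*<sub>P</sub> (μM) factorizes into three independent terms,
*S* = *S*<sub>P</sub> · *S*<sub>T</sub> · *S*<sub>NT</sub>:

**Pharmacology** — a four-parameter log-logistic in concentration:

    S_P = S_Pmin + (S_Pmax − S_Pmin) / (1 + (D_P / ED50)^r_P),   S_Pmax = 1

**DNA-targeted kill** — linear-quadratic with a microdosimetric
correction and dose-protraction factor:

    −ln S_T = (α₀ + γβ₀) D + F β₀ D²
    F = 2[(a+c)T + e^−(a+c)T − 1] / ((a+c)T)²

where *T* is the delivery time, (*a*+*c*) the first-order
sublethal-damage repair rate (h⁻¹), and γ (Gy) the mean specific energy
per event for a 1 μm unit-density domain, γ ≈ 0.204 · *y*<sub>D</sub> / *d*²
from the dose-mean lineal energy *y*<sub>D</sub> (keV/μm).

**Non-targeted (bystander) kill** — lethal lesions proportional to the
product of signal activation and non-activation probabilities:

    −ln S_NT = δ(D_P) · (1 − p) · p,    p = e^{−(α_b + γβ_b) D − β_b D²}

with the lesion ceiling δ rising log-logistically from δ_min to δ_max in
drug concentration, sharing its midpoint ED50 with the pharmacology
term. The bound −ln S_NT ≤ δ/4 (equality at p = ½) makes bystander kill
an intermediate-dose effect, which is what concentrates the drug's
benefit at conventional 2 Gy fractions.

Fractionated courses of *n* identical fractions of *d* Gy accumulate
lesions linearly (24 h intervals, full inter-fraction repair, no
proliferation), with *S*<sub>P</sub> applied once per course; isoeffect total
doses for a target survival *S*<sub>c</sub> follow in closed form.

Parameters are estimated by maximum likelihood (Gaussian on log
survival) with seeded Latin-hypercube multi-start and bounded
trust-region refinement; (*a*+*c*) is boxed to the literature interval
2.18–2.23 h⁻¹. Fit quality is reported as the size-adjusted
determination coefficient R².

## Worked example

```python
import imksurv as ik

params = ik.ht1080_table1()          # packaged fitted parameter set

# survival after an acute 4 Gy exposure, with and without 100 uM 4-MU
ik.combined_survival(ik.Exposure(dose=4, acute=True), params)
# 0.17046354275131076
ik.combined_survival(ik.Exposure(dose=4, concentration=100, acute=True), params)
# 0.022782787195945738

# total dose reaching the 1e-5 survival level at 2 Gy/fraction
q = ik.IsoeffectQuery(target_survival=1e-5, dose_per_fraction=2, concentration=100)
ik.isoeffect_total_dose(q, params).total_dose
# 15.481545319022265
```

At 4 Gy the drug cuts survival from 0.170 to 0.023 — a factor ~7.5,
far beyond its own toxicity (S_P(100 μM) ≈ 0.466) because the bystander
ceiling δ rises from 0.76 to 5.76 lesions/nucleus at 100 μM. The same
mechanism shortens a 2 Gy/fraction course to the 10⁻⁵ level from
36.9 Gy (no drug) to 15.5 Gy (100 μM), while at 10 Gy/fraction the
spread across drug levels is only ≈1.3 Gy (run
`python analysis/04_isoeffect.py`).

The numbered scripts under `analysis/` reproduce the full pipeline —
simulate the 37-condition synthetic dataset, fit the 11 free
parameters, tabulate survival curves, and solve the regimen isoeffect
doses — writing their tables under `results/`. The same operations are
available from the `imksurv` command line (`simulate`, `fit`,
`predict`, `isoeffect`, `regimen`, `gamma`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged parameter set, the total doses at
2 Gy/fraction that bring course survival to 10⁻⁵ for 0, 80 and 100 μM
4-MU (continuous fraction-number solve; both the acute-F and the
1 Gy/min protraction conventions are evaluated, the latter reported).

## Layout

* `src/imksurv/` — model core, fractionation, fitting, synthetic data,
  I/O and CLI
* `analysis/` — numbered pipeline drivers writing to `results/`
* `docs/methods.md` — modelling assumptions, numerical choices, and
  known identifiability limits of the 37-point design
* `tests/` — unit, property and acceptance suites
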