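# renalnmp

Assessment of ex-vivo kidney function during normothermic machine perfusion
(NMP), for transplantation researchers who ask whether blood, urine and
hemodynamic measurements taken while an organ is perfused outside the body
can predict its functional quality before implantation.

During four hours of pressure-controlled NMP, a kidney is perfused with
oxygenated autologous blood while renal blood flow (RBF), arterial pressure
(AP) and organ temperature are logged continuously, arterial/venous blood
gases are sampled every 20 min, and urea, urine volume and glutathione
S-transferase (GST, a tubular-injury enzyme) every 60 min. From these raw
measurements the package derives eleven function and injury markers, locates
the critical oxygen-supply thresholds, screens markers for differences
between three reference function classes (nonfunctional / limited /
functional, defined by inulin clearance and taken as given), removes
multicollinear markers, and benchmarks five classifiers for three-class
function prediction. A synthetic cohort generator emulates the full
measurement schedule with class-conditional physiology, so every stage is
testable and reproducible without animal data.

## The markers and the model

Oxygen metabolism follows the Fick principle. With the per-kidney median
hemoglobin c(Hb) in g/dL:

    C_aO2 = 1.34 · c(Hb) · S_aO2/100 + 0.0031 · p_aO2      [mL O2/dL]
    DO2   = RBF · C_aO2                                     oxygen delivery
    V̇O2   = RBF · (C_aO2 − C_vO2)                           oxygen consumption
    ERO2  = V̇O2 / DO2                                       oxygen extraction
    CO2P  = RBF · (C_vCO2 − C_aCO2)                         CO2 production
    IRR   = AP / RBF                                        intrarenal resistance

with whole-blood CO2 content from the Douglas model, every flow marker
normalized to 100 g kidney weight, and hemodynamic values read as window
means over analysis time ± 2 min. Filtration and injury markers are
baseline-relative urea, per-interval urine production and baseline-relative
GST.

The extraction–delivery relation is biphasic: extraction is roughly constant
while delivery is adequate and rises steeply below a critical delivery.
`fit_two_segment` estimates the elbow by exhaustive-breakpoint two-segment
least squares; `propagate_critical` chains the remaining thresholds (the
critical flow from the RBF~DO2 line, the critical consumption as
ERO2_crit·DO2_crit, the critical pressure as the smaller real root of the
quadratic RBF~AP fit).

Significance screening routes every (marker, time) cell by Shapiro–Wilk
normality and Levene homoscedasticity to classical ANOVA with Bonferroni
post hocs, Welch ANOVA with Games–Howell, or Kruskal–Wallis with
Dunn–Šidák. Multicollinearity is removed by iterative variance-inflation
filtering (VIF = diagonal of the inverse correlation matrix; the maximum is
removed until all VIF ≤ 10). Classifiers (linear SVM, 20-tree random
forest, 5-NN, logistic regression, Gaussian naive Bayes) are validated with
kidney-grouped leave-one-out folds and a stratified 77/23 holdout, on five
feature variants that restrict the significant (marker, time) cells to 240,
180, 120 or 60 min of perfusion.

## Worked example

```
$ python examples/critical_thresholds.py
DO2_crit  = 1.7  mL/min/100 g   (raw 1.7427)
ERO2_crit = 51   %              (raw 51.33)
RBF_crit  = 23   mL/min/100 g   (raw 23.30)
VO2_crit  = 0.9  mL/min/100 g   (raw 0.895)
AP_crit   = 155  mmHg           (raw 154.3)
```

Starting from the fitted extraction/delivery segments, delivery below
1.7 mL O2/min/100 g forces extraction above 51% — the supply-limited
regime; keeping flow above 23 mL/min/100 g (which requires arterial
pressure below 155 mmHg in the fitted autoregulation curve) keeps the organ
supply-adequate. The remaining scripts in `examples/` walk through cohort
simulation, marker derivation, significance screening, VIF filtering and
the classifier bench; the full pipeline is also available from the shell:

```
renalnmp run --seed 1 --out-dir nmp_out
```

which writes the cohort CSVs, marker tables, critical-point JSON,
significance map, VIF removal log, feature matrices and benchmark report.

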