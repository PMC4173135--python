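# qepest

Quantitative estimates of pesticide-likeness: continuous 0–1 scores for
how well a molecule matches the physicochemical profile of herbicides
(QEH), insecticides (QEI) and fungicides (QEF), plus the fusion scores
QEP<sub>max</sub> and QEP<sub>avg</sub>, alongside the classical
rule-based agrochemical filters (Lipinski, Tice, Hao).

It is aimed at agrochemical discovery teams triaging large compound
libraries: instead of the hard pass/fail boundaries of rule-based
filters, a desirability score ranks molecules continuously, so a library
can be cut to any desired size at any level of pesticide-likeness.

## The method

Six descriptors are computed per molecule: molecular weight (MW),
octanol–water log partition coefficient (LogP), hydrogen-bond acceptor
and donor counts (HBA, HBD), rotatable bonds (RB) and aromatic rings
(arR).  For each descriptor *i* and pesticide class, a shared
Gumbel-like peak

&nbsp;&nbsp;&nbsp;&nbsp;*f*(*x*) = *o* + *a* · exp( −exp(−(*x*−*b*)/*c*) − (*x*−*b*)/*c* + 1 )

is fitted by least squares to the class's descriptor histogram
(continuous descriptors are binned at the Shimazaki–Shinomoto optimal
width, count descriptors at unit width).  Dividing by the analytic
maximum *o* + *a* gives a desirability *df*<sub>*i*</sub> ∈ [0, 1] that
equals 1 at the mode *b*.  The class score is the unweighted
Derringer–Suich geometric mean

&nbsp;&nbsp;&nbsp;&nbsp;QEX = exp( (1/6) Σ<sub>*i*</sub> ln *df*<sub>*i*</sub> ),&nbsp;&nbsp;X ∈ {H, I, F},

with QEX = 0 whenever any *df*<sub>*i*</sub> = 0 (one unacceptable
property makes the compound unacceptable).  Finally
QEP<sub>max</sub> = max(QEH, QEI, QEF) and QEP<sub>avg</sub> is their
arithmetic mean.

The packaged default coefficient profiles are fitted on this package's
*synthetic* reference populations (the original training compound sets
are proprietary); they reproduce the method, not the original
coefficient values.  Fit your own profiles with `qepest fit` whenever a
labeled compound set is available, or supply any coefficient JSON via
`--profiles`.

## Worked example

```
qepest synth --out data --n 2000 --seed 7      # synthetic populations + fixtures
qepest score --input data/fixtures.smi --out fixture_scores.csv
head -2 fixture_scores.csv
```

```
id,MW,LogP,HBA,HBD,RB,arR,QEH,QEI,QEF,QEPmax,QEPavg
benzene,78.114,1.687,0,0,0,1,0.0002,0.0238,0.1312,0.1312,0.0517
```

Benzene is far too small and featureless to look like a pesticide:
every class score is near zero and QEP<sub>max</sub> = 0.13.  Real
pesticides in the fixture set score much higher —

```
atrazine,215.688,1.777,5,2,4,1,0.5553,0.2711,0.5508,0.5553,0.4591
2,4-D,221.039,2.457,2,1,3,1,0.4818,0.4034,0.7780,0.7780,0.5544
```

the herbicides atrazine and 2,4-D reach QEP<sub>max</sub> of 0.56 and
0.78 under the (synthetic-reference) default profiles.  The rule-based
filters run the same way:

```
qepest filter --input data/class_H.csv --out filters.csv --summary
lipinski: 83.35% pass
tice_herbicide: 56.60% pass
tice_insecticide: 67.60% pass
hao: 47.80% pass
```

`qepest fit --input <csv|smi|sdf> --class H --out profiles.json` fits a
class profile from your own compound set, and
`qepest evaluate --scores labeled.csv --out roc.csv` reports ROC/AUC
for any score column against binary labels.

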