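# pepqsar

Quantitative structure–activity relationship (QSAR) modelling for short
antioxidant peptides, built for peptide chemists and cheminformaticians
who want a reproducible route from a peptide–activity table to a
validated model, a residue-contribution map, and ranked candidates for
synthesis.

## The model

A tripeptide is encoded position-wise against a panel of amino-acid
property scales (AAindex1 format): with `n = 3` positions and `m`
scales, each peptide becomes `n × m` descriptors `V_jk` — the value of
property `k` for the residue at position `j` (585 descriptors for the
classical 195-scale panel). After autoscaling descriptors and response,
stepwise regression (probability-of-F to enter 0.05, to remove 0.10)
screens the descriptors, variance inflation factors `VIF = 1/(1 − r²)`
check the screened set for collinearity, and four regression methods are
fitted on it: MLR, PLS, ε-SVR (RBF kernel), and random forest.

Validation reports the standard chemometric bundle per model:

- `R²` — squared Pearson correlation of observed vs calculated/predicted,
- `SD = √(RSS/(n − m − 1))` and `F = (R²/m)/((1 − R²)/(n − m − 1))`,
- `PRESS = Σ(yᵢ − ŷ₍₋ᵢ₎)²` from leave-one-out refits and
  `Q² = 1 − PRESS/SS_total`, plus seeded k-fold Q² for k ∈ {4, 6, 10},
- `R²_test` on a descending-activity 1-in-3 hold-out split.

Because fitting happens on standardized variables, linear coefficients
are normalized regression coefficients, and the per-residue,
per-position contribution map
`contribution(a, j) = Σ NRC(v) · z(a)` decomposes every prediction
exactly into residue effects — the basis for model-guided design.
Free-radical assay quantitation (DPPH %, TEAC via a trolox standard
curve, FRAP via an FeSO₄ curve) turns raw plate absorbances into the
µM-equivalent-per-µM-peptide activities the models consume.

## Worked example

```python
import numpy as np
from pepqsar import (autoscale, encode_peptides, fit_mlr, split_train_test,
                     stepwise_select, summarize, vif,
                     residue_contributions, rank_residues)
from pepqsar.synthetic import default_properties, generate_peptide_dataset

panel = default_properties()                       # 20 scales -> 60 descriptors
dataset = generate_peptide_dataset(seed=1, properties=panel)   # 91 tripeptides
train, test = split_train_test(dataset.peptides)               # 60 / 31

y_train = np.array([p.activity for p in train])
y_test = np.array([p.activity for p in test])
Z, scaling = autoscale(encode_peptides(train, panel),
                       activities=y_train, scale_response=True)
Z_test = scaling.transform(encode_peptides(test, panel))

sel = stepwise_select(Z, scaling.scale_y(y_train))
sel.vifs = vif(Z[sel.selected])
model = fit_mlr(Z[sel.selected], scaling.scale_y(y_train), scaling)
metrics = summarize(model, Z, y_train, Z_test, y_test)

table = residue_contributions(model, panel)
ranks = rank_residues(table, top_k=3)
```

Output:

```
selected: ['CHAM820102_p3', 'LEVM760107_p1', 'FAUJ880112_p2', 'CHAM820102_p1']
max VIF: 1.21
R2_train=0.985  SD=0.060  F=927.3  Q2_LOO=0.983  PRESS=0.227  R2_test=0.985
position 3 predominant: ['W', 'Y', 'C']
position 3 deleterious: ['D', 'M', 'P']
```

Reading it: the screen found the three descriptor columns the synthetic
ground truth was built from (plus one correlated extra), all mutually
uncorrelated (VIF < 2). The model generalizes (Q²_LOO ≈ R²_train), and
the contribution map recovers the planted chemistry — aromatic/thiol
residues (Trp, Tyr, Cys) favourable at the C-terminus, Asp/Met/Pro
deleterious there. `enumerate_candidates` + `score_candidates` then rank
e.g. all 1200 `**[WYC]` tripeptides by predicted activity for synthesis
triage.

The same workflow is available from the shell:

```
pepqsar pipeline --config config.yaml     # split -> screen -> fit -> design
pepqsar simulate peptides --seed 1 --out run/
pepqsar assay --type teac --plate plate.csv --out results.csv
```

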