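# qsarligand

A ligand-based QSAR toolkit for small-molecule **TLR7 antagonist** design.
Over-activation of Toll-like receptor 7 drives several autoimmune
disorders, and no small-molecule antagonist is yet in clinical use; this
package implements the quantitative structure–activity machinery used to
design such compounds from reported inhibitory activities (IC50 against a
reporter cell line, modelled as pIC50 = −log10 IC50/µM).

It is aimed at computational/medicinal chemists who want a transparent,
tested, scriptable implementation of:

- **Formula-level 2D descriptors** — the five descriptors of the published
  activity model, each built from its defining formula on the molecular
  graph: the distance/detour eigenvector descriptor VE3sign_D/Dt, the
  intrinsic-state Burden eigenvalue SpMin2_Bh(s), the logP-binned Van der
  Waals surface area P_VSA_logP_5, the dipole-weighted edge-adjacency
  eigenvalue Eig02_EA(dm), and the acceptor-pair count CATS2D_09_AA.
- **MLR model building** — OLS fitting, the frozen published model

      pIC50 = −6.2155 + 0.1409·VE3sign_D/Dt + 4.1832·SpMin2_Bh(s)
              + 0.0366·P_VSA_logP_5 − 0.9329·Eig02_EA(dm) − 0.1016·CATS2D_09_AA

  genetic-algorithm variable subset selection maximizing Q²_LOO, the
  similarity/inter-correlation descriptor pre-filter and the
  sorted-response 70:30 split.
- **Validation** — R², R²adj, RMSE, MAE, s, F, LOF, CCC; leave-one-out and
  leave-many-out cross-validation; Y-scrambling; external Q²_F1/Q²_F2/Q²_F3,
  CCC_ext and r²m metrics.
- **Applicability domain** — leverages, h* = 3(k+1)/n, Williams-plot and
  Insubria-plot data with 2.5σ residual flags.
- **Grid-field 3D-QSAR** — steric (LJ carbon probe, 1.73 Å) and
  electrostatic (+1 probe, ε(r) = r) fields on a shared 1.4 Å grid, PLS
  with LOO validation and contour-coefficient export.
- **Activity arithmetic** — pIC50↔IC50 conversions, the four-class potency
  scale, signed error factors and pharmacophore cost-difference banding.
- **Synthetic data** — a seeded generator producing 54-compound drug-like
  datasets with the statistical structure the analysis assumes, so the
  entire pipeline is testable without any external download.

See `docs/methods.md` for the models, conventions and design choices.

## Worked example

```python
import warnings
from qsarligand import parse_smiles, descriptor_vector, published_tlr7_model, predict
import pandas as pd

mol = parse_smiles("c1cc2c(cc1OC)ncnc2N1CCN(CCO)CC1", "quinazoline-piperazine")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    v = descriptor_vector(mol)
print(v.as_dict())
# {'VE3sign_D_Dt': -0.791, 'SpMin2_Bh_s': -0.8048, 'P_VSA_logP_5': 134.5031,
#  'Eig02_EA_dm': 2.8617, 'CATS2D_09_AA': 1}

model = published_tlr7_model()
pic50 = predict(model, pd.DataFrame([v.as_dict()]))[0]
print(round(pic50, 3))   # -7.542
```

The descriptor dictionary holds the five model inputs (P_VSA in Å²,
CATS2D a pair count, the rest dimensionless); the prediction is a pIC50 in
log-µM units under this package's descriptor conventions — conventions for
the proprietary descriptor tool's tables differ, so absolute predictions
are only comparable within one implementation (see `docs/methods.md`).

A full pipeline run on synthetic data (generate → split 38/16 → fit →
validate → domain check):

```bash
python examples/02_fit_and_validate.py
# split: 38 train / 16 test
# fit:      R2=0.918  R2adj=0.906  RMSE=0.250 s=0.272  F=72.0  CCC=0.957
# internal: Q2_LOO=0.884  RMSE_cv=0.298  Q2_LMO=0.879  R2Yscr=0.131  Q2Yscr=-0.235
# external: RMSE_ext=0.208  R2_ext=0.906  Q2_F1=0.855  Q2_F2=0.855  Q2_F3=0.944 ...
```

A robust model shows Q²_LOO close to R², scrambled-response means far
below both (Q²Yscr < 0), and external Q²_F metrics above ~0.6. The other
`examples/` scripts cover descriptors, the applicability domain, the
3D-QSAR fields and the activity arithmetic, one capability each.

## Command line

```bash
qsarligand simulate --n 54 --sigma 0.30 --seed 1 --out run/
qsarligand descriptors --in run/mols.smi --out run/desc.csv
qsarligand fit --desc run/desc.csv --act run/act.csv --ga --seed 1
qsarligand validate --model model.json --train run/desc.csv --act run/act.csv
qsarligand ad --model model.json --train run/desc.csv --act run/act.csv
qsarligand run --config config.yaml     # the whole workflow, one config
```

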