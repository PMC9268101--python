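"""Leverage-based applicability domain on a synthetic model.

Builds a training design, fits the model and prints the Williams-plot
summary (h* threshold, flagged compounds) plus the Insubria in-domain check
for two hypothetical new compounds — one interpolated, one extrapolated.
"""

import warnings

import pandas as pd

from qsarligand.app_domain import insubria_data, williams_data
from qsarligand.model_core import fit_mlr, split_sorted_response
from qsarligand.synthetic_data import SyntheticSpec, generate_2d_dataset

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    mols, desc, acts, _ = generate_2d_dataset(SyntheticSpec(seed=7))
train_ids, test_ids = split_sorted_response(acts[["pIC50"]])
X_tr, y_tr = desc.loc[train_ids], acts.loc[train_ids, "pIC50"].to_numpy()
X_te, y_te = desc.loc[test_ids], acts.loc[test_ids, "pIC50"].to_numpy()
model = fit_mlr(X_tr, y_tr)

w = williams_data(model, X_tr, y_tr, X_te, y_te)
print(f"h* = {w.attrs['h_star']:.3f}, sigma band = {w.attrs['sigma_limit']}")
print(f"high-leverage compounds: {list(w[w['high_leverage']]['id'])}")
print(f"residual outliers:       {list(w[w['residual_outlier']]['id'])}")

new = pd.concat(
    [X_tr.iloc[[0]].rename(index={X_tr.index[0]: "interpolated"}),
     (X_tr.iloc[[1]] * 6).rename(index={X_tr.index[1]: "extrapolated"})]
)
ins = insubria_data(model, X_tr, new)
print("\nnew-compound domain check (Insubria):")
print(ins.to_string(index=False))
print(
    "\nPredictions are only trustworthy for compounds with leverage "
    "h <= h*; the extrapolated row falls outside the domain."
)
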