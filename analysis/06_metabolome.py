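#!/usr/bin/env python
"""Metabolome modelling in the early-enrollment stratum.

Fits a two-component PLS model of age + treatment on V3+V6 metabolite
profiles, validates it by venetian-blind Q2Y and Y-permutation, computes VIP
and p(corr) (treatment component), runs per-metabolite WMW tests, applies the
discriminant rule (VIP > 1, |p(corr)| > 0.2, WMW p < 0.05), and analyses
bile-acid conjugation ratios with within-arm baseline-shift tests.  Writes
results/metabolome/.
"""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from fctpath.metabolome import (baseline_shift_tests, bile_acid_ratios,
                                fit_pls, p_corr, select_discriminant,
                                validate_pls, vip)
from fctpath.stats import wmw_test
from fctpath.tables import MetaboliteMatrix, SampleTable

IN, OUT = Path("results/cohort"), Path("results/metabolome")
SEED = 11
VISITS = ("V3", "V6")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    metadata = SampleTable.from_tsv(IN / "metadata.tsv")
    meta = metadata.frame.set_index("sample_id")
    mtb = MetaboliteMatrix.from_tsv(IN / "metabolites.tsv").concentrations

    ee = meta[(meta["stratum"] == "EE") & meta["visit"].isin(VISITS)]
    X = mtb.loc[mtb.index.intersection(ee.index)]
    ee = ee.loc[X.index]
    Y = np.column_stack([ee["age"].to_numpy(float),
                         (ee["arm"] == "test").to_numpy(float)])
    print(f"PLS on {len(X)} EE samples at {'+'.join(VISITS)}, "
          f"{X.shape[1]} metabolites; Y = (age, treatment)")

    model = fit_pls(X.to_numpy(), Y, n_components=2, feature_ids=list(X.columns))
    q2, perm_p = validate_pls(X.to_numpy(), Y, n_components=2, folds=7,
                              n_permutations=200, seed=SEED)
    print(f"R2Y = {model.r2y:.3f}, Q2Y = {q2:.3f}, permutation p = {perm_p:.4f}")
    (OUT / "pls_validation.json").write_text(json.dumps(
        {"r2y": model.r2y, "q2y": q2, "permutation_p": perm_p,
         "explained_y_variance": model.explained_y_variance.tolist()}, indent=2))

    vips = vip(model)
    pcorr = p_corr(model, X.to_numpy(), component=2)
    wmw_ps = pd.Series({
        m: wmw_test(X.loc[ee["arm"] == "control", m].dropna(),
                    X.loc[ee["arm"] == "test", m].dropna())
        for m in X.columns})
    decisions = select_discriminant(vips, pcorr, wmw_ps)
    decisions.reset_index().to_csv(OUT / "metabolite_decisions.tsv",
                                   sep="\t", index=False)
    sel = decisions[decisions["selected"]]
    print(f"\n{len(sel)} discriminant metabolites "
          f"(VIP > 1, |p(corr)| > 0.2, WMW p < 0.05):")
    print(sel.head(15).to_string(float_format=lambda v: f"{v:.3f}"))

    ratios = bile_acid_ratios(mtb)
    ratios.to_csv(OUT / "bile_acid_ratios.tsv", sep="\t",
                  index_label="sample_id")
    ee_all = meta[meta["stratum"] == "EE"]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in ratios.columns:
            for arm in ("control", "test"):
                ps = baseline_shift_tests(
                    ratios.loc[ratios.index.intersection(ee_all.index), name],
                    metadata, arm)
                for visit, pval in ps.items():
                    rows.append({"ratio": name, "arm": arm, "visit": visit,
                                 "p_vs_V0": pval})
    shifts = pd.DataFrame(rows)
    shifts.to_csv(OUT / "bile_acid_baseline_shifts.tsv", sep="\t", index=False)
    print("\nbaseline-shift p-values for the total conjugation ratio (EE):")
    print(shifts[shifts["ratio"] == "ba_cba"]
          .pivot(index="visit", columns="arm", values="p_vs_V0")
          .to_string(float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
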