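"""Reanalysis of a deposited per-molecule property table (requires download).

The processed data for the 92-liquid study are archived on Zenodo
(accession 10.5281/zenodo.15236880).  This script is offline-safe: it takes
a locally downloaded CSV and recomputes the table-level aggregates —
maximum Δ_vm, mean Δ_κT, mean isotope effect on κ_T, the LOO R² of the
composite model, and the paired one-tailed t-test of |deviation from
experiment| for PI vs classical molar volumes.

Expected columns (percent units for deltas, fractions are also accepted):
    name, m_w, n_H, alpha_P, delta_vm, delta_kappa_T, isotope_delta_kappa_T
and optionally: vm_cl, vm_pi, vm_exp  (cm³/mol) for the t-test.

Usage:  python examples/zenodo_reanalysis.py path/to/table.csv
"""

import sys

import numpy as np
import pandas as pd

from nqeliq.ml_pipeline import build_feature_table, loo_evaluate
from nqeliq.nqe_stats import paired_one_tailed_ttest


def main(path: str) -> None:
    df = pd.read_csv(path)
    scale = 1.0 if df["delta_vm"].abs().max() > 1.0 else 100.0  # % vs fraction
    print(f"max Delta_vm        = {scale * df['delta_vm'].max():6.2f} %")
    if "delta_kappa_T" in df:
        print(f"mean Delta_kappa_T  = {scale * df['delta_kappa_T'].mean():6.2f} %")
    if "isotope_delta_kappa_T" in df:
        print("mean isotope effect on kappa_T = "
              f"{scale * df['isotope_delta_kappa_T'].mean():6.2f} %")
    table = build_feature_table(
        df[["name", "m_w", "n_H", "alpha_P", "delta_vm"]].assign(
            delta_vm=df["delta_vm"] / (100.0 / scale if scale == 1.0 else 1.0)
        )
    )
    res = loo_evaluate(table, n_seed_iterations=5)
    print(f"composite LOO R^2   = {res['r2_mean']:.3f} +- {res['r2_sem']:.3f}")
    if {"vm_cl", "vm_pi", "vm_exp"} <= set(df.columns):
        t, p = paired_one_tailed_ttest(
            (df["vm_pi"] - df["vm_exp"]).abs(), (df["vm_cl"] - df["vm_exp"]).abs()
        )
        print(f"paired one-tailed t-test (PI closer to experiment): "
              f"t = {t:.2f}, p = {p:.2e}")


if __name__ == "__main__":
    if len(sys.argv) != 2:
        sys.exit(__doc__)
    main(sys.argv[1])
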