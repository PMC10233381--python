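#!/usr/bin/env python
"""Worked quantification examples: co-IP western fold change and ddCt qPCR.

Evaluates the ratio-of-ratios densitometry fold change on a worked band
table and the comparative-CT relative expression on a worked CT table, and
writes both under ``results/``.
"""

from pathlib import Path

import pandas as pd

from rbpcoreg.quantify import BandQuant, CtCondition, ddct_expression, western_fold_change

ROOT = Path(__file__).resolve().parents[1]


def run() -> None:
    subject = BandQuant(ip_x=4.0, input_x=2.0, ip_ref=2.0, input_ref=2.0, loading=1.0)
    control = BandQuant(ip_x=1.0, input_x=1.0, ip_ref=1.0, input_ref=1.0, loading=1.0)
    fc = western_fold_change(subject, control)
    print(f"[05] western ratio-of-ratios fold change (subject vs control): {fc:.3f}")

    test = CtCondition(ct_target=(20.1, 20.0, 19.9), ct_housekeeping=(18.0, 18.1, 17.9))
    calib = CtCondition(ct_target=(22.0, 21.9, 22.1), ct_housekeeping=(18.0, 18.0, 18.0))
    expr = ddct_expression(test, calib)
    print(f"[05] ddCt relative expression (test vs calibrator): {expr:.3f}")

    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    pd.DataFrame([
        {"quantity": "western_fold_change", "value": round(fc, 6)},
        {"quantity": "ddct_relative_expression", "value": round(expr, 6)},
    ]).to_csv(outdir / "05_quantification.tsv", sep="\t", index=False)


if __name__ == "__main__":
    run()
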