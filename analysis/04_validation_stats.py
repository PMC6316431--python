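#!/usr/bin/env python
"""Validation statistics on the normalized run: the PSA-like sex contrast
(median/IQR per sex, rank-sum test) and Pearson correlations between the
platform and the simulated reference immunoassay for the three-analyte
panel.

Writes results/validation/validation_report.json.
"""

import json
from pathlib import Path

import pandas as pd

from somaqc.io import read_dataset_dir
from somaqc.simulate import ElisaTable
from somaqc.stats import group_compare, validate_against_reference

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "validation"
    out.mkdir(parents=True, exist_ok=True)
    norm = read_dataset_dir(ROOT / "normalized")
    summary = json.loads((ROOT / "sim" / "sim_summary.json").read_text())

    gc = group_compare(norm, summary["sex_marker"], grouping="sex")
    m, f = gc.groups["M"], gc.groups["F"]
    print(f"sex marker {gc.analyte}: male median {m['median']:.1f} "
          f"({m['q25']:.1f} to {m['q75']:.1f}), female median {f['median']:.1f} "
          f"({f['q25']:.1f} to {f['q75']:.1f}) RFU, rank-sum p = {gc.p_two_sided:.4g}")

    elisa = ElisaTable(values=pd.read_csv(ROOT / "sim" / "elisa.tsv", sep="\t"))
    results = validate_against_reference(norm, elisa, quantile=True)
    lam = summary["elisa_panel"]
    for res in sorted(results, key=lambda r: -lam[r.analyte]["lambda"]):
        print(f"{res.analyte} (lambda={lam[res.analyte]['lambda']}): "
              f"r = {res.pearson_r:.2f}, p = {res.p_two_sided:.3g}, n = {res.n}")

    payload = {
        "group_comparisons": [gc.to_dict()],
        "correlations": [r.to_dict() for r in results],
    }
    (out / "validation_report.json").write_text(json.dumps(payload, indent=1) + "\n")


if __name__ == "__main__":
    main()
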