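#!/usr/bin/env python
"""Simulate the study-scale run: 2 plates, ~21 study samples, the full
1317-protein menu with 12 hybridization and 5 negative controls, default
bias ranges, and a paired reference-assay table for three analytes in the
well-correlated / intermediate / epitope-mismatched regimes.

Writes the raw dataset, ground truth summary and reference table under
results/sim/.
"""

import json
from pathlib import Path

import numpy as np

from somaqc.io import write_dataset
from somaqc.simulate import SimConfig, simulate_dataset, simulate_elisa

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 20180071


def main() -> None:
    config = SimConfig(seed=SEED)
    dataset, truth = simulate_dataset(config)
    write_dataset(dataset, OUT)

    # validation panel: one FGF23-like (shared epitope), one intermediate,
    # one FGFR1-like (isoform mismatch) analyte among the well-varying ones
    candidates = truth.analyte_sd_log2.drop(truth.sex_effect_analyte)
    panel = list(candidates.sort_values(ascending=False).index[:3])
    lam = dict(zip(panel, (0.97, 0.5, 0.2)))
    cv = {a: 0.05 for a in panel}
    slope = dict(zip(panel, (1.3, 7.8, 0.7)))  # arbitrary pg/mL scales
    elisa = simulate_elisa(truth, dataset, panel, lam, cv, slope, seed=SEED + 1)
    elisa.values.to_csv(OUT / "elisa.tsv", sep="\t", index=False,
                        float_format="%.17g", lineterminator="\n")

    summary = {
        "seed": SEED,
        "n_samples": len(dataset.samples),
        "n_study": len(dataset.sample_ids("study")),
        "n_analytes": len(dataset.analytes),
        "sex_marker": truth.sex_effect_analyte,
        "elisa_panel": {a: {"lambda": lam[a], "noise_cv": cv[a]} for a in panel},
        "hyb_bias_range_injected": [float(truth.h.min()), float(truth.h.max())],
        "negative_control_mean_rfu": float(
            np.mean(dataset.rfu[dataset.negative_control_ids].to_numpy())
        ),
    }
    (OUT / "sim_summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    print(f"simulated {summary['n_samples']} wells x {summary['n_analytes']} analytes -> {OUT}")
    print(f"sex marker: {summary['sex_marker']}; ELISA panel: {panel}")
    print(f"negative-control mean RFU: {summary['negative_control_mean_rfu']:.1f}")


if __name__ == "__main__":
    main()
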