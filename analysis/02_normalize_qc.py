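#!/usr/bin/env python
"""Run the three-stage normalization cascade on the simulated run from
01_simulate.py, check how well each stage recovers its injected bias, and
apply the printed QC criteria.

Writes scale factors and the QC report under results/normalized/, and a
recovery summary to results/normalized/recovery.json.
"""

import json
from pathlib import Path

import numpy as np

from somaqc.io import read_dataset_dir, write_dataset
from somaqc.normalize import (
    calibration_normalize,
    hybridization_normalize,
    median_signal_normalize,
)
from somaqc.qc import qc_summary
from somaqc.simulate import SimConfig, simulate_dataset
from somaqc.stats import pearson

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20180071


def main() -> None:
    dataset = read_dataset_dir(ROOT / "sim")
    # regenerate the ground truth (deterministic) to score recovery
    _, truth = simulate_dataset(SimConfig(seed=SEED))

    d1, hyb = hybridization_normalize(dataset)
    d2, med = median_signal_normalize(d1)
    d3, cal = calibration_normalize(d2)

    out = ROOT / "normalized"
    write_dataset(d3, out)
    hyb.to_tsv(out / "scale_factors_hyb.tsv")
    med.to_tsv(out / "scale_factors_median.tsv")
    cal.to_tsv(out / "scale_factors_calibration.tsv")

    report = qc_summary(d3, hyb, med, cal)
    report.to_json(out / "qc_report.json")
    report.to_tsv(out / "qc_report.tsv")

    r, _ = pearson(np.log(hyb.hyb.loc[truth.h.index]), -np.log(truth.h))
    st = dataset.samples
    cvs = {}
    for plate in dataset.plate_ids:
        study = st.index[(st["sample_type"] == "study") & (st["plate_id"] == plate)]
        for b in ("0.005%", "1%", "40%"):
            prod = med.median.loc[study, b] * truth.m.loc[study, b]
            cvs[f"{plate}:{b}"] = float(prod.std() / prod.mean())

    recovery = {
        "hyb_sf_vs_inverse_bias_pearson_r": float(r),
        "pipetting_recovery_cv_by_plate_bin": cvs,
        "qc_counts": report.counts,
    }
    (out / "recovery.json").write_text(json.dumps(recovery, indent=1) + "\n")

    c = report.counts
    print(f"hybridization recovery: r(log SF, -log h) = {r:.5f}")
    print(f"pipetting recovery CV (worst plate x bin): {100*max(cvs.values()):.2f}%")
    print(f"QC: {c['samples_passed']}/{c['samples_total']} samples, "
          f"{c['plates_passed']}/{c['plates_total']} plates, "
          f"{c['analytes_passed']}/{c['analytes_total']} analytes passed")


if __name__ == "__main__":
    main()
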