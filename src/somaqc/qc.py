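"""Acceptance criteria for scale factors and the assembled QC report.

The platform's printed pass criteria: hybridization and median-signal
scale factors must lie in [0.4, 2.5] per sample; per plate, the median
calibration scale factor must lie in 1.0 +/- 0.2 and at least 95% of
analytes must have a calibration factor within the plate median +/- 0.4.
All intervals are closed. The analyte-level rule mirrors the plate band:
an analyte passes if its calibration factor stays within plate median
+/- 0.4 on every plate (an interpretive reading of the 95% criterion —
the platform reports analyte pass counts without printing the rule).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import Dataset
from .errors import OrderingError
from .normalize import ScaleFactorSet

__all__ = ["QcLimits", "QCReport", "sample_qc", "plate_qc", "analyte_qc", "qc_summary"]


@dataclass(frozen=True)
class QcLimits:
    """Pass bands; defaults are the platform's printed criteria."""

    sf_lo: float = 0.4
    sf_hi: float = 2.5
    cal_median_lo: float = 0.8
    cal_median_hi: float = 1.2
    cal_band: float = 0.4
    cal_frac: float = 0.95

    def __post_init__(self):
        if not (self.sf_lo < self.sf_hi and self.cal_median_lo < self.cal_median_hi):
            raise ValueError("QcLimits: lo must be < hi")
        if not 0 < self.cal_frac <= 1:
            raise ValueError("QcLimits: cal_frac must lie in (0, 1]")


@dataclass
class PlateFlag:
    passed: bool
    median_cal_sf: float
    frac_in_band: float
    reasons: list[str] = field(default_factory=list)


@dataclass
class QCReport:
    """Sample/plate/analyte pass flags with reasons and summary counts."""

    sample_flags: dict[str, dict]
    plate_flags: dict[str, dict]
    analyte_flags: dict[str, dict]
    counts: dict[str, int]
    limits: QcLimits = field(default_factory=QcLimits)

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "sample_flags": self.sample_flags,
            "plate_flags": self.plate_flags,
            "analyte_flags": self.analyte_flags,
            "counts": self.counts,
            "limits": asdict(self.limits),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path) -> "QCReport":
        payload = json.loads(Path(path).read_text())
        return cls(
            sample_flags=payload["sample_flags"],
            plate_flags=payload["plate_flags"],
            analyte_flags=payload["analyte_flags"],
            counts=payload["counts"],
            limits=QcLimits(**payload["limits"]),
        )

    def to_tsv(self, path) -> Path:
        path = Path(path)
        rows = []
        for scope, flags in (
            ("sample", self.sample_flags),
            ("plate", self.plate_flags),
            ("analyte", self.analyte_flags),
        ):
            for key, flag in flags.items():
                rows.append(
                    {
                        "scope": scope,
                        "id": key,
                        "pass": flag["pass"],
                        "reasons": "; ".join(flag["reasons"]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
        return path

    @property
    def n_failing_samples(self) -> int:
        return sum(1 for f in self.sample_flags.values() if not f["pass"])


def sample_qc(
    hyb_sfs: ScaleFactorSet,
    median_sfs: ScaleFactorSet,
    limits: QcLimits = QcLimits(),
    sample_types: pd.Series | None = None,
) -> dict[str, dict]:
    """Flag each sample on its hybridization and median-signal factors.

    A sample passes iff the hybridization factor and every per-bin
    median-signal factor lie in [sf_lo, sf_hi]. Buffer wells carry no
    sample and are skipped when ``sample_types`` is provided.
    """
    if hyb_sfs.hyb is None or median_sfs.median is None:
        raise OrderingError("sample_qc requires the hyb and median stages' factors")
    flags: dict[str, dict] = {}
    for sample in hyb_sfs.hyb.index:
        if sample_types is not None and sample_types.get(sample) == "buffer":
            continue
        reasons = []
        hv = float(hyb_sfs.hyb[sample])
        if not limits.sf_lo <= hv <= limits.sf_hi:
            reasons.append(
                f"hyb SF {hv:.4g} outside [{limits.sf_lo}, {limits.sf_hi}]"
            )
        for b, mv in median_sfs.median.loc[sample].items():
            mv = float(mv)
            if not limits.sf_lo <= mv <= limits.sf_hi:
                reasons.append(
                    f"median SF ({b}) {mv:.4g} outside [{limits.sf_lo}, {limits.sf_hi}]"
                )
        flags[sample] = {"pass": not reasons, "reasons": reasons}
    return flags


def plate_qc(cal_sf_plate: pd.Series, limits: QcLimits = QcLimits()) -> PlateFlag:
    """Flag one plate on its calibration factors (median band and 95%-in-band)."""
    vals = np.asarray(cal_sf_plate, dtype=float)
    if vals.size == 0:
        raise ValueError("plate_qc: empty calibration scale-factor set")
    med = float(np.median(vals))
    frac = float(np.mean(np.abs(vals - med) <= limits.cal_band))
    reasons = []
    if not limits.cal_median_lo <= med <= limits.cal_median_hi:
        reasons.append(
            f"median cal SF {med:.4g} outside "
            f"[{limits.cal_median_lo}, {limits.cal_median_hi}]"
        )
    if frac < limits.cal_frac:
        reasons.append(
            f"fraction within median +/- {limits.cal_band} is {frac:.4g} "
            f"(<{limits.cal_frac})"
        )
    return PlateFlag(passed=not reasons, median_cal_sf=med, frac_in_band=frac, reasons=reasons)


def analyte_qc(
    cal_sfs: pd.DataFrame, limits: QcLimits = QcLimits()
) -> tuple[dict[str, dict], int]:
    """Flag each analyte: pass iff its calibration factor stays within the
    plate median +/- cal_band on every plate. Returns (flags, passed count)."""
    meds = cal_sfs.median(axis=1)
    flags: dict[str, dict] = {}
    passed = 0
    dev = (cal_sfs.sub(meds, axis=0)).abs()
    for analyte in cal_sfs.columns:
        bad_plates = dev.index[dev[analyte] > limits.cal_band]
        reasons = [
            f"cal SF {cal_sfs.at[p, analyte]:.4g} outside plate {p} "
            f"median {meds[p]:.4g} +/- {limits.cal_band}"
            for p in bad_plates
        ]
        ok = not reasons
        passed += ok
        flags[analyte] = {"pass": ok, "reasons": reasons}
    return flags, passed


def qc_summary(
    dataset: Dataset,
    hyb_sfs: ScaleFactorSet,
    median_sfs: ScaleFactorSet,
    cal_sfs: ScaleFactorSet,
    limits: QcLimits = QcLimits(),
) -> QCReport:
    """Assemble sample, plate and analyte flags into one report."""
    if cal_sfs.cal is None:
        raise OrderingError("qc_summary requires the calibration stage's factors")
    sample_flags = sample_qc(
        hyb_sfs, median_sfs, limits, sample_types=dataset.samples["sample_type"]
    )
    plate_flags = {}
    for plate in cal_sfs.cal.index:
        flag = plate_qc(cal_sfs.cal.loc[plate], limits)
        plate_flags[plate] = {
            "pass": flag.passed,
            "median_cal_sf": flag.median_cal_sf,
            "frac_in_band": flag.frac_in_band,
            "reasons": flag.reasons,
        }
    analyte_flags, analytes_passed = analyte_qc(cal_sfs.cal, limits)
    counts = {
        "samples_passed": sum(f["pass"] for f in sample_flags.values()),
        "samples_total": len(sample_flags),
        "plates_passed": sum(f["pass"] for f in plate_flags.values()),
        "plates_total": len(plate_flags),
        "analytes_passed": analytes_passed,
        "analytes_total": len(analyte_flags),
    }
    return QCReport(sample_flags, plate_flags, analyte_flags, counts, limits)
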