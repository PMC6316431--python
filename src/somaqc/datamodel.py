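"""Plate-structured RFU dataset model.

An aptamer-array run reports one relative-fluorescence-unit (RFU) value per
well (sample) per analyte reagent. Wells on a plate play one of four roles:
``study`` (the specimens of interest), ``qc`` (pooled quality-control
plasma), ``calibrator`` (pooled calibrator plasma, shared across plates) and
``buffer`` (no sample). Analytes are either protein reagents assigned to one
of three plasma dilution bins (0.005%, 1%, 40% — capturing high-, mid- and
low-abundance proteins in range) or control reagents: hybridization controls
with a known expected signal, and negative controls reading assay background.

The :class:`Dataset` container pairs the sample roster, the analyte roster,
the RFU matrix, optional reference values and an ordered provenance log of
the transformations applied so far.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import StructuralError

DILUTION_BINS = ("0.005%", "1%", "40%")
CONTROL_BIN = "CONTROL"
ANALYTE_TYPES = ("protein", "hybridization_control", "negative_control")
SAMPLE_TYPES = ("study", "qc", "calibrator", "buffer")
SEX_LEVELS = ("M", "F", "unknown")

#: minimum well counts a well-formed plate is expected to carry
PLATE_DESIGN = {"buffer": 1, "qc": 2, "calibrator": 5}

SAMPLE_COLUMNS = ["sample_type", "plate_id", "subarray_id", "sex"]
ANALYTE_COLUMNS = ["target_name", "uniprot_id", "dilution_bin", "analyte_type"]


@dataclass
class ReferenceValues:
    """External reference RFUs: per hybridization control and (optionally)
    per protein analyte for calibration."""

    hyb: dict[str, float] = field(default_factory=dict)
    cal: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "ReferenceValues":
        return ReferenceValues(dict(self.hyb), dict(self.cal))


@dataclass
class ProvenanceRecord:
    step: str
    params: dict
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def to_dict(self) -> dict:
        return {"step": self.step, "params": self.params, "timestamp": self.timestamp}


@dataclass
class Finding:
    """A validation finding. ``severity`` is ``"warning"`` or ``"error"``."""

    severity: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.severity}] {self.message}"


@dataclass
class Dataset:
    """Sample roster + analyte roster + RFU matrix + references + provenance.

    ``samples`` is indexed by sample_id with columns ``sample_type``,
    ``plate_id``, ``subarray_id``, ``sex`` and zero or more ``group:*``
    stratifier columns. ``analytes`` is indexed by seq_id with columns
    ``target_name``, ``uniprot_id``, ``dilution_bin``, ``analyte_type``.
    ``rfu`` is indexed by sample_id with one column per seq_id, row and
    column order matching the rosters.
    """

    samples: pd.DataFrame
    analytes: pd.DataFrame
    rfu: pd.DataFrame
    references: ReferenceValues = field(default_factory=ReferenceValues)
    provenance: list[ProvenanceRecord] = field(default_factory=list)

    # -- roster helpers -------------------------------------------------
    def analyte_ids(self, analyte_type: str | None = None) -> list[str]:
        if analyte_type is None:
            return list(self.analytes.index)
        mask = self.analytes["analyte_type"] == analyte_type
        return list(self.analytes.index[mask])

    @property
    def protein_ids(self) -> list[str]:
        return self.analyte_ids("protein")

    @property
    def hyb_control_ids(self) -> list[str]:
        return self.analyte_ids("hybridization_control")

    @property
    def negative_control_ids(self) -> list[str]:
        return self.analyte_ids("negative_control")

    def sample_ids(self, *sample_types: str) -> list[str]:
        if not sample_types:
            return list(self.samples.index)
        mask = self.samples["sample_type"].isin(sample_types)
        return list(self.samples.index[mask])

    @property
    def plate_ids(self) -> list[str]:
        seen: list[str] = []
        for p in self.samples["plate_id"]:
            if p not in seen:
                seen.append(p)
        return seen

    def proteins_in_bin(self, dilution_bin: str) -> list[str]:
        mask = (self.analytes["analyte_type"] == "protein") & (
            self.analytes["dilution_bin"] == dilution_bin
        )
        return list(self.analytes.index[mask])

    # -- provenance -----------------------------------------------------
    def has_step(self, step: str) -> bool:
        return any(rec.step == step for rec in self.provenance)

    def log_step(self, step: str, **params) -> None:
        if self.has_step(step):
            raise StructuralError(f"normalization step '{step}' already applied")
        self.provenance.append(ProvenanceRecord(step=step, params=params))

    def copy(self) -> "Dataset":
        return Dataset(
            samples=self.samples.copy(),
            analytes=self.analytes.copy(),
            rfu=self.rfu.copy(),
            references=self.references.copy(),
            provenance=list(self.provenance),
        )


def validate_dataset(dataset: Dataset, strict: bool = False) -> list[Finding]:
    """Check dataset invariants and plate-design expectations.

    Returns a list of findings; empty iff everything holds. Structural
    invariants (duplicate ids, dimension mismatches, nonpositive RFUs,
    inconsistent analyte annotations) are always error severity.
    Plate-design counts (>=1 buffer / >=2 qc / >=5 calibrator wells per
    plate) are warnings by default and errors under ``strict``.
    """
    findings: list[Finding] = []
    plate_sev = "error" if strict else "warning"

    samples, analytes, rfu = dataset.samples, dataset.analytes, dataset.rfu

    for name, frame in (("sample_id", samples), ("seq_id", analytes)):
        dup = frame.index[frame.index.duplicated()].unique()
        for key in dup:
            findings.append(Finding("error", f"duplicate {name} '{key}'"))

    if list(rfu.index) != list(samples.index):
        findings.append(
            Finding("error", "rfu row order does not match the sample roster")
        )
    if list(rfu.columns) != list(analytes.index):
        findings.append(
            Finding("error", "rfu column order does not match the analyte roster")
        )

    values = rfu.to_numpy(dtype=float, copy=False)
    bad = ~(np.isfinite(values) & (values > 0))
    if bad.any():
        rows, cols = np.nonzero(bad)
        for r, c in zip(rows[:20], cols[:20]):  # cap the flood
            findings.append(
                Finding(
                    "error",
                    f"nonpositive or non-finite RFU at sample "
                    f"'{rfu.index[r]}', analyte '{rfu.columns[c]}'",
                )
            )

    for seq_id, row in analytes.iterrows():
        at, db = row["analyte_type"], row["dilution_bin"]
        if at not in ANALYTE_TYPES:
            findings.append(Finding("error", f"analyte '{seq_id}': unknown analyte_type '{at}'"))
            continue
        if at == "protein" and db not in DILUTION_BINS:
            findings.append(
                Finding("error", f"analyte '{seq_id}': protein requires a dilution bin, got '{db}'")
            )
        if at != "protein" and db != CONTROL_BIN:
            findings.append(
                Finding("error", f"analyte '{seq_id}': control analyte must use bin CONTROL, got '{db}'")
            )

    for sample_id, row in samples.iterrows():
        if row["sample_type"] not in SAMPLE_TYPES:
            findings.append(
                Finding("error", f"sample '{sample_id}': unknown sample_type '{row['sample_type']}'")
            )
        if not str(row["plate_id"]):
            findings.append(Finding("error", f"sample '{sample_id}': missing plate_id"))

    hyb_ids = set(dataset.hyb_control_ids)
    missing_ref = hyb_ids - set(dataset.references.hyb)
    for seq_id in sorted(missing_ref):
        findings.append(
            Finding("warning", f"hybridization control '{seq_id}' has no reference value")
        )
    for seq_id, val in dataset.references.hyb.items():
        if not (np.isfinite(val) and val > 0):
            findings.append(Finding("error", f"nonpositive hyb reference for '{seq_id}'"))

    counts = samples.groupby("plate_id")["sample_type"].value_counts()
    for plate in dataset.plate_ids:
        for role, minimum in PLATE_DESIGN.items():
            n = int(counts.get((plate, role), 0))
            if n < minimum:
                findings.append(
                    Finding(
                        plate_sev,
                        f"plate {plate}: {n} {role} sample{'s' if n != 1 else ''} (<{minimum})",
                    )
                )
    return findings
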