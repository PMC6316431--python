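"""Read and write the on-disk TSV dialect.

Four tab-separated files plus a JSON provenance log describe a dataset:

* ``samples.tsv`` — sample_id, sample_type, plate_id, subarray_id, sex,
  then zero or more ``group:*`` stratifier columns;
* ``analytes.tsv`` — seq_id, target_name, uniprot_id, dilution_bin
  ("0.005%" | "1%" | "40%" | "CONTROL"), analyte_type;
* ``rfu.tsv`` — sample_id column, one column per seq_id, decimal values;
* ``references.tsv`` (optional) — seq_id, role ("hyb" | "cal"),
  reference_rfu;
* ``provenance.json`` — ordered array of {step, params, timestamp}.

UTF-8, '.' decimal, LF line endings. Floats are written at 17 significant
digits so a write/read cycle is the identity on the values.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ANALYTE_COLUMNS,
    SAMPLE_COLUMNS,
    Dataset,
    ProvenanceRecord,
    ReferenceValues,
)
from .errors import DataValueError, StructuralError

_FLOAT_FMT = "%.17g"


def _read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StructuralError(f"{path}: missing column(s) {missing}")


def _unique_index(df: pd.DataFrame, key: str, path) -> pd.DataFrame:
    dup = df[key][df[key].duplicated()]
    if len(dup):
        raise StructuralError(f"{path}: duplicate {key} '{dup.iloc[0]}'")
    return df.set_index(key)


def read_dataset(
    samples_path,
    analytes_path,
    rfu_path,
    references_path=None,
    provenance_path=None,
) -> Dataset:
    """Load a dataset from its TSV files, resolving cross-references.

    Raises :class:`StructuralError` for missing/duplicate keys or roster
    mismatches and :class:`DataValueError` (with row/column coordinates)
    for non-numeric or nonpositive RFU cells.
    """
    samples = _read_tsv(samples_path)
    _require_columns(samples, ["sample_id"] + SAMPLE_COLUMNS, samples_path)
    samples = _unique_index(samples, "sample_id", samples_path)

    analytes = _read_tsv(analytes_path)
    _require_columns(analytes, ["seq_id"] + ANALYTE_COLUMNS, analytes_path)
    analytes = _unique_index(analytes, "seq_id", analytes_path)

    raw = _read_tsv(rfu_path)
    _require_columns(raw, ["sample_id"], rfu_path)
    raw = _unique_index(raw, "sample_id", rfu_path)

    unknown = [c for c in raw.columns if c not in analytes.index]
    if unknown:
        raise StructuralError(
            f"{rfu_path}: analyte column '{unknown[0]}' absent from analytes table"
        )
    missing = [a for a in analytes.index if a not in raw.columns]
    if missing:
        raise StructuralError(f"{rfu_path}: missing column for analyte '{missing[0]}'")
    extra_samples = [s for s in raw.index if s not in samples.index]
    if extra_samples:
        raise StructuralError(
            f"{rfu_path}: sample '{extra_samples[0]}' absent from samples table"
        )
    absent = [s for s in samples.index if s not in raw.index]
    if absent:
        raise StructuralError(f"{rfu_path}: missing row for sample '{absent[0]}'")

    raw = raw.loc[samples.index, analytes.index]
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        # numpy's parser is correctly rounded (pandas' fast path is not),
        # so 17-significant-digit text round-trips bit-exactly
        try:
            values[:, j] = np.asarray(raw[col].to_numpy(), dtype=float)
        except ValueError:
            converted = pd.to_numeric(raw[col], errors="coerce")
            r = raw.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise DataValueError(
                f"{rfu_path}: non-numeric RFU at sample '{r}', analyte '{col}'"
            ) from None
    nonpos = ~((values > 0) & np.isfinite(values))
    if nonpos.any():
        r, c = np.argwhere(nonpos)[0]
        raise DataValueError(
            f"{rfu_path}: nonpositive RFU at sample '{raw.index[r]}', "
            f"analyte '{raw.columns[c]}'"
        )
    rfu = pd.DataFrame(values, index=raw.index.copy(), columns=raw.columns.copy())

    references = ReferenceValues()
    if references_path is not None and Path(references_path).exists():
        refs = _read_tsv(references_path)
        _require_columns(refs, ["seq_id", "role", "reference_rfu"], references_path)
        for _, row in refs.iterrows():
            try:
                val = float(row["reference_rfu"])
            except ValueError:
                raise DataValueError(
                    f"{references_path}: non-numeric reference for '{row['seq_id']}'"
                ) from None
            if not (np.isfinite(val) and val > 0):
                raise DataValueError(
                    f"{references_path}: nonpositive reference for '{row['seq_id']}'"
                )
            if row["role"] == "hyb":
                references.hyb[row["seq_id"]] = val
            elif row["role"] == "cal":
                references.cal[row["seq_id"]] = val
            else:
                raise StructuralError(
                    f"{references_path}: unknown role '{row['role']}' for "
                    f"'{row['seq_id']}' (expected 'hyb' or 'cal')"
                )

    provenance: list[ProvenanceRecord] = []
    if provenance_path is not None and Path(provenance_path).exists():
        with open(provenance_path, encoding="utf-8") as fh:
            for rec in json.load(fh):
                provenance.append(
                    ProvenanceRecord(rec["step"], rec["params"], rec["timestamp"])
                )

    return Dataset(samples, analytes, rfu, references, provenance)


def read_dataset_dir(directory) -> Dataset:
    """Load a dataset from a directory written by :func:`write_dataset`."""
    d = Path(directory)
    return read_dataset(
        d / "samples.tsv",
        d / "analytes.tsv",
        d / "rfu.tsv",
        references_path=d / "references.tsv",
        provenance_path=d / "provenance.json",
    )


def write_dataset(dataset: Dataset, out_dir) -> dict[str, Path]:
    """Serialize a dataset to ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    samples = dataset.samples.reset_index(names="sample_id")
    paths["samples"] = out / "samples.tsv"
    samples.to_csv(paths["samples"], sep="\t", index=False, lineterminator="\n")

    analytes = dataset.analytes.reset_index(names="seq_id")
    paths["analytes"] = out / "analytes.tsv"
    analytes.to_csv(paths["analytes"], sep="\t", index=False, lineterminator="\n")

    rfu = dataset.rfu.reset_index(names="sample_id")
    paths["rfu"] = out / "rfu.tsv"
    rfu.to_csv(
        paths["rfu"], sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )

    rows = [("hyb", k, v) for k, v in dataset.references.hyb.items()] + [
        ("cal", k, v) for k, v in dataset.references.cal.items()
    ]
    if rows:
        refs = pd.DataFrame(rows, columns=["role", "seq_id", "reference_rfu"])
        refs = refs[["seq_id", "role", "reference_rfu"]]
        paths["references"] = out / "references.tsv"
        refs.to_csv(
            paths["references"],
            sep="\t",
            index=False,
            float_format=_FLOAT_FMT,
            lineterminator="\n",
        )

    paths["provenance"] = out / "provenance.json"
    with open(paths["provenance"], "w", encoding="utf-8") as fh:
        json.dump([rec.to_dict() for rec in dataset.provenance], fh, indent=1)
        fh.write("\n")
    return paths
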