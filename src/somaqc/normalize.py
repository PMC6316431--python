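"""The three-stage normalization cascade plus matrix transforms.

Stages run in a fixed order, each recorded in dataset provenance:

1. **Hybridization-control normalization** — per sample, the median ratio of
   each spiked hybridization control's reference value to its observed RFU
   gives a scale factor applied to every analyte of that sample. Removes
   post-assay (scanner/hybridization) variability.
2. **Median-signal normalization** — within each plate and dilution bin,
   each sample is rescaled so the median ratio of its protein signals to a
   reference profile (per-analyte median over study+qc wells) equals 1.
   Calibrator wells are normalized against a profile built from calibrator
   wells only, so roles never mix. Removes pipetting/concentration bias.
3. **Calibration normalization** — per plate and protein analyte, the
   median over the plate's calibrator wells is ratioed against a common
   reference (external, or the cross-plate median of plate medians) and the
   resulting factor applied to every well on the plate. Removes run-to-run
   (plate) differences.

Medians over an even count are the mean of the two central order
statistics. ``quantile_normalize`` and ``log_transform`` implement the
downstream matrix transforms applied before statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import DILUTION_BINS, Dataset
from .errors import ConfigError, DataValueError, OrderingError

__all__ = [
    "ScaleFactorSet",
    "hybridization_normalize",
    "median_signal_normalize",
    "calibration_normalize",
    "quantile_normalize",
    "log_transform",
    "transform_matrix",
]

STAGE_HYB = "hybridization_normalize"
STAGE_MEDIAN = "median_signal_normalize"
STAGE_CAL = "calibration_normalize"


@dataclass
class ScaleFactorSet:
    """Scale factors produced by one cascade stage.

    Exactly one of the three containers is populated, matching ``stage``:
    ``hyb`` (sample -> factor), ``median`` (samples x dilution bins) or
    ``cal`` (plates x protein analytes).
    """

    stage: str
    hyb: pd.Series | None = None
    median: pd.DataFrame | None = None
    cal: pd.DataFrame | None = None

    def _check_positive(self) -> None:
        for part in (self.hyb, self.median, self.cal):
            if part is None:
                continue
            vals = part.to_numpy(dtype=float).ravel()
            if not np.all(np.isfinite(vals) & (vals > 0)):
                raise DataValueError(f"{self.stage}: nonpositive or non-finite scale factor")

    def to_tsv(self, path) -> Path:
        """Write the factors as a flat scope-keyed TSV."""
        path = Path(path)
        if self.hyb is not None:
            df = self.hyb.rename("factor").rename_axis("sample_id").reset_index()
        elif self.median is not None:
            df = (
                self.median.rename_axis("sample_id")
                .reset_index()
                .melt(id_vars="sample_id", var_name="dilution_bin", value_name="factor")
            )
        else:
            df = (
                self.cal.rename_axis("plate_id")
                .reset_index()
                .melt(id_vars="plate_id", var_name="seq_id", value_name="factor")
            )
        df.to_csv(path, sep="\t", index=False, float_format="%.17g", lineterminator="\n")
        return path


def hybridization_normalize(dataset: Dataset) -> tuple[Dataset, ScaleFactorSet]:
    """Scale every sample by the median reference/observed ratio of its
    hybridization controls. Applies to all analytes and all roles."""
    hyb_ids = dataset.hyb_control_ids
    if not hyb_ids:
        raise ConfigError("dataset has no hybridization-control analytes")
    missing = [c for c in hyb_ids if c not in dataset.references.hyb]
    if missing:
        raise KeyError(f"no hyb reference value for control '{missing[0]}'")

    ref = np.array([dataset.references.hyb[c] for c in hyb_ids])
    ratios = ref[None, :] / dataset.rfu[hyb_ids].to_numpy()
    sf = pd.Series(np.median(ratios, axis=1), index=dataset.rfu.index)

    out = dataset.copy()
    out.rfu = out.rfu.mul(sf, axis=0)
    out.log_step(STAGE_HYB, n_controls=len(hyb_ids))
    sfs = ScaleFactorSet(stage="hyb", hyb=sf)
    sfs._check_positive()
    return out, sfs


def median_signal_normalize(
    dataset: Dataset,
    reference_roles: tuple[str, ...] = ("study", "qc"),
    min_group: int = 3,
) -> tuple[Dataset, ScaleFactorSet]:
    """Rescale each sample, per dilution bin, to unit median ratio against
    its plate's reference profile.

    The reference profile is the per-analyte median over ``reference_roles``
    wells on the same plate; calibrator wells are normalized against a
    calibrator-only profile. Control analytes are untouched.
    """
    if not dataset.has_step(STAGE_HYB):
        raise OrderingError("median_signal_normalize requires hybridization_normalize first")

    out = dataset.copy()
    samples = dataset.samples
    sf = pd.DataFrame(
        np.ones((len(samples), len(DILUTION_BINS))),
        index=samples.index,
        columns=list(DILUTION_BINS),
    )

    for plate in dataset.plate_ids:
        on_plate = samples.index[samples["plate_id"] == plate]
        ref_rows = [s for s in on_plate if samples.at[s, "sample_type"] in reference_roles]
        cal_rows = [s for s in on_plate if samples.at[s, "sample_type"] == "calibrator"]
        if len(ref_rows) < min_group:
            raise ConfigError(
                f"plate {plate}: only {len(ref_rows)} reference-role samples (<{min_group})"
            )
        for b in DILUTION_BINS:
            cols = dataset.proteins_in_bin(b)
            if not cols:
                continue
            block = out.rfu.loc[on_plate, cols]
            profiles: list[tuple[list[str], np.ndarray]] = []
            non_cal = [s for s in on_plate if samples.at[s, "sample_type"] != "calibrator"]
            profiles.append((non_cal, block.loc[ref_rows].median(axis=0).to_numpy()))
            if cal_rows:
                if len(cal_rows) < min_group:
                    raise ConfigError(
                        f"plate {plate}, bin {b}: only {len(cal_rows)} calibrator "
                        f"samples (<{min_group})"
                    )
                profiles.append((cal_rows, block.loc[cal_rows].median(axis=0).to_numpy()))
            for rows, profile in profiles:
                ratios = block.loc[rows].to_numpy() / profile[None, :]
                factors = 1.0 / np.median(ratios, axis=1)
                sf.loc[rows, b] = factors
                out.rfu.loc[rows, cols] = block.loc[rows].to_numpy() * factors[:, None]

    out.log_step(STAGE_MEDIAN, reference_roles=list(reference_roles))
    sfs = ScaleFactorSet(stage="median", median=sf)
    sfs._check_positive()
    return out, sfs


def calibration_normalize(
    dataset: Dataset, calibrator_reference: dict[str, float] | None = None
) -> tuple[Dataset, ScaleFactorSet]:
    """Align plates on their pooled-calibrator wells, per protein analyte.

    With no external reference the cross-plate median of plate calibrator
    medians serves as the reference, so a single-plate run gets unit
    factors. Control analytes are untouched.
    """
    if not dataset.has_step(STAGE_MEDIAN):
        raise OrderingError("calibration_normalize requires median_signal_normalize first")

    out = dataset.copy()
    samples = dataset.samples
    proteins = dataset.protein_ids
    plates = dataset.plate_ids

    plate_medians = np.empty((len(plates), len(proteins)))
    for i, plate in enumerate(plates):
        cal_rows = samples.index[
            (samples["plate_id"] == plate) & (samples["sample_type"] == "calibrator")
        ]
        if len(cal_rows) == 0:
            raise ConfigError(f"plate {plate}: no calibrator samples")
        plate_medians[i] = out.rfu.loc[cal_rows, proteins].median(axis=0).to_numpy()

    if calibrator_reference is not None:
        missing = [a for a in proteins if a not in calibrator_reference]
        if missing:
            raise KeyError(f"no calibrator reference for analyte '{missing[0]}'")
        cal_ref = np.array([float(calibrator_reference[a]) for a in proteins])
        ok = np.isfinite(cal_ref) & (cal_ref > 0)
        if not ok.all():
            bad = proteins[int(np.nonzero(~ok)[0][0])]
            raise DataValueError(f"nonpositive calibrator reference for analyte '{bad}'")
    else:
        cal_ref = np.median(plate_medians, axis=0)

    sf = pd.DataFrame(cal_ref[None, :] / plate_medians, index=plates, columns=proteins)
    for plate in plates:
        rows = samples.index[samples["plate_id"] == plate]
        out.rfu.loc[rows, proteins] = (
            out.rfu.loc[rows, proteins].to_numpy() * sf.loc[plate].to_numpy()[None, :]
        )

    out.log_step(STAGE_CAL, external_reference=calibrator_reference is not None)
    sfs = ScaleFactorSet(stage="calibration", cal=sf)
    sfs._check_positive()
    return out, sfs


def quantile_normalize(matrix):
    """Force every sample (row) to share one empirical distribution.

    The reference distribution is the per-rank mean of the row-sorted
    values; tied values within a row receive the mean of the reference
    values at their occupied ranks. With tie-free rows, the sorted vectors
    of all rows are exactly identical afterwards. A single-row matrix is
    returned unchanged with a warning.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("quantile_normalize expects a 2-D samples x analytes matrix")
    n, p = X.shape
    if n < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return matrix.copy() if is_frame else X.copy()

    order = np.argsort(X, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(X, order, axis=1)
    ref = sorted_vals.mean(axis=0)

    out = np.empty_like(X)
    for i in range(n):
        row_sorted = sorted_vals[i]
        assigned = np.empty(p)
        j = 0
        while j < p:
            k = j
            while k + 1 < p and row_sorted[k + 1] == row_sorted[j]:
                k += 1
            assigned[j : k + 1] = ref[j : k + 1].mean()
            j = k + 1
        out[i, order[i]] = assigned

    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def log_transform(matrix, base: float = 2.0):
    """Elementwise logarithm; raises with coordinates on nonpositive cells."""
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    bad = ~((X > 0) & np.isfinite(X))
    if bad.any():
        idx = tuple(np.argwhere(bad)[0])
        if is_frame:
            loc = f"row '{matrix.index[idx[0]]}', column '{matrix.columns[idx[1]]}'"
        else:
            loc = f"position {idx}"
        raise DataValueError(f"log_transform: nonpositive value at {loc}")
    out = np.log(X) / np.log(base)
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def transform_matrix(
    dataset: Dataset,
    roles: tuple[str, ...] = ("study",),
    quantile: bool = True,
    log_base: float | None = 2.0,
) -> pd.DataFrame:
    """Protein submatrix for the requested roles, quantile-normalized and
    log-transformed — the representation the statistical layer consumes.
    Control analytes are excluded (they carry no biology and would distort
    the rank reference)."""
    rows = dataset.sample_ids(*roles)
    mat = dataset.rfu.loc[rows, dataset.protein_ids]
    if quantile and len(rows) >= 2:
        mat = quantile_normalize(mat)
    if log_base is not None:
        mat = log_transform(mat, base=log_base)
    return mat
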