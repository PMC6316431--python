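"""End-to-end orchestration: (read | simulate) -> normalization cascade ->
QC -> transforms -> plate-effect check -> group comparison -> reference
validation, with every artifact written under one output directory.

Configuration is a flat ``key = value`` text file with dotted section keys
(diff-friendly; '#' starts a comment). Recognized keys:

  input.samples / input.analytes / input.rfu / input.references  (paths)
  simulate.<SimConfig field>          e.g. simulate.n_plates = 2
  qc.<QcLimits field>                 e.g. qc.sf_lo = 0.4
  normalization.log_base              default 2
  normalization.calibrator_reference  optional path (seq_id, role=cal TSV)
  stats.pca_k / stats.pca_threshold   default 2 / 0.01
  stats.group_analyte / stats.grouping / stats.test
  elisa.analytes                      comma-separated seq_ids (simulated runs)
  elisa.lambda / elisa.noise_cv       comma-separated floats, one per analyte
  output.dir, seed, log_level

Exactly one of the ``input.*`` block or the ``simulate.*`` block may be
present (a bare ``seed`` with neither block simulates with defaults).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import Dataset, Finding, validate_dataset
from .errors import ConfigError, SomaqcError
from .io import read_dataset, write_dataset
from .normalize import (
    calibration_normalize,
    hybridization_normalize,
    median_signal_normalize,
    transform_matrix,
)
from .qc import QcLimits, qc_summary
from .simulate import ElisaTable, GroundTruth, SimConfig, simulate_dataset, simulate_elisa
from .stats import group_compare, pca_plate_assoc, validate_against_reference

logger = logging.getLogger("somaqc")

_BOOL = {"true": True, "false": False, "yes": True, "no": False}


def _coerce(text: str):
    text = text.strip()
    low = text.lower()
    if low in _BOOL:
        return _BOOL[low]
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def load_config(path) -> dict:
    """Parse a flat dotted-key config file into a nested dict."""
    tree: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got '{raw}'")
        key, value = (part.strip() for part in line.split("=", 1))
        node = tree
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
            if not isinstance(node, dict):
                raise ConfigError(f"{path}:{lineno}: key '{key}' conflicts with a scalar")
        node[parts[-1]] = _coerce(value)
    return tree


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration."""

    out_dir: Path
    seed: int = 0
    input_paths: dict | None = None  # samples/analytes/rfu/references
    sim_config: SimConfig | None = None
    qc_limits: QcLimits = field(default_factory=QcLimits)
    log_base: float = 2.0
    calibrator_reference: dict[str, float] | None = None
    pca_k: int = 2
    pca_threshold: float = 0.01
    group_analyte: str | None = None
    grouping: str = "sex"
    group_test: str = "wilcoxon"
    elisa_analytes: list[str] = field(default_factory=list)
    elisa_lambda: list[float] = field(default_factory=list)
    elisa_noise_cv: list[float] = field(default_factory=list)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path, seed: int | None = None, out_dir=None) -> "PipelineConfig":
        tree = load_config(path)
        return cls.from_tree(tree, seed=seed, out_dir=out_dir)

    @classmethod
    def from_tree(cls, tree: dict, seed: int | None = None, out_dir=None) -> "PipelineConfig":
        if "input" in tree and "simulate" in tree:
            raise ConfigError("config must specify input paths or a simulate block, not both")
        cfg_seed = seed if seed is not None else int(tree.get("seed", 0))
        out = Path(out_dir if out_dir is not None else tree.get("output", {}).get("dir", "somaqc_out"))

        sim_config = None
        input_paths = None
        if "input" in tree:
            block = tree["input"]
            for key in ("samples", "analytes", "rfu"):
                if key not in block:
                    raise ConfigError(f"input block missing '{key}' path")
            input_paths = {k: str(v) for k, v in block.items()}
        else:
            sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
            overrides = dict(tree.get("simulate", {}))
            unknown = set(overrides) - sim_fields
            if unknown:
                raise ConfigError(f"unknown simulate option(s): {sorted(unknown)}")
            overrides.setdefault("seed", cfg_seed)
            sim_config = SimConfig(**overrides)

        qc_block = tree.get("qc", {})
        qc_fields = {f.name for f in dataclasses.fields(QcLimits)}
        unknown = set(qc_block) - qc_fields
        if unknown:
            raise ConfigError(f"unknown qc option(s): {sorted(unknown)}")
        limits = QcLimits(**qc_block)

        norm = tree.get("normalization", {})
        stats_block = tree.get("stats", {})
        elisa_block = tree.get("elisa", {})

        def _csv_list(value, cast=str):
            if value is None:
                return []
            return [cast(v.strip()) for v in str(value).split(",") if v.strip()]

        cal_ref = None
        if "calibrator_reference" in norm:
            import pandas as pd

            refs = pd.read_csv(norm["calibrator_reference"], sep="\t")
            cal_ref = dict(zip(refs["seq_id"], refs["reference_rfu"].astype(float)))

        return cls(
            out_dir=out,
            seed=cfg_seed,
            input_paths=input_paths,
            sim_config=sim_config,
            qc_limits=limits,
            log_base=float(norm.get("log_base", 2.0)),
            calibrator_reference=cal_ref,
            pca_k=int(stats_block.get("pca_k", 2)),
            pca_threshold=float(stats_block.get("pca_threshold", 0.01)),
            group_analyte=stats_block.get("group_analyte"),
            grouping=stats_block.get("grouping", "sex"),
            group_test=stats_block.get("test", "wilcoxon"),
            elisa_analytes=_csv_list(elisa_block.get("analytes")),
            elisa_lambda=_csv_list(elisa_block.get("lambda"), float),
            elisa_noise_cv=_csv_list(elisa_block.get("noise_cv"), float),
            log_level=str(tree.get("log_level", "INFO")),
        )


@dataclass
class RunResult:
    exit_status: int
    paths: dict[str, Path]
    qc_report: object | None = None
    findings: list[Finding] = field(default_factory=list)


def _setup_logging(out_dir: Path, level: str) -> logging.FileHandler:
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    return handler


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full pipeline; returns exit status and artifact paths.

    Stage order is fixed: hybridization -> median-signal -> calibration,
    then QC, quantile/log transforms, the PCA plate-effect check, the
    configured group comparison and (when reference values exist) the
    cross-platform correlation. A stage failure stops the run with a
    nonzero status; artifacts written so far are retained.
    """
    out = Path(config.out_dir)
    handler = _setup_logging(out, config.log_level)
    paths: dict[str, Path] = {"log": out / "run.log"}
    stage = "setup"
    try:
        truth: GroundTruth | None = None
        elisa: ElisaTable | None = None
        stage = "load"
        if config.input_paths is not None:
            logger.info("reading dataset from input paths")
            dataset = read_dataset(
                config.input_paths["samples"],
                config.input_paths["analytes"],
                config.input_paths["rfu"],
                references_path=config.input_paths.get("references"),
            )
        else:
            sim = config.sim_config or SimConfig(seed=config.seed)
            logger.info(
                "simulating dataset: %d plates x %d study samples, %d proteins, seed=%d",
                sim.n_plates, sim.samples_per_plate, sim.n_protein_analytes, sim.seed,
            )
            dataset, truth = simulate_dataset(sim)
            write_dataset(dataset, out / "input")
            truth_path = out / "input" / "ground_truth.json"
            truth_path.write_text(
                json.dumps(
                    {
                        "h": {k: float(v) for k, v in truth.h.items()},
                        "sex_effect_analyte": truth.sex_effect_analyte,
                        "sex_effect_log2": truth.sex_effect_log2,
                    },
                    indent=1,
                    sort_keys=True,
                )
                + "\n"
            )
            paths["input"] = out / "input"
            if config.elisa_analytes:
                if not (
                    len(config.elisa_analytes)
                    == len(config.elisa_lambda)
                    == len(config.elisa_noise_cv)
                ):
                    raise ConfigError("elisa.analytes/lambda/noise_cv lengths differ")
                elisa = simulate_elisa(
                    truth,
                    dataset,
                    config.elisa_analytes,
                    dict(zip(config.elisa_analytes, config.elisa_lambda)),
                    dict(zip(config.elisa_analytes, config.elisa_noise_cv)),
                    seed=config.seed + 1,
                )
                elisa.values.to_csv(
                    out / "elisa.tsv", sep="\t", index=False,
                    float_format="%.17g", lineterminator="\n",
                )
                paths["elisa"] = out / "elisa.tsv"

        stage = "validate"
        findings = validate_dataset(dataset)
        for f in findings:
            logger.log(logging.ERROR if f.severity == "error" else logging.WARNING, f.message)
        if any(f.severity == "error" for f in findings):
            raise SomaqcError("dataset failed structural validation")

        stage = "hybridization_normalize"
        dataset, hyb_sfs = hybridization_normalize(dataset)
        paths["sf_hyb"] = hyb_sfs.to_tsv(out / "scale_factors_hyb.tsv")

        stage = "median_signal_normalize"
        dataset, med_sfs = median_signal_normalize(dataset)
        paths["sf_median"] = med_sfs.to_tsv(out / "scale_factors_median.tsv")

        stage = "calibration_normalize"
        dataset, cal_sfs = calibration_normalize(dataset, config.calibrator_reference)
        paths["sf_calibration"] = cal_sfs.to_tsv(out / "scale_factors_calibration.tsv")

        stage = "qc"
        report = qc_summary(dataset, hyb_sfs, med_sfs, cal_sfs, config.qc_limits)
        paths["qc_json"] = report.to_json(out / "qc_report.json")
        paths["qc_tsv"] = report.to_tsv(out / "qc_report.tsv")
        logger.info(
            "QC: %d/%d samples, %d/%d plates, %d/%d analytes passed",
            report.counts["samples_passed"], report.counts["samples_total"],
            report.counts["plates_passed"], report.counts["plates_total"],
            report.counts["analytes_passed"], report.counts["analytes_total"],
        )

        stage = "write_normalized"
        write_dataset(dataset, out / "normalized")
        paths["normalized"] = out / "normalized"

        stage = "transform"
        dataset.log_step("quantile_normalize")
        dataset.log_step("log_transform", base=config.log_base)
        log_qn = transform_matrix(dataset, roles=("study",), log_base=config.log_base)

        stage = "plate_effect"
        plates = dataset.samples.loc[log_qn.index, "plate_id"].to_numpy()
        pe = pca_plate_assoc(log_qn, plates, k=min(config.pca_k, min(log_qn.shape)),
                             threshold=config.pca_threshold)
        paths["plate_effect"] = out / "plate_effect.json"
        paths["plate_effect"].write_text(json.dumps(pe.to_dict(), indent=1) + "\n")
        logger.info("plate effect: %s (p=%s)", pe.verdict, pe.p_values)

        stage = "validation_stats"
        validation: dict[str, list] = {"group_comparisons": [], "correlations": []}
        analyte = config.group_analyte or (truth.sex_effect_analyte if truth else None)
        if analyte is not None:
            gc = group_compare(
                dataset, analyte, grouping=config.grouping, test=config.group_test
            )
            validation["group_comparisons"].append(gc.to_dict())
            logger.info(
                "group comparison %s by %s: p=%.4g", analyte, config.grouping, gc.p_two_sided
            )
        if elisa is not None:
            for res in validate_against_reference(dataset, elisa, quantile=True):
                validation["correlations"].append(res.to_dict())
                logger.info(
                    "correlation %s vs reference: r=%.3f (n=%d)",
                    res.analyte, res.pearson_r, res.n,
                )
        paths["validation"] = out / "validation_report.json"
        paths["validation"].write_text(json.dumps(validation, indent=1) + "\n")

        logger.info("pipeline complete")
        return RunResult(0, paths, qc_report=report, findings=findings)
    except Exception as exc:
        logger.error("stage '%s' failed: %s", stage, exc)
        return RunResult(1, paths)
    finally:
        handler.close()
        logger.removeHandler(handler)


def seeded_rng(seed: int, stream: int = 0) -> np.random.Generator:
    """Derive an independent generator from a base seed (kept below 2**31)."""
    return np.random.default_rng((seed * 1_000_003 + stream) % (2**31 - 1))
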