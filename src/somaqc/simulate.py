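"""Synthetic plate-structured RFU data with known ground truth.

The generator emulates the structure of an aptamer-array plasma run so that
every stage of the normalization cascade is identifiable in isolation:

* a per-sample *hybridization* bias ``h_i`` multiplies everything measured
  in well *i*, including the spiked hybridization controls — exactly the
  variability hybridization-control normalization removes;
* a per-sample, per-dilution-bin *pipetting* bias ``m_{i,d}`` multiplies
  protein signals only (controls are spiked after dilution) — the
  variability median-signal normalization removes;
* a per-plate, per-analyte *run* effect ``g_{p,a}`` multiplies protein
  signals of every well on plate *p* — the variability calibration
  normalization removes via the shared pooled-calibrator wells;
* additive lognormal background with mean ``background_mean`` and CV
  ``background_cv`` saturates low signals at the negative-control floor.

Latent log2 abundances are Normal per analyte; one designated analyte
carries a male/female log2 shift (a PSA-like sex marker). Calibrator wells
share one pooled latent profile across all plates; buffer wells read
background only. Identical config + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    CONTROL_BIN,
    DILUTION_BINS,
    Dataset,
    ReferenceValues,
    validate_dataset,
)
from .errors import ConfigError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ElisaTable",
    "simulate_dataset",
    "simulate_elisa",
    "make_fixture_small",
]


@dataclass
class SimConfig:
    """Generator configuration.

    Defaults emulate the scale of a two-plate validation run: ~21 study
    samples split over 2 plates, the full 1317-protein menu plus 12
    hybridization and 5 negative controls, biases spanning [0.5, 2] (well
    inside the 0.4–2.5 acceptance band), mild run-to-run variation, and a
    ~300 RFU background floor with 10% CV.
    """

    n_plates: int = 2
    samples_per_plate: int = 11  # study wells per plate
    n_protein_analytes: int = 1317
    n_hyb_controls: int = 12
    n_negative_controls: int = 5
    dilution_split: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    hyb_bias_range: tuple[float, float] = (0.5, 2.0)
    pipette_bias_range: tuple[float, float] = (2 / 3, 1.5)
    #: qc/calibrator wells hold one pooled material dispensed robotically, so
    #: their dilution bias spread is much tighter than study specimens'
    pooled_pipette_bias_range: tuple[float, float] = (0.95, 1.05)
    #: optional per-bin jitter multiplying the per-sample bias (independent
    #: error of each dilution prep). Off by default: the per-sample
    #: concentration component dominates in practice, and any systematic
    #: per-bin spread leaves a rank signature that the plate-effect check
    #: (deliberately sensitive at >1000 analytes) would flag in every run.
    bin_jitter_range: tuple[float, float] = (1.0, 1.0)
    plate_effect_sd: float = 0.05  # SD of per-plate per-analyte log2 effect
    plate_shift_log2: dict[str, float] | None = None  # uniform extra shift per plate
    abundance_log2_mean_range: tuple[float, float] = (12.0, 16.0)
    abundance_log2_sd_range: tuple[float, float] = (0.05, 0.25)
    background_mean: float = 300.0
    background_cv: float = 0.1
    hyb_control_cv: float = 0.02
    sex_effect_analyte: str | None = None  # default: first protein analyte
    sex_effect_log2: float = 3.0
    hyb_bias_overrides: dict[str, float] | None = None  # sample_id -> h
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_plates", "samples_per_plate", "n_protein_analytes",
                     "n_hyb_controls", "n_negative_controls"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if abs(sum(self.dilution_split) - 1.0) > 1e-9:
            raise ConfigError("dilution_split proportions must sum to 1")
        for name in ("hyb_bias_range", "pipette_bias_range",
                     "pooled_pipette_bias_range", "bin_jitter_range",
                     "abundance_log2_mean_range", "abundance_log2_sd_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ConfigError(f"{name} must be ordered lo <= hi")
        if self.hyb_bias_range[0] <= 0 or self.pipette_bias_range[0] <= 0:
            raise ConfigError("bias ranges must be strictly positive")
        if self.plate_effect_sd < 0:
            raise ConfigError("plate_effect_sd must be nonnegative")
        if self.background_mean <= 0 or self.background_cv < 0:
            raise ConfigError("background parameters must be positive")


@dataclass
class GroundTruth:
    """Injected biases and latent abundances behind a simulated dataset."""

    h: pd.Series  # sample -> hybridization bias (study/qc/calibrator wells)
    m: pd.DataFrame  # samples x dilution bins, pipetting bias
    g: pd.DataFrame  # plates x protein analytes, multiplicative run effect
    latent_log2: pd.DataFrame  # samples x protein analytes
    calibrator_pool_log2: pd.Series  # analyte -> pooled calibrator abundance
    analyte_mu_log2: pd.Series  # analyte -> latent mean
    analyte_sd_log2: pd.Series  # analyte -> latent SD
    sex_effect_analyte: str = ""
    sex_effect_log2: float = 0.0


@dataclass
class ElisaTable:
    """Paired reference-immunoassay concentrations (pg/mL) for a subset of
    analytes, with the attenuation and noise used to generate them."""

    values: pd.DataFrame  # columns sample_id, seq_id, concentration
    lambda_map: dict[str, float] = field(default_factory=dict)
    noise_cv_map: dict[str, float] = field(default_factory=dict)

    def concentrations(self, seq_id: str) -> pd.Series:
        sub = self.values[self.values["seq_id"] == seq_id]
        return pd.Series(sub["concentration"].to_numpy(), index=sub["sample_id"])


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv * cv)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_dataset(config: SimConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a plate-structured dataset and its full ground truth.

    The observation model, in application order: latent log2 abundances are
    drawn per sample and analyte (with the sex shift on the designated
    analyte); protein RFU = ``h_i * m_{i,bin(a)} * g_{p,a} * 2**latent +
    background``; hybridization controls = ``h_i * reference_c * (1+eps)``
    with eps ~ Normal(0, hyb_control_cv), bypassing ``m`` and ``g``;
    negative controls and every analyte of a buffer well read background
    only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- rosters -------------------------------------------------------
    protein_ids = [f"SL{i + 1:05d}" for i in range(config.n_protein_analytes)]
    hyb_ids = [f"HCE{i + 1:03d}" for i in range(config.n_hyb_controls)]
    neg_ids = [f"NEG{i + 1:03d}" for i in range(config.n_negative_controls)]

    # deterministic dilution-bin assignment honoring the split proportions
    edges = np.floor(np.cumsum(config.dilution_split) * len(protein_ids) + 0.5).astype(int)
    bin_of: dict[str, str] = {}
    start = 0
    for b, stop in zip(DILUTION_BINS, edges):
        for a in protein_ids[start:stop]:
            bin_of[a] = b
        start = stop
    for a in protein_ids[start:]:
        bin_of[a] = DILUTION_BINS[-1]

    sex_analyte = config.sex_effect_analyte or protein_ids[0]
    if sex_analyte not in protein_ids:
        raise ConfigError(f"sex_effect_analyte '{sex_analyte}' not in protein roster")

    analytes = pd.DataFrame(
        {
            "target_name": [f"TGT_{a}" for a in protein_ids]
            + [f"HybControl_{i + 1}" for i in range(len(hyb_ids))]
            + [f"NegControl_{i + 1}" for i in range(len(neg_ids))],
            "uniprot_id": [""] * (len(protein_ids) + len(hyb_ids) + len(neg_ids)),
            "dilution_bin": [bin_of[a] for a in protein_ids]
            + [CONTROL_BIN] * (len(hyb_ids) + len(neg_ids)),
            "analyte_type": ["protein"] * len(protein_ids)
            + ["hybridization_control"] * len(hyb_ids)
            + ["negative_control"] * len(neg_ids),
        },
        index=pd.Index(protein_ids + hyb_ids + neg_ids, name="seq_id"),
    )

    plate_ids = [f"P{p + 1}" for p in range(config.n_plates)]
    rows = []
    study_counter = 0
    for plate in plate_ids:
        well = 0
        def add(role, sex="unknown"):
            nonlocal well
            well += 1
            rows.append(
                {
                    "sample_id": f"{plate}_{role.upper()}{well:02d}",
                    "sample_type": role,
                    "plate_id": plate,
                    "subarray_id": f"{plate}_W{well:02d}",
                    "sex": sex,
                }
            )
        add("buffer")
        for _ in range(2):
            add("qc")
        for _ in range(5):
            add("calibrator")
        for _ in range(config.samples_per_plate):
            add("study", sex="M" if study_counter % 2 == 0 else "F")
            study_counter += 1
    samples = pd.DataFrame(rows).set_index("sample_id")

    # --- ground truth draws (fixed order for determinism) --------------
    mu = rng.uniform(*config.abundance_log2_mean_range, size=len(protein_ids))
    sd = rng.uniform(*config.abundance_log2_sd_range, size=len(protein_ids))
    analyte_mu = pd.Series(mu, index=protein_ids)
    analyte_sd = pd.Series(sd, index=protein_ids)

    hyb_reference = pd.Series(
        10.0 ** rng.uniform(3.0, 4.0, size=len(hyb_ids)), index=hyb_ids
    )

    biased = samples.index[samples["sample_type"] != "buffer"]
    h = pd.Series(
        np.exp(rng.uniform(*np.log(config.hyb_bias_range), size=len(biased))),
        index=biased,
    )
    if config.hyb_bias_overrides:
        for sid, val in config.hyb_bias_overrides.items():
            if sid not in h.index:
                raise ConfigError(f"hyb_bias_overrides: unknown sample '{sid}'")
            h.loc[sid] = float(val)
    # pipetting bias: per-sample concentration component (tight for pooled
    # qc/calibrator material) times a small independent per-bin jitter
    c = np.exp(rng.uniform(*np.log(config.pipette_bias_range), size=len(biased)))
    pooled_mask = samples.loc[biased, "sample_type"].isin(["qc", "calibrator"]).to_numpy()
    c[pooled_mask] = np.exp(
        rng.uniform(*np.log(config.pooled_pipette_bias_range), size=int(pooled_mask.sum()))
    )
    jitter = np.exp(rng.uniform(*np.log(config.bin_jitter_range), size=(len(biased), 3)))
    m = pd.DataFrame(c[:, None] * jitter, index=biased, columns=list(DILUTION_BINS))
    g_log2 = rng.normal(0.0, config.plate_effect_sd, size=(len(plate_ids), len(protein_ids)))
    if config.plate_shift_log2:
        for plate, shift in config.plate_shift_log2.items():
            if plate not in plate_ids:
                raise ConfigError(f"plate_shift_log2: unknown plate '{plate}'")
            g_log2[plate_ids.index(plate), :] += float(shift)
    g = pd.DataFrame(2.0 ** g_log2, index=plate_ids, columns=protein_ids)

    calibrator_pool = pd.Series(
        rng.normal(analyte_mu.to_numpy(), analyte_sd.to_numpy()), index=protein_ids
    )

    # latent abundances for study and qc wells; calibrators share the pool
    own_latent_idx = samples.index[samples["sample_type"].isin(["study", "qc"])]
    latent = rng.normal(
        analyte_mu.to_numpy()[None, :],
        analyte_sd.to_numpy()[None, :],
        size=(len(own_latent_idx), len(protein_ids)),
    )
    latent = pd.DataFrame(latent, index=own_latent_idx, columns=protein_ids)
    male = samples.loc[own_latent_idx, "sex"] == "M"
    latent.loc[male.index[male], sex_analyte] += config.sex_effect_log2

    cal_idx = samples.index[samples["sample_type"] == "calibrator"]
    latent_all = pd.concat(
        [
            latent,
            pd.DataFrame(
                np.tile(calibrator_pool.to_numpy(), (len(cal_idx), 1)),
                index=cal_idx,
                columns=protein_ids,
            ),
        ]
    ).loc[biased]

    # --- assemble RFU matrix -------------------------------------------
    bg_mu, bg_sigma = _lognormal_params(config.background_mean, config.background_cv)
    n_samples, n_analytes = len(samples), len(analytes)
    rfu = np.empty((n_samples, n_analytes))
    rfu[:] = rng.lognormal(bg_mu, bg_sigma, size=(n_samples, n_analytes))

    sample_pos = {s: i for i, s in enumerate(samples.index)}
    col_pos = {a: j for j, a in enumerate(analytes.index)}
    prot_cols = np.array([col_pos[a] for a in protein_ids])
    bins_arr = np.array([bin_of[a] for a in protein_ids])

    biased_pos = np.array([sample_pos[s] for s in biased])
    h_arr = h.loc[biased].to_numpy()
    m_arr = np.empty((len(biased), len(protein_ids)))
    for bi, b in enumerate(DILUTION_BINS):
        m_arr[:, bins_arr == b] = m.loc[biased, b].to_numpy()[:, None]
    plate_of = samples.loc[biased, "plate_id"].to_numpy()
    g_arr = g.loc[plate_of, protein_ids].to_numpy()
    signal = 2.0 ** latent_all.loc[biased, protein_ids].to_numpy()
    rfu[np.ix_(biased_pos, prot_cols)] += h_arr[:, None] * m_arr * g_arr * signal

    hyb_cols = np.array([col_pos[c] for c in hyb_ids])
    eps = rng.normal(0.0, config.hyb_control_cv, size=(len(biased), len(hyb_ids)))
    rfu[np.ix_(biased_pos, hyb_cols)] = (
        h_arr[:, None] * hyb_reference.to_numpy()[None, :] * (1.0 + eps)
    )

    dataset = Dataset(
        samples=samples,
        analytes=analytes,
        rfu=pd.DataFrame(rfu, index=samples.index.copy(), columns=analytes.index.copy()),
        references=ReferenceValues(hyb=dict(hyb_reference)),
    )
    errors = [f for f in validate_dataset(dataset) if f.severity == "error"]
    if errors:  # pragma: no cover - generator contract
        raise ConfigError(f"generated dataset failed validation: {errors[0].message}")

    truth = GroundTruth(
        h=h,
        m=m,
        g=g,
        latent_log2=latent_all,
        calibrator_pool_log2=calibrator_pool,
        analyte_mu_log2=analyte_mu,
        analyte_sd_log2=analyte_sd,
        sex_effect_analyte=sex_analyte,
        sex_effect_log2=config.sex_effect_log2,
    )
    return dataset, truth


def simulate_elisa(
    ground_truth: GroundTruth,
    dataset: Dataset,
    analyte_ids: list[str],
    lambda_map: dict[str, float],
    noise_cv_map: dict[str, float],
    slope_map: dict[str, float] | None = None,
    seed: int = 0,
) -> ElisaTable:
    """Paired immunoassay concentrations for study samples.

    For each study sample *i* and analyte *a* the immunoassay sees an
    attenuated latent ``lam*latent + (1-lam)*z`` where ``z`` is an
    independent Normal draw with the analyte's own marginal mean and SD —
    ``lam`` models shared epitope recognition between the aptamer reagent
    and the antibody pair (lam=1: same epitope; lam=0: unrelated isoform).
    Concentration = ``slope * 2**latent_elisa * (1+eta)``,
    eta ~ Normal(0, noise_cv).
    """
    rng = np.random.default_rng(seed)
    slope_map = slope_map or {}
    study = dataset.sample_ids("study")
    rows = []
    for a in analyte_ids:
        if a not in ground_truth.latent_log2.columns:
            raise KeyError(f"unknown analyte id '{a}'")
        lam = float(lambda_map[a])
        if not 0.0 <= lam <= 1.0:
            raise ConfigError(f"lambda for '{a}' must lie in [0, 1], got {lam}")
        cv = float(noise_cv_map[a])
        slope = float(slope_map.get(a, 1.0))
        latent = ground_truth.latent_log2.loc[study, a].to_numpy()
        z = rng.normal(
            ground_truth.analyte_mu_log2[a],
            ground_truth.analyte_sd_log2[a],
            size=len(study),
        )
        eta = rng.normal(0.0, cv, size=len(study)) if cv > 0 else np.zeros(len(study))
        conc = slope * 2.0 ** (lam * latent + (1.0 - lam) * z) * (1.0 + eta)
        rows.extend(
            {"sample_id": s, "seq_id": a, "concentration": c}
            for s, c in zip(study, conc)
        )
    return ElisaTable(
        values=pd.DataFrame(rows, columns=["sample_id", "seq_id", "concentration"]),
        lambda_map={a: float(lambda_map[a]) for a in analyte_ids},
        noise_cv_map={a: float(noise_cv_map[a]) for a in analyte_ids},
    )


#: fixture scale: 2 plates x (1 buffer + 2 qc + 5 calibrator + 8 study),
#: 20 proteins + 6 hyb controls + 2 negative controls
FIXTURE_CONFIG = SimConfig(
    n_plates=2,
    samples_per_plate=8,
    n_protein_analytes=20,
    n_hyb_controls=6,
    n_negative_controls=2,
)


def make_fixture_small(seed: int = 0) -> tuple[Dataset, GroundTruth, ElisaTable]:
    """Small deterministic fixture used throughout the test suite.

    Pairs the dataset with an immunoassay table for two analytes: one in a
    well-correlated regime (lam=0.97, 5% noise) and one epitope-mismatched
    (lam=0.2, 5% noise).
    """
    config = replace(FIXTURE_CONFIG, seed=seed)
    dataset, truth = simulate_dataset(config)
    proteins = dataset.protein_ids
    high, low = proteins[1], proteins[2]
    elisa = simulate_elisa(
        truth,
        dataset,
        [high, low],
        lambda_map={high: 0.97, low: 0.2},
        noise_cv_map={high: 0.05, low: 0.05},
        slope_map={high: 1.3, low: 0.8},
        seed=seed + 1,
    )
    return dataset, truth, elisa
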