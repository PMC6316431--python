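"""Normalization cascade: worked scale-factor arithmetic, stage ordering,
bias recovery on simulated data, and the matrix transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somaqc.datamodel import Dataset, ReferenceValues
from somaqc.errors import ConfigError, DataValueError, OrderingError
from somaqc.normalize import (
    calibration_normalize,
    hybridization_normalize,
    log_transform,
    median_signal_normalize,
    quantile_normalize,
)
from somaqc.simulate import SimConfig, simulate_dataset


def _manual_dataset(rfu_rows, hyb_ref, n_hyb=1, roles=None, plates=None):
    """Hand-built dataset: last n_hyb columns are hybridization controls."""
    n, p = np.shape(rfu_rows)
    n_prot = p - n_hyb
    roles = roles or ["study"] * n
    plates = plates or ["P1"] * n
    samples = pd.DataFrame(
        {
            "sample_type": roles,
            "plate_id": plates,
            "subarray_id": [f"W{i}" for i in range(n)],
            "sex": ["unknown"] * n,
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )
    analytes = pd.DataFrame(
        {
            "target_name": [f"T{j}" for j in range(p)],
            "uniprot_id": [""] * p,
            "dilution_bin": ["1%"] * n_prot + ["CONTROL"] * n_hyb,
            "analyte_type": ["protein"] * n_prot + ["hybridization_control"] * n_hyb,
        },
        index=pd.Index([f"A{j}" for j in range(n_prot)] + [f"H{j}" for j in range(n_hyb)],
                       name="seq_id"),
    )
    rfu = pd.DataFrame(np.asarray(rfu_rows, dtype=float),
                       index=samples.index.copy(), columns=analytes.index.copy())
    return Dataset(samples, analytes, rfu,
                   ReferenceValues(hyb={f"H{j}": hyb_ref[j] for j in range(n_hyb)}))


# ---------------------------------------------------------------------------
# hybridization normalization


def test_hyb_sf_identity_when_controls_on_reference():
    ds = _manual_dataset([[100.0, 3000.0]], hyb_ref=[3000.0])
    out, sfs = hybridization_normalize(ds)
    assert sfs.hyb["S0"] == pytest.approx(1.0)
    assert out.rfu.at["S0", "A0"] == pytest.approx(100.0)


def test_hyb_sf_half_reference_gives_two():
    ds = _manual_dataset([[100.0, 1500.0, 1000.0]], hyb_ref=[3000.0, 2000.0], n_hyb=2)
    out, sfs = hybridization_normalize(ds)
    assert sfs.hyb["S0"] == pytest.approx(2.0)
    assert out.rfu.at["S0", "A0"] == pytest.approx(200.0)


def test_hyb_sf_is_median_of_ratios():
    # reference/observed ratios {0.5, 1.0, 2.0} -> median 1.0
    ds = _manual_dataset(
        [[10.0, 6000.0, 2000.0, 1000.0]], hyb_ref=[3000.0, 2000.0, 2000.0], n_hyb=3
    )
    _, sfs = hybridization_normalize(ds)
    assert sfs.hyb["S0"] == pytest.approx(1.0)


def test_hyb_requires_controls_and_references():
    ds = _manual_dataset([[100.0, 3000.0]], hyb_ref=[3000.0])
    ds.analytes.loc["H0", "analyte_type"] = "negative_control"
    with pytest.raises(ConfigError):
        hybridization_normalize(ds)
    ds2 = _manual_dataset([[100.0, 3000.0]], hyb_ref=[3000.0])
    ds2.references.hyb.clear()
    with pytest.raises(KeyError):
        hybridization_normalize(ds2)


def test_hyb_post_median_ratio_unity():
    """After the stage, each sample's hyb controls have median ratio 1 to
    their references (exact with an odd control count, where the median is
    a single order statistic)."""
    ds, _ = simulate_dataset(
        SimConfig(n_plates=1, samples_per_plate=6, n_protein_analytes=10,
                  n_hyb_controls=5, n_negative_controls=2, seed=2)
    )
    ds1, _ = hybridization_normalize(ds)
    ref = pd.Series(ds1.references.hyb)
    ratios = ds1.rfu[ds1.hyb_control_ids] / ref[ds1.hyb_control_ids]
    med = ratios.median(axis=1)
    assert np.allclose(med.to_numpy(), 1.0, rtol=1e-12)


# ---------------------------------------------------------------------------
# median signal normalization


def _hyb_done(ds):
    out, _ = hybridization_normalize(ds)
    return out


def test_median_requires_hyb_first():
    ds = _manual_dataset([[1.0, 3000.0]] * 5, hyb_ref=[3000.0])
    with pytest.raises(OrderingError):
        median_signal_normalize(ds)


def test_median_identical_samples_unit_factors():
    rows = [[10.0, 20.0, 30.0, 3000.0]] * 5
    ds = _hyb_done(_manual_dataset(rows, hyb_ref=[3000.0]))
    out, sfs = median_signal_normalize(ds)
    assert np.allclose(sfs.median["1%"].to_numpy(), 1.0)
    np.testing.assert_allclose(out.rfu.to_numpy(), ds.rfu.to_numpy())


def test_median_doubled_sample_gets_half():
    rows = [[10.0, 20.0, 30.0, 3000.0]] * 4 + [[20.0, 40.0, 60.0, 3000.0]]
    ds = _hyb_done(_manual_dataset(rows, hyb_ref=[3000.0]))
    _, sfs = median_signal_normalize(ds)
    assert sfs.median.at["S4", "1%"] == pytest.approx(0.5)


def test_median_even_count_ratio_convention():
    """Ratios {1.2, 1.4, 1.6, 1.8} against the profile -> SF = 1/1.5."""
    profile = np.array([10.0, 20.0, 40.0, 80.0])
    rows = [list(profile) + [3000.0] for _ in range(4)]
    rows.append(list(profile * np.array([1.2, 1.4, 1.6, 1.8])) + [3000.0])
    ds = _hyb_done(_manual_dataset(rows, hyb_ref=[3000.0]))
    _, sfs = median_signal_normalize(ds)
    assert sfs.median.at["S4", "1%"] == pytest.approx(1 / 1.5)


def test_median_small_group_raises():
    rows = [[10.0, 3000.0]] * 2
    ds = _hyb_done(_manual_dataset(rows, hyb_ref=[3000.0]))
    with pytest.raises(ConfigError, match="plate P1"):
        median_signal_normalize(ds)


def test_median_calibrators_normalized_within_role():
    """Calibrator wells at a common 10x offset from study wells keep unit
    factors: roles never mix profiles."""
    study_rows = [[10.0, 20.0, 3000.0]] * 4
    cal_rows = [[100.0, 200.0, 3000.0]] * 3
    ds = _manual_dataset(
        study_rows + cal_rows,
        hyb_ref=[3000.0],
        roles=["study"] * 4 + ["calibrator"] * 3,
    )
    ds = _hyb_done(ds)
    _, sfs = median_signal_normalize(ds)
    cal_ids = [f"S{i}" for i in range(4, 7)]
    assert np.allclose(sfs.median.loc[cal_ids, "1%"].to_numpy(), 1.0)


# ---------------------------------------------------------------------------
# calibration normalization


def _two_plate_for_cal(plate2_scale=1.3):
    rows, roles, plates = [], [], []
    for p, scale in (("P1", 1.0), ("P2", plate2_scale)):
        for i in range(4):
            rows.append([10.0 * scale, 40.0 * scale, 3000.0])
            roles.append("study")
            plates.append(p)
        for i in range(3):
            rows.append([10.0 * scale, 40.0 * scale, 3000.0])
            roles.append("calibrator")
            plates.append(p)
    ds = _manual_dataset(rows, hyb_ref=[3000.0], roles=roles, plates=plates)
    ds, _ = hybridization_normalize(ds)
    ds, _ = median_signal_normalize(ds)
    return ds


def test_calibration_requires_median_first(fixture_small):
    ds, _, _ = fixture_small
    ds1, _ = hybridization_normalize(ds)
    with pytest.raises(OrderingError):
        calibration_normalize(ds1)


def test_calibration_single_plate_unit_factors():
    rows = [[10.0, 40.0, 3000.0]] * 4 + [[10.0, 40.0, 3000.0]] * 3
    ds = _manual_dataset(rows, hyb_ref=[3000.0],
                         roles=["study"] * 4 + ["calibrator"] * 3)
    ds, _ = hybridization_normalize(ds)
    ds, _ = median_signal_normalize(ds)
    _, sfs = calibration_normalize(ds)
    assert np.allclose(sfs.cal.to_numpy(), 1.0)


def test_calibration_two_plate_median_arithmetic():
    """Plate 2 calibrators at 1.3x plate 1: internal reference is the
    cross-plate median 1.15x, so SF1 = 1.15 and SF2 = 1.15/1.3."""
    ds = _two_plate_for_cal(1.3)
    _, sfs = calibration_normalize(ds)
    assert np.allclose(sfs.cal.loc["P1"].to_numpy(), 1.15)
    assert np.allclose(sfs.cal.loc["P2"].to_numpy(), 1.15 / 1.3)


def test_calibration_external_reference_substitution():
    ds = _two_plate_for_cal(1.3)
    external = {"A0": 10.0, "A1": 40.0}  # plate 1's calibrator medians
    _, sfs = calibration_normalize(ds, calibrator_reference=external)
    assert np.allclose(sfs.cal.loc["P1"].to_numpy(), 1.0)
    assert np.allclose(sfs.cal.loc["P2"].to_numpy(), 1 / 1.3)


def test_calibration_missing_calibrators_raises():
    rows = [[10.0, 3000.0]] * 4
    ds = _manual_dataset(rows, hyb_ref=[3000.0])
    ds, _ = hybridization_normalize(ds)
    ds, _ = median_signal_normalize(ds)
    with pytest.raises(ConfigError, match="no calibrator"):
        calibration_normalize(ds)


def test_calibration_nonpositive_reference_raises():
    ds = _two_plate_for_cal()
    with pytest.raises(DataValueError):
        calibration_normalize(ds, calibrator_reference={"A0": -1.0, "A1": 40.0})


# ---------------------------------------------------------------------------
# recovery on simulated data


def test_hyb_sf_recovery_proportional_to_inverse_bias():
    config = SimConfig(n_plates=2, samples_per_plate=25, n_protein_analytes=60,
                       hyb_bias_range=(0.5, 2.0), seed=21)
    ds, truth = simulate_dataset(config)
    _, sfs = hybridization_normalize(ds)
    r = np.corrcoef(np.log(sfs.hyb.loc[truth.h.index]), -np.log(truth.h))[0, 1]
    assert r >= 0.999


def test_per_bin_pipette_recovery_with_jitter():
    """With independent per-bin dilution errors enabled, the per-bin scale
    factors still recover each bin's own bias: SF_{i,d} * m_{i,d} is
    near-constant across samples within every plate and bin."""
    config = SimConfig(n_plates=2, samples_per_plate=40, n_protein_analytes=200,
                       bin_jitter_range=(0.8, 1.25), seed=31)
    ds, truth = simulate_dataset(config)
    d1, _ = hybridization_normalize(ds)
    _, med = median_signal_normalize(d1)
    st = ds.samples
    for plate in ds.plate_ids:
        study = st.index[(st["sample_type"] == "study") & (st["plate_id"] == plate)]
        for b in ("0.005%", "1%", "40%"):
            prod = med.median.loc[study, b] * truth.m.loc[study, b]
            assert prod.std() / prod.mean() < 0.03, (plate, b)
    # the three bins' biases really are distinct for a given sample
    spread = truth.m.loc[ds.sample_ids("study")].max(axis=1) / truth.m.min(axis=1)
    assert (spread > 1.05).mean() > 0.8


def test_single_sample_scaling_does_not_leak():
    """Scaling one sample's raw RFUs only changes that sample's factors;
    other samples' normalized values are untouched (median profiles with
    >= 5 samples are insensitive to one row)."""
    config = SimConfig(n_plates=1, samples_per_plate=10, n_protein_analytes=30,
                       n_hyb_controls=6, n_negative_controls=2, seed=4)
    ds, _ = simulate_dataset(config)
    target = ds.sample_ids("study")[0]
    scaled = ds.copy()
    scaled.rfu.loc[target] *= 1.7

    def run(d):
        d1, _ = hybridization_normalize(d)
        d2, _ = median_signal_normalize(d1)
        return d2

    base, pert = run(ds), run(scaled)
    others = [s for s in ds.samples.index if s != target]
    np.testing.assert_allclose(
        base.rfu.loc[others].to_numpy(), pert.rfu.loc[others].to_numpy(), rtol=1e-10
    )


# ---------------------------------------------------------------------------
# quantile normalization and log transform


def test_quantile_worked_example_2x2():
    out = quantile_normalize(np.array([[1.0, 3.0], [2.0, 4.0]]))
    np.testing.assert_allclose(out, [[1.5, 3.5], [1.5, 3.5]])


def test_quantile_identical_rows_unchanged():
    X = np.tile([5.0, 1.0, 3.0], (4, 1))
    np.testing.assert_allclose(quantile_normalize(X), X)


def test_quantile_ties_get_mean_of_occupied_ranks():
    X = np.array([[5.0, 5.0, 1.0], [1.0, 2.0, 3.0], [10.0, 20.0, 30.0]])
    out = quantile_normalize(X)
    assert out[0, 0] == out[0, 1]
    ref = np.sort(X, axis=1).mean(axis=0)
    assert out[0, 0] == pytest.approx(ref[1:].mean())
    assert out[0, 2] == pytest.approx(ref[0])


def test_quantile_single_sample_warns_noop():
    X = np.array([[1.0, 2.0]])
    with pytest.warns(UserWarning):
        out = quantile_normalize(X)
    np.testing.assert_array_equal(out, X)


@settings(max_examples=25, deadline=None)
@given(
    st.integers(2, 6),
    st.integers(2, 8),
    st.integers(0, 10_000),
)
def test_quantile_rows_share_sorted_vector(n, p, seed):
    """Postcondition: with tie-free rows, every row's sorted vector equals
    the reference distribution exactly."""
    rng = np.random.default_rng(seed)
    X = rng.lognormal(8, 1, size=(n, p))
    out = quantile_normalize(X)
    sorted_rows = np.sort(out, axis=1)
    for i in range(1, n):
        np.testing.assert_array_equal(sorted_rows[i], sorted_rows[0])


def test_log_transform_values_and_round_trip():
    X = np.array([[1.0, 8.0], [2.0, 1024.0]])
    out = log_transform(X, base=2)
    np.testing.assert_allclose(out, [[0.0, 3.0], [1.0, 10.0]])
    back = 2.0 ** log_transform(X, base=2)
    np.testing.assert_allclose(back, X, rtol=1e-12)
    out10 = log_transform(np.array([[100.0]]), base=10)
    assert out10[0, 0] == pytest.approx(2.0)


def test_log_transform_nonpositive_named():
    X = pd.DataFrame([[1.0, -2.0]], index=["s"], columns=["a", "b"])
    with pytest.raises(DataValueError, match="'s'.*'b'"):
        log_transform(X)
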