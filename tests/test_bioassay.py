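import numpy as np
import pytest

from bbbkit import bioassay as ba
from bbbkit import synthetic_data as synth


# ---------------------------------------------------------------------------
# Linear calibration

def test_calibration_recovers_printed_line():
    """Noiseless points on y = 12491x - 12671 refit the line exactly."""
    amounts = [2.0, 4.0, 6.0, 8.0, 10.0]
    points = [(a, 12491.0 * a - 12671.0) for a in amounts]
    curve = ba.fit_linear_calibration(points)
    assert curve.slope == pytest.approx(12491.0, abs=1e-8)
    assert curve.intercept == pytest.approx(-12671.0, abs=1e-7)
    assert curve.r_squared == pytest.approx(1.0)


def test_two_point_calibration_r2_is_one():
    curve = ba.fit_linear_calibration([(1.0, 3.0), (2.0, 17.0)])
    assert curve.r_squared == pytest.approx(1.0)


def test_noisy_calibration_matches_normal_equations_oracle():
    rng = np.random.default_rng(7)
    x = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    y = 12491.0 * x - 12671.0 + rng.normal(scale=500.0, size=5)
    curve = ba.fit_linear_calibration(list(zip(x, y)))
    n = len(x)
    slope = (n * (x * y).sum() - x.sum() * y.sum()) / \
        (n * (x * x).sum() - x.sum() ** 2)
    intercept = (y.sum() - slope * x.sum()) / n
    assert curve.slope == pytest.approx(slope, abs=1e-10)
    assert curve.intercept == pytest.approx(intercept, abs=1e-8)


def test_degenerate_calibration_rejected():
    with pytest.raises(ValueError):
        ba.fit_linear_calibration([(2.0, 1.0), (2.0, 2.0)])
    with pytest.raises(ValueError):
        ba.fit_linear_calibration([(2.0, 1.0)])


# ---------------------------------------------------------------------------
# Viability

def test_viability_examples():
    assert ba.viability_percent(0.9, 0.9, 0.1) == pytest.approx(100.0)
    assert ba.viability_percent(0.1, 0.9, 0.1) == pytest.approx(0.0)
    assert ba.viability_percent(0.55, 0.90, 0.10) == pytest.approx(56.25)


def test_viability_inhibition_complement():
    v = ba.viability_percent(0.47, 0.91, 0.08)
    i = ba.inhibition_percent(0.47, 0.91, 0.08)
    assert v + i == pytest.approx(100.0, abs=1e-12)


def test_viability_requires_control_above_blank():
    with pytest.raises(ValueError):
        ba.viability_percent(0.5, 0.1, 0.1)


# ---------------------------------------------------------------------------
# Dose-response IC50

def test_4pl_noiseless_parameter_recovery():
    """Noiseless 4PL data give back all four parameters to 1e-6 relative."""
    doses = np.geomspace(50, 2000, 12)
    truth = dict(bottom=8.0, top=102.0, ic50=715.0, hill=1.3)
    responses = ba.four_pl(doses, truth["bottom"], truth["top"],
                           truth["ic50"], truth["hill"])
    fit = ba.fit_four_pl(doses, responses, seed=0)
    assert fit.bottom == pytest.approx(truth["bottom"], rel=1e-6)
    assert fit.top == pytest.approx(truth["top"], rel=1e-6)
    assert fit.midpoint == pytest.approx(truth["ic50"], rel=1e-6)
    assert fit.hill == pytest.approx(truth["hill"], rel=1e-6)


def test_ic50_round_trip_on_generated_plate():
    """ic50_dose_response recovers the generator midpoint within 0.1%."""
    plate = synth.gen_mtt_plate(ic50=715.0, hill=1.1, noise_sd=0.0, seed=0)
    curve = ba.plate_to_dose_response(plate)
    result = ba.ic50_dose_response(curve, seed=0)
    assert result.method == "4pl"
    assert result.ic50 == pytest.approx(715.0, rel=1e-3)


def test_interpolation_on_printed_viability_triplet():
    """Linear interpolation between the bracketing printed viabilities:
    300 + (61-50)/(61-43)*700 = 727.78 (a convention check)."""
    curve = ba.DoseResponseCurve([100.0, 300.0, 1000.0], [71.5, 61.0, 43.0])
    result = ba.ic50_dose_response(curve, method="interpolation")
    assert result.method == "interpolation"
    assert result.ic50 == pytest.approx(300 + 11 / 18 * 700, abs=1e-9)


def test_ic50_unidentifiable_when_not_bracketed():
    curve = ba.DoseResponseCurve([10.0, 100.0], [90.0, 70.0])
    with pytest.raises(ValueError, match="not identifiable"):
        ba.ic50_dose_response(curve)


def test_ic50_invariant_to_dose_rescaling():
    plate = synth.gen_mtt_plate(ic50=500.0, hill=0.9, noise_sd=0.005, seed=6)
    curve = ba.plate_to_dose_response(plate)
    scaled = ba.DoseResponseCurve(curve.doses * 3.0, curve.responses)
    r1 = ba.ic50_dose_response(curve, seed=1)
    r2 = ba.ic50_dose_response(scaled, seed=1)
    assert r2.ic50 == pytest.approx(3.0 * r1.ic50, rel=1e-4)


def test_dose_response_validation():
    with pytest.raises(ValueError):
        ba.DoseResponseCurve([0.0, 1.0], [60.0, 40.0])
    with pytest.raises(ValueError):
        ba.DoseResponseCurve([1.0, 2.0], [np.nan, 40.0])


# ---------------------------------------------------------------------------
# TLC-bioautography IC50

def _conversion(zone_volume):
    return ba.TLCConversion(molar_mass_g_per_mol=456.7,
                            stock_conc_mg_per_ml=1.0,
                            zone_volume_ul=zone_volume)


def test_tlc_linear_solve():
    """Calibration y = 2x with reference 100 solves to amount 25."""
    curve = ba.CalibrationCurve(slope=2.0, intercept=0.0, r_squared=1.0)
    assert ba.solve_calibration_amount(curve, 50.0) == pytest.approx(25.0)


def test_tlc_half_reference_identity():
    """reference = 2*(slope*x0 + intercept) makes the solved amount x0."""
    curve = ba.CalibrationCurve(slope=12491.0, intercept=-12671.0,
                                r_squared=0.981)
    x0 = 3.7
    reference = 2.0 * (curve.slope * x0 + curve.intercept)
    amount = ba.solve_calibration_amount(curve, 0.5 * reference)
    assert amount == pytest.approx(x0, abs=1e-10)


def test_tlc_ic50_unit_round_trip():
    """A conversion record constructed so the answer is 9.22 µM round-trips
    within 0.1% through the full calibration -> molarity path."""
    curve = ba.CalibrationCurve(slope=12491.0, intercept=-12671.0,
                                r_squared=0.981)
    x0 = 2.0  # µL of a 1 mg/mL stock, i.e. 0.002 mg applied
    reference = 2.0 * (curve.slope * x0 + curve.intercept)
    # µM = amount_µL * stock * 1e6 / (MW * zone_volume_µL); invert for 9.22
    zone_volume = x0 * 1.0 * 1e6 / (456.7 * 9.22)
    value = ba.ic50_tlc(curve, reference, _conversion(zone_volume))
    assert value == pytest.approx(9.22, rel=1e-3)


def test_tlc_negative_amount_rejected():
    # half-reference (50) below the intercept (100) solves to x < 0
    curve = ba.CalibrationCurve(slope=2.0, intercept=100.0, r_squared=1.0)
    with pytest.raises(ValueError, match="<= 0"):
        ba.ic50_tlc(curve, 100.0, _conversion(100.0))


def test_tlc_missing_constant_rejected():
    curve = ba.CalibrationCurve(slope=2.0, intercept=0.0, r_squared=1.0)
    bad = ba.TLCConversion(molar_mass_g_per_mol=456.7,
                           stock_conc_mg_per_ml=0.0, zone_volume_ul=10.0)
    with pytest.raises(ValueError, match="stock_conc"):
        ba.ic50_tlc(curve, 100.0, bad)


# ---------------------------------------------------------------------------
# Table readers

def test_plate_reader_and_dose_response(tmp_path):
    plate = synth.gen_mtt_plate(noise_sd=0.0, seed=0)
    path = tmp_path / "plate.csv"
    plate.to_csv(path, index=False)
    curve = ba.plate_to_dose_response(ba.read_plate_csv(path))
    assert np.all(np.diff(curve.doses) > 0)
    assert curve.responses.max() <= 100.0 + 1e-9


def test_densitometry_reader_averages_replicates(tmp_path):
    df = synth.gen_densitometry(noise_sd=100.0, seed=1, n_replicates=3)
    path = tmp_path / "tlc.csv"
    df.to_csv(path, index=False)
    points = ba.read_densitometry_csv(path)
    assert len(points) == 5   # five applied volumes
    amounts = [a for a, _ in points]
    assert amounts == sorted(amounts)
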