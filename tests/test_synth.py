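"""Synthetic generator: determinism, case construction, instrument rendering."""
import numpy as np
import pandas as pd
import pytest

from oascreen.quant import calibrate_batch, check_batch_qc, quantify_injection
from oascreen.signals_io import SampleMeta
from oascreen.synth import (
    CaseSpec,
    InstrumentModel,
    SynthError,
    default_case_specs,
    default_cohort_spec,
    render_instrument_data,
    simulate_case,
    simulate_cohort,
    simulate_calibration_r2,
)


def test_cohort_is_deterministic(panel):
    spec = default_cohort_spec(panel, seed=21, n_per_group=4)
    _, t1 = simulate_cohort(spec, panel)
    _, t2 = simulate_cohort(spec, panel)
    pd.testing.assert_frame_equal(t1, t2)


def test_zero_sd_collapses_to_geometric_mean(panel):
    spec = default_cohort_spec(panel, seed=1, n_per_group=3)
    name = "Lactic acid"
    mean, _ = spec.analyte_params[name]
    spec.analyte_params[name] = (mean, 0.0)
    samples, _ = simulate_cohort(spec, panel)
    for sq in samples:
        assert sq.results[name].conc_norm == pytest.approx(2.0 ** mean)


def test_unit_fold_case_equals_control_draw(panel):
    spec = default_cohort_spec(panel, seed=5, n_per_group=2)
    case = CaseSpec(disease="null", fold_changes={"Glutaric acid": 1.0})
    a = simulate_case(case, spec, panel, seed=77)
    b = simulate_case(CaseSpec(disease="null2", fold_changes={}), spec, panel, seed=77)
    assert a.results["Glutaric acid"].conc_norm == pytest.approx(
        b.results["Glutaric acid"].conc_norm
    )


def test_case_rejects_off_panel_biomarker(panel):
    spec = default_cohort_spec(panel, seed=1, n_per_group=2)
    with pytest.raises(SynthError, match="not in panel"):
        simulate_case(CaseSpec(disease="x", fold_changes={"unobtainium": 5.0}),
                      spec, panel)


def test_oxoprolinuria_without_paracetamol_markers(panel):
    """Pyroglutamic elevated while both medication markers stay absent."""
    spec = default_cohort_spec(panel, seed=9)
    case = simulate_case(default_case_specs()["OXOPRO"], spec, panel, seed=10)
    base = simulate_case(CaseSpec(disease="null", fold_changes={}), spec, panel, seed=10)
    assert (case.results["Pyroglutamic acid"].conc_norm
            == pytest.approx(30.0 * base.results["Pyroglutamic acid"].conc_norm))
    for med in ("Acetaminophen glucuronide", "Acetaminophensulphate"):
        assert case.results[med].below_lod


def test_medication_markers_injected_when_specified(panel):
    spec = default_cohort_spec(panel, seed=9)
    case = CaseSpec(disease="paracetamol", fold_changes={},
                    medication_markers=["Acetaminophen glucuronide",
                                        "Acetaminophensulphate"])
    sq = simulate_case(case, spec, panel, seed=3)
    for med in case.medication_markers:
        res = sq.results[med]
        assert not res.below_lod and res.conc_norm > spec.lods[med]


def test_simulated_calibrations_are_linear(panel):
    r2 = simulate_calibration_r2(panel, seed=0, noise_cv=0.05)
    assert len(r2) == 68
    assert min(r2.values()) > 0.9


@pytest.fixture(scope="module")
def rendered_batch():
    from oascreen.panel import load_default_panel

    panel = load_default_panel()
    spec = default_cohort_spec(panel, seed=2, n_per_group=2)
    controls, _ = simulate_cohort(spec, panel)
    args = []
    for sq in controls[:2]:
        meta = SampleMeta(sample_type="control", age_group=sq.age_group,
                          creatinine_mm=sq.creatinine_mm,
                          dilution_factor=sq.dilution_factor)
        args.append((sq.sample_id, meta,
                     {n: r.conc for n, r in sq.results.items() if r.conc > 0}))
    model = InstrumentModel(seed=2)  # noise-free
    pls, injections, manifest, levels = render_instrument_data(args, panel, model)
    return panel, controls[:2], pls, injections, manifest, levels


def test_batch_layout_and_qc_placement(rendered_batch):
    panel, _, pls, injections, manifest, _ = rendered_batch
    types = [i.sample_type for i in injections]
    assert types[:2] == ["qc", "blank"]
    assert types[2:8] == ["calibrant"] * 6
    assert check_batch_qc(injections).placement_ok
    assert len(manifest) == len(pls)


def test_blank_quantifies_below_lod(rendered_batch):
    panel, _, pls, injections, _, levels = rendered_batch
    cal = [(levels[k], pls[2 + k]) for k in range(6)]
    curves = calibrate_batch(cal, panel)
    blank = pls[1]
    quant = quantify_injection(blank, panel, curves)
    assert all(res.below_lod for res in quant.results.values())


def test_noise_free_round_trip_recovers_truth(rendered_batch):
    """truth -> peaks -> EIC -> areas -> concentrations, error < 0.5%."""
    panel, truths, pls, injections, _, levels = rendered_batch
    cal = [(levels[k], pls[2 + k]) for k in range(6)]
    curves = calibrate_batch(cal, panel)
    assert min(c.r2 for c in curves.values()) > 0.9999
    for sq, pl in zip(truths, pls[8:10]):
        quant = quantify_injection(pl, panel, curves)
        for name, res in quant.results.items():
            truth = sq.results[name].conc
            if truth > 0:
                assert res.conc == pytest.approx(truth, rel=0.005), name


def test_rendered_eic_apex_near_generating_rt(rendered_batch):
    from oascreen.signals_io import extract_eic, integrate_peak

    panel, truths, pls, *_ = rendered_batch
    entry = panel.get("Citric acid")
    eic = extract_eic(pls[8], entry.target_mz, 10)
    meas = integrate_peak(eic, entry.rt, 0.2)
    assert meas.found
    # apex within one scan (1/8 Hz = 0.0021 min) of the generating RT
    assert meas.rt_apex == pytest.approx(entry.rt, abs=0.003)
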