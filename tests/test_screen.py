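"""Reference building, z-score rules, flagging, profile plotting."""
import math

import numpy as np
import pytest

from oascreen.quant import AnalyteResult, SampleQuant
from oascreen.screen import (
    ND_SD_LOG2,
    RefEntry,
    ReferenceStats,
    ScreenError,
    assign_age_group,
    build_reference,
    profile_sample,
    render_profile_plot,
    zscore,
)
from oascreen.synth import default_case_specs, default_cohort_spec, simulate_case, simulate_cohort


def _control(sample_id, values, age_group="0-2y", below=()):
    sq = SampleQuant(sample_id=sample_id, age_group=age_group, creatinine_mm=1.0)
    for name, v in values.items():
        sq.results[name] = AnalyteResult(conc=v, conc_norm=v,
                                         below_lod=name in below)
    return sq


def test_not_detected_constant_is_log2_of_5_over_3():
    """0.774 is exactly the SD making 5x LOD score z = 3 on the log2 scale."""
    assert round(math.log2(5) / 3, 3) == ND_SD_LOG2


def test_zscore_five_times_lod_is_three():
    entry = RefEntry(mean_log2=math.log2(2.0), sd_log2=ND_SD_LOG2, n=46,
                     lod_norm=2.0, not_detected=True)
    assert zscore(5 * 2.0, entry) == pytest.approx(3.0, abs=0.01)


def test_zscore_at_or_below_lod_is_zero_for_not_detected():
    entry = RefEntry(mean_log2=math.log2(2.0), sd_log2=ND_SD_LOG2, n=46,
                     lod_norm=2.0, not_detected=True)
    assert zscore(2.0, entry) == 0.0
    assert zscore(0.5, entry) == 0.0  # imputed up to LOD first


def test_zscore_zero_at_geometric_mean():
    entry = RefEntry(mean_log2=math.log2(40.0), sd_log2=0.5, n=46, lod_norm=1.0)
    assert zscore(40.0, entry) == 0.0
    assert zscore(80.0, entry) == pytest.approx(2.0)  # one doubling = 2 SD here


def test_build_reference_marks_never_detected_analyte():
    controls = [_control(f"c{i}", {"x": 0.0}, below={"x"}) for i in range(46)]
    ref = build_reference(controls, lods={"x": 2.0})
    entry = ref.entry("0-2y", "x")
    assert entry.not_detected
    assert entry.sd_log2 == ND_SD_LOG2
    assert entry.mean_log2 == pytest.approx(math.log2(2.0))


def test_build_reference_imputes_below_lod_values():
    vals = [10.0, 12.0, 0.5, 11.0]  # 0.5 below LOD of 2 -> imputed to 2
    controls = [_control(f"c{i}", {"x": v}) for i, v in enumerate(vals)]
    ref = build_reference(controls, lods={"x": 2.0})
    expected = np.log2([10.0, 12.0, 2.0, 11.0])
    entry = ref.entry("0-2y", "x")
    assert not entry.not_detected
    assert entry.mean_log2 == pytest.approx(expected.mean())
    assert entry.sd_log2 == pytest.approx(expected.std(ddof=1))


def test_build_reference_degenerate_cohort_hits_sd_floor():
    controls = [_control(f"c{i}", {"x": 8.0}) for i in range(5)]
    entry = build_reference(controls, lods={"x": 1.0}).entry("0-2y", "x")
    assert entry.mean_log2 == pytest.approx(3.0)
    assert entry.sd_log2 == 0.1  # raised from 0


def test_build_reference_requires_cohort():
    with pytest.raises(ScreenError):
        build_reference([], lods={"x": 1.0})
    with pytest.raises(ScreenError, match=">= 2"):
        build_reference([_control("c0", {"x": 1.0})], lods={"x": 1.0})


def test_reference_recovers_generating_parameters(panel):
    """Log-normal cohort of 46: estimates within 3 SE of the truth."""
    spec = default_cohort_spec(panel, seed=7)
    controls, _ = simulate_cohort(spec, panel)
    ref = build_reference(controls, spec.lods, analytes=panel.names)
    n = spec.n_per_group
    name = "Glutaric acid"
    mean, sd = spec.analyte_params[name]
    for group in ("0-2y", ">2y"):
        entry = ref.entry(group, name)
        assert abs(entry.mean_log2 - mean) <= 3 * sd / math.sqrt(n)
        assert abs(entry.sd_log2 - sd) <= 3 * sd / math.sqrt(2 * (n - 1))


def test_reference_json_round_trip(tmp_path):
    controls = [_control(f"c{i}", {"x": v}) for i, v in enumerate([5.0, 6.0, 7.0])]
    ref = build_reference(controls, lods={"x": 1.0})
    path = tmp_path / "ref.json"
    ref.to_json(path)
    again = ReferenceStats.from_json(path)
    assert again.entry("0-2y", "x") == ref.entry("0-2y", "x")


def test_profile_flags_follow_thresholds(panel):
    spec = default_cohort_spec(panel, seed=3)
    controls, _ = simulate_cohort(spec, panel)
    ref = build_reference(controls, spec.lods, analytes=panel.names)
    # sample exactly at every control geometric mean: all flags normal
    sq = SampleQuant(sample_id="s", age_group="0-2y", creatinine_mm=1.0)
    for entry in panel:
        mean = spec.analyte_params.get(entry.name)
        conc = 2.0 ** mean[0] if mean else 0.0
        sq.results[entry.name] = AnalyteResult(conc=conc, conc_norm=conc,
                                               below_lod=mean is None)
    profile = profile_sample(sq, ref, panel)
    assert set(profile.z) == set(panel.names)
    n = len(panel.names)
    # estimated means differ from truth by O(SE); no flag should fire
    assert sum(f == "normal" for f in profile.flags.values()) == n


def test_profile_unknown_age_group(panel):
    spec = default_cohort_spec(panel, seed=3)
    controls, _ = simulate_cohort(spec, panel)
    ref = build_reference(controls, spec.lods, analytes=panel.names)
    sq = SampleQuant(sample_id="s", age_group="adult", creatinine_mm=1.0)
    with pytest.raises(ScreenError, match="age group"):
        profile_sample(sq, ref, panel)


def test_ga1_case_flags_designated_biomarker(panel):
    spec = default_cohort_spec(panel, seed=11)
    controls, _ = simulate_cohort(spec, panel)
    ref = build_reference(controls, spec.lods, analytes=panel.names)
    case = simulate_case(default_case_specs()["GA1"], spec, panel, seed=99)
    profile = profile_sample(case, ref, panel)
    assert profile.flags["3-Hydroxyglutaric acid"] == "elevated"
    assert profile.z["3-Hydroxyglutaric acid"] > 3.0


def test_z_invariant_under_common_scaling():
    """Multiplying every concentration by one factor leaves z unchanged."""
    vals = [5.0, 9.0, 7.0, 6.0, 8.0]
    for factor in (0.25, 1.0, 40.0):
        controls = [_control(f"c{i}", {"x": v * factor})
                    for i, v in enumerate(vals)]
        ref = build_reference(controls, lods={"x": 0.01 * factor})
        z = zscore(7.5 * factor, ref.entry("0-2y", "x"))
        if factor == 0.25:
            z0 = z
        assert z == pytest.approx(z0, rel=1e-9)


def test_age_group_boundary():
    assert assign_age_group(2.0) == "0-2y"
    assert assign_age_group(2.01) == ">2y"
    assert assign_age_group(0.0) == "0-2y"


def test_render_profile_plot_writes_file(tmp_path, panel):
    spec = default_cohort_spec(panel, seed=5)
    controls, _ = simulate_cohort(spec, panel)
    ref = build_reference(controls, spec.lods, analytes=panel.names)
    case = simulate_case(default_case_specs()["MCADD"], spec, panel, seed=8)
    profile = profile_sample(case, ref, panel)
    out = render_profile_plot(profile, tmp_path / "profile.png")
    assert out.exists() and out.stat().st_size > 0
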