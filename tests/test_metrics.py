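import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgmsens import (
    ANGLE_NAMES,
    GPS_VARIABLES,
    KinematicCurves,
    category_distribution,
    categorize,
    corridors,
    gps,
    overall_rmsd,
    rmsd,
    single_marker_table,
    worst_cases,
)
from cgmsens.displacement import CODES, MARKERS, DisplacementSpec
from cgmsens.exceptions import ValidationError
from cgmsens.metrics import SimulationResult


def _result(overall, per_angle=None, spec=None, curves=None):
    per_angle = per_angle or {a: overall for a in ANGLE_NAMES}
    return SimulationResult(
        spec=spec or DisplacementSpec.null(),
        rmsd_per_angle=per_angle,
        overall_rmsd=overall,
        category=categorize(overall),
        curves=curves,
    )


# ---------------------------------------------------------------- rmsd

def test_rmsd_identity_and_constant_offset():
    y = np.sin(np.linspace(0, 2 * np.pi, 101))
    assert rmsd(y, y) == 0.0
    assert rmsd(y, y + 3.0) == pytest.approx(3.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_rmsd_matches_direct_formula(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(0, 5, 101), rng.normal(0, 5, 101)
    direct = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 101)
    assert rmsd(a, b) == pytest.approx(direct, rel=1e-12)


def test_rmsd_length_mismatch():
    with pytest.raises(ValidationError):
        rmsd(np.zeros(101), np.zeros(100))


# ---------------------------------------------------------------- categories

@pytest.mark.parametrize(
    "x,cat",
    [(0.0, 1), (2.0, 1), (2.0001, 2), (5.0, 2), (5.0001, 3), (10.0, 3),
     (10.0001, 4), (40.0, 4)],
)
def test_category_boundaries_belong_downward(x, cat):
    assert categorize(x) == cat


def test_categorize_rejects_negative():
    with pytest.raises(ValidationError):
        categorize(-0.1)


def test_category_frequencies_match_bin_widths():
    """Uniform RMSDs on [0, 20]: expected shares 10/15/25/50 percent."""
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 20, 200_000)
    counts = np.bincount([categorize(v) - 1 for v in x], minlength=4) / len(x)
    assert np.allclose(counts, [0.10, 0.15, 0.25, 0.50], atol=0.01)


# ---------------------------------------------------------------- overall

def test_overall_rmsd_is_mean_over_angle_set():
    per = {a: 3.0 for a in ANGLE_NAMES}
    per["hip_rotation"] = 5.0
    expected = (3.0 * 11 + 5.0) / 12
    assert overall_rmsd(per) == pytest.approx(expected)
    assert overall_rmsd({"a": 3.0, "b": 5.0}, angles=("a", "b")) == pytest.approx(4.0)
    with pytest.raises(ValidationError):
        overall_rmsd(per, angles=())


# ---------------------------------------------------------------- gps

def _flat_curves(value=0.0):
    return {v: np.full(101, value) for v in GPS_VARIABLES}


def test_gps_zero_iff_subject_equals_reference_mean():
    ref = _flat_curves()
    gvs, score = gps(_flat_curves(), ref)
    assert score == 0.0 and all(v == 0.0 for v in gvs.values())
    bumped = _flat_curves()
    bumped["knee_flexion"] = bumped["knee_flexion"].copy()
    bumped["knee_flexion"][50] = 0.5  # one point off -> strictly positive
    assert gps(bumped, ref)[1] > 0.0


def test_gps_hand_computed_single_variable_offset():
    """One variable off by 2 deg, 8 exact: GVS=2 and GPS=2/3 (RMS over 9)."""
    ref = _flat_curves()
    subj = _flat_curves()
    subj["hip_flexion"] = subj["hip_flexion"] + 2.0
    gvs, score = gps(subj, ref)
    assert gvs["hip_flexion"] == pytest.approx(2.0)
    assert score == pytest.approx(2.0 / 3.0)


def test_gps_homogeneity():
    ref = _flat_curves()
    rng = np.random.default_rng(5)
    dev = {v: rng.normal(0, 2, 101) for v in GPS_VARIABLES}
    s1 = gps({v: ref[v] + dev[v] for v in dev}, ref)[1]
    s3 = gps({v: ref[v] + 3 * dev[v] for v in dev}, ref)[1]
    assert s3 == pytest.approx(3 * s1)


def test_gps_missing_variable():
    ref = _flat_curves()
    subj = _flat_curves()
    del subj["pelvis_tilt"]
    with pytest.raises(ValidationError, match="pelvis_tilt"):
        gps(subj, ref)


# ---------------------------------------------------------------- distribution

def test_category_distribution_constructed_quarters():
    results = [_result(v) for v in (1.0, 3.0, 6.0, 11.0)]
    assert np.allclose(category_distribution(results), [25, 25, 25, 25])
    assert category_distribution(results).sum() == pytest.approx(100.0, abs=0.01)


def test_category_distribution_all_null():
    assert np.allclose(category_distribution([_result(0.0)] * 5), [100, 0, 0, 0])


def test_category_distribution_per_angle_matches_tally():
    rng = np.random.default_rng(2)
    results = [
        _result(1.0, per_angle={a: float(rng.uniform(0, 15)) for a in ANGLE_NAMES})
        for _ in range(300)
    ]
    dist = category_distribution(results, "knee_rotation")
    tally = np.bincount(
        [categorize(r.rmsd_per_angle["knee_rotation"]) - 1 for r in results],
        minlength=4,
    )
    assert np.allclose(dist, 100 * tally / 300)


# ---------------------------------------------------------------- worst cases

def test_worst_cases_against_sort_oracle():
    rng = np.random.default_rng(9)
    results = [
        _result(float(rng.uniform(0, 12)),
                spec=DisplacementSpec(tuple(rng.choice(CODES) for _ in MARKERS)))
        for _ in range(60)
    ]
    top = worst_cases(results, 10)
    oracle = sorted(results, key=lambda r: (-r.overall_rmsd, r.spec.codes))[:10]
    assert [r.spec for r in top] == [r.spec for r in oracle]
    assert worst_cases(results, 1)[0].overall_rmsd == max(r.overall_rmsd for r in results)
    with pytest.raises(ValidationError):
        worst_cases(results, 61)


def test_worst_cases_tie_break_deterministic():
    specs = [DisplacementSpec.single("LTHI", c) for c in ("D90", "D0", "D270")]
    results = [_result(5.0, spec=s) for s in specs]
    top1 = worst_cases(results, 3)
    top2 = worst_cases(list(reversed(results)), 3)
    assert [r.spec for r in top1] == [r.spec for r in top2]


# ---------------------------------------------------------------- table

def _single_marker_results(value=3.0, special=None):
    out = []
    for m in MARKERS:
        for c in ("D0", "D90", "D180", "D270"):
            v = value
            if special and (m, c) in special:
                v = special[(m, c)]
            per = {a: v for a in ANGLE_NAMES}
            out.append(_result(v, per_angle=per, spec=DisplacementSpec.single(m, c)))
    return out


def test_single_marker_table_masks_at_exactly_two_degrees():
    """A cell at exactly 2.0 deg is masked: the threshold is strict."""
    results = _single_marker_results(3.0, special={("LTHI", "D0"): 2.0})
    table = single_marker_table(results)
    assert np.isnan(table.loc[("LTHI", "D0"), "hip_rotation"])
    assert table.loc[("LTIB", "D0"), "hip_rotation"] == pytest.approx(3.0)


def test_single_marker_table_ignores_multi_marker_and_null_specs():
    results = _single_marker_results(4.0)
    results.append(_result(9.0))  # null spec must not contribute
    results.append(
        _result(9.0, spec=DisplacementSpec(("D0", "D0") + ("ORIG",) * 6))
    )
    table = single_marker_table(results, masked=False)
    assert (table.to_numpy() == 4.0).all()
    assert table.shape == (32, len(ANGLE_NAMES))


def test_single_marker_table_requires_complete_direction_set():
    results = _single_marker_results(4.0)
    missing = [r for r in results if r.spec.codes != DisplacementSpec.single("LANK", "D90").codes]
    with pytest.raises(ValidationError, match="LANK"):
        single_marker_table(missing)


def test_single_marker_table_equals_per_cell_mean():
    results = _single_marker_results(3.0) + _single_marker_results(5.0)
    table = single_marker_table(results, masked=False)
    assert np.allclose(table.to_numpy(), 4.0)


# ---------------------------------------------------------------- corridors

def _cycle_curves(values):
    return KinematicCurves({"knee_flexion": np.asarray(values)}, domain="cycle")


def test_corridor_bands_match_brute_force():
    rng = np.random.default_rng(4)
    refs = [_cycle_curves(rng.normal(20, 2, (1, 101))) for _ in range(4)]
    sims = [
        _result(1.0, curves=_cycle_curves(rng.normal(20, 3, (1, 101))))
        for _ in range(3)
    ]
    out = corridors(refs, sims)["knee_flexion"]
    stack = np.vstack([r["knee_flexion"] for r in refs])
    assert np.allclose(out["inter_trial_sd"], stack.std(axis=0, ddof=1))
    ref_mean = stack.mean(axis=0)
    brute = np.max(
        np.abs(np.vstack([s.curves["knee_flexion"][0] for s in sims]) - ref_mean),
        axis=0,
    )
    assert np.allclose(out["max_abs_dev"], brute)


def test_corridor_degenerate_widths():
    same = _cycle_curves(np.full((1, 101), 10.0))
    refs = [same, _cycle_curves(np.full((1, 101), 10.0))]
    sims = [_result(0.0, curves=_cycle_curves(np.full((1, 101), 10.0)))]
    out = corridors(refs, sims)["knee_flexion"]
    assert np.allclose(out["inter_trial_sd"], 0.0)
    assert np.allclose(out["max_abs_dev"], 0.0)
    with pytest.raises(ValidationError):
        corridors([same], sims)
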