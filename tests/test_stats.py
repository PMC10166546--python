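import numpy as np
import pytest

from vfarch import (
    at_prevalence,
    average_td,
    compare_groups,
    decompose_records,
    prognosis_split,
    pw_md_correlation,
    relative_weights,
    simulate_cohort,
)
from vfarch.decomposition import Decomposition
from vfarch.model import ArchetypeModel
from vfarch.records import VisualFieldRecord
from vfarch.simulate import SyntheticCohortSpec, make_pattern_library
from vfarch.stats import t_confidence_interval


def make_dec(pw, record=None, normal_index=0):
    return Decomposition(pw=np.asarray(pw, float), rss=0.0,
                         normal_index=normal_index, record=record)


def vf(pid="P1", eye="OD", day=0, vtype="presentation", md=0.0):
    return VisualFieldRecord(patient_id=pid, eye=eye, visit_day=day,
                             visit_type=vtype, td=np.zeros(52), md=md)


# ------------------------------------------------------------------ RW / TD
def test_rw_of_two_opposite_fields_is_even():
    rw = relative_weights([make_dec([100, 0]), make_dec([0, 100])])
    np.testing.assert_allclose(rw, [50.0, 50.0])


def test_rw_of_identical_fields_is_their_pw():
    decs = [make_dec([70, 20, 10])] * 5
    np.testing.assert_allclose(relative_weights(decs), [70, 20, 10])


def test_rw_matches_dirichlet_mean(rng):
    alpha = np.array([2.0, 1.0, 0.5])
    Z = rng.normal(-5, 6, size=(3, 52))
    model = ArchetypeModel.from_vectors(Z)
    W = np.random.default_rng(11).dirichlet(alpha, size=500)
    decs = []
    for w in W:
        decs.append(make_dec(100 * w))
    rw = relative_weights(decs)
    np.testing.assert_allclose(rw, 100 * alpha / alpha.sum(), atol=2.0)
    assert rw.sum() == pytest.approx(100.0, abs=0.1)


def test_rw_rejects_mixed_models():
    with pytest.raises(ValueError):
        relative_weights([make_dec([100, 0]), make_dec([100, 0, 0])])


def test_average_td_examples():
    assert average_td(np.zeros(52)) == 0.0
    assert average_td(np.full(52, -30.0)) == -30.0
    assert average_td(np.full(52, 2.4)) == pytest.approx(2.4)


# --------------------------------------------------------------- prevalence
def test_prevalence_counts_meaningful_fields():
    decs = [
        make_dec([80, 20, 0]),
        make_dec([70, 30, 0]),
        make_dec([95, 5, 0]),
        make_dec([60, 0, 40]),
    ]
    table = at_prevalence(decs)
    row = table[table["archetype"] == "AT2"].iloc[0]
    assert row["n_meaningful"] == 2 and row["pct_meaningful"] == 50.0
    assert table.attrs["pct_no_abnormal"] == 25.0


def test_prevalence_empty_scope_warns():
    with pytest.warns(RuntimeWarning):
        table = at_prevalence([make_dec([100, 0])], scope="final")
    assert table.empty


# -------------------------------------------------------------- correlation
def test_spearman_perfect_monotone():
    x = np.arange(10.0)
    assert pw_md_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert pw_md_correlation(x, -x)[0] == pytest.approx(-1.0)


def test_spearman_hand_ranked_example():
    rho, _ = pw_md_correlation(np.array([1.0, 2, 3]), np.array([3.0, 1, 2]))
    assert rho == pytest.approx(-0.5)


def test_spearman_constant_input_rejected():
    with pytest.raises(ValueError):
        pw_md_correlation(np.ones(5), np.arange(5.0))


def test_spearman_agrees_with_concordance_oracle(rng):
    """Spearman equals the Pearson correlation of average ranks; check via a
    direct O(n^2)-style rank construction on small random inputs."""
    import scipy.stats

    for _ in range(10):
        n = int(rng.integers(4, 13))
        x = rng.integers(0, 5, n).astype(float)  # ties likely
        y = rng.integers(0, 5, n).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        rx = np.array([(x < v).sum() + 0.5 * ((x == v).sum() - 1) + 1 for v in x])
        ry = np.array([(y < v).sum() + 0.5 * ((y == v).sum() - 1) + 1 for v in y])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert pw_md_correlation(x, y)[0] == pytest.approx(expected, abs=1e-12)


def test_planted_at1_md_coupling_is_strongly_positive():
    """With MD defined as mean TD and AT1 the normal pattern, eyes richer in
    AT1 must rank higher in MD (the planted monotone coupling)."""
    spec = SyntheticCohortSpec(n_patients=60, visit_days=(0, 200), seed=13)
    records, truth = simulate_cohort(spec)
    model = ArchetypeModel.from_vectors(truth.templates)
    pres = [r for r in records if r.visit_type == "presentation"]
    decs = decompose_records(pres, model)
    normal_col = truth.normal_column
    pw1 = np.array([d.pw[normal_col] for d in decs])
    md = np.array([r.md for r in pres])
    rho, p = pw_md_correlation(pw1, md)
    assert rho > 0.7 and p < 0.001


# ------------------------------------------------------------ group testing
def test_ranksum_identical_samples():
    _, p = compare_groups(np.arange(10.0), np.arange(10.0))
    assert p > 0.9


def test_ranksum_complete_separation():
    a = np.arange(1.0, 21)
    b = np.arange(101.0, 121)
    u, p = compare_groups(a, b)
    assert min(u, len(a) * len(b) - u) == 0
    assert p < 1e-3


def test_chisq_balanced_table():
    stat, p = compare_groups(np.array([[50, 50], [50, 50]]), kind="chisq")
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_chisq_zero_expected_raises():
    with pytest.raises(ValueError):
        compare_groups(np.array([[0, 0], [5, 5]]), kind="chisq")


def test_compare_groups_validation():
    with pytest.raises(ValueError):
        compare_groups(np.array([]), np.array([1.0]))
    with pytest.raises(ValueError):
        compare_groups([1.0], [2.0], kind="bogus")


def test_t_confidence_interval_contains_mean():
    lo, hi = t_confidence_interval(np.array([1.0, 2.0, 3.0, 4.0]))
    assert lo < 2.5 < hi


# ---------------------------------------------------------- prognosis split
def _two_eye_setup():
    records, decs = [], []
    for pid, pw1 in (("P1", 40.0), ("P2", 60.0)):
        pres = vf(pid, day=0, vtype="presentation", md=pw1 / 10 - 7)
        fin = vf(pid, day=200, vtype="final", md=pw1 / 10 - 4)
        records += [pres, fin]
        decs.append(make_dec([pw1, 100 - pw1], record=pres))
    return records, decs


def test_mean_split_assigns_one_eye_each_side():
    records, decs = _two_eye_setup()
    split = prognosis_split(decs, records)
    assert split.mean_presentation_pw == pytest.approx(50.0)
    assert split.above_eyes == ["P2:OD"] and split.below_eyes == ["P1:OD"]


def test_eye_exactly_at_mean_goes_above():
    records, decs = _two_eye_setup()
    # add a third eye exactly at the resulting mean of 50
    pres = vf("P3", day=0, md=0.0)
    records += [pres, vf("P3", day=200, vtype="final", md=0.0)]
    decs.append(make_dec([50.0, 50.0], record=pres))
    split = prognosis_split(decs, records)
    assert "P3:OD" in split.above_eyes


def test_degenerate_split_raises():
    records, decs = [], []
    for pid in ("P1", "P2"):
        pres = vf(pid, day=0)
        records += [pres, vf(pid, day=200, vtype="final")]
        decs.append(make_dec([55.0, 45.0], record=pres))
    with pytest.raises(ValueError, match="degenerate"):
        prognosis_split(decs, records)


def test_planted_faster_recovery_separates_groups():
    """Eyes with more presentation normal-pattern mass end higher in MD;
    the rank-sum test on final MD must detect the planted effect."""
    spec = SyntheticCohortSpec(n_patients=60, visit_days=(0, 60, 120, 200), seed=21)
    records, truth = simulate_cohort(spec)
    model = ArchetypeModel.from_vectors(truth.templates)
    pres = [r for r in records if r.visit_type == "presentation"]
    pres_decs = decompose_records(pres, model)
    fin = [r for r in records if r.visit_type == "final"]
    fin_decs = decompose_records(fin, model)
    at_index = truth.normal_column + 1
    split = prognosis_split(pres_decs, records, final_decs=fin_decs, at_index=at_index)
    tbl = split.md_by_window.set_index(["window", "group"])
    assert (
        tbl.loc[("final", "above"), "md_mean"] > tbl.loc[("final", "below"), "md_mean"]
    )
    assert split.md_pvalues["final"] < 0.05
    assert split.final_pw["above"][0] > split.final_pw["below"][0]
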