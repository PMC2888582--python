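"""Sum-Xcorr aggregation, ANOVA differential calls and membership partition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gvprotcomm.quantify import (
    QuantMatrix,
    anova_differential,
    build_quant_matrix,
    classify_membership,
    membership_counts,
    _one_way_anova,
)
from tests.conftest import make_psm_frame


def matrix_from_arrays(a: np.ndarray, b: np.ndarray, samples=("oocyte", "cumulus")):
    """QuantMatrix from per-group row arrays (proteins x replicates)."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    columns = pd.MultiIndex.from_tuples(
        [(samples[0], r + 1) for r in range(a.shape[1])]
        + [(samples[1], r + 1) for r in range(b.shape[1])],
        names=["sample", "replicate"],
    )
    values = pd.DataFrame(
        np.hstack([a, b]),
        index=pd.Index([f"P{i:04d}" for i in range(a.shape[0])], name="accession"),
        columns=columns,
    )
    return QuantMatrix(values=values, samples=tuple(samples))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_cell_is_exact_xcorr_sum():
    rows = [
        ("oocyte", 1, 1, "PEPTIDEK", 2, 2.2, 0.2, 1, "P0001", False),
        ("oocyte", 1, 2, "PEPTIDESK", 2, 3.1, 0.2, 1, "P0001", False),
        ("oocyte", 2, 1, "PEPTIDEK", 2, 2.0, 0.2, 1, "P0001", False),
    ]
    m = build_quant_matrix(make_psm_frame(rows), retained_accessions=["P0001"],
                          samples=("oocyte", "cumulus"))
    assert m.values.loc["P0001", ("oocyte", 1)] == pytest.approx(5.3)
    assert m.values.loc["P0001", ("oocyte", 2)] == pytest.approx(2.0)


def test_unobserved_cells_are_zero_not_missing():
    rows = [("oocyte", r, 1, "PEPTIDEK", 2, 2.5, 0.2, 1, "P0001", False) for r in (1, 2, 3)]
    m = build_quant_matrix(make_psm_frame(rows), retained_accessions=["P0001"],
                          samples=("oocyte", "cumulus"))
    assert (m.values["cumulus"].loc["P0001"] == 0).all()
    assert not m.values.isna().any().any()


def test_shared_peptides_count_for_each_parent():
    rows = [("oocyte", 1, 1, "PEPTIDEK", 2, 2.5, 0.2, 1, "P0001;P0002", False)]
    m = build_quant_matrix(make_psm_frame(rows), samples=("oocyte", "cumulus"))
    assert m.values.loc["P0001", ("oocyte", 1)] == 2.5
    assert m.values.loc["P0002", ("oocyte", 1)] == 2.5


def test_matrix_total_matches_bruteforce_groupby(small_sim):
    tables, _ = small_sim
    from gvprotcomm.filtering import apply_primary_filter

    psms = pd.concat(tables.values(), ignore_index=True)
    targets, _ = apply_primary_filter(psms[~psms["is_decoy"]])
    m = build_quant_matrix(targets, samples=("oocyte", "cumulus"))
    # brute-force oracle: python-loop accumulation per (acc, sample, replicate)
    acc: dict[tuple, float] = {}
    for row in targets.itertuples(index=False):
        for a in row.accession.split(";"):
            key = (a, row.sample, row.replicate)
            acc[key] = acc.get(key, 0.0) + row.xcorr
    for (a, s, r), total in acc.items():
        assert m.values.loc[a, (s, r)] == pytest.approx(total)
    assert m.values.to_numpy().sum() == pytest.approx(sum(acc.values()))


def test_inconsistent_replicate_labels_rejected():
    rows = [
        ("oocyte", 1, 1, "PEPTIDEK", 2, 2.5, 0.2, 1, "P0001", False),
        ("cumulus", 7, 1, "PEPTIDESK", 2, 2.5, 0.2, 1, "P0001", False),
    ]
    with pytest.raises(ValueError, match="replicate labels"):
        build_quant_matrix(make_psm_frame(rows), samples=("oocyte", "cumulus"))


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_anova_hand_computed_sums_of_squares():
    # {1,2,3} vs {4,5,6}: SSB=13.5, SSW=4, MSW=1 -> F=13.5 on (1,4) df
    f, p = _one_way_anova([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
    assert f == pytest.approx(13.5)
    assert p == pytest.approx(float(sps.f.sf(13.5, 1, 4)))


def test_anova_identical_groups_not_differential():
    m = matrix_from_arrays(np.array([5.0, 5, 5]), np.array([5.0, 5, 5]))
    out = anova_differential(m)
    row = out.stats.iloc[0]
    assert row["pvalue"] == 1.0 and not row["differential"]
    assert row["direction"] is None


def test_anova_matches_scipy_f_oneway():
    rng = np.random.default_rng(0)
    a, b = rng.normal(10, 2, (20, 3)), rng.normal(12, 2, (20, 3))
    out = anova_differential(matrix_from_arrays(a, b))
    for i in range(20):
        f_ref, p_ref = sps.f_oneway(a[i], b[i])
        assert out.stats["F"].iloc[i] == pytest.approx(float(f_ref))
        assert out.stats["pvalue"].iloc[i] == pytest.approx(float(p_ref))


def test_two_group_anova_equals_t_squared():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, (50, 3)), rng.normal(0.5, 1, (50, 4))
    out = anova_differential(matrix_from_arrays(a, b))
    t, p = sps.ttest_ind(a, b, axis=1)
    np.testing.assert_allclose(out.stats["F"], t**2, rtol=1e-9)
    np.testing.assert_allclose(out.stats["pvalue"], p, rtol=1e-9)


def test_all_zero_rows_untestable_and_tallied():
    a = np.array([[0.0, 0, 0], [1.0, 2, 3]])
    b = np.array([[0.0, 0, 0], [9.0, 10, 11]])
    out = anova_differential(matrix_from_arrays(a, b))
    assert out.n_untestable == 1
    assert not out.stats["testable"].iloc[0]
    assert not out.stats["differential"].iloc[0]
    assert out.stats["differential"].iloc[1]
    assert out.stats["direction"].iloc[1] == "higher"


def test_fewer_than_two_replicates_rejected():
    m = matrix_from_arrays(np.array([[1.0]]), np.array([[2.0]]))
    with pytest.raises(ValueError, match="fewer than 2"):
        anova_differential(m)


def test_direction_decomposition_identity(small_sim):
    tables, _ = small_sim
    from gvprotcomm.filtering import apply_primary_filter

    psms = pd.concat(tables.values(), ignore_index=True)
    targets, _ = apply_primary_filter(psms[~psms["is_decoy"]])
    out = anova_differential(build_quant_matrix(targets, samples=("oocyte", "cumulus")))
    s = out.stats
    n_diff = int(s["differential"].sum())
    assert n_diff == int((s["direction"] == "higher").sum()) + int((s["direction"] == "lower").sum())


# ---------------------------------------------------------------------------
# membership
# ---------------------------------------------------------------------------

def test_membership_from_printed_totals():
    # 811 oocyte and 1,247 cumulus proteins with 352 common
    # -> 459 oocyte-only and 895 cumulus-only, 2,058 in total
    n_oo_only, n_cc_only, n_common = 459, 895, 352
    a = np.zeros((n_oo_only + n_cc_only + n_common, 3))
    b = np.zeros_like(a)
    a[:n_oo_only] = 1.0
    b[n_oo_only:n_oo_only + n_cc_only] = 1.0
    a[-n_common:] = b[-n_common:] = 1.0
    m = matrix_from_arrays(a, b)
    counts = membership_counts(classify_membership(m), m.samples)
    assert counts["total_oocyte"] == 811
    assert counts["total_cumulus"] == 1247
    assert counts["oocyte-only"] == 459
    assert counts["cumulus-only"] == 895
    assert counts["common"] == 352
    assert counts["total"] == 1706  # distinct proteins; 811 + 1247 = 2058 identifications


def test_protein_only_in_cumulus_is_cumulus_only():
    m = matrix_from_arrays(np.array([0.0, 0, 0]), np.array([3.0, 0, 0]))
    assert classify_membership(m).iloc[0] == "cumulus-only"


def test_partition_recovers_ground_truth(small_sim):
    tables, truth = small_sim
    from gvprotcomm.filtering import apply_primary_filter

    psms = pd.concat(tables.values(), ignore_index=True)
    targets, _ = apply_primary_filter(psms[~psms["is_decoy"]])
    m = build_quant_matrix(targets, samples=("oocyte", "cumulus"))
    observed = classify_membership(m)
    tf = truth.frame.set_index("accession")
    for acc, label in observed.items():
        # only proteins whose PSMs survive filtering are observable
        assert label == tf.loc[acc, "membership"]
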