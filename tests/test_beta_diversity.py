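"""Beta-diversity partitioning: hand-checked values, additivity, and
agreement with independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import braycurtis

from betadrivers import (
    CommunityMatrix,
    ValidationError,
    component_summary,
    multisite_braycurtis,
    multisite_sorensen,
    pairwise_braycurtis,
    pairwise_sorensen,
)


def cm_from_rows(rows, ids=None):
    rows = np.atleast_2d(np.asarray(rows))
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    taxa = [f"t{j}" for j in range(rows.shape[1])]
    return CommunityMatrix(ids, taxa, rows)


def multisite_oracle(x, incidence):
    """Independent brute-force evaluation of the multi-site sum formulas."""
    x = np.asarray(x, dtype=float)
    if incidence:
        x = (x > 0).astype(float)
    n = x.shape[0]
    s_a = s_min = s_max = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            a = np.minimum(x[i], x[j]).sum()
            b = x[i].sum() - a
            c = x[j].sum() - a
            s_a += a
            s_min += min(b, c)
            s_max += max(b, c)
    if incidence:
        pooled = (x.sum(axis=0) > 0).sum()
        k = x.sum() - pooled
    else:
        k = s_a
    turnover = s_min / (k + s_min)
    total = (s_min + s_max) / (2 * k + s_min + s_max)
    return total, turnover, total - turnover


class TestPairwiseHandValues:
    def test_sorensen_partition_examples(self):
        # {A,B,C} vs {B,C,D}: a=2, b=1, c=1
        dm = pairwise_sorensen(cm_from_rows([[1, 1, 1, 0], [0, 1, 1, 1]]))
        assert dm.values[0, 1] == pytest.approx(1 / 3)
        assert dm.components["turnover"][0, 1] == pytest.approx(1 / 3)
        assert dm.components["nestedness"][0, 1] == pytest.approx(0.0)
        # nested {A,B,C,D} contains {A,B}: a=2, b=2, c=0
        dm = pairwise_sorensen(cm_from_rows([[1, 1, 1, 1], [1, 1, 0, 0]]))
        assert dm.values[0, 1] == pytest.approx(1 / 3)
        assert dm.components["turnover"][0, 1] == pytest.approx(0.0)
        assert dm.components["nestedness"][0, 1] == pytest.approx(1 / 3)
        # identical sites
        dm = pairwise_sorensen(cm_from_rows([[1, 2, 3], [1, 2, 3]]))
        assert dm.values[0, 1] == 0.0

    def test_braycurtis_partition_examples(self):
        # (10,0,5) vs (5,5,5): A=10, B=5, C=5
        dm = pairwise_braycurtis(cm_from_rows([[10, 0, 5], [5, 5, 5]]))
        assert dm.values[0, 1] == pytest.approx(1 / 3)
        assert dm.components["turnover"][0, 1] == pytest.approx(1 / 3)
        assert dm.components["nestedness"][0, 1] == pytest.approx(0.0)
        # pure abundance gradient: (2,4,6) vs (1,2,3): A=6, B=6, C=0
        dm = pairwise_braycurtis(cm_from_rows([[2, 4, 6], [1, 2, 3]]))
        assert dm.values[0, 1] == pytest.approx(1 / 3)
        assert dm.components["turnover"][0, 1] == pytest.approx(0.0)
        assert dm.components["nestedness"][0, 1] == pytest.approx(1 / 3)

    def test_braycurtis_total_matches_scipy(self, rng):
        x = rng.integers(0, 20, size=(8, 12))
        x[x.sum(axis=1) == 0, 0] = 1
        dm = pairwise_braycurtis(cm_from_rows(x))
        for i in range(8):
            for j in range(i + 1, 8):
                assert dm.values[i, j] == pytest.approx(braycurtis(x[i], x[j]), abs=1e-12)


class TestMultisite:
    def test_three_site_incidence_hand_value(self):
        # sites {A,B}, {B,C}, {C,D}: K=2, sum-min = sum-max = 4
        cm = cm_from_rows([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]])
        ms = multisite_sorensen(cm)
        assert ms.turnover == pytest.approx(2 / 3)
        assert ms.total == pytest.approx(2 / 3)
        assert ms.nestedness == pytest.approx(0.0)

    def test_identical_sites_give_zero(self):
        cm = cm_from_rows([[3, 1, 0], [3, 1, 0], [3, 1, 0]])
        for fn in (multisite_sorensen, multisite_braycurtis):
            ms = fn(cm)
            assert ms.total == ms.turnover == ms.nestedness == 0.0

    @pytest.mark.parametrize("incidence", [True, False])
    def test_matches_bruteforce_oracle(self, rng, incidence):
        for _ in range(20):
            x = rng.integers(0, 10, size=(rng.integers(3, 7), rng.integers(4, 10)))
            x[x.sum(axis=1) == 0, 0] = 1
            cm = cm_from_rows(x)
            ms = (multisite_sorensen if incidence else multisite_braycurtis)(cm)
            exp = multisite_oracle(x, incidence)
            np.testing.assert_allclose(
                (ms.total, ms.turnover, ms.nestedness), exp, atol=1e-12
            )

    def test_reduces_to_pairwise_at_two_sites(self, rng):
        x = rng.integers(0, 15, size=(2, 9)) + 1
        cm = cm_from_rows(x)
        ms, mb = multisite_sorensen(cm), multisite_braycurtis(cm)
        ps, pb = pairwise_sorensen(cm), pairwise_braycurtis(cm)
        assert ms.total == pytest.approx(ps.values[0, 1], abs=1e-12)
        assert ms.turnover == pytest.approx(ps.components["turnover"][0, 1], abs=1e-12)
        assert mb.total == pytest.approx(pb.values[0, 1], abs=1e-12)
        assert mb.turnover == pytest.approx(pb.components["turnover"][0, 1], abs=1e-12)

    def test_single_site_rejected(self):
        with pytest.raises(ValidationError):
            CommunityMatrix(["a"], ["t"], np.array([[1]]))


@settings(max_examples=60, deadline=None)
@given(
    arrays(
        np.int64,
        st.tuples(st.integers(2, 6), st.integers(1, 8)),
        elements=st.integers(0, 30),
    )
)
def test_partition_additivity_and_bounds(x):
    """total = turnover + nestedness (to 1e-12), all components in [0,1]."""
    if (x.sum(axis=1) == 0).any():
        x = x.copy()
        x[x.sum(axis=1) == 0, 0] = 1
    cm = cm_from_rows(x)
    for pairwise in (pairwise_sorensen, pairwise_braycurtis):
        dm = pairwise(cm)
        tu, ne = dm.components["turnover"], dm.components["nestedness"]
        np.testing.assert_allclose(dm.values, tu + ne, atol=1e-12)
        assert np.nanmin(dm.values) >= -1e-12 and np.nanmax(dm.values) <= 1 + 1e-12
        assert np.all(tu <= dm.values + 1e-12)
    for multisite in (multisite_sorensen, multisite_braycurtis):
        ms = multisite(cm)
        assert ms.total == pytest.approx(ms.turnover + ms.nestedness, abs=1e-12)
        assert 0 <= ms.turnover <= ms.total <= 1


def test_presence_absence_braycurtis_collapses_to_sorensen(rng):
    x = (rng.random((7, 10)) < 0.4).astype(int)
    x[x.sum(axis=1) == 0, 0] = 1
    cm = cm_from_rows(x)
    bc, so = pairwise_braycurtis(cm), pairwise_sorensen(cm)
    np.testing.assert_allclose(bc.values, so.values, atol=1e-12)
    for comp in ("turnover", "nestedness"):
        np.testing.assert_allclose(bc.components[comp], so.components[comp], atol=1e-12)


def test_turnover_unchanged_by_adding_shared_taxa(rng):
    """Adding a taxon present at both sites can only increase a, which
    never increases the pairwise turnover component."""
    x = rng.integers(0, 5, size=(2, 6)) + np.array([[1], [0]])
    x[1, 0] = 1
    base = pairwise_sorensen(cm_from_rows(x)).components["turnover"][0, 1]
    grown = np.hstack([x, np.array([[2], [3]])])  # shared new taxon
    after = pairwise_sorensen(cm_from_rows(grown)).components["turnover"][0, 1]
    assert after <= base + 1e-12


class TestComponentSummary:
    def test_pair_counts_for_study_layout(self, bundle):
        dm = pairwise_sorensen(bundle.communities["April"])
        table = component_summary(dm)
        assert table.loc["all", "n_pairs"] == 1225
        by_region = component_summary(dm, bundle.region_series())
        assert by_region.loc["YRIA", "n_pairs"] == 16 * 15 // 2

    def test_means_are_additive(self, bundle):
        dm = pairwise_braycurtis(bundle.communities["July"])
        t = component_summary(dm, bundle.region_series())
        np.testing.assert_allclose(
            t["mean_dissimilarity"], t["mean_turnover"] + t["mean_nestedness"], atol=1e-12
        )

    def test_small_group_skipped_with_warning(self):
        cm = cm_from_rows([[1, 0], [0, 1], [1, 1]])
        groups = {"s0": "a", "s1": "a", "s2": "lonely"}
        with pytest.warns(UserWarning, match="lonely"):
            table = component_summary(pairwise_sorensen(cm), groups)
        assert list(table.index) == ["a"]


def test_empty_site_pair_handling():
    cm = CommunityMatrix(["a", "b", "c"], ["t1", "t2"], np.array([[0, 0], [2, 0], [1, 1]]))
    dm = pairwise_sorensen(cm, allow_empty_sites=True)
    assert dm.values[0, 1] == 1.0  # one empty site: maximal dissimilarity
    assert np.isnan(dm.components["turnover"][0, 1])  # turnover undefined
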