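"""SNV filters, Otsu thresholding, Fisher/BH oracles, stratified permutations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from mtclone.io_formats import SNVCountTable
from mtclone.simulate import (
    CloneSpec,
    SimConfig,
    SNVSpec,
    simulate_mito_counts,
    simulate_snv_counts,
    variant_universe,
)
from mtclone.snv_concordance import (
    bh_adjust,
    build_matched_control,
    fisher_exact_2x2,
    filter_snvs,
    otsu_vaf_threshold,
    snv_concordance_test,
    stratified_permutation_null,
)

from conftest import make_annotation


def snv_table(rows):
    return SNVCountTable(
        pd.DataFrame(rows, columns=["cell_id", "snv_id", "ref_reads", "alt_reads"])
    )


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def fisher_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if min(r1, c1) == 0 or r1 == n or c1 == n:
        return 1.0
    kmin, kmax = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(ks, n, c1, r1)
    p_obs = hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def bh_oracle(p):
    """Step-up BH by the textbook formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def otsu_bruteforce(v, nbins=256):
    """Minimize intra-class variance over every histogram cut directly."""
    hist, edges = np.histogram(v, bins=nbins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_cut, best_obj = None, np.inf
    for cut in range(1, nbins):
        w0, w1 = hist[:cut].sum(), hist[cut:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:cut] * centers[:cut]).sum() / w0
        m1 = (hist[cut:] * centers[cut:]).sum() / w1
        v0 = (hist[:cut] * (centers[:cut] - m0) ** 2).sum()
        v1 = (hist[cut:] * (centers[cut:] - m1) ** 2).sum()
        obj = (v0 + v1) / hist.sum()
        if obj < best_obj - 1e-15:
            best_obj, best_cut = obj, cut
    return float(edges[best_cut])


# ---------------------------------------------------------------------------
# filters and groups
# ---------------------------------------------------------------------------


class TestFilterSnvs:
    def test_depth_filter(self):
        t = snv_table([("c1", "s1", 1, 1), ("c2", "s1", 3, 1)])
        out = filter_snvs(t, min_depth=3, min_cells=1)
        assert out.records["cell_id"].tolist() == ["c2"]

    def test_min_cells_filter(self):
        rows = [(f"c{i}", "s1", 2, 2) for i in range(3)] + [
            (f"c{i}", "s2", 2, 2) for i in range(4)
        ]
        out = filter_snvs(snv_table(rows), min_depth=3, min_cells=4)
        assert set(out.records["snv_id"]) == {"s2"}

    def test_empty_table(self):
        assert len(filter_snvs(snv_table([]))) == 0


class TestMatchedControl:
    def _ann(self):
        ann = make_annotation(6, 0)
        ann.table["sample_id"] = ["S1", "S1", "S1", "S2", "S2", "S2"]
        ann.table["cell_type"] = ["BE", "BE", "squamous", "BE", "BE", "BE"]
        return ann

    def test_same_stratum_only(self):
        ann = self._ann()
        g1, g2 = build_matched_control(ann, {"c0000"})  # S1/BE clone
        assert g2 == ["c0001"]  # the only other S1/BE cell

    def test_clone_spanning_all_strata(self):
        ann = self._ann()
        g1, g2 = build_matched_control(ann, {"c0000", "c0002", "c0003"})
        assert set(g2) == {"c0001", "c0004", "c0005"}

    def test_no_controls_rejected(self):
        ann = self._ann()
        with pytest.raises(ValueError, match="no control cells"):
            build_matched_control(ann, {"c0002"})  # lone squamous cell


# ---------------------------------------------------------------------------
# Otsu / Fisher / BH
# ---------------------------------------------------------------------------


class TestOtsu:
    def test_perfect_separation(self):
        thr, degenerate = otsu_vaf_threshold([0.0, 0.0, 0.0, 1.0, 1.0])
        assert 0.0 < thr < 1.0 and not degenerate

    def test_constant_input_degenerate(self):
        thr, degenerate = otsu_vaf_threshold([0.4, 0.4, 0.4])
        assert thr == 0.4 and degenerate

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            otsu_vaf_threshold([0.5])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 10_000), st.integers(3, 40))
    def test_matches_bruteforce_minimizer(self, seed, n):
        """Between-class maximization equals direct intra-class minimization."""
        rng = np.random.default_rng(seed)
        v = np.concatenate([rng.beta(1, 8, n), rng.beta(8, 2, max(n // 2, 2))])
        thr, _ = otsu_vaf_threshold(v)
        assert thr == pytest.approx(otsu_bruteforce(v), abs=1e-12)

    def test_matches_skimage_reference(self, rng):
        """Independent cross-check against the image-processing reference."""
        from skimage.filters import threshold_otsu

        v = np.concatenate([rng.beta(1, 8, 200), rng.beta(8, 2, 80)])
        thr, _ = otsu_vaf_threshold(v)
        ref = threshold_otsu(v, nbins=256)
        assert abs(thr - ref) < 1.5 / 256  # same bin up to edge convention

    def test_exact_method_available(self):
        thr, _ = otsu_vaf_threshold([0.0, 0.1, 0.8, 0.9], method="exact")
        assert 0.1 < thr < 0.8


class TestFisher:
    def test_diagonal_table(self):
        """[[3,0],[0,3]]: 2 of the 20 equally-margin-consistent tables are as
        extreme, so p = 0.1 exactly."""
        assert fisher_exact_2x2([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_perfect_independence(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    @pytest.mark.parametrize("table", [[[0, 0], [3, 4]], [[0, 5], [0, 2]]])
    def test_zero_margin(self, table):
        assert fisher_exact_2x2(table) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_enumeration(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        assert fisher_exact_2x2(table) == pytest.approx(fisher_oracle(table), abs=1e-10)


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_step_up_formula(self, ps):
        np.testing.assert_allclose(bh_adjust(ps), bh_oracle(ps), atol=1e-12)


# ---------------------------------------------------------------------------
# end-to-end concordance
# ---------------------------------------------------------------------------


def _world(seed=0):
    u = variant_universe(2)
    cfg = SimConfig(
        n_cells=500,
        n_variants=2,
        clones=[CloneSpec("c1", 50, [u[0]], tissue="BE")],
        snvs=[
            SNVSpec("chr1:100 A>G", "c1", dropout_rate=0.3),
            SNVSpec("chr2:200 C>T", None),
        ],
        fraction_reference_cells=0.2,
        background_tissues=["BE"],
        seed=seed,
    )
    m, ann, truth = simulate_mito_counts(cfg)
    snv = filter_snvs(simulate_snv_counts(cfg, truth))
    return ann, snv, set(truth.clone_cells("c1"))


class TestConcordance:
    def test_planted_snv_detected_decoy_not(self):
        ann, snv, clone = _world()
        results = {r.snv_id: r for r in snv_concordance_test(snv, ann, clone)}
        assert results["chr1:100 A>G"].bh_q <= 0.05
        assert results["chr2:200 C>T"].bh_q > 0.05

    def test_contingency_accounts_for_used_cells(self):
        ann, snv, clone = _world()
        for r in snv_concordance_test(snv, ann, clone):
            assert r.contingency.sum() == r.n_cells_used


class TestPermutationNull:
    def test_planted_snv_below_null(self):
        ann, snv, clone = _world()
        null = stratified_permutation_null(snv, ann, clone, n_perm=100, seed=0)
        assert null.frac_null_le_obs["chr1:100 A>G"] <= 0.05

    def test_random_clone_typical_of_null(self, rng):
        """A fake clone of random non-clone cells gives unremarkable
        p-values."""
        ann, snv, clone = _world()
        candidates = sorted(set(snv.records["cell_id"]) - clone)
        fake = set(rng.choice(candidates, size=40, replace=False))
        null = stratified_permutation_null(snv, ann, fake, n_perm=60, seed=0)
        assert (null.frac_null_le_obs > 0.05).all()

    def test_single_permutation_reproducible(self):
        ann, snv, clone = _world()
        a = stratified_permutation_null(snv, ann, clone, n_perm=1, seed=3)
        b = stratified_permutation_null(snv, ann, clone, n_perm=1, seed=3)
        pd.testing.assert_frame_equal(a.null_p, b.null_p)
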