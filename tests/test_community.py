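"""Community-ecology statistics against closed forms and library oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import pearsonr, spearmanr

from gutaa.community import (
    DistanceMatrix,
    OtuTable,
    anosim,
    bray_curtis,
    dbrda,
    firmicutes_bacteroidetes_ratio,
    pcoa,
    rank_correlation,
    relative_abundance,
    select_axes,
    shannon_diversity,
)


def dm(data, ids=None):
    data = np.asarray(data, float)
    return DistanceMatrix(data=data, ids=ids or [f"s{i}" for i in range(len(data))])


def toy_otu_table() -> OtuTable:
    counts = pd.DataFrame(
        {"t1": [60, 10, 0], "t2": [40, 0, 5], "t3": [0, 90, 5]},
        index=["a", "b", "c"],
    )
    taxonomy = {"t1": ("Firmicutes", "Lactobacillaceae"),
                "t2": ("Bacteroidetes", "Bacteroidaceae"),
                "t3": ("", "")}
    group = {"a": "hi", "b": "lo", "c": "lo"}
    return OtuTable(counts=counts, taxonomy=taxonomy, group=group)


class TestRelativeAbundance:
    def test_phylum_proportions(self):
        # sample "a": counts {Firmicutes 60, Bacteroidetes 40} → {0.6, 0.4}
        props = relative_abundance(toy_otu_table(), "phylum")
        assert props.loc["a", "Firmicutes"] == pytest.approx(0.6)
        assert props.loc["a", "Bacteroidetes"] == pytest.approx(0.4)
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_unassigned_pooled_as_unclassified(self):
        props = relative_abundance(toy_otu_table(), "phylum")
        assert "unclassified" in props.columns

    def test_depth_invariance(self):
        table = toy_otu_table()
        scaled = OtuTable(counts=table.counts * 10, taxonomy=table.taxonomy, group=table.group)
        pd.testing.assert_frame_equal(
            relative_abundance(table, "phylum"), relative_abundance(scaled, "phylum")
        )

    def test_empty_sample_excluded_and_flagged(self):
        table = toy_otu_table()
        counts = table.counts.copy()
        counts.loc["c"] = 0
        props = relative_abundance(
            OtuTable(counts=counts, taxonomy=table.taxonomy, group=table.group), "phylum"
        )
        assert "c" not in props.index
        assert props.attrs["excluded"] == ["c"]

    def test_fb_ratio(self):
        props = relative_abundance(toy_otu_table(), "phylum")
        ratio = firmicutes_bacteroidetes_ratio(props)
        assert ratio["a"] == pytest.approx(0.6 / 0.4)


class TestShannon:
    @pytest.mark.parametrize(
        "counts, expected",
        [([5, 5, 5, 5], math.log(4)), ([7, 0, 0], 0.0),
         ([8, 2], -(0.8 * math.log(0.8) + 0.2 * math.log(0.2)))],
    )
    def test_closed_forms(self, counts, expected):
        assert shannon_diversity(np.array(counts)) == pytest.approx(expected, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon_diversity(np.zeros(3))


class TestBrayCurtis:
    def test_formula_example(self):
        # proportions of (6,0,2) and (0,4,2): d = 10/14 on raw counts; the
        # total-sum-scaled value is computed against scipy on proportions
        x, y = np.array([6, 0, 2], float), np.array([0, 4, 2], float)
        d = bray_curtis(np.vstack([x, y]))
        expected = scipy_braycurtis(x / x.sum(), y / y.sum())
        assert d.data[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_raw_count_formula_when_depth_equal(self):
        # at equal depth the scaling cancels: d = Σ|x−y|/Σ(x+y) = 12/14
        x, y = np.array([6, 0, 1], float), np.array([0, 4, 3], float)
        d = bray_curtis(np.vstack([x, y]))
        assert d.data[0, 1] == pytest.approx(12 / 14, abs=1e-12)

    def test_identical_and_disjoint(self):
        rows = np.array([[3.0, 1.0, 0.0], [3.0, 1.0, 0.0], [0.0, 0.0, 9.0]])
        d = bray_curtis(rows)
        assert d.data[0, 1] == 0.0
        assert d.data[0, 2] == pytest.approx(1.0)

    def test_two_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]]))

    @given(
        arrays(float, (5, 8), elements=st.floats(0.0, 100.0)).filter(
            lambda a: (a.sum(axis=1) > 0).all()
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_metric_properties(self, table):
        """Symmetry, zero diagonal, and [0,1] bounds on random tables."""
        d = bray_curtis(table).data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= -1e-12).all() and (d <= 1.0 + 1e-12).all()


def enumerate_anosim_p(d: DistanceMatrix, labels: np.ndarray) -> float:
    """Exact ANOSIM p by enumerating every distinct relabelling."""
    from scipy.stats import rankdata

    n = d.n
    ranks = rankdata(d.condensed())
    iu, ju = np.triu_indices(n, k=1)

    def r_stat(lab):
        lab = np.asarray(lab)
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4)

    obs = r_stat(labels)
    hits = total = 0
    for perm in set(itertools.permutations(labels)):
        total += 1
        if r_stat(perm) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestAnosim:
    def perfectly_separated(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.0
        return dm(d)

    def test_r_one_on_perfect_separation(self):
        """Hand ranks: between pairs midrank 4.5, within 1.5, denom 3 → R = 1."""
        r, _ = anosim(self.perfectly_separated(), np.array(["g1", "g1", "g2", "g2"]),
                      n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_matches_scikit_bio(self, rng):
        import skbio
        from skbio.stats.distance import anosim as skbio_anosim

        pts = rng.normal(size=(8, 3))
        pts[4:] += 1.0
        d2 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        r, _ = anosim(dm(d2), labels, n_perm=99, seed=1)
        sk = skbio_anosim(skbio.DistanceMatrix(d2), grouping=list(labels), permutations=99)
        assert r == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_permutation_p_matches_enumeration(self, rng):
        """On 6 samples the permutation p agrees with full enumeration."""
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.5
        d2 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        exact = enumerate_anosim_p(dm(d2), labels)
        _, p = anosim(dm(d2), labels, n_perm=1999, seed=2)
        mc_err = 3 * math.sqrt(exact * (1 - exact) / 1999) + 2 / 1999
        assert abs(p - exact) <= mc_err

    def test_null_mean_r_near_zero(self, rng):
        """With randomly shuffled labels E[R] ≈ 0."""
        pts = rng.normal(size=(10, 3))
        d2 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        rs = []
        for _ in range(200):
            labels = rng.permutation(np.array(["a"] * 5 + ["b"] * 5))
            r, _ = anosim(dm(d2), labels, n_perm=1, seed=rng)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05
        assert all(-1.0 - 1e-9 <= r <= 1.0 + 1e-9 for r in rs)

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            anosim(self.perfectly_separated(), np.array(["a", "a", "a", "b"]), n_perm=9)


class TestPcoa:
    def test_collinear_points(self):
        d = dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 1
        recon = np.linalg.norm(res.coordinates[:, None] - res.coordinates[None, :], axis=2)
        assert np.allclose(recon, d.data, atol=1e-10)

    def test_equilateral_degenerate_pair(self):
        d = dm(np.ones((3, 3)) - np.eye(3))
        res = pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-9)

    def test_duplicate_sample_coincident(self, rng):
        pts = rng.normal(size=(4, 2))
        pts[3] = pts[0]
        d2 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(dm(d2))
        assert np.allclose(res.coordinates[0], res.coordinates[3], atol=1e-9)

    def test_euclidean_reconstruction_to_1e8(self, rng):
        """Coordinates reproduce a Euclidean-embeddable matrix to 1e-8."""
        pts = rng.normal(size=(12, 4))
        d2 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(dm(d2))
        recon = np.linalg.norm(res.coordinates[:, None] - res.coordinates[None, :], axis=2)
        assert np.abs(recon - d2).max() < 1e-8

    def test_matches_scikit_bio_eigenvalues(self, rng):
        import skbio
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(size=(7, 3))
        d2 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(dm(d2))
        sk = skbio_pcoa(skbio.DistanceMatrix(d2), number_of_dimensions=5)
        ours = res.eigenvalues[res.eigenvalues > 1e-10]
        theirs = np.asarray(sk.eigvals)[: len(ours)]
        assert np.allclose(np.sort(ours), np.sort(theirs[theirs > 1e-10]), atol=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(data=np.array([[0, 1.0], [2.0, 0]]), ids=["a", "b"])

    def test_lingoes_correction_removes_negatives(self, rng):
        # squared Euclidean distances are not Euclidean-embeddable
        pts = rng.normal(size=(6, 2))
        d = dm(np.linalg.norm(pts[:, None] - pts[None, :], axis=2) ** 2)
        assert pcoa(d).eigenvalues.min() < -1e-6
        corrected = pcoa(d, negative_correction="lingoes")
        assert corrected.eigenvalues.min() > -1e-8


class TestDbrda:
    def test_exact_linear_response(self, rng):
        x = rng.normal(size=(10, 2))
        y = x @ rng.normal(size=(2, 3)) + 5.0
        res = dbrda(y, x, n_perm=199, seed=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.p_perm == pytest.approx(1 / 200)

    def test_single_axis_equals_squared_pearson(self, rng):
        x = rng.normal(size=20)
        y = 0.6 * x + rng.normal(size=20)
        res = dbrda(y, x, n_perm=99, seed=0)
        r, _ = pearsonr(x, y)
        assert res.r2 == pytest.approx(r**2, abs=1e-10)

    def test_adjusted_below_raw_and_f_consistent(self, rng):
        x = rng.normal(size=(15, 3))
        y = rng.normal(size=(15, 4))
        res = dbrda(y, x, n_perm=99, seed=0)
        assert res.r2_adjusted <= res.r2
        f = (res.r2 / 3) / ((1 - res.r2) / (15 - 3 - 1))
        assert res.f_stat == pytest.approx(f)

    def test_rank_deficient_axes_truncated(self, rng):
        x1 = rng.normal(size=(12, 1))
        x = np.hstack([x1, 2 * x1])
        res = dbrda(rng.normal(size=(12, 2)), x, n_perm=49, seed=0)
        assert res.n_axes_used == 1

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="too few samples"):
            dbrda(rng.normal(size=(4, 2)), rng.normal(size=(4, 3)), n_perm=9)

    def test_power_under_dependence(self, rng):
        """A real community→isotope effect is detected in ≥80% of runs."""
        detected = 0
        for _ in range(60):
            x = rng.normal(size=(20, 2))
            y = x @ np.array([[1.0, 0.5], [0.5, 1.0]]) + rng.normal(size=(20, 2)) * 0.8
            res = dbrda(y, x, n_perm=199, seed=rng)
            detected += res.p_perm < 0.05
        assert detected / 60 >= 0.8


class TestRankCorrelation:
    def test_monotone_extremes(self):
        x = np.arange(6.0)
        assert rank_correlation(x, x * 3 + 1, n_perm=99)[0] == pytest.approx(1.0)
        assert rank_correlation(x, -x, n_perm=99)[0] == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        rho, _ = rank_correlation(np.array([1, 2, 3, 4.0]), np.array([2, 1, 4, 3.0]), n_perm=99)
        assert rho == pytest.approx(0.6)

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 4, size=15).astype(float)
        y = x + rng.normal(size=15)
        rho, _ = rank_correlation(x, y, n_perm=99)
        assert rho == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            rank_correlation(np.ones(5), np.arange(5.0))


def test_select_axes_capped_and_covering(rng):
    pts = rng.normal(size=(9, 5))
    d2 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    res = pcoa(dm(d2))
    axes = select_axes(res, variance_target=0.8)
    assert 1 <= axes.shape[1] <= 9 - 2
    k = axes.shape[1]
    assert res.proportion_explained[:k].sum() >= 0.8 - 1e-9
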