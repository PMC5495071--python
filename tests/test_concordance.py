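"""Four-way set logic, quadrant classes and KS concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutreg.concordance import (
    classify_four_way,
    coregulation_summary,
    ks_region_expression,
    ks_two_sample,
    quadrant_classify,
    quadrant_labels,
)
from gutreg.diffcount import ExpressionComparison
from gutreg.errors import DegenerateDataError
from gutreg.regions import PeakGeneAssignment

CONTRASTS = ("WTCV/WTGF", "MutCV/MutGF", "WTCV/MutCV", "WTGF/MutGF")


def _comparison(label, genes, q, fc=None):
    n = len(genes)
    table = pd.DataFrame(
        {
            "base_mean": np.ones(n),
            "log2fc": fc if fc is not None else np.ones(n),
            "p": q,
            "q": q,
            "tested": np.isfinite(q),
            "significant": np.where(np.isfinite(q), np.asarray(q) < 0.05, False),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return ExpressionComparison(label, table, 0.05)


class TestFourWay:
    def test_single_contrast_gene_counted_once(self):
        genes = ["g1", "g2"]
        comps = {
            c: _comparison(c, genes, np.array([0.01 if c == CONTRASTS[0] else 0.5, 0.5]))
            for c in CONTRASTS
        }
        m = classify_four_way(comps)
        assert m.union_size == 1
        venn = m.venn_counts()
        assert venn[CONTRASTS[0]] == 1
        assert sum(venn.values()) == 1

    def test_no_significant_genes_empty_union(self):
        genes = ["g1"]
        comps = {c: _comparison(c, genes, np.array([0.9])) for c in CONTRASTS}
        assert classify_four_way(comps).union_size == 0

    def test_venn_partition_identity_random(self, rng):
        genes = [f"g{i}" for i in range(200)]
        comps = {
            c: _comparison(c, genes, rng.uniform(0, 0.1, size=200)) for c in CONTRASTS
        }
        m = classify_four_way(comps)
        assert sum(m.venn_counts().values()) == m.union_size
        # pairwise intersections consistent with flags
        for a in CONTRASTS:
            for b in CONTRASTS:
                if a != b:
                    assert m.pairwise_intersection(a, b) == int(
                        (m.flags[a] & m.flags[b]).sum()
                    )

    def test_mismatched_universe_rejected(self):
        comps = {c: _comparison(c, ["g1"], np.array([0.5])) for c in CONTRASTS[:3]}
        comps[CONTRASTS[3]] = _comparison(CONTRASTS[3], ["gX"], np.array([0.5]))
        with pytest.raises(ValueError, match="universe"):
            classify_four_way(comps)


class TestQuadrants:
    def test_microbiota_suppressed_tf_activated(self):
        # positive on both axes: suppressed by microbiota, activated by the TF
        assert (
            quadrant_classify(2.0, 0.01, 1.5, 0.001) == "suppressed_activated"
        )

    def test_insignificant_axis_not_coregulated(self):
        assert quadrant_classify(2.0, 0.5, 1.5, 0.001) == "not_coregulated"

    def test_sign_logic(self):
        assert quadrant_classify(-2.0, 0.01, 1.0, 0.01) == "induced_activated"
        assert quadrant_classify(2.0, 0.01, -1.0, 0.01) == "suppressed_repressed"
        assert quadrant_classify(-2.0, 0.01, -1.0, 0.01) == "induced_repressed"

    def test_zero_significant_fold_change_contradicts(self):
        with pytest.raises(DegenerateDataError):
            quadrant_classify(0.0, 0.01, 1.0, 0.01)

    def test_vectorized_labels_partition_and_flip(self, rng):
        genes = [f"g{i}" for i in range(100)]
        fc = rng.normal(size=100)
        fc[fc == 0] = 1.0
        q = rng.uniform(0, 0.1, size=100)
        cx = _comparison("x", genes, q, fc=fc)
        cy = _comparison("y", genes, q, fc=np.ones(100))
        labels = quadrant_labels(cx, cy)
        flipped = quadrant_labels(cx, cy, flip_x=True)
        swap = {"suppressed_activated": "induced_activated",
                "induced_activated": "suppressed_activated",
                "suppressed_repressed": "induced_repressed",
                "induced_repressed": "suppressed_repressed",
                "not_coregulated": "not_coregulated"}
        assert (flipped == labels.map(swap)).all()
        counts = labels.value_counts()
        assert counts.sum() == 100  # classes partition the universe

    def test_summary_fraction_matches_hand_arithmetic(self):
        labels = pd.Series(
            ["suppressed_activated"] * 88
            + ["suppressed_repressed"] * 10
            + ["not_coregulated"] * 5
        )
        s = coregulation_summary(labels)
        assert s.n_shared == 98
        assert s.suppressed_activated_fraction == pytest.approx(88 / 98)

    def test_summary_all_not_coregulated(self):
        s = coregulation_summary(pd.Series(["not_coregulated"] * 4))
        assert s.n_shared == 0 and s.suppressed_activated_fraction is None


class TestKsTwoSample:
    def test_identical_samples(self):
        r = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert r.D == 0.0 and r.p == 1.0

    def test_disjoint_supports(self):
        assert ks_two_sample([1, 2], [3, 4]).D == 1.0

    def test_interleaved_samples(self):
        assert ks_two_sample([1, 3], [2, 4]).D == 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_matches_brute_force_ecdf(self, rng):
        # oracle: evaluate both ECDFs at every pooled point by counting
        for _ in range(200):
            x = rng.integers(0, 6, size=int(rng.integers(1, 9))).astype(float)
            y = rng.integers(0, 6, size=int(rng.integers(1, 9))).astype(float)
            D = max(
                abs((x <= t).mean() - (y <= t).mean())
                for t in np.concatenate([x, y])
            )
            assert ks_two_sample(x, y).D == pytest.approx(D, abs=1e-12)

    def test_exact_mode_matches_scipy(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=9)
        r = ks_two_sample(x, y, mode="exact")
        ref = stats.ks_2samp(x, y, method="exact")
        assert r.D == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)

    def test_shift_sign(self):
        assert ks_two_sample([5, 6], [1, 2]).shift_sign == 1
        assert ks_two_sample([1, 2], [5, 6]).shift_sign == -1


def _assignment(gene_ids):
    table = pd.DataFrame(
        {
            "peak_name": [f"p{i}" for i in range(len(gene_ids))],
            "gene_id": gene_ids,
            "distance": np.zeros(len(gene_ids)),
        }
    )
    return PeakGeneAssignment(table, 10_000)


class TestKsRegionExpression:
    def _expression(self, fc, genes):
        return _comparison("WTCV/WTGF", genes, np.full(len(genes), 0.01), fc=fc)

    def test_planted_shift_detected(self, rng):
        hits = 0
        runs = 50
        for i in range(runs):
            r = np.random.default_rng(1000 + i)
            genes = [f"g{j}" for j in range(120)]
            fc = np.concatenate([r.normal(2, 1, 60), r.normal(0, 1, 60)])
            expr = self._expression(fc, genes)
            res = ks_region_expression(
                _assignment(genes[:60]), _assignment(genes[60:]), expr
            )
            if res.ks.shift_sign == 1 and res.ks.p < 0.01:
                hits += 1
        assert hits / runs >= 0.95

    def test_null_p_values_never_anticonservative(self):
        # The two-sample KS statistic is discrete, so its null p-values sit
        # on atoms and are stochastically >= uniform; the property that
        # matters is the absence of anti-conservatism: the p ECDF must not
        # exceed the uniform line, and nominal rejection rates must hold.
        ps = []
        for i in range(300):
            r = np.random.default_rng(5000 + i)
            genes = [f"g{j}" for j in range(200)]
            fc = r.normal(0, 1, 200)
            expr = self._expression(fc, genes)
            res = ks_region_expression(
                _assignment(genes[:100]), _assignment(genes[100:]), expr
            )
            ps.append(res.ks.p)
        ps = np.sort(ps)
        ecdf = np.arange(1, len(ps) + 1) / len(ps)
        assert np.max(ecdf - ps) < 0.05  # one-sided distance to uniform
        assert np.mean(ps < 0.05) <= 0.08
        assert np.mean(ps < 0.01) <= 0.03

    def test_empty_region_set_rejected(self):
        genes = ["g1", "g2"]
        expr = self._expression(np.array([1.0, -1.0]), genes)
        with pytest.raises(DegenerateDataError, match="GF-enriched"):
            ks_region_expression(_assignment(["g1"]), _assignment([]), expr)

    def test_genes_in_both_counted(self):
        genes = ["g1", "g2", "g3"]
        expr = self._expression(np.array([1.0, -1.0, 0.5]), genes)
        res = ks_region_expression(
            _assignment(["g1", "g2"]), _assignment(["g2", "g3"]), expr
        )
        assert res.n_in_both == 1
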