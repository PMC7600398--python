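"""Evaluation statistics: cosine matching, reconstruction rate, attribution."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plda import (
    ActivityMatrix,
    MutationCatalog,
    SignatureSet,
    attributed_mutations,
    cosine_distance,
    map_to_known,
    match_signatures,
    reconstruction_rate,
)


def _vec(entries):
    v = np.zeros(96)
    v[: len(entries)] = entries
    return v


def _sigset(rows, prefix="S"):
    probs = np.array([r / r.sum() for r in rows])
    return SignatureSet(
        names=tuple(f"{prefix}{i}" for i in range(len(rows))), probs=probs
    )


class TestCosineDistance:
    def test_identical_vectors(self):
        v = _vec([1, 2, 3])
        assert cosine_distance(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support(self):
        assert cosine_distance(_vec([1, 0]), _vec([0, 1])) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        d = cosine_distance(_vec([1, 0]), _vec([1, 1]))
        assert d == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance(np.zeros(96), _vec([1]))


class TestMatchSignatures:
    def test_perfect_match(self, surrogate5):
        m = match_signatures(surrogate5, surrogate5)
        assert (m.correct_matched, m.duplicated, m.not_matched) == (5, 0, 0)
        assert m.unmatched_truths == ()
        assert all(d == pytest.approx(0.0, abs=1e-12) for _, _, d in m.pairs)
        # a perfect zero-distance assignment is found in both directions
        assert sorted(t for t, _, _ in m.truth_nearest) == [0, 1, 2, 3, 4]
        assert all(d < 1e-12 for _, _, d in m.truth_nearest)

    def test_duplicated_predictions(self):
        truth = _sigset([_vec([10, 1, 1]), _vec([1, 1, 10])])
        predicted = _sigset(
            [_vec([10, 1, 1]), _vec([10, 1.5, 1]), _vec([1, 1, 10])], prefix="P"
        )
        m = match_signatures(predicted, truth, threshold=0.1)
        assert m.correct_matched == 2
        assert m.duplicated == 1
        assert m.not_matched == 0

    def test_not_matched_predictions(self):
        truth = _sigset([_vec([1, 0, 0])])
        predicted = _sigset([_vec([1, 0, 0]), _vec([0, 0, 1])], prefix="P")
        m = match_signatures(predicted, truth, threshold=0.1)
        assert m.correct_matched == 1
        assert m.not_matched == 1
        assert m.duplicated == 0

    def test_accounting_identity_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pred = _sigset(list(rng.dirichlet(np.full(96, 0.1), size=4)), prefix="P")
            truth = _sigset(list(rng.dirichlet(np.full(96, 0.1), size=3)))
            m = match_signatures(pred, truth, threshold=0.3)
            assert m.correct_matched + m.duplicated + m.not_matched == pred.K

    def test_hungarian_agrees_on_clean_instances(self, surrogate5):
        greedy = match_signatures(surrogate5, surrogate5, method="greedy")
        hungarian = match_signatures(surrogate5, surrogate5, method="hungarian")
        assert {(p, t) for p, t, _ in greedy.pairs} == {
            (p, t) for p, t, _ in hungarian.pairs
        }


def _catalog_and_theta(counts_rows, theta_rows, labels, sig_names):
    counts = np.zeros((len(counts_rows), 96), dtype=np.int64)
    for i, row in enumerate(counts_rows):
        counts[i, : len(row)] = row
    cat = MutationCatalog.from_samples(
        [f"s{i}" for i in range(len(counts_rows))], labels, counts
    )
    theta = ActivityMatrix(
        sample_ids=cat.sample_ids,
        tumor_types=cat.sample_tumor_types(),
        signature_names=sig_names,
        values=np.array(theta_rows),
    )
    return cat, theta


class TestReconstructionRate:
    def test_exact_reconstruction_is_one(self):
        """Predicted frequencies equal to empirical frequencies give RR = 1."""
        counts_rows = [[4, 6], [2, 0, 8]]
        cat, theta = _catalog_and_theta(
            counts_rows, [[1, 0], [0, 1]], ["A", "B"], ("k1", "k2")
        )
        # one signature per sample carrying exactly its empirical distribution
        phi = SignatureSet(
            names=("k1", "k2"),
            probs=np.array(
                [cat.counts[0] / cat.counts[0].sum(), cat.counts[1] / cat.counts[1].sum()]
            ),
        )
        rr, per_type = reconstruction_rate(cat, theta, phi)
        assert rr == pytest.approx(1.0, abs=1e-12)
        assert per_type == {"A": pytest.approx(1.0), "B": pytest.approx(1.0)}

    def test_hand_example(self):
        """counts (2,2,0), predictions (0.25,0.25,0.5), n=4 -> RR = 0.5."""
        cat, theta = _catalog_and_theta([[2, 2, 0]], [[1.0]], ["T"], ("only",))
        phi = SignatureSet(names=("only",), probs=_vec([0.25, 0.25, 0.5])[None, :])
        rr, _ = reconstruction_rate(cat, theta, phi)
        assert rr == pytest.approx(0.5, abs=1e-12)

    def test_tumor_types_weighted_equally(self):
        """The global rate averages per-type means, not per-sample values."""
        # type A: two samples reconstructed at 1.0; type B: one sample at 0.5
        cat, theta = _catalog_and_theta(
            [[4, 0], [4, 0], [2, 2]], [[1.0], [1.0], [1.0]], ["A", "A", "B"], ("k",)
        )
        phi = SignatureSet(names=("k",), probs=_vec([1.0])[None, :])
        rr, per_type = reconstruction_rate(cat, theta, phi)
        assert per_type["A"] == pytest.approx(1.0)
        assert per_type["B"] == pytest.approx(0.5)
        assert rr == pytest.approx(0.75)

    @given(seed=st.integers(0, 10**6))
    def test_bounds_and_empirical_optimality(self, seed):
        """0 <= RR <= 1, and empirical frequencies are never worse than a
        random prediction."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 10, size=(3, 96)) + np.eye(3, 96, dtype=np.int64)
        cat = MutationCatalog.from_samples(
            ["a", "b", "c"], ["T", "T", "U"], counts
        )
        theta = ActivityMatrix(
            sample_ids=cat.sample_ids,
            tumor_types=cat.sample_tumor_types(),
            signature_names=("k1", "k2", "k3"),
            values=np.eye(3),
        )
        random_phi = SignatureSet(
            names=("k1", "k2", "k3"), probs=rng.dirichlet(np.ones(96), size=3)
        )
        empirical_phi = SignatureSet(
            names=("k1", "k2", "k3"),
            probs=cat.counts / cat.counts.sum(axis=1, keepdims=True),
        )
        rr_rand, _ = reconstruction_rate(cat, theta, random_phi)
        rr_emp, _ = reconstruction_rate(cat, theta, empirical_phi)
        assert 0.0 <= rr_rand <= 1.0 + 1e-12
        assert rr_emp >= rr_rand - 1e-12
        assert rr_emp == pytest.approx(1.0, abs=1e-12)

    def test_permutation_invariance(self, surrogate5):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 20, size=(4, 96))
        cat = MutationCatalog.from_samples(
            ["a", "b", "c", "d"], ["T"] * 4, counts
        )
        values = rng.dirichlet(np.ones(5), size=4)
        perm = rng.permutation(5)
        theta1 = ActivityMatrix(cat.sample_ids, cat.sample_tumor_types(),
                                surrogate5.names, values)
        theta2 = ActivityMatrix(cat.sample_ids, cat.sample_tumor_types(),
                                tuple(surrogate5.names[p] for p in perm), values[:, perm])
        phi2 = SignatureSet(
            names=tuple(surrogate5.names[p] for p in perm), probs=surrogate5.probs[perm]
        )
        rr1, _ = reconstruction_rate(cat, theta1, surrogate5)
        rr2, _ = reconstruction_rate(cat, theta2, phi2)
        assert rr1 == pytest.approx(rr2, abs=1e-12)


class TestAttribution:
    def test_indicator_theta(self):
        cat, theta = _catalog_and_theta([[5, 5]], [[0.0, 1.0]], ["T"], ("k1", "k2"))
        table = attributed_mutations(cat, theta)
        by_sig = table.set_index("signature")["attributed"]
        assert by_sig["k1"] == 0.0
        assert by_sig["k2"] == 10.0

    def test_simple_arithmetic(self):
        cat, theta = _catalog_and_theta(
            [[300, 700]], [[0.3, 0.7]], ["T"], ("k1", "k2")
        )
        wide = attributed_mutations(cat, theta).pivot_table(
            index="sample_id", columns="signature", values="attributed"
        )
        assert wide.loc["s0", "k1"] == pytest.approx(300.0)
        assert wide.loc["s0", "k2"] == pytest.approx(700.0)

    def test_totals_conserved(self, surrogate5):
        rng = np.random.default_rng(9)
        counts = rng.integers(1, 30, size=(6, 96))
        cat = MutationCatalog.from_samples(
            [f"s{i}" for i in range(6)], ["A"] * 3 + ["B"] * 3, counts
        )
        theta = ActivityMatrix(
            cat.sample_ids, cat.sample_tumor_types(), surrogate5.names,
            rng.dirichlet(np.ones(5), size=6),
        )
        table = attributed_mutations(cat, theta)
        totals = table.groupby("sample_id")["attributed"].sum()
        for sid, n in zip(cat.sample_ids, cat.n_mutations):
            assert totals[sid] == pytest.approx(float(n), abs=1e-9)


class TestMapToKnown:
    def test_identical_prediction_banded_close(self, surrogate5):
        table = map_to_known(surrogate5, surrogate5)
        assert (table["band"] == "<0.1").all()
        assert (table["cosine_distance"] < 1e-12).all()
        assert list(table["nearest_known"]) == list(surrogate5.names)

    def test_middle_band_by_construction(self, surrogate5):
        """Mix a known signature toward another until it sits in [0.1, 0.2)."""
        base, other = surrogate5.probs[0], surrogate5.probs[1]
        for w in np.linspace(0, 1, 2001):
            mixed = (1 - w) * base + w * other
            mixed /= mixed.sum()
            d = min(cosine_distance(mixed, p) for p in surrogate5.probs)
            if 0.1 <= d < 0.2:
                break
        else:
            pytest.fail("no mixture landed in the middle band")
        pred = SignatureSet(names=("mix",), probs=mixed[None, :])
        table = map_to_known(pred, surrogate5)
        assert table.loc[0, "band"] == "[0.1,0.2)"

    def test_bands_partition_predictions(self, surrogate5):
        rng = np.random.default_rng(12)
        pred = SignatureSet(
            names=tuple(f"P{i}" for i in range(7)),
            probs=rng.dirichlet(np.full(96, 0.2), size=7),
        )
        table = map_to_known(pred, surrogate5)
        assert len(table) == 7
        assert set(table["band"]).issubset({"<0.1", "[0.1,0.2)", ">=0.2"})
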