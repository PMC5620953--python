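import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actitag import logicfilter as lf
from actitag.tags import ActivityTag, TAG_ORDER, TRANSITION_ENDPOINTS


@pytest.fixture(scope="module")
def theta():
    return lf.default_adjacency()


class TestDefaultAdjacency:
    def test_self_loops_everywhere(self, theta):
        assert np.diag(theta).all()

    def test_predecessors_of_stand2sit(self, theta):
        preds = {
            t.value
            for t in TAG_ORDER
            if lf.allowed(theta, t, ActivityTag.STAND2SIT)
        }
        assert preds == {"stand", "lie2stand", "sit2stand", "walk", "stand2sit"}

    def test_sit_to_stand2lie_disallowed(self, theta):
        assert not lf.allowed(theta, "sit", "stand2lie")
        assert lf.allowed(theta, "sit", "sit2stand")

    def test_walk_successors(self, theta):
        succ = {t.value for t in TAG_ORDER if lf.allowed(theta, "walk", t)}
        assert succ == {"walk", "stand", "stand2sit", "stand2lie"}

    def test_static_postures_need_transition_to_change(self, theta):
        for a in ("sit", "stand", "lie"):
            for b in ("sit", "stand", "lie"):
                if a != b:
                    assert not lf.allowed(theta, a, b)

    def test_every_tag_has_successor_and_predecessor(self, theta):
        assert theta.any(axis=1).all()
        assert theta.any(axis=0).all()

    def test_transition_flows_into_its_destination(self, theta):
        for tr, (_src, dst) in TRANSITION_ENDPOINTS.items():
            assert lf.allowed(theta, tr, dst)

    def test_csv_roundtrip(self, theta, tmp_path):
        path = tmp_path / "theta.csv"
        lf.save_adjacency(theta, path)
        np.testing.assert_array_equal(lf.load_adjacency(path), theta)


class TestConfidenceThreshold:
    def test_separable_confidences_reach_ideal_corner(self):
        cal = lf.confidence_threshold(
            [0.9, 0.8, 0.85, 0.3, 0.2, 0.25], [1, 1, 1, 0, 0, 0]
        )
        assert cal.distance == pytest.approx(0.0)
        assert 0.3 < cal.delta <= 0.8

    def test_four_point_hand_example(self):
        cal = lf.confidence_threshold([0.9, 0.8, 0.3, 0.6], [1, 1, 0, 0])
        assert cal.distance == pytest.approx(0.0)
        assert 0.6 < cal.delta <= 0.8

    def test_uninformative_confidences_tie_toward_higher_threshold(self):
        cal = lf.confidence_threshold([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        # degenerate ROC: all points on the diagonal, distance 1 at best
        assert cal.delta == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lf.confidence_threshold([0.5, 0.6], [True, True])

    def test_delta_is_an_operating_point(self):
        conf = [0.91, 0.7, 0.55, 0.42, 0.3]
        cal = lf.confidence_threshold(conf, [1, 1, 0, 1, 0])
        assert cal.delta in conf


def _brute_force_filter(seq, conf, theta, delta, order):
    """Direct transcription of the correction rule, for cross-checking."""
    retained = [seq[0]]
    for t in range(1, len(seq)):
        cand, prev = seq[t], retained[t - 1]
        if conf[t] >= delta or cand == prev:
            retained.append(cand)
            continue
        hist = retained[max(0, t - 1 - order) : t - 1]
        prev_ok = True if not hist else any(lf.allowed(theta, h, prev) for h in hist)
        retained.append(cand if prev_ok and lf.allowed(theta, prev, cand) else prev)
    return retained


class TestApplyFilter:
    def test_infeasible_low_confidence_replaced(self, theta):
        out, changed = lf.apply_filter(
            ["sit", "stand2lie"], [1.0, 0.2], theta, delta=0.5, order=2
        )
        assert [t.value for t in out] == ["sit", "sit"]
        assert changed.tolist() == [False, True]

    def test_feasible_low_confidence_kept(self, theta):
        out, changed = lf.apply_filter(
            ["stand", "stand2sit"], [1.0, 0.2], theta, delta=0.5, order=2
        )
        assert [t.value for t in out] == ["stand", "stand2sit"]
        assert not changed.any()

    def test_high_confidence_never_altered(self, theta):
        seq = ["sit", "stand2lie", "walk", "lie2sit"]  # wildly infeasible
        out, changed = lf.apply_filter(seq, [0.9] * 4, theta, delta=0.5, order=2)
        assert [t.value for t in out] == seq
        assert not changed.any()

    def test_order_truncated_to_available_history(self, theta):
        out, _ = lf.apply_filter(
            ["sit", "stand2lie"], [1.0, 0.1], theta, delta=0.5, order=10
        )
        assert [t.value for t in out] == ["sit", "sit"]

    def test_exhaustive_agreement_with_brute_force(self, theta):
        """All sequences of length <= 5 over 4 tags with binary confidences."""
        tags4 = [ActivityTag.SIT, ActivityTag.STAND, ActivityTag.SIT2STAND, ActivityTag.STAND2SIT]
        for L in (2, 3, 4, 5):
            for seq in itertools.product(tags4, repeat=L):
                for conf in itertools.product((0.0, 1.0), repeat=L):
                    got, _ = lf.apply_filter(list(seq), list(conf), theta, delta=0.5, order=2)
                    assert got == _brute_force_filter(list(seq), list(conf), theta, 0.5, 2)

    def test_output_length_and_tag_provenance(self, theta):
        seq = ["stand", "walk", "sit2lie", "lie", "stand"]
        out, _ = lf.apply_filter(seq, [0.9, 0.1, 0.1, 0.1, 0.1], theta, delta=0.5, order=2)
        assert len(out) == len(seq)
        assert {t.value for t in out} <= set(seq)

    @settings(max_examples=100, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        order=st.integers(1, 3),
    )
    def test_injected_infeasible_errors_reduced(self, theta, seed, order):
        """Corrupting a feasible sequence with low-confidence infeasible
        labels at 10%: the filter must not increase the violation count."""
        rng = np.random.default_rng(seed)
        seq = [ActivityTag.STAND]
        for _ in range(39):
            succ = [t for t in TAG_ORDER if lf.allowed(theta, seq[-1], t)]
            seq.append(succ[rng.integers(len(succ))])
        conf = np.full(40, 0.9)
        for i in rng.choice(np.arange(1, 40), size=4, replace=False):
            bad = [t for t in TAG_ORDER if not lf.allowed(theta, seq[i - 1], t)]
            seq[i] = bad[rng.integers(len(bad))]
            conf[i] = 0.1

        def violations(s):
            return sum(not lf.allowed(theta, a, b) for a, b in zip(s, s[1:]))

        out, _ = lf.apply_filter(seq, conf, theta, delta=0.5, order=order)
        assert violations(out) <= violations(seq)

    def test_violations_strictly_reduced_on_average(self, theta):
        """Order-2 filtering strictly reduces injected violations over a
        batch of seeded corrupted sequences."""
        rng = np.random.default_rng(0)
        before = after = 0
        for _ in range(100):
            seq = [ActivityTag.STAND]
            for _ in range(29):
                succ = [t for t in TAG_ORDER if lf.allowed(theta, seq[-1], t)]
                seq.append(succ[rng.integers(len(succ))])
            conf = np.full(30, 0.9)
            for i in rng.choice(np.arange(1, 30), size=3, replace=False):
                bad = [t for t in TAG_ORDER if not lf.allowed(theta, seq[i - 1], t)]
                seq[i] = bad[rng.integers(len(bad))]
                conf[i] = 0.1
            out, _ = lf.apply_filter(seq, conf, theta, delta=0.5, order=2)
            before += sum(not lf.allowed(theta, a, b) for a, b in zip(seq, seq[1:]))
            after += sum(not lf.allowed(theta, a, b) for a, b in zip(out, out[1:]))
        assert after < before

    def test_literal_indexing_variant_runs(self, theta):
        seq = ["sit", "stand2lie", "lie"]
        out, _ = lf.apply_filter(
            seq, [0.2, 0.2, 0.9], theta, delta=0.5, order=2, literal_indexing=True
        )
        assert len(out) == 3

    def test_too_short_sequence_rejected(self, theta):
        with pytest.raises(ValueError):
            lf.apply_filter(["sit"], [0.5], theta)
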