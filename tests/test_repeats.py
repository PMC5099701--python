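"""Anchor detection and exact chain optimisation."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tapemeasure.generate import GeneratorParams, generate_sequence
from tapemeasure.repeats import (
    RepeatParams,
    annotation_overlap,
    call_repeats,
    chain_anchors,
    find_anchors,
    summarize,
)


def oracle_chain_size(positions, params):
    """Independent longest-chain oracle via networkx longest path."""
    g = nx.DiGraph()
    g.add_nodes_from(range(len(positions)))
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if params.admissible(positions[j] - positions[i]):
                g.add_edge(i, j)
    if len(positions) == 0:
        return 0
    return len(nx.dag_longest_path(g))


class TestFindAnchors:
    def test_direct_scan(self):
        assert find_anchors("MFAAFAAW") == [2, 5, 8]

    def test_no_anchors(self):
        assert find_anchors("A" * 40) == []

    def test_unknown_residue_reported_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            find_anchors("MAXW")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_anchors("")


class TestChainAnchors:
    def test_forced_spacings(self):
        chain, labels = chain_anchors([1, 12, 23])
        assert chain == [1, 12, 23] and labels == [11, 11]

    def test_mixed_periods(self):
        chain, labels = chain_anchors([1, 19, 30])
        assert chain == [1, 19, 30] and labels == [18, 11]

    def test_empty_input(self):
        assert chain_anchors([]) == ([], [])

    def test_skips_inadmissible_interior_anchor(self):
        # 1 -> 12 -> 23 is longer than anything through 7
        chain, _ = chain_anchors([1, 7, 12, 23])
        assert chain == [1, 12, 23]

    def test_leftmost_tie_break(self):
        # two disjoint 2-chains of equal span; leftmost wins
        chain, _ = chain_anchors([1, 12, 100, 111])
        assert chain == [1, 12]

    def test_matches_oracle_on_random_instances(self):
        params = RepeatParams()
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n = rng.integers(0, 26)
            positions = sorted(rng.choice(np.arange(1, 320), size=n, replace=False))
            positions = [int(p) for p in positions]
            chain, _ = chain_anchors(positions, params)
            assert len(chain) == oracle_chain_size(positions, params)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(1, 200), min_size=0, max_size=18, unique=True),
        st.integers(1, 200),
    )
    def test_adding_an_anchor_never_shrinks_the_chain(self, positions, extra):
        base = sorted(positions)
        augmented = sorted(set(base) | {extra})
        before, _ = chain_anchors(base)
        after, _ = chain_anchors(augmented)
        assert len(after) >= len(before)

    def test_tolerance_admits_off_spacings(self):
        params = RepeatParams(tolerance=1)
        chain, labels = chain_anchors([1, 13, 23], params)
        assert chain == [1, 13, 23] and labels == [11, 11]


class TestCallRepeats:
    def test_round_trip_recovers_planted_annotation(self, arch, reference_sequence):
        seq, _ = reference_sequence
        ann = call_repeats(seq)
        assert ann.spans() == list(arch.repeat_spans())
        stats = summarize(ann)
        assert stats == {"n_repeats": 29, "n_by_length": {11: 25, 18: 4},
                         "total_span": 347}
        # every 18-mer element starts with Trp
        for e in ann.elements:
            if e.length == 18:
                assert e.anchor_residue == "W"

    def test_single_anchor_below_min_repeats(self):
        assert call_repeats("A" * 30 + "W" + "A" * 30).elements == []

    def test_terminal_element_closed_by_anchor_identity(self):
        # chain F..F..W: terminal W opens an 18-mer, clipped at the end
        seq = "M" + "A" * 9 + "F" + "A" * 10 + "F" + "A" * 10 + "W" + "A" * 30
        ann = call_repeats(seq)
        lengths = [e.length for e in ann.elements]
        assert lengths == [11, 11, 18]

    def test_require_closing_anchor_drops_terminal(self):
        seq = "M" + "A" * 9 + "F" + "A" * 10 + "F" + "A" * 10 + "F" + "A" * 30
        params = RepeatParams(require_closing_anchor=True, min_repeats=2)
        ann = call_repeats(seq, params)
        assert [e.length for e in ann.elements] == [11, 11]

    def test_elements_within_bounds_and_disjoint_under_noise(self, arch):
        for seed in range(5):
            seq, _ = generate_sequence(
                arch, GeneratorParams(seed=seed, aromatic_noise_rate=0.05)
            )
            ann = call_repeats(seq)
            for a, b in zip(ann.elements, ann.elements[1:]):
                assert a.end < b.start
            assert all(1 <= e.start <= e.end <= len(seq) for e in ann.elements)

    def test_noise_robustness_reported_over_seeds(self, arch):
        """Mean exact-recovery of planted repeats at 5% aromatic noise."""
        planted = list(arch.repeat_spans())
        overlaps = []
        for seed in range(20):
            seq, _ = generate_sequence(
                arch, GeneratorParams(seed=seed, aromatic_noise_rate=0.05)
            )
            overlaps.append(annotation_overlap(planted, call_repeats(seq)))
        mean = float(np.mean(overlaps))
        assert 0.0 < mean <= 1.0
        # zero-noise recovery is exact by construction
        seq0, _ = generate_sequence(arch, GeneratorParams(seed=0))
        assert annotation_overlap(planted, call_repeats(seq0)) == 1.0


class TestSummarize:
    def test_empty(self):
        from tapemeasure.repeats import RepeatAnnotation

        assert summarize(RepeatAnnotation("x")) == {
            "n_repeats": 0, "n_by_length": {}, "total_span": 0,
        }

    def test_two_elements(self):
        from tapemeasure.repeats import RepeatAnnotation, RepeatElement

        ann = RepeatAnnotation("x", [
            RepeatElement(1, 1, 11, "F"), RepeatElement(2, 12, 29, "W"),
        ])
        assert summarize(ann)["total_span"] == 29


def test_invalid_params():
    with pytest.raises(ValueError):
        RepeatParams(periods=frozenset())
    with pytest.raises(ValueError):
        RepeatParams(min_repeats=1)
    with pytest.raises(ValueError):
        RepeatParams(tolerance=-1)
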