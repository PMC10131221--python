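"""Topology strings: linearization, coarse-graining, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from ctidp.landscape import TopologyLandscape
from ctidp.strings import (
    CoarseString,
    TopologyString,
    align_similarity,
    coarse_grain,
    linearize,
    read_topo,
    representative_string,
    similarity_matrix,
    write_topo,
)
from ctidp.synthetic import sample_landscape
from ctidp.contacts import Contact, ContactTrajectory
from ctidp.topology import topology_matrix

from .conftest import all_contacts, lcs_by_enumeration


class TestLinearize:
    def test_nested_pair_folds_both_triangles_to_p(self):
        s = linearize(topology_matrix([(1, 4), (2, 3)]))
        assert s.symbols == ("Pinv".replace("Pinv", "P"), "P")
        assert s.symbols == ("P", "P")

    def test_three_serial_contacts(self):
        s = linearize(topology_matrix([(1, 2), (4, 5), (7, 8)]))
        assert s.symbols == ("S",) * 6

    def test_length_is_n_times_n_minus_one(self, rng):
        pool = all_contacts(25)
        for n in (2, 4, 6, 9):
            idx = rng.choice(len(pool), size=n, replace=False)
            s = linearize(topology_matrix([pool[k] for k in idx]))
            assert len(s) == n * (n - 1)

    def test_matches_elementwise_traversal_oracle(self, rng):
        pool = all_contacts(18)
        idx = rng.choice(len(pool), size=6, replace=False)
        mat = topology_matrix([pool[k] for k in idx])
        s = linearize(mat)
        fold = {"Pinv": "P", "CPinv": "CP"}
        expected = [
            fold.get(mat.entries[m, k], mat.entries[m, k])
            for m in range(mat.n)
            for k in range(mat.n)
            if m != k
        ]
        assert list(s.symbols) == expected
        assert not {"Pinv", "CPinv"} & set(s.symbols)

    def test_single_contact_rejected(self):
        with pytest.raises(ValueError):
            linearize(topology_matrix([(1, 4)]))


class TestCoarseGrain:
    @pytest.mark.parametrize(
        "symbols,expected",
        [
            (("S", "CS", "P", "CP", "X"), (2,)),          # mean 2.0
            (("S",) * 5, (0,)),
            (("X",) * 5 + ("S",) * 5, (4, 0)),
        ],
    )
    def test_window_means(self, symbols, expected):
        s = TopologyString(symbols)
        assert coarse_grain(s).symbols == expected

    def test_remainder_window_averaged_or_dropped(self):
        s = TopologyString(("S",) * 5 + ("X", "X"))
        assert coarse_grain(s).symbols == (0, 4)
        assert coarse_grain(s, keep_remainder=False).symbols == (0,)

    def test_round_half_away_from_zero(self):
        # window mean 1.5 rounds to 2, not to the even neighbour
        s = TopologyString(("S", "CS", "P", "P", "CS"))  # codes 0,1,2,2,1 -> 1.2
        assert coarse_grain(s).symbols == (1,)
        s2 = TopologyString(("CS", "CS", "P", "P", "CS"))  # 1,1,2,2,1 -> 1.4
        assert coarse_grain(s2).symbols == (1,)
        s3 = TopologyString(("CS", "P", "P", "P", "CS"))  # 1,2,2,2,1 -> 1.6
        assert coarse_grain(s3).symbols == (2,)
        s4 = TopologyString(("S", "CS", "P", "P", "X"))  # 0,1,2,2,4 -> 1.8
        assert coarse_grain(s4).symbols == (2,)
        s5 = TopologyString(("CS", "CS", "P", "CS", "P"))  # 1,1,2,1,2 -> 1.4
        assert coarse_grain(s5).symbols == (1,)
        half = TopologyString(("CS", "P"))  # remainder mean 1.5 -> 2
        assert coarse_grain(half).symbols == (2,)


class TestAlignment:
    def test_identical_strings_score_one(self):
        a = CoarseString((0, 1, 2, 3, 4, 2))
        assert align_similarity(a, a, "global") == 1.0
        assert align_similarity(a, a, "blocks") == 1.0

    def test_disjoint_alphabets_score_zero(self):
        a = CoarseString((0, 0, 0, 0))
        b = CoarseString((4, 4, 4, 4))
        assert align_similarity(a, b, "global") == 0.0
        assert align_similarity(a, b, "blocks") == 0.0

    def test_documented_example(self):
        # two matches, lengths 3 and 2 -> 2 * 2 / 5
        assert align_similarity(CoarseString((0, 1, 2)), CoarseString((0, 2))) \
            == pytest.approx(0.8)

    @given(st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_global_matches_exhaustive_enumeration(self, data):
        """Match-count global alignment equals the longest common
        subsequence, computed here by exhaustive enumeration (l <= 6)."""
        a = data.draw(st.lists(st.integers(0, 4), min_size=1, max_size=6))
        b = data.draw(st.lists(st.integers(0, 4), min_size=1, max_size=6))
        got = align_similarity(CoarseString(tuple(a)), CoarseString(tuple(b)))
        sa = "".join(map(str, a))
        sb = "".join(map(str, b))
        assert got == pytest.approx(
            2.0 * lcs_by_enumeration(sa, sb) / (len(a) + len(b))
        )

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_symmetry_and_bounds(self, data):
        a = data.draw(st.lists(st.integers(0, 4), min_size=1, max_size=12))
        b = data.draw(st.lists(st.integers(0, 4), min_size=1, max_size=12))
        for method in ("global", "blocks"):
            x = align_similarity(CoarseString(tuple(a)), CoarseString(tuple(b)), method)
            y = align_similarity(CoarseString(tuple(b)), CoarseString(tuple(a)), method)
            assert x == pytest.approx(y)
            assert 0.0 <= x <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_similarity("", "0123")

    def test_methods_agree_on_ranking(self, rng):
        """Global and blocks scores rank a family of progressively
        mutated strings the same way."""
        base = rng.integers(0, 5, size=60)
        family = []
        for n_mut in (0, 3, 8, 15, 25, 40):
            mutated = base.copy()
            pos = rng.choice(60, size=n_mut, replace=False)
            mutated[pos] = (mutated[pos] + 1 + rng.integers(0, 4, n_mut)) % 5
            family.append(CoarseString(tuple(int(v) for v in mutated)))
        ref = CoarseString(tuple(int(v) for v in base))
        g = [align_similarity(ref, m, "global") for m in family]
        b = [align_similarity(ref, m, "blocks") for m in family]
        rho = spearmanr(g, b).statistic
        assert rho > 0.9


class TestRepresentativeString:
    def make_traj(self):
        frames = (
            frozenset({Contact(1, 2), Contact(4, 5)}),     # serial: (1,0,0)
            frozenset({Contact(1, 2), Contact(4, 5)}),
            frozenset({Contact(1, 6), Contact(2, 5), Contact(3, 4)}),  # nested
            frozenset({Contact(1, 6), Contact(2, 5)}),
            frozenset({Contact(1, 4), Contact(2, 5), Contact(3, 6)}),  # crossing
            frozenset({Contact(1, 4), Contact(2, 5)}),
        )
        return ContactTrajectory(frames=frames, chain_length=6)

    def test_planted_nearest_frame_selected(self):
        traj = self.make_traj()
        res = TopologyLandscape(traj).fit(k_range=range(1, 4), n_init=4, seed=0)
        s = representative_string(res, traj)
        last = res.ordered_clusters()[-1]
        pts = res.model.scaled[last.frames]
        dist = np.linalg.norm(pts - last.centroid, axis=1)
        planted = int(last.frames[int(np.argmin(dist))])
        assert s.source[2] == str(planted)

    def test_single_frame_cluster_returns_that_frame(self):
        traj = self.make_traj()
        res = TopologyLandscape(traj).fit(k_range=range(1, 2), n_init=2, seed=0)
        # one cluster holding everything: string comes from its centroid frame
        s = representative_string(res, traj)
        assert len(s) > 0


class TestSimilarityMatrixAndIO:
    def test_identical_strings_full_similarity(self):
        s = CoarseString((0, 1, 2, 3))
        mat = similarity_matrix([("A", "1", s), ("B", "1", s)])
        assert mat.loc["A", "B"] == 1.0
        assert mat.loc["A", "A"] == 1.0  # singleton diagonal

    def test_diagonal_averages_within_protein_runs(self):
        runs = [
            ("A", "1", CoarseString((0, 1, 2, 3))),
            ("A", "2", CoarseString((0, 1, 2, 3))),
            ("A", "3", CoarseString((4, 4, 4, 4))),
            ("B", "1", CoarseString((0, 1, 2, 3))),
        ]
        mat = similarity_matrix(runs)
        # pairs: (1,2)=1.0, (1,3)=0.0, (2,3)=0.0 -> mean 1/3
        assert mat.loc["A", "A"] == pytest.approx(1.0 / 3.0)
        expected_ab = np.mean([1.0, 1.0, 0.0])
        assert mat.loc["A", "B"] == pytest.approx(expected_ab)
        assert np.allclose(mat.values, mat.values.T)

    def test_entries_match_pairwise_recomputation(self, rng):
        strings = [
            ("P1", "1", CoarseString(tuple(rng.integers(0, 5, size=10)))),
            ("P2", "1", CoarseString(tuple(rng.integers(0, 5, size=12)))),
            ("P3", "1", CoarseString(tuple(rng.integers(0, 5, size=8)))),
        ]
        mat = similarity_matrix(strings)
        for pa, _, sa in strings:
            for pb, _, sb in strings:
                if pa != pb:
                    assert mat.loc[pa, pb] == pytest.approx(
                        align_similarity(sa, sb)
                    )

    def test_topo_file_roundtrip(self, tmp_path):
        raw = TopologyString(("S", "CS", "P", "CP", "X"), source=("AR", "1", "7"))
        coarse = coarse_grain(raw)
        path = tmp_path / "strings.topo"
        write_topo(path, [raw, coarse])
        back = read_topo(path)
        assert isinstance(back[0], TopologyString)
        assert back[0].symbols == raw.symbols
        assert back[0].source == ("AR", "1", "7")
        assert isinstance(back[1], CoarseString)
        assert back[1].symbols == coarse.symbols

    def test_coarse_then_align_identical_parents(self):
        s = linearize(topology_matrix([(1, 6), (2, 5), (3, 8), (7, 12)]))
        assert align_similarity(coarse_grain(s), coarse_grain(s)) == 1.0
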