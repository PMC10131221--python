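"""Contact detection, trajectories and lifetimes."""

import io
import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ctidp.contacts import (
    Contact,
    ContactCriteria,
    ContactTrajectory,
    LifetimeTable,
    compute_lifetimes,
    cumulative_contact_map,
    detect_contacts,
    filter_by_regime,
    read_pdb_trajectory,
)
from ctidp.synthetic import brute_force_max_run

from .conftest import random_contact_set


def chain_coords(*residue_atoms):
    """Build per-residue coordinate arrays from plain lists."""
    return [np.asarray(a, dtype=float).reshape(-1, 3) for a in residue_atoms]


class TestDetectContacts:
    def test_distance_cutoff_and_separation(self):
        # residues 1 and 4 are 4.0 A apart -> contact at 4.5 A cutoff
        coords = chain_coords(
            [0, 0, 0], [100, 0, 0], [200, 0, 0], [4.0, 0, 0]
        )
        crit = ContactCriteria(distance_cutoff=4.5, min_atom_pairs=1,
                               min_seq_separation=3)
        assert detect_contacts(coords, crit) == {Contact(1, 4)}
        # same geometry but the threshold asks for two atom pairs
        crit2 = ContactCriteria(min_atom_pairs=2)
        assert detect_contacts(coords, crit2) == frozenset()

    def test_sequence_separation_filter(self):
        # adjacent residues within cutoff are ignored at min_sep 3
        coords = chain_coords([0, 0, 0], [1, 0, 0], [50, 0, 0], [60, 0, 0])
        assert detect_contacts(coords, ContactCriteria()) == frozenset()
        crit = ContactCriteria(min_seq_separation=1)
        assert detect_contacts(coords, crit) == {Contact(1, 2)}

    def test_multi_atom_pairs(self):
        coords = chain_coords(
            [[0, 0, 0], [0, 1, 0]], [100, 0, 0], [200, 0, 0],
            [[3, 0, 0], [3, 1, 0]],
        )
        crit = ContactCriteria(min_atom_pairs=4, min_seq_separation=3)
        assert detect_contacts(coords, crit) == {Contact(1, 4)}

    def test_rigid_motion_invariance(self, rng):
        coords = [rng.normal(scale=4.0, size=(3, 3)) for _ in range(8)]
        before = detect_contacts(coords)
        rot = Rotation.random(random_state=7).as_matrix()
        shift = np.array([10.0, -3.0, 2.5])
        moved = [c @ rot.T + shift for c in coords]
        assert detect_contacts(moved) == before

    def test_errors(self):
        with pytest.raises(ValueError, match="empty frame"):
            detect_contacts([])
        bad = chain_coords([0, 0, 0], [np.nan, 0, 0])
        with pytest.raises(ValueError, match="residue 2"):
            detect_contacts(bad)


class TestLifetimes:
    @pytest.mark.parametrize(
        "present,expected_ns",
        [
            ([1, 2, 3, 7, 8], 15.0),   # longest run is 3 frames
            (list(range(10)), 50.0),   # present throughout
            ([4], 5.0),                # single-frame run
        ],
    )
    def test_max_lifetime_examples(self, present, expected_ns):
        n = 10
        frames = tuple(
            frozenset({Contact(1, 5)}) if f in present else frozenset()
            for f in range(n)
        )
        traj = ContactTrajectory(frames=frames, frame_interval=5.0, chain_length=5)
        table = compute_lifetimes(traj)
        assert table.lifetimes.tolist() == [expected_ns]

    def test_exhaustive_schedules_match_run_length_oracle(self):
        # every on/off schedule of up to 8 frames (acceptance runs 12)
        for n in range(1, 9):
            for bits in itertools.product([False, True], repeat=n):
                if not any(bits):
                    continue
                frames = tuple(
                    frozenset({Contact(2, 6)}) if on else frozenset()
                    for on in bits
                )
                traj = ContactTrajectory(frames=frames, frame_interval=5.0,
                                         chain_length=6)
                got = compute_lifetimes(traj).lifetimes[0]
                assert got == brute_force_max_run(bits) * 5.0

    def test_lifetime_bounded_by_duration(self, small_trajectory):
        table = compute_lifetimes(small_trajectory)
        assert (table.lifetimes <= small_trajectory.duration).all()
        steps = table.lifetimes / small_trajectory.frame_interval
        assert np.allclose(steps, np.round(steps))

    def test_empty_trajectory_rejected(self):
        traj = ContactTrajectory(frames=(), frame_interval=5.0, chain_length=5)
        with pytest.raises(ValueError):
            compute_lifetimes(traj)


class TestCumulativeAndFilter:
    def test_cumulative_union(self, small_trajectory):
        assert cumulative_contact_map(small_trajectory) == {
            Contact(1, 5), Contact(2, 4), Contact(7, 11)
        }

    def test_cumulative_idempotent(self):
        frame = frozenset({Contact(1, 5), Contact(3, 9)})
        one = ContactTrajectory(frames=(frame,), chain_length=9)
        three = ContactTrajectory(frames=(frame,) * 3, chain_length=9)
        assert cumulative_contact_map(one) == cumulative_contact_map(three)

    def test_filter_partition(self, small_trajectory):
        table = compute_lifetimes(small_trajectory)
        labels = ["short", "middle", "long"]
        df = table.table.copy()
        df["regime"] = [labels[k % 3] for k in range(len(df))]
        table = LifetimeTable(df, frame_interval=5.0)
        per_regime = [
            filter_by_regime(small_trajectory, table, r) for r in labels
        ]
        for f, frame in enumerate(small_trajectory.frames):
            union = frozenset().union(*(t.frames[f] for t in per_regime))
            assert union == frame
            # regime-filtered frames are disjoint per-frame subsets
            sizes = sum(len(t.frames[f]) for t in per_regime)
            assert sizes == len(frame)

    def test_filter_identity_and_empty(self, small_trajectory):
        table = compute_lifetimes(small_trajectory)
        short = LifetimeTable(
            table.table.assign(regime="short"), frame_interval=5.0
        )
        assert filter_by_regime(small_trajectory, short, "short").frames == \
            small_trajectory.frames
        middle = filter_by_regime(small_trajectory, short, "middle")
        assert all(len(f) == 0 for f in middle.frames)

    def test_unknown_regime_rejected(self, small_trajectory):
        table = compute_lifetimes(small_trajectory)
        with pytest.raises(ValueError, match="unknown regime"):
            filter_by_regime(small_trajectory, table, "eternal")


class TestIO:
    def test_tsv_roundtrip(self, small_trajectory, tmp_path):
        path = tmp_path / "traj.tsv"
        small_trajectory.to_tsv(path)
        back = ContactTrajectory.from_tsv(
            path, frame_interval=5.0, n_frames=len(small_trajectory)
        )
        assert back.frames == small_trajectory.frames

    def test_pdb_two_models(self, tmp_path):
        # two CA-only frames of a 5-residue chain; residues 1 and 5 touch
        # only in the second model
        def model(n, x5):
            lines = [f"MODEL     {n:>4}"]
            xs = [0.0, 8.0, 16.0, 24.0, x5]
            for r, x in enumerate(xs, start=1):
                lines.append(
                    f"ATOM  {r:>5}  CA  ALA A{r:>4}    "
                    f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
                )
            lines.append("ENDMDL")
            return "\n".join(lines)

        pdb = tmp_path / "toy.pdb"
        pdb.write_text(model(1, 40.0) + "\n" + model(2, 3.0) + "\nEND\n")
        traj = read_pdb_trajectory(pdb, ContactCriteria(min_seq_separation=3))
        assert traj.frames == (frozenset(), frozenset({Contact(1, 5)}))
        assert traj.chain_length == 5


def test_noncanonical_contacts_rejected():
    with pytest.raises(ValueError):
        Contact(3, 3) and ContactTrajectory(
            frames=(frozenset({(3, 3)}),), chain_length=5
        )
    with pytest.raises(ValueError):
        ContactTrajectory(frames=(frozenset({(4, 2)}),), chain_length=5)
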