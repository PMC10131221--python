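"""Residue-contact detection and contact-trajectory handling.

A *contact* is an unordered residue pair ``(i, j)`` with ``1 <= i < j`` along a
single polypeptide chain.  Contacts are detected geometrically: two residues are
in contact when at least ``min_atom_pairs`` heavy-atom pairs (one atom from each
residue) lie within ``distance_cutoff`` angstroms, and the residues are at least
``min_seq_separation`` apart in sequence.  A :class:`ContactTrajectory` is an
ordered list of per-frame contact sets sampled at a fixed time interval; the
*lifetime* of a contact is the length of its longest contiguous run of frames,
times the frame interval.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Contact",
    "ContactCriteria",
    "ContactTrajectory",
    "LifetimeTable",
    "REGIMES",
    "detect_contacts",
    "compute_lifetimes",
    "cumulative_contact_map",
    "filter_by_regime",
    "read_pdb_trajectory",
]

#: Recognised lifetime regime labels, in temporal order.
REGIMES = ("short", "middle", "long")


class Contact(NamedTuple):
    """Canonical residue pair: 1-based indices with ``i < j``."""

    i: int
    j: int


def as_contact(i: int, j: int) -> Contact:
    """Build a canonical :class:`Contact`, rejecting non-canonical input."""
    i, j = int(i), int(j)
    if i < 1:
        raise ValueError(f"residue indices are 1-based, got i={i}")
    if j <= i:
        raise ValueError(f"contact must satisfy i < j, got ({i}, {j})")
    return Contact(i, j)


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric rules that define a residue-residue contact.

    Parameters
    ----------
    distance_cutoff : float
        Heavy-atom distance threshold in angstroms (default 4.5).
    min_atom_pairs : int
        Number of inter-residue atom pairs within the cutoff required to
        call a contact (default 1).
    min_seq_separation : int
        Minimum ``|j - i|`` sequence separation (default 3), excluding
        trivially adjacent contacts.
    """

    distance_cutoff: float = 4.5
    min_atom_pairs: int = 1
    min_seq_separation: int = 3

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")
        if self.min_atom_pairs < 1:
            raise ValueError("min_atom_pairs must be >= 1")
        if self.min_seq_separation < 1:
            raise ValueError("min_seq_separation must be >= 1")


def _coerce_residue_coords(
    frame_coordinates: Sequence[np.ndarray] | Mapping[int, np.ndarray],
) -> list[np.ndarray]:
    if isinstance(frame_coordinates, Mapping):
        if not frame_coordinates:
            raise ValueError("empty frame: no residues supplied")
        indices = sorted(frame_coordinates)
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError(
                "residue mapping must use 1-based sequential indices, "
                f"got {indices[:5]}..."
            )
        groups = [np.asarray(frame_coordinates[r], dtype=float) for r in indices]
    else:
        groups = [np.asarray(g, dtype=float) for g in frame_coordinates]
    if not groups:
        raise ValueError("empty frame: no residues supplied")
    for resid, g in enumerate(groups, start=1):
        if g.ndim != 2 or g.shape[1] != 3 or g.shape[0] == 0:
            raise ValueError(
                f"residue {resid}: expected a non-empty (n_atoms, 3) array, "
                f"got shape {g.shape}"
            )
        if not np.all(np.isfinite(g)):
            raise ValueError(f"residue {resid}: non-finite coordinate")
    return groups


def detect_contacts(
    frame_coordinates: Sequence[np.ndarray] | Mapping[int, np.ndarray],
    criteria: ContactCriteria = ContactCriteria(),
) -> frozenset[Contact]:
    """Detect residue-residue contacts in one frame of coordinates.

    Parameters
    ----------
    frame_coordinates
        Per-residue heavy-atom positions: either a sequence whose element
        ``k`` holds the ``(n_atoms, 3)`` array of residue ``k + 1``, or a
        mapping from 1-based residue index to such an array.
    criteria
        Geometric contact definition.

    Returns
    -------
    frozenset of :class:`Contact`
        All canonical contacts satisfying the criteria.
    """
    groups = _coerce_residue_coords(frame_coordinates)
    coords = np.concatenate(groups, axis=0)
    resids = np.concatenate(
        [np.full(len(g), r, dtype=np.int64) for r, g in enumerate(groups, start=1)]
    )
    tree = cKDTree(coords)
    pairs = tree.query_pairs(criteria.distance_cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return frozenset()
    ri = resids[pairs[:, 0]]
    rj = resids[pairs[:, 1]]
    lo = np.minimum(ri, rj)
    hi = np.maximum(ri, rj)
    keep = (hi - lo) >= criteria.min_seq_separation
    if not np.any(keep):
        return frozenset()
    pair_ids = lo[keep] * (len(groups) + 1) + hi[keep]
    ids, counts = np.unique(pair_ids, return_counts=True)
    ids = ids[counts >= criteria.min_atom_pairs]
    base = len(groups) + 1
    return frozenset(Contact(int(p // base), int(p % base)) for p in ids)


@dataclass(frozen=True)
class ContactTrajectory:
    """Ordered frames of contact sets at a fixed time resolution.

    Attributes
    ----------
    frames : tuple of frozenset of Contact
        Per-frame contact sets, in temporal order.
    frame_interval : float
        Time between frames, in ns (default 5).
    chain_length : int
        Number of residues in the chain.
    """

    frames: tuple[frozenset[Contact], ...]
    frame_interval: float = 5.0
    chain_length: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        frames = tuple(frozenset(as_contact(*c) for c in f) for f in self.frames)
        n = self.chain_length
        if n <= 0:
            n = max((c.j for f in frames for c in f), default=0)
        for f in frames:
            for c in f:
                if c.j > n:
                    raise ValueError(
                        f"contact {tuple(c)} exceeds chain length {n}"
                    )
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "chain_length", n)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Total trajectory duration in ns."""
        return len(self.frames) * self.frame_interval

    # -- I/O: TSV dialect `frame<TAB>res_i<TAB>res_j`, 0-based frames ----

    @classmethod
    def from_tsv(
        cls,
        path: str | Path | io.TextIOBase,
        frame_interval: float = 5.0,
        chain_length: int = 0,
        n_frames: int | None = None,
    ) -> "ContactTrajectory":
        """Read a contact trajectory from TSV (`frame res_i res_j` header)."""
        df = pd.read_csv(path, sep="\t")
        required = {"frame", "res_i", "res_j"}
        if not required.issubset(df.columns):
            raise ValueError(f"contact TSV must have columns {sorted(required)}")
        last = int(df["frame"].max()) + 1 if len(df) else 0
        total = max(last, n_frames or 0)
        frames: list[set[Contact]] = [set() for _ in range(total)]
        for f, i, j in df[["frame", "res_i", "res_j"]].itertuples(index=False):
            frames[int(f)].add(as_contact(i, j))
        return cls(
            frames=tuple(frozenset(f) for f in frames),
            frame_interval=frame_interval,
            chain_length=chain_length,
        )

    def to_tsv(self, path: str | Path | io.TextIOBase) -> None:
        rows = [
            (f, c.i, c.j)
            for f, frame in enumerate(self.frames)
            for c in sorted(frame)
        ]
        pd.DataFrame(rows, columns=["frame", "res_i", "res_j"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class LifetimeTable:
    """Per-contact maximum lifetimes and (optional) regime labels.

    Wraps a DataFrame with columns ``res_i, res_j, lifetime_ns, regime``;
    ``regime`` is ``None`` until assigned.
    """

    table: pd.DataFrame
    frame_interval: float = 5.0

    def __post_init__(self) -> None:
        required = {"res_i", "res_j", "lifetime_ns"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"lifetime table needs columns {sorted(required)}")
        if "regime" not in self.table.columns:
            self.table = self.table.assign(regime=None)
        if (self.table["lifetime_ns"] <= 0).any():
            raise ValueError("lifetimes must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def lifetimes(self) -> np.ndarray:
        return self.table["lifetime_ns"].to_numpy(dtype=float)

    @property
    def contacts(self) -> list[Contact]:
        return [
            as_contact(i, j)
            for i, j in self.table[["res_i", "res_j"]].itertuples(index=False)
        ]

    def regime_of(self) -> dict[Contact, str | None]:
        return {
            as_contact(i, j): r
            for i, j, r in self.table[["res_i", "res_j", "regime"]].itertuples(
                index=False
            )
        }

    def to_tsv(self, path: str | Path | io.TextIOBase) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path | io.TextIOBase, frame_interval: float = 5.0
    ) -> "LifetimeTable":
        df = pd.read_csv(path, sep="\t")
        if "regime" in df.columns:
            df["regime"] = df["regime"].where(pd.notna(df["regime"]), None)
        return cls(df, frame_interval=frame_interval)


def _longest_run(frame_indices: Iterable[int]) -> int:
    """Length of the longest run of consecutive integers."""
    best = run = 0
    prev: int | None = None
    for f in sorted(frame_indices):
        run = run + 1 if prev is not None and f == prev + 1 else 1
        best = max(best, run)
        prev = f
    return best


def compute_lifetimes(traj: ContactTrajectory) -> LifetimeTable:
    """Maximum lifetime of every contact appearing in the trajectory.

    A contact may form and break repeatedly; its lifetime is the length of
    its longest contiguous run of frames times the frame interval.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    occurrences: dict[Contact, list[int]] = {}
    for f, frame in enumerate(traj.frames):
        for c in frame:
            occurrences.setdefault(c, []).append(f)
    rows = [
        (c.i, c.j, _longest_run(fr) * traj.frame_interval)
        for c, fr in sorted(occurrences.items())
    ]
    df = pd.DataFrame(rows, columns=["res_i", "res_j", "lifetime_ns"])
    return LifetimeTable(df, frame_interval=traj.frame_interval)


def cumulative_contact_map(traj: ContactTrajectory) -> frozenset[Contact]:
    """Union of all per-frame contact sets ("cumulative contact map")."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    out: set[Contact] = set()
    for frame in traj.frames:
        out |= frame
    return frozenset(out)


def filter_by_regime(
    traj: ContactTrajectory, lifetimes: LifetimeTable, regime: str
) -> ContactTrajectory:
    """Keep only contacts whose assigned lifetime regime matches ``regime``.

    Frame structure is preserved; unlabeled contacts raise.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    labels = lifetimes.regime_of()
    frames = []
    for f, frame in enumerate(traj.frames):
        kept = set()
        for c in frame:
            label = labels.get(c)
            if label is None:
                raise ValueError(
                    f"contact {tuple(c)} in frame {f} has no regime label"
                )
            if label == regime:
                kept.add(c)
        frames.append(frozenset(kept))
    return replace(traj, frames=tuple(frames))


def read_pdb_trajectory(
    path: str | Path,
    criteria: ContactCriteria = ContactCriteria(),
    frame_interval: float = 5.0,
    include_hydrogens: bool = False,
) -> ContactTrajectory:
    """Detect contacts in a multi-MODEL PDB (one model per frame) or a
    directory of per-frame PDB files (sorted by name).

    Residues of the first chain are renumbered sequentially from 1.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    path = Path(path)
    files = sorted(path.glob("*.pdb")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no PDB files found under {path}")

    frames: list[frozenset[Contact]] = []
    chain_length = 0
    for file in files:
        structure = parser.get_structure(file.stem, str(file))
        for model in structure:
            chain = next(iter(model))
            groups: list[np.ndarray] = []
            for residue in chain:
                if residue.id[0] != " ":
                    continue  # skip heteroatoms/water
                atoms = [
                    a.coord
                    for a in residue
                    if include_hydrogens or a.element != "H"
                ]
                if atoms:
                    groups.append(np.asarray(atoms, dtype=float))
            chain_length = max(chain_length, len(groups))
            frames.append(detect_contacts(groups, criteria))
    return ContactTrajectory(
        frames=tuple(frames),
        frame_interval=frame_interval,
        chain_length=chain_length,
    )
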