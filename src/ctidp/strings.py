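"""Topology strings: matrix linearization, coarse-graining and alignment.

A topology matrix is linearized row by row (off-diagonal entries only) into
a string over {S, CS, P, CP, X}; the directional labels Pinv/CPinv fold
into P/CP since they describe the same arrangement.  Because the matrix is
symmetric, row-wise linearization accounts for the locality of relations
along both rows and columns.  For alignment at scale, strings are
coarse-grained by mapping S=0, CS=1, P=2, CP=3, X=4 and averaging
non-overlapping windows of five symbols (rounding to the nearest integer),
a weighting in which entangled relations count more than non-interacting
ones.  Similarity between two strings is scored either by global alignment
(match 1 / mismatch 0 / gap 0) normalised by 2/(l1 + l2), or by the
recursive longest-contiguous-matching-block ratio; both are symmetric and
live in [0, 1].
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .contacts import ContactTrajectory
from .landscape import LandscapeResults
from .topology import CP, CPINV, CS, P, PINV, S, TopologyMatrix, X, topology_matrix

__all__ = [
    "TopologyString",
    "CoarseString",
    "linearize",
    "coarse_grain",
    "align_similarity",
    "representative_string",
    "similarity_matrix",
    "write_topo",
    "read_topo",
]

#: String alphabet (inverse labels never appear in strings).
STRING_ALPHABET = (S, CS, P, CP, X)

#: Coarse-graining code of each relation.
COARSE_CODE = {S: 0, CS: 1, P: 2, CP: 3, X: 4}

_FOLD = {PINV: P, CPINV: CP}

#: Single-character encoding used in .topo files and for alignment.
_SYMBOL_CHAR = {S: "S", CS: "c", P: "P", CP: "Q", X: "X"}
_CHAR_SYMBOL = {v: k for k, v in _SYMBOL_CHAR.items()}


@dataclass(frozen=True)
class TopologyString:
    """Ordered relation labels from a row-major matrix linearization."""

    symbols: tuple[str, ...]
    source: tuple[str, str, str] = ("", "", "")  # (protein, run, frame)

    def __post_init__(self) -> None:
        bad = set(self.symbols) - set(STRING_ALPHABET)
        if bad:
            raise ValueError(f"invalid string symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)

    def to_text(self) -> str:
        return "".join(_SYMBOL_CHAR[s] for s in self.symbols)

    @classmethod
    def from_text(cls, text: str, source=("", "", "")) -> "TopologyString":
        return cls(tuple(_CHAR_SYMBOL[ch] for ch in text), source=tuple(source))


@dataclass(frozen=True)
class CoarseString:
    """Window-averaged integer string over {0..4}."""

    symbols: tuple[int, ...]
    source: tuple[str, str, str] = ("", "", "")

    def __post_init__(self) -> None:
        if any(s not in range(5) for s in self.symbols):
            raise ValueError("coarse symbols must be integers in 0..4")

    def __len__(self) -> int:
        return len(self.symbols)

    def to_text(self) -> str:
        return "".join(str(s) for s in self.symbols)

    @classmethod
    def from_text(cls, text: str, source=("", "", "")) -> "CoarseString":
        return cls(tuple(int(ch) for ch in text), source=tuple(source))


def linearize(matrix: TopologyMatrix) -> TopologyString:
    """Row-major traversal of the off-diagonal entries, inverses folded."""
    if matrix.n < 2:
        raise ValueError("need at least 2 contacts to linearize")
    symbols = []
    for m in range(matrix.n):
        for k in range(matrix.n):
            if m == k:
                continue
            rel = matrix.entries[m, k]
            symbols.append(_FOLD.get(rel, rel))
    return TopologyString(tuple(symbols))


def coarse_grain(
    s: TopologyString,
    window: int = 5,
    keep_remainder: bool = True,
) -> CoarseString:
    """Average non-overlapping windows of relation codes, rounding
    half away from zero; a trailing partial window is averaged too
    (or dropped with ``keep_remainder=False``)."""
    if len(s) == 0:
        raise ValueError("cannot coarse-grain an empty string")
    if window < 1:
        raise ValueError("window must be >= 1")
    codes = np.array([COARSE_CODE[sym] for sym in s.symbols], dtype=float)
    out = []
    for start in range(0, len(codes), window):
        chunk = codes[start : start + window]
        if len(chunk) < window and not keep_remainder:
            break
        out.append(int(np.floor(chunk.mean() + 0.5)))  # round half away from zero
    return CoarseString(tuple(out), source=s.source)


def _as_chars(x) -> str:
    if isinstance(x, TopologyString):
        return x.to_text()
    if isinstance(x, CoarseString):
        return x.to_text()
    if isinstance(x, str):
        return x
    return "".join(str(int(v)) for v in x)


def align_similarity(a, b, method: str = "global") -> float:
    """Similarity score in [0, 1] between two topology strings.

    ``global``: dynamic-programming global alignment with match 1,
    mismatch 0, gap 0 (so the optimal score is the number of matched
    characters), normalised by 2/(l1 + l2).  ``blocks``: recursive
    longest-contiguous-matching-block ratio 2M/(l1 + l2).  Both methods
    are symmetric and score identical strings 1.
    """
    sa, sb = _as_chars(a), _as_chars(b)
    if not sa or not sb:
        raise ValueError("cannot align empty strings")
    if method == "global":
        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=1,
            mismatch_score=0,
            open_gap_score=0,
            extend_gap_score=0,
        )
        matches = aligner.score(sa, sb)
        return 2.0 * matches / (len(sa) + len(sb))
    if method == "blocks":
        # the greedy longest-block recursion is order-dependent; take the
        # better decomposition of the two orders so the score is symmetric
        fwd = difflib.SequenceMatcher(None, sa, sb, autojunk=False).ratio()
        rev = difflib.SequenceMatcher(None, sb, sa, autojunk=False).ratio()
        return max(fwd, rev)
    raise ValueError(f"unknown method {method!r}; expected 'global' or 'blocks'")


def representative_string(
    results: LandscapeResults,
    traj: ContactTrajectory,
    which: str = "last-cluster",
) -> TopologyString:
    """Topology string of the frame closest to the centroid of the
    temporally last topological state (ties broken by the earliest frame).
    """
    if which != "last-cluster":
        raise ValueError("only 'last-cluster' selection is implemented")
    last = results.ordered_clusters()[-1]
    if len(last.frames) == 0:
        raise ValueError("last cluster has no member frames")
    pts = results.model.scaled[last.frames]
    dist = np.linalg.norm(pts - np.asarray(last.centroid), axis=1)
    frame = int(last.frames[int(np.argmin(dist))])  # argmin takes first tie
    contacts = traj.frames[frame]
    if len(contacts) < 2:
        raise ValueError(
            f"representative frame {frame} has fewer than 2 contacts"
        )
    string = linearize(topology_matrix(contacts))
    return TopologyString(string.symbols, source=("", "", str(frame)))


def similarity_matrix(
    strings: Sequence[tuple[str, str, object]],
    method: str = "global",
) -> pd.DataFrame:
    """Protein-by-protein similarity table from labelled strings.

    ``strings`` holds ``(protein, run, string)`` triples.  Off-diagonal
    entries average the pairwise scores across the two proteins' runs;
    the diagonal averages the distinct-run pairs within one protein
    (1.0 for proteins with a single string).
    """
    if len(strings) < 2:
        raise ValueError("need at least 2 strings")
    groups: dict[str, list] = {}
    for protein, _run, s in strings:
        groups.setdefault(str(protein), []).append(s)
    proteins = list(groups)
    mat = pd.DataFrame(
        np.ones((len(proteins), len(proteins))), index=proteins, columns=proteins
    )
    for pi, a in enumerate(proteins):
        for b in proteins[pi:]:
            if a == b:
                runs = groups[a]
                if len(runs) == 1:
                    score = 1.0
                else:
                    pairs = [
                        align_similarity(runs[u], runs[v], method=method)
                        for u in range(len(runs))
                        for v in range(u + 1, len(runs))
                    ]
                    score = float(np.mean(pairs))
            else:
                score = float(
                    np.mean(
                        [
                            align_similarity(x, y, method=method)
                            for x in groups[a]
                            for y in groups[b]
                        ]
                    )
                )
            mat.loc[a, b] = score
            mat.loc[b, a] = score
    return mat


def write_topo(
    path: str | Path, strings: Iterable[TopologyString | CoarseString]
) -> None:
    """Write strings in FASTA-like .topo format (`>protein|run|frame`)."""
    lines = []
    for s in strings:
        protein, run, frame = s.source
        lines.append(f">{protein}|{run}|{frame}")
        lines.append(s.to_text())
    Path(path).write_text("\n".join(lines) + "\n")


def read_topo(path: str | Path) -> list[TopologyString | CoarseString]:
    """Read a .topo file; digit bodies load as coarse strings."""
    out: list[TopologyString | CoarseString] = []
    header: tuple[str, str, str] | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            parts = (line[1:].split("|") + ["", "", ""])[:3]
            header = tuple(parts)
        else:
            if header is None:
                raise ValueError("malformed .topo file: body before header")
            cls = CoarseString if line[0].isdigit() else TopologyString
            out.append(cls.from_text(line, source=header))
            header = None
    return out
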