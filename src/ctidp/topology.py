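"""Circuit-topology classification of contact pairs.

Circuit topology characterises the arrangement of every pair of intrachain
contacts as one of three relations: series (S, the chain intervals are
disjoint), parallel (P, one interval is nested inside the other), or cross
(X, the intervals overlap without containment).  When the two contacts share
exactly one contact site the relation is *concerted*: concerted series (CS)
if the shared residue is the meeting point of two otherwise disjoint
intervals, concerted parallel (CP) if the nested pair shares an endpoint.
Parallel relations are directional — the nested contact is in P (or CP)
relation with its envelope, the envelope in inverse parallel (Pinv/CPinv)
with the nested one — but both labels describe the same arrangement and fold
into P/CP in topology strings.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .contacts import Contact, as_contact

__all__ = [
    "S", "CS", "P", "PINV", "CP", "CPINV", "X",
    "RELATIONS",
    "classify_pair",
    "TopologyMatrix",
    "topology_matrix",
    "TopologyFractions",
    "topology_fractions",
    "Circuit",
    "find_circuits",
]

S = "S"
CS = "CS"
P = "P"
PINV = "Pinv"
CP = "CP"
CPINV = "CPinv"
X = "X"

#: All relation labels that may appear in a topology matrix.
RELATIONS = (S, CS, P, PINV, CP, CPINV, X)

#: Single-character codes used in TSV export of matrices.
_CHAR = {S: "S", CS: "c", P: "P", PINV: "p", CP: "Q", CPINV: "q", X: "X"}
_FROM_CHAR = {v: k for k, v in _CHAR.items()}

#: Mate of each relation across the matrix diagonal.
TRANSPOSED = {S: S, CS: CS, X: X, P: PINV, PINV: P, CP: CPINV, CPINV: CP}

#: Parent class of each relation for (S, P, X) accounting.
PARENT = {S: S, CS: S, P: P, PINV: P, CP: P, CPINV: P, X: X}


def classify_pair(c1: Contact | tuple, c2: Contact | tuple) -> str:
    """Circuit-topology relation of contact ``c1`` relative to ``c2``.

    With ``c1 = (i, j)`` and ``c2 = (r, s)`` canonical (``i < j``,
    ``r < s``), the relation is decided by the ordering of the four
    contact sites along the chain:

    * no shared site, disjoint intervals -> ``S``;
    * no shared site, ``[i, j]`` strictly inside ``(r, s)`` -> ``P``
      (the reverse nesting gives ``Pinv``);
    * no shared site, overlapping without containment -> ``X``;
    * exactly one shared site at the meeting point of two otherwise
      serial intervals -> ``CS``;
    * exactly one shared endpoint with nesting -> ``CP`` / ``CPinv``.
    """
    c1 = as_contact(*c1)
    c2 = as_contact(*c2)
    if c1 == c2:
        raise ValueError("cannot classify a contact against itself")
    i, j = c1
    r, s = c2
    shared = {i, j} & {r, s}
    if len(shared) == 1:
        if j == r or s == i:  # intervals meet end-to-start
            return CS
        if i == r:  # shared left endpoint, nesting decided by right ends
            return CP if j < s else CPINV
        # shared right endpoint (j == s)
        return CP if i > r else CPINV
    # four distinct sites
    if j < r or s < i:
        return S
    if r < i and j < s:
        return P
    if i < r and s < j:
        return PINV
    return X


@dataclass(frozen=True)
class TopologyFractions:
    """Fractions of S, P and X relations over all unordered contact pairs.

    Concerted subclasses fold into their parent class (CS -> S;
    CP/CPinv/Pinv -> P).  With fewer than two contacts the fractions are
    undefined and flagged via ``defined``.
    """

    fS: float
    fP: float
    fX: float
    n_pairs: int
    defined: bool = True

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.fS, self.fP, self.fX)


def canonical_contact_order(contacts: Iterable[Contact | tuple]) -> tuple[Contact, ...]:
    """Sort contacts by first site, ties by second site; reject duplicates."""
    out = sorted(as_contact(*c) for c in contacts)
    for a, b in zip(out, out[1:]):
        if a == b:
            raise ValueError(f"duplicate contact {tuple(a)}")
    return tuple(out)


@dataclass(frozen=True)
class TopologyMatrix:
    """N x N matrix of pairwise CT relations over an indexed contact list.

    Contacts are indexed in canonical order (ascending first site, then
    second).  The diagonal is excluded; off-diagonal entries obey the
    transposition invariants S<->S, CS<->CS, X<->X, P<->Pinv, CP<->CPinv.
    """

    contacts: tuple[Contact, ...]
    entries: np.ndarray  # dtype object, entries[m, n] is relation of m to n

    @property
    def n(self) -> int:
        return len(self.contacts)

    def relation(self, m: int, n: int) -> str:
        if m == n:
            raise IndexError("diagonal (self-relation) is excluded")
        return str(self.entries[m, n])

    def to_tsv(self, path: str | Path | io.TextIOBase) -> None:
        header = "\t".join(f"{c.i}-{c.j}" for c in self.contacts)
        lines = [header]
        for m in range(self.n):
            row = [
                "." if m == n else _CHAR[self.entries[m, n]]
                for n in range(self.n)
            ]
            lines.append("\t".join(row))
        text = "\n".join(lines) + "\n"
        if isinstance(path, io.TextIOBase):
            path.write(text)
        else:
            Path(path).write_text(text)

    @classmethod
    def from_tsv(cls, path: str | Path | io.TextIOBase) -> "TopologyMatrix":
        text = path.read() if isinstance(path, io.TextIOBase) else Path(path).read_text()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        contacts = tuple(
            as_contact(*map(int, tok.split("-"))) for tok in lines[0].split("\t")
        )
        n = len(contacts)
        entries = np.empty((n, n), dtype=object)
        for m, ln in enumerate(lines[1:]):
            for k, tok in enumerate(ln.split("\t")):
                entries[m, k] = None if tok == "." else _FROM_CHAR[tok]
        return cls(contacts=contacts, entries=entries)


def topology_matrix(contacts: Iterable[Contact | tuple]) -> TopologyMatrix:
    """Build the topology matrix of a contact set (canonical ordering)."""
    ordered = canonical_contact_order(contacts)
    n = len(ordered)
    if n < 1:
        raise ValueError("need at least one contact")
    entries = np.empty((n, n), dtype=object)
    for m in range(n):
        for k in range(m + 1, n):
            rel = classify_pair(ordered[m], ordered[k])
            entries[m, k] = rel
            entries[k, m] = TRANSPOSED[rel]
    return TopologyMatrix(contacts=ordered, entries=entries)


def topology_fractions(contacts: Iterable[Contact | tuple]) -> TopologyFractions:
    """Fractions of S, P, X over unordered pairs, normalised to sum to 1."""
    ordered = canonical_contact_order(contacts)
    n = len(ordered)
    if n < 2:
        return TopologyFractions(0.0, 0.0, 0.0, n_pairs=0, defined=False)
    counts = {S: 0, P: 0, X: 0}
    for m in range(n):
        for k in range(m + 1, n):
            counts[PARENT[classify_pair(ordered[m], ordered[k])]] += 1
    total = n * (n - 1) // 2
    return TopologyFractions(
        fS=counts[S] / total,
        fP=counts[P] / total,
        fX=counts[X] / total,
        n_pairs=total,
    )


def topology_counts(contacts: Iterable[Contact | tuple]) -> tuple[int, int, int]:
    """(nS, nP, nX) counts over unordered pairs; (0, 0, 0) when N < 2."""
    ordered = canonical_contact_order(contacts)
    n = len(ordered)
    counts = {S: 0, P: 0, X: 0}
    for m in range(n):
        for k in range(m + 1, n):
            counts[PARENT[classify_pair(ordered[m], ordered[k])]] += 1
    return (counts[S], counts[P], counts[X])


@dataclass(frozen=True)
class Circuit:
    """A topological circuit: a chain subsection whose removal leaves the
    topology of the remaining contacts unchanged."""

    start: int
    end: int
    members: tuple[int, ...]  # indices into the canonical contact order


def find_circuits(contacts: Iterable[Contact | tuple]) -> list[Circuit]:
    """Group contacts into topological circuits.

    Two contacts belong to the same circuit when their closed chain
    intervals intersect (any relation other than S, including CS); circuits
    are the connected components of that intersection graph, reported with
    their spanned residue range.  Component spans are pairwise disjoint.
    """
    ordered = canonical_contact_order(contacts)
    if not ordered:
        raise ValueError("need at least one contact")
    g = nx.Graph()
    g.add_nodes_from(range(len(ordered)))
    for m in range(len(ordered)):
        for k in range(m + 1, len(ordered)):
            if classify_pair(ordered[m], ordered[k]) != S:
                g.add_edge(m, k)
    circuits = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        circuits.append(
            Circuit(
                start=min(ordered[m].i for m in members),
                end=max(ordered[m].j for m in members),
                members=members,
            )
        )
    circuits.sort(key=lambda c: c.start)
    return circuits
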