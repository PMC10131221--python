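"""Shared fixtures and independent brute-force oracles for the suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ctidp.contacts import Contact, ContactTrajectory


def all_contacts(chain_length: int, min_sep: int = 1) -> list[Contact]:
    """Every canonical contact on a chain."""
    return [
        Contact(i, j)
        for i in range(1, chain_length + 1)
        for j in range(i + min_sep, chain_length + 1)
    ]


def lcs_by_enumeration(a: str, b: str) -> int:
    """Longest common subsequence via exhaustive enumeration of the
    subsequences of the shorter string (oracle for tiny strings)."""
    if len(a) > len(b):
        a, b = b, a
    best = 0
    for r in range(len(a), 0, -1):
        for combo in itertools.combinations(a, r):
            # is combo a subsequence of b?
            it = iter(b)
            if all(ch in it for ch in combo):
                best = r
                break
        if best:
            break
    return best


def circuits_by_union_find(contacts) -> list[tuple[int, int]]:
    """Circuit spans via transitive closure of closed-interval
    intersection (union-find, independent of the CT classifier)."""
    cs = sorted(tuple(c) for c in contacts)
    parent = list(range(len(cs)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in range(len(cs)):
        for k in range(m + 1, len(cs)):
            (i, j), (r, s) = cs[m], cs[k]
            if not (j < r or s < i):  # closed intervals intersect
                parent[find(m)] = find(k)
    spans: dict[int, list[int]] = {}
    for m in range(len(cs)):
        spans.setdefault(find(m), []).append(m)
    out = [
        (min(cs[m][0] for m in mem), max(cs[m][1] for m in mem))
        for mem in spans.values()
    ]
    return sorted(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20230407)


@pytest.fixture
def small_trajectory() -> ContactTrajectory:
    """Five frames of hand-picked contacts on a 12-residue chain."""
    frames = (
        frozenset({Contact(1, 5), Contact(2, 4)}),
        frozenset({Contact(1, 5), Contact(2, 4), Contact(7, 11)}),
        frozenset({Contact(1, 5), Contact(7, 11)}),
        frozenset({Contact(7, 11)}),
        frozenset({Contact(2, 4)}),
    )
    return ContactTrajectory(frames=frames, frame_interval=5.0, chain_length=12)


def random_contact_set(rng, chain_length=40, n_max=8, min_sep=1):
    pool = all_contacts(chain_length, min_sep)
    n = int(rng.integers(2, n_max + 1))
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[k] for k in idx]
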