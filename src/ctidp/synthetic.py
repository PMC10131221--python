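"""Synthetic contact trajectories, topology point clouds and string
families with known ground truth, plus the brute-force oracles used to
validate the analysis modules.

The trajectory generator emulates the statistical structure of contact
dynamics in disordered chains: a large population of transient contacts
whose maximum run lengths follow a discrete power law, and a minority of
"scaffold" contacts that persist for most of the trajectory (at least 60%
of frames by default).  When charge coupling is requested, the companion
sequence places opposite-charge residues (K/E) at scaffold contact sites,
mimicking charge-stabilised long-lived contacts.  These generators
reproduce statistical structure, not physics: there is no excluded volume
and no kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .contacts import Contact, ContactTrajectory, as_contact

__all__ = [
    "GeneratorSpec",
    "discrete_powerlaw",
    "sample_contact_set",
    "sample_trajectory",
    "sample_landscape",
    "sample_lifetimes_with_break",
    "short_life_landscape",
    "middle_life_landscape",
    "ct_bruteforce_oracle",
    "brute_force_max_run",
]


def discrete_powerlaw(
    rng: np.random.Generator,
    exponent: float,
    k_max: int,
    size: int,
    k_min: int = 1,
) -> np.ndarray:
    """Exact inverse-CDF sampling of P(k) proportional to k^-exponent on
    the integers k_min..k_max."""
    if exponent <= 1:
        raise ValueError("exponent must exceed 1")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    k = np.arange(k_min, k_max + 1, dtype=float)
    cdf = np.cumsum(k**-exponent)
    cdf /= cdf[-1]
    u = rng.random(size)
    return k_min + np.searchsorted(cdf, u, side="left")


def sample_contact_set(
    chain_length: int,
    n: int,
    bias: str = "mixed",
    seed: int | np.random.Generator | None = None,
    min_sep: int = 3,
) -> frozenset[Contact]:
    """Sample ``n`` canonical contacts with a controlled topology bias.

    ``serial`` yields pairwise disjoint intervals, ``nested`` concentric
    intervals, ``crossing`` interleaved intervals, and ``mixed`` draws
    uniformly from all pairs with the required sequence separation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n < 1:
        raise ValueError("need n >= 1 contacts")
    if bias == "serial":
        # n disjoint intervals, each of width >= min_sep
        need = n * (min_sep + 1) + (n - 1)
        if need > chain_length:
            raise ValueError(f"chain of {chain_length} cannot host {n} serial contacts")
        slack = chain_length - need
        cuts = np.sort(rng.integers(0, slack + 1, size=n))
        contacts, pos = [], 1
        for k in range(n):
            start = pos + (cuts[k] - (cuts[k - 1] if k else 0))
            contacts.append(as_contact(start, start + min_sep))
            pos = start + min_sep + 2  # leave a gap before the next interval
        return frozenset(contacts)
    if bias == "nested":
        if 2 * n + min_sep - 1 > chain_length:
            raise ValueError(f"chain of {chain_length} cannot host {n} nested contacts")
        sites = np.sort(
            rng.choice(np.arange(1, chain_length + 1), size=2 * n, replace=False)
        )
        contacts = [as_contact(int(sites[k]), int(sites[2 * n - 1 - k])) for k in range(n)]
        if any(c.j - c.i < min_sep for c in contacts):
            # fall back to a deterministic concentric layout
            mid = chain_length // 2
            contacts = [
                as_contact(k + 1, chain_length - k)
                for k in range(n)
                if (chain_length - k) - (k + 1) >= min_sep
            ]
            if len(contacts) < n:
                raise ValueError("cannot nest that many contacts with the separation")
        return frozenset(contacts)
    if bias == "crossing":
        # (a_1 < a_2 < ... < a_n < b_1 < ... < b_n) pairwise crossing
        if 2 * n > chain_length or n < 1:
            raise ValueError(f"chain of {chain_length} cannot host {n} crossing contacts")
        sites = np.sort(
            rng.choice(np.arange(1, chain_length + 1), size=2 * n, replace=False)
        )
        contacts = [as_contact(int(sites[k]), int(sites[n + k])) for k in range(n)]
        if any(c.j - c.i < min_sep for c in contacts):
            step = max(min_sep, n)
            if n + step > chain_length:
                raise ValueError("cannot cross that many contacts with the separation")
            contacts = [as_contact(k + 1, k + 1 + step) for k in range(n)]
        return frozenset(contacts)
    if bias == "mixed":
        pairs = [
            (i, j)
            for i in range(1, chain_length + 1)
            for j in range(i + min_sep, chain_length + 1)
        ]
        if n > len(pairs):
            raise ValueError(f"chain of {chain_length} has only {len(pairs)} valid pairs")
        idx = rng.choice(len(pairs), size=n, replace=False)
        return frozenset(as_contact(*pairs[k]) for k in idx)
    raise ValueError(f"unknown bias {bias!r}")


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic contact-trajectory generator.

    Defaults emulate a 1 microsecond stretch of a 5 ns-resolution
    contact trajectory on a ~120-residue disordered chain: many transient
    contacts with power-law run lengths (exponent 2) and a small scaffold
    persisting for at least 60% of the frames.
    """

    seed: int
    chain_length: int = 120
    n_transient_contacts: int = 60
    n_scaffold_contacts: int = 8
    powerlaw_exponent: float = 2.0
    frame_interval: float = 5.0
    n_frames: int = 200
    topology_bias: str = "mixed"
    charge_coupling: bool = False
    scaffold_persistence: float = 0.6
    max_transient_frames: int | None = None

    def __post_init__(self) -> None:
        if self.chain_length < 5 or self.n_frames < 2:
            raise ValueError("degenerate generator spec")
        if self.powerlaw_exponent <= 1:
            raise ValueError("power-law exponent must exceed 1")
        if not 0 < self.scaffold_persistence <= 1:
            raise ValueError("scaffold_persistence must be in (0, 1]")


def _place_run(rng: np.random.Generator, n_frames: int, length: int) -> set[int]:
    start = int(rng.integers(0, n_frames - length + 1))
    return set(range(start, start + length))


def sample_trajectory(
    spec: GeneratorSpec,
) -> tuple[ContactTrajectory, dict]:
    """Generate a contact trajectory plus its ground truth.

    Returns ``(trajectory, truth)`` where ``truth`` carries the true
    maximum lifetime (ns) and regime label of every contact, the planted
    short-regime break time, and the companion sequence.  Each contact is
    scheduled as a single contiguous run, so the generated run length IS
    the maximum lifetime.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_transient_contacts + spec.n_scaffold_contacts
    contacts = sorted(
        sample_contact_set(
            spec.chain_length, n_total, bias=spec.topology_bias, seed=rng
        )
    )
    order = rng.permutation(n_total)
    scaffold = [contacts[k] for k in order[: spec.n_scaffold_contacts]]
    transient = [contacts[k] for k in order[spec.n_scaffold_contacts :]]

    k_max = spec.max_transient_frames or max(2, spec.n_frames // 5)
    break_ns = k_max * spec.frame_interval

    frames: list[set[Contact]] = [set() for _ in range(spec.n_frames)]
    true_lifetimes: dict[Contact, float] = {}
    true_regimes: dict[Contact, str] = {}

    runs = discrete_powerlaw(
        rng, spec.powerlaw_exponent, k_max, size=len(transient)
    ).astype(int)
    for c, length in zip(transient, runs):
        for f in _place_run(rng, spec.n_frames, int(length)):
            frames[f].add(c)
        true_lifetimes[c] = float(length) * spec.frame_interval
        true_regimes[c] = "short"

    min_persist = int(np.ceil(spec.scaffold_persistence * spec.n_frames))
    for c in scaffold:
        length = int(rng.integers(min_persist, spec.n_frames + 1))
        for f in _place_run(rng, spec.n_frames, length):
            frames[f].add(c)
        true_lifetimes[c] = float(length) * spec.frame_interval
        true_regimes[c] = "long" if length == spec.n_frames else "middle"

    sequence = _companion_sequence(rng, spec, scaffold, transient)
    traj = ContactTrajectory(
        frames=tuple(frozenset(f) for f in frames),
        frame_interval=spec.frame_interval,
        chain_length=spec.chain_length,
    )
    truth = {
        "lifetimes_ns": true_lifetimes,
        "regimes": true_regimes,
        "break_ns": break_ns,
        "sequence": sequence,
        "scaffold_contacts": frozenset(scaffold),
        "transient_contacts": frozenset(transient),
    }
    return traj, truth


_UNCHARGED = list("ACFGHILMNPQSTVWY")
_ALL_AA = list("ACDEFGHIKLMNPQRSTVWY")


def _companion_sequence(
    rng: np.random.Generator,
    spec: GeneratorSpec,
    scaffold: Sequence[Contact],
    transient: Sequence[Contact],
) -> str:
    if not spec.charge_coupling:
        return "".join(rng.choice(_ALL_AA, size=spec.chain_length))
    # charge-stabilised scaffold: K/E pairs at scaffold sites, no charges
    # elsewhere, so longer-lived contacts carry the charged pairs
    seq = list(rng.choice(_UNCHARGED, size=spec.chain_length))
    for c in scaffold:
        seq[c.i - 1] = "K"
        seq[c.j - 1] = "E"
    return "".join(seq)


def sample_landscape(
    k: int,
    centers: Sequence[Sequence[float]],
    sigmas: float | Sequence[float],
    n_per_cluster: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian blobs in [0, 1]^3 with known labels, emitted in temporal
    blocks (cluster 0 first) to exercise temporal ordering."""
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (k, 3):
        raise ValueError("centers must be a (k, 3) array")
    sig = np.broadcast_to(np.asarray(sigmas, dtype=float), (k,))
    pts, labels = [], []
    for c in range(k):
        pts.append(rng.normal(centers[c], sig[c], size=(n_per_cluster, 3)))
        labels.append(np.full(n_per_cluster, c))
    return np.concatenate(pts), np.concatenate(labels)


def short_life_landscape(seed: int | None = None) -> np.ndarray:
    """One broad topology-space blob: the diffuse, stateless evolution
    typical of short-lived contact topology."""
    pts, _ = sample_landscape(
        1, centers=[[0.5, 0.5, 0.5]], sigmas=0.18, n_per_cluster=300, seed=seed
    )
    return pts


def middle_life_landscape(seed: int | None = None) -> np.ndarray:
    """Three narrow, sequentially visited blobs: the directional,
    multi-state evolution typical of middle-life contact topology."""
    pts, _ = sample_landscape(
        3,
        centers=[[0.15, 0.2, 0.15], [0.5, 0.55, 0.5], [0.85, 0.8, 0.85]],
        sigmas=0.03,
        n_per_cluster=100,
        seed=seed,
    )
    return pts


def sample_lifetimes_with_break(
    n: int = 2000,
    exponent: float = 2.0,
    break_ns: float = 1000.0,
    frame_interval: float = 5.0,
    long_fraction: float = 0.1,
    long_range_ns: tuple[float, float] = (3000.0, 5000.0),
    seed: int | None = None,
) -> np.ndarray:
    """Lifetime sample with a planted power-law break.

    A fraction ``1 - long_fraction`` of the lifetimes follows a discrete
    power law on multiples of ``frame_interval`` truncated at
    ``break_ns``; the rest are long-lived scaffold lifetimes uniform on
    ``long_range_ns``.
    """
    rng = np.random.default_rng(seed)
    k_break = int(round(break_ns / frame_interval))
    n_long = int(round(long_fraction * n))
    n_short = n - n_long
    short = discrete_powerlaw(rng, exponent, k_break, size=n_short) * frame_interval
    lo = int(round(long_range_ns[0] / frame_interval))
    hi = int(round(long_range_ns[1] / frame_interval))
    long = rng.integers(lo, hi + 1, size=n_long) * frame_interval
    return np.concatenate([short, long])


# ---------------------------------------------------------------------------
# Brute-force oracles (used by the test suite as independent references)
# ---------------------------------------------------------------------------

def ct_bruteforce_oracle(c1: Contact | tuple, c2: Contact | tuple) -> str:
    """Set-theoretic CT classification of ``c1`` relative to ``c2``.

    Builds the integer intervals [i..j] and [r..s] explicitly and decides
    the relation from intersection cardinality and containment.  Intended
    as an independent reference implementation for tests; the production
    classifier is :func:`ctidp.topology.classify_pair`.
    """
    c1 = as_contact(*c1)
    c2 = as_contact(*c2)
    if c1 == c2:
        raise ValueError("cannot classify a contact against itself")
    a = set(range(c1.i, c1.j + 1))
    b = set(range(c2.i, c2.j + 1))
    inter = a & b
    endpoints_shared = len({c1.i, c1.j} & {c2.i, c2.j})
    if not inter:
        return "S"
    if inter == a:
        return "CP" if endpoints_shared else "P"
    if inter == b:
        return "CPinv" if endpoints_shared else "Pinv"
    if len(inter) == 1:
        return "CS"
    return "X"


def brute_force_max_run(schedule: Iterable[bool]) -> int:
    """Longest run of consecutive True values in an on/off schedule."""
    best = run = 0
    for on in schedule:
        run = run + 1 if on else 0
        best = max(best, run)
    return best
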