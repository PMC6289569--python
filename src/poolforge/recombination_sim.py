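"""Stochastic hydrolysis–ligation simulation of oligonucleotide pools.

Models one round of non-enzymatic recombination in a pool of short oligomers:
each molecule is cleaved with some probability at a breakpoint drawn from a
normal distribution centred on its midpoint, and the resulting fragments of
ligatable length (> 2 nt) then ligate at random with partners drawn from the
fragment and survivor populations in proportion to their sizes.  Information
content of the pool is tracked with the Shannon diversity index

    D = -sum_i n_i log2(n_i)

over the proportions n_i of each unique sequence; the change ΔD = D_after -
D_before across one round quantifies the informational gain (or loss) of
recombination.  Nucleotide mass is conserved exactly: cleavage and ligation
move residues between molecules but never create or destroy them.
"""

from __future__ import annotations

import collections
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SequencePool",
    "SimParams",
    "SimOutcome",
    "shannon_index",
    "hydrolyze",
    "ligate",
    "simulate_recombination",
    "delta_D_grid",
]


@dataclass
class SequencePool:
    """A multiset of sequences with copy counts over a declared alphabet."""

    entries: dict[str, int]
    alphabet: str = "ACGU"
    spec: object | None = None  # optional provenance (e.g. the generating PoolSpec)

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.entries.values()):
            raise ValueError("all copy counts must be >= 1")

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], alphabet: str = "ACGU") -> "SequencePool":
        return cls(entries=dict(collections.Counter(seqs)), alphabet=alphabet)

    def to_sequences(self) -> list[str]:
        """Expand the multiset into one string per molecule."""
        out: list[str] = []
        for seq, count in self.entries.items():
            out.extend([seq] * count)
        return out

    @property
    def total_molecules(self) -> int:
        return sum(self.entries.values())

    @property
    def n_unique(self) -> int:
        return len(self.entries)

    @property
    def nucleotide_mass(self) -> int:
        """Total residue count, Σ length × copies — the conserved quantity."""
        return sum(len(s) * c for s, c in self.entries.items())

    def length_histogram(self) -> dict[int, int]:
        hist: collections.Counter[int] = collections.Counter()
        for seq, count in self.entries.items():
            hist[len(seq)] += count
        return dict(sorted(hist.items()))


@dataclass(frozen=True)
class SimParams:
    """Parameters of one hydrolysis–ligation round.

    ``hydrolysis_rate`` and ``ligation_rate`` are per-molecule / per-fragment
    event probabilities in [0, 1].  ``sigma`` is the standard deviation (nt) of
    the normal breakpoint distribution around the molecule midpoint; when None
    it defaults to L/6 per molecule, placing ~99.7% of draws within the strand.
    Fragments shorter than ``min_ligatable_length`` (default 3, i.e. length
    > 2 nt) neither initiate nor accept ligation.
    """

    hydrolysis_rate: float
    ligation_rate: float
    sigma: float | None = None
    min_ligatable_length: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("hydrolysis_rate", "ligation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.min_ligatable_length < 3:
            raise ValueError("min_ligatable_length must be >= 3")


@dataclass
class SimOutcome:
    """Pool states and diversity accounting for one recombination round."""

    pool_before: SequencePool
    pool_after: SequencePool
    D_before: float
    D_after: float
    delta_D: float
    length_hist_before: dict[int, int]
    length_hist_after: dict[int, int]


def shannon_index(pool: SequencePool | Mapping[str, int] | Iterable[str]) -> float:
    """Shannon diversity index D = -Σ n_i log2(n_i), in bits.

    D is zero when all molecules are identical and log2(N) for a uniform pool
    of N unique sequences.
    """
    if isinstance(pool, SequencePool):
        counts = np.fromiter(pool.entries.values(), dtype=float)
    elif isinstance(pool, Mapping):
        counts = np.fromiter(pool.values(), dtype=float)
    else:
        counts = np.fromiter(collections.Counter(pool).values(), dtype=float)
    if counts.size == 0:
        raise ValueError("Shannon index undefined for an empty pool")
    p = counts / counts.sum()
    val = float(-(p * np.log2(p)).sum())
    return 0.0 if val == 0 else val  # avoid IEEE -0.0 for monomorphic pools


def hydrolyze(
    pool: SequencePool, params: SimParams, rng: np.random.Generator
) -> tuple[SequencePool, SequencePool]:
    """Cleave each molecule independently with probability ``hydrolysis_rate``.

    A cleaved molecule of length L is replaced by its two fragments around a
    bond index drawn from Normal(L/2, sigma), rounded and clipped to [1, L-1].
    Returns ``(fragments, survivors)`` as pools; nucleotide mass is conserved.
    """
    molecules = pool.to_sequences()
    n = len(molecules)
    if n == 0:
        empty = SequencePool.from_sequences([], alphabet=pool.alphabet)
        return empty, empty
    cleave = rng.random(n) < params.hydrolysis_rate
    lengths = np.fromiter((len(s) for s in molecules), dtype=np.int64, count=n)
    sigma = params.sigma
    sig = np.full(n, sigma, dtype=float) if sigma is not None else lengths / 6.0
    raw = rng.normal(loc=lengths / 2.0, scale=np.maximum(sig, 1e-12))
    # bond index b means cleavage between positions b and b+1 (1-based)
    bonds = np.clip(np.rint(raw).astype(np.int64), 1, np.maximum(lengths - 1, 1))

    fragments: list[str] = []
    survivors: list[str] = []
    for i, seq in enumerate(molecules):
        if cleave[i] and lengths[i] >= 2:
            b = int(bonds[i])
            fragments.append(seq[:b])
            fragments.append(seq[b:])
        else:
            survivors.append(seq)
    return (
        SequencePool.from_sequences(fragments, alphabet=pool.alphabet)
        if fragments
        else SequencePool({}, alphabet=pool.alphabet),
        SequencePool.from_sequences(survivors, alphabet=pool.alphabet)
        if survivors
        else SequencePool({}, alphabet=pool.alphabet),
    )


def ligate(
    fragments: SequencePool,
    survivors: SequencePool,
    params: SimParams,
    rng: np.random.Generator,
) -> SequencePool:
    """Randomly ligate eligible fragments to partners, weighted by population size.

    Each hydrolysis fragment of length >= ``min_ligatable_length`` initiates a
    ligation with probability ``ligation_rate``; its partner is drawn from the
    union of the remaining eligible fragments and the unhydrolysed survivors,
    choosing the class in proportion to its current size and uniformly within
    it.  Partners are consumed (sampling without replacement); everything not
    ligated passes through unchanged.
    """
    frag_list = fragments.to_sequences()
    surv_list = survivors.to_sequences()
    minlen = params.min_ligatable_length

    short = [s for s in frag_list if len(s) < minlen]
    elig = [s for s in frag_list if len(s) >= minlen]

    out: list[str] = list(short)
    order = rng.permutation(len(elig))
    coins = rng.random(len(elig))

    # swap-remove candidate arrays for O(1) without-replacement draws
    frag_alive = list(elig)
    frag_pos = {i: i for i in range(len(elig))}  # id -> position in frag_alive
    frag_ids = list(range(len(elig)))  # position -> id
    surv_alive = list(surv_list)
    consumed = [False] * len(elig)

    def _remove_frag(fid: int) -> None:
        pos = frag_pos.pop(fid)
        last = len(frag_ids) - 1
        if pos != last:
            moved = frag_ids[last]
            frag_ids[pos] = moved
            frag_alive[pos] = frag_alive[last]
            frag_pos[moved] = pos
        frag_ids.pop()
        frag_alive.pop()

    for k, fid in enumerate(order):
        if consumed[fid]:
            continue
        if coins[k] >= params.ligation_rate:
            continue
        _remove_frag(fid)  # the initiator cannot partner with itself
        consumed[fid] = True
        n_f = len(frag_alive)
        n_s = len(surv_alive)
        if n_f + n_s == 0:
            out.append(elig[fid])  # no partner available; passes through
            continue
        if rng.random() < n_f / (n_f + n_s):
            j = int(rng.integers(n_f))
            partner = frag_alive[j]
            pid = frag_ids[j]
            _remove_frag(pid)
            consumed[pid] = True
            out.append(elig[fid] + partner)
        else:
            j = int(rng.integers(n_s))
            partner = surv_alive[j]
            last = n_s - 1
            surv_alive[j] = surv_alive[last]
            surv_alive.pop()
            out.append(elig[fid] + partner)

    # unligated eligible fragments and unconsumed survivors pass through
    out.extend(frag_alive)
    out.extend(surv_alive)
    return SequencePool.from_sequences(out, alphabet=fragments.alphabet or survivors.alphabet)


def simulate_recombination(
    pool: SequencePool,
    params: SimParams,
    rounds: int = 1,
    rng: np.random.Generator | None = None,
) -> SimOutcome:
    """Run hydrolysis → ligation for ``rounds`` rounds and account diversity.

    Deterministic under a fixed ``params.seed`` (or supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    D_before = shannon_index(pool)
    current = pool
    for _ in range(rounds):
        frags, survs = hydrolyze(current, params, rng)
        current = ligate(frags, survs, params, rng)
    D_after = shannon_index(current)
    return SimOutcome(
        pool_before=pool,
        pool_after=current,
        D_before=D_before,
        D_after=D_after,
        delta_D=D_after - D_before,
        length_hist_before=pool.length_histogram(),
        length_hist_after=current.length_histogram(),
    )


def delta_D_grid(
    base_pool_spec,
    hydrolysis_rates: Sequence[float],
    ligation_rates: Sequence[float],
    replicates: int = 10,
    seed: int | None = None,
    sigma: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean ΔD (and per-cell sd) over a hydrolysis × ligation rate grid.

    A fresh random pool is generated from ``base_pool_spec`` for every
    (cell, replicate) from seeds spawned off the master seed, so the grid is
    reproducible bit-for-bit.  Returns ``(mean, sd)`` arrays of shape
    ``(len(hydrolysis_rates), len(ligation_rates))``.
    """
    from .synthetic_data import make_pool  # local import to avoid a cycle

    if not hydrolysis_rates or not ligation_rates:
        raise ValueError("rate lists must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(hydrolysis_rates) * len(ligation_rates) * replicates)
    mean = np.empty((len(hydrolysis_rates), len(ligation_rates)))
    sd = np.empty_like(mean)
    idx = 0
    for i, h in enumerate(hydrolysis_rates):
        for j, l in enumerate(ligation_rates):
            deltas = np.empty(replicates)
            for r in range(replicates):
                rng = np.random.default_rng(children[idx])
                idx += 1
                pool = make_pool(base_pool_spec, rng=rng)
                params = SimParams(hydrolysis_rate=h, ligation_rate=l, sigma=sigma)
                deltas[r] = simulate_recombination(pool, params, rng=rng).delta_D
            mean[i, j] = deltas.mean()
            sd[i, j] = deltas.std(ddof=1) if replicates > 1 else 0.0
    return mean, sd
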