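"""Synthetic pools and ligation-product reads with known ground truth.

Emulates the study design of random-pool ligation experiments: pools of
random-sequence cores (e.g. eicosamers, N20) optionally flanked by constant
primer-binding sites (C1/C2), homopolymer tails (A10) or a blocked 5' end
(modelling a 5'-FAM label that cannot act as a ligation acceptor), and
bait × prey concatenation products with a tunable junction-dinucleotide bias
and a bait 3'-truncation ladder.  Every generated object carries enough truth
annotation (junction index, truncation, class, injected errors) for downstream
analyses to be validated by parameter recovery rather than golden files.

Junction bias semantics
-----------------------
``junction_bias`` assigns a non-negative weight to each (N-1, N+1)
dinucleotide context.  Products are drawn by rejection sampling over the joint
(bait, truncation, prey) proposal, so the accepted joint law is exactly the
truncation prior tilted by the junction weight.  For uniform random cores this
makes the injected bias analytically recoverable: an ``{"CN": 8}`` bias yields
P(N-1 = C) = 8·¼ / (8·¼ + ¾) and an odds ratio of 8 against the unbiased
background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import Read
from .recombination_sim import SequencePool

__all__ = [
    "PoolSpec",
    "ProductSpec",
    "Product",
    "ErrorProfile",
    "make_pool",
    "make_products",
    "attach_quality",
    "write_truth_table",
]

_BASES = "ACGU"


@dataclass(frozen=True)
class PoolSpec:
    """Composition of a (semi-)random oligomer pool.

    The default models the workhorse pool of the experiments: fully random
    20-mers at redundancy 100 with 1000 distinct cores.  ``blocked5`` marks a
    pool whose members cannot act as prey (no free 5'-OH).
    """

    length: int = 20
    alphabet: str = "ACGU"
    n_unique: int = 1000
    redundancy: int = 100
    constant5: str = ""
    constant3: str = ""
    tail: tuple[str, int] | None = None  # e.g. ("A", 10) for an A10 tag
    blocked5: bool = False

    def __post_init__(self) -> None:
        if self.length < 1 or self.n_unique < 1 or self.redundancy < 1:
            raise ValueError("length, n_unique and redundancy must be positive")
        if len(set(self.alphabet)) != len(self.alphabet) or not self.alphabet:
            raise ValueError("alphabet must be a non-empty set of distinct characters")
        if self.n_unique > len(self.alphabet) ** self.length:
            raise ValueError(
                f"n_unique={self.n_unique} exceeds sequence space "
                f"{len(self.alphabet)}^{self.length}"
            )
        if self.tail is not None and (len(self.tail[0]) != 1 or self.tail[1] < 1):
            raise ValueError("tail must be (single base, positive length)")

    def assemble(self, core: str) -> str:
        tail = self.tail[0] * self.tail[1] if self.tail else ""
        return self.constant5 + core + self.constant3 + tail


@dataclass(frozen=True)
class ProductSpec:
    """How bait × prey ligation products are generated.

    ``junction_bias`` maps dinucleotide contexts (``"CG"``, or with ``N`` as a
    wildcard, ``"CN"``) to relative weights; unmentioned contexts default to 1
    unless any explicit key covers them.  ``truncation_dist`` is a named family
    over bait 3'-truncation lengths: ``("geometric", p)`` or ``("fixed", k)``.
    ``product_mix`` gives proportions of concatenation classes, ``"B-P"``
    (truncated bait + full prey), ``"P-P"`` and ``"B-B"``.
    """

    junction_bias: dict[str, float] = field(default_factory=dict)
    truncation_dist: tuple[str, float] = ("geometric", 0.8)
    product_mix: dict[str, float] = field(default_factory=lambda: {"B-P": 1.0})
    n_products: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_products < 1:
            raise ValueError("n_products must be positive")
        if any(w < 0 for w in self.junction_bias.values()):
            raise ValueError("junction bias weights must be non-negative")
        total = sum(self.product_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"product_mix must sum to 1, got {total}")
        family, _ = self.truncation_dist
        if family not in ("geometric", "fixed"):
            raise ValueError(f"unknown truncation family {family!r}")

    def bias_weight(self, dinuc: str) -> float:
        """Weight of a junction (N-1, N+1) context, wildcard-aware."""
        b = self.junction_bias
        for key in (dinuc, dinuc[0] + "N", "N" + dinuc[1]):
            if key in b:
                return b[key]
        return b.get("NN", 1.0)


@dataclass(frozen=True)
class Product:
    """A ligation/recombination product with truth annotation.

    ``junction`` is the 1-based bond index: the ligation bond lies between
    positions ``junction`` and ``junction + 1`` of ``seq``.
    """

    id: str
    seq: str
    junction: int
    bait_id: str
    prey_id: str
    truncation: int
    klass: str = "B-P"

    def __post_init__(self) -> None:
        if not 1 <= self.junction <= len(self.seq) - 1:
            raise ValueError("junction must be an interior bond index")


def make_pool(
    spec: PoolSpec, seed: int | None = None, rng: np.random.Generator | None = None
) -> SequencePool:
    """Sample a pool of ``n_unique`` distinct random cores at ``redundancy`` copies.

    Cores are drawn uniformly without replacement from the sequence space;
    constant flanks and tails are appended verbatim.  Deterministic under a
    fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    letters = np.array(list(spec.alphabet))
    cores: set[str] = set()
    # rejection on collisions; negligible for spaces much larger than n_unique
    max_rounds = 1000
    for _ in range(max_rounds):
        need = spec.n_unique - len(cores)
        if need == 0:
            break
        draw = letters[rng.integers(len(letters), size=(need, spec.length))]
        cores.update("".join(row) for row in draw)
    if len(cores) < spec.n_unique:
        raise RuntimeError("failed to sample enough distinct cores")
    ordered = sorted(cores)  # deterministic ordering of the sampled set
    entries = {spec.assemble(core): spec.redundancy for core in ordered}
    return SequencePool(entries=entries, alphabet=spec.alphabet, spec=spec)


def _pool_members(pool: SequencePool, prefix: str) -> list[tuple[str, str]]:
    return [(f"{prefix}{i:05d}", seq) for i, seq in enumerate(pool.entries)]


def _sample_truncation(spec: ProductSpec, tmax: int, rng: np.random.Generator) -> int:
    family, param = spec.truncation_dist
    if family == "fixed":
        t = int(param)
        if t > tmax:
            raise ValueError(f"fixed truncation {t} leaves no bait prefix (max {tmax})")
        return t
    # geometric over 0,1,2,... truncated to [0, tmax] by resampling
    while True:
        t = int(rng.geometric(param) - 1)
        if t <= tmax:
            return t


def make_products(
    bait_pool: SequencePool,
    prey_pool: SequencePool,
    spec: ProductSpec,
    seed: int | None = None,
) -> list[Product]:
    """Generate bait–prey concatenation products with junction bias.

    Each product is a possibly 3'-truncated donor prefix joined to a full
    acceptor; the acceptor ("prey" role) keeps its full length, as observed in
    the sequencing ladders.  Donor/acceptor pools per class: B-P uses bait as
    donor and prey as acceptor, P-P prey/prey, B-B bait/bait.  A pool whose
    spec is 5'-blocked cannot provide acceptors.
    """
    if not bait_pool.entries or not prey_pool.entries:
        raise ValueError("pools must be non-empty")
    rng = np.random.default_rng(seed if seed is not None else spec.seed)

    def _blocked(pool: SequencePool) -> bool:
        return bool(getattr(pool.spec, "blocked5", False))

    roles = {
        "B-P": (bait_pool, prey_pool, "bait", "prey"),
        "P-P": (prey_pool, prey_pool, "prey", "prey"),
        "B-B": (bait_pool, bait_pool, "bait", "bait"),
    }
    classes = [k for k, w in spec.product_mix.items() if w > 0]
    for k in classes:
        if k not in roles:
            raise ValueError(f"unknown product class {k!r}")
        acceptor_pool = roles[k][1]
        if _blocked(acceptor_pool):
            raise ValueError(
                f"product class {k!r} requires a 5'-accessible acceptor, but the "
                "acceptor pool is 5'-blocked"
            )
    weights = np.array([spec.product_mix[k] for k in classes])

    members = {
        "bait": _pool_members(bait_pool, "bait"),
        "prey": _pool_members(prey_pool, "prey"),
    }
    # maximum achievable bias weight, for rejection sampling
    max_w = max(
        (spec.bias_weight(a + b) for a in _any_bases(bait_pool, prey_pool)
         for b in _any_bases(bait_pool, prey_pool)),
        default=1.0,
    )
    if max_w <= 0:
        raise ValueError("junction_bias assigns zero weight to every context")

    products: list[Product] = []
    max_reject = 10000
    for i in range(spec.n_products):
        klass = classes[int(rng.choice(len(classes), p=weights / weights.sum()))]
        donor_pool, acceptor_pool, donor_role, acceptor_role = roles[klass]
        donor_members = members[donor_role]
        acceptor_members = members[acceptor_role]
        for attempt in range(max_reject):
            did, dseq = donor_members[int(rng.integers(len(donor_members)))]
            aid, aseq = acceptor_members[int(rng.integers(len(acceptor_members)))]
            t = _sample_truncation(spec, tmax=len(dseq) - 1, rng=rng)
            prefix = dseq[: len(dseq) - t]
            dinuc = prefix[-1] + aseq[0]
            w = spec.bias_weight(dinuc)
            if rng.random() * max_w < w:
                break
        else:
            raise RuntimeError(
                "rejection sampling failed: no candidate junction satisfies the "
                "bias over its support"
            )
        products.append(
            Product(
                id=f"prod{i:06d}",
                seq=prefix + aseq,
                junction=len(prefix),
                bait_id=did,
                prey_id=aid,
                truncation=t,
                klass=klass,
            )
        )
    return products


def _any_bases(*pools: SequencePool) -> str:
    seen = set()
    for p in pools:
        seen.update(p.alphabet)
    return "".join(sorted(seen))


@dataclass(frozen=True)
class ErrorProfile:
    """Sequencing-error model for synthetic reads.

    ``sub_rate`` is a uniform per-base substitution probability; erroneous
    bases receive ``q_error`` and correct bases ``q_correct``.  A fraction
    ``tail_frac`` of reads gets a low-quality 3' tail of ``tail_len`` bases at
    ``tail_q`` (without substitutions), emulating the degraded read ends that
    quality filtering is meant to remove.
    """

    sub_rate: float = 0.0
    q_correct: int = 40
    q_error: int = 12
    tail_frac: float = 0.0
    tail_len: int = 0
    tail_q: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.sub_rate <= 1.0 or not 0.0 <= self.tail_frac <= 1.0:
            raise ValueError("rates must be in [0, 1]")


def attach_quality(
    products: Sequence[Product],
    error_profile: ErrorProfile = ErrorProfile(),
    seed: int | None = None,
) -> tuple[list[Read], list[dict]]:
    """Turn products into FASTQ-ready reads with injected errors and truth rows.

    Returns ``(reads, truth)`` where each truth row records the product's
    class, junction, truncation, number of substitutions and whether a
    low-quality tail was injected — the bookkeeping downstream filters are
    checked against.
    """
    rng = np.random.default_rng(seed)
    ep = error_profile
    reads: list[Read] = []
    truth: list[dict] = []
    for prod in products:
        seq = list(prod.seq)
        L = len(seq)
        qual = [ep.q_correct] * L
        n_err = 0
        if ep.sub_rate > 0:
            hits = np.nonzero(rng.random(L) < ep.sub_rate)[0]
            for pos in hits:
                alternatives = [b for b in _BASES if b != seq[pos]]
                seq[pos] = alternatives[int(rng.integers(3))]
                qual[pos] = ep.q_error
            n_err = len(hits)
        tailed = ep.tail_frac > 0 and ep.tail_len > 0 and rng.random() < ep.tail_frac
        if tailed:
            for pos in range(max(0, L - ep.tail_len), L):
                qual[pos] = ep.tail_q
        reads.append(Read(id=prod.id, seq="".join(seq), qual=tuple(qual)))
        truth.append(
            {
                "id": prod.id,
                "class": prod.klass,
                "junction": prod.junction,
                "truncation": prod.truncation,
                "n_errors": n_err,
                "low_quality_tail": tailed,
            }
        )
    return reads, truth


def write_truth_table(truth: Iterable[dict], path: str | Path) -> None:
    """Write truth rows as a TSV (product id, class, junction index, truncation...)."""
    rows = list(truth)
    cols = ["id", "class", "junction", "truncation", "n_errors", "low_quality_tail"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
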