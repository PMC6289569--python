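"""Positional nucleotide statistics, junction fingerprints and pool arithmetic.

Covers the sequence-level analyses applied to ligation/recombination product
pools: position-specific nucleotide frequency profiles and their RGB colour
signatures, dinucleotide fingerprints of the ligation junction (the CpN bias
of RNA pools, ApN of AtNA), generation of frequency-matched synthetic pools
for structure comparisons, exact pool combinatorics (diversity, redundancy,
molar amount, binary interaction space), and pseudo-first-order fitting of
ligation kinetics.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import CollapsedRecord, Read

__all__ = [
    "FrequencyProfile",
    "JunctionFingerprint",
    "KineticsFit",
    "frequency_profile",
    "rgb_signature",
    "rgb_to_int",
    "junction_fingerprint",
    "generate_matched_pool",
    "pool_combinatorics",
    "fit_ligation_kinetics",
    "save_signature_image",
]

AVOGADRO = 6.02214076e23  # 1/mol


def _seq_of(rec) -> str:
    return rec if isinstance(rec, str) else rec.seq


def _count_of(rec) -> int:
    return rec.count if isinstance(rec, CollapsedRecord) else 1


@dataclass
class FrequencyProfile:
    """Per-position nucleotide frequency matrix.

    ``freqs[i, k]`` is the frequency of ``alphabet[k]`` at position ``i``
    (0-based rows; positions are reported 1-based in text output).  Every row
    sums to 1.
    """

    freqs: np.ndarray
    alphabet: tuple[str, ...] = ("A", "C", "G", "U")

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != len(self.alphabet):
            raise ValueError("freqs must be positions x alphabet")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def column(self, base: str) -> np.ndarray:
        """Frequency vector of one base across positions (T treated as U)."""
        base = base.upper().replace("T", "U")
        letters = [b.upper().replace("T", "U") for b in self.alphabet]
        return self.freqs[:, letters.index(base)]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# position-specific nucleotide frequencies (fraction)\n")
            fh.write("position\t" + "\t".join(self.alphabet) + "\n")
            for i, row in enumerate(self.freqs, start=1):
                fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def frequency_profile(
    records: Iterable[Read | CollapsedRecord | str],
    weighted: bool = False,
    alphabet: Sequence[str] = ("A", "C", "G", "U"),
) -> FrequencyProfile:
    """Position-specific nucleotide frequencies of an equal-length record set.

    With ``weighted=True`` collapsed copy counts weight the tally.  Mixed
    lengths are an error: split the set by length first (``split_by_length``).
    """
    alphabet = tuple(alphabet)
    index = {b: k for k, b in enumerate(alphabet)}
    # accept T for U and vice versa, mapping onto whichever the alphabet declares
    if "U" in index and "T" not in index:
        index["T"] = index["U"]
    elif "T" in index and "U" not in index:
        index["U"] = index["T"]
    counts: np.ndarray | None = None
    length = None
    for rec in records:
        seq = _seq_of(rec)
        w = _count_of(rec) if weighted else 1
        if length is None:
            length = len(seq)
            counts = np.zeros((length, len(alphabet)))
        elif len(seq) != length:
            raise ValueError(
                f"mixed sequence lengths ({length} vs {len(seq)}); "
                "use split_by_length and profile each bucket"
            )
        for i, base in enumerate(seq):
            try:
                counts[i, index[base]] += w
            except KeyError:
                raise ValueError(f"base {base!r} not in alphabet {alphabet}") from None
    if counts is None:
        raise ValueError("no records")
    totals = counts.sum(axis=1, keepdims=True)
    return FrequencyProfile(freqs=counts / totals, alphabet=alphabet)


def rgb_signature(profile: FrequencyProfile) -> np.ndarray:
    """RGB colour signature of a frequency profile, one (R, G, B) row per position.

    The transformation maps the four base frequencies fC, fA, fU, fG at each
    position to

        R = 255·(1 - fC - fA)
        G = 255·(1 - fC - fU)
        B = 255·(1 - fA - fG - fU)

    so that pure compositions render as C-blue (0,0,255), U-red (255,0,0),
    A-green (0,255,0) and G-yellow (255,255,0).  Values are kept as reals in
    [0, 255] (clipped); round only at image export.
    """
    if len(profile.alphabet) != 4:
        raise ValueError("RGB signature requires a 4-letter nucleotide profile")
    fC = profile.column("C")
    fA = profile.column("A")
    fU = profile.column("U")
    fG = profile.column("G")
    R = 255.0 * (1.0 - fC - fA)
    G = 255.0 * (1.0 - fC - fU)
    B = 255.0 * (1.0 - fA - fG - fU)
    return np.clip(np.stack([R, G, B], axis=1), 0.0, 255.0)


def rgb_to_int(rgb: np.ndarray) -> np.ndarray:
    """Round RGB reals half-up to integers for image export."""
    return np.floor(np.asarray(rgb, dtype=float) + 0.5).astype(int)


def save_signature_image(rgb: np.ndarray, path, height: int = 20) -> None:
    """Export an RGB signature as a heat-strip image (one column per position)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strip = np.tile(rgb_to_int(rgb)[None, :, :] / 255.0, (height, 1, 1))
    fig, ax = plt.subplots(figsize=(max(2, rgb.shape[0] / 8), 0.6))
    ax.imshow(strip, aspect="auto", interpolation="nearest")
    ax.set_yticks([])
    ax.set_xlabel("position")
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


@dataclass
class JunctionFingerprint:
    """Dinucleotide composition of the ligation junction (N-1, N+1).

    ``table[i, j]`` is the observed frequency of 5'-base ``alphabet[i]``
    immediately before the junction bond and 3'-base ``alphabet[j]``
    immediately after.  ``enrichment`` holds log2(observed/expected) against
    an independence background, ``difference`` the plain frequency difference;
    contexts observed on a zero background are flagged in ``infinite``.
    """

    table: np.ndarray
    enrichment: np.ndarray
    difference: np.ndarray
    infinite: np.ndarray
    alphabet: tuple[str, ...]
    marginal_5p: np.ndarray = field(init=False)
    marginal_3p: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.marginal_5p = self.table.sum(axis=1)
        self.marginal_3p = self.table.sum(axis=0)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# junction dinucleotide fingerprint: frequency, log2 enrichment, difference\n")
            fh.write("dinucleotide\tfrequency\tlog2_enrichment\tdifference\n")
            for i, a in enumerate(self.alphabet):
                for j, b in enumerate(self.alphabet):
                    enr = self.enrichment[i, j]
                    enr_s = "inf" if self.infinite[i, j] else f"{enr:.4f}"
                    fh.write(
                        f"{a}p{b}\t{self.table[i, j]:.6f}\t{enr_s}\t"
                        f"{self.difference[i, j]:.6f}\n"
                    )


def junction_fingerprint(
    products: Iterable[Read | CollapsedRecord | str],
    junction_index: int,
    background: FrequencyProfile | None = None,
    alphabet: Sequence[str] = ("A", "C", "G", "U"),
) -> JunctionFingerprint:
    """Dinucleotide frequency table at the ligation bond, with enrichment.

    ``junction_index`` is the 1-based bond index: the junction lies between
    sequence positions ``junction_index`` and ``junction_index + 1``.  The
    expected table is the outer product of the background frequencies at those
    two positions (independence assumption); without a background a uniform
    one is used.  Both log2 ratios and plain differences are reported.
    """
    alphabet = tuple(alphabet)
    index = {b: k for k, b in enumerate(alphabet)}
    if "U" in index and "T" not in index:
        index["T"] = index["U"]
    counts = np.zeros((len(alphabet), len(alphabet)))
    n = 0
    for rec in products:
        seq = _seq_of(rec)
        w = _count_of(rec)
        if not 1 <= junction_index <= len(seq) - 1:
            raise ValueError(
                f"junction index {junction_index} not interior to a length-{len(seq)} sequence"
            )
        counts[index[seq[junction_index - 1]], index[seq[junction_index]]] += w
        n += w
    if n == 0:
        raise ValueError("no products")
    table = counts / n
    if background is not None:
        if background.length < junction_index + 1:
            raise ValueError("background profile does not cover the junction positions")
        p5 = background.freqs[junction_index - 1]
        p3 = background.freqs[junction_index]
        expected = np.outer(p5, p3)
    else:
        expected = np.full_like(table, 1.0 / table.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        enrichment = np.log2(table / expected)
    infinite = (expected == 0) & (table > 0)
    enrichment[table == 0] = -np.inf
    return JunctionFingerprint(
        table=table,
        enrichment=enrichment,
        difference=table - expected,
        infinite=infinite,
        alphabet=alphabet,
    )


def generate_matched_pool(
    profile: FrequencyProfile, n: int, seed: int | None = None
) -> list[str]:
    """Sample ``n`` sequences with positions drawn independently from a profile.

    This is the in-silico matched-frequency pool used as the null model for
    secondary-structure comparisons (the study used 3 replicates of 300,000
    sequences).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(profile.alphabet)
    cols = np.empty((profile.length, n), dtype="U1")
    for i in range(profile.length):
        cols[i] = letters[rng.choice(len(letters), size=n, p=profile.freqs[i])]
    return ["".join(row) for row in cols.T]


def pool_combinatorics(
    n_molecules: int | float | None,
    length: int,
    alphabet_size: int = 4,
    avogadro: float = AVOGADRO,
) -> dict:
    """Exact combinatorics of a random oligomer pool.

    Returns sequence-space ``diversity`` (alphabet_size^length, exact int),
    per-sequence ``redundancy`` (floor(n_molecules / diversity)), the molar
    ``amount_nmol`` of the pool, and the ``binary_pairs`` interaction space
    (diversity squared, exact int).  A 10^15-molecule pool of 20-mers over a
    4-letter alphabet gives redundancy 909 at about 1.7 nmol with >10^24
    potential binary interactions.
    """
    if length < 1 or alphabet_size < 2:
        raise ValueError("length must be >= 1 and alphabet_size >= 2")
    diversity = alphabet_size ** length  # exact big-int
    result = {
        "diversity": diversity,
        "binary_pairs": diversity * diversity,
    }
    if n_molecules is not None:
        if n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        n_int = int(n_molecules)
        result["redundancy"] = n_int // diversity
        result["amount_nmol"] = float(n_molecules) / avogadro * 1e9
    return result


@dataclass
class KineticsFit:
    """Pseudo-first-order ligation kinetics fit y(t) = plateau·(1 - exp(-k t))."""

    k_obs: float
    plateau: float
    residual_norm: float
    flags: tuple[str, ...] = ()


def fit_ligation_kinetics(
    timepoints: Sequence[float], yields: Sequence[float]
) -> KineticsFit:
    """Least-squares fit of a single-exponential approach to plateau.

    ``k_obs`` (1/time unit of ``timepoints``) is the apparent rate constant;
    ``plateau`` is the final ligated fraction, constrained to [0, 1].  A flat
    all-zero yield series returns plateau 0 with the rate flagged
    indeterminate rather than a spurious estimate.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(yields, dtype=float)
    if t.size < 3:
        raise ValueError("at least 3 timepoints required")
    if t.size != y.size:
        raise ValueError("timepoints and yields must have equal length")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("yields must be fractions in [0, 1]")
    if np.all(y == 0):
        return KineticsFit(k_obs=0.0, plateau=0.0, residual_norm=0.0,
                           flags=("indeterminate_rate",))

    def model(tt, k, plateau):
        return plateau * (1.0 - np.exp(-k * tt))

    tspan = max(t.max(), 1e-12)
    p0 = (1.0 / tspan, min(max(float(y.max()), 1e-6), 1.0))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, t, y, p0=p0, bounds=([0.0, 0.0], [np.inf, 1.0]), maxfev=10000
            )
    except RuntimeError as exc:
        raise RuntimeError(f"kinetics fit did not converge: {exc}") from exc
    k_obs, plateau = float(popt[0]), float(popt[1])
    resid = float(np.linalg.norm(y - model(t, *popt)))
    flags = []
    if k_obs == 0.0:
        flags.append("rate_at_lower_bound")
    if plateau in (0.0, 1.0):
        flags.append("plateau_at_bound")
    return KineticsFit(k_obs=k_obs, plateau=plateau, residual_norm=resid,
                       flags=tuple(flags))
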