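"""Secondary-structure handling: dot-bracket parsing, an exact base-pair
maximization folder, an external MFE-folder adapter, and per-position
structure profiles.

The internal folder maximizes Watson–Crick + wobble pair count under a
minimum hairpin-loop constraint (Nussinov-style dynamic programming with a
fixed traceback tie-break), which makes it a deterministic, self-contained
stand-in for thermodynamic folding in tests and profiles.  Free-energy MFE
structures come only from a pluggable external backend (e.g. RNAfold) whose
plain-text output is parsed; all downstream profile operations equally accept
precomputed dot-bracket strings.
"""

from __future__ import annotations

import shlex
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DotBracket",
    "StructureProfile",
    "ProfileComparison",
    "BackendNotAvailableError",
    "parse_dotbracket",
    "nussinov_fold",
    "external_fold",
    "structure_profile",
    "compare_structure_profiles",
    "mfe_distribution",
]

DEFAULT_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})


class BackendNotAvailableError(RuntimeError):
    """The configured external folding backend cannot be executed."""


@dataclass(frozen=True)
class DotBracket:
    """A nested secondary structure with its position→partner map (1-based)."""

    structure: str
    pairs: dict[int, int]
    energy: float | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs) // 2

    def __len__(self) -> int:
        return len(self.structure)


def parse_dotbracket(s: str, energy: float | None = None) -> DotBracket:
    """Parse a dot-bracket string into a structure with a pair map.

    Raises ``ValueError`` naming the first offending index (1-based) on
    unbalanced parentheses or foreign characters.
    """
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(s, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unclosed '(' at position {stack[0]}")
    return DotBracket(structure=s, pairs=pairs, energy=energy)


def nussinov_fold(
    seq: str,
    min_loop: int = 3,
    pairs: frozenset[str] | set[str] = DEFAULT_PAIRS,
) -> DotBracket:
    """Maximize base-pair count over nested structures (no pseudoknots).

    ``min_loop`` is the minimum number of unpaired bases a hairpin must
    enclose; wobble G·U pairs are allowed by default.  Traceback is
    deterministic: at each interval the 5' base is paired with the smallest
    admissible partner that achieves the optimum, else left unpaired.
    """
    s = seq.upper().replace("T", "U")
    n = len(s)
    if n == 0:
        return DotBracket(structure="", pairs={})

    def can_pair(i: int, j: int) -> bool:  # 0-based
        return j - i > min_loop and (s[i] + s[j]) in pairs

    # N[i][j] = max pairs on s[i..j]
    N = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(i, k):
                    left = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = N[k + 1, j] if k + 1 <= j else 0
                    best = max(best, 1 + left + right)
            N[i, j] = best

    structure = ["."] * n
    pair_map: dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = N[i, j]
        placed = False
        for k in range(i + min_loop + 1, j + 1):  # smallest admissible partner first
            if can_pair(i, k):
                left = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                right = N[k + 1, j] if k + 1 <= j else 0
                if 1 + left + right == target:
                    structure[i] = "("
                    structure[k] = ")"
                    pair_map[i + 1] = k + 1
                    pair_map[k + 1] = i + 1
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    placed = True
                    break
        if not placed:
            stack.append((i + 1, j))
    return DotBracket(structure="".join(structure), pairs=pair_map)


def external_fold(
    seqs: Sequence[str], backend_command: str | None
) -> list[DotBracket]:
    """Fold sequences with an external MFE backend (e.g. ``RNAfold --noPS``).

    The backend receives one sequence per line on stdin and must print, per
    sequence, the echoed sequence followed by a line of the form
    ``<dot-bracket> (<energy>)``.  A missing backend raises
    ``BackendNotAvailableError`` naming the ``fold.backend_command`` config
    key; downstream profile operations accept precomputed dot-bracket files
    instead.
    """
    if not backend_command:
        raise BackendNotAvailableError(
            "no external folding backend configured: set the 'fold.backend_command' "
            "config key (e.g. 'RNAfold --noPS') or supply precomputed dot-bracket files"
        )
    argv = shlex.split(backend_command)
    if shutil.which(argv[0]) is None:
        raise BackendNotAvailableError(
            f"external folding backend {argv[0]!r} not found on PATH "
            "(config key 'fold.backend_command')"
        )
    proc = subprocess.run(
        argv,
        input="\n".join(seqs) + "\n",
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise RuntimeError(
            f"folding backend exited with status {proc.returncode}: {proc.stderr.strip()}"
        )
    structures: list[DotBracket] = []
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    for line in lines:
        token = line.split()[0]
        if not set(token) <= {"(", ")", "."}:
            continue  # sequence echo or header line
        energy = None
        rest = line[len(token):].strip()
        if rest.startswith("(") and rest.endswith(")"):
            try:
                energy = float(rest[1:-1].strip())
            except ValueError:
                energy = None
        structures.append(parse_dotbracket(token, energy=energy))
    if len(structures) != len(seqs):
        raise RuntimeError(
            f"folding backend returned {len(structures)} structures for "
            f"{len(seqs)} sequences; stderr: {proc.stderr.strip()!r}"
        )
    return structures


ELEMENTS = ("obp", "cbp", "unp")  # opening '(' / closing ')' / unpaired '.'


@dataclass
class StructureProfile:
    """Per-position frequencies of opening/closing base pairs and unpaired bases.

    ``freqs[i]`` = (obp, cbp, unp) at position ``i`` (0-based); each row sums
    to 1.  "Opening" means paired to a downstream nucleotide, "closing" to an
    upstream one.
    """

    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 3:
            raise ValueError("freqs must be positions x (obp, cbp, unp)")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("per-position structure frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# per-position dot-bracket element frequencies (fraction)\n")
            fh.write("position\tobp\tcbp\tunp\n")
            for i, row in enumerate(self.freqs, start=1):
                fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def structure_profile(structures: Iterable[DotBracket | str]) -> StructureProfile:
    """Per-position element frequencies over an equal-length structure set."""
    counts: np.ndarray | None = None
    length = None
    n = 0
    col = {"(": 0, ")": 1, ".": 2}
    for st in structures:
        s = st.structure if isinstance(st, DotBracket) else st
        if isinstance(st, str):
            parse_dotbracket(st)  # validate
        if length is None:
            length = len(s)
            counts = np.zeros((length, 3))
        elif len(s) != length:
            raise ValueError(f"mixed structure lengths ({length} vs {len(s)})")
        for i, ch in enumerate(s):
            counts[i, col[ch]] += 1
        n += 1
    if counts is None:
        raise ValueError("no structures")
    return StructureProfile(freqs=counts / n)


@dataclass
class ProfileComparison:
    """Experimental-minus-synthetic structure profile comparison.

    ``difference[i]`` = experimental − mean over synthetic replicates, per
    element (obp, cbp, unp); ``sd`` is the standard deviation across
    replicates of the synthetic means.
    """

    difference: np.ndarray
    sd: np.ndarray

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# experimental - mean(synthetic) per element, with replicate sd\n")
            fh.write("position\td_obp\td_cbp\td_unp\tsd_obp\tsd_cbp\tsd_unp\n")
            for i in range(self.difference.shape[0]):
                vals = list(self.difference[i]) + list(self.sd[i])
                fh.write(f"{i + 1}\t" + "\t".join(f"{v:.6f}" for v in vals) + "\n")


def compare_structure_profiles(
    experimental: StructureProfile,
    synthetic_replicates: Sequence[StructureProfile],
) -> ProfileComparison:
    """Average difference of base-pairing between an experimental pool and
    matched synthetic pools, with the replicate standard deviation."""
    if not synthetic_replicates:
        raise ValueError("at least one synthetic replicate required")
    if any(rep.length != experimental.length for rep in synthetic_replicates):
        raise ValueError("profile lengths differ between experimental and synthetic")
    stack = np.stack([rep.freqs for rep in synthetic_replicates])
    mean_syn = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(synthetic_replicates) > 1 else np.zeros_like(mean_syn)
    return ProfileComparison(difference=experimental.freqs - mean_syn, sd=sd)


@dataclass
class MFESummary:
    """Distribution summary of folding energies (or pair-count proxies)."""

    mean: float
    sd: float
    n: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def mfe_distribution(
    structures_or_energies: Iterable[DotBracket | float],
    bins: int = 20,
) -> MFESummary:
    """Summarize a set of MFE energies (kcal/mol) or pair-count proxies.

    DotBracket inputs use their ``energy`` when present and fall back to the
    negated pair count as a stability proxy.
    """
    values = []
    for item in structures_or_energies:
        if isinstance(item, DotBracket):
            values.append(item.energy if item.energy is not None else -float(item.n_pairs))
        else:
            values.append(float(item))
    if not values:
        raise ValueError("no energies")
    arr = np.asarray(values, dtype=float)
    counts, edges = np.histogram(arr, bins=bins)
    return MFESummary(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        n=arr.size,
        hist_counts=counts,
        hist_edges=edges,
    )
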