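"""Junction-proximal secondary-structure submotif matching and consensus.

Ligation sites in semi-random pools cluster in specific local secondary
structure contexts — notably internal loops like motif J (four unpaired bases
flanked by 3-nt helical regions) and the hairpin-loop motif H.  This module
matches a catalogue of such element patterns around annotated ligation
junctions, profiles where within each motif the ligation bond falls, and
extracts sequence consensus (PWM + per-column information content) from the
matched members.

Element patterns are strings over ``( ) . p N`` where ``p`` matches either
paired state and ``N`` matches anything.  A parametric catalogue generator
spans internal loops (a unpaired bases flanked by h-nt helices) and hairpin
loops over small a, h; the J and H patterns ship predefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .folding import DotBracket

__all__ = [
    "SubMotif",
    "MotifMatch",
    "MotifLigationProfile",
    "MOTIF_J",
    "MOTIF_H",
    "default_catalogue",
    "match_submotifs",
    "motif_ligation_profile",
    "consensus_matrix",
]

_ELEMENT_CHARS = set("().pN")


@dataclass(frozen=True)
class SubMotif:
    """A local secondary-structure element pattern.

    ``element_pattern`` is matched literally against dot-bracket characters,
    with ``p`` standing for either paired state and ``N`` for any state.
    """

    id: str
    element_pattern: str

    def __post_init__(self) -> None:
        if not self.element_pattern:
            raise ValueError("element pattern must be non-empty")
        bad = set(self.element_pattern) - _ELEMENT_CHARS
        if bad:
            raise ValueError(f"invalid pattern characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.element_pattern)

    def matches_at(self, structure: str, start: int) -> bool:
        """Whether the pattern matches ``structure`` at 0-based ``start``."""
        if start < 0 or start + len(self.element_pattern) > len(structure):
            return False
        for pat, ch in zip(self.element_pattern, structure[start:]):
            if pat == "N":
                continue
            if pat == "p":
                if ch == ".":
                    return False
            elif pat != ch:
                return False
        return True

    def unpaired_bonds(self) -> list[int]:
        """0-based intra-motif bond indices lying inside unpaired stretches."""
        pat = self.element_pattern
        return [k for k in range(len(pat) - 1) if pat[k] == "." and pat[k + 1] == "."]


# Motif J: four unpaired bases flanked by 3-nt helical regions (either strand
# orientation); motif H: the hairpin-loop realisation of the same geometry.
MOTIF_J = SubMotif(id="J", element_pattern="ppp....ppp")
MOTIF_H = SubMotif(id="H", element_pattern="(((....)))")


def default_catalogue(
    loop_sizes: Sequence[int] = range(1, 7),
    helix_sizes: Sequence[int] = range(1, 5),
) -> list[SubMotif]:
    """Parametric catalogue of internal-loop and hairpin submotifs.

    One strand of an internal loop with ``a`` unpaired bases flanked by
    ``h``-nt helices appears locally as ``p*h + '.'*a + p*h``; a hairpin loop
    of ``a`` bases closed by an ``h``-nt helix as ``'('*h + '.'*a + ')'*h``
    (only loops of >= 3 bases are sterically possible).  The J and H motifs
    are included under their own ids.
    """
    catalogue: list[SubMotif] = [MOTIF_J, MOTIF_H]
    seen = {m.element_pattern for m in catalogue}
    for a in loop_sizes:
        for h in helix_sizes:
            pat = "p" * h + "." * a + "p" * h
            if pat not in seen:
                catalogue.append(SubMotif(id=f"IL{a}h{h}", element_pattern=pat))
                seen.add(pat)
            if a >= 3:
                pat = "(" * h + "." * a + ")" * h
                if pat not in seen:
                    catalogue.append(SubMotif(id=f"HP{a}h{h}", element_pattern=pat))
                    seen.add(pat)
    return catalogue


@dataclass(frozen=True)
class MotifMatch:
    """A catalogue pattern found with the ligation bond inside it.

    ``start`` is the 1-based structure position where the pattern begins;
    ``bond_offset`` the 0-based bond index within the motif that carries the
    junction (bond k joins motif positions k and k+1).
    """

    motif: SubMotif
    start: int
    bond_offset: int


def match_submotifs(
    structure: DotBracket | str,
    junction_index: int,
    catalogue: Iterable[SubMotif],
    window: int = 10,
) -> list[MotifMatch]:
    """All catalogue patterns matching near the junction and spanning its bond.

    ``junction_index`` is the 1-based bond index (bond between positions j and
    j+1).  A match must contain the junction bond strictly inside its span and
    start within ``window`` nt of the junction on either side.
    """
    s = structure.structure if isinstance(structure, DotBracket) else structure
    j = junction_index
    if not 1 <= j <= len(s) - 1:
        raise ValueError(f"junction index {j} not interior to a length-{len(s)} structure")
    matches: list[MotifMatch] = []
    for motif in catalogue:
        m = len(motif)
        # starts (0-based) where the bond (j-1 .. j in 0-based positions) is interior
        lo = max(0, j - m + 1, j - window)
        hi = min(len(s) - m, j - 1, j + window - m)
        for start in range(lo, hi + 1):
            if motif.matches_at(s, start):
                matches.append(
                    MotifMatch(motif=motif, start=start + 1, bond_offset=j - 1 - start)
                )
    return matches


@dataclass
class MotifLigationProfile:
    """Normalized ligation-site frequency per intra-motif bond.

    ``frequencies[k]`` is the fraction of junctions at bond k of the motif;
    they sum to 1.  ``flagged`` lists bonds whose frequency exceeds the
    enrichment threshold over the motif's unpaired-region baseline, with the
    estimated fold.
    """

    motif: SubMotif
    frequencies: np.ndarray
    n_matches: int
    flagged: dict[int, float]


def motif_ligation_profile(
    matches: Iterable[MotifMatch],
    enrichment_threshold: float = 2.0,
) -> dict[str, MotifLigationProfile]:
    """Per-motif distribution of ligation bonds, with enrichment flags.

    For each motif, junction counts per intra-motif bond are normalized to
    frequencies; a bond is flagged when its frequency exceeds
    ``enrichment_threshold`` times the mean frequency over the motif's
    unpaired-region bonds (the baseline where ligation generally drops).
    """
    per_motif: dict[str, list[MotifMatch]] = {}
    for m in matches:
        per_motif.setdefault(m.motif.id, []).append(m)
    if not per_motif:
        raise ValueError("no matches")
    out: dict[str, MotifLigationProfile] = {}
    for mid, group in per_motif.items():
        motif = group[0].motif
        n_bonds = len(motif) - 1
        counts = np.zeros(n_bonds)
        for m in group:
            counts[m.bond_offset] += 1
        freqs = counts / counts.sum()
        unpaired = motif.unpaired_bonds()
        baseline = freqs[unpaired].mean() if unpaired else freqs.mean()
        flagged = {}
        if baseline > 0:
            for k in range(n_bonds):
                fold = freqs[k] / baseline
                if fold > enrichment_threshold:
                    flagged[k] = float(fold)
        out[mid] = MotifLigationProfile(
            motif=motif, frequencies=freqs, n_matches=len(group), flagged=flagged
        )
    return out


def consensus_matrix(
    member_sequences: Sequence[str],
    pseudocount: float = 0.5,
    alphabet: Sequence[str] = ("A", "C", "G", "U"),
) -> tuple[np.ndarray, np.ndarray]:
    """Position weight matrix and per-column information content of aligned members.

    Members must be equal-length, anchored at the motif match.  Returns
    ``(pwm, ic)`` where pwm columns sum to 1 and ``ic = 2 - H`` bits per
    column for the 4-letter alphabet (identical members approach 2 bits as the
    pseudocount vanishes, uniform members approach 0).
    """
    if not member_sequences:
        raise ValueError("no member sequences")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    alphabet = tuple(alphabet)
    index = {b: k for k, b in enumerate(alphabet)}
    if "U" in index and "T" not in index:
        index["T"] = index["U"]
    L = len(member_sequences[0])
    if any(len(s) != L for s in member_sequences):
        raise ValueError("member sequences must be equal length (anchored alignment)")
    counts = np.full((L, len(alphabet)), pseudocount, dtype=float)
    for seq in member_sequences:
        for i, base in enumerate(seq.upper()):
            counts[i, index[base]] += 1
    pwm = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(pwm > 0, np.log2(np.where(pwm > 0, pwm, 1.0)), 0.0)
    entropy = -(pwm * logs).sum(axis=1)
    ic = math.log2(len(alphabet)) - entropy
    return pwm, ic
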