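"""Pairwise divergence: p-distances on codon-position partitions and
Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction.

Site counting is the normalized NG86 variant: at each codon position the
three single-base changes are classified as synonymous or nonsynonymous under
the vertebrate mitochondrial code, changes creating a stop codon are excluded
from the denominator, and the position contributes exactly one site split
between S and N. This makes S + N = 3 × (number of codons) an exact identity,
which is maintained in rational arithmetic until the final division.
Multi-difference codon pairs are averaged over all minimal substitution
pathways, excluding pathways that pass through a stop codon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import permutations

from .codon_usage import CODON_TO_AA, STOP_CODONS

_BASES = "ACGT"
_UNAMBIGUOUS = frozenset(_BASES)


# ---------------------------------------------------------------------------
# p-distance

def p_distance(a: str, b: str, positions: list[int] | None = None
               ) -> tuple[float, int]:
    """Proportion of differing sites (pairwise deletion of ambiguous sites).

    ``positions`` is an optional 0-based subset of sites to compare. Returns
    (p, number of compared sites); raises if no site is comparable."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    idx = range(len(a)) if positions is None else positions
    diff = used = 0
    for i in idx:
        x, y = a[i], b[i]
        if x in _UNAMBIGUOUS and y in _UNAMBIGUOUS:
            used += 1
            diff += x != y
    if used == 0:
        raise ValueError("zero comparable sites")
    return diff / used, used


@dataclass(frozen=True)
class PartitionedDistance:
    """p-distance of one gene split by codon position (1st+2nd vs 3rd)."""

    gene: str
    pair: tuple[str, str]
    p12: float
    p3: float
    sites12: int
    sites3: int


def codon_partition_distances(gene: str, pair: tuple[str, str],
                              a: str, b: str) -> PartitionedDistance:
    """p-distance over pooled 1st+2nd codon positions and over 3rd positions
    of one in-frame, codon-aligned gene pair (incomplete stops trimmed)."""
    if len(a) != len(b):
        raise ValueError(f"{gene}: length mismatch {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise ValueError(f"{gene}: alignment length {len(a)} not a multiple of 3")
    pos12 = [i for i in range(len(a)) if i % 3 != 2]
    pos3 = [i for i in range(len(a)) if i % 3 == 2]
    p12, n12 = p_distance(a, b, pos12)
    p3, n3 = p_distance(a, b, pos3)
    return PartitionedDistance(gene, pair, p12, p3, n12, n3)


# ---------------------------------------------------------------------------
# NG86

@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[Fraction, Fraction]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes one site, split by the fraction of its non-stop
    single-base changes that are synonymous; S + N == 3 exactly."""
    aa = CODON_TO_AA.get(codon)
    if aa is None or aa == "*":
        raise ValueError(f"not a sense codon: {codon!r}")
    s = Fraction(0)
    for pos in range(3):
        syn = valid = 0
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            syn += CODON_TO_AA[mutant] == aa
        # valid == 0 cannot occur under table 2, but guard anyway
        s += Fraction(syn, valid) if valid else Fraction(0)
    return s, 3 - s


def pathway_differences(c1: str, c2: str) -> tuple[Fraction, Fraction, bool]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all minimal substitution pathways.

    Pathways passing through a stop codon are excluded; if *every* pathway
    does, the average falls back to all pathways and the returned flag is
    True. Sd + Nd equals the number of differing positions exactly."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    ndiff = len(diff_pos)
    if ndiff == 0:
        return Fraction(0), Fraction(0), False

    def walk(order: tuple[int, ...]) -> tuple[Fraction, Fraction] | None:
        syn = nsyn = 0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                return None
            syn += CODON_TO_AA[cur] == CODON_TO_AA[nxt]
            nsyn += CODON_TO_AA[cur] != CODON_TO_AA[nxt]
            cur = nxt
        return Fraction(syn), Fraction(nsyn)

    results = [walk(order) for order in permutations(diff_pos)]
    valid = [r for r in results if r is not None]
    fallback = not valid
    if fallback:
        # re-walk counting stop-transit steps as nonsynonymous
        valid = []
        for order in permutations(diff_pos):
            syn = nsyn = 0
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                same = CODON_TO_AA[cur] == CODON_TO_AA[nxt]
                syn += same
                nsyn += not same
                cur = nxt
            valid.append((Fraction(syn), Fraction(nsyn)))
    k = len(valid)
    sd = sum(r[0] for r in valid) / k
    nd = sum(r[1] for r in valid) / k
    return sd, nd, fallback


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = −(3/4)·ln(1 − 4p/3); requires p < 3/4."""
    if p < 0 or p >= 0.75:
        raise ValueError(f"proportion {p} outside [0, 3/4)")
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class KaKsResult:
    """Nei–Gojobori counts and corrected rates for one aligned gene pair."""

    gene: str
    pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    flags: list[str]

    @property
    def selection_class(self) -> str:
        return classify_selection(self)


def nei_gojobori(a: str, b: str, gene: str = "",
                 pair: tuple[str, str] = ("a", "b")) -> KaKsResult:
    """NG86 Ka/Ks for two in-frame, equal-length, stop-free codon sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise ValueError(f"length {len(a)} not a multiple of 3")
    a, b = a.upper(), b.upper()
    S = N = Sd = Nd = Fraction(0)
    flags: list[str] = []
    ncodons = 0
    for i in range(0, len(a), 3):
        c1, c2 = a[i:i + 3], b[i:i + 3]
        if not (set(c1) <= _UNAMBIGUOUS and set(c2) <= _UNAMBIGUOUS):
            continue  # pairwise deletion of ambiguous codons
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd, fell_back = pathway_differences(c1, c2)
        if fell_back:
            flags.append(f"codon {i // 3 + 1}: all minimal pathways pass a stop")
        Sd += sd
        Nd += nd
        ncodons += 1
    if ncodons == 0:
        raise ValueError("zero comparable codons")

    pS, pN = float(Sd / S), float(Nd / N)
    Ks = Ka = None
    if pS >= 0.75:
        flags.append("pS >= 3/4: Ks correction undefined")
    else:
        Ks = jukes_cantor(pS)
    if pN >= 0.75:
        flags.append("pN >= 3/4: Ka correction undefined")
    else:
        Ka = jukes_cantor(pN)
    ratio = None
    if Ks is not None and Ka is not None:
        if Ks == 0:
            flags.append("Ks == 0: ratio undefined")
        else:
            ratio = Ka / Ks
    return KaKsResult(gene=gene, pair=pair, S=float(S), N=float(N),
                      Sd=float(Sd), Nd=float(Nd), Ks=Ks, Ka=Ka,
                      ratio=ratio, flags=flags)


def classify_selection(result: KaKsResult, tol: float = 1e-9) -> str:
    """purifying (<1), neutral (=1 within tol), or positive (>1)."""
    if result.ratio is None:
        return "undefined"
    if abs(result.ratio - 1.0) <= tol:
        return "neutral"
    return "purifying" if result.ratio < 1.0 else "positive"
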