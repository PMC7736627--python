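"""Tandem-repeat detection in mitochondrial control regions.

The detector is a lag-profile method: for each candidate period d it scores
the self-match profile m[i] = (seq[i] == seq[i+d]) with +1 per match and −3
per mismatch and extracts maximal positive-scoring segments (a mismatch
tolerance matching the ~80% identity regime of slipped-strand repeat arrays).
A segment of matched length L at lag d spans L + d bases and therefore
(L + d)/d copies. A consensus unit is taken by per-offset majority vote over
the copies, per-copy identity is the mean match fraction against that
consensus, and overlapping calls at different periods (a true period always
echoes at its multiples) are resolved by highest copies × identity, then
smallest period. The procedure is fully deterministic.

Substitution noise within copies is modeled; insertions/deletions inside
copies are not (a copy with an indel simply truncates the matched segment).
Control-region repeat arrays, the target here, are near-perfect slippage
products for which this is adequate; the quantities consumed downstream are
unit length and copy number.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genome_model import Mitogenome, extract_region

_MISMATCH_PENALTY = 3


@dataclass(frozen=True)
class TandemRepeat:
    """One detected repeat array (1-based start within the scanned sequence)."""

    start: int
    period: int
    copies: float
    consensus: str
    identity: float

    @property
    def span(self) -> int:
        """Total bases covered by the array."""
        return round(self.copies * self.period)

    @property
    def end(self) -> int:
        return self.start + self.span - 1


def _segments(match: list[bool], min_matches: int) -> list[tuple[int, int, int]]:
    """Greedy maximal positive-scoring runs over a boolean match profile.

    Each segment starts at a match, extends while its running score
    (+1 match, −penalty mismatch) stays positive, and is trimmed back to the
    prefix with the maximum score (so it also ends at a match). Returns
    (start, end_exclusive, n_matches) for segments with at least
    ``min_matches`` matching positions."""
    out = []
    n = len(match)
    i = 0
    while i < n:
        if not match[i]:
            i += 1
            continue
        score = best = 0
        best_end = i
        j = i
        while j < n:
            score += 1 if match[j] else -_MISMATCH_PENALTY
            if score > best:
                best = score
                best_end = j + 1
            j += 1
            if score <= 0:
                break
        k = sum(match[i:best_end])
        if k >= min_matches:
            out.append((i, best_end, k))
        i = max(j, best_end)
    return out


def _consensus_and_identity(seq: str, start: int, span: int, period: int
                            ) -> tuple[str, float]:
    votes = [Counter() for _ in range(period)]
    for off in range(span):
        votes[off % period][seq[start + off]] += 1
    consensus = "".join(max(sorted(v), key=v.get) if v else "N" for v in votes)
    n_full = span // period
    idents = []
    for c in range(n_full):
        copy = seq[start + c * period:start + (c + 1) * period]
        idents.append(sum(x == y for x, y in zip(copy, consensus)) / period)
    tail = span % period
    if tail and n_full == 0:
        copy = seq[start + n_full * period:start + span]
        idents.append(sum(x == y for x, y in zip(copy, consensus)) / tail)
    identity = sum(idents) / len(idents) if idents else 0.0
    return consensus, identity


def find_tandem_repeats(seq: str, min_period: int = 10, max_period: int = 600,
                        min_copies: float = 1.8, min_identity: float = 0.8,
                        min_score: int | None = None) -> list[TandemRepeat]:
    """Detect tandem repeat arrays in a sequence.

    ``min_score`` is the minimum number of matching positions a lag segment
    must contain (default 2 × min_period); it is what keeps i.i.d. sequence
    from producing chance calls at short periods."""
    if min_period < 1 or max_period < min_period:
        raise ValueError("require 1 <= min_period <= max_period")
    if min_copies < 1.0 or not (0.0 < min_identity <= 1.0):
        raise ValueError("require min_copies >= 1 and 0 < min_identity <= 1")
    s = seq.upper()
    n = len(s)
    if n < 2 * min_period:
        raise ValueError(f"sequence of {n} bp shorter than 2*min_period")
    if min_score is None:
        min_score = 2 * min_period

    candidates: list[TandemRepeat] = []
    for d in range(min_period, min(max_period, n - 1) + 1):
        match = [s[i] == s[i + d] for i in range(n - d)]
        need = max(min_score, int((min_copies - 1.0) * d * min_identity))
        for seg_start, seg_end, _k in _segments(match, need):
            span = (seg_end - seg_start) + d
            copies = span / d
            if copies < min_copies:
                continue
            consensus, identity = _consensus_and_identity(s, seg_start, span, d)
            if identity < min_identity:
                continue
            candidates.append(TandemRepeat(start=seg_start + 1, period=d,
                                           copies=round(copies, 3),
                                           consensus=consensus,
                                           identity=round(identity, 4)))

    # resolve overlaps: best copies*identity wins, then smallest period
    candidates.sort(key=lambda r: (-r.copies * r.identity, r.period, r.start))
    accepted: list[TandemRepeat] = []
    for cand in candidates:
        if any(not (cand.end < acc.start or cand.start > acc.end)
               for acc in accepted):
            continue
        accepted.append(cand)
    accepted.sort(key=lambda r: r.start)
    return accepted


def repeat_report(genome: Mitogenome, **params) -> list[dict]:
    """Run the repeat finder on the annotated control region only.

    Each entry reports the unit, copy number, array span, and the span's
    share of the control-region length. Raises if no D-loop is annotated."""
    if "D-loop" not in genome.table:
        raise ValueError("no control region (D-loop) annotated in gene table")
    dloop = genome.table["D-loop"]
    region = extract_region(genome, dloop, orient="h-strand")
    hits = find_tandem_repeats(region, **params)
    return [{
        "region": "D-loop",
        "start": r.start,
        "period": r.period,
        "copies": r.copies,
        "identity": r.identity,
        "consensus": r.consensus,
        "span": r.span,
        "fraction_of_region": round(r.span / len(region), 4),
    } for r in hits]
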