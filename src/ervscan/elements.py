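"""Candidate LTR retroelement detection via direct-repeat pairs.

A candidate element is a pair of similar direct repeats (the putative 5' and
3' LTRs) with compatible lengths and spacing.  Detection is exact k-mer
seeding on a diagonal (the repeat period) followed by greedy mismatch-tolerant
extension — a deliberately small stand-in for a full LTR harvester.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ConfigurationError
from .search import DomainHit


@dataclass
class LtrParams:
    l_min: int = 100
    l_max: int = 1000
    min_identity: float = 85.0    # percent
    d_min: int = 1001             # start-to-start separation, must exceed l_max
    d_max: int = 15000
    k: int = 12                   # exact seed size
    x_drop: int = 12              # stop extension after this many excess mismatches

    def __post_init__(self) -> None:
        if self.l_min < self.k:
            raise ConfigurationError("l_min must be >= seed size k")
        if self.d_min <= self.l_max:
            raise ConfigurationError("d_min must exceed l_max")


@dataclass
class CandidateElement:
    target_id: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    identity: float               # percent over the repeat alignment
    domain_hits: list[DomainHit] = field(default_factory=list)

    @property
    def ltr_length(self) -> int:
        return self.ltr5[1] - self.ltr5[0]


def _seed_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    return index


MISMATCH_PENALTY = 2.0   # match scores +1; stops extension at repeat edges


def _extend_run(seq: str, i0: int, i1: int, d: int,
                params: LtrParams) -> tuple[int, int, float] | None:
    """Score-maximising two-sided extension of an exact run on diagonal ``d``.

    Extension uses match +1 / mismatch -2 with an X-drop cutoff so the
    window ends at the true repeat boundary instead of diluting into the
    flanks.  Returns ``(start, length, identity_percent)`` or None when the
    resulting window fails the length/identity thresholds.
    """
    n = len(seq)
    # rightwards
    best_hi, best, score = i1, 0.0, 0.0
    j = i1
    while j + d < n and (j - i0) < params.l_max:
        score += 1.0 if seq[j] == seq[j + d] else -MISMATCH_PENALTY
        if score > best:
            best, best_hi = score, j + 1
        if best - score > params.x_drop:
            break
        j += 1
    hi = best_hi
    # leftwards
    best_lo, best, score = i0, 0.0, 0.0
    j = i0 - 1
    while j >= 0 and (hi - j) <= params.l_max:
        score += 1.0 if seq[j] == seq[j + d] else -MISMATCH_PENALTY
        if score > best:
            best, best_lo = score, j
        if best - score > params.x_drop:
            break
        j -= 1
    lo = best_lo
    length = hi - lo
    if length < params.l_min or length > params.l_max:
        return None
    mism = sum(1 for k in range(lo, hi) if seq[k] != seq[k + d])
    identity = 100.0 * (length - mism) / length
    if identity < params.min_identity:
        return None
    if d < length:   # repeats would overlap
        return None
    return lo, length, identity


def find_ltr_pairs(target_id: str, seq: str,
                   params: LtrParams | None = None) -> list[CandidateElement]:
    """Report maximal direct-repeat pairs compatible with an LTR/LTR layout.

    Overlapping candidates are resolved greedily by highest identity, then
    longest repeat, then leftmost start.
    """
    params = params or LtrParams()
    seq = seq.upper()
    index = _seed_positions(seq, params.k)
    # seeds grouped by diagonal
    diagonals: dict[int, set[int]] = {}
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                d = positions[bi] - positions[ai]
                if params.d_min <= d <= params.d_max:
                    diagonals.setdefault(d, set()).add(positions[ai])
    raw: list[CandidateElement] = []
    for d, starts in sorted(diagonals.items()):
        covered_until = -1
        for i in sorted(starts):
            if i + params.k <= covered_until:
                continue
            # grow the exact run rightwards from the seed
            j = i + params.k
            while j + d < len(seq) and seq[j] == seq[j + d] \
                    and j - i < params.l_max:
                j += 1
            ext = _extend_run(seq, i, j, d, params)
            covered_until = j
            if ext is None:
                continue
            lo, length, identity = ext
            raw.append(CandidateElement(
                target_id=target_id,
                start=lo, end=lo + d + length,
                ltr5=(lo, lo + length),
                ltr3=(lo + d, lo + d + length),
                identity=identity))
    # de-duplicate identical repeats discovered from multiple seeds
    uniq = {(c.start, c.end, c.ltr5, c.ltr3): c for c in raw}
    ranked = sorted(uniq.values(),
                    key=lambda c: (-c.identity, -(c.ltr5[1] - c.ltr5[0]),
                                   c.start))
    chosen: list[CandidateElement] = []
    for cand in ranked:
        if all(cand.end <= kept.start or cand.start >= kept.end
               for kept in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c.start)
    return chosen


def assign_domains(elements: Sequence[CandidateElement],
                   hits: Iterable[DomainHit]) -> list[DomainHit]:
    """Assign each domain hit to the first element containing it.

    Returns the hits that fell outside every element (left unassigned).
    """
    orphans = []
    for hit in hits:
        for element in elements:
            if hit.target_id == element.target_id \
                    and hit.start >= element.start and hit.end <= element.end:
                element.domain_hits.append(hit)
                break
        else:
            orphans.append(hit)
    return orphans


CORE_DOMAIN_KINDS = frozenset({"RVP", "RVT_1", "IN", "GAG"})


def cooccurrence_filter(elements: Sequence[CandidateElement],
                        core_kinds: frozenset[str] = CORE_DOMAIN_KINDS,
                        ) -> list[DomainHit]:
    """Keep a domain hit only if its element carries a second core domain kind.

    Standalone reverse-transcriptase (or any single-kind) elements are
    eliminated: those are the LINE-like signatures the locus survey must not
    count.  Output order is deterministic and input-order independent.
    """
    retained: list[DomainHit] = []
    for element in elements:
        kinds = {h.kind for h in element.domain_hits if h.kind in core_kinds}
        for hit in element.domain_hits:
            others = kinds - {hit.kind}
            if others:
                retained.append(hit)
    retained.sort(key=lambda h: (h.target_id, h.start, h.end, h.kind, h.strand))
    return retained
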