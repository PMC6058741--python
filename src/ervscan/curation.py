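"""Curation filters and locus grouping.

Implements the survey's cleanup rules: drop sequences whose private
insertions gap almost every other alignment row, flag suspiciously short
domain hits, cluster annotations into loci by proximity, collapse exact
duplicates, and pair loci across alternative assemblies by flank identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner

from .errors import InputError
from .seqio import GffRecord

GAP_CHARS = frozenset("-!")


def gap_induction_filter(rows: Mapping[str, str],
                         threshold: float = 0.95) -> tuple[list[str], list[str]]:
    """Remove rows owning insertions that gap >= ``threshold`` of all rows.

    A column where the gapped-row fraction is at or above the threshold is an
    "induced gap" column; every row holding a residue there is removed.  The
    removal set is computed against the original alignment in one pass, not
    iteratively.  Returns ``(retained_ids, removed_ids)`` in input order.
    """
    ids = list(rows)
    if len(ids) < 2:
        raise InputError("alignment must have at least 2 rows")
    width = len(rows[ids[0]])
    if any(len(rows[i]) != width for i in ids):
        raise InputError("alignment rows have unequal lengths")
    n = len(ids)
    removed: set[str] = set()
    if threshold <= 1.0:
        for col in range(width):
            residues = [i for i in ids if rows[i][col] not in GAP_CHARS]
            if (n - len(residues)) / n >= threshold:
                removed.update(residues)
    retained = [i for i in ids if i not in removed]
    return retained, [i for i in ids if i in removed]


def short_domain_flag(aligned_length: int, expected_length: int,
                      fraction: float = 0.5) -> bool:
    """True iff the hit covers strictly less than ``fraction`` of the domain."""
    if expected_length <= 0:
        raise InputError("expected length must be positive")
    return aligned_length < fraction * expected_length


@dataclass
class Locus:
    """A cluster of nearby PR/RT annotations treated as one element."""

    locus_id: str
    target_id: str
    start: int
    end: int
    members: list[GffRecord] = field(default_factory=list)
    classification: dict[str, str] = field(default_factory=dict)
    conflict: bool = False


def group_loci(annotations: Sequence[GffRecord],
               max_gap: int = 10000) -> list[Locus]:
    """Single-linkage clustering of same-target annotations by end-to-start gap.

    Two annotations join the same locus when the distance between their
    nearest interval ends is at most ``max_gap``; the relation is closed
    transitively.  Each annotation belongs to exactly one locus.
    """
    by_target: dict[str, list[GffRecord]] = {}
    for ann in annotations:
        by_target.setdefault(ann.seqid, []).append(ann)
    loci: list[Locus] = []
    for target_id in sorted(by_target):
        anns = sorted(by_target[target_id], key=lambda a: (a.start, a.end))
        cluster: list[GffRecord] = []
        cluster_end = None
        for ann in anns:
            if cluster and ann.start - cluster_end > max_gap:
                loci.append(_make_locus(target_id, cluster))
                cluster = []
                cluster_end = None
            cluster.append(ann)
            cluster_end = ann.end if cluster_end is None else max(cluster_end,
                                                                  ann.end)
        if cluster:
            loci.append(_make_locus(target_id, cluster))
    return loci


def _make_locus(target_id: str, members: list[GffRecord]) -> Locus:
    start = min(m.start for m in members)
    end = max(m.end for m in members)
    return Locus(locus_id=f"{target_id}:{start}-{end}", target_id=target_id,
                 start=start, end=end, members=list(members))


def set_locus_classifications(locus: Locus,
                              member_labels: Mapping[str, str]) -> None:
    """Attach per-member clade labels; flags conflict on disagreement.

    UNPLACED members do not contribute to the conflict decision.
    """
    locus.classification = dict(member_labels)
    labels = {v for v in member_labels.values() if v != "UNPLACED"}
    locus.conflict = len(labels) >= 2


@dataclass
class IdentityClass:
    representative: str
    members: list[str]


def dedupe_sequences(seqs: Mapping[str, str]) -> list[IdentityClass]:
    """Partition sequences into exact-identity classes (order-stable)."""
    classes: dict[str, list[str]] = {}
    for name in seqs:
        classes.setdefault(seqs[name].upper(), []).append(name)
    out = [IdentityClass(representative=members[0], members=members)
           for members in classes.values()]
    out.sort(key=lambda c: c.representative)
    return out


TECHNICAL_DUPLICATE = "technical_duplicate"
SIMILAR_INSERTION = "similar_insertion_divergent_locus"
NOVEL = "novel"


def _nt_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _alignment_identity_coverage(query: str, subject: str) -> tuple[float, float]:
    """Best local alignment identity and query coverage between two sequences."""
    aligner = _nt_aligner()
    alignments = aligner.align(subject, query)
    if alignments.score <= 0:
        return 0.0, 0.0
    aln = alignments[0]
    sblocks, qblocks = aln.aligned
    matches = 0
    aligned = 0
    for (s0, s1), (q0, q1) in zip(sblocks, qblocks):
        aligned += s1 - s0
        matches += sum(1 for a, b in zip(subject[s0:s1], query[q0:q1])
                       if a == b)
    identity = matches / aligned if aligned else 0.0
    coverage = (int(qblocks[-1][1]) - int(qblocks[0][0])) / len(query)
    return identity, coverage


def match_alt_assemblies(pr_start: int, primary: str, alternative: str,
                         pr_length: int = 318, flank: int = 15000,
                         exact_coverage: float = 0.99,
                         partial_coverage: float = 0.20,
                         partial_identity: float = 0.90) -> str:
    """Pair a PR locus with an alternative assembly sequence.

    The region flanking the PR start site (``flank`` bp each side, clipped at
    the sequence bounds) is compared to the alternative sequence:

    * identical flank (100% identity over >= ``exact_coverage`` of the
      available flank) -> technical duplicate of the same insertion;
    * PR present verbatim but flank matching only partially
      (>= ``partial_coverage`` at >= ``partial_identity``) -> a closely
      similar insertion at a divergent locus;
    * anything else -> novel.
    """
    lo = max(0, pr_start - flank)
    hi = min(len(primary), pr_start + flank)
    flank_seq = primary[lo:hi]
    pr_seq = primary[pr_start:pr_start + pr_length]
    if flank_seq and flank_seq in alternative:
        return TECHNICAL_DUPLICATE
    identity, coverage = _alignment_identity_coverage(flank_seq, alternative)
    if identity >= 0.999 and coverage >= exact_coverage:
        return TECHNICAL_DUPLICATE
    if pr_seq and pr_seq in alternative:
        if coverage >= partial_coverage and identity >= partial_identity:
            return SIMILAR_INSERTION
    return NOVEL
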