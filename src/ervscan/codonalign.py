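"""Codon-aware multiple alignment with frameshift and stop annotation.

Each nucleotide sequence is first segmented into codons by a small dynamic
program that may "slip" 1-2 nt at a penalty; a slip absorbs the orphan
nucleotides of a broken codon and realigns the reading frame downstream,
which is how indel-interrupted ORFs are recognised without a full
frameshift-aware aligner.  The segment translations are then aligned by
progressive profile-profile alignment (UPGMA guide tree on k-mer distances)
and the nucleotides are threaded back through the protein alignment as
intact codons.

Alignment conventions: gap is ``-``; orphan nucleotides from a slip occupy
their own insertion column padded with ``!`` (so one column block is always
3 characters wide in the nucleotide rows, and removing ``-``/``!`` from any
row reproduces the input sequence exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import InputError
from .search import translate

GAP = "-"
FS = "!"
STANDARD_AA = set("ARNDCQEGHILKMFPSTWYV")

CODON_SCORE = 1
STOP_SCORE = -6
SLIP_PENALTY = 10


@dataclass
class Segmentation:
    """Reading-frame segmentation of one nucleotide sequence."""

    codon_starts: list[int]               # source nt offset of each codon
    translation: str                      # one char per codon, '*' for stops
    slips: list[tuple[int, int, str]]     # (codon_index, src_pos, orphan nts)
    trailing: str                         # leftover nts at the 3' end


def segment_reading_frames(seq: str) -> Segmentation:
    """Best forward path through ``seq`` as codons with optional 1-2 nt slips."""
    seq = seq.upper()
    L = len(seq)
    NEG = float("-inf")
    dp = [NEG] * (L + 1)
    move: list[tuple[int, int] | None] = [None] * (L + 1)  # (prev_pos, kind)
    dp[0] = 0.0
    for pos in range(L + 1):
        if dp[pos] == NEG:
            continue
        if pos + 3 <= L:
            aa = translate(seq[pos:pos + 3])
            gain = STOP_SCORE if aa == "*" else CODON_SCORE
            cand = dp[pos] + gain
            # >= so ties prefer staying in frame (latest possible slip)
            if cand >= dp[pos + 3]:
                dp[pos + 3] = cand
                move[pos + 3] = (pos, 3)
        for s in (1, 2):
            if pos + s <= L:
                cand = dp[pos] - SLIP_PENALTY
                # >= keeps the latest equally-scoring slip point
                if cand >= dp[pos + s]:
                    dp[pos + s] = cand
                    move[pos + s] = (pos, s)
    # allow up to 2 free trailing nucleotides
    end = max(range(max(0, L - 2), L + 1), key=lambda p: (dp[p], p))
    path = []
    pos = end
    while pos > 0:
        prev, kind = move[pos]
        path.append((prev, kind))
        pos = prev
    path.reverse()
    codon_starts: list[int] = []
    translation: list[str] = []
    slips: list[tuple[int, int, str]] = []
    for prev, kind in path:
        if kind == 3:
            codon_starts.append(prev)
            translation.append(translate(seq[prev:prev + 3]))
        else:
            slips.append((len(codon_starts), prev, seq[prev:prev + kind]))
    return Segmentation(codon_starts=codon_starts,
                        translation="".join(translation),
                        slips=slips,
                        trailing=seq[end:])


# ---------------------------------------------------------------------------
# progressive protein alignment
# ---------------------------------------------------------------------------

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = str(_BLOSUM.alphabet)
_AA_INDEX = {a: i for i, a in enumerate(_ALPHA)}
_M = np.array(_BLOSUM)

GAP_OPEN = 10.0
GAP_EXTEND = 0.5


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i:i + k] for i in range(max(0, len(a) - k + 1))}
    kb = {b[i:i + k] for i in range(max(0, len(b) - k + 1))}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    width = len(rows[0])
    counts = np.zeros((width, len(_ALPHA)))
    for row in rows:
        for c, r in enumerate(row):
            idx = _AA_INDEX.get(r)
            if idx is not None:
                counts[c, idx] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return counts / totals


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two profiles; returns re-gapped rows."""
    fa = _profile_counts(rows_a)
    fb = _profile_counts(rows_b)
    S = fa @ _M @ fb.T
    n, m = S.shape
    NEG = -1e18
    Mt = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)   # gap in B (consume A)
    Y = np.full((n + 1, m + 1), NEG)   # gap in A (consume B)
    Mt[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -GAP_OPEN - GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -GAP_OPEN - GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = max(Mt[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            Mt[i, j] = best + S[i - 1, j - 1]
            X[i, j] = max(Mt[i - 1, j] - GAP_OPEN, X[i - 1, j] - GAP_EXTEND,
                          Y[i - 1, j] - GAP_OPEN)
            Y[i, j] = max(Mt[i, j - 1] - GAP_OPEN, Y[i, j - 1] - GAP_EXTEND,
                          X[i, j - 1] - GAP_OPEN)
    # traceback
    i, j = n, m
    state = int(np.argmax([Mt[i, j], X[i, j], Y[i, j]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            prev = [Mt[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            ops.append("M")
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            cands = [Mt[i - 1, j] - GAP_OPEN, X[i - 1, j] - GAP_EXTEND,
                     Y[i - 1, j] - GAP_OPEN]
            ops.append("X")
            state = int(np.argmax(cands))
            i -= 1
        elif state == 2 and j > 0:
            cands = [Mt[i, j - 1] - GAP_OPEN, X[i, j - 1] - GAP_OPEN,
                     Y[i, j - 1] - GAP_EXTEND]
            ops.append("Y")
            state = int(np.argmax(cands))
            j -= 1
        elif i > 0:
            ops.append("X")
            i -= 1
        else:
            ops.append("Y")
            j -= 1
    ops.reverse()
    new_a, new_b = [], []
    for row in rows_a:
        it = iter(row)
        new_a.append("".join(next(it) if op in "MX" else GAP for op in ops))
    for row in rows_b:
        it = iter(row)
        new_b.append("".join(next(it) if op in "MY" else GAP for op in ops))
    return new_a, new_b


def progressive_align(proteins: Mapping[str, str]) -> dict[str, str]:
    """Progressive MSA of protein strings, guide tree = UPGMA on k-mer distance."""
    ids = sorted(proteins)     # lexicographic order fixes tie-breaking
    if len(ids) == 1:
        return {ids[0]: proteins[ids[0]]}
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = kmer_distance(proteins[ids[i]], proteins[ids[j]])
            dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [proteins[ids[i]]]) for i in range(n)}
    for step, (a, b, _, _) in enumerate(Z):
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        new_a, new_b = _align_profiles(rows_a, rows_b)
        clusters[n + step] = (ids_a + ids_b, new_a + new_b)
    (_, (all_ids, all_rows)), = clusters.items()
    return dict(zip(all_ids, all_rows))


# ---------------------------------------------------------------------------
# codon alignment assembly
# ---------------------------------------------------------------------------

@dataclass
class RowAnnotation:
    stops: list[tuple[int, int]] = field(default_factory=list)        # (column, src nt)
    frameshifts: list[tuple[int, int]] = field(default_factory=list)  # (column, src nt)


@dataclass
class CodonAlignment:
    ids: list[str]
    nuc_rows: dict[str, str]
    aa_rows: dict[str, str]
    annotations: dict[str, RowAnnotation]
    column_map: dict[str, list[int | None]]   # per protein column, src nt start

    @property
    def ncols(self) -> int:
        return len(next(iter(self.aa_rows.values())))

    def ungapped(self, seq_id: str) -> str:
        return self.nuc_rows[seq_id].replace(GAP, "").replace(FS, "")


def align_codon_aware(seqs: Mapping[str, str]) -> CodonAlignment:
    """Codon-aware MSA of nucleotide sequences via their translations."""
    if len(seqs) < 2:
        raise InputError("need at least 2 sequences")
    for name, seq in seqs.items():
        if len(seq) < 3:
            raise InputError(f"sequence {name!r} shorter than one codon")
    segs = {name: segment_reading_frames(seq) for name, seq in seqs.items()}
    aligned_aa = progressive_align({n: s.translation for n, s in segs.items()})

    ids = list(seqs)
    # per-row column blocks: (nt_block, src_pos or None, aa_char)
    blocks: dict[str, list[tuple[str, int | None, str]]] = {}
    codon_columns: dict[str, list[int]] = {}
    width = len(next(iter(aligned_aa.values())))
    for name in ids:
        seg = segs[name]
        seq = seqs[name].upper()
        row_blocks = []
        codon_cols = []
        k = 0
        for col in range(width):
            ch = aligned_aa[name][col]
            if ch == GAP:
                row_blocks.append(("---", None, GAP))
            else:
                src = seg.codon_starts[k]
                row_blocks.append((seq[src:src + 3], src, ch))
                codon_cols.append(col)
                k += 1
        blocks[name] = row_blocks
        codon_columns[name] = codon_cols

    # orphan insertion events: (insertion column, owner row, orphans, src, is_slip)
    events: list[tuple[int, str, str, int, bool]] = []
    for name in ids:
        seg = segs[name]
        cols = codon_columns[name]
        for codon_idx, src, orphans in seg.slips:
            if codon_idx < len(cols):
                at = cols[codon_idx]
            else:
                at = width
            events.append((at, name, orphans, src, True))
        if seg.trailing:
            src = len(seqs[name]) - len(seg.trailing)
            events.append((width, name, seg.trailing, src, False))
    events.sort(key=lambda e: (e[0], e[1]), reverse=True)
    slip_cols: dict[str, list[tuple[int, int]]] = {name: [] for name in ids}
    for at, owner, orphans, src, is_slip in events:
        pad = orphans + FS * (3 - len(orphans))
        for name in ids:
            if name == owner:
                blocks[name].insert(at, (pad, src, FS))
            else:
                blocks[name].insert(at, ("---", None, GAP))
        if is_slip:
            slip_cols[owner].append((at, src))

    # events were inserted right-to-left, so recorded column indices shift as
    # later (leftward) insertions happen before them; recompute from blocks.
    nuc_rows = {}
    aa_rows = {}
    column_map = {}
    annotations = {}
    for name in ids:
        row_blocks = blocks[name]
        nuc_rows[name] = "".join(b[0] for b in row_blocks)
        aa_rows[name] = "".join(b[2] for b in row_blocks)
        column_map[name] = [b[1] for b in row_blocks]
        ann = RowAnnotation()
        slip_srcs = {src for _, src in slip_cols[name]}
        for col, (_, src, aa_char) in enumerate(row_blocks):
            if aa_char == "*":
                ann.stops.append((col, src))
            elif aa_char == FS and src in slip_srcs:
                ann.frameshifts.append((col, src))
        annotations[name] = ann
    return CodonAlignment(ids=ids, nuc_rows=nuc_rows, aa_rows=aa_rows,
                          annotations=annotations, column_map=column_map)


def pairwise_protein_distance(aa_rows: Mapping[str, str],
                              ) -> tuple[list[str], np.ndarray,
                                         list[tuple[str, str]]]:
    """Corrected protein distance ``-ln(1 - p - 0.2 p^2)`` from aligned rows.

    ``p`` is the mismatch fraction over columns where both rows carry a
    standard residue.  Pairs with no shared columns are flagged as undefined
    (distance NaN); the log argument is floored so saturated pairs stay
    finite.
    """
    ids = list(aa_rows)
    width = {len(v) for v in aa_rows.values()}
    if len(width) != 1:
        raise InputError("aligned rows must have equal length")
    n = len(ids)
    dist = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aa_rows[ids[i]], aa_rows[ids[j]]
            shared = mism = 0
            for x, y in zip(a, b):
                if x in STANDARD_AA and y in STANDARD_AA:
                    shared += 1
                    if x != y:
                        mism += 1
            if shared == 0:
                dist[i, j] = dist[j, i] = np.nan
                undefined.append((ids[i], ids[j]))
                continue
            p = mism / shared
            arg = max(1.0 - p - 0.2 * p * p, 1e-4)
            d = -np.log(arg)
            dist[i, j] = dist[j, i] = d
    return ids, dist, undefined
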