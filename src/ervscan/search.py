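"""Six-frame translated homology search and profile scanning.

``translated_search`` aligns a protein query locally against all six frame
translations of a nucleotide target.  The dynamic programming itself is
delegated to :class:`Bio.Align.PairwiseAligner` (C implementation); multiple
hits per frame are recovered by iteratively masking the best local alignment
and re-searching.  Long targets are processed in overlapping chunks so that
memory stays flat; a hit is attributed to the chunk whose core region
contains its midpoint, which makes chunking invisible in the output.

Coordinates are 0-based half-open on the plus strand throughout; minus-strand
hits carry ``strand="-"`` with plus-strand projected intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ConfigurationError, InputError
from .seqio import interval_gap, revcomp

IUPAC_NT = set("ACGTURYSWKMBDHVN")
AA20 = "ARNDCQEGHILKMFPSTWYV"
MASK_CHAR = "#"
MIXED_FRAME = -1


@dataclass(frozen=True)
class TranslatedHit:
    """A local alignment of a protein query against one frame translation."""

    target_id: str
    start: int            # nt, plus strand, 0-based half-open
    end: int
    strand: str           # '+' or '-'
    frame: int            # 0..2, or MIXED_FRAME after merging
    query_start: int      # aa, 0-based half-open
    query_end: int
    score: float
    query_id: str

    @property
    def is_merged(self) -> bool:
        return self.frame == MIXED_FRAME


@dataclass(frozen=True)
class DomainHit:
    """A profile (PSSM) match in one frame translation."""

    target_id: str
    start: int
    end: int
    strand: str
    frame: int
    kind: str             # RVP, RVT_1, ...
    score: float          # bits


@dataclass
class SearchParams:
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0        # cost of a gap of length L is open + L*extend
    gap_extend: float = 1.0
    min_score: float = 100.0
    merge_gap: int = 1000         # bp tolerance when merging frame-split hits
    query_overlap_tol: int = 5    # aa overlap allowed between collinear hits
    profile_threshold: float = 10.0  # bits
    stop_score: float = -10.0
    chunk_size: int = 50000       # aa per chunk in frame space

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ConfigurationError("gap penalties must be >= 0")
        if self.merge_gap < 0:
            raise ConfigurationError("merge gap tolerance must be >= 0")


@lru_cache(maxsize=8)
def load_matrix(matrix_name: str, stop_score: float):
    """Substitution matrix extended with a stop symbol override and a mask char.

    The stop symbol ``*`` scores ``stop_score`` against everything (itself
    included) so interrupted ORFs still align but pay for each stop.  The mask
    character scores -1000 against everything, which prevents any alignment
    from crossing a previously reported hit.
    """
    base = substitution_matrices.load(matrix_name)
    alphabet = str(base.alphabet)
    if "*" not in alphabet:
        alphabet += "*"
    ext_alphabet = alphabet + MASK_CHAR
    n = len(ext_alphabet)
    mat = np.full((n, n), -1000.0)
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            if a == "*" or b == "*":
                mat[i, j] = stop_score
            else:
                try:
                    mat[i, j] = base[a, b]
                except IndexError:
                    mat[i, j] = -4.0
    arr = substitution_matrices.Array(alphabet=ext_alphabet, dims=2)
    arr[:, :] = mat
    return arr


def _make_aligner(params: SearchParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = load_matrix(params.matrix_name, params.stop_score)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


_CODON_TABLE: dict[str, str] = {}


def _init_codon_table() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    for codon, aa in standard_dna_table.forward_table.items():
        _CODON_TABLE[codon] = aa
    for codon in standard_dna_table.stop_codons:
        _CODON_TABLE[codon] = "*"


_init_codon_table()


def translate(seq: str) -> str:
    """Translate a nucleotide string; ambiguity codes become ``X``."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(_CODON_TABLE.get(seq[i:i + 3], "X"))
    return "".join(out)


def validate_nucleotides(seq: str) -> None:
    bad = set(seq.upper()) - IUPAC_NT
    if bad:
        raise InputError(f"non-IUPAC nucleotide characters: {sorted(bad)}")


def six_frames(seq: str) -> list[tuple[str, int, str]]:
    """All six frame translations as ``(strand, frame, protein)``."""
    seq = seq.upper().replace("U", "T")
    rc = revcomp(seq)
    frames = []
    for frame in range(3):
        frames.append(("+", frame, translate(seq[frame:])))
        frames.append(("-", frame, translate(rc[frame:])))
    return frames


def frame_aa_to_plus_nt(strand: str, frame: int, aa_start: int, aa_end: int,
                        target_len: int) -> tuple[int, int]:
    """Project an interval in frame-translation space onto plus-strand nt."""
    if strand == "+":
        return frame + 3 * aa_start, frame + 3 * aa_end
    return target_len - frame - 3 * aa_end, target_len - frame - 3 * aa_start


def _iter_chunk_hits(aligner: PairwiseAligner, protein: str, query: str,
                     min_score: float, max_hits: int = 200):
    """Iterative best-hit extraction with masking inside one chunk."""
    seg = list(protein)
    for _ in range(max_hits):
        alignments = aligner.align("".join(seg), query)
        if alignments.score < min_score:
            return
        aln = alignments[0]
        tblocks, qblocks = aln.aligned
        t0, t1 = int(tblocks[0][0]), int(tblocks[-1][1])
        q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
        yield t0, t1, q0, q1, float(alignments.score)
        for i in range(t0, t1):
            seg[i] = MASK_CHAR


def translated_search(target_id: str, target: str, query_id: str, query: str,
                      params: SearchParams | None = None) -> list[TranslatedHit]:
    """Local alignments of ``query`` against all six frames of ``target``."""
    params = params or SearchParams()
    if len(target) < 3:
        raise InputError("target shorter than one codon")
    if not query:
        raise InputError("empty query")
    validate_nucleotides(target)
    target = target.upper().replace("U", "T")
    aligner = _make_aligner(params)
    qlen = len(query)
    overlap = 3 * qlen + 50
    hits: list[TranslatedHit] = []
    for strand, frame, protein in six_frames(target):
        n = len(protein)
        step = max(params.chunk_size, 2 * overlap)
        starts = range(0, max(1, n), step)
        frame_hits: dict[tuple[int, int, int, int], float] = {}
        for cs in starts:
            ce = min(n, cs + step + overlap)
            core_lo = cs if cs == 0 else cs + overlap // 2
            core_hi = n if ce == n else cs + step + overlap // 2
            chunk = protein[cs:ce]
            if len(chunk) == 0:
                continue
            for t0, t1, q0, q1, score in _iter_chunk_hits(
                    aligner, chunk, query, params.min_score):
                mid = cs + (t0 + t1) / 2
                if not (core_lo <= mid < core_hi):
                    continue
                key = (cs + t0, cs + t1, q0, q1)
                if score > frame_hits.get(key, -math.inf):
                    frame_hits[key] = score
        for (a0, a1, q0, q1), score in frame_hits.items():
            s, e = frame_aa_to_plus_nt(strand, frame, a0, a1, len(target))
            hits.append(TranslatedHit(
                target_id=target_id, start=s, end=e, strand=strand,
                frame=frame, query_start=q0, query_end=q1, score=score,
                query_id=query_id))
    hits.sort(key=lambda h: (h.strand, h.frame, h.start, h.end, h.query_start))
    return hits


def hits_mergeable(a: TranslatedHit, b: TranslatedHit,
                   params: SearchParams) -> bool:
    """Merge predicate: same strand, near on the target, collinear on the query."""
    if a.target_id != b.target_id or a.query_id != b.query_id:
        return False
    if a.strand != b.strand:
        return False
    if interval_gap(a.start, a.end, b.start, b.end) > params.merge_gap:
        return False
    first, second = sorted((a, b), key=lambda h: (h.query_start, h.query_end))
    if second.query_start < first.query_end - params.query_overlap_tol:
        return False
    # target order must follow query order in the hit's orientation
    slack = 3 * params.query_overlap_tol
    if a.strand == "+":
        return second.start >= first.start - slack
    return second.end <= first.end + slack


def merge_frame_hits(hits: Sequence[TranslatedHit],
                     params: SearchParams | None = None) -> list[TranslatedHit]:
    """Single-linkage closure of :func:`hits_mergeable` over ``hits``.

    Merged hits span the union of member intervals, score the sum of member
    scores and record a mixed frame.  Singleton groups pass through unchanged.
    """
    params = params or SearchParams()
    hits = list(hits)
    n = len(hits)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if hits_mergeable(hits[i], hits[j], params):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[TranslatedHit]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(hits[i])
    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        merged.append(TranslatedHit(
            target_id=members[0].target_id,
            start=min(m.start for m in members),
            end=max(m.end for m in members),
            strand=members[0].strand,
            frame=MIXED_FRAME,
            query_start=min(m.query_start for m in members),
            query_end=max(m.query_end for m in members),
            score=sum(m.score for m in members),
            query_id=members[0].query_id))
    merged.sort(key=lambda h: (h.target_id, h.start, h.end, h.strand))
    return merged


@dataclass(frozen=True)
class ExtendedInterval:
    start: int
    end: int
    clipped_start: bool = False
    clipped_end: bool = False


def flush_extend(hit: TranslatedHit, query_length: int,
                 target_length: int) -> ExtendedInterval:
    """Extend a hit so the implied alignment is flush to the full query.

    The extension is 3 nt per missing query residue on each side, applied in
    query orientation and clipped at the target bounds.  Never shrinks.
    """
    if not (0 <= hit.query_start <= hit.query_end <= query_length):
        raise InputError("hit query interval outside query")
    up = 3 * hit.query_start
    down = 3 * (query_length - hit.query_end)
    if hit.strand == "+":
        start, end = hit.start - up, hit.end + down
    else:
        start, end = hit.start - down, hit.end + up
    clipped_start = start < 0
    clipped_end = end > target_length
    return ExtendedInterval(
        start=max(0, start),
        end=min(target_length, end),
        clipped_start=clipped_start,
        clipped_end=clipped_end)


# ---------------------------------------------------------------------------
# profile (PSSM) scanning
# ---------------------------------------------------------------------------

@dataclass
class Profile:
    """Log-odds position-specific score matrix over the 20 amino acids."""

    kind: str
    matrix: np.ndarray            # (ncols, 20) bits
    alphabet: str = AA20
    consensus: str = ""
    min_occupancy: float = 0.5

    @property
    def ncols(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())


def build_profile(aligned: Sequence[str], kind: str = "other",
                  pseudocount: float = 0.5,
                  min_occupancy: float = 0.5) -> Profile:
    """Build a PSSM from an alignment of domain exemplars.

    Columns with occupancy below ``min_occupancy`` are dropped.  Scores are
    log2 odds against a uniform background.
    """
    if not aligned:
        raise ConfigurationError("empty exemplar alignment")
    width = len(aligned[0])
    if any(len(row) != width for row in aligned):
        raise ConfigurationError("exemplar rows have unequal lengths")
    aa_index = {a: i for i, a in enumerate(AA20)}
    cols = []
    consensus = []
    n20 = len(AA20)
    for c in range(width):
        residues = [row[c] for row in aligned if row[c] in aa_index]
        if len(residues) / len(aligned) < min_occupancy:
            continue
        counts = np.full(n20, pseudocount)
        for r in residues:
            counts[aa_index[r]] += 1
        freqs = counts / counts.sum()
        cols.append(np.log2(freqs * n20))
        consensus.append(AA20[int(np.argmax(counts))])
    matrix = np.array(cols)
    if matrix.shape[0] < 10:
        raise ConfigurationError(
            f"profile has {matrix.shape[0]} columns; need >= 10")
    return Profile(kind=kind, matrix=matrix, consensus="".join(consensus),
                   min_occupancy=min_occupancy)


def score_window(profile: Profile, window: str) -> float:
    """Score one protein window of exactly ``profile.ncols`` residues."""
    if len(window) != profile.ncols:
        raise InputError("window length does not match profile width")
    aa_index = {a: i for i, a in enumerate(profile.alphabet)}
    total = 0.0
    for j, r in enumerate(window):
        row = profile.matrix[j]
        total += row[aa_index[r]] if r in aa_index else float(row.min())
    return total


def profile_scan(target_id: str, target: str, profile: Profile,
                 params: SearchParams | None = None) -> list[DomainHit]:
    """Scan all six frame translations with a PSSM and report scoring windows.

    Overlapping windows in the same frame are collapsed to the local maximum.
    """
    params = params or SearchParams()
    if set(profile.alphabet) != set(AA20):
        raise ConfigurationError("profile alphabet is not the 20 amino acids")
    if profile.ncols < 10:
        raise ConfigurationError("profile has fewer than 10 columns")
    validate_nucleotides(target)
    target = target.upper().replace("U", "T")
    aa_index = {a: i for i, a in enumerate(profile.alphabet)}
    m = profile.ncols
    col_min = profile.matrix.min(axis=1)
    hits: list[DomainHit] = []
    for strand, frame, protein in six_frames(target):
        n = len(protein)
        if n < m:
            continue
        enc = np.array([aa_index.get(r, -1) for r in protein], dtype=np.int64)
        nwin = n - m + 1
        scores = np.zeros(nwin)
        for j in range(m):
            sl = enc[j:j + nwin]
            col = np.where(sl >= 0, profile.matrix[j][np.clip(sl, 0, None)],
                           col_min[j])
            scores += col
        above = np.flatnonzero(scores >= params.profile_threshold)
        # collapse runs of overlapping windows, keep the best one per run
        i = 0
        while i < len(above):
            j = i
            while j + 1 < len(above) and above[j + 1] - above[j] < m:
                j += 1
            run = above[i:j + 1]
            best = int(run[int(np.argmax(scores[run]))])
            s, e = frame_aa_to_plus_nt(strand, frame, best, best + m,
                                       len(target))
            hits.append(DomainHit(target_id=target_id, start=s, end=e,
                                  strand=strand, frame=frame,
                                  kind=profile.kind,
                                  score=float(scores[best])))
            i = j + 1
    hits.sort(key=lambda h: (h.start, h.end, h.strand, h.frame))
    return hits
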