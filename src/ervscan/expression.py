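"""Locus-level expression quantification and nonparametric contrasts.

Fragment counting uses primary alignments only (one count per fragment, a
mate pair counts once) with a >=1 bp overlap rule.  FPKM is fragments per
kilobase of locus per million mapped fragments.  Group contrasts use the
Mann-Whitney U test for unpaired designs and the Wilcoxon signed-rank test
for paired designs, with exact null enumeration at small sample sizes and a
tie-corrected normal approximation otherwise; p-values are Bonferroni
corrected within families of contrasts sharing the same variables.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.stats import norm, rankdata

from .errors import InputError
from .search import SearchParams, translated_search

EXACT_UNPAIRED_MAX = 16   # n_a + n_b at or below -> exact enumeration
EXACT_PAIRED_MAX = 12


@dataclass
class ExpressionRecord:
    locus_id: str
    sample_id: str
    condition: str
    count: int
    fpkm: float
    pairing_key: str | None = None
    sex: str | None = None
    clade: str | None = None
    motif_class: str | None = None   # DTGAD | DTGVD | other

    def __post_init__(self) -> None:
        if self.count < 0 or self.fpkm < 0:
            raise InputError("negative count or FPKM")
        if (self.count == 0) != (self.fpkm == 0):
            raise InputError("FPKM must be zero exactly when the count is zero")


@dataclass
class ContrastResult:
    grouping: tuple
    test_name: str
    p_value: float
    p_adjusted: float
    family_id: str
    n_a: int
    n_b: int


def motif_class(b1: str) -> str:
    return b1 if b1 in ("DTGAD", "DTGVD") else "other"


# ---------------------------------------------------------------------------
# counting and normalisation
# ---------------------------------------------------------------------------

def count_fragments(sam_path, loci: Sequence[tuple[str, str, int, int]],
                    ) -> tuple[dict[str, int], int]:
    """Count fragments overlapping each locus by >=1 bp.

    ``loci`` is a sequence of ``(locus_id, target_id, start, end)`` with
    0-based half-open intervals.  Only primary alignments count; the two
    mates of a pair contribute a single fragment.  Returns per-locus counts
    and the library size (total mapped fragments).
    """
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        header = sam.header.to_dict()
        hd = header.get("HD", {})
        if hd.get("SO") != "coordinate":
            raise InputError("alignments must be coordinate-sorted (HD SO)")
        by_target: dict[str, list[tuple[int, int, str]]] = {}
        for locus_id, target_id, start, end in loci:
            by_target.setdefault(target_id, []).append((start, end, locus_id))
        for intervals in by_target.values():
            intervals.sort()
        counts = {locus_id: 0 for locus_id, *_ in loci}
        seen_fragments: set[str] = set()
        counted: set[tuple[str, str]] = set()
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            seen_fragments.add(read.query_name)
            intervals = by_target.get(read.reference_name)
            if not intervals:
                continue
            rstart, rend = read.reference_start, read.reference_end
            for start, end, locus_id in intervals:
                if start >= rend:
                    break
                if end > rstart:   # >=1 bp overlap
                    key = (read.query_name, locus_id)
                    if key not in counted:
                        counted.add(key)
                        counts[locus_id] += 1
        return counts, len(seen_fragments)


def fpkm(count: int, locus_length: int, library_size: int) -> float:
    """Fragments per kilobase of locus per million mapped fragments."""
    if locus_length <= 0:
        raise InputError("locus length must be positive")
    if library_size <= 0:
        raise InputError("library size must be positive")
    return count / (locus_length / 1000.0) / (library_size / 1_000_000.0)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _mwu_null_distribution(n_a: int, n_b: int) -> np.ndarray:
    """Counts of rank-sum values for group A over all C(n_a+n_b, n_a) splits.

    Index ``k`` holds the number of arrangements whose A rank-sum (using
    ranks 1..n) equals ``k``.  Standard DP, valid when there are no ties.
    """
    n = n_a + n_b
    max_sum = n_a * n + 1
    # dp[j][s]: number of ways to choose j ranks from those seen so far with sum s
    dp = np.zeros((n_a + 1, max_sum), dtype=np.float64)
    dp[0, 0] = 1
    for rank in range(1, n + 1):
        for j in range(min(rank, n_a), 0, -1):
            dp[j, rank:] += dp[j - 1, :max_sum - rank]
    return dp[n_a]


def _mwu_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p: P(|U - nm/2| >= |u_obs - nm/2|)."""
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mid = n_a * n_b / 2
    dev = abs(u_obs - mid)
    if len(np.unique(pooled)) == len(pooled):
        dist = _mwu_null_distribution(n_a, n_b)
        total = dist.sum()
        offset = n_a * (n_a + 1) / 2
        hits = sum(cnt for s, cnt in enumerate(dist)
                   if abs((s - offset) - mid) >= dev - 1e-9)
        return float(hits / total)
    # ties: enumerate all index splits against the midranks
    idx = range(n_a + n_b)
    hits = total = 0
    for combo in itertools.combinations(idx, n_a):
        total += 1
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
        if abs(u - mid) >= dev - 1e-9:
            hits += 1
    return hits / total


def _mwu_normal_p(a: np.ndarray, b: np.ndarray) -> float:
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return 1.0
    mid = n_a * n_b / 2
    z = (abs(u - mid) - 0.5) / math.sqrt(sigma2)
    return float(min(1.0, 2 * norm.sf(max(z, 0.0))))


def _wilcoxon_exact_p(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    n = len(diffs)
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    mid = n * (n + 1) / 4
    dev = abs(w_obs - mid)
    hits = total = 0
    for signs in itertools.product((0, 1), repeat=n):
        total += 1
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mid) >= dev - 1e-9:
            hits += 1
    return hits / total


def _wilcoxon_normal_p(diffs: np.ndarray) -> float:
    n = len(diffs)
    ranks = rankdata(np.abs(diffs))
    w = ranks[diffs > 0].sum()
    mid = n * (n + 1) / 4
    _, tie_counts = np.unique(np.abs(diffs), return_counts=True)
    sigma2 = (n * (n + 1) * (2 * n + 1)
              - ((tie_counts ** 3 - tie_counts).sum()) / 2) / 24.0
    if sigma2 <= 0:
        return 1.0
    z = (abs(w - mid) - 0.5) / math.sqrt(sigma2)
    return float(min(1.0, 2 * norm.sf(max(z, 0.0))))


def rank_test(values_a: Sequence[float], values_b: Sequence[float],
              paired: bool = False) -> tuple[float, str]:
    """Two-sided rank test: Mann-Whitney U (unpaired) or Wilcoxon (paired).

    Exact null enumeration is used for small samples (unpaired
    ``n_a + n_b <= 16``, paired ``n <= 12``); otherwise a tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise InputError("paired test requires equal-length groups")
        diffs = a - b
        diffs = diffs[diffs != 0]
        if len(diffs) == 0:
            warnings.warn("all paired differences are zero; p = 1")
            return 1.0, "wilcoxon_signed_rank"
        if len(diffs) <= EXACT_PAIRED_MAX:
            return _wilcoxon_exact_p(diffs), "wilcoxon_signed_rank"
        return _wilcoxon_normal_p(diffs), "wilcoxon_signed_rank"
    if len(a) == 0 or len(b) == 0:
        raise InputError("both groups must be nonempty")
    if len(a) + len(b) <= EXACT_UNPAIRED_MAX:
        return _mwu_exact_p(a, b), "mann_whitney_u"
    return _mwu_normal_p(a, b), "mann_whitney_u"


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Adjust one family: ``min(1, p * m)`` with ``m`` the family size."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


# ---------------------------------------------------------------------------
# grouped contrasts
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus_id": r.locus_id, "sample_id": r.sample_id,
        "condition": r.condition, "count": r.count, "fpkm": r.fpkm,
        "pairing_key": r.pairing_key, "sex": r.sex,
        "clade": r.clade, "motif_class": r.motif_class,
    } for r in records])


def contrast_by_group(records: Sequence[ExpressionRecord] | pd.DataFrame,
                      conditions: tuple[str, str],
                      group_cols: Sequence[str] = ("clade", "motif_class"),
                      paired: bool = False,
                      stratify_sex: bool = False) -> list[ContrastResult]:
    """One rank test per grouping cell; Bonferroni within the shared family.

    The family is the full set of contrasts produced by one call (they share
    the same variables), matching the correction scheme of the source design.
    """
    frame = records_to_frame(records) if not isinstance(records, pd.DataFrame) \
        else records.copy()
    cols = list(group_cols) + (["sex"] if stratify_sex else [])
    family_id = "x".join(cols + ["condition"]) + (":paired" if paired else "")
    results: list[ContrastResult] = []
    for key, cell in frame.groupby(cols, dropna=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        ga = cell[cell["condition"] == conditions[0]]
        gb = cell[cell["condition"] == conditions[1]]
        if paired:
            if ga["pairing_key"].isna().any() or gb["pairing_key"].isna().any():
                raise InputError("paired design requires pairing keys")
            merged = ga.merge(gb, on=["pairing_key", "locus_id"],
                              suffixes=("_a", "_b"))
            if merged.empty:
                continue
            p, name = rank_test(merged["fpkm_a"].to_numpy(),
                                merged["fpkm_b"].to_numpy(), paired=True)
            n_a = n_b = len(merged)
        else:
            if ga.empty or gb.empty:
                continue
            p, name = rank_test(ga["fpkm"].to_numpy(), gb["fpkm"].to_numpy())
            n_a, n_b = len(ga), len(gb)
        results.append(ContrastResult(grouping=key, test_name=name,
                                      p_value=p, p_adjusted=math.nan,
                                      family_id=family_id, n_a=n_a, n_b=n_b))
    adjusted = bonferroni([r.p_value for r in results])
    for r, padj in zip(results, adjusted):
        r.p_adjusted = padj
    return results


def normality_diagnostic(values: Sequence[float]) -> dict[str, float]:
    """Reported-only screening of distribution shape (never a gate)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3 or np.allclose(x, x[0]):
        return {"n": float(len(x)), "skewness": 0.0, "excess_kurtosis": 0.0}
    z = (x - x.mean()) / x.std()
    return {"n": float(len(x)),
            "skewness": float((z ** 3).mean()),
            "excess_kurtosis": float((z ** 4).mean() - 3.0)}


def gag_coexpression(read_seqs: Mapping[str, str], gag_query: str,
                     params: SearchParams | None = None,
                     min_reads: int = 2) -> bool:
    """True iff at least ``min_reads`` reads hit the Gag query by translated search."""
    params = params or SearchParams(min_score=60.0)
    hits = 0
    for name, seq in read_seqs.items():
        if len(seq) < 3:
            continue
        if translated_search(name, seq, "gag", gag_query, params):
            hits += 1
            if hits >= min_reads:
                return True
    return False
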