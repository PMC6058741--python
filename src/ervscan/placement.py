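"""Reference phylogeny construction and likelihood-based query placement.

The reference tree is built by neighbor joining on a corrected protein
distance matrix (negative branch lengths clamped to zero).  Queries are
classified by attaching them with a pendant branch to every edge of the
tree, scoring each attachment under a fixed 20-state substitution model
with uniform exchangeabilities (closed-form transition probabilities), and
normalising the per-edge likelihoods into placement weights.  Reference
alignment columns are frozen; queries are profile-aligned onto them and
query-specific insertions are discarded.

The classification verdict is the clade labelling the best edge's side of
the tree, UNPLACED when no edge carries enough weight, or INTERNAL when the
best edge lies on the path between clades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .codonalign import pairwise_protein_distance
from .errors import ConfigurationError, InputError

AA20 = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}
N_STATES = 20

UNPLACED = "UNPLACED"
INTERNAL = "INTERNAL"

PENDANT_GRID = np.exp(np.linspace(np.log(1e-4), np.log(2.0), 15))
MIN_BRANCH = 1e-6


def transition_matrix(t: float) -> np.ndarray:
    """P(t) for the uniform-exchangeability 20-state model (rate 1/site)."""
    decay = math.exp(-N_STATES / (N_STATES - 1) * max(t, 0.0))
    off = (1.0 - decay) / N_STATES
    P = np.full((N_STATES, N_STATES), off)
    np.fill_diagonal(P, off + decay)
    return P


@dataclass
class ReferenceTree:
    tree: TreeNode                       # rooted representation of the NJ tree
    leaf_clades: dict[str, str]
    clade_supergroups: dict[str, str] = field(default_factory=dict)

    def edges(self) -> list[TreeNode]:
        """Every non-root node stands for the edge above it (stable order)."""
        return [node for node in self.tree.preorder() if node.parent is not None]

    def newick(self) -> str:
        return str(self.tree).strip()


def build_reference_tree(aa_rows: Mapping[str, str],
                         leaf_clades: Mapping[str, str],
                         clade_supergroups: Mapping[str, str] | None = None,
                         ) -> ReferenceTree:
    """Neighbor-joining tree from aligned reference translations."""
    if len(aa_rows) < 4:
        raise InputError("need at least 4 reference sequences")
    missing = set(aa_rows) - set(leaf_clades)
    if missing:
        raise ConfigurationError(f"unlabeled reference leaves: {sorted(missing)}")
    ids, dist, undefined = pairwise_protein_distance(aa_rows)
    if undefined:
        raise InputError(f"undefined distances for pairs: {undefined}")
    dm = DistanceMatrix(dist, ids)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return ReferenceTree(tree=tree, leaf_clades=dict(leaf_clades),
                         clade_supergroups=dict(clade_supergroups or {}))


@dataclass
class Placement:
    query_id: str
    edge_weights: dict[int, float]       # edge index -> normalized weight
    best_edge: int | None
    best_weight: float
    verdict: str
    reason: str = ""


def _encode_alignment(aa_rows: Mapping[str, str]) -> dict[str, np.ndarray]:
    """Residues to state indices; gaps/ambiguity become -1 (missing)."""
    out = {}
    for name, row in aa_rows.items():
        out[name] = np.array([_AA_INDEX.get(r, -1) for r in row],
                             dtype=np.int64)
    return out


def _tip_partial(states: np.ndarray) -> np.ndarray:
    """(sites, 20) indicator partial likelihoods; missing sites are all-ones."""
    nsites = len(states)
    F = np.zeros((nsites, N_STATES))
    miss = states < 0
    F[miss, :] = 1.0
    obs = ~miss
    F[np.flatnonzero(obs), states[obs]] = 1.0
    return F


def _branch_length(node: TreeNode) -> float:
    return max(node.length if node.length is not None else 0.0, MIN_BRANCH)


class PlacementEngine:
    """Pre-computes inside/outside partials so many queries place cheaply."""

    def __init__(self, ref_tree: ReferenceTree, aa_rows: Mapping[str, str]):
        self.ref_tree = ref_tree
        widths = {len(v) for v in aa_rows.values()}
        if len(widths) != 1:
            raise InputError("reference rows must be aligned")
        self.ncols = widths.pop()
        enc = _encode_alignment(aa_rows)
        tree = ref_tree.tree
        leaves = {leaf.name for leaf in tree.tips()}
        if leaves - set(enc):
            raise InputError(f"alignment missing leaves: {sorted(leaves - set(enc))}")
        self.edges = ref_tree.edges()
        self._edge_index = {id(node): i for i, node in enumerate(self.edges)}
        # inside pass (partials below each node)
        self._F: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_tip():
                self._F[id(node)] = _tip_partial(enc[node.name])
            else:
                F = np.ones((self.ncols, N_STATES))
                for child in node.children:
                    P = transition_matrix(_branch_length(child))
                    F = F * (self._F[id(child)] @ P.T)
                self._F[id(node)] = F
        # outside pass (partials above each edge, at the parent node)
        self._U: dict[int, np.ndarray] = {}
        for node in tree.preorder():
            if node.parent is None:
                continue
            parent = node.parent
            U = np.ones((self.ncols, N_STATES))
            if parent.parent is not None:
                Pp = transition_matrix(_branch_length(parent))
                U = U * (self._U[id(parent)] @ Pp.T)
            for sib in parent.children:
                if sib is node:
                    continue
                Ps = transition_matrix(_branch_length(sib))
                U = U * (self._F[id(sib)] @ Ps.T)
            self._U[id(node)] = U
        # query-independent per-edge attachment context: the element-wise
        # product of inside and outside partials at the split point
        self._edge_context = []
        for edge in self.edges:
            half = _branch_length(edge) / 2.0
            Ph = transition_matrix(half)
            below = self._F[id(edge)] @ Ph.T
            above = self._U[id(edge)] @ Ph.T
            self._edge_context.append(below * above)
        self._pendant_mats = [transition_matrix(float(lam))
                              for lam in PENDANT_GRID]

    def edge_loglik(self, edge_index: int, query_states: np.ndarray) -> float:
        """Maximum log likelihood of attaching the query along this edge."""
        Q = _tip_partial(query_states)
        qparts = [Q @ P.T for P in self._pendant_mats]
        return self._edge_loglik_from_qparts(edge_index, qparts)[0]

    def _edge_loglik_from_qparts(self, edge_index: int,
                                 qparts: list[np.ndarray],
                                 ) -> tuple[float, int]:
        """Best log likelihood over the pendant grid and the grid index used."""
        context = self._edge_context[edge_index]
        best = -math.inf
        best_k = 0
        for k, qpart in enumerate(qparts):
            site = (context * qpart).sum(axis=1) / N_STATES
            with np.errstate(divide="ignore"):
                ll = float(np.sum(np.log(np.maximum(site, 1e-300))))
            if ll > best:
                best, best_k = ll, k
        return best, best_k

    def place(self, query_id: str, query_row: str,
              min_overlap: float = 0.30,
              threshold: float = 0.90) -> Placement:
        """Place one query (already expressed over the reference columns)."""
        if len(query_row) != self.ncols:
            raise InputError("query row length does not match reference columns")
        states = np.array([_AA_INDEX.get(r, -1) for r in query_row],
                          dtype=np.int64)
        overlap = float((states >= 0).mean())
        if overlap < min_overlap:
            return Placement(query_id=query_id, edge_weights={},
                             best_edge=None, best_weight=0.0,
                             verdict=UNPLACED, reason="insufficient overlap")
        Q = _tip_partial(states)
        qparts = [Q @ P.T for P in self._pendant_mats]
        results = [self._edge_loglik_from_qparts(i, qparts)
                   for i in range(len(self.edges))]
        logliks = np.array([r[0] for r in results])
        weights = np.exp(logliks - logliks.max())
        weights = weights / weights.sum()
        order = np.argsort(-logliks, kind="stable")
        best = int(order[0])
        placement = Placement(
            query_id=query_id,
            edge_weights={i: float(w) for i, w in enumerate(weights)},
            best_edge=best,
            best_weight=float(weights[best]),
            verdict="")
        if results[best][1] == len(PENDANT_GRID) - 1:
            # optimal pendant length pinned at the grid maximum: the query
            # has no affinity to the tree, whatever the weight says
            placement.verdict = UNPLACED
            placement.reason = "pendant length at maximum"
            return placement
        placement.verdict = classify_placement(placement, self.ref_tree,
                                               threshold=threshold)
        return placement


def edge_clade(ref_tree: ReferenceTree, edge: TreeNode) -> str:
    """Clade labelling an edge, or INTERNAL if it separates clades."""
    below = {ref_tree.leaf_clades[t.name] for t in
             ([edge] if edge.is_tip() else edge.tips())}
    if len(below) == 1:
        return below.pop()
    all_leaves = {t.name for t in ref_tree.tree.tips()}
    below_names = {t.name for t in ([edge] if edge.is_tip() else edge.tips())}
    above = {ref_tree.leaf_clades[n] for n in all_leaves - below_names}
    if len(above) == 1:
        return above.pop()
    return INTERNAL


def classify_placement(placement: Placement, ref_tree: ReferenceTree,
                       threshold: float = 0.90) -> str:
    """Best-edge verdict under the minimum-weight rule."""
    if placement.best_edge is None or placement.best_weight < threshold:
        return UNPLACED
    edge = ref_tree.edges()[placement.best_edge]
    return edge_clade(ref_tree, edge)


def reconcile_locus(member_verdicts: Mapping[str, str]) -> tuple[str, bool, list[str]]:
    """Combine member verdicts into one locus verdict.

    UNPLACED members are ignored; unanimity among the rest gives the locus
    label, disagreement raises the conflict flag with the dissenting members
    listed.  Returns ``(verdict, conflict, dissenters)``.
    """
    if not member_verdicts:
        raise InputError("no member verdicts")
    placed = {k: v for k, v in member_verdicts.items() if v != UNPLACED}
    if not placed:
        return UNPLACED, False, []
    labels = sorted(set(placed.values()))
    if len(labels) == 1:
        return labels[0], False, []
    counts = {lab: sum(1 for v in placed.values() if v == lab)
              for lab in labels}
    majority = max(counts, key=lambda lab: (counts[lab], lab))
    if counts[majority] * 2 <= len(placed):
        majority = "conflict"   # no strict majority
    dissenters = sorted(k for k, v in placed.items() if v != majority)
    return majority, True, dissenters


# ---------------------------------------------------------------------------
# profile alignment of a query onto frozen reference columns
# ---------------------------------------------------------------------------

def align_query_to_reference(aa_rows: Mapping[str, str], query: str,
                             gap_open: float = 10.0,
                             gap_extend: float = 0.5) -> str:
    """Express an unaligned query protein over the reference alignment columns.

    Semi-global alignment (free end gaps for the query) of the query against
    the reference profile; query residues that fall between reference columns
    (insertions) are discarded so the reference coordinate frame is frozen.
    """
    from .codonalign import _profile_counts, _AA_INDEX as BAIDX, _M

    rows = list(aa_rows.values())
    prof = _profile_counts(rows)
    qidx = [BAIDX.get(r) for r in query]
    n = prof.shape[0]
    m = len(query)
    qvec = np.zeros((m, prof.shape[1]))
    for i, k in enumerate(qidx):
        if k is not None:
            qvec[i, k] = 1.0
    S = prof @ _M @ qvec.T    # (n, m)
    NEG = -1e18
    dp = np.full((n + 1, m + 1), NEG)
    back = np.zeros((n + 1, m + 1), dtype=np.int8)
    dp[0, 0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0:   # reference column unmatched (gap in query) — free-ish
                cand = dp[i - 1, j] - gap_extend
                if cand > dp[i, j]:
                    dp[i, j] = cand
                    back[i, j] = 1
            if j > 0:   # query insertion, discarded later
                cand = dp[i, j - 1] - gap_open
                if cand > dp[i, j]:
                    dp[i, j] = cand
                    back[i, j] = 2
            if i > 0 and j > 0:
                cand = dp[i - 1, j - 1] + S[i - 1, j - 1]
                if cand > dp[i, j]:
                    dp[i, j] = cand
                    back[i, j] = 3
    out = []
    i, j = n, m
    cells = []
    while i > 0 or j > 0:
        b = back[i, j]
        cells.append((i, j, b))
        if b == 3:
            i, j = i - 1, j - 1
        elif b == 1:
            i -= 1
        else:
            j -= 1
    cells.reverse()
    for i, j, b in cells:
        if b == 3:
            out.append(query[j - 1])
        elif b == 1:
            out.append("-")
        # b == 2: query insertion, dropped
    return "".join(out)
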