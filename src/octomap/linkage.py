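"""Two-point linkage, LOD grouping and map ordering for 1:1 pseudo-testcross bins.

For two presence/absence bins scored in the same progeny, the
recombination evidence is the mismatch count on jointly genotyped
individuals, minimised over phase (a simplex marker's coding is
phase-arbitrary, so a vector and its complement are the same locus
pattern)::

    R  = min(M, n - M)          rf = R / n
    LOD = (n - R) log10(2 (1 - rf)) + R log10(2 rf)

with the R = 0 limit LOD = n log10 2.  Groups are the transitive closure
of pairs at LOD >= 6, followed by a rescue pass attaching each unplaced
bin to the group holding its strongest cross link when that link reaches
LOD >= 4.  Within a group the order is a documented heuristic — greedy
chain extension from the strongest pair, appending at either end the bin
with the smallest rf to that end, then 2-opt refinement minimising the
sum of adjacent rf — and cumulative positions use Kosambi's mapping
function ``cM = 25 ln((1+2r)/(1-2r))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .pileup import MISSING

__all__ = [
    "LinkagePair",
    "LinkageGroupMap",
    "kosambi",
    "kosambi_inverse",
    "two_point_lod",
    "pairwise_linkage",
    "linkage_matrices",
    "group_bins",
    "order_group",
    "build_maps",
]

_RF_CAP = 0.4999  # Kosambi domain guard for adjacent-pair distances


def kosambi(r: float) -> float:
    """Kosambi map distance (cM) of a recombination fraction ``0 <= r < 0.5``."""
    if not 0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r!r}")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def kosambi_inverse(d_cm: float) -> float:
    """Recombination fraction of a Kosambi distance in cM."""
    if d_cm < 0:
        raise ValueError("distance must be non-negative")
    return 0.5 * math.tanh(d_cm / 50.0)


def two_point_lod(n: int, r_count: int) -> float:
    """LOD of linkage versus free recombination for ``r_count`` of ``n``."""
    if not 0 <= r_count <= n:
        raise ValueError("recombinant count out of range")
    if n == 0:
        return 0.0
    if r_count == 0:
        return n * math.log10(2.0)
    rf = r_count / n
    if rf >= 0.5:
        return 0.0
    return (n - r_count) * math.log10(2 * (1 - rf)) + r_count * math.log10(2 * rf)


@dataclass(frozen=True)
class LinkagePair:
    bin_a: str
    bin_b: str
    n_shared: int
    recombinants: int   # phase-minimised
    rf: float
    lod: float


def pairwise_linkage(va, vb, id_a: str = "a", id_b: str = "b",
                     min_shared: int = 10) -> LinkagePair | None:
    """Two-point linkage of two genotype vectors; None below ``min_shared``."""
    va, vb = np.asarray(va), np.asarray(vb)
    shared = (va != MISSING) & (vb != MISSING)
    n = int(shared.sum())
    if n < min_shared:
        return None
    mism = int((va[shared] != vb[shared]).sum())
    r = min(mism, n - mism)
    rf = r / n
    return LinkagePair(bin_a=id_a, bin_b=id_b, n_shared=n, recombinants=r,
                       rf=rf, lod=two_point_lod(n, r))


def linkage_matrices(matrix: pd.DataFrame, min_shared: int = 10):
    """All-pairs shared-n, recombinant, rf and LOD matrices (vectorised).

    Pairs with fewer than ``min_shared`` jointly genotyped progeny get
    rf = 0.5 and LOD = −inf so they can never link.
    """
    v = matrix.to_numpy(dtype=np.int8)
    pres = (v == 1).astype(np.float64)
    abse = (v == 0).astype(np.float64)
    nonmiss = pres + abse
    n = nonmiss @ nonmiss.T
    mism = pres @ abse.T + abse @ pres.T
    r = np.minimum(mism, n - mism)
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(n > 0, r / np.maximum(n, 1), 0.5)
        term = np.where(rf > 0, (n - r) * np.log10(np.maximum(2 * (1 - rf), 1e-300))
                        + r * np.log10(np.maximum(2 * rf, 1e-300)),
                        n * math.log10(2.0))
    lod = np.where(rf >= 0.5, 0.0, term)
    bad = n < min_shared
    rf = np.where(bad, 0.5, rf)
    lod = np.where(bad, -np.inf, lod)
    np.fill_diagonal(lod, -np.inf)
    ids = list(matrix.index)
    return ids, n.astype(int), r, rf, lod


def group_bins(ids, lod: np.ndarray, lod_cutoff: float = 6.0,
               rescue_cutoff: float = 4.0) -> tuple[list[list[str]], list[str]]:
    """Single-linkage grouping at ``lod_cutoff`` with a rescue pass.

    Groups are connected components (>= 2 bins) of the LOD >= cutoff
    graph.  Each bin left unplaced is then attached to the group of its
    strongest remaining link if that LOD reaches ``rescue_cutoff``
    (the strongest-cross-link rescue); rescue evaluates against the
    original groups so rescued bins cannot chain further bins in.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(ids)))
    ii, jj = np.nonzero(np.triu(lod >= lod_cutoff, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) > 1]
    comps.sort(key=lambda c: (-len(c), c))
    member_of = {}
    for gi, comp in enumerate(comps):
        for i in comp:
            member_of[i] = gi
    grouped = sorted(member_of)
    rescued: dict[int, list[int]] = {}
    unplaced = []
    for i in range(len(ids)):
        if i in member_of:
            continue
        if grouped:
            links = lod[i, grouped]
            best = int(np.argmax(links))
            if links[best] >= rescue_cutoff:
                rescued.setdefault(member_of[grouped[best]], []).append(i)
                continue
        unplaced.append(i)
    groups = [[ids[i] for i in comp + sorted(rescued.get(gi, []))]
              for gi, comp in enumerate(comps)]
    return groups, [ids[i] for i in unplaced]


def _chain_order(members: list[int], rf: np.ndarray, lod: np.ndarray) -> list[int]:
    if len(members) <= 2:
        return list(members)
    sub = np.ix_(members, members)
    l = lod[sub].copy()
    np.fill_diagonal(l, -np.inf)
    a, b = np.unravel_index(np.argmax(l), l.shape)
    chain = [members[a], members[b]]
    remaining = [m for m in members if m not in chain]
    while remaining:
        head, tail = chain[0], chain[-1]
        best = None
        for m in remaining:
            for end, anchor in ((0, head), (1, tail)):
                cand = (rf[anchor, m], end, m)
                if best is None or cand < best:
                    best = cand
        _, end, m = best
        if end == 0:
            chain.insert(0, m)
        else:
            chain.append(m)
        remaining.remove(m)
    return chain


def _two_opt(order: list[int], rf: np.ndarray, max_rounds: int = 20) -> list[int]:
    # segment-reversal moves with O(1) delta: reversing o[i..j] only touches
    # the edges entering i and leaving j
    best = list(order)
    n = len(best)
    for _ in range(max_rounds):
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                if i == 0 and j == n - 1:
                    continue
                delta = 0.0
                if i > 0:
                    delta += rf[best[i - 1], best[j]] - rf[best[i - 1], best[i]]
                if j < n - 1:
                    delta += rf[best[i], best[j + 1]] - rf[best[j], best[j + 1]]
                if delta < -1e-12:
                    best[i:j + 1] = best[i:j + 1][::-1]
                    improved = True
        if not improved:
            break
    return best


@dataclass
class LinkageGroupMap:
    """An ordered linkage group with cumulative Kosambi positions."""

    group_id: str
    bin_ids: list[str]
    positions_cm: list[float]

    @property
    def length_cm(self) -> float:
        return self.positions_cm[-1] if self.positions_cm else 0.0


def order_group(member_ids: list[str], ids: list[str], rf: np.ndarray,
                lod: np.ndarray, group_id: str = "LG") -> LinkageGroupMap:
    """Order one group and place it on a cumulative Kosambi cM axis."""
    index = {b: i for i, b in enumerate(ids)}
    members = [index[b] for b in member_ids]
    order = _two_opt(_chain_order(members, rf, lod), rf)
    pos = [0.0]
    for a, b in zip(order, order[1:]):
        pos.append(pos[-1] + kosambi(min(float(rf[a, b]), _RF_CAP)))
    return LinkageGroupMap(group_id=group_id,
                           bin_ids=[ids[i] for i in order], positions_cm=pos)


def build_maps(matrix: pd.DataFrame, lod_cutoff: float = 6.0,
               rescue_cutoff: float = 4.0, min_shared: int = 10
               ) -> tuple[list[LinkageGroupMap], list[str], pd.DataFrame]:
    """Group and order a bin genotype matrix into linkage group maps.

    Returns (maps, unplaced bin ids, summary table).  Groups with a
    single bin are not produced by construction; unplaced bins are
    reported but not ordered.
    """
    ids, n, r, rf, lod = linkage_matrices(matrix, min_shared=min_shared)
    groups, unplaced = group_bins(ids, lod, lod_cutoff=lod_cutoff,
                                  rescue_cutoff=rescue_cutoff)
    maps = [order_group(members, ids, rf, lod, group_id=f"LG{k + 1}")
            for k, members in enumerate(groups)]
    summary = pd.DataFrame([{"group": m.group_id, "n_bins": len(m.bin_ids),
                             "length_cm": round(m.length_cm, 1)} for m in maps])
    return maps, unplaced, summary
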