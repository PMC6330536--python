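"""Segregation filtering and co-segregation binning of single-dose markers.

Markers that survive the screen are kept for mapping only if they
segregate like a simplex pseudo-testcross locus (presence fraction among
genotyped progeny within 0.3-0.7) in enough individuals (>= 39 genotyped
by default), then collapsed into bins of co-segregating markers that map
as one locus.  Presence/absence coding of a simplex allele is
phase-arbitrary, so a marker and its complement co-segregate and share a
bin (repulsion phase).

Bins are built by greedy leader clustering over markers sorted by id:
each marker joins the first existing bin whose leader it matches (in
either phase orientation) with at most ``max_conflicts`` disagreements
on jointly genotyped progeny, else founds a new bin.  Greedy leader
(rather than transitive closure) keeps a nonzero conflict allowance from
chaining incompatible markers; the id sort fixes the order dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pileup import MISSING

__all__ = [
    "MarkerBin",
    "segregation_filter",
    "filter_markers",
    "build_bins",
    "choose_representative",
    "bin_matrix",
]


def segregation_filter(calls, lo: float = 0.3, hi: float = 0.7,
                       min_genotyped: int = 39) -> bool:
    """Keep a marker iff it segregates ~1:1 in enough genotyped progeny.

    ``calls`` holds 1 (presence), 0 (absence) and −1 (missing).  Pass iff
    the presence fraction among non-missing calls lies in ``[lo, hi]``
    and at least ``min_genotyped`` progeny are non-missing.  All-missing
    markers fail.
    """
    v = np.asarray(calls)
    genotyped = int((v != MISSING).sum())
    if genotyped < max(min_genotyped, 1):
        return False
    frac = float((v == 1).sum()) / genotyped
    return lo <= frac <= hi


def filter_markers(genotypes: pd.DataFrame, lo: float = 0.3, hi: float = 0.7,
                   min_genotyped: int = 39,
                   max_missing_frac: float = 0.10) -> pd.DataFrame:
    """Apply the segregation filter and the binnable missing-data cap.

    The two completeness thresholds are deliberately independent knobs: a
    minimum number of genotyped individuals for the segregation test, and
    a maximum missing fraction for a marker to enter bin construction.
    """
    v = genotypes.to_numpy()
    keep = np.array([segregation_filter(row, lo=lo, hi=hi, min_genotyped=min_genotyped)
                     for row in v])
    missing = (v == MISSING).mean(axis=1)
    return genotypes.loc[keep & (missing <= max_missing_frac)]


@dataclass
class MarkerBin:
    """A bin of co-segregating markers mapped as one locus."""

    bin_id: str
    members: list[str]
    flipped: dict[str, bool]       # member -> stored in repulsion phase vs leader
    consensus: np.ndarray          # majority call per progeny (−1 where unresolved)
    representative: str = ""

    def __len__(self) -> int:
        return len(self.members)


def _conflicts(leader: np.ndarray, v: np.ndarray) -> tuple[int, bool]:
    shared = (leader != MISSING) & (v != MISSING)
    direct = int(((leader != v) & shared).sum())
    comp = int(shared.sum()) - direct
    return (direct, False) if direct <= comp else (comp, True)


def choose_representative(bin_: MarkerBin, genotypes: pd.DataFrame) -> str:
    """Member with the least missing data; ties go to the smallest id."""
    if not bin_.members:
        raise ValueError("empty bin")
    na = {(m): int((genotypes.loc[m].to_numpy() == MISSING).sum()) for m in bin_.members}
    return min(bin_.members, key=lambda m: (na[m], m))


def build_bins(genotypes: pd.DataFrame, max_conflicts: int = 0) -> list[MarkerBin]:
    """Greedy leader clustering of markers into co-segregation bins.

    Markers are processed in sorted-id order; phase is resolved per
    comparison by taking whichever orientation (direct or complement)
    yields fewer conflicts.  Consensus is the majority call per progeny
    over phase-oriented members (ties and all-missing columns stay −1).
    Returns a partition: every marker lands in exactly one bin.
    """
    ids = sorted(genotypes.index)
    mat = genotypes.loc[ids].to_numpy(dtype=np.int8)
    n_prog = mat.shape[1]
    leaders = np.empty((0, n_prog), dtype=np.int8)
    bins: list[MarkerBin] = []
    for mid, v in zip(ids, mat):
        placed = False
        if len(bins):
            shared = (leaders != MISSING) & (v != MISSING)
            direct = ((leaders != v) & shared).sum(axis=1)
            comp = shared.sum(axis=1) - direct
            conf = np.minimum(direct, comp)
            ok = np.nonzero(conf <= max_conflicts)[0]
            if ok.size:
                b = int(ok[0])
                flip = bool(comp[b] < direct[b])
                bins[b].members.append(mid)
                bins[b].flipped[mid] = flip
                placed = True
        if not placed:
            leaders = np.vstack([leaders, v[None, :]])
            bins.append(MarkerBin(bin_id=f"bin{len(bins):05d}", members=[mid],
                                  flipped={mid: False}, consensus=v.copy()))
    for b in bins:
        rows = []
        for m in b.members:
            v = genotypes.loc[m].to_numpy(dtype=np.int8)
            if b.flipped[m]:
                v = np.where(v == MISSING, MISSING, 1 - v).astype(np.int8)
            rows.append(v)
        stack = np.stack(rows)
        ones = (stack == 1).sum(axis=0)
        zeros = (stack == 0).sum(axis=0)
        b.consensus = np.where(ones > zeros, 1,
                               np.where(zeros > ones, 0, MISSING)).astype(np.int8)
        b.representative = choose_representative(b, genotypes)
    return bins


def bin_matrix(bins: list[MarkerBin], columns) -> pd.DataFrame:
    """Consensus genotype matrix (bin x progeny) for the linkage stage."""
    return pd.DataFrame([b.consensus for b in bins],
                        index=[b.bin_id for b in bins], columns=columns,
                        dtype=np.int8)
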