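"""Single-dose SNP screening from mpileup-dialect text.

The discovery strategy for a high-ploidy F1 cross: merge the progeny
pileups into one deep column per site, keep sites whose minor/major
allele ratio falls in a window centred on the pooled single-dose
expectation (1:15 for an octoploid cross, screened at 1:6 .. 1:30 to
absorb depth and expression noise), assign each candidate to the parent
whose own pileup shows the in-window ratio while the other parent is
clean, and score each progeny presence/absence ("pseudo-testcross"
coding: a heterozygous allele is scored as presence, its lack as
absence).

The pileup dialect consumed is the 6-column mpileup text form
(name, 1-based position, ref base, depth, read bases, Phred+33
qualities); ``.``/``,`` denote the reference base, letters denote
alternatives, ``^``/``$`` read markers are tolerated, indels are not.
Bases at quality <= 28 are excluded from all counts; per-sample columns
need filtered depth > 7 to be scored at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PileupColumn",
    "MergedColumn",
    "SNPCandidate",
    "CallConfig",
    "CallResult",
    "PileupParseError",
    "read_pileup",
    "load_pileup",
    "merge_columns",
    "prefilter",
    "screen_single_dose",
    "assign_parent",
    "genotype_progeny",
    "call_single_dose_markers",
    "read_sample_sheet",
]

_BASES = ("A", "C", "G", "T")
MISSING = -1  # genotype code for a missing call; presence 1, absence 0


class PileupParseError(ValueError):
    pass


@dataclass
class PileupColumn:
    """Quality-filtered base counts of one sample at one site."""

    name: str
    pos: int
    ref: str
    counts: dict[str, int]
    raw_depth: int

    @property
    def depth(self) -> int:
        """Filtered depth (bases above the quality threshold)."""
        return sum(self.counts.values())


@dataclass
class MergedColumn:
    """Base counts summed over all progeny samples at one site."""

    name: str
    pos: int
    ref: str
    counts: dict[str, int]
    n_samples: int          # progeny with nonzero filtered depth

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class SNPCandidate:
    """A screened single-dose SNP candidate."""

    name: str
    pos: int
    ref: str
    major: str
    minor: str
    ratio: float
    depth: int
    parent: str = "ambiguous"
    calls: dict[str, int] = field(default_factory=dict)

    @property
    def marker_id(self) -> str:
        return f"{self.name}:{self.pos}"


def _parse_bases(ref: str, bases: str, quals: str, min_qual: int) -> dict[str, int]:
    counts = {b: 0 for b in _BASES}
    qi = 0
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret + mapping quality char, consumes no base quality
            continue
        if c == "$":
            i += 1
            continue
        if qi >= len(quals):
            raise PileupParseError("fewer qualities than bases")
        q = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if c in ".,":
            base = ref
        else:
            base = c.upper()
        if base in counts and q > min_qual:
            counts[base] += 1
    if qi != len(quals):
        raise PileupParseError("fewer bases than qualities")
    return counts


def read_pileup(source, min_qual: int = 28):
    """Iterate :class:`PileupColumn` records from 6-column mpileup text.

    ``source`` is a path or an open text stream.  Bases with Phred
    quality <= ``min_qual`` are dropped from the counts; the raw depth
    column is kept as reported.  Malformed lines raise
    :class:`PileupParseError` with the line number.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from read_pileup(fh, min_qual=min_qual)
        return
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise PileupParseError(f"line {lineno}: expected 6 columns, got {len(fields)}")
        name, pos, ref, depth, bases, quals = fields
        try:
            pos_i, depth_i = int(pos), int(depth)
        except ValueError as exc:
            raise PileupParseError(f"line {lineno}: {exc}") from None
        try:
            counts = _parse_bases(ref.upper(), bases, quals, min_qual)
        except PileupParseError as exc:
            raise PileupParseError(f"line {lineno}: {exc}") from None
        yield PileupColumn(name=name, pos=pos_i, ref=ref.upper(),
                           counts=counts, raw_depth=depth_i)


def load_pileup(path, min_qual: int = 28) -> dict[tuple[str, int], PileupColumn]:
    """Read a whole pileup file into a (name, pos) -> column mapping."""
    return {(col.name, col.pos): col for col in read_pileup(path, min_qual=min_qual)}


def prefilter(column: PileupColumn | None, min_depth: int = 7) -> bool:
    """Coverage prefilter: filtered depth strictly greater than ``min_depth``."""
    return column is not None and column.depth > min_depth


def merge_columns(columns) -> MergedColumn | None:
    """Sum filtered base counts over per-sample columns at one locus."""
    columns = [c for c in columns if c is not None]
    if not columns:
        return None
    first = columns[0]
    counts = {b: 0 for b in _BASES}
    covered = 0
    for col in columns:
        if (col.name, col.pos) != (first.name, first.pos):
            raise ValueError("cannot merge columns from different loci")
        for b in _BASES:
            counts[b] += col.counts[b]
        covered += col.depth > 0
    return MergedColumn(name=first.name, pos=first.pos, ref=first.ref,
                        counts=counts, n_samples=covered)


def _major_minor(counts: dict[str, int]) -> tuple[str, str]:
    ranked = sorted(_BASES, key=lambda b: (-counts[b], b))
    return ranked[0], ranked[1]


def screen_single_dose(merged: MergedColumn,
                       window: tuple[float, float] = (1 / 30, 1 / 6),
                       min_total_depth: int = 72,
                       third_allele_frac: float = 0.01) -> SNPCandidate | None:
    """Window screen on the merged column's minor/major allele ratio.

    ``major`` is the most frequent base, ``minor`` the runner-up; a
    candidate is returned iff ``minor/major`` lies in the inclusive
    window.  Residual third/fourth-allele reads above
    ``third_allele_frac`` of the depth reject the site as multi-allelic.
    The default minimum merged depth of 72 is the depth at which a
    pooled 1/16 allele is sampled with 99% probability.
    """
    depth = merged.depth
    if depth < min_total_depth:
        return None
    major, minor = _major_minor(merged.counts)
    if merged.counts[minor] == 0:
        return None
    rest = depth - merged.counts[major] - merged.counts[minor]
    if rest > third_allele_frac * depth:
        return None
    ratio = merged.counts[minor] / merged.counts[major]
    lo, hi = window
    if not lo <= ratio <= hi:
        return None
    return SNPCandidate(name=merged.name, pos=merged.pos, ref=merged.ref,
                        major=major, minor=minor, ratio=ratio, depth=depth)


def _parent_state(col: PileupColumn | None, cand: SNPCandidate,
                  window: tuple[float, float], error_frac: float,
                  min_depth: int) -> str:
    """Classify one parent at the candidate site: 'carrier', 'clean' or 'unusable'."""
    if not prefilter(col, min_depth):
        return "unusable"
    depth = col.depth
    minor_n = col.counts[cand.minor]
    major_n = col.counts[cand.major]
    if major_n > 0 and minor_n > 0 and window[0] <= minor_n / major_n <= window[1]:
        return "carrier"
    if minor_n <= error_frac * depth:
        return "clean"
    return "unusable"


def assign_parent(cand: SNPCandidate, parent1: PileupColumn | None,
                  parent2: PileupColumn | None,
                  window: tuple[float, float] = (1 / 30, 1 / 6),
                  error_frac: float = 0.01, min_depth: int = 7) -> str:
    """Parent of origin of a candidate: ``"P1"``, ``"P2"`` or ``"ambiguous"``.

    The carrier parent must itself show the in-window minor/major ratio
    while the other parent's minor fraction stays at or below the error
    budget; any other combination (both carriers, neither, missing
    parental coverage) is ambiguous and excluded from mapping.
    """
    s1 = _parent_state(parent1, cand, window, error_frac, min_depth)
    s2 = _parent_state(parent2, cand, window, error_frac, min_depth)
    if s1 == "carrier" and s2 == "clean":
        return "P1"
    if s2 == "carrier" and s1 == "clean":
        return "P2"
    return "ambiguous"


def genotype_progeny(cand: SNPCandidate, columns: dict[str, PileupColumn | None],
                     min_minor_reads: int = 2, min_depth: int = 7) -> dict[str, int]:
    """Presence/absence/missing calls per progeny at a candidate site.

    Missing (−1) when the sample fails the coverage prefilter; presence
    (1) with at least ``min_minor_reads`` minor-allele reads (two reads
    guard against a lone sequencing error); otherwise absence (0).
    """
    calls: dict[str, int] = {}
    for sample, col in columns.items():
        if not prefilter(col, min_depth):
            calls[sample] = MISSING
        elif col.counts[cand.minor] >= min_minor_reads:
            calls[sample] = 1
        else:
            calls[sample] = 0
    return calls


@dataclass(frozen=True)
class CallConfig:
    """Thresholds of the single-dose screen."""

    min_qual: int = 28
    min_depth: int = 7
    window: tuple[float, float] = (1 / 30, 1 / 6)
    min_merged_depth: int = 72
    third_allele_frac: float = 0.01
    min_minor_reads: int = 2
    parent_error_frac: float = 0.01


@dataclass
class CallResult:
    """Output of the merged-progeny screen.

    ``candidates``: every site passing the merged ratio window, with the
    parent label (possibly ambiguous).  ``markers``: per-candidate
    metadata restricted to parent-assigned candidates, aligned with
    ``genotypes`` (marker x progeny matrix; 1 presence, 0 absence,
    −1 missing).
    """

    candidates: pd.DataFrame
    markers: pd.DataFrame
    genotypes: pd.DataFrame
    merged_depth: pd.Series  # filtered merged progeny depth of every locus


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, role in {parent1, parent2, progeny}, path."""
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample_id", "role", "path"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    base = Path(path).parent
    sheet["path"] = [str(p) if Path(p).is_absolute() else str(base / p)
                     for p in sheet["path"]]
    for role in ("parent1", "parent2"):
        if (sheet["role"] == role).sum() != 1:
            raise ValueError(f"sample sheet needs exactly one {role}")
    return sheet


def call_single_dose_markers(sample_sheet, config: CallConfig = CallConfig()) -> CallResult:
    """Run the full screen over a sample sheet of pileup files.

    Progeny pileups are merged per site and screened by the ratio
    window; candidates are assigned a parent from the two parental
    pileups, and parent-assigned candidates are genotyped across the
    progeny.
    """
    sheet = sample_sheet if isinstance(sample_sheet, pd.DataFrame) \
        else read_sample_sheet(sample_sheet)
    p1_path = sheet.loc[sheet["role"] == "parent1", "path"].iloc[0]
    p2_path = sheet.loc[sheet["role"] == "parent2", "path"].iloc[0]
    progeny = sheet.loc[sheet["role"] == "progeny"]

    parent_cols = {
        "P1": load_pileup(p1_path, min_qual=config.min_qual),
        "P2": load_pileup(p2_path, min_qual=config.min_qual),
    }
    progeny_cols: dict[str, dict] = {
        row.sample_id: load_pileup(row.path, min_qual=config.min_qual)
        for row in progeny.itertuples()
    }
    loci = sorted({locus for cols in progeny_cols.values() for locus in cols})

    cand_rows, marker_rows, geno_rows = [], [], []
    depth_ids, depth_vals = [], []
    for locus in loci:
        merged = merge_columns([cols.get(locus) for cols in progeny_cols.values()])
        if merged is None:
            continue
        depth_ids.append(f"{merged.name}:{merged.pos}")
        depth_vals.append(merged.depth)
        cand = screen_single_dose(merged, window=config.window,
                                  min_total_depth=config.min_merged_depth,
                                  third_allele_frac=config.third_allele_frac)
        if cand is None:
            continue
        cand.parent = assign_parent(cand, parent_cols["P1"].get(locus),
                                    parent_cols["P2"].get(locus),
                                    window=config.window,
                                    error_frac=config.parent_error_frac,
                                    min_depth=config.min_depth)
        cand_rows.append({"marker_id": cand.marker_id, "name": cand.name,
                          "pos": cand.pos, "major": cand.major, "minor": cand.minor,
                          "ratio": cand.ratio, "depth": cand.depth,
                          "parent": cand.parent})
        if cand.parent == "ambiguous":
            continue
        calls = genotype_progeny(cand, {s: progeny_cols[s].get(locus) for s in progeny_cols},
                                 min_minor_reads=config.min_minor_reads,
                                 min_depth=config.min_depth)
        marker_rows.append(cand_rows[-1])
        geno_rows.append(calls)

    candidates = pd.DataFrame(cand_rows, columns=["marker_id", "name", "pos", "major",
                                                  "minor", "ratio", "depth", "parent"])
    markers = pd.DataFrame(marker_rows, columns=candidates.columns)
    genotypes = pd.DataFrame(geno_rows, index=markers["marker_id"] if marker_rows else None,
                             dtype=np.int8)
    if marker_rows:
        genotypes = genotypes[list(progeny_cols)]
        markers = markers.set_index("marker_id")
    merged_depth = pd.Series(depth_vals, index=depth_ids, dtype=int, name="merged_depth")
    return CallResult(candidates=candidates, markers=markers, genotypes=genotypes,
                      merged_depth=merged_depth)
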