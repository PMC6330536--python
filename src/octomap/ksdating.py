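"""Ortholog pairing, codon alignment, Nei-Gojobori Ks and divergence dating.

Pipeline: pair coding sequences between two species by reciprocal best
hit (RBH) on translated global alignment score, drop pairs covering less
than half of the reference ortholog, align the proteins and back-translate
to a gap-free codon alignment, count synonymous sites and differences with
the Nei-Gojobori (1986) pathway-averaging method, apply the Jukes-Cantor
multiple-hit correction, and date the species split from the median Ks
under a molecular clock::

    T_div = median Ks / (2 * rate)

with the grass synonymous substitution rate 6.5e-9 per site per year as
the default clock.

Synonymous site and difference counting uses the standard nuclear code.
Per codon, the synonymous site count is the number of synonymous one-step
changes divided by 3, averaged over the two sequences; differences between
codons are resolved by equal-weight averaging over all minimal mutational
pathways that avoid stop codons.  Counts are kept as exact rationals
internally and only converted to float in the final estimate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import log
from statistics import median_low

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

__all__ = [
    "CodonAlignment",
    "KsEstimate",
    "OrthologPair",
    "DivergenceEstimate",
    "SaturationError",
    "GRASS_RATE",
    "STOP_CODONS",
    "SENSE_CODONS",
    "codon_aa",
    "synonymous_sites",
    "synonymous_neighbors",
    "pathway_differences",
    "translate_cds",
    "codon_align",
    "nei_gojobori_ks",
    "reciprocal_best_hits",
    "length_filter",
    "divergence_time",
    "ks_pipeline",
    "read_cds_fasta",
]

GRASS_RATE = 6.5e-9  # synonymous substitutions per site per year

_TABLE = unambiguous_dna_by_id[1]
_BASES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))


class SaturationError(ValueError):
    """Raised when ps >= 3/4 and the Jukes-Cantor correction diverges."""


def codon_aa(codon: str) -> str:
    """Amino acid for a codon under the standard code; ``*`` for stops."""
    return "*" if codon in STOP_CODONS else _TABLE.forward_table[codon]


def _one_step_neighbors(codon: str):
    for pos in range(3):
        for base in _BASES:
            if base != codon[pos]:
                yield pos, base, codon[:pos] + base + codon[pos + 1:]


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> Fraction:
    """Synonymous site count of a sense codon (Fraction of 0..3).

    Number of the nine one-step changes that preserve the amino acid,
    divided by 3.  Changes into stop codons never preserve the amino acid
    so they count as nonsynonymous opportunity; TTT scores 1/3 (only
    TTT -> TTC is silent).
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site count")
    aa = codon_aa(codon)
    silent = sum(1 for _, _, nb in _one_step_neighbors(codon)
                 if nb not in STOP_CODONS and codon_aa(nb) == aa)
    return Fraction(silent, 3)


@lru_cache(maxsize=None)
def synonymous_neighbors(codon: str) -> tuple[tuple[int, str], ...]:
    """(position, base) one-step changes of ``codon`` that are silent."""
    aa = codon_aa(codon)
    return tuple((pos, base) for pos, base, nb in _one_step_neighbors(codon)
                 if nb not in STOP_CODONS and codon_aa(nb) == aa)


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[Fraction, Fraction]:
    """Pathway-averaged (synonymous, nonsynonymous) differences of a codon pair.

    Every minimal mutational pathway (one permutation of the differing
    positions) is walked; pathways passing through a stop codon are
    discarded and the step classifications of the survivors are averaged
    with equal weight.  Exact rationals, so a two-difference pair can
    score e.g. (1/2, 3/2).
    """
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        raise ValueError("stop codons are not comparable")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return Fraction(0), Fraction(0)
    per_path: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = codon_a
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != codon_b:
                ok = False
                break
            if codon_aa(cur) == codon_aa(nxt):
                syn += 1
            else:
                non += 1
            cur = nxt
        (per_path if ok else blocked).append((syn, non))
    paths = per_path or blocked  # fall back if every pathway hits a stop
    k = len(paths)
    sd = Fraction(sum(s for s, _ in paths), k)
    nd = Fraction(sum(n for _, n in paths), k)
    return sd, nd


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free codon columns of an aligned CDS pair."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon columns must pair up")

    def __len__(self) -> int:
        return len(self.codons_a)


@dataclass(frozen=True)
class KsEstimate:
    """Nei-Gojobori synonymous divergence of one codon alignment."""

    n_codons: int
    syn_sites: float       # S, averaged over the two sequences
    syn_diffs: float       # sd, pathway-averaged
    ps: float              # sd / S
    ks: float              # Jukes-Cantor corrected


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS; reject frame or internal-stop violations."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon {i}")
    return str(Seq("".join(codons)).translate())


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def codon_align(cds_a: str, cds_b: str, aligner: PairwiseAligner | None = None) -> CodonAlignment:
    """Codon alignment of two CDS via global protein alignment.

    The proteins are aligned, the alignment is back-translated codon-wise,
    and every column containing a gap is removed.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    prot_a, prot_b = translate_cds(cds_a), translate_cds(cds_b)
    aligner = aligner or _protein_aligner()
    aln = aligner.align(prot_a, prot_b)[0]
    cols_a: list[str] = []
    cols_b: list[str] = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            cols_a.append(cds_a[3 * i:3 * i + 3])
            cols_b.append(cds_b[3 * j:3 * j + 3])
    if not cols_a:
        raise ValueError("alignment empty after gap-column removal")
    return CodonAlignment(tuple(cols_a), tuple(cols_b))


def nei_gojobori_ks(aln: CodonAlignment) -> KsEstimate:
    """Nei-Gojobori Ks with Jukes-Cantor correction for one codon alignment.

    ``S`` is the synonymous site total averaged over the two sequences,
    ``sd`` the pathway-averaged synonymous difference total,
    ``ps = sd/S`` and ``Ks = -(3/4) ln(1 - (4/3) ps)``.

    Raises :class:`SaturationError` when ``ps >= 3/4`` and ``ValueError``
    when no synonymous sites exist.
    """
    if len(aln) == 0:
        raise ValueError("empty codon alignment")
    s_a = sum((synonymous_sites(c) for c in aln.codons_a), Fraction(0))
    s_b = sum((synonymous_sites(c) for c in aln.codons_b), Fraction(0))
    s_sites = (s_a + s_b) / 2
    if s_sites == 0:
        raise ValueError("no synonymous sites in alignment")
    sd = sum((pathway_differences(a, b)[0] for a, b in zip(aln.codons_a, aln.codons_b)),
             Fraction(0))
    ps = sd / s_sites
    if ps >= Fraction(3, 4):
        raise SaturationError(f"ps = {float(ps):.3f} >= 0.75: Ks undefined (saturated)")
    ks = -0.75 * log(1.0 - float(ps) * 4.0 / 3.0) + 0.0  # normalise -0.0
    return KsEstimate(n_codons=len(aln), syn_sites=float(s_sites),
                      syn_diffs=float(sd), ps=float(ps), ks=ks)


@dataclass
class OrthologPair:
    """A reciprocal-best-hit CDS pair, with alignment bookkeeping."""

    id_a: str
    id_b: str
    score: float
    n_codons_matched: int | None = None
    coverage: float | None = None  # matched length / reference (B) length


def _valid_cds(seqs: dict[str, str], min_codons: int, label: str) -> dict[str, str]:
    kept = {}
    for name, cds in seqs.items():
        try:
            prot = translate_cds(cds)
        except ValueError as exc:
            warnings.warn(f"{label}:{name} excluded: {exc}")
            continue
        if len(prot) < min_codons:
            continue
        kept[name] = cds
    return kept


def reciprocal_best_hits(seqs_a: dict[str, str], seqs_b: dict[str, str],
                         min_codons: int = 30,
                         aligner: PairwiseAligner | None = None) -> list[OrthologPair]:
    """Reciprocal best hits between two CDS collections.

    Best hit by translated global alignment score (BLOSUM62, affine gaps);
    a pair is kept iff each member is the unique best hit of the other.
    Score ties drop the query (a tied best hit is not an ortholog call).
    """
    aligner = aligner or _protein_aligner()
    seqs_a = _valid_cds(seqs_a, min_codons, "A")
    seqs_b = _valid_cds(seqs_b, min_codons, "B")
    if not seqs_a or not seqs_b:
        return []
    prot_a = {k: translate_cds(v) for k, v in seqs_a.items()}
    prot_b = {k: translate_cds(v) for k, v in seqs_b.items()}
    scores = {(i, j): aligner.score(pa, pb)
              for i, pa in prot_a.items() for j, pb in prot_b.items()}

    def best(ids_other, fixed, key):
        vals = {j: scores[key(fixed, j)] for j in ids_other}
        top = max(vals.values())
        winners = [j for j, v in vals.items() if v == top]
        return winners[0] if len(winners) == 1 else None

    pairs = []
    for i in sorted(prot_a):
        j = best(prot_b, i, lambda a, b: (a, b))
        if j is None:
            warnings.warn(f"A:{i} dropped: tied best hit")
            continue
        back = best(prot_a, j, lambda b, a: (a, b))
        if back is None:
            warnings.warn(f"B:{j} has tied best hits; dropping pair with A:{i}")
        elif back == i:
            pairs.append(OrthologPair(id_a=i, id_b=j, score=scores[(i, j)]))
    return pairs


def length_filter(pair: OrthologPair, min_cov: float = 0.5) -> bool:
    """Keep a pair iff its matched length exceeds ``min_cov`` of the reference.

    Strict inequality: coverage of exactly 50% is dropped.
    """
    if pair.coverage is None:
        raise ValueError("pair has no coverage: align it first")
    return pair.coverage > min_cov


@dataclass(frozen=True)
class DivergenceEstimate:
    """Median-Ks divergence date."""

    median_ks: float
    n_pairs: int
    rate: float
    years: float

    @property
    def mya(self) -> float:
        return self.years / 1e6


def divergence_time(ks_values, rate: float = GRASS_RATE) -> DivergenceEstimate:
    """Date a species split from a collection of per-pair Ks values.

    ``T = median(Ks) / (2 * rate)`` years; the median uses the lower-median
    convention for even counts.
    """
    values = [float(v) for v in ks_values]
    if not values:
        raise ValueError("no Ks values")
    if rate <= 0:
        raise ValueError("rate must be positive")
    med = median_low(sorted(values))
    return DivergenceEstimate(median_ks=med, n_pairs=len(values), rate=rate,
                              years=med / (2.0 * rate))


def read_cds_fasta(path) -> dict[str, str]:
    """Load a CDS FASTA into an id -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def ks_pipeline(seqs_a: dict[str, str], seqs_b: dict[str, str],
                rate: float = GRASS_RATE, min_cov: float = 0.5,
                min_codons: int = 30) -> tuple[pd.DataFrame, DivergenceEstimate]:
    """RBH pairing -> length filter -> codon alignment -> Ks -> dating.

    Species B is treated as the reference side for the coverage filter.
    Returns the per-pair table (id_a, id_b, n_codons, S, sd, ps, ks,
    coverage) and the median-Ks divergence estimate.  Saturated pairs are
    excluded from dating but listed with ``ks = NaN``.
    """
    aligner = _protein_aligner()
    rows = []
    finite = []
    for pair in reciprocal_best_hits(seqs_a, seqs_b, min_codons=min_codons, aligner=aligner):
        aln = codon_align(seqs_a[pair.id_a], seqs_b[pair.id_b], aligner=aligner)
        pair.n_codons_matched = len(aln)
        pair.coverage = len(aln) / (len(seqs_b[pair.id_b]) // 3)
        if not length_filter(pair, min_cov=min_cov):
            continue
        try:
            est = nei_gojobori_ks(aln)
            ks = est.ks
            finite.append(ks)
        except SaturationError:
            est = None
            ks = float("nan")
        rows.append({
            "id_a": pair.id_a, "id_b": pair.id_b,
            "n_codons": pair.n_codons_matched, "coverage": pair.coverage,
            "S": est.syn_sites if est else float("nan"),
            "sd": est.syn_diffs if est else float("nan"),
            "ps": est.ps if est else float("nan"),
            "ks": ks,
        })
    table = pd.DataFrame(rows, columns=["id_a", "id_b", "n_codons", "coverage",
                                        "S", "sd", "ps", "ks"])
    est = divergence_time(finite, rate=rate) if finite else None
    return table, est
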