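"""Allele-dosage combinatorics for autopolyploid crosses.

An autopolyploid with ``2m`` homologous chromosomes (ploidy ``2m``; the
octoploid case is ``2n = 8x``, m = 4) transmits a random half of its
homologs to each gamete.  A locus where one parent carries a variant
allele on ``d`` of its homologs ("dose d": simplex d=1, duplex d=2, ...)
and the other parent carries none therefore segregates in the F1 like a
backcross marker whose presence fraction is fixed by the hypergeometric
probability that the gamete samples at least one carrier homolog.

This module gives the closed forms for those segregation fractions, the
pooled minor-allele read fraction expected when sequence from the whole
F1 family is merged, and the read-depth/detection-probability arithmetic
used to pick minimum coverage thresholds for single-dose SNP discovery.

All probabilities are computed with exact rational binomial coefficients
before conversion to float, so values such as 3/14 or 1/70 are exact to
the last bit.

The model assumes pure random chromosome segregation: no double
reduction and no preferential pairing, which is the appropriate model
for a recent autopolyploid whose homologs pair at random.
"""

from __future__ import annotations

import math
from fractions import Fraction
from math import comb

import pandas as pd

__all__ = [
    "gamete_absence_prob",
    "gamete_absence_fraction",
    "f1_presence_fraction",
    "pooled_minor_fraction",
    "pooled_minor_odds",
    "detection_prob",
    "min_depth",
    "segregation_table",
]


def _check_ploidy(ploidy: int) -> int:
    if not isinstance(ploidy, int) or ploidy < 2 or ploidy % 2:
        raise ValueError(f"ploidy must be an even integer >= 2, got {ploidy!r}")
    return ploidy // 2


def _check_dose(dose: int, ploidy: int) -> None:
    if not isinstance(dose, int) or not 0 <= dose <= ploidy:
        raise ValueError(f"dose must be an integer in 0..{ploidy}, got {dose!r}")


def gamete_absence_fraction(dose: int, ploidy: int = 8) -> Fraction:
    """Exact probability that a gamete carries zero copies of a dose-``d`` allele.

    Under random chromosome segregation a gamete receives ``m = ploidy/2``
    homologs drawn without replacement from the ``ploidy`` homologs, so the
    zero-copy probability is the hypergeometric term::

        C(ploidy - dose, m) / C(ploidy, m)

    Returns a :class:`fractions.Fraction` (e.g. ``Fraction(3, 14)`` for a
    duplex allele in an octoploid).
    """
    m = _check_ploidy(ploidy)
    _check_dose(dose, ploidy)
    if dose > ploidy - m:
        return Fraction(0)
    return Fraction(comb(ploidy - dose, m), comb(ploidy, m))


def gamete_absence_prob(dose: int, ploidy: int = 8) -> float:
    """Float version of :func:`gamete_absence_fraction`.

    For an octoploid this yields 1/2, 3/14, 1/14 and 1/70 for doses 1-4:
    the classical simplex/duplex/triplex/quadruplex absence fractions.
    """
    return float(gamete_absence_fraction(dose, ploidy))


def f1_presence_fraction(dose: int, ploidy: int = 8) -> float:
    """Expected fraction of F1 progeny showing a dose-``d`` allele.

    Assumes the allele is present at dose ``d`` in exactly one parent and
    absent (nulliplex) in the other, so presence in a progeny is presence
    in the carrier parent's gamete.  A simplex allele in an octoploid
    segregates 1:1 (presence fraction 0.5).
    """
    return float(1 - gamete_absence_fraction(dose, ploidy))


def pooled_minor_fraction(dose_p1: int, dose_p2: int, ploidy: int = 8) -> float:
    """Expected minor-allele read fraction in a balanced pooled F1 family.

    Merging reads across a large, balanced F1 family samples the two
    parents' ``2 * ploidy`` haplotypes uniformly, so the minor-allele
    fraction is ``(dose_p1 + dose_p2) / (2 * ploidy)``: 1/16 (odds 1:15)
    for a simplex site in an octoploid cross.
    """
    _check_ploidy(ploidy)
    _check_dose(dose_p1, ploidy)
    _check_dose(dose_p2, ploidy)
    return float(Fraction(dose_p1 + dose_p2, 2 * ploidy))


def pooled_minor_odds(dose_p1: int, dose_p2: int, ploidy: int = 8) -> float:
    """Major-allele copies per minor-allele copy in the pooled family.

    The denominator-normalised odds ``major : minor = x : 1``; returns
    ``x`` (15.0 for a simplex site in an octoploid cross).
    """
    total = dose_p1 + dose_p2
    if total == 0:
        raise ValueError("no minor-allele copies: odds undefined")
    _check_ploidy(ploidy)
    _check_dose(dose_p1, ploidy)
    _check_dose(dose_p2, ploidy)
    return float(Fraction(2 * ploidy - total, total))


def detection_prob(p: float, n: int) -> float:
    """Probability that ``n`` reads sample a per-read-probability-``p`` allele.

    ``P = 1 - (1 - p)**n``: at least one read carries the allele.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p!r}")
    if n < 0 or int(n) != n:
        raise ValueError(f"n must be a non-negative integer, got {n!r}")
    return 1.0 - (1.0 - p) ** int(n)


def min_depth(p: float, certainty: float) -> int:
    """Smallest read depth detecting a fraction-``p`` allele with ``certainty``.

    Returns the least integer ``n`` with ``1 - (1-p)**n >= certainty``,
    i.e. ``ceil(log(1-certainty) / log(1-p))`` with an explicit boundary
    check against floating-point slop.  For the pooled simplex fraction
    p = 1/16 at 99% certainty this is 72 reads.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p!r}")
    if not 0 < certainty < 1:
        raise ValueError(f"certainty must be in (0, 1), got {certainty!r}")
    n = max(1, math.ceil(math.log(1.0 - certainty) / math.log(1.0 - p)))
    while detection_prob(p, n) < certainty:
        n += 1
    while n > 1 and detection_prob(p, n - 1) >= certainty:
        n -= 1
    return n


def segregation_table(ploidy: int = 8, certainties: tuple[float, ...] = (0.95, 0.99)) -> pd.DataFrame:
    """Segregation summary per dose class for a one-parent-carrier locus.

    One row per dose 0..ploidy with the gamete absence fraction, the
    presence:absence odds and, for doses with a nonzero pooled fraction,
    the minimum merged read depth reaching each requested certainty.
    """
    m = _check_ploidy(ploidy)
    rows = []
    for dose in range(ploidy + 1):
        absent = gamete_absence_fraction(dose, ploidy)
        present = 1 - absent
        if 0 < absent < 1:
            ratio = present / absent
            odds = f"{ratio.numerator}:{ratio.denominator}"
        else:
            odds = "0:1" if absent == 1 else "1:0"
        row = {
            "dose": dose,
            "absence_fraction": float(absent),
            "presence_to_absence": odds,
        }
        pooled = Fraction(dose, 2 * ploidy)
        for c in certainties:
            key = f"min_depth_{c:g}"
            row[key] = min_depth(float(pooled), c) if 0 < pooled < 1 else None
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["ploidy"] = ploidy
    table.attrs["gamete_size"] = m
    return table
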