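"""Nei-Gojobori counting vs an exact enumeration oracle; RBH, alignment, dating."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from octomap import ksdating as ks
from octomap import simulate

# ---------------------------------------------------------------------------
# independent oracle: recursive enumeration of minimal mutational pathways
# with exact rational arithmetic
# ---------------------------------------------------------------------------

_AA = {c: ks.codon_aa(c) for c in
       ("".join(t) for t in itertools.product("ACGT", repeat=3))}
_STOPS = {c for c, a in _AA.items() if a == "*"}


def oracle_site_count(codon: str) -> Fraction:
    silent = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            nb = codon[:pos] + base + codon[pos + 1:]
            if nb not in _STOPS and _AA[nb] == _AA[codon]:
                silent += 1
    return Fraction(silent, 3)


def _oracle_paths(cur: str, target: str, avoid_stops: bool):
    if cur == target:
        return [[]]
    out = []
    for pos in range(3):
        if cur[pos] == target[pos]:
            continue
        nxt = cur[:pos] + target[pos] + cur[pos + 1:]
        if avoid_stops and nxt in _STOPS and nxt != target:
            continue
        for rest in _oracle_paths(nxt, target, avoid_stops):
            out.append([(cur, nxt)] + rest)
    return out


def oracle_differences(a: str, b: str) -> tuple[Fraction, Fraction]:
    paths = _oracle_paths(a, b, avoid_stops=True) or \
        _oracle_paths(a, b, avoid_stops=False)
    sd = Fraction(sum(sum(1 for x, y in p if _AA[x] == _AA[y]) for p in paths),
                  len(paths))
    total = len([i for i in range(3) if a[i] != b[i]])
    return sd, total - sd


# ---------------------------------------------------------------------------


class TestSiteCounts:
    def test_ttt_scores_one_third(self):
        assert ks.synonymous_sites("TTT") == Fraction(1, 3)

    def test_fourfold_family_scores_one(self):
        for codon in ("GGT", "GCA", "CCG", "GTC"):
            assert ks.synonymous_sites(codon) == 1

    def test_all_sense_codons_match_oracle(self):
        for codon in ks.SENSE_CODONS:
            assert ks.synonymous_sites(codon) == oracle_site_count(codon)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ks.synonymous_sites("TAA")


class TestPathwayDifferences:
    def test_identical_codons(self):
        assert ks.pathway_differences("ATG", "ATG") == (0, 0)

    def test_single_silent_difference(self):
        sd, nd = ks.pathway_differences("GGT", "GGC")
        assert (sd, nd) == (1, 0)

    def test_two_difference_pathway_average(self):
        # TTT (Phe) vs GTA (Val): paths via GTT (Val) and TTA (Leu)
        sd, nd = ks.pathway_differences("TTT", "GTA")
        osd, ond = oracle_differences("TTT", "GTA")
        assert (sd, nd) == (osd, ond)
        assert sd + nd == 2

    def test_random_codon_pairs_match_oracle(self):
        rng = np.random.default_rng(3)
        codons = list(ks.SENSE_CODONS)
        for _ in range(300):
            a, b = (codons[i] for i in rng.integers(0, len(codons), 2))
            assert ks.pathway_differences(a, b)[0] == oracle_differences(a, b)[0]


class TestNeiGojobori:
    def test_identical_sequences_give_zero(self):
        aln = ks.CodonAlignment(("ATG", "GGT"), ("ATG", "GGT"))
        assert ks.nei_gojobori_ks(aln).ks == 0.0

    def test_worked_six_codon_example(self):
        aln = ks.CodonAlignment(tuple(["GGT"] * 6), tuple(["GGT"] * 5 + ["GGC"]))
        est = ks.nei_gojobori_ks(aln)
        assert est.syn_sites == 6.0
        assert est.syn_diffs == 1.0
        assert est.ps == pytest.approx(1 / 6)
        assert est.ks == pytest.approx(0.1885, abs=5e-4)

    def test_random_alignments_match_oracle(self):
        """Aggregated S and sd of 20-codon alignments equal the oracle sums."""
        rng = np.random.default_rng(9)
        codons = list(ks.SENSE_CODONS)
        for _ in range(100):
            a = [codons[i] for i in rng.integers(0, len(codons), 20)]
            # moderate divergence: resample ~20% of codons, keep ps < 3/4
            b = [codons[rng.integers(0, len(codons))] if rng.random() < 0.2 else c
                 for c in a]
            s = sum((oracle_site_count(c) for c in a), Fraction(0)) + \
                sum((oracle_site_count(c) for c in b), Fraction(0))
            sd = sum((oracle_differences(x, y)[0] for x, y in zip(a, b)), Fraction(0))
            est = ks.nei_gojobori_ks(ks.CodonAlignment(tuple(a), tuple(b)))
            assert est.syn_sites == float(s / 2)
            assert est.syn_diffs == float(sd)

    def test_monotone_in_ps(self):
        base = ["GGT"] * 40
        kss = []
        for ndiff in range(0, 8):
            other = ["GGC"] * ndiff + ["GGT"] * (40 - ndiff)
            kss.append(ks.nei_gojobori_ks(
                ks.CodonAlignment(tuple(base), tuple(other))).ks)
        assert all(a < b for a, b in zip(kss, kss[1:]))

    def test_saturation_raises(self):
        # every codon differs by a silent third-position change: ps = 40/40
        aln = ks.CodonAlignment(tuple(["GGT"] * 40), tuple(["GGC"] * 40))
        with pytest.raises(ks.SaturationError):
            ks.nei_gojobori_ks(aln)


class TestAlignment:
    def test_identical_cds_align_fully(self):
        rng = np.random.default_rng(5)
        cds = simulate.random_cds(rng, 50)
        aln = ks.codon_align(cds, cds)
        assert len(aln) == 50
        assert aln.codons_a == aln.codons_b

    def test_internal_deletion_drops_gap_columns(self):
        rng = np.random.default_rng(6)
        cds = simulate.random_cds(rng, 50)
        deleted = cds[:60] + cds[63:]
        aln = ks.codon_align(cds, deleted)
        assert len(aln) == 49

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            ks.translate_cds("ATGGG")
        with pytest.raises(ValueError):
            ks.translate_cds("ATGTAAGGG")  # internal stop


class TestRBH:
    def _families(self):
        rng = np.random.default_rng(7)
        base = {f"fam{i}": simulate.random_cds(rng, 60) for i in range(4)}
        a = {f"A{i}": seq for i, seq in enumerate(base.values())}
        b = {f"B{i}": simulate.evolve_synonymous(seq, 0.05, rng)
             for i, seq in enumerate(base.values())}
        return a, b

    def test_mutual_best_pairs_found(self):
        a, b = self._families()
        pairs = ks.reciprocal_best_hits(a, b)
        assert sorted((p.id_a, p.id_b) for p in pairs) == \
            [(f"A{i}", f"B{i}") for i in range(4)]

    def test_duplicate_queries_tie_and_drop(self):
        a, b = self._families()
        a["A0dup"] = a["A0"]
        with pytest.warns(UserWarning, match="tied"):
            pairs = ks.reciprocal_best_hits(a, b)
        ids = {p.id_a for p in pairs}
        assert "A0" not in ids and "A0dup" not in ids

    def test_invalid_sequences_excluded(self):
        a, b = self._families()
        a["bad"] = a["A0"][:-1]  # frame violation
        with pytest.warns(UserWarning, match="excluded"):
            pairs = ks.reciprocal_best_hits(a, b)
        assert all(p.id_a != "bad" for p in pairs)


class TestLengthFilter:
    @pytest.mark.parametrize("cov,keep", [(0.51, True), (0.50, False), (1.0, True)])
    def test_strict_boundary(self, cov, keep):
        pair = ks.OrthologPair(id_a="a", id_b="b", score=1.0, coverage=cov)
        assert ks.length_filter(pair) is keep

    def test_unaligned_pair_rejected(self):
        with pytest.raises(ValueError):
            ks.length_filter(ks.OrthologPair(id_a="a", id_b="b", score=1.0))


class TestDating:
    @pytest.mark.parametrize("med,mya", [(0.010, 0.769), (0.009, 0.692),
                                         (0.087, 6.692), (0.106, 8.154)])
    def test_clock_formula(self, med, mya):
        assert round(ks.divergence_time([med]).mya, 3) == mya

    def test_zero_and_empty(self):
        assert ks.divergence_time([0.0]).years == 0.0
        with pytest.raises(ValueError):
            ks.divergence_time([])

    def test_lower_median_convention(self):
        est = ks.divergence_time([0.01, 0.02, 0.03, 0.04])
        assert est.median_ks == 0.02

    def test_linear_in_median(self):
        a = ks.divergence_time([0.01]).years
        b = ks.divergence_time([0.03]).years
        assert b == pytest.approx(3 * a)


def test_pipeline_end_to_end_dating():
    """Two synthetic species diverged at a known Ks are dated consistently."""
    rng = np.random.default_rng(12)
    ancestors = {f"g{i}": simulate.random_cds(rng, 120) for i in range(12)}
    a = {f"A{i}": simulate.evolve_synonymous(seq, 0.05, rng)
         for i, seq in enumerate(ancestors.values())}
    b = {f"B{i}": simulate.evolve_synonymous(seq, 0.05, rng)
         for i, seq in enumerate(ancestors.values())}
    table, est = ks.ks_pipeline(a, b)
    assert len(table) == 12
    assert est.n_pairs == 12
    assert est.median_ks == pytest.approx(0.10, rel=0.5)
    assert est.years == pytest.approx(est.median_ks / 1.3e-8)
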