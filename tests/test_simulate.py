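"""Simulator: determinism, segregation statistics, meiosis and rearrangements."""

import hashlib
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from octomap import dosage, simulate


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(root).rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def test_byte_identical_under_seed(tmp_path):
    cfg = simulate.SimConfig(seed=5, n_progeny=8, n_genes=80, snps_per_gene=1.5)
    simulate.simulate_dataset(cfg, tmp_path / "a")
    simulate.simulate_dataset(cfg, tmp_path / "b")
    assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")
    other = simulate.SimConfig(seed=6, n_progeny=8, n_genes=80, snps_per_gene=1.5)
    simulate.simulate_dataset(other, tmp_path / "c")
    assert _tree_digest(tmp_path / "a") != _tree_digest(tmp_path / "c")


class TestReference:
    def test_layout(self):
        cfg = simulate.SimConfig(seed=1, n_genes=100)
        ref = simulate.build_reference(cfg)
        assert len(ref.genes) == 100
        assert len(ref.chromosomes) == 10
        for chrom, length in ref.chromosomes:
            genes = ref.genes_on(chrom)
            for g in genes:
                assert 0 <= g.start < g.end <= length
                assert len(g.cds) % 3 == 0
                assert (g.end - g.start) == len(g.cds)
            for a, b in zip(genes, genes[1:]):
                assert a.end <= b.start

    def test_different_seed_different_layout(self):
        a = simulate.build_reference(simulate.SimConfig(seed=1, n_genes=100))
        b = simulate.build_reference(simulate.SimConfig(seed=2, n_genes=100))
        assert [g.start for g in a.genes] != [g.start for g in b.genes]

    def test_infeasible_packing_and_empty(self):
        with pytest.raises(ValueError):
            simulate.build_reference(simulate.SimConfig(seed=1, n_genes=0))
        with pytest.raises(ValueError):
            simulate.build_reference(
                simulate.SimConfig(seed=1, n_genes=10_000, bp_per_chromosome=100_000))


class TestVariants:
    def test_dose_mixture_recovered(self):
        cfg = simulate.SimConfig(seed=3, n_genes=1200, snps_per_gene=8.0)
        rng = cfg.rng()
        ref = simulate.build_reference(cfg, rng)
        _, _, sites = simulate.spike_variants(ref, cfg, rng)
        assert len(sites) > 9000
        frac1 = (sites["dose"] == 1).mean()
        se = math.sqrt(0.7 * 0.3 / len(sites))
        assert abs(frac1 - 0.70) <= 3 * se

    def test_degenerate_mixture_and_carrier_counts(self):
        cfg = simulate.SimConfig(seed=4, n_genes=100, snps_per_gene=2.0,
                                 dosage_mixture=(1.0, 0.0, 0.0, 0.0))
        rng = cfg.rng()
        ref = simulate.build_reference(cfg, rng)
        _, _, sites = simulate.spike_variants(ref, cfg, rng)
        assert (sites["dose"] == 1).all()
        assert all(len(c) == 1 for c in sites["carriers"])
        assert all(a != r for a, r in zip(sites["alt"], sites["ref"]))

    def test_sites_split_between_parents(self):
        cfg = simulate.SimConfig(seed=5, n_genes=300, snps_per_gene=3.0)
        rng = cfg.rng()
        ref = simulate.build_reference(cfg, rng)
        p1, p2, sites = simulate.spike_variants(ref, cfg, rng)
        assert len(p1.sites) + len(p2.sites) == len(sites)
        assert set(sites["parent"]) == {"P1", "P2"}


class TestMeiosis:
    @pytest.fixture(scope="class")
    def big_truth(self):
        cfg = simulate.SimConfig(seed=21, n_progeny=30, n_genes=700,
                                 snps_per_gene=8.0)
        rng = cfg.rng()
        ref = simulate.build_reference(cfg, rng)
        karyo = simulate.Karyotype.from_reference(ref, cfg.chrom_length_cm)
        p1, p2, _ = simulate.spike_variants(ref, cfg, rng)
        return simulate.simulate_progeny(p1, p2, cfg, karyo, rng)

    def test_presence_fractions_chi_square(self, big_truth):
        """Goodness of fit of simulated segregation per dose class (alpha 0.001)."""
        sites = big_truth.sites
        assert len(sites) >= 5000
        present = big_truth.copies > 0
        for dose in (1, 2, 3, 4):
            mask = (sites["dose"] == dose).to_numpy()
            obs = present[mask]
            p = dosage.f1_presence_fraction(dose, big_truth.config.ploidy)
            observed = np.array([obs.sum(), obs.size - obs.sum()])
            _, pval = stats.chisquare(observed, [obs.size * p, obs.size * (1 - p)])
            assert pval >= 0.001, f"dose {dose}: p={pval:.2e}"

    def test_same_gene_markers_fully_linked(self, big_truth):
        """Markers 0 cM apart on the same homolog share a presence vector."""
        sites = big_truth.sites
        seen = {}
        checked = 0
        for i, row in sites.iterrows():
            if row["dose"] != 1:
                continue
            key = (row["gene_id"], row["parent"], row["homolog"])
            if key in seen:
                assert (big_truth.copies[seen[key]] > 0).tolist() == \
                    (big_truth.copies[i] > 0).tolist()
                checked += 1
            else:
                seen[key] = i
        assert checked > 50

    @pytest.mark.parametrize("d", [5.0, 20.0])
    def test_recombination_fraction_matches_model(self, d, gamete_presence):
        """rf at 5 and 20 cM approaches the interference-free expectation.

        Crossovers are Poisson along the bivalent, so the generative
        expectation is Haldane's r(d) = (1 - exp(-2d/100)) / 2.
        """
        rng = np.random.default_rng(int(d * 101))
        pres = gamete_presence(rng, 8, 100.0, [40.0, 40.0 + d], 4000)
        rf = (pres[0] != pres[1]).mean()
        expected = 0.5 * (1.0 - math.exp(-2 * d / 100.0))
        se = math.sqrt(expected * (1 - expected) / pres.shape[1])
        assert abs(rf - expected) <= 4 * se


class TestPileups:
    def test_pooled_fraction_and_dialect(self, midcross, midcross_truth):
        """Merged progeny alt fraction at simplex sites sits at ~1/16."""
        calls = midcross.calls
        sites = midcross_truth.sites.set_index("site_id")
        cand = calls.candidates.set_index("marker_id")
        shared = cand.index.intersection(sites.index[sites["dose"] == 1])
        ratios = cand.loc[shared, "ratio"]
        fracs = ratios / (1 + ratios)  # minor/(minor+major)
        se = fracs.std(ddof=1) / math.sqrt(len(fracs))
        assert len(fracs) > 100
        assert abs(fracs.mean() - 1 / 16) <= 3 * se + 0.002

    def test_error_free_noncarriers_have_zero_alt(self, tmp_path):
        from octomap import pileup

        cfg = simulate.SimConfig(seed=8, n_progeny=6, n_genes=60, snps_per_gene=2.0,
                                 base_error_rate=0.0, quality_levels=((40, 1.0),))
        ds = simulate.simulate_dataset(cfg, tmp_path)
        sites = ds.truth.sites.set_index("site_id")
        presence = ds.truth.presence_frame()
        for j, name in enumerate(ds.truth.progeny):
            cols = pileup.load_pileup(ds.pileups[name])
            for (gene, pos), col in cols.items():
                sid = f"{gene}:{pos}"
                row = sites.loc[sid]
                if not presence.loc[sid, name]:
                    assert col.counts[row["alt"]] == 0


class TestRearrangements:
    @pytest.fixture(scope="class")
    def ref_and_plan(self):
        cfg = simulate.SimConfig(seed=9, n_genes=300)
        rng = cfg.rng()
        ref = simulate.build_reference(cfg, rng)
        plan = simulate.random_rearrangement_plan(ref, rng, n_shared=2,
                                                  n_private_a=1, block_genes=5)
        return ref, plan

    def test_event_bookkeeping(self, ref_and_plan):
        ref, plan = ref_and_plan
        base = simulate.Karyotype.from_reference(ref)
        ka, kb, applied = simulate.inject_rearrangements(base, base, plan)
        assert len(applied["A"]) == 3
        assert len(applied["B"]) == 2
        assert sum(ev.shared for ev in applied["A"]) == 2
        for karyo in (ka, kb):
            all_ids = [g for ids in karyo.order.values() for g in ids]
            assert sorted(all_ids) == sorted(g.gene_id for g in ref.genes)

    def test_moved_genes_change_chromosome_not_anchor(self, ref_and_plan):
        ref, plan = ref_and_plan
        base = simulate.Karyotype.from_reference(ref)
        ka, _, applied = simulate.inject_rearrangements(base, base, plan)
        for ev in applied["A"]:
            moved = base.order[ev.source_chrom][ev.start:ev.stop]
            for gid in moved:
                assert ka.chrom_of(gid) == ev.target_chrom
                assert ref.gene(gid).chrom == ev.source_chrom  # anchor unchanged

    def test_empty_plan_is_identity(self, ref_and_plan):
        ref, _ = ref_and_plan
        base = simulate.Karyotype.from_reference(ref)
        ka, kb, applied = simulate.inject_rearrangements(
            base, base, simulate.RearrangementPlan(events=()))
        assert ka.order == base.order and kb.order == base.order
        assert applied == {"A": [], "B": []}

    def test_invalid_plans_rejected(self):
        ev = dict(source_chrom="chr01", start=0, stop=4, target_chrom="chr02",
                  insert_at=0)
        with pytest.raises(ValueError):
            simulate.RearrangementPlan(events=(
                simulate.TranslocationEvent(**{**ev, "stop": 2}),))
        with pytest.raises(ValueError):
            simulate.RearrangementPlan(events=(
                simulate.TranslocationEvent(**ev),
                simulate.TranslocationEvent(**{**ev, "start": 2, "stop": 6,
                                               "target_chrom": "chr03"}),))


def test_evolve_synonymous_preserves_protein():
    from octomap import ksdating

    rng = np.random.default_rng(17)
    cds = simulate.random_cds(rng, 120)
    div = simulate.evolve_synonymous(cds, 0.2, rng)
    assert ksdating.translate_cds(div) == ksdating.translate_cds(cds)
    assert div != cds
    assert simulate.evolve_synonymous(cds, 0.0, rng) == cds
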