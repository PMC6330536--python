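"""Synthetic autooctoploid F1 cross with RNA-seq-style pileups and ground truth.

The generator emulates the data layout of a transcriptome-based mapping
experiment in an octoploid F1 cross between two heterozygous parents that
share a diploid-relative reference gene space:

* a reference model of 10 chromosomes carrying non-overlapping gene
  models with random in-frame CDS (the stand-in for a diploid relative's
  annotated gene set);
* two octoploid parents whose variant sites are assigned a dosage class
  d in 1..4 (defaults 70/20/7/3%, the observed predominance of
  single-dose SNPs) on carrier homologs drawn uniformly;
* F1 meiosis by random bivalent pairing of the 8 homologs, Poisson
  crossovers along a cM axis, and transmission of 4 recombinant
  chromatids per chromosome (random chromosome segregation, no
  preferential pairing, no double reduction);
* per-(gene, individual) sequencing depth from a negative binomial
  (RNA-seq depth acts at the gene level), binomial allele sampling of the
  carrier homolog fraction, uniform base-call errors and Phred+33
  qualities, written as 6-column mpileup-dialect text;
* optional interchromosomal translocations injected into one or two
  simulated species' gene orders, a configurable subset shared between
  them, while the anchor table keeps the ancestral (reference)
  coordinates — the signature a synteny scan must recover.

Every draw flows through one :class:`numpy.random.Generator`, so a
(seed, config) pair reproduces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import ksdating

__all__ = [
    "SimConfig",
    "Gene",
    "ReferenceModel",
    "Karyotype",
    "TranslocationEvent",
    "RearrangementPlan",
    "ParentalGenome",
    "TruthSet",
    "SimDataset",
    "build_reference",
    "spike_variants",
    "inject_rearrangements",
    "random_rearrangement_plan",
    "simulate_progeny",
    "simulate_pileups",
    "simulate_dataset",
    "gamete_sources",
    "random_cds",
    "evolve_synonymous",
    "karyotype_map_frame",
    "anchor_frame",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated cross.

    Defaults mirror the mapping experiment the generator emulates: 59 F1
    progeny of two octoploid parents over a 10-chromosome reference gene
    space, ~70% of variant sites single dose, gene-level negative-binomial
    sequencing depth with mean 40 reads per gene per progeny library and
    deeper (multi-tissue, merged) parental libraries, ~0.1% base-call
    error after upstream read filtering, and 100 cM of genetic length per
    chromosome (a grass-like chromosome map length).
    """

    seed: int = 0
    n_progeny: int = 59
    ploidy: int = 8
    n_chromosomes: int = 10
    n_genes: int = 1000
    gene_min_codons: int = 60
    gene_max_codons: int = 200
    bp_per_chromosome: int = 2_000_000
    chrom_length_cm: float = 100.0
    dosage_mixture: tuple[float, ...] = (0.70, 0.20, 0.07, 0.03)  # doses 1..4
    snps_per_gene: float = 2.5          # Poisson mean per gene
    expressed_fraction: float = 0.9     # genes detectable in the sampled tissue
    mean_depth: float = 40.0            # reads/gene/progeny library
    depth_dispersion: float = 8.0       # negative-binomial size parameter
    parent_depth_factor: float = 4.0    # parents: merged multi-tissue libraries
    base_error_rate: float = 0.001
    quality_levels: tuple[tuple[int, float], ...] = ((40, 0.98), (20, 0.02))
    haplotype_weights: tuple[float, ...] | None = None  # optional expression bias

    def __post_init__(self):
        if self.ploidy < 2 or self.ploidy % 2:
            raise ValueError("ploidy must be an even integer >= 2")
        if self.n_progeny < 2:
            raise ValueError("need at least 2 progeny")
        if self.n_genes < self.n_chromosomes:
            raise ValueError("need at least one gene per chromosome")
        if abs(sum(self.dosage_mixture) - 1.0) > 1e-9:
            raise ValueError("dosage mixture must sum to 1")
        if len(self.dosage_mixture) > self.ploidy:
            raise ValueError("dosage mixture longer than ploidy")
        if not 0 <= self.expressed_fraction <= 1:
            raise ValueError("expressed_fraction must be in [0, 1]")
        if abs(sum(p for _, p in self.quality_levels) - 1.0) > 1e-9:
            raise ValueError("quality level probabilities must sum to 1")
        if self.haplotype_weights is not None and len(self.haplotype_weights) != self.ploidy:
            raise ValueError("haplotype_weights must have one entry per homolog")

    @property
    def gamete_size(self) -> int:
        return self.ploidy // 2

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int   # 0-based half-open reference coordinates
    end: int
    strand: str
    cds: str


@dataclass
class ReferenceModel:
    """Reference gene space: chromosomes and ordered, non-overlapping genes."""

    chromosomes: list[tuple[str, int]]
    genes: list[Gene]

    def __post_init__(self):
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("gene ids not unique")

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def genes_on(self, chrom: str) -> list[Gene]:
        return sorted((g for g in self.genes if g.chrom == chrom), key=lambda g: g.start)

    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame CDS of uniform sense codons (no internal stops)."""
    idx = rng.integers(0, len(ksdating.SENSE_CODONS), size=n_codons)
    return "".join(ksdating.SENSE_CODONS[i] for i in idx)


def build_reference(cfg: SimConfig, rng: np.random.Generator | None = None) -> ReferenceModel:
    """Lay out ``cfg.n_genes`` genes over ``cfg.n_chromosomes`` chromosomes.

    Genes are placed in per-chromosome slots of equal width with random
    jitter, so intervals never overlap; raises if a gene cannot fit its
    slot (infeasible packing).
    """
    rng = cfg.rng() if rng is None else rng
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be positive")
    chroms = [(f"chr{i + 1:02d}", cfg.bp_per_chromosome) for i in range(cfg.n_chromosomes)]
    per = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per[: cfg.n_genes % cfg.n_chromosomes] += 1
    genes: list[Gene] = []
    gidx = 0
    for (name, length), count in zip(chroms, per):
        slot = length // int(count)
        if 3 * cfg.gene_max_codons > slot:
            raise ValueError("gene models do not fit the chromosome: reduce "
                             "n_genes or gene length, or enlarge chromosomes")
        for k in range(int(count)):
            n_codons = int(rng.integers(cfg.gene_min_codons, cfg.gene_max_codons + 1))
            bp = 3 * n_codons
            start = k * slot + int(rng.integers(0, slot - bp + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(gene_id=f"g{gidx:05d}", chrom=name, start=start,
                              end=start + bp, strand=strand,
                              cds=random_cds(rng, n_codons)))
            gidx += 1
    return ReferenceModel(chromosomes=chroms, genes=genes)


@dataclass
class Karyotype:
    """Gene order of a (possibly rearranged) species genome.

    Genetic positions are rank-based: the i-th of n genes on a chromosome
    sits at ``(i + 0.5)/n * length_cm``, which keeps positions monotone
    and well defined after blocks of genes are translocated.
    """

    order: dict[str, tuple[str, ...]]
    length_cm: float

    def __post_init__(self):
        self._chrom = {}
        self._rank = {}
        for chrom, ids in self.order.items():
            for i, gid in enumerate(ids):
                self._chrom[gid] = chrom
                self._rank[gid] = i

    @classmethod
    def from_reference(cls, ref: ReferenceModel, length_cm: float = 100.0) -> "Karyotype":
        order = {name: tuple(g.gene_id for g in ref.genes_on(name))
                 for name in ref.chrom_names()}
        return cls(order=order, length_cm=length_cm)

    def chrom_of(self, gene_id: str) -> str:
        return self._chrom[gene_id]

    def pos_cm(self, gene_id: str) -> float:
        chrom = self._chrom[gene_id]
        n = len(self.order[chrom])
        return (self._rank[gene_id] + 0.5) / n * self.length_cm


@dataclass(frozen=True)
class TranslocationEvent:
    """Move genes [start, stop) of ``source_chrom``'s order into ``target_chrom``.

    ``species`` is ``None`` for events shared by both simulated species,
    otherwise ``"A"`` or ``"B"``.  Blocks must span at least 3 genes so
    the event stays detectable under the >=3-marker rule.
    """

    source_chrom: str
    start: int
    stop: int
    target_chrom: str
    insert_at: int
    species: str | None = None

    @property
    def shared(self) -> bool:
        return self.species is None

    @property
    def n_genes(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class RearrangementPlan:
    events: tuple[TranslocationEvent, ...]

    def __post_init__(self):
        for ev in self.events:
            if ev.n_genes < 3:
                raise ValueError("each event must move at least 3 genes")
            if ev.source_chrom == ev.target_chrom:
                raise ValueError("translocation must change chromosome")
            if ev.species not in (None, "A", "B"):
                raise ValueError("species must be None, 'A' or 'B'")
        for species in ("A", "B"):
            seen: dict[str, list[tuple[int, int]]] = {}
            for ev in self.events:
                if ev.species not in (None, species):
                    continue
                ivs = seen.setdefault(ev.source_chrom, [])
                for s, e in ivs:
                    if ev.start < e and s < ev.stop:
                        raise ValueError("overlapping source intervals")
                ivs.append((ev.start, ev.stop))

    def for_species(self, species: str) -> list[TranslocationEvent]:
        return [ev for ev in self.events if ev.species in (None, species)]


def _apply_events(karyo: Karyotype, events: list[TranslocationEvent]) -> Karyotype:
    base = {c: list(ids) for c, ids in karyo.order.items()}
    moves = []
    for ev in events:
        block = list(base[ev.source_chrom][ev.start:ev.stop])
        anchor = (base[ev.target_chrom][ev.insert_at]
                  if ev.insert_at < len(base[ev.target_chrom]) else None)
        moves.append((ev, block, anchor))
    moved = {gid for _, block, _ in moves for gid in block}
    order = {c: [g for g in ids if g not in moved] for c, ids in base.items()}
    for ev, block, anchor in moves:
        tgt = order[ev.target_chrom]
        at = tgt.index(anchor) if anchor is not None and anchor in tgt else len(tgt)
        order[ev.target_chrom] = tgt[:at] + block + tgt[at:]
    return Karyotype(order={c: tuple(ids) for c, ids in order.items()},
                     length_cm=karyo.length_cm)


def inject_rearrangements(karyo_a: Karyotype, karyo_b: Karyotype,
                          plan: RearrangementPlan
                          ) -> tuple[Karyotype, Karyotype, dict[str, list[TranslocationEvent]]]:
    """Apply a translocation plan to two species' gene orders.

    Shared events go into both species, private events into their own
    species; the returned dict lists the events realised per species.
    Anchor coordinates are untouched — downstream synteny works against
    the ancestral reference, which is exactly the translocation signature.
    """
    applied = {"A": plan.for_species("A"), "B": plan.for_species("B")}
    return (_apply_events(karyo_a, applied["A"]),
            _apply_events(karyo_b, applied["B"]),
            applied)


def random_rearrangement_plan(ref: ReferenceModel, rng: np.random.Generator,
                              n_shared: int, n_private_a: int = 0,
                              n_private_b: int = 0, block_genes: int = 5
                              ) -> RearrangementPlan:
    """Draw non-overlapping translocations over distinct chromosome pairs.

    Distinct unordered chromosome pairs per species keep the event
    bookkeeping unambiguous (one injected event <-> one detected pair).
    """
    chroms = ref.chrom_names()
    sizes = {c: len(ref.genes_on(c)) for c in chroms}
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    used_pairs: set[frozenset] = set()
    events = []
    labels = [None] * n_shared + ["A"] * n_private_a + ["B"] * n_private_b
    for species in labels:
        for _ in range(1000):
            src, tgt = (chroms[i] for i in rng.choice(len(chroms), 2, replace=False))
            pair = frozenset((src, tgt))
            if pair in used_pairs or sizes[src] < block_genes + 2:
                continue
            start = int(rng.integers(0, sizes[src] - block_genes + 1))
            stop = start + block_genes
            if any(start < e and s < stop for s, e in taken[src]):
                continue
            taken[src].append((start, stop))
            used_pairs.add(pair)
            events.append(TranslocationEvent(source_chrom=src, start=start, stop=stop,
                                             target_chrom=tgt,
                                             insert_at=int(rng.integers(0, sizes[tgt] + 1)),
                                             species=species))
            break
        else:
            raise RuntimeError("could not place all requested events")
    return RearrangementPlan(events=tuple(events))


@dataclass
class ParentalGenome:
    """One parent's variant sites; haplotypes are implicit indices 0..ploidy-1."""

    name: str
    ploidy: int
    sites: pd.DataFrame  # rows of the shared site table where parent == name


def spike_variants(ref: ReferenceModel, cfg: SimConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[ParentalGenome, ParentalGenome, pd.DataFrame]:
    """Drop variant sites on the two parents' CDS.

    Per gene a Poisson(``snps_per_gene``) number of distinct CDS offsets
    receives a variant.  Each variant belongs to exactly one parent
    (fair coin), has a dose drawn from the configured mixture and carrier
    haplotypes drawn uniformly without replacement; the other parent is
    nulliplex at the site.
    """
    rng = cfg.rng() if rng is None else rng
    doses = np.arange(1, len(cfg.dosage_mixture) + 1)
    rows = []
    for gene in ref.genes:
        k = int(rng.poisson(cfg.snps_per_gene))
        k = min(k, len(gene.cds))
        if k == 0:
            continue
        offsets = np.sort(rng.choice(len(gene.cds), size=k, replace=False))
        for off in offsets:
            ref_base = gene.cds[off]
            alt = _BASES[(_BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
            parent = "P1" if rng.random() < 0.5 else "P2"
            dose = int(rng.choice(doses, p=cfg.dosage_mixture))
            carriers = tuple(sorted(int(h) for h in
                                    rng.choice(cfg.ploidy, size=dose, replace=False)))
            rows.append({"site_id": f"{gene.gene_id}:{off + 1}", "gene_id": gene.gene_id,
                         "offset": int(off), "ref": ref_base, "alt": alt,
                         "parent": parent, "dose": dose, "carriers": carriers})
    sites = pd.DataFrame(rows, columns=["site_id", "gene_id", "offset", "ref", "alt",
                                        "parent", "dose", "carriers"])
    p1 = ParentalGenome("P1", cfg.ploidy, sites[sites["parent"] == "P1"])
    p2 = ParentalGenome("P2", cfg.ploidy, sites[sites["parent"] == "P2"])
    return p1, p2, sites


def gamete_sources(rng: np.random.Generator, ploidy: int, length_cm: float,
                   positions_cm: np.ndarray) -> np.ndarray:
    """Simulate one meiosis; which founder homolog each chromatid carries where.

    Homologs pair at random into ``ploidy/2`` bivalents (no preferential
    pairing); each transmitted chromatid is a mosaic of its bivalent's two
    homologs with a Poisson(length_cm/100) number of crossover breakpoints
    at uniform positions.  Returns an ``(ploidy/2, n_positions)`` array of
    source homolog indices.
    """
    m = ploidy // 2
    positions_cm = np.asarray(positions_cm, dtype=float)
    pairs = rng.permutation(ploidy).reshape(m, 2)
    out = np.empty((m, positions_cm.size), dtype=np.int64)
    for t in range(m):
        k = int(rng.poisson(length_cm / 100.0))
        breaks = np.sort(rng.uniform(0.0, length_cm, size=k))
        phase = (int(rng.integers(2)) + np.searchsorted(breaks, positions_cm, side="right")) % 2
        out[t] = pairs[t][phase]
    return out


@dataclass
class TruthSet:
    """Ground truth of one simulated cross."""

    sites: pd.DataFrame          # + chrom, pos_cm, homolog columns
    copies: np.ndarray           # (n_sites, n_progeny) carrier copies inherited
    progeny: list[str]
    config: SimConfig
    karyotype: Karyotype
    events: list[TranslocationEvent] = field(default_factory=list)

    def presence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.copies > 0, index=self.sites["site_id"],
                            columns=self.progeny)


def simulate_progeny(p1: ParentalGenome, p2: ParentalGenome, cfg: SimConfig,
                     karyotype: Karyotype,
                     rng: np.random.Generator | None = None) -> TruthSet:
    """Transmit parental haplotypes through F1 meioses.

    Each progeny receives, per chromosome and per parent, the
    ``ploidy/2`` recombinant chromatids of :func:`gamete_sources`; a site
    is present in a progeny iff at least one transmitted chromatid
    derives from a carrier homolog at the site's position.
    """
    rng = cfg.rng() if rng is None else rng
    if p1.ploidy != p2.ploidy:
        raise ValueError("parents must share ploidy")
    sites = pd.concat([p1.sites, p2.sites]).sort_index().reset_index(drop=True)
    sites = sites.assign(
        chrom=[karyotype.chrom_of(g) for g in sites["gene_id"]],
        pos_cm=[karyotype.pos_cm(g) for g in sites["gene_id"]],
        homolog=[c[0] if d == 1 else -1 for c, d in zip(sites["carriers"], sites["dose"])],
    )
    progeny = [f"F{j + 1:02d}" for j in range(cfg.n_progeny)]
    copies = np.zeros((len(sites), cfg.n_progeny), dtype=np.int8)
    chrom_groups = {
        (parent, chrom): idx.to_numpy()
        for (parent, chrom), idx in sites.groupby(["parent", "chrom"]).groups.items()
    }
    for j in range(cfg.n_progeny):
        for parent in ("P1", "P2"):
            for chrom in karyotype.order:
                idx = chrom_groups.get((parent, chrom))
                if idx is None or idx.size == 0:
                    continue
                pos = sites.loc[idx, "pos_cm"].to_numpy(dtype=float)
                o = np.argsort(pos, kind="stable")
                idx, pos = idx[o], pos[o]
                carrier = np.zeros((idx.size, cfg.ploidy), dtype=bool)
                for r, cs in enumerate(sites.loc[idx, "carriers"]):
                    carrier[r, list(cs)] = True
                src = gamete_sources(rng, cfg.ploidy, cfg.chrom_length_cm, pos)
                rows = np.arange(idx.size)
                for t in range(src.shape[0]):
                    copies[idx, j] += carrier[rows, src[t]].astype(np.int8)
    return TruthSet(sites=sites, copies=copies, progeny=progeny, config=cfg,
                    karyotype=karyotype)


@dataclass
class SimDataset:
    """Paths and truth of one written-out simulated experiment."""

    outdir: Path
    sample_sheet: Path
    pileups: dict[str, Path]
    truth: TruthSet
    anchors: pd.DataFrame
    expressed: set[str]
    reference: ReferenceModel


def _pileup_line(rng: np.random.Generator, cfg: SimConfig, gene_id: str, offset: int,
                 ref_base: str, alt_base: str, depth: int, alt_n: int,
                 qual_chars: np.ndarray, qual_probs: np.ndarray) -> str:
    e = cfg.base_error_rate
    ref_n = depth - alt_n
    counts = np.zeros(4, dtype=np.int64)
    ri, ai = _BASES.index(ref_base), _BASES.index(alt_base)
    err = 0
    if e > 0:
        err_ref = int(rng.binomial(ref_n, e)) if ref_n else 0
        err_alt = int(rng.binomial(alt_n, e)) if alt_n else 0
        counts[ri] = ref_n - err_ref
        counts[ai] += alt_n - err_alt
        err = err_ref + err_alt
        if err:
            counts += rng.multinomial(err, [0.25] * 4)
    else:
        counts[ri] = ref_n
        counts[ai] += alt_n
    symbols = []
    for b, c in zip(_BASES, counts):
        if c == 0:
            continue
        if b == ref_base:
            cases = np.where(rng.random(c) < 0.5, ".", ",")
        else:
            cases = np.where(rng.random(c) < 0.5, b, b.lower())
        symbols.append(cases)
    bases = np.concatenate(symbols) if symbols else np.array([], dtype="<U1")
    rng.shuffle(bases)
    quals = qual_chars[rng.choice(len(qual_chars), size=depth, p=qual_probs)]
    return (f"{gene_id}\t{offset + 1}\t{ref_base}\t{depth}\t"
            f"{''.join(bases)}\t{''.join(quals)}")


def simulate_pileups(truth: TruthSet, ref: ReferenceModel, cfg: SimConfig,
                     outdir: str | Path,
                     rng: np.random.Generator | None = None) -> SimDataset:
    """Write per-individual mpileup-dialect files plus truth/reference tables.

    Per expressed gene and individual the read depth is negative
    binomial; at each variant site the alt read count is binomial in the
    individual's carrier-homolog fraction (optionally reweighted by
    per-haplotype expression weights), uniform base-call errors are
    applied, and a 6-column line is emitted.  Only variant sites are
    written — invariant columns carry no marker information.
    """
    rng = cfg.rng() if rng is None else rng
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    (outdir / "reference").mkdir(exist_ok=True)

    expressed = {g.gene_id for g in ref.genes if rng.random() < cfg.expressed_fraction}
    qual_chars = np.array([chr(q + 33) for q, _ in cfg.quality_levels])
    qual_probs = np.array([p for _, p in cfg.quality_levels], dtype=float)
    weights = (np.full(cfg.ploidy, 1.0 / cfg.ploidy) if cfg.haplotype_weights is None
               else np.asarray(cfg.haplotype_weights, float) / sum(cfg.haplotype_weights))

    sites = truth.sites
    by_gene = {g: idx.to_numpy() for g, idx in sites.groupby("gene_id").groups.items()}
    gene_order = [g.gene_id for g in ref.genes if g.gene_id in by_gene and g.gene_id in expressed]

    individuals = [("P1", "parent1"), ("P2", "parent2")] + \
                  [(name, "progeny") for name in truth.progeny]
    prog_index = {name: j for j, name in enumerate(truth.progeny)}
    paths: dict[str, Path] = {}
    nb_size = cfg.depth_dispersion
    for name, role in individuals:
        mean = cfg.mean_depth * (cfg.parent_depth_factor if role != "progeny" else 1.0)
        p_nb = nb_size / (nb_size + mean)
        lines = []
        for gene_id in gene_order:
            depth = int(rng.negative_binomial(nb_size, p_nb))
            if depth == 0:
                continue
            for i in by_gene[gene_id]:
                row = sites.iloc[i]
                if role == "progeny":
                    cp = int(truth.copies[i, prog_index[name]])
                else:
                    cp = int(row["dose"]) if row["parent"] == name else 0
                if cp == 0:
                    frac = 0.0
                elif role == "progeny":
                    # expression weights model parental homolog bias only;
                    # progeny homolog identity is not tracked read-level
                    frac = cp / cfg.ploidy
                else:
                    frac = float(weights[list(row["carriers"])].sum())
                alt_n = int(rng.binomial(depth, frac)) if frac > 0 else 0
                lines.append(_pileup_line(rng, cfg, gene_id, int(row["offset"]),
                                          row["ref"], row["alt"], depth, alt_n,
                                          qual_chars, qual_probs))
        path = outdir / f"{name}.pileup"
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths[name] = path

    sheet = pd.DataFrame([{"sample_id": n, "role": r, "path": f"{n}.pileup"}
                          for n, r in individuals])
    sheet_path = outdir / "samples.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)

    anchors = anchor_frame(ref, sites)
    anchors.to_csv(outdir / "reference" / "anchors.tsv", sep="\t", index=False)
    pd.DataFrame([{"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start + 1,
                   "end": g.end, "strand": g.strand} for g in ref.genes]
                 ).to_csv(outdir / "reference" / "genes.tsv", sep="\t", index=False)
    SeqIO.write((SeqRecord(Seq(g.cds), id=g.gene_id, description="") for g in ref.genes),
                str(outdir / "reference" / "cds.fasta"), "fasta")

    tr = sites.copy()
    tr["carriers"] = [",".join(map(str, c)) for c in tr["carriers"]]
    tr.to_csv(outdir / "truth" / "sites.tsv", sep="\t", index=False)
    truth.presence_frame().astype(int).to_csv(outdir / "truth" / "presence.tsv", sep="\t")
    pd.DataFrame([dataclasses.asdict(ev) for ev in truth.events]
                 ).to_csv(outdir / "truth" / "events.tsv", sep="\t", index=False)

    return SimDataset(outdir=outdir, sample_sheet=sheet_path, pileups=paths,
                      truth=truth, anchors=anchors, expressed=expressed, reference=ref)


def simulate_dataset(cfg: SimConfig, outdir: str | Path,
                     plan: RearrangementPlan | None = None,
                     species: str = "A") -> SimDataset:
    """End-to-end generation: reference, parents, progeny, pileups, truth."""
    rng = cfg.rng()
    ref = build_reference(cfg, rng)
    karyo = Karyotype.from_reference(ref, cfg.chrom_length_cm)
    events: list[TranslocationEvent] = []
    if plan is not None:
        ka, kb, applied = inject_rearrangements(karyo, karyo, plan)
        karyo = ka if species == "A" else kb
        events = applied[species]
    p1, p2, _ = spike_variants(ref, cfg, rng)
    truth = simulate_progeny(p1, p2, cfg, karyo, rng)
    truth.events = events
    return simulate_pileups(truth, ref, cfg, outdir, rng)


def karyotype_map_frame(karyo: Karyotype, sites: pd.DataFrame,
                        genes: set[str] | None = None) -> pd.DataFrame:
    """Idealised map: one linkage group per species chromosome, truth order.

    Useful as a ground-truth stand-in for a mapped species when only the
    synteny stage is under study.  Restricts to ``genes`` when given.
    """
    rows = []
    by_gene = sites.groupby("gene_id").groups
    for chrom, ids in karyo.order.items():
        order = 0
        for gid in ids:
            if genes is not None and gid not in genes:
                continue
            for i in by_gene.get(gid, []):
                rows.append({"group": chrom, "order": order,
                             "marker_id": sites.loc[i, "site_id"]})
                order += 1
    return pd.DataFrame(rows, columns=["group", "order", "marker_id"])


def anchor_frame(ref: ReferenceModel, sites: pd.DataFrame) -> pd.DataFrame:
    """Marker anchors in ancestral reference coordinates (1-based TSV)."""
    rows = []
    for _, row in sites.iterrows():
        gene = ref.gene(row["gene_id"])
        rows.append({"marker_id": row["site_id"], "chrom": gene.chrom,
                     "pos": gene.start + int(row["offset"]) + 1})
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"])


def evolve_synonymous(cds: str, ks: float, rng: np.random.Generator) -> str:
    """Diverge a CDS by ``ks`` expected synonymous substitutions per synonymous site.

    A Poisson(ks * S) number of substitution events is applied, each
    drawn uniformly from the synonymous one-step changes available in the
    current sequence (a neutral Jukes-Cantor-style process restricted to
    silent changes; repeated hits at a site can occur and revert).
    """
    if ks < 0:
        raise ValueError("ks must be non-negative")
    codons = [cds[i:i + 3].upper() for i in range(0, len(cds), 3)]
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    s_total = float(sum(ksdating.synonymous_sites(c) for c in codons))
    n_events = int(rng.poisson(ks * s_total))
    for _ in range(n_events):
        options = [(i, pos, base) for i, c in enumerate(codons)
                   for pos, base in ksdating.synonymous_neighbors(c)]
        if not options:
            break
        i, pos, base = options[int(rng.integers(len(options)))]
        c = codons[i]
        codons[i] = c[:pos] + base + c[pos + 1:]
    return "".join(codons)
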