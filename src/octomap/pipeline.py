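"""End-to-end driver: simulated cross -> markers -> bins -> linkage maps.

Glues the stages together the way the analysis runs on real data, with
the simulator standing in for sequencing: generate (or point at) pileup
files, screen single-dose candidates from the merged progeny, assign
parents, genotype, apply the segregation filter, bin co-segregating
markers per parent, and build LOD-grouped, Kosambi-ordered maps.

Binning and mapping run per parent: in a pseudo-testcross each parent's
simplex markers form an independent backcross-like population.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import binning, linkage, pileup, simulate

__all__ = ["CrossResult", "run_cross_pipeline", "map_frame"]


@dataclass
class CrossResult:
    """Everything one simulated cross produced, stage by stage."""

    dataset: simulate.SimDataset
    calls: pileup.CallResult
    filtered: pd.DataFrame                    # genotypes after segregation QC
    bins: dict[str, list[binning.MarkerBin]]  # per parent
    maps: dict[str, list[linkage.LinkageGroupMap]]
    unplaced: dict[str, list[str]]
    summary: pd.DataFrame

    def marker_bin(self) -> dict[str, str]:
        """marker id -> bin id over both parents."""
        out = {}
        for bins in self.bins.values():
            for b in bins:
                for m in b.members:
                    out[m] = b.bin_id
        return out


def run_cross_pipeline(cfg: simulate.SimConfig, outdir,
                       call_config: pileup.CallConfig = pileup.CallConfig(),
                       lo: float = 0.3, hi: float = 0.7, min_genotyped: int = 39,
                       max_missing_frac: float = 0.10, max_conflicts: int = 0,
                       lod_cutoff: float = 6.0, rescue_cutoff: float = 4.0,
                       min_shared: int = 10,
                       plan: simulate.RearrangementPlan | None = None,
                       species: str = "A") -> CrossResult:
    """Simulate a cross and run the full marker-to-map analysis on it."""
    dataset = simulate.simulate_dataset(cfg, outdir, plan=plan, species=species)
    calls = pileup.call_single_dose_markers(dataset.sample_sheet, config=call_config)
    filtered = binning.filter_markers(calls.genotypes, lo=lo, hi=hi,
                                      min_genotyped=min_genotyped,
                                      max_missing_frac=max_missing_frac)
    bins_by_parent: dict[str, list[binning.MarkerBin]] = {}
    maps: dict[str, list[linkage.LinkageGroupMap]] = {}
    unplaced: dict[str, list[str]] = {}
    summaries = []
    for parent in ("P1", "P2"):
        ids = calls.markers.index[(calls.markers["parent"] == parent)]
        geno = filtered.loc[filtered.index.intersection(ids)]
        if geno.empty:
            bins_by_parent[parent], maps[parent], unplaced[parent] = [], [], []
            continue
        bins = binning.build_bins(geno, max_conflicts=max_conflicts)
        # prefix bin ids by parent so the two marker sets stay separate
        for b in bins:
            b.bin_id = f"{parent}_{b.bin_id}"
        bins_by_parent[parent] = bins
        matrix = binning.bin_matrix(bins, geno.columns)
        gmaps, un, summary = linkage.build_maps(matrix, lod_cutoff=lod_cutoff,
                                                rescue_cutoff=rescue_cutoff,
                                                min_shared=min_shared)
        for m in gmaps:
            m.group_id = f"{parent}_{m.group_id}"
        maps[parent] = gmaps
        unplaced[parent] = un
        summary.insert(0, "parent", parent)
        summaries.append(summary)
    summary = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    return CrossResult(dataset=dataset, calls=calls, filtered=filtered,
                       bins=bins_by_parent, maps=maps, unplaced=unplaced,
                       summary=summary)


def map_frame(result: CrossResult, representative: bool = True) -> pd.DataFrame:
    """Flatten the maps into a (group, order, marker_id, position_cm) table.

    With ``representative`` each bin contributes its representative
    marker (the map's marker list); otherwise every member marker is
    listed at its bin's position.
    """
    by_bin = {}
    for bins in result.bins.values():
        for b in bins:
            by_bin[b.bin_id] = b
    rows = []
    for parent, gmaps in result.maps.items():
        for m in gmaps:
            order = 0
            for bin_id, pos in zip(m.bin_ids, m.positions_cm):
                b = by_bin[bin_id]
                markers = [b.representative] if representative else b.members
                for marker in markers:
                    rows.append({"group": m.group_id, "order": order,
                                 "marker_id": marker, "position_cm": pos,
                                 "bin_id": bin_id, "parent": parent})
                    order += 1
    return pd.DataFrame(rows, columns=["group", "order", "marker_id",
                                       "position_cm", "bin_id", "parent"])
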