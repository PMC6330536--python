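"""Generate a small synthetic octoploid F1 cross with ground truth.

Writes per-individual mpileup-dialect files, the reference CDS/annotation
and the truth tables (sites, doses, presence matrix) to ./example_cross,
then verifies the simplex markers segregate ~1:1 as the dosage model
predicts.
"""

from octomap import dosage, simulate

cfg = simulate.SimConfig(seed=1, n_progeny=20, n_genes=120, snps_per_gene=2.0)
ds = simulate.simulate_dataset(cfg, "example_cross")

sites = ds.truth.sites
print(f"simulated {len(sites)} variant sites over {cfg.n_genes} genes, "
      f"{cfg.n_progeny} progeny")
print("dose mixture observed:", sites["dose"].value_counts(normalize=True)
      .sort_index().round(3).to_dict())

present = ds.truth.copies > 0
for dose in (1, 4):
    mask = (sites["dose"] == dose).to_numpy()
    print(f"dose {dose}: mean F1 presence {present[mask].mean():.3f} "
          f"(expected {dosage.f1_presence_fraction(dose, 8):.3f})")
print("pileups written to:", sorted(p.name for p in ds.pileups.values())[:3], "...")
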