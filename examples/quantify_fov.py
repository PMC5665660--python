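"""Quantify lipid droplets in one synthetic field of view.

Builds a noise-free two-channel image of Nile-Red-stained monocytes with
known ground truth, runs the seeded pipeline, and compares its per-cell
droplet counts with the truth.
"""

from lipidquant.pipeline import quantify_fov
from lipidquant.synthetic_data import SynthConfig, generate_fov

cfg = SynthConfig(noise_sigma=0, poisson_noise=False, artifact_rate=0,
                  merge_fraction=0, rng_seed=3)
fov, seeds, truth = generate_fov(cfg)
result = quantify_fov(fov, seeds, fov_id="demo")

s = result.summary
print(f"cells counted:        {s.n_cells} (truth {len(truth.cells)})")
print(f"lipid-positive cells: {s.n_positive} ({s.pct_positive:.1f} %)")
print(f"total droplets:       {s.total_lds} (truth {truth.total_droplets})")
print(f"LDs per positive cell: {s.lds_per_positive_cell:.2f}")
print()
label_of_seed = {v: k for k, v in result.cell_mask.seed_of.items()}
measured = {r.cell_label: r.ld_count for r in result.records}
print("cell  truth  measured")
for i, cell in enumerate(truth.cells):
    lid = label_of_seed[tuple(seeds.points[i])]
    print(f"{i:4d} {cell.droplet_count:6d} {measured[lid]:9d}")
print()
print("On a clean image the pipeline reproduces the ground truth exactly;")
print("each row is one seeded monocyte and its neutral-lipid droplet count.")
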