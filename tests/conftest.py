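import numpy as np
import pytest

from lipidquant.pipeline import quantify_fov
from lipidquant.synthetic_data import SynthConfig, generate_fov


def clean_config(**overrides) -> SynthConfig:
    """Noise-free world: no sensor noise, no artifacts, no merged droplets."""
    base = dict(noise_sigma=0.0, poisson_noise=False, artifact_rate=0.0, merge_fraction=0.0)
    base.update(overrides)
    return SynthConfig(**base)


def matched_counts(res, seeds, truth):
    """(true, measured) LD count pairs, matched cell-by-cell via the seeds."""
    label_of_seed = {v: k for k, v in res.cell_mask.seed_of.items()}
    measured = {rec.cell_label: rec.ld_count for rec in res.records}
    pairs = []
    for i, cell in enumerate(truth.cells):
        lid = label_of_seed.get(tuple(seeds.points[i]))
        if lid is not None:
            pairs.append((cell.droplet_count, measured[lid]))
    return pairs


@pytest.fixture(scope="session")
def clean_fov_run():
    """One noise-free synthetic FOV pushed through the full pipeline."""
    fov, seeds, truth = generate_fov(clean_config(rng_seed=3))
    res = quantify_fov(fov, seeds, fov_id="clean3")
    return fov, seeds, truth, res


@pytest.fixture(scope="session")
def noisy_fov_run():
    """One FOV at the stressed acquisition defaults (noise + artifacts)."""
    cfg = SynthConfig(merge_fraction=0.0, rng_seed=11)
    fov, seeds, truth = generate_fov(cfg)
    res = quantify_fov(fov, seeds, fov_id="noisy11")
    return fov, seeds, truth, res


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
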