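import numpy as np
import pytest

from plaqueniche import (
    ImageConfig,
    PlantedEnrichment,
    SyntheticConfig,
    geometry,
    preprocess,
    synthdata,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic experiment shared across read-only tests."""
    return synthdata.generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def enriched_dataset():
    """Dataset with a planted Ast.5 odds multiplier of 1.5 at plaque spots."""
    cfg = SyntheticConfig(
        planted_state_enrichment=[PlantedEnrichment("Ast.5", 1.5)], seed=8
    )
    return synthdata.generate_dataset(cfg)


@pytest.fixture(scope="session")
def annotated_default(default_dataset):
    """Pooled AnnData with lognorm layer, strata and true layer labels."""
    adata = default_dataset.concatenated()
    preprocess.lognormalize(adata)
    obs = geometry.annotate_spots(
        adata.obs.assign(layer=adata.obs["true_layer"]), default_dataset.plaques
    )
    adata.obs = obs
    return adata


@pytest.fixture(scope="session")
def clean_image():
    """Zero-noise image fixture with planted 10% proximal factors."""
    icfg = ImageConfig(noise_sd=0.0, seed=5)
    channels, cells, plaques = synthdata.generate_if_image(icfg)
    return icfg, channels, cells, plaques


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
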