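"""Synthetic single-nucleus reference with state-specific marker blocks.

Each cell state receives a disjoint block of marker genes whose mean
expression is elevated above a shared log-normal baseline; nucleus-level
counts are negative-binomial draws around the state signature.  The block
structure is the ground truth that reference-based deconvolution is
expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from ..config import SyntheticConfig


@dataclass
class ReferenceSignatures:
    """True per-state mean expression on the counts-per-nucleus scale."""

    means: pd.DataFrame  # genes x states
    major_type: pd.Series  # state -> major cell type
    marker_blocks: dict[str, list[str]]  # state -> its marker genes

    @property
    def states(self) -> list[str]:
        return list(self.means.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.means.index)


def _gene_names(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


def sample_nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with mean ``mean`` and size (inverse-dispersion
    like) parameter ``dispersion``: Var = mu + mu^2 / dispersion."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 1e-12) / dispersion)
    return rng.poisson(lam)


def generate_reference(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[ReferenceSignatures, ad.AnnData]:
    """Build true state signatures and sample labelled nuclei counts.

    Returns the signatures (genes x states, counts-per-nucleus scale) and an
    AnnData of nuclei x genes with ``obs['state']`` and ``obs['major_type']``.
    Deterministic given ``config.seed`` when no generator is passed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    genes = _gene_names(config.n_genes)
    states = config.states
    n_states = len(states)

    baseline = rng.lognormal(mean=np.log(0.4), sigma=1.0, size=config.n_genes)

    # marker blocks cover half the gene universe; the rest is shared
    # background, as state markers are a minority of a real transcriptome.
    # Markers behave like curated cell-state markers: adequately expressed,
    # elevated in their own state and near-silent in the others.
    block = max(config.n_genes // (2 * n_states), 5)
    n_pool = min(int(1.25 * block * n_states), config.n_genes)
    pool = rng.permutation(np.argsort(baseline)[::-1][:n_pool])
    means = np.tile(baseline[:, None], (1, n_states))
    marker_blocks: dict[str, list[str]] = {}
    elevation = 1.0 + config.marker_strength
    for k, state in enumerate(states):
        idx = pool[k * block : (k + 1) * block]
        if config.marker_strength > 0:
            means[idx, :] *= 0.1  # specificity: low background elsewhere
            means[idx, k] *= 10.0 * elevation
        marker_blocks[state] = [genes[i] for i in idx]

    sig = ReferenceSignatures(
        means=pd.DataFrame(means, index=genes, columns=states),
        major_type=pd.Series(dict(config.states_per_major_type), name="major_type"),
        marker_blocks=marker_blocks,
    )

    counts = np.vstack(
        [
            sample_nb(
                rng,
                np.tile(means[:, k], (config.n_nuclei_per_state, 1)),
                config.nb_dispersion,
            )
            for k in range(n_states)
        ]
    )
    obs = pd.DataFrame(
        {
            "state": np.repeat(states, config.n_nuclei_per_state),
        },
        index=[f"nucleus{i:05d}" for i in range(counts.shape[0])],
    )
    obs["major_type"] = obs["state"].map(config.states_per_major_type)
    nuclei = ad.AnnData(
        X=counts.astype(np.int64), obs=obs, var=pd.DataFrame(index=genes)
    )
    return sig, nuclei
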