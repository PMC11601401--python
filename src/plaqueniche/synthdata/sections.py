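"""Synthetic Visium-like tissue sections with known ground truth.

Each section is a hexagonal (odd-row offset) lattice of spots partitioned
into horizontal bands for cortical layers L1..L6 and white matter.  Plaques
are seeded by a Poisson process whose intensity in the deep layers (L4-L6)
is a configurable multiple of the upper-layer intensity and zero in white
matter by default.  Per-spot cell-state mixtures are Dirichlet draws around
layer-specific base compositions, with planted odds multipliers applied near
plaques (focal) or across AD sections (global); UMI counts are
negative-binomial draws around the mixture-weighted signature sum, with
planted distance-dependent fold changes on selected genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..config import LAYER_NAMES, SyntheticConfig
from .reference import ReferenceSignatures, generate_reference, sample_nb

ROW_SPACING_FACTOR = np.sqrt(3.0) / 2.0


@dataclass
class GroundTruth:
    """Planted parameters the downstream analyses are expected to recover."""

    gene_effects: pd.DataFrame  # gene, effect (log2 at d=0), decay_um, direction
    state_log_odds: pd.Series  # state -> planted focal log odds at plaque spots
    global_log_odds: pd.Series  # state -> planted AD-section log odds
    marker_genes: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    """A full synthetic experiment: sections, plaques, reference, truth."""

    sections: list[ad.AnnData]
    plaques: pd.DataFrame
    reference: ReferenceSignatures
    nuclei: ad.AnnData
    truth: GroundTruth

    def concatenated(self) -> ad.AnnData:
        merged = ad.concat(self.sections, merge="same", uns_merge=None, index_unique=None)
        merged.uns["states"] = list(self.reference.states)
        return merged


_MAJOR_BUDGETS_GM = {"Exc": 0.55, "Ast": 0.18, "Mic": 0.07, "Oli": 0.08}
_MAJOR_BUDGETS_WM = {"Exc": 0.04, "Ast": 0.18, "Mic": 0.08, "Oli": 0.70}


def layer_state_weights(config: SyntheticConfig) -> pd.DataFrame:
    """Base cell-state composition per layer (layers x states, rows sum to 1).

    Major-type budgets follow cortical organisation (neuron-rich grey
    matter, oligodendrocyte-dominated white matter); within a major type the
    states are given Gaussian layer-affinity bumps at staggered depths so
    every state has a laminar abundance profile.
    """
    states = config.states
    majors = pd.Series(dict(config.states_per_major_type))
    unique_majors = list(dict.fromkeys(majors))
    weights = np.zeros((len(LAYER_NAMES), len(states)))
    for li, layer in enumerate(LAYER_NAMES):
        budgets = _MAJOR_BUDGETS_WM if layer == "WM" else dict(_MAJOR_BUDGETS_GM)
        if layer != "WM":
            budgets["Oli"] += 0.08 * (li / 5.0)  # oligodendrocytes increase with depth
        known = {m: b for m, b in budgets.items() if m in unique_majors}
        other = [m for m in unique_majors if m not in budgets]
        leftover = max(1.0 - sum(known.values()), 0.02)
        for m in other:
            known[m] = leftover / max(len(other), 1)
        for m in unique_majors:
            member_idx = [j for j, s in enumerate(states) if majors[s] == m]
            J = len(member_idx)
            centers = (np.arange(J) + 0.5) / J * 6.0
            # width 0.6 layer-units: adjacent laminae get clearly distinct
            # compositions, matching layers being the dominant axis of
            # spot-level variation in cortex
            bump = 0.15 + 0.85 * np.exp(-((li - centers) ** 2) / (2 * 0.6**2))
            bump /= bump.sum()
            for j, idx in enumerate(member_idx):
                weights[li, idx] = known[m] * bump[j]
    weights /= weights.sum(axis=1, keepdims=True)
    return pd.DataFrame(weights, index=list(LAYER_NAMES), columns=states)


def hex_lattice(config: SyntheticConfig) -> pd.DataFrame:
    """Odd-row offset hexagonal lattice in micrometres."""
    rows = np.repeat(np.arange(config.grid_rows), config.grid_cols)
    cols = np.tile(np.arange(config.grid_cols), config.grid_rows)
    x = cols * config.spot_pitch + (rows % 2) * config.spot_pitch / 2.0
    y = rows * config.spot_pitch * ROW_SPACING_FACTOR
    return pd.DataFrame({"row": rows, "col": cols, "x_um": x, "y_um": y})


def _layer_bounds(config: SyntheticConfig, y: np.ndarray) -> np.ndarray:
    dy = config.spot_pitch * ROW_SPACING_FACTOR
    y0, y1 = y.min() - dy / 2.0, y.max() + dy / 2.0
    edges = y0 + np.concatenate([[0.0], np.cumsum(config.layer_fractions)]) * (y1 - y0)
    edges[-1] = y1
    return edges


def assign_layers(config: SyntheticConfig, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = _layer_bounds(config, y)
    idx = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, len(LAYER_NAMES) - 1)
    labels = np.asarray(LAYER_NAMES, dtype=object)[idx]
    counts = pd.Series(labels).value_counts()
    empty = [l for l in LAYER_NAMES if counts.get(l, 0) == 0]
    if empty:
        raise ValueError(f"layer bands with no spots: {empty}; enlarge the grid")
    return labels, edges


def _sample_plaques(
    config: SyntheticConfig,
    rng: np.random.Generator,
    edges: np.ndarray,
    x_range: tuple[float, float],
    section_id: str,
) -> pd.DataFrame:
    """Poisson plaque process with deep-layer intensity bias."""
    n = rng.poisson(config.plaques_per_section)
    factors = np.array([1.0, 1.0, 1.0, *([config.deep_layer_plaque_bias] * 3),
                        1.0 if config.wm_plaques else 0.0])
    heights = np.diff(edges)
    probs = factors * heights
    if probs.sum() <= 0 or n == 0:
        return pd.DataFrame(columns=["section_id", "plaque_id", "x_um", "y_um"])
    probs = probs / probs.sum()
    bands = rng.choice(len(LAYER_NAMES), size=n, p=probs)
    y = edges[bands] + rng.uniform(size=n) * heights[bands]
    x = rng.uniform(x_range[0], x_range[1], size=n)
    return pd.DataFrame(
        {
            "section_id": section_id,
            "plaque_id": [f"{section_id}_p{i:03d}" for i in range(n)],
            "x_um": x,
            "y_um": y,
        }
    )


def _apply_odds(weights: np.ndarray, state_idx: int, multiplier: float) -> None:
    weights[:, state_idx] *= multiplier
    weights /= weights.sum(axis=1, keepdims=True)


def generate_section(
    config: SyntheticConfig,
    reference: ReferenceSignatures,
    section_index: int,
    rng: np.random.Generator,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Generate one section (AnnData of spots x genes) and its plaque table.

    Sections with index >= ``config.n_sections`` are non-AD controls: they
    carry no plaques and no global enrichment.
    """
    if config.grid_rows * config.grid_cols < 100:
        raise ValueError("grid must contain at least 100 spots")
    is_control = section_index >= config.n_sections
    section_id = f"S{section_index:02d}"
    if is_control:
        donor_id = f"C{section_index - config.n_sections:02d}"
        donor_num = config.n_donors + (section_index - config.n_sections)
    else:
        donor_num = section_index % config.n_donors
        donor_id = f"D{donor_num:02d}"
    sex = "F" if donor_num % 2 == 0 else "M"

    lattice = hex_lattice(config)
    layers, edges = assign_layers(config, lattice["y_um"].to_numpy())

    if is_control:
        plaques = pd.DataFrame(columns=["section_id", "plaque_id", "x_um", "y_um"])
    else:
        plaques = _sample_plaques(
            config, rng, edges,
            (lattice["x_um"].min(), lattice["x_um"].max()), section_id,
        )

    xy = lattice[["x_um", "y_um"]].to_numpy()
    if len(plaques):
        tree = cKDTree(plaques[["x_um", "y_um"]].to_numpy())
        dist, _ = tree.query(xy)
    else:
        dist = np.full(len(lattice), np.inf)

    base = layer_state_weights(config)
    weights = base.loc[layers].to_numpy().copy()
    states = reference.states

    # Dirichlet(conc * w) per spot via gamma draws (row-specific alphas)
    alphas = config.dirichlet_concentration * weights
    gam = rng.gamma(shape=np.maximum(alphas, 1e-8))
    comp = gam / gam.sum(axis=1, keepdims=True)

    # planted enrichment multiplies the odds of the state in each affected
    # spot's realized composition, so the per-spot log odds shift is exact
    near = dist <= config.enrichment_radius_um
    for eff in config.planted_state_enrichment:
        if near.any():
            k = states.index(eff.state)
            sub = comp[near]
            sub[:, k] *= eff.odds_multiplier
            sub /= sub.sum(axis=1, keepdims=True)
            comp[near] = sub
    if not is_control:
        for eff in config.planted_global_enrichment:
            _apply_odds(comp, states.index(eff.state), eff.odds_multiplier)

    sig = reference.means.to_numpy()  # genes x states
    mean = config.cells_per_spot_mean * comp @ sig.T  # spots x genes
    gene_index = {g: i for i, g in enumerate(reference.genes)}
    for eff in config.planted_de:
        gi = gene_index[eff.gene]
        log2_mult = np.array([eff.multiplier(d) for d in dist])
        mean[:, gi] *= np.exp2(log2_mult)

    counts = sample_nb(rng, mean, config.nb_dispersion)

    obs = pd.DataFrame(
        {
            "section_id": section_id,
            "donor_id": donor_id,
            "sex": sex,
            "ad": not is_control,
            "x_um": lattice["x_um"].to_numpy(),
            "y_um": lattice["y_um"].to_numpy(),
            "row": lattice["row"].to_numpy(),
            "col": lattice["col"].to_numpy(),
            "in_tissue": True,
            "true_layer": layers,
            "true_plaque_dist_um": dist,
        },
        index=[f"{section_id}_spot{i:04d}" for i in range(len(lattice))],
    )
    section = ad.AnnData(
        X=counts.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=reference.genes),
    )
    section.obsm["true_composition"] = comp
    section.uns["states"] = list(states)
    section.uns["layer_edges_um"] = edges
    return section, plaques


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the reference plus all AD and control sections.

    All randomness derives from ``config.seed`` through spawned child
    streams, so identical configs give bit-identical datasets while each
    section is distinct.
    """
    config.validate()
    n_total = config.n_sections + config.n_control_sections
    seeds = np.random.SeedSequence(config.seed).spawn(n_total + 1)
    reference, nuclei = generate_reference(
        config, rng=np.random.default_rng(seeds[0])
    )
    sections, plaque_tables = [], []
    for i in range(n_total):
        section, plaques = generate_section(
            config, reference, i, np.random.default_rng(seeds[i + 1])
        )
        sections.append(section)
        plaque_tables.append(plaques)
    nonempty = [t for t in plaque_tables if len(t)]
    plaques = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(columns=["section_id", "plaque_id", "x_um", "y_um"])
    )

    truth = GroundTruth(
        gene_effects=pd.DataFrame(
            [
                {
                    "gene": e.gene,
                    "effect": e.effect,
                    "decay_um": np.nan if e.decay_um is None else e.decay_um,
                    "direction": e.direction,
                    "signed_effect": e.direction * e.effect,
                }
                for e in config.planted_de
            ]
        ),
        state_log_odds=pd.Series(
            {e.state: np.log(e.odds_multiplier) for e in config.planted_state_enrichment},
            dtype=float,
        ),
        global_log_odds=pd.Series(
            {e.state: np.log(e.odds_multiplier) for e in config.planted_global_enrichment},
            dtype=float,
        ),
        marker_genes=dict(reference.marker_blocks),
    )
    return SyntheticDataset(
        sections=sections,
        plaques=plaques,
        reference=reference,
        nuclei=nuclei,
        truth=truth,
    )
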