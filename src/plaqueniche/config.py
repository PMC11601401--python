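"""Configuration objects for the synthetic tissue and image generators.

The defaults describe a desk-scale Visium-like experiment: hexagonal spot
lattices at 100 um pitch with 55 um spots, six cortical layer bands plus
white matter, plaques preferentially seeded in the deep layers, and
negative-binomial UMI counts composed from cell-state signatures at an
average of 3.7 nuclei per spot.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

LAYER_NAMES = ("L1", "L2", "L3", "L4", "L5", "L6", "WM")
UPPER_LAYERS = ("L1", "L2", "L3")
DEEP_LAYERS = ("L4", "L5", "L6")

#: default cell states: six excitatory subtypes (one per cortical layer),
#: three astrocyte states (Ast.5 is the plaque-reactive analogue), three
#: microglial states and two oligodendrocyte states.
DEFAULT_STATES: Mapping[str, str] = {
    "Exc.1": "Exc",
    "Exc.2": "Exc",
    "Exc.3": "Exc",
    "Exc.4": "Exc",
    "Exc.5": "Exc",
    "Exc.6": "Exc",
    "Ast.1": "Ast",
    "Ast.5": "Ast",
    "Ast.10": "Ast",
    "Mic.2": "Mic",
    "Mic.12": "Mic",
    "Mic.13": "Mic",
    "Oli.1": "Oli",
    "Oli.4": "Oli",
}


@dataclass(frozen=True)
class PlantedEffect:
    """A distance-dependent expression effect planted on one gene.

    ``effect`` is the log2 fold change at distance zero.  ``decay_um`` is the
    exponential decay length of the spatial profile; ``None`` plants a
    step profile (full effect within ``step_radius_um`` of a plaque, none
    beyond), which makes the dichotomous near/far contrast estimate the
    planted value exactly.
    """

    gene: str
    effect: float
    decay_um: float | None = 100.0
    direction: int = 1
    step_radius_um: float = 150.0

    def multiplier(self, distance_um: float) -> float:
        """Log2 multiplier applied at ``distance_um`` from the nearest plaque."""
        if self.decay_um is None:
            profile = 1.0 if distance_um <= self.step_radius_um else 0.0
        else:
            profile = math.exp(-distance_um / self.decay_um)
        return self.direction * self.effect * profile


@dataclass(frozen=True)
class PlantedEnrichment:
    """Multiplicative odds change of one cell state near plaques (or globally)."""

    state: str
    odds_multiplier: float


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic spatial transcriptomics generator."""

    n_sections: int = 4
    n_control_sections: int = 0
    n_donors: int = 4
    grid_rows: int = 36
    grid_cols: int = 16
    spot_pitch: float = 100.0
    spot_diameter: float = 55.0
    layer_fractions: Sequence[float] = (0.08, 0.10, 0.20, 0.15, 0.20, 0.17, 0.10)
    n_genes: int = 600
    states_per_major_type: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STATES)
    )
    plaques_per_section: float = 12.0
    deep_layer_plaque_bias: float = 2.0
    wm_plaques: bool = False
    planted_de: Sequence[PlantedEffect] = ()
    planted_state_enrichment: Sequence[PlantedEnrichment] = ()
    planted_global_enrichment: Sequence[PlantedEnrichment] = ()
    enrichment_radius_um: float = 150.0
    nb_dispersion: float = 10.0
    cells_per_spot_mean: float = 3.7
    dirichlet_concentration: float = 30.0
    marker_strength: float = 8.0
    n_nuclei_per_state: int = 80
    seed: int = 0

    @property
    def n_states(self) -> int:
        return len(self.states_per_major_type)

    @property
    def states(self) -> list[str]:
        return list(self.states_per_major_type)

    def validate(self) -> None:
        fr = list(self.layer_fractions)
        if len(fr) != len(LAYER_NAMES):
            raise ValueError(f"layer_fractions must have {len(LAYER_NAMES)} entries")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("layer_fractions must sum to 1 within 1e-9")
        if min(fr) <= 0:
            raise ValueError("layer_fractions must be positive")
        for name, value in (
            ("n_sections", self.n_sections),
            ("n_donors", self.n_donors),
            ("grid_rows", self.grid_rows),
            ("grid_cols", self.grid_cols),
            ("n_genes", self.n_genes),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_states < 3:
            raise ValueError("need at least 3 cell states")
        if self.n_genes < 50:
            raise ValueError("need at least 50 genes")
        if self.n_states > self.n_genes / 5:
            raise ValueError(
                "too many states for the gene universe: "
                f"{self.n_states} states need at least {5 * self.n_states} genes"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        states = set(self.states)
        for eff in self.planted_state_enrichment:
            if eff.state not in states:
                raise ValueError(f"unknown state in planted enrichment: {eff.state}")
        seen: set[str] = set()
        for eff in self.planted_de:
            if eff.gene in seen:
                raise ValueError(f"gene planted twice: {eff.gene}")
            seen.add(eff.gene)

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "planted_de" in raw:
            raw["planted_de"] = [PlantedEffect(**d) for d in raw["planted_de"]]
        for key in ("planted_state_enrichment", "planted_global_enrichment"):
            if key in raw:
                raw[key] = [PlantedEnrichment(**d) for d in raw[key]]
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ImageConfig:
    """Knobs of the synthetic immunofluorescence image generator.

    Channels are DAPI (nuclei), GFAP (astrocyte somata and processes),
    SERPINA3 and ABETA (plaques).  Intensities of GFAP and SERPINA3 in
    cells within ``proximal_radius_um`` of a plaque are multiplied by the
    planted proximal factors.
    """

    size_px: int = 1024
    pixel_size_um: float = 1.0
    n_cells: int = 110
    astrocyte_fraction: float = 0.55
    n_plaques: int = 3
    nucleus_radius_px: tuple[float, float] = (9.0, 13.0)
    plaque_radius_px: float = 20.0
    border_margin_px: float = 40.0
    blur_sigma_px: float = 2.0
    noise_sd: float = 3.0
    dapi_intensity: float = 160.0
    gfap_intensity: float = 130.0
    serpina3_intensity: float = 110.0
    abeta_intensity: float = 200.0
    intensity_cv: float = 0.10
    proximal_radius_um: float = 100.0
    proximal_serpina3_factor: float = 1.10
    proximal_gfap_factor: float = 1.10
    seed: int = 0

    def validate(self) -> None:
        if self.size_px < 512:
            raise ValueError("image dimensions must be at least 512x512 px")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if not 0 <= self.astrocyte_fraction <= 1:
            raise ValueError("astrocyte_fraction must be in [0, 1]")
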