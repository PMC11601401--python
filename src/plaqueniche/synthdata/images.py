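"""Synthetic multi-channel immunofluorescence images with known cell tables.

Nuclei are Gaussian-blurred disks in the DAPI channel; a subset of cells
are astrocytes that additionally carry a GFAP soma with short radial
processes and SERPINA3 signal; plaques are ABETA disks.  GFAP and SERPINA3
plateau intensities of cells within a configurable radius of a plaque are
multiplied by planted proximal factors, giving a known proximal/distant
intensity ratio that the segmentation and mixed-model stages must recover.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, line

from ..config import ImageConfig

CHANNELS = ("DAPI", "GFAP", "SERPINA3", "ABETA")


_JITTER_PX = 4.0


def _jittered_grid_positions(
    icfg: ImageConfig, rng: np.random.Generator, n: int, margin: float, step: float
) -> np.ndarray:
    """Cell centres on a jittered grid so cells never touch.

    The jitter is a fixed +-4 px, already budgeted into ``step`` by the
    caller, so the worst-case centre distance still exceeds twice the
    cell reach.
    """
    lo, hi = margin, icfg.size_px - margin
    coords = np.arange(lo, hi, step)
    xs, ys = np.meshgrid(coords, coords)
    sites = np.column_stack([xs.ravel(), ys.ravel()])
    if len(sites) < n:
        raise ValueError(
            f"cannot place {n} non-touching cells on a {icfg.size_px} px image"
        )
    chosen = rng.choice(len(sites), size=n, replace=False)
    jitter = rng.uniform(-_JITTER_PX, _JITTER_PX, size=(n, 2))
    return sites[chosen] + jitter


def _place_plaques(icfg: ImageConfig, rng: np.random.Generator) -> np.ndarray:
    """Plaque centres restricted to the left third so that distant cells
    (350-500 um from any plaque) exist on the right of the frame."""
    margin = icfg.border_margin_px + icfg.plaque_radius_px
    centres = []
    for _ in range(10000):
        if len(centres) == icfg.n_plaques:
            break
        cand = np.array(
            [
                rng.uniform(margin, icfg.size_px / 3.0),
                rng.uniform(margin, icfg.size_px - margin),
            ]
        )
        if all(np.linalg.norm(cand - c) > 4 * icfg.plaque_radius_px for c in centres):
            centres.append(cand)
    if len(centres) < icfg.n_plaques:
        raise ValueError("failed to place plaques")
    out = np.array(centres)
    if (out - icfg.plaque_radius_px < icfg.border_margin_px).any() or (
        out + icfg.plaque_radius_px > icfg.size_px - icfg.border_margin_px
    ).any():
        raise ValueError("plaque overlaps the image border margin")
    return out


def generate_if_image(
    icfg: ImageConfig,
) -> tuple[dict[str, np.ndarray], pd.DataFrame, pd.DataFrame]:
    """Render the four channels and return (channels, cell table, plaque table).

    The cell table holds every cell's true centroid (um), nucleus radius,
    plateau channel intensities after any proximal planting, nearest-plaque
    distance and the implied proximal/distant/excluded class.
    """
    icfg.validate()
    rng = np.random.default_rng(icfg.seed)
    size = icfg.size_px
    px = icfg.pixel_size_um

    plaque_xy_px = _place_plaques(icfg, rng)
    plaques = pd.DataFrame(
        {
            "plaque_id": [f"p{i:02d}" for i in range(len(plaque_xy_px))],
            "x_um": plaque_xy_px[:, 0] * px,
            "y_um": plaque_xy_px[:, 1] * px,
        }
    )

    r_lo, r_hi = icfg.nucleus_radius_px
    soma_factor, process_len = 1.5, 8.0
    # reach = soma + process + blur halo; worst-case separation after the
    # +-4 px jitter must still exceed twice the reach
    reach = soma_factor * r_hi + process_len + 2.0 * icfg.blur_sigma_px
    step = 2 * reach + 4 * _JITTER_PX + 2
    margin = icfg.border_margin_px + reach
    centres = _jittered_grid_positions(icfg, rng, icfg.n_cells, margin, step)

    radii = rng.uniform(r_lo, r_hi, size=icfg.n_cells)
    is_astro = rng.uniform(size=icfg.n_cells) < icfg.astrocyte_fraction
    d_plaque_um = (
        np.sqrt(((centres[:, None, :] - plaque_xy_px[None, :, :]) ** 2).sum(-1)).min(1)
        * px
    )
    proximal = d_plaque_um <= icfg.proximal_radius_um

    def _vary(base: float, n: int) -> np.ndarray:
        return base * rng.lognormal(0.0, icfg.intensity_cv, size=n)

    dapi_i = _vary(icfg.dapi_intensity, icfg.n_cells)
    gfap_i = np.where(is_astro, _vary(icfg.gfap_intensity, icfg.n_cells), 0.0)
    serp_i = np.where(is_astro, _vary(icfg.serpina3_intensity, icfg.n_cells), 0.0)
    gfap_i = np.where(proximal, gfap_i * icfg.proximal_gfap_factor, gfap_i)
    serp_i = np.where(proximal, serp_i * icfg.proximal_serpina3_factor, serp_i)

    channels = {c: np.zeros((size, size), dtype=float) for c in CHANNELS}

    for i in range(icfg.n_cells):
        cx, cy = centres[i]
        rr, cc = disk((cy, cx), radii[i], shape=(size, size))
        channels["DAPI"][rr, cc] = np.maximum(channels["DAPI"][rr, cc], dapi_i[i])
        if not is_astro[i]:
            continue
        soma_r = soma_factor * radii[i]
        rr, cc = disk((cy, cx), soma_r, shape=(size, size))
        channels["GFAP"][rr, cc] = np.maximum(channels["GFAP"][rr, cc], gfap_i[i])
        channels["SERPINA3"][rr, cc] = np.maximum(
            channels["SERPINA3"][rr, cc], serp_i[i]
        )
        for theta in rng.uniform(0, 2 * np.pi, size=3):
            x0 = cx + (soma_r - 1) * np.cos(theta)
            y0 = cy + (soma_r - 1) * np.sin(theta)
            x1 = cx + (soma_r + process_len) * np.cos(theta)
            y1 = cy + (soma_r + process_len) * np.sin(theta)
            for dx, dy in ((0, 0), (1, 0), (0, 1)):
                rr, cc = line(
                    int(round(y0)) + dy,
                    int(round(x0)) + dx,
                    int(round(y1)) + dy,
                    int(round(x1)) + dx,
                )
                keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
                channels["GFAP"][rr[keep], cc[keep]] = np.maximum(
                    channels["GFAP"][rr[keep], cc[keep]], gfap_i[i]
                )

    for j in range(len(plaque_xy_px)):
        rr, cc = disk(
            (plaque_xy_px[j, 1], plaque_xy_px[j, 0]),
            icfg.plaque_radius_px,
            shape=(size, size),
        )
        channels["ABETA"][rr, cc] = icfg.abeta_intensity

    for c in CHANNELS:
        channels[c] = gaussian_filter(channels[c], icfg.blur_sigma_px)
        if icfg.noise_sd > 0:
            channels[c] = channels[c] + rng.normal(0, icfg.noise_sd, size=(size, size))
        channels[c] = np.clip(channels[c], 0.0, None)

    dist_class = np.where(
        d_plaque_um <= icfg.proximal_radius_um,
        "proximal",
        np.where((d_plaque_um >= 350.0) & (d_plaque_um <= 500.0), "distant", "excluded"),
    )
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:03d}" for i in range(icfg.n_cells)],
            "x_um": centres[:, 0] * px,
            "y_um": centres[:, 1] * px,
            "nucleus_radius_px": radii,
            "is_astrocyte": is_astro,
            "true_dapi": dapi_i,
            "true_gfap": gfap_i,
            "true_serpina3": serp_i,
            "dist_um": d_plaque_um,
            "true_class": dist_class,
        }
    )
    return channels, cells, plaques
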