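"""Spot-plaque distance computations and distance-based classification.

Every spot is annotated with the Euclidean distance from its centre to the
centre of the nearest plaque in the same section, then classified into the
plaque-proximal stratum (distance <= 150 um, inclusive), the control
stratum (>= 500 um, inclusive) or the intermediate band in between.  Spots
in sections without plaques are flagged separately.  Plaques themselves are
assigned a cortical layer by an inverse-distance-weighted vote of the layer
labels of spots within 200 um.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .config import DEEP_LAYERS, LAYER_NAMES, UPPER_LAYERS

NEAR_UM = 150.0
FAR_UM = 500.0
LAYER_VOTE_RADIUS_UM = 200.0
#: floor on the voting distance so that a plaque sitting exactly on a spot
#: centre dominates without dividing by zero
MIN_VOTE_DISTANCE_UM = 1.0

STRATUM_PLAQUE = "plaque"
STRATUM_INTERMEDIATE = "intermediate"
STRATUM_CONTROL = "control"
STRATUM_NO_PLAQUE = "no_plaque_section"


def nearest_plaque_distance(
    spots: pd.DataFrame, plaques: pd.DataFrame
) -> pd.Series:
    """Distance (um) from each spot to its section's nearest plaque.

    ``spots`` needs columns section_id, x_um, y_um; ``plaques`` the same.
    Sections without plaques get infinite distances.
    """
    for df, what in ((spots, "spots"), (plaques, "plaques")):
        coords = df[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(coords) and not np.isfinite(coords).all():
            raise ValueError(f"non-finite coordinates in {what}")
    out = np.full(len(spots), np.inf)
    for section_id, idx in spots.groupby("section_id", observed=True).groups.items():
        sp = plaques.loc[plaques["section_id"] == section_id, ["x_um", "y_um"]]
        if len(sp) == 0:
            continue
        tree = cKDTree(sp.to_numpy(dtype=float))
        d, _ = tree.query(spots.loc[idx, ["x_um", "y_um"]].to_numpy(dtype=float))
        out[spots.index.get_indexer(idx)] = d
    return pd.Series(out, index=spots.index, name="plaque_dist_um")


def classify_spots(
    distances: pd.Series, near: float = NEAR_UM, far: float = FAR_UM
) -> pd.Series:
    """Stratify spots by nearest-plaque distance (thresholds inclusive)."""
    if near >= far:
        raise ValueError(f"near threshold ({near}) must be below far ({far})")
    d = distances.to_numpy(dtype=float)
    out = np.where(
        ~np.isfinite(d),
        STRATUM_NO_PLAQUE,
        np.where(
            d <= near,
            STRATUM_PLAQUE,
            np.where(d >= far, STRATUM_CONTROL, STRATUM_INTERMEDIATE),
        ),
    )
    return pd.Series(out, index=distances.index, name="stratum")


def assign_plaque_layer(
    plaque_xy: tuple[float, float],
    spots: pd.DataFrame,
    radius: float = LAYER_VOTE_RADIUS_UM,
) -> str:
    """Layer label winning the inverse-distance-weighted vote around a plaque.

    ``spots`` needs x_um, y_um and a ``layer`` column.  Ties are broken by
    the smallest minimum distance to a spot of the tied label, then by
    lexicographic label order; returns "unassigned" when no spot lies
    within ``radius``.
    """
    dx = spots["x_um"].to_numpy(dtype=float) - plaque_xy[0]
    dy = spots["y_um"].to_numpy(dtype=float) - plaque_xy[1]
    d = np.hypot(dx, dy)
    within = d <= radius
    if not within.any():
        return "unassigned"
    d_in = np.maximum(d[within], MIN_VOTE_DISTANCE_UM)
    labels = spots["layer"].to_numpy(dtype=object)[within]
    votes = pd.DataFrame({"layer": labels, "w": 1.0 / d_in, "d": d_in})
    agg = votes.groupby("layer").agg(weight=("w", "sum"), mind=("d", "min"))
    best_weight = agg["weight"].max()
    tied = agg[np.isclose(agg["weight"], best_weight, rtol=0, atol=1e-12)]
    tied = tied.sort_values(by="mind", kind="stable")
    best_mind = tied["mind"].min()
    finalists = sorted(
        tied[np.isclose(tied["mind"], best_mind, rtol=0, atol=1e-12)].index
    )
    return finalists[0]


def assign_plaque_layers(
    plaques: pd.DataFrame, spots: pd.DataFrame, radius: float = LAYER_VOTE_RADIUS_UM
) -> pd.DataFrame:
    """Vectorised per-section wrapper over :func:`assign_plaque_layer`."""
    out = plaques.copy()
    layers = []
    for _, row in plaques.iterrows():
        section_spots = spots[spots["section_id"] == row["section_id"]]
        layers.append(
            assign_plaque_layer((row["x_um"], row["y_um"]), section_spots, radius)
        )
    out["layer"] = layers
    return out


def layer_plaque_rate(
    plaques: pd.DataFrame, layer_spot_counts: pd.Series
) -> tuple[pd.DataFrame, dict]:
    """Plaques-per-spot rate per layer and the deep/upper (L4-6 / L1-3) ratio.

    Returns the per-layer rate table and a summary dict with the pooled
    deep/upper ratio and a two-sided conditional binomial p-value (deep
    plaque count given the grey-matter total, expected proportion equal to
    the deep spot fraction).
    """
    if len(plaques) == 0:
        return (
            pd.DataFrame(columns=["layer", "n_plaques", "n_spots", "rate"]),
            {"ratio": np.nan, "p_value": np.nan, "n_deep": 0, "n_upper": 0},
        )
    counts = plaques["layer"].value_counts()
    rows = []
    for layer in LAYER_NAMES:
        n_spots = int(layer_spot_counts.get(layer, 0))
        if n_spots == 0:
            continue
        n_pl = int(counts.get(layer, 0))
        rows.append(
            {"layer": layer, "n_plaques": n_pl, "n_spots": n_spots,
             "rate": n_pl / n_spots}
        )
    table = pd.DataFrame(rows)

    n_deep = int(counts.reindex(DEEP_LAYERS).fillna(0).sum())
    n_upper = int(counts.reindex(UPPER_LAYERS).fillna(0).sum())
    spots_deep = float(sum(layer_spot_counts.get(l, 0) for l in DEEP_LAYERS))
    spots_upper = float(sum(layer_spot_counts.get(l, 0) for l in UPPER_LAYERS))
    if spots_deep > 0 and spots_upper > 0 and n_upper > 0:
        ratio = (n_deep / spots_deep) / (n_upper / spots_upper)
    else:
        ratio = np.inf if n_deep > 0 else np.nan
    total = n_deep + n_upper
    if total > 0 and spots_deep + spots_upper > 0:
        p_expected = spots_deep / (spots_deep + spots_upper)
        p_value = stats.binomtest(n_deep, total, p_expected).pvalue
    else:
        p_value = np.nan
    summary = {
        "ratio": ratio,
        "p_value": p_value,
        "n_deep": n_deep,
        "n_upper": n_upper,
    }
    return table, summary


def annotate_spots(
    spots: pd.DataFrame,
    plaques: pd.DataFrame,
    near: float = NEAR_UM,
    far: float = FAR_UM,
) -> pd.DataFrame:
    """Convenience: distances plus strata as a copy of ``spots``."""
    out = spots.copy()
    out["plaque_dist_um"] = nearest_plaque_distance(spots, plaques)
    out["stratum"] = classify_spots(out["plaque_dist_um"], near=near, far=far)
    return out
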