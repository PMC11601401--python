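"""Mixed-model enrichment of cell states at plaques and in AD tissue.

Within-major-type proportions are logit-transformed (with boundary
clipping) and modelled per state by a linear mixed model with a section
random intercept.  The plaque contrast compares plaque-proximal versus
control spots with sex and cortical layer as covariates; the AD contrast
drops all plaque spots, adds non-AD control sections, and replaces the
spot-status term with the donor's AD status.  Status coefficients are
log odds ratios; exp(beta) - 1 is reported as the percent change in odds,
with Wald p-values and Benjamini-Hochberg FDR across states per contrast.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .geometry import STRATUM_CONTROL, STRATUM_PLAQUE
from .mixed import fit_lmm

LOGIT_EPS = 1e-3


def logit_clipped(p: np.ndarray, eps: float = LOGIT_EPS) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def _design(obs: pd.DataFrame, status: np.ndarray) -> tuple[np.ndarray, list[str]]:
    sex = (obs["sex"].astype(str) == "M").astype(float).to_numpy()
    parts = [np.ones(len(obs)), status, sex]
    names = ["intercept", "status", "sex_M"]
    if "layer" in obs:
        dummies = pd.get_dummies(obs["layer"].astype(str), drop_first=True, dtype=float)
        parts.append(dummies.to_numpy())
        names.extend(dummies.columns)
    return np.column_stack(parts), names


def _test_states(
    proportions: pd.DataFrame,
    obs: pd.DataFrame,
    status: np.ndarray,
    contrast: str,
) -> pd.DataFrame:
    X, _ = _design(obs, status)
    groups = obs["section_id"].to_numpy()
    rows = []
    for state in proportions.columns:
        p = proportions[state].to_numpy(dtype=float)
        ok = np.isfinite(p)
        if ok.sum() < X.shape[1] + 2 or np.all(p[ok] <= 0):
            warnings.warn(f"state {state} absent or undefined; skipped")
            continue
        y = logit_clipped(p[ok])
        fit = fit_lmm(y, X[ok], groups[ok])
        z, pval = fit.wald(1)
        rows.append(
            {
                "state": state,
                "log_or": float(fit.beta[1]),
                "se": fit.se(1),
                "pct_higher_odds": 100.0 * (np.exp(fit.beta[1]) - 1.0),
                "p": pval,
                "contrast": contrast,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table.sort_values("p", kind="stable").reset_index(drop=True) if len(table) else table


def test_enrichment(
    proportions: pd.DataFrame, obs: pd.DataFrame
) -> pd.DataFrame:
    """Plaque-versus-control spot enrichment per cell state.

    ``obs`` must align with ``proportions`` rows and provide stratum, sex,
    layer, and section_id; only plaque/control spots are used.
    """
    keep = obs["stratum"].isin([STRATUM_PLAQUE, STRATUM_CONTROL]).to_numpy()
    if "layer" in obs:
        keep &= (obs["layer"] != "WM").to_numpy()
    sub_obs = obs.loc[keep]
    status = (sub_obs["stratum"] == STRATUM_PLAQUE).to_numpy(dtype=float)
    if status.sum() == 0 or status.sum() == len(status):
        raise ValueError("need both plaque and control spots")
    return _test_states(proportions.loc[keep], sub_obs, status, "plaque-vs-control")


def test_ad_vs_control(
    proportions: pd.DataFrame, obs: pd.DataFrame
) -> pd.DataFrame:
    """AD-versus-control tissue contrast on non-plaque spots.

    Only spots distant from any plaque enter: control-stratum spots from AD
    sections and all spots of plaque-free non-AD sections.  ``obs`` needs
    an ``ad`` boolean column.
    """
    keep = obs["stratum"].isin([STRATUM_CONTROL, "no_plaque_section"]).to_numpy()
    if "layer" in obs:
        keep &= (obs["layer"] != "WM").to_numpy()
    sub_obs = obs.loc[keep]
    ad_status = sub_obs["ad"].to_numpy(dtype=float)
    if len(np.unique(ad_status)) < 2:
        raise ValueError("need both AD and non-AD sections")
    return _test_states(proportions.loc[keep], sub_obs, ad_status, "ad-vs-nonad")
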