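"""Two-part hurdle mixed-model differential expression at plaques.

Each gene's normalized expression is modelled in two parts: a logistic
component for the detection indicator (value > 0) and a Gaussian component
for the expression level among detected spots.  Both parts share the same
design -- plaque/control status, cortical layer, and cell detection rate
(CDR) as fixed effects, with a section random intercept -- and the status
effect is tested by a likelihood-ratio test that sums the two components'
chi-square statistics.  Genes pass the significance rule only when both
the Benjamini-Hochberg FDR is below 0.05 and the absolute model-based
log2 fold change exceeds 0.05.

The log2 fold change is the difference of the two-part expectations
(detection probability times conditional mean) between plaque and control
spots, evaluated at the average CDR and the reference layer; when
detection is saturated it reduces to the continuous status coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geometry import STRATUM_CONTROL, STRATUM_PLAQUE
from .mixed import (
    LMMFit,
    LogisticFit,
    fit_lmm,
    fit_logistic,
    fit_logistic_mixed,
    ols_llf,
)

MIN_DETECTION = 0.05
FDR_THRESHOLD = 0.05
LFC_THRESHOLD = 0.05
_SIGMA_BOUNDARY = 1.5e-3  # optimizer floor; at or below, treat variance as zero


def compute_cdr(values: np.ndarray) -> np.ndarray:
    """Fraction of the tested gene universe detected (value > 0) per spot."""
    values = np.asarray(values)
    if values.shape[1] == 0:
        raise ValueError("empty gene universe")
    return (values > 0).mean(axis=1)


def filter_testable_genes(
    values: np.ndarray, gene_names, min_detection: float = MIN_DETECTION
) -> list[str]:
    """Genes detected in at least ``min_detection`` of the pooled spots."""
    frac = (np.asarray(values) > 0).mean(axis=0)
    return [g for g, f in zip(gene_names, frac) if f >= min_detection]


@dataclass
class HurdleDesign:
    """Design matrices shared by the two hurdle components."""

    full: np.ndarray  # intercept, status, layer dummies, CDR
    reduced: np.ndarray  # full minus the status column
    status: np.ndarray  # 0/1 per spot
    sections: np.ndarray
    mean_cdr: float
    status_col: int = 1
    cdr_col: int = -1
    n_sections: int = 0
    columns: list[str] = field(default_factory=list)

    @classmethod
    def from_obs(cls, obs: pd.DataFrame, cdr: np.ndarray) -> "HurdleDesign":
        strata = obs["stratum"].to_numpy()
        bad = set(strata) - {STRATUM_PLAQUE, STRATUM_CONTROL}
        if bad:
            raise ValueError(f"only plaque/control strata allowed, got {bad}")
        status = (strata == STRATUM_PLAQUE).astype(float)
        layers = pd.get_dummies(obs["layer"], drop_first=True, dtype=float)
        cols = np.column_stack(
            [np.ones(len(obs)), status, layers.to_numpy(), cdr]
        )
        names = ["intercept", "status", *layers.columns, "cdr"]
        reduced = np.delete(cols, 1, axis=1)
        sections = obs["section_id"].to_numpy()
        return cls(
            full=cols,
            reduced=reduced,
            status=status,
            sections=sections,
            mean_cdr=float(np.mean(cdr)),
            n_sections=len(np.unique(sections)),
            columns=names,
        )

    def with_section_dummies(self, X: np.ndarray) -> np.ndarray:
        dummies = pd.get_dummies(pd.Series(self.sections), drop_first=True, dtype=float)
        return np.column_stack([X, dummies.to_numpy()])


@dataclass
class ComponentFit:
    chi2: float
    df: int
    beta_status: float
    intercept: float
    beta_cdr: float
    flag: str = ""


def _predict_row(design: HurdleDesign, beta: np.ndarray, status: float) -> float:
    """Linear predictor at given status, mean CDR, reference layer."""
    return float(beta[0] + beta[1] * status + beta[-1] * design.mean_cdr)


def _fit_discrete(detected: np.ndarray, design: HurdleDesign) -> ComponentFit:
    if detected.all() or not detected.any():
        return ComponentFit(0.0, 0, 0.0, np.inf if detected.all() else -np.inf,
                            0.0, flag="degenerate_detection")
    y = detected.astype(float)
    use_mixed = design.n_sections >= 3
    if use_mixed:
        full: LogisticFit = fit_logistic_mixed(y, design.full, design.sections)
        if full.sigma_u <= _SIGMA_BOUNDARY:
            use_mixed = False
        else:
            red = fit_logistic_mixed(y, design.reduced, design.sections)
    if not use_mixed:
        Xf = design.with_section_dummies(design.full)
        Xr = design.with_section_dummies(design.reduced)
        full = fit_logistic(y, Xf)
        red = fit_logistic(y, Xr)
    # perfect separation on the tested contrast: status coefficient diverges
    if full.separated or red.separated or abs(full.beta[1]) > 10.0:
        return ComponentFit(0.0, 0, 0.0, 0.0, 0.0, flag="separation")
    chi2 = max(0.0, 2.0 * (full.llf - red.llf))
    ncov = design.full.shape[1]
    return ComponentFit(
        chi2=chi2,
        df=1,
        beta_status=float(full.beta[1]),
        intercept=float(full.beta[0]),
        beta_cdr=float(full.beta[ncov - 1]),
    )


def _fit_continuous(
    values: np.ndarray, detected: np.ndarray, design: HurdleDesign
) -> ComponentFit:
    det = np.flatnonzero(detected)
    status_det = design.status[det]
    if len(det) < design.full.shape[1] + 2 or len(np.unique(status_det)) < 2:
        return ComponentFit(0.0, 0, 0.0, 0.0, 0.0, flag="singular_continuous")
    y = values[det]
    Xf, Xr = design.full[det], design.reduced[det]
    groups = design.sections[det]
    use_mixed = design.n_sections >= 3 and len(np.unique(groups)) >= 3
    if use_mixed:
        full: LMMFit = fit_lmm(y, Xf, groups)
        if full.tau2 <= 1e-10:
            use_mixed = False
        else:
            red = fit_lmm(y, Xr, groups)
            beta = full.beta
            llf_full, llf_red = full.llf, red.llf
    if not use_mixed:
        dums = pd.get_dummies(pd.Series(groups), drop_first=True, dtype=float).to_numpy()
        beta, llf_full = ols_llf(y, np.column_stack([Xf, dums]))
        _, llf_red = ols_llf(y, np.column_stack([Xr, dums]))
    chi2 = max(0.0, 2.0 * (llf_full - llf_red))
    ncov = design.full.shape[1]
    return ComponentFit(
        chi2=chi2,
        df=1,
        beta_status=float(beta[1]),
        intercept=float(beta[0]),
        beta_cdr=float(beta[ncov - 1]),
    )


def lrt_combined(
    chi2_disc: float, df_disc: int, chi2_cont: float, df_cont: int
) -> tuple[float, int, float]:
    """Sum the component chi-squares; p from the chi-square upper tail."""
    chi2 = max(chi2_disc, 0.0) + max(chi2_cont, 0.0)
    df = df_disc + df_cont
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _log2fc(disc: ComponentFit, cont: ComponentFit, design: HurdleDesign,
            detection_rate: float) -> float:
    """Two-part expectation difference at mean CDR and reference layer."""
    if disc.flag == "degenerate_detection":
        p1 = p0 = detection_rate
    elif disc.flag:
        p1 = p0 = detection_rate
    else:
        eta0 = disc.intercept + disc.beta_cdr * design.mean_cdr
        p0 = 1.0 / (1.0 + np.exp(-np.clip(eta0, -30, 30)))
        p1 = 1.0 / (1.0 + np.exp(-np.clip(eta0 + disc.beta_status, -30, 30)))
    if cont.flag:
        mu0 = mu1 = cont.intercept + cont.beta_cdr * design.mean_cdr
    else:
        mu0 = cont.intercept + cont.beta_cdr * design.mean_cdr
        mu1 = mu0 + cont.beta_status
    return float(p1 * mu1 - p0 * mu0)


def fit_hurdle(values: np.ndarray, design: HurdleDesign) -> dict:
    """Fit full and reduced hurdle models for one gene; return test pieces."""
    values = np.asarray(values, dtype=float)
    detected = values > 0
    disc = _fit_discrete(detected, design)
    cont = _fit_continuous(values, detected, design)
    chi2, df, p = lrt_combined(disc.chi2, disc.df, cont.chi2, cont.df)
    return {
        "detection": float(detected.mean()),
        "log2fc": _log2fc(disc, cont, design, float(detected.mean())),
        "chisq_disc": disc.chi2,
        "chisq_cont": cont.chi2,
        "df": df,
        "p": p,
        "flag": ";".join(f for f in (disc.flag, cont.flag) if f),
    }


def run_de(
    adata: ad.AnnData,
    plaques: pd.DataFrame | None = None,
    layer: str = "lognorm",
    min_detection: float = MIN_DETECTION,
    fdr_threshold: float = FDR_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> pd.DataFrame:
    """Plaque-versus-control differential expression over all testable genes.

    ``adata.obs`` must provide stratum, layer, and section_id; white-matter
    spots and spots outside the plaque/control strata are dropped here.
    When a plaque table with assigned layers is given, only sections with
    at least one grey-matter plaque are analysed.
    """
    obs = adata.obs
    keep = obs["stratum"].isin([STRATUM_PLAQUE, STRATUM_CONTROL]) & (
        obs["layer"] != "WM"
    )
    if plaques is not None and "layer" in plaques:
        gm = plaques[~plaques["layer"].isin(["WM", "unassigned"])]
        good_sections = set(gm["section_id"])
        keep &= obs["section_id"].isin(good_sections)
    sub = adata[np.asarray(keep)]
    if sub.n_obs == 0 or (sub.obs["stratum"] == STRATUM_PLAQUE).sum() == 0:
        import warnings

        warnings.warn("no plaque-bearing spots available; empty DE table")
        return pd.DataFrame(
            columns=["gene", "detection", "log2fc", "chisq_disc", "chisq_cont",
                     "df", "p", "fdr", "significant"]
        )
    values = np.asarray(sub.layers[layer])
    genes = filter_testable_genes(values, sub.var_names, min_detection)
    if not genes:
        return pd.DataFrame(
            columns=["gene", "detection", "log2fc", "chisq_disc", "chisq_cont",
                     "df", "p", "fdr", "significant"]
        )
    gene_idx = [sub.var_names.get_loc(g) for g in genes]
    universe = values[:, gene_idx]
    cdr = compute_cdr(universe)
    design = HurdleDesign.from_obs(sub.obs, cdr)

    rows = []
    for g, gi in zip(genes, gene_idx):
        res = fit_hurdle(values[:, gi], design)
        res["gene"] = g
        rows.append(res)
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = (table["fdr"] < fdr_threshold) & (
        table["log2fc"].abs() > lfc_threshold
    )
    cols = ["gene", "detection", "log2fc", "chisq_disc", "chisq_cont", "df",
            "p", "fdr", "significant", "flag"]
    return table[cols].sort_values("p", kind="stable").reset_index(drop=True)
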