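"""Reference-signature construction and per-spot cell-state abundance.

Signatures are per-state means of library-size-normalized nucleus counts
rescaled to the counts-per-nucleus scale.  Spot abundances are estimated
by penalized nonnegative Poisson regression of the spot's counts on the
signature matrix, solved by multiplicative (EM-style) updates, with a soft
quadratic penalty pulling the total abundance toward a prior expected
number of cells per spot.  Mitochondrial and ribosomal gene families are
excluded before estimation, and abundances are converted to proportions
of each state within its major cell type.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .synthdata.reference import ReferenceSignatures

CELLS_PRIOR = 4.0
EXCLUDED_GENE_PATTERNS = (r"^MT-", r"^RPL", r"^RPS", r"^MRPL", r"^MRPS")


@dataclass
class AbundanceEstimate:
    """Spot x state expected cell counts and within-major-type proportions."""

    abundance: pd.DataFrame  # spots x states
    proportions: pd.DataFrame  # spots x states, within each major type
    major_type: pd.Series  # state -> major type
    flagged_spots: list[str]


def build_signatures(
    nuclei: ad.AnnData,
    state_col: str = "state",
    major_col: str = "major_type",
    cell_count_cutoff: int = 5,
    cell_percentage_cutoff: float = 0.001,
    nonz_mean_cutoff: float = 1.06,
    min_state_frequency: float = 0.0,
) -> ReferenceSignatures:
    """Per-state mean expression from labelled nuclei counts.

    Genes present in fewer than ``cell_percentage_cutoff`` of nuclei AND
    with a nonzero mean below ``nonz_mean_cutoff`` are removed as
    uninformative; states rarer than ``min_state_frequency`` within their
    major type (or with fewer than ``cell_count_cutoff`` nuclei) are
    dropped.
    """
    X = np.asarray(nuclei.X, dtype=float)
    states = nuclei.obs[state_col].astype(str)
    majors = nuclei.obs[major_col].astype(str)

    detected_frac = (X > 0).mean(axis=0)
    with np.errstate(invalid="ignore"):
        nonz_mean = np.where(
            (X > 0).sum(axis=0) > 0,
            X.sum(axis=0) / np.maximum((X > 0).sum(axis=0), 1),
            0.0,
        )
    keep_genes = ~((detected_frac < cell_percentage_cutoff) & (nonz_mean < nonz_mean_cutoff))
    genes = np.asarray(nuclei.var_names)[keep_genes]
    X = X[:, keep_genes]

    lib = X.sum(axis=1)
    ok = lib > 0
    X, states, majors = X[ok], states[ok], majors[ok]
    lib = lib[ok]
    norm = X / lib[:, None]

    kept_states, means, state_major = [], [], {}
    counts = states.value_counts()
    type_totals = majors.value_counts()
    for state in sorted(counts.index):
        n = int(counts[state])
        major = majors[states == state].iloc[0]
        freq = n / int(type_totals[major])
        if n < cell_count_cutoff or freq < min_state_frequency:
            warnings.warn(f"state {state} dropped ({n} nuclei, {freq:.1%} of {major})")
            continue
        mask = (states == state).to_numpy()
        profile = norm[mask].mean(axis=0) * float(lib[mask].mean())
        kept_states.append(state)
        means.append(profile)
        state_major[state] = major
    if not kept_states:
        raise ValueError("no states survive the filters")
    means_df = pd.DataFrame(
        np.column_stack(means), index=genes, columns=kept_states
    )
    return ReferenceSignatures(
        means=means_df,
        major_type=pd.Series(state_major, name="major_type"),
        marker_blocks={},
    )


def exclude_gene_families(
    genes, patterns=EXCLUDED_GENE_PATTERNS
) -> list[str]:
    """Drop mitochondrial/ribosomal-style gene names by prefix regex."""
    compiled = [re.compile(p) for p in patterns]
    return [g for g in genes if not any(c.match(g) for c in compiled)]


def estimate_abundance(
    adata: ad.AnnData,
    signatures: ReferenceSignatures,
    cells_prior: float = CELLS_PRIOR,
    prior_strength: float = 0.1,
    max_iter: int = 200,
    tol: float = 1e-6,
    exclude_patterns=EXCLUDED_GENE_PATTERNS,
) -> AbundanceEstimate:
    """Nonnegative Poisson regression of spot counts on state signatures.

    Maximises  sum_g [ y_g log(yhat_g) - yhat_g ]  -  rho (sum_k a_k - N)^2
    per spot, with yhat = S a, by multiplicative updates that keep every
    abundance nonnegative (all spots are updated simultaneously as one
    matrix operation).  ``cells_prior`` = N is the prior expected total
    number of cells per spot; ``prior_strength`` = rho.
    """
    shared = [g for g in signatures.genes if g in set(adata.var_names)]
    shared = exclude_gene_families(shared, exclude_patterns)
    if not shared:
        raise ValueError("no shared genes between spots and signatures")
    S = signatures.means.loc[shared].to_numpy()  # genes x states
    Y = np.asarray(adata[:, shared].X, dtype=float)  # spots x genes
    n_spots, n_states = Y.shape[0], S.shape[1]

    zero_spots = Y.sum(axis=1) == 0
    A = np.full((n_spots, n_states), cells_prior / n_states)
    colsum = S.sum(axis=0)  # per-state signature mass
    rho = prior_strength
    for _ in range(max_iter):
        Yhat = A @ S.T
        ratio = np.divide(Y, np.maximum(Yhat, 1e-12))
        numer = ratio @ S + 2.0 * rho * cells_prior
        denom = colsum[None, :] + 2.0 * rho * A.sum(axis=1, keepdims=True)
        A_new = A * numer / np.maximum(denom, 1e-12)
        if np.max(np.abs(A_new - A)) < tol:
            A = A_new
            break
        A = A_new
    A[zero_spots] = 0.0

    abundance = pd.DataFrame(A, index=adata.obs_names, columns=signatures.states)
    proportions = abundance.copy()
    majors = signatures.major_type
    for major in majors.unique():
        cols = [s for s in signatures.states if majors[s] == major]
        total = abundance[cols].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            proportions[cols] = abundance[cols].div(total, axis=0)
        proportions.loc[total <= 0, cols] = np.nan
    flagged = list(abundance.index[zero_spots])
    return AbundanceEstimate(
        abundance=abundance,
        proportions=proportions,
        major_type=majors.copy(),
        flagged_spots=flagged,
    )
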