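"""All-pairs Spearman correlation and co-occurrence edge filtering.

Edges of the co-occurrence network are unordered OTU pairs whose abundance
profiles are strongly rank-correlated: |rho| >= 0.6 and p < 0.001 by
default.  The sign is kept as an edge attribute — negative correlations
(e.g. predator-prey) are retained, which is why the threshold is applied to
|rho|.  No multiple-testing correction is applied by default; the stringent
p-gate is the filter.  An optional Benjamini-Hochberg mode exists.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import AbundanceTable, PipelineConfig

logger = logging.getLogger("benthonet")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Average ranks are used for ties.  For n > 9 the p-value comes from the
    t approximation; for n <= 9 it is computed by exact enumeration of all
    n! permutations of one variable (valid with ties as a permutation
    test).  Constant input gives (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"))
    n = x.size
    if n > 9:
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = _rank_corr(rx, ry)
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    cx = rx - rx.mean()
    cp = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((cx**2).sum() * (cp**2).sum(axis=1))
    rhos = cp @ cx / denom
    p = float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return float(rho_obs), p


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def spearman_matrix(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman rho and two-sided p for the rows of ``counts``.

    Vectorised: rows are rank-transformed once, rho is a Pearson product
    over ranks, and p uses the t approximation (appropriate for the sample
    sizes this pipeline runs at).
    """
    n = counts.shape[1]
    ranks = stats.rankdata(counts, axis=1).astype(float)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    constant = norms == 0
    norms[constant] = 1.0
    z = ranks / norms[:, None]
    rho = np.clip(z @ z.T, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return rho, p


def edge_table(
    table: AbundanceTable,
    config: PipelineConfig | None = None,
    return_filtered_otus: bool = False,
    bh_correction: bool = False,
):
    """Filtered signed co-occurrence edges among (core) OTUs.

    A prevalence filter keeps OTUs present in at least
    ``config.prevalence_min_fraction`` of samples (network sensitivity/
    specificity filter), then all pairwise Spearman correlations are
    thresholded at |rho| >= rho_edge_threshold and p < p_edge_threshold.
    Returns a DataFrame with columns otu_a, otu_b (a < b), rho, p, sign.
    """
    config = config or PipelineConfig()
    counts = table.data.to_numpy(dtype=float)
    n_samples = counts.shape[1]
    prevalence = np.count_nonzero(counts, axis=1) / n_samples
    keep = prevalence >= config.prevalence_min_fraction
    kept_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    logger.info(
        "edge_table: prevalence filter kept %d/%d OTUs (>= %.0f%% of samples)",
        len(kept_ids), table.n_otus, 100 * config.prevalence_min_fraction,
    )
    if len(kept_ids) < 2:
        empty = pd.DataFrame(columns=["otu_a", "otu_b", "rho", "p", "sign"])
        return (empty, kept_ids) if return_filtered_otus else empty

    sub = counts[keep]
    rho, p = spearman_matrix(sub)
    if bh_correction:
        iu = np.triu_indices_from(p, k=1)
        flat = p[iu]
        adj = _benjamini_hochberg(flat)
        p = p.copy()
        p[iu] = adj
        p.T[iu] = adj

    iu, ju = np.triu_indices(len(kept_ids), k=1)
    mask = (
        (np.abs(rho[iu, ju]) >= config.rho_edge_threshold)
        & (p[iu, ju] < config.p_edge_threshold)
        & ~np.isnan(rho[iu, ju])
    )
    rows = []
    for i, j in zip(iu[mask], ju[mask]):
        a, b = kept_ids[i], kept_ids[j]
        if b < a:
            a, b = b, a
        r = float(rho[i, j])
        rows.append({
            "otu_a": a, "otu_b": b, "rho": r, "p": float(p[i, j]),
            "sign": "positive" if r >= 0 else "negative",
        })
    edges = pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p", "sign"])
    edges = edges.sort_values(["otu_a", "otu_b"]).reset_index(drop=True)
    return (edges, kept_ids) if return_filtered_otus else edges


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
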