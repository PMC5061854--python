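"""Module eigengenes, eigengene-environment correlation, and PERMANOVA.

A module eigengene is the first right-singular vector of the module's
standardized OTU x sample abundance matrix: a unit-norm per-sample score
summarizing the module's dominant abundance pattern, sign-oriented to
correlate positively with the module's mean standardized profile.

PERMANOVA partitions the variance of a sample x sample distance matrix
among ordered model terms via the Gower-centered inner-product matrix,
with pseudo-F statistics and free-permutation p-values.  Community
distances are Bray-Curtis on (rarefied) counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io_core import AbundanceTable

logger = logging.getLogger("benthonet")


@dataclass
class Eigengene:
    module: int
    scores: pd.Series          # per-sample, unit Euclidean norm
    variance_explained: float  # first squared singular value / total
    orientation_sign: int      # +1/-1 flip applied to meet the orientation rule


def eigengene(module_table: AbundanceTable | pd.DataFrame, module: int = 0) -> Eigengene:
    """First singular vector of a module's standardized abundance profile.

    OTU rows are standardized to zero mean / unit variance across samples
    (constant rows dropped); the eigengene is the first right-singular
    vector of the standardized matrix, oriented to correlate positively
    with the mean standardized profile.
    """
    df = module_table.data if isinstance(module_table, AbundanceTable) else module_table
    if df.shape[0] < 2 or df.shape[1] < 3:
        raise ValueError("module needs >= 2 OTUs and >= 3 samples")
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant OTU profiles in module")
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    v1 = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = z.mean(axis=0)
    sign = 1 if float(np.dot(v1, mean_profile)) >= 0 else -1
    v1 = sign * v1
    return Eigengene(
        module=module,
        scores=pd.Series(v1, index=df.columns, name=f"module_{module}"),
        variance_explained=var_explained,
        orientation_sign=sign,
    )


def module_eigengenes(table: AbundanceTable, modules: dict) -> list[Eigengene]:
    """Eigengene per module (>= 2 member OTUs present in the table)."""
    out = []
    for mod in sorted(set(modules.values())):
        members = [o for o, m in modules.items() if m == mod and o in table.data.index]
        if len(members) < 2:
            logger.warning("module %s has < 2 OTUs in the table; skipped", mod)
            continue
        try:
            out.append(eigengene(table.subset_otus(members), module=mod))
        except ValueError as exc:
            logger.warning("module %s eigengene skipped: %s", mod, exc)
    return out


def eigengenes_frame(eigengenes: list[Eigengene]) -> pd.DataFrame:
    """Modules x samples matrix of eigengene scores."""
    return pd.DataFrame({f"module_{e.module}": e.scores for e in eigengenes}).T


TRANSFORMS = {
    "log": lambda x: np.log(x),
    "log10": lambda x: np.log10(x),
    "log1p": lambda x: np.log1p(x),
    "square": lambda x: np.square(x),
    "identity": lambda x: x,
}


def apply_transform(values: pd.Series, name: str) -> pd.Series:
    if name not in TRANSFORMS:
        raise ValueError(f"unknown transform {name!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = TRANSFORMS[name](values.astype(float))
    return out.replace([np.inf, -np.inf], np.nan)


def correlate_env(
    eigengenes: list[Eigengene],
    metadata: pd.DataFrame,
    variables: list[str] | None = None,
    transforms: dict | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate each module eigengene with each environmental variable.

    Transforms (e.g. log salinity and fluoranthene, squared F/P) are
    applied before correlating; complete cases per pair, needing >= 4
    samples.  Returns a long DataFrame (module, variable, r, p, n).
    """
    transforms = transforms or {}
    if variables is None:
        variables = [c for c in metadata.columns if metadata[c].dtype.kind in "fiu"]
    rows = []
    for eg in eigengenes:
        for var in variables:
            vals = metadata[var].reindex(eg.scores.index)
            if var in transforms:
                vals = apply_transform(vals, transforms[var])
            pair = pd.DataFrame({"eg": eg.scores, "env": vals}).dropna()
            if len(pair) < 4 or pair["env"].nunique() <= 1:
                r, p = float("nan"), float("nan")
            elif method == "pearson":
                r, p = stats.pearsonr(pair["eg"], pair["env"])
            elif method == "spearman":
                r, p = stats.spearmanr(pair["eg"], pair["env"])
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append({"module": eg.module, "variable": var,
                         "r": float(r), "p": float(p), "n": len(pair)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    """Sequential variance decomposition of a distance matrix.

    ``table`` has one row per term plus "Residual" and "Total", with
    columns df, sum_sq, r2, pseudo_f, p.  Term and residual R2 sum to 1.
    """

    table: pd.DataFrame
    n_samples: int
    n_permutations: int

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "r2"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def permanova(
    distances: np.ndarray | pd.DataFrame,
    terms: list[str],
    metadata: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermanovaResult:
    """Distance-based multivariate ANOVA with sequential (ordered) terms.

    Continuous terms enter as single covariate columns; categorical
    (object/category dtype) terms are dummy-coded.  Samples with a missing
    value in any term are dropped (complete cases; n is logged).  P-values
    are by free permutation of sample identities, with the observed
    ordering included: p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if isinstance(distances, pd.DataFrame):
        ids = list(distances.index)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        ids = list(metadata.index[: d.shape[0]])
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")

    meta = metadata.reindex(ids)
    keep_terms = []
    for t in terms:
        col = meta[t]
        if col.dropna().nunique() <= 1:
            logger.warning("permanova: term %r constant after filtering; dropped", t)
            continue
        keep_terms.append(t)
    if not keep_terms:
        raise ValueError("no usable model terms")
    complete = meta[keep_terms].dropna().index
    mask = np.array([i in set(complete) for i in ids])
    d = d[np.ix_(mask, mask)]
    meta = meta.loc[[i for i, m in zip(ids, mask) if m]]
    n = d.shape[0]
    logger.info("permanova: n = %d complete-case samples, %d terms", n, len(keep_terms))
    if n < 3:
        raise ValueError("need >= 3 complete-case samples")

    g = _gower_center(d)
    design_cols: list[np.ndarray] = [np.ones((n, 1))]
    term_dfs: list[int] = []
    for t in keep_terms:
        col = meta[t]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            design_cols.append(dummies)
            term_dfs.append(dummies.shape[1])
        else:
            v = col.to_numpy(dtype=float).reshape(-1, 1)
            design_cols.append((v - v.mean()))
            term_dfs.append(1)

    def decompose(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.empty(len(keep_terms))
        x = design_cols[0]
        h_prev = _hat(x)
        for k in range(len(keep_terms)):
            x = np.hstack([x, design_cols[k + 1]])
            h = _hat(x)
            ss_terms[k] = np.trace((h - h_prev) @ gmat)
            h_prev = h
        ss_res = np.trace((np.eye(n) - h_prev) @ gmat)
        return ss_terms, float(ss_res)

    ss_total = float(np.trace(g))
    ss_terms, ss_res = decompose(g)
    df_res = n - 1 - sum(term_dfs)
    if df_res < 1:
        raise ValueError("model saturates the data; no residual degrees of freedom")
    f_obs = (ss_terms / np.array(term_dfs)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(keep_terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_rp = decompose(gp)
        f_p = (ss_p / np.array(term_dfs)) / (ss_rp / df_res)
        exceed += f_p >= f_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for t, dfk, ssk, fk, pk in zip(keep_terms, term_dfs, ss_terms, f_obs, pvals):
        rows.append({"term": t, "df": dfk, "sum_sq": ssk, "r2": ssk / ss_total,
                     "pseudo_f": fk, "p": pk})
    rows.append({"term": "Residual", "df": df_res, "sum_sq": ss_res,
                 "r2": ss_res / ss_total, "pseudo_f": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "sum_sq": ss_total,
                 "r2": 1.0, "pseudo_f": np.nan, "p": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=table, n_samples=n, n_permutations=n_perm)


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity matrix from counts."""
    x = table.data.to_numpy(dtype=float).T
    d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def permanova_bray_curtis(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermanovaResult:
    """PERMANOVA of community composition (Bray-Curtis) on metadata terms."""
    return permanova(bray_curtis(table), terms, metadata, n_perm=n_perm, seed=seed)
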