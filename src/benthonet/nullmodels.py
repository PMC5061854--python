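"""Checkerboard C-score, ecological null matrices, and standardized effect
size.

The C-score of a pair of taxa with occupancies R_i, R_j sharing S_ij sites
is (R_i - S_ij)(R_j - S_ij): the number of checkerboard units, an inverse
measure of co-occurrence.  The community-level score is the mean over all
unordered pairs.  Non-randomness is assessed against null presence/absence
matrices; the default null preserves each site's (column's) species
richness, reassigning presences to taxa equiprobably within each site.
SES = (observed - null mean) / null sd; positive values indicate
segregation (less co-occurrence than chance), negative values aggregation,
and |SES| <= 2 is the chance band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .io_core import AbundanceTable

NULL_ALGORITHMS = ("fixed_site_frequencies", "fixed_occupancies", "swap")


def presence_matrix(table: AbundanceTable | np.ndarray) -> np.ndarray:
    """Binary taxa x sites matrix: present iff count > 0."""
    arr = table.counts if isinstance(table, AbundanceTable) else np.asarray(table)
    return (arr > 0).astype(np.int8)


def cscore_pair(row_i, row_j) -> int:
    """Checkerboard units for one pair: (R_i - S)(R_j - S)."""
    a = np.asarray(row_i, dtype=bool)
    b = np.asarray(row_j, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("rows must have equal length")
    s = int(np.count_nonzero(a & b))
    return (int(a.sum()) - s) * (int(b.sum()) - s)


def mean_cscore(matrix: np.ndarray, normalized: bool = False) -> float:
    """Mean C-score over all unordered row pairs.

    The normalized variant divides each pair's score by R_i * R_j (its
    maximum given the occupancies), giving a value in [0, 1]; pairs where
    either taxon is absent everywhere are skipped in that variant.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-d matrix with >= 2 rows")
    r = m.sum(axis=1)
    s = m @ m.T
    iu, ju = np.triu_indices(m.shape[0], k=1)
    c = (r[iu] - s[iu, ju]) * (r[ju] - s[iu, ju])
    if normalized:
        denom = r[iu] * r[ju]
        ok = denom > 0
        if not ok.any():
            return float("nan")
        return float(np.mean(c[ok] / denom[ok]))
    return float(np.mean(c))


def generate_null(matrix: np.ndarray, algorithm: str, rng: np.random.Generator,
                  n_swaps: int | None = None) -> np.ndarray:
    """One null presence/absence matrix.

    fixed_site_frequencies (default elsewhere): each column keeps its
    total; presences within a column land on equiprobable rows without
    replacement.  fixed_occupancies: same, row-wise.  swap: sequential
    2x2 checkerboard swaps preserving both margins (``n_swaps`` attempts,
    default 10 x number of presences).
    """
    m = np.asarray(matrix, dtype=np.int8)
    n_rows, n_cols = m.shape
    if algorithm == "fixed_site_frequencies":
        out = np.zeros_like(m)
        for j in range(n_cols):
            k = int(m[:, j].sum())
            if k:
                rows = rng.choice(n_rows, size=k, replace=False)
                out[rows, j] = 1
        return out
    if algorithm == "fixed_occupancies":
        out = np.zeros_like(m)
        for i in range(n_rows):
            k = int(m[i].sum())
            if k:
                cols = rng.choice(n_cols, size=k, replace=False)
                out[i, cols] = 1
        return out
    if algorithm == "swap":
        return _swap_null(m, rng, n_swaps)
    raise ValueError(f"unknown null algorithm {algorithm!r}")


def _swap_null(m: np.ndarray, rng: np.random.Generator,
               n_swaps: int | None) -> np.ndarray:
    out = m.copy()
    n_rows, n_cols = out.shape
    attempts = n_swaps if n_swaps is not None else 10 * max(1, int(out.sum()))
    swapped = 0
    for _ in range(attempts):
        i, j = rng.choice(n_rows, size=2, replace=False)
        k, l = rng.choice(n_cols, size=2, replace=False)
        sub = out[np.ix_([i, j], [k, l])]
        if sub[0, 0] == sub[1, 1] and sub[0, 1] == sub[1, 0] and sub[0, 0] != sub[0, 1]:
            out[np.ix_([i, j], [k, l])] = sub[::-1]
            swapped += 1
    if swapped == 0:
        warnings.warn("no swappable 2x2 submatrix found; returning input matrix",
                      stacklevel=2)
    return out


@dataclass
class NullModelReport:
    observed_cscore: float
    normalized_cscore: float
    null_mean: float
    null_sd: float
    ses: float
    p_greater: float
    p_less: float
    n_null: int
    algorithm: str
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def ses(matrix: np.ndarray, n_null: int = 5000,
        algorithm: str = "fixed_site_frequencies", seed: int = 0) -> NullModelReport:
    """Standardized effect size of the mean C-score against a null ensemble.

    p_greater = (1 + #{null >= observed}) / (1 + n_null), and analogously
    p_less; both include the observed matrix, so neither can be 0 and
    p_greater + p_less >= 1.  A degenerate null (sd = 0) yields SES = nan.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100 for a stable SES")
    m = presence_matrix(matrix)
    if m.shape[0] < 2:
        raise ValueError("need >= 2 taxa")
    rng = np.random.default_rng(seed)
    obs = mean_cscore(m)
    nulls = np.empty(n_null)
    for k in range(n_null):
        nulls[k] = mean_cscore(generate_null(m, algorithm, rng))
    mu = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd == 0.0:
        warnings.warn("null distribution has zero variance; SES undefined",
                      stacklevel=2)
        ses_val = float("nan")
    else:
        ses_val = (obs - mu) / sd
    return NullModelReport(
        observed_cscore=obs,
        normalized_cscore=mean_cscore(m, normalized=True),
        null_mean=mu,
        null_sd=sd,
        ses=ses_val,
        p_greater=float((1 + np.sum(nulls >= obs)) / (1 + n_null)),
        p_less=float((1 + np.sum(nulls <= obs)) / (1 + n_null)),
        n_null=n_null,
        algorithm=algorithm,
        seed=seed,
    )
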