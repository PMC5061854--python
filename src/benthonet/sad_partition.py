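"""Core/satellite partition of the species abundance distribution.

Each OTU's index of dispersion — the variance-to-mean ratio (VMR) of its
counts across samples, multiplied by its occurrence (number of samples where
it is present) — is compared against chi-square confidence limits.  Under a
Poisson (random-dispersal) null the VMR is near 1 and the statistic falls
inside the central band; widely distributed, environmentally structured
OTUs are overdispersed and exceed the upper limit.  OTUs above the upper
limit are classified *core*; all others *satellite*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import AbundanceTable, PipelineConfig

logger = logging.getLogger("benthonet")


def dispersion_index(counts: np.ndarray) -> tuple[int, float, float, float]:
    """Return (occurrence, mean, VMR, dispersion statistic) for one OTU.

    Mean and unbiased (n-1) variance are taken over *all* samples, zeros
    included.  VMR is defined as 0 when the mean is 0 (all-zero OTU), and
    the dispersion statistic is VMR times occurrence.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("need a 1-d count vector over >= 2 samples")
    occurrence = int(np.count_nonzero(counts))
    mean = float(counts.mean())
    if mean == 0.0:
        warnings.warn("all-zero OTU: dispersion statistic set to 0", stacklevel=2)
        return 0, 0.0, 0.0, 0.0
    var = float(counts.var(ddof=1))
    vmr = var / mean
    return occurrence, mean, vmr, vmr * occurrence


def chi2_limits(
    occurrence: int,
    n_samples: int | None = None,
    quantiles: tuple[float, float] = (0.025, 0.975),
    df_convention: str = "occurrence",
) -> tuple[float, float]:
    """Chi-square quantile pair for the dispersion test.

    ``df_convention`` selects the degrees of freedom: ``occurrence``
    (default — matches multiplying VMR by the occurrence),
    ``occurrence_minus_1``, or the classical ``n_samples_minus_1``.
    Returns (nan, nan) when df < 1 after applying the convention; the
    caller then forces the satellite class.
    """
    if df_convention == "occurrence":
        df = occurrence
    elif df_convention == "occurrence_minus_1":
        df = occurrence - 1
    elif df_convention == "n_samples_minus_1":
        if n_samples is None:
            raise ValueError("n_samples required for the n_samples_minus_1 convention")
        df = n_samples - 1
    else:
        raise ValueError(f"unknown df convention {df_convention!r}")
    if df < 1:
        return (float("nan"), float("nan"))
    lo, hi = quantiles
    return (float(stats.chi2.ppf(lo, df)), float(stats.chi2.ppf(hi, df)))


@dataclass
class SadPartition:
    """Per-OTU dispersion records plus core/satellite summary."""

    records: pd.DataFrame  # otu_id index; occurrence, mean, vmr, stat, limits, class
    n_core: int
    n_satellite: int
    core_read_fraction: float
    quantiles: tuple[float, float]
    df_convention: str

    @property
    def core_otus(self) -> list[str]:
        return list(self.records.index[self.records["class"] == "core"])

    @property
    def satellite_otus(self) -> list[str]:
        return list(self.records.index[self.records["class"] == "satellite"])


def partition(table: AbundanceTable, config: PipelineConfig | None = None) -> SadPartition:
    """Classify every OTU as core or satellite by the dispersion test.

    Core iff the dispersion statistic exceeds the upper chi-square limit;
    OTUs inside the band or below the lower limit (underdispersed) are
    satellite.  Works on any table but a rarefied one is recommended:
    unequal column sums are logged.
    """
    config = config or PipelineConfig()
    table.require_min_shape()
    colsums = table.data.sum(axis=0).to_numpy()
    if len(set(colsums.tolist())) > 1:
        logger.info(
            "partition: unequal sample depths (%d..%d); rarefaction recommended",
            colsums.min(), colsums.max(),
        )

    counts = table.data.to_numpy(dtype=float)
    n_samples = counts.shape[1]
    occurrence = np.count_nonzero(counts, axis=1)
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vmr = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    stat = vmr * occurrence

    quantiles = (config.chi2_lower, config.chi2_upper)
    if config.df_convention == "occurrence":
        df = occurrence
    elif config.df_convention == "occurrence_minus_1":
        df = occurrence - 1
    else:
        df = np.full_like(occurrence, n_samples - 1)
    valid = df >= 1
    lower = np.full(len(df), np.nan)
    upper = np.full(len(df), np.nan)
    lower[valid] = stats.chi2.ppf(quantiles[0], df[valid])
    upper[valid] = stats.chi2.ppf(quantiles[1], df[valid])

    is_core = valid & (stat > upper)
    cls = np.where(is_core, "core", "satellite")

    records = pd.DataFrame(
        {
            "occurrence": occurrence,
            "mean": mean,
            "vmr": vmr,
            "stat": stat,
            "chi2_lower": lower,
            "chi2_upper": upper,
            "class": cls,
        },
        index=pd.Index(table.otu_ids, name="otu_id"),
    )
    total_reads = counts.sum()
    core_reads = counts[is_core].sum()
    frac = float(core_reads / total_reads) if total_reads > 0 else 0.0
    part = SadPartition(
        records=records,
        n_core=int(is_core.sum()),
        n_satellite=int((~is_core).sum()),
        core_read_fraction=frac,
        quantiles=quantiles,
        df_convention=config.df_convention,
    )
    logger.info(
        "partition: %d core / %d satellite OTUs; core reads %.1f%%",
        part.n_core, part.n_satellite, 100 * frac,
    )
    return part


def abundance_occupancy_stats(
    part: SadPartition, pseudocount: float = 1e-6
) -> tuple[float, float]:
    """Spearman correlation between log mean abundance and occurrence.

    A positive, significant correlation is the classical abundance-occupancy
    macro-ecological pattern.  Returns (nan, nan) when occurrence is
    constant across OTUs.
    """
    rec = part.records
    if len(rec) < 3:
        raise ValueError("need >= 3 OTUs")
    occ = rec["occurrence"].to_numpy(dtype=float)
    logmean = np.log(rec["mean"].to_numpy(dtype=float) + pseudocount)
    if np.all(occ == occ[0]) or np.all(logmean == logmean[0]):
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(logmean, occ)
    return float(rho), float(p)


def taxonomy_breakdown(
    part: SadPartition,
    table: AbundanceTable,
    taxonomy: pd.DataFrame,
    level: str = "class",
    minor_cutoff: float = 0.0,
) -> pd.DataFrame:
    """Read-weighted relative abundance per taxon within each group.

    Taxa whose group-level fraction is below ``minor_cutoff`` are pooled as
    "Other".  OTUs absent from the taxonomy are "Unclassified".  Each
    group's fractions sum to 1 (when the group has reads).
    """
    reads = table.data.sum(axis=1)
    labels = taxonomy[level] if level in taxonomy.columns else pd.Series(dtype=str)
    out = {}
    for group in ("core", "satellite"):
        otus = part.records.index[part.records["class"] == group]
        grp_reads = reads.reindex(otus).fillna(0.0)
        taxa = labels.reindex(otus).fillna("Unclassified")
        frac = grp_reads.groupby(taxa.to_numpy()).sum()
        total = frac.sum()
        frac = frac / total if total > 0 else frac
        if minor_cutoff > 0:
            minor = frac[frac < minor_cutoff]
            if len(minor):
                frac = frac.drop(minor.index)
                frac["Other"] = minor.sum()
        out[group] = frac
    df = pd.DataFrame(out).fillna(0.0)
    df.index.name = level
    return df
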