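"""PAH chemistry summaries and contaminated/pristine site classification.

Covers the 9-compound PAH sum used for sediment-quality-guideline (SQG)
comparison, the phenanthrene/anthracene (P/A) and fluoranthene/pyrene (F/P)
source-diagnostic ratios, hierarchical clustering of samples on their
11-compound PAH profile, rank-sum group comparison, and collinearity-based
proxy selection among environmental predictors.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_core import PAH9_COMPOUNDS, PAH_COMPOUNDS, ValidationError

logger = logging.getLogger("benthonet")


def pah9_sum(profile: pd.Series | dict) -> float:
    """Sum of the 9 guideline-covered PAH concentrations (ug/kg DW).

    Excludes benzo[g,h,i]perylene and indeno[1,2,3,c-d]pyrene.  Returns NaN
    if any of the 9 compounds is missing.
    """
    prof = pd.Series(profile, dtype=float)
    missing = [c for c in PAH9_COMPOUNDS if c not in prof.index or pd.isna(prof[c])]
    if missing:
        logger.warning("pah9_sum: missing compounds %s -> NA", missing)
        return float("nan")
    return float(prof[list(PAH9_COMPOUNDS)].sum())


def diagnostic_ratios(profile: pd.Series | dict) -> tuple[float, float, str]:
    """P/A and F/P source-diagnostic ratios and the source call.

    P/A = phenanthrene/anthracene, F/P = fluoranthene/pyrene.  P/A < 10
    together with F/P > 1 indicates a pyrogenic (combustion) source; the
    complementary pattern (P/A > 10 and F/P < 1) a petrogenic (fuel) one.
    Anything else, including undefined ratios, is indeterminate.
    """
    prof = pd.Series(profile, dtype=float)

    def _ratio(num: str, den: str) -> float:
        n, d = prof.get(num, np.nan), prof.get(den, np.nan)
        if pd.isna(n) or pd.isna(d) or d <= 0:
            return float("nan")
        return float(n / d)

    pa = _ratio("phenanthrene", "anthracene")
    fp = _ratio("fluoranthene", "pyrene")
    if np.isnan(pa) or np.isnan(fp):
        call = "indeterminate"
    elif pa < 10 and fp > 1:
        call = "pyrogenic"
    elif pa > 10 and fp < 1:
        call = "petrogenic"
    else:
        call = "indeterminate"
    return pa, fp, call


def guideline_exceedance(sigma_pah9: float, sqg_table: dict) -> dict:
    """Compare a 9-PAH sum against each guideline's own 9-compound sum.

    ``sqg_table`` maps guideline name (e.g. PEL/ERL/T50) to a compound ->
    threshold map.  Exceedance is strict (>): equality does not exceed.
    A guideline missing any of the 9 compounds yields None (NA).
    """
    flags: dict = {}
    for name, thresholds in sqg_table.items():
        missing = [c for c in PAH9_COMPOUNDS if c not in thresholds]
        if missing or pd.isna(sigma_pah9):
            flags[name] = None
            continue
        flags[name] = bool(sigma_pah9 > sum(thresholds[c] for c in PAH9_COMPOUNDS))
    return flags


@dataclass
class ContaminationCall:
    """Per-sample contamination labels and PAH summaries.

    ``table`` is indexed by sample id with columns: label, cluster,
    sigma_pah9, pa_ratio, fp_ratio, source, plus one exceeds_<guideline>
    column per guideline supplied.
    """

    table: pd.DataFrame
    merge_heights: dict  # region -> linkage merge heights (ascending)

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]


def classify_sites_hac(
    metadata: pd.DataFrame,
    region: pd.Series | None = None,
    linkage_method: str = "ward",
    log_transform: bool = True,
    sqg_table: dict | None = None,
) -> ContaminationCall:
    """Label samples contaminated/pristine by 2-cluster hierarchical
    agglomerative classification of their 11-PAH profiles.

    Each region (if ``region`` is given) is clustered independently on
    Euclidean distances of (by default) log10(x+1)-transformed
    concentrations; the cluster with the higher mean 9-PAH sum is labeled
    contaminated.  Samples with incomplete PAH vectors are left out.
    """
    pah_cols = [c for c in PAH_COMPOUNDS if c in metadata.columns]
    if len(pah_cols) < 2:
        raise ValidationError("metadata lacks PAH concentration columns")
    complete = metadata[pah_cols].dropna()
    if region is None:
        groups = {"all": complete.index}
    else:
        region = region.reindex(complete.index)
        groups = {str(r): idx for r, idx in complete.groupby(region).groups.items()}

    rows = []
    heights: dict = {}
    for reg, idx in groups.items():
        sub = complete.loc[idx]
        if len(sub) < 4:
            raise ValidationError(
                f"region {reg!r} has {len(sub)} complete samples; need >= 4"
            )
        x = sub.to_numpy(dtype=float)
        if log_transform:
            x = np.log10(x + 1.0)
        if np.allclose(x, x[0]):
            raise ValidationError(f"region {reg!r}: all PAH profiles identical; no separation")
        dist = pdist(x, metric="euclidean")
        link = hierarchy.linkage(dist, method=linkage_method)
        heights[reg] = link[:, 2].tolist()
        clusters = hierarchy.fcluster(link, t=2, criterion="maxclust")
        sums = sub.apply(pah9_sum, axis=1)
        means = {c: sums[clusters == c].mean() for c in np.unique(clusters)}
        contaminated_cluster = max(means, key=lambda c: means[c])
        for sample, cl in zip(sub.index, clusters):
            profile = metadata.loc[sample, pah_cols]
            pa, fp, source = diagnostic_ratios(profile)
            s9 = pah9_sum(profile)
            row = {
                "sample_id": sample,
                "region": reg,
                "cluster": int(cl),
                "label": "contaminated" if cl == contaminated_cluster else "pristine",
                "sigma_pah9": s9,
                "pa_ratio": pa,
                "fp_ratio": fp,
                "source": source,
            }
            for g, flag in guideline_exceedance(s9, sqg_table or {}).items():
                row[f"exceeds_{g}"] = flag
            rows.append(row)
    table = pd.DataFrame(rows).set_index("sample_id")
    logger.info(
        "classify_sites_hac: %d contaminated / %d pristine",
        int((table["label"] == "contaminated").sum()),
        int((table["label"] == "pristine").sum()),
    )
    return ContaminationCall(table=table, merge_heights=heights)


def compare_groups_ranksum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney U test between two groups.

    Exact enumeration when both groups have n <= 8 and there are no ties;
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def collinearity_proxies(
    metadata: pd.DataFrame,
    variables: list[str] | None = None,
    threshold: float = 0.75,
    overrides: list[str] | None = None,
) -> tuple[list[list[str]], dict]:
    """Group collinear variables and pick one proxy per group.

    Builds a graph over variables with an edge wherever |Spearman rho| >=
    ``threshold`` (complete-case pairwise); connected components are the
    groups.  The default proxy is the member with the highest mean |rho|
    to the rest of its group; ``overrides`` lists preferred proxies — if a
    group contains one of them it is chosen (e.g. force fluoranthene for
    the PAH block, salinity for the salinity/latitude/temperature block).
    Constant variables are excluded with a warning.
    """
    if variables is None:
        variables = [
            c for c in metadata.columns
            if metadata[c].dtype.kind in "fiu"
        ]
    df = metadata[variables].astype(float)
    usable = []
    for v in variables:
        col = df[v].dropna()
        if col.nunique() <= 1:
            warnings.warn(f"constant variable {v!r} excluded from collinearity grouping",
                          stacklevel=2)
            continue
        usable.append(v)
    if len(df.dropna()) < 3:
        raise ValidationError("need >= 3 complete-case samples")

    g = nx.Graph()
    g.add_nodes_from(usable)
    rho_cache: dict[tuple[str, str], float] = {}
    for u, v in itertools.combinations(usable, 2):
        pair = df[[u, v]].dropna()
        if len(pair) < 3:
            continue
        rho = stats.spearmanr(pair[u], pair[v]).statistic
        rho_cache[(u, v)] = rho_cache[(v, u)] = float(rho)
        if abs(rho) >= threshold:
            g.add_edge(u, v)

    groups = [sorted(c) for c in nx.connected_components(g)]
    groups.sort(key=lambda c: (-len(c), c))
    proxies: dict = {}
    overrides = overrides or []
    for grp in groups:
        key = tuple(grp)
        forced = [m for m in overrides if m in grp]
        if forced:
            proxies[key] = forced[0]
        elif len(grp) == 1:
            proxies[key] = grp[0]
        else:
            mean_abs = {
                m: np.nanmean([abs(rho_cache.get((m, o), np.nan)) for o in grp if o != m])
                for m in grp
            }
            proxies[key] = max(mean_abs, key=lambda m: mean_abs[m])
    return groups, proxies
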