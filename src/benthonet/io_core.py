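"""Tabular/graph IO, configuration, rarefaction and the pipeline driver.

The central in-memory object is :class:`AbundanceTable`, an OTU x sample
matrix of non-negative integer counts backed by a pandas DataFrame.  All
readers validate on entry so downstream stages can assume clean inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("benthonet")

#: Canonical names of the 11 quantified PAH compounds (ug/kg dry weight).
PAH_COMPOUNDS = (
    "fluoranthene",
    "fluorene",
    "pyrene",
    "anthracene",
    "benz_a_anthracene",
    "benzo_a_pyrene",
    "benzo_ghi_perylene",
    "chrysene",
    "dibenz_ah_anthracene",
    "indeno_123cd_pyrene",
    "phenanthrene",
)

#: The 9 compounds covered by sediment quality guidelines and summed into
#: the total used for guideline comparison (excludes benzo[g,h,i]perylene
#: and indeno[1,2,3,c-d]pyrene).
PAH9_COMPOUNDS = (
    "fluoranthene",
    "pyrene",
    "anthracene",
    "benz_a_anthracene",
    "benzo_a_pyrene",
    "chrysene",
    "dibenz_ah_anthracene",
    "fluorene",
    "phenanthrene",
)

ENV_VARIABLES = ("salinity", "temperature", "latitude", "psd", "toc")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class AbundanceTable:
    """OTU x sample table of non-negative integer counts.

    Rows are OTUs, columns are samples.  Construction validates
    uniqueness of identifiers and non-negativity of every cell.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_non_numeric(df)
            raise ValidationError(f"non-numeric count at {bad}")
        if np.isnan(arr.astype(float)).any():
            r, c = np.argwhere(np.isnan(arr.astype(float)))[0]
            raise ValidationError(
                f"missing count at OTU {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at OTU {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an (n_otus, n_samples) int array (copy)."""
        return self.data.to_numpy(copy=True)

    @property
    def n_otus(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_otus(self, otu_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(otu_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data[list(sample_ids)])

    def require_min_shape(self, min_otus: int = 2, min_samples: int = 2) -> None:
        if self.n_otus < min_otus or self.n_samples < min_samples:
            raise ValidationError(
                f"table of shape {self.data.shape} too small for analysis "
                f"(need >= {min_otus} OTUs and >= {min_samples} samples)"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.data.equals(other.data)


def _first_non_numeric(df: pd.DataFrame) -> str:
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            return f"OTU {df.index[i]!r}, sample {col!r}"
    return "unknown cell"


def read_abundance_table(
    path: str | Path, samples_as_rows: bool = False, sep: str | None = None
) -> AbundanceTable:
    """Read an OTU count table from TSV/CSV.

    Parameters
    ----------
    path:
        File with a header row of sample ids and a first column of OTU ids
        (or transposed; see ``samples_as_rows``).
    samples_as_rows:
        If True the file is sample-rows x OTU-columns and is transposed on
        read, so the in-memory orientation is always OTU x sample.
    sep:
        Field separator; inferred from the extension when None
        (``.csv`` -> comma, otherwise tab).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if samples_as_rows:
        df = df.T
    table = AbundanceTable(df)
    logger.info(
        "read abundance table %s: %d OTUs x %d samples, %d total reads",
        path, table.n_otus, table.n_samples, int(table.data.to_numpy().sum()),
    )
    return table


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.data.to_csv(path, sep=sep, index_label="otu_id")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy table: otu_id, domain, then ranked lineage columns.

    Missing ranks and unknown OTUs are represented as "Unclassified".
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if "domain" not in df.columns:
        raise ValidationError("taxonomy table must have a 'domain' column")
    df = df.fillna("Unclassified")
    return df


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    taxonomy.to_csv(path, sep="\t", index_label="otu_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (environment + PAH concentrations).

    Rows are samples.  Numeric columns are coerced; unparseable entries
    become NaN and propagate as missing values (model fits later use
    complete cases only).  Negative PAH concentrations are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if col in ("a_priori_label", "region"):
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
    pah_cols = [c for c in PAH_COMPOUNDS if c in df.columns]
    if pah_cols and (df[pah_cols] < 0).any().any():
        raise ValidationError("negative PAH concentration in metadata")
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# rarefaction

def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Randomly subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning.  Identical seeds give identical output.  Multivariate
    hypergeometric draws guarantee each retained column sums exactly to
    ``depth`` and no OTU exceeds its original count.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for sample in table.sample_ids:
        col = table.data[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            warnings.warn(
                f"sample {sample!r} has {total} < depth {depth} reads; dropped",
                stacklevel=2,
            )
            logger.warning("rarefy: dropping sample %s (%d < %d)", sample, total, depth)
            continue
        if total == depth:
            cols[sample] = col
        else:
            cols[sample] = rng.multivariate_hypergeometric(col, depth)
    if not cols:
        raise ValidationError("no sample reaches the rarefaction depth")
    out = pd.DataFrame(cols, index=table.data.index)
    return AbundanceTable(out)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Thresholds, null-model settings and transforms for a pipeline run.

    Defaults follow the analysis conventions this package implements:
    Spearman edges at |rho| >= 0.6 and p < 0.001, 5000 null matrices for the
    C-score SES, the 95% chi-square band for the dispersion test, 0.75
    collinearity grouping and 1000 PERMANOVA permutations.
    """

    rho_edge_threshold: float = 0.6
    p_edge_threshold: float = 0.001
    n_null_matrices: int = 5000
    null_algorithm: str = "fixed_site_frequencies"
    chi2_lower: float = 0.025
    chi2_upper: float = 0.975
    df_convention: str = "occurrence"
    collinearity_threshold: float = 0.75
    permutations: int = 1000
    random_seed: int = 0
    prevalence_min_fraction: float = 0.25
    hac_linkage: str = "ward"
    hac_log_transform: bool = True
    transforms: dict = field(default_factory=lambda: {
        "salinity": "log",
        "fluoranthene": "log",
        "fp_ratio": "square",
    })
    sqg_table: dict = field(default_factory=dict)

    _NULL_ALGOS = ("fixed_site_frequencies", "fixed_occupancies", "swap")
    _DF_CONVENTIONS = ("occurrence", "occurrence_minus_1", "n_samples_minus_1")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.rho_edge_threshold <= 1.0:
            raise ValidationError(
                f"rho_edge_threshold must be in (0, 1], got {self.rho_edge_threshold}"
            )
        if not 0.0 < self.p_edge_threshold <= 1.0:
            raise ValidationError("p_edge_threshold must be in (0, 1]")
        if self.n_null_matrices < 1:
            raise ValidationError("n_null_matrices must be >= 1")
        if self.null_algorithm not in self._NULL_ALGOS:
            raise ValidationError(f"unknown null algorithm {self.null_algorithm!r}")
        if self.df_convention not in self._DF_CONVENTIONS:
            raise ValidationError(f"unknown df convention {self.df_convention!r}")
        if not 0.0 < self.chi2_lower < self.chi2_upper < 1.0:
            raise ValidationError("chi-square quantiles must satisfy 0 < lower < upper < 1")
        if not 0.0 < self.collinearity_threshold <= 1.0:
            raise ValidationError("collinearity_threshold must be in (0, 1]")
        if self.permutations < 1:
            raise ValidationError("permutations must be >= 1")
        if not 0.0 <= self.prevalence_min_fraction <= 1.0:
            raise ValidationError("prevalence_min_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# network IO

def write_network(net, path: str | Path, fmt: str = "graphml") -> None:
    """Write a co-occurrence network as GraphML or an edge-list TSV.

    GraphML carries node attributes (domain, taxon class, module, degree)
    and edge attributes (rho, p, sign); the TSV has columns
    otu_a, otu_b, rho, p, sign.
    """
    path = Path(path)
    graph = net.graph if hasattr(net, "graph") else net
    if graph.number_of_edges() == 0:
        warnings.warn("writing an empty network", stacklevel=2)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "edge_list_tsv":
        rows = [
            {
                "otu_a": min(u, v),
                "otu_b": max(u, v),
                "rho": d.get("rho", np.nan),
                "p": d.get("p", np.nan),
                "sign": d.get("sign", ""),
            }
            for u, v, d in graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p", "sign"])
        df.sort_values(["otu_a", "otu_b"]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# pipeline driver

class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig,
    table: AbundanceTable,
    taxonomy: pd.DataFrame | None,
    metadata: pd.DataFrame,
    out_dir: str | Path,
) -> dict:
    """Run contamination -> SAD partition -> association -> null model ->
    network -> module/environment stages, writing per-stage outputs plus a
    machine-readable manifest to ``out_dir``.

    Returns the manifest dict.  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    from . import association, contamination, module_env, network, nullmodels, sad_partition

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.require_min_shape()
    completed: list[str] = []
    manifest: dict = {
        "seed": config.random_seed,
        "config": dataclasses.asdict(config),
        "versions": _versions(),
        "stages": completed,
    }

    stage = "contamination"
    try:
        region = metadata["region"] if "region" in metadata.columns else None
        calls = contamination.classify_sites_hac(
            metadata, region=region,
            linkage_method=config.hac_linkage,
            log_transform=config.hac_log_transform,
        )
        calls.table.to_csv(out / "contamination_calls.tsv", sep="\t")
        completed.append(stage)

        stage = "sad_partition"
        part = sad_partition.partition(table, config)
        part.records.to_csv(out / "sad_partition.tsv", sep="\t")
        manifest["n_core"] = int(part.n_core)
        manifest["n_satellite"] = int(part.n_satellite)
        completed.append(stage)

        stage = "association"
        core_table = table.subset_otus(part.core_otus)
        edges, kept_otus = association.edge_table(
            core_table, config, return_filtered_otus=True
        )
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        completed.append(stage)

        stage = "nullmodels"
        filt = table.subset_otus(kept_otus) if len(kept_otus) >= 2 else core_table
        report = nullmodels.ses(
            nullmodels.presence_matrix(filt),
            n_null=config.n_null_matrices,
            algorithm=config.null_algorithm,
            seed=config.random_seed,
        )
        with open(out / "nullmodel.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        manifest["ses"] = report.ses
        completed.append(stage)

        stage = "network"
        net = network.build(edges, taxonomy)
        modules = network.detect_modules(net, seed=config.random_seed)
        topo = network.topology(net)
        write_network(net, out / "network.graphml", "graphml")
        write_network(net, out / "edges_final.tsv", "edge_list_tsv")
        with open(out / "topology.json", "w") as fh:
            json.dump(topo.to_dict(), fh, indent=2)
        completed.append(stage)

        stage = "module_env"
        if modules and net.graph.number_of_nodes() >= 2:
            egs = module_env.module_eigengenes(core_table, modules)
            module_env.eigengenes_frame(egs).to_csv(out / "eigengenes.tsv", sep="\t")
            corr = module_env.correlate_env(
                egs, metadata, transforms=config.transforms
            )
            corr.to_csv(out / "env_correlations.tsv", sep="\t", index=False)
        perm = module_env.permanova_bray_curtis(
            core_table, metadata,
            terms=[c for c in ("salinity", "fluoranthene") if c in metadata.columns],
            n_perm=config.permutations, seed=config.random_seed,
        )
        perm.table.to_csv(out / "permanova.tsv", sep="\t")
        completed.append(stage)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def _versions() -> dict:
    import networkx
    import scipy

    from . import __version__

    return {
        "benthonet": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }
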