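"""Synthetic sediment-community generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes:

* correlated environmental gradients — salinity and temperature negatively
  coupled to latitude (Gaussian copula, target Spearman rho ~ -0.8);
* an 11-compound PAH suite sharing a log-normal per-site factor (so the
  compounds are mutually rank-correlated above 0.75) and elevated by a
  common multiplier at "contaminated" sites;
* core OTUs whose log expected abundance responds to the environmental
  gradients and to shared module latent factors (one module per OTU at
  most), with one module driven *negatively* by log fluoranthene and
  containing a negatively coupled predator-prey OTU pair;
* satellite OTUs occupying a small random subset of samples with small
  Poisson-mean counts (random dispersal);
* sequencing-depth scaling by per-sample multinomial resampling of
  expected relative abundances, preserving compositionality.

Module latent factors are attenuated in contaminated samples (contamination
dampens the covariation that binds a consortium), so within-module
correlations — and hence network degree and clustering — drop in the
contaminated sample group while the pooled network keeps its modules.

Setting all effect sizes to zero turns the generator into an exchangeable
null for calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_core import AbundanceTable, PAH_COMPOUNDS

# Baseline (pristine) compound concentrations, ug/kg DW.  Chosen so the
# diagnostic ratios land in the pyrogenic region typical of chronic
# atmospheric-deposition inputs (P/A ~ 6, F/P ~ 1.3).
_PAH_BASE = {
    "fluoranthene": 40.0,
    "fluorene": 10.0,
    "pyrene": 30.0,
    "anthracene": 5.0,
    "benz_a_anthracene": 15.0,
    "benzo_a_pyrene": 15.0,
    "benzo_ghi_perylene": 10.0,
    "chrysene": 20.0,
    "dibenz_ah_anthracene": 3.0,
    "indeno_123cd_pyrene": 10.0,
    "phenanthrene": 30.0,
}

_BACTERIA_CLASSES = (
    "Gammaproteobacteria", "Deltaproteobacteria", "Alphaproteobacteria",
    "Actinobacteria", "Bacteroidia", "Planctomycetia", "Clostridia",
)
_ARCHAEA_CLASSES = ("Thermoplasmata", "Methanomicrobia", "Nitrososphaeria")
_EUKARYA_CLASSES = ("Alveolata", "Holozoa", "Stramenopiles")


@dataclass
class SyntheticDesign:
    """Parameters of the synthetic community.

    Effect sizes are on the natural-log abundance scale.  Defaults give a
    42-sample, 1020-OTU community: 120 environmentally structured core
    OTUs (most grouped into 6 co-occurrence modules) and 900 sparse
    satellites, sequenced to depth 3000.
    """

    n_samples: int = 42
    n_core: int = 120
    n_satellite: int = 900
    n_modules: int = 6
    module_size_range: tuple = (12, 20)
    # environment
    env_latitude_rho: float = -0.8     # target rank corr of salinity/temp with latitude
    # PAH suite
    pah_site_sigma: float = 0.8        # sd of the shared per-site log factor
    pah_compound_sigma: float = 0.4    # per-compound idiosyncratic log sd
    contamination_multiplier: float = 20.0
    pah_sensitive_module: int = 5
    pah_module_loading: float = 0.9    # |corr| of the sensitive module's factor with z(log fluoranthene)
    # core OTU responses
    env_beta_sd: float = 0.35
    module_factor_sd: float = 1.8
    module_attenuation_contaminated: float = 0.25
    predator_prey: bool = True
    predator_prey_sigma: float = 2.0
    otu_noise_sd: float = 0.3
    core_base_log_range: tuple = (np.log(20.0), np.log(200.0))
    # satellites
    satellite_occupancy_p: float = 0.1
    satellite_lambda: float = 2.0
    # sequencing
    depth: int = 3000
    noise_model: str = "poisson"
    nb_dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core + self.n_satellite < 2:
            raise ValueError("need at least 2 OTUs")
        if not -1.0 < self.env_latitude_rho < 1.0:
            raise ValueError("environmental correlation target must be in (-1, 1)")
        if not -1.0 < self.pah_module_loading < 1.0:
            raise ValueError("PAH module loading must be in (-1, 1)")
        if self.module_size_range[1] * self.n_modules > self.n_core and self.n_modules > 0:
            lo, hi = self.module_size_range
            if lo * self.n_modules > self.n_core:
                raise ValueError("module sizes exceed the number of core OTUs")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def zero_effects(self) -> "SyntheticDesign":
        """Copy with every planted effect removed (exchangeable null)."""
        d = asdict(self)
        d.update(
            env_beta_sd=0.0, module_factor_sd=0.0, predator_prey=False,
            otu_noise_sd=0.0, contamination_multiplier=1.0, n_modules=0,
        )
        return SyntheticDesign(**d)


@dataclass
class GroundTruth:
    """Planted labels for recovery testing."""

    otu_class: pd.Series                  # otu_id -> core/satellite
    modules: dict = field(default_factory=dict)   # otu_id -> planted module
    sample_labels: pd.Series | None = None        # sample_id -> contaminated/pristine
    predator_prey_pair: tuple | None = None
    env_betas: pd.DataFrame | None = None

    def module_members(self, module: int) -> list[str]:
        return [o for o, m in self.modules.items() if m == module]


def simulate_metadata(design: SyntheticDesign, seed: int | None = None):
    """Sample metadata (environment + PAH suite) with contamination labels.

    Latitude, salinity and temperature come from a Gaussian copula with the
    target inter-gradient correlation; half the samples (balanced within
    each region) are contaminated, multiplying every PAH concentration by
    the contamination multiplier on top of the shared log-normal site
    factor.  Returns (metadata DataFrame, GroundTruth with sample labels).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_samples
    rho = design.env_latitude_rho
    # copula over (latitude, salinity, temperature): salinity and
    # temperature track each other and oppose latitude
    corr = np.array([
        [1.0, rho, rho],
        [rho, 1.0, abs(rho)],
        [rho, abs(rho), 1.0],
    ])
    z = rng.multivariate_normal(np.zeros(3), corr, size=n, method="cholesky")
    latitude = 41.0 + 4.0 * z[:, 0]
    salinity = 36.0 + 2.0 * z[:, 1]
    temperature = 17.0 + 4.0 * z[:, 2]
    psd = np.clip(50.0 - 3.0 * z[:, 0] + rng.normal(0, 12, n), 1.0, 99.0)
    toc = np.exp(rng.normal(0.2, 0.5, n) - 0.1 * z[:, 0])

    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    region = np.where(latitude > np.median(latitude), "atlantic", "mediterranean")

    labels = np.empty(n, dtype=object)
    for reg in ("atlantic", "mediterranean"):
        idx = np.flatnonzero(region == reg)
        idx = rng.permutation(idx)
        half = len(idx) // 2
        labels[idx[:half]] = "contaminated"
        labels[idx[half:]] = "pristine"

    site_factor = rng.normal(0.0, design.pah_site_sigma, n)
    mult = np.where(labels == "contaminated",
                    np.log(design.contamination_multiplier), 0.0)
    pah = {}
    for comp in PAH_COMPOUNDS:
        eps = rng.normal(0.0, design.pah_compound_sigma, n)
        pah[comp] = np.exp(np.log(_PAH_BASE[comp]) + site_factor + mult + eps)

    meta = pd.DataFrame(
        {
            "salinity": salinity,
            "temperature": temperature,
            "latitude": latitude,
            "psd": psd,
            "toc": toc,
            "region": region,
            "a_priori_label": labels,
            **pah,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        otu_class=pd.Series(dtype=object),
        sample_labels=pd.Series(labels, index=sample_ids, name="label"),
    )
    return meta, truth


def simulate_counts(
    design: SyntheticDesign,
    metadata: pd.DataFrame,
    truth: GroundTruth,
    seed: int | None = None,
) -> AbundanceTable:
    """OTU x sample count table from the design, completing ``truth``.

    Core OTU expected abundance is exp(base + beta.env + module factor +
    predator-prey term); the PAH-sensitive module's factor decreases with
    standardized log fluoranthene, and other modules' factors are
    attenuated in contaminated samples.  Satellites occupy a Binomial
    subset of samples with small Poisson means.  Expected abundances are
    resampled to depth per sample (multinomial; an optional gamma
    multiplier gives negative-binomial overdispersion).
    """
    rng = np.random.default_rng((design.seed + 1) if seed is None else seed)
    n = design.n_samples
    n_core, n_sat = design.n_core, design.n_satellite
    core_ids = [f"core_{i + 1:04d}" for i in range(n_core)]
    sat_ids = [f"sat_{i + 1:04d}" for i in range(n_sat)]

    z_sal = _standardize(metadata["salinity"].to_numpy())
    z_temp = _standardize(metadata["temperature"].to_numpy())
    z_fluo = _standardize(np.log(metadata["fluoranthene"].to_numpy()))
    contaminated = (truth.sample_labels.to_numpy() == "contaminated")

    # planted module memberships over the first OTUs of the core block
    modules: dict[str, int] = {}
    cursor = 0
    lo, hi = design.module_size_range
    for m in range(1, design.n_modules + 1):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, n_core - cursor)
        for k in range(size):
            modules[core_ids[cursor + k]] = m
        cursor += size

    # per-sample module latent factors: each consortium has a distinct
    # driver, so factors are residualized to be exactly uncorrelated with
    # the environmental gradients and with one another (finite-sample
    # chance correlations would otherwise blur the planted modules)
    basis = [np.ones(n), z_sal, z_temp, z_fluo]
    factors = {}
    for m in range(1, design.n_modules + 1):
        if m == design.pah_sensitive_module:
            a = design.pah_module_loading
            eps = _residualize(rng.normal(0, 1, n), basis)
            f = -a * z_fluo + np.sqrt(1.0 - a**2) * eps
        else:
            f = _residualize(rng.normal(0.0, 1.0, n), basis)
            f = np.where(contaminated, design.module_attenuation_contaminated * f, f)
        basis.append(f)
        factors[m] = f

    betas = pd.DataFrame(
        {
            "salinity": rng.normal(0.0, design.env_beta_sd, n_core),
            "temperature": rng.normal(0.0, design.env_beta_sd, n_core),
        },
        index=core_ids,
    )
    base = rng.uniform(*design.core_base_log_range, n_core)

    log_mu = (
        base[:, None]
        + np.outer(betas["salinity"].to_numpy(), z_sal)
        + np.outer(betas["temperature"].to_numpy(), z_temp)
    )
    for i, otu in enumerate(core_ids):
        m = modules.get(otu)
        if m is not None:
            log_mu[i] += design.module_factor_sd * factors[m]

    pp_pair = None
    if design.predator_prey and design.n_modules > 0:
        host_module = (design.pah_sensitive_module
                       if design.pah_sensitive_module <= design.n_modules else 1)
        members = [o for o, m in modules.items() if m == host_module]
        if len(members) >= 2:
            predator, prey = members[0], members[1]
            w = rng.normal(0.0, 1.0, n)
            log_mu[core_ids.index(predator)] += design.predator_prey_sigma * w
            log_mu[core_ids.index(prey)] -= design.predator_prey_sigma * w
            pp_pair = (predator, prey)

    if design.otu_noise_sd > 0:
        log_mu += rng.normal(0.0, design.otu_noise_sd, size=log_mu.shape)
    expected_core = np.exp(log_mu)

    occupancy = rng.random((n_sat, n)) < design.satellite_occupancy_p
    expected_sat = occupancy * design.satellite_lambda

    expected = np.vstack([expected_core, expected_sat])
    if design.noise_model == "negative_binomial":
        shape = 1.0 / design.nb_dispersion
        expected = expected * rng.gamma(shape, 1.0 / shape, size=expected.shape)

    counts = np.zeros_like(expected, dtype=np.int64)
    for j in range(n):
        colsum = expected[:, j].sum()
        if colsum > 0:
            counts[:, j] = rng.multinomial(design.depth, expected[:, j] / colsum)

    otu_ids = core_ids + sat_ids
    table = AbundanceTable(
        pd.DataFrame(counts, index=pd.Index(otu_ids, name="otu_id"),
                     columns=metadata.index)
    )
    truth.otu_class = pd.Series(
        ["core"] * n_core + ["satellite"] * n_sat, index=otu_ids, name="class"
    )
    truth.modules = modules
    truth.predator_prey_pair = pp_pair
    truth.env_betas = betas
    return table


def simulate_taxonomy(truth: GroundTruth, seed: int = 0) -> pd.DataFrame:
    """Plausible domain/class assignments for the simulated OTUs.

    Benthic-like composition: ~76% Bacteria, ~9% Archaea, ~15% Eukarya.
    The planted predator is assigned to Alveolata (Eukarya) and its prey
    to Actinobacteria (Bacteria), matching the motif the predator-prey
    pair emulates.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for otu in truth.otu_class.index:
        dom = rng.choice(["Bacteria", "Archaea", "Eukarya"], p=[0.76, 0.09, 0.15])
        if dom == "Bacteria":
            cls = rng.choice(_BACTERIA_CLASSES)
        elif dom == "Archaea":
            cls = rng.choice(_ARCHAEA_CLASSES)
        else:
            cls = rng.choice(_EUKARYA_CLASSES)
        rows[otu] = {"domain": dom, "class": str(cls)}
    if truth.predator_prey_pair:
        pred, prey = truth.predator_prey_pair
        rows[pred] = {"domain": "Eukarya", "class": "Alveolata"}
        rows[prey] = {"domain": "Bacteria", "class": "Actinobacteria"}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "otu_id"
    return df


def simulate_dataset(design: SyntheticDesign, seed: int | None = None):
    """Convenience wrapper: (AbundanceTable, metadata, taxonomy, GroundTruth)."""
    base = design.seed if seed is None else seed
    meta, truth = simulate_metadata(design, seed=base)
    table = simulate_counts(design, meta, truth, seed=base + 1)
    taxonomy = simulate_taxonomy(truth, seed=base + 2)
    return table, meta, taxonomy, truth


def reduced_design(seed: int = 0) -> SyntheticDesign:
    """Desk-scale variant of the default design: 30 samples x 300 OTUs.

    60 core OTUs in 4 modules (the third PAH-sensitive) plus 240
    satellites; same effect sizes as the full design.  Used for replicated
    recovery experiments where the full design would be needlessly slow.
    """
    return SyntheticDesign(
        n_samples=30, n_core=60, n_satellite=240, n_modules=4,
        module_size_range=(10, 14), pah_sensitive_module=3, seed=seed,
    )


def fixture_small():
    """Deterministic 12-sample x 40-OTU miniature with 2 planted modules.

    10 core OTUs (two modules of 5, the second PAH-sensitive) and 30
    satellites; used across unit tests.  Calling twice returns identical
    objects.
    """
    design = SyntheticDesign(
        n_samples=12, n_core=10, n_satellite=30, n_modules=2,
        module_size_range=(5, 5), pah_sensitive_module=2,
        # stronger, undamped planted structure: at 12 samples the p < 0.001
        # edge gate needs |rho| ~ 0.82, so the miniature's modules must be
        # near-deterministic to be recoverable
        module_factor_sd=2.0, otu_noise_sd=0.15, env_beta_sd=0.15,
        module_attenuation_contaminated=1.0, predator_prey_sigma=2.5,
        depth=500, seed=424242,
    )
    table, meta, taxonomy, truth = simulate_dataset(design)
    return table, meta, taxonomy, truth, design


def _residualize(x: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    """Residual of x on the span of basis vectors, rescaled to unit sd."""
    b = np.column_stack(basis)
    coef, *_ = np.linalg.lstsq(b, x, rcond=None)
    r = x - b @ coef
    return _standardize(r)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)
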