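"""Synthetic gradient metacommunities with the structure the analyses assume.

Emulates a 10-plot elevational transect sampled by several survey
methods: species have Gaussian niches along elevation (optima uniform
over the transect, common niche width), lognormal regional abundances,
and per-subplot read counts drawn multinomially at a method-specific
sequencing depth. A mixture weight ``g`` interpolates between the pure
niche model (``g=1``, strong distance decay) and a flat, structureless
community (``g=0``, the "birds-like" null), so power and type-I
calibrations share one code path. The environment table carries a
planted elevation/temperature collinearity and a collinear block of
soil-chemistry variables plus independent nuisance covariates,
mirroring the covariate structure the driver analyses must untangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .drivers import EnvTable

#: Plot metadata for the 10-plot elevational transect fixture:
#: (latitude, longitude, elevation m, mean annual surface soil temperature °C).
_TRANSECT_PLOTS: dict[str, tuple[float, float, float, float]] = {
    "Plot1": (-36.22456597, 175.069838, 50.0, 15.270),
    "Plot2": (-36.21828298, 175.070321, 90.0, 15.225),
    "Plot3": (-36.21672898, 175.073758, 160.0, 14.665),
    "Plot4": (-36.21282997, 175.074535, 260.0, 14.115),
    "Plot5": (-36.21535703, 175.075321, 240.0, 13.935),
    "Plot6": (-36.21347898, 175.075911, 320.0, 13.555),
    "Plot7": (-36.21174602, 175.078817, 420.0, 12.935),
    "Plot8": (-36.21001298, 175.078955, 460.0, 13.645),
    "Plot9": (-36.20151096, 175.071524, 595.0, 12.245),
    "Plot10": (-36.19910401, 175.075777, 640.0, 12.215),
}

_SUBPLOT_CODES = "ABCDEFGHIJKLMNOP"


def table1_fixture() -> EnvTable:
    """The 10-plot transect: elevations and soil temperatures per plot.

    Plots sit in ~60 m elevational bands from 50 m to 640 m; mean annual
    surface soil temperature declines with elevation from 15.27 °C to
    12.22 °C, with a local anomaly at Plot 8 (13.645 °C, warmer than the
    lower-elevation Plot 7).
    """
    df = pd.DataFrame.from_dict(
        _TRANSECT_PLOTS,
        orient="index",
        columns=["latitude", "longitude", "elevation", "temperature"],
    )
    df.index.name = "plot_id"
    return EnvTable(data=df, transforms={})


@dataclass(frozen=True)
class MarkerProfile:
    """Sampling profile of one survey method.

    ``species_pool``: regional species/OTU pool size; ``reads_per_sample``:
    sequencing depth (or census size) per subplot sample; ``niche_width``:
    Gaussian niche SD in meters of elevation; ``gradient_strength``:
    mixture weight g in [0, 1] between the niche model and a flat
    community; ``abundance_sigma``: SD of the lognormal regional
    abundance distribution.
    """

    species_pool: int = 200
    reads_per_sample: int = 5000
    niche_width: float = 50.0
    gradient_strength: float = 1.0
    abundance_sigma: float = 1.0

    def validate(self) -> None:
        if self.species_pool < 1:
            raise ValueError("species_pool must be >= 1")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if self.niche_width <= 0:
            raise ValueError("niche_width must be > 0")
        if not 0.0 <= self.gradient_strength <= 1.0:
            raise ValueError("gradient_strength must be in [0, 1]")
        if self.abundance_sigma < 0:
            raise ValueError("abundance_sigma must be >= 0")


def _default_profiles() -> dict[str, MarkerProfile]:
    return {"eDNA": MarkerProfile()}


@dataclass
class SyntheticConfig:
    """Configuration of the gradient-metacommunity generator.

    Defaults describe the canonical study conditions: 10 plots at the
    transect elevations, 2 sampled subplots per plot, one marker with a
    200-species pool sequenced at 5000 reads per sample, 50 m niche
    width and full gradient strength. ``env_noise_sd`` is the SD (°C)
    of the noise on the planted temperature–elevation collinearity.
    """

    n_plots: int = 10
    subplots_per_plot: int = 2
    elevations: dict[str, float] | None = None
    profiles: dict[str, MarkerProfile] = field(default_factory=_default_profiles)
    temperature_intercept: float = 15.5
    temperature_slope: float = -0.005  # °C per m, lapse-like decline
    env_noise_sd: float = 0.2
    seed: int = 0

    def resolved_elevations(self) -> dict[str, float]:
        if self.elevations is not None:
            if len(self.elevations) != self.n_plots:
                raise ValueError("elevations must cover exactly n_plots plots")
            return dict(self.elevations)
        fixture = table1_fixture()
        if self.n_plots <= 10:
            plots = fixture.plots[: self.n_plots]
            return {p: float(fixture.data.loc[p, "elevation"]) for p in plots}
        # extend beyond the fixture with evenly spaced bands
        return {
            f"Plot{i + 1}": 50.0 + i * 60.0 for i in range(self.n_plots)
        }

    def validate(self) -> None:
        if self.n_plots < 2:
            raise ValueError("need at least 2 plots")
        if not 1 <= self.subplots_per_plot <= len(_SUBPLOT_CODES):
            raise ValueError(
                f"subplots_per_plot must be in 1..{len(_SUBPLOT_CODES)}"
            )
        if self.env_noise_sd < 0:
            raise ValueError("env_noise_sd must be >= 0")
        for name, prof in self.profiles.items():
            prof.validate()


@dataclass
class SyntheticTruth:
    """Generator ground truth for parameter-recovery tests.

    Per marker: niche optima ``mu`` (m), regional abundances ``A``, and
    the expected plot compositions ``expected`` (plots x species row
    distributions). ``config`` and ``seed`` fully determine the outputs.
    """

    config: SyntheticConfig
    seed: int
    mu: dict[str, np.ndarray]
    abundance: dict[str, np.ndarray]
    expected: dict[str, pd.DataFrame]


def _expected_composition(
    elev: np.ndarray, mu: np.ndarray, a: np.ndarray, sigma: float, g: float
) -> np.ndarray:
    """Plot-by-species expected relative abundances under the niche mixture."""
    kernel = np.exp(-((elev[:, None] - mu[None, :]) ** 2) / (2.0 * sigma**2))
    lam = a[None, :] * (g * kernel + (1.0 - g))
    row = lam.sum(axis=1, keepdims=True)
    if (row == 0).any():
        # all-zero expectation (can only happen at g=1 with remote optima):
        # fall back to the flat model for those plots
        flat = np.broadcast_to(a / a.sum(), lam.shape)
        lam = np.where(row > 0, lam, flat)
        row = lam.sum(axis=1, keepdims=True)
    return lam / row


def simulate_gradient_metacommunity(
    config: SyntheticConfig,
) -> tuple[dict[str, CommunityMatrix], EnvTable, SyntheticTruth]:
    """Simulate per-marker community matrices along the elevation gradient.

    For every marker profile, species optima are uniform over the
    elevation range and regional abundances lognormal; the expected
    abundance of species i in plot s is
    ``A_i * (g * exp(-(e_s - mu_i)^2 / (2 sigma^2)) + (1 - g))``, and
    every subplot draws its reads multinomially from the plot's expected
    composition. Returns subplot-level matrices (samples ``Plot3-A``,
    ...), the environment table, and the generating truth.
    """
    config.validate()
    elev_map = config.resolved_elevations()
    plots = list(elev_map)
    elev = np.array([elev_map[p] for p in plots], dtype=float)
    rng = np.random.default_rng(config.seed)

    matrices: dict[str, CommunityMatrix] = {}
    mu_truth: dict[str, np.ndarray] = {}
    a_truth: dict[str, np.ndarray] = {}
    expected: dict[str, pd.DataFrame] = {}
    for name, prof in config.profiles.items():
        s = prof.species_pool
        mu = rng.uniform(elev.min(), elev.max(), size=s)
        a = rng.lognormal(mean=0.0, sigma=prof.abundance_sigma, size=s)
        comp = _expected_composition(
            elev, mu, a, prof.niche_width, prof.gradient_strength
        )
        sample_ids, rows = [], []
        for j, plot in enumerate(plots):
            for k in range(config.subplots_per_plot):
                sample_ids.append(f"{plot}-{_SUBPLOT_CODES[k]}")
                rows.append(rng.multinomial(prof.reads_per_sample, comp[j]))
        counts = np.array(rows, dtype=float)
        occupied = counts.sum(axis=0) > 0
        otu_ids = [f"{name}_OTU{i + 1}" for i in range(s)]
        df = pd.DataFrame(
            counts[:, occupied],
            index=sample_ids,
            columns=[o for o, keep in zip(otu_ids, occupied) if keep],
        )
        plot_of = {sid: sid.rsplit("-", 1)[0] for sid in sample_ids}
        subplot_of = {sid: sid.rsplit("-", 1)[1] for sid in sample_ids}
        matrices[name] = CommunityMatrix(
            data=df, marker=name, plot_of=plot_of, subplot_of=subplot_of
        )
        mu_truth[name] = mu
        a_truth[name] = a
        expected[name] = pd.DataFrame(comp, index=plots, columns=otu_ids)

    env = _simulate_environment(plots, elev, config, rng)
    truth = SyntheticTruth(
        config=config, seed=config.seed, mu=mu_truth, abundance=a_truth,
        expected=expected,
    )
    return matrices, env, truth


def _simulate_environment(
    plots: list[str],
    elev: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> EnvTable:
    """15-variable environment table with planted collinearity.

    Temperature is a noisy linear function of elevation; EC, organic C,
    total N, NH4-N and water content form a collinear block driven by a
    shared latent fertility axis; pH, Olsen-P, NO3-N, slope and aspect
    are independent nuisance variables; the C/N ratio derives from
    organic C and total N.
    """
    n = len(plots)
    temp = (
        config.temperature_intercept
        + config.temperature_slope * elev
        + rng.normal(0.0, config.env_noise_sd, n)
    )
    slope = rng.uniform(5.0, 35.0, n)
    aspect = rng.uniform(0.0, 360.0, n)
    fertility = rng.normal(0.0, 1.0, n)  # latent axis behind the collinear block
    ec = np.exp(3.0 + 0.9 * fertility + rng.normal(0, 0.15, n))  # uS/cm
    org_c = 8.0 + 3.0 * fertility + rng.normal(0, 0.5, n)        # %
    total_n = 0.5 + 0.18 * fertility + rng.normal(0, 0.03, n)    # %
    nh4 = np.exp(1.5 + 0.8 * fertility + rng.normal(0, 0.2, n))  # mg/kg
    water = 35.0 + 8.0 * fertility + rng.normal(0, 1.5, n)       # %
    ph = rng.normal(5.5, 0.4, n)
    olsen_p = np.exp(rng.normal(1.8, 0.5, n))                    # mg/kg
    no3 = np.exp(rng.normal(0.8, 0.5, n))                        # mg/kg
    cn_ratio = org_c / total_n
    df = pd.DataFrame(
        {
            "elevation": elev,
            "temperature": temp,
            "slope": slope,
            "aspect": aspect,
            "pH": ph,
            "Olsen.P": olsen_p,
            "EC": ec,
            "organic.C": org_c,
            "total.N": total_n,
            "NO3.N": no3,
            "NH4.N": nh4,
            "water": water,
            "C.N.ratio": cn_ratio,
        },
        index=pd.Index(plots, name="plot_id"),
    )
    return EnvTable(data=df, transforms={})


def simulate_structureless_community(
    config: SyntheticConfig, marker: str = "birds-like"
) -> CommunityMatrix:
    """Simulate a community with no plot structure at all.

    Species probabilities are shared by every plot (lognormal regional
    abundances only) and samples are independent multinomial draws —
    the null against which distance-decay and turnover contrasts should
    show ~5 % false positives.
    """
    config.validate()
    prof = next(iter(config.profiles.values()))
    elev_map = config.resolved_elevations()
    plots = list(elev_map)
    rng = np.random.default_rng(config.seed)
    a = rng.lognormal(0.0, prof.abundance_sigma, prof.species_pool)
    probs = a / a.sum()
    sample_ids, rows = [], []
    for plot in plots:
        for k in range(config.subplots_per_plot):
            sample_ids.append(f"{plot}-{_SUBPLOT_CODES[k]}")
            rows.append(rng.multinomial(prof.reads_per_sample, probs))
    counts = np.array(rows, dtype=float)
    occupied = counts.sum(axis=0) > 0
    otu_ids = [f"{marker}_OTU{i + 1}" for i in range(prof.species_pool)]
    df = pd.DataFrame(
        counts[:, occupied],
        index=sample_ids,
        columns=[o for o, keep in zip(otu_ids, occupied) if keep],
    )
    plot_of = {sid: sid.rsplit("-", 1)[0] for sid in sample_ids}
    subplot_of = {sid: sid.rsplit("-", 1)[1] for sid in sample_ids}
    return CommunityMatrix(data=df, marker=marker, plot_of=plot_of, subplot_of=subplot_of)


def contrasting_marker_profiles() -> dict[str, MarkerProfile]:
    """Marker set with order-of-magnitude richness/depth contrasts.

    Emulates the qualitative scale differences among real markers: a
    bacterial marker with a huge OTU pool and deep sequencing, mid-sized
    eukaryote markers, and a sparse marker with few OTUs and shallow
    depth.
    """
    return {
        "16S-like": MarkerProfile(species_pool=5000, reads_per_sample=20000,
                                  niche_width=120.0, gradient_strength=0.7),
        "18S-like": MarkerProfile(species_pool=1500, reads_per_sample=10000,
                                  niche_width=80.0, gradient_strength=0.9),
        "COI-like": MarkerProfile(species_pool=800, reads_per_sample=5000,
                                  niche_width=60.0, gradient_strength=0.9),
        "COI-spun-like": MarkerProfile(species_pool=300, reads_per_sample=2000,
                                       niche_width=60.0, gradient_strength=0.8),
    }
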