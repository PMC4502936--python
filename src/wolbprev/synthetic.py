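"""Synthetic screen tables and stand-in phylogenies.

The generator reproduces the statistical structure the estimators assume:
each species has a latent prevalence q drawn from a beta or doubly-inflated
beta distribution; each of its populations is screened by sampling n
individuals and recording k ~ Binomial(n, q).  Species are spread over
countries placed along a latitudinal ladder, optionally with a gradient
that shifts the beta mean on the logit scale by a fixed amount per degree
of absolute latitude (dispersion α+β held fixed).  Defaults emulate the
scale of the literature-compiled Lepidoptera screen database: 300 species,
one to three populations each (≈600 populations), 1–22 individuals per
screen (mean ≈ 11.5, the database's individuals-per-population average),
prevalence beta(0.24, 0.63), 22 countries.

Everything is reproducible from the config seed; the generator returns the
simulated truth (per-species prevalences and all parameters) alongside the
table so recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import special

from .prevalence_model import BetaParams, InflatedBetaParams, PrevalenceModel
from .screen_data import ScreenRecord, ScreenTable

__all__ = ["SimConfig", "simulate_screens", "simulate_tree"]


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_species: int = 300
    populations_per_species: tuple[int, int] = (1, 3)  # inclusive uniform range
    n_per_population: tuple[int, int] = (1, 22)  # inclusive uniform range, mean ~11.5
    prevalence_model: PrevalenceModel = field(default_factory=lambda: BetaParams(0.24, 0.63))
    n_countries: int = 22
    n_families: int = 10
    latitude_effect: float = 0.0  # log-odds of the beta mean per degree |latitude|
    max_latitude: float = 60.0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_countries < 1 or self.n_families < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.populations_per_species
        if not 1 <= lo <= hi:
            raise ValueError("populations_per_species must be an increasing range from >= 1")
        lo, hi = self.n_per_population
        if not 1 <= lo <= hi:
            raise ValueError("n_per_population must be an increasing range from >= 1")


def _country_grid(config: SimConfig, rng: np.random.Generator):
    """Countries on a latitudinal ladder: |lat| evenly spaced in [0, max],
    alternating hemisphere; longitudes uniform."""
    lats = np.linspace(0.0, config.max_latitude, config.n_countries)
    signs = np.where(np.arange(config.n_countries) % 2 == 0, 1.0, -1.0)
    lats = lats * signs
    lons = rng.uniform(-180.0, 180.0, size=config.n_countries)
    names = [f"C{i:02d}" for i in range(config.n_countries)]
    return names, lats, lons


def _draw_prevalence(model: PrevalenceModel, lat_abs: float, effect: float,
                     rng: np.random.Generator) -> float:
    """One species' prevalence; the latitude gradient shifts the beta mean on
    the logit scale with total concentration α+β fixed."""
    a, b = model.alpha, model.beta
    if effect != 0.0:
        s = a + b
        m = special.expit(special.logit(a / s) + effect * lat_abs)
        m = float(np.clip(m, 1e-9, 1 - 1e-9))
        a, b = m * s, (1.0 - m) * s
    if isinstance(model, InflatedBetaParams):
        u = rng.random()
        if u < model.mass_at_zero:
            return 0.0
        if u < model.phi:
            return 1.0
    return float(rng.beta(a, b))


def simulate_screens(config: SimConfig) -> tuple[ScreenTable, dict]:
    """Generate a screen table plus the truth record that produced it."""
    rng = np.random.default_rng(config.seed)
    names, lats, lons = _country_grid(config, rng)

    families = [f"F{i:02d}" for i in range(config.n_families)]
    superfamilies = {f: f"SF{i // 2:02d}" for i, f in enumerate(families)}

    records: list[ScreenRecord] = []
    truth_q = {}
    species_country = {}
    for s in range(config.n_species):
        sp = f"sp{s:04d}"
        ci = int(rng.integers(0, config.n_countries))
        fam = families[int(rng.integers(0, config.n_families))]
        q = _draw_prevalence(
            config.prevalence_model, abs(lats[ci]), config.latitude_effect, rng
        )
        truth_q[sp] = q
        species_country[sp] = names[ci]
        n_pops = int(rng.integers(config.populations_per_species[0],
                                  config.populations_per_species[1] + 1))
        for p in range(n_pops):
            n = int(rng.integers(config.n_per_population[0], config.n_per_population[1] + 1))
            k = int(rng.binomial(n, q))
            records.append(
                ScreenRecord(
                    study_id=f"sim{config.seed}",
                    species=sp,
                    family=fam,
                    superfamily=superfamilies[fam],
                    country=names[ci],
                    latitude=float(lats[ci]),
                    longitude=float(lons[ci]),
                    n_sampled=n,
                    n_infected=k,
                )
            )
    truth = {
        "seed": config.seed,
        "model": config.prevalence_model,
        "latitude_effect": config.latitude_effect,
        "species_prevalence": truth_q,
        "species_country": species_country,
        "country_latitude": dict(zip(names, lats.tolist())),
        "country_longitude": dict(zip(names, lons.tolist())),
    }
    return ScreenTable(records), truth


def centroid_frame(truth: dict):
    """Centroid table (country, latitude, longitude) for a simulated dataset."""
    import pandas as pd

    return pd.DataFrame(
        {
            "country": list(truth["country_latitude"]),
            "latitude": list(truth["country_latitude"].values()),
            "longitude": list(truth["country_longitude"].values()),
            "continent": "SIM",
        }
    )


def simulate_tree(n_taxa: int, seed: int, taxon_names: list[str] | None = None) -> dendropy.Tree:
    """Random bifurcating tree with exponential(1) branch lengths.

    Built by sequential random joining of lineages (a simple coalescent-like
    topology); tip names default to the simulated family labels F00, F01, …
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    if taxon_names is None:
        taxon_names = [f"F{i:02d}" for i in range(n_taxa)]
    if len(taxon_names) != n_taxa:
        raise ValueError("taxon_names length must equal n_taxa")

    nodes = [f"{name}:{rng.exponential(1.0):.6f}" for name in taxon_names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(1.0):.6f}"
        nodes = [n for t, n in enumerate(nodes) if t not in (i, j)] + [merged]
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick")
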