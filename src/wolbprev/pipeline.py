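"""End-to-end analysis: summaries, ML fits, moment estimates, association
tests and bias diagnostics, written as CSV/JSON bundles.

Each stage is a thin orchestration over the library modules; any stage that
fails is logged and its dependents skipped, so a partial bundle is still
produced.  Every output records the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    infection_vs_samplesize_slope,
    latitude_correlation,
    mantel,
    sample_size_bias_binned,
    value_difference_matrix,
)
from .geospatial import country_distance_matrix, load_centroids
from .moments import bootstrap_ci, moment_fit, moment_incidence
from .phylo import patristic_matrix, read_newick
from .prevalence_model import expected_bin_fractions, fit_ml
from .screen_data import (
    ScreenTable,
    bin_prevalences,
    eligible_countries,
    filter_countries,
    pool_by_species,
    read_screens,
    species_infection_flags,
    summaries_to_frame,
    summarize_by,
)

log = logging.getLogger("wolbprev")

DEFAULT_THRESHOLDS = (0.001, 0.0001)


@dataclass
class AnalysisConfig:
    screens_csv: str
    out_dir: str
    centroids_csv: str | None = None
    newick: str | None = None
    family_column: str = "family"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    pool_species: bool = False
    focal_superfamily: str | None = None  # extra per-superfamily fits
    min_primer_sets: int = 2  # "multiple primers" subset cutoff
    min_country_populations: int = 3
    n_permutations: int = 9999
    n_boot: int = 1000
    n_restarts: int = 10
    seed: int = 0
    extras: dict = field(default_factory=dict)


def _fit_pair(table: ScreenTable, cfg: AnalysisConfig, label: str) -> dict:
    unit = pool_by_species(table) if cfg.pool_species else table
    out = {"subset": label, "n_populations": len(unit)}
    fits = {}
    for fam in ("beta", "doubly_inflated"):
        fit = fit_ml(unit, family=fam, n_restarts=cfg.n_restarts, seed=cfg.seed,
                     thresholds=cfg.thresholds)
        fits[fam] = fit
        out[fam] = fit.to_dict()
    out["delta_aic"] = fits["beta"].aic - fits["doubly_inflated"].aic
    out["preferred"] = min(fits, key=lambda f: fits[f].aic)
    return out


def _moment_table(table: ScreenTable, level: str, cfg: AnalysisConfig) -> pd.DataFrame:
    groups: dict[str, list] = {}
    for r in table:
        g = getattr(r, level)
        if g:
            groups.setdefault(g, []).append(r)
    rows = []
    for g, recs in sorted(groups.items()):
        sub = ScreenTable(recs)
        row = {"group": g, "n_populations": len(sub)}
        if len(sub) >= 2:
            est = moment_fit(sub)
            row.update(
                mu_hat=est.mu_hat, sigma2_hat=est.sigma2_hat, valid=est.valid,
                alpha_hat=est.alpha_hat, beta_hat=est.beta_hat,
            )
            ci = bootstrap_ci(sub, "mu", n_boot=cfg.n_boot, seed=cfg.seed)
            row.update(mu_ci_low=ci.low, mu_ci_high=ci.high)
            for c in cfg.thresholds:
                row[f"x_{c}"] = moment_incidence(est, c) if est.valid else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage on the input table and write the output bundle.

    Returns the in-memory bundle (also serialized under ``config.out_dir``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"failures": {}}

    table = read_screens(config.screens_csv)
    centroids = load_centroids(config.centroids_csv)

    def stage(name, fn):
        try:
            bundle[name] = fn()
        except Exception as exc:  # keep going; record the failure
            log.error("stage %s failed: %s", name, exc)
            bundle["failures"][name] = str(exc)
            bundle[name] = None

    # (a) group summaries
    def _summaries():
        out = {}
        for level in ("superfamily", "family", "country", "continent"):
            df = summaries_to_frame(summarize_by(table, level))
            df.to_csv(out_dir / f"summary_{level}.csv", index=False)
            out[level] = df
        flags = species_infection_flags(table)
        out["sample_incidence"] = {
            "n_species": len(flags),
            "n_species_infected": int(sum(flags.values())),
            "sample_incidence": sum(flags.values()) / len(flags),
        }
        return out

    stage("summaries", _summaries)

    # (b) ML fits: full table, focal superfamily, multiple-primer subset
    def _fits():
        reports = [_fit_pair(table, config, "all")]
        if config.focal_superfamily:
            sub = ScreenTable([r for r in table if r.superfamily == config.focal_superfamily])
            if len(sub) >= 4:
                reports.append(_fit_pair(sub, config, config.focal_superfamily))
                multi = ScreenTable(
                    [r for r in sub if r.n_primer_sets >= config.min_primer_sets]
                )
                if len(multi) >= 4:
                    reports.append(
                        _fit_pair(multi, config, f"{config.focal_superfamily}_multiprimer")
                    )
        (out_dir / "fits.json").write_text(json.dumps(reports, indent=2, default=float))
        return reports

    stage("fits", _fits)

    # (c) moment estimates per country and per family
    def _moments():
        out = {}
        for level in ("country", "family", "superfamily"):
            df = _moment_table(table, level, config)
            df.to_csv(out_dir / f"moments_{level}.csv", index=False)
            out[level] = df
        return out

    stage("moments", _moments)

    # (d) Mantel tests
    def _mantel():
        out = {}
        with_country = ScreenTable([r for r in table if r.country])
        mom_all = bundle["moments"]["country"] if bundle.get("moments") else None
        if mom_all is None or mom_all.empty:
            raise ValueError("no per-country moment estimates available")

        def run_geo(tab: ScreenTable, tag: str, stat: str, c: float | None = None):
            df = _moment_table(tab, "country", config)
            if stat == "mu":
                vals = dict(zip(df["group"], df["mu_hat"]))
            else:
                vals = {
                    g: (v if bool(ok) else np.nan)
                    for g, v, ok in zip(df["group"], df[f"x_{c}"], df["valid"].fillna(False))
                }
            vd = value_difference_matrix(vals)
            known = [l for l in vd.labels if l in set(centroids["country"])]
            vd = vd.submatrix(known)
            geo = country_distance_matrix(vd.labels, centroids)
            res = mantel(geo, vd, n_permutations=config.n_permutations, seed=config.seed)
            out[tag] = {"r": res.r, "p": res.p_value, "n": res.n_labels,
                        "n_permutations": res.n_permutations, "labels": vd.labels}

        run_geo(with_country, "geography_mu_all_countries", "mu")
        filt = filter_countries(with_country, config.min_country_populations)
        run_geo(filt, "geography_mu_min3", "mu")
        for c in config.thresholds:
            run_geo(filt, f"geography_x_{c}_min3", "incidence", c)

        if config.newick:
            tree = read_newick(config.newick)
            fam_df = _moment_table(table, config.family_column, config)
            tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
            vals = {g: m for g, m in zip(fam_df["group"], fam_df["mu_hat"]) if g in tips}
            vd = value_difference_matrix(vals)
            pat = patristic_matrix(tree, vd.labels)
            res = mantel(pat, vd, n_permutations=config.n_permutations, seed=config.seed)
            out["phylogeny_mu"] = {"r": res.r, "p": res.p_value, "n": res.n_labels,
                                   "n_permutations": res.n_permutations}
        (out_dir / "mantel.json").write_text(json.dumps(out, indent=2, default=float))
        return out

    stage("mantel", _mantel)

    # (e) latitude / longitude rank correlations
    def _gradient():
        filt = filter_countries(
            ScreenTable([r for r in table if r.country]), config.min_country_populations
        )
        df = _moment_table(filt, "country", config)
        known = set(centroids["country"])
        out = {}
        mu_vals = {g: v for g, v in zip(df["group"], df["mu_hat"]) if g in known}
        for axis in ("absolute_latitude", "longitude"):
            rho, p = latitude_correlation(mu_vals, centroids, axis)
            out[f"mu_{axis}"] = {"rho": rho, "p": p, "n": len(mu_vals)}
        for c in config.thresholds:
            vals = {
                g: v
                for g, v, ok in zip(df["group"], df[f"x_{c}"], df["valid"].fillna(False))
                if g in known and bool(ok)
            }
            if len(vals) >= 3:
                for axis in ("absolute_latitude", "longitude"):
                    rho, p = latitude_correlation(vals, centroids, axis)
                    out[f"x_{c}_{axis}"] = {"rho": rho, "p": p, "n": len(vals)}
        (out_dir / "gradient.json").write_text(json.dumps(out, indent=2, default=float))
        return out

    stage("gradient", _gradient)

    # (f) sample-size bias diagnostics
    def _bias():
        rho, p = sample_size_bias_binned(table)
        slope, se = infection_vs_samplesize_slope(table)
        out = {
            "binned_spearman": {"rho": rho, "p": p},
            "binomial_regression": {"slope": slope, "se": se},
        }
        (out_dir / "bias.json").write_text(json.dumps(out, indent=2, default=float))
        return out

    stage("bias", _bias)

    # (g) species-level histogram with model-expected fractions
    def _histogram():
        pooled = pool_by_species(table)
        hist = bin_prevalences(pooled)
        if bundle.get("fits"):
            from .prevalence_model import BetaParams

            best = bundle["fits"][0]["beta"]["parameters"]
            model = BetaParams(best["alpha"], best["beta"])
            hist["expected_fraction"] = expected_bin_fractions(pooled, model)
        hist.to_csv(out_dir / "histogram_species.csv", index=False)
        return hist

    stage("histogram", _histogram)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "screens_csv": str(config.screens_csv),
        "centroids_csv": str(config.centroids_csv) if config.centroids_csv else "packaged",
        "newick": str(config.newick) if config.newick else None,
        "n_populations": len(table),
        "pool_species": config.pool_species,
        "thresholds": list(config.thresholds),
        "failures": bundle["failures"],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    if bundle["failures"]:
        log.warning("stages failed: %s", sorted(bundle["failures"]))
    return bundle
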