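"""End-to-end scenario runs: standardize, superimpose, analyse, export.

A *scenario* asks what a target community looks like with (or without) one
superimposed species: standardize the target and donor datasets, insert at
most one donor species (inserting two natives at once would confound the
dietary attribution, so it is refused), then run the requested analyses and
write flat tables plus a JSON run manifest that records inputs, seeds and
package version — enough to replay the run bit-for-bit.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import read_isotope_table, write_results
from .standardization import standardize_community, superimpose
from .layman import community_metrics, layman_metrics
from .ellipse import ellipse_boundary, ellipse_intersection_area, fit_niche, percent_overlap
from .nicheprob import directional_overlap_probability, posterior_niche_samples
from .trophic import MCMCConfig, TDFModel, bayesian_trophic_position, point_trophic_position
from .mixing import build_predation_scenario, fit_mixing_model

__all__ = ["ScenarioConfig", "run_scenario"]

ANALYSES = ("metrics", "ellipses", "overlap", "niche_prob", "tp", "simm")


@dataclass
class ScenarioConfig:
    target: str  # path to the target community CSV (raw scale)
    donors: dict[str, str] = field(default_factory=dict)  # species -> CSV path
    species_to_superimpose: str | None = None
    analyses: tuple[str, ...] = ("metrics", "ellipses", "overlap", "tp")
    coverage: float = 0.95
    seed: int = 0
    n_draws: int = 20_000
    points_per_draw: int = 10
    lam: float = 2.0
    bayesian_tp: bool = False
    mcmc_iterations: int = 10_000
    allow_incomparable: bool = True
    mixing_scenarios: tuple[dict, ...] = ()  # {"predator": ..., "prey": [...]}
    output_dir: str | None = None
    verbose: bool = False

    def __post_init__(self):
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}")

    @classmethod
    def from_json(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            doc = json.load(fh)
        doc["donors"] = dict(doc.get("donors", {}))
        for key in ("analyses", "mixing_scenarios"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def _log(cfg: ScenarioConfig, stage: str, t0: float) -> None:
    if cfg.verbose:
        print(f"[isoniche] {stage}: {time.perf_counter() - t0:.2f}s (seed={cfg.seed})")


def run_scenario(cfg: ScenarioConfig) -> dict:
    """Execute the scenario; returns ``{table name: DataFrame, "manifest": dict}``.

    With ``output_dir`` set, each table lands as ``<name>.csv`` next to
    ``manifest.json``.  Deterministic: identical config and seeds reproduce
    identical outputs.
    """
    t0 = time.perf_counter()
    target_raw = read_isotope_table(cfg.target)
    target = standardize_community(target_raw)
    community = target
    sp = cfg.species_to_superimpose
    if sp is not None:
        if sp not in cfg.donors:
            raise KeyError(f"no donor dataset configured for {sp!r}")
        donor = standardize_community(read_isotope_table(cfg.donors[sp]))
        community = superimpose(
            target, donor, sp, allow_incomparable=cfg.allow_incomparable
        )
    _log(cfg, "standardize+superimpose", t0)

    rng = np.random.default_rng(cfg.seed)
    tables: dict[str, pd.DataFrame] = {}
    community_label = "Community" + (f"_{sp[0]}" if sp else "")
    residents = [s for s in community.groups if community.groups[s].provenance == "resident"]

    if "metrics" in cfg.analyses:
        rows = []
        for name, lm in [
            (community_label, community_metrics(community)),
        ] + [(s, layman_metrics(community.groups[s].xy)) for s in community.groups]:
            rows.append(
                {
                    "species": name,
                    "NR": lm.nr, "CR": lm.cr, "TA": lm.ta,
                    "CD": lm.cd, "NND": lm.nnd, "SDNND": lm.sdnnd,
                    "n": lm.n_points,
                }
            )
        tables["metrics"] = pd.DataFrame(rows)
        _log(cfg, "metrics", t0)

    niches = {}
    if {"ellipses", "overlap"} & set(cfg.analyses):
        niches = {
            s: fit_niche(g) for s, g in community.groups.items() if g.n >= 3
        }

    if "ellipses" in cfg.analyses:
        rows, coords = [], []
        for s, niche in niches.items():
            rows.append(
                {
                    "species": s,
                    "mean_d13C": niche.mean[0], "mean_d15N": niche.mean[1],
                    "SEA": niche.sea, "SEAc": niche.seac, "SEAb": niche.seab,
                    "n": niche.n,
                }
            )
            if not niche.degenerate:
                for cov_level, tag in ((cfg.coverage, "seab"),):
                    bnd = ellipse_boundary(niche, cov_level, n_vertices=180)
                    coords.extend(
                        {"species": s, "coverage": tag, "d13C": c, "d15N": n15}
                        for c, n15 in bnd
                    )
        tables["ellipse_areas"] = pd.DataFrame(rows)
        tables["ellipses"] = pd.DataFrame(coords)
        _log(cfg, "ellipses", t0)

    if "overlap" in cfg.analyses:
        pairs = (
            [(sp, r) for r in residents if r in niches]
            if sp is not None and sp in niches
            else [
                (a, b)
                for i, a in enumerate(niches)
                for b in list(niches)[i + 1 :]
            ]
        )
        rows = []
        for a, b in pairs:
            na, nb = niches[a], niches[b]
            if na.degenerate or nb.degenerate:
                continue
            inter = ellipse_intersection_area(na, nb, coverage=cfg.coverage)
            area_a = na.sea * na.correction * _chi2(cfg.coverage)
            area_b = nb.sea * nb.correction * _chi2(cfg.coverage)
            rows.append(
                {
                    "species_a": a, "species_b": b,
                    "intersection": inter,
                    "area_a": area_a, "area_b": area_b,
                    "percent_overlap": percent_overlap(
                        min(inter, area_a, area_b), area_a, area_b
                    ),
                }
            )
        tables["overlap"] = pd.DataFrame(rows)
        _log(cfg, "overlap", t0)

    if "niche_prob" in cfg.analyses:
        posteriors = {
            s: posterior_niche_samples(
                g, n_draws=cfg.n_draws, seed=int(rng.integers(2**31))
            )
            for s, g in community.groups.items()
            if g.n >= 3
        }
        pairs = (
            [(sp, r) for r in residents if r in posteriors]
            if sp is not None and sp in posteriors
            else [(a, b) for a in posteriors for b in posteriors if a != b]
        )
        rows = []
        for a, b in pairs:
            res = directional_overlap_probability(
                posteriors[a], posteriors[b], alpha=cfg.coverage,
                points_per_draw=cfg.points_per_draw,
                seed=int(rng.integers(2**31)),
            )
            rows.append(
                {
                    "from_species": a, "to_species": b, "alpha": res.alpha,
                    "probability_pct": res.probability, "mc_error_pct": res.mc_error,
                }
            )
        tables["niche_prob"] = pd.DataFrame(rows)
        _log(cfg, "niche_prob", t0)

    if "tp" in cfg.analyses:
        rows = []
        tdf = TDFModel()
        for s, g in community.groups.items():
            if s == community.baseline_species:
                continue
            row = {
                "species": s,
                "point_tp": point_trophic_position(
                    float(g.d15N.mean()), lam=cfg.lam, dn_mean=tdf.dn_mean
                ),
                "n": g.n,
            }
            if cfg.bayesian_tp and g.n >= 2:
                res = bayesian_trophic_position(
                    g, community.baseline, tdf=tdf, lam=cfg.lam,
                    mcmc=MCMCConfig(
                        iterations=cfg.mcmc_iterations,
                        seed=int(rng.integers(2**31)),
                    ),
                )
                row.update(
                    median_tp=res.median, ci95_lo=res.ci95[0],
                    ci95_hi=res.ci95[1], rhat=res.rhat,
                )
            rows.append(row)
        tables["tp"] = pd.DataFrame(rows)
        _log(cfg, "tp", t0)

    if "simm" in cfg.analyses:
        srows, draws_rows = [], []
        for scen in cfg.mixing_scenarios:
            consumer, sources = build_predation_scenario(
                community, scen["predator"], list(scen["prey"])
            )
            res = fit_mixing_model(
                consumer, sources,
                mcmc=MCMCConfig(
                    chains=4, iterations=cfg.mcmc_iterations,
                    seed=int(rng.integers(2**31)),
                ),
            )
            for j, src in enumerate(res.sources):
                lo, hi = res.ci95[src]
                srows.append(
                    {
                        "predator": scen["predator"], "source": src,
                        "mean_proportion": res.posterior_means[j],
                        "ci95_lo": lo, "ci95_hi": hi, "rhat": res.rhat[src],
                    }
                )
            thin = res.proportion_draws[:: max(1, len(res.proportion_draws) // 2000)]
            for d_i, row in enumerate(thin):
                for j, src in enumerate(res.sources):
                    draws_rows.append(
                        {
                            "predator": scen["predator"], "draw": d_i,
                            "source": src, "proportion": row[j],
                        }
                    )
        tables["simm_summary"] = pd.DataFrame(srows)
        tables["simm_draws"] = pd.DataFrame(draws_rows)
        _log(cfg, "simm", t0)

    manifest = {
        "config": _jsonable(asdict(cfg)),
        "community": community_label,
        "species": list(community.groups),
        "superimposed": community.audit.get("superimposed", []),
        "baseline_mean_d15N": community.baseline_mean_d15N,
        "baseline_mean_d13C": community.baseline_mean_d13C,
        "version": _version(),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }

    if cfg.output_dir is not None:
        os.makedirs(cfg.output_dir, exist_ok=True)
        write_results(
            {k: v for k, v in tables.items() if len(v)},
            cfg.output_dir, format="csv", decimals=6,
        )
        with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    out: dict = dict(tables)
    out["manifest"] = manifest
    return out


def _chi2(coverage: float) -> float:
    from scipy import stats

    return float(stats.chi2.ppf(coverage, df=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _version() -> str:
    from . import __version__

    return __version__
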