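"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order — simulate, cohort, fit, deviance,
components, associate, brand — and communicate only through files in the
output directory, so any stage can be re-run from its on-disk inputs alone
and an externally supplied deviance matrix (same CSV shape) can replace the
synthetic one from the components stage onward.

One global seed expands to per-stage seeds through
``numpy.random.SeedSequence([seed, stage_index])`` (stage indices are the
position in :data:`STAGES`), so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, brand_price, cohort, components, deviance, national_model
from . import synthetic_claims as sc

log = logging.getLogger(__name__)

STAGES = ["simulate", "cohort", "fit", "deviance", "components", "associate", "brand"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_drugs": 60,
        "n_classes": 12,
        "class_overlap_rate": 0.08,
        "brand_fraction": 0.3,
        "n_counties": 50,
        "n_states": 8,
        "n_latent": 2,
        "n_demographics": 12,
        "demo_noise_sd": 0.3,
        "state_offset_sd": 0.5,
        "brand_pref_sd": 0.3,
        "n_patients": 20000,
        "years": [2003, 2010],
        "effects": {},
    },
    "cohort": {"sex": "F", "r_max": 10, "m_max": 8, "age_max": 85},
    "fit": {"lambdas": [1e-6, 1e-4, 1e-2], "n_folds": 3, "holdout_fraction": 0.2},
    "deviance": {"min_person_years": 1.0},
    "components": {"k": 4, "usage_quantile": 0.67, "cca_n_perm": 0},
    "associate": {
        "n_classes_target": 8,
        "n_assign": 100,
        "n_perm": 1000,
        "max_missing": 10,
    },
    "brand": {"grouping": "county"},
}


def default_config() -> dict:
    return json.loads(json.dumps(DEFAULT_CONFIG))


def load_config(path: str | Path) -> dict:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for key, val in user.items():
        if key not in cfg:
            raise KeyError(f"unknown config key: {key!r}")
        if isinstance(val, dict):
            for k2, v2 in val.items():
                if k2 not in cfg[key]:
                    raise KeyError(f"unknown config key: {key}.{k2}")
                cfg[key][k2] = v2
        else:
            cfg[key] = val
    return cfg


def offset_experiment_config(
    seed: int,
    n_offset_drugs: int = 10,
    counties_per_drug: int = 3,
    log_odds: float = float(np.log(2.0)),
) -> tuple[dict, list[tuple[str, str]]]:
    """Config for the controlled planted-offset experiment.

    Plants a 2x-odds (by default) first-use offset for each of the most
    commonly used drugs (highest baseline log-odds), each drug in its own
    disjoint set of counties, with every other county-level heterogeneity
    switched off, so the offset is the only systematic county signal.

    Two design points keep the experiment minimally perturbing: common
    drugs (rare drugs yield too few county events for a sign test at this
    scale, mirroring the focus on highly prescribed drugs), and disjoint
    county sets (stacking many doubled drugs in one county shifts its whole
    r/m bin distribution, and the model's conditioning on utilization then
    absorbs part of the planted signal).

    Returns (config, planted_cells) with planted_cells a list of
    (drug_id, county_id) pairs.
    """
    cfg = default_config()
    p = cfg["simulate"]
    if n_offset_drugs * counties_per_drug > p["n_counties"]:
        raise ValueError("not enough counties for disjoint planting")
    from . import synthetic_claims as _sc

    catalog = _sc.generate_catalog(
        p["n_drugs"], p["n_classes"], p["class_overlap_rate"], p["brand_fraction"],
        seed=stage_seed(seed, "simulate"),
    )
    drugs = list(catalog.nlargest(n_offset_drugs, "baseline_logit")["drug_id"])
    cells = []
    offsets = {}
    for j, d in enumerate(drugs):
        for i in range(counties_per_drug):
            c = f"{j * counties_per_drug + i + 1:05d}"
            cells.append((d, c))
            offsets[f"{d}|{c}"] = log_odds
    cfg["simulate"]["effects"] = {
        "latent_loading_sd": 0.0,
        "class_effect_sd": 0.0,
        "brand_pref_scale": 0.0,
        "offsets": offsets,
    }
    return cfg, cells


def stage_seed(seed: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([int(seed), STAGES.index(stage)]).generate_state(1)[0]
        % (2**31)
    )


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise FileNotFoundError(f"missing artifact {name}; run the {stage!r} stage first")
    return p


def stage_simulate(cfg: dict, out: Path, seed: int) -> None:
    p = cfg["simulate"]
    catalog = sc.generate_catalog(
        p["n_drugs"], p["n_classes"], p["class_overlap_rate"], p["brand_fraction"],
        seed=seed,
    )
    world = sc.generate_counties(
        p["n_counties"], p["n_states"], p["n_latent"], seed=seed + 1,
        n_demographics=p["n_demographics"], demo_noise_sd=p["demo_noise_sd"],
        state_offset_sd=p["state_offset_sd"], brand_pref_sd=p["brand_pref_sd"],
    )
    effects = sc.EffectSpec(**{
        k: (dict((tuple(kk.split("|")), vv) for kk, vv in v.items()) if k == "offsets" else v)
        for k, v in p["effects"].items()
    })
    claims, truth = sc.simulate_claims(
        catalog, world, p["n_patients"], tuple(p["years"]), effects, seed=seed + 2
    )
    sc.write_world(out, catalog, world, claims, truth)


def stage_cohort(cfg: dict, out: Path, seed: int) -> None:
    claims = pd.read_csv(
        _require(out, "claims.csv", "simulate"),
        dtype={"person_id": str, "county_id": str, "week": str, "drug_id": str},
    )
    catalog = sc.read_catalog(_require(out, "catalog.csv", "simulate"))
    c = cfg["cohort"]
    py = cohort.build_person_years(claims, sex=c["sex"])
    rule = cohort.CollapseRule(r_max=c["r_max"], m_max=c["m_max"], age_max=c["age_max"])
    binned = cohort.assign_bins(py, rule)
    fu = cohort.first_use_table(claims[claims["sex"] == c["sex"]] if c["sex"] else claims)
    # holdout split on persons for the bias check
    persons = np.sort(binned["person_id"].unique())
    rng = np.random.default_rng(seed)
    hold = set(persons[rng.random(len(persons)) < cfg["fit"]["holdout_fraction"]])
    binned["holdout"] = binned["person_id"].isin(hold)
    rs_train = cohort.build_risk_sets(
        binned[~binned["holdout"]], fu, list(catalog["drug_id"])
    )
    rs_hold = cohort.build_risk_sets(
        binned[binned["holdout"]], fu, list(catalog["drug_id"])
    )
    binned.to_csv(out / "person_years.csv", index=False)
    cohort.bin_index(binned).to_csv(out / "bins.csv", index=False)
    rs_train.to_csv(out / "risk_sets.csv", index=False)
    rs_hold.to_csv(out / "risk_sets_holdout.csv", index=False)


def _read_risk_sets(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"drug_id": str, "bin_id": str, "county_id": str})


def stage_fit(cfg: dict, out: Path, seed: int) -> None:
    rs = _read_risk_sets(_require(out, "risk_sets.csv", "cohort"))
    rs_hold = _read_risk_sets(_require(out, "risk_sets_holdout.csv", "cohort"))
    bins = pd.read_csv(_require(out, "bins.csv", "cohort"), dtype={"bin_id": str})
    nat = cohort.national_counts(rs)
    hyper = national_model.FitHyper(
        lambdas=tuple(cfg["fit"]["lambdas"]), n_folds=cfg["fit"]["n_folds"], seed=seed
    )
    models: dict[str, national_model.DrugModel] = {}
    for d in sorted(nat["drug_id"].unique()):
        try:
            models[d] = national_model.fit_drug_model(nat, d, bins, hyper)
        except national_model.DegenerateFitError:
            log.warning("skipping drug %s: zero events nationally", d)
    nat_hold = cohort.national_counts(rs_hold)
    bias = national_model.holdout_bias_check(models, nat_hold, bins)
    (out / "models.json").write_text(
        json.dumps({d: m.to_dict() for d, m in models.items()})
    )
    bias.to_csv(out / "bias_report.csv", index=False)
    # fitted probabilities for every observed (drug, bin)
    p_rows = []
    for d, m in models.items():
        sub = nat[nat["drug_id"] == d].merge(bins, on="bin_id")
        p_rows.append(pd.DataFrame({
            "drug_id": d, "bin_id": sub["bin_id"],
            "p": national_model.predict_bin_probability(m, sub),
        }))
    pd.concat(p_rows, ignore_index=True).to_csv(out / "p_hat.csv", index=False)


def stage_deviance(cfg: dict, out: Path, seed: int) -> None:
    rs = _read_risk_sets(_require(out, "risk_sets.csv", "cohort"))
    p_hat = pd.read_csv(_require(out, "p_hat.csv", "fit"),
                        dtype={"drug_id": str, "bin_id": str})
    nat = cohort.national_counts(rs)
    w = deviance.compute_weights(nat)
    summ = deviance.standardize_and_expect(rs, w, p_hat)
    G = deviance.build_deviance_matrix(summ, cfg["deviance"]["min_person_years"])
    deviance.write_deviance_csv(G, out / "deviance.csv")
    summ.to_csv(out / "county_summaries.csv", index=False)


def stage_components(cfg: dict, out: Path, seed: int) -> None:
    G = deviance.read_deviance_csv(_require(out, "deviance.csv", "deviance"))
    counties = sc.read_counties(_require(out, "counties.csv", "simulate"))
    catalog = sc.read_catalog(_require(out, "catalog.csv", "simulate"))
    k = cfg["components"]["k"]
    basis, proj = components.fit_components(G, k)
    basis.loadings.to_csv(out / "components.csv", index_label="drug_id")
    proj.to_csv(out / "projections.csv", index_label="county_id")
    pd.Series(basis.variance_fraction, name="variance_fraction").to_csv(
        out / "variance_fractions.csv", index_label="component"
    )
    stab = components.stability_leave_class_out(
        G, sc.catalog_class_map(catalog), min(k, 2)
    )
    stab.to_csv(out / "stability.csv", index=False)
    demo = counties.set_index("county_id").loc[
        G.index, [c for c in counties.columns if c.startswith("demo_")]
    ]
    summ = pd.read_csv(_require(out, "county_summaries.csv", "deviance"),
                       dtype={"drug_id": str, "county_id": str})
    users = summ.groupby("drug_id")["y_w"].sum().reindex(G.columns).fillna(0.0)
    try:
        cca = components.canonical_correlation(
            G, demo,
            components.CCAFilter(user_counts=users,
                                 usage_quantile=cfg["components"]["usage_quantile"]),
            n_perm=cfg["components"]["cca_n_perm"], seed=seed,
        )
        cca.significance.assign(correlation=cca.correlations).to_csv(
            out / "cca.csv", index=False
        )
    except (ValueError, np.linalg.LinAlgError) as e:
        log.warning("CCA skipped: %s", e)
        (out / "cca.csv").write_text(f"# skipped: {e}\n")


def stage_associate(cfg: dict, out: Path, seed: int) -> None:
    G = deviance.read_deviance_csv(_require(out, "deviance.csv", "deviance"))
    counties = sc.read_counties(_require(out, "counties.csv", "simulate"))
    adjacency = pd.read_csv(_require(out, "adjacency.csv", "simulate"),
                            dtype={"county_a": str, "county_b": str})
    catalog = sc.read_catalog(_require(out, "catalog.csv", "simulate"))
    a = cfg["associate"]
    counties = association.impute_demographics(counties, a["max_missing"])
    pairs = association.build_pair_table(G, counties, adjacency)
    rho_geo, p_geo = association.spearman_test(pairs["dist_deviance"], pairs["dist_geographic"])
    rho_dem, p_dem = association.spearman_test(pairs["dist_deviance"], pairs["dist_demographic"])
    border = association.border_samestate_regression(pairs)
    rand = association.class_recovery_rand(
        G, sc.catalog_class_map(catalog), a["n_classes_target"],
        a["n_assign"], a["n_perm"], seed=seed,
    )
    report = {
        "distance_spearman": {
            "geographic": {"rho": rho_geo, "p": p_geo},
            "demographic": {"rho": rho_dem, "p": p_dem},
        },
        "border_samestate": border,
        "class_recovery": {
            "separation_p": rand["separation_p"],
            "observed_ari_mean": float(np.mean(rand["observed_ari"])),
            "null_ari_mean": float(np.mean(rand["null_ari"])),
            "n_collapsed_classes": rand["n_collapsed_classes"],
        },
    }
    (out / "association_report.json").write_text(json.dumps(report, indent=1))
    pd.DataFrame({
        "observed_ari": pd.Series(rand["observed_ari"]),
        "null_ari": pd.Series(rand["null_ari"]),
    }).to_csv(out / "rand_report.csv", index=False)


def stage_brand(cfg: dict, out: Path, seed: int) -> None:
    G = deviance.read_deviance_csv(_require(out, "deviance.csv", "deviance"))
    counties = sc.read_counties(_require(out, "counties.csv", "simulate"))
    catalog = sc.read_catalog(_require(out, "catalog.csv", "simulate"))
    pref = brand_price.brand_preference_fit(G, catalog, grouping=cfg["brand"]["grouping"])
    pref.to_csv(out / "brand_preference.csv")
    demo = counties.set_index("county_id").loc[
        G.index, [c for c in counties.columns if c.startswith("demo_")]
    ]
    model = brand_price.brand_demographic_model(pref["coef"], demo, seed=seed)
    (out / "brand_demo_model.json").write_text(json.dumps({
        "r2": model["r2"], "alpha": model["alpha"],
        "coef": model["coef"].to_dict(),
    }, indent=1))
    proj = pd.read_csv(_require(out, "projections.csv", "components"),
                       dtype={"county_id": str}).set_index("county_id")
    corr = brand_price.class_price_correlation(proj, G, catalog, component="PC1")
    corr["per_class"].assign(pooled_rho=corr["pooled_rho"],
                             pooled_p=corr["pooled_p"]).to_csv(
        out / "price_correlations.csv", index=False
    )


_STAGE_FN = {
    "simulate": stage_simulate,
    "cohort": stage_cohort,
    "fit": stage_fit,
    "deviance": stage_deviance,
    "components": stage_components,
    "associate": stage_associate,
    "brand": stage_brand,
}


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    stages: list[str] | None = None,
) -> Path:
    """Run the requested stages (default: all) into ``out_dir``.

    Writes the effective config and a manifest of artifact SHA-256 hashes.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else _validated(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    todo = stages or STAGES
    unknown = [s for s in todo if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    (out / "config.yaml").write_text(yaml.safe_dump(cfg))
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    pkg_log = logging.getLogger("rxvar")
    pkg_log.addHandler(handler)
    try:
        for s in STAGES:
            if s in todo:
                log.info("stage %s", s)
                _STAGE_FN[s](cfg, out, stage_seed(cfg["seed"], s))
    finally:
        pkg_log.removeHandler(handler)
        handler.close()
    manifest = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir())
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _validated(config: dict) -> dict:
    cfg = default_config()
    for key, val in config.items():
        if key not in cfg:
            raise KeyError(f"unknown config key: {key!r}")
        if isinstance(val, dict):
            for k2, v2 in val.items():
                if k2 not in cfg[key]:
                    raise KeyError(f"unknown config key: {key}.{k2}")
                cfg[key][k2] = v2
        else:
            cfg[key] = val
    return cfg
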