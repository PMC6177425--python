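"""Synthetic prescription-claims world with known ground truth.

Generates the three inputs the analysis pipeline consumes — a drug catalog,
a county panel, and a long-format claims table — from a generative model in
which the log-odds of a first-time prescription per person-year combine
drug-level baselines, age / calendar-year / utilization effects, and planted
county-level latent components. The planted quantities are stored in a
:class:`TruthRecord` so downstream estimates can be checked against truth.

The geography is synthetic: counties are points in a box, states are
contiguous Voronoi cells around randomly chosen capitals, and county
adjacency is the Delaunay triangulation of the county coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from scipy.special import expit

__all__ = [
    "EffectSpec",
    "CountyWorld",
    "TruthRecord",
    "generate_catalog",
    "generate_counties",
    "simulate_claims",
    "write_world",
    "read_catalog",
    "read_counties",
]

CLAIMS_COLUMNS = [
    "person_id",
    "sex",
    "county_id",
    "birth_year",
    "start_year",
    "end_year",
    "week",
    "drug_id",
]


@dataclass
class EffectSpec:
    """Effect sizes entering the per-person-year first-use log-odds.

    The linear predictor for drug ``d``, person-year with age ``a``, year
    ``y``, utilization draw ``u`` in county ``c`` is::

        baseline_d + age_slope*(a-45)/10 + year_slope*(y-mid)
        + util_slope*log1p(u) + sum_k loading[d,k]*latent[c,k]
        + class_effect[class(d), c]
        + brand_pref_scale*brand_pref[c]*is_brand[d] + offset[d,c]

    ``latent_loading_sd`` sets the SD of per-component drug loadings.
    ``class_effect_sd`` sets the SD of a per-(therapeutic class, county)
    effect shared by all drugs of a class (the drug's primary class), which
    plants within-class correlation of county profiles.
    """

    age_slope: float = 0.25          # per decade of age
    year_slope: float = 0.05         # per calendar year
    util_slope: float = 0.6          # per unit log1p(utilization)
    latent_loading_sd: float = 0.35  # SD of drug loadings per component
    class_effect_sd: float = 0.35    # SD of shared per-(class, county) effects
    brand_pref_scale: float = 1.0    # multiplies county brand_pref_true
    util_mean: float = 1.5           # negative-binomial mean utilization
    util_size: float = 1.0           # negative-binomial size (overdispersion)
    offsets: dict = field(default_factory=dict)  # (drug_id, county_id) -> log-odds


@dataclass
class CountyWorld:
    """County panel plus the planted ground truth attached to the geography."""

    counties: pd.DataFrame           # county_id, state_id, lat, lon, demo_*
    adjacency: pd.DataFrame          # county_a, county_b (each pair once)
    latent_scores: np.ndarray        # n_counties x K
    demo_loadings: np.ndarray        # n_demographics x K
    brand_pref_true: np.ndarray      # n_counties

    @property
    def county_ids(self) -> pd.Index:
        return pd.Index(self.counties["county_id"])

    def adjacency_pairs(self) -> set[frozenset]:
        return {
            frozenset((a, b))
            for a, b in zip(self.adjacency["county_a"], self.adjacency["county_b"])
        }


@dataclass
class TruthRecord:
    """All planted quantities of one simulated dataset."""

    drug_loadings: pd.DataFrame      # drugs x K
    latent_scores: pd.DataFrame      # counties x K
    demo_loadings: pd.DataFrame      # demographics x K
    brand_pref_true: pd.Series       # per county
    offsets: dict                    # (drug_id, county_id) -> log-odds
    effect_spec: EffectSpec
    class_effects: pd.DataFrame | None = None  # counties x classes

    def to_json(self, path: str | Path) -> None:
        payload = {
            "drug_loadings": self.drug_loadings.to_dict(orient="index"),
            "latent_scores": self.latent_scores.to_dict(orient="index"),
            "demo_loadings": self.demo_loadings.to_dict(orient="index"),
            "brand_pref_true": self.brand_pref_true.to_dict(),
            "class_effects": (
                self.class_effects.to_dict(orient="index")
                if self.class_effects is not None else None
            ),
            "offsets": {f"{d}|{c}": v for (d, c), v in self.offsets.items()},
            "effect_spec": {
                k: v for k, v in asdict(self.effect_spec).items() if k != "offsets"
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def generate_catalog(
    n_drugs: int,
    n_classes: int,
    class_overlap_rate: float = 0.08,
    brand_fraction: float = 0.3,
    seed: int = 0,
    brand_price_ratio: float = 4.0,
    baseline_logit_range: tuple[float, float] = (-5.0, -2.5),
) -> pd.DataFrame:
    """Draw a drug catalog: classes (possibly overlapping), brand flag, price.

    Class sizes are unequal (Dirichlet-weighted) as real therapeutic classes
    are; a drug is multi-class with probability ``class_overlap_rate``.
    Brand-only drugs draw prices ``brand_price_ratio`` times higher on the
    log scale median.
    """
    if n_drugs < 2 or n_classes < 1:
        raise ValueError(f"need n_drugs >= 2 and n_classes >= 1, got {n_drugs}, {n_classes}")
    for name, rate in (("class_overlap_rate", class_overlap_rate), ("brand_fraction", brand_fraction)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    class_labels = [f"CL{i:03d}" for i in range(n_classes)]
    class_probs = rng.dirichlet(np.full(n_classes, 3.0))
    primary = rng.choice(n_classes, size=n_drugs, p=class_probs)
    multi = rng.random(n_drugs) < class_overlap_rate
    rows = []
    for i in range(n_drugs):
        classes = [class_labels[primary[i]]]
        if multi[i] and n_classes > 1:
            extra = int(rng.choice([c for c in range(n_classes) if c != primary[i]]))
            classes.append(class_labels[extra])
        brand = bool(rng.random() < brand_fraction)
        price = float(np.exp(rng.normal(np.log(10.0), 0.6)))
        if brand:
            price *= brand_price_ratio * float(np.exp(rng.normal(0.0, 0.2)))
        lo, hi = baseline_logit_range
        rows.append(
            {
                "drug_id": f"D{i:04d}",
                "generic_name": f"drug_{i:04d}",
                "classes": ";".join(sorted(set(classes))),
                "brand_only": brand,
                "price": price,
                "baseline_logit": float(rng.uniform(lo, hi)),
            }
        )
    return pd.DataFrame(rows)


def catalog_class_map(catalog: pd.DataFrame) -> dict[str, list[str]]:
    """drug_id -> list of therapeutic-class labels."""
    return {
        r.drug_id: r.classes.split(";") for r in catalog.itertuples()
    }


def _adjacency_from_points(lon: np.ndarray, lat: np.ndarray) -> set[tuple[int, int]]:
    pts = np.column_stack([lon, lat])
    n = len(pts)
    edges: set[tuple[int, int]] = set()
    if n >= 4:
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            for i in range(3):
                a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
                edges.add((min(a, b), max(a, b)))
    else:
        for a in range(n):
            for b in range(a + 1, n):
                edges.add((a, b))
    return edges


def generate_counties(
    n_counties: int,
    n_states: int,
    n_latent: int,
    seed: int = 0,
    n_demographics: int = 12,
    demo_noise_sd: float = 0.3,
    state_offset_sd: float = 0.0,
    brand_pref_sd: float = 0.3,
) -> CountyWorld:
    """Generate the county panel with planted latent component scores.

    Latent scores are i.i.d. standard normal per component, plus a per-state
    offset with SD ``state_offset_sd`` (this drives the same-state border
    signal). Demographics are a linear map of the *pre-offset* latent scores
    plus Gaussian noise with SD ``demo_noise_sd``: the state offset models
    state-level prescribing influences (legislation, insurance networks)
    that are not mediated by county demographics, which is what the border
    same-state regression isolates after controlling for demographic
    distance.
    """
    if not (n_counties >= n_states >= 1):
        raise ValueError(f"need n_counties >= n_states >= 1, got {n_counties}, {n_states}")
    if n_latent < 1:
        raise ValueError("n_latent must be >= 1")
    if n_latent > n_demographics:
        raise ValueError(
            f"n_latent ({n_latent}) exceeds demographic dimension ({n_demographics})"
        )
    rng = np.random.default_rng(seed)
    lat = rng.uniform(25.0, 49.0, n_counties)
    lon = rng.uniform(-124.0, -67.0, n_counties)
    # contiguous states: Voronoi cells around capitals placed at random counties
    capitals = rng.choice(n_counties, size=n_states, replace=False)
    d2 = (lon[:, None] - lon[capitals][None, :]) ** 2 + (lat[:, None] - lat[capitals][None, :]) ** 2
    state_idx = np.argmin(d2, axis=1)
    state_idx[capitals] = np.arange(n_states)  # capitals anchor their own state

    z_base = rng.standard_normal((n_counties, n_latent))
    state_off = rng.normal(0.0, state_offset_sd, (n_states, n_latent)) if state_offset_sd > 0 else np.zeros((n_states, n_latent))
    z = z_base + state_off[state_idx]

    demo_load = rng.normal(0.0, 1.0, (n_demographics, n_latent)) / np.sqrt(n_latent)
    demo = z_base @ demo_load.T + rng.normal(0.0, demo_noise_sd, (n_counties, n_demographics))
    brand_pref = rng.normal(0.0, brand_pref_sd, n_counties)

    county_ids = [f"{i + 1:05d}" for i in range(n_counties)]
    counties = pd.DataFrame(
        {
            "county_id": county_ids,
            "state_id": [f"S{s:02d}" for s in state_idx],
            "lat": lat,
            "lon": lon,
        }
    )
    for j in range(n_demographics):
        counties[f"demo_{j:02d}"] = demo[:, j]

    edges = _adjacency_from_points(lon, lat)
    adjacency = pd.DataFrame(
        sorted((county_ids[a], county_ids[b]) for a, b in edges),
        columns=["county_a", "county_b"],
    )
    return CountyWorld(counties, adjacency, z, demo_load, brand_pref)


def simulate_claims(
    catalog: pd.DataFrame,
    world: CountyWorld,
    n_patients: int,
    years: tuple[int, int] = (2003, 2010),
    effect_spec: EffectSpec | None = None,
    seed: int = 0,
    drug_loadings: np.ndarray | None = None,
    return_person_years: bool = False,
):
    """Simulate first-time prescription claims over multi-year enrollment.

    Each person gets a county, sex, birth year and a contiguous enrollment
    window of at least 3 calendar years. Per person-year a utilization count
    is drawn (negative binomial); person-years with zero utilization have no
    first-use events. For every drug not yet used by the person, a first-use
    event occurs with probability given by the logistic model documented in
    :class:`EffectSpec`. One claims row is written per (person, drug) first
    use, with a uniformly placed ISO week within the year.
    """
    if len(catalog) == 0 or len(world.counties) == 0:
        raise ValueError("catalog and county panel must be non-empty")
    y0, y1 = years
    if y1 - y0 + 1 < 3:
        raise ValueError("years must span at least 3 calendar years")
    spec = effect_spec or EffectSpec()
    rng = np.random.default_rng(seed)

    n_counties = len(world.counties)
    n_drugs = len(catalog)
    K = world.latent_scores.shape[1]
    if drug_loadings is None:
        drug_loadings = rng.normal(0.0, spec.latent_loading_sd, (n_drugs, K))
    drug_loadings = np.asarray(drug_loadings, dtype=float)

    county_ids = world.counties["county_id"].to_numpy()
    drug_ids = catalog["drug_id"].to_numpy()
    baseline = catalog["baseline_logit"].to_numpy(float)
    is_brand = catalog["brand_only"].to_numpy(bool)

    # county x drug planted effect
    cd_effect = world.latent_scores @ drug_loadings.T  # counties x drugs
    cd_effect = cd_effect + spec.brand_pref_scale * np.outer(
        world.brand_pref_true, is_brand.astype(float)
    )
    # shared per-(primary class, county) effect: within-class profile correlation
    primary_class = [c.split(";")[0] for c in catalog["classes"]]
    class_labels = sorted(set(primary_class))
    if spec.class_effect_sd > 0:
        class_eff = rng.normal(0.0, spec.class_effect_sd, (n_counties, len(class_labels)))
    else:
        class_eff = np.zeros((n_counties, len(class_labels)))
    cls_idx = np.array([class_labels.index(c) for c in primary_class])
    cd_effect = cd_effect + class_eff[:, cls_idx]
    if spec.offsets:
        did_index = {d: j for j, d in enumerate(drug_ids)}
        cid_index = {c: i for i, c in enumerate(county_ids)}
        for (d, c), v in spec.offsets.items():
            cd_effect[cid_index[c], did_index[d]] += v

    # persons
    county_of = rng.integers(0, n_counties, n_patients)
    sex = np.where(rng.random(n_patients) < 0.5, "F", "M")
    start = rng.integers(y0, y1 - 2, n_patients, endpoint=True)  # at least 3 yrs
    max_dur = y1 - start + 1
    dur = 3 + (rng.random(n_patients) * (max_dur - 2)).astype(int)  # 3..max_dur
    end = start + dur - 1
    age0 = rng.integers(5, 71, n_patients)
    birth_year = start - age0

    # person-years (expanded)
    py_person = np.repeat(np.arange(n_patients), dur)
    offs = np.concatenate([np.arange(d) for d in dur])
    py_year = start[py_person] + offs
    py_age = py_year - birth_year[py_person]
    util = rng.negative_binomial(
        spec.util_size,
        spec.util_size / (spec.util_size + spec.util_mean),
        len(py_person),
    )
    active = util > 0
    a_person = py_person[active]
    a_year = py_year[active]
    a_age = py_age[active]
    a_county = county_of[a_person]
    py_effect = (
        spec.age_slope * (a_age - 45.0) / 10.0
        + spec.year_slope * (a_year - (y0 + y1) / 2.0)
        + spec.util_slope * np.log1p(util[active])
    )

    # first-use year per (person, drug); chunk over drugs to bound memory
    rows_person: list[np.ndarray] = []
    rows_year: list[np.ndarray] = []
    rows_drug: list[np.ndarray] = []
    order = np.lexsort((a_year, a_person))
    s_person, s_year = a_person[order], a_year[order]
    s_effect, s_county = py_effect[order], a_county[order]
    for j0 in range(0, n_drugs, 8):
        j1 = min(j0 + 8, n_drugs)
        logit = (
            s_effect[:, None]
            + baseline[None, j0:j1]
            + cd_effect[s_county, j0:j1]
        )
        hits = rng.random(logit.shape) < expit(logit)
        for dj in range(j0, j1):
            h = hits[:, dj - j0]
            if not h.any():
                continue
            hp, hy = s_person[h], s_year[h]
            # rows are sorted by (person, year); first hit per person = first use
            first = np.ones(len(hp), dtype=bool)
            first[1:] = hp[1:] != hp[:-1]
            rows_person.append(hp[first])
            rows_year.append(hy[first])
            rows_drug.append(np.full(first.sum(), dj))

    if rows_person:
        ev_person = np.concatenate(rows_person)
        ev_year = np.concatenate(rows_year)
        ev_drug = np.concatenate(rows_drug)
    else:
        ev_person = ev_year = ev_drug = np.array([], dtype=int)

    week = rng.integers(1, 53, len(ev_person))
    claims = pd.DataFrame(
        {
            "person_id": [f"P{p:07d}" for p in ev_person],
            "sex": sex[ev_person],
            "county_id": county_ids[county_of[ev_person]],
            "birth_year": birth_year[ev_person],
            "start_year": start[ev_person],
            "end_year": end[ev_person],
            "week": [f"{y}-W{w:02d}" for y, w in zip(ev_year, week)],
            "drug_id": drug_ids[ev_drug],
        }
    )
    claims = claims.sort_values(["person_id", "week", "drug_id"], kind="mergesort").reset_index(drop=True)

    truth = TruthRecord(
        drug_loadings=pd.DataFrame(drug_loadings, index=drug_ids, columns=[f"k{k}" for k in range(K)]),
        latent_scores=pd.DataFrame(world.latent_scores, index=county_ids, columns=[f"k{k}" for k in range(K)]),
        demo_loadings=pd.DataFrame(
            world.demo_loadings,
            index=[f"demo_{j:02d}" for j in range(world.demo_loadings.shape[0])],
            columns=[f"k{k}" for k in range(K)],
        ),
        brand_pref_true=pd.Series(world.brand_pref_true, index=county_ids, name="brand_pref_true"),
        offsets=dict(spec.offsets),
        effect_spec=spec,
        class_effects=pd.DataFrame(class_eff, index=county_ids, columns=class_labels),
    )
    if return_person_years:
        # diagnostic view of the latent person-year grid (active years only)
        py = pd.DataFrame(
            {
                "person_id": [f"P{p:07d}" for p in s_person],
                "county_id": county_ids[s_county],
                "year": s_year,
                "linpred_base": s_effect,
            }
        )
        return claims, truth, py
    return claims, truth


def write_world(
    out_dir: str | Path,
    catalog: pd.DataFrame,
    world: CountyWorld,
    claims: pd.DataFrame,
    truth: TruthRecord,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog.to_csv(out / "catalog.csv", index=False)
    world.counties.to_csv(out / "counties.csv", index=False)
    world.adjacency.to_csv(out / "adjacency.csv", index=False)
    claims.to_csv(out / "claims.csv", index=False)
    truth.to_json(out / "truth.json")


def read_catalog(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"drug_id": str, "classes": str})


def read_counties(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"county_id": str, "state_id": str})
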