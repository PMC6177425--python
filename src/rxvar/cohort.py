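"""Person-year cohort construction from claims.

Converts a long-format claims table into the sampling units of the
discrete-time incidence model: person-years after a two-year washout, each
assigned to a bin jointly defined by 5-year age band, calendar year, number
of incident prescriptions that year (r) and number of years in the person's
record with any incident prescription (m). Per drug, risk sets count
at-risk person-years n and first-use events y, nationally and per county.

Conventions (configurable where noted):

* Washout = the first 2 calendar years of each person's observation,
  regardless of whether events occurred in them; persons observed for 2 or
  fewer years contribute nothing.
* A prescription is *incident* if the drug was never dispensed earlier in
  the person's record, washout years included.
* m is a static per-person covariate counting post-washout years with at
  least one incident prescription (consistency of care over time).
* A person-year enters drug d's risk set iff it has r > 0 and the person
  has no d exposure before that year; the year of first use counts in both
  the numerator and the denominator (discrete-time survival convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CollapseRule",
    "build_person_years",
    "assign_bins",
    "build_risk_sets",
    "first_use_table",
]

WASHOUT_YEARS = 2


def _event_year(week_col: pd.Series) -> pd.Series:
    """Calendar year from an ISO-week string like ``2005-W23``."""
    return week_col.str.slice(0, 4).astype(int)


def first_use_table(claims: pd.DataFrame) -> pd.DataFrame:
    """Earliest dispensing year per (person, drug), with enrollment bounds.

    Includes washout-year uses: downstream logic needs them to exclude
    prevalent users from risk sets.
    """
    df = claims[["person_id", "drug_id", "start_year", "end_year"]].copy()
    df["year"] = _event_year(claims["week"])
    bad = (df["year"] < df["start_year"]) | (df["year"] > df["end_year"])
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"claims row {claims.index[idx]}: event year outside enrollment "
            f"({df['year'].iloc[idx]} not in "
            f"[{df['start_year'].iloc[idx]}, {df['end_year'].iloc[idx]}])"
        )
    fu = (
        df.groupby(["person_id", "drug_id"], sort=True)
        .agg(first_year=("year", "min"), start_year=("start_year", "first"))
        .reset_index()
    )
    fu["in_washout"] = fu["first_year"] < fu["start_year"] + WASHOUT_YEARS
    return fu


def build_person_years(claims: pd.DataFrame, sex: str | None = None) -> pd.DataFrame:
    """Expand claims into post-washout person-years with (r, m) covariates.

    Parameters
    ----------
    claims
        Long-format claims (one row per dispensing event).
    sex
        If given, keep only persons of this sex before expansion.

    Returns
    -------
    DataFrame with columns person_id, county_id, sex, year, age, r, m.
    Persons with 2 or fewer observed years are dropped.
    """
    if sex is not None:
        claims = claims[claims["sex"] == sex]
    if len(claims) == 0:
        return pd.DataFrame(
            columns=["person_id", "county_id", "sex", "year", "age", "r", "m"]
        )
    persons = (
        claims.groupby("person_id", sort=True)
        .agg(
            county_id=("county_id", "first"),
            sex=("sex", "first"),
            birth_year=("birth_year", "first"),
            start_year=("start_year", "first"),
            end_year=("end_year", "first"),
        )
        .reset_index()
    )
    persons = persons[persons["end_year"] - persons["start_year"] + 1 > WASHOUT_YEARS]
    if len(persons) == 0:
        return pd.DataFrame(
            columns=["person_id", "county_id", "sex", "year", "age", "r", "m"]
        )

    fu = first_use_table(claims)
    incident = fu[~fu["in_washout"]]
    # r: incident prescriptions per (person, year)
    r_tab = (
        incident.groupby(["person_id", "first_year"], sort=False)
        .size()
        .rename("r")
        .reset_index()
        .rename(columns={"first_year": "year"})
    )
    # m: number of post-washout years with >= 1 incident prescription
    m_tab = r_tab.groupby("person_id").size().rename("m").reset_index()

    n_years = (persons["end_year"] - persons["start_year"] + 1 - WASHOUT_YEARS).to_numpy()
    rep = np.repeat(np.arange(len(persons)), n_years)
    offs = np.concatenate([np.arange(k) for k in n_years])
    py = pd.DataFrame(
        {
            "person_id": persons["person_id"].to_numpy()[rep],
            "county_id": persons["county_id"].to_numpy()[rep],
            "sex": persons["sex"].to_numpy()[rep],
            "year": persons["start_year"].to_numpy()[rep] + WASHOUT_YEARS + offs,
        }
    )
    py["age"] = py["year"] - persons["birth_year"].to_numpy()[rep]
    py = py.merge(r_tab, on=["person_id", "year"], how="left")
    py = py.merge(m_tab, on="person_id", how="left")
    py["r"] = py["r"].fillna(0).astype(int)
    py["m"] = py["m"].fillna(0).astype(int)
    return py


@dataclass(frozen=True)
class CollapseRule:
    """Caps pooling sparse upper tails of the bin variables."""

    r_max: int = 10
    m_max: int = 8
    age_max: int = 85  # top age band is [age_max, inf)
    age_width: int = 5


def assign_bins(person_years: pd.DataFrame, collapse_rule: CollapseRule | None = None) -> pd.DataFrame:
    """Map each person-year to its bin (age band, year, r level, m level).

    Age bands are half-open 5-year intervals labelled by their left edge;
    r and m values above the caps are pooled into the top level. Adds
    columns age_band, r_level, m_level, bin_id.
    """
    rule = collapse_rule or CollapseRule()
    py = person_years.copy()
    if (py["age"] < 0).any():
        raise ValueError("negative age encountered")
    if (py["year"] < 0).any():
        raise ValueError("negative calendar year encountered")
    band = (py["age"] // rule.age_width) * rule.age_width
    py["age_band"] = band.clip(upper=rule.age_max).astype(int)
    py["r_level"] = py["r"].clip(upper=rule.r_max).astype(int)
    py["m_level"] = py["m"].clip(upper=rule.m_max).astype(int)
    py["bin_id"] = (
        "a" + py["age_band"].astype(str)
        + "_y" + py["year"].astype(str)
        + "_r" + py["r_level"].astype(str)
        + "_m" + py["m_level"].astype(str)
    )
    return py


def bin_index(binned: pd.DataFrame) -> pd.DataFrame:
    """Lookup of observed bins and their factor levels."""
    return (
        binned[["bin_id", "age_band", "year", "r_level", "m_level"]]
        .drop_duplicates()
        .sort_values("bin_id", kind="mergesort")
        .reset_index(drop=True)
    )


def build_risk_sets(
    binned: pd.DataFrame,
    first_use: pd.DataFrame,
    drug_ids: list[str],
) -> pd.DataFrame:
    """Per-drug risk-set counts by (bin, county).

    A person-year enters drug d's denominator iff r > 0 and the person was
    never observed on d before that year (persons whose first d use fell in
    washout are excluded outright); it enters the numerator iff that year is
    the person's post-washout first use of d. Returns a long DataFrame
    (drug_id, bin_id, county_id, n, y); national counts are the county sums.
    """
    known = set(first_use["drug_id"].unique())
    missing = [d for d in known if d not in set(drug_ids)]
    if missing:
        raise KeyError(f"claims contain drugs absent from catalog: {missing[:5]}")

    at_risk = binned[binned["r"] > 0]
    person = at_risk["person_id"].to_numpy()
    year = at_risk["year"].to_numpy()
    base_key = at_risk["bin_id"].to_numpy() + "|" + at_risk["county_id"].to_numpy()

    person_order = pd.Index(pd.unique(person))
    pidx = person_order.get_indexer(person)

    fu_by_drug = dict(tuple(first_use.groupby("drug_id", sort=False)))
    out = []
    for d in drug_ids:
        fu = fu_by_drug.get(d)
        if fu is None:
            fyear = np.full(len(person_order), np.inf)
            washed = np.zeros(len(person_order), dtype=bool)
        else:
            fyear = np.full(len(person_order), np.inf)
            washed = np.zeros(len(person_order), dtype=bool)
            loc = person_order.get_indexer(fu["person_id"].to_numpy())
            ok = loc >= 0
            fyear[loc[ok]] = fu["first_year"].to_numpy(float)[ok]
            washed[loc[ok]] = fu["in_washout"].to_numpy()[ok]
        f = fyear[pidx]
        in_risk = (~washed[pidx]) & (year <= f)
        if not in_risk.any():
            continue
        ev = in_risk & (year == f)
        key = base_key[in_risk]
        frame = pd.DataFrame({"key": key, "y": ev[in_risk].astype(int)})
        agg = frame.groupby("key", sort=True).agg(n=("y", "size"), y=("y", "sum")).reset_index()
        agg[["bin_id", "county_id"]] = agg["key"].str.split("|", expand=True)
        agg["drug_id"] = d
        out.append(agg[["drug_id", "bin_id", "county_id", "n", "y"]])
    if not out:
        return pd.DataFrame(columns=["drug_id", "bin_id", "county_id", "n", "y"])
    return pd.concat(out, ignore_index=True)


def national_counts(risk_sets: pd.DataFrame) -> pd.DataFrame:
    """Collapse county risk sets to national (drug, bin) totals."""
    return (
        risk_sets.groupby(["drug_id", "bin_id"], sort=True)[["n", "y"]]
        .sum()
        .reset_index()
    )
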