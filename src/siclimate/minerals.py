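"""Sediment mineralogy and chert-occurrence analyses.

Computes the sediment-expressed reverse weathering ratio f_rw_s from
bulk mineral abundances -- the weight of cation-bearing clay minerals
(berthierine/chamosite, glauconite, Fe-smectite, Fe-illite) over
cation-bearing clays plus quartz. Kaolinite, which carries no
alkalinity demand, and all non-silicate phases are excluded, which
makes the ratio insensitive to dilution by other phases and to
sedimentation rate.

Also tabulates the fraction of marine sections bearing chert
(f_chert) per time bin, optionally grouped by lithology, paleolatitude
band, or chert type -- the "chert gap" diagnostic.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: clay phases that consume alkalinity when they form
CATION_BEARING_CLAYS = frozenset(
    {"berthierine_chamosite", "glauconite", "fe_smectite", "fe_illite"}
)

MINERAL_VOCAB = CATION_BEARING_CLAYS | {"quartz", "pyrite", "kaolinite", "other"}

#: ordered Late Permian - Middle Triassic stage/substage vocabulary
AGE_BINS = (
    "Wuchiapingian",
    "Changhsingian",
    "Griesbachian",
    "Dienerian",
    "Smithian",
    "Spathian",
    "Anisian",
    "Ladinian",
)

LITHOLOGIES = ("siliciclastic", "carbonate", "mixed")
CHERT_TYPES = ("biogenic", "nodule", "replacement")
LATITUDE_BANDS = ((0.0, 30.0), (30.0, 60.0), (60.0, 90.0))

#: per-sample weight fractions may exceed 1 by at most this tolerance
WEIGHT_SUM_TOL = 0.02


def _validate_mineral_frame(df: pd.DataFrame) -> None:
    required = {"section_id", "height", "interval", "mineral", "weight_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mineral table missing columns: {sorted(missing)}")
    bad = set(df["mineral"]) - MINERAL_VOCAB
    if bad:
        raise ValueError(f"unknown minerals: {sorted(bad)}")
    if (df["weight_fraction"] < 0).any():
        raise ValueError("weight fractions must be nonnegative")
    sums = df.groupby(["section_id", "height"])["weight_fraction"].sum()
    if (sums > 1.0 + WEIGHT_SUM_TOL).any():
        offender = sums.idxmax()
        raise ValueError(
            f"weight fractions of sample {offender} sum to {sums.max():.3f} > 1"
        )


def f_rw_s_from_minerals(
    sample: Mapping[str, float] | pd.DataFrame,
    si_weights: Mapping[str, float] | None = None,
) -> float:
    """Sediment-expressed reverse weathering ratio of one sample.

    sum(cation-bearing clays) / (sum(cation-bearing clays) + quartz),
    with kaolinite and non-silicate phases excluded. Returns NaN when
    the denominator is zero (flagged missing value).

    By default the ratio uses weight fractions directly; an optional
    si_weights mapping (mineral -> Si mass per unit mineral mass)
    reweights each phase to a mole-Si basis before forming the ratio.
    """
    if isinstance(sample, pd.DataFrame):
        weights = dict(zip(sample["mineral"], sample["weight_fraction"]))
    else:
        weights = dict(sample)
    bad = set(weights) - MINERAL_VOCAB
    if bad:
        raise ValueError(f"unknown minerals: {sorted(bad)}")
    if si_weights is not None:
        weights = {m: w * si_weights.get(m, 1.0) for m, w in weights.items()}
    clays = sum(w for m, w in weights.items() if m in CATION_BEARING_CLAYS)
    quartz = weights.get("quartz", 0.0)
    if clays < 0 or quartz < 0:
        raise ValueError("weight fractions must be nonnegative")
    denom = clays + quartz
    if denom == 0.0:
        return float("nan")
    return clays / denom


def section_frw_profile(
    samples: pd.DataFrame, si_weights: Mapping[str, float] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-height f_rw_s profile and pre/post interval ranges.

    Returns a height-sorted profile (one row per section_id/height) and
    a dict mapping interval label -> (min, max) of f_rw_s. si_weights
    optionally switches the ratio to a Si-mass basis (see
    f_rw_s_from_minerals).
    """
    _validate_mineral_frame(samples)
    rows = []
    for (section, height), grp in samples.groupby(["section_id", "height"]):
        intervals = grp["interval"].unique()
        if len(intervals) != 1:
            raise ValueError(f"sample {(section, height)} has mixed interval labels")
        rows.append({
            "section_id": section,
            "height": height,
            "interval": intervals[0],
            "f_rw_s": f_rw_s_from_minerals(grp, si_weights=si_weights),
        })
    profile = (
        pd.DataFrame(rows)
        .sort_values(["section_id", "height"], kind="mergesort")
        .reset_index(drop=True)
    )
    ranges = {}
    valid = profile.dropna(subset=["f_rw_s"])
    for interval, grp in valid.groupby("interval"):
        ranges[interval] = (float(grp["f_rw_s"].min()), float(grp["f_rw_s"].max()))
    return profile, ranges


def _validate_chert_frame(df: pd.DataFrame) -> None:
    required = {"site_id", "age_bin", "lithology", "paleolat_deg", "chert_types"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chert table missing columns: {sorted(missing)}")
    bad_bins = set(df["age_bin"]) - set(AGE_BINS)
    if bad_bins:
        raise ValueError(f"age bins outside the documented vocabulary: {sorted(bad_bins)}")
    bad_lith = set(df["lithology"]) - set(LITHOLOGIES)
    if bad_lith:
        raise ValueError(f"unknown lithologies: {sorted(bad_lith)}")
    lat = df["paleolat_deg"]
    if ((lat < 0) | (lat > 90)).any():
        raise ValueError("paleolatitude must lie in [0, 90] (absolute degrees)")


def parse_chert_types(value) -> frozenset:
    """Parse a chert_types cell: iterable or ';'-separated string."""
    if isinstance(value, str):
        items = [v.strip() for v in value.split(";") if v.strip()]
    elif isinstance(value, Iterable):
        items = list(value)
    else:
        raise ValueError(f"cannot parse chert types from {value!r}")
    items = [i for i in items if i != "none"]
    bad = set(items) - set(CHERT_TYPES)
    if bad:
        raise ValueError(f"unknown chert types: {sorted(bad)}")
    return frozenset(items)


def latitude_band(lat: float) -> str:
    for lo, hi in LATITUDE_BANDS:
        if lo <= lat < hi or (hi == 90.0 and lat == 90.0):
            return f"{lo:.0f}-{hi:.0f}"
    raise ValueError(f"latitude {lat} outside [0, 90]")


def chert_fraction(records: pd.DataFrame, grouping: str = "none") -> pd.DataFrame:
    """Fraction of distinct sites bearing chert per age bin.

    grouping: 'none' (all sites), 'lithology', 'latitude_band', or
    'type' (one row per chert deposit type). A site counts once per age
    bin however many beds bear chert; empty bins report count 0 and an
    undefined (NaN) fraction.
    """
    if grouping not in ("none", "lithology", "latitude_band", "type"):
        raise ValueError(f"unknown grouping {grouping!r}")
    _validate_chert_frame(records)
    df = records.copy()
    df["types"] = df["chert_types"].map(parse_chert_types)
    df["band"] = df["paleolat_deg"].map(latitude_band)

    def site_table(sub: pd.DataFrame, chert_type: str | None) -> pd.DataFrame:
        rows = []
        for age_bin in AGE_BINS:
            in_bin = sub[sub["age_bin"] == age_bin]
            sites = in_bin.groupby("site_id")["types"].agg(
                lambda ts: frozenset().union(*ts)
            )
            n_sites = len(sites)
            if chert_type is None:
                n_chert = int(sum(len(t) > 0 for t in sites))
            else:
                n_chert = int(sum(chert_type in t for t in sites))
            rows.append({
                "age_bin": age_bin,
                "n_sites": n_sites,
                "n_chert": n_chert,
                "f_chert": (n_chert / n_sites) if n_sites else float("nan"),
            })
        return pd.DataFrame(rows)

    if grouping == "none":
        return site_table(df, None)
    if grouping == "type":
        parts = []
        for ct in CHERT_TYPES:
            t = site_table(df, ct)
            t.insert(0, "chert_type", ct)
            parts.append(t)
        return pd.concat(parts, ignore_index=True)
    key = "lithology" if grouping == "lithology" else "band"
    parts = []
    for value, sub in df.groupby(key):
        t = site_table(sub, None)
        t.insert(0, key, value)
        parts.append(t)
    return pd.concat(parts, ignore_index=True)
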