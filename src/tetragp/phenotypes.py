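"""Phenotype processing: derived traits, check-based location adjustment,
and AUDPC for repeated disease scores.

Phenotype tables are long-format DataFrames with one plot record per row:
columns ``genotype``, ``location``, ``rep``, ``trait``, ``value`` (plus
``day`` for dated disease scores).  The eight traits of a potato trial are
tuber weight (TW, kg/plant), tuber number (TN), average tuber weight
(ATW = TW/TN), specific gravity (SG), the 1-9 uniformity scores Size,
Shape and Eye, and late-blight severity (LB).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAITS = ("TW", "TN", "ATW", "SG", "Size", "Shape", "Eye", "LB")
REQUIRED_COLUMNS = ("genotype", "location", "rep", "trait", "value")

#: traits never adjusted by location (scored on a per-plant basis only)
UNADJUSTED_TRAITS = ("LB",)


def validate_table(pheno: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")


def derive_atw(pheno: pd.DataFrame) -> pd.DataFrame:
    """Append ATW = TW / TN rows, computed per plot.

    Plots with TN = 0 get no ATW record (logged); plots lacking either
    component are skipped.
    """
    validate_table(pheno)
    keys = ["genotype", "location", "rep"]
    wide = (
        pheno[pheno["trait"].isin(["TW", "TN"])]
        .pivot_table(index=keys, columns="trait", values="value", aggfunc="first")
        .reset_index()
    )
    if "TW" not in wide.columns or "TN" not in wide.columns:
        raise ValueError("derive_atw needs paired TW and TN records")
    paired = wide.dropna(subset=["TW", "TN"])
    zero_tn = paired["TN"] == 0
    if zero_tn.any():
        logger.warning("%d plot(s) with TN=0: ATW left missing", int(zero_tn.sum()))
    ok = paired[~zero_tn]
    atw = ok[keys].copy()
    atw["trait"] = "ATW"
    atw["value"] = (ok["TW"] / ok["TN"]).to_numpy()
    extra = [c for c in pheno.columns if c not in atw.columns]
    for c in extra:
        atw[c] = np.nan
    return pd.concat([pheno, atw[pheno.columns]], ignore_index=True)


def adjust_by_location(
    pheno: pd.DataFrame,
    check_ids,
    traits=None,
) -> pd.DataFrame:
    """Additively center each location on its check-cultivar mean.

    adjusted = raw - (check mean at that location - grand check mean), where
    the grand mean averages the per-location check means.  Within-location
    differences between genotypes are preserved exactly, and the grand mean
    of the checks is unchanged.
    """
    validate_table(pheno)
    check_ids = set(check_ids)
    out = pheno.copy()
    if traits is None:
        traits = [t for t in out["trait"].unique() if t not in UNADJUSTED_TRAITS]
    out["adjusted"] = out.get("adjusted", False)
    for trait in traits:
        sel = out["trait"] == trait
        sub = out[sel]
        checks = sub[sub["genotype"].isin(check_ids)]
        loc_means = checks.groupby("location")["value"].mean()
        locs_present = sub["location"].unique()
        no_checks = [loc for loc in locs_present if loc not in loc_means.index]
        if no_checks:
            raise ValueError(
                f"location(s) {no_checks} have no check records for trait {trait!r}"
            )
        grand = loc_means.loc[[loc for loc in loc_means.index if loc in locs_present]].mean()
        shift = (loc_means - grand).reindex(sub["location"]).to_numpy()
        out.loc[sel, "value"] = sub["value"].to_numpy() - shift
        out.loc[sel, "adjusted"] = True
    return out


def audpc(times, scores) -> float:
    """Area under the disease progress curve by the trapezoidal rule.

    ``times`` in days, strictly increasing; ``scores`` the severity at each
    time.  Units are score x days.
    """
    times = np.asarray(times, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if times.ndim != 1 or times.shape != scores.shape:
        raise ValueError("times and scores must be aligned 1-D sequences")
    if len(times) < 2:
        raise ValueError("AUDPC needs at least two time points")
    if not (np.diff(times) > 0).all():
        raise ValueError("times must be strictly increasing without duplicates")
    return float(np.trapezoid(scores, times))


def audpc_table(lb_records: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype AUDPC from long-format dated severity scores.

    Expects columns ``genotype``, ``day``, ``value`` (one score per genotype
    per day; replicate scores for a day are averaged first).
    """
    for c in ("genotype", "day", "value"):
        if c not in lb_records.columns:
            raise ValueError(f"late-blight records need column {c!r}")
    rows = []
    for g, sub in lb_records.groupby("genotype", sort=False):
        series = sub.groupby("day")["value"].mean().sort_index()
        rows.append((g, audpc(series.index.to_numpy(), series.to_numpy())))
    return pd.DataFrame(rows, columns=["genotype", "audpc"])


def genotype_means(pheno: pd.DataFrame, trait: str) -> pd.Series:
    """Mean value per genotype across all plots for one trait."""
    validate_table(pheno)
    sub = pheno[pheno["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    return sub.groupby("genotype")["value"].mean().rename(trait)
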