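"""Variance components and broad-sense heritability for multi-location trials.

The trial model treats genotype, location, genotype-by-location and
replicate-within-location as independent random effects with identity
covariances plus an i.i.d. residual; the only fixed effect is the
intercept.  Components are estimated by EM-REML on Henderson's mixed-model
equations.  Broad-sense heritability is then reported on an entry-mean
basis:

    H2 = sigma2_g / (sigma2_g + sigma2_gxe / Hm1 + sigma2_E / Hm2)

where Hm1 is the harmonic mean of replicate counts per genotype-location
cell and Hm2 the harmonic mean of total replicate counts per genotype
across locations -- the usual correction for unbalanced replication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hmean

from .phenotypes import validate_table

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_gxe: float
    sigma2_E: float
    sigma2_loc: float | None = None
    sigma2_rep: float | None = None
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_gxe", "sigma2_E"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DesignSummary:
    hm1: float  # harmonic mean of reps per genotype per location
    hm2: float  # harmonic mean of reps per genotype across all locations


def harmonic_means(pheno: pd.DataFrame, genotypes=None, trait: str | None = None) -> DesignSummary:
    """Hm1 and Hm2 from the realized replication of a phenotype table."""
    validate_table(pheno)
    sub = pheno if trait is None else pheno[pheno["trait"] == trait]
    if genotypes is not None:
        genotypes = list(genotypes)
        missing = set(genotypes) - set(sub["genotype"])
        if missing:
            raise ValueError(f"genotype(s) with no records: {sorted(missing)[:5]}")
        sub = sub[sub["genotype"].isin(genotypes)]
    if sub.empty:
        raise ValueError("no records to summarize")
    cell_counts = sub.groupby(["genotype", "location"]).size()
    total_counts = sub.groupby("genotype").size()
    return DesignSummary(
        hm1=float(hmean(cell_counts)), hm2=float(hmean(total_counts))
    )


def _indicator(codes: pd.Series) -> np.ndarray:
    levels, idx = np.unique(codes, return_inverse=True)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), idx] = 1.0
    return Z


def fit_varcomp_reml(
    pheno: pd.DataFrame,
    trait: str,
    include_rep: bool = True,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> VarianceComponents:
    """EM-REML for the random-terms trial model.

    Iterates Henderson's mixed-model equations: solve for BLUEs/BLUPs at the
    current variance ratios, then update each component from its BLUP sum of
    squares plus the trace of the corresponding block of the inverse
    coefficient matrix.  Estimates are kept positive during iteration and
    clamped to zero at the end if they collapse to the boundary.
    """
    validate_table(pheno)
    sub = pheno[pheno["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    y = sub["value"].to_numpy(dtype=float)
    n = len(y)
    if sub["genotype"].nunique() < 2 or sub["location"].nunique() < 2:
        raise ValueError("need >= 2 genotypes and >= 2 locations")

    vy = float(np.var(y))
    if vy == 0.0:
        return VarianceComponents(0.0, 0.0, 0.0, 0.0, 0.0 if include_rep else None)

    gxe = sub["genotype"].astype(str) + ":" + sub["location"].astype(str)
    terms = [
        ("sigma2_g", _indicator(sub["genotype"])),
        ("sigma2_loc", _indicator(sub["location"])),
        ("sigma2_gxe", _indicator(gxe)),
    ]
    if include_rep:
        rep_in_loc = sub["location"].astype(str) + ":" + sub["rep"].astype(str)
        terms.append(("sigma2_rep", _indicator(rep_in_loc)))

    names = [t[0] for t in terms]
    Z = np.concatenate([t[1] for t in terms], axis=1)
    q = [t[1].shape[1] for t in terms]
    offsets = np.concatenate([[0], np.cumsum(q)])
    X = np.ones((n, 1))
    W = np.concatenate([X, Z], axis=1)
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    rank_x = 1

    floor = vy * 1e-10
    comps = np.full(len(terms), vy / (len(terms) + 1.0))
    s2e = vy / (len(terms) + 1.0)
    frozen = np.zeros(len(terms), dtype=bool)  # components pinned at ~0
    history: list[np.ndarray] = []

    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        C = WtW.copy()
        for k in range(len(terms)):
            a, b = 1 + offsets[k], 1 + offsets[k + 1]
            C[np.arange(a, b), np.arange(a, b)] += s2e / comps[k]
        Cinv = np.linalg.inv(C)
        sol = Cinv @ Wty
        new_s2e = (yty - sol @ Wty) / (n - rank_x)
        new = comps.copy()
        for k in range(len(terms)):
            if frozen[k]:
                continue
            a, b = 1 + offsets[k], 1 + offsets[k + 1]
            u = sol[a:b]
            tr = np.trace(Cinv[a:b, a:b])
            new[k] = (u @ u + s2e * tr) / q[k]
        new = np.maximum(new, floor)
        new_s2e = max(new_s2e, floor)

        # EM converges linearly; every few sweeps apply Aitken extrapolation
        # per component, and pin components whose extrapolated fixed point
        # is at or below the zero boundary
        history.append(np.append(new, new_s2e))
        if len(history) >= 3 and it % 5 == 0:
            x2, x1, x0 = history[-1], history[-2], history[-3]
            d1, d2 = x2 - x1, x1 - x0
            for k in range(len(terms)):
                if frozen[k] or d2[k] == 0:
                    continue
                r = d1[k] / d2[k]
                if 0 < r < 1:
                    acc = x2[k] + d1[k] * r / (1 - r)
                    if acc <= floor:
                        frozen[k] = True
                        new[k] = floor
                    else:
                        new[k] = acc

        before = np.append(comps, s2e)
        after = np.append(new, new_s2e)
        active = np.append(~frozen, True)
        rel = np.max(np.abs(after - before)[active] / np.maximum(np.abs(before)[active], floor))
        comps, s2e = new, new_s2e
        if rel < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM-REML did not reach tol=%g in %d iterations", tol, max_iter)

    clamp = vy * 1e-8
    vals = {}
    for name, v in zip(names, comps):
        if v < clamp:
            logger.warning("component %s at boundary; clamped to 0", name)
            v = 0.0
        vals[name] = float(v)
    return VarianceComponents(
        sigma2_g=vals["sigma2_g"],
        sigma2_gxe=vals["sigma2_gxe"],
        sigma2_E=float(s2e if s2e >= clamp else 0.0),
        sigma2_loc=vals.get("sigma2_loc"),
        sigma2_rep=vals.get("sigma2_rep"),
        n_iter=it,
        converged=converged,
    )


def broad_sense_h2(vc: VarianceComponents, d: DesignSummary) -> float:
    """Entry-mean broad-sense heritability with harmonic-mean corrections."""
    if d.hm1 <= 0 or d.hm2 <= 0:
        raise ValueError("harmonic means must be positive")
    denom = vc.sigma2_g + vc.sigma2_gxe / d.hm1 + vc.sigma2_E / d.hm2
    if denom == 0:
        raise ValueError("all variance components are zero; H2 undefined")
    return vc.sigma2_g / denom


def anova_ems_components(pheno: pd.DataFrame, trait: str) -> VarianceComponents:
    """Method-of-moments (expected mean squares) estimator for a *balanced*
    genotype x location design with equal replication.

    For a genotypes, b locations and r replicates:
        E[MS_G]  = s2e + r*s2gl + b*r*s2g
        E[MS_L]  = s2e + r*s2gl + a*r*s2l
        E[MS_GL] = s2e + r*s2gl
        E[MS_E]  = s2e
    Used as the closed-form check on REML, which it equals on balanced data.
    """
    validate_table(pheno)
    sub = pheno[pheno["trait"] == trait]
    counts = sub.groupby(["genotype", "location"]).size()
    r = counts.iloc[0]
    if counts.nunique() != 1:
        raise ValueError("EMS method requires a balanced design")
    a = sub["genotype"].nunique()
    b = sub["location"].nunique()
    y = sub["value"].to_numpy(dtype=float)
    grand = y.mean()
    gm = sub.groupby("genotype")["value"].mean()
    lm = sub.groupby("location")["value"].mean()
    cm = sub.groupby(["genotype", "location"])["value"].mean()

    ss_g = b * r * ((gm - grand) ** 2).sum()
    ss_l = a * r * ((lm - grand) ** 2).sum()
    ss_gl = r * sum(
        (cm[g, l] - gm[g] - lm[l] + grand) ** 2 for g, l in cm.index
    )
    cell_of = cm.reindex(list(zip(sub["genotype"], sub["location"]))).to_numpy()
    ss_e = ((y - cell_of) ** 2).sum()

    ms_g = ss_g / (a - 1)
    ms_l = ss_l / (b - 1)
    ms_gl = ss_gl / ((a - 1) * (b - 1))
    ms_e = ss_e / (a * b * (r - 1)) if r > 1 else 0.0

    s2e = ms_e
    s2gl = max((ms_gl - s2e) / r, 0.0)
    s2g = max((ms_g - s2e - r * s2gl) / (b * r), 0.0)
    s2l = max((ms_l - s2e - r * s2gl) / (a * r), 0.0)
    return VarianceComponents(
        sigma2_g=s2g, sigma2_gxe=s2gl, sigma2_E=s2e, sigma2_loc=s2l
    )
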