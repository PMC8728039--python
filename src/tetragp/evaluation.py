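"""Prediction-accuracy evaluation: cross-generation, cross-family and
repeated k-fold cross-validation.

Accuracy is the Pearson correlation between observed (location-adjusted)
phenotypes and GEBVs on the test set.  Negative accuracies are reported as
computed -- a trait with r <= 0 is flagged as not predictable, never
clipped.  Cross-generation partitions are deterministic; k-fold partitions
are randomized per replicate, every individual receives a prediction from
a model that never saw its phenotype, and one r is computed per replicate
on the assembled prediction vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .brr import BRRModelSpec, fit_brr, predict_gebv
from .qc import DosageMatrix, filter_maf

logger = logging.getLogger(__name__)


@dataclass
class Partition:
    train_ids: list[str]
    test_ids: list[str]
    scheme: str  # cross_generation | cross_family | kfold

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
        if not self.train_ids or not self.test_ids:
            raise ValueError("train and test sets must both be non-empty")


@dataclass
class AccuracyResult:
    trait: str
    scheme: str
    r_values: list[float]
    labels: list[str] = field(default_factory=list)

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r_values))

    @property
    def sd_r(self) -> float:
        return float(np.std(self.r_values, ddof=1)) if len(self.r_values) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        labels = self.labels or [f"rep{i + 1}" for i in range(len(self.r_values))]
        out = pd.DataFrame({"label": labels, "r": self.r_values})
        out["trait"] = self.trait
        out["scheme"] = self.scheme
        out["predictable"] = out["r"] > 0
        return out


def prediction_accuracy(observed, predicted) -> float:
    """Pearson correlation between observed and predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be aligned 1-D vectors")
    if len(obs) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(pearsonr(obs, pred).statistic)


def split_by_generation(
    sample_meta: pd.DataFrame,
    train_gens,
    test_gens,
    include_parents: bool = False,
) -> Partition:
    """Deterministic partition by generation label.

    ``include_parents`` appends the samples labelled ``parent`` (the
    parents/grandparents of the T1 families) to the training set,
    increasing the genetic overlap between cohorts.
    """
    train_gens, test_gens = set(train_gens), set(test_gens)
    if train_gens & test_gens:
        raise ValueError(f"generations in both sets: {sorted(train_gens & test_gens)}")
    gen = sample_meta["generation"]
    for g in train_gens | test_gens:
        if g not in set(gen):
            raise ValueError(f"generation {g!r} has no samples")
    train = list(sample_meta.index[gen.isin(train_gens)])
    test = list(sample_meta.index[gen.isin(test_gens)])
    if include_parents:
        train += list(sample_meta.index[gen == "parent"])
    return Partition(train_ids=train, test_ids=test, scheme="cross_generation")


def cross_generation_eval(
    dm: DosageMatrix,
    y: pd.Series,
    train_gens,
    test_gens,
    spec: BRRModelSpec,
    include_parents: bool = False,
    trait: str = "",
) -> AccuracyResult:
    """Train on later cohorts, predict the earlier one, report one r."""
    part = split_by_generation(dm.sample_meta, train_gens, test_gens, include_parents)
    train = [s for s in part.train_ids if s in y.index]
    test = [s for s in part.test_ids if s in y.index]
    fit = fit_brr(y.loc[train], dm.dosages.loc[train], spec)
    gebv = predict_gebv(fit, dm.dosages.loc[test])
    r = prediction_accuracy(y.loc[test], gebv)
    label = "+".join(sorted(train_gens)) + "->" + "+".join(sorted(test_gens))
    return AccuracyResult(trait=trait, scheme="cross_generation", r_values=[r], labels=[label])


def kfold_cv(
    y: pd.Series,
    X: pd.DataFrame,
    k: int = 5,
    reps: int = 100,
    spec: BRRModelSpec | None = None,
    seed: int = 0,
    trait: str = "",
) -> AccuracyResult:
    """Repeated k-fold cross-validation.

    Per replicate: shuffle, split into k folds of sizes differing by at
    most one, predict each fold from a model trained on the rest, then
    compute one Pearson r on the full assembled prediction vector.  The
    mean over replicates is the headline accuracy; the across-replicate
    standard deviation is available from the result.
    """
    spec = spec or BRRModelSpec()
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    if not y.index.equals(X.index):
        X = X.loc[y.index]
    rng = np.random.default_rng(seed)
    r_values = []
    for rep in range(reps):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        pred = pd.Series(np.nan, index=y.index)
        for f, fold in enumerate(folds):
            test_idx = y.index[fold]
            train_idx = y.index.difference(test_idx, sort=False)
            fold_spec = BRRModelSpec(
                **{
                    **spec.__dict__,
                    "seed": int(rng.integers(0, 2**31 - 1)),
                }
            )
            fit = fit_brr(y.loc[train_idx], X.loc[train_idx], fold_spec)
            pred.loc[test_idx] = predict_gebv(fit, X.loc[test_idx]).to_numpy()
        r_values.append(prediction_accuracy(y, pred))
    res = AccuracyResult(trait=trait, scheme="kfold", r_values=r_values)
    logger.info(
        "%d-fold CV x %d reps: mean r=%.3f (sd %.3f)", k, reps, res.mean_r, res.sd_r
    )
    return res


def cross_family_eval(
    dm: DosageMatrix,
    y: pd.Series,
    families: tuple[str, str],
    spec: BRRModelSpec | None = None,
    min_maf: float = 0.05,
    trait: str = "",
) -> AccuracyResult:
    """Train on one full-sib family and predict the other, both directions.

    Markers are re-filtered by MAF on the two families' samples, mirroring
    subset-specific marker panels.
    """
    spec = spec or BRRModelSpec()
    fam = dm.sample_meta["family"] if "family" in dm.sample_meta else dm.sample_meta["generation"]
    ids = {}
    for f in families:
        members = [s for s in dm.sample_ids if fam.get(s) == f and s in y.index]
        if not members:
            raise ValueError(f"family {f!r} has no phenotyped samples")
        ids[f] = members
    subset = dm.subset_samples(ids[families[0]] + ids[families[1]])
    subset, _ = filter_maf(subset, min_maf)
    r_values, labels = [], []
    for train_f, test_f in (families, families[::-1]):
        fit = fit_brr(y.loc[ids[train_f]], subset.dosages.loc[ids[train_f]], spec)
        gebv = predict_gebv(fit, subset.dosages.loc[ids[test_f]])
        r = prediction_accuracy(y.loc[ids[test_f]], gebv)
        r_values.append(r)
        labels.append(f"{train_f}->{test_f}")
        if r <= 0:
            logger.warning("%s: r=%.3f <= 0, prediction not possible", labels[-1], r)
    return AccuracyResult(trait=trait, scheme="cross_family", r_values=r_values, labels=labels)
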