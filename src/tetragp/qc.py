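"""Quality control for autotetraploid allele-dosage matrices.

Dosage data code each biallelic SNP as the count of the alternate allele in
a tetraploid genotype: 0 (OOOO) through 4 (AAAA), with 1/2/3 the simplex,
duplex and triplex heterozygotes.  The QC pipeline is marker-wise and runs
in a fixed order: drop markers with too many missing calls, impute the
remainder by the population mode, then drop low-MAF markers.  Samples are
never filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_DOSAGES = (0, 1, 2, 3, 4)

DEFAULT_MAX_MISSING = 0.10
DEFAULT_MIN_MAF = 0.05


@dataclass
class DosageMatrix:
    """Samples x markers integer dosage matrix with sample metadata.

    Parameters
    ----------
    dosages
        DataFrame indexed by sample id with marker ids as columns.  Entries
        are dosages in {0,1,2,3,4}; missing calls are NaN (the frame is
        float-typed whenever anything is missing).
    sample_meta
        Optional DataFrame indexed by sample id.  Recognised columns:
        ``generation`` (e.g. ``T1-A`` .. ``T1-E``, ``T2``, ``T3-7``,
        ``parent``, ``check``), ``family``, ``is_check``.
    """

    dosages: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.dosages.index.has_duplicates:
            raise ValueError("duplicate sample ids in dosage matrix")
        if self.dosages.columns.has_duplicates:
            raise ValueError("duplicate marker ids in dosage matrix")
        vals = self.dosages.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, VALID_DOSAGES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {vals[i, j]!r} for sample "
                f"{self.dosages.index[i]!r}, marker {self.dosages.columns[j]!r}; "
                "entries must be 0-4 or missing"
            )
        if self.sample_meta is not None:
            missing = self.dosages.index.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(f"sample_meta missing entries for {list(missing[:5])}")

    # -- convenience ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def has_missing(self) -> bool:
        return bool(self.dosages.isna().any().any())

    def subset_samples(self, ids) -> "DosageMatrix":
        meta = self.sample_meta.loc[ids] if self.sample_meta is not None else None
        return DosageMatrix(self.dosages.loc[ids], meta)

    def subset_markers(self, marker_ids) -> "DosageMatrix":
        return DosageMatrix(self.dosages[list(marker_ids)], self.sample_meta)


@dataclass
class QCReport:
    """Bookkeeping for a QC pass; counts always balance:
    markers_in == removed_missingness + removed_maf + markers_out."""

    markers_in: int
    removed_missingness: int = 0
    removed_maf: int = 0
    markers_out: int = 0
    per_marker: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.markers_in != self.removed_missingness + self.removed_maf + self.markers_out:
            raise ValueError("QC report counts do not balance")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": [
                    self.markers_in,
                    self.removed_missingness,
                    self.removed_maf,
                    self.markers_out,
                ]
            },
            index=["markers_in", "removed_missingness", "removed_maf", "markers_out"],
        )


def allele_frequency(dm: DosageMatrix) -> pd.Series:
    """Alternate-allele frequency per marker: mean dosage / 4 over
    non-missing calls (dosage-weighted, the standard for polyploid data)."""
    vals = dm.dosages.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(vals), axis=0)
    if (n_obs == 0).any():
        bad = dm.dosages.columns[n_obs == 0]
        raise ValueError(f"marker(s) with no observed calls: {list(bad[:5])}")
    p = np.nansum(vals, axis=0) / (4.0 * n_obs)
    return pd.Series(p, index=dm.dosages.columns, name="allele_freq")


def minor_allele_frequency(dm: DosageMatrix) -> pd.Series:
    p = allele_frequency(dm)
    return np.minimum(p, 1.0 - p).rename("maf")


def missing_rate(dm: DosageMatrix) -> pd.Series:
    return dm.dosages.isna().mean(axis=0).rename("missing_rate")


def filter_missingness(
    dm: DosageMatrix, max_rate: float = DEFAULT_MAX_MISSING
) -> tuple[DosageMatrix, QCReport]:
    """Drop markers whose missing fraction is strictly greater than ``max_rate``."""
    rate = missing_rate(dm)
    keep = rate <= max_rate
    out = dm.subset_markers(dm.dosages.columns[keep])
    if out.n_markers == 0:
        logger.warning("missingness filter removed every marker (max_rate=%g)", max_rate)
    report = QCReport(
        markers_in=dm.n_markers,
        removed_missingness=int((~keep).sum()),
        markers_out=int(keep.sum()),
        per_marker=rate.to_frame(),
    )
    return out, report


def impute_mode(dm: DosageMatrix) -> DosageMatrix:
    """Replace missing calls by the marker's modal dosage (population mode).

    Ties between equally frequent dosage classes break to the numerically
    lowest dosage, so imputation is deterministic.
    """
    vals = dm.dosages.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(vals), axis=0)
    if (n_obs == 0).any():
        bad = dm.dosages.columns[n_obs == 0]
        raise ValueError(f"cannot impute all-missing marker(s): {list(bad[:5])}")
    # counts[d, j] = number of samples with dosage d at marker j;
    # argmax returns the first (lowest) dosage on ties.
    counts = np.stack([(vals == d).sum(axis=0) for d in VALID_DOSAGES])
    modes = np.argmax(counts, axis=0).astype(float)
    filled = np.where(np.isnan(vals), modes[None, :], vals)
    out = pd.DataFrame(
        filled.astype(np.int64), index=dm.dosages.index, columns=dm.dosages.columns
    )
    return DosageMatrix(out, dm.sample_meta)


def filter_maf(
    dm: DosageMatrix, min_maf: float = DEFAULT_MIN_MAF
) -> tuple[DosageMatrix, QCReport]:
    """Drop markers whose minor allele frequency is strictly below ``min_maf``.

    The frequency is computed on exactly the samples present in ``dm``, so
    subsetting samples before filtering changes the retained marker set.
    """
    maf = minor_allele_frequency(dm)
    keep = maf >= min_maf
    out = dm.subset_markers(dm.dosages.columns[keep])
    report = QCReport(
        markers_in=dm.n_markers,
        removed_maf=int((~keep).sum()),
        markers_out=int(keep.sum()),
        per_marker=pd.concat([allele_frequency(dm), maf], axis=1),
    )
    return out, report


def run_qc(
    dm: DosageMatrix,
    max_missing: float = DEFAULT_MAX_MISSING,
    min_maf: float = DEFAULT_MIN_MAF,
) -> tuple[DosageMatrix, QCReport]:
    """Full marker QC in the fixed order missingness -> mode imputation -> MAF."""
    after_miss, rep1 = filter_missingness(dm, max_missing)
    imputed = impute_mode(after_miss) if after_miss.n_markers else after_miss
    after_maf, rep2 = filter_maf(imputed, min_maf) if imputed.n_markers else (
        imputed,
        QCReport(markers_in=0),
    )
    per_marker = rep1.per_marker.join(rep2.per_marker, how="left")
    report = QCReport(
        markers_in=rep1.markers_in,
        removed_missingness=rep1.removed_missingness,
        removed_maf=rep2.removed_maf,
        markers_out=rep2.markers_out,
        per_marker=per_marker,
    )
    logger.info(
        "QC: %d markers in, %d removed by missingness>%g, %d by MAF<%g, %d retained",
        report.markers_in,
        report.removed_missingness,
        max_missing,
        report.removed_maf,
        min_maf,
        report.markers_out,
    )
    return after_maf, report


def pairwise_difference(dm: DosageMatrix, sample_i: str, sample_j: str) -> float:
    """Fraction of jointly observed markers at which two samples disagree.

    Used as an array sanity check: technical duplicates should differ at well
    under 1% of calls while unrelated clones differ at roughly half.
    """
    for s in (sample_i, sample_j):
        if s not in dm.dosages.index:
            raise KeyError(f"sample {s!r} not in dosage matrix")
    a = dm.dosages.loc[sample_i].to_numpy(dtype=float)
    b = dm.dosages.loc[sample_j].to_numpy(dtype=float)
    both = ~(np.isnan(a) | np.isnan(b))
    if not both.any():
        raise ValueError(
            f"samples {sample_i!r} and {sample_j!r} share no observed markers"
        )
    return float(np.mean(a[both] != b[both]))
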