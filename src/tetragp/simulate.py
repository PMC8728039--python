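"""Synthetic autotetraploid breeding program.

Simulates the structure a finite-size potato breeding program hands to a
genomic-prediction analysis: a handful of founder cultivars, five
bi-parental full-sib seedling families (T1) that share parents, older
cohorts that have survived one (T2) or several (T3-7) rounds of truncation
selection, check cultivars replicated at every trial location, and
multi-location phenotypes with genotype, location, GxE and residual
variance components.

Meiosis is tetrasomic: each gamete receives two of the parent's four
allele copies, drawn without replacement (random chromatid segregation),
except that with probability ``alpha_dr`` a double-reduction event places
two copies of a single parental allele in the gamete.  Loci segregate
independently; chromosome labels are carried for realism of output files
only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import DosageMatrix

logger = logging.getLogger(__name__)

#: theoretical ceiling of the double-reduction rate under random chromatid
#: segregation (a locus at the far end of an arm in a multivalent).
MAX_ALPHA_DR = 1.0 / 6.0

#: the six unordered pairs of 4 chromatid slots.
_PAIRS = np.array([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], dtype=np.int64)

FOUNDER_NAMES = ("Bionica", "Sarpo Mira", "Desiree", "SW93-1015")
CHECK_NAMES = ("Bintje", "Carolus", "Connect", "King Edward", "Solist")

# Family layout of the emulated program: (family, mother, father, default size).
FAMILY_PLAN = (
    ("T1-A", "Bionica", "Sarpo Mira", 51),
    ("T1-B", "C08II69", "Bionica", 51),
    ("T1-C", "L17", "Sarpo Mira", 149),
    ("T1-D", "L26", "Sarpo Mira", 152),
    ("T1-E", "L4", "Sarpo Mira", 62),
)


@dataclass
class SimConfig:
    """Parameters of the simulated breeding program.

    Variances are on the trait scale (arbitrary units); the defaults give a
    plot-level heritability of ~0.33 and an entry-mean broad-sense
    heritability in the 0.6-0.7 range of the tuber yield traits.
    """

    n_markers: int = 2000
    family_sizes: tuple[int, ...] = tuple(f[3] for f in FAMILY_PLAN)
    alpha_dr: float = 0.05
    sigma2_g: float = 1.0
    sigma2_loc: float = 0.5
    sigma2_gxe: float = 0.5
    sigma2_e: float = 1.0
    mu: float = 10.0
    n_locations: int = 3
    n_reps: int = 2
    selection_fraction: float = 0.3
    n_cycles: int = 2
    #: target sizes of the selected cohorts (T2, T3-7).
    generation_sizes: tuple[int, int] = (138, 62)
    n_t2_crosses: int = 29
    n_t37_crosses: int = 33
    n_checks: int = 5
    founder_freq_range: tuple[float, float] = (0.1, 0.9)
    #: fraction of dosage calls masked to NA in the emitted matrix (array
    #: no-calls); 0 keeps the matrix complete
    missing_rate: float = 0.0
    trait: str = "TW"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_loc", "sigma2_gxe", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.alpha_dr <= MAX_ALPHA_DR:
            raise ValueError(
                f"alpha_dr={self.alpha_dr} outside [0, 1/6]; 1/6 is the "
                "theoretical maximum under random chromatid segregation"
            )
        if any(s < 1 for s in self.family_sizes):
            raise ValueError("family sizes must be >= 1")
        if not 0.0 < self.selection_fraction <= 1.0:
            raise ValueError("selection_fraction must be in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")


@dataclass
class FounderGenome:
    """A named tetraploid genotype: 4 allele copies per marker.

    ``alleles`` is a (4, n_markers) 0/1 array, 1 marking the alternate (A)
    allele; dosage at a marker is the column sum.
    """

    founder_id: str
    alleles: np.ndarray
    chromosome_of_marker: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] != 4:
            raise ValueError("alleles must be a (4, n_markers) array")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele states must be 0 (O) or 1 (A)")

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    @property
    def dosage(self) -> np.ndarray:
        return self.alleles.sum(axis=0)


@dataclass
class BreedingProgramSim:
    """Everything the downstream analysis consumes from one simulated run."""

    genotypes: DosageMatrix
    phenotypes: pd.DataFrame
    pedigree: pd.DataFrame
    true_values: pd.Series
    populations: dict[str, list[str]]
    marker_effects: pd.Series
    config: SimConfig


def _check_alpha(alpha_dr: float) -> None:
    if not 0.0 <= alpha_dr <= MAX_ALPHA_DR:
        raise ValueError(
            f"alpha_dr={alpha_dr} outside [0, 1/6]; 1/6 is the theoretical "
            "maximum under random chromatid segregation"
        )


def make_gamete(
    parent: np.ndarray, alpha_dr: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one diploid gamete from a tetraploid parent.

    Per locus independently: with probability ``alpha_dr`` one of the four
    allele copies is drawn uniformly and duplicated (double reduction);
    otherwise two copies are drawn without replacement.
    """
    _check_alpha(alpha_dr)
    parent = np.asarray(parent)
    if parent.ndim != 2 or parent.shape[0] != 4:
        raise ValueError("parent must be a (4, n_markers) allele array")
    m = parent.shape[1]
    cols = np.arange(m)
    pair = _PAIRS[rng.integers(0, 6, size=m)]  # (m, 2)
    gamete = np.stack([parent[pair[:, 0], cols], parent[pair[:, 1], cols]])
    if alpha_dr > 0:
        dr = rng.random(m) < alpha_dr
        if dr.any():
            dup = rng.integers(0, 4, size=m)
            dup_alleles = parent[dup[dr], cols[dr]]
            gamete[0, dr] = dup_alleles
            gamete[1, dr] = dup_alleles
    return gamete


def cross(
    parent1: np.ndarray | FounderGenome,
    parent2: np.ndarray | FounderGenome,
    n_offspring: int,
    alpha_dr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce ``n_offspring`` full-sib genotypes as a (n, 4, m) allele array."""
    p1 = parent1.alleles if isinstance(parent1, FounderGenome) else np.asarray(parent1)
    p2 = parent2.alleles if isinstance(parent2, FounderGenome) else np.asarray(parent2)
    if p1.shape[1] != p2.shape[1]:
        raise ValueError(
            f"parents have mismatched marker sets: {p1.shape[1]} vs {p2.shape[1]}"
        )
    _check_alpha(alpha_dr)
    out = np.empty((n_offspring, 4, p1.shape[1]), dtype=np.int8)
    for i in range(n_offspring):
        out[i, :2] = make_gamete(p1, alpha_dr, rng)
        out[i, 2:] = make_gamete(p2, alpha_dr, rng)
    return out


def gamete_dosage_pmf(parent_dosage: int, alpha_dr: float) -> np.ndarray:
    """Exact P(gamete carries 0,1,2 copies of A) for a parent of given dosage.

    Mixture of hypergeometric sampling (2 of 4 without replacement) and, with
    probability ``alpha_dr``, duplication of a uniformly drawn allele.  Used
    as the enumeration oracle for segregation tests.
    """
    _check_alpha(alpha_dr)
    d = parent_dosage
    from scipy.stats import hypergeom

    no_dr = hypergeom.pmf(np.arange(3), 4, d, 2)
    dr = np.array([1 - d / 4.0, 0.0, d / 4.0])
    return (1 - alpha_dr) * no_dr + alpha_dr * dr


def simulate_phenotypes(
    genetic_values: pd.Series,
    design: pd.DataFrame,
    *,
    mu: float = 0.0,
    sigma2_loc: float = 0.0,
    sigma2_gxe: float = 0.0,
    sigma2_e: float = 0.0,
    trait: str = "TW",
    rng: np.random.Generator,
    location_effects: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate plot records y_ijk = mu + g_i + l_j + (gl)_ij + e_ijk.

    Parameters
    ----------
    genetic_values
        True genetic value per genotype id.
    design
        One row per genotype x location cell: columns ``genotype``,
        ``location``, ``n_reps``.
    location_effects
        Optional fixed draws for l_j (shared across calls); by default drawn
        Normal(0, sigma2_loc) per unique location in the design.
    """
    for name, v in (("sigma2_loc", sigma2_loc), ("sigma2_gxe", sigma2_gxe), ("sigma2_e", sigma2_e)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    missing = set(design["genotype"]) - set(genetic_values.index)
    if missing:
        raise KeyError(f"design references genotypes without genetic values: {sorted(missing)[:5]}")
    locs = list(pd.unique(design["location"]))
    if location_effects is None:
        draws = rng.normal(0.0, math.sqrt(sigma2_loc), size=len(locs))
        location_effects = dict(zip(locs, draws))
    records = []
    for _, row in design.iterrows():
        g_id, loc, n_reps = row["genotype"], row["location"], int(row["n_reps"])
        gl = rng.normal(0.0, math.sqrt(sigma2_gxe))
        base = mu + genetic_values[g_id] + location_effects[loc] + gl
        eps = rng.normal(0.0, math.sqrt(sigma2_e), size=n_reps)
        for r in range(n_reps):
            records.append((g_id, loc, r + 1, trait, base + eps[r]))
    return pd.DataFrame(records, columns=["genotype", "location", "rep", "trait", "value"])


def genetic_values_from_markers(
    dosages: pd.DataFrame,
    sigma2_g: float,
    rng: np.random.Generator,
) -> tuple[pd.Series, pd.Series]:
    """Additive genetic values g = Xc beta with beta scaled so var(g) = sigma2_g.

    Returns (genetic values, marker effects).  The same effects applied to
    any later generation keep the trait heritable across selection cycles.
    """
    if sigma2_g < 0:
        raise ValueError("sigma2_g must be >= 0")
    X = dosages.to_numpy(dtype=float)
    beta = rng.normal(0.0, 1.0, size=X.shape[1])
    Xc = X - X.mean(axis=0)
    g = Xc @ beta
    sd = g.std()
    scale = math.sqrt(sigma2_g) / sd if sd > 0 else 0.0
    beta *= scale
    g *= scale
    return (
        pd.Series(g, index=dosages.index, name="g"),
        pd.Series(beta, index=dosages.columns, name="beta"),
    )


def _dosage_frame(alleles: np.ndarray, ids: list[str], marker_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(alleles.sum(axis=1), index=ids, columns=marker_ids, dtype=np.int64)


def _true_values(alleles: np.ndarray, beta: np.ndarray, centers: np.ndarray) -> np.ndarray:
    return (alleles.sum(axis=1) - centers) @ beta


def simulate_breeding_program(config: SimConfig) -> BreedingProgramSim:
    """Run the whole program: founders -> T1 families -> selected T2 and T3-7.

    T1 is five full-sib families with overlapping parents (the family plan
    mirrors a published pedigree: three of the mothers are themselves
    full-sibs from one grandparental cross).  T2 and T3-7 are separate
    crossing cohorts from the same parental pool, truncation-selected on a
    single-location phenotype once (T2) or ``n_cycles + 1`` times (T3-7)
    down to the configured cohort sizes.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_markers
    logger.info("simulating breeding program: seed=%d, %d markers", config.seed, m)

    lo, hi = config.founder_freq_range
    freqs = rng.uniform(lo, hi, size=m)
    chrom = (np.arange(m) % 12) + 1

    def new_genotype() -> np.ndarray:
        return (rng.random((4, m)) < freqs).astype(np.int8)

    founders = {name: new_genotype() for name in FOUNDER_NAMES}
    pedigree_rows: list[tuple[str, str, str]] = [(n, "NA", "NA") for n in FOUNDER_NAMES]

    # Derived T1 parents: L17/L26/L4 are full-sibs (SW93-1015 x Desiree);
    # C08II69 has SW93-1015 as one parent.
    derived: dict[str, np.ndarray] = {}
    for name in ("L17", "L26", "L4"):
        derived[name] = cross(
            founders["SW93-1015"], founders["Desiree"], 1, config.alpha_dr, rng
        )[0]
        pedigree_rows.append((name, "SW93-1015", "Desiree"))
    extra = new_genotype()
    derived["C08II69"] = cross(founders["SW93-1015"], extra, 1, config.alpha_dr, rng)[0]
    pedigree_rows.append(("C08II69", "SW93-1015", "unknown"))
    parent_pool = {**founders, **derived}

    # --- T1: five full-sib families ------------------------------------
    if len(config.family_sizes) != len(FAMILY_PLAN):
        raise ValueError(
            f"family_sizes must have {len(FAMILY_PLAN)} entries, got {len(config.family_sizes)}"
        )
    sample_alleles: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[tuple[str, str, str, bool]] = []
    populations: dict[str, list[str]] = {}

    for (family, mother, father, _), size in zip(FAMILY_PLAN, config.family_sizes):
        offs = cross(parent_pool[mother], parent_pool[father], size, config.alpha_dr, rng)
        ids = [f"{family}_{i + 1:03d}" for i in range(size)]
        sample_alleles.append(offs)
        sample_ids.extend(ids)
        populations[family] = ids
        for oid in ids:
            pedigree_rows.append((oid, mother, father))
            meta_rows.append((oid, family, family, False))

    # --- marker effects calibrated on the T1 cohort --------------------
    t1_alleles = np.concatenate(sample_alleles)
    t1_dosage = t1_alleles.sum(axis=1).astype(float)
    centers = t1_dosage.mean(axis=0)
    beta = rng.normal(0.0, 1.0, size=m)
    g_t1 = (t1_dosage - centers) @ beta
    sd = g_t1.std()
    if config.sigma2_g > 0 and sd > 0:
        beta *= math.sqrt(config.sigma2_g) / sd
    else:
        beta[:] = 0.0

    locations = [f"loc{i + 1}" for i in range(config.n_locations)]
    loc_effects = dict(
        zip(locations, rng.normal(0.0, math.sqrt(config.sigma2_loc), len(locations)))
    )

    def select_cohort(
        prefix: str, n_crosses: int, target: int, n_rounds: int
    ) -> tuple[np.ndarray, list[str], list[tuple[str, str, str]]]:
        """Candidate seedlings from crosses in the parent pool, then
        ``n_rounds`` of phenotypic truncation selection down to ``target``."""
        pool_size = math.ceil(target / config.selection_fraction**n_rounds)
        if config.selection_fraction * pool_size < 1:
            raise ValueError("selection_fraction times candidate pool size is below 1")
        names = list(parent_pool)
        per_cross = [pool_size // n_crosses] * n_crosses
        for i in range(pool_size - sum(per_cross)):
            per_cross[i] += 1
        alleles_list, ped = [], []
        for k, size_k in enumerate(per_cross):
            if size_k == 0:
                continue
            i1, i2 = rng.choice(len(names), size=2, replace=False)
            offs = cross(
                parent_pool[names[i1]], parent_pool[names[i2]], size_k, config.alpha_dr, rng
            )
            alleles_list.append(offs)
            ped.extend((f"{prefix}cand", names[i1], names[i2]) for _ in range(size_k))
        alleles = np.concatenate(alleles_list)
        for r in range(n_rounds):
            n = alleles.shape[0]
            keep_n = max(target, int(round(n * config.selection_fraction)))
            if r == n_rounds - 1:
                keep_n = target
            g = _true_values(alleles, beta, centers)
            ids = [f"cand{i}" for i in range(n)]
            design = pd.DataFrame(
                {"genotype": ids, "location": locations[0], "n_reps": 1}
            )
            ph = simulate_phenotypes(
                pd.Series(g, index=ids),
                design,
                mu=config.mu,
                sigma2_loc=config.sigma2_loc,
                sigma2_gxe=config.sigma2_gxe,
                sigma2_e=config.sigma2_e,
                trait=config.trait,
                rng=rng,
                location_effects=loc_effects,
            )
            means = ph.groupby("genotype", sort=False)["value"].mean()
            order = np.argsort(-means.loc[ids].to_numpy(), kind="stable")
            keep = np.sort(order[:keep_n])
            alleles = alleles[keep]
            ped = [ped[i] for i in keep]
        ids = [f"{prefix}_{i + 1:03d}" for i in range(alleles.shape[0])]
        ped = [(oid, p1, p2) for oid, (_, p1, p2) in zip(ids, ped)]
        return alleles, ids, ped

    t2_target, t37_target = config.generation_sizes
    t2_alleles, t2_ids, t2_ped = select_cohort("T2", config.n_t2_crosses, t2_target, 1)
    t37_alleles, t37_ids, t37_ped = select_cohort(
        "T37", config.n_t37_crosses, t37_target, config.n_cycles + 1
    )

    sample_alleles.extend([t2_alleles, t37_alleles])
    sample_ids.extend(t2_ids + t37_ids)
    populations["T2"] = t2_ids
    populations["T3-7"] = t37_ids
    pedigree_rows.extend(t2_ped + t37_ped)
    meta_rows.extend((oid, "T2", "", False) for oid in t2_ids)
    meta_rows.extend((oid, "T3-7", "", False) for oid in t37_ids)

    # parents and checks enter the genotype matrix too
    parent_ids = list(FOUNDER_NAMES)
    parent_alleles = np.stack([founders[n] for n in parent_ids])
    checks = {CHECK_NAMES[i]: new_genotype() for i in range(config.n_checks)}
    check_ids = list(checks)
    check_alleles = np.stack([checks[n] for n in check_ids])
    sample_alleles.extend([parent_alleles, check_alleles])
    sample_ids.extend(parent_ids + check_ids)
    populations["parent"] = parent_ids
    populations["check"] = check_ids
    pedigree_rows.extend((n, "NA", "NA") for n in check_ids)
    meta_rows.extend((oid, "parent", "", False) for oid in parent_ids)
    meta_rows.extend((oid, "check", "", True) for oid in check_ids)

    all_alleles = np.concatenate(sample_alleles)
    marker_ids = [f"M{c:02d}_{i + 1:05d}" for i, c in enumerate(chrom)]
    dosages = _dosage_frame(all_alleles, sample_ids, marker_ids)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages = dosages.astype(float).mask(mask)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "generation", "family", "is_check"]
    ).set_index("sample_id")
    dm = DosageMatrix(dosages, meta)

    g_all = pd.Series(
        _true_values(all_alleles, beta, centers), index=sample_ids, name="g"
    )

    # --- trial phenotypes ----------------------------------------------
    # T1/T2 at one site (1 and 2 reps); T3-7 at one site, with a 38-clone
    # subset grown at all three sites (1-2 reps); parents at the main site;
    # checks at every site.
    design_rows: list[tuple[str, str, int]] = []
    for oid in populations["T1-A"] + populations["T1-B"] + populations["T1-C"] + populations["T1-D"] + populations["T1-E"]:
        design_rows.append((oid, locations[0], 1))
    for oid in t2_ids:
        design_rows.append((oid, locations[0], min(2, config.n_reps)))
    multi_site = t37_ids[: min(38, len(t37_ids))]
    for oid in t37_ids:
        design_rows.append((oid, locations[0], min(2, config.n_reps)))
    for oid in multi_site:
        for loc in locations[1:]:
            design_rows.append((oid, loc, int(rng.integers(1, config.n_reps + 1))))
    for oid in parent_ids:
        design_rows.append((oid, locations[0], min(2, config.n_reps)))
    for oid in check_ids:
        for loc in locations:
            design_rows.append((oid, loc, config.n_reps))
    design = pd.DataFrame(design_rows, columns=["genotype", "location", "n_reps"])
    phenotypes = simulate_phenotypes(
        g_all,
        design,
        mu=config.mu,
        sigma2_loc=config.sigma2_loc,
        sigma2_gxe=config.sigma2_gxe,
        sigma2_e=config.sigma2_e,
        trait=config.trait,
        rng=rng,
        location_effects=loc_effects,
    )

    pedigree = pd.DataFrame(pedigree_rows, columns=["id", "parent1", "parent2"])
    return BreedingProgramSim(
        genotypes=dm,
        phenotypes=phenotypes,
        pedigree=pedigree,
        true_values=g_all,
        populations=populations,
        marker_effects=pd.Series(beta, index=marker_ids, name="beta"),
        config=config,
    )
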