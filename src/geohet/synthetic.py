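"""Synthetic study data with the statistical structure the pipeline assumes.

Real cohort genotypes of this kind are rarely shareable, so the generator
emulates the data shape end to end: land units tiled on a schematic grid,
subjects assigned to units as natives or immigrants, genotypes drawn under
Hardy-Weinberg equilibrium from pool-specific allele frequencies, and
spatially structured covariate fields produced by a simultaneous
autoregressive (SAR) process with known lambda.

A spatial gradient in the immigrant fraction combined with an immigrant
allele-frequency shift ``delta`` induces spatial autocorrelation in per-unit
observed heterozygosity — the signal the downstream Moran and SAR stages are
designed to detect.  With ``delta = 0`` and a flat immigrant field the
per-unit differences are pure sampling noise (the null case).

:func:`reference_fixture` returns a counts-exact 13-unit fixture matching
the published per-unit sample composition (total 728 subjects: 549 natives,
179 immigrants of which 146 from the major CZ/RO/PL/UA group), with
deterministic ages and education values; genotypes are not part of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .genetics import GenotypeMatrix
from .regionalization import LandUnit, RegionSet, SpatialWeights, binary_weights, build_contiguity
from .sociodemo import SubjectRecord

import pandas as pd

__all__ = [
    "SimulationConfig",
    "STUDY_UNIT_COUNTS",
    "generate_synthetic_study",
    "simulate_sar_outcome",
    "grid_region",
    "rook_lattice_weights",
    "reference_fixture",
]

#: Published per-unit sample composition:
#: (unit name, all, natives, immigrants, major immigrant group).
STUDY_UNIT_COUNTS = (
    ("Augsburg", 359, 258, 101, 79),
    ("Aichach", 23, 18, 5, 3),
    ("Eurasburg", 9, 9, 0, 0),
    ("Friedberg", 25, 21, 4, 2),
    ("Pöttmes", 12, 12, 0, 0),
    ("Rehling", 13, 12, 1, 1),
    ("Bobingen", 51, 36, 15, 13),
    ("Königsbrunn", 42, 24, 18, 17),
    ("Langweid", 34, 22, 12, 9),
    ("Neusäß", 60, 52, 8, 8),
    ("Altenmünster", 53, 48, 5, 5),
    ("Aystetten", 31, 23, 8, 7),
    ("Schwabmünchen", 16, 14, 2, 2),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions: 13 land units with the published
    sample sizes, 212 biallelic SNPs with native minor-allele frequencies
    uniform in [0.10, 0.50], an east-west gradient in the per-unit immigrant
    fraction, and an immigrant allele-frequency shift ``delta`` toward 0.5.
    Covariate fields (unit mean age / education) follow a SAR process with
    spatial parameter ``sar_lambda``.
    """

    n_units: int = 13
    unit_size_m: float = 10_000.0
    sample_sizes: tuple[int, ...] = tuple(r[1] for r in STUDY_UNIT_COUNTS)
    n_loci: int = 212
    maf_range: tuple[float, float] = (0.10, 0.50)
    delta: float = 0.10
    immigrant_fraction_range: tuple[float, float] = (0.0, 0.40)
    main_immigrant_share: float = 0.80
    sar_lambda: float = 0.15
    sar_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sample_sizes) != self.n_units:
            raise ValueError("sample_sizes length must equal n_units")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must lie inside (0, 1)")
        if not (0 <= hi + self.delta < 1) or lo + self.delta <= 0:
            raise ValueError("delta pushes allele frequencies outside (0, 1)")


def grid_region(n_units: int, unit_size_m: float = 10_000.0) -> RegionSet:
    """Schematic tiling: square units laid out row-major on a near-square grid."""
    ncols = int(np.ceil(np.sqrt(n_units)))
    units = []
    for k in range(n_units):
        r, c = divmod(k, ncols)
        x0, y0 = c * unit_size_m, -r * unit_size_m
        poly = Polygon(
            [(x0, y0), (x0 + unit_size_m, y0), (x0 + unit_size_m, y0 - unit_size_m),
             (x0, y0 - unit_size_m)]
        )
        units.append(LandUnit(unit_id=f"U{k + 1}", name=f"U{k + 1}", polygon=poly))
    return RegionSet(units=units)


def rook_lattice_weights(nrows: int, ncols: int) -> SpatialWeights:
    """Binary rook-contiguity weights of an ``nrows x ncols`` lattice.

    The standard simulation testbed for spatial statistics: units on a grid,
    neighbours sharing an edge (not a corner).
    """
    n = nrows * ncols
    W = np.zeros((n, n))
    for r in range(nrows):
        for c in range(ncols):
            k = r * ncols + c
            if c + 1 < ncols:
                W[k, k + 1] = W[k + 1, k] = 1.0
            if r + 1 < nrows:
                W[k, k + ncols] = W[k + ncols, k] = 1.0
    ids = [f"L{r}_{c}" for r in range(nrows) for c in range(ncols)]
    return SpatialWeights(unit_ids=ids, W=W)


def simulate_sar_outcome(
    W: SpatialWeights,
    X: np.ndarray,
    beta: np.ndarray,
    lam: float,
    sigma: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw y = X beta + (I - lambda W)^-1 eps with eps ~ N(0, sigma^2 I)."""
    Xm = np.asarray(X, dtype=float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    beta = np.asarray(beta, dtype=float)
    eig = np.linalg.eigvalsh(W.W)
    lo, hi = 1.0 / eig[0], 1.0 / eig[-1]
    if not lo < lam < hi:
        raise ValueError(f"lambda {lam} outside the feasible interval ({lo:.4f}, {hi:.4f})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = W.n
    eps = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    u = np.linalg.solve(np.eye(n) - lam * W.W, eps)
    return Xm @ beta + u


def _sar_field(W: SpatialWeights, mean: float, lam: float, sigma: float,
               rng: np.random.Generator) -> np.ndarray:
    return simulate_sar_outcome(W, np.ones((W.n, 1)), np.array([mean]), lam, sigma, rng)


def generate_synthetic_study(
    config: SimulationConfig,
) -> tuple[RegionSet, list[SubjectRecord], GenotypeMatrix]:
    """Generate a full synthetic study (region, subjects, genotypes).

    Subjects are assigned to units with an east-west gradient in the
    immigrant fraction; genotypes are drawn under HWE from a native
    allele-frequency vector or its ``delta``-shifted immigrant counterpart.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    region = grid_region(config.n_units, config.unit_size_m)
    region = build_contiguity(region)
    W = binary_weights(region)

    # east-west gradient in immigrant fraction, by centroid x rank
    xs = np.array([u.centroid[0] for u in region.units])
    order = xs.argsort().argsort()
    f_lo, f_hi = config.immigrant_fraction_range
    frac = f_lo + (f_hi - f_lo) * (order / max(1, config.n_units - 1))

    # spatially autocorrelated covariate fields per unit
    age_mean = _sar_field(W, 50.0, config.sar_lambda, config.sar_sigma, rng)
    ey_mean = _sar_field(W, 11.5, config.sar_lambda, 0.4 * config.sar_sigma, rng)

    q_native = rng.uniform(*config.maf_range, size=config.n_loci)
    q_immigrant = q_native + config.delta
    if np.any(q_immigrant <= 0) or np.any(q_immigrant >= 1):
        raise ValueError("infeasible immigrant allele frequencies")

    subjects: list[SubjectRecord] = []
    codes_rows: list[np.ndarray] = []
    sid = 0
    for k, unit in enumerate(region.units):
        n_k = config.sample_sizes[k]
        n_img = int(round(frac[k] * n_k))
        n_main = int(round(config.main_immigrant_share * n_img))
        for j in range(n_k):
            is_native = j >= n_img
            is_main = (not is_native) and j < n_main
            age = float(np.clip(rng.normal(age_mean[k], 8.0), 25, 74))
            ey = float(np.clip(rng.normal(ey_mean[k], 1.5), 8, 17))
            level = float(np.clip(rng.normal(4.0 + 0.5 * (ey - 11.5), 1.0), 0, 9))
            subjects.append(
                SubjectRecord(
                    subject_id=f"S{sid:05d}",
                    unit_id=unit.unit_id,
                    native=is_native,
                    main_immigrant=is_main,
                    age=age,
                    education_years=ey,
                    education_level=level,
                )
            )
            q = q_native if is_native else q_immigrant
            codes_rows.append(rng.binomial(2, q).astype(np.int8))
            sid += 1
        unit.n_samples = n_k
    loci = pd.DataFrame(
        {
            "locus_id": [f"rs{100000 + i}" for i in range(config.n_loci)],
            "locus_class": np.where(
                np.arange(config.n_loci) < 68, "intragenic", "intergenic"
            ),
            "maf": q_native,
        }
    )
    geno = GenotypeMatrix(
        subject_ids=[s.subject_id for s in subjects],
        codes=np.vstack(codes_rows),
        loci=loci,
    )
    return region, subjects, geno


def reference_fixture() -> tuple[RegionSet, list[SubjectRecord]]:
    """Counts-exact 13-unit fixture of the published sample composition.

    Unit polygons are a schematic contiguous tiling (the pipeline consumes
    only topology and centroids); the pooled city unit (Augsburg) carries 14
    sub-centroids for interpolation smoothing.  Subject ages and education
    values are filled deterministically within the study ranges (age 25-74,
    education years 8-17, education level 0-9).  Genotypes are not included.
    """
    region = grid_region(13)
    main_lands = ("CZ", "RO", "PL", "UA")
    subjects: list[SubjectRecord] = []
    sid = 0
    for k, (name, n_all, n_nat, n_img, n_main) in enumerate(STUDY_UNIT_COUNTS):
        unit = region.units[k]
        unit.name = name
        unit.n_samples = n_all
        for j in range(n_all):
            native = j < n_nat
            main = n_nat <= j < n_nat + n_main
            subjects.append(
                SubjectRecord(
                    subject_id=f"K{sid:04d}",
                    unit_id=unit.unit_id,
                    native=native,
                    main_immigrant=main,
                    age=float(25 + (7 * sid) % 50),
                    education_years=float(8 + sid % 10),
                    education_level=float(sid % 10),
                )
            )
            sid += 1
    # 14 interpolation anchors inside the pooled city unit
    aug = region.units[0]
    minx, miny, maxx, maxy = aug.polygon.bounds
    gx = np.linspace(minx + 0.15 * (maxx - minx), maxx - 0.15 * (maxx - minx), 7)
    gy = np.linspace(miny + 0.3 * (maxy - miny), maxy - 0.3 * (maxy - miny), 2)
    aug.sub_centroids = [(float(x), float(y)) for y in gy for x in gx]
    return region, subjects
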