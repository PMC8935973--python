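"""Synthetic landscapes, colonies, genotypes, and capture records.

The generator emulates the study design the analysis assumes: a city split
into 2 x 2 km grid cells, bumblebee colonies scattered at covariate-linked
densities, haplodiploid full-sib families (one singly mated queen per colony),
hypervariable microsatellite genotypes with a small mistyping rate, and
workers netted at covariate-linked distances from their nest. Truth tables
(worker -> colony, colony locations, kernel scales) are returned alongside so
every downstream estimator can be checked by parameter recovery.

Genetic realism is calibrated to the study species: 12 microsatellite loci
with 12-30 alleles each on a 2-bp fragment-size ladder and expected
heterozygosities between 0.43 and 0.92, generated by truncated-geometric
allele frequencies solved to hit each locus's target heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .grid import Grid

__all__ = [
    "ErrorModel",
    "SamplingProtocol",
    "LandscapeConfig",
    "ColonyTruth",
    "DensityModel",
    "KernelModel",
    "COVARIATE_KINDS",
    "default_locus_table",
    "allele_frequencies",
    "simulate_landscape",
    "simulate_colonies",
    "simulate_genotypes",
    "simulate_sampling",
    "simulate_study",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorModel:
    """Genotyping error model: allelic dropout and residual mistyping.

    ``mistype_rate`` is the per-allele probability that the observed call is
    replaced by a random allele drawn from the locus's frequency
    distribution; ``dropout_rate`` is the per-allele probability that the
    call is missing. Defaults follow the study's scoring QC: no dropout,
    1% other errors.
    """

    dropout_rate: float = 0.0
    mistype_rate: float = 0.01

    def __post_init__(self):
        for name in ("dropout_rate", "mistype_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SamplingProtocol:
    """Field protocol: cap per-cell catches; optionally restrict cells."""

    max_per_cell: int = 60
    cells_sampled: tuple[int, ...] | None = None  # None = every cell
    seed: int = 0

    def __post_init__(self):
        if self.max_per_cell < 1:
            raise ValueError("max_per_cell must be >= 1")


@dataclass(frozen=True)
class CovariateModel:
    """Smooth spatial gradient plus (optionally correlated) Gaussian noise.

    Each variable v is mean_v + sd_v * (g * directional gradient + sqrt(1-g^2)
    * noise); the noise vector across variables may carry a correlation
    matrix. ``gradient_weight=0`` with ``noise_scale=0`` yields constant
    covariates.
    """

    gradient_weight: float = 0.6
    noise_scale: float = 1.0
    correlation: np.ndarray | None = None  # (n_vars, n_vars), order of COVARIATE_KINDS


@dataclass(frozen=True)
class LandscapeConfig:
    n_rows: int = 10
    n_cols: int = 27
    cell_size_m: float = 2000.0
    origin_lonlat: tuple[float, float] = (-79.6393, 43.581)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0


@dataclass
class ColonyTruth:
    colony_id: str
    true_lonlat: tuple[float, float]
    cell_id: int
    n_workers: int
    kernel_scale_m: float

    def __post_init__(self):
        if self.n_workers < 0:
            raise ValueError("n_workers must be >= 0")
        if self.kernel_scale_m < 0:
            raise ValueError("kernel_scale_m must be >= 0")


@dataclass(frozen=True)
class DensityModel:
    """Expected colonies per cell: linear in standardized covariates.

    lambda_cell = intercept + sum_j coef_j * z_j(cell); counts are Poisson.
    A negative expected count anywhere is rejected rather than clipped.
    """

    intercept: float = 3.0
    coefs: dict[str, float] = field(default_factory=dict)

    def expected(self, covariates: pd.DataFrame) -> np.ndarray:
        lam = np.full(len(covariates), self.intercept, dtype=float)
        for name, c in self.coefs.items():
            col = covariates[name].to_numpy(dtype=float)
            sd = col.std()
            z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
            lam += c * z
        if np.any(lam < 0):
            raise ValueError("density model yields negative expected colony counts")
        return lam


@dataclass(frozen=True)
class KernelModel:
    """Half-normal foraging-kernel scale per cell, linear in covariates."""

    base_m: float = 1000.0
    coefs: dict[str, float] = field(default_factory=dict)
    min_m: float = 50.0

    def scale(self, covariates: pd.DataFrame) -> np.ndarray:
        s = np.full(len(covariates), self.base_m, dtype=float)
        for name, c in self.coefs.items():
            col = covariates[name].to_numpy(dtype=float)
            sd = col.std()
            z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
            s += c * z
        return np.maximum(s, self.min_m)


# ---------------------------------------------------------------------------
# landscape covariates
# ---------------------------------------------------------------------------

# 28 per-cell physical and demographic variables: (kind, mean, sd).
# kind governs the post-transform: percents clipped to [0, 100], counts
# rounded and floored at 0, weighted averages floored at 0 where the quantity
# is physically nonnegative.
COVARIATE_KINDS: dict[str, tuple[str, float, float]] = {
    "buildPerc": ("percent", 20.0, 10.0),
    "roofPerc": ("percent", 0.5, 0.5),
    "green1Perc": ("percent", 8.0, 6.0),
    "treeCount": ("count", 1500.0, 700.0),
    "treeCanopyPerc": ("percent", 25.0, 10.0),
    "grassShrubPerc": ("percent", 20.0, 8.0),
    "waterPerc": ("percent", 3.0, 4.0),
    "bareEarthPerc": ("percent", 2.0, 2.0),
    "roadPerc": ("percent", 10.0, 4.0),
    "otherPavedPerc": ("percent", 15.0, 7.0),
    "elevat": ("wavg", 120.0, 40.0),
    "slope": ("wavg", 2.0, 1.0),
    "beachPerc": ("percent", 0.5, 1.0),
    "forestPerc": ("percent", 5.0, 5.0),
    "meadPerc": ("percent", 2.0, 2.0),
    "succPerc": ("percent", 1.5, 1.5),
    "wetPerc": ("percent", 1.0, 1.0),
    "popTotalCom": ("wavg", 15000.0, 7000.0),
    "popMale": ("wavg", 7300.0, 3500.0),
    "popFemale": ("wavg", 7700.0, 3500.0),
    "pop_less20": ("wavg", 3200.0, 1500.0),
    "pop_20-39": ("wavg", 4500.0, 2200.0),
    "pop_40-59": ("wavg", 4100.0, 1900.0),
    "pop_60plus": ("wavg", 3200.0, 1500.0),
    "popDensity": ("wavg", 4000.0, 2500.0),
    "houseDensity": ("wavg", 1500.0, 900.0),
    "indTI": ("wavg", 45000.0, 15000.0),
    "famTI": ("wavg", 95000.0, 30000.0),
}


def simulate_landscape(config: LandscapeConfig) -> tuple[Grid, pd.DataFrame]:
    """Build the grid and one covariate row per cell, deterministically.

    Percent variables land in [0, 100]; identical seeds give identical
    tables. A non-positive-semidefinite covariate correlation matrix is
    rejected.
    """
    grid = Grid(config.n_rows, config.n_cols, config.cell_size_m, config.origin_lonlat)
    rng = np.random.default_rng(config.seed)
    model = config.covariate_model
    names = list(COVARIATE_KINDS)
    n_vars = len(names)
    n = grid.n_cells

    # standardized planar cell-center coordinates for the gradient term
    row, col = np.divmod(np.arange(n), grid.n_cols)
    xy = np.column_stack([col, row]).astype(float)
    xy -= xy.mean(axis=0)
    span = np.maximum(xy.std(axis=0), 1e-12)
    xy /= span

    if model.correlation is not None:
        corr = np.asarray(model.correlation, dtype=float)
        if corr.shape != (n_vars, n_vars):
            raise ValueError(f"correlation matrix must be {n_vars}x{n_vars}")
        eigmin = np.linalg.eigvalsh(corr).min()
        if eigmin < -1e-10:
            raise ValueError(
                f"covariate correlation matrix is not positive semi-definite (min eigenvalue {eigmin:.3g})"
            )
        chol_like = _psd_factor(corr)
        noise = rng.standard_normal((n, n_vars)) @ chol_like.T
    else:
        noise = rng.standard_normal((n, n_vars))

    g = model.gradient_weight
    data = {}
    for j, name in enumerate(names):
        kind, mean, sd = COVARIATE_KINDS[name]
        direction = rng.standard_normal(2)
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0])
        gradient = xy @ direction
        z = g * gradient + np.sqrt(max(0.0, 1.0 - g * g)) * model.noise_scale * noise[:, j]
        vals = mean + sd * z
        if kind == "percent":
            vals = np.clip(vals, 0.0, 100.0)
        elif kind == "count":
            vals = np.maximum(np.round(vals), 0.0)
        else:  # weighted average; all defaults are physically nonnegative
            vals = np.maximum(vals, 0.0)
        data[name] = vals

    table = pd.DataFrame(data)
    table.insert(0, "cell_id", grid.cell_ids)
    return grid, table


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """Matrix square root usable for sampling from a PSD correlation."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


# ---------------------------------------------------------------------------
# colonies
# ---------------------------------------------------------------------------


def simulate_colonies(
    grid: Grid,
    covariates: pd.DataFrame,
    density_model: DensityModel | None = None,
    seed: int = 0,
    kernel_model: KernelModel | None = None,
    workers_mean: float = 4.0,
) -> list[ColonyTruth]:
    """Place colonies: per-cell Poisson counts, uniform locations in cell.

    Worker counts per colony are 1 + Poisson(workers_mean - 1) so every
    colony has at least one forager. The foraging-kernel scale is the cell's
    covariate-linked value.
    """
    density_model = density_model or DensityModel()
    kernel_model = kernel_model or KernelModel()
    lam = density_model.expected(covariates)
    scales = kernel_model.scale(covariates)
    rng = np.random.default_rng(seed)

    cell_ids = covariates["cell_id"].to_numpy()
    scale_of = dict(zip(cell_ids, scales))

    colonies: list[ColonyTruth] = []
    counts = rng.poisson(lam)
    idx = 0
    for cell_id, k in zip(cell_ids, counts):
        w, s, e, n = grid.cell_bounds_xy(int(cell_id))
        for _ in range(int(k)):
            x = rng.uniform(w, e)
            y = rng.uniform(s, n)
            lon, lat = grid.plane.to_lonlat(x, y)
            n_workers = 1 + rng.poisson(max(workers_mean - 1.0, 0.0))
            colonies.append(
                ColonyTruth(
                    colony_id=f"c{idx:05d}",
                    true_lonlat=(float(lon), float(lat)),
                    cell_id=int(cell_id),
                    n_workers=int(n_workers),
                    kernel_scale_m=float(scale_of[cell_id]),
                )
            )
            idx += 1
    return colonies


# ---------------------------------------------------------------------------
# microsatellite genotypes
# ---------------------------------------------------------------------------

# Study-calibrated locus panel: allele count, fragment-size range (bp), and
# target expected heterozygosity for each of the 12 microsatellites.
_LOCUS_PANEL = [
    ("BT01", 18, 143, 201, 0.796),
    ("BT23", 14, 158, 206, 0.428),
    ("BT08", 12, 156, 182, 0.643),
    ("BT26", 19, 93, 155, 0.887),
    ("B124", 30, 226, 306, 0.915),
    ("B126", 20, 136, 182, 0.871),
    ("B96", 19, 228, 266, 0.775),
    ("BL13", 15, 144, 194, 0.618),
    ("BL15", 20, 117, 173, 0.853),
    ("B10", 20, 171, 229, 0.806),
    ("BT10", 27, 135, 189, 0.923),
    ("BTERN01", 22, 98, 162, 0.799),
]


def default_locus_table() -> pd.DataFrame:
    """The 12-locus microsatellite panel used by default simulations."""
    return pd.DataFrame(
        _LOCUS_PANEL, columns=["locus", "n_alleles", "size_min", "size_max", "target_he"]
    )


def _geometric_freqs(k: int, target_he: float) -> np.ndarray:
    """Truncated-geometric allele frequencies with 1 - sum p^2 = target_he.

    The family spans He in (0, 1 - 1/k]; the decay ratio is solved by root
    finding. r = 1 gives equifrequent alleles.
    """
    if k == 1:
        return np.ones(1)
    he_max = 1.0 - 1.0 / k

    def he_of(r):
        if r >= 1.0:
            p = np.full(k, 1.0 / k)
        else:
            p = (1 - r) * r ** np.arange(k) / (1 - r**k)
        return 1.0 - np.sum(p**2)

    if target_he >= he_max - 1e-12:
        return np.full(k, 1.0 / k)
    r = brentq(lambda r: he_of(r) - target_he, 1e-9, 1 - 1e-9, xtol=1e-12)
    p = (1 - r) * r ** np.arange(k)
    return p / p.sum()


def allele_frequencies(locus_table: pd.DataFrame | None = None, seed: int = 0) -> dict[str, pd.Series]:
    """Per-locus allele-frequency tables on a 2-bp fragment-size ladder.

    Allele sizes are spread across each locus's printed size range; the
    frequency ranks are shuffled across sizes (seeded) so neighbouring
    fragment sizes are not systematically common or rare.
    """
    locus_table = locus_table if locus_table is not None else default_locus_table()
    rng = np.random.default_rng(seed)
    freqs: dict[str, pd.Series] = {}
    for _, row in locus_table.iterrows():
        k = int(row["n_alleles"])
        lo, hi = int(row["size_min"]), int(row["size_max"])
        ladder = np.arange(lo, hi + 1, 2)
        if len(ladder) < k:
            raise ValueError(f"locus {row['locus']}: size range too narrow for {k} alleles")
        pos = np.unique(np.round(np.linspace(0, len(ladder) - 1, k)).astype(int))
        sizes = ladder[pos]
        p = _geometric_freqs(len(sizes), float(row["target_he"]))
        rng.shuffle(p)
        freqs[str(row["locus"])] = pd.Series(p, index=sizes, name=str(row["locus"]))
    return freqs


def _worker_ids(colonies: list[ColonyTruth]) -> list[tuple[str, str]]:
    """Deterministic (worker_id, colony_id) pairs shared by genotype and
    capture simulation."""
    out = []
    for col in colonies:
        for j in range(col.n_workers):
            out.append((f"{col.colony_id}_w{j:02d}", col.colony_id))
    return out


def simulate_genotypes(
    colonies: list[ColonyTruth],
    allele_freqs: dict[str, pd.Series],
    error: ErrorModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Haplodiploid full-sib genotypes in long format.

    Per colony: one diploid queen (two alleles i.i.d. from the locus
    frequencies) and one haploid father. Each worker inherits one maternal
    allele (probability 1/2 each) plus the paternal allele. Each observed
    allele is then independently mistyped (replaced by a frequency-weighted
    random allele) with probability ``mistype_rate`` and dropped to missing
    with probability ``dropout_rate``.

    Returns columns worker_id, locus, allele1_bp, allele2_bp (NaN = missing).
    """
    if not allele_freqs:
        raise ValueError("empty allele-frequency table")
    error = error or ErrorModel()
    for locus, f in allele_freqs.items():
        if abs(float(f.sum()) - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies at locus {locus} do not sum to 1")
    rng = np.random.default_rng(seed)

    workers = _worker_ids(colonies)
    records: list[tuple] = []
    for locus, f in allele_freqs.items():
        sizes = f.index.to_numpy()
        p = f.to_numpy(dtype=float)
        w_off = 0
        for col in colonies:
            queen = rng.choice(sizes, size=2, p=p)
            father = rng.choice(sizes, p=p)
            for j in range(col.n_workers):
                maternal = queen[rng.integers(2)]
                obs = [maternal, father]
                for a in range(2):
                    if error.mistype_rate > 0 and rng.random() < error.mistype_rate:
                        obs[a] = rng.choice(sizes, p=p)
                    if error.dropout_rate > 0 and rng.random() < error.dropout_rate:
                        obs[a] = np.nan
                wid = workers[w_off + j][0]
                a1, a2 = sorted(obs, key=lambda v: (np.isnan(v), v))
                records.append((wid, locus, a1, a2))
            w_off += col.n_workers

    return pd.DataFrame(records, columns=["worker_id", "locus", "allele1_bp", "allele2_bp"])


# ---------------------------------------------------------------------------
# field sampling
# ---------------------------------------------------------------------------


def simulate_sampling(
    colonies: list[ColonyTruth],
    grid: Grid,
    protocol: SamplingProtocol | None = None,
    seed: int = 0,
    start_date: str = "2016-07-01",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Capture records: colony location plus an isotropic half-normal kick.

    Each worker's capture point is its colony's location displaced by a
    uniformly-oriented vector whose length is half-normal with the colony's
    kernel scale; workers may therefore be netted outside their colony's
    cell. Captures falling outside ``cells_sampled`` (when given) are
    dropped, and per-cell catches are truncated at ``max_per_cell`` by a
    seeded random subset.

    Returns (captures, truth): captures has worker_id, lon, lat, date,
    cell_id; truth maps worker_id -> colony_id for recovery checks.
    """
    protocol = protocol or SamplingProtocol()
    rng = np.random.default_rng(seed)
    rows = []
    for col in colonies:
        lon0, lat0 = col.true_lonlat
        x0, y0 = grid.plane.to_xy(lon0, lat0)
        for j in range(col.n_workers):
            d = abs(rng.normal(0.0, col.kernel_scale_m)) if col.kernel_scale_m > 0 else 0.0
            theta = rng.uniform(0.0, 2.0 * np.pi)
            x = float(x0) + d * np.cos(theta)
            y = float(y0) + d * np.sin(theta)
            lon, lat = grid.plane.to_lonlat(x, y)
            cell = int(grid.cell_of_xy(x, y))
            rows.append((f"{col.colony_id}_w{j:02d}", float(lon), float(lat), cell, col.colony_id))

    df = pd.DataFrame(rows, columns=["worker_id", "lon", "lat", "cell_id", "colony_id"])
    if protocol.cells_sampled is not None:
        df = df[df["cell_id"].isin(protocol.cells_sampled)]
    df = df[df["cell_id"] >= 0]

    # truncate per-cell catches, seeded
    kept = []
    for _, sub in df.groupby("cell_id", sort=True):
        if len(sub) > protocol.max_per_cell:
            take = rng.choice(len(sub), size=protocol.max_per_cell, replace=False)
            sub = sub.iloc[np.sort(take)]
        kept.append(sub)
    df = pd.concat(kept, ignore_index=True) if kept else df.reset_index(drop=True)

    # one synthetic collection date per visited cell, spread over the season
    cells = sorted(df["cell_id"].unique())
    base = pd.Timestamp(start_date)
    date_of = {c: (base + pd.Timedelta(days=int(i * 90 / max(len(cells), 1)))).date().isoformat() for i, c in enumerate(cells)}
    df["date"] = df["cell_id"].map(date_of)

    truth = df[["worker_id", "colony_id"]].copy()
    captures = df[["worker_id", "lon", "lat", "date", "cell_id"]].copy()
    return captures, truth


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    """All four pipeline inputs plus truth tables from one simulation."""

    grid: Grid
    covariates: pd.DataFrame
    genotypes: pd.DataFrame
    captures: pd.DataFrame
    truth_workers: pd.DataFrame     # worker_id -> colony_id
    colonies: list[ColonyTruth]
    allele_freqs: dict[str, pd.Series]
    seed: int


def simulate_study(
    config: LandscapeConfig | None = None,
    density_model: DensityModel | None = None,
    kernel_model: KernelModel | None = None,
    error: ErrorModel | None = None,
    protocol: SamplingProtocol | None = None,
    workers_mean: float = 4.0,
    seed: int = 0,
) -> StudyData:
    """Run the full generative chain from one master seed.

    Sub-seeds for each stage are split from ``seed`` so stages are
    independently reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_land, s_col, s_gen, s_samp, s_freq = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5))
    config = config or LandscapeConfig()
    config = replace(config, seed=s_land)
    grid, covariates = simulate_landscape(config)
    colonies = simulate_colonies(
        grid, covariates, density_model, seed=s_col, kernel_model=kernel_model, workers_mean=workers_mean
    )
    freqs = allele_frequencies(seed=s_freq)
    genotypes = simulate_genotypes(colonies, freqs, error, seed=s_gen)
    captures, truth = simulate_sampling(colonies, grid, protocol, seed=s_samp)
    # workers never captured (outside sampled cells) still carry genotypes;
    # the pipeline analyses the intersection, as the field study does.
    genotypes = genotypes[genotypes["worker_id"].isin(captures["worker_id"])].reset_index(drop=True)
    return StudyData(grid, covariates, genotypes, captures, truth, colonies, freqs, seed)
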