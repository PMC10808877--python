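"""Synthetic worlds: climate, terrain, societies, language tree, traits.

Generates data with the statistical structure the downstream analysis
assumes: latitudinally structured monthly climate with tunable seasonality
and noise, a smooth elevation field, societies placed on land cells, an
ultrametric Yule tree over society ids, and discrete trait histories shaped
by vertical inheritance down the tree plus horizontal copying whose odds
decay with geographic distance and environmental dissimilarity.

The generator is the test harness for the whole pipeline: every stage can
be exercised end-to-end without external downloads, and the causal effect
sizes (``beta_dist``, ``beta_env``) are known by construction.
"""

from __future__ import annotations

import dataclasses
import json
import random
import zlib
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grids import Raster

__all__ = [
    "WorldConfig",
    "World",
    "generate_climate",
    "generate_elevation",
    "place_societies",
    "assign_origin_areas",
    "simulate_tree",
    "evolve_traits",
    "evolve_trait_table",
    "simulate_pair_sharing",
    "generate_world",
    "write_world",
]


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a synthetic world.

    Climate amplitudes are degrees Celsius (temperature) and millimetres
    per month (precipitation); ``elevation_scale`` is the standard
    deviation of the terrain field in metres. ``beta_dist`` and
    ``beta_env`` are log-odds slopes of the horizontal-copy event per
    standard deviation of pairwise distance and temperature-harshness
    dissimilarity; ``mu_vertical`` is the per-unit-branch-length switch
    probability scale of vertical trait evolution.
    """

    grid_n_lat: int = 30
    grid_n_lon: int = 40
    lat_range: tuple[float, float] = (-60.0, 60.0)
    lon_range: tuple[float, float] = (0.0, 80.0)
    years: int = 100
    seasonality_amp: float = 10.0
    noise_sd_temp: float = 1.0
    noise_sd_precip: float = 15.0
    precip_base: float = 80.0
    elevation_scale: float = 1000.0
    n_societies: int = 150
    n_trait_categories: int = 6
    donor_pool_size: int = 10
    alpha_horizontal: float = -1.0
    beta_env: float = 0.0
    beta_dist: float = 0.0
    mu_vertical: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_n_lat < 2:
            raise ValueError("grid must cover at least 2 latitude bands")
        if self.grid_n_lon < 1 or self.grid_n_lat * self.grid_n_lon < 2:
            raise ValueError("degenerate (single-cell) grid")
        for name in ("years", "n_societies"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_trait_categories < 3:
            raise ValueError("need >= 3 trait categories (binary traits are excluded)")
        if not 0.0 <= self.mu_vertical <= 1.0:
            raise ValueError("mu_vertical must be in [0, 1]")
        if self.precip_base < 0:
            raise ValueError("precip_base must be >= 0")
        for name in ("beta_env", "beta_dist"):
            if np.isnan(getattr(self, name)):
                raise ValueError(f"{name} is not a number")

    def rng(self, stream: str) -> np.random.Generator:
        """A named, reproducible substream of the master seed."""
        key = zlib.crc32(stream.encode())  # stable across processes
        return np.random.default_rng(np.random.SeedSequence((self.seed, key)))

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray]:
        lat0, lat1 = self.lat_range
        lon0, lon1 = self.lon_range
        dlat = (lat1 - lat0) / self.grid_n_lat
        dlon = (lon1 - lon0) / self.grid_n_lon
        lats = lat0 + dlat * (np.arange(self.grid_n_lat) + 0.5)
        lons = lon0 + dlon * (np.arange(self.grid_n_lon) + 0.5)
        return lats, lons


def generate_climate(config: WorldConfig) -> tuple[Raster, Raster]:
    """Monthly temperature and precipitation stacks.

    Temperature is a latitude-dependent mean plus a seasonal sinusoid whose
    amplitude grows with |latitude| (opposite phase across hemispheres)
    plus white noise. Precipitation is a smooth lat/lon base level with a
    seasonal component scaled by the same seasonality knob, plus noise,
    clipped at zero.
    """
    lats, lons = config.grid_coords()
    months = np.arange(12 * config.years)
    lat2 = lats[:, None] * np.ones((1, lons.size))

    rng_t = config.rng("climate-temp")
    rng_p = config.rng("climate-precip")

    t_mean = 28.0 - 0.45 * np.abs(lat2)
    amp = config.seasonality_amp * (np.abs(lat2) / 90.0)
    phase = np.where(lat2 >= 0, 0.0, np.pi)
    cyc = np.cos(2 * np.pi * (months[:, None, None] % 12 - 6.5) / 12.0 + phase)
    temp = t_mean + amp * cyc
    if config.noise_sd_temp > 0:
        temp = temp + rng_t.normal(0.0, config.noise_sd_temp, temp.shape)

    lon_frac = (lons - lons[0]) / max(lons[-1] - lons[0], 1e-12)
    p_base = (
        config.precip_base
        * (0.25 + 0.75 * np.cos(np.deg2rad(lat2)) ** 2)
        * (0.55 + 0.45 * np.sin(np.pi * lon_frac)[None, :])
    )
    # precip seasonality rides the same knob so the noise-free limit is a
    # genuinely constant world
    p_amp = min(config.seasonality_amp / 20.0, 1.0)
    p_cyc = 1.0 + p_amp * 0.6 * np.cos(2 * np.pi * (months[:, None, None] % 12 - 1.5) / 12.0 + phase)
    precip = p_base * p_cyc
    if config.noise_sd_precip > 0:
        precip = precip + rng_p.normal(0.0, config.noise_sd_precip, precip.shape)
    precip = np.clip(precip, 0.0, None)

    return Raster(temp, lats, lons), Raster(precip, lats, lons)


def generate_elevation(config: WorldConfig) -> Raster:
    """Smooth random terrain: low-pass filtered white noise x elevation_scale."""
    lats, lons = config.grid_coords()
    rng = config.rng("elevation")
    noise = rng.standard_normal((lats.size, lons.size))
    sigma = max(min(lats.size, lons.size) / 10.0, 1.0)
    field = gaussian_filter(noise, sigma=sigma, mode="nearest")
    sd = field.std()
    if sd > 0:
        field = field / sd
    return Raster(field * config.elevation_scale, lats, lons)


def place_societies(config: WorldConfig, land_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Place societies on distinct land cells (jittered inside the cell)."""
    lats, lons = config.grid_coords()
    if land_mask is None:
        land_mask = np.ones((lats.size, lons.size), dtype=bool)
    land = np.flatnonzero(land_mask.ravel())
    rng = config.rng("societies")
    replace = config.n_societies > land.size
    cells = rng.choice(land, size=config.n_societies, replace=replace)
    ii, jj = np.unravel_index(cells, land_mask.shape)
    dlat = (config.lat_range[1] - config.lat_range[0]) / config.grid_n_lat
    dlon = (config.lon_range[1] - config.lon_range[0]) / config.grid_n_lon
    lat = lats[ii] + rng.uniform(-0.25, 0.25, config.n_societies) * dlat
    lon = lons[jj] + rng.uniform(-0.25, 0.25, config.n_societies) * dlon
    return pd.DataFrame(
        {
            "id": [f"S{k:04d}" for k in range(config.n_societies)],
            "lat": lat,
            "lon": lon,
            "origin_area": pd.Series([pd.NA] * config.n_societies, dtype="object"),
        }
    )


def assign_origin_areas(
    societies: pd.DataFrame, n_areas: int, seed: int = 0
) -> pd.DataFrame:
    """Label societies with spatially clustered area memberships.

    Emulates membership in centres-of-origin polygons: k-means on
    coordinates yields compact, contiguous area footprints.
    """
    from sklearn.cluster import KMeans

    xy = societies[["lat", "lon"]].to_numpy()
    km = KMeans(n_clusters=n_areas, n_init=5, random_state=seed).fit(xy)
    out = societies.copy()
    out["origin_area"] = [f"area_{k:02d}" for k in km.labels_]
    return out


def simulate_tree(
    n_societies: int, seed: int, ids: list[str] | None = None
) -> dendropy.Tree:
    """Ultrametric Yule (pure-birth) tree with society ids as tip labels."""
    if n_societies < 2:
        raise ValueError("need at least 2 tips")
    py_rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_societies,
        rng=py_rng,
    )
    # the simulation stops at the final birth, leaving the two newest tips
    # with zero-length pendant edges; extend every tip by the (common)
    # waiting time to the next event, preserving ultrametry
    tail = py_rng.expovariate(n_societies * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + tail
    if ids is None:
        ids = [f"S{k:04d}" for k in range(n_societies)]
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    ns = dendropy.TaxonNamespace()
    for leaf, sid in zip(leaves, ids):
        leaf.taxon = ns.new_taxon(sid)
    tree.taxon_namespace = ns
    return tree


def _pair_standardizers(
    societies: pd.DataFrame, th_by_society: np.ndarray, pools: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """z-scored distance and TH-dissimilarity matrices.

    Standardization uses the realized distribution over the candidate
    (society, pool-donor) pairs that copy events can actually draw, which
    makes beta values comparable across worlds and keeps the logistic in
    its informative range.
    """
    from .cost_paths import geodesic_km_matrix

    dist = geodesic_km_matrix(
        societies["lat"].to_numpy(), societies["lon"].to_numpy()
    )
    th = np.abs(th_by_society[:, None] - th_by_society[None, :])
    rows = np.repeat(np.arange(len(pools)), pools.shape[1])
    cols = pools.ravel()

    def z(mat: np.ndarray) -> np.ndarray:
        vals = mat[rows, cols]
        mu, sd = vals.mean(), vals.std()
        return (mat - mu) / (sd if sd > 0 else 1.0)

    return z(dist), z(th)


def evolve_traits(
    tree: dendropy.Tree,
    societies: pd.DataFrame,
    th_by_society: np.ndarray,
    config: WorldConfig,
    trait_id: str = "T000",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One discrete trait: vertical inheritance plus biased horizontal copying.

    Codes are inherited down the tree, switching on each edge with
    probability ``1 - exp(-mu_vertical * branch_length)`` (new code uniform
    over the other categories). Then, in one pass over societies in random
    order, each society draws a candidate donor uniformly among its
    ``donor_pool_size`` geodesic-nearest societies (cultural diffusion is
    local) and copies its current code with probability
    ``logistic(alpha + beta_dist * z(distance) + beta_env * z(|dTH|))``.
    Provenance (vertical | horizontal) is recorded per value.
    """
    if rng is None:
        rng = config.rng(f"trait-{trait_id}")
    k = config.n_trait_categories
    ids = societies["id"].tolist()
    idx = {sid: i for i, sid in enumerate(ids)}

    root = tree.seed_node
    codes_node: dict[int, int] = {id(root): int(rng.integers(1, k + 1))}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_code = codes_node[id(node.parent_node)]
        bl = node.edge.length or 0.0
        if rng.random() < 1.0 - np.exp(-config.mu_vertical * bl):
            others = [c for c in range(1, k + 1) if c != parent_code]
            codes_node[id(node)] = int(others[rng.integers(0, k - 1)])
        else:
            codes_node[id(node)] = parent_code

    codes = np.zeros(len(ids), dtype=int)
    for leaf in tree.leaf_node_iter():
        codes[idx[leaf.taxon.label]] = codes_node[id(leaf)]
    provenance = np.array(["vertical"] * len(ids), dtype=object)

    from .cost_paths import geodesic_km_matrix

    dist = geodesic_km_matrix(
        societies["lat"].to_numpy(), societies["lon"].to_numpy()
    )
    np.fill_diagonal(dist, np.inf)
    n = len(ids)
    pool_k = min(config.donor_pool_size, n - 1)
    pools = np.argsort(dist, axis=1, kind="stable")[:, :pool_k]
    zdist, zth = _pair_standardizers(societies, th_by_society, pools)
    order = rng.permutation(n)
    for i in order:
        donor = int(pools[i, rng.integers(0, pool_k)])
        eta = (
            config.alpha_horizontal
            + config.beta_dist * zdist[i, donor]
            + config.beta_env * zth[i, donor]
        )
        if rng.random() < expit(eta):
            codes[i] = codes[donor]
            provenance[i] = "horizontal"

    return pd.DataFrame(
        {
            "society_id": ids,
            "trait_id": trait_id,
            "code": codes,
            "provenance": provenance,
        }
    )


def evolve_trait_table(
    tree: dendropy.Tree,
    societies: pd.DataFrame,
    th_by_society: np.ndarray,
    config: WorldConfig,
    n_traits: int,
) -> pd.DataFrame:
    """Independent trait histories on a shared tree, stacked long-form."""
    parts = [
        evolve_traits(tree, societies, th_by_society, config, trait_id=f"T{t:03d}")
        for t in range(n_traits)
    ]
    return pd.concat(parts, ignore_index=True)


def simulate_pair_sharing(
    design: np.ndarray,
    beta: np.ndarray,
    id_a: np.ndarray,
    id_b: np.ndarray,
    sigma_society: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw dyadic sharing flags from the crossed random-intercept logit model.

    ``logit P(share) = design @ beta + u[id_a] + u[id_b]`` with
    ``u ~ N(0, sigma_society^2)``. This is the generator matched exactly to
    the model family fit downstream, used for parameter-recovery checks.
    """
    societies = np.unique(np.concatenate([id_a, id_b]))
    remap = {s: i for i, s in enumerate(societies)}
    u = rng.normal(0.0, sigma_society, societies.size)
    a = np.array([remap[s] for s in id_a])
    b = np.array([remap[s] for s in id_b])
    eta = design @ beta + u[a] + u[b]
    return (rng.random(eta.size) < expit(eta)).astype(int)


@dataclass
class World:
    """A fully realized synthetic world (traits generated separately)."""

    config: WorldConfig
    temperature: Raster
    precipitation: Raster
    elevation: Raster
    societies: pd.DataFrame
    tree: dendropy.Tree
    th: Raster
    ai: Raster
    th_by_society: np.ndarray
    ai_by_society: np.ndarray


def generate_world(config: WorldConfig) -> World:
    """Climate, terrain, societies, tree, and the derived TH/AI axes."""
    from .climate_components import env_pca, summarize_series

    temp, precip = generate_climate(config)
    elev = generate_elevation(config)
    societies = place_societies(config)
    tree = simulate_tree(config.n_societies, config.seed, societies["id"].tolist())
    summary = summarize_series(temp, precip)
    axes = env_pca(summary)
    cells = [temp.cell_of(la, lo) for la, lo in zip(societies["lat"], societies["lon"])]
    th_soc = np.array([axes.th.values[i, j] for i, j in cells])
    ai_soc = np.array([axes.ai.values[i, j] for i, j in cells])
    return World(
        config, temp, precip, elev, societies, tree, axes.th, axes.ai, th_soc, ai_soc
    )


def write_world(world: World, out_dir: str | Path, traits: pd.DataFrame | None = None) -> None:
    """Write society CSV, Newick tree, grids, config echo (and trait CSV)."""
    from .grids import write_grid

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world.societies.to_csv(out / "societies.csv", index=False)
    world.tree.write(path=str(out / "tree.nwk"), schema="newick")
    write_grid(out / "temperature.txt", world.temperature)
    write_grid(out / "precipitation.txt", world.precipitation)
    write_grid(out / "elevation.txt", world.elevation)
    write_grid(out / "th.txt", world.th)
    write_grid(out / "ai.txt", world.ai)
    (out / "config.json").write_text(json.dumps(dataclasses.asdict(world.config)))
    if traits is not None:
        traits.to_csv(out / "traits.csv", index=False)
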