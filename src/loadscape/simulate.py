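"""Synthetic genotype, annotation and landscape generator.

Emulates two long-diverged populations of a clinally distributed diploid,
one of which passed through a recent severe bottleneck, with mutation
classes (synonymous / missense / loss-of-function / intergenic) under
class-specific purifying selection, per-site conservation (GERP-like)
scores, Grantham-scored missense sites, two error-prone outgroup allele
columns for ancestral polarization, and present plus future climate grids
with a clinal focal variable.

The genotype engine is a forward Wright--Fisher simulation on per-site
allele frequencies with free recombination (sites independent), additive
selection with tunable dominance, and one-way mutation toward the derived
allele.  Individuals are drawn from population frequencies under
Hardy--Weinberg proportions with an optional per-population inbreeding
coefficient.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ClimateGrid, ClimateLayerSet

__all__ = [
    "SimParams",
    "LandscapeParams",
    "SimResult",
    "SimulationExtinctionError",
    "simulate_genotypes",
    "simulate_landscape",
    "embed_adaptive_cline",
    "embed_sweep",
]

EFFECT_CLASSES = ("synonymous", "missense", "lof", "intergenic")
BASES = np.array(["A", "C", "G", "T"])


class SimulationExtinctionError(RuntimeError):
    """A population's mean fitness reached zero during the simulation."""


@dataclass
class SimParams:
    """Demography, mutation classes and sampling design for the simulator.

    Times are in generations before sampling and must satisfy
    ``t_split > t_bottleneck > t_recovery >= 0``.  Population A passes
    through the bottleneck; population B keeps the ancestral size.
    Selection coefficients are class means of a per-site exponential
    distribution of fitness effects, truncated at -1.
    """

    n_pop_a: int = 12
    n_pop_b: int = 14
    ne_ancestral: int = 200
    ne_bottleneck: int = 12
    t_split: int = 300
    t_bottleneck: int = 100
    t_recovery: int = 20
    n_sites: dict[str, int] = field(
        default_factory=lambda: {
            "synonymous": 1500,
            "missense": 1500,
            "lof": 1200,
            "intergenic": 2500,
        }
    )
    s_missense: float = -0.015
    s_lof: float = -0.9
    dominance: float = 0.5
    dominance_lof: float = 0.0  # severe LOF alleles modeled fully recessive
    mu: float = 2e-4
    n_chromosomes: int = 4
    chrom_length_bp: int = 5_000_000
    burn_in: int | None = None  # default 4 * ne_ancestral
    outgroup_error: float = 0.02
    outgroup_missing: float = 0.01
    missing_rate: float = 0.02
    inbreeding_a: float = 0.0
    inbreeding_b: float = 0.0
    anc_is_alt_prob: float = 0.3  # fraction of sites where VCF ALT is ancestral
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_pop_a", "n_pop_b", "ne_ancestral", "ne_bottleneck",
                     "n_chromosomes", "chrom_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.t_split > self.t_bottleneck > self.t_recovery >= 0):
            raise ValueError("need t_split > t_bottleneck > t_recovery >= 0")
        for name in ("s_missense", "s_lof"):
            s = getattr(self, name)
            if not (-1.0 <= s <= 0.0):
                raise ValueError(f"{name} must lie in [-1, 0]")
        if not all(k in self.n_sites for k in EFFECT_CLASSES):
            raise ValueError(f"n_sites must contain all of {EFFECT_CLASSES}")
        if any(v <= 0 for v in self.n_sites.values()):
            raise ValueError("all n_sites counts must be > 0")


@dataclass
class LandscapeParams:
    """Geometry and climatology of the synthetic landscape.

    The first variable carries the main cline along ``cline_axis``; any
    further variables get a weaker gradient along the orthogonal axis so
    the set is not collinear.  Future scenarios are the present grid plus
    a uniform per-variable shift.
    """

    lon_min: float = 100.0
    lon_max: float = 112.0
    lat_min: float = 24.0
    lat_max: float = 33.0
    resolution: float = 0.5
    variables: tuple[str, ...] = ("bio7", "bio15")
    cline_axis: str = "lat"
    cline_range: float = 10.0  # units of the focal variable across the extent
    noise_sd: float = 0.4
    future_shift: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "ssp126_2050": {"bio7": 1.5, "bio15": 0.5},
            "ssp585_2090": {"bio7": 4.0, "bio15": 1.5},
        }
    )
    n_causal_loci: int = 25
    cline_steepness: float = 4.0
    n_sample_clusters: int = 5  # sampling-site clusters per population
    seed: int = 0

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("grid extent is empty")
        if self.cline_axis not in ("lon", "lat"):
            raise ValueError("cline_axis must be 'lon' or 'lat'")
        if len(self.variables) == 0:
            raise ValueError("need at least one climate variable")


@dataclass
class SimResult:
    """Genotypes (ALT-allele dosage, -1 missing) plus site and sample tables.

    ``genotypes`` holds segregating sites only; ``sites`` is the full
    ledger with a ``segregating`` flag, truth columns (``ancestral_true``,
    ``s``) and the observable annotation (class, Grantham, GERP, outgroup
    alleles).  ``site_index`` maps genotype columns into ``sites`` rows.
    """

    genotypes: np.ndarray  # (n_individuals, n_segregating) int8
    sites: pd.DataFrame
    samples: pd.DataFrame
    site_index: np.ndarray

    @property
    def seg_sites(self) -> pd.DataFrame:
        return self.sites.iloc[self.site_index].reset_index(drop=True)

    def copy(self) -> "SimResult":
        return SimResult(
            self.genotypes.copy(), self.sites.copy(),
            self.samples.copy(), self.site_index.copy(),
        )


def _selection_update(p: np.ndarray, s: np.ndarray, h: float) -> np.ndarray:
    q = 1.0 - p
    w11 = 1.0 + s
    w01 = 1.0 + h * s
    wbar = p * p * w11 + 2 * p * q * w01 + q * q
    if np.any(wbar <= 0):
        raise SimulationExtinctionError(
            "population mean fitness reached zero (a lethal allele fixed); "
            "regime too severe for the population size"
        )
    return (p * p * w11 + p * q * w01) / wbar


def _evolve(p, s, h, n_diploid, n_gen, mu, rng):
    two_n = 2 * n_diploid
    for _ in range(int(n_gen)):
        ps = _selection_update(p, s, h)
        ps = ps + (1.0 - ps) * mu
        p = rng.binomial(two_n, ps) / two_n
    return p


def _extinction_context(fn, params: SimParams):
    try:
        return fn()
    except SimulationExtinctionError as err:
        raise SimulationExtinctionError(
            f"{err} [ne_ancestral={params.ne_ancestral}, "
            f"ne_bottleneck={params.ne_bottleneck}, s_lof={params.s_lof}, "
            f"dominance={params.dominance}]"
        ) from None


def _sample_genotypes(p, n_ind, inbreeding, rng):
    """Diploid dosages from frequencies; HWE with inbreeding coefficient F."""
    n_sites = p.size
    hwe = rng.binomial(2, np.broadcast_to(p, (n_ind, n_sites)))
    if inbreeding > 0:
        hom = 2 * rng.binomial(1, np.broadcast_to(p, (n_ind, n_sites)))
        use_hom = rng.random((n_ind, n_sites)) < inbreeding
        hwe = np.where(use_hom, hom, hwe)
    return hwe.astype(np.int8)


def simulate_genotypes(params: SimParams) -> SimResult:
    """Run the two-population bottleneck scenario and draw a sample.

    Returns a :class:`SimResult` with ALT-coded dosages at segregating
    sites, the full site ledger, and the sample table (coordinates and
    environments are attached later by :func:`simulate_landscape`).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    # --- site layout and per-site selection coefficients -----------------
    counts = {c: int(params.n_sites[c]) for c in EFFECT_CLASSES}
    classes = np.concatenate([np.repeat(c, n) for c, n in counts.items()])
    n_total = classes.size
    h = np.where(classes == "lof", params.dominance_lof, params.dominance)
    s = np.zeros(n_total)
    for cls, s_mean in (("missense", params.s_missense), ("lof", params.s_lof)):
        idx = np.flatnonzero(classes == cls)
        if s_mean < 0:
            s[idx] = -np.minimum(rng.exponential(-s_mean, idx.size), 1.0)

    chrom = rng.integers(1, params.n_chromosomes + 1, n_total)
    pos = rng.integers(1, params.chrom_length_bp + 1, n_total)
    order = np.lexsort((pos, chrom))
    classes, s, h = classes[order], s[order], h[order]
    chrom, pos = chrom[order], pos[order]

    # --- forward Wright--Fisher -----------------------------------------
    burn = params.burn_in if params.burn_in is not None else 4 * params.ne_ancestral

    def run():
        p = np.zeros(n_total)
        p = _evolve(p, s, h, params.ne_ancestral, burn, params.mu, rng)
        p_a, p_b = p.copy(), p.copy()
        # split -> bottleneck start
        seg1 = params.t_split - params.t_bottleneck
        p_a = _evolve(p_a, s, h, params.ne_ancestral, seg1, params.mu, rng)
        p_b = _evolve(p_b, s, h, params.ne_ancestral, seg1, params.mu, rng)
        # bottleneck in A only
        seg2 = params.t_bottleneck - params.t_recovery
        p_a = _evolve(p_a, s, h, params.ne_bottleneck, seg2, params.mu, rng)
        p_b = _evolve(p_b, s, h, params.ne_ancestral, seg2, params.mu, rng)
        # recovery
        p_a = _evolve(p_a, s, h, params.ne_ancestral, params.t_recovery, params.mu, rng)
        p_b = _evolve(p_b, s, h, params.ne_ancestral, params.t_recovery, params.mu, rng)
        return p_a, p_b

    p_a, p_b = _extinction_context(run, params)

    # --- sample individuals (derived-allele dosages) ---------------------
    g_a = _sample_genotypes(p_a, params.n_pop_a, params.inbreeding_a, rng)
    g_b = _sample_genotypes(p_b, params.n_pop_b, params.inbreeding_b, rng)
    derived = np.vstack([g_a, g_b])
    n_ind = derived.shape[0]
    miss = rng.random(derived.shape) < params.missing_rate
    derived = np.where(miss, -1, derived).astype(np.int8)

    # --- alleles, outgroups, annotation ----------------------------------
    anc_base_idx = rng.integers(0, 4, n_total)
    der_base_idx = (anc_base_idx + rng.integers(1, 4, n_total)) % 4
    anc_base, der_base = BASES[anc_base_idx], BASES[der_base_idx]
    anc_is_alt = rng.random(n_total) < params.anc_is_alt_prob
    ref = np.where(anc_is_alt, der_base, anc_base)
    alt = np.where(anc_is_alt, anc_base, der_base)

    def outgroup_column():
        col = np.where(rng.random(n_total) < params.outgroup_error, der_base, anc_base)
        return np.where(rng.random(n_total) < params.outgroup_missing, ".", col)

    aa1, aa2 = outgroup_column(), outgroup_column()

    grantham = np.where(
        classes == "missense", rng.integers(5, 216, n_total), -1
    )
    gerp_base = {"intergenic": -2.0, "synonymous": -1.0, "missense": 2.0, "lof": 5.0}
    gerp = (
        np.vectorize(gerp_base.get)(classes)
        + 5.0 * np.abs(s)
        + rng.normal(0.0, 1.5, n_total)
    )

    # --- monomorphic dropping --------------------------------------------
    called = derived >= 0
    any_called = called.any(axis=0)
    mx = np.where(called, derived, 0).max(axis=0, initial=0)
    mn = np.where(called, derived, 2).min(axis=0, initial=2)
    segregating = any_called & (mx > mn)

    sites = pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in chrom],
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "effect_class": classes,
            "grantham": grantham,
            "gerp": np.round(gerp, 4),
            "aa1": aa1,
            "aa2": aa2,
            "ancestral_true": anc_base,
            "s": s,
            "segregating": segregating,
        }
    )

    site_index = np.flatnonzero(segregating)
    derived_seg = derived[:, site_index]
    # re-code to ALT dosage where the ancestral allele is ALT
    flip = anc_is_alt[site_index]
    geno = np.where(
        (derived_seg >= 0) & flip[None, :], 2 - derived_seg, derived_seg
    ).astype(np.int8)

    samples = pd.DataFrame(
        {
            "id": [f"A{i:02d}" for i in range(params.n_pop_a)]
            + [f"B{i:02d}" for i in range(params.n_pop_b)],
            "population": ["A"] * params.n_pop_a + ["B"] * params.n_pop_b,
        }
    )
    return SimResult(genotypes=geno, sites=sites, samples=samples, site_index=site_index)


# ---------------------------------------------------------------------------
# landscape


def _smooth_noise(lon, lat, sd, rng):
    """Low-frequency random surface: a few random sinusoids."""
    z = np.zeros_like(lon)
    for _ in range(4):
        kx, ky = rng.normal(0, 0.5, 2)
        phase = rng.uniform(0, 2 * np.pi)
        z += rng.normal(0, 1) * np.sin(kx * lon + ky * lat + phase)
    zs = z.std()
    return z * (sd / zs) if zs > 0 else z


def simulate_landscape(
    params: LandscapeParams, samples: pd.DataFrame | None = None
) -> tuple[ClimateLayerSet, dict[str, ClimateLayerSet], pd.DataFrame | None]:
    """Build present and future climate grids; optionally place samples.

    Each variable is a smooth gradient plus low-frequency noise; futures
    add the configured uniform shift.  If a sample table is given, each
    population is placed in its own longitude band, individuals grouped
    into ``n_sample_clusters`` sampling sites spread along the cline
    axis, and per-sample environments (columns ``env_<var>``) are
    bilinear interpolations of the present grids at sample coordinates.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ncols = int(round((params.lon_max - params.lon_min) / params.resolution))
    nrows = int(round((params.lat_max - params.lat_min) / params.resolution))
    lon_c = params.lon_min + (np.arange(ncols) + 0.5) * params.resolution
    lat_c = params.lat_min + (nrows - np.arange(nrows) - 0.5) * params.resolution
    lon, lat = np.meshgrid(lon_c, lat_c)

    def unit_axis(axis):
        if axis == "lat":
            return (lat - params.lat_min) / (params.lat_max - params.lat_min)
        return (lon - params.lon_min) / (params.lon_max - params.lon_min)

    other_axis = "lon" if params.cline_axis == "lat" else "lat"
    layers: dict[str, ClimateGrid] = {}
    for k, var in enumerate(params.variables):
        if k == 0:
            base = params.cline_range * unit_axis(params.cline_axis)
        else:
            # secondary variables: diagonal gradient, mostly along the cline
            # axis so no variable is a pure proxy of the between-population
            # axis (which would make structure and climate unidentifiable)
            base = 0.5 * params.cline_range * (
                0.7 * unit_axis(params.cline_axis) + 0.3 * unit_axis(other_axis)
            )
        vals = base + _smooth_noise(lon, lat, params.noise_sd, rng)
        layers[var] = ClimateGrid(
            values=vals,
            xll=params.lon_min,
            yll=params.lat_min,
            cellsize=params.resolution,
        )
    present = ClimateLayerSet(scenario="present", layers=layers)

    futures: dict[str, ClimateLayerSet] = {}
    for scen, shifts in params.future_shift.items():
        fl = {
            var: ClimateGrid(
                values=layers[var].values + shifts.get(var, 0.0),
                xll=params.lon_min,
                yll=params.lat_min,
                cellsize=params.resolution,
            )
            for var in params.variables
        }
        futures[scen] = ClimateLayerSet(scenario=scen, layers=fl)

    out_samples = None
    if samples is not None:
        out_samples = samples.copy()
        pops = list(dict.fromkeys(out_samples["population"]))
        lon_span = params.lon_max - params.lon_min
        lat_span = params.lat_max - params.lat_min
        lons = np.empty(len(out_samples))
        lats = np.empty(len(out_samples))
        cluster = np.empty(len(out_samples), dtype=object)
        for pi, pop in enumerate(pops):
            idx = np.flatnonzero((out_samples["population"] == pop).to_numpy())
            # population longitude band with margin
            band_lo = params.lon_min + lon_span * (0.1 + 0.8 * pi / len(pops))
            band_hi = params.lon_min + lon_span * (0.1 + 0.8 * (pi + 1) / len(pops)) - 0.1 * lon_span
            k = min(params.n_sample_clusters, idx.size)
            centers_main = params.lat_min + lat_span * (0.5 + np.arange(k)) / k
            centers_lon = rng.uniform(band_lo, band_hi, k)
            for j, ind in enumerate(idx):
                c = j % k
                lats[ind] = np.clip(
                    centers_main[c] + rng.normal(0, 0.1 * lat_span / k),
                    params.lat_min + 0.26 * params.resolution,
                    params.lat_max - 0.26 * params.resolution,
                )
                lons[ind] = np.clip(
                    centers_lon[c] + rng.normal(0, 0.02 * lon_span),
                    params.lon_min + 0.26 * params.resolution,
                    params.lon_max - 0.26 * params.resolution,
                )
                cluster[ind] = f"{pop}_s{c}"
        out_samples["lon"] = np.round(lons, 5)
        out_samples["lat"] = np.round(lats, 5)
        out_samples["site"] = cluster
        env = present.extract(out_samples["lon"], out_samples["lat"])
        for j, var in enumerate(params.variables):
            out_samples[f"env_{var}"] = np.round(env[:, j], 5)
    return present, futures, out_samples


# ---------------------------------------------------------------------------
# signal embedding


def embed_adaptive_cline(
    sim: SimResult,
    env: np.ndarray,
    n_causal: int,
    steepness: float,
    seed: int,
) -> tuple[SimResult, pd.DataFrame]:
    """Re-draw ``n_causal`` intergenic loci as env-driven clinal loci.

    Per individual, the derived-allele probability is a logistic function
    of the standardized focal environment: p = 1/(1+exp(-steepness * z)).
    Returns a new :class:`SimResult` plus a truth ledger of causal loci.
    """
    env = np.asarray(env, dtype=float)
    if env.size != sim.genotypes.shape[0]:
        raise ValueError("need one environmental value per individual")
    rng = np.random.default_rng(seed)
    seg = sim.seg_sites
    pool = np.flatnonzero((seg["effect_class"] == "intergenic").to_numpy())
    if n_causal > pool.size:
        raise ValueError(
            f"n_causal={n_causal} exceeds the {pool.size} available intergenic loci"
        )
    chosen = rng.choice(pool, size=n_causal, replace=False)
    sd = env.std()
    z = (env - env.mean()) / sd if sd > 0 else np.zeros_like(env)
    out = sim.copy()
    flip = (
        seg["ancestral_true"].to_numpy()[chosen] == seg["alt"].to_numpy()[chosen]
    )
    for col, fl in zip(chosen, flip):
        p = 1.0 / (1.0 + np.exp(-steepness * z))
        derived = rng.binomial(2, p)
        alt_coded = 2 - derived if fl else derived
        missing = out.genotypes[:, col] < 0
        out.genotypes[:, col] = np.where(missing, -1, alt_coded).astype(np.int8)
    ledger = seg.iloc[np.sort(chosen)][["chrom", "pos"]].reset_index(drop=True)
    ledger["causal"] = True
    return out, ledger


def embed_sweep(
    sim: SimResult,
    seed: int,
    width_bp: int = 50_000,
    n_loci: int = 12,
    p_high: float = 0.98,
    p_low: float = 0.02,
) -> tuple[SimResult, dict]:
    """Overwrite a contiguous region so population A looks swept.

    Loci inside one ``width_bp`` region get derived-allele frequency near
    fixation in population A and near loss in B, emulating the local
    differentiation and diversity loss of a hard sweep.  Returns the new
    result and the region (chrom, start, end, loci count).
    """
    rng = np.random.default_rng(seed)
    seg = sim.seg_sites
    pop = sim.samples["population"].to_numpy()
    is_a = pop == pop[0]
    chroms = seg["chrom"].to_numpy()
    positions = seg["pos"].to_numpy()
    # pick a region with enough loci
    best = None
    for _ in range(200):
        c = rng.choice(np.unique(chroms))
        on_c = np.flatnonzero(chroms == c)
        start = rng.integers(positions[on_c].min(), max(positions[on_c].max() - width_bp, positions[on_c].min() + 1))
        in_win = on_c[(positions[on_c] >= start) & (positions[on_c] < start + width_bp)]
        if in_win.size >= n_loci:
            best = (c, int(start), in_win[:n_loci])
            break
        if best is None or in_win.size > best[2].size:
            best = (c, int(start), in_win)
    c, start, loci = best
    out = sim.copy()
    flip = seg["ancestral_true"].to_numpy()[loci] == seg["alt"].to_numpy()[loci]
    n_ind = out.genotypes.shape[0]
    for col, fl in zip(loci, flip):
        p = np.where(is_a, p_high, p_low)
        derived = rng.binomial(2, p)
        alt_coded = np.where(fl, 2 - derived, derived)
        missing = out.genotypes[:, col] < 0
        out.genotypes[:, col] = np.where(missing, -1, alt_coded).astype(np.int8)
    region = {
        "chrom": str(c),
        "start": int(start),
        "end": int(start + width_bp),
        "n_loci": int(loci.size),
    }
    return out, region


def simulate_occurrences(
    present: ClimateLayerSet,
    n: int = 200,
    focal_var: str | None = None,
    optimum: float | None = None,
    tolerance: float = 1.0,
    sharpness: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw presence records from a Gaussian niche on the focal variable.

    True suitability is exp(-0.5 ((v - optimum)/tolerance)^2); cells are
    sampled proportionally to suitability^sharpness and records jittered
    within their cell.  The defaults give a crisp unimodal niche whose
    fitted models discriminate presence from background about as well as
    published ensemble habitat models for range-restricted species.
    """
    rng = np.random.default_rng(seed)
    focal_var = focal_var or present.variables[0]
    grid = present[focal_var]
    v = grid.values.ravel()
    if optimum is None:
        optimum = float(np.nanquantile(v, 0.3))
    suit = np.exp(-0.5 * ((v - optimum) / tolerance) ** 2) ** sharpness
    suit = np.where(grid.mask().ravel(), suit, 0.0)
    p = suit / suit.sum()
    cells = rng.choice(v.size, size=n, p=p, replace=True)
    lon_g, lat_g = grid.cell_centers()
    jit = (rng.random((n, 2)) - 0.5) * grid.cellsize * 0.98
    return pd.DataFrame(
        {
            "lon": lon_g.ravel()[cells] + jit[:, 0],
            "lat": lat_g.ravel()[cells] + jit[:, 1],
        }
    )


def default_params(seed: int = 0) -> tuple[SimParams, LandscapeParams]:
    """The bundled study conditions: bottlenecked A vs stable B on a cline."""
    return SimParams(seed=seed), LandscapeParams(seed=seed + 1)


def _replace(params, **kw):
    return dataclasses.replace(params, **kw)
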