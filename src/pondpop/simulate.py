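"""Seeded generators emulating the basin-wide survey's statistical structure.

The generator mirrors what the real data look like: a 658-bp mtDNA COI
alignment dominated by one central haplotype (~79% of specimens, the
observed basin-wide share), surrounded by derived haplotypes one to six
substitutions away with geometrically decaying frequencies; ponds carrying
multinomial samples of ~20 genotyped specimens; a planted between-pond
cluster structure (cluster-private rare haplotypes at geographically grouped
ponds); an isolation-by-distance cline in haplotype frequencies; and
overwintering outcomes that fail logistically with the concrete revetment
rate (intercept/slope defaults are the binomial-GLM estimates from the
printed survey counts).

Mutations are placed at globally distinct alignment positions (an
infinite-sites approximation): at <= 6 steps over 658 bp homoplasy is
negligible, so Hamming distances equal true mutational steps by
construction.

All randomness flows from a single top-level seed; each internal stage draws
from ``numpy.random.default_rng([seed, stage_index])`` so any stage can be
replayed in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assessment import (
    OverwinteringRecord,
    median_inclusion_threshold,
    overwintering_rate,
)
from .errors import ValidationError
from .io_survey import AlignedSequenceSet, HaplotypeCountTable, PondEnvironment

__all__ = ["SimulationConfig", "simulate_haplotype_pool", "simulate_pond_dataset"]

_BASES = np.array(list("ACGT"))
# stage indices for derived rng streams
_STAGE_POOL, _STAGE_GEOGRAPHY, _STAGE_COUNTS, _STAGE_ENV, _STAGE_WINTER = range(5)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic basin.

    Defaults reproduce the study conditions: 20 genotyped specimens per
    pond, a 658-bp alignment, a ~0.79 central-haplotype share, derived
    haplotypes at most 6 steps out, and four planted between-pond clusters.
    ``ibd_slope`` is the haplotype-frequency mass (fraction per km)
    reallocated along the west-east cline; ``overwinter_*`` are logit-scale
    coefficients of spring survival on the concrete revetment rate (%).
    """

    seed: int = 0
    n_sites: int = 25
    n_per_site: int = 20
    alignment_length: int = 658
    central_fraction: float = 0.79
    max_steps: int = 6
    n_haplotypes: int = 26
    n_clusters: int = 4
    cluster_weight: float = 0.30
    ibd_slope: float = 0.012
    basin_extent_km: float = 25.0
    overwinter_intercept: float = -0.756
    overwinter_slope: float = -0.0307
    autumn_mean: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 < self.central_fraction < 1.0:
            raise ValidationError("central_fraction must lie in (0, 1)")
        for name in ("n_sites", "n_per_site", "alignment_length", "max_steps",
                     "n_haplotypes", "n_clusters"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_clusters > self.n_sites:
            raise ValidationError("n_clusters cannot exceed n_sites")
        if self.n_haplotypes < 1 + 2 * self.n_clusters + 2:
            raise ValidationError(
                "need at least 2 cluster-private haplotypes per cluster "
                "plus two cline haplotypes"
            )
        reserved = self.cluster_weight + self.ibd_slope * self.basin_extent_km
        if self.central_fraction - reserved <= 0.05:
            raise ValidationError(
                "cluster_weight plus the cline mass would exhaust the "
                "central haplotype's frequency"
            )


def _stage_rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def simulate_haplotype_pool(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], dict[str, float]]:
    """Basin-wide haplotype pool: sequences and relative frequencies.

    One random central sequence; each derived haplotype adds one fresh
    substitution to a parent already in the pool (most often the centre),
    so depths range 1..max_steps and the pool is star-like. Frequencies
    decay geometrically over the derived haplotypes and sum to 1 with the
    centre at ``central_fraction``. Deterministic under a fixed seed.
    """
    rng = _stage_rng(cfg, _STAGE_POOL)
    length = cfg.alignment_length
    central = rng.integers(0, 4, size=length)
    sequences = [central.copy()]
    depths = [0]
    used_positions: set[int] = set()
    n_derived = cfg.n_haplotypes - 1
    for index in range(n_derived):
        # prefer the centre as parent; otherwise extend an existing chain.
        # The rarest 2*n_clusters haplotypes (used downstream as
        # cluster-private markers) always attach to the centre, matching the
        # observed pattern that most haplotypes are single-step neighbours
        # of the dominant one.
        candidates = [i for i, d in enumerate(depths) if d < cfg.max_steps]
        is_private = index >= n_derived - 2 * cfg.n_clusters
        if (
            not is_private
            and len(candidates) > 1
            and rng.random() >= 0.7
        ):
            parent = int(rng.choice([i for i in candidates if i != 0] or [0]))
        else:
            parent = 0
        position = int(rng.choice(
            [p for p in range(length) if p not in used_positions]
        ))
        used_positions.add(position)
        child = sequences[parent].copy()
        child[position] = (child[position] + 1 + rng.integers(0, 3)) % 4
        sequences.append(child)
        depths.append(depths[parent] + 1)
    hap_ids = [f"H{i + 1}" for i in range(cfg.n_haplotypes)]
    hap_seqs = {
        hap: "".join(_BASES[seq]) for hap, seq in zip(hap_ids, sequences)
    }
    decay = 0.6
    weights = decay ** np.arange(cfg.n_haplotypes - 1)
    derived = (1.0 - cfg.central_fraction) * weights / weights.sum()
    freqs = dict(zip(hap_ids, [cfg.central_fraction, *derived.tolist()]))
    return hap_seqs, freqs


def _layout_sites(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Site ids, cluster assignment, and (x, y) km coordinates.

    Cluster centres sit along the basin's west-east axis, so inter-cluster
    geographic separation carries both the planted cluster structure and the
    IBD cline.
    """
    site_ids = [f"S{i + 1}" for i in range(cfg.n_sites)]
    clusters = np.arange(cfg.n_sites) % cfg.n_clusters
    centers_x = (np.arange(cfg.n_clusters) + 0.5) / cfg.n_clusters * cfg.basin_extent_km
    centers_y = rng.uniform(-0.1, 0.1, size=cfg.n_clusters) * cfg.basin_extent_km
    jitter = cfg.basin_extent_km / 25.0
    xy = np.column_stack(
        [
            centers_x[clusters] + rng.normal(0, jitter, cfg.n_sites),
            centers_y[clusters] + rng.normal(0, jitter, cfg.n_sites),
        ]
    )
    xy[:, 0] = np.clip(xy[:, 0], 0.0, cfg.basin_extent_km)
    return site_ids, clusters, xy


def _site_frequencies(
    cfg: SimulationConfig,
    base: np.ndarray,
    clusters: np.ndarray,
    xy: np.ndarray,
    cline_pair: tuple[int, int],
) -> np.ndarray:
    """Per-site haplotype frequencies: basin pool + cline + cluster privates.

    Haplotype index 0 is the centre; ``cline_pair`` are the two derived
    haplotypes carrying the west/east frequency cline (the most divergent
    derived pair, so the cline is visible in sequence-level distances); the
    last ``2 * n_clusters`` (the rarest) are cluster-private. Reallocated
    mass always comes out of the centre, so its dominance is preserved.
    """
    n_haps = base.size
    p = np.tile(base, (cfg.n_sites, 1))
    private = np.arange(n_haps - 2 * cfg.n_clusters, n_haps).reshape(
        cfg.n_clusters, 2
    )
    east, west = cline_pair
    for i in range(cfg.n_sites):
        x = xy[i, 0]
        shift_east = cfg.ibd_slope * x
        shift_west = cfg.ibd_slope * (cfg.basin_extent_km - x)
        p[i, east] += shift_east
        p[i, west] += shift_west
        p[i, private[clusters[i]]] += cfg.cluster_weight / 2.0
        p[i, 0] -= shift_east + shift_west + cfg.cluster_weight
    if np.any(p < 0):
        raise ValidationError("frequency reallocation drove a haplotype negative")
    return p / p.sum(axis=1, keepdims=True)


def _cline_pair(
    cfg: SimulationConfig, hap_seqs: dict[str, str]
) -> tuple[int, int]:
    """Indices of the most divergent non-private derived pair.

    Maximising the mutational distance between the two cline carriers makes
    the planted isolation-by-distance signal visible in p-distances, not
    only in haplotype profiles. Deterministic: ties resolve to the first
    pair in index order.
    """
    from .diversity import hamming_steps

    ids = list(hap_seqs)
    n_private = 2 * cfg.n_clusters
    candidates = range(1, len(ids) - n_private)
    best = (1, 2)
    best_d = -1
    for i in candidates:
        for j in candidates:
            if j <= i:
                continue
            d = hamming_steps(hap_seqs[ids[i]], hap_seqs[ids[j]])
            if d > best_d:
                best_d = d
                best = (i, j)
    return best


def simulate_pond_dataset(
    cfg: SimulationConfig,
) -> tuple[
    HaplotypeCountTable,
    AlignedSequenceSet,
    list[PondEnvironment],
    list[OverwinteringRecord],
]:
    """Full synthetic survey: counts, alignment, environments, overwintering.

    Grand total of the count table is exactly ``n_sites * n_per_site``; the
    alignment round-trips through haplotype collapsing with conserved
    totals. Overwintering spring counts are binomial with
    logit(p) = overwinter_intercept + overwinter_slope * concrete_rate, and
    the inclusion threshold is the realized autumn median.
    """
    hap_seqs, freqs = simulate_haplotype_pool(cfg)
    hap_ids = list(hap_seqs)
    base = np.array([freqs[h] for h in hap_ids])

    geo_rng = _stage_rng(cfg, _STAGE_GEOGRAPHY)
    site_ids, clusters, xy = _layout_sites(cfg, geo_rng)
    p = _site_frequencies(cfg, base, clusters, xy, _cline_pair(cfg, hap_seqs))

    counts_rng = _stage_rng(cfg, _STAGE_COUNTS)
    counts = np.vstack(
        [counts_rng.multinomial(cfg.n_per_site, p[i]) for i in range(cfg.n_sites)]
    )
    observed = np.flatnonzero(counts.sum(axis=0) > 0)
    table = HaplotypeCountTable(
        site_ids, [hap_ids[j] for j in observed], counts[:, observed]
    )

    records = []
    for i, site in enumerate(site_ids):
        specimen = 0
        for j in np.flatnonzero(counts[i]):
            for _ in range(counts[i, j]):
                specimen += 1
                records.append((f"{site}_{specimen:03d}", site, hap_seqs[hap_ids[j]]))
    alignment = AlignedSequenceSet(tuple(records), cfg.alignment_length)

    env_rng = _stage_rng(cfg, _STAGE_ENV)
    lat0, lon0 = 36.20, 137.85
    ponds = []
    for i, site in enumerate(site_ids):
        surface = float(np.exp(env_rng.normal(7.0, 0.9)))
        concrete = float(env_rng.uniform(0.0, 100.0))
        ponds.append(
            PondEnvironment(
                site_id=site,
                latitude=lat0 + xy[i, 1] / 111.195,
                longitude=lon0 + xy[i, 0] / (111.195 * math.cos(math.radians(lat0))),
                altitude=float(env_rng.uniform(550, 1200)),
                surface_area=surface,
                perimeter=4.0 * math.sqrt(surface),
                vegetation_grade="II",
                shoreline_vegetation_rate=float(env_rng.uniform(10, 100)),
                concrete_revetment_rate=concrete,
                shore_gradient_mean=float(env_rng.uniform(10, 70)),
                shore_gradient_sd=float(env_rng.uniform(3, 35)),
                inflow_count=int(env_rng.poisson(1.8)),
                outflow_count=int(env_rng.poisson(0.9)),
                transparency_mean=float(env_rng.uniform(15, 100)),
                tn_mean=float(env_rng.uniform(0, 5)),
                nh4_mean=0.0,
                po4_mean=0.1,
            )
        )

    winter_rng = _stage_rng(cfg, _STAGE_WINTER)
    autumn = winter_rng.poisson(cfg.autumn_mean, size=cfg.n_sites)
    survival = 1.0 / (
        1.0
        + np.exp(
            -(
                cfg.overwinter_intercept
                + cfg.overwinter_slope
                * np.array([p_.concrete_revetment_rate for p_ in ponds])
            )
        )
    )
    spring = winter_rng.binomial(autumn, survival)
    threshold = median_inclusion_threshold(autumn)
    overwinter = [
        overwintering_rate(int(a), int(s), threshold, site_id=site)
        for site, a, s in zip(site_ids, autumn, spring)
    ]
    return table, alignment, ponds, overwinter


def planted_clusters(cfg: SimulationConfig) -> dict[str, int]:
    """The generator's true cluster assignment (site_id -> 1-based label)."""
    rng = _stage_rng(cfg, _STAGE_GEOGRAPHY)
    site_ids, clusters, _ = _layout_sites(cfg, rng)
    return {s: int(c) + 1 for s, c in zip(site_ids, clusters)}
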