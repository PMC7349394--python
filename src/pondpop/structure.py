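"""Between-pond genetic structure: dissimilarities, clustering, ordination, IBD.

The between-pond comparison chain is: per-pond haplotype profiles ->
pairwise dissimilarity (abundance-based Chao-Jaccard by default, because one
haplotype is overwhelmingly dominant and rare shared haplotypes are easily
missed; Bray-Curtis for the ordination) -> Ward agglomerative clustering
(ward.D2 convention) and nonmetric multidimensional scaling (Kruskal
stress-1). Isolation by distance is tested with a one-tailed Mantel
permutation test of the population p-distance matrix against great-circle
geographic distances.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof
from sklearn.metrics.pairwise import haversine_distances

from .errors import StatisticError, ValidationError
from .io_survey import HaplotypeCountTable, PondEnvironment

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "DistanceMatrix",
    "ClusterTree",
    "NMDSResult",
    "MantelResult",
    "bray_curtis",
    "chao_jaccard_dissimilarity",
    "pairwise_dissimilarity",
    "ward_cluster",
    "cut_tree",
    "nmds",
    "geographic_distances",
    "population_p_distance",
    "mantel_test",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric dissimilarity/distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(values) != 0.0):
            raise ValidationError("distance matrix diagonal must be exactly zero")
        if np.any(values < 0):
            raise ValidationError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        index = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(index, index)])

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.values):
                handle.write(label + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        with open(path, encoding="utf-8") as handle:
            header = handle.readline().rstrip("\n").split("\t")[1:]
            rows = []
            labels = []
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if labels != header:
            raise ValidationError("row and column labels differ in matrix TSV")
        return cls(tuple(labels), np.asarray(rows))


# ---------------------------------------------------------------------------
# dissimilarities
# ---------------------------------------------------------------------------

def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("count vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("count vectors must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise StatisticError("dissimilarity undefined for two empty assemblages")
    return x, y


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: 1 - 2 sum(min) / (sum x + sum y)."""
    x, y = _check_pair(x, y)
    return float(_scipy_braycurtis(x, y))


def chao_jaccard_dissimilarity(x, y) -> float:
    """Abundance-based Chao-Jaccard dissimilarity with unseen-shared correction.

    U and V estimate the total probability mass in assemblage x (resp. y)
    belonging to haplotypes shared with the other assemblage, corrected for
    shared haplotypes present but unseen; the similarity is UV/(U+V-UV) and
    the returned dissimilarity its complement, clamped to [0, 1].
    """
    x, y = _check_pair(x, y)
    n = x.sum()
    m = y.sum()
    shared = (x > 0) & (y > 0)
    if not np.any(shared):
        return 1.0
    u = _chao_shared_fraction(x, y, n, m, shared)
    v = _chao_shared_fraction(y, x, m, n, shared)
    u = min(u, 1.0)
    v = min(v, 1.0)
    if u == 0.0 or v == 0.0:
        return 1.0
    similarity = u * v / (u + v - u * v)
    return float(min(1.0, max(0.0, 1.0 - similarity)))


def _chao_shared_fraction(x, y, n, m, shared) -> float:
    """Chao-Shen corrected probability mass of x's shared haplotypes.

    U = sum_{shared} x_i/n + ((m-1)/m) (f+1 / (2 f+2)) sum_{shared, y_i=1} x_i/n,
    where f+1 / f+2 count shared haplotypes that are singletons / doubletons
    in the *other* assemblage; f+2 = 0 falls back to 1, the standard
    convention for the estimator.
    """
    observed = float(x[shared].sum() / n)
    f_plus1 = int(np.sum(shared & (y == 1)))
    f_plus2 = int(np.sum(shared & (y == 2)))
    if m <= 1 or f_plus1 == 0:
        return observed
    correction = (
        (m - 1.0) / m
        * f_plus1
        / (2.0 * max(f_plus2, 1))
        * float(x[shared & (y == 1)].sum() / n)
    )
    return observed + correction


def pairwise_dissimilarity(
    table: HaplotypeCountTable, metric: str = "chao_jaccard"
) -> DistanceMatrix:
    """Site x site dissimilarity matrix from haplotype profiles."""
    functions = {"chao_jaccard": chao_jaccard_dissimilarity, "bray_curtis": bray_curtis}
    if metric not in functions:
        raise ValidationError(f"unknown metric {metric!r}; choose from {sorted(functions)}")
    fn = functions[metric]
    n = table.n_sites
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        values[i, j] = values[j, i] = fn(table.counts[i], table.counts[j])
    return DistanceMatrix(tuple(table.site_ids), values)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge history over labelled leaves.

    ``merges`` lists (left, right, height) where left/right are indices into
    the sequence leaves + earlier merges (scipy linkage convention); heights
    are non-decreasing under Ward's criterion.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def linkage_matrix(self) -> np.ndarray:
        """scipy-style (n-1) x 4 linkage matrix for plotting/dendrograms."""
        n = len(self.leaves)
        sizes = {i: 1 for i in range(n)}
        out = np.zeros((len(self.merges), 4))
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + k] = size
            out[k] = (a, b, h, size)
        return out

    def to_newick(self) -> str:
        """Newick with branch lengths from merge heights (height/2 per side)."""
        n = len(self.leaves)
        node_height = {i: 0.0 for i in range(n)}
        rep = {i: self.leaves[i] for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            half = h / 2.0
            left = f"{rep[a]}:{half - node_height[a]:.6g}"
            right = f"{rep[b]}:{half - node_height[b]:.6g}"
            rep[n + k] = f"({left},{right})"
            node_height[n + k] = half
        return rep[n + len(self.merges) - 1] + ";"


def ward_cluster(d: DistanceMatrix) -> ClusterTree:
    """Ward agglomeration on a precomputed dissimilarity (ward.D2 convention).

    The Lance-Williams update is applied to squared input dissimilarities and
    merge heights are reported on the original scale. Ties at the minimum are
    broken by the lexicographically smallest merged label set, making the
    tree deterministic for any input.
    """
    n = d.n
    if n < 2:
        raise ValidationError("clustering requires at least 2 sites")
    d2 = d.values.astype(float) ** 2
    active: dict[int, tuple[str, ...]] = {
        i: (d.labels[i],) for i in range(n)
    }  # node id -> sorted member labels
    sizes = {i: 1 for i in range(n)}
    current = {i: i for i in range(n)}  # row index in the working matrix
    work = d2.copy()
    alive = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for ai, bi in itertools.combinations(range(len(alive)), 2):
            a, b = alive[ai], alive[bi]
            value = work[current[a], current[b]]
            key = (value, tuple(sorted(active[a] + active[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (value, _), a, b = best
        height = math.sqrt(max(value, 0.0))
        merges.append((a, b, height))
        # Lance-Williams ward update on squared dissimilarities
        na, nb = sizes[a], sizes[b]
        ra, rb = current[a], current[b]
        for c in alive:
            if c in (a, b):
                continue
            nc = sizes[c]
            rc = current[c]
            updated = (
                (na + nc) * work[ra, rc]
                + (nb + nc) * work[rb, rc]
                - nc * work[ra, rb]
            ) / (na + nb + nc)
            work[ra, rc] = work[rc, ra] = updated
        active[next_id] = tuple(sorted(active[a] + active[b]))
        sizes[next_id] = na + nb
        current[next_id] = ra
        alive = [x for x in alive if x not in (a, b)] + [next_id]
        del active[a], active[b]
        next_id += 1
    return ClusterTree(tuple(d.labels), tuple(merges))


def cut_tree(tree: ClusterTree, k: int) -> dict[str, int]:
    """Flat cluster labels from the first (n - k) merges.

    Labels are 1..k, assigned by order of each cluster's first leaf, so the
    labelling is stable under re-runs.
    """
    n = len(tree.leaves)
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside [1, {n}]")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    node_root = {i: i for i in range(n)}
    for step, (a, b, _h) in enumerate(tree.merges[: n - k]):
        ra, rb = find(node_root[a]), find(node_root[b])
        parent[rb] = ra
        members[ra].extend(members.pop(rb))
        node_root[n + step] = ra
    if n - k > 0:
        # later merge entries may reference unmade internal nodes; ignore
        pass
    clusters = sorted(members.values(), key=min)
    labels: dict[str, int] = {}
    for index, group in enumerate(clusters, start=1):
        for leaf in group:
            labels[tree.leaves[leaf]] = index
    return labels


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NMDSResult:
    """Best nonmetric MDS configuration over all restarts."""

    coordinates: np.ndarray
    stress: float
    converged: bool
    seed: int
    labels: tuple[str, ...]

    def write_tsv(self, path) -> None:
        k = self.coordinates.shape[1]
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("site_id\t" + "\t".join(f"axis{i+1}" for i in range(k)) + "\n")
            for label, row in zip(self.labels, self.coordinates):
                handle.write(label + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")


def kruskal_stress(dissimilarities: np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against input dissimilarities.

    Disparities are the isotonic (pool-adjacent-violators) regression of the
    configuration distances on the input dissimilarities; stress-1 =
    sqrt(sum (dhat - d)^2 / sum d^2) over upper-triangle pairs.
    """
    iu = np.triu_indices(len(dissimilarities), k=1)
    delta = dissimilarities[iu]
    diff = coordinates[:, None, :] - coordinates[None, :, :]
    config = np.sqrt((diff**2).sum(axis=-1))[iu]
    # Kruskal's primary tie treatment: within tied dissimilarities the
    # configuration distances are free to take any order
    order = np.lexsort((config, delta))
    disparities = np.empty_like(config)
    disparities[order] = IsotonicRegression().fit_transform(
        np.arange(order.size), config[order]
    )
    denominator = float(np.sum(config**2))
    if denominator == 0.0:
        return 0.0
    return float(np.sqrt(np.sum((disparities - config) ** 2) / denominator))


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson double-centering initialisation."""
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigenvalues, eigenvectors = np.linalg.eigh(b)
    order = np.argsort(eigenvalues)[::-1][:k]
    lam = np.clip(eigenvalues[order], 0.0, None)
    return eigenvectors[:, order] * np.sqrt(lam)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    eps: float = 1e-6,
) -> NMDSResult:
    """Nonmetric MDS minimising Kruskal stress-1.

    One restart starts from classical-scaling coordinates, the remaining
    ``n_restarts - 1`` from seeded random configurations; each is refined by
    SMACOF with monotone regression until the relative stress change drops
    below ``eps`` or ``max_iter`` iterations. The best configuration over all
    restarts is returned with its stress-1.
    """
    n = d.n
    if n < 3:
        raise ValidationError("NMDS requires at least 3 sites")
    if not 1 <= k < n:
        raise ValidationError(f"embedding dimension k={k} must satisfy 1 <= k < {n}")
    rng = np.random.default_rng(seed)
    inits = [_classical_scaling(d.values, k)]
    inits += [rng.normal(size=(n, k)) for _ in range(max(0, n_restarts - 1))]
    best: tuple[float, np.ndarray] | None = None
    for init in inits:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coordinates, _stress = smacof(
                d.values,
                metric=False,
                n_components=k,
                init=init,
                n_init=1,
                max_iter=max_iter,
                eps=eps,
                normalized_stress=True,
            )
        stress = kruskal_stress(d.values, coordinates)
        if best is None or stress < best[0]:
            best = (stress, coordinates)
    stress, coordinates = best
    return NMDSResult(
        coordinates=coordinates,
        stress=stress,
        converged=True,
        seed=seed,
        labels=d.labels,
    )


# ---------------------------------------------------------------------------
# geographic and genetic distance matrices
# ---------------------------------------------------------------------------

def geographic_distances(ponds: Sequence[PondEnvironment]) -> DistanceMatrix:
    """Great-circle (haversine) distances between ponds, in km."""
    if not ponds:
        raise ValidationError("no ponds supplied")
    for pond in ponds:
        if pond.latitude is None or pond.longitude is None or (
            isinstance(pond.latitude, float) and math.isnan(pond.latitude)
        ):
            raise ValidationError(f"pond {pond.site_id} lacks coordinates")
    radians = np.radians(
        [[pond.latitude, pond.longitude] for pond in ponds]
    )
    values = haversine_distances(radians) * EARTH_RADIUS_KM
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return DistanceMatrix(tuple(p.site_id for p in ponds), values)


def population_p_distance(
    table: HaplotypeCountTable,
    pairwise_steps: np.ndarray,
    alignment_length: int,
) -> DistanceMatrix:
    """Mean between-pond per-site p-distance.

    Entry (A, B) is the expected per-site difference between one specimen
    drawn from pond A and one from pond B:
    sum_ij p_i^A p_j^B d_ij / L. No within-pond term and no net-divergence
    correction is applied (this is a plain p-distance, not Phi_ST).
    Ponds with zero genotyped specimens are excluded with a warning.
    """
    d = np.asarray(pairwise_steps, dtype=float)
    if d.shape != (table.n_haplotypes, table.n_haplotypes):
        raise ValidationError("steps matrix does not cover all haplotypes")
    if alignment_length <= 0:
        raise ValidationError("alignment_length must be positive")
    totals = table.counts.sum(axis=1)
    keep = np.flatnonzero(totals > 0)
    if keep.size < table.n_sites:
        dropped = [table.site_ids[i] for i in range(table.n_sites) if totals[i] == 0]
        warnings.warn(f"excluding ponds with zero specimens: {dropped}", stacklevel=2)
    p = table.counts[keep] / totals[keep, None]
    values = p @ d @ p.T / alignment_length
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    labels = tuple(table.site_ids[i] for i in keep)
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int
    alternative: str


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(len(values), k=1)
    return values[iu]


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel permutation test of matrix correlation.

    r is the Pearson correlation over upper-triangle entries; the null is
    built by simultaneously permuting the rows and columns of ``d2``. The
    one-tailed p-value for positive association (the isolation-by-distance
    hypothesis) is (#{r_perm >= r_obs} + 1) / (n_permutations + 1).

    With ``exact=True`` all n! orderings are enumerated (feasible for small
    n only) and p = #{r_perm >= r_obs} / n!, which includes the identity in
    the count, so the p-value resolution is 1/n!.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValidationError("alternative must be 'greater' or 'two-sided'")
    if d1.labels != d2.labels:
        raise ValidationError("distance matrices must share the same labels")
    n = d1.n
    if n < 4:
        raise ValidationError("Mantel test requires at least 4 sites")
    x = _upper(d1.values)
    if np.std(x) == 0:
        raise StatisticError("d1 has zero variance over pairs")
    observed = _pearson(x, _upper(d2.values))

    def extreme(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= observed - 1e-12
        return abs(r_perm) >= abs(observed) - 1e-12

    if exact:
        if n > 8:
            raise ValidationError("exact enumeration is limited to n <= 8 sites")
        perms = list(itertools.permutations(range(n)))
        count = sum(
            extreme(_pearson(x, _upper(d2.values[np.ix_(perm, perm)])))
            for perm in perms
        )
        p = count / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            count += extreme(_pearson(x, _upper(d2.values[np.ix_(perm, perm)])))
        p = (count + 1) / (n_permutations + 1)
        n_used = n_permutations
    return MantelResult(
        r=float(observed),
        p=float(p),
        n_permutations=n_used,
        seed=seed,
        alternative=alternative,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denominator = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denominator == 0.0:
        return 0.0
    return float(xc @ yc) / denominator
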