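"""Per-pond and basin-wide genetic diversity and the haplotype network.

Haplotype diversity uses Nei's unbiased estimator

    Hd = n (1 - sum p_i^2) / (n - 1),    p_i = count_i / n,

which is the only form consistent with every printed per-pond value in the
survey this package reimplements, including the small-n ponds. Nucleotide
diversity is Nei's pi with the same n/(n-1) correction, expressed per
aligned site. Within-pond haplotype richness uses the bias-corrected Chao1
estimator, appropriate when a single haplotype is overwhelmingly dominant
and rare haplotypes are easily missed at n ~ 20.

The haplotype network is a minimum spanning network (MSN): Kruskal-style
growth over pairwise Hamming (mutational-step) distances, keeping *all* tied
alternative connections at the joining distance, so the result is a network
rather than a tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import AlignmentError, StatisticError, ValidationError
from .io_survey import HaplotypeCountTable

__all__ = [
    "haplotype_diversity",
    "nucleotide_diversity",
    "chao1",
    "hamming_steps",
    "pairwise_step_matrix",
    "build_msn",
    "DiversitySummary",
    "HaplotypeNetwork",
    "summarize_diversity",
    "write_diversity_table",
]


def haplotype_diversity(counts) -> float:
    """Unbiased haplotype diversity of one count vector.

    Raises :class:`StatisticError` for n < 2, where the estimator is
    undefined. Returned at full precision; rounding is a display concern.
    """
    counts = np.asarray(counts, dtype=float).ravel()
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    n = counts.sum()
    if n < 2:
        raise StatisticError(f"haplotype diversity undefined for n={int(n)} < 2")
    p = counts / n
    return float(n * (1.0 - np.sum(p**2)) / (n - 1.0))


def nucleotide_diversity(counts, pairwise_steps, alignment_length: int) -> float:
    """Nei's per-site nucleotide diversity from haplotype counts and steps.

    ``pairwise_steps[i, j]`` is the number of substitutions separating
    haplotypes i and j. Pi = [n/(n-1)] * sum_{i<j} 2 p_i p_j d_ij / L.
    """
    counts = np.asarray(counts, dtype=float).ravel()
    d = np.asarray(pairwise_steps, dtype=float)
    if alignment_length <= 0:
        raise ValidationError("alignment_length must be positive")
    if d.shape != (counts.size, counts.size):
        raise ValidationError(
            f"steps matrix shape {d.shape} does not match {counts.size} haplotypes"
        )
    if not np.allclose(d, d.T):
        raise ValidationError("pairwise steps matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValidationError("pairwise steps matrix must have zero diagonal")
    n = counts.sum()
    if n < 2:
        raise StatisticError(f"nucleotide diversity undefined for n={int(n)} < 2")
    p = counts / n
    cross = float(p @ d @ p)  # sums both (i,j) and (j,i): equals sum_{i<j} 2 p_i p_j d_ij
    return cross / alignment_length * n / (n - 1.0)


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: h + f1(f1 - 1) / (2 (f2 + 1)).

    f1 and f2 are the numbers of singleton and doubleton haplotypes. Always
    >= the observed richness h.
    """
    counts = np.asarray(counts).ravel()
    counts = counts[counts > 0]
    if counts.size == 0:
        raise StatisticError("chao1 undefined for an empty sample")
    h = counts.size
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    return float(h + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


_UNAMBIGUOUS = frozenset("ACGT")


def hamming_steps(a: str, b: str) -> int:
    """Mutational steps between two aligned sequences.

    Positions where either sequence carries N or a gap are skipped, so the
    distance is computed over mutually resolved sites only.
    """
    if len(a) != len(b):
        raise AlignmentError(
            f"sequence lengths differ: {len(a)} vs {len(b)}"
        )
    a = a.upper()
    b = b.upper()
    return sum(
        1
        for x, y in zip(a, b)
        if x != y and x in _UNAMBIGUOUS and y in _UNAMBIGUOUS
    )


def pairwise_step_matrix(
    haplotype_sequences: Mapping[str, str],
    order: Sequence[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Hamming step matrix over haplotypes, in ``order`` (default: mapping order)."""
    ids = list(order) if order is not None else list(haplotype_sequences)
    k = len(ids)
    d = np.zeros((k, k), dtype=np.int64)
    for i, j in itertools.combinations(range(k), 2):
        d[i, j] = d[j, i] = hamming_steps(
            haplotype_sequences[ids[i]], haplotype_sequences[ids[j]]
        )
    return ids, d


@dataclass
class HaplotypeNetwork:
    """Frequency-weighted haplotype nodes joined by mutational-step edges.

    ``nodes`` maps haplotype id to total frequency; inferred intermediate
    nodes (added by :meth:`expand_intermediates`) carry frequency 0.
    ``total_length`` is the weight of the minimal spanning backbone; tied
    alternative connections retained by the MSN are extra edges and do not
    inflate it.
    """

    nodes: dict[str, int]
    edges: list[tuple[str, str, int]]
    total_length: int

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for hap, freq in self.nodes.items():
            g.add_node(hap, frequency=int(freq))
        for u, v, steps in self.edges:
            g.add_edge(u, v, steps=int(steps))
        return g

    def expand_intermediates(self) -> "HaplotypeNetwork":
        """Split every multi-step edge into unit steps via inferred nodes.

        Mirrors the usual network drawing, where unobserved haplotypes are
        rendered as small hollow circles along multi-step connections.
        """
        nodes = dict(self.nodes)
        edges: list[tuple[str, str, int]] = []
        counter = itertools.count(1)
        for u, v, steps in self.edges:
            if steps <= 1:
                edges.append((u, v, steps))
                continue
            chain = [u]
            for _ in range(steps - 1):
                name = f"mv{next(counter)}"
                nodes[name] = 0
                chain.append(name)
            chain.append(v)
            edges.extend((a, b, 1) for a, b in zip(chain, chain[1:]))
        return HaplotypeNetwork(nodes, edges, self.total_length)

    def write_edgelist(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("from\tto\tsteps\n")
            for u, v, steps in self.edges:
                handle.write(f"{u}\t{v}\t{steps}\n")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_msn(
    haplotype_sequences: Mapping[str, str],
    frequencies: Mapping[str, int],
) -> HaplotypeNetwork:
    """Minimum spanning network over haplotypes.

    Edges are considered in increasing Hamming distance; within one distance
    class, every pair that connected two *previously* separate components is
    retained (tie retention), then components merge. The result connects all
    haplotypes, its backbone weight is minimal among spanning structures, and
    construction is deterministic: ties are visited in lexicographic
    haplotype-id order.
    """
    ids = sorted(haplotype_sequences)
    if not ids:
        raise ValidationError("no haplotypes to connect")
    missing = [h for h in ids if h not in frequencies]
    if missing:
        raise ValidationError(f"frequencies missing for haplotypes: {missing}")
    nodes = {h: int(frequencies[h]) for h in ids}
    if len(ids) == 1:
        return HaplotypeNetwork(nodes, [], 0)
    _, d = pairwise_step_matrix(haplotype_sequences, ids)
    pairs = sorted(
        ((int(d[i, j]), ids[i], ids[j])
         for i, j in itertools.combinations(range(len(ids)), 2)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    parent = {h: h for h in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[str, str, int]] = []
    total_length = 0
    for _, group in itertools.groupby(pairs, key=lambda t: t[0]):
        group = list(group)
        # component structure frozen at the start of the distance class
        before = {h: find(h) for h in ids}
        merges: list[tuple[str, str]] = []
        for steps, u, v in group:
            if before[u] != before[v]:
                edges.append((u, v, steps))
                merges.append((before[u], before[v]))
        for ru, rv in merges:
            ru, rv = find(ru), find(rv)
            if ru != rv:
                parent[rv] = ru
                total_length += group[0][0]
    return HaplotypeNetwork(nodes, edges, total_length)


@dataclass(frozen=True)
class DiversitySummary:
    """Diversity statistics for one pond (or the pooled "TOTAL" row)."""

    site_id: str
    n: int
    h: int
    hd: float
    pi: float | None = None
    chao1: float | None = None


def summarize_diversity(
    table: HaplotypeCountTable,
    pairwise_steps: np.ndarray | None = None,
    alignment_length: int | None = None,
    with_chao1: bool = True,
) -> list[DiversitySummary]:
    """Per-pond diversity table plus a pooled TOTAL row.

    Nucleotide diversity is filled only when a haplotype step matrix and the
    alignment length are available (i.e. sequences were supplied). Ponds with
    a single genotyped specimen are reported with Hd as NaN.
    """
    if pairwise_steps is not None and alignment_length is None:
        raise ValidationError("alignment_length required with pairwise_steps")
    rows = []
    vectors = [*table.counts, table.pooled()]
    labels = [*table.site_ids, "TOTAL"]
    for label, vector in zip(labels, vectors):
        n = int(vector.sum())
        h = int(np.sum(vector > 0))
        hd = haplotype_diversity(vector) if n >= 2 else float("nan")
        pi = None
        if pairwise_steps is not None and n >= 2:
            pi = nucleotide_diversity(vector, pairwise_steps, alignment_length)
        rows.append(
            DiversitySummary(
                site_id=label,
                n=n,
                h=h,
                hd=hd,
                pi=pi,
                chao1=chao1(vector) if with_chao1 and n >= 1 else None,
            )
        )
    return rows


def write_diversity_table(summaries: Sequence[DiversitySummary], path) -> None:
    """TSV export; Hd shown to 3 decimals and Pi to 5, matching field custom."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("site_id\tn\th\tHd\tPi\tchao1\n")
        for s in summaries:
            pi = "" if s.pi is None else f"{s.pi:.5f}"
            c = "" if s.chao1 is None else f"{c_fmt(s.chao1)}"
            handle.write(f"{s.site_id}\t{s.n}\t{s.h}\t{s.hd:.3f}\t{pi}\t{c}\n")


def c_fmt(value: float) -> str:
    return f"{value:.2f}"
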