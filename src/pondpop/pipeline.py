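"""End-to-end orchestration: diversity -> network -> structure -> assessment.

A single YAML (or dict) configuration names either real input files or a
simulation block, never both. Stages that need sequences (nucleotide
diversity, the haplotype network, the p-distance Mantel test) are skipped
with a logged notice when only a count matrix is supplied. The run report
echoes the configuration and seed so a rerun reproduces it bit-for-bit for
every deterministic stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .assessment import (
    SourceSinkThresholds,
    classify_source_sink,
    glm_fit,
    overwintering_rate,
    radar_profiles,
)
from .diversity import (
    build_msn,
    pairwise_step_matrix,
    summarize_diversity,
    write_diversity_table,
)
from .errors import ConfigError
from .io_survey import (
    counts_from_sequences,
    read_capture_table,
    read_environment_table,
    read_fasta,
    read_haplotype_table,
)
from .simulate import SimulationConfig, simulate_pond_dataset
from .structure import (
    geographic_distances,
    mantel_test,
    nmds,
    pairwise_dissimilarity,
    population_p_distance,
    cut_tree,
    ward_cluster,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "alignment_length": 658,
    "cluster": {"metric": "chao_jaccard", "k": 4},
    "nmds": {"k": 2, "n_restarts": 20, "metric": "bray_curtis"},
    "mantel": {"n_permutations": 1000, "alternative": "greater"},
    "overwinter": {"inclusion_threshold": 10},
    "sourcesink": {},
}


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    config: dict[str, Any]
    seed: int
    version: str
    diversity: list[dict[str, Any]]
    cluster_assignments: dict[str, int] | None = None
    cluster_newick: str | None = None
    nmds_stress: float | None = None
    nmds_coordinates: dict[str, list[float]] | None = None
    mantel: dict[str, Any] | None = None
    network_edges: list[tuple[str, str, int]] | None = None
    network_total_length: int | None = None
    assessment: list[dict[str, Any]] | None = None
    glm: dict[str, Any] | None = None
    skipped: list[str] = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def _merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(source) -> dict[str, Any]:
    """Load configuration from a YAML path or a mapping; apply defaults."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    else:
        raw = dict(source)
    config = _merge(DEFAULT_CONFIG, raw)
    has_inputs = config.get("inputs") is not None
    has_simulation = config.get("simulation") is not None
    if has_inputs and has_simulation:
        raise ConfigError("configure either real inputs or a simulation block, not both")
    if not has_inputs and not has_simulation:
        raise ConfigError("configuration names neither input files nor a simulation block")
    return config


def _require_file(path_value, role: str) -> Path:
    path = Path(path_value)
    if not path.exists():
        raise FileNotFoundError(f"{role} file not found: {path}")
    return path


def run_pipeline(config, outdir=None) -> RunReport:
    """Execute every configured stage in order and assemble the run report.

    When ``outdir`` is given, TSV/Newick/GraphML/JSON artifacts are written
    there; each artifact is a valid standalone input to the matching CLI
    subcommand, so a run is resumable stage by stage.
    """
    config = load_config(config)
    seed = int(config.get("seed", 0))
    alignment_length = int(config.get("alignment_length", 658))
    report = RunReport(
        config=config, seed=seed, version=__version__, diversity=[]
    )

    hap_seqs = None
    ponds = None
    overwinter = None
    if config.get("simulation") is not None:
        sim_kwargs = dict(config["simulation"])
        sim_kwargs.setdefault("seed", seed)
        sim_cfg = SimulationConfig(**sim_kwargs)
        table, alignment, ponds, overwinter = simulate_pond_dataset(sim_cfg)
        table, hap_seqs = counts_from_sequences(alignment)
        alignment_length = sim_cfg.alignment_length
        logger.info("simulated %d ponds (seed %d)", sim_cfg.n_sites, sim_cfg.seed)
    else:
        inputs = config["inputs"]
        if "sequences" in inputs:
            alignment = read_fasta(_require_file(inputs["sequences"], "sequence"))
            table, hap_seqs = counts_from_sequences(alignment)
            alignment_length = alignment.alignment_length
        elif "haplotypes" in inputs:
            table = read_haplotype_table(
                _require_file(inputs["haplotypes"], "haplotype table")
            )
        else:
            raise ConfigError("inputs must name 'haplotypes' or 'sequences'")
        if "environment" in inputs:
            ponds = read_environment_table(
                _require_file(inputs["environment"], "environment table")
            )
        if "captures" in inputs:
            threshold = int(config["overwinter"]["inclusion_threshold"])
            records = read_capture_table(
                _require_file(inputs["captures"], "capture table")
            )
            by_site: dict[str, dict[str, int]] = {}
            for record in records:
                by_site.setdefault(record.site_id, {})[record.season] = record.count
            overwinter = [
                overwintering_rate(
                    seasons.get("autumn", 0),
                    seasons.get("spring", 0),
                    threshold,
                    site_id=site,
                )
                for site, seasons in by_site.items()
            ]

    # --- diversity ------------------------------------------------------
    steps = None
    if hap_seqs is not None:
        ids, steps = pairwise_step_matrix(hap_seqs, order=table.haplotype_ids)
    summaries = summarize_diversity(table, steps, alignment_length if steps is not None else None)
    report.diversity = [
        {
            "site_id": s.site_id,
            "n": s.n,
            "h": s.h,
            "Hd": None if np.isnan(s.hd) else s.hd,
            "Pi": s.pi,
            "chao1": s.chao1,
        }
        for s in summaries
    ]

    # --- haplotype network ----------------------------------------------
    if hap_seqs is not None:
        network = build_msn(hap_seqs, table.haplotype_totals())
        report.network_edges = list(network.edges)
        report.network_total_length = network.total_length
    else:
        report.skipped.append("network: no sequences supplied")
        logger.info("skipping haplotype network: no sequences supplied")
        network = None

    # --- clustering and ordination ---------------------------------------
    cluster_cfg = config["cluster"]
    genetic = pairwise_dissimilarity(table, metric=cluster_cfg.get("metric", "chao_jaccard"))
    tree = ward_cluster(genetic)
    k = int(cluster_cfg.get("k", 4))
    k = min(k, len(tree.leaves))
    report.cluster_assignments = cut_tree(tree, k)
    report.cluster_newick = tree.to_newick()

    nmds_cfg = config["nmds"]
    ordination_input = pairwise_dissimilarity(
        table, metric=nmds_cfg.get("metric", "bray_curtis")
    )
    if ordination_input.n >= 3:
        result = nmds(
            ordination_input,
            k=int(nmds_cfg.get("k", 2)),
            n_restarts=int(nmds_cfg.get("n_restarts", 20)),
            seed=seed,
        )
        report.nmds_stress = result.stress
        report.nmds_coordinates = {
            label: [float(x) for x in row]
            for label, row in zip(result.labels, result.coordinates)
        }
    else:
        report.skipped.append("nmds: fewer than 3 sites")

    # --- isolation by distance -------------------------------------------
    if steps is not None and ponds is not None:
        pond_ids = {p.site_id for p in ponds}
        usable = [s for s in table.site_ids if s in pond_ids]
        if len(usable) >= 4:
            genetic_d = population_p_distance(table, steps, alignment_length)
            genetic_d = genetic_d.submatrix(
                [s for s in usable if s in genetic_d.labels]
            )
            geo = geographic_distances(
                [p for p in ponds if p.site_id in genetic_d.labels]
            )
            geo = geo.submatrix(genetic_d.labels)
            mantel_cfg = config["mantel"]
            result = mantel_test(
                genetic_d,
                geo,
                n_permutations=int(mantel_cfg.get("n_permutations", 1000)),
                seed=seed,
                alternative=mantel_cfg.get("alternative", "greater"),
            )
            report.mantel = dataclasses.asdict(result)
        else:
            report.skipped.append("mantel: fewer than 4 ponds with coordinates")
    else:
        reason = "no sequences supplied" if steps is None else "no environment table"
        report.skipped.append(f"mantel: {reason}")
        logger.info("skipping Mantel test: %s", reason)

    # --- assessment -------------------------------------------------------
    if ponds is not None and overwinter is not None:
        by_site = {r.site_id: r for r in overwinter}
        hd_by_site = {
            s.site_id: (0.0 if np.isnan(s.hd) else s.hd)
            for s in summaries
            if s.site_id != "TOTAL"
        }
        cohort = [
            p for p in ponds
            if p.site_id in by_site
        ]
        densities = {p.site_id: float(by_site[p.site_id].autumn_count) for p in cohort}
        hds = {p.site_id: hd_by_site.get(p.site_id, 0.0) for p in cohort}
        profiles = radar_profiles(cohort, densities, hds)
        threshold_cfg = SourceSinkThresholds(**config.get("sourcesink", {}))
        calls = [
            classify_source_sink(profiles[site], by_site[site], threshold_cfg)
            for site in sorted(profiles)
        ]
        report.assessment = [
            {
                "site_id": c.site_id,
                "label": c.label,
                "density_grade": c.density_grade,
                "hd_grade": c.hd_grade,
                "rate": c.rate,
                "included": c.included,
                "flags": list(c.flags),
            }
            for c in calls
        ]
        included = [r for r in overwinter if r.included and r.site_id in {p.site_id for p in cohort}]
        if len(included) >= 3:
            concrete = {p.site_id: p.concrete_revetment_rate for p in cohort}
            fit = glm_fit(
                (
                    [r.spring_count for r in included],
                    [r.autumn_count for r in included],
                ),
                [[concrete[r.site_id]] for r in included],
                family="binomial",
            )
            report.glm = {
                "family": fit.family,
                "coefficients": fit.coefficients.tolist(),
                "standard_errors": fit.standard_errors.tolist(),
                "p_values": fit.p_values.tolist(),
                "converged": fit.converged,
            }
    else:
        report.skipped.append("assessment: environment or capture data missing")

    # --- artifacts --------------------------------------------------------
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_diversity_table(summaries, outdir / "diversity.tsv")
        genetic.write_tsv(outdir / "genetic_dissimilarity.tsv")
        (outdir / "dendrogram.nwk").write_text(report.cluster_newick + "\n")
        if network is not None:
            network.write_edgelist(outdir / "network_edges.tsv")
            network.write_graphml(outdir / "network.graphml")
        report.write(outdir / "report.json")
    return report
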