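"""End-to-end orchestration: simulate/load → predict → build → screen → enrich.

`run_all` executes the stages in order, writes every intermediate in a plain
core_io format under the output directory, and returns a machine-readable
RunSummary. The summary JSON is a pure function of the run configuration
(byte-identical across reruns; the output directory itself is never embedded),
and every dropped record — self-loops, symbols absent from the PPI, query
genes outside the enrichment universe — is counted in it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import core_io, predict, synth, topology
from .core_io import (
    GeneSetCollection,
    InteractionNetwork,
    KnownTargetSet,
    load_anti_ra_overlap,
    load_omim_ra_targets,
)
from .enrich import EnrichmentRow, enrich
from .predict import KernelSpec, herb_profile, overlap_with_drug_targets, score_matrix
from .synth import PRESETS, SyntheticBundle, SyntheticConfig
from .topology import ScreenResult, build_target_network, screen_targets, topology_frame

logger = logging.getLogger("herbnet")

__all__ = ["RunConfig", "RunSummary", "run_all", "report", "fixture_checks"]


@dataclass
class RunConfig:
    """One resolved pipeline configuration.

    Exactly one of ``preset``, ``synth`` or ``inputs`` selects where the data
    come from: a named synthetic preset, an explicit synthetic configuration,
    or a mapping of input file paths (``ppi`` [list], ``compounds``,
    ``panel``, ``known_targets`` [list of (label, path)], ``gene_sets``,
    ``fingerprint_length``).
    """

    preset: str | None = None
    synth: SyntheticConfig | None = None
    inputs: dict | None = None
    top_k: int = 100
    kernel: str = "gaussian-of-distance"
    seed: int = 0
    ease: bool = False
    top_sets: int = 10

    def __post_init__(self) -> None:
        supplied = sum(x is not None for x in (self.preset, self.synth, self.inputs))
        if supplied != 1:
            raise ValueError("exactly one of preset, synth or inputs must be supplied")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.preset is not None:
            if self.preset not in PRESETS:
                raise ValueError(f"unknown preset {self.preset!r}; have {sorted(PRESETS)}")
            self.synth = dataclasses.replace(PRESETS[self.preset], seed=self.seed)
            # keep preset label for provenance; synth now carries the config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = SyntheticConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw["synth"].items()
                }
            )
        return cls(**raw)


@dataclass
class RunSummary:
    herbs: dict[str, int]
    total_compounds: int
    n_proteins: int
    n_panel_drugs: int
    putative_count: int
    known_target_count: int
    known_overlap_count: int
    known_overlap_pct: float
    target_network_nodes: int
    target_network_edges: int
    hub_threshold: float
    hub_count: int
    major_hub_count: int
    candidate_count: int
    feature_medians: dict[str, float]
    top_sets: list[dict]
    dropped: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _load_inputs(inputs: dict) -> SyntheticBundle:
    """Assemble a bundle-shaped object from user-supplied files."""
    fp_len = int(inputs.get("fingerprint_length", 1024))
    network = core_io.load_ppi(
        inputs["ppi"] if isinstance(inputs["ppi"], (list, tuple)) else [inputs["ppi"]]
    )
    compounds, _ = core_io.load_compound_catalogue(inputs["compounds"], fp_len)
    panel = core_io.load_panel(inputs["panel"], fp_len)
    known = core_io.load_known_targets(inputs["known_targets"])
    gene_sets = core_io.read_gmt(inputs["gene_sets"])
    return SyntheticBundle(
        config=None,  # type: ignore[arg-type]
        network=network,
        panel=panel,
        compounds=compounds,
        known_targets=known,
        gene_sets=gene_sets,
        truth=synth.GroundTruth(),
    )


def run_all(config: RunConfig, outdir: str | Path) -> RunSummary:
    """Execute the full pipeline and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_all(config, outdir)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _stage(name: str):
    logger.info("stage: %s", name)


def _run_all(config: RunConfig, outdir: Path) -> RunSummary:
    dropped: dict[str, int] = {}

    _stage("simulate/load inputs")
    try:
        if config.synth is not None:
            bundle = synth.generate_bundle(config.synth)
            synth.write_bundle(bundle, outdir / "inputs")
        else:
            bundle = _load_inputs(config.inputs)
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc
    dropped["ppi_self_loops"] = bundle.network.dropped_self_loops

    _stage("predict targets")
    try:
        kernel = KernelSpec(kind=config.kernel)
        nodes, scores = score_matrix(bundle.compounds, bundle.panel, bundle.network, kernel)
        herbs = sorted({c.herb for c in bundle.compounds})
        profiles = [
            herb_profile(h, bundle.compounds, nodes, scores, k=config.top_k) for h in herbs
        ]
    except Exception as exc:
        raise RuntimeError(f"stage 'predict' failed: {exc}") from exc

    profile_dir = outdir / "profiles"
    profile_dir.mkdir(exist_ok=True)
    for p in profiles:
        with open(profile_dir / f"{p.herb}.tsv", "w") as fh:
            fh.write("symbol\tscore\n")
            for sym, sc in p.entries:
                fh.write(f"{sym}\t{sc:.6f}\n")
    if len(profiles) >= 2:
        predict.profile_overlap_matrix(profiles).to_csv(outdir / "profile_overlaps.tsv", sep="\t")

    # Pipeline-level putative targets = every ranked protein with a defined
    # concordance score for at least one compound (the herb profiles are the
    # top-k views used for the herb-overlap analysis, not the screening set).
    defined = np.zeros(len(nodes), dtype=bool)
    for vec in scores.values():
        defined |= ~np.isnan(vec)
    putative = {nodes[i] for i in range(len(nodes)) if defined[i]}
    overlap = overlap_with_drug_targets(putative, bundle.known_targets.members)

    _stage("build target network")
    try:
        target_net = build_target_network(putative, bundle.known_targets, bundle.network)
    except Exception as exc:
        raise RuntimeError(f"stage 'build-net' failed: {exc}") from exc
    dropped["target_members_absent_from_ppi"] = len(
        (putative | bundle.known_targets.members) - bundle.network.nodes
    )

    _stage("screen hubs")
    try:
        screen: ScreenResult = screen_targets(target_net, putative)
    except Exception as exc:
        raise RuntimeError(f"stage 'screen' failed: {exc}") from exc

    records = topology.topology(target_net)
    topology_frame(records).to_csv(outdir / "topology.tsv", sep="\t")
    if screen.hubs:
        core_io.write_graphml(
            topology.hub_subnetwork(target_net, screen.hubs), outdir / "hub_network.graphml"
        )
    (outdir / "screen.json").write_text(
        json.dumps(
            {
                "hub_threshold": screen.hub_threshold,
                "feature_medians": screen.feature_medians,
                "hubs": sorted(screen.hubs),
                "major_hubs": sorted(screen.major_hubs),
                "candidates": sorted(screen.candidates),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    _stage("pathway enrichment")
    try:
        universe = bundle.gene_sets.universe or bundle.network.nodes
        dropped["enrich_query_outside_universe"] = len(screen.candidates - set(universe))
        rows = enrich(screen.candidates, bundle.gene_sets, universe, ease=config.ease)
    except Exception as exc:
        raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc

    with open(outdir / "enrichment.tsv", "w") as fh:
        fh.write("set_id\tset_name\tk\tK\tn\tN\tp_raw\tp_bonferroni\toverlap_genes\n")
        for r in rows:
            fh.write(
                f"{r.set_id}\t{r.set_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_raw:.6g}\t{r.p_bonferroni:.6g}\t{'/'.join(r.overlap_genes)}\n"
            )

    summary = RunSummary(
        herbs={h: sum(1 for c in bundle.compounds if c.herb == h) for h in herbs},
        total_compounds=len(bundle.compounds),
        n_proteins=len(bundle.network),
        n_panel_drugs=len(bundle.panel),
        putative_count=len(putative),
        known_target_count=len(bundle.known_targets),
        known_overlap_count=overlap.n_overlap,
        known_overlap_pct=overlap.percentage,
        target_network_nodes=len(target_net),
        target_network_edges=target_net.number_of_edges(),
        hub_threshold=screen.hub_threshold,
        hub_count=len(screen.hubs),
        major_hub_count=len(screen.major_hubs),
        candidate_count=len(screen.candidates),
        feature_medians=screen.feature_medians,
        top_sets=[
            {"set_id": r.set_id, "p_bonferroni": r.p_bonferroni, "k": r.k}
            for r in rows[: config.top_sets]
        ],
        dropped=dropped,
    )
    (outdir / "summary.json").write_text(summary.to_json())
    return summary


def fixture_checks() -> dict[str, int]:
    """Counts derivable from the packaged curated fixtures."""
    _, distinct = load_anti_ra_overlap()
    omim = load_omim_ra_targets()
    return {
        "anti_ra_overlap_distinct_targets": distinct,
        "omim_ra_target_count": len(omim),
    }


def report(summary: RunSummary) -> str:
    """Human-readable run report with fixture-derived counts alongside."""
    fx = fixture_checks()
    lines = [
        "== pipeline run report ==",
        "per-herb compound counts: "
        + ", ".join(f"{h}={n}" for h, n in sorted(summary.herbs.items())),
        f"total compounds: {summary.total_compounds}",
        f"proteome size: {summary.n_proteins}",
        f"putative targets (union of herb profiles): {summary.putative_count}",
        f"overlap with known disease targets: {summary.known_overlap_count} "
        f"({summary.known_overlap_pct:.2f}%)",
        f"hubs: {summary.hub_count} (degree > {summary.hub_threshold:g})",
        f"major hubs: {summary.major_hub_count}",
        f"candidate targets: {summary.candidate_count}",
        "feature medians over hubs: "
        + ", ".join(f"{k}={v:.4g}" for k, v in sorted(summary.feature_medians.items())),
        "top enriched sets: "
        + "; ".join(f"{d['set_id']} (p={d['p_bonferroni']:.3g})" for d in summary.top_sets[:5]),
        "-- fixture checks --",
        f"curated herb/anti-RA-drug shared targets: {fx['anti_ra_overlap_distinct_targets']}",
        f"OMIM rheumatoid-arthritis symbols: {fx['omim_ra_target_count']}",
    ]
    return "\n".join(lines)
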