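"""Seeded synthetic inputs with planted ground truth.

The generator emulates the statistical structure the analysis chain assumes:

* a druggable proteome as a connected scale-free interaction network,
* a reference drug panel whose target sets are network-localised modules
  (functional relatedness encoded as bounded shortest-path radius),
* herb compounds whose fingerprints are noisy copies of panel-drug
  fingerprints (each compound has exactly one planted parent drug),
* a disease target set partially drawn from the planted drug modules, and
* a gene-set collection containing one positive-control set equal to the
  disease module (set id ``PLANTED_DISEASE``) plus random sets.

One root seed deterministically spawns independent per-stage substreams, so
e.g. changing the number of gene sets never perturbs the network. The whole
bundle is a pure function of the configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .core_io import (
    CompoundRecord,
    GeneSet,
    GeneSetCollection,
    InteractionNetwork,
    KnownTargetSet,
    ReferenceDrug,
    write_compound_catalogue,
    write_edge_list,
    write_gmt,
    write_panel,
    write_symbol_list,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticBundle",
    "PRESETS",
    "generate_ppi",
    "generate_panel",
    "generate_herbs",
    "generate_disease_targets",
    "generate_gene_sets",
    "generate_bundle",
    "write_bundle",
]

# stage indices for the spawned substreams
_STAGE_PPI, _STAGE_PANEL, _STAGE_HERBS, _STAGE_DISEASE, _STAGE_SETS = range(5)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; every stage is a pure function of this."""

    seed: int = 0
    n_proteins: int = 1746
    ppi_model: str = "scale-free"  # or "block-model"
    # mean number of edges a new protein attaches with (drawn per node from a
    # geometric distribution); 8 gives mean degree ~16, matching the density
    # of merged multi-database human interactomes, and the heavy-tailed
    # attachment produces the deep, graded k-core hierarchy real
    # interactomes show
    ba_attachment: int = 8
    block_sizes: tuple[int, ...] = ()  # block-model partition (must sum to n_proteins)
    block_p_in: float = 0.05
    block_p_out: float = 0.002
    n_panel_drugs: int = 50
    targets_per_drug: int = 4
    target_module_size: int = 8
    target_module_radius: int = 2
    n_herbs: int = 5
    compounds_per_herb: tuple[int, ...] = (22, 122, 39, 65, 203)
    fingerprint_length: int = 512
    fingerprint_on_bits: int = 48
    bit_flip_rate: float = 0.05
    n_disease_targets: int = 208
    disease_module_overlap: float = 0.5
    n_gene_sets: int = 50
    gene_set_size_range: tuple[int, int] = (10, 100)

    def __post_init__(self) -> None:
        counts = {
            "n_proteins": self.n_proteins,
            "n_panel_drugs": self.n_panel_drugs,
            "targets_per_drug": self.targets_per_drug,
            "target_module_size": self.target_module_size,
            "target_module_radius": self.target_module_radius,
            "n_herbs": self.n_herbs,
            "fingerprint_length": self.fingerprint_length,
            "fingerprint_on_bits": self.fingerprint_on_bits,
            "n_disease_targets": self.n_disease_targets,
            "n_gene_sets": self.n_gene_sets,
        }
        for name, val in counts.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        for name, val in (
            ("bit_flip_rate", self.bit_flip_rate),
            ("disease_module_overlap", self.disease_module_overlap),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if len(self.compounds_per_herb) != self.n_herbs:
            raise ValueError("compounds_per_herb must have one entry per herb")
        if any(c <= 0 for c in self.compounds_per_herb):
            raise ValueError("compounds_per_herb entries must be positive")
        if self.n_disease_targets > self.n_proteins:
            raise ValueError("n_disease_targets exceeds n_proteins")
        if self.targets_per_drug > self.target_module_size:
            raise ValueError("targets_per_drug exceeds target_module_size")
        if self.fingerprint_on_bits > self.fingerprint_length:
            raise ValueError("fingerprint_on_bits exceeds fingerprint_length")
        lo, hi = self.gene_set_size_range
        if not (0 < lo <= hi <= self.n_proteins):
            raise ValueError("gene_set_size_range infeasible")

    def stage_rng(self, stage: int) -> np.random.Generator:
        child = np.random.SeedSequence(self.seed).spawn(5)[stage]
        return np.random.default_rng(child)


PRESETS: dict[str, SyntheticConfig] = {
    # mirrors the study scale: 5 herbs / 451 compounds / 1746 proteins /
    # 208 disease targets
    "study_scale": SyntheticConfig(),
    "toy": SyntheticConfig(
        n_proteins=50,
        ba_attachment=2,
        n_panel_drugs=8,
        targets_per_drug=2,
        target_module_size=4,
        n_herbs=2,
        compounds_per_herb=(6, 6),
        fingerprint_length=64,
        fingerprint_on_bits=10,
        n_disease_targets=10,
        n_gene_sets=10,
        gene_set_size_range=(3, 8),
    ),
}


@dataclass
class GroundTruth:
    """Planted structure: who is whose parent and where the modules are."""

    compound_parent: dict[str, str] = field(default_factory=dict)
    drug_modules: dict[str, frozenset[str]] = field(default_factory=dict)
    disease_module: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        return {
            "compound_parent": dict(sorted(self.compound_parent.items())),
            "drug_modules": {k: sorted(v) for k, v in sorted(self.drug_modules.items())},
            "disease_module": sorted(self.disease_module),
        }


def _symbol(i: int) -> str:
    return f"G{i:05d}"


def _preferential_attachment_graph(
    n: int, mean_m: int, rng: np.random.Generator
) -> nx.Graph:
    """Barabási–Albert-style growth with per-node attachment count.

    Each new node attaches to m ~ Geometric(1/mean_m) existing nodes chosen
    preferentially by degree. The heavy-tailed attachment keeps the heavy
    degree tail while producing a deep, graded k-core hierarchy (a fixed-m
    model is m-degenerate, so every core index saturates at m, and the median
    screen on k-core then degenerates).
    """
    g = nx.Graph()
    g.add_node(0)
    repeated: list[int] = [0]  # nodes repeated proportionally to degree
    for v in range(1, n):
        m = min(int(rng.geometric(1.0 / mean_m)), v)
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(repeated[int(rng.integers(len(repeated)))])
        for t in targets:
            g.add_edge(v, t)
            repeated.extend((v, t))
    return g


def generate_ppi(config: SyntheticConfig) -> InteractionNetwork:
    """Connected undirected simple protein interaction graph.

    ``scale-free`` uses preferential attachment with per-node attachment
    counts (connected by construction); ``block-model`` uses a stochastic
    block model whose components, if any, are deterministically bridged.
    """
    rng = config.stage_rng(_STAGE_PPI)
    n = config.n_proteins
    if config.ppi_model == "scale-free":
        if config.ba_attachment < 1 or config.ba_attachment >= n:
            raise ValueError("ba_attachment incompatible with a connected graph")
        g = _preferential_attachment_graph(n, config.ba_attachment, rng)
    elif config.ppi_model == "block-model":
        sizes = config.block_sizes or (n,)
        if sum(sizes) != n:
            raise ValueError("block_sizes must sum to n_proteins")
        k = len(sizes)
        p = [
            [config.block_p_in if i == j else config.block_p_out for j in range(k)]
            for i in range(k)
        ]
        g = nx.stochastic_block_model(sizes, p, seed=rng)
        g = nx.Graph(g)  # strip block metadata/multi info
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: c[0])
        for a, b in zip(comps, comps[1:]):  # deterministic bridges
            g.add_edge(a[0], b[0])
    else:
        raise ValueError(f"unknown ppi_model {config.ppi_model!r}")
    g = nx.relabel_nodes(g, {i: _symbol(i) for i in g.nodes})
    net = InteractionNetwork()
    for node in g.nodes:
        net.add_node(node)
    for u, v in g.edges:
        net.add_edge(u, v, {"synthetic"})
    return net


def _random_fingerprint(rng: np.random.Generator, config: SyntheticConfig) -> frozenset[int]:
    bits = rng.choice(config.fingerprint_length, size=config.fingerprint_on_bits, replace=False)
    return frozenset(int(b) for b in bits)


def generate_panel(
    config: SyntheticConfig, network: InteractionNetwork
) -> tuple[list[ReferenceDrug], GroundTruth]:
    """Reference drugs with random fingerprints and network-localised targets.

    Each drug's module is a centre node plus neighbours, so all module members
    are within pairwise shortest-path distance 2 (more generally within the
    configured radius via a ball of half that radius around the centre).
    """
    if config.target_module_size > config.n_proteins:
        raise ValueError("target_module_size exceeds n_proteins")
    rng = config.stage_rng(_STAGE_PANEL)
    g = network.graph
    ball_radius = max(1, config.target_module_radius // 2)
    nodes = sorted(g.nodes)
    centres = [
        v
        for v in nodes
        if len(nx.single_source_shortest_path_length(g, v, cutoff=ball_radius)) >= config.target_module_size
    ]
    if not centres:
        raise ValueError("no node has a large enough neighbourhood for a target module")
    drugs: list[ReferenceDrug] = []
    truth = GroundTruth()
    for i in range(config.n_panel_drugs):
        centre = centres[int(rng.integers(len(centres)))]
        ball = sorted(nx.single_source_shortest_path_length(g, centre, cutoff=ball_radius))
        ball.remove(centre)
        extra = rng.choice(len(ball), size=config.target_module_size - 1, replace=False)
        module = frozenset([centre] + [ball[int(j)] for j in extra])
        targets = rng.choice(sorted(module), size=config.targets_per_drug, replace=False)
        drug_id = f"D{i:03d}"
        drugs.append(
            ReferenceDrug(
                drug_id=drug_id,
                fingerprint=_random_fingerprint(rng, config),
                fingerprint_length=config.fingerprint_length,
                targets=frozenset(str(t) for t in targets),
                indication="synthetic",
            )
        )
        truth.drug_modules[drug_id] = module
    return drugs, truth


def generate_herbs(
    config: SyntheticConfig, panel: list[ReferenceDrug]
) -> tuple[list[CompoundRecord], GroundTruth]:
    """Herb compounds as noisy copies of panel-drug fingerprints.

    Every compound gets exactly one parent drug (recorded in the ground
    truth); its fingerprint is the parent's with every bit independently
    flipped at ``bit_flip_rate``.
    """
    rng = config.stage_rng(_STAGE_HERBS)
    truth = GroundTruth()
    compounds: list[CompoundRecord] = []
    L = config.fingerprint_length
    for h, n_comp in enumerate(config.compounds_per_herb):
        herb = f"herb{h + 1}"
        for j in range(n_comp):
            parent = panel[int(rng.integers(len(panel)))]
            on = np.zeros(L, dtype=bool)
            on[list(parent.fingerprint)] = True
            flips = rng.random(L) < config.bit_flip_rate
            fp = frozenset(int(b) for b in np.nonzero(on ^ flips)[0])
            cid = f"{herb}_c{j:03d}"
            compounds.append(
                CompoundRecord(
                    compound_id=cid,
                    herb=herb,
                    fingerprint=fp,
                    fingerprint_length=L,
                    name=f"synthetic compound {cid}",
                )
            )
            truth.compound_parent[cid] = parent.drug_id
    return compounds, truth


def generate_disease_targets(
    config: SyntheticConfig, network: InteractionNetwork, truth: GroundTruth
) -> tuple[KnownTargetSet, GroundTruth]:
    """Disease target set: a fraction from planted drug modules, rest uniform.

    ``disease_module_overlap`` of the symbols are drawn from the union of the
    planted drug-target modules; the remainder uniformly from the not yet
    selected proteome. The resulting member set is recorded as the disease
    module in the ground truth (and later doubles as the positive-control
    gene set).
    """
    rng = config.stage_rng(_STAGE_DISEASE)
    pool = sorted(set().union(*truth.drug_modules.values())) if truth.drug_modules else []
    n_mod = round(config.disease_module_overlap * config.n_disease_targets)
    if n_mod > len(pool):
        raise ValueError(
            f"disease_module_overlap infeasible: need {n_mod} module symbols, "
            f"planted modules cover {len(pool)}"
        )
    chosen: list[str] = []
    if n_mod:
        idx = rng.choice(len(pool), size=n_mod, replace=False)
        chosen.extend(pool[int(i)] for i in idx)
    rest_pool = sorted(set(network.nodes) - set(chosen))
    n_rest = config.n_disease_targets - len(chosen)
    if n_rest:
        idx = rng.choice(len(rest_pool), size=n_rest, replace=False)
        chosen.extend(rest_pool[int(i)] for i in idx)
    members = set(chosen)
    module_part = set(chosen[:n_mod])
    tags = {
        m: ({"planted_module"} if m in module_part else set()) | {"synthetic"}
        for m in members
    }
    kts = KnownTargetSet(disease="synthetic", members=members, source_tags=tags)
    truth.disease_module = frozenset(members)
    return kts, truth


def generate_gene_sets(
    config: SyntheticConfig, network: InteractionNetwork, truth: GroundTruth
) -> GeneSetCollection:
    """Random gene sets plus the planted positive control ``PLANTED_DISEASE``."""
    rng = config.stage_rng(_STAGE_SETS)
    nodes = sorted(network.nodes)
    sets = [
        GeneSet(
            set_id="PLANTED_DISEASE",
            name="planted disease module (positive control)",
            members=frozenset(truth.disease_module),
        )
    ]
    lo, hi = config.gene_set_size_range
    for i in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(nodes), size=size, replace=False)
        sets.append(
            GeneSet(
                set_id=f"RAND{i:03d}",
                name=f"random gene set {i}",
                members=frozenset(nodes[int(j)] for j in idx),
            )
        )
    return GeneSetCollection(sets=sets)


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    network: InteractionNetwork
    panel: list[ReferenceDrug]
    compounds: list[CompoundRecord]
    known_targets: KnownTargetSet
    gene_sets: GeneSetCollection
    truth: GroundTruth


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate every pipeline input from one configuration (pure function)."""
    network = generate_ppi(config)
    panel, truth = generate_panel(config, network)
    compounds, herb_truth = generate_herbs(config, panel)
    truth.compound_parent = herb_truth.compound_parent
    known, truth = generate_disease_targets(config, network, truth)
    gene_sets = generate_gene_sets(config, network, truth)
    return SyntheticBundle(
        config=config,
        network=network,
        panel=panel,
        compounds=compounds,
        known_targets=known,
        gene_sets=gene_sets,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write all inputs in the formats the loaders read, plus ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": outdir / "ppi.tsv",
        "compounds": outdir / "compounds.tsv",
        "panel": outdir / "panel.tsv",
        "known_targets": outdir / "known_targets.txt",
        "gene_sets": outdir / "gene_sets.gmt",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "config.json",
    }
    write_edge_list(bundle.network, paths["ppi"])
    write_compound_catalogue(bundle.compounds, paths["compounds"])
    write_panel(bundle.panel, paths["panel"])
    write_symbol_list(bundle.known_targets.members, paths["known_targets"])
    write_gmt(bundle.gene_sets, paths["gene_sets"])
    paths["ground_truth"].write_text(
        json.dumps(bundle.truth.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    paths["config"].write_text(
        json.dumps(dataclasses.asdict(bundle.config), indent=2, sort_keys=True, default=list)
        + "\n"
    )
    return paths
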