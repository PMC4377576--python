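"""Domain types and file I/O for the network-pharmacology pipeline.

Tabular inputs are plain TSV, interaction networks come from 2-3 column edge
lists or SIF files and are exported as GraphML, and gene sets use the GMT
format. Gene identifiers are treated as plain case-insensitive symbols and
normalised to upper case everywhere; no cross-database identifier mapping is
attempted. Edge provenance (which source database contributed an interaction)
is kept as a set of tags per edge, never as parallel edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("herbnet")

__all__ = [
    "CompoundRecord",
    "ReferenceDrug",
    "KnownTargetSet",
    "InteractionNetwork",
    "GeneSet",
    "GeneSetCollection",
    "AntiRADrugOverlapRow",
    "normalize_symbol",
    "smiles_to_fingerprint",
    "load_compound_catalogue",
    "write_compound_catalogue",
    "load_panel",
    "write_panel",
    "load_ppi",
    "write_edge_list",
    "load_known_targets",
    "write_symbol_list",
    "load_symbol_list",
    "load_anti_ra_overlap",
    "load_omim_ra_targets",
    "read_gmt",
    "write_gmt",
    "read_graphml",
    "write_graphml",
]


def normalize_symbol(symbol: str) -> str:
    """Case-insensitive gene symbols, normalised to upper case."""
    return str(symbol).strip().upper()


def _parse_bits(text: str) -> frozenset[int]:
    text = text.strip()
    if not text:
        return frozenset()
    for sep in (";", ",", " "):
        if sep in text:
            return frozenset(int(tok) for tok in text.split(sep) if tok.strip())
    return frozenset([int(text)])


def _format_bits(bits: Iterable[int]) -> str:
    return ";".join(str(b) for b in sorted(bits))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    """One herb compound: the query side of target prediction.

    The fingerprint is an abstract fixed-length binary feature set, stored as
    the set of "on" bit indices.
    """

    compound_id: str
    herb: str
    fingerprint: frozenset[int]
    fingerprint_length: int
    name: str = ""

    def __post_init__(self) -> None:
        if not self.herb:
            raise ValueError(f"compound {self.compound_id!r}: herb label is empty")
        if self.fingerprint_length <= 0:
            raise ValueError("fingerprint_length must be positive")
        bad = [b for b in self.fingerprint if b < 0 or b >= self.fingerprint_length]
        if bad:
            raise ValueError(
                f"compound {self.compound_id!r}: fingerprint bits {sorted(bad)} "
                f"out of range [0, {self.fingerprint_length})"
            )


@dataclass(frozen=True)
class ReferenceDrug:
    """Reference-panel drug with fingerprint and known target symbols.

    The panel defines both the drug space (for chemical similarity) and the
    target space (for network proximity).
    """

    drug_id: str
    fingerprint: frozenset[int]
    fingerprint_length: int
    targets: frozenset[str]
    indication: str = ""

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"drug {self.drug_id!r}: target set is empty")
        object.__setattr__(
            self, "targets", frozenset(normalize_symbol(t) for t in self.targets)
        )


@dataclass
class KnownTargetSet:
    """Disease-associated gene symbols with per-symbol source provenance."""

    disease: str
    members: set[str] = field(default_factory=set)
    source_tags: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = {normalize_symbol(m) for m in self.members}
        self.source_tags = {
            normalize_symbol(k): set(v) for k, v in self.source_tags.items()
        }
        for m in self.members:
            if not self.source_tags.get(m):
                raise ValueError(f"member {m!r} has no source tag")

    @property
    def per_source_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for tags in self.source_tags.values():
            for tag in tags:
                counts[tag] = counts.get(tag, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.members)


class InteractionNetwork:
    """Undirected simple graph of gene symbols with per-edge source tags.

    Invariants: no self-loops, no parallel edges; an edge merged from k
    sources appears once with k provenance tags.
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()
        self.dropped_self_loops = 0

    # -- construction -----------------------------------------------------
    def add_node(self, symbol: str) -> None:
        self.graph.add_node(normalize_symbol(symbol))

    def add_edge(self, u: str, v: str, sources: Iterable[str] = ()) -> bool:
        """Add/merge an undirected edge; returns False for dropped self-loops."""
        u, v = normalize_symbol(u), normalize_symbol(v)
        if u == v:
            self.dropped_self_loops += 1
            return False
        tags = set(sources)
        if self.graph.has_edge(u, v):
            self.graph.edges[u, v]["sources"] |= tags
        else:
            self.graph.add_edge(u, v, sources=tags)
        return True

    # -- views -------------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def edge_sources(self, u: str, v: str) -> set[str]:
        return set(self.graph.edges[normalize_symbol(u), normalize_symbol(v)]["sources"])

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        if self.nodes != other.nodes or self.edges != other.edges:
            return False
        return all(
            self.edge_sources(u, v) == other.edge_sources(u, v)
            for u, v in self.graph.edges
        )

    def induced(self, symbols: Iterable[str]) -> "InteractionNetwork":
        """Induced subgraph on the given symbols (those present in the graph)."""
        keep = {normalize_symbol(s) for s in symbols} & set(self.graph.nodes)
        return InteractionNetwork(self.graph.subgraph(keep).copy())


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")
        object.__setattr__(
            self, "members", frozenset(normalize_symbol(m) for m in self.members)
        )


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene-set ids: {dupes}")
        if self.universe is not None:
            self.universe = {normalize_symbol(s) for s in self.universe}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass(frozen=True)
class AntiRADrugOverlapRow:
    """One curated putative target shared between formula herbs and a known
    anti-rheumatoid-arthritis drug (compiled from the Therapeutic Target
    Database)."""

    herbs: frozenset[str]
    target_name: str
    target_symbol: str
    known_drug: str
    indication: str
    target_class: str

    def __post_init__(self) -> None:
        if not self.target_symbol:
            raise ValueError("target_symbol is empty")


# ---------------------------------------------------------------------------
# optional chemistry bridge (kept isolated so the core never needs rdkit)
# ---------------------------------------------------------------------------


def smiles_to_fingerprint(smiles: str, n_bits: int) -> frozenset[int]:
    """Morgan (radius 2) fingerprint of a SMILES string, as on-bit indices.

    Requires the optional rdkit dependency; everything else in the package
    works with pre-computed binary fingerprints.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "structure-string conversion requires the optional 'chem' extra (rdkit)"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    return frozenset(gen.GetFingerprint(mol).GetOnBits())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def load_compound_catalogue(
    path: str | Path, fingerprint_length: int
) -> tuple[list[CompoundRecord], dict]:
    """Read a compound catalogue TSV.

    Requires columns ``compound_id`` and ``herb`` plus either ``fingerprint``
    (separator-joined on-bit indices) or ``structure`` (SMILES, needs rdkit).
    Returns the validated records and a summary with per-herb counts and the
    total.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        return [], {"per_herb": {}, "total": 0}
    for col in ("compound_id", "herb"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "fingerprint" not in df.columns and "structure" not in df.columns:
        raise ValueError(f"{path}: need a 'fingerprint' or 'structure' column")

    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        cid = row["compound_id"].strip()
        if cid in seen:
            raise ValueError(f"{path}: duplicate compound_id {cid!r}")
        seen.add(cid)
        if "fingerprint" in df.columns and row["fingerprint"].strip():
            bits = _parse_bits(row["fingerprint"])
        elif "structure" in df.columns and row["structure"].strip():
            bits = smiles_to_fingerprint(row["structure"], fingerprint_length)
        else:
            raise ValueError(f"{path}: row {idx + 2}: no fingerprint or structure")
        try:
            rec = CompoundRecord(
                compound_id=cid,
                herb=row["herb"].strip(),
                fingerprint=bits,
                fingerprint_length=fingerprint_length,
                name=row["name"].strip() if "name" in df.columns else "",
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx + 2}: {exc}") from exc
        records.append(rec)

    per_herb: dict[str, int] = {}
    for rec in records:
        per_herb[rec.herb] = per_herb.get(rec.herb, 0) + 1
    return records, {"per_herb": per_herb, "total": len(records)}


def write_compound_catalogue(records: Sequence[CompoundRecord], path: str | Path) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "herb": r.herb,
            "name": r.name,
            "fingerprint": _format_bits(r.fingerprint),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["compound_id", "herb", "name", "fingerprint"]).to_csv(
        path, sep="\t", index=False
    )


def load_panel(path: str | Path, fingerprint_length: int) -> list[ReferenceDrug]:
    """Read a reference drug panel TSV (drug_id, fingerprint, targets[, indication])."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    drugs: list[ReferenceDrug] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        did = row["drug_id"].strip()
        if did in seen:
            raise ValueError(f"{path}: duplicate drug_id {did!r}")
        seen.add(did)
        drugs.append(
            ReferenceDrug(
                drug_id=did,
                fingerprint=_parse_bits(row["fingerprint"]),
                fingerprint_length=fingerprint_length,
                targets=frozenset(
                    t for t in row["targets"].split(";") if t.strip()
                ),
                indication=row.get("indication", "") if "indication" in df.columns else "",
            )
        )
    return drugs


def write_panel(drugs: Sequence[ReferenceDrug], path: str | Path) -> None:
    rows = [
        {
            "drug_id": d.drug_id,
            "fingerprint": _format_bits(d.fingerprint),
            "targets": ";".join(sorted(d.targets)),
            "indication": d.indication,
        }
        for d in drugs
    ]
    pd.DataFrame(rows, columns=["drug_id", "fingerprint", "targets", "indication"]).to_csv(
        path, sep="\t", index=False
    )


def load_ppi(
    paths: Sequence[str | Path], sources: Sequence[str] | None = None
) -> InteractionNetwork:
    """Merge edge-list/SIF files into one undirected simple interaction graph.

    Duplicate edges across files collapse with provenance union; self-loops
    are dropped with a logged count. TSV files need two symbol columns plus an
    optional per-line source column; SIF lines are ``A relation B [C ...]``.
    The default source tag is the file stem.
    """
    net = InteractionNetwork()
    if sources is not None and len(sources) != len(paths):
        raise ValueError("sources must match paths one-to-one")
    for i, p in enumerate(paths):
        p = Path(p)
        default_source = sources[i] if sources is not None else p.stem
        is_sif = p.suffix.lower() == ".sif"
        with open(p) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                if is_sif:
                    tokens = line.split()
                    if len(tokens) == 1:
                        net.add_node(tokens[0])
                        continue
                    if len(tokens) < 3:
                        raise ValueError(f"{p}:{lineno}: unparseable SIF line: {line!r}")
                    for tgt in tokens[2:]:
                        net.add_edge(tokens[0], tgt, {default_source})
                else:
                    fields = [f for f in line.split("\t") if f.strip()]
                    if len(fields) == 2:
                        net.add_edge(fields[0], fields[1], {default_source})
                    elif len(fields) == 3:
                        net.add_edge(fields[0], fields[1], {fields[2].strip()})
                    else:
                        raise ValueError(f"{p}:{lineno}: unparseable edge line: {line!r}")
    if net.dropped_self_loops:
        logger.info("load_ppi: dropped %d self-loop(s)", net.dropped_self_loops)
    return net


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    """TSV edge list (symbol, symbol, |-joined sources); isolated nodes as SIF-style singles are lost, use GraphML to preserve them."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            tags = "|".join(sorted(network.edge_sources(u, v)))
            fh.write(f"{u}\t{v}\t{tags}\n")


def load_known_targets(
    sources: Mapping[str, str | Path] | Sequence[tuple[str, str | Path]],
    disease: str = "disease",
) -> KnownTargetSet:
    """Union symbol lists from several sources into one known-target set.

    Each source file lists one symbol per line ('#' comments and blanks
    ignored). Symbols are case-normalised; provenance is the union of source
    labels per symbol. An empty union is a warning, not an error.
    """
    items = list(sources.items()) if isinstance(sources, Mapping) else list(sources)
    members: set[str] = set()
    tags: dict[str, set[str]] = {}
    for label, path in items:
        for sym in load_symbol_list(path):
            members.add(sym)
            tags.setdefault(sym, set()).add(label)
    if not members:
        logger.warning("load_known_targets: empty union across %d source(s)", len(items))
    kts = KnownTargetSet(disease=disease, members=members, source_tags=tags)
    logger.info(
        "load_known_targets: %d deduplicated symbols; per-source %s",
        len(kts),
        kts.per_source_counts,
    )
    return kts


def load_symbol_list(path: str | Path) -> list[str]:
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(normalize_symbol(line))
    return out


def write_symbol_list(symbols: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sym in sorted({normalize_symbol(s) for s in symbols}):
            fh.write(sym + "\n")


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def _fixture_path(name: str) -> Path:
    p = resources.files("herbnet") / "fixtures" / name
    path = Path(str(p))
    if not path.exists():
        raise FileNotFoundError(f"packaged fixture missing: {name}")
    return path


def load_anti_ra_overlap() -> tuple[list[AntiRADrugOverlapRow], int]:
    """Curated herb/anti-RA-drug shared-target table.

    Returns the rows and the number of distinct target symbols (22).
    """
    df = pd.read_csv(
        _fixture_path("anti_ra_drug_overlap.tsv"), sep="\t", dtype=str, keep_default_na=False
    )
    rows = [
        AntiRADrugOverlapRow(
            herbs=frozenset(h.strip() for h in row["herbs"].split("/")),
            target_name=row["target_name"],
            target_symbol=normalize_symbol(row["target_symbol"]),
            known_drug=row["known_drug"],
            indication=row["indication"],
            target_class=row["target_class"],
        )
        for _, row in df.iterrows()
    ]
    return rows, len({r.target_symbol for r in rows})


def load_omim_ra_targets() -> KnownTargetSet:
    """The seven rheumatoid-arthritis gene symbols curated from OMIM."""
    path = _fixture_path("omim_ra_targets.txt")
    return load_known_targets([("OMIM", path)], disease="rheumatoid arthritis")


# ---------------------------------------------------------------------------
# GMT and GraphML round-trip formats
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, name, >=1 member")
            sets.append(
                GeneSet(
                    set_id=fields[0],
                    name=fields[1],
                    members=frozenset(f for f in fields[2:] if f.strip()),
                )
            )
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection.sets:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")


def write_graphml(network: InteractionNetwork, path: str | Path) -> None:
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes)
    for u, v, data in network.graph.edges(data=True):
        g.add_edge(u, v, sources="|".join(sorted(data.get("sources", set()))))
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> InteractionNetwork:
    g = nx.read_graphml(path)
    net = InteractionNetwork()
    for node in g.nodes:
        net.add_node(node)
    for u, v, data in g.edges(data=True):
        tags = {t for t in data.get("sources", "").split("|") if t}
        net.add_edge(u, v, tags)
    return net
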