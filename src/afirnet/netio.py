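"""Reading, writing and construction of molecular interaction networks.

A curated interaction database arrives either as a multi-sheet workbook
(sheets ``ages``, ``receptors``, an interaction sheet such as ``AGE-TRPV1``,
``analysis``, ``reference``), as a flat CSV/TSV edge list, or as a SIF file.
Whatever the dialect, the product is a :class:`MolecularNetwork`: an
undirected graph over molecule identifiers in which every interaction record
from the source is retained verbatim, while the *simple adjacency* used for
all topological computation collapses duplicate edges and drops self-loops.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("afirnet")

COMPARTMENTS = ("glycemic_control", "fertility", "immunity")

#: column names accepted (case-insensitively) when sniffing a header row
_SOURCE_NAMES = {"source", "src", "node1", "from"}
_TARGET_NAMES = {"target", "tgt", "node2", "to"}
_TYPE_NAMES = {"interaction_type", "interaction", "type", "relation"}
_PROV_NAMES = {"provenance", "pmid", "reference", "ref"}

#: sheet names (lowercased, dash-normalized) recognized in a workbook
_INTERACTION_SHEETS = {"age-trpv1", "interactions", "edges", "network"}
_KNOWN_SHEETS = {"ages", "receptors", "analysis", "reference", "references"}


class InputError(ValueError):
    """The input file cannot be read at all."""


class SchemaError(ValueError):
    """The input was readable but no interaction rows could be located."""


class SIFParseError(ValueError):
    """A malformed line in a SIF file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class InteractionRecord:
    """One curated interaction: an edge between two molecule identifiers."""

    source: str
    target: str
    interaction_type: str = "interacts"
    provenance: str | None = None

    def __post_init__(self):
        if not self.source or not self.target:
            raise ValueError("source and target must be non-empty strings")


@dataclass
class CuratedDatabase:
    """The parsed curated database, mirroring the workbook's sheet layout."""

    ages: list[str] = field(default_factory=list)
    receptors: list[tuple[str, str]] = field(default_factory=list)
    interactions: list[InteractionRecord] = field(default_factory=list)
    references: list[str] = field(default_factory=list)


class MolecularNetwork:
    """Undirected molecular network with record-level edge provenance.

    Parameters
    ----------
    records
        Interaction records in input order.  Duplicates and self-loops are
        kept here but excluded from the simple adjacency, which reconciles a
        curated link count with the mean distinct-neighbor count and keeps
        shortest-path centralities well defined (they are only meaningful on
        multigraph-free networks).
    nodes
        Optional iterable of declared node identifiers (isolated nodes that
        appear in no interaction are retained).
    compartments
        Optional mapping node -> compartment label (one of
        :data:`COMPARTMENTS`); unmapped nodes are ``None`` ("unlabeled").
    """

    def __init__(
        self,
        records: Iterable[InteractionRecord],
        nodes: Iterable[str] = (),
        compartments: Mapping[str, str] | None = None,
    ):
        self.edge_records: list[InteractionRecord] = list(records)
        self.graph = nx.Graph()
        for n in nodes:
            self.graph.add_node(n)
        for rec in self.edge_records:
            self.graph.add_node(rec.source)
            self.graph.add_node(rec.target)
            if rec.source != rec.target:
                self.graph.add_edge(rec.source, rec.target)
        self.compartments: dict[str, str | None] = {n: None for n in self.graph}
        if compartments:
            for n, c in compartments.items():
                if n in self.compartments:
                    self.compartments[n] = c

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def num_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def num_edge_records(self) -> int:
        return len(self.edge_records)

    @property
    def num_simple_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, n: str) -> set[str]:
        return set(self.graph[n])

    def degree(self, n: str) -> int:
        return self.graph.degree[n]

    def __contains__(self, n: str) -> bool:
        return n in self.graph

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MolecularNetwork {self.num_nodes} nodes, "
            f"{self.num_edge_records} records, {self.num_simple_edges} simple edges>"
        )


# ---------------------------------------------------------------------------
# database reading
# ---------------------------------------------------------------------------

def _norm_sheet(name: str) -> str:
    # en/em dashes appear in curated sheet names ("AGE–TRPV1")
    return name.strip().lower().replace("–", "-").replace("—", "-")


def _clean(value) -> str:
    return str(value).strip() if value is not None else ""


def _records_from_rows(rows: list[Sequence], origin: str) -> list[InteractionRecord]:
    """Interpret tabular rows as interaction records.

    If a header row names source/target columns it is honored; otherwise the
    first three columns are taken in SIF order (source, type, target), the
    convention of the Cytoscape ecosystem these databases interoperate with.
    """
    rows = [r for r in rows if any(_clean(c) for c in r)]
    if not rows:
        return []
    header = [_clean(c).lower() for c in rows[0]]
    src_i = tgt_i = typ_i = prov_i = None
    for i, h in enumerate(header):
        if h in _SOURCE_NAMES and src_i is None:
            src_i = i
        elif h in _TARGET_NAMES and tgt_i is None:
            tgt_i = i
        elif h in _TYPE_NAMES and typ_i is None:
            typ_i = i
        elif h in _PROV_NAMES and prov_i is None:
            prov_i = i
    if src_i is not None and tgt_i is not None:
        body = rows[1:]
        logger.info(
            "%s: using named columns source=%d target=%d type=%s", origin, src_i, tgt_i, typ_i
        )
    else:
        src_i, typ_i, tgt_i, prov_i = 0, 1, 2, 3
        body = rows[1:] if header and header[0] in {"source"} else rows
        # positional SIF order: source, interaction type, target
        logger.info("%s: no recognized header; assuming SIF column order", origin)
    out = []
    for r in body:
        r = list(r)
        src = _clean(r[src_i]) if src_i < len(r) else ""
        tgt = _clean(r[tgt_i]) if tgt_i < len(r) else ""
        if not src or not tgt:
            continue
        typ = _clean(r[typ_i]) if typ_i is not None and typ_i < len(r) else ""
        prov = _clean(r[prov_i]) if prov_i is not None and prov_i < len(r) else ""
        out.append(
            InteractionRecord(src, tgt, typ or "interacts", prov or None)
        )
    return out


def read_database(path: str | Path, dialect: str | None = None) -> CuratedDatabase:
    """Read a curated database from a workbook or a CSV/TSV edge list.

    Parameters
    ----------
    path
        Input file.  ``.xlsx`` workbooks are parsed sheet-by-sheet; ``.csv``
        and ``.tsv``/``.txt`` are treated as flat edge lists.
    dialect
        Optional explicit format hint: ``"xlsx"``, ``"csv"``, ``"tsv"``.

    Raises
    ------
    InputError
        If the file is missing or unreadable.
    SchemaError
        If no interaction rows can be located (the error names the sheets
        that were seen).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    kind = (dialect or path.suffix.lstrip(".")).lower()
    if kind in {"xlsx", "xls", "workbook"}:
        return _read_workbook(path)
    sep = "\t" if kind in {"tsv", "txt", "sif"} else ","
    try:
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh, delimiter=sep))
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise InputError(str(exc)) from exc
    records = _records_from_rows(rows, path.name)
    if not records:
        raise SchemaError(f"no interaction rows found in {path.name}")
    return CuratedDatabase(interactions=records)


def _read_workbook(path: Path) -> CuratedDatabase:
    try:
        sheets = pd.read_excel(path, sheet_name=None, header=None, engine="openpyxl")
    except Exception as exc:
        raise InputError(f"cannot read workbook {path}: {exc}") from exc
    db = CuratedDatabase()
    seen = []
    for raw_name, frame in sheets.items():
        name = _norm_sheet(raw_name)
        seen.append(raw_name)
        rows = frame.where(pd.notna(frame), None).values.tolist()
        if name == "ages":
            db.ages = [_clean(r[0]) for r in rows if r and _clean(r[0])]
            if db.ages and db.ages[0].lower() in {"age", "ages", "name", "identifier"}:
                db.ages = db.ages[1:]
        elif name == "receptors":
            body = [r for r in rows if r and _clean(r[0])]
            if body and _clean(body[0][0]).lower() in {"receptor", "receptors", "name", "identifier"}:
                body = body[1:]
            db.receptors = [
                (_clean(r[0]), _clean(r[1]) if len(r) > 1 else "") for r in body
            ]
        elif name in _INTERACTION_SHEETS:
            db.interactions = _records_from_rows(rows, f"{path.name}:{raw_name}")
        elif name in {"reference", "references"}:
            db.references = [_clean(r[0]) for r in rows if r and _clean(r[0])]
        elif name == "analysis":
            pass  # derived analysis sheet; everything in it is recomputed here
        else:
            logger.warning("ignoring unrecognized sheet %r in %s", raw_name, path.name)
    if not db.interactions:
        # fall back: any unclaimed sheet that parses to records
        for raw_name, frame in sheets.items():
            if _norm_sheet(raw_name) in _KNOWN_SHEETS | _INTERACTION_SHEETS:
                continue
            rows = frame.where(pd.notna(frame), None).values.tolist()
            recs = _records_from_rows(rows, f"{path.name}:{raw_name}")
            if recs:
                logger.warning("using sheet %r as the interaction sheet", raw_name)
                db.interactions = recs
                break
    if not db.interactions:
        raise SchemaError(
            f"no interaction rows found in {path.name}; sheets seen: {seen}"
        )
    return db


def build_network(
    db: CuratedDatabase, labels: Mapping[str, str] | None = None
) -> MolecularNetwork:
    """Assemble the :class:`MolecularNetwork` from a curated database.

    The node set is the union of all interaction endpoints plus any declared
    AGE / receptor identifiers; records are preserved verbatim while the
    simple adjacency drops self-loops and collapses duplicates.
    """
    if not db.interactions:
        raise SchemaError("database contains no interactions")
    declared = list(db.ages) + [r[0] for r in db.receptors]
    return MolecularNetwork(db.interactions, nodes=declared, compartments=labels)


# ---------------------------------------------------------------------------
# SIF / GraphML / tables
# ---------------------------------------------------------------------------

def read_sif(path: str | Path) -> MolecularNetwork:
    """Read a SIF file (``source<TAB>type<TAB>target...``).

    Cytoscape's multi-target form ``A type B C`` is accepted and expanded to
    one record per target.  A line with fewer than three fields is a
    :class:`SIFParseError` carrying the line number.
    """
    records = []
    isolated = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if len(fields) == 1:
                isolated.append(fields[0])
                continue
            if len(fields) == 2:
                raise SIFParseError(
                    f"expected source<TAB>type<TAB>target, got {len(fields)} fields", lineno
                )
            src, typ, *targets = fields
            for tgt in targets:
                records.append(InteractionRecord(src, tgt, typ))
    return MolecularNetwork(records, nodes=isolated)


def write_sif(net: MolecularNetwork, path: str | Path) -> None:
    """Write every edge record as one tab-separated SIF line."""
    covered = set()
    with open(Path(path), "w") as fh:
        for rec in net.edge_records:
            fh.write(f"{rec.source}\t{rec.interaction_type}\t{rec.target}\n")
            covered.update((rec.source, rec.target))
        for n in net.nodes:  # isolated nodes: bare-identifier lines
            if n not in covered:
                fh.write(f"{n}\n")


def write_graphml(net: MolecularNetwork, path: str | Path) -> None:
    """Export the simple graph (with compartment labels) as GraphML."""
    g = net.graph.copy()
    for n in g:
        g.nodes[n]["compartment"] = net.compartments.get(n) or "unlabeled"
    nx.write_graphml(g, Path(path))


def write_node_table(metrics: pd.DataFrame, path: str | Path) -> None:
    """Write a per-node metric table as plain CSV (index column ``node``)."""
    metrics.to_csv(Path(path), index_label="node")
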