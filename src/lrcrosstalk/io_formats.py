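"""Readers and writers for the external formats the pipeline touches.

All tabular inputs and outputs are UTF-8 TSV with a header row; gene-set
collections use the GMT dialect.  Gene symbols are uppercased at ingestion
so that a human ligand-receptor database can be matched against data from
other species at the symbol level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

CELL_TYPES = ("IMAdC", "SMSC")
CULTURES = ("mono", "co")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# sample sheet and counts


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: cell type, culture condition, replicate number.

    The study design is a 2x2 layout (IMAdC/SMSC x mono/co) with biological
    replicates; any two-group contrast drawn from it needs at least two
    replicates per group.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "cell_type", "culture", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise FormatError(f"duplicate sample ids: {dupes}")
        bad_ct = set(self.table["cell_type"]) - set(CELL_TYPES)
        if bad_ct:
            raise FormatError(f"unknown cell_type values: {sorted(bad_ct)}")
        bad_cu = set(self.table["culture"]) - set(CULTURES)
        if bad_cu:
            raise FormatError(f"unknown culture values: {sorted(bad_cu)}")
        reps = pd.to_numeric(self.table["replicate"], errors="coerce")
        if reps.isna().any() or (reps < 1).any() or (reps != reps.astype(int)).any():
            raise FormatError("replicate must be a positive integer")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group(self, cell_type: str, culture: str) -> list[str]:
        """Sample ids belonging to one (cell_type, culture) group."""
        mask = (self.table["cell_type"] == cell_type) & (self.table["culture"] == culture)
        return list(self.table.loc[mask, "sample_id"])


@dataclass(frozen=True)
class CountsMatrix:
    """Integer gene x sample count matrix with its sample sheet."""

    counts: pd.DataFrame  # genes x samples, int64
    sheet: SampleSheet

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = sorted(self.counts.index[self.counts.index.duplicated()].unique())
            raise FormatError(f"duplicate gene ids: {dupes}")
        if list(self.counts.columns) != self.sheet.sample_ids:
            extra = set(self.counts.columns) ^ set(self.sheet.sample_ids)
            raise FormatError(
                f"count matrix columns do not match the sample sheet; unmatched: {sorted(extra)}"
            )
        if (self.counts.values < 0).any():
            raise FormatError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_type": str, "culture": str})
    return SampleSheet(table)


def read_counts(path: str | Path, sheet_path: str | Path) -> CountsMatrix:
    """Read a gene x sample TSV count matrix plus its companion sample sheet.

    The first column holds gene ids; the header row holds sample ids.
    Non-integer cells are rejected with their coordinates.
    """
    sheet = read_sample_sheet(sheet_path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    for j, col in enumerate(raw.columns):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            i = int(bad.to_numpy().argmax())
            raise FormatError(
                f"non-integer count at gene {raw.index[i]!r} (row {i + 1}), sample {col!r} (column {j + 1})"
            )
    counts = raw.astype("int64")
    return CountsMatrix(counts, sheet)


def write_counts(matrix: CountsMatrix, counts_path: str | Path, sheet_path: str | Path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    matrix.sheet.table.to_csv(sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene lengths


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read a two-column TSV (gene_id, length_bp) into a Series of ints."""
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    if table.shape[1] < 2:
        raise FormatError("gene length table needs columns gene_id and length_bp")
    lengths = pd.Series(
        pd.to_numeric(table.iloc[:, 1]).to_numpy(), index=table.iloc[:, 0].astype(str)
    )
    if (lengths < 1).any():
        offenders = sorted(lengths.index[lengths < 1])
        raise FormatError(f"gene lengths must be >= 1 bp; offending genes: {offenders}")
    return lengths.astype("int64")


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length_bp").rename_axis("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# ligand-receptor database


@dataclass(frozen=True)
class LRDatabase:
    """Curated ligand -> receptor symbol pairs (human symbols, uppercased)."""

    pairs: frozenset[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for lig, rec in self.pairs:
            if not lig or not rec:
                raise FormatError("ligand/receptor symbols must be non-empty")

    @property
    def ligands(self) -> frozenset[str]:
        return frozenset(l for l, _ in self.pairs)

    @property
    def receptors(self) -> frozenset[str]:
        return frozenset(r for _, r in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def read_lr_database(path: str | Path) -> LRDatabase:
    """Read a CellTalkDB-dialect TSV (ligand_gene_symbol / receptor_gene_symbol).

    Extra annotation columns are ignored; duplicate rows collapse silently
    (count logged); symbols are uppercased.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ligand_gene_symbol", "receptor_gene_symbol"):
        if col not in table.columns:
            raise FormatError(f"LR database missing required column {col!r}")
    ligs = table["ligand_gene_symbol"].fillna("")
    recs = table["receptor_gene_symbol"].fillna("")
    if (ligs.str.strip() == "").any() or (recs.str.strip() == "").any():
        raise FormatError("LR database contains an empty ligand or receptor symbol")
    pairs = frozenset(zip(ligs.str.upper(), recs.str.upper()))
    n_dupes = len(table) - len(pairs)
    if n_dupes:
        logger.info("LR database: collapsed %d duplicate pair rows", n_dupes)
    return LRDatabase(pairs, provenance=str(path))


def write_lr_database(db: LRDatabase, path: str | Path) -> None:
    rows = pd.DataFrame(sorted(db.pairs), columns=["ligand_gene_symbol", "receptor_gene_symbol"])
    rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass(frozen=True)
class GeneSetCollection:
    """term_id -> (term_name, member symbol set)."""

    sets: Mapping[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {term_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            term_id, desc, *members = fields
            if term_id in sets:
                raise FormatError(f"GMT line {lineno}: duplicate term id {term_id!r}")
            sets[term_id] = (desc, frozenset(m.upper() for m in members if m))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id in sorted(collection.sets):
            name, members = collection.sets[term_id]
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# interaction network (undirected edge list)


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-symbol-column TSV (optional third weight column) as an
    undirected graph.  Self-loops are dropped with a warning; reversed
    duplicates collapse to one edge."""
    table = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    graph = nx.Graph()
    weighted = table.shape[1] >= 3
    for row in table.itertuples(index=False):
        a, b = str(row[0]).upper(), str(row[1]).upper()
        if a == b:
            logger.warning("dropping self-loop edge %s-%s", a, b)
            continue
        if weighted:
            w = float(row[2])
            if not 0.0 <= w <= 1.0:
                raise FormatError(f"edge weight out of [0,1] for {a}-{b}: {w}")
            graph.add_edge(a, b, weight=w)
        else:
            graph.add_edge(a, b)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = []
    for a, b, data in graph.edges(data=True):
        a, b = sorted((a, b))
        if "weight" in data:
            rows.append((a, b, data["weight"]))
        else:
            rows.append((a, b))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tweight\n" if rows and len(rows[0]) == 3 else "node_a\tnode_b\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# generic table writer


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with a header row.

    Column order is the DataFrame's; callers are responsible for sorting rows
    deterministically before writing.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index, lineterminator="\n")
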