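"""Domain types and delimited-text I/O shared by every analysis stage.

The central container is :class:`AbundanceTable`, a samples x OTUs matrix
with an explicit abundance ``kind`` (counts, relative or absolute).  Sample
metadata records the selection-switch design: each microcosm belongs to a
selection group (``RK`` started under r-selection and switched to
K-selection between days 28 and 29; ``KR`` the reverse) and a resource
supply level (high ``H`` / low ``L``), with three replicates per condition.

Tables are stored samples-as-rows internally.  File orientation is declared
by the caller, never guessed, and all joins are by identifier rather than
position.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "TaxonomyTable",
    "current_regime",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "read_density_table",
    "write_density_table",
    "read_taxonomy",
    "write_network",
    "read_edge_table",
]

#: Day of the last sample taken under the initial selection regime; the
#: regime is switched strictly between this day and the next sampling day.
SWITCH_DAY = 28

ABUNDANCE_KINDS = ("counts", "relative", "absolute")
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class AbundanceTable:
    """Samples x OTUs abundance matrix with aligned identifiers.

    Parameters
    ----------
    values
        Non-negative matrix of shape ``(n_samples, n_otus)``.
    sample_ids, otu_ids
        Ordered, unique identifiers matching the matrix axes.
    kind
        One of ``counts``, ``relative`` or ``absolute``.  For ``relative``
        tables every row sum must lie in ``[0, 1 + 1e-9]``.
    """

    values: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    kind: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        if self.kind not in ABUNDANCE_KINDS:
            raise ValueError(f"unknown abundance kind {self.kind!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")
        if (self.values < 0).any():
            s, o = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[s]!r}, "
                f"OTU {self.otu_ids[o]!r}"
            )
        if self.kind == "relative":
            sums = self.values.sum(axis=1)
            if (sums > 1 + 1e-9).any():
                s = int(np.argmax(sums))
                raise ValueError(
                    f"relative row sum {sums[s]:.6g} > 1 for sample "
                    f"{self.sample_ids[s]!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)

    def select_otus(self, otu_ids: Sequence[str]) -> "AbundanceTable":
        """Return the sub-table for ``otu_ids`` (order preserved)."""
        index = {o: j for j, o in enumerate(self.otu_ids)}
        cols = [index[o] for o in otu_ids]
        return AbundanceTable(
            self.values[:, cols], list(self.sample_ids), list(otu_ids), self.kind
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return AbundanceTable(
            self.values[rows], list(sample_ids), list(self.otu_ids), self.kind
        )


def current_regime(selection_group: str, day: int) -> str:
    """Selection regime (``"r"`` or ``"K"``) active on a given day.

    The regime is the first letter of the selection group up to and
    including day 28 and the second letter from day 29 onward (the switch
    happens strictly between the two).
    """
    if selection_group not in ("RK", "KR"):
        raise ValueError(f"unknown selection group {selection_group!r}")
    letter = selection_group[0] if day <= SWITCH_DAY else selection_group[1]
    return "r" if letter == "R" else "K"


@dataclass(frozen=True)
class SampleMetadata:
    """Design metadata for one sample of the crossover experiment."""

    sample_id: str
    microcosm_id: str
    day: int
    selection_group: str  # RK | KR
    resource_supply: str  # H | L
    replicate: int

    def __post_init__(self) -> None:
        if self.selection_group not in ("RK", "KR"):
            raise ValueError(f"unknown selection group {self.selection_group!r}")
        if self.resource_supply not in ("H", "L"):
            raise ValueError(f"unknown resource supply {self.resource_supply!r}")
        if self.day < 1:
            raise ValueError("day must be >= 1")
        if not 1 <= self.replicate <= 3:
            raise ValueError("replicate must be in 1..3")

    @property
    def current_regime(self) -> str:
        return current_regime(self.selection_group, self.day)


@dataclass
class TaxonomyTable:
    """Ranked taxonomic labels per OTU; any rank may be absent."""

    labels: dict[str, dict[str, str]] = field(default_factory=dict)

    def rank_labels(self, rank: str, otu_ids: Iterable[str] | None = None) -> dict[str, str]:
        """Mapping otu_id -> label at ``rank`` for OTUs that carry it."""
        otus = self.labels.keys() if otu_ids is None else otu_ids
        out = {}
        for o in otus:
            label = self.labels.get(o, {}).get(rank)
            if label:
                out[o] = label
        return out

    def check_against(self, table: AbundanceTable) -> None:
        unknown = set(self.labels) - set(table.otu_ids)
        if unknown:
            raise ValueError(f"taxonomy refers to unknown OTUs: {sorted(unknown)[:5]}")


# ---------------------------------------------------------------------------
# delimited-text readers / writers


def _sniff_delimiter(path: str, override: str | None) -> str:
    if override is not None:
        return override
    with open(path, newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_abundance_table(
    path: str,
    orientation: str = "samples_as_rows",
    kind: str = "counts",
    delimiter: str | None = None,
) -> AbundanceTable:
    """Read an abundance matrix from delimited text.

    ``orientation`` declares whether rows are samples (``samples_as_rows``)
    or OTUs (``otus_as_rows``); the file is transposed on read in the latter
    case.  The delimiter is auto-detected among tab/comma unless given.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {cell!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"invalid abundance {cell!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}"
                )
            values[i, j] = v
    if orientation == "otus_as_rows":
        return AbundanceTable(values.T, col_ids, row_ids, kind)
    return AbundanceTable(values, row_ids, col_ids, kind)


def write_abundance_table(
    table: AbundanceTable, path: str, orientation: str = "samples_as_rows",
    delimiter: str = "\t",
) -> None:
    df = table.to_frame()
    if orientation == "otus_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    # integer counts are written without a decimal point so round-trips are exact
    if table.kind == "counts" and np.all(table.values == np.round(table.values)):
        df = df.astype(np.int64)
    df.to_csv(path, sep=delimiter, index_label="id", float_format="%.17g")


METADATA_COLUMNS = (
    "sample_id", "microcosm_id", "day", "selection_group", "resource_supply", "replicate",
)


def read_metadata(path: str, delimiter: str | None = None) -> list[SampleMetadata]:
    """Read per-sample design metadata; validates enums and design uniqueness."""
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    records = []
    seen: set[tuple[str, int]] = set()
    for row in df.itertuples(index=False):
        rec = SampleMetadata(
            sample_id=str(row.sample_id),
            microcosm_id=str(row.microcosm_id),
            day=int(row.day),
            selection_group=str(row.selection_group),
            resource_supply=str(row.resource_supply),
            replicate=int(row.replicate),
        )
        key = (rec.microcosm_id, rec.day)
        if key in seen:
            raise ValueError(f"duplicate (microcosm, day) pair {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(METADATA_COLUMNS)
        for r in records:
            w.writerow([r.sample_id, r.microcosm_id, r.day,
                        r.selection_group, r.resource_supply, r.replicate])


def read_density_table(path: str, delimiter: str | None = None) -> pd.Series:
    """Per-sample total cell-density estimates as a Series indexed by sample id."""
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("density table needs sample_id and density columns")
    s = pd.Series(df.iloc[:, 1].astype(float).to_numpy(),
                  index=[str(i) for i in df.iloc[:, 0]], name="density")
    if s.index.has_duplicates:
        raise ValueError("duplicate sample ids in density table")
    return s


def write_density_table(density: Mapping[str, float] | pd.Series, path: str,
                        delimiter: str = "\t") -> None:
    s = pd.Series(dict(density)) if not isinstance(density, pd.Series) else density
    s.rename("density").rename_axis("sample_id").to_csv(path, sep=delimiter,
                                                        float_format="%.17g")


def read_taxonomy(path: str, delimiter: str | None = None) -> TaxonomyTable:
    """Read a taxonomy table with an ``otu_id`` column and rank columns."""
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str).set_index("otu_id")
    labels: dict[str, dict[str, str]] = {}
    for otu, row in df.iterrows():
        labels[str(otu)] = {
            rank: str(v) for rank, v in row.items() if isinstance(v, str) and v
        }
    return TaxonomyTable(labels)


EDGE_COLUMNS = ("otu_a", "otu_b", "similarity", "z", "p", "q", "sign")


def write_network(net, path_graphml: str, path_edges: str) -> None:
    """Export a co-occurrence network as GraphML plus a TSV edge list.

    Unassigned nodes keep an empty-string ``module`` attribute rather than
    being dropped.  Edge signs are written as ``+``/``-``.
    """
    g = nx.Graph()
    for otu, attrs in net.nodes.items():
        node_attrs = {"module": "" if attrs.get("module") is None
                      else str(attrs["module"])}
        for key in ("mean_abundance", "mean_relative_abundance"):
            if attrs.get(key) is not None:
                node_attrs[key] = float(attrs[key])
        if attrs.get("taxonomy"):
            node_attrs["taxonomy"] = str(attrs["taxonomy"])
        g.add_node(otu, **node_attrs)
    rows = []
    for (a, b), e in net.edges.items():
        g.add_edge(a, b, sign=e["sign"], similarity=float(e["similarity"]),
                   z=float(e["z"]), q=float(e["q"]))
        rows.append((a, b, e["similarity"], e["z"], e["p"], e["q"], e["sign"]))
    nx.write_graphml(g, path_graphml)
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(
        path_edges, sep="\t", index=False, float_format="%.17g")


def read_edge_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"otu_a": str, "otu_b": str})
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"edge table is missing columns: {sorted(missing)}")
    return df
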