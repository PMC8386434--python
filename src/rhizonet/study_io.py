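"""Reading, writing and validation of study tables.

Canonical on-disk dialect is UTF-8 TSV with '.' decimal separator.  OTU
tables are samples-as-columns (one row per OTU, optional trailing
``taxonomy`` column); a leading ``#OTU ID`` header cell (BIOM dense-TSV
convention) is accepted on read.  Metadata and network edge lists are plain
TSV with a header row.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MARKERS = ("16S", "ITS")
TIME_POINTS = ("T0", "T1", "T2", "T3")
BULK_TIME_POINTS = frozenset({"T0", "T3"})
TAXONOMY_RANKS = 7


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclasses.dataclass
class OtuTable:
    """Integer count matrix (samples x OTUs) with per-OTU taxonomy."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_otus), integer, >= 0
    taxonomy: list[str]
    marker: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.marker not in MARKERS:
            raise ValidationError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        _check_unique(self.otu_ids, "otu_id")
        _check_unique(self.sample_ids, "sample_id")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(self.taxonomy) != len(self.otu_ids):
            raise ValidationError(
                f"taxonomy length {len(self.taxonomy)} != number of OTUs {len(self.otu_ids)}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                bad = np.argwhere(self.counts != self.counts.astype(np.int64))[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
            self.counts = as_int
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def genus(self) -> list[str]:
        """Genus-level label per OTU ('' when unannotated)."""
        out = []
        for lineage in self.taxonomy:
            parts = lineage.split(";")
            out.append(parts[5].strip() if len(parts) > 5 else "")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


@dataclasses.dataclass
class SampleMetadata:
    """Design factors and block yield for one sample."""

    sample_id: str
    location: str
    time_point: str
    treatment: str
    block_id: str
    soil_type: str
    variety: str = ""
    yield_t_ha: float | None = None

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown time_point {self.time_point!r}"
            )
        if self.treatment not in ("control", "treated"):
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown treatment {self.treatment!r}"
            )
        if self.soil_type not in ("bulk", "rhizosphere"):
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown soil_type {self.soil_type!r}"
            )
        expected = "bulk" if self.time_point in BULK_TIME_POINTS else "rhizosphere"
        if self.soil_type != expected:
            raise ValidationError(
                f"sample {self.sample_id!r}: soil_type {self.soil_type!r} inconsistent "
                f"with time_point {self.time_point} (expected {expected!r})"
            )
        if self.yield_t_ha is not None:
            if math.isnan(self.yield_t_ha):
                self.yield_t_ha = None
            elif self.yield_t_ha < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: negative yield {self.yield_t_ha}"
                )


def _check_unique(ids: Sequence[str], kind: str) -> None:
    dupes = [k for k, v in Counter(ids).items() if v > 1]
    if dupes:
        raise ValidationError(f"duplicate {kind}: {dupes[0]!r}")


def validate_metadata(records: Iterable[SampleMetadata]) -> list[SampleMetadata]:
    """Cross-record checks: unique sample ids, yield constant within block."""
    records = list(records)
    _check_unique([r.sample_id for r in records], "sample_id")
    block_yield: dict[str, float | None] = {}
    for r in records:
        if r.block_id in block_yield:
            prev = block_yield[r.block_id]
            if prev is None and r.yield_t_ha is None:
                continue
            if prev is None or r.yield_t_ha is None or abs(prev - r.yield_t_ha) > 1e-9:
                raise ValidationError(
                    f"block {r.block_id!r} has inconsistent yields "
                    f"({prev} vs {r.yield_t_ha})"
                )
        else:
            block_yield[r.block_id] = r.yield_t_ha
    return records


def metadata_frame(records: Sequence[SampleMetadata]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# OTU tables


def read_otu_table(path: str | Path, marker: str) -> OtuTable:
    """Parse an OTU-by-sample TSV (optional trailing 'taxonomy' column)."""
    # read the header directly: pandas mangles duplicate column names
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ValidationError(f"{path}: need at least one sample column")
    has_tax = header[-1].lower() == "taxonomy"
    sample_cols = header[1 : -1 if has_tax else None]
    _check_unique(sample_cols, "sample column")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    df.columns = header
    otu_ids = df.iloc[:, 0].tolist()
    taxonomy = df.iloc[:, -1].tolist() if has_tax else [""] * len(otu_ids)
    counts = np.empty((len(sample_cols), len(otu_ids)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, raw in enumerate(df[col]):
            try:
                val = int(raw)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-integer count {raw!r} at OTU {otu_ids[i]!r}, "
                    f"sample {col!r}"
                ) from None
            if val < 0:
                raise ValidationError(
                    f"{path}: negative count at OTU {otu_ids[i]!r}, sample {col!r}"
                )
            counts[j, i] = val
    return OtuTable(
        otu_ids=otu_ids,
        sample_ids=sample_cols,
        counts=counts,
        taxonomy=taxonomy,
        marker=marker,
    )


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\ttaxonomy\n")
        for i, otu in enumerate(table.otu_ids):
            row = "\t".join(str(int(c)) for c in table.counts[:, i])
            fh.write(f"{otu}\t{row}\t{table.taxonomy[i]}\n")


# ---------------------------------------------------------------------------
# Metadata

_META_COLS = [
    "sample_id",
    "location",
    "time_point",
    "treatment",
    "block_id",
    "soil_type",
    "variety",
    "yield_t_ha",
]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLS if c not in df.columns and c != "variety"]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    records = []
    for _, row in df.iterrows():
        raw_yield = row.get("yield_t_ha", "")
        records.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                location=row["location"],
                time_point=row["time_point"],
                treatment=row["treatment"],
                block_id=row["block_id"],
                soil_type=row["soil_type"],
                variety=row.get("variety", ""),
                yield_t_ha=float(raw_yield) if raw_yield != "" else None,
            )
        )
    return validate_metadata(records)


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_META_COLS) + "\n")
        for r in records:
            y = "" if r.yield_t_ha is None else format(r.yield_t_ha, ".6f")
            fh.write(
                "\t".join(
                    [
                        r.sample_id,
                        r.location,
                        r.time_point,
                        r.treatment,
                        r.block_id,
                        r.soil_type,
                        r.variety,
                        y,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Networks (edge lists); the graph object lives in cooccurrence_networks

_NET_COLS = ["otu_a", "otu_b", "edge_type", "p_lt", "p_gt", "observed_j", "expected_j"]


def write_network(network, path: str | Path, graphml_path: str | Path | None = None) -> None:
    """Write a metacommunity network as an edge-list TSV (12 printed decimals).

    A header comment line carries the node list and filter provenance so the
    TSV round-trips through :func:`read_network` exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# nodes=" + ",".join(network.nodes) + "\n")
        prov = network.provenance or {}
        fh.write(
            "# provenance="
            + ";".join(f"{k}={v}" for k, v in sorted(prov.items()))
            + "\n"
        )
        fh.write("\t".join(_NET_COLS) + "\n")
        for edge_type, edges in (
            ("cooccurrence", network.cooccurrence_edges),
            ("coexclusion", network.coexclusion_edges),
        ):
            for pair in edges:
                fh.write(
                    f"{pair.otu_a}\t{pair.otu_b}\t{edge_type}\t"
                    f"{pair.p_lt:.12f}\t{pair.p_gt:.12f}\t"
                    f"{pair.j_obs}\t{pair.expected_j:.12f}\n"
                )
    if graphml_path is not None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(network.nodes)
        for edge_type, edges in (
            ("cooccurrence", network.cooccurrence_edges),
            ("coexclusion", network.coexclusion_edges),
        ):
            for pair in edges:
                g.add_edge(
                    pair.otu_a,
                    pair.otu_b,
                    edge_type=edge_type,
                    p_lt=pair.p_lt,
                    p_gt=pair.p_gt,
                    observed_j=pair.j_obs,
                    expected_j=pair.expected_j,
                )
        nx.write_graphml(g, graphml_path)


def read_network(path: str | Path):
    from rhizonet.cooccurrence_networks import MetacommunityNetwork, PairTest

    nodes: list[str] = []
    provenance: dict[str, str] = {}
    cooc, coex = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# nodes="):
                raw = line[len("# nodes=") :]
                nodes = raw.split(",") if raw else []
                continue
            if line.startswith("# provenance="):
                raw = line[len("# provenance=") :]
                if raw:
                    provenance = dict(kv.split("=", 1) for kv in raw.split(";"))
                continue
            if line.startswith("otu_a\t") or not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_NET_COLS):
                raise ValidationError(f"{path}: malformed edge row {line!r}")
            pair = PairTest(
                otu_a=fields[0],
                otu_b=fields[1],
                N=0,
                N1=0,
                N2=0,
                j_obs=int(fields[5]),
                expected_j=float(fields[6]),
                p_lt=float(fields[3]),
                p_gt=float(fields[4]),
                classification=fields[2],
                _validate=False,
            )
            (cooc if fields[2] == "cooccurrence" else coex).append(pair)
    return MetacommunityNetwork(
        nodes=nodes,
        cooccurrence_edges=cooc,
        coexclusion_edges=coex,
        provenance=provenance,
    )
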