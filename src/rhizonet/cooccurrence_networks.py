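"""Exact probabilistic pairwise co-occurrence testing and local network properties.

For two OTUs observed in N1 and N2 of N samples, the number of joint
occurrences under random, independent placement follows a hypergeometric
distribution.  Pairs in the lower/upper tail beyond ``alpha`` form the
co-exclusion/co-occurrence edge sets of a metacommunity network; per-sample
"local" networks are the induced subgraphs on the OTUs detected in each
sample, summarised by modularity, transitivity, and edge proportion.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from rhizonet.study_io import OtuTable, SampleMetadata, metadata_frame

DEFAULT_ALPHA = 0.05
DEFAULT_MAX_OTUS = 4000
DEFAULT_MAX_PAIRS = 10_000_000
# prevalence thresholds used for the two marker domains
DEFAULT_MIN_PREVALENCE = {"16S": 0.30, "ITS": 0.10}


@dataclasses.dataclass
class PairTest:
    """Exact two-tailed incidence test for one OTU pair.

    ``p_lt`` = P(X <= j_obs) and ``p_gt`` = P(X >= j_obs) with
    X ~ Hypergeometric(N, N1, N2); both tails are inclusive.
    """

    otu_a: str
    otu_b: str
    N: int
    N1: int
    N2: int
    j_obs: int
    expected_j: float
    p_lt: float
    p_gt: float
    classification: str = "random"
    _validate: bool = True

    def __post_init__(self) -> None:
        if not self._validate:
            return
        lo = max(0, self.N1 + self.N2 - self.N)
        hi = min(self.N1, self.N2)
        if not lo <= self.j_obs <= hi:
            raise ValueError(
                f"pair ({self.otu_a}, {self.otu_b}): observed joint count "
                f"{self.j_obs} outside support [{lo}, {hi}] for "
                f"N={self.N}, N1={self.N1}, N2={self.N2}"
            )


@dataclasses.dataclass
class MetacommunityNetwork:
    nodes: list[str]
    cooccurrence_edges: list[PairTest]
    coexclusion_edges: list[PairTest]
    provenance: dict = dataclasses.field(default_factory=dict)
    abundance_captured: float | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for pair in self.cooccurrence_edges + self.coexclusion_edges:
            if pair.otu_a not in node_set or pair.otu_b not in node_set:
                raise ValueError(f"edge endpoint outside node set: {pair.otu_a}, {pair.otu_b}")
            if pair.otu_a == pair.otu_b:
                raise ValueError(f"self-edge on {pair.otu_a}")
        cooc = {frozenset((p.otu_a, p.otu_b)) for p in self.cooccurrence_edges}
        coex = {frozenset((p.otu_a, p.otu_b)) for p in self.coexclusion_edges}
        if cooc & coex:
            raise ValueError("co-occurrence and co-exclusion edge sets overlap")

    def graph(self, edge_type: str) -> nx.Graph:
        edges = (
            self.cooccurrence_edges if edge_type == "cooccurrence" else self.coexclusion_edges
        )
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((p.otu_a, p.otu_b) for p in edges)
        return g


@dataclasses.dataclass
class LocalNetworkProperties:
    """Six structural statistics of one sample's local networks."""

    sample_id: str
    marker: str
    S: int
    cooccurrence_modularity: float
    cooccurrence_transitivity: float
    cooccurrence_proportion: float
    coexclusion_modularity: float
    coexclusion_transitivity: float
    coexclusion_proportion: float


PROPERTY_NAMES = [
    "cooccurrence_modularity",
    "cooccurrence_transitivity",
    "cooccurrence_proportion",
    "coexclusion_modularity",
    "coexclusion_transitivity",
    "coexclusion_proportion",
]


def incidence_matrix(table: OtuTable) -> pd.DataFrame:
    """Binary presence matrix from raw counts (before any zero replacement)."""
    return pd.DataFrame(
        (table.counts > 0).astype(np.int8),
        index=table.sample_ids,
        columns=table.otu_ids,
    )


def filter_otus(
    incidence: pd.DataFrame,
    min_prevalence_fraction: float,
    max_otus: int = DEFAULT_MAX_OTUS,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    total_counts: Mapping[str, int] | None = None,
) -> list[str]:
    """Prevalence filter plus a hard cap on OTU (and hence pair) count.

    Keeps OTUs present in at least ``min_prevalence_fraction`` of all samples;
    if more than ``max_otus`` survive, the most prevalent are kept, ties broken
    by total count (if given) then OTU id.  The cap is lowered if needed so
    that C(kept, 2) <= max_pairs.
    """
    if not 0 < min_prevalence_fraction < 1:
        raise ValueError("min_prevalence_fraction must be in (0, 1)")
    n_samples = incidence.shape[0]
    prevalence = incidence.sum(axis=0)
    survivors = prevalence[prevalence >= min_prevalence_fraction * n_samples]
    if survivors.empty:
        raise ValueError(
            "no OTU passes the prevalence threshold "
            f"{min_prevalence_fraction:.2f}; lower the threshold"
        )
    cap = max_otus
    while cap * (cap - 1) // 2 > max_pairs:
        cap -= 1
    if len(survivors) > cap:
        totals = total_counts or {}
        order = sorted(
            survivors.index,
            key=lambda o: (-survivors[o], -totals.get(o, 0), o),
        )
        kept = order[:cap]
        return [o for o in incidence.columns if o in set(kept)]
    return list(survivors.index)


def veech_pair_test(N: int, N1: int, N2: int, j_obs: int) -> tuple[float, float, float]:
    """Inclusive hypergeometric tails for one pair.

    Returns ``(p_lt, p_gt, expected_j)``.  Evaluated via the log-pmf to stay
    exact in the extreme tails.
    """
    if not (0 <= N1 <= N and 0 <= N2 <= N):
        raise ValueError(f"incidence counts out of range: N={N}, N1={N1}, N2={N2}")
    lo = max(0, N1 + N2 - N)
    hi = min(N1, N2)
    if not lo <= j_obs <= hi:
        raise ValueError(
            f"j_obs={j_obs} outside hypergeometric support [{lo}, {hi}]"
        )
    dist = hypergeom(N, N1, N2)
    p_lt = float(dist.cdf(j_obs))
    p_gt = float(dist.sf(j_obs - 1))
    return min(p_lt, 1.0), min(p_gt, 1.0), N1 * N2 / N


def build_metacommunity(
    incidence: pd.DataFrame,
    kept_otus: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    table: OtuTable | None = None,
    provenance: dict | None = None,
) -> MetacommunityNetwork:
    """Classify every unordered pair of kept OTUs by its exact tail test.

    A pair is a co-occurrence edge iff ``p_gt < alpha`` and the observed joint
    count exceeds expectation; a co-exclusion edge iff ``p_lt < alpha`` and the
    count falls short of expectation.  All pair tails are computed vectorised.
    """
    missing = [o for o in kept_otus if o not in incidence.columns]
    if missing:
        raise ValueError(f"kept OTUs not in incidence matrix: {missing[:5]}")
    sub = incidence.loc[:, list(kept_otus)].to_numpy(dtype=np.int64)
    n_samples = sub.shape[0]
    prev = sub.sum(axis=0)
    joint = sub.T @ sub  # joint occurrence counts
    iu, ju = np.triu_indices(len(kept_otus), k=1)
    n1 = prev[iu]
    n2 = prev[ju]
    j_obs = joint[iu, ju]
    expected = n1 * n2 / n_samples
    p_lt = hypergeom.cdf(j_obs, n_samples, n1, n2)
    p_gt = hypergeom.sf(j_obs - 1, n_samples, n1, n2)
    np.minimum(p_lt, 1.0, out=p_lt)
    np.minimum(p_gt, 1.0, out=p_gt)

    is_cooc = (p_gt < alpha) & (j_obs > expected)
    is_coex = (p_lt < alpha) & (j_obs < expected)
    kept = list(kept_otus)

    def _pairs(mask: np.ndarray, label: str) -> list[PairTest]:
        idx = np.flatnonzero(mask)
        return [
            PairTest(
                otu_a=kept[iu[k]],
                otu_b=kept[ju[k]],
                N=n_samples,
                N1=int(n1[k]),
                N2=int(n2[k]),
                j_obs=int(j_obs[k]),
                expected_j=float(expected[k]),
                p_lt=float(p_lt[k]),
                p_gt=float(p_gt[k]),
                classification=label,
            )
            for k in idx
        ]

    abundance_captured = None
    if table is not None:
        totals = table.counts.sum(axis=1).astype(float)
        kept_idx = [table.otu_ids.index(o) for o in kept]
        kept_totals = table.counts[:, kept_idx].sum(axis=1)
        with np.errstate(invalid="ignore"):
            frac = np.where(totals > 0, kept_totals / totals, 0.0)
        abundance_captured = float(frac.mean())

    prov = dict(provenance or {})
    prov.setdefault("alpha", alpha)
    return MetacommunityNetwork(
        nodes=kept,
        cooccurrence_edges=_pairs(is_cooc, "cooccurrence"),
        coexclusion_edges=_pairs(is_coex, "coexclusion"),
        provenance=prov,
        abundance_captured=abundance_captured,
    )


def _graph_stats(nodes: Sequence[str], edges: Sequence[tuple[str, str]]) -> tuple[float, float]:
    """(transitivity, greedy modularity) of an undirected simple graph.

    Transitivity is 3*triangles/connected-triples (0 without triples);
    modularity scores the partition found by greedy agglomeration (igraph
    fast-greedy, deterministic) and is 0 for edgeless graphs.
    """
    if not edges:
        return 0.0, 0.0
    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes), edges=[(index[a], index[b]) for a, b in edges], directed=False
    )
    transitivity = float(g.transitivity_undirected(mode="zero"))
    clustering = g.community_fastgreedy().as_clustering()
    modularity = float(g.modularity(clustering.membership))
    return transitivity, modularity


def local_properties(
    network: MetacommunityNetwork,
    sample_presence: set[str],
    S: int,
    sample_id: str = "",
    marker: str = "16S",
) -> LocalNetworkProperties:
    """Structural statistics of the induced subgraphs on detected OTUs.

    ``S`` counts all OTUs detected in the sample (the proportion denominator
    C(S, 2) uses every detected OTU, not only network nodes).
    """
    present_nodes = sample_presence & set(network.nodes)
    n_pairs = S * (S - 1) // 2
    node_list = sorted(present_nodes)
    stats: dict[str, float] = {}
    for edge_type, all_edges in (
        ("cooccurrence", network.cooccurrence_edges),
        ("coexclusion", network.coexclusion_edges),
    ):
        edges = [
            (p.otu_a, p.otu_b)
            for p in all_edges
            if p.otu_a in present_nodes and p.otu_b in present_nodes
        ]
        trans, mod = _graph_stats(node_list, edges)
        stats[f"{edge_type}_transitivity"] = trans
        stats[f"{edge_type}_modularity"] = mod
        stats[f"{edge_type}_proportion"] = len(edges) / n_pairs if n_pairs else 0.0
    return LocalNetworkProperties(sample_id=sample_id, marker=marker, S=S, **stats)


def properties_table(
    networks: Mapping[str, MetacommunityNetwork],
    tables: Mapping[str, OtuTable],
    meta: Sequence[SampleMetadata],
) -> pd.DataFrame:
    """Per-sample local properties for both markers, joined to metadata.

    Columns are ``<marker-tag>_<property>`` with marker tags ``bac``/``fun``
    for 16S/ITS, plus ``<tag>_S`` detected-OTU counts.
    """
    meta_df = metadata_frame(meta)
    rows: dict[str, dict[str, float]] = {s: {} for s in meta_df.index}
    tags = {"16S": "bac", "ITS": "fun"}
    for marker, network in networks.items():
        table = tables[marker]
        inc = incidence_matrix(table)
        tag = tags[marker]
        for sample_id in meta_df.index:
            if sample_id not in inc.index:
                continue
            row = inc.loc[sample_id]
            present = set(row.index[row > 0])
            props = local_properties(
                network, present, S=len(present), sample_id=sample_id, marker=marker
            )
            rows[sample_id][f"{tag}_S"] = props.S
            for name in PROPERTY_NAMES:
                rows[sample_id][f"{tag}_{name}"] = getattr(props, name)
    props_df = pd.DataFrame.from_dict(rows, orient="index")
    props_df.index.name = "sample_id"
    return meta_df.drop(columns=["sample_id"]).join(props_df)
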