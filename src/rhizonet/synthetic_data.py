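"""Synthetic study generator with planted ground truth.

Generates two marker-domain OTU tables, metadata and block yields for a
multi-location, four-time-point field-trial design:

* presence/absence is driven by latent binary habitat factors — OTUs in a
  planted block share a factor, so they co-occur above chance; blocks tied to
  the complement of a factor co-exclude the factor's positive block;
* counts are multinomial draws from log-normal relative abundances carrying
  location, time and treatment effects (treatment-differential OTUs are
  planted in two of the three locations only);
* block yield is a location intercept plus a slope on the block's mean fungal
  co-occurrence transitivity in the generating network, plus Gaussian noise;
  two low and one high location intercept make the distribution bimodal.

Every planted element is recorded in a :class:`SyntheticTruth` for recovery
tests.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from rhizonet.study_io import (
    OtuTable,
    SampleMetadata,
    validate_metadata,
    write_metadata,
    write_otu_table,
)

_BLOCK_SIZES = {"16S": 6, "ITS": 10}  # OTUs per planted factor block, per sign
_BACKGROUND_EDGE_P = 0.05  # cross-block edges in the generating fungal graph
_QUALITY_FLOOR = 0.15  # weakest fungal block assembly relative to full strength


@dataclasses.dataclass
class SyntheticConfig:
    n_locations: int = 3
    blocks_per_arm_per_location: int = 10
    time_points: tuple[str, ...] = ("T0", "T1", "T2", "T3")
    n_otus_bacteria: int = 500
    n_otus_fungi: int = 200
    sequencing_depth_range: tuple[int, int] = (8_000, 60_000)
    n_habitat_factors: int = 6
    planted_pair_strength: float = 0.9
    baseline_presence: float = 0.2
    n_planted_differential_otus: int = 12
    treatment_effect_log2fc: float = 2.0
    yield_transitivity_slope: float = 60.0
    yield_noise_sd: float = 0.7
    yield_intercepts: tuple[float, ...] | None = None  # per location; default bimodal
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_locations,
            self.blocks_per_arm_per_location,
            self.n_otus_bacteria,
            self.n_otus_fungi,
            self.n_habitat_factors,
        ) < 1:
            raise ValueError("all design counts must be positive")
        lo, hi = self.sequencing_depth_range
        if not 0 < lo <= hi:
            raise ValueError("sequencing_depth_range must be ordered and positive")
        for p in (self.planted_pair_strength, self.baseline_presence):
            if not 0 < p < 1:
                raise ValueError("presence probabilities must lie in (0, 1)")
        if self.yield_noise_sd < 0:
            raise ValueError("yield_noise_sd must be non-negative")
        if self.yield_intercepts is not None and len(self.yield_intercepts) != self.n_locations:
            raise ValueError("need one yield intercept per location")


@dataclasses.dataclass
class SyntheticTruth:
    planted_cooccurrence_pairs: dict[str, list[tuple[str, str]]]  # per marker
    planted_coexclusion_pairs: dict[str, list[tuple[str, str]]]
    planted_differential_otus: list[tuple[str, str, str, float]]  # otu, loc, interval, effect
    yield_params: dict
    block_yields: dict[str, float]
    block_generating_transitivity: dict[str, float]


def _default_intercepts(n_locations: int) -> np.ndarray:
    # two low groups and one high group -> bimodal yields straddling 30 t/ha
    base = [22.5, 27.5, 40.0]
    if n_locations <= 3:
        return np.array(base[:n_locations])
    rng = np.arange(n_locations)
    return np.where(rng % 3 == 2, 40.0, 22.5 + 5.0 * (rng % 3))


def _marker_layout(n_otus: int, n_factors: int, prefix: str, block_size: int) -> dict:
    """Assign the first OTUs to positive/negative factor blocks."""
    otu_ids = [f"{prefix}{i:04d}" for i in range(n_otus)]
    pos_blocks, neg_blocks = [], []
    cursor = 0
    for _ in range(n_factors):
        if cursor + 2 * block_size > n_otus:
            break
        pos_blocks.append(list(range(cursor, cursor + block_size)))
        cursor += block_size
        neg_blocks.append(list(range(cursor, cursor + block_size)))
        cursor += block_size
    return {"otu_ids": otu_ids, "pos": pos_blocks, "neg": neg_blocks, "free_from": cursor}


def _planted_pairs(layout: dict) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    ids = layout["otu_ids"]
    cooc, coex = [], []
    for pos, neg in zip(layout["pos"], layout["neg"]):
        for block in (pos, neg):
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    cooc.append((ids[block[i]], ids[block[j]]))
        for a in pos:
            for b in neg:
                coex.append((ids[a], ids[b]))
    return cooc, coex


def _presence(
    layout: dict,
    factors: np.ndarray,  # samples x n_factors, binary
    strength: np.ndarray,  # per-sample effective "factor on" presence prob
    baseline: float,
    free_prev: np.ndarray,  # per-OTU presence prob for unplanted OTUs
    rng: np.random.Generator,
) -> np.ndarray:
    n_samples = factors.shape[0]
    n_otus = len(layout["otu_ids"])
    prob = np.tile(free_prev, (n_samples, 1))
    on = strength[:, None]
    for f, (pos, neg) in enumerate(zip(layout["pos"], layout["neg"])):
        active = factors[:, f].astype(bool)[:, None]
        prob[:, pos] = np.where(active, on, baseline)
        prob[:, neg] = np.where(active, baseline, on)
    return (rng.random((n_samples, n_otus)) < prob).astype(np.int8)


def _taxonomy(n_otus: int, kingdom: str, rng: np.random.Generator) -> list[str]:
    genera = [f"Genus{g:02d}" for g in range(max(8, n_otus // 10))]
    out = []
    for i in range(n_otus):
        g = genera[int(rng.integers(len(genera)))]
        out.append(f"{kingdom};Phylum;Class;Order;Family;{g};")
    return out


def generate_study(
    config: SyntheticConfig,
) -> tuple[OtuTable, OtuTable, list[SampleMetadata], SyntheticTruth]:
    """Deterministic (seeded) synthetic study with full truth record."""
    rng = np.random.default_rng(config.seed)
    locations = [f"L{i + 1}" for i in range(config.n_locations)]
    varieties = {loc: ("VarA" if i < max(1, config.n_locations - 1) else "VarB")
                 for i, loc in enumerate(locations)}

    # ---- design: blocks and samples -------------------------------------
    blocks: list[tuple[str, str, str]] = []  # (block_id, location, treatment)
    for loc in locations:
        for arm, tag in (("control", "C"), ("treated", "T")):
            for b in range(config.blocks_per_arm_per_location):
                blocks.append((f"{loc}-{tag}{b + 1:02d}", loc, arm))
    samples: list[dict] = []
    for block_id, loc, arm in blocks:
        for tp in config.time_points:
            samples.append(
                {
                    "sample_id": f"{block_id}-{tp}",
                    "location": loc,
                    "time_point": tp,
                    "treatment": arm,
                    "block_id": block_id,
                    "soil_type": "bulk" if tp in ("T0", "T3") else "rhizosphere",
                    "variety": varieties[loc],
                }
            )
    n_samples = len(samples)

    # ---- latent habitat factors and presence ----------------------------
    factors = (rng.random((n_samples, config.n_habitat_factors)) < 0.5).astype(np.int8)
    layouts = {
        "16S": _marker_layout(
            config.n_otus_bacteria, config.n_habitat_factors, "B", _BLOCK_SIZES["16S"]
        ),
        "ITS": _marker_layout(
            config.n_otus_fungi, config.n_habitat_factors, "F", _BLOCK_SIZES["ITS"]
        ),
    }
    # per-block habitat quality drives how completely the *fungal* planted
    # blocks assemble, creating block-level variation in co-occurrence
    # structure that the yield link can act on; quality ranges shift with the
    # location's yield intercept so the transitivity-yield association
    # survives pooling across locations
    intercepts = (
        np.asarray(config.yield_intercepts, dtype=float)
        if config.yield_intercepts is not None
        else _default_intercepts(config.n_locations)
    )
    rank = {loc: r for r, loc in enumerate(
        sorted(locations, key=lambda l: intercepts[locations.index(l)]))}
    denom = max(config.n_locations - 1, 1)
    linked = config.yield_transitivity_slope != 0  # slope 0 = yield-structure link off
    block_quality = {}
    for block_id, loc, _ in blocks:
        lo = 0.5 * rank[loc] / denom if linked else 0.25
        block_quality[block_id] = float(rng.uniform(lo, lo + 0.5))
    quality_vec = np.array([block_quality[s["block_id"]] for s in samples])
    base_strength = np.full(n_samples, config.planted_pair_strength)
    span = config.planted_pair_strength - config.baseline_presence
    fungal_strength = config.baseline_presence + span * (
        _QUALITY_FLOOR + (1.0 - _QUALITY_FLOOR) * quality_vec
    )
    strengths = {"16S": base_strength, "ITS": fungal_strength}
    presence, free_prev = {}, {}
    for marker, layout in layouts.items():
        n_otus = len(layout["otu_ids"])
        prev = rng.uniform(0.25, 0.95, size=n_otus)
        free_prev[marker] = prev
        presence[marker] = _presence(
            layout, factors, strengths[marker],
            config.baseline_presence, prev, rng,
        )

    # ---- planted treatment-differential OTUs (2 of n_locations) ---------
    diff_truth: list[tuple[str, str, str, float]] = []
    effect_map: dict[tuple[str, str, str], float] = {}  # (otu, loc, tp) -> log effect
    affected_locations = locations[: min(2, len(locations))]
    for loc in affected_locations:
        for marker, n_pick in (("16S", config.n_planted_differential_otus),
                               ("ITS", max(2, config.n_planted_differential_otus // 3))):
            layout = layouts[marker]
            candidates = list(range(layout["free_from"], len(layout["otu_ids"])))
            chosen = rng.choice(candidates, size=min(n_pick, len(candidates)), replace=False)
            for idx in chosen:
                otu = layout["otu_ids"][int(idx)]
                t_to = str(rng.choice(["T1", "T2"]))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                eff = sign * config.treatment_effect_log2fc * np.log(2.0)
                diff_truth.append((otu, loc, f"T0->{t_to}", eff))
                effect_map[(otu, loc, t_to)] = eff

    # ---- abundances and counts ------------------------------------------
    tables: dict[str, OtuTable] = {}
    for marker, layout in layouts.items():
        otu_ids = layout["otu_ids"]
        n_otus = len(otu_ids)
        base = rng.normal(0.0, 1.0, size=n_otus)
        loc_eff = {loc: rng.normal(0.0, 0.5, size=n_otus) for loc in locations}
        time_eff = {tp: rng.normal(0.0, 0.3, size=n_otus) for tp in config.time_points}
        otu_index = {o: i for i, o in enumerate(otu_ids)}
        counts = np.zeros((n_samples, n_otus), dtype=np.int64)
        depth_lo, depth_hi = config.sequencing_depth_range
        for i, s in enumerate(samples):
            logw = (
                base
                + loc_eff[s["location"]]
                + time_eff[s["time_point"]]
                + rng.normal(0.0, 0.2, size=n_otus)
            )
            if s["treatment"] == "treated":
                for (otu, loc, tp), eff in effect_map.items():
                    if loc == s["location"] and tp == s["time_point"] and otu in otu_index:
                        logw[otu_index[otu]] += eff
            w = np.exp(logw) * presence[marker][i]
            if w.sum() == 0:  # pathological tiny configs: force one OTU present
                w[int(np.argmax(free_prev[marker]))] = 1.0
                presence[marker][i, int(np.argmax(free_prev[marker]))] = 1
            depth = int(rng.integers(depth_lo, depth_hi + 1))
            counts[i] = rng.multinomial(depth, w / w.sum())
        kingdom = "Bacteria" if marker == "16S" else "Fungi"
        tables[marker] = OtuTable(
            otu_ids=list(otu_ids),
            sample_ids=[s["sample_id"] for s in samples],
            counts=counts,
            taxonomy=_taxonomy(n_otus, kingdom, rng),
            marker=marker,
        )

    # ---- yield from generating fungal network ---------------------------
    fun_layout = layouts["ITS"]
    gen_graph = nx.Graph()
    planted_fun = sorted({i for blk in fun_layout["pos"] + fun_layout["neg"] for i in blk})
    gen_graph.add_nodes_from(planted_fun)
    cooc_pairs_f, _ = _planted_pairs(fun_layout)
    id_to_idx = {o: i for i, o in enumerate(fun_layout["otu_ids"])}
    gen_graph.add_edges_from((id_to_idx[a], id_to_idx[b]) for a, b in cooc_pairs_f)
    for ii in range(len(planted_fun)):  # sparse cross-block edges break clique saturation
        for jj in range(ii + 1, len(planted_fun)):
            a, b = planted_fun[ii], planted_fun[jj]
            if not gen_graph.has_edge(a, b) and rng.random() < _BACKGROUND_EDGE_P:
                gen_graph.add_edge(a, b)

    sample_transitivity = np.zeros(n_samples)
    fun_presence = presence["ITS"]
    for i in range(n_samples):
        present = [o for o in planted_fun if fun_presence[i, o]]
        sub = gen_graph.subgraph(present)
        sample_transitivity[i] = nx.transitivity(sub) if sub.number_of_edges() else 0.0

    loc_index = {loc: i for i, loc in enumerate(locations)}
    early = [tp for tp in config.time_points if tp != "T3"]
    block_trans: dict[str, float] = {}
    for block_id, loc, arm in blocks:
        idx = [
            i for i, s in enumerate(samples)
            if s["block_id"] == block_id and s["time_point"] in early
        ]
        block_trans[block_id] = float(np.mean(sample_transitivity[idx]))
    center = float(np.mean(list(block_trans.values())))
    block_yields: dict[str, float] = {}
    for block_id, loc, arm in blocks:
        y = (
            intercepts[loc_index[loc]]
            + config.yield_transitivity_slope * (block_trans[block_id] - center)
            + rng.normal(0.0, config.yield_noise_sd)
        )
        block_yields[block_id] = float(max(y, 0.0))

    meta = validate_metadata(
        SampleMetadata(yield_t_ha=block_yields[s["block_id"]], **s) for s in samples
    )

    truth = SyntheticTruth(
        planted_cooccurrence_pairs={
            m: _planted_pairs(layouts[m])[0] for m in ("16S", "ITS")
        },
        planted_coexclusion_pairs={
            m: _planted_pairs(layouts[m])[1] for m in ("16S", "ITS")
        },
        planted_differential_otus=diff_truth,
        yield_params={
            "intercepts": {loc: float(intercepts[loc_index[loc]]) for loc in locations},
            "slope": config.yield_transitivity_slope,
            "noise_sd": config.yield_noise_sd,
            "transitivity_center": center,
            "block_quality": block_quality,
        },
        block_yields=block_yields,
        block_generating_transitivity=block_trans,
    )
    return tables["16S"], tables["ITS"], meta, truth


FIXTURE_CONFIGS = {
    "tiny": dict(
        n_locations=1,
        blocks_per_arm_per_location=1,
        n_otus_bacteria=12,
        n_otus_fungi=8,
        n_habitat_factors=1,
        sequencing_depth_range=(500, 2000),
        n_planted_differential_otus=2,
    ),
    "default": dict(),
    "yield-linked": dict(yield_transitivity_slope=80.0, yield_noise_sd=0.5),
}


def fixture_config(name: str, seed: int) -> SyntheticConfig:
    if name not in FIXTURE_CONFIGS:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_CONFIGS)}")
    return SyntheticConfig(seed=seed, **FIXTURE_CONFIGS[name])


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = dataclasses.asdict(truth)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def regenerate_fixture(name: str, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write a named fixture study to disk; byte-identical per (name, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = fixture_config(name, seed)
    t16s, tits, meta, truth = generate_study(config)
    paths = {
        "otu_16s": out / "otu_16s.tsv",
        "otu_its": out / "otu_its.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.json",
    }
    write_otu_table(t16s, paths["otu_16s"])
    write_otu_table(tits, paths["otu_its"])
    write_metadata(meta, paths["metadata"])
    write_truth(truth, paths["truth"])
    return paths
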