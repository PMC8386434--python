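"""Config-driven end-to-end orchestration with logging and a digest manifest.

Stages: transform -> diversity -> networks -> local properties -> effects ->
yield model.  Every stochastic stage takes an explicit seed from the config;
re-running an identical config reproduces identical output digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from rhizonet import compositional, cooccurrence_networks as nets, diversity_stats
from rhizonet import study_io, synthetic_data, treatment_effects, yield_model

logger = logging.getLogger(__name__)

STAGES = ["transform", "diversity", "networks", "local_properties", "effects", "yield"]
REQUIRED_SEEDS = ("synthetic", "permanova", "forest")


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    seeds: dict[str, int]
    synthetic: dict[str, Any] | None = None  # SyntheticConfig kwargs
    otu_16s: str | None = None
    otu_its: str | None = None
    metadata: str | None = None
    min_prevalence: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(nets.DEFAULT_MIN_PREVALENCE)
    )
    alpha: float = 0.05
    prior_strength: float | None = None
    permanova_terms: tuple[str, ...] = ("location", "time_point", "treatment")
    n_perm: int = 999
    n_components: int = 70
    scheme: str = "two"
    n_trees: int = 500
    max_otus: int = nets.DEFAULT_MAX_OTUS

    def __post_init__(self) -> None:
        missing = [s for s in REQUIRED_SEEDS if s not in self.seeds]
        if missing:
            raise ValueError(f"config missing seeds for stochastic stages: {missing}")
        for marker, thr in self.min_prevalence.items():
            if not 0 < thr < 1:
                raise ValueError(f"prevalence threshold for {marker} must be in (0,1)")
        if self.synthetic is None and not (self.otu_16s and self.otu_its and self.metadata):
            raise ValueError("config needs either a synthetic block or all input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw.setdefault("seeds", {})
        if "permanova_terms" in raw:
            raw["permanova_terms"] = tuple(raw["permanova_terms"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_all(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }
    t_start = time.time()

    def _record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t_stage, 3)}
        for p in paths:
            manifest["outputs"][p.name] = _sha256(p)

    # ---- inputs ----------------------------------------------------------
    t_stage = time.time()
    if config.synthetic is not None:
        syn_cfg = synthetic_data.SyntheticConfig(
            seed=config.seeds["synthetic"], **config.synthetic
        )
        t16s, tits, meta, truth = synthetic_data.generate_study(syn_cfg)
        study_io.write_otu_table(t16s, out / "otu_16s.tsv")
        study_io.write_otu_table(tits, out / "otu_its.tsv")
        study_io.write_metadata(meta, out / "metadata.tsv")
        synthetic_data.write_truth(truth, out / "truth.json")
        _record("inputs", [out / f for f in
                           ("otu_16s.tsv", "otu_its.tsv", "metadata.tsv", "truth.json")])
    else:
        t16s = study_io.read_otu_table(config.otu_16s, "16S")
        tits = study_io.read_otu_table(config.otu_its, "ITS")
        meta = study_io.read_metadata(config.metadata)
        manifest["stages"]["inputs"] = {
            "digests": {p: _sha256(Path(p)) for p in
                        (config.otu_16s, config.otu_its, config.metadata)}
        }
    tables = {"16S": t16s, "ITS": tits}

    try:
        # ---- transform ---------------------------------------------------
        t_stage = time.time()
        clr = {}
        for marker, table in tables.items():
            props_m = compositional.replace_zeros(table, strength=config.prior_strength)
            clr[marker] = compositional.clr_transform(props_m)
            _write_tsv(clr[marker].to_frame(), out / f"clr_{marker.lower()}.tsv")
        _record("transform", [out / "clr_16s.tsv", out / "clr_its.tsv"])

        # ---- diversity -----------------------------------------------------
        t_stage = time.time()
        paths = []
        for marker, table in tables.items():
            alpha_df = diversity_stats.alpha_frame(diversity_stats.alpha_diversity(table))
            p = out / f"alpha_{marker.lower()}.tsv"
            _write_tsv(alpha_df, p)
            paths.append(p)
            d = compositional.aitchison_distance(clr[marker])
            res = diversity_stats.permanova(
                d, meta, list(config.permanova_terms),
                n_perm=config.n_perm, seed=config.seeds["permanova"],
            )
            p = out / f"permanova_{marker.lower()}.tsv"
            _write_tsv(res.table, p)
            paths.append(p)
        _record("diversity", paths)

        # ---- networks ------------------------------------------------------
        t_stage = time.time()
        networks, paths = {}, []
        for marker, table in tables.items():
            inc = nets.incidence_matrix(table)
            totals = dict(zip(table.otu_ids, table.counts.sum(axis=0)))
            kept = nets.filter_otus(
                inc, config.min_prevalence[marker],
                max_otus=config.max_otus, total_counts=totals,
            )
            networks[marker] = nets.build_metacommunity(
                inc, kept, alpha=config.alpha, table=table,
                provenance={
                    "marker": marker,
                    "min_prevalence": config.min_prevalence[marker],
                    "max_otus": config.max_otus,
                },
            )
            p = out / f"network_{marker.lower()}.tsv"
            study_io.write_network(networks[marker], p)
            paths.append(p)
        _record("networks", paths)

        # ---- local properties ----------------------------------------------
        t_stage = time.time()
        props = nets.properties_table(networks, tables, meta)
        _write_tsv(props, out / "local_properties.tsv")
        _record("local_properties", [out / "local_properties.tsv"])

        # ---- effects -------------------------------------------------------
        t_stage = time.time()
        paths = []
        for marker in tables:
            scan = treatment_effects.differential_abundance_scan(
                clr[marker].to_frame(), meta
            )
            p = out / f"differential_{marker.lower()}.tsv"
            _write_tsv(scan, p, index=False)
            paths.append(p)
        prop_cols = [c for c in props.columns
                     if c.startswith(("bac_", "fun_")) and not c.endswith("_S")]
        prop_scan = treatment_effects.property_trajectory_scan(props, prop_cols)
        _write_tsv(prop_scan, out / "property_effects.tsv", index=False)
        paths.append(out / "property_effects.tsv")
        summary = treatment_effects.significance_summary(prop_scan, use_q=False)
        _write_tsv(summary, out / "property_effects_summary.tsv", index=False)
        paths.append(out / "property_effects_summary.tsv")
        _record("effects", paths)

        # ---- yield ---------------------------------------------------------
        t_stage = time.time()
        ordination = compositional.joint_projection(
            clr["16S"], clr["ITS"], n_components=config.n_components
        )
        schemes = {config.scheme: yield_model.DEFAULT_SCHEMES[config.scheme]}
        reports, comparison = yield_model.sensitivity_splits(
            ordination, props, schemes=schemes,
            seed=config.seeds["forest"], n_trees=config.n_trees,
        )
        report = reports[config.scheme]
        _write_tsv(report.confusion, out / "confusion.tsv")
        _write_tsv(report.importances.rename("gini_importance").to_frame(),
                   out / "importances.tsv")
        _write_tsv(comparison, out / "scheme_comparison.tsv", index=False)
        slope, r2, pval = yield_model.transitivity_yield_regression(props)
        with open(out / "yield_summary.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "accuracy": report.accuracy,
                    "n_train": report.n_train,
                    "n_test": report.n_test,
                    "transitivity_yield": {"slope": slope, "r2": r2, "p": pval},
                },
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
        _record("yield", [out / f for f in
                          ("confusion.tsv", "importances.tsv",
                           "scheme_comparison.tsv", "yield_summary.json")])
    except Exception as exc:
        stage = next((s for s in STAGES if s not in manifest["stages"]), "unknown")
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["total_seconds"] = round(time.time() - t_start, 3)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def output_digests(manifest: dict) -> dict[str, str]:
    return dict(manifest["outputs"])
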