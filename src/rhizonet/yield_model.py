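"""Yield categorisation at density minima, feature assembly, probability-forest
classification with Gini importances, sensitivity splits, and the
transitivity–yield regression."""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelmax, argrelmin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from rhizonet.compositional import OrdinationResult

FUNGAL_TRANSITIVITY = "fun_cooccurrence_transitivity"


@dataclasses.dataclass
class ForestReport:
    probabilities: pd.DataFrame  # held-out samples x classes
    predictions: pd.Series
    truth: pd.Series
    confusion: pd.DataFrame
    accuracy: float
    importances: pd.Series  # ranked, descending
    n_train: int
    n_test: int
    seed: int


def find_density_split(yields: Sequence[float], n_thresholds: int = 1) -> list[float]:
    """Thresholds at the deepest local minima of a Gaussian KDE (Silverman
    bandwidth) of block-level yields."""
    y = np.asarray(yields, dtype=float)
    if y.size < 6:
        raise ValueError("need at least 6 yield values for density estimation")
    kde = stats.gaussian_kde(y, bw_method="silverman")
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(y.min() - bw, y.max() + bw, 2048)
    dens = kde(grid)
    minima = argrelmin(dens)[0]
    # a mode must be a substantial peak, not a tail ripple
    maxima = argrelmax(dens)[0]
    maxima = maxima[dens[maxima] >= 0.05 * dens.max()]
    if minima.size == 0 or maxima.size < 2:
        raise ValueError(
            "yield density appears unimodal; pass an explicit threshold instead"
        )
    # restrict to minima lying between the two highest modes
    top_two = sorted(maxima[np.argsort(dens[maxima])][-2:])
    inside = minima[(minima > top_two[0]) & (minima < top_two[1])]
    if inside.size < n_thresholds:
        inside = minima
    order = inside[np.argsort(dens[inside])]  # deepest first
    chosen = sorted(float(grid[i]) for i in order[:n_thresholds])
    if len(chosen) < n_thresholds:
        raise ValueError(
            f"only {len(chosen)} density minima found, {n_thresholds} requested"
        )
    return chosen


def categorize_yield(yields: Sequence[float], thresholds: Sequence[float]) -> list[str]:
    """Left-closed labelling: boundary values belong to the lower category."""
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be ascending")
    labels = []
    for y in yields:
        k = 0
        while k < len(thresholds) and y > thresholds[k]:
            k += 1
        if not thresholds:
            labels.append("all")
        elif k == 0:
            labels.append(f"<={thresholds[0]:g}")
        elif k == len(thresholds):
            labels.append(f">{thresholds[-1]:g}")
        else:
            labels.append(f"({thresholds[k - 1]:g},{thresholds[k]:g}]")
    return labels


def assemble_features(
    ordination: OrdinationResult,
    props: pd.DataFrame,
    thresholds: Sequence[float],
    property_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Feature table for the forest: joint PC scores, the 12 local network
    properties, treatment and soil-type indicators, a single geo+variety
    categorical, and the yield category label.

    T3 samples and samples without yield are excluded; any missing feature is
    a hard error naming the sample.
    """
    if property_columns is None:
        property_columns = [
            c for c in props.columns
            if c.startswith(("bac_", "fun_")) and not c.endswith("_S")
        ]
    keep = props[(props["time_point"] != "T3") & props["yield_t_ha"].notna()]
    scores = ordination.scores
    missing_samples = [s for s in keep.index if s not in scores.index]
    if missing_samples:
        raise ValueError(f"samples missing from ordination: {missing_samples[:5]}")
    feats = scores.loc[keep.index].copy()
    for col in property_columns:
        vals = keep[col]
        if vals.isna().any():
            bad = vals.index[vals.isna()][0]
            raise ValueError(f"sample {bad!r} is missing feature {col!r}")
        feats[col] = vals
    feats["treatment"] = (keep["treatment"] == "treated").astype(int)
    feats["soil_type"] = (keep["soil_type"] == "rhizosphere").astype(int)
    geo = (keep["location"].astype(str) + "|" + keep["variety"].astype(str))
    feats["geo_variety"] = pd.Categorical(geo).codes
    feats["label"] = categorize_yield(keep["yield_t_ha"].to_numpy(), thresholds)
    return feats


def fit_probability_forest(
    features: pd.DataFrame,
    test_fraction: float = 0.25,
    n_trees: int = 500,
    seed: int = 0,
) -> ForestReport:
    """Stratified split + random forest emitting averaged terminal-node class
    frequencies; reports confusion matrix, accuracy and Gini importances."""
    x = features.drop(columns=["label"])
    y = features["label"]
    if y.nunique() < 2:
        raise ValueError("need at least two yield classes to fit the forest")
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    if y_tr.nunique() < 2:
        raise ValueError("training split ended up single-class")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(x_tr, y_tr)
    proba = pd.DataFrame(
        forest.predict_proba(x_te), index=x_te.index, columns=forest.classes_
    )
    pred = proba.idxmax(axis=1)
    classes = sorted(y.unique())
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for true, hat in zip(y_te, pred):
        confusion.loc[true, hat] += 1
    accuracy = float((pred == y_te).mean())
    importances = pd.Series(
        forest.feature_importances_, index=x.columns
    ).sort_values(ascending=False)
    return ForestReport(
        probabilities=proba,
        predictions=pred,
        truth=y_te,
        confusion=confusion,
        accuracy=accuracy,
        importances=importances,
        n_train=len(x_tr),
        n_test=len(x_te),
        seed=seed,
    )


DEFAULT_SCHEMES: Mapping[str, Sequence[float] | None] = {
    "two": None,  # KDE minimum, found from the data
    "three": (26.0, 35.0),
    "four": (20.0, 26.0, 35.0),
}


def sensitivity_splits(
    ordination: OrdinationResult,
    props: pd.DataFrame,
    schemes: Mapping[str, Sequence[float] | None] = DEFAULT_SCHEMES,
    seed: int = 0,
    n_trees: int = 500,
    test_fraction: float = 0.25,
) -> tuple[dict[str, ForestReport], pd.DataFrame]:
    """One forest per category scheme plus an importance-rank comparison of
    fungal co-occurrence transitivity against the geo+variety covariate."""
    reports: dict[str, ForestReport] = {}
    rows = []
    for name, thresholds in schemes.items():
        if thresholds is None:
            keep = props[(props["time_point"] != "T3") & props["yield_t_ha"].notna()]
            block_yields = keep.groupby("block_id")["yield_t_ha"].first()
            thresholds = find_density_split(block_yields.to_numpy(), 1)
        feats = assemble_features(ordination, props, thresholds)
        report = fit_probability_forest(
            feats, test_fraction=test_fraction, n_trees=n_trees, seed=seed
        )
        reports[name] = report
        ranks = pd.Series(
            np.arange(1, len(report.importances) + 1), index=report.importances.index
        )
        rows.append(
            {
                "scheme": name,
                "n_classes": feats["label"].nunique(),
                "accuracy": report.accuracy,
                "fungal_transitivity_rank": int(ranks.get(FUNGAL_TRANSITIVITY, -1)),
                "geo_variety_rank": int(ranks.get("geo_variety", -1)),
                "transitivity_outranks_geo": bool(
                    ranks.get(FUNGAL_TRANSITIVITY, np.inf) < ranks.get("geo_variety", np.inf)
                ),
            }
        )
    return reports, pd.DataFrame(rows)


def transitivity_yield_regression(
    props: pd.DataFrame,
    property_column: str = FUNGAL_TRANSITIVITY,
    per_block: bool = True,
) -> tuple[float, float, float]:
    """OLS of block yield on block-mean fungal co-occurrence transitivity
    (T0–T2 samples).  Returns (slope, R^2, two-sided p)."""
    keep = props[(props["time_point"] != "T3") & props["yield_t_ha"].notna()]
    if per_block:
        grouped = keep.groupby("block_id").agg(
            x=(property_column, "mean"), y=("yield_t_ha", "first")
        )
        x, y = grouped["x"].to_numpy(), grouped["y"].to_numpy()
    else:
        x = keep[property_column].to_numpy(dtype=float)
        y = keep["yield_t_ha"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 blocks with yield")
    if np.isclose(x.std(), 0):
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)
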