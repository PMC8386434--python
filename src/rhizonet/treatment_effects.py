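"""Treatment x time interaction contrasts per location, applied to CLR
abundances and to local network properties, with BH multiple-testing control.

The contrast is an ordinary-least-squares two-way model on the two time
points of an interval within one location:

    value ~ treatment + time + treatment:time

whose interaction coefficient equals (change in treated) - (change in
control) — a difference of fold changes when values are CLR-scaled.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rhizonet.study_io import SampleMetadata, metadata_frame

INTERVALS = (("T0", "T1"), ("T0", "T2"), ("T0", "T3"))


@dataclasses.dataclass
class InteractionResult:
    target: str
    location: str
    interval: str  # e.g. "T0->T1"
    estimate: float
    stderr: float
    p: float
    q: float | None = None
    note: str = ""


def interaction_contrast(
    values: pd.Series,
    meta: Sequence[SampleMetadata] | pd.DataFrame,
    location: str,
    interval: tuple[str, str],
    target: str = "",
) -> InteractionResult:
    """OLS interaction estimate for one target in one location and interval."""
    meta_df = meta if isinstance(meta, pd.DataFrame) else metadata_frame(meta)
    t_from, t_to = interval
    label = f"{t_from}->{t_to}"
    sel = meta_df[
        (meta_df["location"] == location) & (meta_df["time_point"].isin([t_from, t_to]))
    ]
    sel = sel.loc[sel.index.intersection(values.index)]
    y = values.loc[sel.index].to_numpy(dtype=float)

    treated = (sel["treatment"] == "treated").to_numpy(dtype=float)
    after = (sel["time_point"] == t_to).to_numpy(dtype=float)
    cells = {(tr, af): int(((treated == tr) & (after == af)).sum())
             for tr, af in itertools.product((0.0, 1.0), repeat=2)}
    if min(cells.values()) < 2:
        return InteractionResult(target, location, label, np.nan, np.nan, np.nan,
                                 note="untestable: empty or singleton cell")

    x = np.column_stack([np.ones_like(treated), treated, after, treated * after])
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df_resid = len(y) - rank
    rss = float(resid @ resid)
    if df_resid <= 0:
        return InteractionResult(target, location, label, float(beta[3]), np.nan,
                                 np.nan, note="untestable: no residual df")
    sigma2 = rss / df_resid
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        est = float(beta[3])
        # degenerate noise-free geometry: exact estimate, no sampling variation
        p = 1.0 if abs(est) < 1e-12 else 0.0
        return InteractionResult(target, location, label, est, 0.0, p,
                                 note="degenerate: zero residual variance")
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = float(np.sqrt(cov[3, 3]))
    t_stat = beta[3] / se
    p = float(2 * stats.t.sf(abs(t_stat), df_resid))
    return InteractionResult(target, location, label, float(beta[3]), se, p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving on input index."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _results_frame(results: list[InteractionResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def differential_abundance_scan(
    clr: pd.DataFrame,
    meta: Sequence[SampleMetadata] | pd.DataFrame,
    intervals: Sequence[tuple[str, str]] = INTERVALS,
    locations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Interaction contrast per OTU x location x interval with BH q-values
    within each (location, interval) family."""
    meta_df = meta if isinstance(meta, pd.DataFrame) else metadata_frame(meta)
    if locations is None:
        locations = sorted(meta_df["location"].unique())
    results: list[InteractionResult] = []
    for location in locations:
        for interval in intervals:
            family: list[InteractionResult] = []
            for otu in clr.columns:
                family.append(
                    interaction_contrast(clr[otu], meta_df, location, interval, target=otu)
                )
            testable = [r for r in family if not np.isnan(r.p)]
            if testable:
                qs = bh_adjust([r.p for r in testable])
                for r, q in zip(testable, qs):
                    r.q = float(q)
            results.extend(family)
    return _results_frame(results)


def property_trajectory_scan(
    props: pd.DataFrame,
    property_columns: Sequence[str],
    intervals: Sequence[tuple[str, str]] = INTERVALS,
    locations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Interaction contrasts of local network properties (metadata columns and
    property columns live in the same frame, as built by properties_table)."""
    if locations is None:
        locations = sorted(props["location"].unique())
    results: list[InteractionResult] = []
    for location in locations:
        for interval in intervals:
            for col in property_columns:
                r = interaction_contrast(
                    props[col].dropna(), props, location, interval, target=col
                )
                results.append(r)
    df = _results_frame(results)
    testable = df["p"].notna()
    if testable.any():
        df.loc[testable, "q"] = bh_adjust(df.loc[testable, "p"].to_numpy())
    df["direction"] = np.sign(df["estimate"]).fillna(0).astype(int)
    return df


def significance_summary(scan: pd.DataFrame, alpha: float = 0.05, use_q: bool = True) -> pd.DataFrame:
    """Count significant targets per (location, interval), Fig-3C-style."""
    col = "q" if use_q else "p"
    sig = scan[scan[col].notna() & (scan[col] < alpha)]
    return (
        sig.groupby(["location", "interval"])
        .size()
        .rename("n_significant")
        .reset_index()
    )
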