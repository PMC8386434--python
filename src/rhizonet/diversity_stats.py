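"""Alpha diversity, subgroup tests, per-group normalisation, PERMANOVA on
distance matrices, and genus-level composition summaries."""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rhizonet.study_io import OtuTable, SampleMetadata, metadata_frame

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AlphaRecord:
    sample_id: str
    richness: int
    shannon: float


@dataclasses.dataclass
class PermanovaResult:
    """Sequential (Type I) partition of a distance matrix's sum of squares."""

    table: pd.DataFrame  # rows: terms + Residual + Total
    total_ss: float
    n_permutations: int

    def r_squared(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def alpha_diversity(table: OtuTable) -> list[AlphaRecord]:
    """Richness (OTUs with count > 0) and Shannon H' in nats, per sample."""
    records = []
    for i, sample_id in enumerate(table.sample_ids):
        counts = table.counts[i]
        nz = counts[counts > 0]
        richness = int(nz.size)
        if richness == 0:
            logger.warning("sample %s has no counts; H'=0", sample_id)
            records.append(AlphaRecord(sample_id, 0, 0.0))
            continue
        p = nz / nz.sum()
        shannon = float(-(p * np.log(p)).sum())
        records.append(AlphaRecord(sample_id, richness, max(shannon, 0.0)))
    return records


def alpha_frame(records: Sequence[AlphaRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.set_index("sample_id")


def wilcoxon_rank_sum(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided rank-sum test; exact for combined n <= 20 without ties."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def zscore_by_group(values: Sequence[float], grouping: Sequence[str]) -> np.ndarray:
    """Center and scale (sd with n-1 denominator) within each group."""
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    out = np.empty_like(values)
    for g in pd.unique(grouping):
        mask = grouping == g
        sub = values[mask]
        if sub.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        sd = sub.std(ddof=1)
        if sd == 0:
            raise ValueError(f"group {g!r} has zero variance")
        out[mask] = (sub - sub.mean()) / sd
    return out


def time_effect_tests(
    alpha: pd.DataFrame,
    meta: Sequence[SampleMetadata],
    metric: str = "shannon",
    reference: str = "T0",
) -> pd.DataFrame:
    """Contrasts of each later time point against the reference on per-location
    Z-scored alpha diversity (one-way ANOVA framework with pairwise t tests)."""
    meta_df = metadata_frame(meta)
    df = meta_df.join(alpha[[metric]], how="inner")
    df = df.dropna(subset=[metric])
    df["z"] = zscore_by_group(df[metric].to_numpy(), df["location"].to_numpy())

    groups = [g["z"].to_numpy() for _, g in df.groupby("time_point") if len(g) >= 2]
    f_stat, f_p = (np.nan, np.nan)
    if len(groups) >= 2:
        f_stat, f_p = stats.f_oneway(*groups)

    ref = df[df["time_point"] == reference]["z"].to_numpy()
    rows = []
    for tp in sorted(df["time_point"].unique()):
        if tp == reference:
            continue
        other = df[df["time_point"] == tp]["z"].to_numpy()
        if ref.size < 2 or other.size < 2:
            rows.append({"contrast": f"{reference}_vs_{tp}", "estimate": np.nan,
                         "t": np.nan, "p": np.nan, "note": "insufficient samples"})
            continue
        est = float(other.mean() - ref.mean())
        if np.allclose(other, other.mean()) and np.allclose(ref, ref.mean()) and est == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(other, ref, equal_var=True)
        rows.append({"contrast": f"{reference}_vs_{tp}", "estimate": est,
                     "t": float(t), "p": float(p), "note": ""})
    out = pd.DataFrame(rows)
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(f_p)
    return out


# ---------------------------------------------------------------------------
# PERMANOVA


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -1/2 J D^2 J."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d**2) @ j


def _design(meta_df: pd.DataFrame, term: str) -> np.ndarray:
    """Full-rank-agnostic dummy design for a term, ':' denoting interaction."""
    factors = term.split(":")
    combined = meta_df[factors[0]].astype(str)
    for f in factors[1:]:
        combined = combined + "\x1f" + meta_df[f].astype(str)
    return pd.get_dummies(combined, dtype=float).to_numpy()


def permanova(
    d: pd.DataFrame | np.ndarray,
    meta: Sequence[SampleMetadata] | pd.DataFrame,
    terms: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (Type I) distance-based multivariate ANOVA.

    Terms are added in the given order; each term's SS is the trace of the
    projector increment applied to the Gower-centered matrix.  P-values use
    whole-row permutations with the (1 + exceedances) / (1 + n_perm) estimator.
    Aliased terms (no new degrees of freedom) are reported with df 0.
    """
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
        ids = None
    if not np.allclose(dm, dm.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    meta_df = meta if isinstance(meta, pd.DataFrame) else metadata_frame(meta)
    if ids is not None:
        meta_df = meta_df.loc[ids]

    n = dm.shape[0]
    g = gower_center(dm)
    total_ss = float(np.trace(g))

    # cumulative hat matrices; projector increments per term
    x = np.ones((n, 1))
    h_prev = np.full((n, n), 1.0 / n)
    rank_prev = 1
    increments: list[np.ndarray] = []
    dfs: list[int] = []
    for term in terms:
        x = np.hstack([x, _design(meta_df, term)])
        u, sv, _ = np.linalg.svd(x, full_matrices=False)
        rank = int((sv > sv[0] * 1e-10).sum())
        uk = u[:, :rank]
        h = uk @ uk.T
        increments.append(h - h_prev)
        dfs.append(rank - rank_prev)
        h_prev, rank_prev = h, rank
    resid_proj = np.eye(n) - h_prev
    df_resid = n - rank_prev

    def _stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float((p * gmat).sum()) for p in increments])
        ss_res = float((resid_proj * gmat).sum())
        return ss, ss_res

    ss_terms, ss_res = _stats(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_res = ss_res / df_resid if df_resid > 0 else np.nan
        f_obs = np.array(
            [
                (ss_terms[i] / dfs[i]) / ms_res if dfs[i] > 0 and ms_res > 0 else np.nan
                for i in range(len(terms))
            ]
        )

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = _stats(gp)
        ms_res_p = ss_res_p / df_resid if df_resid > 0 else np.nan
        for i in range(len(terms)):
            if dfs[i] > 0 and ms_res_p > 0:
                f_p = (ss_p[i] / dfs[i]) / ms_res_p
                if f_p >= f_obs[i] - 1e-12:
                    exceed[i] += 1
    p_vals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": dfs[i],
                "SS": ss_terms[i],
                "R2": ss_terms[i] / total_ss if total_ss > 0 else np.nan,
                "F": f_obs[i],
                "p": p_vals[i] if dfs[i] > 0 else np.nan,
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_resid,
            "SS": ss_res,
            "R2": ss_res / total_ss if total_ss > 0 else np.nan,
            "F": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {"term": "Total", "df": n - 1, "SS": total_ss, "R2": 1.0, "F": np.nan, "p": np.nan}
    )
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=table, total_ss=total_ss, n_permutations=n_perm)


def top_genera(table: OtuTable, k: int = 15) -> pd.DataFrame:
    """Relative abundance per sample aggregated by genus; top k by overall mean."""
    genera = ["unclassified" if g == "" else g for g in table.genus()]
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=table.otu_ids)
    agg = df.T.groupby(pd.Index(genera, name="genus")).sum().T
    totals = agg.sum(axis=1)
    rel = agg.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    order = rel.mean(axis=0).sort_values(ascending=False)
    return rel[order.index[: min(k, len(order))]].T
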