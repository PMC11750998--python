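"""Group-difference statistics over functional-connectivity features.

For every ROI-pair connection the three diagnostic groups are compared
with a one-way fixed-effects ANOVA; p-values are Benjamini-Hochberg
adjusted within each (estimator, chromophore) family; connections
surviving the corrected 0.05 gate get Fisher LSD-t pairwise post-hoc
contrasts using the omnibus within-group mean square. Features failing a
Shapiro-Wilk normality check are z-score standardized beforehand (a rank-
preserving rescaling; it does not change the ANOVA, but is applied for
procedural fidelity and exposed in the results).

The statsmodels-style entry point is :class:`GroupDifferenceModel`, whose
``fit()`` returns a :class:`GroupDifferenceResults` carrying the tidy
per-connection table and a ``summary()``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_feature",
    "anova_oneway",
    "fdr_adjust",
    "lsd_posthoc",
    "GroupDifferenceModel",
    "GroupDifferenceResults",
    "run_group_analysis",
]


def normalize_feature(values: np.ndarray) -> np.ndarray:
    """z-score standardize a feature vector: (x - mean) / sample sd.

    Raises on zero variance (such connections are excluded upstream).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: feature cannot be standardized")
    return (x - x.mean()) / sd


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """Classical one-way fixed-effects ANOVA from explicit sums of squares.

    Returns (F, df_between, df_within, p). F = MS_between / MS_within with
    MS_between = SSB/(k-1), MS_within = SSW/(N-k).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least two observations")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = all_vals.size - len(groups)
    if ssw <= 0:
        raise ValueError("zero within-group variance: F undefined")
    f = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def lsd_posthoc(
    groups: list[np.ndarray], pair: tuple[int, int]
) -> tuple[float, float]:
    """Fisher least-significant-difference pairwise t-test.

    Uses the omnibus ANOVA's pooled within-group mean square:
    t = (mean_a - mean_b) / sqrt(MSW * (1/n_a + 1/n_b)), df = N - k.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    a, b = pair
    msw_num = sum(((g - g.mean()) ** 2).sum() for g in groups)
    n_total = sum(g.size for g in groups)
    df = n_total - len(groups)
    msw = msw_num / df
    if msw <= 0:
        raise ValueError("zero within-group mean square: t undefined")
    ga, gb = groups[a], groups[b]
    t = (ga.mean() - gb.mean()) / np.sqrt(msw * (1 / ga.size + 1 / gb.size))
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), p


@dataclass
class GroupDifferenceResults:
    """Per-connection ANOVA/FDR/LSD-t results.

    ``table`` columns: estimator, chromophore, roi_i, roi_j, n, normal,
    F, df1, df2, p_raw, p_fdr, then per pairwise contrast X_vs_Y a
    (t, p) column pair (NaN where the corrected gate was not passed).
    """

    table: pd.DataFrame
    alpha: float
    fdr_family: str
    excluded: list[str]

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p_fdr"] < self.alpha]

    def summary(self) -> str:
        n_sig = int((self.table["p_fdr"] < self.alpha).sum())
        lines = [
            "Group-difference analysis (one-way ANOVA + BH-FDR + LSD-t)",
            f"  connections tested : {len(self.table)}",
            f"  FDR family         : {self.fdr_family}",
            f"  significant (q<{self.alpha:g}) : {n_sig}",
            f"  excluded (degenerate): {len(self.excluded)}",
        ]
        if n_sig:
            lines.append("")
            cols = ["estimator", "chromophore", "roi_i", "roi_j", "F", "p_raw", "p_fdr"]
            lines.append(
                self.significant[cols]
                .sort_values("p_fdr")
                .to_string(index=False, float_format=lambda v: f"{v:.4g}")
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


class GroupDifferenceModel:
    """Three-group comparison of connection-wise FC values.

    Parameters
    ----------
    features : DataFrame
        Wide feature table, one row per subject, FC columns named
        ``{estimator}_{chromophore}_ROI{i}_ROI{j}``.
    labels : Series or array
        Group label per subject (aligned with ``features`` rows).
    alpha : float
        Gate for post-hoc testing on the FDR-corrected p-value.
    fdr_family : {"per", "pooled"}
        Whether BH correction runs within each (estimator, chromophore)
        family of 45 connections or pooled over all connections.
    normality_alpha : float
        Shapiro-Wilk level deciding whether a connection is z-scored.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels,
        alpha: float = 0.05,
        fdr_family: str = "per",
        normality_alpha: float = 0.05,
    ) -> None:
        if fdr_family not in ("per", "pooled"):
            raise ValueError("fdr_family must be 'per' or 'pooled'")
        self.features = features
        self.labels = np.asarray(labels)
        if len(self.labels) != len(features):
            raise ValueError("labels must align with feature rows")
        self.groups = sorted(pd.unique(self.labels))
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        self.alpha = alpha
        self.fdr_family = fdr_family
        self.normality_alpha = normality_alpha

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "group", **kwargs
    ) -> "GroupDifferenceModel":
        feature_cols = [c for c in df.columns if _parse_fc_column(c) is not None]
        return cls(df[feature_cols], df[label_col], **kwargs)

    def fit(self) -> GroupDifferenceResults:
        rows: list[dict] = []
        excluded: list[str] = []
        pairs = list(itertools.combinations(range(len(self.groups)), 2))
        for col in self.features.columns:
            parsed = _parse_fc_column(col)
            if parsed is None:
                continue
            est, ch, i, j = parsed
            vals = self.features[col].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            vals, labs = vals[ok], self.labels[ok]
            grouped = [vals[labs == g] for g in self.groups]
            if any(g.size < 2 for g in grouped):
                excluded.append(col)
                continue
            if np.std(vals, ddof=1) == 0:
                excluded.append(col)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normal = stats.shapiro(vals).pvalue >= self.normality_alpha
            if not normal:
                z = normalize_feature(vals)
                grouped = [z[labs == g] for g in self.groups]
            try:
                f, df1, df2, p = anova_oneway(grouped)
            except ValueError:
                excluded.append(col)
                continue
            row = {
                "estimator": est,
                "chromophore": ch,
                "roi_i": i,
                "roi_j": j,
                "n": int(vals.size),
                "normal": bool(normal),
                "F": f,
                "df1": df1,
                "df2": df2,
                "p_raw": p,
                "_grouped": grouped,
            }
            rows.append(row)
        if not rows:
            table = pd.DataFrame(
                columns=["estimator", "chromophore", "roi_i", "roi_j", "n",
                         "normal", "F", "df1", "df2", "p_raw", "p_fdr"]
            )
            return GroupDifferenceResults(table, self.alpha, self.fdr_family, excluded)

        table = pd.DataFrame(rows)
        if self.fdr_family == "pooled":
            table["p_fdr"] = fdr_adjust(table["p_raw"].to_numpy())
        else:
            table["p_fdr"] = np.nan
            for _, idx in table.groupby(["estimator", "chromophore"]).groups.items():
                table.loc[idx, "p_fdr"] = fdr_adjust(
                    table.loc[idx, "p_raw"].to_numpy()
                )

        for a, b in pairs:
            name = f"{self.groups[a]}_vs_{self.groups[b]}"
            table[f"t_{name}"] = np.nan
            table[f"p_{name}"] = np.nan
        for ridx, row in table.iterrows():
            if row["p_fdr"] >= self.alpha:
                continue
            grouped = row["_grouped"]
            for a, b in pairs:
                name = f"{self.groups[a]}_vs_{self.groups[b]}"
                try:
                    t, p = lsd_posthoc(grouped, (a, b))
                except ValueError:
                    continue
                table.loc[ridx, f"t_{name}"] = t
                table.loc[ridx, f"p_{name}"] = p
        table = table.drop(columns="_grouped")
        return GroupDifferenceResults(table, self.alpha, self.fdr_family, excluded)


def _parse_fc_column(name: str):
    """Parse 'est_chrom_ROIi_ROIj' feature names; None if not an FC column."""
    parts = str(name).split("_")
    if len(parts) != 4:
        return None
    est, ch, ri, rj = parts
    if not (ri.startswith("ROI") and rj.startswith("ROI")):
        return None
    try:
        return est, ch, int(ri[3:]), int(rj[3:])
    except ValueError:
        return None


def run_group_analysis(
    features: pd.DataFrame, labels, **kwargs
) -> GroupDifferenceResults:
    """Functional wrapper: build a :class:`GroupDifferenceModel` and fit it."""
    return GroupDifferenceModel(features, labels, **kwargs).fit()
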