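"""Cross-modality concordance and group comparisons.

The concordance analysis pairs a class's regional prevalence between two
modalities (e.g. transcript vs protein), reports the Pearson correlation with
a two-sided p-value, the ordinary-least-squares line of best fit, and 95%
prediction intervals

    ŷ(x) ± t(0.975, n−2) · s · sqrt(1 + 1/n + (x − x̄)² / Sxx)

where s² is the residual mean square. Regions with absent prevalence (no
cells) are excluded pairwise; the exclusion count is reported.

Group comparisons are a two-factor ANOVA (Type II sums of squares for
unbalanced data) with Tukey–Kramer pairwise adjusted p-values across the cell
means, computed from the studentized range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.formula.api import ols


class ConcordanceError(ValueError):
    pass


@dataclass
class ConcordanceResult:
    cls: str
    n_regions: int
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    region_ids: list[int]
    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    pi_half_width: np.ndarray
    n_excluded: int = 0
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "class": self.cls,
            "n_regions": self.n_regions,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "slope": self.slope,
            "intercept": self.intercept,
            "n_excluded": self.n_excluded,
            "status": self.status,
            "region_ids": [int(r) for r in self.region_ids],
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "x": self.x,
                "y": self.y,
                "fitted": self.fitted,
                "pi_half_width": self.pi_half_width,
            }
        )


def prediction_interval_half_width(
    x: np.ndarray, x_train: np.ndarray, resid_ms: float, level: float = 0.95
) -> np.ndarray:
    """Half-width of the OLS prediction interval at each ``x``."""
    n = len(x_train)
    xbar = float(np.mean(x_train))
    sxx = float(np.sum((x_train - xbar) ** 2))
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 2)
    return tcrit * np.sqrt(resid_ms) * np.sqrt(1.0 + 1.0 / n + (x - xbar) ** 2 / sxx)


def correlate_modalities(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    cls: str = "high",
    min_cells: int = 1,
) -> ConcordanceResult:
    """Correlate one class's prevalence across regions matched between two
    RegionStats tables.

    Regions must appear in both tables with ``n_total >= min_cells`` and a
    defined prevalence; at least 3 such regions are required. Pearson r uses
    the t transform with n−2 df for its two-sided p; slope/intercept are OLS
    of b on a; prediction intervals are evaluated at each matched x.
    """
    col = f"prev_{cls[:4] if cls == 'medium' else cls}"
    col = {"low": "prev_low", "medium": "prev_med", "high": "prev_high"}[cls]
    merged = stats_a.merge(
        stats_b, on="region_id", suffixes=("_a", "_b"), how="inner"
    )
    merged = merged[merged["region_id"] != 0]
    before = len(merged)
    merged = merged[
        (merged["n_total_a"] >= min_cells)
        & (merged["n_total_b"] >= min_cells)
        & merged[f"{col}_a"].notna()
        & merged[f"{col}_b"].notna()
    ]
    n_excluded = before - len(merged)
    n = len(merged)
    if n < 3:
        raise ConcordanceError(
            f"only {n} matched regions with >= {min_cells} cells; need >= 3"
        )
    x = merged[f"{col}_a"].to_numpy(dtype=float)
    y = merged[f"{col}_b"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return ConcordanceResult(
            cls=cls,
            n_regions=n,
            pearson_r=np.nan,
            p_value=np.nan,
            slope=np.nan,
            intercept=np.nan,
            region_ids=merged["region_id"].tolist(),
            x=x,
            y=y,
            fitted=np.full(n, np.nan),
            pi_half_width=np.full(n, np.nan),
            n_excluded=n_excluded,
            status="undefined: zero variance in one modality",
        )
    r, p = stats.pearsonr(x, y)
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    fitted = intercept + slope * x
    resid_ms = float(np.sum((y - fitted) ** 2) / (n - 2))
    half = prediction_interval_half_width(x, x, resid_ms)
    return ConcordanceResult(
        cls=cls,
        n_regions=n,
        pearson_r=float(r),
        p_value=float(p),
        slope=slope,
        intercept=intercept,
        region_ids=merged["region_id"].tolist(),
        x=x,
        y=y,
        fitted=fitted,
        pi_half_width=half,
        n_excluded=n_excluded,
    )


def prediction_interval_coverage(
    n_regions: int = 20,
    noise_sd: float = 5.0,
    n_reps: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> float:
    """Monte-Carlo check of the nominal prediction-interval level.

    Each replicate simulates linear data y = a + b·x + ε over ``n_regions``
    x-positions, fits OLS, then draws one fresh observation at every x and
    scores whether it falls inside its interval. Returns the empirical
    coverage fraction over all replicates × positions.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if noise_sd < 0:
        raise ValueError("noise SD must be nonnegative")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 100.0, n_regions)
    a, b = 10.0, 0.7
    hits = 0
    total = 0
    for _ in range(n_reps):
        y = a + b * x + rng.normal(0.0, noise_sd, n_regions)
        coef = np.polyfit(x, y, 1)
        fitted = np.polyval(coef, x)
        resid_ms = float(np.sum((y - fitted) ** 2) / (n_regions - 2))
        half = prediction_interval_half_width(x, x, resid_ms, level)
        fresh = a + b * x + rng.normal(0.0, noise_sd, n_regions)
        hits += int(np.sum(np.abs(fresh - fitted) <= half))
        total += n_regions
    return hits / total


# ---------------------------------------------------------------------------
# two-factor ANOVA with Tukey–Kramer post hoc


@dataclass
class GroupComparison:
    anova: pd.DataFrame
    tukey: pd.DataFrame
    n_obs: int
    interaction_included: bool
    ss_type: str = "II"

    def to_dict(self) -> dict:
        return {
            "anova": self.anova.reset_index()
            .rename(columns={"index": "effect"})
            .to_dict(orient="records"),
            "tukey": self.tukey.to_dict(orient="records"),
            "n_obs": self.n_obs,
            "interaction_included": self.interaction_included,
            "ss_type": self.ss_type,
        }


def tukey_kramer(
    values: np.ndarray,
    groups: np.ndarray,
    mse: float,
    df_resid: int,
) -> pd.DataFrame:
    """Tukey–Kramer pairwise comparisons of group means.

    For groups i, j: q = |m_i − m_j| / sqrt(MSE/2 · (1/n_i + 1/n_j)); the
    adjusted p is the studentized-range survival function at q with k groups
    and ``df_resid`` degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups).tolist(), key=str)
    k = len(names)
    means = {g: values[groups == g].mean() for g in names}
    ns = {g: int((groups == g).sum()) for g in names}
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = names[i], names[j]
            diff = means[g2] - means[g1]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_resid))
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "mean_diff": float(diff),
                    "q": float(q),
                    "p_adj": min(max(p, 0.0), 1.0),
                }
            )
    return pd.DataFrame(rows)


def compare_groups_anova(
    values,
    factor_a,
    factor_b,
    interaction: bool | None = None,
) -> GroupComparison:
    """Two-factor ANOVA (Type II) with Tukey–Kramer post hoc across the
    factor-cell means.

    The interaction term is included when every occupied cell holds at least
    2 observations (or as forced by ``interaction``). The residual mean
    square of the fitted model feeds the Tukey–Kramer comparisons across the
    a×b cells.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": np.asarray(factor_a).astype(str),
            "b": np.asarray(factor_b).astype(str),
        }
    )
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    if df["value"].nunique() == 1:
        raise ValueError("all observations identical; ANOVA undefined")
    cell_sizes = df.groupby(["a", "b"]).size()
    if interaction is None:
        interaction = bool((cell_sizes >= 2).all())
    formula = "value ~ C(a) * C(b)" if interaction else "value ~ C(a) + C(b)"
    model = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    mse = float(model.mse_resid)
    df_resid = int(model.df_resid)
    cell = (df["a"] + ":" + df["b"]).to_numpy()
    tukey = tukey_kramer(df["value"].to_numpy(), cell, mse, df_resid)
    return GroupComparison(
        anova=table,
        tukey=tukey,
        n_obs=len(df),
        interaction_included=interaction,
    )
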