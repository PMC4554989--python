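"""Group-level analysis of per-individual fits.

Takes the flat fit table produced by :func:`springdamp.fitting.fit_cohort`
(one row per individual x measure) and provides:

* Tukey-fence outlier exclusion on the raw K and C scales (+-1.5 x IQR per
  measure) — flagged, never dropped;
* per-line summaries of K, C and the derived T and x_inf (each averaged as
  per-individual values, so the printed mean T is deliberately not the ratio
  of the printed means);
* a line-effect contrast on log-parameters by ordinary least squares with
  backward elimination of non-significant replicate terms;
* Pearson correlations between every measure x parameter column.

K and C are log-transformed before inferential statistics to improve
normality; exclusion precedes the log transform and operates on the raw
scale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "exclude_outliers",
    "tukey_fences",
    "summarize_by_line",
    "LineEffectResult",
    "line_effect_test",
    "CorrelationResult",
    "parameter_correlations",
]


def tukey_fences(values, k: float = 1.5) -> tuple[float, float]:
    """[Q1 - k*IQR, Q3 + k*IQR] with linearly interpolated quartiles (type 7)."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def exclude_outliers(
    table: pd.DataFrame,
    parameters: tuple[str, ...] = ("K", "C"),
    k: float = 1.5,
    group_col: str = "measure",
    min_rows: int = 4,
) -> pd.DataFrame:
    """Flag rows whose K or C falls outside the Tukey fences of their measure.

    Fences are computed once per measure from all rows of that measure (a
    single frozen pass, so the operation is idempotent on its own output),
    on the raw parameter scale.  A row is flagged when either parameter falls
    strictly outside its fences; equal-to-fence values — including the
    degenerate all-identical case where the fences collapse to a point — are
    inside.  Groups with fewer than ``min_rows`` rows are left unflagged with
    a warning.  Returns a copy with the ``excluded`` column set.
    """
    out = table.copy()
    out["excluded"] = False
    for group, idx in out.groupby(group_col).groups.items():
        sub = out.loc[idx]
        if len(sub) < min_rows:
            warnings.warn(
                f"{group_col}={group!r}: only {len(sub)} rows, too few for "
                "meaningful Tukey fences; no exclusion applied",
                stacklevel=2,
            )
            continue
        flag = np.zeros(len(sub), dtype=bool)
        for p in parameters:
            lo, hi = tukey_fences(sub[p].to_numpy(), k)
            v = sub[p].to_numpy()
            flag |= (v < lo) | (v > hi)
        out.loc[idx, "excluded"] = flag
    return out


def summarize_by_line(table: pd.DataFrame) -> pd.DataFrame:
    """Per line x measure arithmetic means of K, C, T and x_inf.

    Excluded rows are omitted.  T and x_inf are averaged as per-individual
    derived values, not recomputed from the mean K and mean C — so in general
    mean(T) != mean(C)/mean(K).
    """
    kept = table[~table["excluded"]]
    if kept.empty:
        warnings.warn("no non-excluded rows to summarize", stacklevel=2)
        return pd.DataFrame(columns=["line", "measure", "K", "C", "T", "x_inf", "n"])
    grouped = kept.groupby(["line", "measure"], dropna=False)
    summary = grouped[["K", "C", "T", "x_inf"]].mean()
    summary["n"] = grouped.size()
    lines = kept["line"].unique()
    measures = kept["measure"].unique()
    n_cells = len(lines) * len(measures)
    if len(summary) < n_cells:
        warnings.warn(
            f"{n_cells - len(summary)} empty line x measure cell(s) absent "
            "from the summary",
            stacklevel=2,
        )
    return summary.reset_index()


@dataclass(frozen=True)
class LineEffectResult:
    """Back-transformed per-line means and the p-value of the line effect."""

    measure: str
    parameter: str
    estimates: dict
    p_value: float
    formula: str
    n: int


def _term_p(model_fit, term: str) -> float:
    table = anova_lm(model_fit, typ=2)
    return float(table.loc[term, "PR(>F)"])


def line_effect_test(
    table: pd.DataFrame,
    measure: str,
    parameter: str = "K",
    alpha: float = 0.05,
) -> LineEffectResult:
    """Test the line effect on log(K) or log(C) for one measure.

    An ordinary least-squares model of the log-parameter on line, replicate
    and their interaction is fitted on non-excluded rows; non-significant
    replicate terms (interaction first, then the main effect) are dropped at
    ``alpha`` and the model refitted, the backward step.  The line term is
    always retained.  Per-line estimates are model-predicted log-means,
    averaged over any retained replicate levels and back-transformed.
    """
    if parameter not in ("K", "C"):
        raise ValueError("parameter must be 'K' or 'C'")
    sub = table[(table["measure"] == measure) & (~table["excluded"])].copy()
    lines = sorted(sub["line"].dropna().unique())
    if len(lines) < 2:
        raise ValueError(f"need >= 2 lines for measure {measure!r}, got {lines}")
    counts = sub.groupby("line").size()
    if (counts < 2).any():
        raise ValueError(f"need >= 2 non-excluded rows per line, got {dict(counts)}")
    # minimal modelling frame: the fit table's own "C" column would shadow
    # patsy's categorical operator C() in the formula namespace
    sub = pd.DataFrame({
        "logp": np.log(sub[parameter].to_numpy()),
        "line": sub["line"].to_numpy(),
        "replicate": sub["replicate"].to_numpy(),
    })
    replicates = sub["replicate"].dropna().unique()

    terms = ["C(line)"]
    if len(replicates) >= 2:
        terms += ["C(replicate)", "C(line):C(replicate)"]
    while True:
        formula = "logp ~ " + " + ".join(terms)
        fit = smf.ols(formula, data=sub).fit()
        if "C(line):C(replicate)" in terms:
            if _term_p(fit, "C(line):C(replicate)") >= alpha:
                terms.remove("C(line):C(replicate)")
                continue
            break  # significant interaction: keep the full model (hierarchy)
        if "C(replicate)" in terms and _term_p(fit, "C(replicate)") >= alpha:
            terms.remove("C(replicate)")
            continue
        break

    p_line = _term_p(fit, "C(line)")
    # balanced prediction grid: average over retained replicate levels
    if any("replicate" in t for t in terms):
        grid = pd.DataFrame(
            list(itertools.product(lines, replicates)),
            columns=["line", "replicate"],
        )
    else:
        grid = pd.DataFrame({"line": lines})
    grid["pred"] = fit.predict(grid)
    estimates = {
        line: float(np.exp(g["pred"].mean()))
        for line, g in grid.groupby("line")
    }
    return LineEffectResult(
        measure=measure, parameter=parameter, estimates=estimates,
        p_value=p_line, formula=formula, n=len(sub),
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation matrix across measure x parameter columns.

    ``r`` is symmetric with unit diagonal; ``p`` holds the two-sided
    p-values (NaN on the diagonal); ``n`` the pairwise-complete counts.
    ``adjusted_p``, present when Benjamini–Hochberg adjustment is requested,
    corrects the off-diagonal p-values.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    adjusted_p: pd.DataFrame | None = None


def parameter_correlations(
    table: pd.DataFrame,
    parameters: tuple[str, ...] = ("K", "C"),
    min_pairs: int = 3,
    adjust: bool = False,
) -> CorrelationResult:
    """Pearson correlations between all measure x parameter columns.

    Rows flagged ``excluded`` are omitted; each pair uses pairwise-complete
    individuals and entries with fewer than ``min_pairs`` complete pairs are
    absent (NaN).  Unadjusted p-values are reported by default, matching
    common practice for exploratory parameter-correlation tables; set
    ``adjust`` for an optional Benjamini–Hochberg correction.
    """
    kept = table[~table["excluded"]]
    wide = {}
    for measure, g in kept.groupby("measure"):
        for p in parameters:
            wide[f"{measure}:{p}"] = g.set_index("individual_id")[p]
    wide_df = pd.DataFrame(wide)
    cols = [
        f"{m}:{p}"
        for m in kept["measure"].unique()
        for p in parameters
        if f"{m}:{p}" in wide_df
    ]
    wide_df = wide_df[cols]

    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pmat = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    nmat = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    np.fill_diagonal(nmat.values, wide_df.notna().sum().to_numpy())
    for i, a in enumerate(cols):
        for j in range(i + 1, k):
            b = cols[j]
            pair = wide_df[[a, b]].dropna()
            nmat.loc[a, b] = nmat.loc[b, a] = len(pair)
            if len(pair) < min_pairs:
                r.loc[a, b] = r.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = float(res.statistic)
            pmat.loc[a, b] = pmat.loc[b, a] = float(res.pvalue)

    adjusted = None
    if adjust:
        iu = np.triu_indices(k, 1)
        raw = pmat.to_numpy()[iu]
        ok = ~np.isnan(raw)
        adj = np.full_like(raw, np.nan)
        if ok.any():
            adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
        amat = np.full((k, k), np.nan)
        amat[iu] = adj
        amat.T[iu] = adj
        adjusted = pd.DataFrame(amat, index=cols, columns=cols)
    return CorrelationResult(r=r, p=pmat, n=nmat, adjusted_p=adjusted)
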