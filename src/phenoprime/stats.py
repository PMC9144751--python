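"""Statistical analysis of trait and metabolite tables.

Covers the analysis surface of a plate-based priming screen:

* Kruskal–Wallis rank tests of the growth AUC for each treatment
  against the unprimed control within a growth condition.
* Per-metabolite one-way ANOVA on ln-transformed concentrations with a
  Tukey-HSD (default) or Duncan multiple-range post hoc versus control;
  an optional two-way treatment×condition ANOVA.
* PCA by singular value decomposition with biplot coordinates.
* Pearson correlation matrices with two-sided t-distribution p-values.
* The ln group-mean matrix underlying class-blocked metabolite
  heatmaps.

Trait tables are tidy frames from
:func:`phenoprime.traits.compute_trait_table`; metabolite data travel
as :class:`MetaboliteTable`.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "MetaboliteTable",
    "StatsError",
    "AnovaResult",
    "PCAResult",
    "PearsonResult",
    "HeatmapResult",
    "kruskal_auc",
    "metabolite_anova",
    "pca_svd",
    "pca_metabolites",
    "pearson_matrix",
    "heatmap_matrix",
    "METABOLITE_CLASSES",
]

METABOLITE_CLASSES = ("free amino acid", "total polyamine", "free polyamine")


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


@dataclass
class MetaboliteTable:
    """Sample × metabolite concentration table with group labels.

    ``values`` holds strictly positive concentrations (rows indexed by
    sample id), ``meta`` the per-sample design columns
    (treatment, concentration, condition) on the same index, and
    ``classes`` maps each metabolite to its class (free amino acid,
    total polyamine or free polyamine).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    classes: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise StatsError("duplicate sample ids")
        if not self.values.index.equals(self.meta.index):
            raise StatsError("values and meta must share the sample index")
        for col in ("treatment", "concentration", "condition"):
            if col not in self.meta.columns:
                raise StatsError(f"meta is missing required column {col!r}")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise StatsError("concentrations must be finite and strictly positive")
        missing = [m for m in self.values.columns if m not in self.classes.index]
        if missing:
            raise StatsError(f"metabolites without a class: {missing}")
        if self.classes.isna().any():
            raise StatsError("every metabolite needs a class label")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def group_labels(self) -> pd.Series:
        """Human-readable treatment×condition label per sample."""
        def lab(row):
            if row["treatment"] == "control":
                t = "control"
            else:
                t = f"{row['concentration']:g} mM {row['treatment']}"
            return f"{t} | {row['condition']}"

        return self.meta.apply(lab, axis=1)

    def log_values(self) -> pd.DataFrame:
        """Natural-log transformed concentrations (normalisation used throughout)."""
        return np.log(self.values)


# ---------------------------------------------------------------------------
# Kruskal–Wallis on the growth AUC
# ---------------------------------------------------------------------------

def kruskal_auc(
    trait_table: pd.DataFrame,
    condition: str,
    *,
    value: str = "auc",
    alpha: float = 0.05,
    control: str = "control",
) -> pd.DataFrame:
    """Rank test of each treatment's AUC against the unprimed control.

    For every treatment×concentration within ``condition`` a two-group
    Kruskal–Wallis test (equivalent to a Wilcoxon rank-sum up to the
    chi-square reference) compares the per-plant ``value`` column
    against the control group.  The ``significant`` column flags
    p < ``alpha`` (the asterisk of the usual AUC bar chart).  No
    multiplicity correction is applied by default.
    """
    sub = trait_table[trait_table["condition"] == condition]
    ctrl = sub[sub["treatment"] == control][value].dropna().to_numpy()
    if ctrl.size == 0:
        raise StatsError(f"no control group in condition {condition!r}")
    rows = []
    groups = sub[sub["treatment"] != control].groupby(
        ["treatment", "concentration"], sort=True
    )
    for (treatment, conc), g in groups:
        x = g[value].dropna().to_numpy()
        if x.size < 2 or ctrl.size < 2:
            raise StatsError(
                f"need >= 2 plants per group ({treatment} {conc} mM, {condition})"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-tied inputs
            try:
                stat, p = sps.kruskal(x, ctrl)
            except ValueError:  # all values identical across both groups
                stat, p = 0.0, 1.0
        rows.append(
            {
                "test": "kruskal-wallis",
                "condition": condition,
                "treatment": treatment,
                "concentration": conc,
                "n_treatment": x.size,
                "n_control": ctrl.size,
                "statistic": stat,
                "p_value": p,
                "significant": bool(p < alpha),
                "alpha": alpha,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-metabolite ANOVA with post hoc vs control
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Tidy ANOVA output: one row per (condition, metabolite) in
    ``anova``; pairwise-vs-control post hoc rows in ``posthoc`` (None
    when post hoc was disabled)."""

    anova: pd.DataFrame
    posthoc: pd.DataFrame | None = None


def _duncan_vs_control(groups: dict, lnvals: np.ndarray, labels: np.ndarray,
                       control_key, alpha: float) -> dict:
    """Duncan's multiple range test, comparisons against control only.

    Critical values use the studentized range at the stepwise level
    1 − (1 − alpha)^(p−1) where p is the number of ordered means spanned
    by the comparison.  Returns {group_key: p_value_like_flag}; we report
    the protected significance decision and an approximate p-value from
    the studentized range distribution at the spanned p.
    """
    keys = list(groups)
    means = {k: lnvals[labels == k].mean() for k in keys}
    ns = {k: (labels == k).sum() for k in keys}
    # pooled within-group variance
    sse = sum(((lnvals[labels == k] - means[k]) ** 2).sum() for k in keys)
    df_err = sum(ns.values()) - len(keys)
    mse = sse / df_err if df_err > 0 else np.nan
    order = sorted(keys, key=lambda k: means[k])
    out = {}
    for k in keys:
        if k == control_key:
            continue
        i, j = order.index(k), order.index(control_key)
        p_span = abs(i - j) + 1
        nh = 2.0 / (1.0 / ns[k] + 1.0 / ns[control_key])
        if mse <= 0 or not np.isfinite(mse):
            out[k] = (np.nan, False)
            continue
        q_obs = abs(means[k] - means[control_key]) / np.sqrt(mse / nh)
        p_raw = sps.studentized_range.sf(q_obs, p_span, df_err)
        alpha_p = 1.0 - (1.0 - alpha) ** (p_span - 1)
        out[k] = (float(p_raw), bool(p_raw < alpha_p))
    return out


def metabolite_anova(
    table: MetaboliteTable,
    *,
    posthoc: str | None = "tukey",
    alpha: float = 0.05,
    two_way: bool = False,
    control: str = "control",
) -> AnovaResult:
    """Per-metabolite ANOVA on ln concentrations across treatment groups.

    Within each condition, a one-way ANOVA over the treatment groups is
    run per metabolite on ln-transformed values, followed by pairwise
    post hoc comparisons against the control group (``posthoc`` =
    ``"tukey"`` (default), ``"duncan"``, or None to skip).  Metabolites
    with zero within-group variance everywhere are flagged undefined.

    With ``two_way=True`` an additional treatment×condition two-way
    ANOVA (type-II, via statsmodels OLS) is returned in the ``anova``
    frame with ``condition`` set to ``"(all)"``.
    """
    lnv = table.log_values()
    meta = table.meta
    group_key = meta.apply(
        lambda r: f"{r['treatment']}|{float(r['concentration']):g}", axis=1
    )
    anova_rows = []
    posthoc_rows = []
    for condition in pd.unique(meta["condition"]):
        cmask = (meta["condition"] == condition).to_numpy()
        labels = group_key[cmask].to_numpy()
        keys = pd.unique(labels)
        if len(keys) < 2:
            raise StatsError(f"condition {condition!r}: need >= 2 groups")
        sub = lnv.loc[cmask].to_numpy()
        gidx = [labels == k for k in keys]
        if min(int(m.sum()) for m in gidx) < 2:
            raise StatsError(f"condition {condition!r}: need >= 2 replicates per group")
        group_arrays = [sub[m] for m in gidx]
        # within-group variance per metabolite; zero everywhere -> undefined
        within = np.vstack([g.var(axis=0, ddof=1) for g in group_arrays])
        undefined = within.sum(axis=0) == 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fstat, pvals = sps.f_oneway(*group_arrays, axis=0)
        fstat = np.where(undefined, np.nan, fstat)
        pvals = np.where(undefined, np.nan, pvals)
        for mi, met in enumerate(lnv.columns):
            anova_rows.append(
                {
                    "test": "anova-1way",
                    "condition": condition,
                    "metabolite": met,
                    "statistic": float(fstat[mi]),
                    "p_value": float(pvals[mi]),
                    "significant": bool(np.isfinite(pvals[mi]) and pvals[mi] < alpha),
                    "undefined": bool(undefined[mi]),
                    "alpha": alpha,
                }
            )
        if posthoc is None:
            continue
        ctrl_keys = [k for k in keys if k.split("|")[0] == control]
        if not ctrl_keys:
            raise StatsError(f"no control group in condition {condition!r}")
        ctrl_key = ctrl_keys[0]

        def key_parts(k: str) -> tuple[str, float]:
            t, c = k.rsplit("|", 1)
            return t, float(c)
        if posthoc == "tukey":
            # Tukey-HSD comparisons against control, batched over
            # metabolites (one studentized-range call per condition)
            k_groups = len(keys)
            ns = np.array([int(m.sum()) for m in gidx])
            gmeans = np.vstack([g.mean(axis=0) for g in group_arrays])
            sse = sum(
                ((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in group_arrays
            )
            df_err = int(ns.sum()) - k_groups
            mse = sse / df_err
            ci = list(keys).index(ctrl_key)
            other = [kj for kj in range(k_groups) if kj != ci]
            se = np.sqrt(
                np.outer(0.5 * (1.0 / ns[other] + 1.0 / ns[ci]), mse)
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                q_obs = np.abs(gmeans[other] - gmeans[ci]) / se
            defined = ~undefined
            pmat = np.full_like(q_obs, np.nan)
            pmat[:, defined] = sps.studentized_range.sf(
                q_obs[:, defined], k_groups, df_err
            )
            for oi, kj in enumerate(other):
                kt, kc = key_parts(keys[kj])
                for mi, met in enumerate(lnv.columns):
                    if undefined[mi]:
                        continue
                    p = float(pmat[oi, mi])
                    posthoc_rows.append(
                        {
                            "posthoc": "tukey-hsd",
                            "condition": condition,
                            "metabolite": met,
                            "treatment": kt,
                            "concentration": kc,
                            "p_value": p,
                            "significant": bool(p < alpha),
                        }
                    )
            continue
        for mi, met in enumerate(lnv.columns):
            if undefined[mi]:
                continue
            col = sub[:, mi]
            if posthoc == "duncan":
                res = _duncan_vs_control(
                    {k: None for k in keys}, col, labels, ctrl_key, alpha
                )
                for k, (p, sig) in res.items():
                    kt, kc = key_parts(k)
                    posthoc_rows.append(
                        {
                            "posthoc": "duncan",
                            "condition": condition,
                            "metabolite": met,
                            "treatment": kt,
                            "concentration": kc,
                            "p_value": p,
                            "significant": sig,
                        }
                    )
            else:
                raise StatsError(f"unknown posthoc {posthoc!r}")

    if two_way:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        long = lnv.stack().rename("lnvalue").reset_index()
        long.columns = ["sample_id", "metabolite", "lnvalue"]
        md = meta.reset_index(names="sample_id")
        md["group"] = [f"{t}_{c:g}" for t, c in zip(md["treatment"], md["concentration"])]
        long = long.merge(md[["sample_id", "group", "condition"]], on="sample_id")
        for met in lnv.columns:
            d = long[long["metabolite"] == met]
            model = smf.ols("lnvalue ~ C(group) * C(condition)", data=d).fit()
            tbl = sm.stats.anova_lm(model, typ=2)
            for term in ("C(group)", "C(condition)", "C(group):C(condition)"):
                p = float(tbl.loc[term, "PR(>F)"])
                anova_rows.append(
                    {
                        "test": f"anova-2way[{term}]",
                        "condition": "(all)",
                        "metabolite": met,
                        "statistic": float(tbl.loc[term, "F"]),
                        "p_value": p,
                        "significant": bool(p < alpha),
                        "undefined": False,
                        "alpha": alpha,
                    }
                )

    ph = pd.DataFrame(posthoc_rows) if posthoc is not None else None
    return AnovaResult(pd.DataFrame(anova_rows), ph)


# ---------------------------------------------------------------------------
# PCA by SVD
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Scores (samples × PCs), loadings (variables × PCs, orthonormal
    columns), fraction of variance per PC (descending), and the names of
    constant columns dropped under unit-variance scaling."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    dropped: tuple[str, ...] = ()

    def reconstruct(self) -> pd.DataFrame:
        """Centered/scaled data reconstructed from all components."""
        return self.scores.to_numpy() @ self.loadings.to_numpy().T


def pca_svd(X: pd.DataFrame, *, scale: bool = True) -> PCAResult:
    """Principal component analysis via singular value decomposition.

    Columns are mean-centered and (by default) scaled to unit sample
    variance; ``X = U S Vᵀ`` then gives scores ``U S`` and loadings
    ``V``, with variance fractions σ_k²/Σσ².  Constant columns cannot be
    unit-scaled and are dropped with a warning.
    """
    X = pd.DataFrame(X)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise StatsError("PCA needs at least 2 samples and 2 variables")
    vals = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise StatsError("PCA input must be finite")
    dropped: tuple[str, ...] = ()
    Xc = vals - vals.mean(axis=0)
    if scale:
        sd = vals.std(axis=0, ddof=1)
        keep = sd > 0
        if not np.all(keep):
            dropped = tuple(np.asarray(X.columns)[~keep])
            logger.warning("dropping constant columns under scaling: %s", dropped)
        Xc = Xc[:, keep] / sd[keep]
        cols = X.columns[keep]
    else:
        cols = X.columns
    if Xc.shape[1] < 2:
        raise StatsError("fewer than 2 non-constant variables")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading per component positive
    for k in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[k]))
        if Vt[k, i] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = S**2
    var_frac = var / var.sum() if var.sum() > 0 else var
    pcs = [f"PC{k + 1}" for k in range(S.size)]
    scores = pd.DataFrame(U * S, index=X.index, columns=pcs)
    loadings = pd.DataFrame(Vt.T, index=cols, columns=pcs)
    return PCAResult(scores, loadings, var_frac, dropped)


def pca_metabolites(
    table: MetaboliteTable,
    *,
    group_means: bool = True,
    scale: bool = True,
    growth: pd.DataFrame | None = None,
) -> PCAResult:
    """PCA of a metabolite table, biplot-ready.

    ln-transforms concentrations and (by default) averages the
    biological replicates of each treatment×condition group before the
    SVD, so each score point is one group mean, matching the usual
    biplot of mean symbols.  ``growth`` optionally appends growth
    variables (e.g. final size, dry biomass) indexed compatibly.
    """
    X = table.log_values()
    if group_means:
        X = X.groupby(table.group_labels()).mean()
    if growth is not None:
        X = X.join(growth, how="inner")
    return pca_svd(X, scale=scale)


# ---------------------------------------------------------------------------
# Pearson correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class PearsonResult:
    r: pd.DataFrame
    p: pd.DataFrame


def pearson_matrix(X: pd.DataFrame) -> PearsonResult:
    """All-pairs Pearson correlations with two-sided p-values.

    p-values come from the exact t transform
    ``t = r sqrt((n−2)/(1−r²))`` with n−2 degrees of freedom.
    Zero-variance variables yield NaN rows/columns (flagged by warning),
    never a silent 0.
    """
    X = pd.DataFrame(X)
    n = X.shape[0]
    if n < 3:
        raise StatsError("Pearson correlations need at least 3 samples")
    vals = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise StatsError("correlation input must be finite")
    sd = vals.std(axis=0, ddof=1)
    if np.any(sd == 0):
        logger.warning(
            "zero-variance variables, correlations undefined: %s",
            list(np.asarray(X.columns)[sd == 0]),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(vals, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, np.where(sd > 0, 1.0, np.nan))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    np.fill_diagonal(p, np.where(sd > 0, 0.0, np.nan))
    cols = X.columns
    return PearsonResult(
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


# ---------------------------------------------------------------------------
# Heatmap matrix (ln group means, class-blocked)
# ---------------------------------------------------------------------------

@dataclass
class HeatmapResult:
    """``values``: metabolites × group ln(mean concentration);
    ``classes``: class per metabolite row (rows ordered in class
    blocks); ``significant``: same-shape boolean marks from the post hoc
    (None if no ANOVA was supplied)."""

    values: pd.DataFrame
    classes: pd.Series
    significant: pd.DataFrame | None = None


def heatmap_matrix(
    table: MetaboliteTable, anova: AnovaResult | None = None
) -> HeatmapResult:
    """ln of group-mean concentrations, ordered for a class-blocked heatmap.

    Rows are metabolites grouped into class blocks (free amino acids,
    total polyamines, free polyamines); columns are treatment×condition
    groups in condition-major order.  Significance marks (the heatmap
    dots) come from a supplied :class:`AnovaResult` post hoc versus
    control.
    """
    means = table.values.groupby(table.group_labels()).mean()
    if np.any(means.to_numpy() <= 0):
        raise StatsError("nonpositive group mean; cannot ln-transform")
    lnmeans = np.log(means).T  # metabolites × groups

    cls = table.classes.reindex(lnmeans.index)
    order_key = {c: i for i, c in enumerate(METABOLITE_CLASSES)}
    row_order = sorted(
        lnmeans.index, key=lambda m: (order_key.get(cls[m], len(order_key)),)
    )
    lnmeans = lnmeans.loc[row_order]

    # condition-major column order, conditions in design order
    cond_of = {}
    for lab, cond in zip(table.group_labels(), table.meta["condition"]):
        cond_of[lab] = cond
    cond_order = list(pd.unique(table.meta["condition"]))
    col_order = sorted(
        lnmeans.columns, key=lambda c: (cond_order.index(cond_of[c]), c)
    )
    lnmeans = lnmeans[col_order]

    sig = None
    if anova is not None and anova.posthoc is not None and len(anova.posthoc):
        sig = pd.DataFrame(False, index=lnmeans.index, columns=lnmeans.columns)
        for _, row in anova.posthoc.iterrows():
            if not row["significant"]:
                continue
            lab = f"{row['concentration']:g} mM {row['treatment']} | {row['condition']}"
            if lab in sig.columns and row["metabolite"] in sig.index:
                sig.loc[row["metabolite"], lab] = True
    return HeatmapResult(lnmeans, cls.loc[row_order], sig)
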