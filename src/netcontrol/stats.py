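"""Covariate-adjusted group statistics for controllability outcomes.

Each analysis is an ANCOVA: ordinary least squares of one dependent variable
(whole-brain or regional controllability) on one effect of interest plus a
covariate set, with

* listwise deletion of rows missing any referenced column,
* single-pass removal of dependent-variable outliers beyond 3 sample SDs
  from the mean,
* a partial F test of the effect via full-vs-reduced model comparison,
* partial eta-squared  SS_effect / (SS_effect + SS_residual)  as effect size,
* a percentile 95% bootstrap CI on partial eta-squared from case resampling
  (1000 draws with replacement by default), and
* Benjamini-Hochberg FDR at 0.05 across the parcellation for regional
  (per-node) analyses.

Categorical predictors use treatment coding against the first declared level
of their codebook; F and eta-squared are invariant to the coding, the
convention only pins down reproducibility of coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CATEGORICAL_LEVELS",
    "AncovaSpec",
    "AncovaResult",
    "RegionalResults",
    "remove_outliers_3sd",
    "build_design",
    "fit_ancova",
    "partial_eta_from_F",
    "bootstrap_ci_eta",
    "bh_fdr",
    "run_regional_analysis",
    "analysis_roster",
    "DEFAULT_ROSTER",
]

#: Declared codebooks; the first level of each is the treatment-coding
#: reference.  Scanner site has three levels because one scanner's body coil
#: was replaced mid-study.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "diagnosis": ("HC", "MDD"),
    "gender": ("female", "male"),
    "site": ("site1", "site2", "site3"),
    "remission": ("acute", "partial", "full"),
}

BASE_COVARIATES = ("age", "gender", "site", "edge_count")
ANCESTRY_COVARIATES = ("mds1", "mds2", "mds3")


@dataclass(frozen=True)
class AncovaSpec:
    """One analysis: dependent ~ effect + covariates on a row subset."""

    dependent: str
    effect: str
    covariates: tuple[str, ...]
    subset: Mapping[str, str] | None = None  # e.g. {"diagnosis": "MDD"}
    outlier_sd: float = 3.0
    n_boot: int = 1000
    alpha: float = 0.05
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.effect in self.covariates:
            raise ValueError(f"effect {self.effect!r} repeated in covariates")
        if self.dependent == self.effect or self.dependent in self.covariates:
            raise ValueError(f"dependent {self.dependent!r} among predictors")


@dataclass(frozen=True)
class AncovaResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    ci95: tuple[float, float] | None
    n_used: int
    n_outliers_removed: int
    n_missing_dropped: int = 0
    error: str | None = None


@dataclass
class RegionalResults:
    """Per-node ANCOVA results with BH-adjusted q-values and FDR flags."""

    node_labels: list[str]
    results: list[AncovaResult]
    q_values: np.ndarray = field(default_factory=lambda: np.array([]))
    significant: np.ndarray = field(default_factory=lambda: np.array([], bool))

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "F": [r.F for r in self.results],
                "df1": [r.df1 for r in self.results],
                "df2": [r.df2 for r in self.results],
                "p": [r.p for r in self.results],
                "partial_eta_sq": [r.partial_eta_sq for r in self.results],
                "n_used": [r.n_used for r in self.results],
                "q": self.q_values,
                "significant": self.significant,
            },
            index=self.node_labels,
        )
        df.index.name = "region"
        return df


# ---------------------------------------------------------------------------
# Outlier handling


def remove_outliers_3sd(values: np.ndarray | pd.Series, sd: float = 3.0) -> np.ndarray:
    """Inclusion mask keeping values within ``sd`` sample SDs of the mean.

    Single pass (no iteration); ddof=1.  A zero-variance column keeps every
    row.  NaNs are excluded from the mean/SD and masked out.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise ValueError("need >= 2 non-missing values")
    mu = v[finite].mean()
    sigma = v[finite].std(ddof=1)
    if sigma == 0.0:
        return finite.copy()
    return finite & (np.abs(v - mu) <= sd * sigma)


# ---------------------------------------------------------------------------
# Design construction


@dataclass(frozen=True)
class Design:
    y: np.ndarray
    X_full: np.ndarray  # intercept + covariates + effect columns
    X_reduced: np.ndarray  # intercept + covariates
    df1: int
    n_used: int
    n_outliers_removed: int
    n_missing_dropped: int
    column_names: tuple[str, ...]


def _encode(col: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    """Numeric column as-is; categorical to treatment-coded indicators."""
    if name in CATEGORICAL_LEVELS:
        levels = CATEGORICAL_LEVELS[name]
        bad = set(col.dropna().unique()) - set(levels)
        if bad:
            raise ValueError(f"{name}: undeclared levels {sorted(bad)}")
        cols = [(col == lv).to_numpy(float) for lv in levels[1:]]
        return np.column_stack(cols), [f"{name}[{lv}]" for lv in levels[1:]]
    return col.to_numpy(float)[:, None], [name]


def build_design(spec: AncovaSpec, table: pd.DataFrame) -> Design:
    """Assemble response and full/reduced design matrices for one analysis.

    Order of operations: subset rows, drop rows with any missing referenced
    column (listwise), remove dependent-variable outliers, encode.  Residual
    df is n_used minus the full-model column count.
    """
    cols = [spec.dependent, spec.effect, *spec.covariates]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in cohort table: {missing}")
    df = table
    if spec.subset:
        for k, v in spec.subset.items():
            df = df[df[k] == v]
    sub = df[cols].dropna()
    n_missing = len(df) - len(sub)
    if len(sub) < 2:
        raise ValueError("subset empty (or nearly) after missing-value removal")

    keep = remove_outliers_3sd(sub[spec.dependent], sd=spec.outlier_sd)
    n_out = int((~keep).sum())
    sub = sub[keep]

    if sub[spec.effect].nunique() < 2:
        raise ValueError(f"effect column {spec.effect!r} is constant")

    eff, eff_names = _encode(sub[spec.effect], spec.effect)
    parts, names = [np.ones((len(sub), 1))], ["intercept"]
    for c in spec.covariates:
        enc, nm = _encode(sub[c], c)
        parts.append(enc)
        names.extend(nm)
    X_red = np.column_stack(parts)
    X_full = np.column_stack([X_red, eff])
    names.extend(eff_names)

    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError(f"rank-deficient design for {spec.name or spec.dependent}")

    return Design(
        y=sub[spec.dependent].to_numpy(float),
        X_full=X_full,
        X_reduced=X_red,
        df1=eff.shape[1],
        n_used=len(sub),
        n_outliers_removed=n_out,
        n_missing_dropped=n_missing,
        column_names=tuple(names),
    )


# ---------------------------------------------------------------------------
# Fitting


def partial_eta_from_F(F: float, df1: int, df2: int) -> float:
    """partial eta^2 = F*df1 / (F*df1 + df2)."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be positive")
    if F < 0:
        raise ValueError("F must be non-negative")
    return F * df1 / (F * df1 + df2)


def _partial_f(y, X_full, X_red) -> tuple[float, int, int, float, float]:
    """Partial F for the effect block via OLS model comparison."""
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df1 = X_full.shape[1] - X_red.shape[1]
    df2 = int(full.df_resid)
    ss_eff = red.ssr - full.ssr
    F = (ss_eff / df1) / (full.ssr / df2) if full.ssr > 0 else np.inf
    eta = ss_eff / (ss_eff + full.ssr) if (ss_eff + full.ssr) > 0 else 0.0
    return float(F), df1, df2, float(max(eta, 0.0)), float(full.ssr)


def fit_ancova(
    spec: AncovaSpec,
    table: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> AncovaResult:
    """Fit one ANCOVA; bootstrap the eta^2 CI when spec.n_boot > 0."""
    d = build_design(spec, table)
    F, df1, df2, eta, _ = _partial_f(d.y, d.X_full, d.X_reduced)
    p = float(scipy.stats.f.sf(F, df1, df2))
    ci = None
    if spec.n_boot > 0:
        ci = bootstrap_ci_eta(d, n_boot=spec.n_boot, rng=rng, alpha=spec.alpha)
    return AncovaResult(
        F=F,
        df1=df1,
        df2=df2,
        p=p,
        partial_eta_sq=eta,
        ci95=ci,
        n_used=d.n_used,
        n_outliers_removed=d.n_outliers_removed,
        n_missing_dropped=d.n_missing_dropped,
    )


# ---------------------------------------------------------------------------
# Bootstrap


def _batched_eta(y, Xf, Xr, idx) -> tuple[np.ndarray, np.ndarray]:
    """Partial eta^2 for each case-resample in ``idx`` ((B, n) index array).

    Vectorized normal equations; returns (eta, degenerate flag).  The
    resampled designs inherit the original column scaling so conditioning
    failure (a resample dropping a factor level) is detected via singular /
    ill-conditioned Gram matrices.
    """
    yb = y[idx]  # (B, n)
    etas = np.full(idx.shape[0], np.nan)
    degen = np.zeros(idx.shape[0], dtype=bool)

    def ssr(Xb, yb_row):
        G = Xb.T @ Xb
        c = Xb.T @ yb_row
        # rank / conditioning guard: eigenvalue ratio of the Gram matrix
        w = np.linalg.eigvalsh(G)
        if w[0] <= w[-1] * 1e-12:
            return None
        beta = np.linalg.solve(G, c)
        return float(yb_row @ yb_row - beta @ c)

    for b in range(idx.shape[0]):
        rows = idx[b]
        s_full = ssr(Xf[rows], yb[b])
        s_red = ssr(Xr[rows], yb[b])
        if s_full is None or s_red is None or s_red <= 0:
            degen[b] = True
            continue
        etas[b] = np.clip((s_red - s_full) / s_red, 0.0, 1.0)
    return etas, degen


def bootstrap_ci_eta(
    design: Design,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    max_degenerate_frac: float = 0.10,
) -> tuple[float, float]:
    """Percentile CI on partial eta^2 from case resampling.

    Rows (cases) of the post-outlier, post-listwise design are drawn with
    replacement; degenerate resamples (rank-deficient designs) are redrawn
    and counted, erroring out above 10% of n_boot.
    """
    rng = np.random.default_rng(rng)
    n = design.n_used
    idx = rng.integers(0, n, size=(n_boot, n))
    etas, degen = _batched_eta(design.y, design.X_full, design.X_reduced, idx)
    n_degen = int(degen.sum())
    while degen.any():
        if n_degen > max_degenerate_frac * n_boot:
            raise RuntimeError(
                f"{n_degen} degenerate bootstrap resamples (> "
                f"{max_degenerate_frac:.0%} of {n_boot}): design too fragile"
            )
        redraw = rng.integers(0, n, size=(int(degen.sum()), n))
        new_etas, new_degen = _batched_eta(
            design.y, design.X_full, design.X_reduced, redraw
        )
        etas[degen] = new_etas
        degen_idx = np.flatnonzero(degen)
        degen = np.zeros_like(degen)
        degen[degen_idx[new_degen]] = True
        n_degen += int(new_degen.sum())
    lo, hi = np.percentile(etas, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Multiple testing


def bh_fdr(
    pvalues: Sequence[float] | np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted q-values, significance flags).

    Missing p-values are excluded from the procedure and come back NaN /
    not-significant.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    flags = np.zeros(p.shape, dtype=bool)
    if ok.any():
        rej, q_adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        adj[ok] = q_adj
        flags[ok] = rej
    return adj, flags


# ---------------------------------------------------------------------------
# Regional analyses


def run_regional_analysis(
    spec: AncovaSpec,
    table: pd.DataFrame,
    node_labels: Sequence[str],
    prefix: str | None = None,
    rng: np.random.Generator | None = None,
) -> RegionalResults:
    """Fit the spec's ANCOVA once per region, then BH-FDR across regions.

    ``spec.dependent`` names the metric prefix (e.g. ``avg_ctrl``) unless
    ``prefix`` overrides it; each node's column is ``<prefix>_<label>``.
    Outlier removal is per node on that node's dependent variable.  The
    per-node fits skip the bootstrap (CIs are reported for whole-brain
    analyses); a node whose fit fails is recorded, not fatal.
    """
    prefix = prefix or spec.dependent
    results: list[AncovaResult] = []
    for lbl in node_labels:
        node_spec = replace(spec, dependent=f"{prefix}_{lbl}", n_boot=0)
        try:
            results.append(fit_ancova(node_spec, table, rng=rng))
        except (ValueError, KeyError, RuntimeError) as exc:
            results.append(
                AncovaResult(
                    F=np.nan, df1=0, df2=0, p=np.nan, partial_eta_sq=np.nan,
                    ci95=None, n_used=0, n_outliers_removed=0, error=str(exc),
                )
            )
    q, flags = bh_fdr([r.p for r in results], q=spec.alpha)
    return RegionalResults(
        node_labels=list(node_labels), results=results, q_values=q,
        significant=flags,
    )


# ---------------------------------------------------------------------------
# Analysis roster

#: construct -> (effect column, subsets it is run in).  "all" pools both
#: groups; patient-only analyses additionally control for medication load;
#: polygenic-score analyses additionally control for ancestry (MDS 1-3).
DEFAULT_ROSTER: dict[str, dict] = {
    "age": {"effect": "age", "subsets": ("HC", "MDD")},
    "gender": {"effect": "gender", "subsets": ("HC", "MDD")},
    "diagnosis": {"effect": "diagnosis", "subsets": ("all",)},
    "bdi": {"effect": "bdi", "subsets": ("MDD", "HC")},
    "remission": {"effect": "remission", "subsets": ("MDD",)},
    "famrisk_mdd": {"effect": "famrisk_mdd", "subsets": ("MDD",)},
    "famrisk_bd": {"effect": "famrisk_bd", "subsets": ("MDD",)},
    "prs_mdd": {"effect": "prs_mdd", "subsets": ("MDD",), "prs": True},
    "prs_bd": {"effect": "prs_bd", "subsets": ("MDD",), "prs": True},
    "prs_cross": {"effect": "prs_cross", "subsets": ("MDD",), "prs": True},
    "bmi": {"effect": "bmi", "subsets": ("MDD",)},
    "height": {"effect": "height", "subsets": ("all",)},
    "inclusion_order": {"effect": "inclusion_order", "subsets": ("all",)},
}

DEPENDENTS = ("wb_avg", "wb_modal")


def analysis_roster(
    constructs: Sequence[str] | None = None,
    dependents: Sequence[str] = DEPENDENTS,
    n_boot: int = 1000,
) -> list[AncovaSpec]:
    """Expand construct names into fully specified ANCOVA analyses.

    Every construct is tested independently (no cross-construct correction);
    each yields one spec per dependent variable per subset.
    """
    constructs = list(constructs) if constructs is not None else list(DEFAULT_ROSTER)
    specs: list[AncovaSpec] = []
    for name in constructs:
        if name not in DEFAULT_ROSTER:
            raise KeyError(
                f"unknown construct {name!r}; known: {sorted(DEFAULT_ROSTER)}"
            )
        entry = DEFAULT_ROSTER[name]
        effect = entry["effect"]
        for subset_name in entry["subsets"]:
            covs = [c for c in BASE_COVARIATES if c != effect]
            subset = None if subset_name == "all" else {"diagnosis": subset_name}
            if entry.get("prs"):
                covs.extend(ANCESTRY_COVARIATES)
            if subset_name == "MDD":
                covs.append("medication_load")
            for dep in dependents:
                tag = f"{name}_{subset_name}_{dep}"
                specs.append(
                    AncovaSpec(
                        dependent=dep,
                        effect=effect,
                        covariates=tuple(covs),
                        subset=subset,
                        n_boot=n_boot,
                        name=tag,
                    )
                )
    return specs
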