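"""SES screen and per-indicator linear mixed-model association suites.

The analysis design mirrors large multi-site developmental cohorts: for each
of the 11 environmental indicators and each outcome (CBCL total problem
score, cognitive total score, DMN clustering coefficient) a linear mixed
model is fitted with the z-scored indicator, age and sex as fixed effects —
once without and once with the SES covariates (household income, parental
education) — and random intercepts for site and for family nested in site,
estimated by REML.  One indicator per model, never all 11 jointly, because
the indicators are strongly collinear by construction.

Significance labels follow a Bonferroni correction over the 11 indicator
tests at alpha = 0.05 (threshold 0.05/11 ≈ 4.5e-3), with a "trending" band
between that threshold and 0.01.

"% variance" is operationalized as the difference in Nakagawa marginal R²
(fixed-effects variance over total variance) between the full fit and a
reduced fit without the indicator, floored at zero, with the sign of the
indicator's fixed effect attached.  A semi-partial alternative is not
currently exposed; the definition is pinned here for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .indicators import INDICATOR_NAMES

__all__ = [
    "AssociationResult",
    "AssocConfig",
    "bonferroni_threshold",
    "label_pvalue",
    "ses_screen",
    "fit_indicator_model",
    "variance_explained",
    "run_association_suite",
    "render_report",
]

SES_COVARIATES = ("household_income", "parent_education")
DEFAULT_OUTCOMES = ("cbcl_total", "cog_total", "dmn_clustering")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def label_pvalue(p: float, threshold: float) -> str:
    """'significant' iff p <= threshold; 'trending' iff threshold < p < 0.01."""
    if p <= threshold:
        return "significant"
    if p < 0.01:
        return "trending"
    return "n.s."


@dataclass
class AssocConfig:
    alpha: float = 0.05
    n_tests: int = 11
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    model_sets: tuple[str, ...] = ("no_ses", "with_ses")
    reml: bool = True

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.n_tests)


@dataclass
class AssociationResult:
    indicator: str
    outcome: str
    model_set: str
    beta: float
    se: float
    p_value: float
    pct_variance: float
    effect_sign: str
    label: str
    n_obs: int
    converged: bool
    diagnostic: str = ""


def ses_screen(
    table: pd.DataFrame,
    indicators: tuple[str, ...] = INDICATOR_NAMES,
    ses_vars: tuple[str, ...] = SES_COVARIATES,
) -> pd.DataFrame:
    """Pearson correlation of each SES variable with each indicator.

    Documents the exposure-SES multicollinearity before modelling.  Rows:
    (ses_var, indicator, r, p, n, constant) over pairwise-complete cases;
    a constant column is flagged (r, p = NaN), never reported as zero.
    """
    rows = []
    for ses in ses_vars:
        for ind in indicators:
            pair = table[[ses, ind]].dropna()
            n = len(pair)
            if n < 10:
                raise ValueError(
                    f"need >= 10 complete rows for ({ses}, {ind}); got {n}"
                )
            x, y = pair[ses].to_numpy(float), pair[ind].to_numpy(float)
            constant = x.std() == 0 or y.std() == 0
            if constant:
                r = p = np.nan
            else:
                r, p = stats.pearsonr(x, y)
            rows.append(
                {
                    "ses_var": ses,
                    "indicator": ind,
                    "r": r,
                    "p_value": p,
                    "n": n,
                    "constant": constant,
                }
            )
    return pd.DataFrame(rows)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def _marginal_r2(result, exog: pd.DataFrame) -> float:
    """Nakagawa marginal R²: var(fixed-effect predictions) / total variance."""
    fe_pred = np.asarray(exog @ result.fe_params)
    var_f = fe_pred.var()
    var_site = float(np.asarray(result.cov_re).ravel()[0]) if result.cov_re.size else 0.0
    var_vc = float(np.sum(result.vcomp)) if result.vcomp.size else 0.0
    return var_f / (var_f + var_site + var_vc + result.scale)


def _fit_lmm(data: pd.DataFrame, formula: str, reml: bool):
    import statsmodels.formula.api as smf

    model = smf.mixedlm(
        formula,
        data,
        groups="site_id",
        re_formula="1",
        vc_formula={"family": "0 + C(family_id)"},
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = model.fit(reml=reml)
    notes = "; ".join(
        str(w.message)
        for w in caught
        if "converge" in str(w.message).lower() or "singular" in str(w.message).lower()
    )
    return result, notes


def fit_indicator_model(
    data: pd.DataFrame,
    indicator: str,
    outcome: str,
    include_ses: bool,
    cfg: AssocConfig | None = None,
) -> AssociationResult:
    """Fit one indicator-outcome mixed model and summarize it.

    ``data`` must carry the outcome, the raw indicator, ``age``, ``sex``,
    the SES ordinals, ``site_id`` and ``family_id``.  The indicator is
    z-scored before fitting so betas are comparable across indicators.
    Complete cases only; requires >= 50 of them.  A non-converged or
    singular fit is reported with a diagnostic, never silently dropped.
    """
    cfg = cfg or AssocConfig()
    cols = [outcome, indicator, "age", "sex", "site_id", "family_id"]
    if include_ses:
        cols += list(SES_COVARIATES)
    d = data[cols].dropna().copy()
    if len(d) < 50:
        raise ValueError(f"need >= 50 complete-case rows, got {len(d)}")
    fam_site = d.groupby("family_id")["site_id"].nunique()
    if (fam_site > 1).any():
        bad = fam_site[fam_site > 1].index[0]
        raise ValueError(f"family {bad!r} spans multiple sites")
    d["ind_z"] = _zscore(d[indicator].to_numpy(float))
    terms = ["ind_z", "age", "C(sex)"]
    if include_ses:
        terms += list(SES_COVARIATES)
    formula = f"{outcome} ~ " + " + ".join(terms)
    full, notes = _fit_lmm(d, formula, cfg.reml)
    reduced_formula = f"{outcome} ~ " + " + ".join(terms[1:])
    reduced, _ = _fit_lmm(d, reduced_formula, cfg.reml)

    beta = float(full.fe_params["ind_z"])
    se = float(full.bse_fe["ind_z"])
    p = float(full.pvalues["ind_z"])
    pct = variance_explained(full, reduced)
    label = label_pvalue(p, cfg.threshold)
    return AssociationResult(
        indicator=indicator,
        outcome=outcome,
        model_set="with_ses" if include_ses else "no_ses",
        beta=beta,
        se=se,
        p_value=p,
        pct_variance=pct,
        effect_sign="+" if beta >= 0 else "-",
        label=label,
        n_obs=len(d),
        converged=bool(full.converged),
        diagnostic=notes,
    )


def variance_explained(full_fit, reduced_fit) -> float:
    """Percent outcome variance attributable to the indicator.

    100 x (marginal R² of the full fit minus marginal R² of the reduced fit
    without the indicator), floored at 0.  Both fits must be on the same
    rows with the same random-effects structure.
    """
    n_full = full_fit.model.exog.shape[0]
    n_red = reduced_fit.model.exog.shape[0]
    if n_full != n_red:
        raise ValueError(
            f"full and reduced fits use different rows ({n_full} vs {n_red})"
        )
    exog_full = pd.DataFrame(
        full_fit.model.exog, columns=full_fit.model.exog_names
    )
    exog_red = pd.DataFrame(
        reduced_fit.model.exog, columns=reduced_fit.model.exog_names
    )
    r2_full = _marginal_r2(full_fit, exog_full)
    r2_red = _marginal_r2(reduced_fit, exog_red)
    return max(0.0, 100.0 * (r2_full - r2_red))


def prepare_analysis_table(
    linked: pd.DataFrame,
    subjects: pd.DataFrame,
    connectome_metrics: pd.DataFrame | None = None,
    address_index: int = 1,
) -> pd.DataFrame:
    """Merge baseline-address exposures, subject covariates and brain metrics."""
    base = linked[linked["address_index"] == address_index]
    keep = ["subject_id", *INDICATOR_NAMES]
    out = subjects.merge(base[keep], on="subject_id", how="left", validate="1:1")
    if connectome_metrics is not None:
        out = out.merge(connectome_metrics, on="subject_id", how="left", validate="1:1")
    return out


def run_association_suite(
    linked: pd.DataFrame,
    subjects: pd.DataFrame,
    connectome_metrics: pd.DataFrame | None = None,
    cfg: AssocConfig | None = None,
) -> pd.DataFrame:
    """Fit all indicator x outcome x model-set mixed models.

    Returns one row per :class:`AssociationResult`, ordered model-set first
    (no-SES block on top, with-SES below), then outcome, then indicator in
    canonical order.  Deterministic for a deterministic input (REML fits
    involve no randomness), so re-running on the same world reproduces the
    report byte for byte.
    """
    cfg = cfg or AssocConfig()
    data = prepare_analysis_table(linked, subjects, connectome_metrics)
    rows = []
    for model_set in cfg.model_sets:
        for outcome in cfg.outcomes:
            if outcome not in data.columns:
                continue
            for indicator in INDICATOR_NAMES:
                res = fit_indicator_model(
                    data, indicator, outcome,
                    include_ses=(model_set == "with_ses"), cfg=cfg,
                )
                rows.append(res.__dict__)
    return pd.DataFrame(rows)


def render_report(report: pd.DataFrame, cfg: AssocConfig | None = None) -> str:
    """Plain-text association table: no-SES panel on top, with-SES below.

    Cells show ``p-value  %variance(sign)`` for significant/trending rows
    and ``N.S.`` otherwise, one row per indicator, one column pair per
    outcome — mirroring the standard presentation of such screens.
    """
    cfg = cfg or AssocConfig()
    outcomes = [o for o in cfg.outcomes if (report["outcome"] == o).any()]
    lines = []
    width = 24
    for model_set in cfg.model_sets:
        sub = report[report["model_set"] == model_set]
        if sub.empty:
            continue
        title = "Without SES covariates" if model_set == "no_ses" else "With SES covariates"
        lines.append(title)
        header = "indicator".ljust(20) + "".join(o.ljust(width) for o in outcomes)
        lines.append(header)
        lines.append("-" * len(header))
        for ind in INDICATOR_NAMES:
            cells = []
            for o in outcomes:
                row = sub[(sub["indicator"] == ind) & (sub["outcome"] == o)]
                if row.empty:
                    cells.append("".ljust(width))
                    continue
                r = row.iloc[0]
                if r["label"] == "n.s.":
                    cell = "N.S."
                else:
                    mark = "" if r["label"] == "significant" else " (trend)"
                    cell = f"{r['p_value']:.2e} {r['pct_variance']:.2f}%({r['effect_sign']}){mark}"
                cells.append(cell.ljust(width))
            lines.append(ind.ljust(20) + "".join(cells))
        lines.append("")
    lines.append(
        f"significant: p <= {cfg.threshold:.2e} (Bonferroni, alpha={cfg.alpha}, "
        f"{cfg.n_tests} tests); trending: threshold < p < 1.00e-02"
    )
    return "\n".join(lines)
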