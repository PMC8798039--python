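"""Thin statistical-comparison and reporting layer.

Every test delegates to a standard implementation (scipy, statsmodels,
pingouin); this module contributes the comparison plans, the
Brown–Forsythe equal-variance gate (when an equal-variance test is
planned but the groups fail Brown–Forsythe at 0.05, the Welch variant is
substituted and the substitution logged), and uniform report rows.

Available plans
---------------
``t`` / ``welch_t``            two-group unpaired t (pooled / Welch)
``anova_tukey``                one-way ANOVA + Tukey HSD
``welch_anova_dunnettT3``      Welch ANOVA + Games–Howell pairwise (the
                               installed studentized-range unequal-variance
                               post hoc; see docs/methods.md)
``anova_gameshowell``          Welch ANOVA + Games–Howell
``multi_t_holm_sidak``         per-measurement t tests, Holm–Šidák adjusted
``mixed_effects_tukey``        random-intercept (per animal) mixed model,
                               Tukey-style studentized-range pairwise
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ComparisonPlan", "run_comparison", "render_report"]

_TESTS = (
    "t",
    "welch_t",
    "anova_tukey",
    "welch_anova_dunnettT3",
    "anova_gameshowell",
    "multi_t_holm_sidak",
    "mixed_effects_tukey",
)

_WELCH_SUBSTITUTE = {"t": "welch_t", "anova_tukey": "welch_anova_dunnettT3"}


@dataclass(frozen=True)
class ComparisonPlan:
    """What to compare and how."""

    measurement: str
    group: str  # grouping column, e.g. age or spot class
    test: str
    alpha: float = 0.05
    random_effect: Optional[str] = None  # e.g. "animal" for mixed models

    def __post_init__(self) -> None:
        if self.test not in _TESTS:
            raise ValueError(f"unknown test {self.test!r}; choose from {_TESTS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _group_summary(values: dict[str, np.ndarray]) -> dict[str, str]:
    return {
        g: f"{v.mean():.4g} ± {v.std(ddof=1):.4g} (n={len(v)})"
        for g, v in values.items()
    }


def _row(plan, contrast, statistic, df, p, p_adj, summary, method, substituted):
    return {
        "measurement": plan.measurement,
        "contrast": contrast,
        "method": method,
        "statistic": statistic,
        "df": df,
        "p": p,
        "p_adj": p_adj,
        "groups": "; ".join(f"{g}: {s}" for g, s in summary.items()),
        "substituted": substituted,
    }


def _pairwise_tukey_from_mixed(fit, levels, df_resid):
    """Tukey-style pairwise contrasts on mixed-model group estimates.

    Group means come from the treatment-coded fixed effects; the adjusted
    p uses the studentized-range distribution with k groups at residual
    df (an approximation; see docs/methods.md).
    """
    params = fit.params
    cov = fit.cov_params()
    names = list(fit.model.exog_names)
    est = {}
    for lev in levels:
        match = [n for n in names if n.endswith(f"[T.{lev}]")]
        est[lev] = (match[0] if match else None)
    rows = []
    k = len(levels)
    for a, b in itertools.combinations(levels, 2):
        vec = np.zeros(len(names))
        if est[a] is not None:
            vec[names.index(est[a])] += 1
        if est[b] is not None:
            vec[names.index(est[b])] -= 1
        diff = float(vec @ params[names])
        se = float(np.sqrt(vec @ cov.loc[names, names].values @ vec))
        q = abs(diff) / se * np.sqrt(2.0)
        p_raw = float(stats.studentized_range.sf(q, 2, df_resid))
        p_adj = float(stats.studentized_range.sf(q, k, df_resid))
        rows.append((f"{a} vs {b}", diff / se, df_resid, p_raw, p_adj))
    return rows


def run_comparison(table: pd.DataFrame, plan: ComparisonPlan) -> pd.DataFrame:
    """Run one planned comparison on a tidy table.

    ``table`` needs columns ``value``, the grouping column named by
    ``plan.group`` and, for ``multi_t_holm_sidak``, a ``measurement``
    column; ``mixed_effects_tukey`` additionally needs the random-effect
    column (default ``animal``).
    Returns one report row per contrast with statistic, df, raw and
    adjusted p, group summaries and any Welch substitution.
    """
    if plan.group not in table.columns or "value" not in table.columns:
        raise ValueError(f"table needs columns 'value' and {plan.group!r}")
    values_all = pd.to_numeric(table["value"], errors="raise")
    table = table.assign(value=values_all)

    # Holm–Šidák family: one t test per measurement, adjusted across them
    if plan.test == "multi_t_holm_sidak":
        from statsmodels.stats.multitest import multipletests

        if "measurement" not in table.columns:
            raise ValueError("multi_t_holm_sidak needs a 'measurement' column")
        rows = []
        raw_ps = []
        for meas, sub in table.groupby("measurement", sort=True):
            groups = {g: v["value"].to_numpy() for g, v in sub.groupby(plan.group)}
            if len(groups) != 2:
                raise ValueError(f"{meas}: need exactly 2 groups")
            (ga, va), (gb, vb) = sorted(groups.items())
            t, p = stats.ttest_ind(va, vb)
            rows.append(
                _row(
                    ComparisonPlan(meas, plan.group, "t", plan.alpha),
                    f"{ga} vs {gb}", float(t), len(va) + len(vb) - 2, float(p),
                    np.nan, _group_summary(groups), "multi_t_holm_sidak", False,
                )
            )
            raw_ps.append(float(p))
        _, p_adj, _, _ = multipletests(raw_ps, alpha=plan.alpha, method="holm-sidak")
        for row, pa in zip(rows, p_adj):
            row["p_adj"] = float(pa)
        return pd.DataFrame(rows)

    groups = {g: v["value"].to_numpy() for g, v in table.groupby(plan.group, sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("every group needs n >= 2")
    summary = _group_summary(groups)
    names = sorted(groups)
    arrays = [groups[g] for g in names]

    # Brown–Forsythe gate (Levene with median centering)
    test = plan.test
    substituted = False
    if test in _WELCH_SUBSTITUTE and all(np.std(a) > 0 for a in arrays):
        _, bf_p = stats.levene(*arrays, center="median")
        if bf_p < 0.05:
            test = _WELCH_SUBSTITUTE[test]
            substituted = True
            logger.info(
                "%s: Brown–Forsythe p=%.3g < 0.05; substituting %s for %s",
                plan.measurement, bf_p, test, plan.test,
            )

    rows = []
    if test in ("t", "welch_t"):
        if len(names) != 2:
            raise ValueError("t tests need exactly 2 groups")
        a, b = arrays
        equal_var = test == "t"
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        df = (len(a) + len(b) - 2) if equal_var else float(res.df)
        rows.append(
            _row(plan, f"{names[0]} vs {names[1]}", float(res.statistic), df,
                 float(res.pvalue), float(res.pvalue), summary, test, substituted)
        )
    elif test == "anova_tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        f, p = stats.f_oneway(*arrays)
        n_tot = sum(len(a) for a in arrays)
        df_resid = n_tot - len(names)
        rows.append(
            _row(plan, "omnibus", float(f), (len(names) - 1, df_resid), float(p),
                 float(p), summary, "anova", substituted)
        )
        tk = pairwise_tukeyhsd(
            table["value"].to_numpy(), table[plan.group].astype(str).to_numpy(),
            alpha=plan.alpha,
        )
        lookup = {str(g): g for g in groups}
        for (a, b), p_adj in zip(
            itertools.combinations(tk.groupsunique, 2), tk.pvalues
        ):
            va, vb = groups[lookup[str(a)]], groups[lookup[str(b)]]
            t_raw, p_raw = stats.ttest_ind(va, vb)
            rows.append(
                _row(plan, f"{a} vs {b}", float(t_raw), df_resid, float(p_raw),
                     float(p_adj), summary, "tukey_hsd", substituted)
            )
    elif test in ("welch_anova_dunnettT3", "anova_gameshowell"):
        import pingouin as pg

        sub = table[[plan.group, "value"]].copy()
        sub[plan.group] = sub[plan.group].astype(str)
        wa = pg.welch_anova(data=sub, dv="value", between=plan.group)
        rows.append(
            _row(plan, "omnibus", float(wa["F"].iloc[0]),
                 (float(wa["ddof1"].iloc[0]), float(wa["ddof2"].iloc[0])),
                 float(wa["p_unc"].iloc[0]), float(wa["p_unc"].iloc[0]),
                 summary, "welch_anova", substituted)
        )
        gh = pg.pairwise_gameshowell(data=sub, dv="value", between=plan.group)
        lookup = {str(g): g for g in groups}
        for _, r in gh.iterrows():
            va, vb = groups[lookup[str(r["A"])]], groups[lookup[str(r["B"])]]
            _, p_raw = stats.ttest_ind(va, vb, equal_var=False)
            rows.append(
                _row(plan, f"{r['A']} vs {r['B']}", float(r["T"]), float(r["df"]),
                     float(p_raw), float(r["pval"]), summary, "games_howell",
                     substituted)
            )
    elif test == "mixed_effects_tukey":
        import statsmodels.formula.api as smf

        effect = plan.random_effect or "animal"
        if effect not in table.columns:
            raise ValueError(f"mixed_effects_tukey needs a {effect!r} column")
        sub = table[[plan.group, "value", effect]].copy()
        sub[plan.group] = sub[plan.group].astype(str)
        model = smf.mixedlm(f"value ~ C({plan.group})", sub, groups=sub[effect])
        fit = model.fit(reml=True)
        df_resid = len(sub) - len(names)
        for contrast, tval, df, p_raw, p_adj in _pairwise_tukey_from_mixed(
            fit, [str(n) for n in names], df_resid
        ):
            rows.append(
                _row(plan, contrast, float(tval), df, p_raw, p_adj, summary,
                     "mixed_effects_tukey", substituted)
            )
    else:  # pragma: no cover
        raise AssertionError(test)
    return pd.DataFrame(rows)


def render_report(
    sections: dict[str, pd.DataFrame],
    out_markdown: Optional[str | Path] = None,
    out_csv: Optional[str | Path] = None,
) -> str:
    """Assemble comparison tables into a deterministic human-readable
    summary (Markdown) plus one machine-readable CSV.

    One section per figure-analog (densities, intensities, vascular,
    coverage, microniche, radial); every row names its method and any
    Welch substitution.
    """
    lines = ["# Statistical report", ""]
    all_rows = []
    for name in sections:
        df = sections[name]
        lines.append(f"## {name}")
        lines.append("")
        if len(df) == 0:
            lines.append("_no comparisons_")
            lines.append("")
            continue
        for _, r in df.iterrows():
            sub = " (Welch-substituted after Brown–Forsythe)" if r.get("substituted") else ""
            lines.append(
                f"- **{r['measurement']}** [{r['contrast']}] via {r['method']}{sub}: "
                f"stat={r['statistic']:.4g}, df={r['df']}, p={r['p']:.4g}, "
                f"adj. p={r['p_adj']:.4g} | {r['groups']}"
            )
            all_rows.append({**r, "section": name})
        lines.append("")
    text = "\n".join(lines)
    if out_markdown is not None:
        Path(out_markdown).write_text(text)
    if out_csv is not None and all_rows:
        pd.DataFrame(all_rows).to_csv(out_csv, index=False)
    return text
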