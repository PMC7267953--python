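"""Group-level comparisons of prediction scores across conditions.

Repeated-measures one-way ANOVA with Greenhouse–Geisser correction and
Bonferroni-adjusted pairwise post hocs (via pingouin), plus paired and
two-sample t-tests (via scipy) for pairwise designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = ["StatsReport", "compare_scores"]


@dataclass
class StatsReport:
    design: str
    table: pd.DataFrame          # main test statistics
    posthoc: pd.DataFrame | None  # pairwise comparisons (repeated design)

    def summary(self) -> str:
        out = [f"Design: {self.design}", self.table.to_string()]
        if self.posthoc is not None:
            out += ["", "Post hoc (Bonferroni):", self.posthoc.to_string()]
        return "\n".join(out)


def _paired_t(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    if np.ptp(d) == 0:
        # zero within-pair variance: flag as degenerate, maximal evidence
        # unless the constant difference is itself zero
        t = 0.0 if np.allclose(d, 0) else np.inf * np.sign(d.mean())
        p = 1.0 if np.allclose(d, 0) else 0.0
        return t, p, True
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), False


def compare_scores(scores: pd.DataFrame, design: str) -> StatsReport:
    """Compare condition columns of a subjects×conditions score table.

    design : 'repeated_anova' | 'paired_t' | 'two_sample_t'
        The t designs require exactly two condition columns; the
        repeated design requires complete rows.
    """
    scores = pd.DataFrame(scores)
    if scores.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    conds = list(scores.columns)

    if design == "repeated_anova":
        if scores.isna().any().any():
            raise ValueError("repeated design requires complete rows")
        if len(conds) < 2:
            raise ValueError("need >= 2 conditions")
        long = scores.reset_index(names="subject").melt(
            id_vars="subject", var_name="condition", value_name="score"
        )
        if np.ptp(long["score"].to_numpy()) == 0:
            # identical values everywhere: F = 0, all post hoc p = 1
            table = pd.DataFrame(
                {"F": [0.0], "p_GG": [1.0], "eps_GG": [1.0],
                 "df1": [len(conds) - 1],
                 "df2": [(len(conds) - 1) * (scores.shape[0] - 1)]}
            )
            pairs = [(a, b) for i, a in enumerate(conds)
                     for b in conds[i + 1:]]
            posthoc = pd.DataFrame(
                {"A": [a for a, _ in pairs], "B": [b for _, b in pairs],
                 "T": 0.0, "p_bonf": 1.0}
            )
            return StatsReport("repeated_anova", table, posthoc)
        aov = pg.rm_anova(data=long, dv="score", within="condition",
                          subject="subject", correction=True, detailed=False)

        def col(frame, *names):
            for name in names:  # pingouin renamed p-GG-corr → p_GG_corr etc.
                if name in frame.columns:
                    return name
            raise KeyError(names)

        gg = col(aov, "p_GG_corr", "p-GG-corr")
        p_gg = aov.loc[0, gg]
        if np.isnan(p_gg):
            p_gg = aov.loc[0, col(aov, "p_unc", "p-unc")]
        table = pd.DataFrame({
            "F": [float(aov.loc[0, "F"])],
            "p_GG": [float(p_gg)],
            "eps_GG": [float(aov.loc[0, "eps"])
                       if "eps" in aov.columns else np.nan],
            "df1": [float(aov.loc[0, "ddof1"])],
            "df2": [float(aov.loc[0, "ddof2"])],
        })
        ph = pg.pairwise_tests(data=long, dv="score", within="condition",
                               subject="subject", padjust="bonf")
        pcol = col(ph, "p_corr", "p-corr", "p_unc", "p-unc")
        posthoc = ph[["A", "B", "T", pcol]].rename(columns={pcol: "p_bonf"})
        return StatsReport("repeated_anova", table, posthoc)

    if design in ("paired_t", "two_sample_t"):
        if len(conds) != 2:
            raise ValueError("t designs require exactly two conditions")
        a = scores[conds[0]].dropna().to_numpy()
        b = scores[conds[1]].dropna().to_numpy()
        if design == "paired_t":
            if len(a) != len(b):
                raise ValueError("paired design requires complete rows")
            t, p, degenerate = _paired_t(a, b)
        else:
            t, p = stats.ttest_ind(a, b)
            t, p, degenerate = float(t), float(p), False
        table = pd.DataFrame(
            {"A": [conds[0]], "B": [conds[1]], "t": [t], "p": [p],
             "degenerate_variance": [degenerate]}
        )
        return StatsReport(design, table, None)

    raise ValueError(f"unknown design {design!r}")
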