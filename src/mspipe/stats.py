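"""Group-comparison decision procedure for behavioral and electrophysiology
measures.

The design is a split-plot: two between-subject factors — aerobic training
(trained or not) and 6-OHDA lesion (lesioned or not), jointly defining the
four groups C, CE, PD, PE — crossed with one within-subject factor (week of
training, or pre/post light state).  The analysis follows a fixed branching
rule at alpha = 0.05:

* run the repeated-measures ANOVA for all main effects and interactions;
* if any interaction is significant, test simple effects of each
  between-subject factor at each level of the other (pooled error term);
* otherwise interpret the main effects;
* pairwise follow-ups use Fisher's least-significant-difference (LSD) test,
  i.e. unadjusted t tests on the pooled error term, flagged when the
  omnibus test was not itself significant;
* pre/post-light within-group contrasts use the paired-samples t test.

The split-plot ANOVA is computed from the classic balanced sums-of-squares
decomposition (between-subject effects tested against subjects-within-groups,
within-subject effects against the subject-by-time residual), with a
Greenhouse-Geisser correction applied when Mauchly's test rejects
sphericity.  Ordinary (single-timepoint) two-way ANOVA is delegated to
statsmodels OLS.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "GROUP_FACTORS",
    "StatsReport",
    "DegenerateDataError",
    "attach_group_factors",
    "rm_anova",
    "decision_tree",
    "paired_t",
    "lsd_posthoc",
    "anova_twoway",
]

#: Mapping of group code -> (training, lesion) factor levels.
GROUP_FACTORS = {
    "C": ("untrained", "intact"),
    "CE": ("trained", "intact"),
    "PD": ("untrained", "lesioned"),
    "PE": ("trained", "lesioned"),
}


class DegenerateDataError(ValueError):
    """Raised when the response carries no variance and F is undefined."""


@dataclass
class StatsReport:
    """Outcome of the branching decision procedure."""

    anova: pd.DataFrame
    branch: list[str]
    terminal_tests: pd.DataFrame
    posthoc: pd.DataFrame | None
    alpha: float
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "branch": list(self.branch),
            "anova": self.anova.reset_index().to_dict(orient="records"),
            "terminal_tests": self.terminal_tests.to_dict(orient="records"),
            "posthoc": None
            if self.posthoc is None
            else self.posthoc.to_dict(orient="records"),
            "notes": list(self.notes),
        }


def attach_group_factors(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Add ``training`` and ``lesion`` columns derived from the C/CE/PD/PE
    group code."""
    out = table.copy()
    bad = set(out[group_col].unique()) - set(GROUP_FACTORS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")
    out["training"] = out[group_col].map(lambda g: GROUP_FACTORS[g][0])
    out["lesion"] = out[group_col].map(lambda g: GROUP_FACTORS[g][1])
    return out


def _cell_array(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    within: str,
    between: tuple[str, ...],
) -> tuple[np.ndarray, list, list]:
    """Reshape a long table into Y[cell, subject, time] for a balanced
    design; raises on missing cells or unbalanced group sizes."""
    wide = table.pivot_table(
        index=[*between, subject], columns=within, values=dv, aggfunc="mean"
    )
    if wide.isna().any().any():
        raise ValueError("incomplete design: some subjects lack within-factor cells")
    levels = [sorted(table[b].unique()) for b in between]
    cells = list(itertools.product(*levels))
    counts = wide.groupby(level=list(range(len(between)))).size()
    if len(counts) != len(cells):
        raise ValueError("missing between-subject cells in the design")
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced design (unequal group sizes); the balanced split-plot "
            "decomposition does not apply"
        )
    n = int(counts.iloc[0])
    t = wide.shape[1]
    Y = np.empty((len(cells), n, t))
    for i, cell in enumerate(cells):
        key = cell if len(cell) > 1 else cell[0]
        Y[i] = wide.loc[key].to_numpy()
    return Y, cells, list(wide.columns)


def _gg_epsilon(S: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled covariance of the repeated
    measures (via the double-centred covariance matrix)."""
    t = S.shape[0]
    row = S.mean(axis=0, keepdims=True)
    M = S - row - row.T + S.mean()
    num = np.trace(M) ** 2
    den = (t - 1) * np.sum(M**2)
    return float(np.clip(num / den, 1.0 / (t - 1), 1.0)) if den > 0 else 1.0


def _mauchly(S: np.ndarray, df_err: int) -> tuple[float, float]:
    """Mauchly's sphericity test on the pooled covariance; returns (W, p)."""
    t = S.shape[0]
    # orthonormal contrast basis (normalized Helmert)
    C = np.zeros((t - 1, t))
    for i in range(t - 1):
        C[i, : i + 1] = 1.0
        C[i, i + 1] = -(i + 1)
        C[i] /= np.linalg.norm(C[i])
    T = C @ S @ C.T
    eig = np.linalg.eigvalsh(T)
    if np.any(eig <= 0):
        return 0.0, 0.0
    p_dim = t - 1
    W = float(np.prod(eig) / (np.mean(eig) ** p_dim))
    d = 1.0 - (2 * p_dim**2 + p_dim + 2) / (6.0 * p_dim * df_err)
    chi2 = -d * df_err * np.log(W)
    df = p_dim * (p_dim + 1) // 2 - 1
    p = float(spstats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return W, p


def rm_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: str = "time",
    between: tuple[str, ...] = ("training", "lesion"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Balanced split-plot ANOVA: 1-2 between-subject factors crossed with
    one within-subject (repeated) factor.

    Returns one row per effect with sums of squares, df, F and p.  For
    within-subject effects with more than two repeated levels, a
    Greenhouse-Geisser-corrected p (``p_gg``) is reported and substituted
    for ``p`` when Mauchly's test rejects sphericity at ``alpha``.
    """
    if "group" in table.columns and not set(between) <= set(table.columns):
        table = attach_group_factors(table)
    if len(between) not in (1, 2):
        raise ValueError("between must name one or two factors")
    Y, cells, t_levels = _cell_array(table, dv, subject, within, between)
    n_cell, n, t = Y.shape
    if np.ptp(Y) == 0:
        raise DegenerateDataError("response is constant; F ratios are undefined")

    grand = Y.mean()
    m_cell = Y.mean(axis=(1, 2))  # per between-cell
    m_subj = Y.mean(axis=2)  # per subject
    m_time = Y.mean(axis=(0, 1))  # per within level
    m_cell_time = Y.mean(axis=1)  # cell x time

    # between-subject stratum
    ss_between_cells = n * t * np.sum((m_cell - grand) ** 2)
    ss_subj_err = t * np.sum((m_subj - m_cell[:, None]) ** 2)
    df_subj_err = n_cell * (n - 1)

    # within-subject stratum
    ss_time = n_cell * n * np.sum((m_time - grand) ** 2)
    ss_cell_time = n * np.sum(
        (m_cell_time - m_cell[:, None] - m_time[None, :] + grand) ** 2
    )
    ss_within_err = np.sum(
        (Y - m_cell_time[:, None, :] - m_subj[:, :, None] + m_cell[:, None, None]) ** 2
    )
    df_within_err = n_cell * (n - 1) * (t - 1)

    rows: list[dict] = []

    def add(name, ss, df1, ms_err, df2, within_effect):
        if ms_err <= 0:
            raise DegenerateDataError(f"zero error variance for effect {name}")
        F = (ss / df1) / ms_err
        rows.append(
            {
                "effect": name,
                "ss": ss,
                "df1": df1,
                "df2": df2,
                "F": F,
                "p": float(spstats.f.sf(F, df1, df2)),
                "within": within_effect,
            }
        )

    ms_subj = ss_subj_err / df_subj_err
    if len(between) == 1:
        A = len(cells)
        add(between[0], ss_between_cells, A - 1, ms_subj, df_subj_err, False)
    else:
        a_lv = sorted({c[0] for c in cells})
        b_lv = sorted({c[1] for c in cells})
        A, B = len(a_lv), len(b_lv)
        mc = m_cell.reshape(A, B)
        m_a, m_b = mc.mean(axis=1), mc.mean(axis=0)
        ss_a = B * n * t * np.sum((m_a - grand) ** 2)
        ss_b = A * n * t * np.sum((m_b - grand) ** 2)
        ss_ab = ss_between_cells - ss_a - ss_b
        add(between[0], ss_a, A - 1, ms_subj, df_subj_err, False)
        add(between[1], ss_b, B - 1, ms_subj, df_subj_err, False)
        add(f"{between[0]}:{between[1]}", ss_ab, (A - 1) * (B - 1), ms_subj, df_subj_err, False)

    ms_within = ss_within_err / df_within_err
    add(within, ss_time, t - 1, ms_within, df_within_err, True)
    if len(between) == 1:
        add(
            f"{within}:{between[0]}",
            ss_cell_time,
            (len(cells) - 1) * (t - 1),
            ms_within,
            df_within_err,
            True,
        )
    else:
        mct = m_cell_time.reshape(A, B, t)
        m_at = mct.mean(axis=1)
        m_bt = mct.mean(axis=0)
        ss_at = B * n * np.sum((m_at - m_a[:, None] - m_time[None, :] + grand) ** 2)
        ss_bt = A * n * np.sum((m_bt - m_b[:, None] - m_time[None, :] + grand) ** 2)
        ss_abt = ss_cell_time - ss_at - ss_bt
        add(f"{within}:{between[0]}", ss_at, (A - 1) * (t - 1), ms_within, df_within_err, True)
        add(f"{within}:{between[1]}", ss_bt, (B - 1) * (t - 1), ms_within, df_within_err, True)
        add(
            f"{within}:{between[0]}:{between[1]}",
            ss_abt,
            (A - 1) * (B - 1) * (t - 1),
            ms_within,
            df_within_err,
            True,
        )

    out = pd.DataFrame(rows).set_index("effect")
    out.attrs["ms_subject_error"] = ms_subj
    out.attrs["df_subject_error"] = df_subj_err
    out.attrs["ms_within_error"] = ms_within
    out.attrs["df_within_error"] = df_within_err
    out.attrs["n_per_cell"] = n
    out.attrs["n_within_levels"] = t

    # sphericity handling for the within stratum
    if t > 2:
        dev = Y - m_cell_time[:, None, :]  # cell-mean-centred per time
        S = sum(d.T @ d for d in dev) / df_subj_err
        eps = _gg_epsilon(S)
        W, p_sph = _mauchly(S, df_subj_err)
        out.attrs["gg_epsilon"] = eps
        out.attrs["mauchly_w"] = W
        out.attrs["mauchly_p"] = p_sph
        p_gg = np.full(len(out), np.nan)
        for i, (name, row) in enumerate(out.iterrows()):
            if row["within"]:
                p_gg[i] = float(
                    spstats.f.sf(row["F"], eps * row["df1"], eps * row["df2"])
                )
        out["p_gg"] = p_gg
        if p_sph < alpha:
            mask = out["within"].to_numpy()
            out.loc[mask, "p"] = out.loc[mask, "p_gg"]
            out.attrs["sphericity_corrected"] = True
    return out


def paired_t(pre: np.ndarray, post: np.ndarray) -> dict[str, float]:
    """Paired-samples t test on post - pre differences."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D vectors")
    n = pre.size
    if n < 2:
        raise ValueError("paired t requires n >= 2")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return {"t": 0.0, "p": 1.0, "df": n - 1}
        return {"t": float(np.inf * np.sign(d.mean())), "p": 0.0, "df": n - 1}
    res = spstats.ttest_rel(post, pre)
    return {"t": float(res.statistic), "p": float(res.pvalue), "df": n - 1}


def lsd_posthoc(
    means: dict[str, float],
    n_per_group: dict[str, int] | int,
    ms_error: float,
    df_error: int,
    alpha: float = 0.05,
    omnibus_p: float | None = None,
) -> pd.DataFrame:
    """Fisher LSD pairwise comparisons on the pooled ANOVA error term.

    Unadjusted t tests (the LSD definition); with two groups this reduces to
    the pooled two-sample t test.  Every row carries
    ``omnibus_significant`` so an unprotected use is visible.
    """
    names = list(means)
    if isinstance(n_per_group, int):
        n_per_group = {k: n_per_group for k in names}
    rows = []
    protected = None if omnibus_p is None else bool(omnibus_p < alpha)
    for g1, g2 in itertools.combinations(names, 2):
        diff = means[g1] - means[g2]
        se = np.sqrt(ms_error * (1.0 / n_per_group[g1] + 1.0 / n_per_group[g2]))
        if se == 0:
            raise DegenerateDataError("zero pooled error in LSD comparison")
        tval = diff / se
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "mean_diff": diff,
                "t": tval,
                "df": df_error,
                "p": float(2.0 * spstats.t.sf(abs(tval), df_error)),
                "significant": bool(2.0 * spstats.t.sf(abs(tval), df_error) < alpha),
                "omnibus_significant": protected,
            }
        )
    return pd.DataFrame(rows)


def anova_twoway(
    table: pd.DataFrame,
    dv: str = "value",
    factors: tuple[str, str] = ("training", "lesion"),
) -> pd.DataFrame:
    """Ordinary two-way between-subject ANOVA (type-II, statsmodels OLS)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if "group" in table.columns and not set(factors) <= set(table.columns):
        table = attach_group_factors(table)
    data = table.rename(columns={dv: "_dv"})
    if data["_dv"].nunique() <= 1:
        raise DegenerateDataError("response is constant; F ratios are undefined")
    f1, f2 = factors
    for f in factors:
        if data[f].nunique() < 2:
            raise DegenerateDataError(f"factor {f!r} has fewer than 2 levels")
    if len(data) <= data[f1].nunique() * data[f2].nunique():
        raise DegenerateDataError("no residual degrees of freedom")
    model = smf.ols(f"_dv ~ C({f1}) * C({f2})", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(
        index={
            f"C({f1})": f1,
            f"C({f2})": f2,
            f"C({f1}):C({f2})": f"{f1}:{f2}",
        }
    )
    aov.attrs["ms_error"] = float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"])
    aov.attrs["df_error"] = int(aov.loc["Residual", "df"])
    return aov


def _simple_effects(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    within: str,
    between: tuple[str, str],
    ms_err: float,
    df_err: int,
) -> pd.DataFrame:
    """Simple effects of each between factor at each level of the other,
    tested against the pooled subjects-within-groups error."""
    subj_means = (
        table.groupby([*between, subject])[dv].mean().reset_index()
    )
    rows = []
    for fac, other in ((between[0], between[1]), (between[1], between[0])):
        for lvl in sorted(subj_means[other].unique()):
            sub = subj_means[subj_means[other] == lvl]
            cell_means = sub.groupby(fac)[dv].mean()
            counts = sub.groupby(fac)[dv].size()
            grand = sub[dv].mean()
            t_lv = table[within].nunique()
            ss = t_lv * float(np.sum(counts.to_numpy() * (cell_means - grand) ** 2))
            df1 = len(cell_means) - 1
            F = (ss / df1) / ms_err
            rows.append(
                {
                    "test": f"{fac} at {other}={lvl}",
                    "F": F,
                    "df1": df1,
                    "df2": df_err,
                    "p": float(spstats.f.sf(F, df1, df_err)),
                }
            )
    return pd.DataFrame(rows)


def decision_tree(
    table: pd.DataFrame,
    alpha: float = 0.05,
    dv: str = "value",
    subject: str = "subject",
    within: str = "time",
    between: tuple[str, str] = ("training", "lesion"),
) -> StatsReport:
    """Run the full branching comparison procedure on a long-format table.

    Deterministic: the same table and alpha always yield the same branch
    trace and the same numbers.
    """
    if "group" in table.columns and not set(between) <= set(table.columns):
        table = attach_group_factors(table)
    aov = rm_anova(table, dv=dv, subject=subject, within=within, between=between, alpha=alpha)
    branch = ["rm_anova"]
    notes: list[str] = []
    interactions = aov[[(":" in e) for e in aov.index]]
    any_interaction = bool((interactions["p"] < alpha).any())

    ms_subj = aov.attrs["ms_subject_error"]
    df_subj = aov.attrs["df_subject_error"]
    t_lv = aov.attrs["n_within_levels"]

    if any_interaction:
        branch += ["interaction_significant", "simple_effects"]
        terminal = _simple_effects(table, dv, subject, within, between, ms_subj, df_subj)
    else:
        branch += ["no_interaction", "main_effects"]
        mains = aov[[(":" not in e) for e in aov.index]]
        terminal = (
            mains.reset_index()[["effect", "F", "df1", "df2", "p"]]
            .rename(columns={"effect": "test"})
        )

    # LSD pairwise follow-up on the four group cells (subject means)
    subj_means = table.groupby([*between, subject])[dv].mean().reset_index()
    subj_means["cell"] = subj_means[list(between)].agg("/".join, axis=1)
    means = subj_means.groupby("cell")[dv].mean().to_dict()
    counts = subj_means.groupby("cell")[dv].size().to_dict()
    omnibus_p = float(interactions["p"].min()) if any_interaction else float(
        aov.loc[[e for e in aov.index if ":" not in e], "p"].min()
    )
    # MS_subj estimates t * Var(subject mean), so comparing cell means of n
    # subjects uses se^2 = MS_subj * (1/(n_i t) + 1/(n_j t))
    posthoc = lsd_posthoc(
        means,
        {k: int(v) * t_lv for k, v in counts.items()},
        ms_subj,
        df_subj,
        alpha=alpha,
        omnibus_p=omnibus_p,
    )
    return StatsReport(
        anova=aov,
        branch=branch,
        terminal_tests=terminal,
        posthoc=posthoc,
        alpha=alpha,
        notes=notes,
    )
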