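"""Repeated-measures statistics for the trial design: one between-subject
factor (dietary group) crossed with one or two within-subject factors
(clamp insulin step or meal-test time, and pre/post intervention).

The three-way split-plot partitioning is computed directly from the
orthogonal strata of the within-subject decomposition:

* between stratum: subject means -> group effect, error = subjects(group);
* each within stratum: subject-centred profiles -> within main effect and
  its group interaction, error = factor x subjects(group).

Greenhouse-Geisser sphericity corrections are reported for within effects
with more than two levels (corrected and uncorrected p side by side).
The two-way mixed ANOVA for summary measures delegates to
``pingouin.mixed_anova``; Tukey HSD post hoc tests delegate to
statsmodels.  All entry points consume the long-format cohort table
(subject_id, group, intervention, within_level, outcome, value).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

COHORT_COLUMNS = ["subject_id", "group", "intervention", "within_level", "outcome", "value"]


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    ngroups = table.groupby("subject_id")["group"].nunique()
    if (ngroups > 1).any():
        bad = ngroups[ngroups > 1].index.tolist()
        raise ValidationError(f"subjects in more than one group: {bad}")
    return table


# ---------------------------------------------------------------------------
# split-plot engine on complete arrays
# ---------------------------------------------------------------------------

def _gg_epsilon(profiles: list[np.ndarray], d: int) -> float:
    """Greenhouse-Geisser epsilon for one within stratum.

    ``profiles[g]`` holds per-subject stratum scores that already live in
    the stratum's d-dimensional contrast subspace (subject-centred or
    double-centred), so Box's epsilon reduces to tr(S)^2 / (d tr(S^2))
    on the pooled within-group covariance S, bounded to [1/d, 1].
    """
    if d <= 1:
        return 1.0
    centered = [x - x.mean(axis=0, keepdims=True) for x in profiles]
    pooled_df = sum(x.shape[0] for x in profiles) - len(profiles)
    if pooled_df < 2:
        return 1.0
    S = sum(c.T @ c for c in centered) / pooled_df
    denom = d * np.trace(S @ S)
    if denom <= 0:
        return 1.0
    return float(max(1.0 / d, min(1.0, np.trace(S) ** 2 / denom)))


def _f_row(factor: str, ss: float, df1: float, ss_err: float, df2: float, eps: float = 1.0) -> dict:
    ms, ms_err = ss / df1, ss_err / df2
    F = ms / ms_err if ms_err > 0 else np.inf
    p = float(sps.f.sf(F, df1, df2))
    p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps)) if eps < 1.0 else p
    return {"factor": factor, "SS": ss, "df1": df1, "df2": df2, "F": F, "p": p,
            "p_gg": p_gg, "eps_gg": eps}


def _split_plot_anova(groups: list[np.ndarray], names: tuple[str, ...]) -> pd.DataFrame:
    """Split-plot ANOVA on complete data.

    ``groups[g]`` has shape (n_g, b) for one within factor or (n_g, b, c)
    for two; ``names`` = (between, within1[, within2]).
    """
    a = len(groups)
    if a < 2:
        raise ValidationError("need at least 2 groups")
    shapes = {g.shape[1:] for g in groups}
    if len(shapes) != 1:
        raise ValidationError("within-cell layouts differ between groups")
    two_within = groups[0].ndim == 3
    n_g = np.array([g.shape[0] for g in groups])
    if (n_g < 2).any():
        raise ValidationError("need at least 2 subjects per group")
    N = int(n_g.sum())
    b = groups[0].shape[1]
    c = groups[0].shape[2] if two_within else 1
    between, w1 = names[0], names[1]
    w2 = names[2] if two_within else None

    flat = [g.reshape(g.shape[0], b, c) for g in groups]
    rows = []

    # --- between stratum: one-way ANOVA on subject means, scaled by cell count
    m = [g.mean(axis=(1, 2)) for g in flat]
    grand = np.concatenate(m).mean()
    ss_between = b * c * float(sum(n * (mi.mean() - grand) ** 2 for n, mi in zip(n_g, m)))
    ss_subj = b * c * float(sum(((mi - mi.mean()) ** 2).sum() for mi in m))
    rows.append(_f_row(between, ss_between, a - 1, ss_subj, N - a))

    def within_stratum(profiles: list[np.ndarray], d: int, label: str, inter_label: str, scale: float):
        """profiles[g]: (n_g, cells) subject-centred stratum scores."""
        allp = np.concatenate(profiles)
        overall = allp.mean(axis=0)
        ss_main = scale * N * float((overall**2).sum())
        gmeans = [p.mean(axis=0) for p in profiles]
        ss_inter = scale * float(sum(n * ((gm - overall) ** 2).sum() for n, gm in zip(n_g, gmeans)))
        ss_err = scale * float(sum(((p - gm) ** 2).sum() for p, gm in zip(profiles, gmeans)))
        eps = _gg_epsilon(profiles, d)
        df_err = (N - a) * d
        rows.append(_f_row(label, ss_main, d, ss_err, df_err, eps))
        rows.append(_f_row(inter_label, ss_inter, (a - 1) * d, ss_err, df_err, eps))

    # --- first within factor stratum
    w1_prof = [g.mean(axis=2) - g.mean(axis=(1, 2), keepdims=True)[:, :, 0] for g in flat]
    within_stratum(w1_prof, b - 1, w1, f"{between} * {w1}", float(c))

    if two_within:
        # --- second within factor stratum
        w2_prof = [g.mean(axis=1) - g.mean(axis=(1, 2), keepdims=True)[:, 0, :] for g in flat]
        within_stratum(w2_prof, c - 1, w2, f"{between} * {w2}", float(b))
        # --- interaction stratum (double-centred within subject)
        inter_prof = []
        for g in flat:
            v = (g - g.mean(axis=2, keepdims=True) - g.mean(axis=1, keepdims=True)
                 + g.mean(axis=(1, 2), keepdims=True))
            inter_prof.append(v.reshape(g.shape[0], b * c))
        within_stratum(inter_prof, (b - 1) * (c - 1), f"{w1} * {w2}",
                       f"{between} * {w1} * {w2}", 1.0)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# long-table entry points
# ---------------------------------------------------------------------------

def _pivot_complete(
    table: pd.DataFrame,
    outcome: str,
    within: tuple[str, ...],
) -> tuple[list[np.ndarray], list[str]]:
    """Pivot one outcome into per-group complete arrays; listwise-exclude
    subjects with any missing within-cell (with a warning)."""
    df = validate_cohort_table(table)
    df = df[df["outcome"] == outcome]
    if df.empty:
        raise ValidationError(f"outcome {outcome!r} not present in table")
    idx = ["subject_id"] + list(within)
    wide = df.pivot_table(index="subject_id", columns=list(within), values="value", aggfunc="mean")
    complete = wide.dropna()
    dropped = set(wide.index) - set(complete.index)
    if dropped:
        warnings.warn(f"excluding {len(dropped)} subject(s) with incomplete data: {sorted(dropped)}",
                      stacklevel=3)
    if complete.empty:
        raise ValidationError("no subject has complete within-cell data")
    subj_group = df.drop_duplicates("subject_id").set_index("subject_id")["group"]
    levels = [sorted(df[w].unique()) for w in within]
    shape = tuple(len(lv) for lv in levels)
    # reindex columns into the full factorial order
    if len(within) == 1:
        cols = levels[0]
    else:
        cols = pd.MultiIndex.from_product(levels)
    complete = complete.reindex(columns=cols)
    if complete.isna().any().any():
        raise ValidationError("within-level combinations missing entirely")
    group_names = sorted(subj_group.unique())
    groups = []
    for gname in group_names:
        subs = [s for s in complete.index if subj_group[s] == gname]
        if not subs:
            raise ValidationError(f"group {gname!r} has no complete subjects")
        arr = complete.loc[subs].to_numpy(float).reshape((len(subs),) + shape)
        groups.append(arr)
    return groups, group_names


def rm_anova_3way(
    table: pd.DataFrame,
    outcome: str,
    within: tuple[str, str] = ("within_level", "intervention"),
) -> pd.DataFrame:
    """Three-way repeated-measures ANOVA: group (between) x two within factors.

    Returns an effect table with F, uncorrected p and Greenhouse-Geisser
    corrected p (``p_gg``; equal to p for 2-level factors).
    """
    groups, _ = _pivot_complete(table, outcome, within)
    return _split_plot_anova(groups, ("group",) + tuple(within))


def anova_2way_summary(table: pd.DataFrame, outcome: str, within: str = "intervention") -> pd.DataFrame:
    """Two-way mixed ANOVA (group x intervention) for summary measures (AUCs, indices).

    Thin wrapper over ``pingouin.mixed_anova`` mapped onto the same effect-table
    format as :func:`rm_anova_3way`.
    """
    import pingouin as pg

    df = validate_cohort_table(table)
    df = df[df["outcome"] == outcome]
    if df.empty:
        raise ValidationError(f"outcome {outcome!r} not present in table")
    if df["group"].nunique() < 2:
        raise ValidationError("need at least 2 groups")
    collapsed = (
        df.groupby(["subject_id", "group", within], as_index=False)["value"].mean()
    )
    counts = collapsed.groupby("subject_id")[within].nunique()
    keep = counts[counts == collapsed[within].nunique()].index
    if len(keep) < len(counts):
        warnings.warn(f"excluding {len(counts) - len(keep)} subject(s) with incomplete data",
                      stacklevel=2)
    collapsed = collapsed[collapsed["subject_id"].isin(keep)]
    aov = pg.mixed_anova(
        data=collapsed, dv="value", within=within, subject="subject_id", between="group"
    )
    rename = {"group": "group", within: within, "Interaction": f"group * {within}"}
    out = pd.DataFrame(
        {
            "factor": [rename.get(s, s) for s in aov["Source"]],
            "SS": aov["SS"].to_numpy(float),
            "df1": aov["DF1"].to_numpy(float),
            "df2": aov["DF2"].to_numpy(float),
            "F": aov["F"].to_numpy(float),
            "p": aov["p_unc"].to_numpy(float),
        }
    )
    out["p_gg"] = out["p"]
    out["eps_gg"] = 1.0
    return out


def tukey_posthoc(table: pd.DataFrame, outcome: str, factor: str = "group") -> pd.DataFrame:
    """Tukey HSD pairwise comparisons across the levels of one factor.

    For the between factor, one value per subject (the subject mean) enters
    the comparison; for within factors, subject-by-level means are compared
    (ignoring the repeated-measures correlation — a conservative screen,
    documented as such).  With two levels Tukey's p equals the unadjusted
    equal-variance t-test p.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = validate_cohort_table(table)
    df = df[df["outcome"] == outcome]
    if df.empty:
        raise ValidationError(f"outcome {outcome!r} not present in table")
    if factor not in ("group", "intervention", "within_level"):
        raise ValidationError(f"unknown factor {factor!r}")
    if df[factor].nunique() < 2:
        raise ValidationError(f"factor {factor!r} has fewer than 2 levels")
    per = df.groupby(["subject_id", factor], as_index=False)["value"].mean()
    res = pairwise_tukeyhsd(per["value"].to_numpy(), per[factor].to_numpy(str))
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    frame["p-adj"] = res.pvalues
    return frame


def outcome_summary(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Mean +/- SD per group x intervention (and within level if present)."""
    df = validate_cohort_table(table)
    df = df[df["outcome"] == outcome]
    keys = ["group", "intervention"]
    if df["within_level"].nunique() > 1:
        keys.append("within_level")
    agg = df.groupby(keys)["value"].agg(["mean", "std", "count"]).reset_index()
    agg.insert(0, "outcome", outcome)
    return agg
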