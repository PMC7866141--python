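"""Cohort-level inference for the two-plate assay.

The readout per mouse, session and timepoint is the percentage of session
time spent on the colder plate (``pct_colder``); the warmer plate's share
is its complement.  Two comparison families are reported per session:

* **plate family** (figure stars): is ``pct_colder`` different from 50%
  within a timepoint?  Because the two plates' times are complementary,
  the plate-vs-plate contrast is exactly a paired comparison of
  ``pct_colder`` against ``pct_warmer``, i.e. a one-sample test of
  ``pct_colder - 50``.
* **timepoint family** (figure hashes): does the same plate's share change
  across the three timepoints?  Pairwise contrasts of ``pct_colder``
  across timepoints, Tukey-adjusted on the studentized range with k = 3.

The omnibus test is a one-way repeated-measures ANOVA on ``pct_colder``
with the within-subject factor timepoint.  Both families use the
studentized-range adjustment (with k = 2 it reduces exactly to the paired
t-test, so the plate family's adjustment is the identity).

An analgesic effect is declared per session from the pre-drug and
post-drug preference directions: a significant preference that disappears
is **lost**, one that flips sign is **reversed**, one that persists is
**maintained**; sessions with no pre-drug preference carry no baseline and
support no analgesia claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy.stats import studentized_range

from .protocol import Timepoint

__all__ = [
    "CohortError",
    "PreferenceCall",
    "DrugEffectCall",
    "RMAnovaResult",
    "validate_cohort",
    "rm_anova",
    "tukey_pairwise",
    "stars",
    "call_preference",
    "call_drug_effect",
    "analyze_cohort",
]

ALPHA_DEFAULT = 0.05
_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


class CohortError(ValueError):
    """Malformed or incomplete cohort table."""


# ---------------------------------------------------------------------------
# Table validation
# ---------------------------------------------------------------------------

_REQUIRED = ("subject", "session_id", "timepoint", "pct_colder")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy cohort table and return it.

    Requires columns ``subject, session_id, timepoint, pct_colder``; every
    subject must cover the full session x timepoint grid, with no duplicate
    cells and percentages in [0, 100].
    """
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise CohortError(f"missing required columns: {missing_cols}")
    if len(df) == 0:
        raise CohortError("empty cohort table")
    bad = df[(df["pct_colder"] < 0) | (df["pct_colder"] > 100)]
    if len(bad):
        raise CohortError(
            f"pct_colder outside [0, 100] at rows {list(bad.index[:5])}"
        )
    keys = df[["subject", "session_id", "timepoint"]]
    dup = keys.duplicated()
    if dup.any():
        raise CohortError(
            f"duplicate (subject, session, timepoint) rows at {list(df.index[dup][:5])}"
        )
    subjects = df["subject"].unique()
    sessions = df["session_id"].unique()
    tps = df["timepoint"].unique()
    full = {(s, ses, tp) for s in subjects for ses in sessions for tp in tps}
    have = set(map(tuple, keys.itertuples(index=False)))
    holes = sorted(full - have)
    if holes:
        raise CohortError(
            f"incomplete grid: {len(holes)} missing cells, e.g. {holes[:5]}"
        )
    return df


def _session_wide(df: pd.DataFrame, session_id) -> pd.DataFrame:
    """subject x timepoint matrix of pct_colder for one session."""
    sub = df[df["session_id"] == session_id]
    if len(sub) == 0:
        raise CohortError(f"no rows for session {session_id}")
    order = [tp.value for tp in Timepoint.ordered() if tp.value in set(sub["timepoint"])]
    wide = sub.pivot(index="subject", columns="timepoint", values="pct_colder")
    wide = wide[order]
    if wide.isna().any().any():
        holes = [
            (s, tp)
            for s in wide.index
            for tp in wide.columns
            if pd.isna(wide.loc[s, tp])
        ]
        raise CohortError(f"incomplete timepoint grid for session {session_id}: {holes}")
    if len(wide) < 2:
        raise CohortError(f"need >= 2 subjects with complete data, session {session_id}")
    return wide


# ---------------------------------------------------------------------------
# Omnibus test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    p: float
    df1: float
    df2: float
    degenerate: bool = False


def rm_anova(
    df: pd.DataFrame, session_id, correction: bool = False
) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on pct_colder across timepoints.

    ``correction=True`` applies the Greenhouse-Geisser epsilon.  If the
    within-subject variance is exactly zero the test is degenerate and is
    flagged with p = 1.
    """
    wide = _session_wide(df, session_id)
    vals = wide.to_numpy()
    # residual after removing subject and timepoint means
    resid = vals - vals.mean(1, keepdims=True) - vals.mean(0, keepdims=True) + vals.mean()
    if np.allclose(resid, 0.0) and np.allclose(vals - vals.mean(1, keepdims=True), 0.0):
        return RMAnovaResult(F=float("nan"), p=1.0, df1=0, df2=0, degenerate=True)
    long = wide.reset_index().melt(
        id_vars="subject", var_name="timepoint", value_name="pct_colder"
    )
    aov = pg.rm_anova(
        data=long,
        dv="pct_colder",
        within="timepoint",
        subject="subject",
        correction=correction,
        detailed=True,
    )
    row = aov.iloc[0]
    candidates = (
        ["p_GG_corr", "p-GG-corr"] if correction else []
    ) + ["p_unc", "p-unc"]
    p_col = next(c for c in candidates if c in aov.columns)
    p = float(row[p_col])
    if np.isnan(row["F"]):
        return RMAnovaResult(F=float("nan"), p=1.0, df1=0, df2=0, degenerate=True)
    return RMAnovaResult(
        F=float(row["F"]),
        p=p,
        df1=float(row["DF"]),
        df2=float(aov.iloc[1]["DF"]),
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# Pairwise contrasts (Tukey on the studentized range, paired SEs)
# ---------------------------------------------------------------------------


def _paired_tukey_p(diff: np.ndarray, k: int) -> tuple[float, float]:
    """(t, adjusted p) for one paired contrast inside a k-level family.

    Uses the pair-specific paired t statistic referred to the studentized
    range with ``k`` means and n - 1 degrees of freedom (q = t * sqrt(2)).
    With k = 2 this equals the two-sided paired t-test exactly.  Degenerate
    zero-variance differences map to p = 1 (no difference) or p = 0
    (constant nonzero difference).
    """
    n = len(diff)
    mean = diff.mean()
    sd = diff.std(ddof=1)
    if sd == 0.0:
        return (0.0, 1.0) if mean == 0.0 else (float("inf"), 0.0)
    tstat = mean / (sd / np.sqrt(n))
    p = float(studentized_range.sf(abs(tstat) * np.sqrt(2.0), k, n - 1))
    return float(tstat), min(max(p, 0.0), 1.0)


def tukey_pairwise(df: pd.DataFrame, session_id, family: str) -> pd.DataFrame:
    """Adjusted pairwise contrasts for one session.

    ``family="plate"``: colder vs warmer plate within each timepoint (the
    star family).  Each contrast has two complementary cells, so k = 2 and
    the adjustment is the identity (paired t-test).

    ``family="timepoint"``: same-plate (colder) share across timepoint
    pairs (the hash family), Tukey-adjusted with k = 3.

    Returns a frame with columns ``level_a, level_b, mean_diff, t, p_adj``.
    """
    wide = _session_wide(df, session_id)
    rows = []
    if family == "plate":
        for tp in wide.columns:
            colder = wide[tp].to_numpy()
            diff = colder - (100.0 - colder)  # pct_colder - pct_warmer
            t, p = _paired_tukey_p(diff, k=2)
            rows.append(
                {
                    "level_a": f"colder@{tp}",
                    "level_b": f"warmer@{tp}",
                    "timepoint": tp,
                    "mean_diff": diff.mean(),
                    "t": t,
                    "p_adj": p,
                }
            )
    elif family == "timepoint":
        tps = list(wide.columns)
        k = len(tps)
        for i in range(k):
            for j in range(i + 1, k):
                diff = wide[tps[j]].to_numpy() - wide[tps[i]].to_numpy()
                t, p = _paired_tukey_p(diff, k=k)
                rows.append(
                    {
                        "level_a": tps[i],
                        "level_b": tps[j],
                        "timepoint": None,
                        "mean_diff": diff.mean(),
                        "t": t,
                        "p_adj": p,
                    }
                )
    else:
        raise ValueError("family must be 'plate' or 'timepoint'")
    return pd.DataFrame(rows)


def stars(p: float) -> str:
    """Map an (adjusted) p-value to the conventional significance stars.

    Strict inequalities at 0.05, 0.01, 0.001, 0.0001; anything at or above
    0.05 is "ns".
    """
    if not (0.0 <= p <= 1.0) or np.isnan(p):
        raise ValueError(f"p-value must lie in [0, 1], got {p!r}")
    for cut, label in _STAR_LEVELS:
        if p < cut:
            return label
    return "ns"


# ---------------------------------------------------------------------------
# Preference and drug-effect calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PreferenceCall:
    """Direction of plate preference at one session x timepoint."""

    session_id: int
    timepoint: str
    direction: str  # warmer | colder | none
    p_adj: float
    mean_pct_colder: float
    stars: str


@dataclass(frozen=True)
class DrugEffectCall:
    """Analgesia classification of one session from pre vs post preference."""

    session_id: int
    category: str  # maintained | lost | reversed | no_baseline
    pre: PreferenceCall
    post: PreferenceCall
    cross_p_adj: float  # same-plate pre-vs-post contrast (hash family)
    cross_stars: str


def call_preference(
    df: pd.DataFrame, session_id, timepoint, alpha: float = ALPHA_DEFAULT
) -> PreferenceCall:
    """Preference direction at one timepoint of one session.

    warmer if the cohort mean favors the warmer plate and the adjusted
    plate contrast is significant; colder symmetrically; otherwise none
    (including an exact 50/50 mean, which has no direction).
    """
    tp = timepoint.value if isinstance(timepoint, Timepoint) else str(timepoint)
    fam = tukey_pairwise(df, session_id, family="plate")
    row = fam[fam["timepoint"] == tp]
    if len(row) == 0:
        raise CohortError(f"timepoint {tp!r} absent from session {session_id}")
    p = float(row["p_adj"].iloc[0])
    mean_colder = 50.0 + float(row["mean_diff"].iloc[0]) / 2.0
    if p < alpha and mean_colder > 50.0:
        direction = "colder"
    elif p < alpha and mean_colder < 50.0:
        direction = "warmer"
    else:
        direction = "none"
    return PreferenceCall(
        session_id=session_id,
        timepoint=tp,
        direction=direction,
        p_adj=p,
        mean_pct_colder=mean_colder,
        stars=stars(p) if direction != "none" else "ns",
    )


def call_drug_effect(
    pre: PreferenceCall,
    post: PreferenceCall,
    cross_p_adj: float = float("nan"),
) -> DrugEffectCall:
    """Classify the analgesic readout of one session.

    lost      — a pre-drug preference that is gone post-drug;
    reversed  — a pre-drug preference that flipped to the opposite plate;
    maintained— the same preference on both sides of drug administration;
    no_baseline — no pre-drug preference existed, so the session supports
    no analgesia claim.
    """
    if pre.session_id != post.session_id:
        raise ValueError(
            f"mismatched sessions: pre={pre.session_id}, post={post.session_id}"
        )
    if pre.direction == "none":
        category = "no_baseline"
    elif post.direction == "none":
        category = "lost"
    elif post.direction == pre.direction:
        category = "maintained"
    else:
        category = "reversed"
    return DrugEffectCall(
        session_id=pre.session_id,
        category=category,
        pre=pre,
        post=post,
        cross_p_adj=cross_p_adj,
        cross_stars="ns" if np.isnan(cross_p_adj) else stars(cross_p_adj),
    )


def analyze_cohort(
    df: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    pre_tp: Timepoint = Timepoint.PRE_DRUG,
    post_tp: Timepoint = Timepoint.POST_DRUG,
    omnibus: bool = True,
) -> pd.DataFrame:
    """Full per-session analysis of a cohort table.

    For every session: the omnibus RM-ANOVA across timepoints, preference
    calls at the pre- and post-drug timepoints, the same-plate pre-vs-post
    Tukey contrast, and the analgesia category.  Returns one row per
    session.
    """
    validate_cohort(df)
    rows = []
    for session_id in sorted(df["session_id"].unique()):
        pre = call_preference(df, session_id, pre_tp, alpha)
        post = call_preference(df, session_id, post_tp, alpha)
        fam_t = tukey_pairwise(df, session_id, family="timepoint")
        cross = fam_t[
            (fam_t["level_a"] == pre_tp.value) & (fam_t["level_b"] == post_tp.value)
        ]
        cross_p = float(cross["p_adj"].iloc[0]) if len(cross) else float("nan")
        call = call_drug_effect(pre, post, cross_p)
        row = {
            "session_id": session_id,
            "t_cold": df.loc[df["session_id"] == session_id, "t_cold"].iloc[0]
            if "t_cold" in df.columns
            else float("nan"),
            "t_warm": df.loc[df["session_id"] == session_id, "t_warm"].iloc[0]
            if "t_warm" in df.columns
            else float("nan"),
            "pre_direction": pre.direction,
            "pre_p_adj": pre.p_adj,
            "pre_stars": pre.stars,
            "pre_mean_pct_colder": pre.mean_pct_colder,
            "post_direction": post.direction,
            "post_p_adj": post.p_adj,
            "post_stars": post.stars,
            "post_mean_pct_colder": post.mean_pct_colder,
            "cross_p_adj": call.cross_p_adj,
            "cross_stars": call.cross_stars,
            "category": call.category,
        }
        if omnibus:
            aov = rm_anova(df, session_id)
            row["anova_F"] = aov.F
            row["anova_p"] = aov.p
        rows.append(row)
    return pd.DataFrame(rows)
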