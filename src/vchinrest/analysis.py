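"""Cohort-level statistics on simulated (or logged) sessions.

Covers the quantities a virtual-chinrest deployment reports: mean
crowding per eccentricity cell (and its ratio to eccentricity, Bouma's
constant), dyslexic vs non-dyslexic cell means, the distribution and
test-retest reliability of the distance estimates (within-subject SD,
pairwise correlations, and the one-way random-effects intraclass
correlation with absolute agreement), two-group comparisons (Welch t
and Mann-Whitney U), and an OLS regression of crowding on eccentricity,
dyslexia, age and age squared.

Participant-level random effects are deliberately not modelled: each
simulated participant contributes a single threshold per session, so a
random intercept is not identifiable and ordinary least squares on the
per-session crowding effects is the appropriate fit here.

Missing data are excluded listwise per analysis and counted, never
silently dropped.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .session import SessionRecord, sessions_to_df

_PAIRS = (("pre", "mid"), ("mid", "post"), ("pre", "post"))


@dataclass
class CohortSummary:
    n_sessions: int
    mean_crowding_by_ecc: dict
    sem_crowding_by_ecc: dict
    mean_crowding_by_dyslexia_and_ecc: dict
    bouma_ratio_by_ecc: dict
    distance_mean_mm: float
    distance_sd_mm: float
    within_subject_sd_mm: float
    icc: float | None
    pairwise_r: dict
    n_excluded: int


WithinSubjectSD = namedtuple("WithinSubjectSD", ["mean_sd_mm", "n_used", "n_excluded"])

GroupComparison = namedtuple(
    "GroupComparison",
    ["factor", "groups", "n", "means", "welch_t", "welch_p",
     "mannwhitney_u", "mannwhitney_p", "normality_advisory"],
)

AgeQuadraticFit = namedtuple("AgeQuadraticFit", ["params", "bse", "results"])


def _phase_table(records: Sequence[SessionRecord]) -> tuple[pd.DataFrame, int]:
    """Subjects x {pre, mid, post} distance estimates; drops incomplete rows."""
    df = sessions_to_df(records)[["d_pre_mm", "d_mid_mm", "d_post_mm"]]
    df.columns = ["pre", "mid", "post"]
    complete = df.dropna()
    return complete, len(df) - len(complete)


def summarize(records: Sequence[SessionRecord]) -> CohortSummary:
    """All cohort summary statistics in one pass.

    Cells with no members are absent from the maps, not reported as
    zero.  Order-invariant in the records.
    """
    if len(records) == 0:
        raise ValueError("need at least one session record")
    df = sessions_to_df(records)

    mean_by_ecc, sem_by_ecc, ratio_by_ecc = {}, {}, {}
    for ecc, grp in df.groupby("eccentricity_deg"):
        vals = grp["crowding_effect_deg"].dropna()
        if len(vals) == 0:
            continue
        mean_by_ecc[ecc] = float(vals.mean())
        sem_by_ecc[ecc] = float(vals.sem()) if len(vals) > 1 else float("nan")
        ratio_by_ecc[ecc] = mean_by_ecc[ecc] / ecc

    by_dys = {}
    for (dys, ecc), grp in df.groupby(["dyslexia", "eccentricity_deg"]):
        vals = grp["crowding_effect_deg"].dropna()
        if len(vals) > 0:
            by_dys[(bool(dys), ecc)] = float(vals.mean())

    phases, n_excl = _phase_table(records)
    per_session_mean = phases.mean(axis=1)
    wss = within_subject_sd(phases)
    icc = icc_oneway_absolute(phases.to_numpy()) if len(phases) >= 2 else None
    pairwise = {}
    if len(phases) >= 2:
        for a, b in _PAIRS:
            if phases[a].nunique() < 2 or phases[b].nunique() < 2:
                pairwise[(a, b)] = float("nan")  # correlation undefined
                continue
            r, _ = stats.pearsonr(phases[a], phases[b])
            pairwise[(a, b)] = float(r)

    return CohortSummary(
        n_sessions=len(records),
        mean_crowding_by_ecc=mean_by_ecc,
        sem_crowding_by_ecc=sem_by_ecc,
        mean_crowding_by_dyslexia_and_ecc=by_dys,
        bouma_ratio_by_ecc=ratio_by_ecc,
        distance_mean_mm=float(per_session_mean.mean()),
        distance_sd_mm=float(per_session_mean.std(ddof=1)) if len(phases) > 1 else float("nan"),
        within_subject_sd_mm=wss.mean_sd_mm,
        icc=icc,
        pairwise_r=pairwise,
        n_excluded=n_excl + wss.n_excluded,
    )


def icc_oneway_absolute(table) -> float | None:
    """ICC(1): one-way random effects, absolute agreement.

    For a complete subjects x sessions table with k sessions,

        ICC(1) = (MSB - MSW) / (MSB + (k - 1) * MSW)

    from the one-way ANOVA decomposition (between-subject vs
    within-subject mean squares).  Returns ``None`` (an explicit
    undefined marker) when the table has no variance at all.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError(f"need a complete table with >=2 subjects and >=2 "
                         f"sessions, got shape {x.shape}")
    if np.isnan(x).any():
        raise ValueError("table must be complete (no NaN)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    ss_between = k * float(((row_means - grand) ** 2).sum())
    ss_within = float(((x - row_means[:, None]) ** 2).sum())
    if ss_between + ss_within == 0.0:
        return None
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


def within_subject_sd(distances) -> WithinSubjectSD:
    """Cohort mean of per-subject SDs across the three phases.

    Accepts a DataFrame with columns pre/mid/post (rows = subjects) or a
    sequence of ``{"pre": .., "mid": .., "post": ..}`` mappings.  The
    per-subject SD uses the n-1 denominator.  Subjects with a missing
    phase are excluded and counted in ``n_excluded``.
    """
    if isinstance(distances, pd.DataFrame):
        df = distances[["pre", "mid", "post"]]
    else:
        df = pd.DataFrame(list(distances)).reindex(columns=["pre", "mid", "post"])
    complete = df.dropna()
    n_excluded = len(df) - len(complete)
    if len(complete) == 0:
        return WithinSubjectSD(float("nan"), 0, n_excluded)
    sds = complete.std(axis=1, ddof=1)
    return WithinSubjectSD(float(sds.mean()), len(complete), n_excluded)


def _normality_advisory(groups: dict) -> str:
    """Documented rule: D'Agostino-Pearson per group when n >= 20.

    Advises the non-parametric test when either group deviates at
    p < 0.05; with n < 20 the omnibus test is unreliable and the
    advisory defers to the non-parametric result.
    """
    notes = []
    for name, vals in groups.items():
        if len(vals) >= 20:
            _, p = stats.normaltest(vals)
            notes.append(f"{name}: normaltest p={p:.3g}"
                         + (" (non-normal; prefer Mann-Whitney)" if p < 0.05 else ""))
        else:
            notes.append(f"{name}: n<20, normality not assessed; prefer Mann-Whitney")
    return "; ".join(notes)


def compare_groups(records: Sequence[SessionRecord], factor: str) -> GroupComparison:
    """Two-group comparison of crowding effects (Welch t + Mann-Whitney U).

    ``factor`` is ``"eccentricity"`` (4 vs 6 deg) or ``"dyslexia"``.
    """
    df = sessions_to_df(records).dropna(subset=["crowding_effect_deg"])
    if factor == "eccentricity":
        col = "eccentricity_deg"
    elif factor == "dyslexia":
        col = "dyslexia"
    else:
        raise ValueError(f"factor must be 'eccentricity' or 'dyslexia', got {factor!r}")
    levels = sorted(df[col].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups for {factor}, found {levels}")
    a = df.loc[df[col] == levels[0], "crowding_effect_deg"].to_numpy()
    b = df.loc[df[col] == levels[1], "crowding_effect_deg"].to_numpy()
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least 2 sessions")
    t, tp = stats.ttest_ind(a, b, equal_var=False)
    u, up = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        factor=factor,
        groups=tuple(levels),
        n=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        welch_t=float(t),
        welch_p=float(tp),
        mannwhitney_u=float(u),
        mannwhitney_p=float(up),
        normality_advisory=_normality_advisory(
            {str(levels[0]): a, str(levels[1]): b}),
    )


def fit_age_quadratic(data) -> AgeQuadraticFit:
    """OLS: crowding ~ eccentricity + dyslexia + age + age^2.

    Accepts session records or a DataFrame with columns
    ``crowding_effect_deg``, ``eccentricity_deg``, ``dyslexia``, ``age``.
    Eccentricity enters numerically (degrees), so its coefficient is the
    per-degree crowding slope (the Bouma ratio under the generative
    model).  Raises on a rank-deficient design (e.g. no age variation).
    """
    df = data if isinstance(data, pd.DataFrame) else sessions_to_df(data)
    df = df.dropna(subset=["crowding_effect_deg", "eccentricity_deg",
                           "dyslexia", "age"])
    if df["age"].nunique() < 3:
        raise ValueError("age must vary (>= 3 distinct values) to fit a quadratic")
    X = np.column_stack([
        np.ones(len(df)),
        df["eccentricity_deg"].to_numpy(float),
        df["dyslexia"].to_numpy(float),
        df["age"].to_numpy(float),
        df["age"].to_numpy(float) ** 2,
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix: check that eccentricity, "
                         "dyslexia and age all vary in the cohort")
    names = ["intercept", "eccentricity", "dyslexia", "age", "age_sq"]
    res = sm.OLS(df["crowding_effect_deg"].to_numpy(float), X).fit()
    return AgeQuadraticFit(
        params=dict(zip(names, map(float, res.params))),
        bse=dict(zip(names, map(float, res.bse))),
        results=res,
    )
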