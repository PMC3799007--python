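"""Repeated-measures statistics for the study design.

The design is split-plot: one between-subject factor (Group: trained vs
control, equal n) crossed with one or two within-subject factors (Time:
pre/post; Task: 2/3/4), one observation per subject x cell.  The ANOVA is
the classical balanced sums-of-squares decomposition: the between effect
is tested against subject-within-group variation, and each within effect
(and its interaction with Group) against the matching
effect x subject-within-group stratum.  No sphericity correction is
applied by default; Greenhouse-Geisser is available behind a flag.

Within-subject error bars use the Cousineau normalization (remove each
subject's mean, add back the grand mean) with Morey's bias correction
sqrt(M / (M - 1)) for M conditions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class DesignError(ValueError):
    """Raised when data are unbalanced or incomplete for the RM design."""


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    df_num: int
    df_den: int
    F: float
    p: float
    ss: float
    ss_error: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# within-subject error bars

def cousineau_morey(matrix: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Within-subject SEM per condition (Cousineau-Morey).

    ``matrix`` is subjects x conditions, complete.  Each cell is
    normalized as ``y - subject_mean + grand_mean``; the per-condition
    SEM of the normalized values is scaled by sqrt(M / (M - 1)).
    Invariant to adding any per-subject constant.
    """
    if isinstance(matrix, pd.DataFrame):
        conditions = list(matrix.columns)
        arr = matrix.to_numpy(float)
    else:
        arr = np.asarray(matrix, float)
        conditions = list(range(arr.shape[1])) if arr.ndim == 2 else []
    if arr.ndim != 2:
        raise DesignError("matrix must be 2-D (subjects x conditions)")
    n, m = arr.shape
    if n < 2 or m < 2:
        raise DesignError(f"need >= 2 subjects and >= 2 conditions, got {n} x {m}")
    if np.isnan(arr).any():
        raise DesignError("missing cells: within-subject SEMs need complete data")
    normalized = arr - arr.mean(axis=1, keepdims=True) + arr.mean()
    sem = normalized.std(axis=0, ddof=1) / np.sqrt(n)
    sem = sem * np.sqrt(m / (m - 1))  # Morey correction
    return pd.DataFrame({"condition": conditions,
                         "mean": arr.mean(axis=0),
                         "within_subject_sem": sem})


# ---------------------------------------------------------------------------
# balanced split-plot ANOVA

def _to_array(data: pd.DataFrame, dv: str, subject: str, between: str,
              within: Sequence[str]) -> tuple[np.ndarray, dict]:
    """Reshape long data to a dense array [group, subject, w1, (w2)].

    Validates that the design is complete and balanced (equal group
    sizes, exactly one observation per subject x within-cell).
    """
    required = [subject, between, dv, *within]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise DesignError(f"missing columns: {missing}")
    if data[dv].isna().any():
        raise DesignError("missing values in the response")
    data = data[required]  # keep itertuples field names predictable
    groups_by_subject = data.groupby(subject)[between].nunique()
    if (groups_by_subject > 1).any():
        bad = groups_by_subject[groups_by_subject > 1].index.tolist()
        raise DesignError(f"subjects appear in more than one group: {bad}")
    glevels = sorted(data[between].unique())
    wlevels = [sorted(data[w].unique()) for w in within]
    subj_per_group = {g: sorted(data.loc[data[between] == g, subject].unique())
                      for g in glevels}
    ns = {g: len(s) for g, s in subj_per_group.items()}
    if len(set(ns.values())) != 1:
        raise DesignError(f"unequal group sizes {ns}: balanced design required")
    n = next(iter(ns.values()))
    if n < 2:
        raise DesignError("need >= 2 subjects per group")
    shape = (len(glevels), n, *[len(w) for w in wlevels])
    arr = np.full(shape, np.nan)
    gidx = {g: i for i, g in enumerate(glevels)}
    sidx = {g: {s: i for i, s in enumerate(subs)} for g, subs in subj_per_group.items()}
    widx = [{lv: i for i, lv in enumerate(w)} for w in wlevels]
    for row in data.itertuples(index=False):
        rec = row._asdict()
        pos = (gidx[rec[between]], sidx[rec[between]][rec[subject]],
               *[widx[k][rec[w]] for k, w in enumerate(within)])
        if not np.isnan(arr[pos]):
            raise DesignError(f"duplicate observation for cell {pos}")
        arr[pos] = rec[dv]
    if np.isnan(arr).any():
        raise DesignError("incomplete design: some subject x cell combinations missing")
    labels = {"groups": glevels, "n_per_group": n, "within_levels": wlevels}
    return arr, labels


def _ss(component: np.ndarray, shape: tuple[int, ...]) -> float:
    """Sum of squares of a keepdims-margin component over the full grid."""
    return float(np.sum(np.broadcast_to(component, shape) ** 2))


def _margin(arr: np.ndarray, keep: frozenset[int]) -> np.ndarray:
    axes = tuple(ax for ax in range(arr.ndim) if ax not in keep)
    return arr.mean(axis=axes, keepdims=True) if axes else arr


def _effect_component(arr: np.ndarray, factors: Sequence[int]) -> np.ndarray:
    """Inclusion-exclusion effect estimate for a set of crossed factor axes."""
    comp = np.zeros((1,) * arr.ndim)
    fs = list(factors)
    for r in range(len(fs) + 1):
        for sub in itertools.combinations(fs, r):
            sign = (-1) ** (len(fs) - r)
            comp = comp + sign * _margin(arr, frozenset(sub))
    return comp


def _f_and_p(ss_eff: float, df_eff: int, ss_err: float, df_err: int
             ) -> tuple[float, float]:
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    if not np.isfinite(ms_err) or df_err <= 0:
        return np.nan, np.nan
    if ms_err == 0:
        if ms_eff == 0:
            return 0.0, 1.0
        warnings.warn("zero error variance with a nonzero effect: F is infinite")
        return np.inf, 0.0
    f = ms_eff / ms_err
    return f, float(sps.f.sf(f, df_eff, df_err))


def mixed_rm_anova(data: pd.DataFrame, dv: str = "value",
                   subject: str = "subject", between: str = "group",
                   within: Sequence[str] = ("time", "task"),
                   gg_correction: bool = False) -> pd.DataFrame:
    """Balanced split-plot repeated-measures ANOVA.

    Returns a table with one row per tested effect (between main effect,
    each within effect and its Group interaction) and one per error
    stratum (``F`` and ``p`` are NaN there), so that the sum of the
    ``ss`` column equals the total sum of squares.

    ``gg_correction`` applies Greenhouse-Geisser epsilon to the df of
    within effects with more than one numerator df (off by default; the
    study reports uncorrected df).
    """
    within = list(within)
    if not 1 <= len(within) <= 2:
        raise DesignError("one or two within-subject factors are supported")
    arr, labels = _to_array(data, dv, subject, between, within)
    shape = arr.shape
    a, n = shape[0], shape[1]
    wsizes = shape[2:]
    grand = arr.mean()
    centered = arr - grand

    rows = []

    # between-subject stratum
    ss_group = _ss(_margin(centered, frozenset({0})), shape)
    ss_subj = _ss(_margin(centered, frozenset({0, 1})) - _margin(centered, frozenset({0})),
                  shape)
    df_group, df_subj = a - 1, a * (n - 1)
    if a > 1:  # with a single group there is no between effect to test
        f, p = _f_and_p(ss_group, df_group, ss_subj, df_subj)
        rows.append(AnovaResult(between, df_group, df_subj, f, p, ss_group, ss_subj))

    # within strata: every nonempty subset S of within factors
    w_axes = list(range(2, arr.ndim))
    subsets = [list(c) for r in range(1, len(w_axes) + 1)
               for c in itertools.combinations(w_axes, r)]
    err_ss: dict[tuple[int, ...], float] = {}
    err_df: dict[tuple[int, ...], int] = {}
    for S in subsets:
        df_S = int(np.prod([shape[ax] - 1 for ax in S]))
        # pooled subject x combined-S interaction within groups, then strip
        # lower-order subject strata to isolate S x subject(group)
        comp = (_margin(centered, frozenset({0, 1, *S}))
                - _margin(centered, frozenset({0, 1}))
                - _margin(centered, frozenset({0, *S}))
                + _margin(centered, frozenset({0})))
        c_ss = _ss(comp, shape)
        for T in subsets:
            if set(T) < set(S):
                c_ss -= err_ss[tuple(T)]
        err_ss[tuple(S)] = c_ss
        err_df[tuple(S)] = df_S * a * (n - 1)

    for S in subsets:
        names = [within[ax - 2] for ax in S]
        df_S = int(np.prod([shape[ax] - 1 for ax in S]))
        ss_err, df_err = err_ss[tuple(S)], err_df[tuple(S)]
        eps = 1.0
        if gg_correction and df_S > 1:
            eps = _gg_epsilon(arr, S)
        ss_main = _ss(_effect_component(centered, S), shape)
        f, p = _f_and_p(ss_main, df_S, ss_err, df_err)
        if eps < 1.0:
            p = float(sps.f.sf(f, df_S * eps, df_err * eps)) if np.isfinite(f) else p
        rows.append(AnovaResult(" * ".join(names), df_S, df_err, f, p, ss_main, ss_err))

        if a > 1:
            ss_int = _ss(_effect_component(centered, [0, *S]), shape)
            df_int = (a - 1) * df_S
            f, p = _f_and_p(ss_int, df_int, ss_err, df_err)
            if eps < 1.0:
                p = float(sps.f.sf(f, df_int * eps, df_err * eps)) if np.isfinite(f) else p
            rows.append(AnovaResult(f"{between} * " + " * ".join(names),
                                    df_int, df_err, f, p, ss_int, ss_err))

    out = pd.DataFrame([r.__dict__ for r in rows])
    # error strata, for the SS-conservation identity
    err_rows = [{"effect": f"subject({between})", "df_num": df_subj,
                 "df_den": np.nan, "F": np.nan, "p": np.nan,
                 "ss": ss_subj, "ss_error": np.nan}]
    for S in subsets:
        names = " * ".join(within[ax - 2] for ax in S)
        err_rows.append({"effect": f"{names} * subject({between})",
                         "df_num": err_df[tuple(S)], "df_den": np.nan,
                         "F": np.nan, "p": np.nan,
                         "ss": err_ss[tuple(S)], "ss_error": np.nan})
    return pd.concat([out, pd.DataFrame(err_rows)], ignore_index=True)


def _gg_epsilon(arr: np.ndarray, S: Sequence[int]) -> float:
    """Greenhouse-Geisser epsilon for the covariance across S-cells."""
    other = [ax for ax in range(2, arr.ndim) if ax not in S]
    collapsed = arr.mean(axis=tuple(other)) if other else arr
    flat = collapsed.reshape(collapsed.shape[0] * collapsed.shape[1], -1)
    k = flat.shape[1]
    sigma = np.cov(flat, rowvar=False)
    c = np.eye(k) - np.ones((k, k)) / k
    s = c @ sigma @ c
    eig_sum = np.trace(s)
    eps = eig_sum ** 2 / ((k - 1) * np.sum(s * s.T))
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def anova_total_ss(data: pd.DataFrame, dv: str = "value") -> float:
    y = data[dv].to_numpy(float)
    return float(np.sum((y - y.mean()) ** 2))


# ---------------------------------------------------------------------------
# t tests

def _finalize_t(t: float, df: int) -> TTestResult:
    if not np.isfinite(t):
        warnings.warn("zero variance with nonzero mean difference: p set to 0")
        return TTestResult(t=float(np.sign(t) * np.inf), df=df, p=0.0)
    return TTestResult(t=float(t), df=df, p=float(2 * sps.t.sf(abs(t), df)))


def paired_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sided paired t test on per-subject differences; df = n - 1."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise DesignError("paired_t needs two equal-length vectors, n >= 2")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
    return _finalize_t(t, n - 1)


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sample t test; df = n_a + n_b - 2."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise DesignError("two_sample_t needs two vectors with n >= 2 each")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    diff = a.mean() - b.mean()
    if denom == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / denom
    return _finalize_t(t, df)


# ---------------------------------------------------------------------------
# Task 4 - Task 2 contrast

def difference_score(summary: pd.DataFrame, *, value: str = "value",
                     task: str = "task", hi: int = 4, lo: int = 2,
                     keys: Sequence[str] = ("subject", "time")) -> pd.DataFrame:
    """Per-subject (Task 4 - Task 2) contrast of the normalized pupil
    measure, per phase.

    Because Task 2 is the percent-change reference (identically 0), the
    score equals the Task-4 value; the subtraction is still performed so
    the identity is asserted rather than assumed.
    """
    keys = list(keys)
    wide = summary.pivot_table(index=keys, columns=task, values=value)
    for t in (hi, lo):
        if t not in wide.columns or wide[t].isna().any():
            raise DesignError(f"task {t} missing for some {keys} combination")
    out = wide[hi] - wide[lo]
    return out.rename("difference").reset_index()
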