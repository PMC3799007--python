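"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own sums-of-squares shortcuts:
the ANOVA oracle builds explicit sum-coded design-matrix blocks for every
effect and error stratum of the balanced split-plot design and computes
each SS as the squared norm of the least-squares projection of the data
onto that block.  The staircase oracle re-states the adaptive rules as a
plain if/else walk for deterministic observers.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps


def _sum_contrasts(levels: int) -> np.ndarray:
    """levels x (levels-1) sum-coded contrast matrix (columns sum to 0)."""
    return np.vstack([np.eye(levels - 1), -np.ones(levels - 1)])


def anova_oracle(data: pd.DataFrame, dv: str = "value", subject: str = "subject",
                 between: str = "group", within=("task",)) -> pd.DataFrame:
    """Projection-based split-plot ANOVA for balanced designs."""
    within = list(within)
    glevels = sorted(data[between].unique())
    wlevels = [sorted(data[w].unique()) for w in within]
    subjects = {g: sorted(data.loc[data[between] == g, subject].unique())
                for g in glevels}
    a = len(glevels)
    n = len(subjects[glevels[0]])

    y = []
    rows = []
    for rec in data.to_dict("records"):
        g = glevels.index(rec[between])
        s = subjects[rec[between]].index(rec[subject])
        ks = tuple(wlevels[i].index(rec[w]) for i, w in enumerate(within))
        rows.append((g, s, ks))
        y.append(float(rec[dv]))
    y = np.asarray(y)

    cg = _sum_contrasts(a) if a > 1 else np.zeros((1, 0))
    cs = _sum_contrasts(n)
    cw = [_sum_contrasts(len(w)) for w in wlevels]

    def block(with_group: bool, with_subject: bool, wset: tuple[int, ...]) -> np.ndarray:
        cols = []
        w_col_sets = [range(cw[i].shape[1]) for i in wset]
        g_cols = range(cg.shape[1]) if with_group else [None]
        s_cols = range(cs.shape[1]) if with_subject else [None]
        s_groups = range(a) if with_subject else [None]
        for gi in g_cols:
            for sg in s_groups:
                for si in s_cols:
                    for wcols in itertools.product(*w_col_sets):
                        col = np.ones(len(y))
                        for r, (g, s, ks) in enumerate(rows):
                            v = 1.0
                            if gi is not None:
                                v *= cg[g, gi]
                            if si is not None:
                                v *= cs[s, si] * (1.0 if g == sg else 0.0)
                            for wi, wc in zip(wset, wcols):
                                v *= cw[wi][ks[wi], wc]
                            col[r] = v
                        cols.append(col)
        return np.column_stack(cols) if cols else np.zeros((len(y), 0))

    def ss_of(x: np.ndarray) -> tuple[float, int]:
        if x.shape[1] == 0:
            return 0.0, 0
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ beta
        return float(fitted @ fitted), int(np.linalg.matrix_rank(x))

    out = []
    ss_subj, df_subj = ss_of(block(False, True, ()))
    if a > 1:
        ss_g, df_g = ss_of(block(True, False, ()))
        f = (ss_g / df_g) / (ss_subj / df_subj)
        out.append({"effect": between, "df_num": df_g, "df_den": df_subj,
                    "F": f, "p": float(sps.f.sf(f, df_g, df_subj)), "ss": ss_g})
    w_idx = list(range(len(within)))
    for r in range(1, len(w_idx) + 1):
        for S in itertools.combinations(w_idx, r):
            ss_err, df_err = ss_of(block(False, True, S))
            ss_w, df_w = ss_of(block(False, False, S))
            f = (ss_w / df_w) / (ss_err / df_err)
            out.append({"effect": " * ".join(within[i] for i in S),
                        "df_num": df_w, "df_den": df_err, "F": f,
                        "p": float(sps.f.sf(f, df_w, df_err)), "ss": ss_w})
            if a > 1:
                ss_i, df_i = ss_of(block(True, False, S))
                f = (ss_i / df_i) / (ss_err / df_err)
                out.append({"effect": f"{between} * " + " * ".join(within[i] for i in S),
                            "df_num": df_i, "df_den": df_err, "F": f,
                            "p": float(sps.f.sf(f, df_i, df_err)), "ss": ss_i})
    return pd.DataFrame(out)


def staircase_oracle_deterministic(n_trials: int, all_correct: bool,
                                   ladder=(306, 259, 200, 153, 106, 82, 59, 35, 24),
                                   start_index: int = 2) -> list[tuple[int, float]]:
    """(level, duration) after each 4-trial check, for an observer who is
    always right (``all_correct``) or always wrong.  Plain restatement of
    the adaptive rules, independent of the package."""
    level, idx = 1, start_index
    states = []
    for check in range(n_trials // 4):
        if all_correct:  # 100% > 75% -> harder
            if idx < len(ladder) - 1:
                idx += 1
            elif level < 4:
                level += 1
        else:  # 0% < 37.5% -> easier
            if idx > 0:
                idx -= 1
            elif level > 1:
                level -= 1
        states.append((level, float(ladder[idx])))
    return states
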