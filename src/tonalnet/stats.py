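"""Repeated-measures analyses of learning trajectories.

Runs play the role of subjects in a two-way (condition x epoch) fully
within-subject design. The omnibus ANOVA uses the classical sums-of-squares
decomposition with each effect tested against its own subject-interaction
error term and uncorrected degrees of freedom (a Greenhouse-Geisser epsilon
is reported alongside for the condition effect).

Simple main effects of condition at each epoch use the *pooled-error*
convention: the error sum of squares pools the condition-by-subject and the
condition-by-epoch-by-subject strata, giving an error df of
``(a-1)(S-1) + (a-1)(b-1)(S-1)`` shared by all epochs. Pairwise contrasts at
each epoch are t tests of the condition-mean difference against the same
pooled error term, flagged at a Bonferroni-adjusted alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .evaluation import TestCondition, TrajectoryRecord, records_to_frame


class DesignError(ValueError):
    """The records do not form a balanced subjects x condition x epoch grid."""


def _rm_anova_arrays(y: np.ndarray) -> dict:
    """Sums-of-squares decomposition for data shaped (subjects, A, B).

    Returns per-effect SS/df/MS/F/p for A, B and AxB, plus the three error
    strata (AxS, BxS, AxBxS) needed for pooled-error follow-ups.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("data must be (subjects, A, B)")
    n_s, n_a, n_b = y.shape
    if n_s < 2 or n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects and 2 levels per factor")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_s = n_a * n_b * np.sum((m_s - grand) ** 2)
    ss_a = n_s * n_b * np.sum((m_a - grand) ** 2)
    ss_b = n_s * n_a * np.sum((m_b - grand) ** 2)
    ss_ab = n_s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = n_b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = n_a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_abs = ss_total - (ss_s + ss_a + ss_b + ss_ab + ss_as + ss_bs)

    df = {
        "A": n_a - 1,
        "B": n_b - 1,
        "AB": (n_a - 1) * (n_b - 1),
        "AS": (n_a - 1) * (n_s - 1),
        "BS": (n_b - 1) * (n_s - 1),
        "ABS": (n_a - 1) * (n_b - 1) * (n_s - 1),
    }
    out = {"n_subjects": n_s, "n_a": n_a, "n_b": n_b, "ss": {}, "df": df, "ms": {},
           "F": {}, "p": {}}
    out["ss"] = {"S": ss_s, "A": ss_a, "B": ss_b, "AB": ss_ab,
                 "AS": ss_as, "BS": ss_bs, "ABS": ss_abs}
    for effect, error in (("A", "AS"), ("B", "BS"), ("AB", "ABS")):
        ms_e = out["ss"][effect] / df[effect]
        ms_err = out["ss"][error] / df[error]
        f = ms_e / ms_err if ms_err > 0 else np.inf
        out["ms"][effect] = ms_e
        out["ms"][error] = ms_err
        out["F"][effect] = f
        out["p"][effect] = float(sps.f.sf(f, df[effect], df[error]))
    return out


def _simple_main_effects(y: np.ndarray, res: dict) -> pd.DataFrame:
    """F test of factor A at each level of B, against the pooled error term."""
    n_s, n_a, n_b = y.shape
    ss_pool = res["ss"]["AS"] + res["ss"]["ABS"]
    df_pool = res["df"]["AS"] + res["df"]["ABS"]
    ms_pool = ss_pool / df_pool
    rows = []
    for j in range(n_b):
        m_aj = y[:, :, j].mean(axis=0)
        ss = n_s * np.sum((m_aj - m_aj.mean()) ** 2)
        ms = ss / (n_a - 1)
        f = ms / ms_pool if ms_pool > 0 else np.inf
        rows.append(
            {"b_level": j, "F": f, "df1": n_a - 1, "df2": df_pool,
             "p": float(sps.f.sf(f, n_a - 1, df_pool))}
        )
    return pd.DataFrame(rows)


def _pooled_t(mean_diff: float, n_s: int, ms_pool: float, df_pool: int) -> float:
    """Two-sided p for a two-condition contrast at one epoch, tested against
    the pooled within-subject error term (same stratum as the simple main
    effects). A degenerate zero error term makes any nonzero difference
    significant and a zero difference not."""
    if ms_pool <= 0:
        return 1.0 if np.isclose(mean_diff, 0.0) else 0.0
    t = mean_diff / np.sqrt(2.0 * ms_pool / n_s)
    return float(2.0 * sps.t.sf(abs(t), df_pool))


@dataclass(eq=False)
class AnovaReport:
    """Omnibus two-way RM-ANOVA plus per-epoch follow-ups.

    ``anova``: one row per effect (condition, epoch, interaction) with SS,
    df1/df2, MS, F and p. ``simple_main_effects``: condition effect at each
    epoch with the pooled-error df. ``pairwise``: per-epoch paired contrasts
    with raw p values and Bonferroni significance flags.
    """

    dv: str
    anova: pd.DataFrame
    simple_main_effects: pd.DataFrame
    pairwise: pd.DataFrame
    n_subjects: int
    alpha: float


def _to_grid(records, dv: str):
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    required = {"run_id", "epoch", "condition", dv}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns: {sorted(missing)}")
    conditions = [c.value for c in TestCondition]
    epochs = sorted(records["epoch"].unique())
    runs = sorted(records["run_id"].unique())
    pivot = records.pivot_table(
        index="run_id", columns=["condition", "epoch"], values=dv, aggfunc="first"
    )
    cells = [(c, e) for c in conditions for e in epochs]
    missing_cells = [
        (r, c, e) for r in runs for (c, e) in cells
        if (c, e) not in pivot.columns or pd.isna(pivot.loc[r, (c, e)])
    ]
    if missing_cells:
        raise DesignError(f"unbalanced design; missing cells: {missing_cells[:5]}"
                          + ("..." if len(missing_cells) > 5 else ""))
    y = np.empty((len(runs), len(conditions), len(epochs)))
    for si, r in enumerate(runs):
        for ai, c in enumerate(conditions):
            for bi, e in enumerate(epochs):
                y[si, ai, bi] = pivot.loc[r, (c, e)]
    return y, conditions, epochs, runs


def rm_anova(
    records: pd.DataFrame | Iterable[TrajectoryRecord],
    dv: str = "percent_correct",
    alpha: float = 0.05,
) -> AnovaReport:
    """Two-way (condition x epoch) repeated-measures ANOVA over runs.

    ``records`` is a tidy table (or TrajectoryRecord list) with one row per
    run x epoch x condition; the design must be balanced. ``alpha`` is the
    familywise level for the Bonferroni-adjusted pairwise comparisons.
    """
    y, conditions, epochs, runs = _to_grid(records, dv)
    res = _rm_anova_arrays(y)

    # Greenhouse-Geisser epsilon for the condition effect (reported only).
    gg_eps = _gg_epsilon(y.mean(axis=2))

    label = {"A": "condition", "B": "epoch", "AB": "condition:epoch"}
    err = {"A": "AS", "B": "BS", "AB": "ABS"}
    anova = pd.DataFrame(
        [
            {
                "effect": label[e],
                "ss": res["ss"][e],
                "df1": res["df"][e],
                "df2": res["df"][err[e]],
                "ms": res["ms"][e],
                "F": res["F"][e],
                "p": res["p"][e],
            }
            for e in ("A", "B", "AB")
        ]
    )
    anova.attrs["gg_epsilon_condition"] = gg_eps

    sme = _simple_main_effects(y, res)
    sme.insert(0, "epoch", [epochs[j] for j in sme["b_level"]])
    sme = sme.drop(columns="b_level")

    pairs = list(combinations(range(len(conditions)), 2))
    n_comparisons = len(pairs)
    ms_pool = (res["ss"]["AS"] + res["ss"]["ABS"]) / (res["df"]["AS"] + res["df"]["ABS"])
    df_pool = res["df"]["AS"] + res["df"]["ABS"]
    rows = []
    for bi, epoch in enumerate(epochs):
        for ai, aj in pairs:
            diff = float((y[:, ai, bi] - y[:, aj, bi]).mean())
            p = _pooled_t(diff, y.shape[0], ms_pool, df_pool)
            rows.append(
                {
                    "epoch": epoch,
                    "contrast": f"{conditions[ai]} vs {conditions[aj]}",
                    "mean_diff": diff,
                    "p": p,
                    "significant": bool(p < alpha / n_comparisons),
                }
            )
    pairwise = pd.DataFrame(rows)

    return AnovaReport(
        dv=dv, anova=anova, simple_main_effects=sme, pairwise=pairwise,
        n_subjects=len(runs), alpha=alpha,
    )


def _gg_epsilon(y2: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for a one-within design (subjects x levels)."""
    v = np.cov(y2, rowvar=False)
    k = v.shape[0]
    mean_diag = np.trace(v) / k
    mean_all = v.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(v**2) - 2 * k * np.sum(v.mean(axis=1) ** 2) + k**2 * mean_all**2)
    return float(num / den) if den > 0 else 1.0
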