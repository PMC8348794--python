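"""Within-subject statistics on lobe-averaged band-power features.

Epoch-level features are first averaged within each (subject, day, condition,
channel, band) cell — epochs from one recording are not independent, so they
never enter the model individually — and then averaged across the channels of
each lobe.  The resulting cell means feed a four-factor repeated-measures
ANOVA with within-subject factors Condition (L0–L3), Band (delta, theta,
alpha, beta), Lobe (frontal, parietal, temporal, occipital) and Day (1, 2):
the classical sum-of-squares decomposition for a balanced fully-crossed
design with subjects as the random factor, each effect tested against its
own effect-by-subject interaction.  No sphericity correction is applied
(degrees of freedom are reported uncorrected).  Partial eta squared is
SS_effect / (SS_effect + SS_error).

Post hoc comparisons are paired two-sided t-tests across subjects (averaged
over days) for all six condition pairs within each (lobe, band), flagged at
p < 0.01 uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import BANDS
from .montage import DEFAULT_MONTAGE, MontageSpec

__all__ = [
    "CellMeans",
    "AnovaResult",
    "aggregate_cells",
    "rm_anova",
    "rm_anova_array",
    "posthoc_pairs",
]

POSTHOC_ALPHA = 0.01
FACTORS = ("condition", "band", "lobe", "day")


@dataclass(frozen=True)
class CellMeans:
    """Long-format cell means: subject, day, condition, lobe, band, value."""

    table: pd.DataFrame = field(repr=False)
    missing: tuple[tuple, ...] = ()

    @property
    def subjects(self) -> list:
        return sorted(self.table["subject"].unique())


def aggregate_cells(
    features: pd.DataFrame,
    montage: MontageSpec = DEFAULT_MONTAGE,
    scheme=BANDS,
) -> CellMeans:
    """Epoch-then-channel averaging to one value per design cell.

    Means are taken over epochs within (subject, day, condition, channel,
    band), then over the channels of each lobe (NaN columns from rejected
    channels are skipped).  Cells with no epochs at all are reported in
    ``missing``, never imputed.
    """
    group = features.groupby(["subject", "day", "condition"], sort=True)
    rows = []
    for (subject, day, cond), grp in group:
        for band in scheme.names:
            for lobe, chs in montage.lobes.items():
                cols = [f"{band}_{ch}" for ch in chs]
                vals = grp[cols].to_numpy(dtype=float)
                with np.errstate(invalid="ignore"):
                    value = np.nanmean(vals)
                rows.append(
                    {
                        "subject": subject,
                        "day": day,
                        "condition": cond,
                        "lobe": lobe,
                        "band": band,
                        "value": value,
                    }
                )
    table = pd.DataFrame(rows)

    # balance report: every (subject, day, condition) combination present?
    missing = []
    subjects = table["subject"].unique()
    days = table["day"].unique()
    conds = sorted(features["condition"].unique())
    seen = set(map(tuple, table[["subject", "day", "condition"]].drop_duplicates().to_numpy()))
    for s in subjects:
        for d in days:
            for c in conds:
                if (s, d, c) not in seen:
                    missing.append((s, d, c))
    nan_cells = table.loc[table["value"].isna(), ["subject", "day", "condition", "lobe", "band"]]
    missing.extend(map(tuple, nan_cells.to_numpy()))
    return CellMeans(table=table, missing=tuple(missing))


@dataclass(frozen=True)
class AnovaResult:
    """Per-effect F, df, p and partial eta squared, plus the SS breakdown."""

    table: pd.DataFrame = field(repr=False)
    ss: dict[str, float] = field(repr=False, default_factory=dict)
    ss_total: float = 0.0
    note: str = "uncorrected degrees of freedom (no sphericity correction)"

    def effect(self, name: str) -> pd.Series:
        """Look up one effect row, e.g. ``"condition"`` or ``"condition:band:lobe"``."""
        hit = self.table.loc[self.table["effect"] == name]
        if hit.empty:
            raise KeyError(name)
        return hit.iloc[0]


def _subsets(items):
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


def rm_anova_array(data: np.ndarray, factor_names: tuple[str, ...] = FACTORS) -> AnovaResult:
    """Repeated-measures ANOVA on an array of shape (subjects, *factor levels).

    Implements the balanced fully-crossed within-subject decomposition: for
    every subset of factors the sum of squares follows from the marginal
    means by inclusion-exclusion, and each within-effect is tested against
    its interaction with the subject factor.
    """
    data = np.asarray(data, dtype=float)
    if np.isnan(data).any():
        raise ValueError("missing cells; the design must be balanced")
    n_subj = data.shape[0]
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")
    if data.ndim != len(factor_names) + 1:
        raise ValueError("data must have one axis per factor plus the subject axis")
    levels = data.shape
    n_total = data.size
    all_axes = tuple(range(data.ndim))  # axis 0 = subject

    grand = data.mean()
    # U_A = (obs per marginal cell) * sum of squared marginal means, for every
    # subset A of {subject, factors}; SS_A then follows by inclusion-exclusion.
    U: dict[tuple, float] = {}
    for A in _subsets(all_axes):
        other = tuple(ax for ax in all_axes if ax not in A)
        marg = data.mean(axis=other) if other else data
        n_per = int(np.prod([levels[ax] for ax in other])) if other else 1
        U[A] = n_per * float(np.sum(np.square(marg)))

    SS: dict[tuple, float] = {}
    for A in _subsets(all_axes):
        if not A:
            continue
        total = 0.0
        for B in _subsets(A):
            total += (-1) ** (len(A) - len(B)) * (U[B] if B else n_total * grand**2)
        SS[A] = total

    def df_of(A: tuple) -> int:
        return int(np.prod([levels[ax] - 1 for ax in A]))

    rows = []
    ss_out: dict[str, float] = {}
    for A in _subsets(tuple(range(1, data.ndim))):
        if not A:
            continue
        name = ":".join(factor_names[ax - 1] for ax in A)
        err = tuple(sorted((0,) + A))
        ss_e, ss_err = SS[A], SS[err]
        df1, df2 = df_of(A), df_of(err)
        ss_total_guard = 1e-12 * max(float(np.sum(np.square(data - grand))), 1e-300)
        if ss_e <= ss_total_guard:  # degenerate effect (e.g. duplicated factor levels)
            F, p = 0.0, 1.0
        else:
            ms_e = ss_e / df1
            ms_err = ss_err / df2 if df2 else np.nan
            F = ms_e / ms_err if ms_err > 0 else np.inf
            p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        rows.append(
            {
                "effect": name,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "partial_eta_sq": ss_e / (ss_e + ss_err) if (ss_e + ss_err) > 0 else np.nan,
                "SS": ss_e,
                "SS_error": ss_err,
            }
        )
        ss_out[name] = ss_e
    ss_out["subject"] = SS[(0,)]
    ss_total = float(np.sum(np.square(data - grand)))
    return AnovaResult(table=pd.DataFrame(rows), ss={
        ":".join(factor_names[ax - 1] if ax else "subject" for ax in A): SS[A]
        for A in _subsets(all_axes) if A
    }, ss_total=ss_total)


def _to_array(cells: CellMeans, factors: tuple[str, ...]) -> tuple[np.ndarray, dict]:
    table = cells.table
    subjects = sorted(table["subject"].unique())
    level_values = {f: sorted(table[f].unique()) for f in factors}
    shape = [len(subjects)] + [len(level_values[f]) for f in factors]
    arr = np.full(shape, np.nan)
    s_idx = {s: i for i, s in enumerate(subjects)}
    f_idx = [{v: i for i, v in enumerate(level_values[f])} for f in factors]
    for row in table.itertuples(index=False):
        pos = (s_idx[row.subject],) + tuple(
            f_idx[k][getattr(row, f)] for k, f in enumerate(factors)
        )
        arr[pos] = row.value
    if np.isnan(arr).any():
        miss = np.argwhere(np.isnan(arr))
        labels = [
            (subjects[i[0]],) + tuple(level_values[f][i[k + 1]] for k, f in enumerate(factors))
            for i in miss[:20]
        ]
        raise ValueError(f"unbalanced design; missing cells (first 20): {labels}")
    return arr, level_values


def rm_anova(cells: CellMeans, factors: tuple[str, ...] = FACTORS) -> AnovaResult:
    """Four-factor within-subject ANOVA on cell means (see module docstring)."""
    arr, _ = _to_array(cells, factors)
    return rm_anova_array(arr, factors)


def posthoc_pairs(cells: CellMeans, alpha: float = POSTHOC_ALPHA) -> pd.DataFrame:
    """Paired t-tests for all condition pairs within each (lobe, band).

    Days are averaged within subject before pairing.  Returns a frame with
    one row per (lobe, band, condition pair): t, df, p, significant flag at
    ``alpha`` (uncorrected).
    """
    table = cells.table
    subjects = sorted(table["subject"].unique())
    if len(subjects) < 3:
        raise ValueError("post hoc tests need at least 3 subjects")
    conds = sorted(table["condition"].unique())
    day_mean = (
        table.groupby(["subject", "condition", "lobe", "band"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    rows = []
    for (lobe, band), grp in day_mean.groupby(["lobe", "band"]):
        wide = grp.pivot(index="subject", columns="condition", values="value")
        for a, b in combinations(conds, 2):
            x, y = wide[a].to_numpy(), wide[b].to_numpy()
            if np.allclose(x, y):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(x, y)
            rows.append(
                {
                    "lobe": lobe,
                    "band": band,
                    "pair": f"{a}-{b}",
                    "t": float(t),
                    "df": len(x) - 1,
                    "p": float(p),
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)
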