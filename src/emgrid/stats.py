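"""Factorial ANOVA and multiple-comparison layer.

Normalized barycenters are pooled into a table of one row per
contraction (subject x task x %MVC level) and analyzed per axis:

* a two-way fixed-effects ANOVA (subject + task, main effects only —
  with one observation per cell the design is otherwise saturated)
  tests whether the task performed moves the active region;
* a three-way ANOVA (subject + direction + force level) over the
  force-tracked directions tests whether contraction intensity shifts
  the region;
* a step-down Sidak (Holm-Sidak) procedure corrects the family of all
  pairwise task comparisons per axis, yielding a per-pair, per-axis
  separability report.

"Subject" is treated as a fixed effect, matching the original analysis
rather than a random-effects ideal. Sums of squares are Type II; in the
balanced designs produced by the pipeline all types coincide.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .errors import DesignError, IntegrityError, InvalidConfigError

__all__ = [
    "BarycenterTable",
    "AnovaTable",
    "HolmSidakResult",
    "build_barycenter_table",
    "twoway_anova",
    "threeway_anova",
    "holm_sidak",
    "pairwise_discrimination",
]

_COLUMNS = ["subject", "task", "level_pct_mvc", "X", "Y"]


@dataclass(frozen=True)
class BarycenterTable:
    """One row per contraction: subject, task, %MVC level, X, Y."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise IntegrityError(f"table missing columns {missing}")
        if len(df):
            if df[["X", "Y"]].isna().any().any() or not np.isfinite(
                df[["X", "Y"]].to_numpy(dtype=float)
            ).all():
                raise IntegrityError("non-finite barycenter coordinates")
            dup = df.duplicated(subset=["subject", "task", "level_pct_mvc"])
            if dup.any():
                raise IntegrityError(
                    f"duplicate (subject, task, level) rows: "
                    f"{df.loc[dup, ['subject', 'task', 'level_pct_mvc']].to_dict('records')}"
                )
        object.__setattr__(self, "df", df.reset_index(drop=True)[_COLUMNS])

    def __len__(self) -> int:
        return len(self.df)

    def at_lowest_level(self) -> "BarycenterTable":
        """One row per (subject, task): the lowest tested force level.

        Mirrors restricting force-tracked directions to 20% MVC when
        comparing tasks.
        """
        df = self.df.sort_values(["subject", "task", "level_pct_mvc"])
        return BarycenterTable(df.groupby(["subject", "task"], as_index=False).first())

    def force_levels(self, tasks) -> "BarycenterTable":
        """Rows of the given tasks at every tested level."""
        return BarycenterTable(self.df[self.df["task"].isin(list(tasks))])

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarycenterTable":
        return cls(pd.read_csv(path, sep="\t"))


def build_barycenter_table(results) -> BarycenterTable:
    """Assemble a table from localization results.

    Each result must carry subject/task metadata and a normalized
    barycenter; duplicates of (subject, task, level) are rejected.
    """
    rows = []
    for r in results:
        meta = r.meta
        if meta is None or meta.subject is None or meta.task is None:
            raise IntegrityError("localization result lacks subject/task metadata")
        if r.barycenter_norm is None:
            raise IntegrityError(
                f"result for ({meta.subject}, {meta.task}) lacks a "
                "normalized barycenter (missing anatomy?)"
            )
        rows.append(
            {
                "subject": meta.subject,
                "task": meta.task,
                "level_pct_mvc": meta.level_pct_mvc,
                "X": r.barycenter_norm[0],
                "Y": r.barycenter_norm[1],
            }
        )
    return BarycenterTable(pd.DataFrame(rows, columns=_COLUMNS))


@dataclass(frozen=True)
class AnovaTable:
    """Per-factor F/df/p for one response axis, plus the residual."""

    response: str
    table: pd.DataFrame  # index: factor names + "Residual"; cols df, sum_sq, F, p

    def f(self, factor: str) -> float:
        return float(self.table.loc[factor, "F"])

    def p(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])

    def df(self, factor: str) -> float:
        return float(self.table.loc[factor, "df"])

    @property
    def residual_df(self) -> float:
        return float(self.table.loc["Residual", "df"])

    @property
    def residual_mse(self) -> float:
        r = self.table.loc["Residual"]
        return float(r["sum_sq"] / r["df"])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "response", self.response)
        return out.reset_index(names="factor")


def _check_response(response: str) -> str:
    if response not in ("X", "Y"):
        raise InvalidConfigError(f"response must be 'X' or 'Y', got {response!r}")
    return response


def _fit_main_effects(df: pd.DataFrame, response: str, factors: list[str]) -> AnovaTable:
    for f in factors:
        if df[f].nunique() < 2:
            raise DesignError(
                f"factor {f!r} needs >= 2 levels, found {df[f].nunique()}"
            )
    counts = df.groupby(factors, observed=True).size()
    full = 1
    for f in factors:
        full *= df[f].nunique()
    if len(counts) < full:
        raise DesignError(
            f"deficient design: {full - len(counts)} empty cell(s) in "
            f"{' x '.join(factors)}"
        )
    work = df.copy()
    work["_y"] = work[response].astype(float)
    terms = " + ".join(f"C({f})" for f in factors)
    fit = ols(f"_y ~ {terms}", data=work).fit()
    aov = anova_lm(fit, typ=2)
    aov = aov.rename(
        index={f"C({f})": f for f in factors},
        columns={"PR(>F)": "p"},
    )
    aov = aov[["df", "sum_sq", "F", "p"]]
    return AnovaTable(response=response, table=aov)


def twoway_anova(table: BarycenterTable, response: str = "X") -> AnovaTable:
    """Fixed-effects subject x task ANOVA, main effects only."""
    return _fit_main_effects(
        table.df, _check_response(response), ["subject", "task"]
    )


def threeway_anova(table: BarycenterTable, response: str = "X") -> AnovaTable:
    """Fixed-effects subject x task x force-level ANOVA, main effects."""
    return _fit_main_effects(
        table.df,
        _check_response(response),
        ["subject", "task", "level_pct_mvc"],
    )


@dataclass(frozen=True)
class HolmSidakResult:
    """Step-down Sidak decisions, in the input order of the p-values."""

    p_raw: np.ndarray
    p_adjusted: np.ndarray
    reject: np.ndarray
    alpha: float


def holm_sidak(p_values, alpha: float = 0.05) -> HolmSidakResult:
    """Step-down Sidak (Holm-Sidak) multiple-comparison correction.

    Sorted ascending, the i-th (1-based) of m p-values is adjusted to
    ``1 - (1 - p_(i))^(m - i + 1)``, with a running maximum enforcing
    monotonicity; hypotheses with adjusted p <= alpha are rejected.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise InvalidConfigError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise InvalidConfigError("alpha must lie in (0, 1)")
    m = p.size
    if m == 0:
        z = np.array([])
        return HolmSidakResult(z, z, z.astype(bool), alpha)
    order = np.argsort(p, kind="stable")
    exponents = m - np.arange(m)  # m, m-1, ..., 1
    adj_sorted = 1.0 - (1.0 - p[order]) ** exponents
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return HolmSidakResult(
        p_raw=p, p_adjusted=adj, reject=adj <= alpha, alpha=alpha
    )


def pairwise_discrimination(
    table: BarycenterTable, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-pair, per-axis separability of the tasks' active regions.

    For each axis, task-pair contrasts are tested with the pooled
    residual variance of the subject + task ANOVA (the standard
    post-hoc t for a fixed-effects factorial), and the family of all
    C(k, 2) pairs on that axis is corrected with Holm-Sidak.

    Returns a tidy frame with columns axis, task_a, task_b, mean_diff,
    t, df, p_raw, p_adjusted, separable.
    """
    tasks = sorted(table.df["task"].unique())
    if len(tasks) < 2:
        raise DesignError("pairwise discrimination needs >= 2 tasks")
    rows = []
    for axis in ("X", "Y"):
        aov = twoway_anova(table, axis)
        mse, dfr = aov.residual_mse, aov.residual_df
        g = table.df.groupby("task")[axis]
        means, counts = g.mean(), g.size()
        raw, pairs = [], []
        for a, b in itertools.combinations(tasks, 2):
            diff = means[a] - means[b]
            se = np.sqrt(mse * (1.0 / counts[a] + 1.0 / counts[b]))
            t = diff / se if se > 0 else np.inf * np.sign(diff)
            p = 2.0 * sstats.t.sf(abs(t), dfr)
            raw.append(min(p, 1.0))
            pairs.append((a, b, diff, t))
        hs = holm_sidak(raw, alpha=alpha)
        for (a, b, diff, t), p, padj, rej in zip(
            pairs, hs.p_raw, hs.p_adjusted, hs.reject
        ):
            rows.append(
                {
                    "axis": axis,
                    "task_a": a,
                    "task_b": b,
                    "mean_diff": float(diff),
                    "t": float(t),
                    "df": float(dfr),
                    "p_raw": float(p),
                    "p_adjusted": float(padj),
                    "separable": bool(rej),
                }
            )
    return pd.DataFrame(rows)
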