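"""Statistical framework for the post/pre RMS ratio table.

Two complementary families, each corrected with an in-repo Benjamini–Hochberg
step-up within its 7-test family:

* **Intragroup** (within-session): a linear mixed-effects model of the ratios
  with one fixed effect per follow-up time point and a random intercept per
  participant, fitted by REML.  On the default log scale the response is
  log(ratio), so "ratio equal to baseline" becomes "coefficient equal to 0"
  and multiplicative subject effects become additive; each coefficient is
  tested with a Wald z statistic.  A raw-ratio-scale variant (coefficients
  tested against 1) is available via ``scale="ratio"``.
* **Intergroup** (between sessions, per time point): paired differences of the
  two sessions' ratios over participants with both sessions; a Shapiro–Wilk
  test gates between a paired t-test (df = n_pairs - 1) and a Wilcoxon
  signed-rank test.

The module exposes both the plain functions and a statsmodels-style
:class:`RmsRatioModel` / :class:`RmsRatioResults` pair wrapping them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .exceptions import StatsError

__all__ = [
    "benjamini_hochberg",
    "IntragroupResult",
    "IntergroupResult",
    "StatsReport",
    "fit_intragroup",
    "compare_groups",
    "summarize",
    "RmsRatioModel",
    "RmsRatioResults",
]


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini–Hochberg FDR-adjusted p-values (standard step-up).

    With order statistics ``p_(1) <= ... <= p_(m)``, the adjusted value for
    ``p_(i)`` is ``min_{j >= i} (m * p_(j) / j)`` capped at 1, mapped back to
    the input order.  Ties are handled naturally by the running minimum.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# intragroup: mixed model per session
# ---------------------------------------------------------------------------

@dataclass
class IntragroupResult:
    """Per-session mixed-model contrasts of each follow-up point vs baseline."""

    session: str
    scale: str
    table: pd.DataFrame  # follow_up_min, n, ratio_mean, ratio_sd, coef, se, ratio_estimate, z, p_raw, p_adj
    converged: bool = True


def _wald_p(coef: float, se: float, null: float) -> tuple[float, float]:
    """Wald z and two-sided p with degenerate-SE guard (constant response)."""
    if not np.isfinite(se) or se <= 0:
        return 0.0, 1.0 if np.isclose(coef, null) else 0.0
    z = (coef - null) / se
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def _check_ratio_table(rt: pd.DataFrame) -> None:
    required = {"participant_id", "session", "follow_up_min", "ratio"}
    missing = required - set(rt.columns)
    if missing:
        raise StatsError(f"ratio table missing column(s) {sorted(missing)}")


def fit_intragroup(rt: pd.DataFrame, session: str, scale: str = "log") -> IntragroupResult:
    """Fit the within-session mixed model and BH-adjust its 7 contrasts.

    Model: response ~ 0 + C(follow_up_min) with a random intercept per
    participant, REML.  ``scale="log"`` (default) uses log(ratio) and tests
    each coefficient against 0; ``scale="ratio"`` uses the raw ratio and tests
    against 1.  Missing/unbalanced rows are handled natively by the
    likelihood.
    """
    _check_ratio_table(rt)
    if scale not in ("log", "ratio"):
        raise StatsError(f"unknown model scale {scale!r}")
    sub = rt.loc[rt["session"] == session].copy()
    if sub.empty:
        raise StatsError(f"no rows for session {session!r}")
    if sub["participant_id"].nunique() < 2:
        raise StatsError(f"session {session!r} has fewer than 2 participants")
    if scale == "log":
        if (sub["ratio"] <= 0).any():
            raise StatsError("non-positive ratio: log-scale model undefined")
        sub["response"] = np.log(sub["ratio"])
        null = 0.0
    else:
        sub["response"] = sub["ratio"]
        null = 1.0

    points = sorted(sub["follow_up_min"].unique())
    exog = pd.DataFrame(
        {f"t{int(t)}": (sub["follow_up_min"] == t).astype(float) for t in points},
        index=sub.index,
    )
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(sub["response"], exog, groups=sub["participant_id"])
            res = model.fit(reml=True)
        coefs = np.asarray(res.fe_params, dtype=float)
        ses = np.asarray(res.bse_fe, dtype=float)
        converged = bool(getattr(res, "converged", True))
    except Exception:
        # Degenerate data (e.g. constant response) can defeat the optimizer;
        # fall back to per-point means with undefined SEs, which the Wald
        # guard maps onto the boundary p-values.
        coefs = np.array([sub.loc[sub["follow_up_min"] == t, "response"].mean() for t in points])
        ses = np.full(len(points), np.nan)
        converged = False

    rows = []
    for i, t in enumerate(points):
        vals = sub.loc[sub["follow_up_min"] == t, "ratio"]
        z, p = _wald_p(coefs[i], ses[i], null)
        rows.append(
            {
                "follow_up_min": int(t),
                "n": int(vals.size),
                "ratio_mean": float(vals.mean()),
                "ratio_sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "coef": float(coefs[i]),
                "se": float(ses[i]) if np.isfinite(ses[i]) else np.nan,
                "ratio_estimate": float(np.exp(coefs[i])) if scale == "log" else float(coefs[i]),
                "z": z,
                "p_raw": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = benjamini_hochberg(table["p_raw"].to_numpy())
    return IntragroupResult(session=session, scale=scale, table=table, converged=converged)


# ---------------------------------------------------------------------------
# intergroup: per-time-point paired comparisons
# ---------------------------------------------------------------------------

@dataclass
class IntergroupResult:
    """Per-time-point paired comparison of the two sessions' ratios."""

    table: pd.DataFrame  # follow_up_min, n_pairs, mean_diff, sd_diff, shapiro_p, test_used, statistic, df, p_raw, p_adj
    alpha_normality: float = 0.05
    order: tuple[str, str] = ("fmv", "control")  # differences are order[0] - order[1]


def compare_groups(
    rt: pd.DataFrame,
    alpha_normality: float = 0.05,
    order: tuple[str, str] = ("fmv", "control"),
) -> IntergroupResult:
    """Paired per-time-point session comparison with a Shapiro–Wilk gate.

    For each follow-up point, differences ``order[0] - order[1]`` are formed
    over participants with both sessions.  If Shapiro–Wilk does not reject
    normality at ``alpha_normality`` a paired t-test is used (df = n - 1),
    otherwise a two-sided Wilcoxon signed-rank test (zero differences
    dropped).  All-zero differences are degenerate: p = 1 with a warning.
    The 7 raw p-values are BH-adjusted as one family.
    """
    _check_ratio_table(rt)
    a, b = order
    wide = rt.pivot_table(
        index=["participant_id", "follow_up_min"], columns="session", values="ratio"
    )
    for s in order:
        if s not in wide.columns:
            raise StatsError(f"session {s!r} absent from ratio table")
    rows = []
    for t in sorted(rt["follow_up_min"].unique()):
        sub = wide.xs(t, level="follow_up_min")[list(order)].dropna()
        diffs = (sub[a] - sub[b]).to_numpy()
        n = diffs.size
        if n < 3:
            raise StatsError(f"follow-up {t}: only {n} complete pair(s), need at least 3")
        row = {
            "follow_up_min": int(t),
            "n_pairs": int(n),
            "mean_diff": float(np.mean(diffs)),
            "sd_diff": float(np.std(diffs, ddof=1)),
        }
        if np.allclose(diffs, 0.0):
            warnings.warn(
                f"follow-up {t}: all paired differences are zero; degenerate comparison",
                stacklevel=2,
            )
            row.update(shapiro_p=np.nan, test_used="degenerate", statistic=0.0,
                       df=np.nan, p_raw=1.0)
        else:
            shapiro_p = float(sps.shapiro(diffs).pvalue)
            if shapiro_p >= alpha_normality:
                t_res = sps.ttest_rel(sub[a], sub[b])
                row.update(
                    shapiro_p=shapiro_p,
                    test_used="paired_t",
                    statistic=float(t_res.statistic),
                    df=float(n - 1),
                    p_raw=float(t_res.pvalue),
                )
            else:
                w_res = sps.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided")
                row.update(
                    shapiro_p=shapiro_p,
                    test_used="wilcoxon",
                    statistic=float(w_res.statistic),
                    df=np.nan,
                    p_raw=float(w_res.pvalue),
                )
        rows.append(row)
    table = pd.DataFrame(rows)
    table["p_adj"] = benjamini_hochberg(table["p_raw"].to_numpy())
    return IntergroupResult(table=table, alpha_normality=alpha_normality, order=order)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class StatsReport:
    """Machine- and human-readable summaries of both statistical families."""

    summary: pd.DataFrame  # session x time point: n, mean, sd, quartiles
    intragroup: dict[str, IntragroupResult]
    intergroup: IntergroupResult | None
    alpha: float = 0.05

    def to_text(self) -> str:
        lines = ["Within-session RMS-ratio contrasts vs baseline (mixed model, BH-adjusted)"]
        lines.append(f"{'min':>5} {'session':>9} {'ratio mean±SD':>16} {'adj. p':>8}")
        for session, res in self.intragroup.items():
            for _, r in res.table.iterrows():
                star = "*" if r["p_adj"] < self.alpha else " "
                lines.append(
                    f"{int(r['follow_up_min']):>5} {session:>9} "
                    f"{r['ratio_mean']:.2f} ± {r['ratio_sd']:.2f}      {r['p_adj']:.3f}{star}"
                )
        if self.intergroup is not None:
            a, b = self.intergroup.order
            lines.append("")
            lines.append(f"Between-session comparison ({a} - {b}), BH-adjusted")
            lines.append(f"{'min':>5} {'test':>10} {'adj. p':>8}")
            for _, r in self.intergroup.table.iterrows():
                star = "*" if r["p_adj"] < self.alpha else " "
                lines.append(
                    f"{int(r['follow_up_min']):>5} {r['test_used']:>10} {r['p_adj']:.3f}{star}"
                )
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "ratio_summary.csv", index=False)
        for session, res in self.intragroup.items():
            res.table.to_csv(out / f"intragroup_{session}.csv", index=False)
        if self.intergroup is not None:
            self.intergroup.table.to_csv(out / "intergroup.csv", index=False)
        (out / "report.txt").write_text(self.to_text() + "\n", encoding="utf-8")


def summarize(
    rt: pd.DataFrame,
    intragroup: dict[str, IntragroupResult],
    intergroup: IntergroupResult | None,
    alpha: float = 0.05,
) -> StatsReport:
    """Per session × time point descriptive summary plus both test families."""
    _check_ratio_table(rt)
    rows = []
    for (session, t), grp in rt.groupby(["session", "follow_up_min"], sort=True):
        q = grp["ratio"].quantile([0.25, 0.5, 0.75])
        rows.append(
            {
                "session": session,
                "follow_up_min": int(t),
                "n": int(grp["ratio"].size),
                "ratio_mean": float(grp["ratio"].mean()),
                "ratio_sd": float(grp["ratio"].std(ddof=1)) if len(grp) > 1 else np.nan,
                "q25": float(q.loc[0.25]),
                "median": float(q.loc[0.5]),
                "q75": float(q.loc[0.75]),
            }
        )
    return StatsReport(
        summary=pd.DataFrame(rows), intragroup=intragroup, intergroup=intergroup, alpha=alpha
    )


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

class RmsRatioModel:
    """Statistical model of a post/pre RMS ratio table.

    Parameters
    ----------
    data : DataFrame
        Long-format ratio table with columns ``participant_id``, ``session``,
        ``follow_up_min``, ``ratio`` (as produced by
        :func:`vibemg.metrics.build_ratio_table`).
    scale : {"log", "ratio"}
        Response scale of the within-session mixed model.
    alpha, alpha_normality : float
        Significance level for reporting and for the normality gate.

    Examples
    --------
    >>> model = RmsRatioModel(ratio_table)          # doctest: +SKIP
    >>> res = model.fit()                           # doctest: +SKIP
    >>> print(res.summary())                        # doctest: +SKIP
    """

    def __init__(
        self,
        data: pd.DataFrame,
        scale: str = "log",
        alpha: float = 0.05,
        alpha_normality: float = 0.05,
    ):
        _check_ratio_table(data)
        if data.empty:
            raise StatsError("empty ratio table")
        self.data = data.copy()
        self.scale = scale
        self.alpha = alpha
        self.alpha_normality = alpha_normality

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "RmsRatioModel":
        return cls(pd.read_csv(path), **kwargs)

    @property
    def sessions(self) -> list[str]:
        return sorted(self.data["session"].unique())

    def fit(self) -> "RmsRatioResults":
        intragroup = {
            s: fit_intragroup(self.data, s, scale=self.scale) for s in self.sessions
        }
        intergroup = None
        if set(self.sessions) >= {"control", "fmv"}:
            intergroup = compare_groups(self.data, alpha_normality=self.alpha_normality)
        report = summarize(self.data, intragroup, intergroup, alpha=self.alpha)
        return RmsRatioResults(self, intragroup, intergroup, report)


@dataclass
class RmsRatioResults:
    """Fitted results: per-session contrasts, paired comparisons, summaries."""

    model: RmsRatioModel
    intragroup: dict[str, IntragroupResult]
    intergroup: IntergroupResult | None
    report: StatsReport = field(repr=False)

    def summary(self) -> str:
        return self.report.to_text()

    def significant_points(self, session: str) -> list[int]:
        """Follow-up minutes with BH-adjusted p below alpha in the session."""
        t = self.intragroup[session].table
        return [int(m) for m in t.loc[t["p_adj"] < self.model.alpha, "follow_up_min"]]

    def save(self, out_dir: str | Path) -> None:
        self.report.save(out_dir)

    def plot_boxplots(self, path: str | Path | None = None, ax=None):
        """Boxplots of the ratio per time point and session, means connected."""
        import matplotlib

        if path is not None and ax is None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        rt = self.model.data
        points = sorted(rt["follow_up_min"].unique())
        sessions = self.model.sessions
        colors = {"control": "tab:green", "fmv": "tab:orange"}
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4.5))
        width = 0.35
        for j, session in enumerate(sessions):
            offs = (j - (len(sessions) - 1) / 2) * width
            data = [
                rt.loc[(rt["session"] == session) & (rt["follow_up_min"] == t), "ratio"]
                for t in points
            ]
            pos = [i + offs for i in range(len(points))]
            color = colors.get(session, f"C{j}")
            bp = ax.boxplot(
                data, positions=pos, widths=width * 0.9, patch_artist=True,
                showfliers=False,
            )
            for box in bp["boxes"]:
                box.set(facecolor=color, alpha=0.4)
            means = [d.mean() for d in data]
            ax.plot(pos, means, "o--", color=color, label=session)
        ax.axhline(1.0, color="grey", lw=0.8, ls=":")
        ax.set_xticks(range(len(points)))
        ax.set_xticklabels([str(t) for t in points])
        ax.set_xlabel("follow-up time (min)")
        ax.set_ylabel("RMS ratio (post/pre)")
        ax.legend()
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax
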