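"""Group-level evaluation: BCI chance bounds and Wilcoxon signed-rank tests.

Two pieces of statistical machinery evaluate whether decoding
accuracies exceed what a random classifier could achieve:

* **Adjusted-Wald chance bound.**  With n trials and c classes, a random
  classifier's accuracy is Binomial(n, 1/c)/n; the adjusted-Wald
  ("add z²/2 successes and z²/2 failures") confidence interval around
  p₀ = 1/c gives an upper limit that a real classifier must beat.  For
  20 trials, two classes and α = 0.05 the upper limit is ~70%.

* **One-sample Wilcoxon signed-rank test** of the group accuracies
  against a reference level µ, with the rank-biserial correlation
  r_rb = (T⁺ − T⁻)/(T⁺ + T⁻) as effect size.  Differences equal to µ
  are removed; |differences| are ranked with midranks for ties.  The
  p-value uses exact sign-flip enumeration for small samples and a
  tie-corrected normal approximation with 0.5 continuity correction
  otherwise — common desktop statistics packages default to the latter,
  so :func:`wilcoxon_one_sample` reports its method and
  :func:`reproduce_results` prints both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .classify import SubjectResult

__all__ = [
    "ChanceBound",
    "WilcoxonResult",
    "GroupStats",
    "chance_upper_bound",
    "wilcoxon_one_sample",
    "group_summary",
    "flag_below_chance",
    "load_accuracy_table",
    "reproduce_results",
]

EXACT_MAX_N = 20


@dataclass(frozen=True)
class ChanceBound:
    n_trials: int
    n_classes: int
    alpha: float
    lower_bound: float  # percent
    upper_bound: float  # percent

    @property
    def upper_bound_rounded(self) -> int:
        return int(round(self.upper_bound))


@dataclass(frozen=True)
class WilcoxonResult:
    t_plus: float
    t_minus: float
    n_effective: int
    p_value: float
    r_rb: float
    method: str  # exact-enumeration | normal-approx


@dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float  # percent
    sd: float  # percent, n-1 denominator


def chance_upper_bound(
    n_trials: int, n_classes: int = 2, alpha: float = 0.05
) -> ChanceBound:
    """Adjusted-Wald confidence interval around p₀ = 1/n_classes, in %.

    With z = z_{1−α/2}: p̃ = (n·p₀ + z²/2)/(n + z²) and half-width
    z·sqrt(p̃(1−p̃)/(n + z²)).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    p0 = 1.0 / n_classes
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    p_tilde = (n_trials * p0 + z * z / 2.0) / (n_trials + z * z)
    half = z * math.sqrt(p_tilde * (1.0 - p_tilde) / (n_trials + z * z))
    return ChanceBound(
        n_trials=n_trials,
        n_classes=n_classes,
        alpha=alpha,
        lower_bound=100.0 * (p_tilde - half),
        upper_bound=100.0 * (p_tilde + half),
    )


def _exact_p(ranks: np.ndarray, t_plus: float) -> float:
    """Two-sided exact p by dynamic programming over all 2^n sign flips.

    Midranks are half-integers at worst, so doubling makes every rank an
    integer and the null distribution of 2·T⁺ lives on 0..n(n+1).
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    t2 = int(round(2.0 * t_plus))
    cdf = dist[: t2 + 1].sum()
    sf = dist[t2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _approx_p(ranks: np.ndarray, t_plus: float) -> float:
    """Tie-corrected normal approximation with 0.5 continuity correction."""
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(((counts**3 - counts).sum())) / 48.0
    d = t_plus - mean
    d_corr = max(abs(d) - 0.5, 0.0)
    z = d_corr / math.sqrt(var)
    return float(2.0 * sps.norm.sf(z))


def wilcoxon_one_sample(
    values, mu: float, method: str = "auto"
) -> WilcoxonResult:
    """One-sample signed-rank test of ``values`` against location ``mu``.

    ``method``: ``"exact"`` (sign-flip enumeration, valid with midrank
    ties), ``"approx"`` (tie/continuity-corrected normal), or ``"auto"``
    (exact for n_effective ≤ 20).  Values equal to ``mu`` are removed
    before ranking.
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all values equal mu; the signed-rank test is undefined")
    ranks = sps.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    t_minus = float(ranks[d < 0].sum())
    if method == "auto":
        method = "exact" if n <= EXACT_MAX_N else "approx"
    if method == "exact":
        p = _exact_p(ranks, t_plus)
        label = "exact-enumeration"
    elif method == "approx":
        p = _approx_p(ranks, t_plus)
        label = "normal-approx"
    else:
        raise ValueError("method must be 'auto', 'exact' or 'approx'")
    return WilcoxonResult(
        t_plus=t_plus,
        t_minus=t_minus,
        n_effective=n,
        p_value=p,
        r_rb=(t_plus - t_minus) / (t_plus + t_minus),
        method=label,
    )


def group_summary(values) -> GroupStats:
    """Arithmetic mean and sample SD (n−1 denominator), in percent."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two values for a group summary")
    return GroupStats(n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))


def flag_below_chance(
    results: list[SubjectResult], bound: ChanceBound
) -> list[tuple[SubjectResult, bool]]:
    """Mark subjects whose accuracy is strictly below the upper chance bound."""
    return [(r, r.accuracy < bound.upper_bound) for r in results]


def load_accuracy_table(path=None) -> dict[str, dict[str, float | None]]:
    """Read the bundled (or a user) per-subject accuracy TSV.

    Returns {subject: {"calibration": %, "online": % or None}}.
    """
    if path is None:
        with resources.as_file(
            resources.files("nirstate.data").joinpath("table1.tsv")
        ) as p:
            text = Path(p).read_text()
    else:
        text = Path(path).read_text()
    out: dict[str, dict[str, float | None]] = {}
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = rows[0].split("\t")
    if header != ["subject", "calibration", "online"]:
        raise ValueError("accuracy table must have columns subject/calibration/online")
    for ln in rows[1:]:
        parts = (ln.split("\t") + ["", ""])[:3]
        subject, calib, online = parts
        out[subject] = {
            "calibration": float(calib) if calib.strip() else None,
            "online": float(online) if online.strip() else None,
        }
    return out


#: Published group-level values the reproduction report compares against.
REPORTED = {
    "calibration_mean": 88.58,
    "calibration_sd": 8.49,
    "online_mean": 61.0,
    "online_sd": 14.89,
    "chance_upper_pct": 70,
    "calib_vs_70": {"t_plus": 78, "r_rb": 1.0},
    "calib_vs_50": {"t_plus": 78, "r_rb": 1.0},
    "online_vs_50": {"t_plus": 31, "r_rb": 0.72},
    "online_vs_70": {"t_plus": 6, "p": 0.107},
}


def reproduce_results(path=None, n_trials: int = 20) -> dict:
    """Recompute every group-level statistic from the accuracy table.

    Returns a nested report dict; each entry carries the recomputed
    value, the published value where one exists, and a match verdict.
    The online-vs-70 test is computed under both p-value methods, since
    the published p follows the normal approximation.
    """
    table = load_accuracy_table(path)
    calib = [v["calibration"] for v in table.values() if v["calibration"] is not None]
    online = [v["online"] for v in table.values() if v["online"] is not None]
    missing = [s for s, v in table.items() if v["online"] is None]

    bound = chance_upper_bound(n_trials, 2, 0.05)
    gs_c = group_summary(calib)
    gs_o = group_summary(online)

    def _wx(values, mu, method="auto"):
        r = wilcoxon_one_sample(values, mu, method=method)
        return {
            "t_plus": r.t_plus, "t_minus": r.t_minus, "n": r.n_effective,
            "p": r.p_value, "r_rb": r.r_rb, "method": r.method,
        }

    report = {
        "n_subjects": len(table),
        "online_missing": missing,
        "chance_bound": {
            "n_trials": n_trials,
            "upper_pct": bound.upper_bound,
            "upper_pct_rounded": bound.upper_bound_rounded,
            "published": REPORTED["chance_upper_pct"],
            "match": bound.upper_bound_rounded == REPORTED["chance_upper_pct"],
        },
        "calibration": {
            "n": gs_c.n, "mean": round(gs_c.mean, 2), "sd": round(gs_c.sd, 2),
            "published_mean": REPORTED["calibration_mean"],
            "published_sd": REPORTED["calibration_sd"],
            "match": round(gs_c.mean, 2) == REPORTED["calibration_mean"]
            and round(gs_c.sd, 2) == REPORTED["calibration_sd"],
        },
        "online": {
            "n": gs_o.n, "mean": round(gs_o.mean, 2), "sd": round(gs_o.sd, 2),
            "published_mean": REPORTED["online_mean"],
            "published_sd": REPORTED["online_sd"],
            "match": round(gs_o.mean, 2) == REPORTED["online_mean"]
            and round(gs_o.sd, 2) == REPORTED["online_sd"],
        },
        "wilcoxon": {
            "calibration_vs_70": _wx(calib, 70),
            "calibration_vs_50": _wx(calib, 50),
            "online_vs_50": _wx(online, 50),
            "online_vs_70_exact": _wx(online, 70, method="exact"),
            "online_vs_70_approx": _wx(online, 70, method="approx"),
        },
    }
    wx = report["wilcoxon"]
    wx["calibration_vs_70"]["match"] = (
        wx["calibration_vs_70"]["t_plus"] == REPORTED["calib_vs_70"]["t_plus"]
        and wx["calibration_vs_70"]["r_rb"] == REPORTED["calib_vs_70"]["r_rb"]
    )
    wx["calibration_vs_50"]["match"] = (
        wx["calibration_vs_50"]["t_plus"] == REPORTED["calib_vs_50"]["t_plus"]
    )
    wx["online_vs_50"]["match"] = (
        wx["online_vs_50"]["t_plus"] == REPORTED["online_vs_50"]["t_plus"]
        and round(wx["online_vs_50"]["r_rb"], 2) == REPORTED["online_vs_50"]["r_rb"]
    )
    wx["online_vs_70_approx"]["match"] = (
        wx["online_vs_70_approx"]["t_plus"] == REPORTED["online_vs_70"]["t_plus"]
        and round(wx["online_vs_70_approx"]["p"], 3) == REPORTED["online_vs_70"]["p"]
    )
    wx["online_vs_70_exact"]["match"] = (
        round(wx["online_vs_70_exact"]["p"], 3) == REPORTED["online_vs_70"]["p"]
    )
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of :func:`reproduce_results` output."""
    def verdict(m):
        return "match" if m else "MISMATCH"

    lines = [
        f"subjects: {report['n_subjects']}  "
        f"(online missing: {', '.join(report['online_missing']) or 'none'})",
        f"chance upper bound ({report['chance_bound']['n_trials']} trials, 2 classes, 95%): "
        f"{report['chance_bound']['upper_pct']:.2f}% -> "
        f"{report['chance_bound']['upper_pct_rounded']}%  "
        f"[published {report['chance_bound']['published']}%: "
        f"{verdict(report['chance_bound']['match'])}]",
    ]
    for sess in ("calibration", "online"):
        s = report[sess]
        lines.append(
            f"{sess}: n={s['n']}  M={s['mean']:.2f}  SD={s['sd']:.2f}  "
            f"[published M={s['published_mean']}, SD={s['published_sd']}: "
            f"{verdict(s['match'])}]"
        )
    for name, w in report["wilcoxon"].items():
        lines.append(
            f"wilcoxon {name}: T+={w['t_plus']:.0f}  T-={w['t_minus']:.0f}  "
            f"n={w['n']}  p={w['p']:.4f}  r_rb={w['r_rb']:.2f}  ({w['method']})"
            + (f"  [{verdict(w['match'])}]" if "match" in w else "")
        )
    return "\n".join(lines)
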