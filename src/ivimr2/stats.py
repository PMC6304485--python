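"""Nonparametric group comparison, paired testing and rank correlation.

The battery mirrors common practice in small-animal imaging studies:
Kruskal-Wallis H across time points or fibrosis stages, Mann-Whitney U for
pairwise group contrasts, a paired-samples t test between irradiated and
control lobes of the same animals, and Spearman rank correlation between
each imaging parameter and the ordinal fibrosis stage, with conventional
strength bands (|r| >= 0.8 high, 0.5 <= |r| < 0.8 mild, otherwise weak).

Midranks handle ties throughout; the Kruskal-Wallis H carries the tie
correction.  p-values come from exact permutation enumeration when the
pooled sample is small (n <= 12) and from the asymptotic reference
distribution otherwise.  All tests are two-sided; no multiple-testing
correction is applied.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "StatsReport",
    "STAGE_CODES",
    "kruskal_wallis",
    "mann_whitney",
    "paired_t",
    "spearman",
    "strength_label",
    "build_study_report",
]

ALPHA = 0.05
EXACT_N_MAX = 12
STAGE_CODES = {"control": 0, "F0": 1, "F1": 2, "F2": 3}


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_value: Optional[float]
    group_labels: tuple[str, ...]
    group_sizes: tuple[int, ...]
    alpha: float = ALPHA
    flags: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < self.alpha


@dataclass(frozen=True)
class CorrelationResult:
    r: Optional[float]
    p_value: Optional[float]
    n: int
    flags: tuple[str, ...] = ()

    @property
    def strength(self) -> Optional[str]:
        return None if self.r is None else strength_label(self.r)


def strength_label(r: float) -> str:
    """Conventional correlation-strength band: high / mild / weak."""
    if abs(r) >= 0.8:
        return "high"
    if abs(r) >= 0.5:
        return "mild"
    return "weak"


def _kw_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from midranks."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Kruskal-Wallis H test across two or more independent groups.

    Identical values everywhere give H = 0, p = 1 (no evidence, not an
    error).  Exact permutation p when the pooled n <= 12, chi-square
    otherwise.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 1 for a in arrs):
        raise ValueError("need >= 2 non-empty groups")
    labels = tuple(labels) if labels else tuple(f"g{i}" for i in range(len(arrs)))
    sizes = tuple(a.size for a in arrs)
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return ComparisonResult("kruskal_wallis", 0.0, 1.0, labels, sizes, alpha, ("all_identical",))
    h_obs = _kw_h(arrs)
    n = pooled.size
    if n <= EXACT_N_MAX:
        p = _kw_exact_p(pooled, sizes, h_obs)
        flags = ("exact",)
    else:
        p = float(sps.chi2.sf(h_obs, len(arrs) - 1))
        flags = ()
    return ComparisonResult("kruskal_wallis", float(h_obs), p, labels, sizes, alpha, flags)


def _kw_exact_p(pooled: np.ndarray, sizes: tuple[int, ...], h_obs: float) -> float:
    """Exact permutation p: fraction of group assignments with H >= observed."""
    n = pooled.size
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    count = total = 0
    for split in _partitions(range(n), sizes):
        h = 12.0 / (n * (n + 1)) * sum(
            ranks[list(part)].sum() ** 2 / len(part) for part in split
        ) - 3 * (n + 1)
        total += 1
        if h / tie >= h_obs - 1e-12:
            count += 1
    return count / total


def _partitions(idx, sizes):
    """All ordered partitions of ``idx`` into blocks of the given sizes."""
    idx = list(idx)
    if len(sizes) == 1:
        yield (tuple(idx),)
        return
    for head in itertools.combinations(idx, sizes[0]):
        rest = [i for i in idx if i not in head]
        for tail in _partitions(rest, sizes[1:]):
            yield (head,) + tail


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact enumeration (doubled one-sided tail) when n_a + n_b <= 12,
    normal approximation with tie correction otherwise.
    """
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = sps.rankdata(np.concatenate([x, y]))
    u = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2)
    n = x.size + y.size
    if n <= EXACT_N_MAX:
        p = _mwu_exact_p(np.concatenate([x, y]), x.size, u)
        flags = ("exact",)
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p, flags = float(res.pvalue), ()
    return ComparisonResult("mann_whitney", u, p, labels, (x.size, y.size), alpha, flags)


def _mwu_exact_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    n = pooled.size
    u_small = min(u_obs, n1 * (n - n1) - u_obs)
    ranks = sps.rankdata(pooled)
    count = total = 0
    for pick in itertools.combinations(range(n), n1):
        u = ranks[list(pick)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if min(u, n1 * (n - n1) - u) <= u_small + 1e-12:
            count += 1
    return min(1.0, count / total)


def paired_t(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str] = ("x", "y"),
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Two-sided paired-samples t test on y - x differences.

    Degenerate difference variance is flagged: a constant non-zero shift is
    reported as p = 0 (infinite t in the limit); all-zero differences carry
    no p-value.
    """
    a, b = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = b - a
    if np.ptp(d) == 0:
        if d[0] == 0:
            return ComparisonResult("paired_t", float("nan"), None, labels,
                                    (a.size, b.size), alpha, ("zero_differences",))
        return ComparisonResult("paired_t", float("inf") if d[0] > 0 else float("-inf"),
                                0.0, labels, (a.size, b.size), alpha, ("degenerate_variance",))
    res = sps.ttest_rel(b, a)
    return ComparisonResult("paired_t", float(res.statistic), float(res.pvalue),
                            labels, (a.size, b.size), alpha)


def spearman(
    values: Sequence[float],
    stages: Sequence[float],
    alpha: float = ALPHA,
) -> CorrelationResult:
    """Spearman rank correlation (midrank ties) between a parameter and stage codes."""
    v, s = np.asarray(values, dtype=float), np.asarray(stages, dtype=float)
    if v.shape != s.shape or v.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if np.ptp(v) == 0 or np.ptp(s) == 0:
        return CorrelationResult(None, None, v.size, ("constant_input",))
    res = sps.spearmanr(v, s)
    return CorrelationResult(float(res.statistic), float(res.pvalue), v.size)


# ---------------------------------------------------------------------------
# study-level report


@dataclass
class StatsReport:
    """Assembled study tables: group comparisons plus the stage-correlation block."""

    timepoint_right: pd.DataFrame
    stage_comparison: pd.DataFrame
    left_stability: pd.DataFrame
    relative_signal: pd.DataFrame
    correlations: dict[str, CorrelationResult]
    paired_lobe: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def correlation_json(self) -> str:
        payload = {
            p: {
                "r": c.r,
                "p_value": c.p_value,
                "n": c.n,
                "strength": c.strength,
                "flags": list(c.flags),
            }
            for p, c in self.correlations.items()
        }
        return json.dumps(payload, indent=2)

    def to_markdown(self) -> str:
        parts = []
        for title, df in (
            ("Right-lobe parameters by time point", self.timepoint_right),
            ("Right-lobe parameters by fibrosis stage", self.stage_comparison),
            ("Left-lobe (control) stability across time points", self.left_stability),
            ("Relative T1/T2 signal ratios", self.relative_signal),
            ("Paired right-vs-left lobe t tests", self.paired_lobe),
        ):
            parts.append(f"## {title}\n\n{df.to_markdown(index=False)}\n")
        corr = pd.DataFrame(
            {
                "parameter": list(self.correlations),
                "spearman_r": [c.r for c in self.correlations.values()],
                "p_value": [c.p_value for c in self.correlations.values()],
                "n": [c.n for c in self.correlations.values()],
                "strength": [c.strength for c in self.correlations.values()],
            }
        )
        parts.append(f"## Correlation with fibrosis stage\n\n{corr.to_markdown(index=False)}\n")
        if self.warnings:
            parts.append("## Warnings\n\n" + "\n".join(f"- {w}" for w in self.warnings) + "\n")
        return "\n".join(parts)

    def to_csv(self, out_dir: Union[str, Path]) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in (
            ("timepoint_right", self.timepoint_right),
            ("stage_comparison", self.stage_comparison),
            ("left_stability", self.left_stability),
            ("relative_signal", self.relative_signal),
            ("paired_lobe", self.paired_lobe),
        ):
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        path = out / "correlations.json"
        path.write_text(self.correlation_json())
        written.append(path)
        return written


_REPORT_PARAMS = ("D_star", "D", "f", "R2_star")
_TIMEPOINT_ORDER = ("baseline", "1m", "2m", "3m")
_STAGE_ORDER = ("control", "F0", "F1", "F2")


def _mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.3f} ± {x.std(ddof=1):.3f}"


def _group_table(
    df: pd.DataFrame, by: str, order: Sequence[str], params: Sequence[str],
    warnings: list[str],
) -> pd.DataFrame:
    present = [g for g in order if g in set(df[by])]
    missing = [g for g in order if g not in set(df[by])]
    if missing:
        warnings.append(f"groups missing from {by!r} table: {', '.join(missing)}")
    rows = []
    for g in present:
        sub = df[df[by] == g]
        row = {by: g, "n": len(sub)}
        row.update({p: _mean_sd(sub[p]) for p in params})
        rows.append(row)
    pvals = {by: "KW p", "n": ""}
    for p in params:
        groups = [df.loc[df[by] == g, p].to_numpy() for g in present]
        if len(groups) >= 2:
            res = kruskal_wallis(groups, labels=present)
            pvals[p] = f"{res.p_value:.3f}"
        else:
            pvals[p] = ""
    rows.append(pvals)
    return pd.DataFrame(rows)


def build_study_report(
    table: pd.DataFrame,
    alpha: float = ALPHA,
    include_control_in_correlation: bool = True,
) -> StatsReport:
    """Assemble the full study report from a lobe-measurement table.

    Expects the columns written by :func:`ivimr2.cohort.tabular_mode`
    (rat_id, timepoint, lobe, stage, D_star, D, f, R2_star, t1_ratio,
    t2_ratio).  Sub-tables: right-lobe parameters by time point, by fibrosis
    stage (left control lobes pooled as stage "control"), left-lobe
    stability, relative T1/T2 ratios, paired right-vs-left t tests per time
    point, and the Spearman stage-correlation block.  Deterministic: an
    identical input table yields a byte-identical report.
    """
    warnings: list[str] = []
    right = table[table["lobe"] == "right"]
    left = table[(table["lobe"] == "left")]
    followup = table[table["timepoint"] != "baseline"]

    timepoint_right = _group_table(right, "timepoint", _TIMEPOINT_ORDER, _REPORT_PARAMS, warnings)

    staged = pd.concat(
        [
            followup[followup["lobe"] == "left"].assign(stage="control"),
            followup[followup["lobe"] == "right"],
        ],
        ignore_index=True,
    )
    stage_comparison = _group_table(staged, "stage", _STAGE_ORDER, _REPORT_PARAMS, warnings)

    left_stability = _group_table(left, "timepoint", _TIMEPOINT_ORDER, _REPORT_PARAMS, warnings)

    rel_rows = []
    for lobe in ("right", "left"):
        sub = table[table["lobe"] == lobe]
        for ratio in ("t1_ratio", "t2_ratio"):
            row = {"measure": f"{ratio[:2].upper()} of {lobe} lobes"}
            groups = []
            for tp in _TIMEPOINT_ORDER:
                vals = sub.loc[sub["timepoint"] == tp, ratio]
                row[tp] = _mean_sd(vals) if len(vals) else ""
                if len(vals):
                    groups.append(vals.to_numpy())
            row["KW p"] = f"{kruskal_wallis(groups).p_value:.3f}" if len(groups) >= 2 else ""
            rel_rows.append(row)
    relative_signal = pd.DataFrame(rel_rows)

    paired_rows = []
    for tp in _TIMEPOINT_ORDER:
        sub = followup[followup["timepoint"] == tp]
        if sub.empty:
            continue
        wide = sub.pivot(index="rat_id", columns="lobe", values=list(_REPORT_PARAMS))
        for p in _REPORT_PARAMS:
            if ("left" not in wide[p]) or ("right" not in wide[p]):
                continue
            res = paired_t(wide[p]["left"], wide[p]["right"], labels=("left", "right"))
            paired_rows.append(
                {
                    "timepoint": tp,
                    "parameter": p,
                    "t": res.statistic,
                    "p_value": res.p_value,
                    "n_pairs": res.group_sizes[0],
                    "flags": ";".join(res.flags),
                }
            )
    paired_lobe = pd.DataFrame(paired_rows)

    if include_control_in_correlation:
        corr_df = staged
    else:
        corr_df = followup[followup["lobe"] == "right"]
    codes = corr_df["stage"].map(STAGE_CODES)
    correlations = {}
    for p in _REPORT_PARAMS:
        if codes.isna().any() or len(corr_df) < 3:
            warnings.append(f"correlation for {p} skipped: unusable stage labels")
            correlations[p] = CorrelationResult(None, None, len(corr_df), ("missing_stages",))
        else:
            correlations[p] = spearman(corr_df[p].to_numpy(), codes.to_numpy(), alpha)

    return StatsReport(
        timepoint_right=timepoint_right,
        stage_comparison=stage_comparison,
        left_stability=left_stability,
        relative_signal=relative_signal,
        correlations=correlations,
        paired_lobe=paired_lobe,
        warnings=warnings,
    )
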