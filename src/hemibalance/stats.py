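"""Normality-gated statistical battery for the laterality-outcome analysis.

All tests are two-sided at alpha = 0.05 on raw (uncorrected) p-values, with an
optional Benjamini-Hochberg switch. Test selection is gated on Shapiro-Wilk
normality of every variable involved: parametric (paired t / Pearson) only if
all pass, otherwise nonparametric (Wilcoxon signed-rank / Spearman).
Correlation strengths are labelled on |r| with the closed-lower-bound
intervals: negligible [0, 0.21), weak [0.21, 0.36), moderate [0.36, 0.68),
strong [0.68, 0.91), very strong [0.91, 1].

The declared correlation battery crosses every clinical score
(FMA-UE/FMA-d/FMA-p at both timepoints) with every laterality metric
(LI-RMT, LI-M1, LI-SMA, LI-PMC, LI-combined at both timepoints) and adds all
pairings among the laterality metrics. The combined-metric mean split groups
patients by s = LI-SMA(T1) + LI-RMT(T1) against the cohort mean of s and
compares outcome scores between the two groups with Mann-Whitney U,
reporting medians with quartiles and the normal-approximation Z.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sst

from .records import AnalysisError
from .tms import AH_DOMINANT, UH_DOMINANT, DominanceGroup

ALPHA = 0.05

FMA_VARS = tuple(f"{m}_{t}" for m in ("fma_ue", "fma_d", "fma_p")
                 for t in ("t1", "t2"))
LI_VARS = tuple(f"{m}_{t}" for m in ("li_rmt", "li_m1", "li_sma",
                                     "li_pmc", "li_combined")
                for t in ("t1", "t2"))

# (lower |r| bound, label); intervals are closed below, open above
STRENGTH_BOUNDS = (
    (0.91, "very strong"),
    (0.68, "strong"),
    (0.36, "moderate"),
    (0.21, "weak"),
    (0.00, "negligible"),
)


def strength_label(r: float) -> str:
    """Label a correlation coefficient by magnitude."""
    a = abs(r)
    if a > 1.0 + 1e-12:
        raise ValueError(f"|r| = {a} exceeds 1")
    for bound, label in STRENGTH_BOUNDS:
        if a >= bound:
            return label
    return "negligible"


@dataclass
class TestSelection:
    parametric: bool
    shapiro_p: tuple[float, ...]
    degenerate: bool = False   # zero-variance input forced the nonparametric arm


def choose_test(*samples: np.ndarray, alpha: float = ALPHA) -> TestSelection:
    """Shapiro-Wilk gate: parametric only if every sample looks normal."""
    pvals = []
    degenerate = False
    for x in samples:
        x = np.asarray(x, dtype=float)
        x = x[~np.isnan(x)]
        if x.size < 3:
            raise AnalysisError(f"need >= 3 observations, got {x.size}")
        if np.ptp(x) == 0:
            warnings.warn("degenerate (constant) sample; using the "
                          "nonparametric arm", stacklevel=2)
            pvals.append(0.0)
            degenerate = True
            continue
        pvals.append(float(sst.shapiro(x).pvalue))
    parametric = (not degenerate) and all(p > alpha for p in pvals)
    return TestSelection(parametric=parametric, shapiro_p=tuple(pvals),
                         degenerate=degenerate)


@dataclass
class CorrelationResult:
    var_x: str
    var_y: str
    n: int
    method: str | None          # "pearson" | "spearman" | None if not computable
    r: float
    p: float
    strength_label: str | None
    group: str | None = None    # dominance stratum, if any

    @property
    def computable(self) -> bool:
        return self.method is not None

    @property
    def significant(self) -> bool:
        return self.computable and self.p < ALPHA


def correlate(x, y, var_x: str = "x", var_y: str = "y",
              group: str | None = None) -> CorrelationResult:
    """One battery cell: normality-gated Pearson/Spearman on complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(var_x, var_y, n, None, float("nan"),
                                 float("nan"), None, group)
    sel = choose_test(x, y)
    if sel.parametric:
        res = sst.pearsonr(x, y)
        method = "pearson"
    else:
        res = sst.spearmanr(x, y)
        method = "spearman"
    r = float(res.statistic if hasattr(res, "statistic") else res.correlation)
    p = float(res.pvalue)
    return CorrelationResult(var_x, var_y, n, method, r, p,
                             strength_label(r), group)


def battery_cells() -> list[tuple[str, str]]:
    """The declared set of correlation cells: score x LI, plus LI x LI."""
    cells = [(f, l) for f in FMA_VARS for l in LI_VARS]
    cells += list(itertools.combinations(LI_VARS, 2))
    return cells


def correlation_matrix(df: pd.DataFrame,
                       group: str | None = None) -> list[CorrelationResult]:
    """Run every declared cell present in the wide per-subject table.

    Cells whose variables are absent from the table, or have fewer than three
    complete pairs, are returned marked not-computable rather than dropped so
    the battery cardinality is stable.
    """
    results = []
    for vx, vy in battery_cells():
        if vx not in df.columns or vy not in df.columns:
            results.append(CorrelationResult(vx, vy, 0, None, float("nan"),
                                             float("nan"), None, group))
            continue
        results.append(correlate(df[vx], df[vy], vx, vy, group))
    return results


@dataclass
class GroupComparison:
    variable: str
    test: str                    # "paired-t" | "wilcoxon" | "mann-whitney-u"
    statistic: float             # t, W, or Z depending on the test
    p: float
    n: tuple[int, ...]
    medians: tuple[float, ...]   # one per group/timepoint
    q25: tuple[float, ...]
    q75: tuple[float, ...]
    direction: str | None = None

    def __post_init__(self) -> None:
        for lo, med, hi in zip(self.q25, self.medians, self.q75):
            assert lo <= med <= hi


def _summaries(*groups) -> tuple[tuple, tuple, tuple]:
    med = tuple(float(np.median(g)) for g in groups)
    q25 = tuple(float(np.percentile(g, 25)) for g in groups)
    q75 = tuple(float(np.percentile(g, 75)) for g in groups)
    return med, q25, q75


def paired_change(t1, t2, variable: str = "score") -> GroupComparison:
    """Baseline vs one-month paired comparison with the normality gate."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if t1.shape != t2.shape:
        raise AnalysisError(f"{variable}: T1/T2 lengths differ "
                            f"({t1.size} vs {t2.size})")
    ok = ~(np.isnan(t1) | np.isnan(t2))
    t1, t2 = t1[ok], t2[ok]
    if t1.size < 3:
        raise AnalysisError(f"{variable}: need >= 3 complete pairs")
    diff = t2 - t1
    med, q25, q75 = _summaries(t1, t2)
    direction = ("increase" if np.mean(diff) > 0
                 else "decrease" if np.mean(diff) < 0 else "none")
    if np.all(diff == 0):
        return GroupComparison(variable, "wilcoxon", 0.0, 1.0,
                               (t1.size, t2.size), med, q25, q75, "none")
    sel = choose_test(t1, t2)
    if sel.parametric:
        res = sst.ttest_rel(t2, t1)
        return GroupComparison(variable, "paired-t", float(res.statistic),
                               float(res.pvalue), (t1.size, t2.size),
                               med, q25, q75, direction)
    res = sst.wilcoxon(t2, t1, zero_method="wilcox")
    return GroupComparison(variable, "wilcoxon", float(res.statistic),
                           float(res.pvalue), (t1.size, t2.size),
                           med, q25, q75, direction)


def _mann_whitney_z(g1, g2) -> tuple[float, float]:
    """Mann-Whitney U as a tie-corrected normal-approximation Z, plus p."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n1, n2 = g1.size, g2.size
    u1 = float(sst.mannwhitneyu(g1, g2, alternative="two-sided",
                                method="asymptotic").statistic)
    n = n1 + n2
    pooled = np.concatenate([g1, g2])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 0.0, 1.0
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(sigma2)
    p = 2.0 * sst.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def mann_whitney(g1, g2, variable: str = "score") -> GroupComparison:
    """Two-group comparison reported as medians (P25, P75) and Z."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    g1, g2 = g1[~np.isnan(g1)], g2[~np.isnan(g2)]
    if g1.size < 1 or g2.size < 1:
        raise AnalysisError(f"{variable}: both groups must be non-empty")
    z, p = _mann_whitney_z(g1, g2)
    med, q25, q75 = _summaries(g1, g2)
    direction = ("g1>g2" if med[0] > med[1]
                 else "g1<g2" if med[0] < med[1] else "none")
    return GroupComparison(variable, "mann-whitney-u", z, p,
                           (g1.size, g2.size), med, q25, q75, direction)


@dataclass
class MeanSplitResult:
    g1_ids: list[str]            # s = li_sma_t1 + li_rmt_t1 below the mean
    g2_ids: list[str]            # above the mean
    excluded_ids: list[str]      # exactly at the mean
    mean_s: float
    comparisons: list[GroupComparison]


def mean_split_groups(df: pd.DataFrame,
                      score_vars: tuple[str, ...] = ("fma_ue_t1", "fma_ue_t2",
                                                     "fma_d_t1", "fma_d_t2"),
                      ) -> MeanSplitResult:
    """Split patients on the cohort mean of s = LI-SMA(T1) + LI-RMT(T1) and
    compare outcome scores between the strict-below (g1) and strict-above (g2)
    groups with Mann-Whitney U."""
    for col in ("subject_id", "li_sma_t1", "li_rmt_t1"):
        if col not in df.columns:
            raise AnalysisError(f"mean split requires column '{col}'")
    sub = df.dropna(subset=["li_sma_t1", "li_rmt_t1"]).copy()
    if len(sub) < 2:
        raise AnalysisError("mean split needs >= 2 subjects with both T1 metrics")
    s = sub["li_sma_t1"].to_numpy(float) + sub["li_rmt_t1"].to_numpy(float)
    m = float(np.mean(s))
    ids = sub["subject_id"].astype(str).to_numpy()
    g1_mask, g2_mask = s < m, s > m
    excluded = [str(i) for i in ids[~(g1_mask | g2_mask)]]
    for sid in excluded:
        warnings.warn(f"subject {sid}: s equals the cohort mean exactly; "
                      "excluded from the mean-split comparison", stacklevel=2)
    if not g1_mask.any() or not g2_mask.any():
        raise AnalysisError("mean split is degenerate: one group is empty")
    comparisons = []
    for var in score_vars:
        if var not in sub.columns or sub[var].dropna().empty:
            continue
        vals = sub[var].to_numpy(float)
        ok = ~np.isnan(vals)
        comparisons.append(mann_whitney(vals[g1_mask & ok], vals[g2_mask & ok],
                                        variable=var))
    return MeanSplitResult(
        g1_ids=[str(i) for i in ids[g1_mask]],
        g2_ids=[str(i) for i in ids[g2_mask]],
        excluded_ids=excluded, mean_s=m, comparisons=comparisons)


def subgroup_correlations(dominance: list[DominanceGroup], df: pd.DataFrame,
                          ) -> dict[str, list[CorrelationResult]]:
    """Run the correlation battery separately within the d(R) > 0 and
    d(R) < 0 dominance strata; strata with n < 3 are skipped."""
    assignment = {d.subject_id: d.group for d in dominance}
    out: dict[str, list[CorrelationResult]] = {}
    for label in (UH_DOMINANT, AH_DOMINANT):
        ids = [sid for sid, g in assignment.items() if g == label]
        sub = df[df["subject_id"].astype(str).isin(ids)]
        if len(sub) < 3:
            warnings.warn(f"dominance group {label}: n={len(sub)} < 3; "
                          "skipped", stacklevel=2)
            continue
        out[label] = correlation_matrix(sub, group=label)
    return out


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (off by default in the battery)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class AnalysisReport:
    correlations: list[CorrelationResult] = field(default_factory=list)
    paired: list[GroupComparison] = field(default_factory=list)
    mean_split: MeanSplitResult | None = None
    subgroups: dict[str, list[CorrelationResult]] = field(default_factory=dict)

    def correlation_frame(self) -> pd.DataFrame:
        rows = [asdict(c) for c in self.correlations]
        for group_results in self.subgroups.values():
            rows.extend(asdict(c) for c in group_results)
        cols = ["var_x", "var_y", "n", "method", "r", "p",
                "strength_label", "group"]
        return pd.DataFrame(rows, columns=cols)

    def to_dict(self) -> dict:
        return {
            "correlations": [asdict(c) for c in self.correlations],
            "paired": [asdict(c) for c in self.paired],
            "mean_split": asdict(self.mean_split) if self.mean_split else None,
            "subgroups": {k: [asdict(c) for c in v]
                          for k, v in self.subgroups.items()},
        }

    def summary_lines(self) -> list[str]:
        lines = ["laterality-outcome analysis report",
                 "label intervals on |r|: negligible [0,0.21) weak [0.21,0.36) "
                 "moderate [0.36,0.68) strong [0.68,0.91) very strong [0.91,1]",
                 ""]
        for c in self.paired:
            lines.append(f"paired {c.variable}: {c.test} statistic="
                         f"{c.statistic:.3f} p={c.p:.4f} ({c.direction})")
        frame = self.correlation_frame()
        n_cells = len(frame)
        lines.append(f"correlation battery: {n_cells} cells "
                     f"({int(frame['method'].notna().sum())} computable)")
        for c in self.correlations + [x for v in self.subgroups.values()
                                      for x in v]:
            if c.significant:
                grp = f" [{c.group}]" if c.group else ""
                lines.append(
                    f"  {c.var_x} ~ {c.var_y}{grp}: {c.method} r={c.r:+.3f} "
                    f"p={c.p:.4f} n={c.n} ({c.strength_label})")
        if self.mean_split is not None:
            ms = self.mean_split
            lines.append(f"mean split s=li_sma_t1+li_rmt_t1 @ {ms.mean_s:+.3f}: "
                         f"g1 n={len(ms.g1_ids)}, g2 n={len(ms.g2_ids)}")
            for c in ms.comparisons:
                lines.append(
                    f"  {c.variable}: g1 {c.medians[0]:.1f} ({c.q25[0]:.1f}, "
                    f"{c.q75[0]:.1f}) vs g2 {c.medians[1]:.1f} ({c.q25[1]:.1f}, "
                    f"{c.q75[1]:.1f}); Z={c.statistic:.3f} p={c.p:.4f}")
        return lines

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.correlation_frame().to_csv(out / "results.csv", index=False)
        with open(out / "results.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        (out / "summary.txt").write_text("\n".join(self.summary_lines()) + "\n")
        scatter = self.correlation_frame()
        sig = scatter[(scatter["p"] < ALPHA) & scatter["method"].notna()]
        sig.to_csv(out / "significant_pairs.csv", index=False)


def read_report(out_dir: str | Path) -> AnalysisReport:
    """Re-load a written report (round-trips :meth:`AnalysisReport.write`)."""
    with open(Path(out_dir) / "results.json") as fh:
        payload = json.load(fh)
    corr = [CorrelationResult(**c) for c in payload["correlations"]]
    paired = [GroupComparison(**{**c, "n": tuple(c["n"]),
                                 "medians": tuple(c["medians"]),
                                 "q25": tuple(c["q25"]),
                                 "q75": tuple(c["q75"])})
              for c in payload["paired"]]
    ms = None
    if payload["mean_split"] is not None:
        d = payload["mean_split"]
        ms = MeanSplitResult(
            g1_ids=d["g1_ids"], g2_ids=d["g2_ids"],
            excluded_ids=d["excluded_ids"], mean_s=d["mean_s"],
            comparisons=[GroupComparison(**{**c, "n": tuple(c["n"]),
                                            "medians": tuple(c["medians"]),
                                            "q25": tuple(c["q25"]),
                                            "q75": tuple(c["q75"])})
                         for c in d["comparisons"]])
    subgroups = {k: [CorrelationResult(**c) for c in v]
                 for k, v in payload["subgroups"].items()}
    return AnalysisReport(correlations=corr, paired=paired, mean_split=ms,
                          subgroups=subgroups)
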