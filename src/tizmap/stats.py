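"""Statistical engine: logPDR histogram features, nonparametric tests,
correlations, and the unequal-variance sample-size calculation.

PDR distributions span several orders of magnitude, so features are taken
on log10(PDR): median, mode (tallest Freedman-Diaconis histogram bin) and
the 10th percentile.  Group comparisons use the Wilcoxon rank-sum test
(exact enumeration for small tie-free samples, normal approximation with
tie and continuity corrections otherwise); associations use Pearson
correlation with the t-transform p-value.  The minimum per-group n to
detect a two-group difference with unequal variances comes from the
iterative t-based calculation with Welch-Satterthwaite degrees of freedom.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "LogPdrFeatures",
    "StatsReport",
    "logpdr_features",
    "wilcoxon_ranksum",
    "pearson_corr",
    "welch_sample_size",
    "build_report",
]

log = logging.getLogger(__name__)


@dataclass
class LogPdrFeatures:
    """Histogram features of log10(PDR) over a named ROI."""

    roi_name: str
    median: float
    mode: float
    p10: float
    n_voxels: int
    log_base: float = 10.0


@dataclass
class StatsReport:
    alpha: float = 0.05
    tests: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    dice: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    sample_size: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=float, **kwargs)


def _fd_mode(values: np.ndarray) -> float:
    """Center of the tallest Freedman-Diaconis bin; ties go to the lower bin."""
    vals = np.asarray(values, dtype=float)
    if np.ptp(vals) == 0:
        return float(vals[0])
    counts, edges = np.histogram(vals, bins="fd")
    i = int(np.argmax(counts))  # argmax takes the first (lower) maximal bin
    return float(0.5 * (edges[i] + edges[i + 1]))


def logpdr_features(pdr_values: np.ndarray, roi_name: str) -> LogPdrFeatures:
    """Median, FD-histogram mode and 10th percentile of log10(PDR)."""
    vals = np.asarray(pdr_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty ROI")
    if np.any(vals <= 0):
        raise ValueError("PDR values must be > 0 (epsilon-floored upstream)")
    lv = np.log10(vals)
    return LogPdrFeatures(
        roi_name=roi_name,
        median=float(np.median(lv)),
        mode=_fd_mode(lv),
        p10=float(np.percentile(lv, 10)),
        n_voxels=int(vals.size),
    )


def wilcoxon_ranksum(x: np.ndarray, y: np.ndarray,
                     alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum test.

    Exact null enumeration when ``min(n, m) <= 10`` and the pooled sample
    is tie-free; otherwise the normal approximation with midranks, tie
    correction and continuity correction.  Returns the rank-sum statistic
    of the first sample and the p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    w = float(sps.rankdata(pooled)[: x.size].sum())
    if np.ptp(pooled) == 0:
        log.warning("wilcoxon_ranksum: all pooled values identical; p = 1")
        return w, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    exact = (min(x.size, y.size) <= 10) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return w, float(res.pvalue)


def pearson_corr(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Pearson correlation with two-sided t-transform p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("samples must be paired")
    if a.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p), int(a.size)


def welch_sample_size(mean1: float, sd1: float, mean2: float, sd2: float,
                      alpha: float = 0.05, power: float = 0.80,
                      two_sided: bool = True,
                      use_z_approximation: bool = False) -> int:
    """Minimum equal-group n for a two-sample comparison with unequal variances.

    Iterates ``n >= (t_{1-a/2, nu} + t_{power, nu})^2 (sd1^2 + sd2^2) / delta^2``
    to a fixed point, with nu the Welch-Satterthwaite degrees of freedom at
    the current n.  The z-approximation (no df correction) is available
    behind a flag; it returns a smaller n.  The result is floored at 2.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    delta = mean1 - mean2
    if delta == 0:
        raise ValueError("group means are equal; no finite sample size")
    a_tail = alpha / 2.0 if two_sided else alpha
    var_sum = sd1**2 + sd2**2
    base = var_sum / delta**2

    z_n = (sps.norm.ppf(1 - a_tail) + sps.norm.ppf(power)) ** 2 * base
    if use_z_approximation:
        return max(int(np.ceil(z_n)), 2)

    def welch_df(n: int) -> float:
        a, b = sd1**2 / n, sd2**2 / n
        return (a + b) ** 2 / (a**2 / (n - 1) + b**2 / (n - 1))

    n = max(int(np.ceil(z_n)), 2)
    for _ in range(200):
        nu = welch_df(n)
        t_crit = sps.t.ppf(1 - a_tail, nu) + sps.t.ppf(power, nu)
        n_new = max(int(np.ceil(t_crit**2 * base)), 2)
        if n_new == n:
            return n
        # move monotonically toward the fixed point to guarantee termination
        n = n + 1 if n_new > n else n - 1
    return n  # pragma: no cover - iteration always terminates in practice


def build_report(*, pdr_by_roi: dict[str, np.ndarray] | None = None,
                 comparisons: list[tuple[str, str]] | None = None,
                 covariates: dict[str, np.ndarray] | None = None,
                 feature_table: dict[str, np.ndarray] | None = None,
                 dice_values: dict[str, float] | None = None,
                 thresholds: dict[str, float] | None = None,
                 volumes: dict[str, float] | None = None,
                 alpha: float = 0.05,
                 provenance: dict | None = None) -> StatsReport:
    """Assemble the deterministic statistics report.

    ``pdr_by_roi`` maps ROI names to PDR value arrays; ``comparisons``
    lists ROI pairs for rank-sum tests; ``covariates``/``feature_table``
    drive Pearson correlations (paired by subject); missing sections are
    marked absent rather than failing.
    """
    rep = StatsReport(alpha=alpha, provenance=provenance or {})
    pdr_by_roi = pdr_by_roi or {}
    for roi, vals in pdr_by_roi.items():
        f = logpdr_features(vals, roi)
        rep.features[roi] = asdict(f)
    for roi_a, roi_b in comparisons or []:
        if roi_a not in pdr_by_roi or roi_b not in pdr_by_roi:
            rep.tests[f"{roi_a}_vs_{roi_b}"] = {"status": "absent"}
            continue
        xa, xb = pdr_by_roi[roi_a], pdr_by_roi[roi_b]
        stat, p = wilcoxon_ranksum(xa, xb)
        rep.tests[f"{roi_a}_vs_{roi_b}"] = {
            "test": "wilcoxon_ranksum", "statistic": stat, "p": p,
            "n1": int(np.size(xa)), "n2": int(np.size(xb)),
            "significant": bool(p < alpha),
        }
    if covariates and feature_table:
        for cov_name, cov in covariates.items():
            for feat_name, feat in feature_table.items():
                try:
                    r, p, n = pearson_corr(np.asarray(feat), np.asarray(cov))
                except ValueError as exc:
                    rep.correlations[f"{feat_name}_vs_{cov_name}"] = {
                        "status": f"undefined: {exc}"}
                    continue
                rep.correlations[f"{feat_name}_vs_{cov_name}"] = {
                    "r": r, "p": p, "n": n, "significant": bool(p < alpha)}
    elif covariates or feature_table:
        rep.correlations["status"] = "absent"
    rep.dice = dict(dice_values or {})
    rep.thresholds = dict(thresholds or {})
    if volumes:
        rep.provenance["volumes"] = {k: float(v) for k, v in volumes.items()}
    return rep
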