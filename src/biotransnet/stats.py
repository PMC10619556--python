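"""Univariate statistics for biotransformant profiles.

Group comparison uses the two-sided Mann-Whitney U test. With the study
design of n=3 per arm the exact permutation distribution has only 20
arrangements, so the smallest achievable exact two-sided p-value is 0.1 —
below-0.05 significance at n=3 is only reachable through the normal
approximation without continuity correction (the convention of some legacy
microarray tools); that approximation carries an inflated false-positive
rate and is opt-in here. See docs/methods.md for the full discussion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .msio import MsFeature, SampleDesign

__all__ = [
    "FeatureStat",
    "mann_whitney",
    "fold_change",
    "feature_stats",
    "volcano_table",
    "volcano_plot",
    "metabolic_rate",
]

#: largest pooled sample size for which the exact enumeration is used by default
EXACT_LIMIT = 12


@dataclass(frozen=True)
class FeatureStat:
    feature_id: str
    fc: float
    log2fc: float
    p: float
    significant: bool
    direction: str  # up | down | ns


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y; ties count one half."""
    u = 0.0
    for xv in x:
        u += np.sum(xv > y) + 0.5 * np.sum(xv == y)
    return float(u)


def _exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of the C(n+m, n) group
    assignments of the pooled values (ties handled via half-counts)."""
    pooled = np.concatenate([x, y])
    n = x.size
    u_obs = _u_statistic(x, y)
    idx = range(pooled.size)
    n_le = n_ge = total = 0
    for comb in itertools.combinations(idx, n):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / total
    return min(p, 1.0)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    use_continuity: bool = True,
) -> float:
    """Two-sided Mann-Whitney U test p-value.

    method="exact" enumerates all rank assignments (feasible for pooled size
    <= ~14); method="normal" uses the tie-corrected normal approximation
    (continuity-corrected by default; ``use_continuity=False`` reproduces the
    legacy uncorrected convention). "auto" picks exact when the pooled size
    is at most 12.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if method == "auto":
        method = "exact" if pooled.size <= EXACT_LIMIT else "normal"
    if method == "exact":
        return _exact_p(x, y)
    if method == "normal":
        res = _sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=use_continuity
        )
        return float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def _arm_values(feature: MsFeature, design: SampleDesign, arm: str) -> np.ndarray:
    vals = []
    for sid in design.ids(arm):
        a = feature.areas.get(sid)
        if a is None or (isinstance(a, float) and math.isnan(a)):
            raise ValueError(
                f"feature {feature.feature_id}: missing area for sample {sid!r}; "
                "impute before computing statistics"
            )
        vals.append(float(a))
    if not vals:
        raise ValueError(f"design has no samples in arm {arm!r}")
    return np.asarray(vals)


def fold_change(feature: MsFeature, design: SampleDesign) -> tuple[float, float]:
    """Fold change = mean reaction-arm area / mean control-arm area."""
    rxn = _arm_values(feature, design, "reaction")
    ctl = _arm_values(feature, design, "control")
    if ctl.mean() <= 0:
        raise ValueError(f"feature {feature.feature_id}: nonpositive control mean")
    fc = float(rxn.mean() / ctl.mean())
    return fc, math.log2(fc)


def feature_stats(
    features: Sequence[MsFeature],
    design: SampleDesign,
    alpha: float = 0.05,
    method: str = "auto",
    use_continuity: bool = True,
    fdr: bool = False,
) -> list[FeatureStat]:
    """Per-feature fold change, p-value and direction call.

    ``fdr=True`` applies Benjamini-Hochberg adjustment before the
    significance call (off by default).
    """
    raw = []
    for f in features:
        fc, l2 = fold_change(f, design)
        p = mann_whitney(
            _arm_values(f, design, "reaction"),
            _arm_values(f, design, "control"),
            method=method,
            use_continuity=use_continuity,
        )
        raw.append((f.feature_id, fc, l2, p))
    pvals = np.array([r[3] for r in raw])
    adj = _bh_adjust(pvals) if fdr else pvals
    out = []
    for (fid, fc, l2, _), p in zip(raw, adj):
        sig = bool(p < alpha)
        if sig and fc > 1:
            direction = "up"
        elif sig and fc < 1:
            direction = "down"
        else:
            direction = "ns"
        out.append(FeatureStat(fid, fc, l2, float(p), sig and direction != "ns", direction))
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def volcano_table(stats: Sequence[FeatureStat], alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Volcano-ready table (log2 FC vs -log10 p) with up/down counts.

    The direction partition is recomputed at ``alpha`` so the same stats can
    be re-thresholded: up (fc>1, p<alpha), down (fc<1, p<alpha), else ns.
    """
    rows = []
    for s in stats:
        if s.p < alpha and s.fc > 1:
            direction = "up"
        elif s.p < alpha and s.fc < 1:
            direction = "down"
        else:
            direction = "ns"
        rows.append(
            {
                "feature_id": s.feature_id,
                "fc": s.fc,
                "log2fc": s.log2fc,
                "p": s.p,
                "neg_log10_p": -math.log10(s.p) if s.p > 0 else math.inf,
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows, columns=["feature_id", "fc", "log2fc", "p", "neg_log10_p", "direction"])
    counts = {
        "up": int((df["direction"] == "up").sum()) if len(df) else 0,
        "down": int((df["direction"] == "down").sum()) if len(df) else 0,
        "ns": int((df["direction"] == "ns").sum()) if len(df) else 0,
    }
    return df, counts


def volcano_plot(table: pd.DataFrame, alpha: float = 0.05, ax=None):
    """Scatter of log2 FC vs -log10 p, colored by direction."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = {"up": "#c0392b", "down": "#2980b9", "ns": "#555555"}
    for direction, grp in table.groupby("direction"):
        ax.scatter(grp["log2fc"], grp["neg_log10_p"], s=12, c=colors.get(direction, "grey"),
                   label=direction, alpha=0.7)
    ax.axhline(-math.log10(alpha), ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change (reaction / control)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    return ax


def metabolic_rate(parent_feature: MsFeature, design: SampleDesign) -> float:
    """Percent depletion of the parent after the enzymatic reaction:
    100 x (1 - mean reaction / mean control). Negative values indicate the
    parent increased (e.g. regenerated by a reverse reaction)."""
    rxn = _arm_values(parent_feature, design, "reaction")
    ctl = _arm_values(parent_feature, design, "control")
    if ctl.mean() <= 0:
        raise ValueError("nonpositive control mean")
    return 100.0 * (1.0 - rxn.mean() / ctl.mean())


def stats_frame(stats: Sequence[FeatureStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": s.feature_id,
                "fc": s.fc,
                "log2fc": s.log2fc,
                "p": s.p,
                "significant": s.significant,
                "direction": s.direction,
            }
            for s in stats
        ]
    )
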