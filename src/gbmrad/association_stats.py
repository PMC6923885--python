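"""Univariate association screening of features against the four subtypes.

Each feature is tested with the tie-corrected Kruskal–Wallis rank test
(chi-square approximation, groups − 1 degrees of freedom); results are
ranked by p-value with Benjamini–Hochberg q-values appended.  Group-wise
normalized histograms support qualitative comparison of distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

__all__ = [
    "AssociationResult",
    "kruskal_wallis",
    "kruskal_wallis_permutation",
    "bh_adjust",
    "screen_features",
    "group_histograms",
]


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    h_statistic: float
    p_value: float
    group_medians: dict
    direction: str  # "<group> low" / "<group> high" / "none"
    flag: str | None = None


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    H = [12 / (N (N+1))] Σ_j R_j²/n_j − 3 (N+1), divided by the tie
    correction 1 − Σ(t³ − t)/(N³ − N); p from χ² with (groups − 1) df.
    All values identical → (0, 1) by convention.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    names, inverse = np.unique(groups, return_inverse=True)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    if values.size < 3:
        raise ValueError("need >= 3 observations")
    n_total = values.size
    ranks = rankdata(values)  # mid-ranks for ties
    rank_sums = np.bincount(inverse, weights=ranks)
    sizes = np.bincount(inverse)
    if np.any(sizes == 0):
        raise ValueError("empty group")
    h = 12.0 / (n_total * (n_total + 1)) * np.sum(rank_sums**2 / sizes) - 3.0 * (
        n_total + 1
    )
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n_total**3 - n_total)
    if correction == 0.0:  # all values identical
        return 0.0, 1.0
    h = float(h / correction)
    h = max(h, 0.0)
    p = float(chi2.sf(h, df=len(names) - 1))
    return h, min(max(p, np.nextafter(0, 1)), 1.0)


def kruskal_wallis_permutation(
    values, groups, n_permutations: int = 10_000, seed: int = 0
) -> float:
    """Permutation p-value for the Kruskal–Wallis H (label reshuffling)."""
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    h_obs, _ = kruskal_wallis(values, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        h_perm, _ = kruskal_wallis(values, rng.permutation(groups))
        if h_perm >= h_obs:
            count += 1
    return (count + 1) / (n_permutations + 1)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _direction(medians: dict) -> str:
    """Which group's median is most extreme relative to the others."""
    items = list(medians.items())
    vals = np.array([v for _, v in items], dtype=np.float64)
    if np.ptp(vals) == 0:
        return "none"
    center = np.median(vals)
    k = int(np.argmax(np.abs(vals - center)))
    name, v = items[k]
    return f"{name} {'low' if v < center else 'high'}"


def screen_features(table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Kruskal–Wallis screen of every feature column against the labels.

    Returns a frame sorted by ascending p with columns: feature, h, p, q,
    per-group medians, direction, flag.  Constant features get (H=0, p=1)
    and a flag; missing values are dropped per feature.
    """
    labels = labels.reindex(table.index)
    rows = []
    for feature in table.columns:
        col = table[feature]
        ok = col.notna()
        values = col[ok].to_numpy(dtype=np.float64)
        grp = labels[ok].to_numpy()
        group_names = sorted(map(str, pd.unique(labels.dropna())))
        medians = {g: float(np.median(values[grp == g])) for g in group_names}
        flag = None
        if values.size == 0 or np.ptp(values) == 0:
            h, p = 0.0, 1.0
            flag = "constant or empty feature"
        else:
            h, p = kruskal_wallis(values, grp)
        rows.append(
            {
                "feature": feature,
                "h": h,
                "p": p,
                **{f"median_{g}": m for g, m in medians.items()},
                "direction": _direction(medians),
                "flag": flag,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["p", "feature"], kind="stable").reset_index(drop=True)
    return out


def group_histograms(values, groups, n_bins: int = 10) -> dict:
    """Per-group normalized histograms on shared pooled-range bin edges.

    Returns {"edges": array, "groups": {name: frequencies}}; each group's
    frequencies sum to 1 (empty groups are flagged with None).
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    lo, hi = values.min(), values.max()
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    out = {}
    for g in np.unique(groups):
        v = values[groups == g]
        if v.size == 0:
            out[str(g)] = None
            continue
        counts, _ = np.histogram(np.clip(v, lo, hi), bins=edges)
        out[str(g)] = counts / v.size
    return {"edges": edges, "groups": out}
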