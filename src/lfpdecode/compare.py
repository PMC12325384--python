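"""Pre/post accuracy comparison with an exact Wilcoxon signed-rank test.

For each (layer, band, feature kind, task) cell the per-animal change in
decoding accuracy (post % - pre %) is tested against zero with a
two-sided Wilcoxon signed-rank test.  Cohorts are small (7-8 animals),
so the test uses the exact permutation distribution of the signed-rank
statistic: zeros are dropped (Wilcoxon's original treatment), tied
absolute deltas receive midranks, and the null distribution is built
over all 2^n sign assignments of the observed rank multiset (computed by
dynamic programming, which enumerates the same distribution without
materializing the 2^n patterns).  No multiple-comparison correction is
applied by default — each cell reports its own p-value — but
Benjamini-Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decoder import DecodingResult


def accuracy_delta(pre: DecodingResult, post: DecodingResult) -> float:
    """Post-minus-pre mean accuracy, in percentage points.

    The two results must describe the same task, band, feature kind and
    CV scheme; anything else is a bookkeeping error, not a delta.
    """
    for attr in ("task", "band", "kind", "scheme"):
        if getattr(pre, attr) != getattr(post, attr):
            raise ValueError(
                f"mismatched {attr}: {getattr(pre, attr)!r} vs {getattr(post, attr)!r}")
    return post.mean_accuracy - pre.mean_accuracy


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for W+ given the |delta| rank multiset.

    Midranks can be half-integers, so everything is doubled onto an
    integer lattice.  The DP convolution counts, for every achievable
    doubled statistic value, how many of the 2^n sign assignments reach
    it — exactly the enumeration distribution.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total_sum = int(r2.sum())
    counts = np.zeros(total_sum + 1, dtype=float)
    counts[0] = 1.0
    top = 0
    for r in r2:
        counts[r: top + r + 1] += counts[: top + 1]
        top += r
    n = len(ranks)
    total = 2.0 ** n
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum() / total
    p_ge = counts[w2:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(deltas, *, exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of ``deltas`` against zero.

    Returns (W+, p).  Zeros are dropped before ranking; if every delta
    is zero the test is undefined and a ValueError is raised.  The exact
    distribution is used up to ``exact_max_n`` non-zero deltas, beyond
    that a normal approximation with tie correction.
    """
    d = np.asarray(deltas, dtype=float)
    if d.ndim != 1 or len(d) == 0:
        raise ValueError("deltas must be a non-empty 1-D sequence")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all deltas are zero: signed-rank test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        # tie correction on the rank variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts ** 3 - tie_counts) / 48.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return w_plus, p


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class ComparisonResult:
    """One cell of the layers x bands x kinds x tasks comparison grid."""

    layer: str
    band: str
    kind: str
    task: str
    n: int
    deltas: tuple
    median_delta: float
    statistic: float
    p_value: float
    significant: bool


def summarize(accuracies: pd.DataFrame, *, min_n_for_test: int = 5,
              correction: str = "none") -> pd.DataFrame:
    """Build the comparison grid from tidy per-animal accuracies.

    ``accuracies`` needs columns layer, band, kind, task, animal, pre,
    post (accuracies in %).  Each (layer, band, kind, task) cell gets
    the per-animal deltas, their median, and — when the cohort is large
    enough for a meaningful exact test — the two-sided signed-rank
    p-value with significance stars at 0.05 and 0.01.  Cells with fewer
    animals report deltas only (p is NaN, never imputed).

    ``correction="bh"`` applies Benjamini-Hochberg across the grid's
    p-values; the default mirrors per-cell reporting with no correction.
    """
    required = {"layer", "band", "kind", "task", "animal", "pre", "post"}
    missing = required - set(accuracies.columns)
    if missing:
        raise ValueError(f"accuracies frame missing columns {sorted(missing)}")
    rows = []
    for (layer, band, kind, task), g in accuracies.groupby(
            ["layer", "band", "kind", "task"], sort=True):
        deltas = (g["post"] - g["pre"]).to_numpy(dtype=float)
        n = len(deltas)
        if n >= min_n_for_test and np.any(deltas != 0):
            w, p = wilcoxon_signed_rank(deltas)
        else:
            w, p = np.nan, np.nan
        rows.append({
            "layer": layer, "band": band, "kind": kind, "task": task,
            "n": n, "median_delta": float(np.median(deltas)),
            "statistic": w, "p_value": p,
        })
    out = pd.DataFrame(rows)
    if correction == "bh" and out["p_value"].notna().any():
        mask = out["p_value"].notna()
        out.loc[mask, "p_value"] = stats.false_discovery_control(
            out.loc[mask, "p_value"].to_numpy(), method="bh")
    elif correction not in ("none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    out["significant"] = out["p_value"] < 0.05
    out["stars"] = out["p_value"].map(lambda p: _stars(p) if pd.notna(p) else "")
    return out


def plot_delta_heatmap(grid: pd.DataFrame, *, kind: str, task: str, ax=None):
    """Layer x band heatmap of median deltas (red improvement, blue inhibition)."""
    import matplotlib.pyplot as plt

    sub = grid[(grid["kind"] == kind) & (grid["task"] == task)]
    pivot = sub.pivot(index="layer", columns="band", values="median_delta")
    if ax is None:
        _, ax = plt.subplots()
    vmax = max(1e-9, np.nanmax(np.abs(pivot.to_numpy())))
    im = ax.imshow(pivot.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns)
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.figure.colorbar(im, ax=ax, label="median Δaccuracy (pp)")
    ax.set_title(f"{kind} / {task}")
    return ax
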