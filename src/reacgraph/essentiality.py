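"""Joining externally produced reaction essentiality labels with
centrality and cascade results.

Essentiality labels come from constraint-based growth simulation
(a reaction is essential when its deletion drops the simulated growth
rate below 5% of wild type); producing them is outside this package —
it only consumes a ``reaction_id -> 0/1`` table.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cascade import CascadeResult

__all__ = [
    "EnrichmentReport",
    "read_labels",
    "topk_essential_proportion",
    "binned_essentiality",
    "cascade_essentiality_summary",
]


@dataclass
class EnrichmentReport:
    metric: str
    top_fraction: float
    n_top: int
    n_essential_in_top: int
    proportion_essential: float
    hypergeometric_p: float


def read_labels(path: str | os.PathLike) -> dict[str, bool]:
    """Read a ``reaction_id<TAB>{0,1}`` label file."""
    labels: dict[str, bool] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("reaction_id"):
                continue
            rid, _, flag = line.partition("\t")
            if flag not in {"0", "1"}:
                raise ValueError(f"{path}:{lineno}: label must be 0/1, got {flag!r}")
            labels[rid] = flag == "1"
    return labels


def _check_coverage(table: pd.DataFrame, labels: dict[str, bool]) -> pd.DataFrame:
    labeled = table[table["node"].isin(labels)]
    if len(labeled) < 0.5 * len(table):
        warnings.warn(
            f"labels cover only {len(labeled)}/{len(table)} nodes (<50%)"
        )
    return labeled


def topk_essential_proportion(
    table: pd.DataFrame,
    labels: dict[str, bool],
    metric: str,
    fraction: float = 0.05,
) -> EnrichmentReport:
    """Essential proportion among the top ``fraction`` of nodes by ``metric``.

    n_top = round(fraction x |V|); ties at the cutoff are broken by
    lexicographic node id so the report is deterministic.  The p-value is
    the hypergeometric upper tail for drawing that many essentials.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if metric not in table.columns:
        raise KeyError(metric)
    labeled = _check_coverage(table, labels)
    n_top = int(round(fraction * len(table)))
    n_top = max(n_top, 1)
    ranked = table.sort_values(
        [metric, "node"], ascending=[False, True], kind="mergesort"
    )
    top = ranked.head(n_top)["node"]
    n_ess_top = sum(bool(labels.get(n, False)) for n in top)
    population = len(labeled)
    n_ess_total = sum(bool(labels[n]) for n in labeled["node"])
    # upper tail P(X >= n_ess_top), X ~ Hypergeom(population, n_ess_total, n_top)
    p = float(stats.hypergeom.sf(n_ess_top - 1, population, n_ess_total, n_top))
    return EnrichmentReport(
        metric=metric,
        top_fraction=fraction,
        n_top=n_top,
        n_essential_in_top=n_ess_top,
        proportion_essential=n_ess_top / n_top,
        hypergeometric_p=min(p, 1.0),
    )


def binned_essentiality(
    table: pd.DataFrame,
    labels: dict[str, bool],
    metric: str,
    n_bins: int = 10,
    binning: str = "rank",
) -> pd.DataFrame:
    """Per-bin essential counts along a metric, for stacked-bar summaries.

    ``rank`` (default) splits the labeled nodes into equal-occupancy
    rank bins of the metric (deciles for n_bins=10); ``value`` uses
    equal-width bins on the metric value.  Returns columns bin,
    n_total, n_essential, percent_essential (NaN for an empty bin).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    labeled = _check_coverage(table, labels).copy()
    labeled["essential"] = [bool(labels[n]) for n in labeled["node"]]
    labeled = labeled.sort_values([metric, "node"], kind="mergesort")
    if binning == "rank":
        idx = np.arange(len(labeled))
        labeled["bin"] = (idx * n_bins) // max(len(labeled), 1)
    elif binning == "value":
        lo, hi = labeled[metric].min(), labeled[metric].max()
        width = (hi - lo) / n_bins or 1.0
        labeled["bin"] = np.minimum(
            ((labeled[metric] - lo) / width).astype(int), n_bins - 1
        )
    else:
        raise ValueError(f"unknown binning {binning!r}")
    rows = []
    for b in range(n_bins):
        sub = labeled[labeled["bin"] == b]
        n_tot = len(sub)
        n_ess = int(sub["essential"].sum())
        rows.append(
            {
                "bin": b,
                "n_total": n_tot,
                "n_essential": n_ess,
                "percent_essential": 100.0 * n_ess / n_tot if n_tot else np.nan,
            }
        )
    return pd.DataFrame(rows)


def cascade_essentiality_summary(
    cascades: dict[str, CascadeResult],
    labels: dict[str, bool],
    pool_at: int = 7,
) -> tuple[pd.DataFrame, float]:
    """Essential proportion of leading cascade nodes per cascade number.

    Leading nodes are binned by cascade number 0..pool_at-1 with
    >= pool_at pooled.  Returns the per-bin table and the Pearson
    correlation between the bin's cascade-number value (the pooled bin
    contributes ``pool_at``) and its percent essential, over non-empty
    bins.
    """
    leading = [r for r in cascades.values() if r.independent and r.node in labels]
    rows = []
    for r_val in range(pool_at + 1):
        if r_val < pool_at:
            members = [c for c in leading if c.cascade_number == r_val]
        else:
            members = [c for c in leading if c.cascade_number >= pool_at]
        n_tot = len(members)
        n_ess = sum(bool(labels[c.node]) for c in members)
        rows.append(
            {
                "cascade_number": r_val,
                "n_leading": n_tot,
                "n_essential": n_ess,
                "percent_essential": 100.0 * n_ess / n_tot if n_tot else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    filled = df.dropna(subset=["percent_essential"])
    if filled.empty:
        raise ValueError("no leading cascade node carries a label")
    if len(filled) < 2 or filled["percent_essential"].nunique() == 1:
        r = 0.0
    else:
        r = float(
            np.corrcoef(filled["cascade_number"], filled["percent_essential"])[0, 1]
        )
    return df, r
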