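"""Characterize classifier-selected edges: signed weighted degrees per region,
intra/inter-network categorization with standardized percentages, and
edge–clinical correlations in the patient group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import NETWORKS, RegionAtlas, edge_endpoints, possible_edge_counts
from .mvpa import SelectedEdgeSet
from .univariate import bh_fdr_mask


def weighted_degree(
    selected: SelectedEdgeSet, atlas: RegionAtlas, absolute: bool = False
) -> pd.DataFrame:
    """Per-region sums of positive and negative weights of incident selected edges.

    Regions are flagged when their positive degree exceeds mean + SD
    (and mean + 2 SD) of the positive degrees over all regions, and when their
    negative degree falls below mean - SD (mean - 2 SD); means and SDs are
    taken over all regions, zeros included.  With ``absolute`` the thresholds
    for the negative side are applied on magnitudes instead of signed values.

    The conservation identity holds exactly: the positive degrees sum to twice
    the sum of positive edge weights (each edge counts at both endpoints).
    """
    n = atlas.n_regions
    ii, jj = edge_endpoints(n)
    pos = np.zeros(n)
    neg = np.zeros(n)
    for e, w in zip(selected.edges, selected.weights):
        if w > 0:
            pos[ii[e]] += w
            pos[jj[e]] += w
        elif w < 0:
            neg[ii[e]] += w
            neg[jj[e]] += w

    pm, psd = pos.mean(), pos.std(ddof=0)
    nv = np.abs(neg) if absolute else neg
    nm, nsd = nv.mean(), nv.std(ddof=0)
    if absolute:
        neg_1sd, neg_2sd = nv > nm + nsd, nv > nm + 2 * nsd
    else:
        neg_1sd, neg_2sd = nv < nm - nsd, nv < nm - 2 * nsd
    return pd.DataFrame(
        {
            "region": atlas.labels,
            "network": atlas.networks,
            "positive_degree": pos,
            "negative_degree": neg,
            "pos_above_mean_1sd": pos > pm + psd,
            "pos_above_mean_2sd": pos > pm + 2 * psd,
            "neg_below_mean_1sd": neg_1sd,
            "neg_below_mean_2sd": neg_2sd,
        }
    )


@dataclass
class NetworkFCSummary:
    """Intra/inter-network counts of selected edges with standardized percentages.

    ``count``, ``possible`` and ``percent`` are symmetric 6x6 tables over the
    functional networks; ``percent`` standardizes each cell's selected-edge
    count by the number of region pairs that could fall in that cell
    (100 * count / possible).  ``mean_intra_pct`` pools the diagonal
    (100 * total intra count / total possible intra pairs) and
    ``mean_inter_pct`` pools the off-diagonal cells.
    """

    count: pd.DataFrame
    possible: pd.DataFrame
    percent: pd.DataFrame
    intra_total: int
    inter_total: int
    mean_intra_pct: float
    mean_inter_pct: float


def network_summary(edges: SelectedEdgeSet | np.ndarray, atlas: RegionAtlas) -> NetworkFCSummary:
    """Classify selected edges by their endpoints' networks and standardize counts."""
    idx = edges.edges if isinstance(edges, SelectedEdgeSet) else np.asarray(edges, dtype=int)
    nets = atlas.networks
    ii, jj = edge_endpoints(atlas.n_regions)
    count = pd.DataFrame(0, index=list(NETWORKS), columns=list(NETWORKS), dtype=int)
    for e in idx:
        a, b = nets[ii[e]], nets[jj[e]]
        count.loc[a, b] += 1
        if a != b:
            count.loc[b, a] += 1
    possible = possible_edge_counts(atlas)
    percent = 100.0 * count / possible

    diag = np.diag(count.to_numpy())
    intra_total = int(diag.sum())
    inter_total = int(idx.size - intra_total)
    possible_diag = np.diag(possible.to_numpy())
    intra_possible = int(possible_diag.sum())
    inter_possible = atlas.n_edges - intra_possible
    return NetworkFCSummary(
        count=count,
        possible=possible,
        percent=percent,
        intra_total=intra_total,
        inter_total=inter_total,
        mean_intra_pct=100.0 * intra_total / intra_possible,
        mean_inter_pct=100.0 * inter_total / inter_possible,
    )


def clinical_correlation(
    selected: SelectedEdgeSet | np.ndarray,
    patient_edges: np.ndarray,
    patient_table: pd.DataFrame,
    variables: tuple[str, ...] = ("ahi", "pct_tst_below_90"),
    alpha: float = 0.005,
    edge_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each selected edge with each clinical variable.

    Computed within the patient group only.  Significance is flagged at the
    uncorrected ``alpha`` (the convention for this analysis at small n); BH-FDR
    q-style rejection flags are included as a supplementary column for reuse at
    a corrected level.
    """
    idx = selected.edges if isinstance(selected, SelectedEdgeSet) else np.asarray(selected, dtype=int)
    x = np.asarray(patient_edges, dtype=float)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 patients for correlation analysis")
    rows = []
    for v in variables:
        if v not in patient_table.columns:
            raise ValueError(f"clinical variable {v!r} missing from patient table")
        c = patient_table[v].to_numpy(float)
        const = np.std(c) == 0
        for e in idx:
            if const:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x[:, e], c)
            rows.append(
                {
                    "edge": e,
                    "edge_label": edge_labels[e] if edge_labels else str(e),
                    "variable": v,
                    "r": r,
                    "p": p,
                    "n": x.shape[0],
                    "constant_variable": const,
                }
            )
    df = pd.DataFrame(rows)
    df["significant"] = (df["p"] < alpha).fillna(False)
    df["fdr_significant"] = bh_fdr_mask(df["p"].to_numpy(), 0.05)
    return df
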