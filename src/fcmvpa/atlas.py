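"""AAL-90 cerebral parcellation, functional-network membership and canonical edge indexing.

The package works on region-pair ("edge") features of a 90-region cortical and
subcortical parcellation.  Each region belongs to exactly one of six resting-state
functional networks:

* VN  — visual network
* SMN — somatomotor network
* AN  — attention network (dorsal and ventral attention merged)
* FPN — frontoparietal network
* LS  — limbic system
* DMN — default mode network

Edges (unordered region pairs) are stored in a single canonical order shared by all
modules: the row-major upper triangle of the 90x90 matrix, giving
E = 90*89/2 = 4005 edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NETWORKS: tuple[str, ...] = ("VN", "SMN", "AN", "FPN", "LS", "DMN")

# Bilateral region codes in AAL numerical order (odd index = left, even = right),
# with the functional network each code belongs to.  The inferior temporal gyrus
# is the one laterality-split assignment: ITG.R sits in the attention network,
# ITG.L in the default mode network.
_AAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("PreCG", "SMN"),
    ("SFG", "DMN"),
    ("SFGorb", "LS"),
    ("MFG", "FPN"),
    ("MFGorb", "FPN"),
    ("IFGoper", "FPN"),
    ("IFGtri", "FPN"),
    ("IFGorb", "DMN"),
    ("ROL", "SMN"),
    ("SMA", "AN"),
    ("OLF", "LS"),
    ("SFGmed", "DMN"),
    ("SFGmorb", "DMN"),
    ("REC", "LS"),
    ("INS", "AN"),
    ("ACG", "DMN"),
    ("MCG", "AN"),
    ("PCG", "DMN"),
    ("HIP", "DMN"),
    ("PHG", "DMN"),
    ("AMYG", "LS"),
    ("CAL", "VN"),
    ("CUN", "VN"),
    ("LING", "VN"),
    ("SOG", "VN"),
    ("MOG", "VN"),
    ("IOG", "VN"),
    ("FFG", "VN"),
    ("PoCG", "SMN"),
    ("SPG", "AN"),
    ("IPL", "FPN"),
    ("SMG", "AN"),
    ("ANG", "DMN"),
    ("PCUN", "DMN"),
    ("PCL", "SMN"),
    ("CAU", "LS"),
    ("PUT", "AN"),
    ("PAL", "AN"),
    ("THA", "LS"),
    ("HES", "SMN"),
    ("STG", "SMN"),
    ("TPOsup", "LS"),
    ("MTG", "DMN"),
    ("TPOmid", "LS"),
    ("ITG", None),  # split: left -> DMN, right -> AN
)


@dataclass(frozen=True)
class Region:
    """One parcellation region."""

    index: int  # 0-based position in AAL order
    label: str  # e.g. "PHG.L"
    hemisphere: str  # "L" or "R"
    network: str  # one of NETWORKS


class RegionAtlas:
    """Ordered collection of parcellation regions with network membership.

    Parameters
    ----------
    regions
        Regions in canonical order; indices must be 0..n-1 consecutive and
        labels unique.
    """

    def __init__(self, regions: Sequence[Region]):
        regions = tuple(regions)
        labels = [r.label for r in regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        for pos, r in enumerate(regions):
            if r.index != pos:
                raise ValueError(f"region {r.label!r} has index {r.index}, expected {pos}")
            if r.network not in NETWORKS:
                raise ValueError(f"unknown network {r.network!r} for region {r.label!r}")
            if r.hemisphere not in ("L", "R"):
                raise ValueError(f"hemisphere must be 'L' or 'R', got {r.hemisphere!r}")
        self.regions = regions
        self._label_to_index = {r.label: r.index for r in regions}

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_regions)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regions]

    @property
    def networks(self) -> np.ndarray:
        """Array of network names, one per region, in region order."""
        return np.array([r.network for r in self.regions])

    def index_of(self, label: str) -> int:
        return self._label_to_index[label]

    def network_members(self, network: str) -> list[Region]:
        if network not in NETWORKS:
            raise ValueError(f"unknown network {network!r}")
        return [r for r in self.regions if r.network == network]

    def network_sizes(self) -> dict[str, int]:
        return {net: len(self.network_members(net)) for net in NETWORKS}

    def edge_labels(self) -> list[str]:
        """Canonical-order edge names 'label_i—label_j' (i < j)."""
        lab = self.labels
        n = self.n_regions
        return [f"{lab[i]}—{lab[j]}" for i, j in iter_edges(n)]

    # -- TSV round trip ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [r.index for r in self.regions],
                "label": [r.label for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
                "network": [r.network for r in self.regions],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionAtlas":
        required = {"index", "label", "hemisphere", "network"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        df = df.sort_values("index")
        regions = [
            Region(int(row["index"]), str(row["label"]), str(row["hemisphere"]), str(row["network"]))
            for _, row in df.iterrows()
        ]
        return cls(regions)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionAtlas":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sizes = ", ".join(f"{k}={v}" for k, v in self.network_sizes().items())
        return f"RegionAtlas(n_regions={self.n_regions}; {sizes})"


def build_default_atlas() -> RegionAtlas:
    """Build the default 90-region atlas with its six-network assignment.

    Every bilateral code expands to a left (odd AAL number) and right (even)
    region; the inferior temporal gyrus splits by hemisphere (ITG.L in DMN,
    ITG.R in AN).  Network sizes after expansion: VN 14, SMN 12, AN 15,
    FPN 10, LS 16, DMN 23.
    """
    regions: list[Region] = []
    for code, network in _AAL_PAIRS:
        for hemi in ("L", "R"):
            if code == "ITG":
                net = "DMN" if hemi == "L" else "AN"
            else:
                net = network
            regions.append(Region(len(regions), f"{code}.{hemi}", hemi, net))
    return RegionAtlas(regions)


# -- canonical edge indexing ----------------------------------------------


def n_edges(n: int) -> int:
    """Number of unordered region pairs among ``n`` regions."""
    return n * (n - 1) // 2


def edge_index(i: int, j: int, n: int) -> int:
    """Canonical edge index of the unordered pair (i, j) among n regions.

    Row-major upper-triangle order: (0,1), (0,2), ..., (0,n-1), (1,2), ...
    Symmetric in its first two arguments.
    """
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"region indices must be in [0, {n}), got ({i}, {j})")
    if i == j:
        raise ValueError("an edge joins two distinct regions")
    if i > j:
        i, j = j, i
    return i * (2 * n - i - 1) // 2 + (j - i - 1)


def pair_of(k: int, n: int) -> tuple[int, int]:
    """Inverse of :func:`edge_index`: the (i, j) pair, i < j, at position k."""
    if not (0 <= k < n_edges(n)):
        raise ValueError(f"edge index must be in [0, {n_edges(n)}), got {k}")
    # Solve for the row: the first index i whose block still contains k.
    i = int(n - 2 - np.floor(np.sqrt(-8 * k + 4 * n * (n - 1) - 7) / 2.0 - 0.5))
    j = k + i + 1 - i * (2 * n - i - 1) // 2
    return i, j


def iter_edges(n: int) -> Iterable[tuple[int, int]]:
    """Yield all (i, j), i < j, in canonical order."""
    for i in range(n - 1):
        for j in range(i + 1, n):
            yield i, j


def edge_endpoints(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized endpoints of all edges in canonical order (matches numpy triu)."""
    return np.triu_indices(n, k=1)


def edges_among(region_indices: Sequence[int], n: int) -> np.ndarray:
    """Canonical edge indices of all pairs within a region subset.

    Useful for planting clique-structured effects or counting within-network
    pairs.  Returned in canonical (ascending) order.
    """
    idx = sorted(set(int(r) for r in region_indices))
    out = [edge_index(a, b, n) for p, a in enumerate(idx) for b in idx[p + 1 :]]
    return np.array(sorted(out), dtype=int)


def possible_edge_counts(atlas: RegionAtlas) -> pd.DataFrame:
    """Count region pairs per (network, network) cell.

    Returns a symmetric 6x6 table (NETWORKS order); the diagonal holds the
    within-network pair counts C(size, 2) and each off-diagonal cell the
    product of the two network sizes.  All cells sum to n_edges.
    """
    sizes = atlas.network_sizes()
    table = pd.DataFrame(0, index=list(NETWORKS), columns=list(NETWORKS), dtype=int)
    for a in NETWORKS:
        for b in NETWORKS:
            if a == b:
                table.loc[a, b] = sizes[a] * (sizes[a] - 1) // 2
            else:
                table.loc[a, b] = sizes[a] * sizes[b]
    return table


def edge_networks(atlas: RegionAtlas) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge endpoint networks (two arrays of network names, canonical order)."""
    nets = atlas.networks
    ii, jj = edge_endpoints(atlas.n_regions)
    return nets[ii], nets[jj]
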