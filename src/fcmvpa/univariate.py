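"""Edgewise two-sample statistics with Bonferroni, BH-FDR and network-based-statistic
(NBS) corrections, plus group comparison of clinical variables.

All edgewise tests are pooled-variance (Student) two-sample t-tests with
nA + nB - 2 degrees of freedom, the convention of the common connectome
toolboxes; the sign convention is t > 0 when group A (controls, by pipeline
convention) has the larger mean.

NBS performs cluster-level inference on the region graph: edges passing a
cluster-defining t threshold are split by contrast direction, connected
components are formed per direction, and each observed component's extent
(edge count) is compared with a permutation null of the maximal extent over
both directions under group-label exchange.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .atlas import edge_endpoints
from .simulate import CLINICAL_VARIABLES, SubjectRecord


# -- pooled two-sample t ---------------------------------------------------

def _pooled_t_from_moments(sa, ssa, na, sb, ssb, nb):
    """Vectorized pooled-variance t from per-group sums and sums of squares.

    Returns (t, df, valid) where valid flags edges with positive pooled
    variance; t is NaN where invalid.
    """
    ma, mb = sa / na, sb / nb
    va = (ssa - na * ma**2) / (na - 1)
    vb = (ssb - nb * mb**2) / (nb - 1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    sp2 = np.maximum(sp2, 0.0)  # guard fp cancellation
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    valid = se > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(valid, (ma - mb) / np.where(valid, se, 1.0), np.nan)
    return t, df, valid


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled two-sample t and two-tailed p along axis 0.

    ``a`` and ``b`` are (n_subjects, n_features) arrays (1-D allowed).
    Positive t means mean(a) > mean(b).  Features with zero pooled variance
    get t = NaN, p = NaN and valid = False.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(b, dtype=float).T).T
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, df, valid = _pooled_t_from_moments(
        a.sum(0), (a**2).sum(0), a.shape[0], b.sum(0), (b**2).sum(0), b.shape[0]
    )
    p = np.where(valid, 2 * stats.t.sf(np.abs(t), df), np.nan)
    return t, p, valid


def two_sample_t_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float]:
    """Pooled two-sample t and two-tailed p from group summary statistics.

    Lets published group means/SDs (e.g. a demographics table) be re-tested
    without subject-level data.
    """
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    se = math.sqrt(sp2 * (1 / n_a + 1 / n_b))
    t = (mean_a - mean_b) / se
    return t, 2 * stats.t.sf(abs(t), df)


# -- multiple-comparison masks --------------------------------------------

def bonferroni_mask(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni significance mask: p * m < alpha over the m finite p-values."""
    p = np.asarray(p, dtype=float)
    m = int(np.isfinite(p).sum())
    out = np.zeros(p.shape, dtype=bool)
    if m:
        out[np.isfinite(p)] = p[np.isfinite(p)] * m < alpha
    return out


def bh_fdr_mask(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up mask at FDR level q (NaNs excluded)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    out = np.zeros(p.shape, dtype=bool)
    if finite.any():
        out[finite] = multipletests(p[finite], alpha=q, method="fdr_bh")[0]
    return out


@dataclass
class UnivariateResult:
    """Edgewise group comparison with correction masks."""

    t: np.ndarray
    p: np.ndarray
    valid: np.ndarray
    alpha: float = 0.05
    q: float = 0.05
    bonferroni: np.ndarray = field(init=False)
    fdr: np.ndarray = field(init=False)

    def __post_init__(self):
        self.bonferroni = bonferroni_mask(self.p, self.alpha) & self.valid
        self.fdr = bh_fdr_mask(self.p, self.q) & self.valid

    def to_frame(self, edge_labels: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t": self.t,
                "p": self.p,
                "valid": self.valid,
                "bonferroni": self.bonferroni,
                "fdr": self.fdr,
            }
        )
        if edge_labels is not None:
            df.insert(0, "edge", edge_labels)
        return df


def edgewise_ttest(
    edges_a: np.ndarray, edges_b: np.ndarray, alpha: float = 0.05, q: float = 0.05
) -> UnivariateResult:
    """Independent pooled t-test at every edge; A is the control group by convention."""
    t, p, valid = two_sample_t(edges_a, edges_b)
    return UnivariateResult(t=t, p=p, valid=valid, alpha=alpha, q=q)


# -- network-based statistic ----------------------------------------------

@dataclass
class NBSComponent:
    direction: str  # "A>B" or "B>A"
    edges: np.ndarray  # canonical edge indices
    extent: int
    p_corrected: float


@dataclass
class NBSResult:
    components: list[NBSComponent]
    cdt_p: float
    t_threshold: float
    n_perm: int
    null_max_extent: np.ndarray
    seed: int | None
    exact: bool = False

    @property
    def min_p(self) -> float:
        return min((c.p_corrected for c in self.components), default=1.0)

    def significant(self, alpha: float = 0.05) -> list[NBSComponent]:
        return [c for c in self.components if c.p_corrected < alpha]


def _components_max_extent(sup: np.ndarray, ii, jj, n_regions: int) -> int:
    """Max connected-component extent (edge count) of a suprathreshold edge mask."""
    best = 0
    for direction_mask in sup:
        if not direction_mask.any():
            continue
        best = max(best, max(c.extent for c in _components(direction_mask, ii, jj, n_regions)))
    return best


def _components(mask: np.ndarray, ii, jj, n_regions: int, direction: str = "") -> list[NBSComponent]:
    """Connected components of the graph formed by the masked edges."""
    ei, ej = ii[mask], jj[mask]
    eidx = np.flatnonzero(mask)
    adj = sparse.coo_matrix(
        (np.ones(ei.size), (ei, ej)), shape=(n_regions, n_regions)
    )
    _, labels = connected_components(adj, directed=False)
    comp_of_edge = labels[ei]  # both endpoints share a label by construction
    out = []
    for lab in np.unique(comp_of_edge):
        edges = eidx[comp_of_edge == lab]
        out.append(NBSComponent(direction=direction, edges=edges, extent=edges.size, p_corrected=np.nan))
    return out


def nbs(
    edges_a: np.ndarray,
    edges_b: np.ndarray,
    n_regions: int,
    cdt_p: float = 0.001,
    n_perm: int = 10000,
    seed: int | None = None,
    exact: bool = False,
) -> NBSResult:
    """Network-based statistic for a two-group edgewise comparison.

    Parameters
    ----------
    edges_a, edges_b
        (n_subjects, n_edges) Fisher-z edge matrices for the two groups.
    n_regions
        Region count; edge columns must follow the canonical order.
    cdt_p
        Two-tailed cluster-defining p threshold on the edgewise t
        (each direction is thresholded one-tailed at cdt_p / 2).
    n_perm
        Number of group-label permutations for the null of the maximal
        component extent.  Ignored when ``exact`` is set.
    exact
        Enumerate all label assignments instead of sampling (feasible for
        small cohorts only); corrected p-values are then exact.

    Notes
    -----
    Components are scored by extent (edge count); corrected p is the
    proportion of null maxima >= the observed extent, floored at 1/n_perm.
    An empty component list is a valid null outcome, not an error.
    """
    a = np.asarray(edges_a, dtype=float)
    b = np.asarray(edges_b, dtype=float)
    na, nb = a.shape[0], b.shape[0]
    if not exact and n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    x = np.vstack([a, b])
    n, e = x.shape
    ii, jj = edge_endpoints(n_regions)
    if ii.size != e:
        raise ValueError(f"edge count {e} does not match n_regions={n_regions}")

    df = na + nb - 2
    t_thr = stats.t.isf(cdt_p / 2, df)

    x2 = x**2
    tot_s, tot_ss = x.sum(0), x2.sum(0)

    def t_for_selection(sel: np.ndarray) -> np.ndarray:
        """Pooled t for a boolean (n_draws, n) selection matrix of pseudo-A rows."""
        sa = sel @ x
        ssa = sel @ x2
        nb_ = n - na
        t, _, valid = _pooled_t_from_moments(sa, ssa, na, tot_s - sa, tot_ss - ssa, nb_)
        t[~valid] = 0.0
        return t

    obs_t = t_for_selection(np.arange(n)[None, :] < na)[0]
    sup_pos = obs_t > t_thr
    sup_neg = obs_t < -t_thr

    comps = _components(sup_pos, ii, jj, n_regions, "A>B") + _components(
        sup_neg, ii, jj, n_regions, "B>A"
    )

    if exact:
        draws = np.array(
            [np.isin(np.arange(n), c) for c in combinations(range(n), na)], dtype=float
        )
        n_draws = draws.shape[0]
    else:
        rng = np.random.default_rng(seed)
        draws = np.zeros((n_perm, n))
        for k in range(n_perm):
            draws[k, rng.permutation(n)[:na]] = 1.0
        n_draws = n_perm

    null_max = np.zeros(n_draws, dtype=int)
    chunk = max(1, int(2e7) // max(e, 1))  # bound memory of the t matrix
    for start in range(0, n_draws, chunk):
        t_chunk = t_for_selection(draws[start : start + chunk])
        sup = np.stack([t_chunk > t_thr, t_chunk < -t_thr], axis=1)
        for k in range(t_chunk.shape[0]):
            null_max[start + k] = _components_max_extent(sup[k], ii, jj, n_regions)

    for c in comps:
        exceed = int((null_max >= c.extent).sum())
        c.p_corrected = max(exceed, 1) / n_draws

    return NBSResult(
        components=sorted(comps, key=lambda c: -c.extent),
        cdt_p=cdt_p,
        t_threshold=float(t_thr),
        n_perm=n_draws,
        null_max_extent=null_max,
        seed=seed,
        exact=exact,
    )


# -- demographics ----------------------------------------------------------

def demographics_table(subjects: list[SubjectRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-variable group means/SDs and pooled two-sample t-tests.

    Missing values are excluded pairwise per variable; the counts used are
    reported.  Rows follow the clinical-variable schema.
    """
    if not isinstance(subjects, pd.DataFrame):
        subjects = pd.DataFrame([vars(s) for s in subjects])
    for g in ("OSA", "HC"):
        if not (subjects["group"] == g).any():
            raise ValueError(f"group {g!r} is empty")
    rows = []
    for v in CLINICAL_VARIABLES:
        osa = subjects.loc[subjects["group"] == "OSA", v].dropna().to_numpy(float)
        hc = subjects.loc[subjects["group"] == "HC", v].dropna().to_numpy(float)
        t, p, _ = two_sample_t(osa, hc)
        rows.append(
            {
                "variable": v,
                "osa_mean": osa.mean(),
                "osa_sd": osa.std(ddof=1),
                "osa_n": osa.size,
                "hc_mean": hc.mean(),
                "hc_sd": hc.std(ddof=1),
                "hc_n": hc.size,
                "t": float(t[0]),
                "p": float(p[0]),
            }
        )
    return pd.DataFrame(rows)
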