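"""Region time series -> Pearson correlation matrices -> Fisher-z edge vectors.

Functional connectivity between two regions is the Pearson correlation of their
time series.  The full per-subject result is a symmetric R x R matrix with unit
diagonal; downstream statistics operate on the Fisher r-to-z transformed upper
triangle laid out in the canonical edge order of :mod:`fcmvpa.atlas`.
"""

from __future__ import annotations

import numpy as np

from .atlas import edge_endpoints

# Exact collinearity (|r| = 1) only arises in constructed data; the synthetic
# path may clip to this bound before arctanh, the real-data path must error.
_CLIP = 1.0 - 1e-12


def compute_fc(ts: np.ndarray, labels: list[str] | None = None) -> np.ndarray:
    """Pearson correlation matrix of a T x R time-series array.

    Parameters
    ----------
    ts
        Time series, rows are time points, columns are regions.
    labels
        Optional region names used in error messages.

    Returns
    -------
    R x R symmetric correlation matrix with diagonal exactly 1.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D (timepoints x regions) array")
    t, r = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        name = labels[bad] if labels is not None else f"column {bad}"
        raise ValueError(f"zero-variance time series for region {name}")
    fc = np.corrcoef(ts, rowvar=False)
    fc = np.clip(fc, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return fc


def fisher_z(r, clip: bool = False):
    """Fisher r-to-z transform, z = arctanh(r) = 0.5 * ln((1+r)/(1-r)).

    Strictly increasing and odd.  Requires |r| < 1 unless ``clip`` is set, in
    which case values at or beyond the bound are pulled just inside it (only
    appropriate for constructed data with exact collinearity).
    """
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -_CLIP, _CLIP)
    elif np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1; exclude the diagonal / perfect correlations")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def vectorize(fc: np.ndarray, clip: bool = False) -> np.ndarray:
    """Fisher-z edge vector of a correlation matrix, canonical edge order.

    The diagonal is excluded (arctanh(1) is undefined); the result has length
    R*(R-1)/2.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError("FC matrix must be square")
    if not np.allclose(fc, fc.T, atol=1e-10):
        raise ValueError("FC matrix must be symmetric")
    ii, jj = edge_endpoints(fc.shape[0])
    return fisher_z(fc[ii, jj], clip=clip)


def unvectorize(z: np.ndarray, n: int) -> np.ndarray:
    """Rebuild a correlation matrix from a Fisher-z edge vector (inverse plumbing)."""
    z = np.asarray(z, dtype=float)
    ii, jj = edge_endpoints(n)
    if z.shape != ii.shape:
        raise ValueError(f"expected {ii.size} edge values for n={n}, got {z.size}")
    fc = np.eye(n)
    fc[ii, jj] = fc[jj, ii] = np.tanh(z)
    return fc


def cohort_edge_matrix(series: list[np.ndarray], clip: bool = False) -> np.ndarray:
    """Stack per-subject Fisher-z edge vectors into a subjects x edges matrix."""
    return np.vstack([vectorize(compute_fc(ts), clip=clip) for ts in series])
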