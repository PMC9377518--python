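"""Synthetic two-group cohorts of region time series with planted FC effects.

The generator draws each subject's T x R time series from a group-specific
multivariate-Gaussian spatial correlation structure, optionally AR(1)-smoothed
in time, and produces a matching clinical table.  The control-group population
correlation is a network block structure (rho_in within each functional
network, rho_out elsewhere); the patient group differs by a correlation shift
planted on a designated edge subset.  Clinical variables can be tied to
designated edges with a target correlation, giving downstream correlation
analyses a known ground truth.

Shifted block matrices are not automatically valid correlation matrices, so the
patient matrix is repaired by projection to the nearest correlation matrix; a
spec whose repair erodes any planted effect by more than half its size is
rejected rather than silently weakened.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import warnings

import numpy as np
from scipy import signal
from statsmodels.stats.correlation_tools import corr_nearest
from statsmodels.tools.sm_exceptions import IterationLimitWarning


def _nearest_corr(mat: np.ndarray, n_fact: int) -> np.ndarray:
    """Nearest-correlation projection; repair quality is checked by the caller,
    so the projector's own iteration-limit warning is redundant noise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IterationLimitWarning)
        return corr_nearest(mat, threshold=1e-8, n_fact=n_fact)

from .atlas import RegionAtlas, build_default_atlas, edge_endpoints, n_edges
from .connectivity import compute_fc, fisher_z

CLINICAL_VARIABLES = ("age", "education", "bmi", "mmse", "ahi", "pct_tst_below_90", "ess")

# Marginal means/SDs per group and plausible hard ranges used for clipping.
# Values mirror a moderate-to-severe middle-aged male OSA cohort and matched
# controls (AHI >= 15 events/h for patients, < 5 for controls).
_MARGINALS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    # name: {group: (mean, sd, lo, hi)}
    "age": {"OSA": (44.0, 7.3, 25, 70), "HC": (40.6, 11.4, 25, 70)},
    "education": {"OSA": (13.5, 3.1, 6, 22), "HC": (14.8, 2.9, 6, 22)},
    "bmi": {"OSA": (29.5, 4.2, 18, 45), "HC": (25.0, 3.2, 18, 45)},
    "mmse": {"OSA": (29.5, 0.8, 24, 30), "HC": (29.9, 0.36, 24, 30)},
    "ahi": {"OSA": (54.4, 20.0, 15, 120), "HC": (2.5, 1.4, 0, 4.99)},
    "pct_tst_below_90": {"OSA": (18.7, 21.1, 0, 100), "HC": (1.0, 2.7, 0, 100)},
    "ess": {"OSA": (14.7, 7.3, 0, 24), "HC": (1.1, 1.1, 0, 24)},
}


@dataclass(frozen=True)
class ClinicalLink:
    """Tie a clinical variable to a planted edge at a target correlation."""

    edge: int
    variable: str
    r: float

    def __post_init__(self):
        if self.variable not in CLINICAL_VARIABLES:
            raise ValueError(f"unknown clinical variable {self.variable!r}")
        if not -1 < self.r < 1:
            raise ValueError("target correlation must be in (-1, 1)")


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the cohort clinical table."""

    id: str
    group: str  # "OSA" or "HC"
    age: float
    education: float
    bmi: float
    mmse: float
    ahi: float
    pct_tst_below_90: float
    ess: float

    def __post_init__(self):
        if self.group not in ("OSA", "HC"):
            raise ValueError(f"group must be 'OSA' or 'HC', got {self.group!r}")
        if self.mmse > 30 or self.ess > 24 or self.ahi < 0:
            raise ValueError("clinical value out of range")
        if not (0 <= self.pct_tst_below_90 <= 100):
            raise ValueError("pct_tst_below_90 must be a percentage in [0, 100]")


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults reproduce the study conditions this package targets: 21 subjects
    per group, 90 regions, 170 retained volumes per subject, and mildly
    autocorrelated (AR(1) = 0.3) band-pass-like noise.
    """

    n_per_group: int = 21
    n_regions: int = 90
    n_timepoints: int = 170
    rho_in: float = 0.3
    rho_out: float = 0.1
    effect_edges: Sequence[int] = field(default_factory=tuple)
    effect_delta: float = 0.0
    ar1_coefficient: float = 0.3
    clinical_links: Sequence[ClinicalLink] = field(default_factory=tuple)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        if not (0 <= self.ar1_coefficient < 1):
            raise ValueError("ar1_coefficient must be in [0, 1)")
        if not (-1 < self.rho_out <= self.rho_in < 1 and self.rho_in >= 0):
            raise ValueError("require 0 <= rho_out <= rho_in < 1 for a valid block structure")
        e = n_edges(self.n_regions)
        for k in self.effect_edges:
            if not 0 <= int(k) < e:
                raise ValueError(f"effect edge {k} out of range for {e} edges")
        for link in self.clinical_links:
            if not 0 <= link.edge < e:
                raise ValueError(f"clinical link edge {link.edge} out of range")


def _membership(spec: CohortSpec) -> np.ndarray:
    """Region -> block labels used for the control-group block structure.

    At 90 regions the six-network atlas assignment is used; at other sizes
    regions are split into two contiguous blocks so small test cohorts still
    have within/between-block structure.
    """
    if spec.n_regions == 90:
        atlas = build_default_atlas()
        nets = atlas.networks
        codes = {net: i for i, net in enumerate(dict.fromkeys(nets))}
        return np.array([codes[x] for x in nets])
    half = spec.n_regions // 2
    return np.array([0] * half + [1] * (spec.n_regions - half))


def make_group_covariances(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Population correlation matrices for (control, patient) groups.

    The control matrix is the block structure; the patient matrix adds
    ``effect_delta`` on ``effect_edges`` and is then projected to the nearest
    valid correlation matrix.

    Returns
    -------
    (corr_hc, corr_osa, achieved_deltas)
        ``achieved_deltas`` are the patient-minus-control differences actually
        realized on the effect edges after repair.

    Raises
    ------
    ValueError
        If repair moved any planted effect by more than half of
        ``effect_delta`` — the requested effect is then not honestly
        realizable and the spec must change.
    """
    spec.validate()
    m = _membership(spec)
    same = m[:, None] == m[None, :]
    hc = np.where(same, spec.rho_in, spec.rho_out).astype(float)
    np.fill_diagonal(hc, 1.0)

    min_eig = np.linalg.eigvalsh(hc)[0]
    if min_eig <= 1e-10:
        hc = _nearest_corr(hc, n_fact=50)

    effect = np.asarray(spec.effect_edges, dtype=int)
    osa = hc.copy()
    if effect.size and spec.effect_delta != 0.0:
        ii, jj = edge_endpoints(spec.n_regions)
        osa[ii[effect], jj[effect]] += spec.effect_delta
        osa[jj[effect], ii[effect]] += spec.effect_delta
        if np.any(np.abs(osa) > 1):
            raise ValueError("effect_delta pushes a correlation outside [-1, 1]")
        if np.linalg.eigvalsh(osa)[0] <= 1e-10:
            osa = _nearest_corr(osa, n_fact=50)
        achieved = osa[ii[effect], jj[effect]] - hc[ii[effect], jj[effect]]
        worst = np.max(np.abs(achieved - spec.effect_delta))
        if worst > abs(spec.effect_delta) / 2:
            raise ValueError(
                "correlation-matrix repair eroded a planted effect by "
                f"{worst:.3f} (> half of effect_delta={spec.effect_delta}); "
                "choose fewer/structured effect edges or a smaller delta"
            )
    else:
        achieved = np.zeros(effect.size)

    for mat in (hc, osa):
        np.fill_diagonal(mat, 1.0)
    return hc, osa, achieved


def _factor(mat: np.ndarray) -> np.ndarray:
    """Cholesky factor, with an eigenvalue-floor fallback for repaired
    matrices sitting numerically on the positive-semidefinite boundary."""
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(mat)
        vals = np.maximum(vals, 1e-10)
        return vecs * np.sqrt(vals)


def _ar1_noise(rng: np.random.Generator, t: int, r: int, phi: float) -> np.ndarray:
    """Unit-variance AR(1) innovations, independent across columns."""
    eps = rng.standard_normal((t + 50, r))
    if phi == 0.0:
        return eps[50:]
    x = signal.lfilter([np.sqrt(1 - phi**2)], [1.0, -phi], eps, axis=0)
    return x[50:]  # burn-in leaves the series at its stationary distribution


def sample_cohort(spec: CohortSpec) -> tuple[list[np.ndarray], list[SubjectRecord]]:
    """Draw a full cohort: per-subject time series plus clinical table.

    Controls come first (ids HC01..), then patients (OSA01..).  The spatial
    correlation is imposed after temporal AR(1) filtering, so the population
    FC equals the group correlation matrix regardless of the autocorrelation.
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    hc, osa, _ = make_group_covariances(spec)
    chol = {"HC": _factor(hc), "OSA": _factor(osa)}

    series: list[np.ndarray] = []
    groups: list[str] = []
    for group in ("HC", "OSA"):
        for _ in range(spec.n_per_group):
            z = _ar1_noise(rng, spec.n_timepoints, spec.n_regions, spec.ar1_coefficient)
            series.append(z @ chol[group].T)
            groups.append(group)

    records = _draw_clinical(spec, rng, series, groups)
    return series, records


def _draw_clinical(
    spec: CohortSpec,
    rng: np.random.Generator,
    series: list[np.ndarray],
    groups: list[str],
) -> list[SubjectRecord]:
    n = len(groups)
    values = {v: np.empty(n) for v in CLINICAL_VARIABLES}
    linked = {link.variable: link for link in spec.clinical_links}

    for v in CLINICAL_VARIABLES:
        for g in ("HC", "OSA"):
            idx = [i for i, x in enumerate(groups) if x == g]
            mean, sd, lo, hi = _MARGINALS[v][g]
            if g == "OSA" and v in linked:
                link = linked[v]
                ii, jj = edge_endpoints(spec.n_regions)
                a, b = ii[link.edge], jj[link.edge]
                z = np.array(
                    [fisher_z(compute_fc(series[i])[a, b], clip=True) for i in idx]
                )
                zs = (z - z.mean()) / z.std() if z.std() > 0 else np.zeros_like(z)
                latent = link.r * zs + np.sqrt(1 - link.r**2) * rng.standard_normal(len(idx))
            else:
                latent = rng.standard_normal(len(idx))
            values[v][idx] = np.clip(mean + sd * latent, lo, hi)

    records = []
    counters = {"HC": 0, "OSA": 0}
    for i, g in enumerate(groups):
        counters[g] += 1
        records.append(
            SubjectRecord(
                id=f"{g}{counters[g]:02d}",
                group=g,
                age=float(values["age"][i]),
                education=float(values["education"][i]),
                bmi=float(values["bmi"][i]),
                mmse=float(values["mmse"][i]),
                ahi=float(values["ahi"][i]),
                pct_tst_below_90=float(values["pct_tst_below_90"][i]),
                ess=float(values["ess"][i]),
            )
        )
    return records
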