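"""End-to-end orchestration: cohort -> connectivity -> univariate -> MVPA ->
characterization, with a reproducibility manifest.

A single global seed is expanded into independent per-stage streams (cohort
sampling, NBS permutations, MVPA permutations), so any stage rerun in
isolation with its manifest-recorded seed reproduces its output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import build_default_atlas
from .characterize import clinical_correlation, network_summary, weighted_degree
from .connectivity import cohort_edge_matrix
from .io import (
    read_cohort,
    write_cohort,
    write_feature_matrix,
    write_json,
)
from .mvpa import DEFAULT_GRID, encode_labels, run_mvpa
from .simulate import CohortSpec, sample_cohort
from .univariate import demographics_table, edgewise_ttest, nbs


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything needed to (re)run the full analysis.

    Exactly one of ``input_dir`` (a cohort on disk: timeseries/ + subjects.csv)
    or ``synthetic`` (a :class:`CohortSpec`) must be given.
    """

    out_dir: str
    input_dir: str | None = None
    synthetic: CohortSpec | None = None
    percentages: tuple[int, ...] = DEFAULT_GRID
    C: float = 1.0
    n_perm_nbs: int = 10000
    n_perm_mvpa: int = 0  # 0 skips the MVPA permutation test
    alpha: float = 0.05
    q: float = 0.05
    cdt_p: float = 0.001
    clinical_variables: tuple[str, ...] = ("ahi", "pct_tst_below_90")
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_dir or synthetic")
        for name in ("alpha", "q", "cdt_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not self.percentages:
            raise ValueError("percentage grid must be non-empty")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"]["effect_edges"] = [int(e) for e in self.synthetic.effect_edges]
            d["synthetic"]["clinical_links"] = [
                dataclasses.asdict(link) for link in self.synthetic.clinical_links
            ]
        return d


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("cohort", "nbs", "mvpa")
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(names, ss.spawn(len(names)))
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all results under ``config.out_dir``.

    Returns the manifest dict (also written as ``manifest.json``).  On a stage
    failure, partial outputs are kept, a ``FAILED`` marker names the stage, and
    :class:`PipelineError` is raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = build_default_atlas() if (
        config.synthetic is None or config.synthetic.n_regions == 90
    ) else None
    seeds = _stage_seeds(config.seed)
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as err:
                (out / "FAILED").write_text(f"{name}: {err}\n")
                raise PipelineError(name, err) from err
            timings[name] = round(time.perf_counter() - t0, 3)
            return result

        return deco

    # -- stage 1: cohort ---------------------------------------------------
    @stage("cohort")
    def cohort():
        if config.synthetic is not None:
            spec = dataclasses.replace(config.synthetic, seed=seeds["cohort"])
            series, records = sample_cohort(spec)
            subjects = pd.DataFrame([vars(r) for r in records])
            if atlas is not None:
                write_cohort(out / "cohort", series, records, atlas)
            return series, subjects
        return read_cohort(config.input_dir, atlas)

    series, subjects = cohort
    groups = subjects["group"].to_numpy()
    labels = atlas.labels if atlas is not None else [
        f"R{i:02d}" for i in range(series[0].shape[1])
    ]
    edge_labels = (
        atlas.edge_labels()
        if atlas is not None
        else [f"{labels[i]}—{labels[j]}" for i in range(len(labels)) for j in range(i + 1, len(labels))]
    )
    n_regions = series[0].shape[1]

    # -- stage 2: connectivity --------------------------------------------
    @stage("connectivity")
    def connectivity():
        x = cohort_edge_matrix(series, clip=config.synthetic is not None)
        write_feature_matrix(out / "edge_features.tsv", x, list(subjects["id"]), edge_labels)
        return x

    x = connectivity
    hc_mask = groups == "HC"
    x_hc, x_osa = x[hc_mask], x[~hc_mask]

    # -- stage 3: univariate ----------------------------------------------
    @stage("univariate")
    def univariate():
        res = edgewise_ttest(x_hc, x_osa, alpha=config.alpha, q=config.q)
        res.to_frame(edge_labels).to_csv(out / "edgewise_ttest.tsv", sep="\t", index=False)
        nbs_res = nbs(
            x_hc, x_osa, n_regions,
            cdt_p=config.cdt_p, n_perm=config.n_perm_nbs, seed=seeds["nbs"],
        )
        write_json(
            out / "nbs.json",
            {
                "cdt_p": nbs_res.cdt_p,
                "t_threshold": nbs_res.t_threshold,
                "n_perm": nbs_res.n_perm,
                "seed": seeds["nbs"],
                "components": [
                    {
                        "direction": c.direction,
                        "extent": c.extent,
                        "p_corrected": c.p_corrected,
                        "edges": [edge_labels[e] for e in c.edges],
                    }
                    for c in nbs_res.components
                ],
            },
        )
        demo = demographics_table(subjects)
        demo.to_csv(out / "demographics.tsv", sep="\t", index=False)
        return res, nbs_res

    univariate_res, nbs_res = univariate

    # -- stage 4: MVPA ------------------------------------------------------
    @stage("mvpa")
    def mvpa_stage():
        y = encode_labels(groups)
        res = run_mvpa(
            x, y,
            percentages=config.percentages, C=config.C,
            n_perm=config.n_perm_mvpa, seed=seeds["mvpa"],
        )
        write_json(
            out / "mvpa.json",
            {
                "percentages": list(res.percentages),
                "accuracy": res.accuracy,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "best_percentage": res.best_percentage,
                "final_accuracy": res.final_accuracy,
                "auc": res.auc,
                "fwe_p": res.fwe_p,
                "n_perm": res.n_perm,
                "seed": seeds["mvpa"],
                "C": config.C,
            },
        )
        pd.DataFrame(
            {
                "subject": subjects["id"],
                "true_group": groups,
                **{
                    f"decision_{p}": res.decision_values[:, i]
                    for i, p in enumerate(res.percentages)
                },
            }
        ).to_csv(out / "mvpa_folds.tsv", sep="\t", index=False)
        fpr, tpr = res.roc_points
        pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(out / "roc.tsv", sep="\t", index=False)
        sel = res.selected
        pd.DataFrame(
            {
                "edge": [edge_labels[e] for e in sel.edges],
                "weight": sel.weights,
                "frequency": sel.frequency,
            }
        ).to_csv(out / "selected_edges.tsv", sep="\t", index=False)
        return res

    mvpa_res = mvpa_stage

    # -- stage 5: characterization -----------------------------------------
    @stage("characterization")
    def characterization():
        if atlas is None:
            return None
        sel = mvpa_res.selected
        weighted_degree(sel, atlas).to_csv(out / "weighted_degree.tsv", sep="\t", index=False)
        summary = network_summary(sel, atlas)
        with open(out / "network_summary.tsv", "w") as fh:
            for name, table in (
                ("count", summary.count),
                ("possible", summary.possible),
                ("percent", summary.percent),
            ):
                fh.write(f"# {name}\n")
                table.to_csv(fh, sep="\t")
            fh.write(
                f"# intra_total\t{summary.intra_total}\n"
                f"# inter_total\t{summary.inter_total}\n"
                f"# mean_intra_pct\t{summary.mean_intra_pct:.6f}\n"
                f"# mean_inter_pct\t{summary.mean_inter_pct:.6f}\n"
            )
        corr = clinical_correlation(
            sel, x[~hc_mask], subjects.loc[~hc_mask].reset_index(drop=True),
            variables=config.clinical_variables, edge_labels=edge_labels,
        )
        corr.to_csv(out / "clinical_correlations.tsv", sep="\t", index=False)
        return summary

    characterization  # noqa: B018 - stage executes at definition

    # -- manifest -----------------------------------------------------------
    files = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": config.to_dict(),
        "stage_seconds": timings,
        "checksums": {f: _sha256(out / f) for f in files},
    }
    write_json(out / "manifest.json", manifest)
    return manifest


def config_from_dict(d: dict) -> PipelineConfig:
    """Build a config from a plain dict (e.g. parsed JSON)."""
    d = dict(d)
    if d.get("synthetic") is not None:
        from .simulate import ClinicalLink

        s = dict(d["synthetic"])
        s["clinical_links"] = tuple(
            ClinicalLink(**link) for link in s.get("clinical_links", ())
        )
        s["effect_edges"] = tuple(s.get("effect_edges", ()))
        d["synthetic"] = CohortSpec(**s)
    if "percentages" in d:
        d["percentages"] = tuple(d["percentages"])
    if "clinical_variables" in d:
        d["clinical_variables"] = tuple(d["clinical_variables"])
    return PipelineConfig(**d)


def config_from_json(path: str | Path) -> PipelineConfig:
    return config_from_dict(json.loads(Path(path).read_text()))
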