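"""Pipeline orchestration: generate/load -> metrics -> nulls -> inference.

Drives the full analysis from a :class:`RunConfig` (or a YAML file) and
writes every artifact — matrices, metadata, metric tables, test reports,
and a provenance record — into one output directory.  Identical configs
produce identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import CohortConfig, SubjectMeta, derive_seed
from .construction import (
    ConnectivityMatrix,
    build_connectivity,
    read_fibers,
    read_matrix,
    write_matrix,
)
from .model import ConnectomeGroupModel

INPUT_MODES = ("synthetic", "fibers", "matrices")


@dataclass
class RunConfig:
    """One pipeline run: input mode, paths, and analysis settings."""

    mode: str = "synthetic"
    # synthetic mode
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # fibers mode: one CSV with all subjects' fiber records
    fiber_path: Optional[str] = None
    n_nodes: int = 90
    # matrices mode: directory of per-subject TSVs
    matrix_dir: Optional[str] = None
    # metadata CSV (fibers/matrices modes)
    meta_path: Optional[str] = None
    # analysis settings
    n_perm: int = 10000
    n_random: int = 100
    swaps_per_edge: int = 10
    alpha: float = 0.05
    q: float = 0.05
    pooled_nodal_fdr: bool = False
    small_world: bool = True
    seed: int = 2018
    outdir: str = "fanet_run"

    def __post_init__(self):
        if self.mode not in INPUT_MODES:
            raise ValueError(f"mode must be one of {INPUT_MODES}, got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "cohort"}
        d["cohort"] = self.cohort.to_dict()
        return d


def read_metadata(path) -> list[SubjectMeta]:
    df = pd.read_csv(path)
    metas = []
    for r in df.itertuples(index=False):
        cars = getattr(r, "cars", None)
        if cars is not None and (isinstance(cars, float) and np.isnan(cars)):
            cars = None
        metas.append(SubjectMeta(
            subject_id=str(r.subject_id), group=str(r.group),
            age_years=float(r.age_years), sex=str(r.sex),
            cars=None if cars is None else float(cars)))
    return metas


def write_metadata(metas, path) -> None:
    pd.DataFrame(
        [(m.subject_id, m.group, m.age_years, m.sex,
          "" if m.cars is None else m.cars) for m in metas],
        columns=["subject_id", "group", "age_years", "sex", "cars"],
    ).to_csv(path, index=False)


def _load_inputs(cfg: RunConfig) -> tuple[list[ConnectivityMatrix], list[SubjectMeta]]:
    if cfg.mode == "synthetic":
        from .synthetic import generate_cohort
        return generate_cohort(cfg.cohort)
    if cfg.mode == "fibers":
        if not cfg.fiber_path or not cfg.meta_path:
            raise ValueError("fibers mode needs fiber_path and meta_path")
        fibers = read_fibers(cfg.fiber_path)
        by_subject: dict[str, list] = {}
        for f in fibers:
            by_subject.setdefault(f.subject_id, []).append(f)
        matrices = [build_connectivity(v, cfg.n_nodes, subject_id=k)
                    for k, v in sorted(by_subject.items())]
        return matrices, read_metadata(cfg.meta_path)
    # matrices mode
    if not cfg.matrix_dir or not cfg.meta_path:
        raise ValueError("matrices mode needs matrix_dir and meta_path")
    metas = read_metadata(cfg.meta_path)
    matrices = []
    for m in metas:
        path = Path(cfg.matrix_dir) / f"{m.subject_id}.tsv"
        matrices.append(read_matrix(path, subject_id=m.subject_id))
    return matrices, metas


def run(cfg: RunConfig):
    """Execute the pipeline; returns the fitted results (or None when the
    cohort cannot support a two-group comparison, in which case only the
    metric tables are written)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, metas = _load_inputs(cfg)

    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for m in matrices:
        write_matrix(m, mat_dir / f"{m.subject_id}.tsv")
    write_metadata(metas, out / "cohort.csv")

    provenance = {
        "fanet_version": __version__,
        "config": cfg.to_dict(),
        "stage_seeds": {
            "global": cfg.seed,
            "analysis": derive_seed(cfg.seed, "analysis"),
        },
        "n_subjects": len(matrices),
    }
    (out / "provenance.yaml").write_text(yaml.safe_dump(provenance, sort_keys=True))

    groups = {m.group for m in metas}
    counts = {g: sum(m.group == g for m in metas) for g in groups}
    if len(groups) < 2 or min(counts.values()) < 2:
        warnings.warn(
            f"group sizes {counts} cannot support inference; "
            "writing metric tables only", stacklevel=2)
        from .metrics import global_metrics
        rows = []
        for m in matrices:
            g = global_metrics(m)
            rows.append((m.subject_id, g.clustering_cw, g.path_length_lw,
                         g.strength_sw, g.e_global, g.e_local))
        pd.DataFrame(rows, columns=["subject_id", "Cw", "Lw", "Sw",
                                    "Eglobal", "Elocal"]) \
            .to_csv(out / "metrics_global.csv", index=False)
        return None

    model = ConnectomeGroupModel(matrices, metas)
    results = model.fit(n_perm=cfg.n_perm, n_random=cfg.n_random,
                        swaps_per_edge=cfg.swaps_per_edge, alpha=cfg.alpha,
                        q=cfg.q, pooled_nodal_fdr=cfg.pooled_nodal_fdr,
                        small_world=cfg.small_world,
                        seed=derive_seed(cfg.seed, "analysis"))
    results.save(out)
    return results
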