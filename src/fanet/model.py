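"""Group-comparison model for FA-weighted connectome cohorts.

statsmodels-style surface: :class:`ConnectomeGroupModel` holds the data
(per-subject connectivity matrices plus metadata); ``fit()`` computes all
whole-network and per-node metrics, normalizes clustering/path length
against matched random ensembles, runs the permutation tests (uncorrected
alpha for the 8 global metrics, BH-FDR at Q across the 90 regions for
each nodal family), and correlates CARS severity with every metric that
differed between groups.  The returned
:class:`ConnectomeGroupResults` carries tidy DataFrames and a printable
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import CohortConfig, SubjectMeta, derive_seed
from .construction import ConnectivityMatrix
from .inference import (
    bh_fdr,
    pearson_with_cars,
    permutation_test_table,
)
from .metrics import global_metrics, nodal_metrics
from .nullmodels import small_world_indices

GLOBAL_METRIC_NAMES = ("Cw", "Lw", "gamma", "lambda", "sigma", "Sw",
                       "Eglobal", "Elocal")
NODAL_METRIC_NAMES = ("nodal_strength", "nodal_efficiency", "betweenness")


class ConnectomeGroupModel:
    """Two-group structural-connectome comparison.

    Parameters
    ----------
    matrices
        One :class:`ConnectivityMatrix` per subject.
    meta
        Matching :class:`SubjectMeta` records (same order or matched by
        ``subject_id``).
    """

    def __init__(self, matrices: Sequence[ConnectivityMatrix],
                 meta: Sequence[SubjectMeta]):
        if len(matrices) != len(meta):
            raise ValueError("matrices and metadata differ in length")
        by_id = {m.subject_id: m for m in meta}
        if len(by_id) != len(meta):
            raise ValueError("duplicate subject_id in metadata")
        ordered = []
        for mat in matrices:
            if mat.subject_id not in by_id:
                raise ValueError(f"no metadata for subject {mat.subject_id!r}")
            ordered.append(by_id[mat.subject_id])
        sizes = {m.n_nodes for m in matrices}
        if len(sizes) > 1:
            raise ValueError(f"inconsistent network sizes: {sorted(sizes)}")
        self.matrices = list(matrices)
        self.meta = ordered
        self.n_nodes = matrices[0].n_nodes if matrices else 0

    @classmethod
    def from_cohort(cls, config: Optional[CohortConfig] = None) -> "ConnectomeGroupModel":
        """Build the model from a synthetic cohort (default: calibrated profile)."""
        from .synthetic import generate_cohort
        matrices, meta = generate_cohort(config)
        return cls(matrices, meta)

    @property
    def groups(self) -> np.ndarray:
        return np.array([m.group for m in self.meta])

    def fit(self, n_perm: int = 10000, n_random: int = 100,
            swaps_per_edge: int = 10, alpha: float = 0.05, q: float = 0.05,
            pooled_nodal_fdr: bool = False, seed: int | None = None,
            small_world: bool = True) -> "ConnectomeGroupResults":
        """Run metrics, null models, and group inference.

        ``n_perm`` permutations per test, ``n_random`` matched random
        networks per subject for gamma/lambda/sigma (skipped entirely when
        ``small_world=False``), BH-FDR per nodal metric family (or pooled
        across the three families with ``pooled_nodal_fdr``).
        """
        seed = 0 if seed is None else int(seed)
        is_asd = self.groups == "ASD"
        n_sub = len(self.matrices)

        glob = np.full((n_sub, len(GLOBAL_METRIC_NAMES)), np.nan)
        nodal = {name: np.zeros((n_sub, self.n_nodes)) for name in NODAL_METRIC_NAMES}
        ens_rows = []
        for s, mat in enumerate(self.matrices):
            gamma = lam = None
            if small_world:
                gamma, lam, _, ens = small_world_indices(
                    mat, n_random=n_random, swaps_per_edge=swaps_per_edge,
                    seed=derive_seed(seed, "nulls", mat.subject_id))
                ens_rows.append((mat.subject_id, ens.n_random,
                                 ens.c_random_mean, ens.l_random_mean))
            g = global_metrics(mat, gamma=gamma, lam=lam)
            glob[s] = [g.clustering_cw, g.path_length_lw,
                       np.nan if g.gamma is None else g.gamma,
                       np.nan if g.lam is None else g.lam,
                       np.nan if g.sigma is None else g.sigma,
                       g.strength_sw, g.e_global, g.e_local]
            nm = nodal_metrics(mat)
            nodal["nodal_strength"][s] = nm.strength
            nodal["nodal_efficiency"][s] = nm.efficiency
            nodal["betweenness"][s] = nm.betweenness

        subject_ids = [m.subject_id for m in self.matrices]
        global_df = pd.DataFrame(glob, columns=GLOBAL_METRIC_NAMES)
        global_df.insert(0, "subject_id", subject_ids)
        global_df.insert(1, "group", self.groups)
        ensemble_df = pd.DataFrame(
            ens_rows, columns=["subject_id", "n_random", "c_random_mean",
                               "l_random_mean"]) if ens_rows else None

        # --- global tests: uncorrected permutation p per metric
        tested = [m for m in GLOBAL_METRIC_NAMES
                  if not np.isnan(glob[:, GLOBAL_METRIC_NAMES.index(m)]).all()]
        cols = [GLOBAL_METRIC_NAMES.index(m) for m in tested]
        diffs, pvals = permutation_test_table(
            glob[:, cols], is_asd, n_perm=n_perm,
            seed=derive_seed(seed, "perm-global"))
        gt = pd.DataFrame({
            "metric": tested,
            "mean_asd": glob[is_asd][:, cols].mean(axis=0),
            "sd_asd": glob[is_asd][:, cols].std(axis=0, ddof=1),
            "mean_hc": glob[~is_asd][:, cols].mean(axis=0),
            "sd_hc": glob[~is_asd][:, cols].std(axis=0, ddof=1),
            "diff": diffs,
            "p": pvals,
        })
        gt["significant"] = gt["p"] < alpha

        # --- nodal tests: permutation p per node, BH-FDR per family
        labels = self.matrices[0].labels
        frames = []
        for name in NODAL_METRIC_NAMES:
            data = nodal[name]
            d, p = permutation_test_table(
                data, is_asd, n_perm=n_perm,
                seed=derive_seed(seed, "perm-nodal", name))
            frames.append(pd.DataFrame({
                "metric": name,
                "node": np.arange(1, self.n_nodes + 1),
                "region": labels,
                "mean_asd": data[is_asd].mean(axis=0),
                "mean_hc": data[~is_asd].mean(axis=0),
                "diff": d,
                "p": p,
            }))
        nt = pd.concat(frames, ignore_index=True)
        if pooled_nodal_fdr:
            fdr = bh_fdr(nt["p"].to_numpy(), q_threshold=q)
            nt["q"] = fdr.q_values
            nt["significant"] = fdr.significant
        else:
            nt["q"] = np.nan
            nt["significant"] = False
            for name in NODAL_METRIC_NAMES:
                sel = nt["metric"] == name
                fdr = bh_fdr(nt.loc[sel, "p"].to_numpy(), q_threshold=q)
                nt.loc[sel, "q"] = fdr.q_values
                nt.loc[sel, "significant"] = fdr.significant

        corr = self._severity_correlations(gt, nt, global_df, nodal, is_asd)

        return ConnectomeGroupResults(
            model=self, global_metrics=global_df, nodal_metrics=nodal,
            ensembles=ensemble_df, global_tests=gt, nodal_tests=nt,
            correlations=corr, n_perm=n_perm, n_random=n_random,
            alpha=alpha, q=q, seed=seed)

    def _severity_correlations(self, gt, nt, global_df, nodal, is_asd):
        """Pearson r between CARS and every metric that differed between groups."""
        cars = np.array([m.cars for m in self.meta if m.group == "ASD"],
                        dtype=float)
        rows = []
        if cars.size >= 3 and not np.any(np.isnan(cars)):
            for _, row in gt[gt["significant"]].iterrows():
                vals = global_df.loc[is_asd, row["metric"]].to_numpy()
                try:
                    r, p = pearson_with_cars(vals, cars)
                except ValueError:
                    continue
                rows.append((row["metric"], None, None, r, p))
            for _, row in nt[nt["significant"]].iterrows():
                vals = nodal[row["metric"]][is_asd][:, int(row["node"]) - 1]
                try:
                    r, p = pearson_with_cars(vals, cars)
                except ValueError:
                    continue
                rows.append((row["metric"], int(row["node"]), row["region"], r, p))
        return pd.DataFrame(rows, columns=["metric", "node", "region", "r", "p"])


@dataclass
class ConnectomeGroupResults:
    """Fitted group comparison: metric tables, tests, and correlations."""

    model: ConnectomeGroupModel
    global_metrics: pd.DataFrame            # one row per subject
    nodal_metrics: dict                     # family -> (n_subjects, n_nodes)
    ensembles: Optional[pd.DataFrame]       # null-ensemble summaries
    global_tests: pd.DataFrame              # one row per global metric
    nodal_tests: pd.DataFrame               # one row per family x node
    correlations: pd.DataFrame              # CARS correlations
    n_perm: int
    n_random: int
    alpha: float
    q: float
    seed: int

    @property
    def significant_global(self) -> list[str]:
        t = self.global_tests
        return t.loc[t["significant"], "metric"].tolist()

    def significant_nodes(self, metric: str = "nodal_efficiency") -> list[int]:
        t = self.nodal_tests
        sel = (t["metric"] == metric) & t["significant"]
        return t.loc[sel, "node"].astype(int).tolist()

    def nodal_metrics_long(self) -> pd.DataFrame:
        """Per-subject x per-node metrics in tidy long format."""
        ids = self.global_metrics["subject_id"]
        groups = self.global_metrics["group"]
        labels = self.model.matrices[0].labels
        frames = []
        for name, data in self.nodal_metrics.items():
            df = pd.DataFrame(data, columns=[str(i + 1) for i in range(data.shape[1])])
            df.insert(0, "subject_id", ids)
            df.insert(1, "group", groups)
            long = df.melt(id_vars=["subject_id", "group"], var_name="node",
                           value_name="value")
            long["node"] = long["node"].astype(int)
            long["region"] = [labels[i - 1] for i in long["node"]]
            long.insert(2, "metric", name)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Human-readable report of the group comparison."""
        lines = []
        lines.append("Connectome group comparison (ASD vs HC)")
        lines.append(f"  subjects: {int((self.model.groups == 'ASD').sum())} ASD, "
                     f"{int((self.model.groups == 'HC').sum())} HC; "
                     f"nodes: {self.model.n_nodes}")
        lines.append(f"  permutations: {self.n_perm}; random networks/subject: "
                     f"{self.n_random}; alpha={self.alpha}, Q={self.q}")
        lines.append("")
        lines.append("Global metrics (permutation test, uncorrected):")
        lines.append(f"  {'metric':<8} {'ASD mean±SD':>16} {'HC mean±SD':>16} "
                     f"{'diff':>9} {'p':>8}")
        for _, r in self.global_tests.iterrows():
            star = " *" if r["significant"] else ""
            lines.append(
                f"  {r['metric']:<8} {r['mean_asd']:>8.3f}±{r['sd_asd']:<6.3f} "
                f"{r['mean_hc']:>8.3f}±{r['sd_hc']:<6.3f} "
                f"{r['diff']:>9.4f} {r['p']:>8.4f}{star}")
        lines.append("")
        sig = self.nodal_tests[self.nodal_tests["significant"]]
        lines.append(f"Nodal metrics surviving FDR (Q < {self.q}): {len(sig)}")
        for _, r in sig.iterrows():
            lines.append(f"  {r['metric']:<17} node {int(r['node']):>2} "
                         f"({r['region']}): diff={r['diff']:+.4f}, "
                         f"p={r['p']:.4f}, q={r['q']:.4f}")
        if len(self.correlations):
            lines.append("")
            lines.append("CARS correlations (ASD group, metrics with group differences):")
            for _, r in self.correlations.iterrows():
                has_node = pd.notna(r["node"])
                where = (f" node {int(r['node'])} ({r['region']})"
                         if has_node else "")
                star = " *" if r["p"] < 0.05 else ""
                lines.append(f"  {r['metric']}{where}: r={r['r']:+.3f}, "
                             f"p={r['p']:.4f}{star}")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write all tables as CSV into a directory."""
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        gm = self.global_metrics
        if self.ensembles is not None:
            gm = gm.merge(self.ensembles, on="subject_id", how="left")
        gm.to_csv(out / "metrics_global.csv", index=False)
        self.nodal_metrics_long().to_csv(out / "metrics_nodal.csv", index=False)
        self.global_tests.to_csv(out / "group_tests_global.csv", index=False)
        self.nodal_tests.to_csv(out / "group_tests_nodal.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        (out / "summary.txt").write_text(self.summary() + "\n")

    def plot_global_metrics(self, ax=None):
        """Group comparison of the global metrics as grouped bars (+/- SD)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        t = self.global_tests
        x = np.arange(len(t))
        width = 0.38
        ax.bar(x - width / 2, t["mean_asd"], width, yerr=t["sd_asd"],
               label="ASD", capsize=3)
        ax.bar(x + width / 2, t["mean_hc"], width, yerr=t["sd_hc"],
               label="HC", capsize=3)
        for i, sig in enumerate(t["significant"]):
            if sig:
                top = max(t["mean_asd"].iloc[i] + t["sd_asd"].iloc[i],
                          t["mean_hc"].iloc[i] + t["sd_hc"].iloc[i])
                ax.text(i, top * 1.03, "*", ha="center")
        ax.set_xticks(x, t["metric"])
        ax.set_ylabel("metric value")
        ax.legend()
        return ax


def run_group_analysis(matrices: Sequence[ConnectivityMatrix],
                       meta: Sequence[SubjectMeta],
                       **fit_kwargs) -> ConnectomeGroupResults:
    """Functional entry point: fit the group model on a cohort."""
    return ConnectomeGroupModel(matrices, meta).fit(**fit_kwargs)
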