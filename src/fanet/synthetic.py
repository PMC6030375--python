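"""Synthetic two-group cohorts of FA-weighted small-world connectomes.

The generator emulates, not infers: it produces cohorts with the
statistical structure a preschool ASD-vs-control DTI study assumes — a
small-world binary substrate shared by the cohort, per-subject FA-like
edge weights in (0, 1], an ASD group effect carried by a weight boost on
every edge incident to four target regions (elevating nodal efficiency at
left precuneus, left thalamus, bilateral superior parietal cortex, and —
through shortcut paths — the whole network's efficiency) together with a
compensating global weight scale, jointly calibrated to the study's group
contrast in L^w, E_global and E_local, and CARS severity scores linearly
linked to the left-precuneus nodal efficiency.

The default :class:`~fanet.config.CohortConfig` is the calibrated
profile: its constants were fitted once (see ``calibrate_default_profile``
and docs/methods.md) so that group means of L^w, E_global and E_local
reproduce the target group statistics 4.17/4.35, 0.24/0.23 and
0.37/0.36.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .aal import AAL90_LABELS
from .config import CARS_MAX, CARS_MIN, CohortConfig, SubjectMeta, derive_seed
from .construction import ConnectivityMatrix, FiberRecord, as_weights
from .metrics import global_efficiency, shortest_path_lengths, single_node_efficiency

# Demographics used for metadata only (groups are matched; age and sex have
# no effect on the generated networks): mean +/- SD of age in years and
# male fraction, per group.
_AGE_PROFILE = {"ASD": (2.89, 0.97), "HC": (3.15, 1.12)}
_MALE_FRACTION = {"ASD": 32 / 39, "HC": 13 / 19}
_AGE_RANGE = (2.0, 6.0)


def generate_topology(n_nodes: int, base_degree: int, rewire_prob: float,
                      seed: int | None = None, tries: int = 100) -> np.ndarray:
    """Connected Watts-Strogatz-style binary substrate (0/1 matrix).

    A ring lattice of even degree ``base_degree`` rewired with probability
    ``rewire_prob``; realizations are rejected and resampled until
    connected (bounded retries).  Node labels are then scattered by a
    seeded permutation so that label order carries no ring adjacency —
    anatomical region indices are not spatially consecutive, and without
    the scatter any set of nearby labels would share an artifactual
    common neighborhood.
    """
    if base_degree % 2 != 0 or base_degree >= n_nodes:
        raise ValueError("base_degree must be even and < n_nodes")
    try:
        G = nx.connected_watts_strogatz_graph(
            n_nodes, base_degree, rewire_prob, tries=tries, seed=seed)
    except nx.NetworkXError as err:
        raise RuntimeError(
            f"no connected topology after {tries} tries: {err}") from err
    A = nx.to_numpy_array(G, nodelist=range(n_nodes), dtype=float)
    order = np.random.default_rng(seed).permutation(n_nodes)
    return A[np.ix_(order, order)]


def generate_subject_matrix(topology: np.ndarray, config: CohortConfig,
                            group: str, seed: int | None = None) -> np.ndarray:
    """One subject's FA-weighted matrix on the shared binary substrate.

    Per-edge base weights are Beta(weight_shape_a, weight_shape_b) draws,
    multiplied by a shared lognormal subject factor, per-node regional
    factors (zero-sum on the log scale, entering each edge as
    ``(eta_i * eta_j) ** node_jitter_exponent``), and — for ASD subjects —
    the global scale and the incident-edge boost at the target nodes.
    Weights are clipped to (0, 1].
    """
    if group not in ("ASD", "HC"):
        raise ValueError(f"group must be 'ASD' or 'HC', got {group!r}")
    A = np.asarray(topology, dtype=float)
    n = A.shape[0]
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(np.triu(A, k=1))
    m = rows.size

    w = rng.beta(config.weight_shape_a, config.weight_shape_b, size=m)
    if config.subject_jitter_sd > 0:
        tau = config.subject_jitter_sd
        w = w * np.exp(rng.normal(0.0, tau) - tau**2 / 2)
    if config.node_jitter_sd > 0:
        # Relative regional deviations: zero-sum on the log scale, so the
        # subject's overall weight level (and with it every whole-network
        # metric) is carried by the subject factor alone while per-region
        # metrics keep their full heterogeneity.
        x = rng.normal(0.0, config.node_jitter_sd, size=n)
        eta = np.exp(x - x.mean())
        w = w * (eta[rows] * eta[cols]) ** config.node_jitter_exponent
    if group == "ASD":
        w = w * config.asd_global_scale
        targets0 = np.array([t - 1 for t in config.target_nodes])
        incident = np.isin(rows, targets0) | np.isin(cols, targets0)
        w = np.where(incident, w * config.nodal_boost, w)
    w = np.minimum(w, 1.0)

    W = np.zeros((n, n))
    W[rows, cols] = w
    return W + W.T


def generate_cars(precuneus_efficiency, config: CohortConfig,
                  seed: int | None = None) -> np.ndarray:
    """CARS severity scores linearly linked to nodal efficiency.

    cars_i = mu + rho * sd * z(e_i) + sqrt(1 - rho^2) * sd * eps_i, with
    z(e) the standardized efficiency, so the population correlation is
    ``cars_r_target`` and the marginal mean/SD are ``cars_mean`` /
    ``cars_sd``; values are clipped to the CARS instrument range.
    """
    e = np.asarray(precuneus_efficiency, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 efficiency values")
    sd_e = e.std(ddof=1)
    if sd_e == 0:
        raise ValueError(
            "constant nodal efficiencies: cannot induce a correlation")
    rng = np.random.default_rng(seed)
    rho = config.cars_r_target
    z = (e - e.mean()) / sd_e
    noise = rng.standard_normal(e.size)
    cars = (config.cars_mean + config.cars_sd *
            (rho * z + np.sqrt(1.0 - rho**2) * noise))
    return np.clip(cars, CARS_MIN, CARS_MAX)


def generate_cohort(config: CohortConfig | None = None
                    ) -> tuple[list[ConnectivityMatrix], list[SubjectMeta]]:
    """Full two-group cohort: connectivity matrices plus subject metadata.

    Deterministic given ``config`` (all sub-streams are hash-derived from
    ``config.seed``).  CARS scores are generated from each ASD subject's
    realized nodal efficiency at the first target node (left precuneus by
    default).
    """
    if config is None:
        config = calibrate_default_profile()
    topology = generate_topology(config.n_nodes, config.base_degree,
                                 config.rewire_prob,
                                 seed=derive_seed(config.seed, "topology"))
    labels = (AAL90_LABELS if config.n_nodes == len(AAL90_LABELS) else None)

    matrices: list[ConnectivityMatrix] = []
    metas: list[SubjectMeta] = []
    groups = [("ASD", config.n_asd), ("HC", config.n_hc)]
    for group, size in groups:
        for i in range(size):
            sid = f"{group.lower()}{i + 1:03d}"
            W = generate_subject_matrix(
                topology, config, group,
                seed=derive_seed(config.seed, "weights", sid))
            matrices.append(ConnectivityMatrix(W, labels=labels, subject_id=sid))

    demo_rng = np.random.default_rng(derive_seed(config.seed, "demographics"))
    cars_by_sid: dict[str, float] = {}
    asd_ids = [m.subject_id for m in matrices[:config.n_asd]]
    eff = np.array([
        single_node_efficiency(m, config.target_nodes[0] - 1)
        for m in matrices[:config.n_asd]
    ])
    cars = generate_cars(eff, config, seed=derive_seed(config.seed, "cars"))
    cars_by_sid.update(zip(asd_ids, cars))

    for mat in matrices:
        group = "ASD" if mat.subject_id.startswith("asd") else "HC"
        mu, sd = _AGE_PROFILE[group]
        age = float(np.clip(demo_rng.normal(mu, sd), *_AGE_RANGE))
        sex = "M" if demo_rng.random() < _MALE_FRACTION[group] else "F"
        metas.append(SubjectMeta(
            subject_id=mat.subject_id, group=group, age_years=round(age, 2),
            sex=sex, cars=(round(float(cars_by_sid[mat.subject_id]), 2)
                           if group == "ASD" else None)))
    return matrices, metas


def matrix_to_fibers(W, fibers_per_edge: int = 1, spread: float = 0.0,
                     seed: int | None = None,
                     subject_id: str | None = None) -> list[FiberRecord]:
    """Expand a connectivity matrix into per-fiber records (inverse of
    :func:`fanet.construction.build_connectivity`).

    Every nonzero edge emits ``fibers_per_edge`` records whose FA values
    are a mean-preserving perturbation of the edge weight (uniform spread,
    re-centered, shrunk if needed to stay in (0, 1]); rebuilding the
    matrix from the records recovers it to numeric tolerance.
    """
    if fibers_per_edge < 1:
        raise ValueError("fibers_per_edge must be >= 1")
    if spread < 0:
        raise ValueError("spread must be nonnegative")
    A = as_weights(W)
    if subject_id is None:
        subject_id = W.subject_id if isinstance(W, ConnectivityMatrix) else ""
    rng = np.random.default_rng(seed)
    records: list[FiberRecord] = []
    rows, cols = np.nonzero(np.triu(A, k=1))
    for i, j in zip(rows, cols):
        w = A[i, j]
        if fibers_per_edge == 1 or spread == 0:
            fa = np.full(fibers_per_edge, w)
        else:
            d = rng.uniform(-spread, spread, size=fibers_per_edge)
            d = d - d.mean()
            hi, lo = d.max(), d.min()
            # shrink deviations so every FA stays inside (0, 1]
            scale = 1.0
            if hi > 0:
                scale = min(scale, (1.0 - w) / hi)
            if lo < 0:
                scale = min(scale, (w - 1e-9) / -lo)
            fa = w + d * max(scale, 0.0)
        for v in fa:
            records.append(FiberRecord(subject_id, int(i) + 1, int(j) + 1, float(v)))
    return records


def fit_weight_scale(config: CohortConfig, e_global_target: float,
                     n_subjects: int = 10, seed: int = 0) -> CohortConfig:
    """Solve the overall weight scale for a control-group E_global target.

    Every efficiency is homogeneous of degree 1 in the weights, so the
    Beta mean that hits ``e_global_target`` follows from one simulated
    control group by a linear rescale (keeping the Beta concentration
    a + b fixed).  One extra iteration absorbs the mild nonlinearity that
    clipping at 1 introduces.
    """
    cfg = config
    conc = config.weight_shape_a + config.weight_shape_b
    for _ in range(2):
        topo = generate_topology(cfg.n_nodes, cfg.base_degree, cfg.rewire_prob,
                                 seed=derive_seed(seed, "calib-topology"))
        e0 = np.mean([
            global_efficiency(shortest_path_lengths(
                generate_subject_matrix(topo, cfg, "HC",
                                        seed=derive_seed(seed, "calib", i))))
            for i in range(n_subjects)
        ])
        mean = cfg.weight_shape_a / conc * (e_global_target / e0)
        if not 0 < mean < 1:
            raise ValueError(f"target implies Beta mean outside (0,1): {mean}")
        cfg = cfg.replace(weight_shape_a=mean * conc,
                          weight_shape_b=(1 - mean) * conc)
    return cfg


def calibrate_default_profile() -> CohortConfig:
    """The packaged calibrated cohort profile.

    The defaults of :class:`~fanet.config.CohortConfig` *are* the
    calibration: base_degree and rewire_prob were tuned so the substrate's
    E_local/E_global ratio matches 0.37/0.24; the Beta weight scale was
    solved by linearity (``fit_weight_scale``) so the control-group
    E_global is 0.23; subject_jitter_sd matches the reference
    between-subject spread; asd_global_scale and nodal_boost jointly set
    the ASD/control ratio L^w 4.35 -> 4.17.  See docs/methods.md.
    """
    return CohortConfig()
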