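"""Cohort configuration and subject metadata containers."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence
import hashlib

from .aal import DEFAULT_TARGET_NODES

#: CARS (Childhood Autism Rating Scale) instrument range, in score points.
CARS_MIN = 15.0
CARS_MAX = 60.0


def derive_seed(master: int, *tokens) -> int:
    """Derive a stable sub-stream seed (< 2**31) from a master seed and tokens.

    Hash-based derivation keeps sub-stages statistically independent and
    means adding a subject or a stage never perturbs the streams of the
    existing ones.
    """
    key = repr((int(master),) + tuple(str(t) for t in tokens)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass(frozen=True)
class SubjectMeta:
    """Demographics and clinical score for one subject.

    ``cars`` (autism severity, CARS points) is present only for ASD
    subjects; controls carry ``None``.
    """

    subject_id: str
    group: str                      # "ASD" | "HC"
    age_years: float
    sex: str                        # "M" | "F"
    cars: Optional[float] = None

    def __post_init__(self):
        if self.group not in ("ASD", "HC"):
            raise ValueError(f"group must be 'ASD' or 'HC', got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.group == "HC":
            if self.cars is not None:
                raise ValueError("HC subjects carry no CARS score")
        elif self.cars is not None and not (CARS_MIN <= self.cars <= CARS_MAX):
            raise ValueError(
                f"CARS outside instrument range [{CARS_MIN}, {CARS_MAX}]: {self.cars}"
            )


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the two-group synthetic connectome cohort.

    The generative model is a shared small-world binary substrate
    (rewired ring lattice with scattered labels) on which each subject
    receives FA-like edge weights in (0, 1]:

    ``w_ij = clip(B_ij * g_s * (eta_i * eta_j)^q * group effects, 0, 1]``

    where ``B_ij ~ Beta(weight_shape_a, weight_shape_b)`` is redrawn per
    subject, ``g_s`` is a shared per-subject lognormal factor
    (``subject_jitter_sd`` on the log scale) carrying the between-subject
    variation of whole-network metrics, and ``eta_i`` are per-node factors
    (lognormal, ``node_jitter_sd``, zero-sum on the log scale within each
    subject so they move regional metrics without moving the whole-network
    level; ``q = node_jitter_exponent``).  ASD subjects get a global
    multiplicative scale ``asd_global_scale`` and a ``nodal_boost`` factor
    on every edge incident to the four ``target_nodes``; the two are
    calibrated jointly so their combined effect reproduces the target
    group contrast (the boost over-delivers network-wide efficiency via
    shortcut paths through the boosted regions, which is why the
    compensating global scale sits slightly below 1).

    The defaults are the packaged calibrated profile (see
    docs/methods.md for the calibration procedure and targets).
    """

    # group sizes and parcellation
    n_asd: int = 39
    n_hc: int = 19
    n_nodes: int = 90
    # binary substrate (Watts-Strogatz-style rewired ring lattice)
    base_degree: int = 12
    rewire_prob: float = 0.055
    # edge-weight distribution on (0, 1)
    weight_shape_a: float = 4.5262
    weight_shape_b: float = 7.4738
    # between-subject / between-node multiplicative noise (log-scale SD)
    subject_jitter_sd: float = 0.069
    node_jitter_sd: float = 0.42
    node_jitter_exponent: float = 1.0
    # group effects
    asd_global_scale: float = 0.9665
    target_nodes: Sequence[int] = DEFAULT_TARGET_NODES
    nodal_boost: float = 2.0
    # severity-score linkage
    cars_mean: float = 33.67
    cars_sd: float = 1.49
    cars_r_target: float = 0.343
    seed: int = 2018

    def __post_init__(self):
        if self.n_asd < 2 or self.n_hc < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not (0 <= self.rewire_prob <= 1):
            raise ValueError("rewire_prob must lie in [0, 1]")
        if self.base_degree % 2 != 0 or not (0 < self.base_degree < self.n_nodes):
            raise ValueError("base_degree must be even and in (0, n_nodes)")
        if self.weight_shape_a <= 0 or self.weight_shape_b <= 0:
            raise ValueError("weight shape parameters must be positive")
        if self.subject_jitter_sd < 0 or self.node_jitter_sd < 0:
            raise ValueError("jitter SDs must be nonnegative")
        if self.asd_global_scale <= 0 or self.nodal_boost <= 0:
            raise ValueError("scale factors must be positive")
        if not (-1 < self.cars_r_target < 1):
            raise ValueError("cars_r_target must lie in the open interval (-1, 1)")
        if self.cars_sd <= 0:
            raise ValueError("cars_sd must be positive")
        for t in self.target_nodes:
            if not (1 <= int(t) <= self.n_nodes):
                raise ValueError(f"target node {t} outside 1..{self.n_nodes}")
        object.__setattr__(self, "target_nodes", tuple(int(t) for t in self.target_nodes))

    def replace(self, **kwargs) -> "CohortConfig":
        """Return a copy with the given fields replaced."""
        d = asdict(self)
        d.update(kwargs)
        return CohortConfig(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["target_nodes"] = list(self.target_nodes)
        return d
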