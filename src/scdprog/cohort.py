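"""Synthetic labeled cohorts with planted progression signal.

Generates cohorts with the statistical structure the pipeline assumes — by
default 76 subjects (24 progressive, 52 stable) and 223 named features
(25 clinical + 198 MRI) — so that every stage is testable without access to
the original cohort.  Five features carry planted group effects whose
directions match the reported findings: lower education, lower baseline
MoCA, higher baseline stroke prevalence, a smaller left amygdala, and a
larger white-matter volume under the right banks of the superior temporal
sulcus in the progressive group.  All remaining features are label-free
noise with an exchangeable background correlation.

``effect_scale`` multiplies every planted group difference about the stable
group's parameters; at 0 the cohort is an exact null, at 1 the differences
match the configured (tabulated) group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import assembly
from .matrix import FeatureMatrix
from .validation import ConfusionMatrix

__all__ = [
    "PlantedContinuous",
    "PlantedBinary",
    "SyntheticConfig",
    "SyntheticCohort",
    "DEFAULT_PLANTED",
    "generate_cohort",
    "make_worked_confusion",
]


@dataclass(frozen=True)
class PlantedContinuous:
    """A continuous feature with per-group mean/sd (stable first)."""

    name: str
    stable_mean: float
    stable_sd: float
    progressive_mean: float
    progressive_sd: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.progressive_mean - self.stable_mean))


@dataclass(frozen=True)
class PlantedBinary:
    """A binary feature with per-group prevalence (stable first)."""

    name: str
    stable_p: float
    progressive_p: float

    def __post_init__(self):
        for p in (self.stable_p, self.progressive_p):
            if not 0 <= p <= 1:
                raise ValueError("prevalences must lie in [0, 1]")

    @property
    def direction(self) -> int:
        return int(np.sign(self.progressive_p - self.stable_p))


#: The five default planted signal features.  Education, baseline MoCA and
#: baseline stroke use the tabulated cohort group summaries; the two MRI
#: volumes use a standardized effect of Cohen's d = 0.6 on plausible raw
#: volume scales (their group summaries are not tabulated), with the
#: reported directions.
DEFAULT_PLANTED: tuple = (
    PlantedContinuous("education", 9.50, 3.06, 7.17, 4.15),
    PlantedContinuous("moca_baseline", 24.04, 3.90, 22.96, 4.49),
    PlantedBinary("stroke_baseline", 3 / 52, 4 / 24),
    PlantedContinuous("subcort:Left-Amygdala", 1600.0, 200.0, 1480.0, 200.0),
    PlantedContinuous("wm:wm-rh-bankssts", 2500.0, 300.0, 2680.0, 300.0),
)

#: Plausible generation scales for background features, per block.
_BLOCK_SCALES = {
    "clinical": (10.0, 5.0),
    "global": (6000.0, 700.0),
    "thick": (2.5, 0.15),
    "wm": (2500.0, 300.0),
    "subcort": (1500.0, 200.0),
}


@dataclass
class SyntheticConfig:
    """Cohort size, feature schema, planted effects, and noise structure."""

    n_total: int = 76
    n_positive: int = 24
    n_clinical: int = 25
    n_mri: int = 198
    planted: tuple = DEFAULT_PLANTED
    noise_correlation: float = 0.2
    effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.n_positive < self.n_total:
            raise ValueError("require 0 < n_positive < n_total")
        if not 0 <= self.noise_correlation < 1:
            raise ValueError("noise_correlation must lie in [0, 1)")
        names = self.feature_names()
        if len(set(names)) != len(names):
            raise ValueError("feature names collide")
        unknown = [p.name for p in self.planted if p.name not in names]
        if unknown:
            raise ValueError(f"planted feature(s) not in schema: {unknown}")

    def feature_names(self) -> list[str]:
        if self.n_clinical == 25 and self.n_mri == 198:
            return list(assembly.DEFAULT_CLINICAL_FEATURES) + list(assembly.MRI_FEATURE_NAMES)
        return [f"clin_{i:03d}" for i in range(self.n_clinical)] + [
            f"mri_{i:03d}" for i in range(self.n_mri)
        ]


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth of what was planted."""

    matrix: FeatureMatrix
    config: SyntheticConfig
    planted_truth: dict[str, dict]


def _block_of(name: str) -> str:
    for prefix in ("global", "thick", "wm", "subcort"):
        if name.startswith(prefix + ":"):
            return prefix
    return "clinical"


def generate_cohort(cfg: SyntheticConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate one labeled synthetic cohort.

    Deterministic for a fixed ``cfg.seed`` (seeded ``numpy`` PCG64
    generator).  Binary features are drawn before continuous ones; the WM
    and subcortical blocks are normalized to sum to 1 per subject after
    planting, matching the semantics of assembled real data.
    """
    cfg = cfg or SyntheticConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)
    names = cfg.feature_names()
    n, d = cfg.n_total, len(names)
    col = {name: j for j, name in enumerate(names)}

    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=cfg.n_positive, replace=False)] = 1
    pos = labels == 1

    planted_names = {p.name for p in cfg.planted}
    binary_clinical = [
        name
        for name in names
        if name in assembly.BINARY_CLINICAL_FEATURES and name not in planted_names
    ]
    planted_binary = [p for p in cfg.planted if isinstance(p, PlantedBinary)]
    planted_cont = [p for p in cfg.planted if isinstance(p, PlantedContinuous)]

    X = np.zeros((n, d))

    # 1. binary features (background prevalence 0.3; planted per group).
    for name in binary_clinical:
        X[:, col[name]] = rng.binomial(1, 0.3, size=n)
    for p in planted_binary:
        p_prog = float(np.clip(p.stable_p + cfg.effect_scale * (p.progressive_p - p.stable_p), 0, 1))
        draws = np.where(pos, rng.binomial(1, p_prog, size=n), rng.binomial(1, p.stable_p, size=n))
        X[:, col[p.name]] = draws

    # 2. continuous background: exchangeable correlation via a shared
    #    per-subject factor.
    rho = cfg.noise_correlation
    shared = rng.standard_normal(n)
    cont_cols = [
        j
        for name, j in col.items()
        if name not in planted_names and name not in binary_clinical
    ]
    eps = rng.standard_normal((n, len(cont_cols)))
    z = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * eps
    for idx, j in enumerate(cont_cols):
        mean, sd = _BLOCK_SCALES[_block_of(names[j])]
        X[:, j] = mean + sd * z[:, idx]

    # 3. planted continuous features, independent of the background factor.
    for p in planted_cont:
        prog_mean = p.stable_mean + cfg.effect_scale * (p.progressive_mean - p.stable_mean)
        draws = np.where(
            pos,
            rng.normal(prog_mean, p.progressive_sd, size=n),
            rng.normal(p.stable_mean, p.stable_sd, size=n),
        )
        X[:, col[p.name]] = draws

    # volumes and thicknesses must stay positive
    for j, name in enumerate(names):
        block = _block_of(name)
        if block in ("global", "wm", "subcort"):
            X[:, j] = np.maximum(X[:, j], 1.0)
        elif block == "thick":
            X[:, j] = np.clip(X[:, j], 0.5, 6.0)

    # 4. normalized-block realism: WM and subcortical rows sum to 1.
    for prefix in ("wm", "subcort"):
        idx = [j for j, name in enumerate(names) if name.startswith(prefix + ":")]
        if idx:
            X[:, idx] /= X[:, idx].sum(axis=1, keepdims=True)

    truth: dict[str, dict] = {}
    for p in cfg.planted:
        if isinstance(p, PlantedContinuous):
            truth[p.name] = {
                "type": "continuous",
                "direction": p.direction,
                "stable_mean": p.stable_mean,
                "progressive_mean": p.stable_mean
                + cfg.effect_scale * (p.progressive_mean - p.stable_mean),
            }
        else:
            truth[p.name] = {
                "type": "binary",
                "direction": p.direction,
                "stable_p": p.stable_p,
                "progressive_p": float(
                    np.clip(p.stable_p + cfg.effect_scale * (p.progressive_p - p.stable_p), 0, 1)
                ),
            }

    fm = FeatureMatrix(
        subject_ids=[f"S{i:03d}" for i in range(n)],
        feature_names=names,
        values=X,
        labels=labels,
    )
    return SyntheticCohort(matrix=fm, config=cfg, planted_truth=truth)


def make_worked_confusion() -> ConfusionMatrix:
    """The canonical printed outer-LOOCV confusion counts.

    15 of 24 progressive and 38 of 52 stable subjects correctly identified:
    TP=15, FN=9, TN=38, FP=14.
    """
    return ConfusionMatrix(tp=15, fp=14, fn=9, tn=38)
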