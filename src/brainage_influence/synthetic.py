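"""Synthetic aging-cohort generator with planted age and disease structure.

All synthetic parameters are stand-ins: restricted clinical cohorts cannot be
redistributed, so this module emulates the *structure* such data exhibits —
volumetric brain features that track chronological age strongly but separate
diagnostic groups weakly, and cognitive test scores that track age weakly but
separate diagnostic groups strongly, with collinearity among the volumetric
features induced by a shared per-subject latent factor.

The generative model for feature ``j`` of subject ``i`` is

    x_ij = intercept_j + slope_j * age_i + offset_j(label_i)
           + loading * z_i * [j shares latent] + eps_ij,

with ``age_i`` uniform on the configured range, ``z_i`` standard normal and
``eps_ij ~ N(0, noise_sd_j^2)``.  Fixed seed => bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable

__all__ = [
    "FeatureSpec",
    "SyntheticSpec",
    "generate_cohort",
    "default_adni_like_spec",
    "VOLUMETRIC_FEATURES",
    "COGNITIVE_FEATURES",
    "spec_to_yaml",
    "spec_from_yaml",
]

#: The ten normalized volumetric features and six neuropsychological scores
#: used throughout; volume features carry the age signal, scores the
#: diagnostic signal.
VOLUMETRIC_FEATURES: tuple[str, ...] = (
    "Grey Matter",
    "White Matter",
    "Cerebrospinal Fluid",
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens",
)

COGNITIVE_FEATURES: tuple[str, ...] = (
    "MMSE",
    "ADAS",
    "FAQ",
    "MoCA",
    "ADNI Memory",
    "ADNI Executive Function",
)


@dataclass
class FeatureSpec:
    """Generative parameters of one synthetic feature.

    ``age_slope`` is per year on the feature's (arbitrary, z-like) scale;
    ``group_offsets`` maps clinical labels to additive shifts (labels absent
    from the mapping get offset 0); ``shares_latent`` marks the feature as
    loading on the shared collinearity factor.
    """

    name: str
    age_slope: float
    group_offsets: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    shares_latent: bool = False
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be > 0 for feature {self.name!r}")


@dataclass
class SyntheticSpec:
    """Full cohort recipe: group sizes, age range, features, collinearity, seed."""

    n_per_group: dict[str, int]
    age_range: tuple[float, float]
    feature_specs: list[FeatureSpec]
    latent_loading: float = 0.0
    seed: int = 0
    age_distribution: str = "uniform"  # "uniform" | "normal"

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range must satisfy min < max, got {self.age_range}")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group counts must be >= 0")
        if self.latent_loading < 0:
            raise ValueError("latent_loading must be >= 0")
        if self.age_distribution not in ("uniform", "normal"):
            raise ValueError(f"unknown age_distribution {self.age_distribution!r}")
        names = [f.name for f in self.feature_specs]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")


def generate_cohort(spec: SyntheticSpec) -> CohortTable:
    """Draw a cohort from ``spec``; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    labels: list[str] = []
    for label, n in spec.n_per_group.items():
        labels.extend([label] * n)
    n_total = len(labels)
    if n_total == 0:
        raise ValueError("spec produces an empty cohort")

    lo, hi = spec.age_range
    if spec.age_distribution == "uniform":
        ages = rng.uniform(lo, hi, size=n_total)
    else:
        mid, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
        ages = np.clip(rng.normal(mid, sd, size=n_total), lo, hi)
    latent = rng.standard_normal(n_total)

    data = {"age": ages, "label": labels}
    for fs in spec.feature_specs:
        offsets = np.array([fs.group_offsets.get(lab, 0.0) for lab in labels])
        values = (
            fs.intercept
            + fs.age_slope * ages
            + offsets
            + (spec.latent_loading * latent if fs.shares_latent else 0.0)
            + rng.normal(0.0, fs.noise_sd, size=n_total)
        )
        data[fs.name] = values

    width = max(4, len(str(n_total)))
    ids = [f"S{i:0{width}d}" for i in range(1, n_total + 1)]
    frame = pd.DataFrame(data, index=pd.Index(ids, name="subject_id"))
    return CohortTable(frame, [fs.name for fs in spec.feature_specs])


def default_adni_like_spec(seed: int = 0) -> SyntheticSpec:
    """The default study conditions: a 870-subject cohort shaped like an
    Alzheimer's aging study.

    Group sizes: CN 300, MCI 300, AD 100, sMCI 120, pMCI 50; ages uniform on
    55-90 years.  Volumetric features get large |age slope| relative to their
    noise and small diagnostic offsets; cognitive scores get small |age slope|
    and large CN -> MCI -> AD offsets, with sMCI and pMCI nearly equal at
    baseline (both groups present as MCI when first seen).  Signs follow
    anatomy: volumes and cognitive scores decline with age/disease, while
    cerebrospinal fluid, FAQ and ADAS increase with impairment.
    """
    # (age_slope per yr, {label: offset}) on a scale with noise_sd 0.15
    vol = {
        "Grey Matter": (-0.035, {"MCI": -0.05, "AD": -0.10, "sMCI": -0.05, "pMCI": -0.07}),
        "Thalamus": (-0.030, {"MCI": -0.03, "AD": -0.06, "sMCI": -0.03, "pMCI": -0.04}),
        "Cerebrospinal Fluid": (0.028, {"MCI": 0.03, "AD": 0.06, "sMCI": 0.03, "pMCI": 0.04}),
        "Hippocampus": (-0.026, {"MCI": -0.08, "AD": -0.15, "sMCI": -0.06, "pMCI": -0.11}),
        "Accumbens": (-0.022, {"MCI": -0.02, "AD": -0.05, "sMCI": -0.02, "pMCI": -0.04}),
        "Putamen": (-0.020, {"MCI": -0.02, "AD": -0.04, "sMCI": -0.02, "pMCI": -0.03}),
        "Amygdala": (-0.018, {"MCI": -0.05, "AD": -0.10, "sMCI": -0.04, "pMCI": -0.07}),
        "Pallidum": (-0.016, {"MCI": -0.01, "AD": -0.03, "sMCI": -0.01, "pMCI": -0.02}),
        "Caudate": (-0.012, {"MCI": -0.01, "AD": -0.02, "sMCI": -0.01, "pMCI": -0.02}),
        "White Matter": (-0.008, {"MCI": -0.01, "AD": -0.03, "sMCI": -0.01, "pMCI": -0.02}),
    }
    # (age_slope per yr, {label: offset}) on a scale with noise_sd 1.0.
    # Cognitive slopes are weak but detectable (|corr with age| ~ 0.15-0.2,
    # an order of magnitude below the volumes): scores do decline measurably
    # with age in healthy controls, and a control-trained regressor must be
    # able to resolve the coefficient's sign for the delta to be meaningful.
    cog = {
        "ADNI Memory": (-0.020, {"MCI": -1.20, "AD": -2.40, "sMCI": -1.15, "pMCI": -1.45}),
        "MMSE": (-0.016, {"MCI": -1.00, "AD": -2.20, "sMCI": -0.95, "pMCI": -1.25}),
        "ADAS": (0.017, {"MCI": 0.95, "AD": 2.10, "sMCI": 0.90, "pMCI": 1.30}),
        "FAQ": (0.014, {"MCI": 0.90, "AD": 2.00, "sMCI": 0.85, "pMCI": 1.15}),
        "MoCA": (-0.015, {"MCI": -0.80, "AD": -1.80, "sMCI": -0.78, "pMCI": -1.00}),
        "ADNI Executive Function": (-0.018, {"MCI": -0.70, "AD": -1.60, "sMCI": -0.68, "pMCI": -0.90}),
    }
    feature_specs = [
        FeatureSpec(name, age_slope=s, group_offsets=dict(off), noise_sd=0.15, shares_latent=True)
        for name, (s, off) in vol.items()
    ] + [
        FeatureSpec(name, age_slope=s, group_offsets=dict(off), noise_sd=1.0)
        for name, (s, off) in cog.items()
    ]
    # keep the declared feature order matching the canonical listing
    order = {n: i for i, n in enumerate(VOLUMETRIC_FEATURES + COGNITIVE_FEATURES)}
    feature_specs.sort(key=lambda fs: order[fs.name])
    return SyntheticSpec(
        n_per_group={"CN": 300, "MCI": 300, "AD": 100, "sMCI": 120, "pMCI": 50},
        age_range=(55.0, 90.0),
        feature_specs=feature_specs,
        latent_loading=0.08,
        seed=seed,
    )


# -- YAML (de)serialization for the CLI ------------------------------------

def spec_to_yaml(spec: SyntheticSpec, path: str | Path) -> Path:
    path = Path(path)
    doc = asdict(spec)
    doc["age_range"] = list(spec.age_range)
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return path


def spec_from_yaml(path: str | Path) -> SyntheticSpec:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    features = [FeatureSpec(**fs) for fs in doc.pop("feature_specs")]
    doc["age_range"] = tuple(doc["age_range"])
    return SyntheticSpec(feature_specs=features, **doc)
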