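"""Synthetic PU-masked tabular datasets with the structure the analysis assumes.

Emulates a high-dimensional acoustic-functional feature table: a small block of
informative features (class-conditional Gaussians), a large block of redundant
features (noisy linear combinations of the informative ones — real functional
features are highly correlated), and pure-noise features. Labels follow a
balanced-ish Bernoulli; PU flags follow SCAR masking, where each positive is
labeled independently with constant probability c = p(s=1 | y=1).

Because the informative block is class-conditionally Gaussian with unit variance
and mean shift ±class_sep/2, the true posterior has the closed form

    logit p(y=1|x) = class_sep * sum_k x_k + logit(pos_fraction)

over the informative columns only — redundant and noise columns carry no extra
information given the informative block. :func:`true_log_odds` exposes this
oracle for ranking/calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import ParameterError, SampleTable

__all__ = ["SynthSpec", "gen_pu_dataset", "true_log_odds", "spec_metadata"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic draw.

    Defaults mirror the balanced heart-sound setup at desk scale: 1,330 samples
    (665+665 after balancing), 200 features of which 165 carry signal
    (15 informative + 150 redundant) and 35 are noise, with 20% of positives
    labeled (c = 0.2).
    """

    n_samples: int = 1330
    d_informative: int = 15
    d_redundant: int = 150
    d_noise: int = 35
    class_sep: float = 2.0
    pos_fraction: float = 0.5
    labeled_fraction: float = 0.2
    redundancy_noise: float = 0.5
    seed: int = 0
    # the redundant-feature mixing matrix is part of the population, not of one
    # draw: it comes from its own stream so train and test draws of the same
    # population define every feature identically
    structure_seed: int = 20160101

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        if self.d_informative < 1:
            raise ParameterError("d_informative must be >= 1")
        if self.d_redundant < 0 or self.d_noise < 0:
            raise ParameterError("feature counts must be non-negative")
        if not 0.0 < self.pos_fraction < 1.0:
            raise ParameterError("pos_fraction must be in (0,1)")
        if not 0.0 < self.labeled_fraction <= 1.0:
            raise ParameterError("labeled_fraction must be in (0,1]")
        if self.class_sep < 0:
            raise ParameterError("class_sep must be >= 0")
        if self.redundancy_noise < 0:
            raise ParameterError("redundancy_noise must be >= 0")

    def with_seed(self, seed: int) -> "SynthSpec":
        return replace(self, seed=int(seed))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    # one sub-stream per component at a fixed offset: reproducible component-wise
    return {
        name: np.random.default_rng([seed, off])
        for off, name in enumerate(["y", "informative", "redundant", "noise", "mask"])
    }


def feature_names(spec: SynthSpec) -> list[str]:
    return (
        [f"inf_{i:03d}" for i in range(spec.d_informative)]
        + [f"red_{i:03d}" for i in range(spec.d_redundant)]
        + [f"noise_{i:03d}" for i in range(spec.d_noise)]
    )


def gen_pu_dataset(spec: SynthSpec) -> SampleTable:
    """Draw one PU-masked table, fully reproducible from ``spec.seed``."""
    spec.validate()
    rngs = _streams(spec.seed)
    n = spec.n_samples
    y = (rngs["y"].random(n) < spec.pos_fraction).astype(np.int8)
    shift = np.where(y == 1, spec.class_sep / 2.0, -spec.class_sep / 2.0)
    informative = rngs["informative"].standard_normal((n, spec.d_informative))
    informative += shift[:, None]
    blocks = [informative]
    if spec.d_redundant:
        structure_rng = np.random.default_rng(
            [spec.structure_seed, spec.d_informative, spec.d_redundant]
        )
        coef = structure_rng.standard_normal((spec.d_informative, spec.d_redundant))
        coef /= np.linalg.norm(coef, axis=0, keepdims=True)
        redundant = informative @ coef
        redundant += spec.redundancy_noise * rngs["redundant"].standard_normal(
            (n, spec.d_redundant)
        )
        blocks.append(redundant)
    if spec.d_noise:
        blocks.append(rngs["noise"].standard_normal((n, spec.d_noise)))
    X = np.concatenate(blocks, axis=1)
    s = ((y == 1) & (rngs["mask"].random(n) < spec.labeled_fraction)).astype(np.int8)
    features = pd.DataFrame(
        X,
        columns=feature_names(spec),
        index=pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id"),
    )
    return SampleTable(features=features, s=s, y=y)


def true_log_odds(spec: SynthSpec, table: SampleTable) -> np.ndarray:
    """Closed-form log-odds of y=1 given the informative columns (oracle)."""
    inf_cols = [f"inf_{i:03d}" for i in range(spec.d_informative)]
    x = table.features[inf_cols].to_numpy()
    prior = np.log(spec.pos_fraction / (1.0 - spec.pos_fraction))
    return spec.class_sep * x.sum(axis=1) + prior


def spec_metadata(spec: SynthSpec) -> dict:
    """Ground-truth sidecar: the SCAR constant and the feature-role lists."""
    names = feature_names(spec)
    return {
        "labeling_frequency_c": spec.labeled_fraction,
        "informative_features": names[: spec.d_informative],
        "redundant_features": names[
            spec.d_informative : spec.d_informative + spec.d_redundant
        ],
        "noise_features": names[spec.d_informative + spec.d_redundant :],
        "class_sep": spec.class_sep,
        "pos_fraction": spec.pos_fraction,
        "seed": spec.seed,
    }
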