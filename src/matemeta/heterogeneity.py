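"""I² heterogeneity partitioning for the multilevel model.

Total I² is the share of effect-size variance not attributable to sampling
error, computed against a "typical" sampling variance derived from the
inverse-variance weights; each random level contributes its own additive
slice (phylogenetic, species, study, observation I²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meta_model import VarianceComponents

__all__ = ["HeterogeneityPartition", "typical_sampling_variance", "i2_partition"]


@dataclass
class HeterogeneityPartition:
    """Typical sampling variance and the level-wise I² decomposition (%)."""

    sigma2_m: float
    i2_total: float
    i2_by_level: dict[str, float]

    @property
    def i2_phylo(self) -> float:
        return self.i2_by_level.get("phylogeny", 0.0)

    @property
    def i2_species(self) -> float:
        return self.i2_by_level.get("species", 0.0)

    @property
    def i2_study(self) -> float:
        return self.i2_by_level.get("study", 0.0)

    @property
    def i2_obs(self) -> float:
        return self.i2_by_level.get("observation", 0.0)


def typical_sampling_variance(v) -> float:
    """Typical within-study variance from inverse-variance weights.

    sigma2_m = (k - 1) * sum(w) / (sum(w)^2 - sum(w^2)),  w_i = 1 / v_i.
    Reduces to the common v when all sampling variances are equal.
    """
    v = np.asarray(v, float)
    if v.size < 2:
        raise ValueError("need at least 2 sampling variances")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    w = 1.0 / v
    sw = w.sum()
    return float((v.size - 1) * sw / (sw**2 - (w**2).sum()))


def i2_partition(sigma2: VarianceComponents, sigma2_m: float) -> HeterogeneityPartition:
    """Partition I² across the model's random levels.

    I²_level = 100 * sigma²_level / (total sigma² + sigma²_m); the level
    values sum to the total by construction.
    """
    if sigma2_m <= 0:
        raise ValueError("sigma2_m must be positive")
    denom = sigma2.total + sigma2_m
    by_level = {name: 100.0 * val / denom
                for name, val in sigma2.components.items()}
    return HeterogeneityPartition(
        sigma2_m=sigma2_m,
        i2_total=100.0 * sigma2.total / denom,
        i2_by_level=by_level,
    )
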