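"""Ground-truth simulation of state-dependent mate-choice datasets.

The generator reproduces the statistical structure the analysis assumes:
species-level true effects drawn over a simulated phylogeny (a Brownian
component with covariance s2_phylo * A plus an independent species
component), study- and observation-level normal deviations, sample-size
driven sampling error with variance 1/(n-3), an optional linear
publication-year trend, categorical moderators, and a reporting-censoring
process that turns a fraction of nonsignificant effects into directionless
zeros — mirroring how such results reach the literature.

A single root seed is split into per-stage streams (tree, design, effects,
noise, censoring, payloads), so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import effect_sizes as es
from .data_io import CodedEffect, Dataset, EffectSizeRecord
from .phylogeny import PhyloTree, brownian_correlation, grafen_calibrate, \
    tree_from_string

__all__ = ["SimulationTruth", "simulate_tree", "simulate_dataset",
           "simulate_raw_payloads"]

#: Two-sided 5% Wald threshold used by the censoring mechanism: effects with
#: |zr|/se below this may be reported as significance-only ("directionless").
CENSOR_Z = 1.959963984540054

_DEFAULT_FACTORS = ("age", "attractiveness", "body_size", "condition",
                    "mating_status", "parasite_load")


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters for one simulated meta-analytic dataset.

    Defaults are the package's standard recovery design: 40 species, 80
    studies of 2 effects each (k = 160), a grand mean of 0.1 on the Zr
    scale, variance components (phylogeny, species, study, observation) =
    (0.02, 0.01, 0.03, 0.04), per-test sample sizes uniform on 10..100, no
    year trend and no censoring.
    """

    beta0: float = 0.1
    moderator_effects: dict = field(
        default_factory=lambda: {f: 0.0 for f in _DEFAULT_FACTORS})
    sigma2_phylo: float = 0.02
    sigma2_species: float = 0.01
    sigma2_study: float = 0.03
    sigma2_obs: float = 0.04
    n_species: int = 40
    n_studies: int = 80
    effects_per_study: int = 2
    n_range: tuple = (10, 100)
    censor_prob: float = 0.0
    year_range: tuple = (1980, 2020)
    trend_per_year: float = 0.0
    study_level_moderator: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.censor_prob <= 1.0:
            raise ValueError("censor_prob must be in [0, 1]")
        if self.n_range[0] < 4:
            raise ValueError("n_range lower bound must be >= 4")
        for name in ("sigma2_phylo", "sigma2_species", "sigma2_study",
                     "sigma2_obs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_species < 2 or self.n_studies < 1 or self.effects_per_study < 1:
            raise ValueError("counts must be positive (n_species >= 2)")

    @property
    def sigma2(self) -> dict:
        return {"phylogeny": self.sigma2_phylo, "species": self.sigma2_species,
                "study": self.sigma2_study, "observation": self.sigma2_obs}

    @property
    def k(self) -> int:
        return self.n_studies * self.effects_per_study


class _Node:
    __slots__ = ("children", "label")

    def __init__(self, label=None):
        self.children = []
        self.label = label

    def newick(self) -> str:
        if not self.children:
            return self.label
        return "(" + ",".join(ch.newick() for ch in self.children) + ")"


def simulate_tree(n_species: int, seed) -> PhyloTree:
    """Pure-birth (Yule) topology, Grafen-calibrated to depth 1.

    Grown by sequential random tip splitting: starting from a two-tip tree,
    a uniformly chosen extant tip speciates until ``n_species`` tips exist.
    Deterministic given the seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_species)))
    root = _Node()
    leaves = [_Node("L"), _Node("L")]
    root.children = list(leaves)
    while len(leaves) < n_species:
        tip = leaves[int(rng.integers(len(leaves)))]
        kids = [_Node("L"), _Node("L")]
        tip.children = kids
        tip.label = None
        leaves.remove(tip)
        leaves.extend(kids)
    for i, leaf in enumerate(leaves, start=1):
        leaf.label = f"sp{i:0{width}d}"
    tree = tree_from_string(root.newick() + ";")
    return grafen_calibrate(tree)


def simulate_dataset(truth: SimulationTruth):
    """Draw one dataset and its latent truth table.

    Returns ``(dataset, latent)``: a full-variant :class:`Dataset` of coded
    effects over the simulated tree, and a DataFrame of the per-effect latent
    components (for recovery scoring).  Effects that are nonsignificant at
    the two-sided 5% level are converted to directionless zeros with
    probability ``censor_prob``; significant effects are never censored.
    """
    ss = np.random.SeedSequence(truth.seed)
    s_tree, s_design, s_effects, s_noise, s_censor = ss.spawn(5)

    tree = simulate_tree(truth.n_species, s_tree)
    corr = brownian_correlation(tree)
    species_labels = corr.labels

    rng_d = np.random.default_rng(s_design)
    k = truth.k
    study_species = rng_d.integers(0, truth.n_species, truth.n_studies)
    study_year = rng_d.integers(truth.year_range[0], truth.year_range[1] + 1,
                                truth.n_studies)
    levels = sorted(truth.moderator_effects)
    if truth.study_level_moderator:
        study_level = rng_d.integers(0, len(levels), truth.n_studies)
        effect_level = np.repeat(study_level, truth.effects_per_study)
    else:
        effect_level = rng_d.integers(0, len(levels), k)
    n_total = rng_d.integers(truth.n_range[0], truth.n_range[1] + 1, k)
    state_variation = rng_d.integers(0, 2, k)
    courter = rng_d.integers(0, 3, k)

    rng_e = np.random.default_rng(s_effects)
    A = corr.matrix
    chol = np.linalg.cholesky(A + 1e-12 * np.eye(len(A)))
    u_phylo = math.sqrt(truth.sigma2_phylo) * (chol @ rng_e.standard_normal(len(A)))
    u_species = math.sqrt(truth.sigma2_species) * rng_e.standard_normal(len(A))
    u_study = math.sqrt(truth.sigma2_study) * rng_e.standard_normal(truth.n_studies)
    e_obs = math.sqrt(truth.sigma2_obs) * rng_e.standard_normal(k)

    rng_n = np.random.default_rng(s_noise)
    v = 1.0 / (n_total - 3)
    study_of = np.repeat(np.arange(truth.n_studies), truth.effects_per_study)
    sp_of = study_species[study_of]
    year = study_year[study_of].astype(float)
    offsets = np.array([truth.moderator_effects[levels[i]] for i in effect_level])
    zr_true = (truth.beta0 + offsets
               + truth.trend_per_year * (year - year.mean())
               + u_phylo[sp_of] + u_species[sp_of] + u_study[study_of]
               + e_obs)
    zr_obs = zr_true + rng_n.standard_normal(k) * np.sqrt(v)

    rng_c = np.random.default_rng(s_censor)
    nonsig = np.abs(zr_obs) / np.sqrt(v) < CENSOR_Z
    censored = nonsig & (rng_c.random(k) < truth.censor_prob)

    sv_names = ("natural", "manipulated")
    ci_names = ("physical", "behavioral_only", "no_live_mate")
    effects = []
    for i in range(k):
        zr = 0.0 if censored[i] else float(zr_obs[i])
        effects.append(CodedEffect(
            record_id=f"e{i + 1:04d}",
            study_id=f"study{study_of[i] + 1:03d}",
            species=species_labels[sp_of[i]],
            sex="female",
            state_factor=levels[effect_level[i]],
            taxonomic_group="simulated",
            state_variation=sv_names[state_variation[i]],
            courter_interaction=ci_names[courter[i]],
            data_type="correlation",
            publication_year=int(year[i]),
            n_total=int(n_total[i]),
            directionless=bool(censored[i]),
            zr=zr,
            v=float(v[i]),
            r=math.tanh(zr),
        ))
    dataset = Dataset(effects, tree, "full", corr)
    latent = pd.DataFrame({
        "record_id": [e.record_id for e in effects],
        "species": [e.species for e in effects],
        "study_id": [e.study_id for e in effects],
        "state_factor": [e.state_factor for e in effects],
        "publication_year": year.astype(int),
        "n_total": n_total,
        "v": v,
        "u_phylo": u_phylo[sp_of],
        "u_species": u_species[sp_of],
        "u_study": u_study[study_of],
        "e_obs": e_obs,
        "zr_true": zr_true,
        "zr_obs": zr_obs,
        "censored": censored,
    })
    return dataset, latent


# ---------------------------------------------------------------------------
# Re-expressing coded effects as the four raw payload types

def _invert_r_to_d(r: float, n_1: int, n_2: int) -> float:
    a = (n_1 + n_2) ** 2 / (n_1 * n_2)
    return r * math.sqrt(a) / math.sqrt(1.0 - r * r)


def _best_freq_table(r_target: float, n: int) -> es.FreqTable:
    """Integer 2×2 table (counts summing to n, positive margins) whose phi
    is closest to the target correlation."""
    n1 = n // 2
    n2 = n - n1
    best, best_err = None, float("inf")
    for a in range(0, n1 + 1):
        b = n1 - a
        for c in range(0, n2 + 1):
            d = n2 - c
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            phi = (a * d - b * c) / math.sqrt(
                (a + b) * (c + d) * (a + c) * (b + d))
            err = abs(phi - r_target)
            if err < best_err:
                best, best_err = (a, b, c, d), err
    if best is None:
        raise ValueError(f"no valid 2x2 table for n = {n}")
    return es.FreqTable(*best)


def simulate_raw_payloads(dataset: Dataset, truth: SimulationTruth,
                          seed) -> list[EffectSizeRecord]:
    """Re-express each coded effect as one of the four raw data types.

    Payload types rotate round-robin (reported r, group means, two-group
    test statistic, 2×2 frequency table); direction metadata is randomized,
    with the raw statistic's sign flipped accordingly so that coding
    recovers the effect.  Conversions are exact except for frequency tables,
    which are the nearest integer-count table.  Directionless effects become
    zero-valued reported correlations flagged as directionless.
    """
    rng = np.random.default_rng(seed)
    order = ("correlation", "group_means", "group_test", "frequency")
    records = []
    for i, e in enumerate(dataset.effects):
        reversed_dir = bool(rng.integers(2))
        direction = "reversed" if reversed_dir else "as_predicted"
        sign = -1.0 if reversed_dir else 1.0
        n = e.n_total
        n1, n2 = n // 2, n - n // 2
        if e.directionless:
            data_type, payload = "correlation", es.RawCorrelation(0.0)
            direction = "as_predicted"
        else:
            data_type = order[i % len(order)]
            if data_type == "correlation":
                payload = es.RawCorrelation(sign * e.r)
            elif data_type == "group_means":
                d = _invert_r_to_d(e.r, n1, n2)
                j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
                payload = es.GroupSummary(mean_1=sign * d / j, sd_1=1.0, n_1=n1,
                                          mean_2=0.0, sd_2=1.0, n_2=n2)
            elif data_type == "group_test":
                d = _invert_r_to_d(e.r, n1, n2)
                t = d / math.sqrt(1.0 / n1 + 1.0 / n2)
                if i % (2 * len(order)) < len(order):
                    payload = es.GroupTestStat("t", sign * t, n - 2, n1, n2)
                else:
                    # F carries no sign: the direction field alone orients it.
                    direction = "reversed" if e.r < 0 else "as_predicted"
                    payload = es.GroupTestStat("F_1df", t * t, n - 2, n1, n2)
            else:
                tbl = _best_freq_table(sign * e.r, n)
                payload = tbl
        records.append(EffectSizeRecord(
            record_id=e.record_id, study_id=e.study_id, species=e.species,
            sex=e.sex, state_factor=e.state_factor,
            taxonomic_group=e.taxonomic_group,
            state_variation=e.state_variation,
            courter_interaction=e.courter_interaction,
            data_type=data_type, publication_year=e.publication_year,
            n_total=e.n_total, high_state_direction=direction,
            directionless=e.directionless, payload=payload))
    return records
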