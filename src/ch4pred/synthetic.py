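"""Synthetic sheep datasets with the statistical structure the analysis assumes.

The generator emulates the study design the pipeline targets: 117 sheep of
which 101 contribute two measurement rounds and 16 contribute one (218
observations), a 330-genus compositional abundance table partitioned
308/9/5/8 across bacteria, archaea, protozoa and fungi, a per-animal random
intercept, a bimodal emitter structure (high vs low emitters), and a sparse
set of true effects acting on standardized log abundances plus the animal
covariates.

Per animal: body weight is drawn, dry matter intake follows BW linearly with
noise (animals fed to an energy requirement based on BW), and the A:P ratio
is drawn independently. Log genus abundances decompose into a genus baseline
(spread chosen to give a realistic rank-abundance curve), an animal-level
component, and a small record-level component, then are exponentiated and
closed to sum to one per record; structural zeros are injected at a
configurable rate (causal genera exempt by default so the ground-truth effect
scale stays well defined). The CH4 production response is

    y_ij = intercept + sum_j beta_j z_ij + alpha_i + eps_ij

with z the population-standardized causal features, alpha_i a Gaussian animal
intercept shifted +/- bimodal_offset/2 by emitter group, and eps_ij Gaussian
residual noise. CH4 yield is production divided by DMI.

Because a fitted random-intercept model cannot separate the emitter-group
offset from the Gaussian intercept, ``GroundTruth.sigma_alpha_marginal``
records the marginal animal-level SD sqrt(sigma_alpha^2 + p(1-p) d^2), the
quantity an LMM's sigma_alpha estimates on bimodal data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset_io import CANONICAL_COLUMNS, ConfigurationError, ObservationTable

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "recovery_report"]

_BREEDS = ("Coopworth", "Corriedale", "FinnishLandrace", "Perendale", "Romney", "Texel")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the study-shaped conditions.

    Effect sizes are in response units (g/d) per SD of the (log-transformed,
    for genera) predictor. ``sigma_alpha``/``sigma`` are the animal-intercept
    and residual SDs in g/d. ``bimodal_offset`` separates the high- and
    low-emitter group means; with ``group_mix`` = 0.5 and offset 3 g/d the
    marginal animal-level SD is ~2.1 g/d.
    """

    n_animals: int = 117
    n_single_record_animals: int = 16
    n_bacteria: int = 308
    n_archaea: int = 9
    n_protozoa: int = 5
    n_fungi: int = 8
    n_causal_genera: int = 8
    genus_effect_low: float = 0.8
    genus_effect_high: float = 1.2
    animal_effects: Mapping[str, float] = field(
        default_factory=lambda: {"dmi": 1.2, "bw": 1.2, "ap_ratio": 1.0}
    )
    intercept: float = 21.9
    sigma_alpha: float = 1.5
    sigma: float = 1.5
    bimodal_offset: float = 3.0
    group_mix: float = 0.5
    bw_mean: float = 42.0
    bw_sd: float = 6.0
    dmi_slope: float = 0.033
    dmi_noise_sd: float = 0.12
    ap_mean: float = 3.0
    ap_sd: float = 0.5
    genus_base_log_sd: float = 2.0
    genus_animal_log_sd: float = 1.0
    genus_record_log_sd: float = 0.15
    structural_zero_rate: float = 0.05
    zeros_exempt_causal: bool = True
    pseudocount: float = 1e-6
    seed: int = 0

    @property
    def n_genera(self) -> int:
        return self.n_bacteria + self.n_archaea + self.n_protozoa + self.n_fungi

    @property
    def n_obs(self) -> int:
        return 2 * self.n_animals - self.n_single_record_animals

    def validate(self) -> None:
        if self.n_animals < 2:
            raise ConfigurationError("need at least 2 animals")
        if not 0 <= self.n_single_record_animals <= self.n_animals:
            raise ConfigurationError(
                "n_single_record_animals must be between 0 and n_animals"
            )
        if self.n_causal_genera > self.n_bacteria:
            raise ConfigurationError("n_causal_genera cannot exceed n_bacteria")
        if min(self.n_bacteria, 0) < 0 or self.n_genera <= 0:
            raise ConfigurationError("genus counts must be positive")
        for name in ("sigma_alpha", "sigma", "bw_sd", "dmi_noise_sd", "ap_sd",
                     "genus_base_log_sd", "genus_animal_log_sd",
                     "genus_record_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.group_mix <= 1:
            raise ConfigurationError("group_mix must be in [0, 1]")
        if not 0 <= self.structural_zero_rate < 1:
            raise ConfigurationError("structural_zero_rate must be in [0, 1)")
        if self.genus_effect_low > self.genus_effect_high:
            raise ConfigurationError("genus effect range is inverted")


@dataclass(frozen=True)
class GroundTruth:
    """True data-generating quantities for recovery assessment."""

    true_support: tuple[str, ...]
    true_beta: Mapping[str, float]
    sigma_alpha: float
    sigma: float
    sigma_alpha_marginal: float
    intercept: float
    causal_genera: tuple[str, ...]
    group_labels: Mapping[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_support": list(self.true_support),
                "true_beta": {k: float(v) for k, v in self.true_beta.items()},
                "sigma_alpha": self.sigma_alpha,
                "sigma": self.sigma,
                "sigma_alpha_marginal": self.sigma_alpha_marginal,
                "intercept": self.intercept,
                "causal_genera": list(self.causal_genera),
                "group_labels": dict(self.group_labels),
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "GroundTruth":
        d = json.loads(text)
        return GroundTruth(
            true_support=tuple(d["true_support"]),
            true_beta=d["true_beta"],
            sigma_alpha=d["sigma_alpha"],
            sigma=d["sigma"],
            sigma_alpha_marginal=d["sigma_alpha_marginal"],
            intercept=d["intercept"],
            causal_genera=tuple(d["causal_genera"]),
            group_labels=d["group_labels"],
        )


def _genus_names(config: SyntheticConfig) -> list[str]:
    names = []
    for domain, count in (
        ("bacteria", config.n_bacteria),
        ("archaea", config.n_archaea),
        ("protozoa", config.n_protozoa),
        ("fungi", config.n_fungi),
    ):
        names.extend(f"{domain}__Genus{i + 1:03d}" for i in range(count))
    return names


def generate(config: SyntheticConfig) -> tuple[ObservationTable, GroundTruth]:
    """Generate one dataset plus its ground truth, deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_animals, n_obs = config.n_animals, config.n_obs
    animal_ids = [f"A{i + 1:03d}" for i in range(n_animals)]

    # which animals contribute one vs two records
    single = set(rng.choice(n_animals, size=config.n_single_record_animals,
                            replace=False).tolist())
    rows_animal, rows_round = [], []
    for i in range(n_animals):
        rows_animal.append(i)
        rows_round.append(1)
        if i not in single:
            rows_animal.append(i)
            rows_round.append(2)
    rows_animal = np.array(rows_animal)
    rows_round = np.array(rows_round)

    # emitter groups: deterministic count, random assignment
    n_high = int(round(config.group_mix * n_animals))
    high = np.zeros(n_animals, dtype=bool)
    high[rng.choice(n_animals, size=n_high, replace=False)] = True

    # animal covariates (constant within animal across rounds)
    bw = np.maximum(rng.normal(config.bw_mean, config.bw_sd, n_animals), 15.0)
    dmi = np.maximum(
        config.dmi_slope * bw + rng.normal(0.0, config.dmi_noise_sd, n_animals), 0.3
    )
    ap = np.maximum(rng.normal(config.ap_mean, config.ap_sd, n_animals), 0.5)
    sex = rng.choice(["F", "M"], size=n_animals)
    breed = rng.choice(_BREEDS, size=n_animals)

    # compositional genus abundances: log-normal draws closed to the simplex
    genus_names = _genus_names(config)
    G = config.n_genera
    base = rng.normal(0.0, config.genus_base_log_sd, G)
    animal_part = rng.normal(0.0, config.genus_animal_log_sd, (n_animals, G))
    record_part = rng.normal(0.0, config.genus_record_log_sd, (n_obs, G))
    log_ab = base[None, :] + animal_part[rows_animal] + record_part
    abundance = np.exp(log_ab)

    # causal genera: bacteria from the more abundant half (detectable biomarkers)
    bact_order = np.argsort(-base[: config.n_bacteria])
    pool_size = min(config.n_bacteria,
                    max(config.n_causal_genera, config.n_bacteria // 2))
    causal_idx = np.sort(rng.choice(bact_order[:pool_size],
                                    size=config.n_causal_genera, replace=False))
    causal_genera = tuple(genus_names[i] for i in causal_idx)

    if config.structural_zero_rate > 0:
        zero_mask = rng.random((n_obs, G)) < config.structural_zero_rate
        if config.zeros_exempt_causal:
            zero_mask[:, causal_idx] = False
        abundance[zero_mask] = 0.0
    abundance /= abundance.sum(axis=1, keepdims=True)

    # true effects on population-standardized features
    signs = rng.choice([-1.0, 1.0], size=config.n_causal_genera)
    mags = rng.uniform(config.genus_effect_low, config.genus_effect_high,
                       config.n_causal_genera)
    genus_beta = dict(zip(causal_genera, signs * mags))
    true_beta: dict[str, float] = {k: float(v) for k, v in config.animal_effects.items()}
    true_beta.update({k: float(v) for k, v in genus_beta.items()})

    def _zscore(x: np.ndarray) -> np.ndarray:
        s = x.std(ddof=1)
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    signal = np.zeros(n_obs)
    covariate_rows = {"dmi": dmi[rows_animal], "bw": bw[rows_animal],
                      "ap_ratio": ap[rows_animal]}
    for name, beta_j in config.animal_effects.items():
        if name not in covariate_rows:
            raise ConfigurationError(f"unknown animal covariate {name!r}")
        signal += beta_j * _zscore(covariate_rows[name])
    log_closed = np.log(abundance + config.pseudocount)
    for g, beta_j in genus_beta.items():
        j = genus_names.index(g)
        signal += beta_j * _zscore(log_closed[:, j])

    offset = np.where(high, config.bimodal_offset / 2.0, -config.bimodal_offset / 2.0)
    alpha = offset + rng.normal(0.0, config.sigma_alpha, n_animals)
    eps = rng.normal(0.0, config.sigma, n_obs)
    production = config.intercept + signal + alpha[rows_animal] + eps
    ch4_yield = production / dmi[rows_animal]

    data = pd.DataFrame(
        {
            "animal_id": [animal_ids[i] for i in rows_animal],
            "round_index": rows_round,
            "ch4_production": production,
            "ch4_yield": ch4_yield,
            "dmi": dmi[rows_animal],
            "bw": bw[rows_animal],
            "ap_ratio": ap[rows_animal],
            "sex": sex[rows_animal],
            "breed": breed[rows_animal],
        }
    )
    ab_frame = pd.DataFrame(abundance, columns=genus_names)
    data = pd.concat([data, ab_frame], axis=1)

    table = ObservationTable(
        data=data[list(CANONICAL_COLUMNS) + genus_names],
        genus_columns=tuple(genus_names),
        genus_domains={g: g.split("__", 1)[0] for g in genus_names},
    )
    p = config.group_mix
    mixture_var = p * (1 - p) * config.bimodal_offset**2
    truth = GroundTruth(
        true_support=tuple(config.animal_effects) + causal_genera,
        true_beta=true_beta,
        sigma_alpha=config.sigma_alpha,
        sigma=config.sigma,
        sigma_alpha_marginal=float(np.sqrt(config.sigma_alpha**2 + mixture_var)),
        intercept=config.intercept,
        causal_genera=causal_genera,
        group_labels={
            animal_ids[i]: ("high" if high[i] else "low") for i in range(n_animals)
        },
    )
    return table, truth


def recovery_report(
    selected: Sequence[str],
    truth: GroundTruth,
    coefficients: Mapping[str, float] | None = None,
    sigma_alpha: float | None = None,
    sigma: float | None = None,
) -> dict[str, float]:
    """Support precision/recall, coefficient RMSE and variance relative errors.

    Coefficient RMSE is computed over the union of true and selected supports
    with absent coefficients treated as zero. The fitted sigma_alpha is
    compared against the marginal animal-level SD (what an LMM estimates on
    bimodal data).
    """
    sel = set(selected)
    true = set(truth.true_support)
    tp = len(sel & true)
    precision = 1.0 if not sel and not true else (tp / len(sel) if sel else 0.0)
    recall = 1.0 if not true else tp / len(true)
    out: dict[str, float] = {"precision": float(precision), "recall": float(recall),
                             "n_selected": float(len(sel)), "n_true": float(len(true))}
    if coefficients is not None:
        union = sel | true
        sq = [
            (float(coefficients.get(c, 0.0)) - float(truth.true_beta.get(c, 0.0))) ** 2
            for c in union
        ]
        out["coefficient_rmse"] = float(np.sqrt(np.mean(sq))) if sq else 0.0
    if sigma_alpha is not None:
        ref = truth.sigma_alpha_marginal
        out["sigma_alpha_relative_error"] = float(abs(sigma_alpha - ref) / ref)
    if sigma is not None:
        out["sigma_relative_error"] = float(abs(sigma - truth.sigma) / truth.sigma)
    return out
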