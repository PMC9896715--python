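"""Synthetic multi-region tumour/normal cohort generator with planted truth.

The generator emulates the statistical structure the downstream analysis
assumes: ~90 patients each contributing one adjacent-normal sample and 2-5
tumour-region samples; patient-specific baseline expression (pervasive
between-patient variability, with a distinctly high-variance stratum for
subgroup-restricted genes); cohort-wide up/down-regulated genes; up-regulated
genes restricted to one latent patient group; sparse patient-private
dysregulation; negative-binomial count noise on top of log-normal library
sizes; and exponential recurrence times with group-specific hazards.

Every planted assignment is returned as :class:`SimTruth` so recovery can be
asserted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, CountMatrix, SampleTable

CORE_UP = "CORE_UP"
CORE_DOWN = "CORE_DOWN"
SUBGROUP_UP = "SUBGROUP_UP"
NULL = "NULL"

GENE_CLASSES = (CORE_UP, CORE_DOWN, SUBGROUP_UP, NULL)


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Baseline parameters are on the natural-log scale of expected counts;
    effect sizes are log2 fold changes applied to tumour samples.
    """

    n_patients: int = 90
    tumour_regions_range: tuple[int, int] = (2, 5)
    n_genes: int = 2000
    gene_class_props: dict[str, float] = field(
        default_factory=lambda: {CORE_UP: 0.01, CORE_DOWN: 0.01, SUBGROUP_UP: 0.05, NULL: 0.93}
    )
    n_patient_groups: int = 3
    group_probs: tuple[float, ...] = (0.467, 0.4, 0.133)
    # probabilities that a SUBGROUP_UP gene targets each group; None ->
    # group_probs with the last (smallest, quiescent) group zeroed, renormalized
    subgroup_target_probs: tuple[float, ...] | None = None
    baseline_log_mean: float = 4.6
    baseline_log_sd: float = 1.2
    between_patient_sd: float = 0.8
    high_var_sd: float = 2.0
    core_up_log2fc: float = 2.0
    core_down_log2fc: float = -2.0
    subgroup_up_log2fc: float = 2.0
    private_rate: float = 0.05
    private_log2fc: float = 2.0
    dispersion: float = 0.05
    library_log_sd: float = 0.2
    hazards: tuple[float, ...] = (1 / 350, 1 / 550, 1 / 900)
    censor_horizon: float = 1500.0
    female_probs: tuple[float, ...] = (0.15, 0.25, 0.10)
    hbv_probs: tuple[float, ...] = (0.75, 0.65, 0.45)

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_genes < 1:
            raise ConfigError("n_patients and n_genes must be positive")
        lo, hi = self.tumour_regions_range
        if lo < 1 or hi < lo:
            raise ConfigError(f"empty tumour_regions_range {self.tumour_regions_range}")
        props = self.gene_class_props
        if set(props) != set(GENE_CLASSES):
            raise ConfigError(f"gene_class_props must cover {GENE_CLASSES}")
        if any(p < 0 for p in props.values()) or abs(sum(props.values()) - 1) > 1e-9:
            raise ConfigError("gene class proportions must be >=0 and sum to 1")
        k = self.n_patient_groups
        if len(self.group_probs) != k or abs(sum(self.group_probs) - 1) > 1e-9:
            raise ConfigError("group_probs must have one entry per group and sum to 1")
        if len(self.hazards) != k or any(h <= 0 for h in self.hazards):
            raise ConfigError("hazards must be positive, one per group")
        if self.subgroup_target_probs is not None:
            tp = self.subgroup_target_probs
            if len(tp) != k or any(p < 0 for p in tp) or abs(sum(tp) - 1) > 1e-9:
                raise ConfigError("subgroup_target_probs must be a distribution over groups")
        if self.dispersion < 0 or self.between_patient_sd < 0 or self.high_var_sd < 0:
            raise ConfigError("variance parameters must be non-negative")
        if self.censor_horizon < 0:
            raise ConfigError("censor_horizon must be >= 0")

    def target_probs(self) -> np.ndarray:
        if self.subgroup_target_probs is not None:
            return np.asarray(self.subgroup_target_probs, dtype=float)
        p = np.asarray(self.group_probs, dtype=float).copy()
        if len(p) > 1:
            p[-1] = 0.0
        return p / p.sum()


@dataclass
class SimTruth:
    """Planted ground truth: gene classes/targets, patient groups, baselines."""

    gene_classes: pd.DataFrame  # gene_id, gene_class, target_group (-1 if n/a)
    patient_groups: pd.DataFrame  # patient_id, group
    baselines: pd.DataFrame  # genes x patients, expected normal-tissue mean counts

    def group_of(self) -> dict[str, int]:
        return dict(zip(self.patient_groups["patient_id"], self.patient_groups["group"]))

    def genes_of_class(self, gene_class: str) -> list[str]:
        f = self.gene_classes
        return list(f.loc[f["gene_class"] == gene_class, "gene_id"])


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + dispersion * mu^2."""
    mean = np.maximum(mean, 1e-12)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mean * dispersion))


def simulate_cohort(
    config: SimConfig, seed: int
) -> tuple[CountMatrix, SampleTable, ClinicalTable, SimTruth]:
    """Simulate one multi-region cohort; a fixed seed gives bit-identical output."""
    config.validate()
    rng = np.random.default_rng(seed)
    G, P, K = config.n_genes, config.n_patients, config.n_patient_groups

    gene_ids = [f"G{i:05d}" for i in range(G)]
    patient_ids = [f"P{i:03d}" for i in range(P)]

    classes = rng.choice(
        GENE_CLASSES, size=G, p=[config.gene_class_props[c] for c in GENE_CLASSES]
    )
    target_group = np.full(G, -1, dtype=int)
    sub_mask = classes == SUBGROUP_UP
    target_group[sub_mask] = rng.choice(K, size=sub_mask.sum(), p=config.target_probs())

    groups = rng.choice(K, size=P, p=config.group_probs)

    # baselines: gene-level mean, patient-level deviation (wider for SUBGROUP_UP)
    mu_g = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=G)
    sd_g = np.where(sub_mask, config.high_var_sd, config.between_patient_sd)
    log_base = mu_g[:, None] + rng.normal(0.0, 1.0, size=(G, P)) * sd_g[:, None]
    baselines = np.exp(log_base)

    # tumour log2 effects per (gene, patient)
    effects = np.zeros((G, P))
    effects[classes == CORE_UP, :] = config.core_up_log2fc
    effects[classes == CORE_DOWN, :] = config.core_down_log2fc
    targeted = sub_mask[:, None] & (target_group[:, None] == groups[None, :])
    effects[targeted] = config.subgroup_up_log2fc
    if config.private_rate > 0:
        private = rng.random((G, P)) < config.private_rate
        signs = rng.choice([-1.0, 1.0], size=(G, P))
        effects = effects + private * signs * config.private_log2fc
    else:
        private = np.zeros((G, P), dtype=bool)

    lo, hi = config.tumour_regions_range
    n_regions = rng.integers(lo, hi + 1, size=P)

    sample_rows = []
    cols = []  # (patient index, is_tumour)
    for i, pid in enumerate(patient_ids):
        sample_rows.append((f"{pid}_N", pid, "normal", ""))
        cols.append((i, False))
        for r in range(1, int(n_regions[i]) + 1):
            sample_rows.append((f"{pid}_T{r}", pid, "tumour", f"R{r}"))
            cols.append((i, True))

    S = len(cols)
    lib = np.exp(rng.normal(0.0, config.library_log_sd, size=S))
    mean_matrix = np.empty((G, S))
    for j, (i, is_tumour) in enumerate(cols):
        m = baselines[:, i]
        if is_tumour:
            m = m * np.exp2(effects[:, i])
        mean_matrix[:, j] = m * lib[j]
    counts = _nb_counts(rng, mean_matrix, config.dispersion)

    sample_table = SampleTable(
        pd.DataFrame(sample_rows, columns=["sample_id", "patient_id", "sample_type", "region"])
    )
    count_matrix = CountMatrix(gene_ids, [r[0] for r in sample_rows], counts)

    clinical = _simulate_clinical(config, rng, patient_ids, groups)

    truth = SimTruth(
        gene_classes=pd.DataFrame(
            {"gene_id": gene_ids, "gene_class": classes, "target_group": target_group}
        ),
        patient_groups=pd.DataFrame({"patient_id": patient_ids, "group": groups}),
        baselines=pd.DataFrame(baselines, index=gene_ids, columns=patient_ids),
    )
    return count_matrix, sample_table, clinical, truth


def _simulate_clinical(
    config: SimConfig, rng: np.random.Generator, patient_ids: list[str], groups: np.ndarray
) -> ClinicalTable:
    surv = simulate_recurrence(
        dict(zip(patient_ids, (int(g) for g in groups))),
        {k: config.hazards[k] for k in range(config.n_patient_groups)},
        config.censor_horizon,
        rng=rng,
    )
    female = rng.random(len(patient_ids)) < np.asarray(config.female_probs)[groups]
    hbv = rng.random(len(patient_ids)) < np.asarray(config.hbv_probs)[groups]
    # AFP-like marker: log-normal, elevated in faster-recurring groups
    afp = np.exp(rng.normal(3.0 + 0.8 * (groups == int(np.argmax(config.hazards))), 1.2))
    frame = surv.frame.copy()
    frame["sex"] = np.where(female, "female", "male")
    frame["hbv_status"] = np.where(hbv, "positive", "negative")
    frame["afp"] = np.round(afp, 2)
    return ClinicalTable(frame)


def simulate_recurrence(
    groups: dict[str, int],
    hazards: dict[int, float],
    censor_horizon: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ClinicalTable:
    """Exponential event times per group, censored at the horizon.

    ``groups`` maps patient -> group label; ``hazards`` maps each group to its
    exponential rate (events per day).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    missing = {g for g in groups.values() if g not in hazards}
    if missing:
        raise ConfigError(f"no hazard for groups {sorted(missing)}")
    if any(h <= 0 for h in hazards.values()):
        raise ConfigError("hazards must be positive")
    if censor_horizon < 0:
        raise ConfigError("censor_horizon must be >= 0")
    rows = []
    for pid, g in groups.items():
        t = rng.exponential(1.0 / hazards[g])
        if t > censor_horizon:
            rows.append((pid, censor_horizon, 0))
        else:
            rows.append((pid, t, 1))
    return ClinicalTable(pd.DataFrame(rows, columns=["patient_id", "rfs_days", "recurrence_event"]))
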