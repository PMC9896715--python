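"""DEPC aggregation of per-patient DE calls, AP/NAP classification and the
pairing-permutation null.

The Differentially Expressed Patient Count (DEPC) of a gene is the number of
patients in whose per-patient analysis the gene is called up- (or down-)
regulated.  Genes with per-patient calls split into AP genes (also called in
the cohort-level all-patients analysis, same direction) and NAP genes (not
called there) — the NAP stratum is where subgroup-restricted dysregulation
hides from the conventional analysis.  The subgroup-gene threshold is two
sample standard deviations above the mean DEPC, computed over genes with at
least one call in the given direction; the comparison is inclusive
(depc >= threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import run_per_patient
from .io import NORMAL, CountMatrix, SampleTable

DIRECTIONS = ("up", "down")


def compute_depc(per_patient_calls: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Count, per gene, the patients calling it up and down.

    The gene universe is the outer union across patients; a gene absent from
    a patient's table counts as "none" for that patient.
    """
    if not per_patient_calls:
        raise ValueError("no per-patient results")
    genes: dict[str, int] = {}
    for table in per_patient_calls.values():
        for g in table["gene_id"]:
            genes.setdefault(g, len(genes))
    up = np.zeros(len(genes), dtype=int)
    down = np.zeros(len(genes), dtype=int)
    for table in per_patient_calls.values():
        idx = table["gene_id"].map(genes).to_numpy()
        call = table["call"].to_numpy()
        np.add.at(up, idx[call == "up"], 1)
        np.add.at(down, idx[call == "down"], 1)
    return pd.DataFrame(
        {
            "gene_id": list(genes),
            "depc_up": up,
            "depc_down": down,
            "n_patients": len(per_patient_calls),
        }
    )


def depc_threshold(depc_values, universe: str = "nonzero") -> float:
    """mean + 2 * sample SD of the DEPC values (over genes with depc >= 1)."""
    vals = np.asarray(depc_values, dtype=float)
    if universe == "nonzero":
        vals = vals[vals >= 1]
    elif universe != "all":
        raise ValueError("universe must be 'nonzero' or 'all'")
    if vals.size == 0 or np.all(vals == 0):
        raise ValueError("no informative DEPC values (all zero)")
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    return float(vals.mean() + 2.0 * sd)


def classify_ap_nap(
    depc: pd.DataFrame,
    ap_calls: pd.DataFrame,
    direction: str,
    threshold_universe: str = "nonzero",
) -> pd.DataFrame:
    """Split per-patient DE genes into AP/NAP for one direction.

    Rows cover genes with depc >= 1 in ``direction``; ``above_threshold``
    marks genes at/above the mean + 2 SD DEPC threshold.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    col = f"depc_{direction}"
    ap_genes = set(ap_calls.loc[ap_calls["call"] == direction, "gene_id"])
    sub = depc.loc[depc[col] >= 1, ["gene_id", col]].copy()
    thr = depc_threshold(depc[col], universe=threshold_universe)
    sub["direction"] = direction
    sub["gene_class"] = np.where(sub["gene_id"].isin(ap_genes), "AP", "NAP")
    sub["above_threshold"] = sub[col] >= thr
    sub = sub.rename(columns={col: "depc"})
    sub.attrs["threshold"] = thr
    return sub.reset_index(drop=True)


def depc_curve(depc: pd.DataFrame, class_table: pd.DataFrame, direction: str) -> pd.DataFrame:
    """#AP and #NAP genes with depc >= t, for t = 1..n_patients."""
    n_patients = int(depc["n_patients"].iloc[0]) if len(depc) else 0
    cls = class_table.set_index("gene_id")["gene_class"]
    col = f"depc_{direction}"
    merged = depc[["gene_id", col]].copy()
    merged["gene_class"] = merged["gene_id"].map(cls)
    rows = []
    for t in range(1, n_patients + 1):
        at = merged[merged[col] >= t]
        rows.append(
            (t, int((at["gene_class"] == "AP").sum()), int((at["gene_class"] == "NAP").sum()))
        )
    return pd.DataFrame(rows, columns=["threshold", "ap_count", "nap_count"])


def depc_value_counts(depc: pd.DataFrame, direction: str, n_patients: int) -> np.ndarray:
    """#genes with depc >= t for t = 1..n_patients (classification-free curve)."""
    col = f"depc_{direction}"
    vals = depc[col].to_numpy()
    return np.array([(vals >= t).sum() for t in range(1, n_patients + 1)])


@dataclass
class PermutationResult:
    """Observed vs pairing-permuted DEPC curves (counts of genes at depc >= t)."""

    thresholds: np.ndarray
    observed_up: np.ndarray
    observed_down: np.ndarray
    permuted_up: np.ndarray  # (n_perm, n_thresholds)
    permuted_down: np.ndarray

    @property
    def perm_mean_up(self) -> np.ndarray:
        return self.permuted_up.mean(axis=0)

    @property
    def perm_sd_up(self) -> np.ndarray:
        return self.permuted_up.std(axis=0, ddof=1)

    @property
    def perm_mean_down(self) -> np.ndarray:
        return self.permuted_down.mean(axis=0)

    @property
    def perm_sd_down(self) -> np.ndarray:
        return self.permuted_down.std(axis=0, ddof=1)

    def genes_in_band(self, lo: int, hi: int, direction: str = "up") -> tuple[float, float]:
        """(observed, permuted-mean) count of genes with depc in [lo, hi]."""
        obs = self.observed_up if direction == "up" else self.observed_down
        perm = self.perm_mean_up if direction == "up" else self.perm_mean_down
        upper_obs = obs[hi] if hi < len(obs) else 0.0
        upper_perm = perm[hi] if hi < len(perm) else 0.0
        return float(obs[lo - 1] - upper_obs), float(perm[lo - 1] - upper_perm)


def permuted_sample_table(samples: SampleTable, perm: np.ndarray) -> SampleTable:
    """Reassign normal samples among patients: patient i receives the normal
    sample of patient perm[i]; tumour samples keep their patient."""
    patients = samples.patient_ids
    frame = samples.frame.copy()
    normal_of = {p: samples.samples_of(p, NORMAL) for p in patients}
    for p, donors in normal_of.items():
        if len(donors) != 1:
            raise ValueError(f"patient {p!r} does not have exactly 1 normal sample")
    for i, p in enumerate(patients):
        donor_normal = normal_of[patients[perm[i]]][0]
        frame.loc[frame["sample_id"] == donor_normal, "patient_id"] = p
    return SampleTable(frame)


def permute_normals(
    cm: CountMatrix,
    samples: SampleTable,
    n_perm: int = 100,
    seed: int = 0,
    **de_kwargs,
) -> PermutationResult:
    """Rerun per-patient DE + DEPC under random reassignments of the normals.

    Each permutation redistributes the adjacent-normal samples uniformly at
    random over patients (fixed points allowed), then recomputes the
    per-patient analysis and the DEPC curves.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    sub = samples.subset(cm.sample_ids)
    patients = sub.patient_ids
    if len(patients) < 3:
        raise ValueError("need >=3 patients to permute pairings")
    n_pat = len(patients)

    observed = compute_depc(run_per_patient(cm, sub, **de_kwargs))
    obs_up = depc_value_counts(observed, "up", n_pat)
    obs_down = depc_value_counts(observed, "down", n_pat)

    rng = np.random.default_rng(seed)
    perm_up = np.zeros((n_perm, n_pat))
    perm_down = np.zeros((n_perm, n_pat))
    for k in range(n_perm):
        perm = rng.permutation(n_pat)
        shuffled = permuted_sample_table(sub, perm)
        depc = compute_depc(run_per_patient(cm, shuffled, **de_kwargs))
        perm_up[k] = depc_value_counts(depc, "up", n_pat)
        perm_down[k] = depc_value_counts(depc, "down", n_pat)

    return PermutationResult(
        thresholds=np.arange(1, n_pat + 1),
        observed_up=obs_up,
        observed_down=obs_down,
        permuted_up=perm_up,
        permuted_down=perm_down,
    )
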