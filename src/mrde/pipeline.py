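"""End-to-end orchestration: simulate -> filter -> DE -> DEPC -> co-cluster
-> survival/associations (-> enrichment -> classify), with one global seed.

Every stochastic stage derives its own seed from the global seed and the
stage name (hashed offsets), so stages are individually reproducible and two
runs with the same configuration are identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, de, depc, io, simulate, survstats
from .stratify import assign_groups, categorize, lbm_cocluster

log = logging.getLogger("mrde")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    outdir: str = "mrde_run"
    seed: int = 0
    # inputs; when counts is None the synthetic cohort is generated
    counts: str | None = None
    samples: str | None = None
    clinical: str | None = None
    gene_sets: str | None = None
    sim: dict = field(default_factory=dict)
    # thresholds mirroring the published defaults
    alpha: float = 0.05
    lfc_min: float = 1.0
    min_count: int = 1
    min_fraction: float = 0.3
    threshold_universe: str = "nonzero"
    n_row_clusters: int = 3
    n_col_clusters: int = 3
    n_restarts: int = 20
    survival_weight: str = "modified_peto"
    run_permutations: bool = False
    n_perm: int = 100


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the report directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items() if k != "sim"},
        "sim": dict(config.sim),
        "stage_seeds": {},
        "timings_s": {},
    }

    def timed(name):
        manifest["stage_seeds"][name] = stage_seed(config.seed, name)
        t0 = time.time()

        def done():
            manifest["timings_s"][name] = round(time.time() - t0, 3)
            log.info("stage %s finished in %.1fs", name, manifest["timings_s"][name])

        return manifest["stage_seeds"][name], done

    # ------------------------------------------------------------------ input
    if config.counts is None:
        seed, done = timed("simulate")
        sim_cfg = simulate.SimConfig(**config.sim)
        cm, samples, clinical, truth = simulate.simulate_cohort(sim_cfg, seed)
        io.write_counts(cm, outdir / "counts.tsv")
        io.write_sample_table(samples, outdir / "samples.tsv")
        io.write_clinical(clinical, outdir / "clinical.tsv")
        _write(truth.gene_classes, outdir / "truth_genes.tsv")
        _write(truth.patient_groups, outdir / "truth_patients.tsv")
        done()
    else:
        cm = io.read_counts(config.counts)
        samples = io.read_sample_table(config.samples)
        clinical = io.read_clinical(config.clinical) if config.clinical else None

    gene_sets = io.read_gmt(config.gene_sets) if config.gene_sets else None

    # ----------------------------------------------------------------- filter
    _, done = timed("filter")
    filtered = de.filter_genes(cm, min_count=config.min_count, min_fraction=config.min_fraction)
    done()

    # --------------------------------------------------------------------- DE
    _, done = timed("de_all")
    ap = de.run_all_patients(filtered, samples, alpha=config.alpha, lfc_min=config.lfc_min)
    _write(ap, outdir / "de_all_patients.tsv")
    done()

    _, done = timed("de_per_patient")
    per_patient = de.run_per_patient(filtered, samples, alpha=config.alpha,
                                     lfc_min=config.lfc_min)
    pp_dir = outdir / "per_patient"
    pp_dir.mkdir(exist_ok=True)
    for p, table in per_patient.items():
        _write(table, pp_dir / f"{p}.tsv")
    done()

    # ------------------------------------------------------------------- DEPC
    _, done = timed("depc")
    depc_table = depc.compute_depc(per_patient)
    _write(depc_table, outdir / "depc.tsv")
    classes = {}
    for direction in depc.DIRECTIONS:
        cls = depc.classify_ap_nap(depc_table, ap, direction,
                                   threshold_universe=config.threshold_universe)
        classes[direction] = cls
        _write(cls, outdir / f"classes_{direction}.tsv")
        _write(depc.depc_curve(depc_table, cls, direction), outdir / f"curve_{direction}.tsv")
    done()

    if config.run_permutations:
        seed, done = timed("permute")
        perm = depc.permute_normals(filtered, samples, n_perm=config.n_perm, seed=seed,
                                    alpha=config.alpha, lfc_min=config.lfc_min)
        _write(
            pd.DataFrame(
                {
                    "threshold": perm.thresholds,
                    "observed_up": perm.observed_up,
                    "perm_mean_up": perm.perm_mean_up,
                    "perm_sd_up": perm.perm_sd_up,
                    "observed_down": perm.observed_down,
                    "perm_mean_down": perm.perm_mean_down,
                    "perm_sd_down": perm.perm_sd_down,
                }
            ),
            outdir / "permutation_curves.tsv",
        )
        done()

    # ------------------------------------------------------------- co-cluster
    seed, done = timed("cocluster")
    nap_up = classes["up"]
    subset = list(nap_up.loc[nap_up["gene_class"].eq("NAP") & nap_up["above_threshold"],
                             "gene_id"])
    if len(subset) < config.n_row_clusters:
        log.warning("only %d NAP genes above threshold; falling back to all NAP genes",
                    len(subset))
        subset = list(nap_up.loc[nap_up["gene_class"].eq("NAP"), "gene_id"])
    cat = categorize(per_patient, subset)
    cat.to_csv(outdir / "categorical_matrix.tsv", sep="\t", index_label="gene_id")
    fit = lbm_cocluster(cat, n_row_clusters=config.n_row_clusters,
                        n_col_clusters=config.n_col_clusters,
                        n_restarts=config.n_restarts, seed=seed)
    grouping = assign_groups(fit, cat)
    _write(grouping.assignments, outdir / "grouping.tsv")
    theta_rows = [
        (l, k, *fit.theta[l, k]) for l in range(fit.theta.shape[0])
        for k in range(fit.theta.shape[1])
    ]
    _write(pd.DataFrame(theta_rows,
                        columns=["gene_cluster", "patient_cluster",
                                 "p_down", "p_none", "p_up"]),
           outdir / "blocks.tsv")
    (outdir / "cocluster_fit.json").write_text(json.dumps(
        {"loglik": fit.loglik, "objective": fit.objective, "seed": fit.seed,
         "n_restarts": fit.n_restarts}, indent=2))
    done()

    # ------------------------------------------------------------ de between
    sizes = grouping.assignments["group"].value_counts()
    if (sizes >= 2).sum() >= 2:
        _, done = timed("de_between")
        g0, g1 = list(sizes[sizes >= 2].index[:2])  # two largest groups
        between = de.run_between_groups(filtered, samples, grouping.as_dict(), g0, g1,
                                        alpha=config.alpha, lfc_min=config.lfc_min)
        _write(between, outdir / f"de_between_{g0}_vs_{g1}.tsv")
        done()

    # --------------------------------------------------------------- survival
    if clinical is not None:
        _, done = timed("survival")
        cf = clinical.frame.copy()
        cf["group"] = cf["patient_id"].map(grouping.as_dict())
        cf = cf.dropna(subset=["group"])
        km_rows = []
        for g, sub in cf.groupby("group"):
            km = survstats.km_estimate(sub["rfs_days"], sub["recurrence_event"])
            km.insert(0, "group", g)
            km_rows.append(km)
        _write(pd.concat(km_rows, ignore_index=True), outdir / "km_curves.tsv")
        res = survstats.weighted_logrank(cf["rfs_days"], cf["recurrence_event"], cf["group"],
                                         weight=config.survival_weight)
        _write(pd.DataFrame([{"method": res.method, "statistic": res.statistic,
                              "df": res.df, "p": res.p}]),
               outdir / "survival_test.tsv")
        categorical = [c for c in cf.columns
                       if cf[c].dtype == object and c not in ("patient_id", "group")]
        continuous = [c for c in cf.columns
                      if np.issubdtype(cf[c].dtype, np.number)
                      and c not in ("rfs_days", "recurrence_event")]
        assoc = survstats.association_report(clinical.frame, grouping.as_dict(),
                                             categorical, continuous,
                                             mc_seed=stage_seed(config.seed, "assoc"))
        _write(assoc, outdir / "associations.tsv")
        done()

    # ------------------------------------------------------------- enrichment
    if gene_sets is not None and subset:
        from .enrichment import enrich

        _, done = timed("enrich")
        table = enrich(subset, gene_sets, list(filtered.gene_ids), fdr_alpha=config.alpha)
        _write(table, outdir / "enrichment_nap_up.tsv")
        done()

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
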