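"""Negative-binomial Wald differential-expression engine.

Implements count filtering, median-of-ratios and TMM normalization, a
moment/trend dispersion estimator with log-scale shrinkage, and a batched
IRLS fit of per-gene NB log-link GLMs with size-factor offsets, for three
designs:

* ``all_patients`` — patient blocking plus a tumour-vs-normal term, the
  conventional cohort-level comparison;
* ``per_patient`` — tumour vs normal within a single patient, treating the
  patient's multi-region tumour samples as replicates;
* ``between_groups`` — difference of tumour-vs-normal effects between two
  patient groups, with patients nested inside their group.

Genes are called up/down when the BH-adjusted Wald p-value is below ``alpha``
(default 0.05) and |log2 fold change| exceeds ``lfc_min`` (default 1).

Log-fold-change shrinkage is deliberately not performed: the reported log2fc
is the (optionally ridge-stabilized) maximum-likelihood estimate, and the
decision rule operates on it directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import NORMAL, TUMOUR, CountMatrix, SampleTable

LN2 = math.log(2.0)
MIN_DISP = 1e-8
P_FLOOR = 1e-300

DE_COLUMNS = ["gene_id", "log2fc", "se", "pvalue", "padj", "call", "converged"]


class DesignError(ValueError):
    """Raised for rank-deficient or under-determined design matrices."""


class DegenerateInputError(ValueError):
    """Raised when an input admits no valid normalization."""


@dataclass
class NormalizedMatrix:
    """Log2-scale normalized expression with the method recorded."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    method: str  # {mor_log2, tmm_cpm_log, shifted_log}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_genes(cm: CountMatrix, min_count: int = 1, min_fraction: float = 0.3) -> CountMatrix:
    """Keep genes with >= min_count in >= ceil(min_fraction * n_samples) samples."""
    need = math.ceil(min_fraction * cm.n_samples)
    keep = (cm.counts >= min_count).sum(axis=1) >= need
    if not keep.any():
        warnings.warn("count filter removed every gene", stacklevel=2)
    kept = [g for g, k in zip(cm.gene_ids, keep) if k]
    return CountMatrix(kept, list(cm.sample_ids), cm.counts[keep])


def size_factors(cm: CountMatrix | np.ndarray, pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    Uses genes with all-positive counts as the reference; with
    ``pseudo_reference=True`` the geometric mean is instead taken over
    positive entries of genes expressed in at least half the samples, which
    rescues matrices with no all-positive row.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else np.asarray(cm)
    counts = counts.astype(float)
    positive = counts > 0
    allpos = positive.all(axis=1)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    if allpos.any():
        loggeo = logc[allpos].mean(axis=1)
        ratios = logc[allpos] - loggeo[:, None]
    elif pseudo_reference:
        usable = positive.sum(axis=1) >= max(1, counts.shape[1] // 2)
        if not usable.any():
            raise DegenerateInputError("no usable genes for pseudo-reference size factors")
        sub = logc[usable]
        pos = positive[usable]
        loggeo = np.where(pos, sub, 0.0).sum(axis=1) / pos.sum(axis=1)
        ratios = np.where(pos, sub - loggeo[:, None], np.nan)
    else:
        raise DegenerateInputError(
            "no gene has positive counts in every sample; "
            "retry with pseudo_reference=True"
        )
    factors = np.exp(np.nanmedian(ratios, axis=0))
    if not np.all(np.isfinite(factors)) or np.any(factors <= 0):
        raise DegenerateInputError("size factors are not finite and positive")
    return factors


def mor_log2(cm: CountMatrix, pseudocount: float = 1.0,
             pseudo_reference: bool = False) -> NormalizedMatrix:
    """log2(count / size_factor + pseudocount) on median-of-ratios factors."""
    sf = size_factors(cm, pseudo_reference=pseudo_reference)
    vals = np.log2(cm.counts / sf[None, :] + pseudocount)
    return NormalizedMatrix(list(cm.gene_ids), list(cm.sample_ids), vals, "mor_log2")


def shifted_log(cm: CountMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Shifted log on median-of-ratios normalized counts (display transform)."""
    out = mor_log2(cm, pseudocount=pseudocount, pseudo_reference=True)
    return NormalizedMatrix(out.gene_ids, out.sample_ids, out.values, "shifted_log")


def tmm_factors(counts: np.ndarray, trim_m: float = 0.3, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the one whose upper-quartile (of library-scaled
    counts) is closest to the mean upper-quartile. Per sample, M- and
    A-values over genes positive in both sample and reference are trimmed
    (``trim_m`` / ``trim_a`` from each tail) and the factor is the
    precision-weighted mean M.
    """
    counts = np.asarray(counts, dtype=float)
    G, S = counts.shape
    if S == 1:
        return np.ones(1)
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise DegenerateInputError("sample with zero library size")
    uq = np.array([np.quantile(counts[:, s] / lib[s], 0.75) for s in range(S)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(S)
    yr = counts[:, ref]
    for s in range(S):
        if s == ref:
            continue
        ys = counts[:, s]
        ok = (ys > 0) & (yr > 0)
        if ok.sum() < 10:
            continue
        a, b = ys[ok] / lib[s], yr[ok] / lib[ref]
        m = np.log2(a / b)
        av = 0.5 * np.log2(a * b)
        n = len(m)
        lo_m, hi_m = math.floor(n * trim_m), n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a), n - math.floor(n * trim_a)
        rank_m = stats.rankdata(m, method="ordinal")
        rank_a = stats.rankdata(av, method="ordinal")
        keep = (rank_m > lo_m) & (rank_m <= hi_m) & (rank_a > lo_a) & (rank_a <= hi_a)
        if not keep.any():
            continue
        # asymptotic inverse variance of M (delta method on two binomials)
        w = 1.0 / (
            (lib[s] - ys[ok]) / (lib[s] * ys[ok]) + (lib[ref] - yr[ok]) / (lib[ref] * yr[ok])
        )
        factors[s] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def tmm_cpm_log(cm: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05) -> NormalizedMatrix:
    """log2(CPM + 0.5) with TMM effective library sizes."""
    factors = tmm_factors(cm.counts, trim_m=trim_m, trim_a=trim_a)
    eff_lib = cm.counts.sum(axis=0) * factors
    cpm = cm.counts / eff_lib[None, :] * 1e6
    return NormalizedMatrix(list(cm.gene_ids), list(cm.sample_ids), np.log2(cpm + 0.5), "tmm_cpm_log")


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Design matrix, tested contrast (natural-log scale), and column names."""

    kind: str
    matrix: np.ndarray
    contrast: np.ndarray
    columns: list[str]
    sample_ids: list[str]

    def check_rank(self) -> None:
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            aliased = _aliased_columns(self.matrix, self.columns)
            raise DesignError(f"design is rank deficient; aliased columns: {aliased}")
        if self.matrix.shape[0] <= self.matrix.shape[1]:
            raise DesignError(
                f"{self.matrix.shape[0]} samples cannot identify "
                f"{self.matrix.shape[1]} design columns"
            )


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    # columns whose pivot magnitude collapses are (heuristically) aliased
    return [names[i] for i in range(len(diag)) if diag[i] < tol]


def _tumour_indicator(samples: SampleTable, sample_ids: list[str]) -> np.ndarray:
    f = samples.frame.set_index("sample_id")
    return (f.loc[sample_ids, "sample_type"] == TUMOUR).to_numpy(dtype=float)


def design_per_patient(samples: SampleTable, sample_ids: list[str]) -> DesignSpec:
    t = _tumour_indicator(samples, sample_ids)
    X = np.column_stack([np.ones(len(sample_ids)), t])
    return DesignSpec("per_patient", X, np.array([0.0, 1.0]), ["intercept", "tumour"], sample_ids)


def design_all_patients(samples: SampleTable, sample_ids: list[str]) -> DesignSpec:
    f = samples.frame.set_index("sample_id")
    pats = list(dict.fromkeys(f.loc[sample_ids, "patient_id"]))
    if len(pats) < 2:
        raise DesignError("all-patients design needs >=2 patients")
    t = _tumour_indicator(samples, sample_ids)
    cols = [np.ones(len(sample_ids))]
    names = ["intercept"]
    pat_of = f.loc[sample_ids, "patient_id"].to_numpy()
    for p in pats[1:]:  # drop-first patient coding
        cols.append((pat_of == p).astype(float))
        names.append(f"patient[{p}]")
    cols.append(t)
    names.append("tumour")
    X = np.column_stack(cols)
    c = np.zeros(X.shape[1])
    c[-1] = 1.0
    return DesignSpec("all_patients", X, c, names, sample_ids)


def design_between_groups(
    samples: SampleTable, sample_ids: list[str], grouping: dict[str, object], g0, g1
) -> DesignSpec:
    """Group + group:nested-patient + group:sample_type design.

    The tested contrast is the difference of tumour-vs-normal effects,
    group g1 minus group g0.
    """
    f = samples.frame.set_index("sample_id")
    pat_of = f.loc[sample_ids, "patient_id"].to_numpy()
    t = _tumour_indicator(samples, sample_ids)
    grp = np.array([grouping[p] for p in pat_of], dtype=object)
    n = len(sample_ids)
    cols = [np.ones(n)]
    names = ["intercept"]
    cols.append((grp == g1).astype(float))
    names.append(f"group[{g1}]")
    for g in (g0, g1):
        pats = list(dict.fromkeys(pat_of[grp == g]))
        if len(pats) < 2:
            raise DesignError(f"group {g!r} has fewer than 2 patients")
        for p in pats[1:]:  # renumbered within group, drop-first
            cols.append(((pat_of == p) & (grp == g)).astype(float))
            names.append(f"group[{g}]:patient[{p}]")
    for g in (g0, g1):
        cols.append(((grp == g) & (t == 1)).astype(float))
        names.append(f"group[{g}]:tumour")
    X = np.column_stack(cols)
    c = np.zeros(X.shape[1])
    c[names.index(f"group[{g1}]:tumour")] = 1.0
    c[names.index(f"group[{g0}]:tumour")] = -1.0
    spec = DesignSpec("between_groups", X, c, names, sample_ids)
    spec.check_rank()
    return spec


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(
    counts: np.ndarray,
    design: DesignSpec,
    sf: np.ndarray,
    shrink_weight: float = 0.5,
) -> np.ndarray:
    """Per-gene NB dispersions: moments estimate, 1/mu trend, log-scale blend.

    The gene-wise estimate comes from the residual variance of size-factor
    normalized counts around the design fit.  A robust regression of those
    estimates on 1/mean gives the trend alpha(mu) = a0 + a1/mu, and the final
    value blends gene and trend on the log scale with weight ``shrink_weight``
    on the trend.  When residual degrees of freedom are <= 1 (e.g. per-patient
    designs) the trend is used outright.
    """
    X = design.matrix
    n, p = X.shape
    if n < 2:
        raise DesignError("dispersion estimation needs >=2 samples")
    df = n - np.linalg.matrix_rank(X)
    if df < 1:
        raise DesignError("no residual degrees of freedom in design")
    z = counts / sf[None, :]
    beta, *_ = np.linalg.lstsq(X, z.T, rcond=None)
    resid = z - (X @ beta).T
    var = (resid**2).sum(axis=1) / df
    mu = z.mean(axis=1)
    xi = float(np.mean(1.0 / sf))  # Poisson part of var(count/sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gene = np.where(mu > 0, (var - xi * mu) / np.maximum(mu, 1e-12) ** 2, MIN_DISP)
    alpha_gene = np.clip(alpha_gene, MIN_DISP, 100.0)

    ok = mu > 1.0
    if ok.sum() >= 10:
        try:
            rlm = sm.RLM(
                alpha_gene[ok],
                np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]]),
                M=sm.robust.norms.HuberT(),
            ).fit()
            a0, a1 = float(rlm.params[0]), float(rlm.params[1])
        except Exception:  # singular fallback on pathological inputs
            a0, a1 = float(np.median(alpha_gene[ok])), 0.0
    else:
        a0, a1 = float(np.median(alpha_gene)), 0.0
    a0, a1 = max(a0, MIN_DISP), max(a1, 0.0)
    alpha_trend = np.clip(a0 + a1 / np.maximum(mu, 1e-12), MIN_DISP, 100.0)

    w = 1.0 if df <= 1 else float(np.clip(shrink_weight, 0.0, 1.0))
    return np.exp(w * np.log(alpha_trend) + (1.0 - w) * np.log(alpha_gene))


# ---------------------------------------------------------------------------
# NB GLM Wald test
# ---------------------------------------------------------------------------

def _irls_nb(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    ridge: float = 1e-9,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for per-gene NB log-link GLMs sharing one design.

    Returns (beta (G,p), var_beta (G,p,p), converged (G,)).
    """
    G, n = Y.shape
    p = X.shape[1]
    # working response initialisation on the log scale
    eta0 = np.log((Y + 0.5) / np.exp(offset)[None, :]) + offset[None, :]
    beta = np.linalg.lstsq(X, (eta0 - offset[None, :]).T, rcond=None)[0].T
    converged = np.zeros(G, dtype=bool)
    A_last = np.empty((G, p, p))
    active = np.arange(G)
    pen = ridge * np.eye(p)

    for _ in range(max_iter):
        if active.size == 0:
            break
        eta = np.clip(beta[active] @ X.T + offset[None, :], -50.0, 50.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[active, None] * mu)
        zc = (eta - offset[None, :]) + (Y[active] - mu) / mu  # centred working response
        XWt = (X[None, :, :] * W[:, :, None]).transpose(0, 2, 1)  # (g, p, n)
        A = XWt @ X + pen[None, :, :]
        b = (XWt @ zc[:, :, None])[..., 0]
        new = np.linalg.solve(A, b[..., None])[..., 0]
        step = np.abs(new - beta[active]).max(axis=1)
        beta[active] = new
        A_last[active] = A
        done = step < tol
        converged[active[done]] = True
        active = active[~done]

    # information at the final estimate for non-converged genes too
    eta = np.clip(beta @ X.T + offset[None, :], -50.0, 50.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    XWt = (X[None, :, :] * W[:, :, None]).transpose(0, 2, 1)
    A = XWt @ X + pen[None, :, :]
    var_beta = np.linalg.inv(A)
    return beta, var_beta, converged


def wald_test_nb(
    cm: CountMatrix,
    design: DesignSpec,
    dispersions: np.ndarray,
    sf: np.ndarray,
    ridge_prior: bool = False,
    chunk_size: int | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of the design's contrast; BH-adjusted p-values.

    ``ridge_prior`` enables a weak Normal(0, 4) log2-scale ridge on the
    coefficients as a stabiliser for separable designs (off by default; the
    reported fold changes are otherwise plain maximum likelihood).
    """
    design.check_rank()
    Y = cm.counts.astype(float)
    G, n = Y.shape
    p = design.matrix.shape[1]
    offset = np.log(sf)
    alpha = np.asarray(dispersions, dtype=float)
    if alpha.shape != (G,):
        raise ValueError("dispersions must be per-gene")
    ridge = 1.0 / (4.0 * LN2**2) if ridge_prior else 1e-9

    nonzero = Y.sum(axis=1) > 0
    log2fc = np.zeros(G)
    se = np.full(G, np.inf)
    converged = np.ones(G, dtype=bool)

    idx = np.flatnonzero(nonzero)
    if chunk_size is None:
        chunk_size = max(1, int(4_000_000 / max(n * p, 1)))
    c = design.contrast
    for start in range(0, idx.size, chunk_size):
        sel = idx[start : start + chunk_size]
        beta, var_beta, conv = _irls_nb(Y[sel], design.matrix, offset, alpha[sel], ridge=ridge)
        log2fc[sel] = beta @ c / LN2
        var_c = np.einsum("p,gpq,q->g", c, var_beta, c)
        se[sel] = np.sqrt(np.maximum(var_c, 0.0)) / LN2
        converged[sel] = conv

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)
    pvalue[~converged] = 1.0  # flagged below
    pvalue[~nonzero] = 1.0
    log2fc[~nonzero] = 0.0
    padj = multipletests(pvalue, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "log2fc": log2fc,
            "se": se,
            "pvalue": pvalue,
            "padj": np.clip(padj, 0.0, 1.0),
            "call": "none",
            "converged": converged,
        }
    )


def call_de(results: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 1.0) -> pd.DataFrame:
    """Apply the DE decision rule: padj < alpha and |log2fc| > lfc_min."""
    out = results.copy()
    sig = out["padj"] < alpha
    out["call"] = np.where(
        sig & (out["log2fc"] > lfc_min),
        "up",
        np.where(sig & (out["log2fc"] < -lfc_min), "down", "none"),
    )
    return out


# ---------------------------------------------------------------------------
# the three analyses
# ---------------------------------------------------------------------------

def run_all_patients(
    cm: CountMatrix,
    samples: SampleTable,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    shrink_weight: float = 0.5,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Cohort-level tumour-vs-normal DE with patient blocking."""
    sub = samples.subset(cm.sample_ids)
    one_sided = [
        p
        for p in sub.patient_ids
        if not (sub.samples_of(p, TUMOUR) and sub.samples_of(p, NORMAL))
    ]
    if one_sided:
        warnings.warn(
            f"patients with a single sample type contribute no contrast: {one_sided}",
            stacklevel=2,
        )
    design = design_all_patients(sub, cm.sample_ids)
    sf = size_factors(cm, pseudo_reference=pseudo_reference)
    disp = estimate_dispersions(cm.counts, design, sf, shrink_weight=shrink_weight)
    res = wald_test_nb(cm, design, disp, sf)
    return call_de(res, alpha=alpha, lfc_min=lfc_min)


def eligible_patients(samples: SampleTable) -> list[str]:
    """Patients with >=2 tumour samples and exactly 1 normal sample."""
    out = []
    for p in samples.patient_ids:
        if len(samples.samples_of(p, TUMOUR)) >= 2 and len(samples.samples_of(p, NORMAL)) == 1:
            out.append(p)
    return out


def run_per_patient(
    cm: CountMatrix,
    samples: SampleTable,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    pseudo_reference: bool = True,
) -> dict[str, pd.DataFrame]:
    """Tumour-vs-normal DE within each eligible patient.

    Eligibility requires >=2 tumour samples and exactly 1 normal sample;
    other patients are skipped with a warning.  Dispersion shrinkage is
    forced to the trend (a handful of samples cannot support gene-wise
    estimates).
    """
    sub = samples.subset(cm.sample_ids)
    eligible = eligible_patients(sub)
    skipped = [p for p in sub.patient_ids if p not in eligible]
    if skipped:
        warnings.warn(f"skipping patients without 2 tumours + 1 normal: {skipped}", stacklevel=2)
    if not eligible:
        raise ValueError("no patient has >=2 tumour samples and exactly 1 normal sample")
    out: dict[str, pd.DataFrame] = {}
    for p in eligible:
        ids = sub.samples_of(p, TUMOUR) + sub.samples_of(p, NORMAL)
        pcm = cm.subset_samples(ids)
        design = design_per_patient(sub, ids)
        sf = size_factors(pcm, pseudo_reference=pseudo_reference)
        disp = estimate_dispersions(pcm.counts, design, sf, shrink_weight=1.0)
        res = wald_test_nb(pcm, design, disp, sf)
        out[p] = call_de(res, alpha=alpha, lfc_min=lfc_min)
    return out


def run_between_groups(
    cm: CountMatrix,
    samples: SampleTable,
    grouping: dict[str, object],
    g0,
    g1,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    shrink_weight: float = 0.5,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Difference of tumour effects between patient groups g1 and g0."""
    sub = samples.subset(cm.sample_ids)
    keep = [
        s
        for s in cm.sample_ids
        if grouping.get(sub.patient_of(s)) in (g0, g1)
    ]
    sub_cm = cm.subset_samples(keep)
    sub_samples = sub.subset(keep)
    design = design_between_groups(sub_samples, keep, grouping, g0, g1)
    sf = size_factors(sub_cm, pseudo_reference=pseudo_reference)
    disp = estimate_dispersions(sub_cm.counts, design, sf, shrink_weight=shrink_weight)
    res = wald_test_nb(sub_cm, design, disp, sf)
    return call_de(res, alpha=alpha, lfc_min=lfc_min)
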