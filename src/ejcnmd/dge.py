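"""Gene-level differential expression with unwanted-variation correction.

The model is a per-gene negative-binomial log-linear regression of counts
on genotype plus k factors of unwanted variation, with log library-size
offsets.  Significance comes from a likelihood-ratio test of the full
design (intercept + genotype + W) against the reduced design (intercept +
W), referred to chi-square with 1 df.  Multiple testing is controlled by
Benjamini-Hochberg over all tested genes with no independent filtering,
and genes are called UP/DOWN at fold change 1.5 and FDR 0.05.

Unwanted-variation factors are estimated RUVs-style: log counts are
centred within replicate groups (removing the biological signal shared by
a group), and the leading singular directions of the centred sample
profiles are returned as the factor matrix W.

Library-size offsets use median-of-ratios size factors; per-gene
dispersions come from method-of-moments on normalised counts with a small
floor.  This is a contract-level reimplementation of the standard
NB-GLM/LRT workflow, not a clone of any particular tool's shrinkage
estimators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-6


class DEStatus(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    UNCHANGED = "UNCHANGED"
    EXCLUDED = "EXCLUDED"


@dataclass
class CountMatrix:
    """Gene x sample integer counts with sample metadata."""

    counts: pd.DataFrame  # genes x samples
    genotype: pd.Series  # sample -> {"WT", "mutant"}
    replicate_group: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for meta in (self.genotype, self.replicate_group):
            missing = set(counts.columns) - set(meta.index)
            if missing:
                raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.genotype = self.genotype.reindex(counts.columns)
        self.replicate_group = self.replicate_group.reindex(counts.columns)

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
        return cls(counts, sheet["genotype"], sheet["replicate_group"])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes positive in every sample."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        logger.warning("no gene positive in all samples; using total-count factors")
        total = mat.sum(axis=0)
        return pd.Series(total / np.exp(np.mean(np.log(total))), index=counts.columns)
    logs = np.log(mat[positive])
    ref = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_unwanted_variation(m: CountMatrix, k: int = 1) -> np.ndarray:
    """RUVs-style factors of unwanted variation (samples x k).

    Log2 counts are centred within replicate groups of biologically
    comparable samples, which cancels the signal of interest; the top-k
    left singular vectors of the centred sample-by-gene matrix capture
    residual technical structure.  k = 0 returns an empty matrix.
    """
    n_samples = m.counts.shape[1]
    if not 0 <= k < n_samples:
        raise ValueError(f"k must satisfy 0 <= k < {n_samples}")
    if k == 0:
        return np.empty((n_samples, 0))
    logc = np.log2(m.counts.to_numpy(dtype=float) + 1.0)  # genes x samples
    centred = np.zeros_like(logc)
    for group, samples in m.replicate_group.groupby(m.replicate_group):
        cols = [m.counts.columns.get_loc(s) for s in samples.index]
        if len(cols) == 1:
            logger.warning(
                "replicate group %r has a single sample; it contributes nothing",
                group,
            )
            continue
        sub = logc[:, cols]
        centred[:, cols] = sub - sub.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centred.T, full_matrices=False)
    return u[:, :k]


def _fit_nb_glm(y, X, offset, alpha):
    model = sm.GLM(
        y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100, tol=1e-8)


def _moments_dispersion(y: np.ndarray, sf: np.ndarray) -> float:
    """Method-of-moments NB dispersion on normalised counts of one group."""
    norm = y / sf
    mu = norm.mean()
    var = norm.var(ddof=1)
    if mu <= 0:
        return np.nan
    return (var - mu) / mu**2


def _genewise_moments(mat: np.ndarray, sf: np.ndarray, is_mut: np.ndarray) -> np.ndarray:
    """Raw (unfloored, possibly negative) moments dispersion per gene."""
    out = np.empty(mat.shape[0])
    for i in range(mat.shape[0]):
        y = mat[i]
        per_group = [
            _moments_dispersion(y[is_mut == g], sf[is_mut == g]) for g in (0, 1)
        ]
        per_group = [a for a in per_group if np.isfinite(a)]
        out[i] = np.mean(per_group) if per_group else np.nan
    return out


def _design_moments(
    mat: np.ndarray, X_full: np.ndarray, offset: np.ndarray
) -> np.ndarray:
    """Moments dispersion given fitted means under the full design.

    A Poisson GLM under the full design (genotype plus unwanted-variation
    factors) supplies per-sample fitted means; the dispersion is then
    alpha = (sum (y - mu)^2 * n/(n - p) - sum mu) / sum mu^2, so variance
    explained by the design (including W) does not masquerade as biological
    dispersion.  Entries may be negative; the trend fit handles that.
    """
    n, p = X_full.shape[0], X_full.shape[1]
    correction = n / max(n - p, 1)
    out = np.full(mat.shape[0], np.nan)
    for i in range(mat.shape[0]):
        y = mat[i]
        if y.sum() == 0:
            continue
        try:
            fit = sm.GLM(y, X_full, family=sm.families.Poisson(), offset=offset).fit()
            mu = fit.fittedvalues
        except Exception:
            continue
        denom = np.sum(mu**2)
        if denom <= 0:
            continue
        out[i] = (np.sum((y - mu) ** 2) * correction - np.sum(mu)) / denom
    return out


def _dispersion_trend(alpha_mom: np.ndarray, base_mean: np.ndarray) -> Optional[tuple]:
    """Fit alpha(mu) = a0 + a1/mu by trimmed least squares on raw moments.

    Genewise moments from a handful of samples are far too noisy to use
    directly (they frequently fall below zero and get floored, which makes
    the LRT anticonservative); pooling across genes through a mean-dispersion
    trend stabilises them.  Returns None when too few genes inform the fit.
    """
    pos = np.isfinite(alpha_mom) & (alpha_mom > 0) & (base_mean > 0)
    if pos.sum() < 20:
        return None
    x = 1.0 / base_mean[pos]
    y = alpha_mom[pos]
    keep = np.ones(y.size, dtype=bool)
    coef = np.array([np.median(y), 0.0])
    for _ in range(3):
        A = np.column_stack([np.ones(keep.sum()), x[keep]])
        coef, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
        resid = y - (coef[0] + coef[1] * x)
        mad = np.median(np.abs(resid[keep] - np.median(resid[keep])))
        keep = np.abs(resid) < 3 * 1.4826 * mad + 1e-12
        if keep.sum() < 20:
            break
    return max(float(coef[0]), 0.0), max(float(coef[1]), 0.0)


def nb_lrt_test(
    m: CountMatrix,
    W: Optional[np.ndarray] = None,
    dispersion_mode: str = "trend",
) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of genotype given W.

    Genes with zero counts in every sample are removed before testing (they
    appear in the output with status EXCLUDED).  ``dispersion_mode`` is
    ``"trend"`` (default: genewise moments shrunk fully onto a fitted
    mean-dispersion trend; falls back to genewise when fewer than 20 genes
    inform the fit) or ``"genewise"`` (raw floored moments).  Returns a
    frame with mean_expression, log2fc (mutant vs WT), p.
    """
    if dispersion_mode not in ("trend", "genewise"):
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")
    counts = m.counts
    if not np.allclose(counts.to_numpy() % 1, 0):
        raise ValueError("counts must be integers")
    geno = m.genotype
    n_wt = int((geno == "WT").sum())
    n_mut = int((geno == "mutant").sum())
    if n_wt < 2 or n_mut < 2:
        raise ValueError("need at least 2 samples per genotype")
    if W is None:
        W = np.empty((counts.shape[1], 0))
    if W.shape[0] != counts.shape[1]:
        raise ValueError("W rows must match samples")

    sf = size_factors(counts).to_numpy()
    offset = np.log(sf)
    is_mut = (geno == "mutant").to_numpy(dtype=float)
    intercept = np.ones(counts.shape[1])
    X_full = np.column_stack([intercept, is_mut, W])
    X_red = np.column_stack([intercept, W])

    nonzero = counts.sum(axis=1) > 0
    mat = counts.to_numpy(dtype=float)
    base_mean = (mat / sf).mean(axis=1)
    if W.shape[1] > 0:
        alpha_mom = _design_moments(mat, X_full, offset)
    else:
        alpha_mom = _genewise_moments(mat, sf, is_mut)
    trend = _dispersion_trend(alpha_mom, base_mean) if dispersion_mode == "trend" else None
    if dispersion_mode == "trend" and trend is None:
        logger.warning("too few genes for a dispersion trend; using genewise moments")
    if trend is not None:
        a0, a1 = trend
        with np.errstate(divide="ignore"):
            alphas = np.maximum(a0 + a1 / base_mean, DISPERSION_FLOOR)
    else:
        alphas = np.maximum(np.nan_to_num(alpha_mom), DISPERSION_FLOOR)

    records = []
    for i, gene in enumerate(counts.index):
        if not nonzero.iloc[i]:
            records.append((gene, 0.0, np.nan, np.nan, True))
            continue
        y = mat[i]
        alpha = float(alphas[i])
        try:
            full = _fit_nb_glm(y, X_full, offset, alpha)
            red = _fit_nb_glm(y, X_red, offset, alpha)
            lrt = max(2.0 * (full.llf - red.llf), 0.0)
            p = float(stats.chi2.sf(lrt, df=1))
            log2fc = float(full.params[1] / np.log(2))
        except Exception as err:  # singular fits on degenerate genes
            logger.warning("gene %s: NB fit failed (%s)", gene, err)
            p, log2fc = np.nan, np.nan
        records.append((gene, float((y / sf).mean()), log2fc, p, False))

    return pd.DataFrame(
        records, columns=["gene_id", "mean_expression", "log2fc", "p", "excluded"]
    ).set_index("gene_id")


def adjust_and_call(
    results: pd.DataFrame,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """BH adjustment over all tested genes and UP/DOWN/UNCHANGED calls.

    No independent filtering: every gene with a p-value enters the BH
    procedure.  UP requires fold change > fc_threshold and padj <
    fdr_threshold; DOWN the reciprocal.  Warns when the p-value histogram
    looks hill-shaped (departure from uniformity on p > 0.5), a sign that
    the chi-square null is miscalibrated for this dataset.
    """
    from statsmodels.stats.multitest import multipletests

    out = results.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
    tested = out["p"].notna() & ~out["excluded"]
    out["padj"] = np.nan
    if tested.any():
        pvals = out.loc[tested, "p"].to_numpy()
        out.loc[tested, "padj"] = multipletests(pvals, method="fdr_bh")[1]
        _warn_if_hill_shaped(pvals)

    status = np.full(len(out), DEStatus.UNCHANGED.value, dtype=object)
    excluded = out["excluded"].to_numpy(bool)
    status[excluded | out["p"].isna().to_numpy()] = DEStatus.EXCLUDED.value
    fc = np.power(2.0, out["log2fc"].to_numpy())
    sig = (out["padj"].to_numpy() < fdr_threshold) & tested.to_numpy()
    status[sig & (fc > fc_threshold)] = DEStatus.UP.value
    status[sig & (fc < 1.0 / fc_threshold)] = DEStatus.DOWN.value
    out["status"] = status
    return out


def _warn_if_hill_shaped(pvals: np.ndarray, alpha: float = 0.01) -> None:
    upper = pvals[pvals > 0.5]
    if upper.size < 20:
        return
    rescaled = (upper - 0.5) / 0.5
    ks = stats.kstest(rescaled, "uniform")
    if ks.pvalue < alpha:
        logger.warning(
            "p-value histogram deviates from uniform on (0.5, 1] "
            "(KS p = %.2g); distribution may be hill-shaped and BH "
            "adjustment conservative/anticonservative",
            ks.pvalue,
        )


def run_dge(
    m: CountMatrix,
    k: int = 1,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full DE contract: RUVs factors, NB LRT, BH, threshold calls."""
    W = estimate_unwanted_variation(m, k)
    res = nb_lrt_test(m, W)
    return adjust_and_call(res, fc_threshold, fdr_threshold)


def write_de_tsv(results: pd.DataFrame, path) -> None:
    out = results.reset_index()[
        ["gene_id", "mean_expression", "log2fc", "p", "padj", "status"]
    ].rename(columns={"mean_expression": "mean"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
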