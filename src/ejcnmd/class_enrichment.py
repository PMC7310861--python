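"""Gene-class enrichment among expression changes.

Two statistical questions recur downstream of differential expression:

* do two upregulated gene sets from different datasets overlap more than
  chance, judged by an upper-tail hypergeometric test over the smaller of
  the two datasets' tested-gene universes; and
* does a gene class (3'UI proximal/distal, NMD-biotype, uORF) shift toward
  upregulation relative to a control class (intron-less genes), judged by
  a two-sample Kolmogorov-Smirnov test on fold-change distributions, with
  ECDF coordinates exported for plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation3ui import IsoformPair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    k: int
    size_a: int
    size_b: int
    universe: int
    p: float


@dataclass
class ClassShiftResult:
    """Distribution shift of one gene class versus a control class."""

    label: str
    n: int
    n_control: int
    ecdf_x: np.ndarray
    ecdf_y: np.ndarray
    D: float
    p: float
    median_log2fc: float
    median_paired_difference: float = float("nan")


def overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe_a: Iterable[str],
    universe_b: Iterable[str],
) -> OverlapResult:
    """Upper-tail hypergeometric overlap test on the smaller universe.

    Each dataset's universe is its set of tested genes (those assigned an
    adjusted p-value); the smaller universe is used for both sets, which
    are intersected with it first.  p = P(X >= k) for
    X ~ Hypergeom(N, |A|, |B|).
    """
    ua, ub = set(universe_a), set(universe_b)
    sa, sb = set(set_a), set(set_b)
    stray = (sa | sb) - (ua | ub)
    if stray:
        raise ValueError(f"set elements outside both universes: {sorted(stray)[:5]}")
    universe = ua if len(ua) <= len(ub) else ub
    a = sa & universe
    b = sb & universe
    k = len(a & b)
    N, K, n = len(universe), len(a), len(b)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(k, K, n, N, min(p, 1.0))


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Step-function coordinates: a jump of 1/N at each sorted value."""
    x = np.sort(values)
    y = np.arange(1, x.size + 1) / x.size
    return x, y


def class_shift(
    fold_changes: Mapping[str, float] | pd.Series,
    class_genes: Iterable[str],
    control_genes: Iterable[str],
    label: str = "class",
    exclude: Optional[Iterable[str]] = None,
) -> ClassShiftResult:
    """KS comparison of a gene class's fold changes against a control class.

    Both sets are intersected with the genes carrying fold changes;
    ``exclude`` removes genes (e.g. uORF-overlapping ones) from the class
    set before testing.
    """
    fc = pd.Series(fold_changes).dropna()
    cls = set(class_genes) & set(fc.index)
    ctrl = set(control_genes) & set(fc.index)
    if exclude is not None:
        cls -= set(exclude)
    if not cls or not ctrl:
        raise ValueError("class or control set empty after filtering")
    x_cls = fc.reindex(sorted(cls)).to_numpy()
    x_ctrl = fc.reindex(sorted(ctrl)).to_numpy()
    ks = stats.ks_2samp(x_cls, x_ctrl, method="asymp")
    ex, ey = _ecdf(x_cls)
    return ClassShiftResult(
        label,
        len(cls),
        len(ctrl),
        ex,
        ey,
        float(ks.statistic),
        float(ks.pvalue),
        float(np.median(x_cls)),
    )


FC_BINS = (
    ("gt_1.5", lambda x: x > 1.5),
    ("1.5_to_0", lambda x: (x > 0) & (x <= 1.5)),
    ("0_to_-1.5", lambda x: (x > -1.5) & (x <= 0)),
    ("lt_-1.5", lambda x: x <= -1.5),
)


def fc_bin_proportions(
    de_results: pd.DataFrame,
    feature_genes: Iterable[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Feature prevalence across log2 fold-change bins of significant genes.

    Among genes with padj < threshold, reports per bin (>1.5, 1.5..0,
    0..-1.5, <=-1.5; boundaries assigned to the lower bin) the fraction
    carrying the feature.  Empty bins report proportion 0 with n = 0.
    """
    feats = set(feature_genes)
    sig = de_results[de_results["padj"] < fdr_threshold]
    rows = []
    for name, pred in FC_BINS:
        members = sig[pred(sig["log2fc"])]
        n = len(members)
        with_feat = sum(g in feats for g in members.index)
        rows.append(
            dict(
                bin=name,
                n=n,
                n_feature=with_feat,
                proportion=with_feat / n if n else 0.0,
            )
        )
    return pd.DataFrame(rows)


def isoform_shift_compare(pairs: Sequence[IsoformPair]) -> ClassShiftResult:
    """Fold-change shift of 3'UI+ isoforms against their 3'UI- partners.

    KS comparison of the two isoform fold-change distributions plus the
    median paired difference, over pairs built by ``pair_isoforms``.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 isoform pairs")
    fc_3ui = np.array([p.utr3_isoform.log2fc for p in pairs])
    fc_ctrl = np.array([p.control_isoform.log2fc for p in pairs])
    ks = stats.ks_2samp(fc_3ui, fc_ctrl, method="asymp")
    ex, ey = _ecdf(fc_3ui)
    return ClassShiftResult(
        "3ui_isoforms",
        len(pairs),
        len(pairs),
        ex,
        ey,
        float(ks.statistic),
        float(ks.pvalue),
        float(np.median(fc_3ui)),
        float(np.median(fc_3ui - fc_ctrl)),
    )


def write_shift_tsv(results: Sequence[ClassShiftResult], path) -> None:
    rows = [
        dict(
            label=r.label,
            n=r.n,
            n_control=r.n_control,
            D=r.D,
            p=r.p,
            median_log2fc=r.median_log2fc,
        )
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_ecdf_tsv(results: Sequence[ClassShiftResult], path) -> None:
    frames = [
        pd.DataFrame({"label": r.label, "log2fc": r.ecdf_x, "ecdf": r.ecdf_y})
        for r in results
    ]
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.6g")
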