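"""RNA-seq normalization and IFN-gamma response gene-signature scoring.

Tumors with loss-of-function succinate dehydrogenase (SDHB/SDHD) mutations
accumulate succinate; if succinate blunts T cell IFN-gamma secretion, the
transcriptional footprint of IFN-gamma signaling in those tumors should be
reduced.  That footprint is quantified here as the geometric mean of the log2
normalized counts of a set of IFN-gamma-induced genes, one score per sample,
compared between mutation groups with a rank-sum (Wilcoxon) or t test.

Counts are normalized by median-of-ratios size factors (the DESeq2
definition), computed here explicitly so every step is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GeneSignature",
    "size_factors",
    "log2_normalized",
    "signature_score",
    "relative_abundance",
    "compare_groups",
]


@dataclass
class GeneSignature:
    """An ordered, de-duplicated list of gene identifiers."""

    genes: list[str]
    name: str = "signature"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene signature must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene signature contains duplicate ids")

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "GeneSignature":
        genes = [
            line.strip()
            for line in open(path)
            if line.strip() and not line.startswith("#")
        ]
        return cls(genes, name or str(path))


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids in count matrix")
    arr = counts.to_numpy()
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")


def size_factors(counts: pd.DataFrame, strict: bool = True) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each gene the geometric mean of its counts across samples is the
    pseudo-reference; sample ``j``'s factor is the median over genes of
    ``count_gj / reference_g``.  With ``strict=True`` (the standard
    definition) genes with a zero count in any sample are excluded; with
    ``strict=False`` the reference is the geometric mean over positive counts
    only and genes that are zero everywhere are dropped.
    """
    _validate_counts(counts)
    arr = counts.to_numpy(dtype=float)
    if arr.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    if strict:
        keep = np.all(arr > 0, axis=1)
        if not keep.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; "
                "cannot compute strict median-of-ratios size factors"
            )
        log_ref = log_arr[keep].mean(axis=1)
        log_ratios = log_arr[keep] - log_ref[:, None]
    else:
        keep = np.any(arr > 0, axis=1)
        if not keep.any():
            raise ValueError("count matrix is all zeros")
        masked = np.where(arr[keep] > 0, log_arr[keep], np.nan)
        log_ref = np.nanmean(masked, axis=1)
        log_ratios = np.where(np.isnan(masked), np.nan, log_arr[keep] - log_ref[:, None])
    factors = np.exp(np.nanmedian(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log2_normalized(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """``log2(count / size_factor + pseudocount)`` per gene and sample."""
    _validate_counts(counts)
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    normed = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :] + pseudocount
    if np.any(normed <= 0):
        raise ValueError("zero normalized count with pseudocount 0; use pseudocount > 0")
    return pd.DataFrame(np.log2(normed), index=counts.index, columns=counts.columns)


def signature_score(
    log2_matrix: pd.DataFrame,
    signature: GeneSignature,
    groups: pd.Series | None = None,
    allow_missing: bool = False,
    geometric_mean_of_logs: bool = True,
) -> pd.DataFrame:
    """Per-sample signature score.

    Default (``geometric_mean_of_logs=True``): the geometric mean, over
    signature genes, of each sample's log2 normalized values — which requires
    those values to be non-negative (guaranteed by pseudocount >= 1).  The
    alternative reading (arithmetic mean of log2 values, i.e. the log2 of the
    geometric mean of normalized counts) is available with
    ``geometric_mean_of_logs=False``.
    """
    missing = [g for g in signature.genes if g not in log2_matrix.index]
    if missing:
        if not allow_missing:
            raise KeyError(
                f"{len(missing)} signature genes absent from matrix: {missing[:5]}"
            )
        genes = [g for g in signature.genes if g not in missing]
        if not genes:
            raise KeyError("no signature genes present in matrix")
    else:
        genes = list(signature.genes)
    sub = log2_matrix.loc[genes].to_numpy()
    if geometric_mean_of_logs:
        if np.any(sub < 0):
            raise ValueError(
                "negative log2 values under the geometric mean; increase the "
                "pseudocount (>= 1 guarantees non-negative log2 values) or use "
                "geometric_mean_of_logs=False"
            )
        # geometric mean via log-sum-exp; exact zeros give a zero score
        if np.any(sub == 0):
            scores = np.where(
                np.any(sub == 0, axis=0),
                0.0,
                np.exp(np.log(np.where(sub > 0, sub, 1.0)).mean(axis=0)),
            )
        else:
            scores = np.exp(np.log(sub).mean(axis=0))
    else:
        scores = sub.mean(axis=0)
    out = pd.DataFrame({"score": scores}, index=log2_matrix.columns)
    out.index.name = "sample"
    if groups is not None:
        out["group"] = groups.reindex(out.index)
    return out


def relative_abundance(values: pd.DataFrame, signature: GeneSignature | None = None) -> pd.DataFrame:
    """Each gene's value expressed relative to its mean across all samples."""
    if values.shape[1] < 2:
        raise ValueError("relative abundance needs >= 2 samples")
    if signature is not None:
        missing = [g for g in signature.genes if g not in values.index]
        if missing:
            raise KeyError(f"signature genes absent from matrix: {missing[:5]}")
        values = values.loc[signature.genes]
    means = values.mean(axis=1)
    if (means == 0).any():
        bad = means.index[means == 0].tolist()
        raise ValueError(f"zero mean abundance for genes: {bad[:5]}")
    return values.div(means, axis=0)


def compare_groups(
    scores: pd.DataFrame, method: str = "wilcoxon", group_col: str = "group"
) -> dict[str, object]:
    """Two-sided comparison of signature scores between two groups.

    ``wilcoxon`` performs the two-sample rank-sum (Mann-Whitney) test, exact
    for small untied samples and normal-approximated with tie correction
    otherwise; ``t`` performs Welch's t test.
    """
    if group_col not in scores.columns:
        raise ValueError(f"scores table lacks a {group_col!r} column")
    labels = [g for g in pd.unique(scores[group_col].dropna())]
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {labels}")
    x = scores.loc[scores[group_col] == labels[0], "score"].to_numpy(dtype=float)
    y = scores.loc[scores[group_col] == labels[1], "score"].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if method == "wilcoxon":
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        stat_name = "U"
    elif method == "t":
        res = sps.ttest_ind(x, y, equal_var=False)
        stat_name = "t"
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "test": method,
        "statistic_name": stat_name,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "groups": [str(l) for l in labels],
        "n": [int(len(x)), int(len(y))],
        "mean_scores": [float(x.mean()), float(y.mean())],
    }
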