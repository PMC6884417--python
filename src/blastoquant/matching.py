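"""Twin-pair recovery by hierarchical clustering, and interblastomere
expression-ratio / CV ranking.

The question both tools address: are the two products of one bisected
2-cell embryo more similar to each other than to unrelated embryos? If so,
agglomerative clustering of germ-layer count vectors (or blastomere
transcriptomes) should merge twin and co-twin as dendrogram siblings — a
pair is "recovered" iff its two members merge with each other before
either merges with anything else. The fraction of recovered pairs, judged
against a simulated null, measures interblastomere concordance.

The CV ranking tool summarises per-gene blastomere asymmetry: for each
gene, the expression ratio between sister blastomeres (always higher over
lower) across pairs, its mean, and the coefficient of variation of those
ratios; genes are ranked by CV (rank 1 = highest).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "InterblastomereRatioSummary",
    "PairRecoveryResult",
    "interblastomere_ratios",
    "cluster_pair_recovery",
    "recovery_null",
    "pair_labels_from_samples",
    "count_feature_matrix",
]

_LABEL_RE = re.compile(r"^(.+?)([a-z])$")


def pair_labels_from_samples(sample_labels: Sequence[str]) -> list[str]:
    """Extract pair ids from labels like '7a'/'7b' (number + member letter).

    Each pair id must occur exactly twice; anything else is an error naming
    the offending sample.
    """
    pairs = []
    for s in sample_labels:
        m = _LABEL_RE.match(str(s))
        if not m:
            raise ValueError(f"sample label {s!r} is not '<pair><member-letter>'")
        pairs.append(m.group(1))
    counts = pd.Series(pairs).value_counts()
    bad = counts[counts != 2]
    if len(bad):
        raise ValueError(f"unpaired sample label(s) for pair id(s): {list(bad.index)}")
    return pairs


# ---------------------------------------------------------------------------
# Interblastomere ratios


@dataclass
class InterblastomereRatioSummary:
    """Per-gene interblastomere ratio statistics across pairs.

    ``per_gene`` columns: mean_ratio, cv, rank_cv (1 = highest CV, ties by
    input gene order), n_finite, n_unbounded, n_undefined. ``ratios`` is
    the gene x pair matrix of finite ratios (NaN where not finite).
    """

    per_gene: pd.DataFrame
    ratios: pd.DataFrame


def interblastomere_ratios(
    matrix: pd.DataFrame, gene_subset: Optional[Sequence[str]] = None
) -> InterblastomereRatioSummary:
    """Ratio of each mRNA between sister blastomeres, across all pairs.

    ``matrix`` is genes x samples with paired sample labels ('7a', '7b').
    For each gene and pair the ratio is the higher expression divided by
    the lower. A zero lower value with a positive higher value makes the
    ratio unbounded; both-zero makes it undefined; either case is excluded
    from the mean and CV and tallied. CV is the sample SD (ddof=1) of the
    finite ratios divided by their mean.
    """
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in matrix.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        matrix = matrix.loc[list(gene_subset)]
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    pairs = pair_labels_from_samples(matrix.columns)
    pair_ids = list(dict.fromkeys(pairs))
    ratio_cols = {}
    for pid in pair_ids:
        cols = [c for c, p in zip(matrix.columns, pairs) if p == pid]
        a = matrix[cols[0]].to_numpy(float)
        b = matrix[cols[1]].to_numpy(float)
        hi = np.maximum(a, b)
        lo = np.minimum(a, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = hi / lo
        r[(lo == 0) & (hi > 0)] = np.inf
        r[(lo == 0) & (hi == 0)] = np.nan
        ratio_cols[pid] = r
    ratios = pd.DataFrame(ratio_cols, index=matrix.index)
    finite = ratios.replace(np.inf, np.nan)
    n_unbounded = np.isinf(ratios).sum(axis=1)
    n_undefined = ratios.isna().sum(axis=1)
    n_finite = finite.notna().sum(axis=1)
    mean = finite.mean(axis=1)
    sd = finite.std(axis=1, ddof=1)
    cv = sd / mean
    per_gene = pd.DataFrame(
        dict(
            mean_ratio=mean,
            cv=cv,
            n_finite=n_finite,
            n_unbounded=n_unbounded,
            n_undefined=n_undefined,
        )
    )
    # rank 1 = highest CV; NaN CVs rank last; ties broken by gene order
    order = np.lexsort((np.arange(len(per_gene)), -np.nan_to_num(cv.to_numpy(), nan=-np.inf)))
    rank = np.empty(len(per_gene), int)
    rank[order] = np.arange(1, len(per_gene) + 1)
    per_gene["rank_cv"] = rank
    return InterblastomereRatioSummary(per_gene=per_gene, ratios=ratios)


# ---------------------------------------------------------------------------
# Clustering pair recovery


@dataclass
class PairRecoveryResult:
    """Outcome of dendrogram-sibling pair recovery."""

    n_pairs: int
    n_recovered: int
    fraction_recovered: float
    recovered_pairs: list
    linkage_record: np.ndarray  # scipy linkage matrix

    def __post_init__(self) -> None:
        assert 0 <= self.n_recovered <= self.n_pairs


def _sample_matrix(
    values, standardize: bool, distance: str
) -> tuple[np.ndarray, list]:
    if isinstance(values, pd.DataFrame):
        X = values.to_numpy(float).T  # samples x features
        samples = list(values.columns)
    else:
        X = np.asarray(values, float).T
        samples = list(range(X.shape[0]))
    if distance == "euclidean" and standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return X, samples


def cluster_pair_recovery(
    values,
    pair_labels: Optional[Sequence] = None,
    distance: str = "euclidean",
    linkage: str = "average",
    standardize: bool = True,
) -> PairRecoveryResult:
    """Agglomerative clustering of samples; count dendrogram-sibling pairs.

    Parameters
    ----------
    values
        Feature x sample matrix (DataFrame columns = samples, or ndarray).
    pair_labels
        Hidden true pair id per sample. If omitted, they are parsed from
        DataFrame column labels ('7a'/'7b').
    distance, linkage
        ``euclidean`` (on per-feature z-scores when ``standardize``) with
        average linkage is the default for count vectors; ``correlation``
        (1 - Pearson) is the convention for expression matrices. The
        recovery definition — twin and co-twin merged as dendrogram
        siblings — carries the meaning; the metric is configurable.
    """
    X, samples = _sample_matrix(values, standardize, distance)
    n = X.shape[0]
    if n % 2:
        raise ValueError("sample count must be even (pairs)")
    if pair_labels is None:
        pair_labels = pair_labels_from_samples(samples)
    pair_labels = list(pair_labels)
    if len(pair_labels) != n:
        raise ValueError("pair_labels length must match sample count")
    n_pairs = n // 2
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs to cluster")
    d = pdist(X, metric=distance)
    # identical samples across different pairs make siblinghood
    # tie-break-dependent; scipy's merge order is deterministic, but warn.
    dm = squareform(d)
    zero = np.argwhere(np.triu(dm == 0, k=1))
    if any(pair_labels[i] != pair_labels[j] for i, j in zero):
        warnings.warn(
            "identical samples in different pairs; recovery depends on a "
            "deterministic tie-break",
            stacklevel=2,
        )
    Z = _linkage(d, method=linkage)
    recovered = []
    for left, right in Z[:, :2].astype(int):
        if left < n and right < n and pair_labels[left] == pair_labels[right]:
            recovered.append(pair_labels[left])
    return PairRecoveryResult(
        n_pairs=n_pairs,
        n_recovered=len(recovered),
        fraction_recovered=len(recovered) / n_pairs,
        recovered_pairs=recovered,
        linkage_record=Z,
    )


def count_feature_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Germ-layer count features (cdx2, sox17, nanog, total) x samples,
    plus the hidden pair labels, from a lineage count table."""
    twins = table[table["member"] != "intact"].reset_index(drop=True)
    feats = twins[["cdx2", "sox17", "nanog"]].astype(float).copy()
    feats["total"] = feats.sum(axis=1)
    mat = feats.T
    mat.columns = twins["embryo_id"]
    return mat, list(twins["pair_id"])


def recovery_null(
    n_pairs: int,
    n_features: int,
    reps: int = 1000,
    seed: int = 0,
    distance: str = "euclidean",
    linkage: str = "average",
) -> "NullRecoveryDistribution":
    """Null distribution of the recovered fraction for i.i.d. samples.

    Samples have no pair structure at all (standard normal features), so
    any recovery is chance. With a single pair the two samples must be
    siblings and the fraction is identically 1.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n_pairs < 1 or n_features < 1:
        raise ValueError("n_pairs and n_features must be >= 1")
    rng = np.random.default_rng(seed)
    fractions = np.empty(reps)
    labels = np.repeat(np.arange(n_pairs), 2)
    for r in range(reps):
        if n_pairs == 1:
            fractions[r] = 1.0
            continue
        X = rng.standard_normal((n_features, 2 * n_pairs))
        res = cluster_pair_recovery(
            X, pair_labels=labels, distance=distance, linkage=linkage
        )
        fractions[r] = res.fraction_recovered
    return NullRecoveryDistribution(fractions=fractions, n_pairs=n_pairs, seed=seed)


@dataclass
class NullRecoveryDistribution:
    fractions: np.ndarray
    n_pairs: int
    seed: int

    @property
    def mean(self) -> float:
        return float(self.fractions.mean())

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.fractions, q)
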