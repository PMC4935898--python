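"""Cohort-level transcriptome profiling: PCA, correlation clustering,
fold-change/FDR differential expression and marker-panel reports.

All operations work on log2(size-factor-normalized + 1) values unless stated
otherwise.  The per-gene differential-expression test is a Welch t-test on
those log values — deliberately simpler than a negative-binomial GLM — and
candidates follow the classic rule: at least 2-fold change with
BH-adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .dosage import benjamini_hochberg
from .io import CountMatrix, ValidationError
from .normalize import NormalizedMatrix, log_transform, normalize_by_size_factors


def _values(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, NormalizedMatrix) else matrix


def log_normalized(counts: CountMatrix) -> NormalizedMatrix:
    """log2(size-factor-normalized counts + 1), the profiling input."""
    return log_transform(normalize_by_size_factors(counts))


# ---------------------------------------------------------------------------
# PCA


def pca_profile(log_norm_matrix, n_top_variance_genes: int | None = None,
                n_components: int | None = None):
    """Principal components of samples in gene-expression space.

    Genes are centered; components are ordered by decreasing variance.
    Returns ``(coordinates, explained_variance_fractions)`` with samples in
    rows and columns ``PC1..PCk``.
    """
    values = _values(log_norm_matrix)
    if values.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if np.ptp(values.to_numpy()) == 0:
        raise ValidationError("constant matrix: no variance to decompose")
    data = values.T  # samples x genes
    if n_top_variance_genes is not None:
        top = values.var(axis=1).nlargest(n_top_variance_genes).index
        data = data[top]
    centered = data - data.mean(axis=0)
    if np.allclose(centered.to_numpy(), 0.0):
        # identical samples: degenerate but well-defined — everything at the origin
        k = n_components or 1
        coords = pd.DataFrame(0.0, index=data.index, columns=[f"PC{i+1}" for i in range(k)])
        return coords, np.zeros(k)
    k = n_components or min(data.shape[0], data.shape[1])
    pca = PCA(n_components=min(k, data.shape[0] - 1, data.shape[1]))
    scores = pca.fit_transform(data.to_numpy())
    coords = pd.DataFrame(
        scores, index=data.index, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
    )
    return coords, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Correlation clustering


def correlation_clustering(log_norm_matrix, linkage_method: str = "average"):
    """Sample-sample Pearson correlation and hierarchical clustering.

    Clustering runs on distance 1 - r with the given linkage (default
    average).  Returns ``(correlation_matrix, linkage)`` where ``linkage`` is
    a scipy linkage matrix whose third column holds merge heights.
    """
    values = _values(log_norm_matrix)
    if values.shape[1] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    sd = values.std(axis=0)
    flat = sd.index[sd == 0].tolist()
    if flat:
        raise ValidationError(f"zero-variance sample(s): {flat}; correlation undefined")
    corr = pd.DataFrame(
        np.corrcoef(values.to_numpy().T), index=values.columns, columns=values.columns
    )
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    return corr, linkage


def replicates_merge_first(linkage, samples, lines) -> bool:
    """True if every same-line replicate pair joins before any cross-line merge.

    Checks that cutting the dendrogram into one cluster per line groups the
    samples exactly by line.
    """
    lines = pd.Series(list(lines), index=list(samples))
    n_lines = lines.nunique()
    labels = hierarchy.fcluster(linkage, t=n_lines, criterion="maxclust")
    labels = pd.Series(labels, index=lines.index)
    grouped = labels.groupby(lines).nunique()
    return bool((grouped == 1).all() and labels.nunique() == n_lines)


# ---------------------------------------------------------------------------
# Differential expression


@dataclass
class DEResult:
    """Per-gene fold changes, Welch-t p-values, BH adjustment and candidate flags."""

    frame: pd.DataFrame
    group_a: list[str]
    group_b: list[str]
    lfc_threshold: float
    fdr_threshold: float

    @property
    def candidates(self) -> pd.Index:
        return self.frame.index[self.frame["candidate"]]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def differential_expression(counts: CountMatrix, group_a, group_b,
                            lfc_threshold: float = 1.0,
                            fdr_threshold: float = 0.05) -> DEResult:
    """Two-group differential expression with the 2-fold / FDR 0.05 filter.

    ``group_a`` and ``group_b`` are disjoint sample lists with >= 2 replicates
    each.  Fold change is computed on size-factor-normalized group means with
    a pseudo-count of 1; the per-gene test is a Welch t on log2(normalized+1);
    BH adjustment runs across genes.  A gene is a candidate when
    ``|log2FC| >= lfc_threshold`` and ``p_adj < fdr_threshold``.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 replicates for the Welch test")
    norm = normalize_by_size_factors(counts.subset_samples(group_a + group_b)).values
    log_norm = np.log2(norm + 1.0)
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    t, p = sps.ttest_ind(
        log_norm[group_a].to_numpy(), log_norm[group_b].to_numpy(), axis=1, equal_var=False
    )
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance genes carry no evidence
    p_adj = benjamini_hochberg(p)
    frame = pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "t": t,
            "p_value": p,
            "p_adjusted": p_adj,
        },
        index=norm.index,
    )
    frame["candidate"] = (frame["log2_fold_change"].abs() >= lfc_threshold) & (
        frame["p_adjusted"] < fdr_threshold
    )
    return DEResult(frame, group_a, group_b, lfc_threshold, fdr_threshold)


# ---------------------------------------------------------------------------
# Marker panels


@dataclass
class MarkerReport:
    """Replicate-averaged normalized marker expression and ratios to a reference line."""

    expression: pd.DataFrame  # markers x lines
    ratio: pd.DataFrame  # markers x lines, NaN where reference is undetected
    reference_line: str

    def formatted(self) -> pd.DataFrame:
        """Human-readable table: 'not detected' where a marker has zero mean."""
        out = self.expression.round(2).astype(object)
        out[self.expression == 0] = "not detected"
        return out

    def to_tsv(self, path) -> None:
        self.formatted().to_csv(path, sep="\t", index_label="marker")


def marker_panel(counts: CountMatrix, gene_list, reference_line: str) -> MarkerReport:
    """Size-factor-normalized expression of a marker panel, per line, with
    ratios to a declared reference line."""
    genes = pd.Index(gene_list)
    present = genes.intersection(counts.genes)
    if len(present) == 0:
        raise ValidationError("no marker genes present in the count matrix")
    if reference_line not in counts.lines:
        raise ValidationError(f"reference line {reference_line!r} absent from the cohort")
    norm = normalize_by_size_factors(counts).values.loc[present]
    lines = counts.sample_meta.loc[norm.columns, "line"]
    expr = norm.T.groupby(lines).mean().T[list(dict.fromkeys(lines))]
    ref = expr[reference_line]
    ratio = expr.div(ref.where(ref > 0), axis=0)
    return MarkerReport(expression=expr, ratio=ratio, reference_line=reference_line)


# ---------------------------------------------------------------------------
# Plots (optional outputs)


def plot_pca(coords: pd.DataFrame, explained, path, color_by=None) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    groups = pd.Series(color_by, index=coords.index) if color_by is not None else pd.Series(
        coords.index, index=coords.index
    )
    for name, sub in coords.groupby(groups):
        ax.scatter(sub["PC1"], sub.get("PC2", 0.0), label=str(name))
        for s, row in sub.iterrows():
            ax.annotate(s, (row["PC1"], row.get("PC2", 0.0)), fontsize=7)
    ax.set_xlabel(f"PC1 ({explained[0]*100:.2f}%)")
    if len(explained) > 1:
        ax.set_ylabel(f"PC2 ({explained[1]*100:.2f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_correlation_heatmap(corr: pd.DataFrame, linkage, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = hierarchy.leaves_list(linkage)
    ordered = corr.iloc[order, order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(ordered, cmap="Blues", vmin=ordered.min().min(), vmax=1.0)
    ax.set_xticks(range(len(ordered)), ordered.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(ordered)), ordered.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
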