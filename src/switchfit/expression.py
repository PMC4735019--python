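"""Marker-based expression stratification.

Implements the human-cohort expression analysis around a marker gene
(TRIM28 in the motivating study): multi-housekeeping 2^-ΔΔCt
quantification, a median split of samples into Marker_High / Marker_Low
strata, per-gene obese-vs-lean contrasts of an imprinted-gene panel within
each stratum, marker-panel correlations, and transcriptome-level sample
structure (top-variable-gene PCA, correlation matrix, hierarchical
clustering).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "ddct_quantify",
    "stratify_by_marker",
    "panel_compare",
    "marker_panel_correlation",
    "transcriptome_structure",
    "ExpressionError",
]

CT_RANGE = (0.0, 45.0)


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene labels (e.g. the IGN1 panel)."""

    name: str
    genes: tuple
    description: str = ""

    def __post_init__(self):
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if not genes:
            raise ExpressionError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ExpressionError(f"gene set {self.name!r} has duplicate members")

    def __len__(self):
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def _require_genes(matrix: pd.DataFrame, genes: Sequence[str], what: str) -> None:
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ExpressionError(f"{what} gene(s) missing from matrix: {missing}")


# ---------------------------------------------------------------------------
# ΔΔCt


def ddct_quantify(
    ct: pd.DataFrame,
    housekeeping: GeneSet,
    reference_samples: Sequence[str],
) -> pd.DataFrame:
    """Relative quantification by the 2^-ΔΔCt method.

    ΔCt = Ct_gene − mean(Ct over housekeeping genes) per sample (the
    arithmetic-mean-Ct reference, i.e. the geometric mean of the
    housekeeping abundances); ΔΔCt references the mean ΔCt of the
    ``reference_samples`` group; the result is the fold level 2^-ΔΔCt.
    Every gene's geometric-mean fold over the reference group is exactly 1.
    """
    _require_genes(ct, housekeeping.genes, "housekeeping")
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise ExpressionError("reference group is empty")
    missing = [s for s in reference_samples if s not in ct.columns]
    if missing:
        raise ExpressionError(f"reference sample(s) missing from matrix: {missing}")
    vals = ct.to_numpy(dtype=float)
    if np.any(vals <= CT_RANGE[0]) or np.any(vals >= CT_RANGE[1]):
        raise ExpressionError(f"Ct values must lie strictly within {CT_RANGE}")

    hk_mean = ct.loc[list(housekeeping.genes)].mean(axis=0)
    dct = ct.sub(hk_mean, axis=1)
    ddct = dct.sub(dct[reference_samples].mean(axis=1), axis=0)
    return 2.0 ** (-ddct)


# ---------------------------------------------------------------------------
# marker split


def stratify_by_marker(
    matrix: pd.DataFrame,
    marker: str,
    split: str = "median",
) -> pd.Series:
    """Partition samples at the across-sample median of marker expression.

    Returns a Series indexed by sample with values "Marker_Low" /
    "Marker_High".  Samples exactly at the median go to the Low stratum
    (spilling into High only as needed to keep the partition sizes within
    one of each other).
    """
    if split != "median":
        raise ValueError(f"unknown split {split!r}")
    if marker not in matrix.index:
        raise ExpressionError(f"marker gene {marker!r} not in matrix")
    values = matrix.loc[marker].astype(float)
    if len(values) < 4:
        raise ExpressionError("stratification needs at least 4 samples")
    if values.nunique() == 1:
        raise ExpressionError("degenerate marker distribution (all values equal)")

    med = values.median()
    n = len(values)
    n_low_target = (n + 1) // 2
    labels = pd.Series(index=values.index, dtype=object, name="stratum")
    labels[values < med] = "Marker_Low"
    labels[values > med] = "Marker_High"
    at_median = values.index[values == med]
    room = n_low_target - int((labels == "Marker_Low").sum())
    for i, s in enumerate(at_median):
        labels[s] = "Marker_Low" if i < room else "Marker_High"
    return labels


# ---------------------------------------------------------------------------
# panel contrasts


def panel_compare(
    matrix: pd.DataFrame,
    panel: GeneSet,
    partition: pd.Series,
    adiposity_labels: pd.Series,
    test: str = "ranksum",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Obese-vs-lean contrasts for each panel gene within each marker stratum.

    ``matrix`` holds linear-scale abundances (fold levels are fine); the
    contrast is computed on log2 values.  ``test`` is "ranksum"
    (Mann-Whitney, default: small strata) or "t" (Welch).  Raw p values are
    Benjamini-Hochberg adjusted across the panel within each stratum.
    Cells with fewer than 2 samples make that contrast not-evaluable.
    """
    _require_genes(matrix, panel.genes, "panel")
    samples = list(matrix.columns)
    for name, labels in (("partition", partition), ("adiposity_labels", adiposity_labels)):
        uncovered = [s for s in samples if s not in labels.index or pd.isna(labels[s])]
        if uncovered:
            raise ExpressionError(f"{name} does not cover samples: {uncovered}")
    if test not in ("ranksum", "t"):
        raise ValueError(f"unknown test {test!r}")

    log2 = np.log2(matrix.astype(float))
    rows = []
    for stratum in sorted(partition.unique()):
        in_stratum = [s for s in samples if partition[s] == stratum]
        obese = [s for s in in_stratum if adiposity_labels[s] == "obese"]
        lean = [s for s in in_stratum if adiposity_labels[s] == "lean"]
        for gene in panel.genes:
            if len(obese) < 2 or len(lean) < 2:
                rows.append({
                    "stratum": stratum, "gene": gene, "evaluable": False,
                    "log2_fold": np.nan, "fold": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan,
                    "p_raw": np.nan, "p_adj": np.nan, "significant": False,
                    "n_obese": len(obese), "n_lean": len(lean),
                })
                continue
            a = log2.loc[gene, obese].to_numpy()
            b = log2.loc[gene, lean].to_numpy()
            diff = float(a.mean() - b.mean())
            se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
            if test == "ranksum":
                p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            else:
                p = stats.ttest_ind(a, b, equal_var=False).pvalue
            rows.append({
                "stratum": stratum, "gene": gene, "evaluable": True,
                "log2_fold": diff, "fold": float(2.0 ** diff),
                "ci_low": float(2.0 ** (diff - 1.96 * se)),
                "ci_high": float(2.0 ** (diff + 1.96 * se)),
                "p_raw": float(p), "p_adj": np.nan, "significant": False,
                "n_obese": len(obese), "n_lean": len(lean),
            })
    out = pd.DataFrame(rows)
    for stratum in out["stratum"].unique():
        mask = (out["stratum"] == stratum) & out["evaluable"]
        if mask.sum():
            rej, adj, *_ = multipletests(
                out.loc[mask, "p_raw"], alpha=alpha, method="fdr_bh"
            )
            out.loc[mask, "p_adj"] = adj
            out.loc[mask, "significant"] = rej
    return out


def marker_panel_correlation(
    matrix: pd.DataFrame,
    marker: str,
    panel: GeneSet,
) -> pd.DataFrame:
    """Linear correlation of marker expression against each panel gene.

    Computed on log2 abundances across samples; returns Pearson r with a
    Fisher-z 95% CI per gene.  Zero-variance genes are not-evaluable.
    """
    _require_genes(matrix, [marker, *panel.genes], "correlation")
    if matrix.shape[1] < 5:
        raise ExpressionError("correlation needs at least 5 samples")
    log2 = np.log2(matrix.astype(float))
    m = log2.loc[marker].to_numpy()
    rows = []
    n = len(m)
    for gene in panel.genes:
        g = log2.loc[gene].to_numpy()
        if np.std(g) == 0 or np.std(m) == 0:
            rows.append({"gene": gene, "r": np.nan, "p": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "evaluable": False})
            continue
        r, p = stats.pearsonr(m, g)
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        half = 1.96 / np.sqrt(n - 3)
        rows.append({
            "gene": gene, "r": float(r), "p": float(p),
            "ci_low": float(np.tanh(z - half)), "ci_high": float(np.tanh(z + half)),
            "evaluable": True,
        })
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# transcriptome structure


@dataclass
class StructureSummary:
    """Sample-space structure of the top-variable expressed genes."""

    selected_genes: list
    coordinates: pd.DataFrame        # samples x components
    variance_explained: np.ndarray
    correlation: pd.DataFrame        # sample x sample Pearson r
    linkage: Optional[np.ndarray]
    clusters: Optional[pd.Series]    # k=2 assignment per sample


def transcriptome_structure(
    matrix: pd.DataFrame,
    n_top: int = 6000,
    methods: Sequence[str] = ("pca", "correlation_matrix", "hierarchical"),
    expressed_floor: float = 1.0,
    n_components: int = 2,
) -> StructureSummary:
    """Summarize sample structure from the most variable expressed genes.

    Genes with mean abundance above ``expressed_floor`` are ranked by
    log2-scale variance and the top ``n_top`` kept.  PCA runs on
    gene-standardized log2 values; the correlation matrix is sample-sample
    Pearson r on the selected genes; hierarchical clustering is
    average-linkage on correlation distance, cut at k=2.
    """
    expressed = matrix.index[matrix.mean(axis=1) > expressed_floor]
    if n_top > len(expressed):
        raise ExpressionError(
            f"n_top={n_top} exceeds the {len(expressed)} expressed genes available"
        )
    log2 = np.log2(matrix.loc[expressed].astype(float) + 1e-9)
    variances = log2.var(axis=1)
    # deterministic under gene reordering: break variance ties by label
    ranked = variances.to_frame("var").assign(g=variances.index)
    ranked = ranked.sort_values(["var", "g"], ascending=[False, True])
    selected = list(ranked.index[:n_top])
    sub = log2.loc[selected]
    # sample ordering must not matter either: compute on a sorted view,
    # then report in the input order
    sample_order = sorted(matrix.columns)
    sub = sub[sample_order]

    coords = var_exp = corr = link = clusters = None
    if "pca" in methods:
        sd = sub.std(axis=1).replace(0, 1.0)
        standardized = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        pca = PCA(n_components=min(n_components, len(sample_order) - 1),
                  svd_solver="full")
        xy = pca.fit_transform(standardized.T.to_numpy())
        # fix component sign for ordering invariance
        for j in range(xy.shape[1]):
            if xy[np.argmax(np.abs(xy[:, j])), j] < 0:
                xy[:, j] *= -1
        coords = pd.DataFrame(
            xy, index=sample_order,
            columns=[f"PC{i + 1}" for i in range(xy.shape[1])],
        ).loc[list(matrix.columns)]
        var_exp = pca.explained_variance_ratio_
    if "correlation_matrix" in methods or "hierarchical" in methods:
        corr = pd.DataFrame(
            np.corrcoef(sub.T.to_numpy()), index=sample_order, columns=sample_order
        ).loc[list(matrix.columns), list(matrix.columns)]
    if "hierarchical" in methods:
        dist = 1.0 - corr.loc[sample_order, sample_order].to_numpy()
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
        clusters = pd.Series(labels, index=sample_order, name="cluster")
        clusters = clusters.loc[list(matrix.columns)]

    return StructureSummary(
        selected_genes=selected,
        coordinates=coords,
        variance_explained=var_exp,
        correlation=corr,
        linkage=link,
        clusters=clusters,
    )
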