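"""Single-EB qPCR normalization: reference-gene stability, −ΔΔCT, imputation.

CT matrices (genes × EBs, missing cells = failed reactions) are normalized
in three steps. First, candidate housekeeping genes are ranked for
stability by two independent methods — geNorm's mean pairwise variation M
and the NormFinder inter/intra-group variance decomposition — and the two
most stable genes are accepted only when both methods agree on the pair.
Second, each gene's CT is expressed relative to the mean of the two
normalizers (ΔCT, cancelling cell-number/loading differences between EBs)
and shifted gene-wise by the control group's median, giving −ΔΔCT on a
log2-expression scale where +1 means about a two-fold increase. Third, for
clustering only, missing cells are imputed from the nearest-neighbor EB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionPanel",
    "NormalizedPanel",
    "NormalizerDisagreement",
    "genorm_stability",
    "normfinder_stability",
    "select_normalizers",
    "normalize_neg_ddct",
    "impute_nn",
    "cluster_corr",
    "fold_range",
    "filter_genes",
]

logger = logging.getLogger(__name__)

CT_MAX_CYCLES = 30.0  # qPCR runs use 30 amplification cycles


@dataclass
class ExpressionPanel:
    """CT matrix (genes × EBs) plus per-EB metadata.

    ``ct``: DataFrame, rows = gene names, columns = EB ids, NaN = failed
    reaction. ``metadata``: DataFrame indexed by EB id with at least a
    ``group`` column; ``harvest_h``, ``radius_um`` and ``devA_h`` optional.
    """

    ct: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.ct.to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if obs.size and (obs.min() <= 0 or obs.max() > CT_MAX_CYCLES):
            raise ValueError(f"CT values must lie in (0, {CT_MAX_CYCLES:g}]")
        missing = set(self.ct.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"EBs without metadata: {sorted(missing)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.ct.index)

    @property
    def ebs(self) -> list[str]:
        return list(self.ct.columns)


@dataclass
class NormalizedPanel:
    """−ΔΔCT matrix (higher = more expression) with its normalization context."""

    neg_ddct: pd.DataFrame
    normalizer_genes: tuple[str, str]
    reference_group: str
    metadata: pd.DataFrame


class NormalizerDisagreement(RuntimeError):
    """geNorm and NormFinder disagree on the top housekeeping pair."""

    def __init__(self, genorm_ranking: list[str], normfinder_ranking: list[str]):
        self.genorm_ranking = genorm_ranking
        self.normfinder_ranking = normfinder_ranking
        super().__init__(
            "stability methods disagree on the top normalizer pair: "
            f"geNorm ranks {genorm_ranking[:2]}, NormFinder ranks {normfinder_ranking[:2]}"
        )


def _complete_candidate_matrix(panel: ExpressionPanel, candidates: list[str]) -> pd.DataFrame:
    sub = panel.ct.loc[list(candidates)]
    complete = sub.dropna(axis=1)
    if complete.shape[1] < 3:
        raise ValueError("need >= 3 EBs with complete candidate data")
    return complete


def genorm_stability(panel: ExpressionPanel, candidates: list[str]) -> pd.Series:
    """geNorm expression-stability measure M per candidate (lower = stabler).

    M_j is the mean, over all other candidates k, of the standard deviation
    across EBs of the pairwise difference CT_j − CT_k (the log-ratio of the
    two genes' expression). Computed on EBs with complete candidate data.
    """
    if len(candidates) < 3:
        raise ValueError("geNorm needs >= 3 candidate genes")
    mat = _complete_candidate_matrix(panel, candidates)
    m = {}
    for j in candidates:
        sds = [
            float(np.std(mat.loc[j] - mat.loc[k], ddof=1))
            for k in candidates
            if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m, name="geNorm_M").sort_values()


def normfinder_stability(
    panel: ExpressionPanel, candidates: list[str], groups: pd.Series | None = None
) -> pd.Series:
    """NormFinder-style stability per candidate (lower = stabler).

    Decomposes each candidate's CT into a gene × group interaction (the
    systematic inter-group bias left after removing gene and group means)
    and a residual intra-group variance; stability is the root of their
    sum. With a single group the measure reduces to the intra-group
    standard deviation.
    """
    mat = _complete_candidate_matrix(panel, candidates)
    if groups is None:
        groups = panel.metadata.loc[mat.columns, "group"]
    else:
        groups = groups.loc[mat.columns]
    labels = groups.unique().tolist()
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 EBs")
    x = mat.to_numpy(dtype=float)
    if len(labels) == 1:
        sd = x.std(axis=1, ddof=1)
        return pd.Series(sd, index=mat.index, name="normfinder").sort_values()
    gene_group_mean = np.column_stack(
        [x[:, (groups == g).to_numpy()].mean(axis=1) for g in labels]
    )
    intra_var = np.column_stack(
        [x[:, (groups == g).to_numpy()].var(axis=1, ddof=1) for g in labels]
    )
    # two-way decomposition: interaction d_ig = m_ig - m_i. - m_.g + m_..
    m_i = gene_group_mean.mean(axis=1, keepdims=True)
    m_g = gene_group_mean.mean(axis=0, keepdims=True)
    m_all = gene_group_mean.mean()
    d = gene_group_mean - m_i - m_g + m_all
    inter = (d**2).mean(axis=1)
    stability = np.sqrt(inter + intra_var.mean(axis=1))
    return pd.Series(stability, index=mat.index, name="normfinder").sort_values()


def select_normalizers(
    panel: ExpressionPanel, candidates: list[str], groups: pd.Series | None = None
) -> tuple[str, str]:
    """The two most stable housekeeping genes, accepted only on agreement.

    Both geNorm and NormFinder rank the candidates; the top pair is
    returned when the two methods agree on the same two genes (in any
    order), otherwise a NormalizerDisagreement carrying both rankings is
    raised — there is no silent fallback choice.
    """
    if len(candidates) < 3:
        raise ValueError("need >= 3 candidate genes")
    g_rank = genorm_stability(panel, candidates).index.tolist()
    n_rank = normfinder_stability(panel, candidates, groups).index.tolist()
    if set(g_rank[:2]) != set(n_rank[:2]):
        raise NormalizerDisagreement(g_rank, n_rank)
    return (g_rank[0], g_rank[1])


def normalize_neg_ddct(
    panel: ExpressionPanel,
    normalizers: tuple[str, str],
    reference_group: str,
) -> NormalizedPanel:
    """Housekeeping-normalized, control-median-shifted expression (−ΔΔCT).

    ΔCT = CT_gene − mean(CT of the two normalizers); −ΔΔCT = −(ΔCT − median
    ΔCT over the reference group), so one cycle below the reference median
    reads +1 (≈ two-fold up) and the reference-group median of every gene
    is exactly 0. EBs missing both normalizer values are dropped (logged);
    with one normalizer missing the other is used alone.
    """
    for g in normalizers:
        if g not in panel.ct.index:
            raise ValueError(f"normalizer {g!r} absent from the panel")
    norm_ct = panel.ct.loc[list(normalizers)]
    usable = norm_ct.notna().sum(axis=0) > 0
    dropped = [e for e in panel.ebs if not usable[e]]
    if dropped:
        logger.warning("dropping %d EBs missing both normalizers: %s", len(dropped), dropped)
    cols = [e for e in panel.ebs if usable[e]]
    norm_mean = norm_ct[cols].mean(axis=0)
    genes = [g for g in panel.genes if g not in normalizers]
    dct = panel.ct.loc[genes, cols].sub(norm_mean, axis=1)
    ref_cols = [e for e in cols if panel.metadata.loc[e, "group"] == reference_group]
    if not ref_cols:
        raise ValueError(f"no EBs in reference group {reference_group!r}")
    ref_median = dct[ref_cols].median(axis=1)
    neg = -(dct.sub(ref_median, axis=0))
    return NormalizedPanel(
        neg_ddct=neg,
        normalizer_genes=tuple(normalizers),
        reference_group=reference_group,
        metadata=panel.metadata.loc[cols],
    )


def impute_nn(matrix: pd.DataFrame) -> pd.DataFrame:
    """Nearest-neighbor imputation of missing cells, column-wise over EBs.

    Each missing cell (gene g, EB e) is filled with the value of g in the
    EB nearest to e — Euclidean distance over the genes the two EBs
    co-observe — among EBs that observed g. Observed cells are untouched.
    """
    x = matrix.to_numpy(dtype=float)
    if np.all(np.isnan(x), axis=1).any():
        raise ValueError("gene with no observed values cannot be imputed")
    if np.all(np.isnan(x), axis=0).any():
        raise ValueError("EB with no observed values cannot be imputed")
    out = x.copy()
    n = x.shape[1]
    for e in range(n):
        miss = np.isnan(x[:, e])
        if not miss.any():
            continue
        dists = np.full(n, np.inf)
        for other in range(n):
            if other == e:
                continue
            shared = ~np.isnan(x[:, e]) & ~np.isnan(x[:, other])
            if shared.any():
                diff = x[shared, e] - x[shared, other]
                dists[other] = float(np.sqrt(np.mean(diff**2)))
        order = np.argsort(dists)
        for gi in np.nonzero(miss)[0]:
            for other in order:
                if np.isfinite(dists[other]) and not np.isnan(x[gi, other]):
                    out[gi, e] = x[gi, other]
                    break
            else:  # pragma: no cover - guarded by the all-missing checks
                raise ValueError("no donor EB found for imputation")
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def cluster_corr(matrix: pd.DataFrame, axis: str = "genes") -> dict:
    """Average-linkage hierarchical clustering on Pearson-correlation distance.

    Profiles (rows for ``axis='genes'``, columns for ``axis='ebs'``) are
    compared by d = 1 − r; the linkage and the dendrogram leaf order are
    deterministic given the input order. Constant profiles have undefined
    correlation and are rejected.
    """
    data = matrix if axis == "genes" else matrix.T
    x = data.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 profiles to cluster")
    if np.any(x.std(axis=1) == 0):
        raise ValueError("constant profile: Pearson correlation undefined")
    corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # numerical symmetry
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(link)
    return {
        "linkage": link,
        "leaf_order": [data.index[i] for i in leaves],
        "labels": list(data.index),
    }


def fold_range(gene_values: np.ndarray | pd.Series) -> float:
    """Fold change spanned by a gene across EBs: 2^(max − min) of −ΔΔCT.

    A 12-cycle spread corresponds to a 4096-fold expression range.
    """
    v = np.asarray(gene_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need >= 2 observed values")
    return float(2.0 ** (v.max() - v.min()))


def filter_genes(
    matrix: pd.DataFrame,
    max_missing_frac: float = 0.5,
    min_sd: float = 0.5,
) -> pd.DataFrame:
    """Drop genes with high sampling-failure rate or low inter-EB variance.

    Genes missing in more than ``max_missing_frac`` of EBs, or with an
    observed standard deviation below ``min_sd`` −ΔΔCT units, are removed
    before stability ranking / trend analysis.
    """
    frac_missing = matrix.isna().mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    keep = (frac_missing <= max_missing_frac) & (sd >= min_sd)
    return matrix.loc[keep]
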