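"""Perturbation effects and Wnt3-dependency mode classification.

CHIR (a GSK3β inhibitor) activates canonical Wnt signaling downstream of
the Wnt3 ligand while simultaneously down-regulating Wnt3 transcription.
This dual effect dissociates pathway activity from ligand level: a gene
regulated through the canonical pathway moves off its control gene-vs-Wnt3
trend under CHIR, a gene driven by Wnt3 through another route slides along
the trend to its low-Wnt3 end, a gene that merely co-varies with Wnt3 in
time stays at control levels, and an indirect target responds only to the
long treatment. The classifier operationalizes these four modes from the
control trend line, per-group residual z-scores and per-group expression
shift z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .qpcrnorm import NormalizedPanel, impute_nn

__all__ = [
    "DependencyCall",
    "GroupShift",
    "group_shift",
    "pca_groups",
    "classify_dependency_modes",
    "MODES",
]

MODES = (
    "canonical_regulation",
    "trend_continuation",
    "decoupled_parallel",
    "indirect_long_term_only",
    "not_correlated",
)

CHIR_SHORT_GROUPS = ("chir_short_early", "chir_short_late")
CHIR_LONG_GROUP = "chir_long"


@dataclass
class GroupShift:
    """Median expression shift of one gene in one perturbation group."""

    gene: str
    group: str
    delta: float  # group median − control median, −ΔΔCT units
    p_value: float
    significant: bool  # BH-adjusted across genes at alpha


@dataclass
class DependencyCall:
    """Per-gene Wnt3-dependency classification with supporting statistics."""

    gene: str
    r_wnt3: float
    trend: tuple[float, float]  # (slope, intercept) of gene ~ Wnt3 on controls
    residual_z: dict[str, float] = field(default_factory=dict)
    shift_z: dict[str, float] = field(default_factory=dict)
    mode: str = "not_correlated"


def _values(normalized: NormalizedPanel | pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    if isinstance(normalized, NormalizedPanel):
        return normalized.neg_ddct, normalized.metadata["group"]
    raise TypeError("pass a NormalizedPanel, or use the explicit-matrix signature")


def group_shift(
    normalized: NormalizedPanel | pd.DataFrame,
    group: str,
    control: str = "control",
    groups: pd.Series | None = None,
    alpha: float = 0.05,
) -> list[GroupShift]:
    """Per-gene median expression difference of a perturbation group vs control.

    delta = group median − control median in −ΔΔCT units, with an advisory
    significance flag from a rank-sum (Mann-Whitney) test, Benjamini-
    Hochberg corrected across genes. Deltas are antisymmetric under
    swapping the two groups.
    """
    if isinstance(normalized, pd.DataFrame):
        if groups is None:
            raise ValueError("groups labels required with a bare matrix")
        mat, labels = normalized, groups.reindex(normalized.columns)
    else:
        mat, labels = _values(normalized)
    g_cols = mat.columns[(labels == group).to_numpy()]
    c_cols = mat.columns[(labels == control).to_numpy()]
    if len(g_cols) < 3 or len(c_cols) < 3:
        raise ValueError("both groups need >= 3 EBs")
    deltas, pvals = [], []
    for gene in mat.index:
        gv = mat.loc[gene, g_cols].dropna().to_numpy(dtype=float)
        cv = mat.loc[gene, c_cols].dropna().to_numpy(dtype=float)
        deltas.append(float(np.median(gv) - np.median(cv)))
        if np.array_equal(np.sort(gv), np.sort(cv)):
            pvals.append(1.0)  # identical samples: no evidence of a shift
        else:
            pvals.append(float(stats.mannwhitneyu(gv, cv, alternative="two-sided").pvalue))
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return [
        GroupShift(gene=g, group=group, delta=d, p_value=p, significant=bool(r))
        for g, d, p, r in zip(mat.index, deltas, pvals, reject)
    ]


def pca_groups(
    normalized: NormalizedPanel | pd.DataFrame,
    groups: pd.Series | None = None,
    n_components: int | None = None,
) -> dict:
    """Principal components of the EB expression space, annotated by group.

    The gene × EB matrix is median-imputed (clustering-style NaN handling),
    gene-centered and decomposed; EB coordinates, per-component percent
    explained variance, and per-group centroid projections are returned.
    """
    if isinstance(normalized, pd.DataFrame):
        mat = normalized
        if groups is None:
            raise ValueError("groups labels required with a bare matrix")
        labels = groups.reindex(mat.columns)
    else:
        mat, labels = _values(normalized)
    if mat.shape[1] < 3 or mat.shape[0] < 2:
        raise ValueError("need >= 3 EBs and >= 2 genes")
    filled = impute_nn(mat) if mat.isna().to_numpy().any() else mat
    x = filled.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)  # gene-centered
    if not np.any(x):
        raise ValueError("rank-0 matrix: no variance to decompose")
    k = n_components or min(x.shape[0], x.shape[1] - 1)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x.T)  # EBs in rows
    pct = 100.0 * pca.explained_variance_ratio_
    coord_df = pd.DataFrame(
        coords, index=mat.columns, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
    )
    centroids = coord_df.groupby(labels).mean()
    return {"coords": coord_df, "percent_variance": pct, "centroids": centroids}


def classify_dependency_modes(
    normalized: NormalizedPanel | pd.DataFrame,
    wnt3_gene: str = "Wnt3",
    groups: pd.Series | None = None,
    control: str = "control",
    r_min: float = 0.5,
    k: float = 2.0,
) -> list[DependencyCall]:
    """Classify each gene's dependency on Wnt3 under CHIR perturbations.

    Per gene: (1) Pearson r against Wnt3 on control EBs — |r| < r_min means
    not_correlated; (2) a control trend line gene ~ Wnt3; (3) per CHIR
    group, residual_z = median residual from that trend over the control
    residual SD, and shift_z = (group median − control median) over the
    control SD of the gene; (4) a decision tree on the z-scores:

    - expression unshifted in the short pulses but shifted by the long
      treatment → indirect_long_term_only;
    - expression unshifted in every CHIR group despite the Wnt3 drop →
      decoupled_parallel;
    - off the control trend in a CHIR group (|residual_z| > k) →
      canonical_regulation (the CHIR response contradicts the ligand level);
    - otherwise on-trend but shifted along it → trend_continuation.

    Missing groups shrink the resolvable mode set: without both short and
    long durations the indirect mode cannot be separated and the call list
    reports which groups were available.
    """
    if isinstance(normalized, pd.DataFrame):
        if groups is None:
            raise ValueError("groups labels required with a bare matrix")
        mat, labels = normalized, groups.reindex(normalized.columns)
    else:
        mat, labels = _values(normalized)
    if wnt3_gene not in mat.index:
        raise ValueError(f"{wnt3_gene!r} absent from the panel")
    c_cols = mat.columns[(labels == control).to_numpy()]
    if len(c_cols) < 5:
        raise ValueError("control group needs >= 5 EBs")
    chir_groups = [g for g in (*CHIR_SHORT_GROUPS, CHIR_LONG_GROUP) if (labels == g).any()]
    have_short = any(g in chir_groups for g in CHIR_SHORT_GROUPS)
    have_long = CHIR_LONG_GROUP in chir_groups
    w = mat.loc[wnt3_gene]
    w_ctrl = w[c_cols].to_numpy(dtype=float)
    calls: list[DependencyCall] = []
    for gene in mat.index:
        if gene == wnt3_gene:
            continue
        y_ctrl = mat.loc[gene, c_cols].to_numpy(dtype=float)
        ok = ~np.isnan(y_ctrl) & ~np.isnan(w_ctrl)
        r = float(stats.pearsonr(y_ctrl[ok], w_ctrl[ok]).statistic)
        slope, intercept = np.polyfit(w_ctrl[ok], y_ctrl[ok], 1)
        resid_ctrl = y_ctrl[ok] - (slope * w_ctrl[ok] + intercept)
        resid_sd = float(np.std(resid_ctrl, ddof=2)) or 1e-12
        ctrl_sd = float(np.std(y_ctrl[ok], ddof=1)) or 1e-12
        ctrl_med = float(np.median(y_ctrl[ok]))
        call = DependencyCall(gene=gene, r_wnt3=r, trend=(float(slope), float(intercept)))
        for g in chir_groups:
            g_cols = mat.columns[(labels == g).to_numpy()]
            yg = mat.loc[gene, g_cols].to_numpy(dtype=float)
            wg = w[g_cols].to_numpy(dtype=float)
            okg = ~np.isnan(yg) & ~np.isnan(wg)
            resid = yg[okg] - (slope * wg[okg] + intercept)
            call.residual_z[g] = float(np.median(resid) / resid_sd)
            call.shift_z[g] = float((np.median(yg[okg]) - ctrl_med) / ctrl_sd)
        if abs(r) < r_min:
            call.mode = "not_correlated"
        else:
            short_shifted = any(
                abs(call.shift_z.get(g, 0.0)) > k for g in CHIR_SHORT_GROUPS
            )
            long_shifted = abs(call.shift_z.get(CHIR_LONG_GROUP, 0.0)) > k
            off_trend = any(abs(z) > k for z in call.residual_z.values())
            if have_short and have_long and not short_shifted and long_shifted:
                call.mode = "indirect_long_term_only"
            elif not short_shifted and not long_shifted:
                call.mode = "decoupled_parallel"
            elif off_trend:
                call.mode = "canonical_regulation"
            else:
                call.mode = "trend_continuation"
        calls.append(call)
    return calls
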