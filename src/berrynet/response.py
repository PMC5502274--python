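"""Stage-wise treatment response: log2FC profiles, per-stage ANOVA,
profile clustering for heatmaps, PCA scores, and DE-set overlap counts."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from berrynet.datatypes import (
    DETable,
    ExpressionMatrix,
    MetaboliteTable,
    ResponseProfiles,
    ValidationError,
)


def default_pseudocount(x: ExpressionMatrix | MetaboliteTable) -> float:
    """1.0 for counts; half the smallest positive value for concentrations."""
    if isinstance(x, ExpressionMatrix):
        return 1.0
    arr = x.values.to_numpy(dtype=float)
    pos = arr[arr > 0]
    if pos.size == 0:
        return 1.0
    return float(pos.min() * 0.5)


def log2_fold_change(
    x: ExpressionMatrix | MetaboliteTable, pseudocount: float | None = None
) -> ResponseProfiles:
    """Per-feature, per-stage log2((mean_WD + pc) / (mean_CT + pc)).

    Replicates are averaged with plain arithmetic means. Swapping the
    treatment labels negates every value (the pseudocount is applied
    symmetrically).
    """
    if pseudocount is None:
        pseudocount = default_pseudocount(x)
    if pseudocount < 0:
        raise ValidationError("pseudocount must be nonnegative")
    stages = x.stages
    means: dict[str, pd.DataFrame] = {}
    for trt in ("CT", "WD"):
        cols = {}
        for stage in stages:
            samples = x.samples_for(stage, trt)
            if not samples:
                raise ValidationError(
                    f"no replicates for treatment {trt} at stage {stage}"
                )
            cols[stage] = x.values[samples].mean(axis=1)
        means[trt] = pd.DataFrame(cols)
    num = means["WD"] + pseudocount
    den = means["CT"] + pseudocount
    if (num <= 0).any().any() or (den <= 0).any().any():
        raise ValidationError(
            "nonpositive stage mean with zero pseudocount; supply pseudocount > 0"
        )
    return ResponseProfiles(np.log2(num / den))


def stagewise_anova(m: MetaboliteTable) -> pd.DataFrame:
    """One-way fixed-effects ANOVA (CT vs WD) per metabolite and stage.

    With two groups F equals the squared pooled-variance t statistic.
    Degenerate convention: zero within-group variance in both groups
    gives p = 1 for equal group means and p = 0 otherwise.
    """
    stages = m.stages
    out = pd.DataFrame(np.nan, index=m.values.index, columns=stages)
    for stage in stages:
        groups = {
            trt: m.values[m.samples_for(stage, trt)].to_numpy(dtype=float)
            for trt in ("CT", "WD")
        }
        for trt, arr in groups.items():
            if arr.shape[1] < 2:
                raise ValidationError(
                    f"ANOVA needs >= 2 replicates for {trt} at stage {stage}"
                )
        ct, wd = groups["CT"], groups["WD"]
        out[stage] = np.array([
            _anova_p([ct[i], wd[i]]) for i in range(ct.shape[0])
        ])
    return out


def _anova_p(groups: list[np.ndarray]) -> float:
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        return 1.0 if ss_between == 0.0 else 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(sps.f.sf(f, df_b, df_w))


@dataclass
class ClusterResult:
    """Leaf order and merge tree from correlation-distance clustering."""

    leaf_order: list[str]
    linkage: np.ndarray  # scipy linkage matrix over clustered features
    clustered_ids: list[str]  # row order matching the linkage matrix
    set_aside: list[str]  # zero-variance profiles appended after the leaves


def cluster_response_profiles(profiles: ResponseProfiles) -> ClusterResult:
    """Agglomerative clustering of response profiles.

    Distance d(a, b) = 1 - PCC(a, b), complete linkage. Rows are sorted
    lexicographically by feature id before linkage so ties break
    deterministically and the result is invariant to input row order.
    Zero-variance profiles cannot enter a correlation distance; they are
    set aside with a warning and appended after the ordered leaves.
    """
    df = profiles.log2fc.sort_index()
    if df.shape[0] < 2:
        raise ValidationError("clustering requires at least 2 profiles")
    variances = df.var(axis=1, ddof=0)
    flat = list(df.index[variances == 0.0])
    if flat:
        if len(flat) == df.shape[0]:
            raise ValidationError("all profiles have zero variance")
        warnings.warn(
            f"{len(flat)} zero-variance profile(s) set aside from clustering",
            stacklevel=2,
        )
    kept = df.drop(index=flat)
    if kept.shape[0] == 1:
        return ClusterResult(list(kept.index) + flat, np.empty((0, 4)),
                             list(kept.index), flat)
    corr = np.corrcoef(kept.to_numpy(dtype=float))
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    order = [kept.index[i] for i in hierarchy.leaves_list(z)]
    return ClusterResult(order + flat, z, list(kept.index), flat)


@dataclass
class PCAResult:
    """PCA scores with percent variance explained per component."""

    scores: pd.DataFrame  # samples x components
    variance_explained_pct: np.ndarray
    loadings: pd.DataFrame  # features x components

    def __post_init__(self) -> None:
        v = self.variance_explained_pct
        if np.any(np.diff(v) > 1e-9) or v.sum() > 100.0 + 1e-6:
            raise ValidationError(
                "variance_explained_pct must be nonincreasing and sum to <= 100"
            )


def pca_scores(
    x: pd.DataFrame, center: bool = True, scale: bool = False
) -> PCAResult:
    """Principal-component scores of a samples x features matrix.

    Eigendecomposition is done through the SVD of the (centered,
    optionally unit-variance scaled) data. Zero-variance features are
    dropped with a warning when scaling. Component signs are fixed so
    each component's largest-magnitude loading is positive.
    """
    if x.shape[0] < 2:
        raise ValidationError("PCA requires at least 2 samples")
    arr = x.to_numpy(dtype=float)
    cols = list(x.columns)
    sd = arr.std(axis=0, ddof=1)
    if scale:
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance feature(s) before "
                "scaled PCA",
                stacklevel=2,
            )
            arr = arr[:, keep]
            cols = [c for c, k in zip(cols, keep) if k]
            sd = sd[keep]
    if arr.shape[1] < 2:
        raise ValidationError("PCA requires at least 2 usable features")
    if center:
        arr = arr - arr.mean(axis=0)
    if scale:
        arr = arr / sd
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    # sign convention: largest-magnitude loading positive per component
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    eig = s**2
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    pcs = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        pd.DataFrame(scores, index=x.index, columns=pcs),
        pct,
        pd.DataFrame(vt.T, index=cols, columns=pcs),
    )


@dataclass
class DEOverlap:
    """Per-stage DE counts and exclusive Venn-region cardinalities."""

    per_stage: pd.DataFrame  # index stage; columns total, up, down
    regions: dict[tuple[int, ...], int]  # stages-combination -> exclusive count
    union_size: int

    def common_to_all(self) -> int:
        all_stages = tuple(sorted(self.per_stage.index))
        return self.regions.get(all_stages, 0)


def de_overlap(de: DETable) -> DEOverlap:
    """Exact set algebra over per-stage DE gene sets.

    ``regions`` maps each nonempty combination of stages to the number
    of genes DE in exactly those stages; region counts sum to the size
    of the union of all per-stage sets.
    """
    stages = de.stages
    sets = {s: de.genes_at(s) for s in stages}
    per_stage = pd.DataFrame(
        {
            "total": [len(sets[s]) for s in stages],
            "up": [len(de.genes_at(s, "up")) for s in stages],
            "down": [len(de.genes_at(s, "down")) for s in stages],
        },
        index=pd.Index(stages, name="stage_daa"),
    )
    regions: dict[tuple[int, ...], int] = {}
    for r in range(1, len(stages) + 1):
        for combo in itertools.combinations(stages, r):
            inside = set.intersection(*(sets[s] for s in combo))
            outside = set().union(*(sets[s] for s in stages if s not in combo)) \
                if len(combo) < len(stages) else set()
            regions[tuple(combo)] = len(inside - outside)
    union_size = len(set().union(*sets.values())) if sets else 0
    return DEOverlap(per_stage, regions, union_size)
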