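"""Weighted co-expression network module detection.

Implements the WGCNA-style chain: soft-threshold power selection by the
scale-free topology criterion, adjacency and topological overlap (TOM)
matrices, average-linkage clustering of 1 - TOM with a simplified
recursive tree cut, module eigengenes, and eigengene-based module
merging. Works both on log2FC response profiles (a handful of stages
per feature) and on full expression matrices (all samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from berrynet.datatypes import (
    ModuleAssignment,
    NetworkParams,
    ValidationError,
)

DEFAULT_CANDIDATE_POWERS = tuple(range(1, 21))


def _correlation(profiles: pd.DataFrame) -> np.ndarray:
    arr = profiles.to_numpy(dtype=float)
    var = arr.var(axis=1)
    if (var == 0).any():
        bad = profiles.index[int(np.argmax(var == 0))]
        raise ValidationError(
            f"zero-variance feature {bad!r}; filter constant features first"
        )
    r = np.corrcoef(arr)
    return np.clip(r, -1.0, 1.0)


def _adjacency(corr: np.ndarray, power: float, network_type: str) -> np.ndarray:
    if network_type == "unsigned":
        a = np.abs(corr) ** power
    else:
        a = ((1.0 + corr) / 2.0) ** power
    np.fill_diagonal(a, 0.0)  # connectivity excludes self
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) vs log10 k over connectivity bins.

    Connectivities are binned at their quantiles (equal-count bins) and
    the bin densities (count / total / bin width) regressed on the mean
    bin connectivity, both on log10 scales. The R^2 is set to 0 when the
    slope is positive (scale-free topology requires a decreasing degree
    density) and NaN when the fit is undefined (degenerate
    connectivity, e.g. all values identical).
    """
    k = np.asarray(k, dtype=float)
    if k.max() <= 0 or np.isclose(k.min(), k.max()):
        return float("nan")
    edges = np.unique(np.quantile(k, np.linspace(0.0, 1.0, n_bins + 1)))
    if len(edges) < 4:
        return float("nan")
    xs, ys = [], []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        mask = (k >= lo) & ((k < hi) if i < len(edges) - 2 else (k <= hi))
        cnt = int(mask.sum())
        if cnt == 0 or hi <= lo:
            continue
        mean_k = k[mask].mean()
        density = cnt / k.size / (hi - lo)
        if mean_k > 0 and density > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(density))
    if len(xs) < 3 or np.isclose(min(xs), max(xs)):
        return float("nan")
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = np.polyval([slope, intercept], xs)
    ss_res = float(((np.asarray(ys) - fitted) ** 2).sum())
    ss_tot = float(((np.asarray(ys) - np.mean(ys)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return 0.0 if slope > 0 else r2


@dataclass
class PowerSelection:
    power: float
    fits: pd.DataFrame  # columns power, r2, mean_k
    reached_target: bool


def select_soft_power(
    profiles: pd.DataFrame,
    candidate_powers: tuple[float, ...] = DEFAULT_CANDIDATE_POWERS,
    target_r2: float = 0.8,
    network_type: str = "unsigned",
) -> PowerSelection:
    """Smallest candidate power whose network meets the scale-free
    topology fit ``target_r2``; otherwise the best-fitting power, with a
    warning. Degenerate inputs (undefined fits for every candidate) fall
    back to the smallest candidate, with a warning."""
    if not candidate_powers:
        raise ValidationError("candidate_powers must be nonempty")
    if profiles.shape[0] < 20:
        warnings.warn(
            f"soft-power selection on only {profiles.shape[0]} features; "
            "the scale-free criterion is unreliable below ~20",
            stacklevel=2,
        )
    corr = _correlation(profiles)
    rows = []
    for power in candidate_powers:
        a = _adjacency(corr, power, network_type)
        k = a.sum(axis=1)
        rows.append({"power": power, "r2": scale_free_fit(k), "mean_k": k.mean()})
    fits = pd.DataFrame(rows)
    if len(candidate_powers) == 1:
        only = float(candidate_powers[0])
        ok = bool(fits["r2"].iloc[0] >= target_r2)
        if not ok:
            warnings.warn(
                f"single candidate power {only} returned with scale-free fit "
                f"R2={fits['r2'].iloc[0]:.3f} below target {target_r2}",
                stacklevel=2,
            )
        return PowerSelection(only, fits, ok)
    if fits["r2"].isna().all():
        warnings.warn(
            "scale-free fit undefined for every candidate power "
            "(degenerate connectivity); returning the smallest candidate",
            stacklevel=2,
        )
        return PowerSelection(float(min(candidate_powers)), fits, False)
    good = fits[fits["r2"] >= target_r2]
    if len(good):
        return PowerSelection(float(good["power"].iloc[0]), fits, True)
    if fits["r2"].max() < 0.1:
        # no scale-free signal at any power; fall back to the canonical
        # sample-size-based default rather than chase fit noise
        n_obs = profiles.shape[1]
        if network_type == "unsigned":
            default = 9.0 if n_obs < 20 else 8.0 if n_obs < 30 else \
                7.0 if n_obs < 40 else 6.0
        else:
            default = 18.0 if n_obs < 20 else 16.0 if n_obs < 30 else \
                14.0 if n_obs < 40 else 12.0
        chosen = float(min(candidate_powers, key=lambda p: abs(p - default)))
        warnings.warn(
            f"scale-free fit is poor at every candidate power (max R2 = "
            f"{fits['r2'].max():.3f}); using the sample-size default power "
            f"{chosen}",
            stacklevel=2,
        )
        return PowerSelection(chosen, fits, False)
    best = fits.loc[fits["r2"].idxmax()]
    warnings.warn(
        f"no candidate power reached scale-free R2 >= {target_r2}; using "
        f"power {best['power']} with R2={best['r2']:.3f}",
        stacklevel=2,
    )
    return PowerSelection(float(best["power"]), fits, False)


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Topological overlap from an adjacency matrix (zero diagonal).

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k_i = sum_u a_iu and TOM_ii = 1; symmetric, entries in [0, 1].
    """
    a = np.asarray(a, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = (a @ a + a) / (np.minimum.outer(k, k) + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def adjacency_tom(profiles: pd.DataFrame, params: NetworkParams) -> pd.DataFrame:
    """Topological overlap similarity of the soft-thresholded network.

    Unsigned adjacency a_ij = |r_ij|^beta; signed a_ij = ((1+r_ij)/2)^beta.
    """
    corr = _correlation(profiles)
    a = _adjacency(corr, params.power, params.network_type)
    tom = tom_from_adjacency(a)
    return pd.DataFrame(tom, index=profiles.index, columns=profiles.index)


def _height_cut(
    z: np.ndarray, n: int, cut_height: float, min_size: int
) -> np.ndarray:
    """Simplified dynamic tree cut: best static cut under a ceiling.

    Every merge height up to ``cut_height`` is tried as a static cut of
    the dendrogram; the cut retained is the one producing the most
    clusters of at least ``min_size`` members, ties resolved toward the
    highest such cut (largest clusters). Clusters below ``min_size``
    become unassigned (label 0). Unlike a single fixed-height cut this
    stays meaningful when short profiles inflate every correlation and
    compress the whole dendrogram below the ceiling.
    """
    if n == 1:
        return np.array([1 if min_size <= 1 else 0], dtype=int)
    heights = z[:, 2]
    candidates = np.unique(heights[heights <= cut_height + 1e-12])
    if candidates.size == 0:
        return np.zeros(n, dtype=int)
    # evaluate just above each merge so the merge itself is included
    candidates = np.unique(np.append(candidates + 1e-9, cut_height))
    memberships = hierarchy.cut_tree(z, height=list(candidates))
    best_labels: np.ndarray | None = None
    best_count = -1
    for j in range(memberships.shape[1]):
        col = memberships[:, j]
        ids, counts = np.unique(col, return_counts=True)
        keep = ids[counts >= min_size]
        if len(keep) >= best_count:  # >= prefers the highest qualifying cut
            best_count = len(keep)
            labels = np.zeros(n, dtype=int)
            for rank, cid in enumerate(keep, start=1):
                labels[col == cid] = rank
            best_labels = labels
    assert best_labels is not None
    return best_labels


def module_eigengene(data: pd.DataFrame) -> tuple[pd.Series, float]:
    """First right-singular direction of the feature-standardized module.

    ``data`` is features x observations restricted to one module. The
    eigengene has unit norm and is oriented so its correlation with the
    mean standardized member profile is nonnegative; var_explained is
    the first squared singular value over the total.
    """
    if data.shape[0] < 2:
        raise ValidationError("module eigengene requires >= 2 members")
    arr = data.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    if (sd == 0).any():
        bad = data.index[int(np.argmax(sd.ravel() == 0))]
        raise ValidationError(f"zero-variance feature {bad!r} in module")
    zs = (arr - mu) / sd
    u, s, vt = np.linalg.svd(zs, full_matrices=False)
    eig = vt[0]
    mean_profile = zs.mean(axis=0)
    if eig @ mean_profile < 0:
        eig = -eig
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(eig, index=data.columns), var_explained


def _build_assignment(
    labels_int: np.ndarray,
    feature_ids: list[str],
    data: pd.DataFrame,
    prefix: str,
    min_module_size: int,
) -> ModuleAssignment:
    """Relabel integer clusters by descending size and compute eigengenes."""
    series = pd.Series(labels_int, index=feature_ids)
    sizes = series[series > 0].value_counts()
    order = sorted(sizes.index, key=lambda l: (-sizes[l], l))
    rename = {old: f"{prefix}{i + 1}" for i, old in enumerate(order)}
    labels = series.map(lambda v: rename.get(v, ModuleAssignment.UNASSIGNED))

    eigengenes = {}
    var_explained = {}
    for mod in rename.values():
        members = labels.index[labels == mod]
        eig, ve = module_eigengene(data.loc[members])
        eigengenes[mod] = eig
        var_explained[mod] = ve
    eg = (
        pd.DataFrame(eigengenes).T.reindex(list(rename.values()))
        if eigengenes
        else pd.DataFrame(columns=data.columns)
    )
    return ModuleAssignment(labels, eg, pd.Series(var_explained, dtype=float))


def detect_modules(
    tom: pd.DataFrame,
    params: NetworkParams,
    data: pd.DataFrame,
    prefix: str = "WD",
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a height-based cut.

    A numeric ``cut_height`` is the ceiling of the best-static-cut
    search (see :func:`_height_cut`); ``cut_height='dynamic'`` sets the
    ceiling to 0.99 of the tree's own root height. Clusters below
    ``min_module_size`` land in the "unassigned" sink; surviving modules
    are labelled ``prefix`` + rank by descending size.
    """
    if not tom.index.equals(tom.columns) or not tom.index.equals(data.index):
        raise ValidationError("TOM and data must share one feature axis")
    n = tom.shape[0]
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    if params.cut_height == "dynamic":
        cut = 0.99 * float(z[-1, 2]) if len(z) else 1.0
    else:
        cut = float(params.cut_height)
    labels_int = _height_cut(z, n, cut, params.min_module_size)
    if params.pam_stage and labels_int.max() > 0 and (labels_int == 0).any():
        # PAM-like rescue: attach each leftover feature to the module with
        # the highest mean topological overlap to its members
        t = tom.to_numpy(dtype=float)
        module_idx = {
            lab: np.flatnonzero(labels_int == lab)
            for lab in range(1, labels_int.max() + 1)
        }
        for i in np.flatnonzero(labels_int == 0):
            sims = {lab: t[i, mem].mean() for lab, mem in module_idx.items()}
            labels_int[i] = max(sims, key=lambda l: (sims[l], -l))
    return _build_assignment(labels_int, list(tom.index), data, prefix,
                             params.min_module_size)


def merge_close_modules(
    assignment: ModuleAssignment,
    data: pd.DataFrame,
    merge_cut: float,
    prefix: str | None = None,
) -> ModuleAssignment:
    """Iteratively merge module pairs with eigengene dissimilarity
    1 - PCC below ``merge_cut``, closest pair first (ties by label),
    recomputing eigengenes after every merge."""
    labels = assignment.labels.copy()

    def eigs() -> dict[str, pd.Series]:
        return {
            m: module_eigengene(data.loc[labels.index[labels == m]])[0]
            for m in sorted(set(labels) - {ModuleAssignment.UNASSIGNED})
        }

    current = eigs()
    while len(current) >= 2:
        mods = sorted(current)
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                ea, eb = current[a].to_numpy(), current[b].to_numpy()
                d = 1.0 - float(np.corrcoef(ea, eb)[0, 1])
                if d < merge_cut and (best is None or d < best[0] - 1e-15):
                    best = (d, a, b)
        if best is None:
            break
        _, a, b = best
        keep, drop = (a, b) if (labels == a).sum() >= (labels == b).sum() else (b, a)
        labels[labels == drop] = keep
        current = eigs()

    if prefix is None:
        # retain existing labels, rebuild eigengenes
        mods = sorted(set(labels) - {ModuleAssignment.UNASSIGNED})
        eigengenes, var_explained = {}, {}
        for m in mods:
            eig, ve = module_eigengene(data.loc[labels.index[labels == m]])
            eigengenes[m] = eig
            var_explained[m] = ve
        eg = (
            pd.DataFrame(eigengenes).T.reindex(mods)
            if eigengenes
            else pd.DataFrame(columns=data.columns)
        )
        return ModuleAssignment(labels, eg, pd.Series(var_explained, dtype=float))
    # relabel by descending size under the given prefix
    ints = pd.factorize(labels.mask(labels == ModuleAssignment.UNASSIGNED))[0] + 1
    return _build_assignment(np.where(labels == ModuleAssignment.UNASSIGNED, 0, ints),
                             list(labels.index), data, prefix, 1)


@dataclass
class ModuleDetectionResult:
    assignment: ModuleAssignment
    power: float
    excluded: list[str] = field(default_factory=list)
    power_fits: pd.DataFrame | None = None


def find_modules(
    profiles: pd.DataFrame,
    params: NetworkParams | None = None,
    prefix: str = "WD",
    candidate_powers: tuple[float, ...] = DEFAULT_CANDIDATE_POWERS,
    target_r2: float = 0.8,
) -> ModuleDetectionResult:
    """End-to-end module detection on a features x observations matrix.

    Zero-variance features are excluded up front and reported; the soft
    power is selected by the scale-free criterion unless ``params`` is
    given with an explicit power and ``candidate_powers`` is that single
    power; detection runs adjacency -> TOM -> tree cut -> eigengene
    merge.
    """
    params = params or NetworkParams()
    variances = profiles.var(axis=1, ddof=0)
    excluded = list(profiles.index[variances == 0.0])
    kept = profiles.drop(index=excluded)
    if kept.shape[0] < 2:
        raise ValidationError("module detection requires >= 2 variable features")
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} zero-variance feature(s) before network "
            "construction",
            stacklevel=2,
        )
    sel = select_soft_power(kept, candidate_powers, target_r2, params.network_type)
    params = NetworkParams(
        power=sel.power,
        network_type=params.network_type,
        min_module_size=params.min_module_size,
        cut_height=params.cut_height,
        merge_cut=params.merge_cut,
    )
    tom = adjacency_tom(kept, params)
    assignment = detect_modules(tom, params, kept, prefix=prefix)
    if len(assignment.module_ids) >= 2 and params.merge_cut > 0:
        assignment = merge_close_modules(assignment, kept, params.merge_cut,
                                         prefix=prefix)
    return ModuleDetectionResult(assignment, sel.power, excluded, sel.fits)
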