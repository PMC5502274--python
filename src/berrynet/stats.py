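"""Statistical kernel: correlation, permutation p-values, enrichment, FDR.

Every downstream stage (module detection, module-metabolite screening,
promoter enrichment) goes through these four primitives, so their
contracts are deliberately strict: zero-variance vectors are rejected
rather than silently producing NaN, and permutation streams are keyed
so results do not depend on evaluation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from berrynet.datatypes import ValidationError


@dataclass(frozen=True)
class AssociationResult:
    """A correlation with its permutation-based empirical p-value."""

    id_a: str
    id_b: str
    pcc: float
    p_emp: float
    n_perm: int

    def __post_init__(self) -> None:
        if self.p_emp < 1.0 / (self.n_perm + 1) - 1e-12:
            raise ValidationError("p_emp below the permutation floor 1/(n_perm+1)")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One (gene set, annotation) hypergeometric enrichment test."""

    set_id: str
    annotation_id: str
    k: int  # annotated members of the set
    n: int  # set size
    K: int  # annotated members of the background
    N: int  # background size
    p: float
    fdr: float
    enriched: bool

    @property
    def score(self) -> float:
        """Enrichment score -log10(FDR), floored at the float limit."""
        return float(-np.log10(max(self.fdr, np.finfo(float).tiny)))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient.

    Raises :class:`ValidationError` on unequal lengths, n < 3, or a
    zero-variance argument (callers must filter constant features).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson requires two equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("pearson requires length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise ValidationError("correlation undefined: zero-variance input")
    r = float((xc @ yc) / (sx * sy))
    return min(1.0, max(-1.0, r))


def pair_seed(seed: int, id_a: str, id_b: str) -> list[int]:
    """Stable per-pair seed key so permutation results are order-independent.

    The key combines the run seed with CRC32 digests of the two ids;
    identical (seed, id_a, id_b) always yields the same stream.
    """
    return [int(seed) & 0x7FFFFFFF, zlib.crc32(id_a.encode()), zlib.crc32(id_b.encode())]


def empirical_pcc_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int | list[int] = 0,
    id_a: str = "a",
    id_b: str = "b",
    two_sided: bool = True,
) -> AssociationResult:
    """Permutation-based empirical p-value for the Pearson correlation.

    ``y`` is shuffled ``n_perm`` times; the p-value uses the standard
    add-one correction p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1),
    so it can never be exactly zero. Two-sided by absolute value unless
    ``two_sided`` is False (then the upper tail of signed r).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = pearson(x, y)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    key = seed if isinstance(seed, list) else pair_seed(seed, id_a, id_b)
    rng = np.random.default_rng(np.random.SeedSequence(key))

    # All permutations at once: correlations against a fixed x reduce to a
    # matrix-vector product on standardized data.
    n = x.size
    xs = (x - x.mean())
    xs /= np.sqrt(xs @ xs)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    yp = y[perm_idx]
    yc = yp - yp.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", yc, yc))
    r_perm = (yc @ xs) / norms
    if two_sided:
        hits = int(np.count_nonzero(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    else:
        hits = int(np.count_nonzero(r_perm >= r_obs - 1e-12))
    p_emp = (1 + hits) / (n_perm + 1)
    return AssociationResult(id_a, id_b, r_obs, p_emp, n_perm)


def hypergeometric_upper(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    X counts annotated genes in a size-``n`` set drawn without
    replacement from a background of ``N`` genes of which ``K`` are
    annotated. Evaluated through the survival function of
    :class:`scipy.stats.hypergeom`, which works on log-gamma terms and
    is stable for the (N up to genome-size) problems met here.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValidationError(
            f"invalid hypergeometric counts k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
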