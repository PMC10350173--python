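"""Per-subject module expression, intramodular connectivity and hubs.

Module expression is the module-eigengene construction: the module's
subject x region count submatrix is standardized per region (zero mean,
unit variance across subjects) and decomposed by SVD, X = U S V^T; the
leading left-singular vector gives one score per subject, and the leading
singular value's share of sum(s_k^2) is the proportion of variance the
module's common activity pattern explains. Scores are sign-oriented to
correlate positively with the mean standardized count profile so results
do not depend on the sign convention of the linear-algebra backend.

Hub ranking uses intramodular connectivity kIM (sum of a region's
adjacency to the other module members); kME (correlation of a region's
counts with the module scores, "module membership") and MAR (maximum
adjacency ratio, sum a^2 / sum a) are the other per-region bases the
preservation statistics build on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import CountMatrix
from .network import CoactivationNetwork


@dataclass
class ModuleExpression:
    module_label: str
    subject_ids: list[str]
    subject_scores: np.ndarray  # leading left-singular vector (unit norm)
    prop_var_explained: float
    sign_convention: str = "positive-mean-profile"


@dataclass
class ConnectivityProfile:
    region_id: str
    kIM: float
    kME: float
    MAR: float


def standardized_submatrix(
    matrix: CountMatrix, module_regions: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Subjects x regions z-scored counts; zero-variance regions dropped."""
    missing = [r for r in module_regions if r not in matrix.counts.index]
    if missing:
        raise KeyError(f"regions not in count matrix: {missing}")
    X = matrix.counts.loc[module_regions].to_numpy(dtype=float).T
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [r for r, k in zip(module_regions, keep) if not k]
        warnings.warn(f"dropping zero-variance module regions: {dropped}")
        X = X[:, keep]
        module_regions = [r for r, k in zip(module_regions, keep) if k]
    if X.shape[1] == 0:
        raise ValueError("no usable regions in module")
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return X, list(module_regions)


def module_expression(
    matrix: CountMatrix, module_regions: list[str], module_label: str = ""
) -> ModuleExpression:
    """Leading-SVD per-subject expression score of one module."""
    if len(module_regions) < 2:
        raise ValueError("module must have at least 2 regions")
    if matrix.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    X, _ = standardized_submatrix(matrix, module_regions)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, 0]
    if np.corrcoef(scores, X.mean(axis=1))[0, 1] < 0:
        scores = -scores
    pve = float(s[0] ** 2 / np.sum(s**2))
    return ModuleExpression(module_label, matrix.subject_ids, scores, pve)


def module_expression_tom(network: CoactivationNetwork, module_regions: list[str]) -> float:
    """Audit variant: leading singular value share of the module's TOM
    submatrix (a region-level quantity; yields no per-subject scores)."""
    idx = network.index_of(module_regions)
    s = np.linalg.svd(network.tom[np.ix_(idx, idx)], compute_uv=False)
    return float(s[0] ** 2 / np.sum(s**2))


def _kme(matrix: CountMatrix, regions: list[str], scores: np.ndarray) -> np.ndarray:
    X = matrix.counts.loc[regions].to_numpy(dtype=float)
    out = np.zeros(len(regions))
    for i in range(len(regions)):
        sd = X[i].std()
        out[i] = np.corrcoef(X[i], scores)[0, 1] if sd > 0 else 0.0
    return out


def mar(A_sub: np.ndarray) -> np.ndarray:
    """Maximum adjacency ratio per region within a module submatrix."""
    num = (A_sub**2).sum(axis=1)
    den = A_sub.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = 0.0
    return out


def connectivity_profile(
    network: CoactivationNetwork,
    matrix: CountMatrix,
    module_label: str,
    module_regions: list[str] | None = None,
) -> tuple[list[ConnectivityProfile], dict[str, float]]:
    """kIM, kME and MAR per module region, plus kME of every region in the
    network against this module's scores (kMEall) for preservation use."""
    regions = module_regions or network.module_regions(module_label)
    if len(regions) < 2:
        raise ValueError("singleton module rejected")
    idx = network.index_of(regions)
    A_sub = network.A[np.ix_(idx, idx)]
    kim = A_sub.sum(axis=1)
    expr = module_expression(matrix, regions, module_label)
    kme = _kme(matrix, regions, expr.subject_scores)
    mars = mar(A_sub)
    profiles = [
        ConnectivityProfile(r, float(kim[i]), float(kme[i]), float(mars[i]))
        for i, r in enumerate(regions)
    ]
    kme_all = _kme(matrix, network.region_ids, expr.subject_scores)
    return profiles, dict(zip(network.region_ids, (float(v) for v in kme_all)))


def rank_hubs(profiles: list[ConnectivityProfile]) -> list[tuple[str, float, float]]:
    """Regions by decreasing kIM (ties lexicographic); each entry carries
    (region, kIM, mean within-module edge weight kIM/(m-1))."""
    if not profiles:
        raise ValueError("empty profiles")
    m = len(profiles)
    ordered = sorted(profiles, key=lambda p: (-p.kIM, p.region_id))
    denom = max(m - 1, 1)
    return [(p.region_id, p.kIM, p.kIM / denom) for p in ordered]


def expression_contrast(
    expr: ModuleExpression, matrix: CountMatrix, field: str, level0: str, level1: str
) -> tuple[float, float]:
    """Rank-sum comparison of module expression between two subject groups.

    Returns (mean score difference level1 - level0, two-sided p). This is
    the module-expression group comparison (e.g. male vs female AGGs)."""
    pos = {s: i for i, s in enumerate(expr.subject_ids)}
    i0 = [pos[s] for s in matrix.subject_ids_where(field, level0) if s in pos]
    i1 = [pos[s] for s in matrix.subject_ids_where(field, level1) if s in pos]
    if len(i0) < 2 or len(i1) < 2:
        raise ValueError("need >= 2 subjects per group")
    s0, s1 = expr.subject_scores[i0], expr.subject_scores[i1]
    p = float(stats.mannwhitneyu(s0, s1, alternative="two-sided").pvalue)
    return float(s1.mean() - s0.mean()), p
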