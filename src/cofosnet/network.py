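"""Group-level c-Fos co-activation networks.

A network is built from one group's count matrix in four steps:

1. ``S``: inter-region Pearson correlation across subjects (s_ij);
2. soft thresholding with the power adjacency function a_ij = |s_ij|^beta,
   which suppresses weak (potentially spurious) correlations while keeping
   edge weights in [0, 1];
3. the topological overlap measure, which augments the direct connection
   between two regions with their shared neighbourhood:

       omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
       l_ij = sum_u a_iu a_uj,   k_i = sum_{j != i} a_ij;

4. average-linkage hierarchical clustering on the dissimilarity 1 - TOM
   with a static height cut, small clusters discarded to "unassigned".

Modules are named by decreasing size with conventional colour labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datasets import CountMatrix

UNASSIGNED = "unassigned"

# colour labels assigned by decreasing module size
MODULE_COLOURS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue",
)

DEFAULT_POWER = 4.0
DEFAULT_CUT_HEIGHT = 0.96
DEFAULT_MIN_MODULE_SIZE = 5


@dataclass
class CoactivationNetwork:
    """One group's network: correlation, adjacency, TOM and module labels."""

    region_ids: list[str]
    S: np.ndarray
    beta_power: float
    A: np.ndarray
    tom: np.ndarray
    modules: dict[str, str]

    @property
    def k(self) -> np.ndarray:
        """Per-region connectivity k_i = sum_{j != i} a_ij."""
        return self.A.sum(axis=1)

    def module_regions(self, label: str) -> list[str]:
        return [r for r in self.region_ids if self.modules[r] == label]

    def module_labels(self) -> list[str]:
        """Module labels ordered by decreasing size (unassigned excluded)."""
        sizes: dict[str, int] = {}
        for lab in self.modules.values():
            if lab != UNASSIGNED:
                sizes[lab] = sizes.get(lab, 0) + 1
        return sorted(sizes, key=lambda m: (-sizes[m], m))

    def index_of(self, regions: list[str]) -> np.ndarray:
        pos = {r: i for i, r in enumerate(self.region_ids)}
        return np.array([pos[r] for r in regions], dtype=int)


def correlation_matrix(
    matrix: CountMatrix,
    subjects_subset: list[str] | None = None,
    method: str = "pearson",
    zero_variance: str = "drop",
) -> tuple[np.ndarray, list[str]]:
    """Inter-region correlation across subjects.

    Returns ``(S, region_ids)``; zero-variance regions are dropped with a
    warning by default (``zero_variance='zero'`` keeps them with
    correlation 0 to every other region).
    """
    m = matrix if subjects_subset is None else matrix.subset_subjects(subjects_subset)
    if m.n_subjects < 3:
        raise ValueError("need at least 3 subjects for a correlation network")
    data = m.counts.to_numpy(dtype=float)
    regions = list(m.region_ids)
    sd = data.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [regions[i] for i in flat]
        if zero_variance == "drop":
            warnings.warn(f"dropping zero-variance regions: {names}")
            keep = np.flatnonzero(sd > 0)
            data, regions = data[keep], [regions[i] for i in keep]
        elif zero_variance == "zero":
            warnings.warn(f"zero-variance regions set to r=0: {names}")
        else:
            raise ValueError(f"unknown zero_variance policy {zero_variance!r}")
    if method == "spearman":
        data = stats.rankdata(data, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    with np.errstate(invalid="ignore"):
        S = np.corrcoef(data)
    S = np.nan_to_num(S, nan=0.0)
    np.fill_diagonal(S, 1.0)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S, regions


def scale_free_fit_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of binned degree frequency on degree."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() > 0:
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.mean()))
    if len(xs) < 3 or np.ptp(xs) == 0:
        return 0.0
    r = stats.pearsonr(xs, ys)[0]
    return float(r * r)


def pick_soft_power(
    S: np.ndarray,
    candidate_powers: list[float] | None = None,
    r2_threshold: float = 0.8,
    fallback: float = DEFAULT_POWER,
    signed_mode: str = "unsigned",
) -> float:
    """Smallest candidate power with scale-free fit R^2 over threshold.

    Falls back to ``fallback`` with a warning if no candidate qualifies
    (e.g. a network of independent noise has no scale-free structure).
    """
    if candidate_powers is None:
        candidate_powers = list(range(1, 13))
    if not candidate_powers:
        raise ValueError("candidate_powers must be non-empty")
    if any(b <= 0 for b in candidate_powers):
        raise ValueError("candidate powers must be positive")
    for b in sorted(candidate_powers):
        A = adjacency(S, b, signed_mode)
        if scale_free_fit_r2(A.sum(axis=1)) > r2_threshold:
            return float(b)
    warnings.warn(
        f"no candidate power reached scale-free R^2 > {r2_threshold}; "
        f"falling back to beta = {fallback}"
    )
    return float(fallback)


def adjacency(S: np.ndarray, beta_power: float, signed_mode: str = "unsigned") -> np.ndarray:
    """Power adjacency a_ij = |s_ij|^beta (unsigned) with zero diagonal.

    ``signed_mode='signed-hybrid'`` keeps a_ij = s_ij^beta for positive
    correlations and zeroes negative ones.
    """
    if beta_power <= 0:
        raise ValueError("beta_power must be positive")
    S = np.asarray(S, dtype=float)
    if signed_mode == "unsigned":
        A = np.abs(S) ** beta_power
    elif signed_mode == "signed-hybrid":
        A = np.where(S > 0, S, 0.0) ** beta_power
    else:
        raise ValueError(f"unknown signed_mode {signed_mode!r}")
    np.fill_diagonal(A, 0.0)
    return A


def topological_overlap(A: np.ndarray) -> np.ndarray:
    """TOM omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    Requires a symmetric adjacency with zero diagonal and entries in
    [0, 1]; with a zero diagonal the shared-neighbour sum l_ij = (A @ A)_ij
    automatically excludes u in {i, j}. The diagonal is set to 1.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if A.min() < 0 or A.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / denom
    tom[denom == 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def _rescue_unassigned(
    tom: np.ndarray,
    region_ids: list[str],
    labels: dict[str, str],
    affinity_fraction: float,
) -> dict[str, str]:
    """Assignment stage after the height cut: an unassigned region joins
    the module it has the highest mean TOM to, provided that affinity is at
    least ``affinity_fraction`` of the module's own mean internal TOM.

    Rescues branch members that fall off at the static cut (the role of
    the PAM stage in dynamic-hybrid tree cutting); the module-relative
    threshold keeps genuinely unconnected regions out regardless of the
    absolute TOM scale.
    """
    mods = sorted(set(labels.values()) - {UNASSIGNED})
    if not mods:
        return labels
    idx = {r: i for i, r in enumerate(region_ids)}
    members = {m: [idx[r] for r in region_ids if labels[r] == m] for m in mods}
    internal = {}
    for m in mods:
        sub = tom[np.ix_(members[m], members[m])]
        iu, ju = np.triu_indices(len(members[m]), k=1)
        internal[m] = sub[iu, ju].mean()
    out = dict(labels)
    for r in sorted(region_ids):
        if labels[r] != UNASSIGNED:
            continue
        affs = {m: tom[idx[r], members[m]].mean() for m in mods}
        best = min(mods, key=lambda m: (-affs[m], m))
        if affs[best] >= affinity_fraction * internal[best]:
            out[r] = best
    return out


def detect_modules(
    tom: np.ndarray,
    region_ids: list[str],
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    affinity_fraction: float | None = 0.5,
) -> dict[str, str]:
    """Average-linkage clustering of 1 - TOM with a height cut and an
    affinity-based assignment stage.

    Clusters smaller than ``min_module_size`` are discarded to
    ``unassigned``; surviving clusters are labelled by decreasing size with
    colour names, ties broken by lexicographically smallest member region.
    Unassigned regions are then rescued into the nearest module when their
    mean TOM to it reaches ``affinity_fraction`` of that module's internal
    mean TOM (pass ``None`` to disable the assignment stage).
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if len(region_ids) != n:
        raise ValueError("region_ids length mismatch")
    # lexicographic region order fixes all clustering ties
    order = np.argsort(np.asarray(region_ids, dtype=object))
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    d = 1.0 - tom[np.ix_(order, order)]
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    Z = linkage(squareform(d, checks=False), method="average")
    flat = fcluster(Z, t=cut_height, criterion="distance")
    flat = flat[inv]  # back to original region order

    groups: dict[int, list[str]] = {}
    for r, c in zip(region_ids, flat):
        groups.setdefault(int(c), []).append(r)
    kept = [sorted(m) for m in groups.values() if len(m) >= min_module_size]
    kept.sort(key=lambda m: (-len(m), m[0]))
    if len(kept) == 1 and len(kept[0]) == n:
        warnings.warn("all regions fell into a single module")
    modules = {r: UNASSIGNED for r in region_ids}
    for i, members in enumerate(kept):
        colour = MODULE_COLOURS[i] if i < len(MODULE_COLOURS) else f"module{i + 1}"
        for r in members:
            modules[r] = colour
    if affinity_fraction is not None:
        modules = _rescue_unassigned(tom, region_ids, modules, affinity_fraction)
    return modules


def build_network(
    matrix: CountMatrix,
    subjects_subset: list[str] | None = None,
    beta_power: float | None = None,
    candidate_powers: list[float] | None = None,
    signed_mode: str = "unsigned",
    correlation: str = "pearson",
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    modules: dict[str, str] | None = None,
) -> CoactivationNetwork:
    """Full construction for one subject group.

    With ``beta_power=None`` the power is chosen by scale-free fit over
    ``candidate_powers`` (falling back to the default). Passing ``modules``
    transfers an existing module assignment (reference-network labels) by
    region identity instead of re-clustering.
    """
    S, regions = correlation_matrix(matrix, subjects_subset, method=correlation)
    if beta_power is None:
        beta_power = pick_soft_power(S, candidate_powers, signed_mode=signed_mode)
    A = adjacency(S, beta_power, signed_mode)
    tom = topological_overlap(A)
    if modules is None:
        labels = detect_modules(tom, regions, min_module_size, cut_height)
    else:
        labels = {r: modules.get(r, UNASSIGNED) for r in regions}
    return CoactivationNetwork(regions, S, float(beta_power), A, tom, labels)


def modules_frame(network: CoactivationNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        {"region": network.region_ids,
         "module": [network.modules[r] for r in network.region_ids]}
    )


def edge_list(network: CoactivationNetwork, weight: str = "tom") -> pd.DataFrame:
    """Upper-triangle edge list for graph tooling."""
    W = network.tom if weight == "tom" else network.A
    iu, ju = np.triu_indices(len(network.region_ids), k=1)
    return pd.DataFrame(
        {
            "region_i": [network.region_ids[i] for i in iu],
            "region_j": [network.region_ids[j] for j in ju],
            "weight": W[iu, ju],
        }
    )
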