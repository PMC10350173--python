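"""Permutation-based module preservation between two networks.

A module detected in a reference network (e.g. the AGG network) is scored
in a test network (e.g. NON, or hM4Di vs mCherry) by connectivity bases

    cor.kIM     correlation over module regions of intramodular
                connectivity in reference vs test
    cor.kME     same for module membership (correlation with the module's
                SVD subject scores)
    cor.kMEall  kME of EVERY network region against this module, reference
                vs test
    cor.cor     correlation between the vectorized off-diagonal
                inter-region correlation submatrices
    cor.MAR     correlation of maximum-adjacency-ratio vectors

and density bases

    propVarExplained      variance share of the module's leading singular
                          pair computed in the TEST data with reference
                          membership
    meanSignAwareCorDat   mean over module pairs of sign(s_ref) * s_test
    meanAdj               mean off-diagonal test adjacency within module
    meanMAR               mean test MAR over module regions

Each base statistic b gives Z = (b_observed - mean(b_perm)) / sd(b_perm),
where the permutations shuffle module labels uniformly over the regions of
the test network with module sizes preserved (one joint shuffle per
permutation drives all modules and all statistics). These definitions
follow the established module-preservation literature the statistic names
come from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CountMatrix
from .network import CoactivationNetwork

CONNECTIVITY_STATS = ("cor.kIM", "cor.kME", "cor.kMEall", "cor.cor", "cor.MAR")
DENSITY_STATS = ("propVarExplained", "meanSignAwareCorDat", "meanAdj", "meanMAR")
ALL_STATS = CONNECTIVITY_STATS + DENSITY_STATS


@dataclass
class PreservationResult:
    module_label: str
    observed: dict[str, float]
    perm_mean: dict[str, float]
    perm_sd: dict[str, float]
    z: dict[str, float]
    draws: dict[str, np.ndarray]
    n_permutations: int
    seed: int
    degenerate: list[str] = field(default_factory=list)

    @property
    def connectivity_stats(self) -> dict[str, float]:
        return {f"Z.{s}": self.z[s] for s in CONNECTIVITY_STATS}

    @property
    def density_stats(self) -> dict[str, float]:
        return {f"Z.{s}": self.z[s] for s in DENSITY_STATS}

    def z_summary_median(self) -> float:
        """Median of all Z statistics (a summary convention, not a
        literature-mandated composite)."""
        vals = [v for v in self.z.values() if np.isfinite(v)]
        return float(np.median(vals)) if vals else np.nan


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Row z-scores (population sd); constant rows become zero rows."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


class _SideData:
    """Per-network cache: adjacency, correlations, standardized counts."""

    def __init__(self, network: CoactivationNetwork, matrix: CountMatrix):
        self.network = network
        self.regions = list(network.region_ids)
        counts = matrix.counts.loc[self.regions].to_numpy(dtype=float)
        self.Zc = _standardize_rows(counts)  # regions x subjects
        self.n_sub = counts.shape[1]
        self.A = network.A
        self.S = network.S

    def module_stats(self, idx: np.ndarray) -> dict[str, np.ndarray | float]:
        """kIM, kME, MAR, scores, PVE and correlation submatrix for the
        module at row positions ``idx`` (paired order preserved)."""
        A_sub = self.A[np.ix_(idx, idx)]
        kim = A_sub.sum(axis=1)
        num = (A_sub**2).sum(axis=1)
        den = A_sub.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mar = np.where(den > 0, num / den, 0.0)
        X = self.Zc[idx].T  # subjects x regions, standardized
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        scores = U[:, 0]
        profile = X.mean(axis=1)
        if profile.std() > 0 and np.corrcoef(scores, profile)[0, 1] < 0:
            scores = -scores
        pve = float(s[0] ** 2 / np.sum(s**2))
        zscores = (scores - scores.mean()) / scores.std()
        kme_all = self.Zc @ zscores / self.n_sub
        iu, ju = np.triu_indices(len(idx), k=1)
        s_vec = self.S[np.ix_(idx, idx)][iu, ju]
        return {
            "kIM": kim,
            "kME": kme_all[idx],
            "MAR": mar,
            "kMEall": kme_all,
            "pve": pve,
            "s_vec": s_vec,
        }


def _bases(ref: dict, test: dict) -> dict[str, float]:
    return {
        "cor.kIM": _safe_corr(ref["kIM"], test["kIM"]),
        "cor.kME": _safe_corr(ref["kME"], test["kME"]),
        "cor.kMEall": _safe_corr(ref["kMEall"], test["kMEall"]),
        "cor.cor": _safe_corr(ref["s_vec"], test["s_vec"]),
        "cor.MAR": _safe_corr(ref["MAR"], test["MAR"]),
        "propVarExplained": test["pve"],
        "meanSignAwareCorDat": float(np.mean(np.sign(ref["s_vec"]) * test["s_vec"])),
        "meanAdj": np.nan,  # needs the adjacency submatrix; filled by the caller
        "meanMAR": float(np.mean(test["MAR"])),
    }


def base_statistics(
    ref_net: CoactivationNetwork,
    ref_mat: CountMatrix,
    test_net: CoactivationNetwork,
    test_mat: CountMatrix,
    module_regions: list[str],
) -> dict[str, float]:
    """Observed (unpermuted) preservation bases for one module."""
    if len(module_regions) < 3:
        raise ValueError("module smaller than 3 regions")
    for r in module_regions:
        if r not in ref_net.modules or r not in test_net.modules:
            raise KeyError(f"module region {r!r} missing from a network")
    ref_side = _SideData(ref_net, ref_mat)
    test_side = _SideData(test_net, test_mat)
    ref_idx = ref_net.index_of(module_regions)
    test_idx = test_net.index_of(module_regions)
    out = _bases(ref_side.module_stats(ref_idx), test_side.module_stats(test_idx))
    A_sub = test_net.A[np.ix_(test_idx, test_idx)]
    iu, ju = np.triu_indices(len(test_idx), k=1)
    out["meanAdj"] = float(A_sub[iu, ju].mean())
    return out


def permutation_z(
    ref_net: CoactivationNetwork,
    ref_mat: CountMatrix,
    test_net: CoactivationNetwork,
    test_mat: CountMatrix,
    modules: list[str] | None = None,
    n_permutations: int = 200,
    seed: int = 0,
) -> list[PreservationResult]:
    """Preservation Z statistics for each module via label permutation.

    One uniform shuffle of the test network's regions per permutation
    drives all modules and all statistics jointly; module sizes are
    preserved. Degenerate permutation distributions (sd = 0) give a signed
    infinite Z and are listed in ``degenerate``.
    """
    if n_permutations < 2:
        raise ValueError("need at least 2 permutations")
    if modules is None:
        modules = ref_net.module_labels()
    if not modules:
        raise ValueError("no modules to score")
    common = [r for r in test_net.region_ids if r in set(ref_net.region_ids)]
    if len(common) != len(test_net.region_ids):
        raise ValueError("reference and test networks must share regions")

    rng = np.random.default_rng(seed)
    ref_side = _SideData(ref_net, ref_mat)
    test_side = _SideData(test_net, test_mat)
    n = len(test_net.region_ids)

    results = []
    module_members = {}
    ref_stats = {}
    for m in modules:
        members = ref_net.module_regions(m)
        if len(members) < 3:
            raise ValueError(f"module {m!r} smaller than 3 regions")
        module_members[m] = members
        ref_stats[m] = ref_side.module_stats(ref_net.index_of(members))

    def test_bases(m: str, idx: np.ndarray) -> dict[str, float]:
        t = test_side.module_stats(idx)
        out = _bases(ref_stats[m], t)
        A_sub = test_side.A[np.ix_(idx, idx)]
        iu, ju = np.triu_indices(len(idx), k=1)
        out["meanAdj"] = float(A_sub[iu, ju].mean())
        return out

    observed = {m: test_bases(m, test_net.index_of(module_members[m])) for m in modules}
    draws: dict[str, dict[str, list[float]]] = {m: {s: [] for s in ALL_STATS} for m in modules}
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        for m in modules:
            idx = perm[test_net.index_of(module_members[m])]
            b = test_bases(m, idx)
            for s in ALL_STATS:
                draws[m][s].append(b[s])

    for m in modules:
        perm_mean, perm_sd, zvals, degenerate, arr = {}, {}, {}, [], {}
        for s in ALL_STATS:
            d = np.asarray(draws[m][s])
            arr[s] = d
            mu, sd = float(d.mean()), float(d.std(ddof=1))
            perm_mean[s], perm_sd[s] = mu, sd
            if sd == 0:
                degenerate.append(s)
                diff = observed[m][s] - mu
                zvals[s] = float(np.sign(diff) * np.inf) if diff != 0 else np.nan
            else:
                zvals[s] = (observed[m][s] - mu) / sd
        results.append(
            PreservationResult(
                m, dict(observed[m]), perm_mean, perm_sd, zvals, arr,
                n_permutations, seed, degenerate,
            )
        )
    return results


def results_frame(results: list[PreservationResult]) -> pd.DataFrame:
    """Long-format export: module, statistic, observed, perm moments, Z."""
    rows = []
    for r in results:
        for s in ALL_STATS:
            rows.append(
                {
                    "module": r.module_label,
                    "statistic": f"Z.{s}",
                    "observed": r.observed[s],
                    "perm_mean": r.perm_mean[s],
                    "perm_sd": r.perm_sd[s],
                    "Z": r.z[s],
                    "n_perm": r.n_permutations,
                    "seed": r.seed,
                }
            )
    return pd.DataFrame(rows)


def compare_preservation(
    result_a: PreservationResult, result_b: PreservationResult
) -> pd.DataFrame:
    """Pair each named metric across two preservation runs.

    Returns per-metric Z values and their difference (a - b); the frame's
    attrs carry a paired Wilcoxon signed-rank p over the shared metrics.
    """
    if set(result_a.z) != set(result_b.z):
        raise ValueError("mismatched metric sets")
    names = sorted(result_a.z)
    za = np.array([result_a.z[s] for s in names])
    zb = np.array([result_b.z[s] for s in names])
    out = pd.DataFrame({"statistic": [f"Z.{s}" for s in names], "z_a": za, "z_b": zb,
                        "difference": za - zb})
    finite = np.isfinite(za) & np.isfinite(zb)
    if finite.sum() >= 2 and np.any((za - zb)[finite] != 0):
        out.attrs["p_paired"] = float(stats.wilcoxon(za[finite], zb[finite]).pvalue)
    else:
        out.attrs["p_paired"] = np.nan
    return out
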