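"""End-to-end orchestration of the network and photometry arms.

The network arm runs the complete count-side analysis on one dataset:
build the reference group's co-activation network and detect its modules,
transfer those module labels onto the test group's network, score module
expression and hub connectivity, run the permutation preservation test,
and screen every region with the negative-binomial contrast. The
photometry arm preprocesses each session, classifies behaviour bouts and
pools peri-event summaries.

All outputs are tab-delimited text stamped with the config hash and seed;
reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import modules as mod
from . import network as net
from . import photometry as phot
from .datasets import CountMatrix
from .preservation import permutation_z, results_frame
from .region_stats import run_region_screen, screen_to_frame

log = logging.getLogger("cofosnet")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """One run's complete configuration (YAML-serialisable)."""

    counts_path: str = ""
    subjects_path: str = ""
    output_dir: str = "results/run"
    # subject filters: metadata field -> level
    reference_group: dict[str, str] = field(default_factory=lambda: {"phenotype": "AGG"})
    test_group: dict[str, str] | None = field(default_factory=lambda: {"phenotype": "NON"})
    # network settings
    correlation: str = "pearson"
    signed_mode: str = "unsigned"
    beta_power: float | None = net.DEFAULT_POWER
    candidate_powers: list[float] | None = None
    cut_height: float = net.DEFAULT_CUT_HEIGHT
    min_module_size: int = net.DEFAULT_MIN_MODULE_SIZE
    # preservation
    n_permutations: int = 200
    # region screen: (field, level0, level1), optionally within a subset
    screen_contrast: tuple[str, str, str] | None = ("phenotype", "AGG", "NON")
    screen_filter: dict[str, str] | None = None
    # expression contrast within the reference network, e.g. male vs female
    expression_contrast: tuple[str, str, str] | None = ("sex", "female", "male")
    # photometry
    photometry_sessions: list[dict] = field(default_factory=list)
    peri_window_s: tuple[float, float] = (4.0, 4.0)
    bout_gap_s: float = 2.0
    zscore_scope: str = "session"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("screen_contrast", "expression_contrast"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        if raw.get("peri_window_s") is not None:
            raw["peri_window_s"] = tuple(raw["peri_window_s"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("screen_contrast", "expression_contrast", "peri_window_s"):
            if d.get(key) is not None:
                d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _group_ids(matrix: CountMatrix, flt: dict[str, str]) -> list[str]:
    ids = matrix.subject_ids
    for f, level in flt.items():
        keep = set(matrix.subject_ids_where(f, level))
        ids = [s for s in ids if s in keep]
    return ids


def run_network_arm(config: PipelineConfig, matrix: CountMatrix | None = None) -> dict:
    """Run the whole network arm; returns the artefact bundle in memory
    and writes every table under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if matrix is None:
        matrix = CountMatrix.from_files(config.counts_path, config.subjects_path)

    ref_ids = _group_ids(matrix, config.reference_group)
    log.info("reference group: %d subjects", len(ref_ids))
    ref_mat = matrix.subset_subjects(ref_ids)
    ref_net = net.build_network(
        ref_mat,
        beta_power=config.beta_power,
        candidate_powers=config.candidate_powers,
        signed_mode=config.signed_mode,
        correlation=config.correlation,
        min_module_size=config.min_module_size,
        cut_height=config.cut_height,
    )
    _write(net.modules_frame(ref_net), out / "modules.tsv")
    pd.DataFrame(ref_net.S, index=ref_net.region_ids, columns=ref_net.region_ids).to_csv(
        out / "reference_correlation.tsv", sep="\t", float_format=_FLOAT_FMT
    )
    pd.DataFrame(ref_net.tom, index=ref_net.region_ids, columns=ref_net.region_ids).to_csv(
        out / "reference_tom.tsv", sep="\t", float_format=_FLOAT_FMT
    )

    bundle: dict = {"reference_network": ref_net, "matrix": matrix}

    # module expression (all subjects, reference module definitions)
    expr_rows, contrast_rows = [], []
    for label in ref_net.module_labels():
        regions = ref_net.module_regions(label)
        if len(regions) < 2:
            continue
        expr = mod.module_expression(matrix, regions, label)
        for s, v in zip(expr.subject_ids, expr.subject_scores):
            expr_rows.append({"subject": s, "module": label, "score": v})
        if config.expression_contrast is not None:
            f, l0, l1 = config.expression_contrast
            try:
                diff, p = mod.expression_contrast(expr, matrix, f, l0, l1)
                contrast_rows.append(
                    {"module": label, "contrast": f"{f}:{l1}-{l0}", "mean_diff": diff, "p": p}
                )
            except ValueError as e:
                log.warning("expression contrast skipped for %s: %s", label, e)
    _write(pd.DataFrame(expr_rows), out / "module_expression.tsv")
    if contrast_rows:
        _write(pd.DataFrame(contrast_rows), out / "expression_contrast.tsv")
    bundle["expression"] = expr_rows

    # connectivity / hub ranking per module (reference network + data)
    conn_rows = []
    for label in ref_net.module_labels():
        regions = ref_net.module_regions(label)
        if len(regions) < 2:
            continue
        profiles, _ = mod.connectivity_profile(ref_net, ref_mat, label, regions)
        for rank, (region, kim, mean_w) in enumerate(mod.rank_hubs(profiles), start=1):
            prof = next(p for p in profiles if p.region_id == region)
            conn_rows.append(
                {
                    "module": label, "region": region, "rank": rank, "kIM": kim,
                    "mean_edge_weight": mean_w, "kME": prof.kME, "MAR": prof.MAR,
                }
            )
    _write(pd.DataFrame(conn_rows), out / "connectivity.tsv")
    bundle["connectivity"] = conn_rows

    # test network + preservation
    if config.test_group is not None:
        test_ids = _group_ids(matrix, config.test_group)
        log.info("test group: %d subjects", len(test_ids))
        test_mat = matrix.subset_subjects(test_ids)
        test_net = net.build_network(
            test_mat,
            beta_power=ref_net.beta_power,
            signed_mode=config.signed_mode,
            correlation=config.correlation,
            modules=ref_net.modules,  # transfer reference labels
        )
        scoreable = [
            m for m in ref_net.module_labels() if len(ref_net.module_regions(m)) >= 3
        ]
        pres = permutation_z(
            ref_net, ref_mat, test_net, test_mat,
            modules=scoreable, n_permutations=config.n_permutations, seed=config.seed,
        )
        _write(results_frame(pres), out / "preservation.tsv")
        bundle["test_network"] = test_net
        bundle["preservation"] = pres
    else:
        log.info("no test group configured; preservation skipped")

    # region screen
    if config.screen_contrast is not None:
        screen_mat = matrix
        if config.screen_filter:
            screen_mat = matrix.subset_subjects(_group_ids(matrix, config.screen_filter))
        screen = run_region_screen(screen_mat, config.screen_contrast)
        _write(screen_to_frame(screen), out / "region_screen.tsv")
        bundle["screen"] = screen

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "beta_power": ref_net.beta_power,
        "n_regions": len(ref_net.region_ids),
        "modules": {m: len(ref_net.module_regions(m)) for m in ref_net.module_labels()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    bundle["manifest"] = manifest
    return bundle


def run_photometry_arm(
    config: PipelineConfig, sessions: list[phot.PhotometrySession] | None = None
) -> dict:
    """Preprocess, classify and summarise every photometry session."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sessions is None:
        sessions = []
        for entry in config.photometry_sessions:
            try:
                sessions.append(
                    phot.PhotometrySession.from_files(
                        entry["trace"], entry["events"],
                        rate_hz=float(entry.get("rate_hz", 40.0)),
                        baseline_window_s=tuple(entry.get("baseline_window_s", (0.0, 120.0))),
                    )
                )
            except Exception as e:  # unreadable session: skip, keep going
                log.error("skipping session %s: %s", entry, e)
    if not sessions:
        raise RuntimeError("no readable photometry sessions")

    trial_rows, class_diffs = [], {}
    for si, session in enumerate(sessions):
        trace = phot.preprocess(session, zscore_scope=config.zscore_scope)
        labelled, day = phot.classify_bouts(session.events, gap_s=config.bout_gap_s)
        sets = phot.peri_event(trace, session.rate_hz, labelled, config.peri_window_s)
        summaries, _ = phot.pre_post_stats(sets)
        for cls, summ in summaries.items():
            class_diffs.setdefault(cls, []).extend(summ.differences.tolist())
            for t, (pre, post) in enumerate(zip(summ.pre_means, summ.post_means)):
                trial_rows.append(
                    {
                        "session": si, "day_type": day, "bout_class": cls, "trial": t,
                        "pre_mean": pre, "post_mean": post, "difference": post - pre,
                    }
                )
    _write(pd.DataFrame(trial_rows), out / "photometry_trials.tsv")

    pooled_rows = []
    names = sorted(class_diffs)
    for cls in names:
        d = np.asarray(class_diffs[cls])
        pooled_rows.append(
            {"bout_class": cls, "n_trials": len(d), "mean_post_minus_pre": d.mean()}
        )
    _write(pd.DataFrame(pooled_rows), out / "photometry_classes.tsv")
    return {"trials": trial_rows, "pooled": pooled_rows, "class_diffs": class_diffs}
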