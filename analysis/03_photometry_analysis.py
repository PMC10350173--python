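#!/usr/bin/env python
"""Peri-event analysis of the photometry sessions.

Preprocesses each session (control subtraction, dF/F against the final
baseline minute, session z-score), classifies investigation and attack
bouts by the attack-transition taxonomy, pools per-class post-minus-pre
activity under results/photometry/, and prints the pooled class means.
"""

from pathlib import Path

import numpy as np

from cofosnet.pipeline import PipelineConfig, run_photometry_arm

SEED = 20260928
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "data"
    cfg = PipelineConfig(
        output_dir=str(ROOT / "photometry"),
        photometry_sessions=[
            {"trace": str(data / "attack_day_trace.tsv"),
             "events": str(data / "attack_day_events.tsv")},
            {"trace": str(data / "no_attack_day_trace.tsv"),
             "events": str(data / "no_attack_day_events.tsv")},
        ],
        peri_window_s=(4.0, 4.0),
        bout_gap_s=2.0,
        seed=SEED,
    )
    out = run_photometry_arm(cfg)
    print("pooled post-minus-pre z-scored dF/F by bout class:")
    for row in out["pooled"]:
        print(
            f"  {row['bout_class']}: mean diff = {row['mean_post_minus_pre']:+.3f} "
            f"({row['n_trials']} trials)"
        )
    pre = np.array(out["class_diffs"].get("investigation_preceding_attack", []))
    iso = np.array(out["class_diffs"].get("investigation_isolated", []))
    if len(pre) and len(iso):
        from scipy import stats

        p = stats.mannwhitneyu(pre, iso, alternative="two-sided").pvalue
        print(f"preceding-attack vs isolated investigation: p = {p:.2e}")


if __name__ == "__main__":
    main()
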