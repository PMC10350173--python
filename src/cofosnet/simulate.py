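"""Synthetic cohorts and photometry sessions for end-to-end verification.

Real inputs to this pipeline are whole-brain c-Fos counts from cleared,
light-sheet-imaged brains and two-channel fibre-photometry recordings.
Neither is needed to exercise the analysis code: this module plants known
structure (correlated modules, group effects, event-locked calcium
transients) so every downstream stage can be checked against ground truth.

Counts are drawn through a Gaussian copula: a latent multivariate normal
with a one-factor block per module (equicorrelation ``rho`` within the
module, zero elsewhere) is pushed through the standard-normal CDF and
mapped to negative-binomial quantiles, giving correlated overdispersed
counts whose marginals follow variance = mu + mu^2 / dispersion — the same
model the region-wise regression assumes. Group effects multiply the NB
mean of member regions. A module may carry a designated hub region whose
factor loading is multiplied, making it more strongly correlated with every
other member.

Photometry sessions are two channels sampled at a fixed rate: a calcium
signal (470 nm) and a calcium-independent control (415 nm), both riding a
shared exponentially bleaching baseline. The signal channel additionally
carries a constant fluorescence offset (GCaMP baseline brightness above
autofluorescence) and double-exponential transients locked to event onsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CountMatrix
from .photometry import PhotometrySession


# ---------------------------------------------------------------------------
# count cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One experimental group (phenotype x sex, optional virus group)."""

    phenotype: str
    sex: str
    virus_group: str = "none"

    @property
    def label(self) -> str:
        return f"{self.phenotype}:{self.sex}"


@dataclass(frozen=True)
class ModuleSpec:
    """A planted module: ``region_count`` regions with latent
    equicorrelation ``within_correlation`` (one-factor structure).

    ``hub_loading_multiplier`` > 1 scales the factor loading of the first
    member region (capped below 1), planting a hub that is more strongly
    correlated with every other member.

    ``loading_spread`` in [0, 1) grades the member correlations linearly
    from ``within_correlation * (1 + spread)`` (first region) down to
    ``within_correlation * (1 - spread)`` (last region, capped at 0.95),
    emulating the hub-to-periphery connectivity gradient of real modules;
    0 gives exchangeable equicorrelation.
    """

    label: str
    region_count: int
    within_correlation: float
    hub_loading_multiplier: float = 1.0
    loading_spread: float = 0.0


DEFAULT_GROUPS = (
    GroupSpec("AGG", "male"),
    GroupSpec("AGG", "female"),
    GroupSpec("NON", "male"),
    GroupSpec("NON", "female"),
)

# Defaults emulate a typical aggression-mapping cohort: ~12
# residents per phenotype x sex cell, a dominant 28-region module (the
# "pink" amygdalo-hypothalamic cluster) elevated in male aggressors, two
# smaller modules, and background regions with no planted correlation.
DEFAULT_MODULES = (
    ModuleSpec("pink", 28, 0.6),
    ModuleSpec("blue", 15, 0.5),
    ModuleSpec("brown", 10, 0.5),
)
DEFAULT_GROUP_MODULE_EFFECTS = {("AGG:male", "pink"): 1.5}


@dataclass
class CountSimConfig:
    """Configuration for :func:`simulate_counts`.

    ``nb_mean`` is the baseline expected c-Fos count per region (hundreds of
    cells for a mid-sized region); ``nb_dispersion`` is the NB size
    parameter, variance = mu + mu^2/dispersion.
    """

    n_regions: int = 100
    n_subjects_per_group: int = 12
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    module_spec: tuple[ModuleSpec, ...] = DEFAULT_MODULES
    group_module_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MODULE_EFFECTS)
    )
    nb_mean: float = 500.0
    nb_dispersion: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions <= 0 or self.n_subjects_per_group <= 0:
            raise ValueError("n_regions and n_subjects_per_group must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.nb_mean <= 0:
            raise ValueError("nb_mean must be positive")
        labels = [m.label for m in self.module_spec]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate module labels in module_spec")
        if sum(m.region_count for m in self.module_spec) > self.n_regions:
            raise ValueError("module region counts exceed n_regions")
        for m in self.module_spec:
            if not 0.0 <= m.within_correlation < 1.0:
                raise ValueError("within_module_correlation must be in [0, 1)")
            if not 0.0 <= m.loading_spread < 1.0:
                raise ValueError("loading_spread must be in [0, 1)")
        for (glabel, mlabel), eff in self.group_module_effects.items():
            if eff <= 0:
                raise ValueError("group_module_effects must be positive multipliers")
            if mlabel not in labels:
                raise ValueError(f"effect references unknown module {mlabel!r}")
            if glabel not in {g.label for g in self.groups}:
                raise ValueError(f"effect references unknown group {glabel!r}")


def _region_names(config: CountSimConfig) -> tuple[list[str], dict[str, str]]:
    """Synthetic region acronyms and their planted module membership."""
    names: list[str] = []
    membership: dict[str, str] = {}
    for m in config.module_spec:
        for i in range(m.region_count):
            name = f"{m.label.upper()}{i + 1:02d}"
            names.append(name)
            membership[name] = m.label
    n_bg = config.n_regions - len(names)
    for i in range(n_bg):
        name = f"BG{i + 1:03d}"
        names.append(name)
        membership[name] = "background"
    return names, membership


def simulate_counts(config: CountSimConfig) -> CountMatrix:
    """Draw a region x subject count matrix with planted structure.

    Returns a :class:`CountMatrix`; the planted module membership is
    recoverable from :func:`planted_modules` on the same config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names, membership = _region_names(config)
    n_sub = config.n_subjects_per_group * len(config.groups)

    # latent MVN draws, one-factor block per module
    z = rng.standard_normal((config.n_regions, n_sub))
    row = 0
    for m in config.module_spec:
        rhos = np.clip(
            np.linspace(
                m.within_correlation * (1 + m.loading_spread),
                m.within_correlation * (1 - m.loading_spread),
                m.region_count,
            ),
            0.0,
            0.95,
        )
        lam = np.sqrt(rhos)
        if m.hub_loading_multiplier != 1.0 and m.region_count > 0:
            lam[0] = min(lam[0] * m.hub_loading_multiplier, 0.999)
        f = rng.standard_normal(n_sub)
        block = lam[:, None] * f[None, :] + np.sqrt(1 - lam**2)[:, None] * z[
            row : row + m.region_count
        ]
        z[row : row + m.region_count] = block
        row += m.region_count

    # per-cell NB mean with group effects
    mu = np.full((config.n_regions, n_sub), config.nb_mean)
    subj_rows = []
    for gi, g in enumerate(config.groups):
        cols = slice(gi * config.n_subjects_per_group, (gi + 1) * config.n_subjects_per_group)
        for ri, name in enumerate(names):
            eff = config.group_module_effects.get((g.label, membership[name]))
            if eff is not None:
                mu[ri, cols] *= eff
        for j in range(config.n_subjects_per_group):
            subj_rows.append(
                {
                    "subject_id": f"{g.phenotype}-{g.sex}-{j + 1:02d}",
                    "phenotype": g.phenotype,
                    "sex": g.sex,
                    "virus_group": g.virus_group,
                }
            )

    # copula: latent normal -> uniform -> NB quantile
    u = np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12)
    r = config.nb_dispersion
    p = r / (r + mu)
    counts = stats.nbinom.ppf(u, r, p).astype(np.int64)

    subjects = pd.DataFrame(subj_rows)
    frame = pd.DataFrame(counts, index=names, columns=subjects["subject_id"])
    frame.columns.name = None
    return CountMatrix(frame, subjects)


def planted_modules(config: CountSimConfig) -> dict[str, str]:
    """Ground-truth region -> module map for a config ("background" for
    regions with no planted correlation)."""
    return _region_names(config)[1]


# ---------------------------------------------------------------------------
# photometry sessions
# ---------------------------------------------------------------------------

@dataclass
class PhotomSimConfig:
    """Configuration for :func:`simulate_photometry`.

    ``baseline_drift`` is the exponential bleach time-constant in seconds
    (<= 0 disables bleaching). ``signal_offset`` is the constant extra
    fluorescence of the signal channel over the control; the
    control-subtracted baseline equals this offset, so it must be positive
    for a well-defined dF/F downstream (0 makes the two channels identical
    up to transients and noise). ``transient_amplitude`` is in dF/F units
    relative to that offset. Events before ``baseline_s`` are rejected: the
    session starts with an event-free baseline period, as in a
    resident-intruder recording that begins before the intruder enters.
    """

    duration_s: float = 420.0
    rate_hz: float = 40.0
    baseline_drift: float = 600.0
    baseline_level: float = 100.0
    signal_offset: float = 25.0
    transient_amplitude: float = 2.0
    transient_tau_rise_s: float = 0.2
    transient_tau_decay_s: float = 1.5
    event_times_s: tuple[float, ...] = ()
    event_labels: tuple[str, ...] | None = None
    event_durations_s: tuple[float, ...] | None = None
    transient_times_s: tuple[float, ...] | None = None
    noise_sd: float = 0.5
    baseline_s: float = 120.0
    seed: int = 0

    def validate(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.transient_tau_rise_s <= 0 or self.transient_tau_decay_s <= 0:
            raise ValueError("transient time constants must be positive")
        if self.transient_tau_rise_s >= self.transient_tau_decay_s:
            raise ValueError("tau_rise must be smaller than tau_decay")
        for t in self.event_times_s:
            if not 0 <= t < self.duration_s:
                raise ValueError("event times must lie within [0, duration)")
        if self.event_labels is not None and len(self.event_labels) != len(
            self.event_times_s
        ):
            raise ValueError("event_labels length mismatch")
        if self.event_durations_s is not None and len(self.event_durations_s) != len(
            self.event_times_s
        ):
            raise ValueError("event_durations_s length mismatch")


def transient_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials calcium transient, peak-normalised to 1."""
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t >= 0
    h[pos] = np.exp(-t[pos] / tau_decay) - np.exp(-t[pos] / tau_rise)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    return h / peak


def simulate_photometry(config: PhotomSimConfig) -> PhotometrySession:
    """Generate a two-channel session with event-locked transients.

    signal  = baseline * bleach + offset * bleach + transients + noise
    control = baseline * bleach + independent noise

    Transient absolute height is ``transient_amplitude * signal_offset``
    (so the planted dF/F equals ``transient_amplitude``); when the offset
    is zero it falls back to ``transient_amplitude * baseline_level`` so
    timing checks remain possible.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.rate_hz))
    t = np.arange(n) / config.rate_hz

    if config.baseline_drift > 0:
        bleach = np.exp(-t / config.baseline_drift)
    else:
        bleach = np.ones_like(t)

    scale = config.signal_offset if config.signal_offset > 0 else config.baseline_level
    height = config.transient_amplitude * scale
    onsets = (
        config.transient_times_s
        if config.transient_times_s is not None
        else config.event_times_s
    )
    transients = np.zeros_like(t)
    for t0 in onsets:
        transients += height * transient_kernel(
            t - t0, config.transient_tau_rise_s, config.transient_tau_decay_s
        )

    base = config.baseline_level * bleach
    signal = (
        base
        + config.signal_offset * bleach
        + transients
        + config.noise_sd * rng.standard_normal(n)
    )
    control = base + config.noise_sd * rng.standard_normal(n)

    labels = config.event_labels or tuple("event" for _ in config.event_times_s)
    durs = config.event_durations_s or tuple(1.0 for _ in config.event_times_s)
    events = pd.DataFrame(
        {
            "label": list(labels),
            "start_s": list(config.event_times_s),
            "stop_s": [s + d for s, d in zip(config.event_times_s, durs)],
        }
    )
    return PhotometrySession(
        time_s=t,
        signal=signal,
        control=control,
        rate_hz=config.rate_hz,
        baseline_window_s=(0.0, config.baseline_s),
        events=events,
    )
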