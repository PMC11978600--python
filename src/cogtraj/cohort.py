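"""Synthetic longitudinal cohort generator.

Emulates a three-wave male birth-cohort study of cognitive aging: 582 unique
participants observed at ages 57-68 over one to three visits, a 77-score
neuropsychological battery driven by four latent trajectory archetypes,
35 ICV-corrected regional brain volumes, 64-channel 2 kHz EEG with steady-state
visual evoked responses at 8 and 36 Hz, and per-participant lifestyle/familial
risk factors with archetype-dependent distributions.

Every generator is a pure function of its configuration and seed: the same
``CohortConfig`` always yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArchetypeSpec",
    "CohortConfig",
    "Participant",
    "EEGRecording",
    "SyntheticCohort",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_RISK_TABLE",
    "default_score_names",
    "direction_flags",
    "generate_cohort",
    "generate_cognitive_scores",
    "generate_mri",
    "generate_eeg_signals",
    "generate_risk_factors",
    "apply_missingness",
    "MRI_REGIONS",
]

ARCHETYPE_NAMES = ("low_stable", "high_upper", "low_declining", "high_lower")

# Seed-stream indices: each generator draws from its own spawned stream so that
# e.g. regenerating MRI does not perturb the cognitive scores.
_STREAMS = {
    "archetype": 0,
    "ages": 1,
    "loadings": 2,
    "cognitive": 3,
    "mri": 4,
    "eeg": 5,
    "risk": 6,
    "missing": 7,
    "latent": 8,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))
    )


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass(frozen=True)
class ArchetypeSpec:
    """One latent trajectory class: cognition = baseline + slope * (age - 57).

    Levels and slopes are on the latent z-scale (cohort-SD units); the four
    archetypes encode low/high performers with stable or declining courses.
    """

    name: str
    baseline_level: float
    slope_per_year: float
    mixing_weight: float


def _validate_archetypes(specs: Sequence[ArchetypeSpec]) -> None:
    names = [s.name for s in specs]
    if sorted(names) != sorted(ARCHETYPE_NAMES):
        raise ConfigurationError(f"archetype names must be {ARCHETYPE_NAMES}, got {names}")
    total = sum(s.mixing_weight for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"mixing weights sum to {total!r}, not 1")
    by = {s.name: s for s in specs}
    low_max = max(by["low_stable"].baseline_level, by["low_declining"].baseline_level)
    high_min = min(by["high_upper"].baseline_level, by["high_lower"].baseline_level)
    if not low_max < high_min:
        raise ConfigurationError("low_* baseline levels must lie strictly below high_*")
    slopes = {s.name: s.slope_per_year for s in specs}
    if min(slopes, key=slopes.get) != "low_declining":
        raise ConfigurationError("low_declining must have the most negative slope")


# Group sizes 69 / 256 / 65 / 136 (of 526 analyzed participants) set the
# default mixing weights. Levels are equally spaced and the declining slope is
# kept below the between-level gap so that (a) the level band each archetype
# sweeps over ages 57-68 stays disjoint from its neighbours — most of the
# cohort has a single visit, so recoverability must come from level
# separation — and (b) within-group scatter stays below the between-group
# separation, the regime in which Davies-Bouldin minimization resolves all
# four groups rather than the high/low super-groups.
DEFAULT_ARCHETYPES = (
    ArchetypeSpec("low_stable", -4.5, 0.0, 69 / 526),
    ArchetypeSpec("high_upper", 4.5, 0.0, 256 / 526),
    ArchetypeSpec("low_declining", -1.5, -0.06, 65 / 526),
    ArchetypeSpec("high_lower", 1.5, -0.02, 136 / 526),
)


@dataclass(frozen=True)
class CohortConfig:
    """Structural and noise parameters of the synthetic study."""

    n_participants: int = 582
    wave_sizes: tuple[int, int, int] = (211, 503, 113)
    # (wave2 members seen in wave1, wave3 members seen in waves 1+2,
    #  wave3 members seen in wave1 only)
    wave_overlaps: tuple[int, int, int] = (136, 99, 10)
    age_range: tuple[float, float] = (57.0, 68.0)
    wave_age_windows: tuple[tuple[float, float], ...] = (
        (57.0, 59.0),
        (61.0, 67.0),
        (66.0, 68.0),
    )
    n_cognitive_scores: int = 77
    n_mri_regions: int = 35
    n_eeg_channels: int = 64
    eeg_sampling_hz: float = 2000.0
    stim_freqs_hz: Mapping[str, float] = field(
        default_factory=lambda: {"alpha": 8.0, "gamma": 36.0}
    )
    loading_matrix_rank: int = 10
    noise_sd: float = 0.25
    nuisance_scale: float = 0.12
    intercept_sd: float = 0.15
    mri_missing_rate: float = 0.5
    eeg_missing_rate: float = 0.35
    archetypes: tuple[ArchetypeSpec, ...] = DEFAULT_ARCHETYPES
    seed: int = 0

    def validate(self) -> None:
        w1, w2, w3 = self.wave_sizes
        o21, o312, o31 = self.wave_overlaps
        if o21 > w2 or o21 > w1:
            raise ConfigurationError(
                f"wave-2 overlap {o21} exceeds wave sizes {w1}/{w2}"
            )
        if o312 > o21:
            raise ConfigurationError(
                f"wave-3 overlap with waves 1+2 ({o312}) exceeds the {o21} "
                "participants present in both waves 1 and 2"
            )
        if o31 > w1 - o21:
            raise ConfigurationError(
                f"wave-3 overlap with wave-1-only ({o31}) exceeds the "
                f"{w1 - o21} wave-1-only participants"
            )
        if o312 + o31 > w3:
            raise ConfigurationError("wave-3 overlaps exceed wave-3 size")
        unique = w1 + (w2 - o21) + (w3 - o312 - o31)
        if unique != self.n_participants:
            raise ConfigurationError(
                f"wave sizes {self.wave_sizes} with overlaps {self.wave_overlaps} "
                f"imply {w1} + ({w2} - {o21}) + ({w3} - {o312} - {o31}) = {unique} "
                f"unique participants, but n_participants = {self.n_participants}"
            )
        nyquist = self.eeg_sampling_hz / 2.0
        for band, f in self.stim_freqs_hz.items():
            if f >= nyquist:
                raise ConfigurationError(
                    f"stimulation frequency {band}={f} Hz is not below the "
                    f"Nyquist frequency {nyquist} Hz"
                )
        if not 0 < self.loading_matrix_rank <= self.n_cognitive_scores:
            raise ConfigurationError("loading_matrix_rank out of range")
        _validate_archetypes(self.archetypes)


@dataclass(frozen=True)
class Participant:
    id: str
    archetype: str
    wave_membership: tuple[int, ...]
    visit_ages: tuple[float, ...]


@dataclass(frozen=True)
class EEGRecording:
    participant_id: str
    visit_index: int
    sampling_rate: float
    channel_names: tuple[str, ...]
    samples: np.ndarray  # (n_channels, n_samples), microvolts


@dataclass
class SyntheticCohort:
    """Bundle of all generated modalities plus the ground-truth labels."""

    config: CohortConfig
    participants: list[Participant]
    cognitive: pd.DataFrame
    mri: pd.DataFrame
    icv: pd.Series  # per-participant intracranial volume, mm^3
    risk_factors: pd.DataFrame
    truth: pd.Series  # participant_id -> archetype name

    def eeg_signals(self, snr: float = 1.0, duration_s: float = 8.0) -> Iterator[EEGRecording]:
        """Lazily regenerate the per-visit EEG recordings (deterministic)."""
        return generate_eeg_signals(self, snr=snr, duration_s=duration_s)

    @property
    def visit_table(self) -> pd.DataFrame:
        rows = [
            (p.id, v + 1, age, p.archetype)
            for p in self.participants
            for v, age in enumerate(p.visit_ages)
        ]
        return pd.DataFrame(rows, columns=["participant_id", "visit_index", "age", "archetype"])


# ---------------------------------------------------------------------------
# cohort structure


def _membership_groups(config: CohortConfig) -> list[tuple[int, ...]]:
    """Expand wave sizes/overlaps into per-participant wave-membership sets."""
    w1, w2, w3 = config.wave_sizes
    o21, o312, o31 = config.wave_overlaps
    groups: list[tuple[int, ...]] = []
    groups += [(1, 2, 3)] * o312
    groups += [(1, 2)] * (o21 - o312)
    groups += [(1, 3)] * o31
    groups += [(1,)] * (w1 - o21 - o31)
    groups += [(2,)] * (w2 - o21)
    groups += [(3,)] * (w3 - o312 - o31)
    return groups


def _latent_value(spec: ArchetypeSpec, age: float, intercept: float,
                  age_origin: float = 57.0) -> float:
    return spec.baseline_level + spec.slope_per_year * (age - age_origin) + intercept


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort (structure, all modalities, truth)."""
    config = config or CohortConfig()
    config.validate()

    groups = _membership_groups(config)
    n = len(groups)
    width = len(str(n))

    rng_arch = _rng(config.seed, "archetype")
    weights = np.array([s.mixing_weight for s in config.archetypes])
    arch_idx = rng_arch.choice(len(config.archetypes), size=n, p=weights)

    rng_ages = _rng(config.seed, "ages")
    participants: list[Participant] = []
    for i, waves in enumerate(groups):
        ages: list[float] = []
        prev = -math.inf
        for w in waves:
            lo, hi = config.wave_age_windows[w - 1]
            lo = max(lo, prev + 0.25)  # keep visit ages strictly increasing
            lo = min(lo, hi - 1e-3)
            ages.append(float(rng_ages.uniform(lo, hi)))
            prev = ages[-1]
        participants.append(
            Participant(
                id=f"P{i + 1:0{width}d}",
                archetype=config.archetypes[arch_idx[i]].name,
                wave_membership=waves,
                visit_ages=tuple(ages),
            )
        )

    partial = _Partial(config, participants)
    cognitive = generate_cognitive_scores(partial)
    mri, icv = generate_mri(partial)
    risk = generate_risk_factors(partial)
    truth = pd.Series(
        {p.id: p.archetype for p in participants}, name="archetype"
    ).rename_axis("participant_id")
    return SyntheticCohort(
        config=config,
        participants=participants,
        cognitive=cognitive,
        mri=mri,
        icv=icv,
        risk_factors=risk,
        truth=truth,
    )


@dataclass
class _Partial:
    """Minimal cohort view (config + participants) the per-modality generators need."""

    config: CohortConfig
    participants: list[Participant]


# ---------------------------------------------------------------------------
# cognitive scores


_CANTAB_METRICS = {
    "PAL": ["total_errors*", "errors_6shapes*", "first_trial_memory", "stages_completed",
            "mean_trials*", "memory_score"],
    "RVP": ["A_prime", "hits", "correct_rejections", "misses*", "false_alarms*",
            "latency*", "probability_hit"],
    "SOC": ["problems_solved", "mean_moves*", "initial_thinking_time*",
            "subsequent_thinking_time*", "perfect_solutions"],
    "RTI": ["simple_reaction_time*", "choice_reaction_time*", "simple_movement_time*",
            "choice_movement_time*", "errors*"],
    "PRM": ["percent_correct", "correct_latency*", "number_correct"],
    "SRM": ["percent_correct", "correct_latency*", "number_correct"],
    "MOT": ["mean_latency*", "mean_error*"],
}


def _raw_score_names(n: int) -> list[str]:
    names: list[str] = []
    general = ["MMSE_total", "ACE_total", "SDMT_correct", "TMT_A_time*", "TMT_B_time*",
               "word_pairs_recall", "word_pairs_retention"]
    names.extend(general)
    for test, metrics in _CANTAB_METRICS.items():
        for m in metrics:
            names.append(f"{test}_{m}")
    k = 1
    while len(names) < n:
        names.append(f"aux_score_{k:02d}")
        k += 1
    return names[:n]


def default_score_names(n: int = 77) -> list[str]:
    """Battery-flavoured variable names; a trailing ``*`` in the internal
    metric list marks latency/error scores where higher values mean worse
    performance — it is stripped here and recorded by :func:`direction_flags`.
    """
    return [name.rstrip("*") for name in _raw_score_names(n)]


def direction_flags(names: Sequence[str] | None = None, n: int = 77) -> pd.Series:
    """Boolean per-score flag: True where higher raw values mean worse cognition."""
    raw = names if names is not None else _raw_score_names(n)
    flags = {}
    for name in raw:
        bad = name.endswith("*") or any(
            tok in name for tok in ("_time", "latency", "errors", "error",
                                    "misses", "false_alarms", "moves", "trials")
        )
        flags[name.rstrip("*")] = bool(bad)
    return pd.Series(flags, name="higher_is_worse")


def default_loading_matrix(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """(loadings, intercepts): loadings is (n_scores, rank); column 0 carries the
    archetype signal, the remaining columns are nuisance factors shared across
    scores. Signs of column 0 follow the direction flags so that latency-type
    scores worsen (increase) as latent cognition falls."""
    rng = _rng(config.seed, "loadings")
    names = default_score_names(config.n_cognitive_scores)
    flags = direction_flags(names).to_numpy()
    p, r = config.n_cognitive_scores, config.loading_matrix_rank
    signal = rng.uniform(0.6, 1.0, size=p)
    signal[flags] *= -1.0
    L = np.zeros((p, r))
    L[:, 0] = signal
    if r > 1:
        L[:, 1:] = rng.normal(0.0, config.nuisance_scale / math.sqrt(r - 1),
                              size=(p, r - 1))
    intercepts = rng.normal(0.0, 1.0, size=p)
    return L, intercepts


def generate_cognitive_scores(
    cohort,
    loading_matrix: np.ndarray | None = None,
    noise_sd: float | None = None,
    intercepts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-format cognitive scores: loading · latent + Gaussian noise.

    The per-visit latent vector is ``[c_i(t), z_1 .. z_{r-1}]`` where ``c_i(t)``
    is the archetype trajectory (level + slope x years since 57 + participant
    intercept) and the ``z`` components are standard-normal nuisance factors
    drawn independently per visit.
    """
    config: CohortConfig = cohort.config
    if loading_matrix is None:
        loading_matrix, default_inter = default_loading_matrix(config)
        if intercepts is None:
            intercepts = default_inter
    loading_matrix = np.asarray(loading_matrix, dtype=float)
    if loading_matrix.ndim != 2 or loading_matrix.shape[0] != config.n_cognitive_scores:
        raise ValueError(
            f"loading matrix shape {loading_matrix.shape} does not map rank-r latents "
            f"to {config.n_cognitive_scores} scores"
        )
    r = loading_matrix.shape[1]
    if intercepts is None:
        intercepts = np.zeros(config.n_cognitive_scores)
    noise = config.noise_sd if noise_sd is None else noise_sd

    by_name = {s.name: s for s in config.archetypes}
    rng_lat = _rng(config.seed, "latent")
    rng_obs = _rng(config.seed, "cognitive")
    names = default_score_names(config.n_cognitive_scores)

    records = []
    for p in cohort.participants:
        spec = by_name[p.archetype]
        b = rng_lat.normal(0.0, config.intercept_sd)
        for v, age in enumerate(p.visit_ages):
            latent = np.zeros(r)
            latent[0] = _latent_value(spec, age, b)
            if r > 1:
                latent[1:] = rng_lat.normal(0.0, 1.0, size=r - 1)
            scores = intercepts + loading_matrix @ latent
            if noise > 0:
                scores = scores + rng_obs.normal(0.0, noise, size=len(scores))
            for name, val in zip(names, scores):
                records.append((p.id, v + 1, age, name, float(val)))
    return pd.DataFrame(
        records, columns=["participant_id", "visit_index", "age", "variable", "value"]
    )


# ---------------------------------------------------------------------------
# MRI volumes

# (region name, tag, baseline volume mm^3). Ventricle/CSF-tagged regions grow
# with age; neocortical regions atrophy fastest, steeper for declining
# archetypes; tags drive both slopes and archetype level offsets.
MRI_REGIONS: tuple[tuple[str, str, float], ...] = (
    ("lateral_ventricle", "ventricle", 15000.0),
    ("inferior_lateral_ventricle", "ventricle", 800.0),
    ("third_ventricle", "ventricle", 1100.0),
    ("fourth_ventricle", "ventricle", 1800.0),
    ("csf", "ventricle", 1200.0),
    ("frontal_cortex", "neocortical", 82000.0),
    ("parietal_cortex", "neocortical", 60000.0),
    ("temporal_cortex", "neocortical", 55000.0),
    ("occipital_cortex", "neocortical", 25000.0),
    ("cingulate_cortex", "neocortical", 11000.0),
    ("insula", "neocortical", 7000.0),
    ("precuneus", "neocortical", 10000.0),
    ("fusiform_gyrus", "neocortical", 9500.0),
    ("entorhinal_cortex", "neocortical", 1900.0),
    ("supramarginal_gyrus", "neocortical", 10500.0),
    ("lingual_gyrus", "neocortical", 7300.0),
    ("pericalcarine_cortex", "neocortical", 2200.0),
    ("hippocampus", "subcortical", 4300.0),
    ("amygdala", "subcortical", 1700.0),
    ("thalamus", "subcortical", 7200.0),
    ("caudate", "subcortical", 3600.0),
    ("putamen", "subcortical", 4800.0),
    ("pallidum", "subcortical", 1900.0),
    ("accumbens_area", "subcortical", 550.0),
    ("brain_stem", "subcortical", 21000.0),
    ("cerebellum_cortex", "subcortical", 105000.0),
    ("cerebellum_white_matter", "subcortical", 14000.0),
    ("cerebral_white_matter", "other", 450000.0),
    ("corpus_callosum", "other", 3300.0),
    ("total_gray_matter", "other", 600000.0),
    ("supratentorial", "other", 1050000.0),
    ("optic_chiasm", "other", 200.0),
    ("ventral_diencephalon", "other", 4000.0),
    ("choroid_plexus", "other", 1600.0),
    ("cortex_total", "other", 480000.0),
)

_TAG_SLOPE = {"ventricle": 0.015, "neocortical": -0.004, "subcortical": -0.002, "other": -0.001}
# per-archetype multipliers on the atrophy/growth slope
_ARCH_SLOPE_FACTOR = {
    "ventricle": {"low_stable": 1.0, "high_upper": 0.9, "low_declining": 1.5, "high_lower": 1.0},
    "neocortical": {"low_stable": 1.0, "high_upper": 0.8, "low_declining": 2.0, "high_lower": 1.0},
    "subcortical": {"low_stable": 1.0, "high_upper": 1.0, "low_declining": 1.3, "high_lower": 1.0},
    "other": {"low_stable": 1.0, "high_upper": 1.0, "low_declining": 1.0, "high_lower": 1.0},
}
# per-archetype baseline level multipliers (atrophy already accrued before 57)
_ARCH_LEVEL = {
    "ventricle": {"low_stable": 1.05, "high_upper": 0.97, "low_declining": 1.04, "high_lower": 0.99},
    "neocortical": {"low_stable": 0.985, "high_upper": 1.015, "low_declining": 0.99, "high_lower": 1.005},
    "subcortical": {"low_stable": 0.995, "high_upper": 1.005, "low_declining": 0.995, "high_lower": 1.0},
    "other": {"low_stable": 1.0, "high_upper": 1.0, "low_declining": 1.0, "high_lower": 1.0},
}


def generate_mri(
    cohort,
    atrophy_scale: float = 1.0,
    noise_sd: float = 0.01,
    subject_sd: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Long-format regional volumes plus per-participant ICV (constant in time).

    ``noise_sd`` and ``subject_sd`` are relative (fraction of regional baseline);
    the subject effect is constant across visits so within-participant change
    reflects the archetype slope.
    """
    config: CohortConfig = cohort.config
    regions = MRI_REGIONS[: config.n_mri_regions]
    rng = _rng(config.seed, "mri")
    records = []
    icv = {}
    for p in cohort.participants:
        icv[p.id] = float(np.clip(rng.normal(1.5e6, 1.2e5), 1.0e6, 2.0e6))
        subj = rng.normal(0.0, subject_sd, size=len(regions))
        for v, age in enumerate(p.visit_ages):
            for j, (name, tag, base) in enumerate(regions):
                slope = _TAG_SLOPE[tag] * _ARCH_SLOPE_FACTOR[tag][p.archetype] * atrophy_scale
                level = _ARCH_LEVEL[tag][p.archetype]
                vol = base * level * (1.0 + subj[j]) * (1.0 + slope * (age - 57.0))
                if noise_sd > 0:
                    vol *= 1.0 + rng.normal(0.0, noise_sd)
                records.append((p.id, v + 1, age, name, float(vol)))
    table = pd.DataFrame(
        records, columns=["participant_id", "visit_index", "age", "variable", "value"]
    )
    return table, pd.Series(icv, name="icv").rename_axis("participant_id")


# ---------------------------------------------------------------------------
# EEG

_REGION_GAIN = {"occipital": 1.5, "parietal": 1.2, "temporal": 1.0, "central": 0.8, "frontal": 0.7}
_BAND_AMP = {"alpha": 2.0, "gamma": 1.0}  # microvolt tone amplitude at gain 1
# archetype gain on evoked amplitude; low_stable lowest across the board
_GROUP_GAIN = {"low_stable": 0.6, "low_declining": 0.8, "high_lower": 1.0, "high_upper": 1.2}
_BACKGROUND_RMS = 5.0  # microvolts of 1/f background at snr = 1


def pink_noise(rng: np.random.Generator, n_samples: int, fs: float,
               rms: float, shape: tuple[int, ...] = ()) -> np.ndarray:
    """1/f-power noise via spectral shaping of white noise (PSD proportional to 1/f)."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    current = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x * (rms / np.where(current > 0, current, 1.0))


def generate_eeg_signals(
    cohort, snr: float = 1.0, duration_s: float = 8.0
) -> Iterator[EEGRecording]:
    """Yield one synthetic recording per participant-visit (lazy, deterministic).

    Each channel is 1/f background plus 8 Hz and 36 Hz sinusoids whose
    amplitudes depend on the archetype, the channel's scalp region (parietal
    and temporal channels carry the full group effect, other regions a damped
    one) and a per-participant evoked-amplitude factor. ``snr`` divides the
    background amplitude; ``snr -> inf`` leaves a pure two-tone signal.
    """
    from .eeg import default_montage, default_region_map  # local import, no cycle

    if duration_s < 4.0:
        raise ValueError("duration_s must be at least 4 s to resolve the 8 Hz response")
    config: CohortConfig = cohort.config
    channels = default_montage(config.n_eeg_channels)
    region_map = default_region_map(channels)
    chan_region = {ch: reg for reg, chs in region_map.items() for ch in chs}
    fs = config.eeg_sampling_hz
    n_samples = int(round(duration_s * fs))
    t = np.arange(n_samples) / fs

    rng = _rng(config.seed, "eeg")
    for p in cohort.participants:
        # participant-level evoked-amplitude factor, shared across channels/bands
        subj_amp = math.exp(rng.normal(0.0, 0.5))
        g = _GROUP_GAIN[p.archetype]
        for v, _age in enumerate(p.visit_ages):
            band_jit = {b: math.exp(rng.normal(0.0, 0.1)) for b in config.stim_freqs_hz}
            # per-visit regional variability keeps between-region contrasts noisy
            region_jit = {r: math.exp(rng.normal(0.0, 0.45)) for r in _REGION_GAIN}
            phases = rng.uniform(0, 2 * np.pi, size=(len(channels), len(config.stim_freqs_hz)))
            data = (
                pink_noise(rng, n_samples, fs, _BACKGROUND_RMS / snr, shape=(len(channels),))
                if np.isfinite(snr)
                else np.zeros((len(channels), n_samples))
            )
            for ci, ch in enumerate(channels):
                region = chan_region[ch]
                group_gain = g if region in ("parietal", "temporal") else math.sqrt(g)
                for bi, (band, f) in enumerate(config.stim_freqs_hz.items()):
                    amp = (_BAND_AMP[band] * _REGION_GAIN[region] * group_gain
                           * subj_amp * band_jit[band] * region_jit[region])
                    data[ci] += amp * np.sin(2 * np.pi * f * t + phases[ci, bi])
            yield EEGRecording(
                participant_id=p.id,
                visit_index=v + 1,
                sampling_rate=fs,
                channel_names=tuple(channels),
                samples=data,
            )


# ---------------------------------------------------------------------------
# risk factors

# Defaults calibrated to the printed per-group counts (binary yes/no and
# mean +/- SD): group 1 = low_stable, group 2 = high_upper,
# group 3 = low_declining, group 4 = high_lower.
_LS, _HU, _LD, _HL = ARCHETYPE_NAMES[0], ARCHETYPE_NAMES[1], ARCHETYPE_NAMES[2], ARCHETYPE_NAMES[3]

_FATHER_OCC_LEVELS = tuple(f"occupation_{i:02d}" for i in range(1, 21))


def _father_occupation_probs(tilt: float) -> list[float]:
    w = np.exp(-tilt * np.arange(20))
    return list(w / w.sum())


DEFAULT_RISK_TABLE: dict = {
    "binary": {
        "alcohol_use": {_LS: 65 / 69, _HU: 243 / 256, _LD: 63 / 65, _HL: 128 / 136},
        "smoking": {_LS: 40 / 69, _HU: 147 / 256, _LD: 41 / 65, _HL: 78 / 136},
        "illness": {_LS: 58 / 69, _HU: 213 / 256, _LD: 58 / 65, _HL: 114 / 136},
        "familial_hypertension": {_LS: 27 / 66, _HU: 88 / 241, _LD: 26 / 62, _HL: 44 / 128},
        "familial_diabetes": {_LS: 10 / 69, _HU: 51 / 252, _LD: 17 / 61, _HL: 16 / 132},
        "familial_depression": {_LS: 11 / 69, _HU: 63 / 250, _LD: 16 / 64, _HL: 20 / 132},
        "familial_dementia": {_LS: 19 / 69, _HU: 65 / 249, _LD: 15 / 64, _HL: 38 / 134},
    },
    "categorical": {
        "father_education": {
            "levels": ("primary", "middle", "high"),
            _LS: [17 / 66, 20 / 66, 29 / 66],
            _HU: [41 / 233, 90 / 233, 102 / 233],
            _LD: [14 / 58, 17 / 58, 27 / 58],
            _HL: [29 / 125, 45 / 125, 51 / 125],
        },
        "father_occupation": {
            "levels": _FATHER_OCC_LEVELS,
            # higher-status categories first; high-performing groups tilt upward
            _LS: _father_occupation_probs(0.06),
            _HU: _father_occupation_probs(0.18),
            _LD: _father_occupation_probs(0.06),
            _HL: _father_occupation_probs(0.12),
        },
    },
    "gaussian": {
        "school_years": {_LS: (10.76, 2.59), _HU: (12.27, 2.84), _LD: (11.05, 2.56), _HL: (11.52, 2.66)},
        "iq_score": {_LS: (65.09, 15.60), _HU: (79.85, 14.27), _LD: (65.27, 16.65), _HL: (71.91, 14.43)},
        "bmi": {_LS: (27.2, 3.6), _HU: (26.0, 3.4), _LD: (27.0, 3.5), _HL: (26.5, 3.5)},
    },
}


def generate_risk_factors(cohort, prevalence_table: Mapping | None = None) -> pd.DataFrame:
    """Per-participant risk factors drawn independently given the archetype.

    Binary factors come out as "yes"/"no", categorical as their level string,
    Gaussian factors as floats. Probabilities are validated to lie in [0, 1].
    """
    table = prevalence_table if prevalence_table is not None else DEFAULT_RISK_TABLE
    for factor, per_arch in table.get("binary", {}).items():
        for arch, prob in per_arch.items():
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"binary factor {factor!r}: p({arch})={prob} outside [0, 1]")
    for factor, entry in table.get("categorical", {}).items():
        for arch in ARCHETYPE_NAMES:
            probs = np.asarray(entry[arch], dtype=float)
            if (probs < 0).any() or (probs > 1).any():
                raise ValueError(f"categorical factor {factor!r}: probabilities outside [0, 1]")

    rng = _rng(cohort.config.seed, "risk")
    rows = {}
    for p in cohort.participants:
        rec: dict = {}
        for factor, per_arch in table.get("binary", {}).items():
            rec[factor] = "yes" if rng.random() < per_arch[p.archetype] else "no"
        for factor, entry in table.get("categorical", {}).items():
            levels = entry["levels"]
            probs = np.asarray(entry[p.archetype], dtype=float)
            probs = probs / probs.sum()
            rec[factor] = levels[rng.choice(len(levels), p=probs)]
        for factor, per_arch in table.get("gaussian", {}).items():
            mean, sd = per_arch[p.archetype]
            rec[factor] = float(rng.normal(mean, sd))
        rows[p.id] = rec
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("participant_id")


# ---------------------------------------------------------------------------
# missingness


def apply_missingness(table: pd.DataFrame, missing_rate: float, seed: int) -> pd.DataFrame:
    """Remove whole participant-visit cells completely at random (MCAR).

    Dropping acts at the participant-visit level (all of that visit's variables
    for the modality disappear together, as when a participant skips a scan).
    The input table is never mutated.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    if missing_rate == 0.0:
        return table.copy()
    rng = np.random.Generator(np.random.PCG64(seed))
    cells = table[["participant_id", "visit_index"]].drop_duplicates().reset_index(drop=True)
    keep_mask = rng.random(len(cells)) >= missing_rate
    kept = cells[keep_mask]
    out = table.merge(kept, on=["participant_id", "visit_index"], how="inner")
    return out.reset_index(drop=True)
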