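"""SSVEP regional power extraction from multi-channel EEG.

Per channel: Welch power spectral density, multiplied by frequency to flatten
the 1/f background, peak picked around each stimulation frequency (8 Hz alpha,
36 Hz gamma). Channel peaks are averaged into five scalp regions (temporal,
frontal, parietal, central, occipital) and log-z-scored across the cohort,
yielding exactly ten standardized features per participant-visit.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "default_montage",
    "default_region_map",
    "welch_psd",
    "peak_power_at",
    "compensate_1overf",
    "aggregate_regions",
    "zscore_powers",
    "extract_regional_powers",
    "REGIONS",
]

REGIONS = ("temporal", "frontal", "parietal", "central", "occipital")

# 64-channel extended 10-20 montage (Quick-Cap style layout).
_MONTAGE_64 = (
    "FP1", "FPZ", "FP2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "CB1", "O1", "OZ", "O2", "CB2", "M1", "M2",
)


def default_montage(n_channels: int = 64) -> tuple[str, ...]:
    if n_channels > len(_MONTAGE_64):
        raise ValueError(f"montage table has only {len(_MONTAGE_64)} channels")
    return _MONTAGE_64[:n_channels]


def default_region_map(channels: Sequence[str] | None = None) -> dict[str, tuple[str, ...]]:
    """Assign channels to the five scalp regions by 10-20 prefix.

    Midline (…Z) channels go to ``central``; temporal covers T/FT/TP and the
    mastoids; parietal covers CP/P; occipital covers PO/O/CB.
    """
    channels = channels if channels is not None else default_montage()

    def region_of(ch: str) -> str:
        if ch.endswith("Z"):
            return "central"
        if ch.startswith(("FT", "TP", "T", "M")):
            return "temporal"
        if ch.startswith(("PO", "O", "CB")):
            return "occipital"
        if ch.startswith(("CP", "P")):
            return "parietal"
        if ch.startswith(("FP", "AF", "FC", "F")):
            return "frontal"
        if ch.startswith("C"):
            return "central"
        raise ValueError(f"channel {ch!r} not in the montage table")

    out: dict[str, list[str]] = {r: [] for r in REGIONS}
    for ch in channels:
        out[region_of(ch)].append(ch)
    for r, chs in out.items():
        if not chs:
            raise ValueError(f"region {r!r} has no channels in this montage")
    return {r: tuple(chs) for r, chs in out.items()}


def welch_psd(
    x: np.ndarray,
    sampling_rate: float,
    segment_s: float = 2.0,
    overlap_frac: float = 0.5,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (density scaling, µV²/Hz).

    2 s segments give a 0.5 Hz frequency grid on which both the 8 Hz and the
    36 Hz stimulation frequencies fall exactly on a bin. Works on a single
    channel (1-d) or a channels x time array (last axis = time).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(segment_s * sampling_rate))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal has {x.shape[-1]} samples but one Welch segment needs {nperseg} "
            f"({segment_s} s at {sampling_rate} Hz)"
        )
    freqs, psd = sps.welch(
        x,
        fs=sampling_rate,
        window=window,
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap_frac)),
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def peak_power_at(
    frequencies: np.ndarray,
    psd: np.ndarray,
    target_hz: float,
    search_halfwidth_hz: float = 0.5,
) -> float | np.ndarray:
    """Maximum PSD value within ``target_hz ± search_halfwidth_hz``."""
    frequencies = np.asarray(frequencies, dtype=float)
    mask = (frequencies >= target_hz - search_halfwidth_hz) & (
        frequencies <= target_hz + search_halfwidth_hz
    )
    if not mask.any():
        raise ValueError(
            f"search window {target_hz}±{search_halfwidth_hz} Hz contains no "
            f"spectral bins (range {frequencies[0]}–{frequencies[-1]} Hz)"
        )
    sub = np.asarray(psd, dtype=float)[..., mask]
    out = sub.max(axis=-1)
    return float(out) if out.ndim == 0 else out


def compensate_1overf(frequencies: np.ndarray, psd: np.ndarray) -> np.ndarray:
    """Multiply each spectral value by its frequency (flattens a 1/f background;
    the DC bin becomes zero)."""
    frequencies = np.asarray(frequencies, dtype=float)
    if (frequencies < 0).any():
        raise ValueError("frequencies must be non-negative")
    return np.asarray(psd, dtype=float) * frequencies


def aggregate_regions(
    channel_powers: Mapping[str, float],
    region_map: Mapping[str, Sequence[str]],
) -> dict[str, float]:
    """Mean of member-channel powers per region; regions with no usable
    (finite) channel are omitted with a log message."""
    out: dict[str, float] = {}
    for region, chans in region_map.items():
        vals = [channel_powers[c] for c in chans
                if c in channel_powers and np.isfinite(channel_powers[c])]
        if not vals:
            logger.warning("region %s has no usable channels; omitted", region)
            continue
        out[region] = float(np.mean(vals))
    return out


def extract_regional_powers(
    recordings: Iterable,
    stim_freqs_hz: Mapping[str, float] | None = None,
    region_map: Mapping[str, Sequence[str]] | None = None,
    segment_s: float = 2.0,
    overlap_frac: float = 0.5,
    search_halfwidth_hz: float = 0.5,
) -> pd.DataFrame:
    """Raw (pre-z-scoring) regional SSVEP powers, long format.

    Consumes recordings lazily, so a full cohort's EEG never has to be held in
    memory at once. Columns: participant_id, visit_index, region, band, power.
    """
    stim = dict(stim_freqs_hz or {"alpha": 8.0, "gamma": 36.0})
    rows = []
    for rec in recordings:
        rmap = region_map or default_region_map(rec.channel_names)
        freqs, psd = welch_psd(rec.samples, rec.sampling_rate,
                               segment_s=segment_s, overlap_frac=overlap_frac)
        comp = compensate_1overf(freqs, psd)
        for band, f in stim.items():
            peaks = peak_power_at(freqs, comp, f, search_halfwidth_hz)
            chan_powers = dict(zip(rec.channel_names, np.atleast_1d(peaks)))
            for region, val in aggregate_regions(chan_powers, rmap).items():
                rows.append((rec.participant_id, rec.visit_index, region, band, val))
    return pd.DataFrame(
        rows, columns=["participant_id", "visit_index", "region", "band", "power"]
    )


def zscore_powers(power_table: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """Standardize powers to Z-scores within each (region, band) across all
    participant-visits, after an (optional, default) log transform.

    Returns the table with a ``z_power`` column replacing ``power``.
    """
    df = power_table.copy()
    vals = df["power"].to_numpy(dtype=float)
    if log_transform:
        if (vals <= 0).any():
            raise ValueError("log transform requires strictly positive powers")
        vals = np.log(vals)
    df["_v"] = vals
    out_parts = []
    for (region, band), grp in df.groupby(["region", "band"], sort=False):
        if len(grp) < 2:
            raise ValueError(f"need >=2 observations to z-score ({region}, {band})")
        sd = grp["_v"].std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance in ({region}, {band}); cannot z-score")
        z = (grp["_v"] - grp["_v"].mean()) / sd
        part = grp[["participant_id", "visit_index", "region", "band"]].copy()
        part["z_power"] = z
        out_parts.append(part)
    return pd.concat(out_parts, ignore_index=True)


def regional_power_feature_table(z_table: pd.DataFrame) -> pd.DataFrame:
    """Reshape the z-scored regional powers into the standard long feature
    format (variable = ``eeg_<region>_<band>``)."""
    df = z_table.copy()
    df["variable"] = "eeg_" + df["region"] + "_" + df["band"]
    df = df.rename(columns={"z_power": "value"})
    df["age"] = np.nan
    return df[["participant_id", "visit_index", "age", "variable", "value"]]
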