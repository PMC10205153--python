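"""Deterministic ERP pipeline: filtering, segmentation, baseline correction,
artifact rejection, ROI x window averaging, and trial-table assembly.

Time conventions: sample index ``time0`` marks stimulus onset (t = 0 ms);
millisecond windows are half-open ``[start, end)`` and are converted to
sample ranges with floor (start) / ceil (end), so the same helper is used
by the synthetic epoch generator and exact template recovery holds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .cloze import center_predictor

logger = logging.getLogger("erpseq")

__all__ = [
    "EpochSet",
    "ROISpec",
    "DEFAULT_ROIS",
    "ms_to_sample_range",
    "bandpass_filter",
    "segment_epochs",
    "baseline_correct",
    "reject_artifacts",
    "roi_window_mean",
    "build_trial_table",
    "subset_for_analysis",
    "write_epochs",
    "read_epochs",
]


@dataclass
class EpochSet:
    """Trials x channels x samples in microvolts."""

    data: np.ndarray
    srate: float
    time0: int  # sample index of stimulus onset
    channel_labels: list[str]
    reject_flags: np.ndarray = field(default=None)
    reject_reasons: list[str] = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis does not match labels")
        if self.reject_flags is None:
            self.reject_flags = np.zeros(self.data.shape[0], dtype=bool)
        if self.reject_reasons is None:
            self.reject_reasons = [""] * self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.time0) * 1000.0 / self.srate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            srate=self.srate,
            time0=self.time0,
            channel_labels=list(self.channel_labels),
            reject_flags=self.reject_flags.copy(),
            reject_reasons=list(self.reject_reasons),
        )


@dataclass(frozen=True)
class ROISpec:
    name: str
    electrodes: tuple[str, ...]
    window_ms: tuple[float, float]


# Pre-registered dependent-variable definitions plus the exploratory
# posterior late window.
DEFAULT_ROIS = {
    "N400": ROISpec("N400", ("Cz", "CP1", "CP2", "P3", "Pz", "P4", "POz"), (300.0, 500.0)),
    "PNP": ROISpec("PNP", ("Fpz", "Fp1", "Fp2", "F3", "Fz", "F4"), (600.0, 1000.0)),
    "P600": ROISpec("P600", ("Cz", "CP1", "CP2", "P3", "Pz", "P4", "POz"), (600.0, 1000.0)),
}


def ms_to_sample_range(start_ms: float, end_ms: float, srate: float, time0: int):
    """Half-open [start, end) ms window -> half-open sample range."""
    s0 = time0 + int(np.floor(start_ms * srate / 1000.0))
    s1 = time0 + int(np.ceil(end_ms * srate / 1000.0))
    return s0, s1


# ---------------------------------------------------------------------------
# filtering


def bandpass_filter(
    x: np.ndarray,
    srate: float,
    low: float = 0.01,
    high: float = 30.0,
    variant: str = "fir",
    l_trans: float = 0.01,
    h_trans: float = 7.5,
    iir_order: int = 16,
) -> np.ndarray:
    """Zero-phase bandpass along the last axis.

    ``fir``: windowed-sinc (Hamming) kernel with -6 dB points half a
    transition band outside the passband edges, applied once by symmetric
    convolution (linear phase + delay compensation = zero net phase).
    ``iir``: Butterworth of effective order ``iir_order`` applied
    forward-backward (two-pass), cutoffs at -6.02 dB.
    """
    x = np.asarray(x, dtype=float)
    if srate <= 2 * high:
        raise ValueError("sampling rate must exceed twice the high cutoff")
    n = x.shape[-1]
    if variant == "fir":
        trans = min(l_trans, h_trans)
        numtaps = int(np.ceil(3.3 / (trans / srate)))
        numtaps += 1 - numtaps % 2  # odd -> symmetric -> exactly linear phase
        if numtaps > n:
            raise ValueError(
                f"signal of {n} samples shorter than filter settling length "
                f"({numtaps} taps); relax the transition bands or filter the "
                "continuous recording"
            )
        lo_edge = max(low - l_trans / 2, 1e-6)
        hi_edge = high + h_trans / 2
        kernel = sps.firwin(
            numtaps, [lo_edge, hi_edge], pass_zero=False, fs=srate, window="hamming"
        )
        half = numtaps // 2
        pad_width = [(0, 0)] * (x.ndim - 1) + [(half, half)]
        padded = np.pad(x, pad_width, mode="reflect")
        return sps.fftconvolve(padded, kernel.reshape((1,) * (x.ndim - 1) + (-1,)), mode="valid", axes=-1)
    if variant == "iir":
        sos = sps.butter(iir_order // 2, [low, high], btype="bandpass", fs=srate, output="sos")
        padlen = 3 * (2 * (iir_order // 2) + 1)
        if n <= padlen:
            raise ValueError(f"signal of {n} samples shorter than filter settling length")
        return sps.sosfiltfilt(sos, x, axis=-1)
    raise ValueError(f"unknown filter variant {variant!r}")


# ---------------------------------------------------------------------------
# segmentation / baseline / rejection


def segment_epochs(
    continuous: np.ndarray,
    event_samples,
    window: tuple[int, int],
    srate: float,
    channel_labels: list[str],
) -> EpochSet:
    """Cut inclusive ``[window[0], window[1]]``-sample epochs around events.

    Events whose window falls outside the recording are skipped with a
    warning; overlapping events are extracted independently.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    w0, w1 = int(window[0]), int(window[1])
    n = continuous.shape[-1]
    epochs = []
    for ev in event_samples:
        lo, hi = ev + w0, ev + w1 + 1
        if lo < 0 or hi > n:
            warnings.warn(f"event at sample {ev} too close to recording edge; skipped")
            continue
        epochs.append(continuous[:, lo:hi])
    data = np.stack(epochs) if epochs else np.empty((0, continuous.shape[0], w1 - w0 + 1))
    return EpochSet(data=data, srate=srate, time0=-w0, channel_labels=list(channel_labels))


def baseline_correct(epochs: EpochSet, baseline_ms: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract the per-epoch per-channel mean over the baseline window."""
    s0, s1 = ms_to_sample_range(baseline_ms[0], baseline_ms[1], epochs.srate, epochs.time0)
    if s0 < 0 or s1 > epochs.n_samples or s1 <= s0:
        raise ValueError("baseline window outside epoch span")
    out = epochs.copy()
    out.data -= out.data[:, :, s0:s1].mean(axis=2, keepdims=True)
    return out


def reject_artifacts(
    epochs: EpochSet,
    p2p_limit: float = 100.0,
    p2p_window_ms: float = 150.0,
    step_limit: float = 50.0,
) -> EpochSet:
    """Flag trials with >100 uV peak-to-peak inside any sliding 150 ms window
    (1-sample hop) or any successive-sample step over 50 uV/ms, per channel."""
    out = epochs.copy()
    if epochs.n_trials == 0:
        return out
    w = int(round(p2p_window_ms * epochs.srate / 1000.0))
    w = max(w, 2)
    data = epochs.data
    s = data.shape[-1]
    mx = maximum_filter1d(data, size=w, axis=-1)
    mn = minimum_filter1d(data, size=w, axis=-1)
    lo, hi = w // 2, s - w + w // 2 + 1  # centers whose window lies fully inside
    p2p = (mx - mn)[:, :, lo:hi].max(axis=(1, 2))
    dt_ms = 1000.0 / epochs.srate
    step = np.abs(np.diff(data, axis=-1)).max(axis=(1, 2)) / dt_ms

    for i in range(epochs.n_trials):
        reasons = []
        if p2p[i] > p2p_limit:
            reasons.append("p2p")
        if step[i] > step_limit:
            reasons.append("step")
        if reasons:
            out.reject_flags[i] = True
            out.reject_reasons[i] = "+".join(reasons)
    return out


def roi_window_mean(epochs: EpochSet, roi: ROISpec) -> np.ndarray:
    """Per-trial mean over the ROI channels and [start, end) ms window."""
    idx = [epochs.channel_index(ch) for ch in roi.electrodes]
    s0, s1 = ms_to_sample_range(roi.window_ms[0], roi.window_ms[1], epochs.srate, epochs.time0)
    if s0 < 0 or s1 > epochs.n_samples:
        raise ValueError(f"ROI window {roi.window_ms} outside epoch span")
    return epochs.data[:, idx, s0:s1].mean(axis=(1, 2))


# ---------------------------------------------------------------------------
# table assembly


def build_trial_table(
    epochs: EpochSet,
    rois,
    predictors: pd.DataFrame,
    layout: pd.DataFrame,
    *,
    recenter: bool = True,
) -> pd.DataFrame:
    """One row per retained trial x ROI, joining amplitudes with predictors.

    ``layout`` rows must correspond 1:1 (in order) with epoch trials and
    carry subject/item/condition plus trial metadata. Rejected trials are
    excluded; the rejected fraction is logged.
    """
    if len(layout) != epochs.n_trials:
        raise ValueError(
            f"layout has {len(layout)} rows but epochs have {epochs.n_trials} trials"
        )
    keys = predictors.set_index(["item_id", "condition"])
    missing = [
        (it, co)
        for it, co in zip(layout["item"], layout["condition"])
        if (it, co) not in keys.index
    ]
    if missing:
        raise ValueError(f"no predictors for keys: {sorted(set(missing))[:10]}")

    if isinstance(rois, dict):
        rois = list(rois.values())
    retained = ~epochs.reject_flags
    frac = 1.0 - retained.mean() if epochs.n_trials else 0.0
    logger.info("artifact rejection removed %.1f%% of trials", 100 * frac)

    frames = []
    for roi in rois:
        amps = roi_window_mean(epochs, roi)
        df = layout.loc[retained].copy().reset_index(drop=True)
        df["roi_name"] = roi.name
        df["amplitude"] = amps[retained]
        pr = keys.loc[list(zip(df["item"], df["condition"]))]
        df["entropy_bits"] = pr["entropy_bits"].to_numpy()
        df["log2_cloze_smoothed"] = pr["log2_cloze_smoothed"].to_numpy()
        frames.append(df)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(table) == 0:
        warnings.warn("all trials rejected; emitting empty trial table")
        return table
    if recenter:
        for roi_name, grp in table.groupby("roi_name"):
            table.loc[grp.index, "entropy_centered"] = center_predictor(
                grp["entropy_bits"].to_numpy()
            )
            table.loc[grp.index, "log2_cloze_centered"] = center_predictor(
                grp["log2_cloze_smoothed"].to_numpy()
            )
    return table


def subset_for_analysis(table: pd.DataFrame, conditions, roi_name: str) -> pd.DataFrame:
    """Rows for one analysis (e.g. conditions b+d, PNP), predictors re-centred
    over exactly the retained rows."""
    sub = table[(table["condition"].isin(list(conditions))) & (table["roi_name"] == roi_name)]
    sub = sub.copy().reset_index(drop=True)
    if len(sub):
        sub["entropy_centered"] = center_predictor(sub["entropy_bits"].to_numpy())
        sub["log2_cloze_centered"] = center_predictor(sub["log2_cloze_smoothed"].to_numpy())
    return sub


# ---------------------------------------------------------------------------
# epoch container I/O (HDF5)


def write_epochs(path, epochs: EpochSet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("reject_flags", data=epochs.reject_flags)
        f.attrs["srate"] = epochs.srate
        f.attrs["time0"] = epochs.time0
        f.attrs["channel_labels"] = [s.encode() for s in epochs.channel_labels]
        f.attrs["reject_reasons"] = [s.encode() for s in epochs.reject_reasons]


def read_epochs(path) -> EpochSet:
    import h5py

    def _as_str(v):
        return v.decode() if isinstance(v, bytes) else str(v)

    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            srate=float(f.attrs["srate"]),
            time0=int(f.attrs["time0"]),
            channel_labels=[_as_str(v) for v in f.attrs["channel_labels"]],
            reject_flags=f["reject_flags"][()].astype(bool),
            reject_reasons=[_as_str(v) for v in f.attrs["reject_reasons"]],
        )
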