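"""Recordings -> per-subject, per-pair connectivity table.

Each recording is band-pass filtered (1-45 Hz) with a 50 Hz mains
notch, restricted to the montage's 10 analyzed channels, cut into
non-overlapping epochs, and screened with a simple amplitude rule: an
epoch is dropped for all channels when any channel's peak absolute
amplitude exceeds ``reject_sd`` whole-recording SDs.  C-ApEn is then
computed per electrode pair and epoch and averaged over retained
epochs.  Per pair the analysis table carries the rest and task values
at both timepoints, the task-minus-rest *difference value*, and the
post-minus-baseline *change* of that difference.  A condition with
fewer than ``min_epochs`` retained epochs yields a missing cell (NaN),
which propagates to the difference and change rather than becoming 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .core import EmbeddingParams, cross_apen_epochs
from .montage import CHANNEL_ORDER, PairSet, build_default_montage, pair_name

__all__ = [
    "PipelineConfig",
    "Recording",
    "preprocess",
    "epoch_and_reject",
    "pair_capen",
    "difference_value",
    "change_score",
    "connectivity_table",
    "subject_change_scores",
    "TABLE_COLUMNS",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "subject",
    "arm",
    "pair",
    "category",
    "capen_rest_baseline",
    "capen_task_baseline",
    "diff_baseline",
    "capen_rest_post",
    "capen_task_post",
    "diff_post",
    "change",
    "epochs_rest",
    "epochs_task",
    "flags",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Preprocessing, epoching and estimator settings."""

    band: tuple[float, float] = (1.0, 45.0)
    notch: float = 50.0
    epoch_seconds: float = 2.0
    reject_sd: float = 5.0
    min_epochs: int = 10
    params: EmbeddingParams = field(default_factory=EmbeddingParams)

    @classmethod
    def for_design(cls, design, **kwargs) -> "PipelineConfig":
        """Config whose epoch length matches ``design.rate`` and epoch seconds."""
        epoch_len = int(round(design.epoch_seconds * design.rate))
        params = kwargs.pop("params", None) or EmbeddingParams(epoch_len=epoch_len)
        if params.epoch_len != epoch_len:
            params = replace(params, epoch_len=epoch_len)
        return cls(epoch_seconds=design.epoch_seconds, params=params, **kwargs)


@dataclass
class Recording:
    """A multichannel recording: ``data`` is (n_samples, n_channels)."""

    data: np.ndarray
    rate: float
    channels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-dimensional (samples x channels)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel labels must match data columns")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def preprocess(rec: Recording, config: PipelineConfig | None = None) -> Recording:
    """Band-pass + notch filter and restrict to the 10 analyzed channels.

    Channels beyond the montage (e.g. the 6 recorded-but-unanalyzed
    electrodes of a 16-channel setup) are dropped; a missing analyzed
    channel raises, listing the absent electrodes.
    """
    config = config or PipelineConfig()
    missing = [c for c in CHANNEL_ORDER if c not in rec.channels]
    if missing:
        raise ValueError(f"recording lacks analyzed channels: {', '.join(missing)}")
    cols = [rec.channels.index(c) for c in CHANNEL_ORDER]
    data = rec.data[:, cols]

    nyq = rec.rate / 2.0
    # mains notch first: removing the 50 Hz component before the
    # band-pass keeps its zero-phase edge transients out of the passband
    if 0 < config.notch < nyq:
        b, a = _notch_ba(rec.rate, config.notch)
        data = spsig.filtfilt(b, a, data, axis=0)
    sos = _band_sos(rec.rate, config.band[0], config.band[1])
    data = spsig.sosfiltfilt(sos, data, axis=0)
    return Recording(data, rec.rate, list(CHANNEL_ORDER))


@lru_cache(maxsize=32)
def _band_sos(rate: float, lo: float, hi: float):
    nyq = rate / 2.0
    hi = min(hi, 0.95 * nyq)
    return spsig.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")


@lru_cache(maxsize=32)
def _notch_ba(rate: float, freq: float):
    # Q=10 (~5 Hz stop width at 50 Hz): narrower notches ring so long
    # that zero-phase filtering leaves visible mains residue at the
    # recording edges
    return spsig.iirnotch(freq, Q=10.0, fs=rate)


def epoch_and_reject(
    rec: Recording,
    epoch_len: int | None = None,
    reject_sd: float = 5.0,
) -> tuple[np.ndarray, dict]:
    """Cut into non-overlapping epochs and apply the amplitude rule.

    Returns ``(epochs, tally)`` where ``epochs`` is
    ``(n_kept, epoch_len, n_channels)`` and ``tally`` records total and
    rejected epoch counts.  An epoch is rejected for all channels when
    any channel's peak |amplitude| exceeds ``reject_sd`` times that
    channel's whole-recording SD.  Raises if everything is rejected.
    """
    if epoch_len is None:
        epoch_len = int(round(2.0 * rec.rate))
    n_total = rec.data.shape[0] // epoch_len
    if n_total < 1:
        raise ValueError(
            f"recording of {rec.data.shape[0]} samples shorter than one "
            f"epoch ({epoch_len} samples)"
        )
    sd = rec.data.std(axis=0)
    sd[sd == 0] = np.inf  # flat channel cannot trip the amplitude rule
    cut = rec.data[: n_total * epoch_len].reshape(n_total, epoch_len, -1)
    peak = np.abs(cut).max(axis=1)  # (n_total, n_channels)
    keep = (peak <= reject_sd * sd).all(axis=1)
    tally = {"total": int(n_total), "rejected": int((~keep).sum())}
    if not keep.any():
        raise ValueError(f"all epochs rejected by amplitude rule: {tally}")
    return cut[keep], tally


def pair_capen(
    epochs: np.ndarray,
    pair: tuple[str, str],
    params: EmbeddingParams,
    channels: list[str] | tuple[str, ...] = CHANNEL_ORDER,
    min_epochs: int = 1,
) -> tuple[float, dict]:
    """Mean C-ApEn over epochs for one electrode pair.

    ``epochs`` is (n_epochs, epoch_len, n_channels). Returns
    ``(value, info)`` with floor/degeneracy counts; value is NaN when
    fewer than ``min_epochs`` epochs are available (missing cell).
    """
    i, j = channels.index(pair[0]), channels.index(pair[1])
    info = {"n_epochs": int(epochs.shape[0]), "floored": 0, "degenerate": 0}
    if epochs.shape[0] < min_epochs:
        return float("nan"), info
    values, floors, degen = cross_apen_epochs(
        epochs[:, :, i], epochs[:, :, j], params
    )
    info["floored"] = int(floors.sum())
    info["degenerate"] = int(degen.sum())
    return float(values.mean()), info


def difference_value(capen_task: float, capen_rest: float) -> float:
    """Task-minus-rest difference value; NaN if either side is missing."""
    if capen_task is None or capen_rest is None:
        return float("nan")
    return float(capen_task) - float(capen_rest)


def change_score(diff_post: float, diff_baseline: float) -> float:
    """Post-minus-baseline change of the difference value; NaN-propagating."""
    if diff_post is None or diff_baseline is None:
        return float("nan")
    return float(diff_post) - float(diff_baseline)


def _condition_values(
    rec: Recording | None,
    pairs: list[tuple[str, str]],
    config: PipelineConfig,
) -> tuple[dict, int, dict]:
    """Per-pair mean C-ApEn for one recording (or all-missing if None)."""
    if rec is None:
        return {p: float("nan") for p in pairs}, 0, {}
    clean = preprocess(rec, config)
    epoch_len = int(round(config.epoch_seconds * clean.rate))
    epochs, tally = epoch_and_reject(clean, epoch_len, config.reject_sd)
    values: dict = {}
    flags = {"floored": 0, "degenerate": 0}
    for p in pairs:
        v, info = pair_capen(
            epochs, p, config.params, clean.channels, config.min_epochs
        )
        values[p] = v
        flags["floored"] += info["floored"]
        flags["degenerate"] += info["degenerate"]
    return values, int(epochs.shape[0]), flags


def connectivity_table(
    get_recording,
    subjects: pd.DataFrame,
    config: PipelineConfig | None = None,
    pair_set: PairSet | None = None,
) -> pd.DataFrame:
    """Build the per-subject, per-pair analysis table.

    ``get_recording(subject, timepoint, condition)`` returns a
    :class:`Recording` or ``None`` for a missing session; missing
    sessions yield missing (NaN) cells and the run continues.  Output
    columns are :data:`TABLE_COLUMNS`; ``epochs_rest``/``epochs_task``
    report the minimum retained epochs across timepoints for that
    condition (the count that drives missingness).
    """
    config = config or PipelineConfig()
    if pair_set is None:
        _, pair_set = build_default_montage()
    pairs = list(pair_set)
    rows = []
    for _, subj in subjects.iterrows():
        sid = subj["subject"]
        per_tp: dict = {}
        counts: dict = {}
        flag_tally = {"floored": 0, "degenerate": 0, "missing_sessions": 0}
        for tp in ("baseline", "post"):
            for cond in ("rest", "task"):
                rec = get_recording(sid, tp, cond)
                if rec is None:
                    flag_tally["missing_sessions"] += 1
                vals, n_kept, flags = _condition_values(rec, pairs, config)
                per_tp[(tp, cond)] = vals
                counts[(tp, cond)] = n_kept
                for k in ("floored", "degenerate"):
                    flag_tally[k] += flags.get(k, 0)
        flag_str = ";".join(f"{k}={v}" for k, v in flag_tally.items() if v) or ""
        for p in pairs:
            rb = per_tp[("baseline", "rest")][p]
            tb = per_tp[("baseline", "task")][p]
            rp = per_tp[("post", "rest")][p]
            tk = per_tp[("post", "task")][p]
            db = difference_value(tb, rb)
            dp = difference_value(tk, rp)
            rows.append(
                {
                    "subject": sid,
                    "arm": subj["arm"],
                    "pair": pair_name(p),
                    "category": pair_set.category_of(p),
                    "capen_rest_baseline": rb,
                    "capen_task_baseline": tb,
                    "diff_baseline": db,
                    "capen_rest_post": rp,
                    "capen_task_post": tk,
                    "diff_post": dp,
                    "change": change_score(dp, db),
                    "epochs_rest": min(
                        counts[("baseline", "rest")], counts[("post", "rest")]
                    ),
                    "epochs_task": min(
                        counts[("baseline", "task")], counts[("post", "task")]
                    ),
                    "flags": flag_str,
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def subject_change_scores(
    recordings: dict[tuple[str, str], Recording | np.ndarray],
    pairs,
    config: PipelineConfig,
    rate: float | None = None,
) -> np.ndarray:
    """Change scores for one subject over ``pairs``.

    ``recordings`` maps (timepoint, condition) to a Recording or a raw
    (n_samples, 10) array in montage order (then ``rate`` is taken
    from ``config`` epoch settings via the array length only if given).
    Used by the generator's effect-size calibration loop.
    """
    pairs = list(pairs)
    vals: dict = {}
    for key, rec in recordings.items():
        if not isinstance(rec, Recording):
            if rate is None:
                rate = config.params.epoch_len / config.epoch_seconds
            rec = Recording(rec, rate, list(CHANNEL_ORDER))
        vals[key], _, _ = _condition_values(rec, pairs, config)
    out = []
    for p in pairs:
        db = difference_value(vals[("baseline", "task")][p], vals[("baseline", "rest")][p])
        dp = difference_value(vals[("post", "task")][p], vals[("post", "rest")][p])
        out.append(change_score(dp, db))
    return np.asarray(out)
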