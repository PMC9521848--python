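"""Readers, writers and run configuration.

Delimited text is the canonical on-disk format: one CSV per recording
(header row of electrode labels, one column per channel), a subjects
CSV, a ground-truth coupling CSV for simulated data, and a JSON
manifest holding the seed, sampling rate and a config hash.  Recording
files follow the naming contract ``SUBJECT_{baseline|post}_{rest|task}.csv``.
EDF recordings can be read when mne is installed; text remains the
format written by this package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EmbeddingParams
from .montage import ELECTRODE_REGIONS
from .pipeline import PipelineConfig, Recording
from .simulate import CONDITIONS, TIMEPOINTS, EffectSpec, TrialDataset, TrialDesign

__all__ = [
    "RunConfig",
    "write_dataset",
    "load_dataset",
    "read_recording_csv",
    "write_recording_csv",
    "read_recording_edf",
    "recording_filename",
]


def recording_filename(subject: str, timepoint: str, condition: str) -> str:
    return f"{subject}_{timepoint}_{condition}.csv"


def write_recording_csv(path, data: np.ndarray, channels) -> None:
    df = pd.DataFrame(np.asarray(data), columns=list(channels))
    df.to_csv(path, index=False, float_format="%.6g")


def read_recording_csv(path, rate: float) -> Recording:
    df = pd.read_csv(path)
    return Recording(df.to_numpy(dtype=float), rate, list(df.columns))


def read_recording_edf(path) -> Recording:
    """Read an EDF recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF requires mne; install capen[edf] or supply CSV"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(raw.get_data().T, float(raw.info["sfreq"]), list(raw.ch_names))


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs, serializable to YAML.

    A copy of the active config is written into every output
    directory so runs are self-describing and reproducible.
    """

    design: TrialDesign = dataclasses.field(default_factory=TrialDesign)
    effects: EffectSpec = dataclasses.field(default_factory=EffectSpec)
    pipeline: PipelineConfig = dataclasses.field(default_factory=PipelineConfig)
    #: electrode -> (region, hemisphere); serialized with every run
    montage: dict = dataclasses.field(
        default_factory=lambda: {e: list(v) for e, v in ELECTRODE_REGIONS.items()}
    )
    alpha: float = 0.05
    screen_alpha: float = 0.2
    fdr: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        design = TrialDesign(**raw.get("design", {}))
        eff = dict(raw.get("effects", {}))
        for key in ("tdcs_pairs", "control_pairs"):
            if key in eff:
                eff[key] = tuple(tuple(p) for p in eff[key])
        effects = EffectSpec(**eff)
        pipe = dict(raw.get("pipeline", {}))
        if "params" in pipe:
            pipe["params"] = EmbeddingParams(**pipe["params"])
        if "band" in pipe:
            pipe["band"] = tuple(pipe["band"])
        pipeline = PipelineConfig(**pipe)
        extra = {
            k: raw[k]
            for k in ("montage", "alpha", "screen_alpha", "fdr", "seed")
            if k in raw
        }
        return cls(design=design, effects=effects, pipeline=pipeline, **extra)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_dataset(dataset: TrialDataset, outdir) -> Path:
    """Write a simulated trial to ``outdir``; returns the manifest path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.subjects.to_csv(out / "subjects.csv", index=False)
    dataset.coupling_truth.to_csv(out / "ground_truth.csv", index=False)
    files = []
    for (sid, tp, cond), arr in dataset.recordings.items():
        name = recording_filename(sid, tp, cond)
        write_recording_csv(out / name, arr, dataset.channels)
        files.append(name)
    manifest = {
        "seed": dataset.seed,
        "rate": dataset.design.rate,
        "n_per_arm": dataset.design.n_per_arm,
        "channels": list(dataset.channels),
        "timepoints": list(TIMEPOINTS),
        "conditions": list(CONDITIONS),
        "n_recordings": len(files),
        "design": dataclasses.asdict(dataset.design),
        "effects": dataclasses.asdict(dataset.effects),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def load_dataset(datadir):
    """Load a written dataset: (get_recording, subjects, manifest).

    ``get_recording(subject, timepoint, condition)`` returns a
    :class:`Recording` or None when the session file is absent, so a
    run continues with missing cells rather than aborting.
    """
    d = Path(datadir)
    manifest = json.loads((d / "manifest.json").read_text())
    subjects = pd.read_csv(d / "subjects.csv")
    rate = float(manifest["rate"])

    def get(sid, tp, cond):
        path = d / recording_filename(sid, tp, cond)
        if not path.exists():
            edf = path.with_suffix(".edf")
            if edf.exists():
                return read_recording_edf(edf)
            return None
        return read_recording_csv(path, rate)

    return get, subjects, manifest
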