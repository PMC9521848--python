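"""Named analysis scales.

``study`` is the source trial's recording geometry: 500 Hz sampling,
about five minutes of rest and one minute of task per session, 2 s
epochs of 1000 samples analyzed at the standard tolerance
``r = 0.2`` SD.

``reduced`` is the package's own down-scaled geometry for Monte-Carlo
validation: 125 Hz, 20 s per condition (ten 2 s epochs of 250
samples).  At 250-sample epochs the expected number of
(m+1)-dimensional template matches at ``r = 0.2`` falls below one, so
the zero-match floor dominates the estimate and the estimator loses
(and can even invert) its coupling response; the reduced preset
therefore widens the tolerance to ``r = 0.3``, which restores an
adequate match count.  The epoch-count minimum is relaxed to 8 so a
single amplitude-rejected epoch does not blank a 10-epoch condition.
"""

from __future__ import annotations

from .core import EmbeddingParams
from .pipeline import PipelineConfig
from .simulate import TrialDesign

__all__ = [
    "study_design",
    "study_config",
    "reduced_design",
    "reduced_config",
]


def study_design(n_per_arm: int = 12) -> TrialDesign:
    """Trial design at the source study's recording geometry."""
    return TrialDesign(
        n_per_arm=n_per_arm, rate=500.0, rest_duration=300.0, task_duration=60.0
    )


def study_config() -> PipelineConfig:
    """Pipeline settings for study-scale recordings (N=1000 epochs, r=0.2)."""
    return PipelineConfig(params=EmbeddingParams(m=2, r_frac=0.2, lag=1, epoch_len=1000))


def reduced_design(n_per_arm: int = 12) -> TrialDesign:
    """Down-scaled design for simulation studies (125 Hz, 20 s/condition)."""
    return TrialDesign(
        n_per_arm=n_per_arm, rate=125.0, rest_duration=20.0, task_duration=20.0
    )


def reduced_config() -> PipelineConfig:
    """Pipeline settings matched to :func:`reduced_design` (N=250, r=0.3)."""
    return PipelineConfig(
        min_epochs=8,
        params=EmbeddingParams(m=2, r_frac=0.3, lag=1, epoch_len=250),
    )
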