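"""Seeded synthetic data for the two-arm speech-rehabilitation trial.

Nothing of the source study's raw EEG or clinical records is public,
so this module generates datasets that carry the statistical structure
the analysis pipeline assumes: 2 arms x 2 timepoints (baseline, post)
x 2 eyes-closed conditions (rest, syllable-repetition task), with
10-channel recordings whose pairwise coupling is controlled, plus
per-subject covariates and five speech subtest scores drawn from the
trial's printed summary statistics.

Coupling mechanism
------------------
Channels are band-limited (1-45 Hz) mixtures of independent AR(2)
latent sources plus white private noise.  The requested pairwise
couplings define a target channel correlation matrix ``R`` (diagonal
1, unrequested pairs at a background level).  ``R`` is split as

    R = C + d I,   d = min eigenvalue of R,

with the rank-reduced part ``C`` realized by *smooth* AR(2) sources
(via its eigendecomposition) and the diagonal remainder ``d`` by
white noise, topped by a small white sensor-noise floor.  The split
matters: C-ApEn discriminates a smooth shared waveform against
template-scale-independent (white) channel-private activity, whereas
smooth channel-private activity masks coupling entirely.  Putting as
much variance as possible into the white part (the minimum-trace
split) maximizes the estimator's sensitivity to the programmed
couplings, and the construction is exactly feasible whenever ``R`` is
positive semidefinite (violations raise and name the most implicated
channels).  Under this construction mean pair C-ApEn decreases
monotonically in the pair's coupling: more shared waveform, less
asynchrony.

Within a subject the white/smooth split is held constant across the
four sessions, and treatment effects are realized as *additive*
dedicated smooth sources shared by a programmed pair's two channels
during post-treatment rest recordings (channels renormalized to unit
variance).  Strengthened rest-phase coupling lowers rest C-ApEn and
thereby raises the task-minus-rest difference value, reproducing the
trial's task-related activation pattern without disturbing the
global signal composition that all other pairs see.

The default effect topology mirrors the trial's findings: five
left-hemisphere pairs in the active arm; two right-hemisphere and
two interhemispheric pairs in the control arm.  The effect magnitude
is the variance of the added pair source; :func:`calibrate_effect`
maps it empirically onto a target between-arm change-score effect
size, since no closed form links coupling to C-ApEn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .montage import CHANNEL_ORDER, build_default_montage, pair_name

__all__ = [
    "TrialDesign",
    "EffectSpec",
    "TrialDataset",
    "simulate_trial",
    "simulate_subjects",
    "simulate_recording",
    "calibrate_effect",
    "TIMEPOINTS",
    "CONDITIONS",
    "SPEECH_TESTS",
]

TIMEPOINTS = ("baseline", "post")
CONDITIONS = ("rest", "task")
ARMS = ("tDCS", "control")

#: speech subtest -> (score range lo, hi)
SPEECH_TESTS: dict[str, tuple[float, float]] = {
    "counting": (0, 10),
    "imitation": (0, 20),
    "alphabet": (0, 20),
    "mono": (0, 10),
    "di": (0, 10),
}

# Printed per-arm summary statistics used as generator parameters:
# speech subtests (baseline mean, SD, post mean, SD) ...
_SCORE_PARAMS = {
    "tDCS": {
        "counting": (3.58, 4.17, 7.25, 3.02),
        "imitation": (4.88, 3.00, 10.50, 3.85),
        "alphabet": (2.58, 3.45, 9.08, 4.03),
        "mono": (1.00, 2.37, 6.00, 3.28),
        "di": (0.75, 2.05, 4.67, 3.08),
    },
    "control": {
        "counting": (1.67, 3.14, 5.50, 3.83),
        "imitation": (5.38, 2.87, 6.58, 3.35),
        "alphabet": (2.00, 3.05, 4.75, 2.70),
        "mono": (0.75, 2.01, 2.50, 2.07),
        "di": (0.58, 1.16, 2.00, 2.17),
    },
}

# ... and covariates: (mean, SD, truncation lo, hi)
_COVARIATE_PARAMS = {
    "tDCS": {
        "age": (47.42, 10.87, 18.0, 80.0),
        "education": (12.25, 2.90, 0.0, 22.0),
        "lesion_size": (64.42, 13.92, 5.0, 150.0),
        "onset_weeks": (7.5, 3.29, 2.0, 18.0),
    },
    "control": {
        "age": (52.17, 14.10, 18.0, 80.0),
        "education": (10.33, 3.47, 0.0, 22.0),
        "lesion_size": (60.00, 11.80, 5.0, 150.0),
        "onset_weeks": (5.67, 2.64, 2.0, 18.0),
    },
}
_SEX_MALE_P = {"tDCS": 10 / 12, "control": 9 / 12}
_APHASIA_TYPE_P = {"tDCS": (0.5, 1 / 3, 1 / 6), "control": (0.5, 1 / 3, 1 / 6)}
_SEVERITY_P = {"tDCS": (5 / 12, 5 / 12, 2 / 12), "control": (0.5, 1 / 3, 1 / 6)}
APHASIA_TYPES = ("Global", "Mixed", "Broca")


@dataclass(frozen=True)
class TrialDesign:
    """Sizes, sampling and durations of one simulated trial.

    Defaults are the study conditions: 12 subjects per arm, 500 Hz,
    about five minutes of eyes-closed rest and one minute of the
    repetition task per session.
    """

    n_per_arm: int = 12
    rate: float = 500.0
    rest_duration: float = 300.0
    task_duration: float = 60.0
    epoch_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        min_dur = 10 * self.epoch_seconds
        if self.rest_duration < min_dur or self.task_duration < min_dur:
            raise ValueError(
                f"each condition needs at least 10 epochs' worth of signal "
                f"({min_dur:g} s at {self.epoch_seconds:g} s epochs)"
            )

    def n_samples(self, condition: str) -> int:
        dur = self.rest_duration if condition == "rest" else self.task_duration
        return int(round(dur * self.rate))


#: pairs whose task recordings decouple post-treatment, per arm
DEFAULT_TDCS_PAIRS: tuple[tuple[str, str], ...] = (
    ("F3", "F7"),
    ("F7", "C3"),
    ("P3", "F7"),
    ("T5", "P3"),
    ("T5", "F7"),
)
DEFAULT_CONTROL_PAIRS: tuple[tuple[str, str], ...] = (
    ("F8", "C4"),
    ("T6", "F8"),
    ("F3", "F4"),
    ("F7", "F8"),
)


@dataclass(frozen=True)
class EffectSpec:
    """Coupling structure and treatment effects of the generator.

    All couplings are dimensionless channel correlations in [0, 1].
    ``post_rest_delta`` is the variance of a dedicated smooth source
    added to both channels of each programmed pair in the arm's
    post-treatment rest recordings: consolidated resting-state
    coupling lowers rest C-ApEn, which raises the task-minus-rest
    difference value — the direction the trial reports as
    task-related network activation.  The default magnitude is
    nominal; :func:`calibrate_effect` replaces it with the value that
    realizes a target between-arm effect size.
    """

    base_coupling: float = 0.6
    baseline_task_offset: float = -0.02
    post_rest_delta: float = 0.1
    tdcs_pairs: tuple[tuple[str, str], ...] = DEFAULT_TDCS_PAIRS
    control_pairs: tuple[tuple[str, str], ...] = DEFAULT_CONTROL_PAIRS
    subject_sd: float = 0.02
    condition_jitter_sd: float = 0.02
    sensor_noise: float = 0.02
    score_rho: float = 0.5
    coupling_max: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_coupling <= 1.0:
            raise ValueError("base_coupling must lie in [0, 1]")
        if not 0.0 <= self.score_rho < 1.0:
            raise ValueError("score_rho must lie in [0, 1)")

    @classmethod
    def null(cls, **kwargs) -> "EffectSpec":
        """A zero-effect spec: arms are exchangeable."""
        return cls(post_rest_delta=0.0, **kwargs)

    def programmed_pairs(self, arm: str) -> tuple[tuple[str, str], ...]:
        return self.tdcs_pairs if arm == "tDCS" else self.control_pairs


@dataclass
class TrialDataset:
    """One simulated trial: subject table, recordings and ground truth."""

    subjects: pd.DataFrame
    recordings: dict[tuple[str, str, str], np.ndarray]
    coupling_truth: pd.DataFrame
    design: TrialDesign
    effects: EffectSpec
    seed: int
    channels: tuple[str, ...] = CHANNEL_ORDER

    def recording(self, subject: str, timepoint: str, condition: str) -> np.ndarray:
        return self.recordings[(subject, timepoint, condition)]


# ---------------------------------------------------------------------------
# subjects


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    for _ in range(1000):
        draw = rng.normal(mean, sd, size=size * 2)
        keep = draw[(draw >= lo) & (draw <= hi)][: size - filled]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
        if filled == size:
            return out
    out[filled:] = np.clip(rng.normal(mean, sd, size - filled), lo, hi)
    return out


def _truncated_bivariate(rng, mean1, sd1, mean2, sd2, rho, lo, hi):
    """One (baseline, post) score pair from a truncated bivariate normal."""
    for _ in range(1000):
        z1, z2 = rng.standard_normal(2)
        z2 = rho * z1 + np.sqrt(1 - rho * rho) * z2
        x1 = mean1 + sd1 * z1
        x2 = mean2 + sd2 * z2
        if lo <= x1 <= hi and lo <= x2 <= hi:
            return x1, x2
    return float(np.clip(x1, lo, hi)), float(np.clip(x2, lo, hi))


def simulate_subjects(
    design: TrialDesign, effects: EffectSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-subject covariates and speech scores for both arms.

    Covariates come from truncated normals / categorical frequencies
    matching the trial's baseline table; the five subtest scores are
    truncated bivariate normals with the arm-specific printed
    means/SDs at each timepoint and within-subject baseline-post
    correlation ``effects.score_rho``.  Scores may decline.
    """
    rows = []
    for arm in ARMS:
        cov = _COVARIATE_PARAMS[arm]
        n = design.n_per_arm
        age = _truncated_normal(rng, *cov["age"], n)
        edu = _truncated_normal(rng, *cov["education"], n)
        lesion = _truncated_normal(rng, *cov["lesion_size"], n)
        onset = _truncated_normal(rng, *cov["onset_weeks"], n)
        sex = rng.random(n) < _SEX_MALE_P[arm]
        atype = rng.choice(3, size=n, p=_APHASIA_TYPE_P[arm])
        sev = rng.choice(3, size=n, p=_SEVERITY_P[arm])
        for i in range(n):
            sid = f"{'T' if arm == 'tDCS' else 'C'}{i + 1:02d}"
            row = {
                "subject": sid,
                "arm": arm,
                "age": round(float(age[i]), 1),
                "sex": "male" if sex[i] else "female",
                "education": round(float(edu[i]), 1),
                "lesion_size": round(float(lesion[i]), 1),
                "onset_weeks": round(float(onset[i]), 1),
                "aphasia_type": APHASIA_TYPES[atype[i]],
                "severity": int(sev[i]),
            }
            for test, (lo, hi) in SPEECH_TESTS.items():
                m1, s1, m2, s2 = _SCORE_PARAMS[arm][test]
                b, p = _truncated_bivariate(
                    rng, m1, s1, m2, s2, effects.score_rho, lo, hi
                )
                row[f"{test}_baseline"] = round(b, 1)
                row[f"{test}_post"] = round(p, 1)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recordings


def _ar2_sources(rng, n_sources: int, n_samples: int, rate: float) -> np.ndarray:
    """Independent unit-variance AR(2) sources, smooth with a ~6 Hz peak."""
    theta = 2.0 * np.pi * 6.0 / rate
    radius = 0.95
    a = [1.0, -2.0 * radius * np.cos(theta), radius * radius]
    burn = 300
    noise = rng.standard_normal((n_sources, n_samples + burn))
    src = spsig.lfilter([1.0], a, noise, axis=1)[:, burn:]
    sd = src.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return src / sd


from functools import lru_cache


@lru_cache(maxsize=32)
def _bandlimit_sos(rate: float, lo: float, hi: float):
    nyq = rate / 2.0
    hi = min(hi, 0.95 * nyq)
    return spsig.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")


def _bandlimit(x: np.ndarray, rate: float, band=(1.0, 45.0)) -> np.ndarray:
    return spsig.sosfiltfilt(_bandlimit_sos(rate, band[0], band[1]), x, axis=0)


def _build_correlation(coupling, background: float) -> np.ndarray:
    channels = list(CHANNEL_ORDER)
    ch_index = {c: k for k, c in enumerate(channels)}
    n_ch = len(channels)
    R = np.full((n_ch, n_ch), float(background))
    np.fill_diagonal(R, 1.0)
    for p, c in coupling.items():
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"coupling for {pair_name(p)} is {c}, outside [0, 1]")
        if p[0] not in ch_index or p[1] not in ch_index:
            raise ValueError(f"pair {pair_name(p)} uses unknown channels")
        i, j = ch_index[p[0]], ch_index[p[1]]
        R[i, j] = R[j, i] = float(c)
    return R


def _check_feasible(R: np.ndarray, coupling) -> np.ndarray:
    """Eigenvalues of R, raising a named error when R is not PSD."""
    channels = list(CHANNEL_ORDER)
    lam, vec = np.linalg.eigh(R)
    if lam[0] < -1e-8:
        v = np.abs(vec[:, 0])
        worst = [channels[k] for k in np.argsort(v)[::-1][:3]]
        bad_pairs = [
            pair_name(p) for p in coupling if p[0] in worst or p[1] in worst
        ]
        raise ValueError(
            "infeasible coupling pattern (correlation matrix not positive "
            f"semidefinite; min eigenvalue {lam[0]:.3f}); most implicated "
            f"channels {', '.join(worst)} via pairs {', '.join(bad_pairs)}"
        )
    return lam


def simulate_recording(
    coupling: dict[tuple[str, str], float],
    n_samples: int,
    rate: float,
    rng: np.random.Generator,
    background: float = 0.0,
    sensor_noise: float = 0.02,
    white_var: float | None = None,
    extra_smooth: dict[tuple[str, str], float] | None = None,
    band=(1.0, 45.0),
) -> np.ndarray:
    """One 10-channel recording realizing the requested pairwise coupling.

    ``coupling`` maps electrode pairs to channel correlations in
    [0, 1]; unlisted pairs sit at ``background``.  Returns an
    ``(n_samples, 10)`` array in montage channel order.  The implied
    correlation matrix is split into a smooth AR(2) layer plus a white
    diagonal of variance ``white_var`` (default: the largest feasible
    value, the matrix's minimum eigenvalue; see module docstring); a
    small white ``sensor_noise`` variance fraction is stirred in on
    top, so realized channel correlations are the requested ones
    scaled by ``1 - sensor_noise``.  Raises if a coupling lies outside
    [0, 1] or if the requested pattern is not positive semidefinite,
    naming the most implicated channels.
    """
    R = _build_correlation(coupling, background)
    lam = _check_feasible(R, coupling)
    vec = np.linalg.eigh(R)[1]
    n_ch = R.shape[0]
    if white_var is None:
        white_var = float(max(0.0, lam[0]))
    elif white_var > lam[0] + 1e-8:
        raise ValueError(
            f"white_var {white_var:.3f} exceeds the feasible maximum "
            f"{lam[0]:.3f} for this coupling pattern"
        )
    loadings = vec * np.sqrt(np.clip(lam - white_var, 0.0, None))
    sources = _ar2_sources(rng, n_ch, n_samples, rate)
    data = (loadings @ sources).T
    if white_var > 0:
        data = data + np.sqrt(white_var) * rng.standard_normal((n_samples, n_ch))
    if extra_smooth:
        # dedicated shared smooth sources on top of the base mixture;
        # channels are renormalized to unit variance afterwards
        channels = list(CHANNEL_ORDER)
        ch_index = {c: k for k, c in enumerate(channels)}
        extra_var = np.zeros(n_ch)
        pair_src = _ar2_sources(rng, len(extra_smooth), n_samples, rate)
        for k, (p, dv) in enumerate(extra_smooth.items()):
            if dv < 0:
                raise ValueError(f"extra smooth variance for {pair_name(p)} is negative")
            i, j = ch_index[p[0]], ch_index[p[1]]
            data[:, i] += np.sqrt(dv) * pair_src[k]
            data[:, j] += np.sqrt(dv) * pair_src[k]
            extra_var[i] += dv
            extra_var[j] += dv
        data = data / np.sqrt(1.0 + extra_var)[None, :]
    if sensor_noise > 0:
        data = (
            np.sqrt(1.0 - sensor_noise) * data
            + np.sqrt(sensor_noise) * rng.standard_normal((n_samples, n_ch))
        )
    return _bandlimit(data, rate, band)


def _all_channel_pairs() -> list[tuple[str, str]]:
    chans = list(CHANNEL_ORDER)
    return [
        (chans[i], chans[j])
        for i in range(len(chans))
        for j in range(i + 1, len(chans))
    ]


def _subject_couplings(
    effects: EffectSpec,
    arm: str,
    rng: np.random.Generator,
    pair_set,
) -> dict[tuple[str, str], dict[tuple[str, str], float]]:
    """Per (timepoint, condition) coupling maps for one subject.

    Every channel pair carries the background coupling with jitter;
    the montage pairs in ``pair_set`` additionally carry the subject's
    persistent offset, the task offset, and (post, task, programmed
    pairs only) the treatment decrement.
    """
    programmed = effects.programmed_pairs(arm)
    montage = {frozenset(p) for p in pair_set}
    all_pairs = _all_channel_pairs()
    subj_offset = {
        frozenset(p): rng.normal(0.0, effects.subject_sd) for p in pair_set
    }
    out = {}
    extras = {}
    for tp in TIMEPOINTS:
        for cond in CONDITIONS:
            cmap = {}
            for p in all_pairs:
                key = frozenset(p)
                c = effects.base_coupling
                c += rng.normal(0.0, effects.condition_jitter_sd)
                if key in montage:
                    c += subj_offset[key]
                    if cond == "task":
                        c += effects.baseline_task_offset
                cmap[p] = float(np.clip(c, 0.0, effects.coupling_max))
            out[(tp, cond)] = cmap
            if tp == "post" and cond == "rest" and effects.post_rest_delta > 0:
                extras[(tp, cond)] = {
                    p: effects.post_rest_delta for p in programmed
                }
            else:
                extras[(tp, cond)] = {}
    return out, extras


def _effective_coupling(cmap: dict, extra: dict) -> dict:
    """Realized channel correlations after the additive effect sources."""
    load: dict[str, float] = {}
    for (a, b), dv in extra.items():
        load[a] = load.get(a, 0.0) + dv
        load[b] = load.get(b, 0.0) + dv
    ex = {frozenset(p): dv for p, dv in extra.items()}
    out = {}
    for p, c in cmap.items():
        num = c + ex.get(frozenset(p), 0.0)
        den = np.sqrt((1.0 + load.get(p[0], 0.0)) * (1.0 + load.get(p[1], 0.0)))
        out[p] = float(num / den)
    return out


def _subject_recordings(
    design: TrialDesign,
    effects: EffectSpec,
    arm: str,
    rng: np.random.Generator,
    pair_set,
) -> tuple[dict[tuple[str, str], np.ndarray], dict]:
    """All four recordings for one subject, with per-subject white split.

    The white/smooth variance split is held constant across the
    subject's four sessions (at the largest value feasible for all
    four coupling matrices), so condition contrasts reflect the
    programmed pairwise couplings rather than session-to-session
    changes in global signal composition.  Treatment effects ride on
    dedicated additive smooth pair sources, leaving the split intact.
    """
    cmaps, extras = _subject_couplings(effects, arm, rng, pair_set)
    lam_min = min(
        _check_feasible(_build_correlation(cmap, 0.0), cmap).min()
        for cmap in cmaps.values()
    )
    white = float(max(0.0, lam_min))
    rec = {
        (tp, cond): simulate_recording(
            cmaps[(tp, cond)],
            design.n_samples(cond),
            design.rate,
            rng,
            sensor_noise=effects.sensor_noise,
            white_var=white,
            extra_smooth=extras[(tp, cond)],
        )
        for tp in TIMEPOINTS
        for cond in CONDITIONS
    }
    return rec, (cmaps, extras)


def simulate_trial(
    design: TrialDesign,
    effects: EffectSpec | None = None,
    seed: int = 0,
    with_recordings: bool = True,
) -> TrialDataset:
    """Generate one full trial dataset, bit-reproducible for a fixed seed."""
    effects = effects or EffectSpec()
    _, pair_set = build_default_montage()
    root = np.random.SeedSequence(seed)
    subj_rng = np.random.default_rng(root.spawn(1)[0])
    subjects = simulate_subjects(design, effects, subj_rng)

    recordings: dict[tuple[str, str, str], np.ndarray] = {}
    truth_rows = []
    rec_seeds = root.spawn(len(subjects))
    for (_, subj), seq in zip(subjects.iterrows(), rec_seeds):
        rng = np.random.default_rng(seq)
        if with_recordings:
            rec, (cmaps, extras) = _subject_recordings(
                design, effects, subj["arm"], rng, list(pair_set)
            )
            for key, arr in rec.items():
                recordings[(subj["subject"],) + key] = arr
        else:
            cmaps, extras = _subject_couplings(
                effects, subj["arm"], rng, list(pair_set)
            )
        for tp in TIMEPOINTS:
            for cond in CONDITIONS:
                eff_map = {
                    frozenset(k): v
                    for k, v in _effective_coupling(
                        cmaps[(tp, cond)], extras[(tp, cond)]
                    ).items()
                }
                ex = {frozenset(k): v for k, v in extras[(tp, cond)].items()}
                for p in pair_set:
                    truth_rows.append(
                        {
                            "subject": subj["subject"],
                            "timepoint": tp,
                            "condition": cond,
                            "pair": pair_name(p),
                            "coupling": eff_map[frozenset(p)],
                            "shared_extra": ex.get(frozenset(p), 0.0),
                        }
                    )
    return TrialDataset(
        subjects=subjects,
        recordings=recordings,
        coupling_truth=pd.DataFrame(truth_rows),
        design=design,
        effects=effects,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# effect-size calibration


def calibrate_effect(
    design: TrialDesign,
    effects: EffectSpec,
    config=None,
    target_d: float = 1.0,
    n_pilot: int = 300,
    probe: float = 0.1,
    seed: int = 0,
    refine: bool = True,
) -> EffectSpec:
    """Choose ``post_rest_delta`` so the active arm's programmed pairs
    carry a between-arm change-score effect size of ``target_d``.

    No closed form links a coupling increment to a C-ApEn change, so
    the mapping is measured: pilot batches of subjects from *both*
    arms are simulated at a probe delta (and a zero-delta reference),
    the pipeline's change scores on the active arm's programmed pairs
    give the between-arm shift — including the leakage of the control
    arm's own programmed effect into those pairs — and its pooled SD,
    and the delta is set by linear scaling (optionally refined with a
    second pilot at the proposed delta).  Returns a copy of
    ``effects`` with the calibrated increment.
    """
    from .pipeline import PipelineConfig, subject_change_scores

    config = config or PipelineConfig.for_design(design)
    pairs = effects.tdcs_pairs
    _, pair_set = build_default_montage()
    montage_pairs = list(pair_set)
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(seed)

    def batch(delta: float, arm: str, seq) -> np.ndarray:
        spec = replace(effects, post_rest_delta=delta)
        vals = []
        rngs = seq.spawn(n_pilot)
        for child in rngs:
            rng = np.random.default_rng(child)
            rec, _ = _subject_recordings(design, spec, arm, rng, montage_pairs)
            vals.append(subject_change_scores(rec, pairs, config))
        return np.asarray(vals)  # (n_pilot, n_pairs)

    def contrast(delta: float, seq) -> float:
        """Mean per-pair between-arm effect size at this delta."""
        s1, s2 = seq.spawn(2)
        active = batch(delta, "tDCS", s1)
        control = batch(delta, "control", s2)
        shift = active.mean(axis=0) - control.mean(axis=0)
        sd = np.sqrt(
            (active.std(axis=0, ddof=1) ** 2 + control.std(axis=0, ddof=1) ** 2)
            / 2.0
        )
        return float(np.mean(shift / sd))

    seqs = root.spawn(2)
    achieved = contrast(probe, seqs[0])
    if achieved <= 0:
        raise RuntimeError("probe delta produced no positive between-arm shift")
    delta = probe * target_d / achieved
    if refine:
        achieved2 = contrast(delta, seqs[1])
        if achieved2 > 0:
            delta *= target_d / achieved2
    return replace(effects, post_rest_delta=float(delta))
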