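"""End-to-end validation experiments.

Collects the package's standing Monte-Carlo checks in one place so the
test suite and the reproduction script run the same code: worked
examples recomputed from the trial's printed summary statistics,
brute-force oracle agreement for the C-ApEn kernel, coupling
monotonicity of the estimator under a common-source model, full
pipeline effect-pattern recovery and null calibration, and the
regression screening rule's retention rate under pure noise.

Problem sizes here are the package's reduced validation scale (see
:mod:`capen.presets`); the experiments are seeded and deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .core import EmbeddingParams, cross_apen, cross_apen_naive
from .montage import PairSet, build_default_montage, pair_name
from .pipeline import Recording, connectivity_table
from .presets import reduced_config, reduced_design
from .simulate import EffectSpec, calibrate_effect, simulate_trial
from .stats import (
    chi_square,
    cohens_d_pooled,
    paired_t_power,
    route_and_compare,
    screen_then_model,
    two_sample_t_power,
)

__all__ = [
    "worked_examples",
    "oracle_max_error",
    "coupling_monotonicity",
    "effect_recovery",
    "null_type_one_error",
    "screening_retention",
]


def worked_examples() -> dict:
    """Recompute the trial's printed worked examples.

    Pooled-SD effect sizes from printed means/SDs of the four report
    tables, Pearson chi-square p-values from the printed baseline
    contingency counts, and the paired-design achieved power from the
    published planning parameters (dz = 1.0, n = 11, alpha = 0.05;
    the printed 0.924 is the one-sided value).
    """
    out = {
        # speech subtests: post vs baseline (within arm), change (between arms)
        "d_mono_post_vs_baseline_tdcs": cohens_d_pooled(6.00, 3.28, 1.00, 2.37),
        "d_alphabet_post_vs_baseline_control": cohens_d_pooled(4.75, 2.70, 2.00, 3.05),
        "d_imitation_change_between_arms": cohens_d_pooled(5.63, 2.41, 1.21, 2.10),
        "d_mono_change_between_arms": cohens_d_pooled(5.00, 3.10, 1.75, 1.91),
        # connectivity difference values and change scores
        "d_f3f7_post_vs_baseline_tdcs": cohens_d_pooled(0.12, 0.09, 0.03, 0.05),
        "d_f8c4_post_vs_baseline_control": cohens_d_pooled(0.04, 0.06, -0.01, 0.05),
        "d_f3f7_change_between_arms": cohens_d_pooled(0.09, 0.10, 0.00, 0.06),
        "d_t5p3_change_between_arms": cohens_d_pooled(0.06, 0.08, -0.01, 0.04),
        # baseline categorical comparability
        "chi2_p_sex": chi_square([[10, 2], [9, 3]]).p_value,
        "chi2_p_insula": chi_square([[2, 10], [1, 11]]).p_value,
        "chi2_p_severity": chi_square([[5, 5, 2], [6, 4, 2]]).p_value,
        # sample-size planning
        "paired_power_dz1_n11": paired_t_power(1.0, 11, 0.05, alternative="larger"),
    }
    return out


def oracle_max_error(
    n_pairs: int = 50, max_len: int = 300, seed: int = 0
) -> float:
    """Worst absolute disagreement between the optimized C-ApEn and the
    pure-Python brute-force enumeration over random signal pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    settings = [(2, 1, 0.2), (2, 1, 0.3), (1, 1, 0.3), (2, 2, 0.3)]
    for k in range(n_pairs):
        n = int(rng.integers(120, max_len + 1))
        m, lag, r = settings[k % len(settings)]
        u = rng.standard_normal(n)
        v = rng.standard_normal(n)
        if k % 5 == 0:  # correlated pairs exercise the high-match regime
            v = 0.8 * u + 0.6 * v
        params = EmbeddingParams(m=m, r_frac=r, lag=lag, epoch_len=n)
        err = abs(cross_apen(u, v, params).value - cross_apen_naive(u, v, params))
        worst = max(worst, err)
    return worst


def coupling_monotonicity(
    alphas=(0.0, 0.3, 0.6, 0.9),
    n_rep: int = 100,
    n_samples: int = 1000,
    seed: int = 0,
) -> dict:
    """Mean C-ApEn under the common-source model as coupling grows.

    ``x = a*s + sqrt(1-a^2)*n1`` and likewise ``y``, with a smooth
    AR(1) common source (phi = 0.95) and white private noise; common
    random numbers across the coupling grid within each replicate.
    The tolerance is widened to r = 0.5 SD because at the default
    r = 0.2 the estimator has essentially no sensitivity to weak
    common-source coupling (a documented limitation).
    """
    params = EmbeddingParams(m=2, r_frac=0.5, epoch_len=n_samples)
    root = np.random.SeedSequence(seed)
    sums = {a: 0.0 for a in alphas}
    for child in root.spawn(n_rep):
        rng = np.random.default_rng(child)
        w = rng.standard_normal(n_samples + 300)
        s = spsig.lfilter([1.0], [1.0, -0.95], w)[300:]
        s /= s.std()
        n1, n2 = rng.standard_normal((2, n_samples))
        for a in alphas:
            b = np.sqrt(1.0 - a * a)
            x = a * s + b * n1
            y = a * s + b * n2
            sums[a] += cross_apen(x, y, params).value
    means = {a: sums[a] / n_rep for a in alphas}
    ordered = [means[a] for a in alphas]
    return {
        "alphas": list(alphas),
        "means": ordered,
        "strictly_decreasing": all(
            x > y for x, y in zip(ordered, ordered[1:])
        ),
    }


def _programmed_pair_set(effects: EffectSpec) -> PairSet:
    names = {pair_name(p) for p in effects.tdcs_pairs}
    _, full = build_default_montage()
    keep = [i for i, p in enumerate(full.pairs) if pair_name(p) in names]
    return PairSet(
        tuple(full.pairs[i] for i in keep),
        tuple(full.categories[i] for i in keep),
    )


def _pair_detections(dataset, config, pair_set, alpha=0.05) -> list[bool]:
    def get(sid, tp, cond):
        return Recording(
            dataset.recordings[(sid, tp, cond)],
            dataset.design.rate,
            list(dataset.channels),
        )

    table = connectivity_table(get, dataset.subjects, config, pair_set=pair_set)
    hits = []
    for _, g in table.groupby("pair", sort=False):
        a = g.loc[g["arm"] == "tDCS", "change"].dropna()
        b = g.loc[g["arm"] == "control", "change"].dropna()
        hits.append(route_and_compare(a, b).p_value < alpha)
    return hits


def effect_recovery(
    n_rep: int = 200,
    n_pilot: int = 500,
    n_per_arm: int = 12,
    seed: int = 0,
) -> dict:
    """Full-pipeline recovery of the programmed effect topology.

    The default effect spec is calibrated to a between-arm change-score
    effect size of 1.0 on the programmed left-hemisphere pairs, then
    ``n_rep`` trials are simulated and analyzed end to end; returns the
    detection frequency (two-tailed p < 0.05) averaged over the
    programmed pairs, with the theoretical two-sample-t power at
    d = 1.0 and its 95% binomial band at ``n_rep`` as reference.
    """
    design = reduced_design(n_per_arm)
    config = reduced_config()
    root = np.random.SeedSequence(seed)
    cal_seed, sim_seed = root.spawn(2)
    effects = calibrate_effect(
        design,
        EffectSpec(),
        config,
        target_d=1.0,
        n_pilot=n_pilot,
        seed=cal_seed,
    )
    prog = _programmed_pair_set(effects)
    per_rep = []
    for child in sim_seed.spawn(n_rep):
        ds = simulate_trial(
            design, effects, seed=int(child.generate_state(1)[0] % 2**31)
        )
        per_rep.append(np.mean(_pair_detections(ds, config, prog)))
    power = two_sample_t_power(1.0, n_per_arm)
    half = 1.96 * np.sqrt(power * (1.0 - power) / n_rep)
    return {
        "detection_rate": float(np.mean(per_rep)),
        "theoretical_power": float(power),
        "band": (float(power - half), float(power + half)),
        "calibrated_delta": effects.post_rest_delta,
        "n_rep": n_rep,
    }


def null_type_one_error(
    n_comparisons: int = 1000, n_per_arm: int = 12, seed: int = 0
) -> dict:
    """Pair-wise type-I error of the pipeline under a zero-effect spec."""
    design = reduced_design(n_per_arm)
    config = reduced_config()
    _, full = build_default_montage()
    n_rep = int(np.ceil(n_comparisons / len(full)))
    root = np.random.SeedSequence(seed)
    hits = []
    for child in root.spawn(n_rep):
        ds = simulate_trial(
            design,
            EffectSpec.null(),
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        hits.extend(_pair_detections(ds, config, full))
    return {
        "type_one_error": float(np.mean(hits)),
        "n_comparisons": len(hits),
    }


def screening_retention(
    n_rep: int = 1000, n_subjects: int = 24, n_candidates: int = 3, seed: int = 0
) -> dict:
    """Retention rate of pure-noise candidates at the p < 0.2 screen."""
    root = np.random.SeedSequence(seed)
    kept = 0
    total = 0
    names = [f"x{i}" for i in range(n_candidates)]
    for child in root.spawn(n_rep):
        rng = np.random.default_rng(child)
        data = pd.DataFrame(
            rng.standard_normal((n_subjects, n_candidates + 1)),
            columns=names + ["y"],
        )
        uni, _ = screen_then_model(data, "y", names)
        kept += int((uni.table["p"] < 0.2).sum())
        total += n_candidates
    rate = kept / total
    half = 1.96 * np.sqrt(0.2 * 0.8 / total)
    return {
        "retention_rate": float(rate),
        "band": (0.2 - half, 0.2 + half),
        "n": total,
    }
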