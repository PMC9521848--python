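"""Trial-level analysis presented as a model / results pair.

:class:`ConnectivityTrial` binds a per-subject, per-pair connectivity
table to the subject table; :meth:`ConnectivityTrial.fit` runs the
full statistics layer and returns a :class:`TrialResults` carrying
the report tables: baseline comparability, speech subtests within and
between arms, per-pair difference values within arms and change
scores between arms, and the regression screen for word-repetition
improvement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as st
from .montage import build_default_montage
from .simulate import APHASIA_TYPES, SPEECH_TESTS

__all__ = ["ConnectivityTrial", "TrialResults"]

_COVARIATES = ["age", "education", "lesion_size", "onset_weeks"]


def _ms(x: pd.Series) -> str:
    x = x.dropna()
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


class ConnectivityTrial:
    """Two-arm trial analysis model.

    Parameters
    ----------
    connectivity : DataFrame
        Output of :func:`capen.pipeline.connectivity_table`.
    subjects : DataFrame
        One row per subject with arm, covariates and speech scores.
    alpha : float
        Two-tailed significance level (default 0.05).
    fdr : bool
        Add Benjamini-Hochberg adjusted p-values across the 21 pairs
        (off by default; the source analysis applies no correction).
    """

    def __init__(
        self,
        connectivity: pd.DataFrame,
        subjects: pd.DataFrame,
        alpha: float = 0.05,
        fdr: bool = False,
    ):
        self.connectivity = connectivity
        self.subjects = subjects
        self.alpha = alpha
        self.fdr = fdr
        for arm in ("tDCS", "control"):
            if (subjects["arm"] == arm).sum() < 3:
                raise ValueError(f"arm {arm!r} has fewer than 3 subjects")

    @classmethod
    def from_dataset(cls, dataset, config=None, **kwargs) -> "ConnectivityTrial":
        """Build straight from a simulated :class:`TrialDataset`."""
        from .pipeline import PipelineConfig, Recording, connectivity_table

        config = config or PipelineConfig.for_design(dataset.design)

        def get(sid, tp, cond):
            arr = dataset.recordings.get((sid, tp, cond))
            if arr is None:
                return None
            return Recording(arr, dataset.design.rate, list(dataset.channels))

        table = connectivity_table(get, dataset.subjects, config)
        return cls(table, dataset.subjects, **kwargs)

    # -- pieces -----------------------------------------------------------

    def _arm(self, arm: str) -> pd.DataFrame:
        return self.subjects[self.subjects["arm"] == arm]

    def _baseline_table(self) -> pd.DataFrame:
        rows = []
        a, b = self._arm("tDCS"), self._arm("control")
        for var in _COVARIATES:
            res = st.route_and_compare(a[var], b[var])
            rows.append(
                {
                    "variable": var,
                    "tDCS": _ms(a[var]),
                    "control": _ms(b[var]),
                    "test": res.test_name,
                    "p": res.p_value,
                }
            )
        cats = [
            ("sex", ["male", "female"]),
            ("aphasia_type", list(APHASIA_TYPES)),
            ("severity", [0, 1, 2]),
        ]
        for var, levels in cats:
            counts = np.array(
                [[(g[var] == lv).sum() for lv in levels] for g in (a, b)]
            )
            keep = counts.sum(axis=0) > 0
            if keep.sum() >= 2:  # a one-level variable has nothing to test
                res = st.chi_square(counts[:, keep])
                test_name, p = res.test_name, res.p_value
            else:
                test_name, p = "Pearson chi-square", np.nan
            rows.append(
                {
                    "variable": var,
                    "tDCS": "/".join(str(c) for c in counts[0]),
                    "control": "/".join(str(c) for c in counts[1]),
                    "test": test_name,
                    "p": p,
                }
            )
        for test in SPEECH_TESTS:
            col = f"{test}_baseline"
            res = st.route_and_compare(a[col], b[col])
            rows.append(
                {
                    "variable": col,
                    "tDCS": _ms(a[col]),
                    "control": _ms(b[col]),
                    "test": res.test_name,
                    "p": res.p_value,
                }
            )
        return pd.DataFrame(rows).set_index("variable")

    def _speech_within(self) -> pd.DataFrame:
        rows = []
        for arm in ("tDCS", "control"):
            g = self._arm(arm)
            for test in SPEECH_TESTS:
                base, post = g[f"{test}_baseline"], g[f"{test}_post"]
                res = st.route_and_compare(post, base, paired=True)
                rows.append(
                    {
                        "arm": arm,
                        "test": test,
                        "baseline": _ms(base),
                        "post": _ms(post),
                        "p": res.p_value,
                        "effect_size": st.cohens_d_pooled(
                            post.mean(), post.std(ddof=1), base.mean(), base.std(ddof=1)
                        ),
                    }
                )
        return pd.DataFrame(rows).set_index(["arm", "test"])

    def _speech_between(self) -> pd.DataFrame:
        rows = []
        a, b = self._arm("tDCS"), self._arm("control")
        for test in SPEECH_TESTS:
            ca = a[f"{test}_post"] - a[f"{test}_baseline"]
            cb = b[f"{test}_post"] - b[f"{test}_baseline"]
            res = st.route_and_compare(ca, cb)
            rows.append(
                {
                    "test": test,
                    "tDCS_change": _ms(ca),
                    "control_change": _ms(cb),
                    "p": res.p_value,
                    "effect_size": res.effect_size,
                }
            )
        return pd.DataFrame(rows).set_index("test")

    def _pair_within(self) -> pd.DataFrame:
        rows = []
        for arm in ("tDCS", "control"):
            t = self.connectivity[self.connectivity["arm"] == arm]
            for pair, g in t.groupby("pair", sort=False):
                base = g["diff_baseline"].dropna()
                post = g["diff_post"].dropna()
                ok = g[["diff_baseline", "diff_post"]].dropna()
                row = {
                    "arm": arm,
                    "pair": pair,
                    "category": g["category"].iloc[0],
                    "baseline": _ms(g["diff_baseline"]),
                    "post": _ms(g["diff_post"]),
                    "n": len(ok),
                }
                if len(ok) >= 3:
                    res = st.route_and_compare(
                        ok["diff_post"], ok["diff_baseline"], paired=True
                    )
                    row["p"] = res.p_value
                    row["effect_size"] = (
                        st.cohens_d_pooled(
                            post.mean(), post.std(ddof=1), base.mean(), base.std(ddof=1)
                        )
                        if post.std(ddof=1) > 0 or base.std(ddof=1) > 0
                        else 0.0
                    )
                else:
                    row["p"] = np.nan
                    row["effect_size"] = np.nan
                rows.append(row)
        df = pd.DataFrame(rows).set_index(["arm", "pair"])
        if self.fdr:
            for arm in ("tDCS", "control"):
                df.loc[arm, "p_adj"] = st.benjamini_hochberg(df.loc[arm, "p"]).tolist()
        return df

    def _pair_between(self) -> pd.DataFrame:
        rows = []
        t = self.connectivity
        for pair, g in t.groupby("pair", sort=False):
            ca = g.loc[g["arm"] == "tDCS", "change"].dropna()
            cb = g.loc[g["arm"] == "control", "change"].dropna()
            row = {
                "pair": pair,
                "category": g["category"].iloc[0],
                "tDCS_change": _ms(g.loc[g["arm"] == "tDCS", "change"]),
                "control_change": _ms(g.loc[g["arm"] == "control", "change"]),
                "n_tDCS": len(ca),
                "n_control": len(cb),
            }
            if len(ca) >= 3 and len(cb) >= 3:
                res = st.route_and_compare(ca, cb)
                row["p"] = res.p_value
                row["effect_size"] = res.effect_size
            else:
                row["p"] = np.nan
                row["effect_size"] = np.nan
            rows.append(row)
        df = pd.DataFrame(rows).set_index("pair")
        if self.fdr:
            df["p_adj"] = st.benjamini_hochberg(df["p"])
        return df

    def _regression(self):
        s = self.subjects.copy()
        s["word_repetition_change"] = (
            s["mono_post"] + s["di_post"] - s["mono_baseline"] - s["di_baseline"]
        )
        s["group"] = (s["arm"] == "tDCS").astype(float)
        s["sex_male"] = (s["sex"] == "male").astype(float)
        s["aphasia_type_code"] = s["aphasia_type"].map(
            {t: i for i, t in enumerate(APHASIA_TYPES)}
        ).astype(float)
        candidates = [
            "age",
            "sex_male",
            "education",
            "lesion_size",
            "onset_weeks",
            "aphasia_type_code",
            "severity",
        ]
        s["severity"] = s["severity"].astype(float)
        return st.screen_then_model(
            s, "word_repetition_change", candidates, group="group"
        )

    def fit(self) -> "TrialResults":
        uni, multi = self._regression()
        return TrialResults(
            model=self,
            baseline_table=self._baseline_table(),
            speech_within=self._speech_within(),
            speech_between=self._speech_between(),
            pair_within=self._pair_within(),
            pair_between=self._pair_between(),
            regression_univariate=uni,
            regression_multivariate=multi,
        )


@dataclass
class TrialResults:
    """Fitted trial analysis: report tables plus convenience accessors."""

    model: ConnectivityTrial
    baseline_table: pd.DataFrame
    speech_within: pd.DataFrame
    speech_between: pd.DataFrame
    pair_within: pd.DataFrame
    pair_between: pd.DataFrame
    regression_univariate: st.RegressionResult
    regression_multivariate: st.RegressionResult

    @property
    def alpha(self) -> float:
        return self.model.alpha

    def significant_pairs(self, arm: str) -> list[str]:
        """Pairs whose within-arm baseline->post difference change is significant."""
        t = self.pair_within.loc[arm]
        return list(t.index[t["p"] < self.alpha])

    def significant_between(self) -> list[str]:
        t = self.pair_between
        return list(t.index[t["p"] < self.alpha])

    def summary(self) -> str:
        lines = []
        lines.append("Two-arm C-ApEn connectivity trial analysis")
        lines.append("=" * 58)
        n = self.model.subjects.groupby("arm").size()
        lines.append(
            f"Subjects: tDCS n={n.get('tDCS', 0)}, control n={n.get('control', 0)}; "
            f"alpha={self.alpha} (two-tailed)"
        )
        lines.append("")
        lines.append("Within-arm significant pairs (difference value, baseline->post):")
        for arm in ("tDCS", "control"):
            sig = ", ".join(self.significant_pairs(arm)) or "none"
            lines.append(f"  {arm:8s}: {sig}")
        sig = ", ".join(self.significant_between()) or "none"
        lines.append(f"Between-arm significant change-score pairs: {sig}")
        lines.append("")
        lines.append("Speech subtests, between-arm change comparison:")
        for test, row in self.speech_between.iterrows():
            lines.append(
                f"  {test:10s} tDCS {row['tDCS_change']:>14s}  control "
                f"{row['control_change']:>14s}  p={row['p']:.3f}  d={row['effect_size']:.3f}"
            )
        m = self.regression_multivariate
        grp = m.table.loc["group"] if "group" in m.table.index else None
        if grp is not None:
            lines.append("")
            lines.append(
                f"Multivariate OLS for word-repetition change: group B={grp['B']:.3f} "
                f"(SE {grp['SE']:.3f}), b={grp['b']:.3f}, p={grp['p']:.3f}, "
                f"R2={m.r_squared:.3f}"
            )
        return "\n".join(lines)

    def plot_network(self, arm: str = "tDCS", ax=None):
        """Schematic montage graph with the arm's significant pairs in bold."""
        import matplotlib.pyplot as plt

        pos = {
            "F3": (-0.5, 1.0), "F4": (0.5, 1.0),
            "F7": (-1.0, 0.6), "F8": (1.0, 0.6),
            "C3": (-0.6, 0.1), "C4": (0.6, 0.1),
            "T5": (-1.0, -0.6), "T6": (1.0, -0.6),
            "P3": (-0.5, -0.4), "P4": (0.5, -0.4),
        }
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        _, pair_set = build_default_montage()
        sig = set(self.significant_pairs(arm))
        from .montage import pair_name

        for p in pair_set:
            x = [pos[p[0]][0], pos[p[1]][0]]
            y = [pos[p[0]][1], pos[p[1]][1]]
            if pair_name(p) in sig:
                ax.plot(x, y, "r-", lw=2.5, zorder=2)
            else:
                ax.plot(x, y, color="0.8", lw=0.8, zorder=1)
        for ch, (x, y) in pos.items():
            ax.plot(x, y, "o", color="0.2", ms=14, zorder=3)
            ax.annotate(ch, (x, y), color="w", ha="center", va="center", fontsize=7, zorder=4)
        ax.set_title(f"{arm}: significant difference-value pairs")
        ax.set_axis_off()
        return ax
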