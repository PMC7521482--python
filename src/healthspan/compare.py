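"""Group comparisons of health expectancies with bootstrap uncertainty.

Differences in TLE, CIFLE and the proportion of life CI-free between
exposure levels are point-estimated from one fit and given 95% percentile
bootstrap intervals by resampling subjects with replacement and refitting.
A deterministic rule classifies each comparison as an absolute increase,
relative increase or relative reduction in CI-free life years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .expectancy import AgeGrid, ExpectancyResult, expectancies
from .model import IllnessDeathSpec, PanelLikelihood, _fit_compiled, compile_panel


class Interval(NamedTuple):
    """Point estimate with a (lower, upper) confidence interval."""

    point: float
    lower: float
    upper: float

    def excludes_zero_below(self) -> bool:
        return self.lower > 0.0

    def excludes_zero_above(self) -> bool:
        return self.upper < 0.0


@dataclass
class DifferenceEstimate:
    """Pairwise expectancy differences (comparison level minus reference)."""

    label: str
    start_age: float
    tle: Interval
    cifle: Interval
    proportion: Interval  # percentage points
    B: int = 0
    n_failed: int = 0
    seed: int | None = None
    unreliable: bool = False

    @property
    def cile(self) -> float:
        """Point difference in impaired years; ΔTLE = ΔCIFLE + ΔCILE."""
        return self.tle.point - self.cifle.point


ABSOLUTE_INCREASE = "absolute_increase"
RELATIVE_INCREASE = "relative_increase"
RELATIVE_REDUCTION = "relative_reduction"
NO_CHANGE = "no_change"


def classify_change(diff: DifferenceEstimate) -> str:
    """Classify a comparison's effect on CI-free life years.

    * ``absolute_increase`` — CI-free years rise significantly and impaired
      years do not grow (ΔCILE < 0): every year gained is CI-free.
    * ``relative_increase`` — CI-free and impaired years both grow, and the
      share of life CI-free rises significantly.
    * ``relative_reduction`` — the share of life CI-free falls significantly.
    * ``no_change`` otherwise.
    """
    if diff.proportion.excludes_zero_above():
        return RELATIVE_REDUCTION
    if diff.cifle.excludes_zero_below():
        if diff.cile < 0:
            return ABSOLUTE_INCREASE
        if diff.proportion.excludes_zero_below():
            return RELATIVE_INCREASE
    return NO_CHANGE


def expectancy_difference(
    reference: ExpectancyResult, comparison: ExpectancyResult
) -> dict[str, float]:
    """Point differences (comparison minus reference) in TLE, CIFLE, CILE and
    the CI-free proportion (percentage points)."""
    if reference.start_age != comparison.start_age:
        raise ValueError("expectancies have different starting ages")
    return {
        "d_tle": comparison.tle - reference.tle,
        "d_cifle": comparison.cifle - reference.cifle,
        "d_cile": comparison.cile - reference.cile,
        "d_proportion": comparison.proportion_cifle - reference.proportion_cifle,
    }


@dataclass
class BootstrapComparison:
    """Full output of a bootstrap comparison run."""

    expectancies: dict[tuple[str, float], ExpectancyResult]
    differences: list[DifferenceEstimate]
    B: int
    n_failed: int
    seed: int
    unreliable: bool
    profiles: dict[str, dict[str, float]] = field(default_factory=dict)


def bootstrap_differences(
    panel: pd.DataFrame,
    spec: IllnessDeathSpec,
    profiles: Mapping[str, Mapping[str, float]],
    start_ages: Sequence[float] = (65.0, 85.0),
    B: int = 500,
    seed: int = 0,
    weights: Mapping | pd.Series | None = None,
    weight_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    grid_stop: float = 110.0,
    grid_step: float = 1.0 / 12.0,
    piece_step: float = 0.25,
    max_failed_frac: float = 0.10,
) -> BootstrapComparison:
    """Expectancy differences between covariate profiles with bootstrap CIs.

    ``profiles`` maps level labels to covariate profiles; the first entry is
    the reference.  Subjects (not observations) are resampled with
    replacement — implemented as multinomial frequency weights on the
    compiled panel, so nothing is recompiled per replicate — the model is
    refit (warm-started at the point estimate), expectancies recomputed at
    every profile and start age, and 2.5/97.5 percentiles of the replicate
    differences form the intervals.  Replicates that fail to converge are
    dropped and counted; more than ``max_failed_frac`` failures flags the
    result unreliable.  Deterministic given ``seed``.

    ``weight_fn(subject_ids, counts) -> per-subject weights`` optionally
    recomputes post-stratification weights on each resampled cohort.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    labels = list(profiles)
    if len(labels) < 2:
        raise ValueError("need a reference and at least one comparison profile")
    ref = labels[0]

    compiled = compile_panel(panel, covariate_names=spec.covariate_names(), weights=weights)
    lik = PanelLikelihood(compiled, spec, piece_step=piece_step)
    point_fit = _fit_compiled(lik, compute_covariance=False)
    if not point_fit.converged:
        raise RuntimeError("point-estimate fit did not converge")

    def _expectancy_set(params) -> dict[tuple[str, float], ExpectancyResult]:
        out = {}
        for age in start_ages:
            grid = AgeGrid(start=float(age), stop=grid_stop, step=grid_step)
            for lab in labels:
                out[(lab, float(age))] = expectancies(
                    params, profiles[lab], grid, piece_step=piece_step,
                    truncation_warn=np.inf,
                )
        return out

    point = _expectancy_set(point_fit.params)

    rng = np.random.default_rng(seed)
    n = compiled.n_subjects
    reps: dict[tuple[str, float], list[tuple[float, float, float]]] = {
        (lab, float(a)): [] for lab in labels[1:] for a in start_ages
    }
    n_failed = 0
    for _ in range(B):
        counts = rng.multinomial(n, np.full(n, 1.0 / n))
        if weight_fn is not None:
            w = np.asarray(weight_fn(compiled.subject_ids, counts), dtype=float) * counts
        else:
            w = compiled.base_weights * counts
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_b = _fit_compiled(
                    lik, subject_weights=w, start=point_fit.theta,
                    compute_covariance=False,
                )
            if not fit_b.converged or not np.isfinite(fit_b.loglik):
                n_failed += 1
                continue
            exp_b = _expectancy_set(fit_b.params)
        except (ValueError, ArithmeticError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        for age in start_ages:
            a = float(age)
            eref = exp_b[(ref, a)]
            for lab in labels[1:]:
                d = expectancy_difference(eref, exp_b[(lab, a)])
                reps[(lab, a)].append((d["d_tle"], d["d_cifle"], d["d_proportion"]))

    unreliable = n_failed > max_failed_frac * B
    diffs: list[DifferenceEstimate] = []
    for age in start_ages:
        a = float(age)
        pref = point[(ref, a)]
        for lab in labels[1:]:
            dpt = expectancy_difference(pref, point[(lab, a)])
            arr = np.asarray(reps[(lab, a)], dtype=float)
            if len(arr):
                lo = np.percentile(arr, 2.5, axis=0)
                hi = np.percentile(arr, 97.5, axis=0)
            else:
                lo = hi = np.full(3, np.nan)
            diffs.append(
                DifferenceEstimate(
                    label=f"{lab} vs {ref}",
                    start_age=a,
                    tle=Interval(dpt["d_tle"], lo[0], hi[0]),
                    cifle=Interval(dpt["d_cifle"], lo[1], hi[1]),
                    proportion=Interval(dpt["d_proportion"], lo[2], hi[2]),
                    B=B,
                    n_failed=n_failed,
                    seed=seed,
                    unreliable=unreliable,
                )
            )
    return BootstrapComparison(
        expectancies=point,
        differences=diffs,
        B=B,
        n_failed=n_failed,
        seed=seed,
        unreliable=unreliable,
        profiles={k: dict(v) for k, v in profiles.items()},
    )


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "Variables",
    "TLE",
    "CIFLE",
    "Proportion of CIFLE (%)",
    "Difference in TLE (95%CI)",
    "Difference in CIFLE (95%CI)",
    "Difference in proportion of CIFLE (95%CI)",
]


def _fmt(x: float) -> str:
    return f"{x:.1f}"


def _fmt_ci(iv: Interval) -> str:
    return f"{iv.point:.1f} ({iv.lower:.1f} to {iv.upper:.1f})"


@dataclass
class ComparisonReport:
    """One variable's levels with expectancies and differences, for a table."""

    variable: str
    start_age: float
    levels: list[str]  # reference first
    expectancies: dict[str, ExpectancyResult]
    differences: dict[str, DifferenceEstimate] = field(default_factory=dict)


def report_table(
    comparisons: Sequence[ComparisonReport],
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble the per-age report table (one row per exposure level).

    Reference levels carry "Reference" in the difference columns.  Requested
    levels without results are listed in the returned gaps instead of being
    silently dropped.
    """
    rows: list[dict[str, str]] = []
    gaps: list[str] = []
    for comp in comparisons:
        rows.append({c: "" for c in REPORT_COLUMNS} | {"Variables": comp.variable})
        for i, level in enumerate(comp.levels):
            exp = comp.expectancies.get(level)
            if exp is None:
                gaps.append(f"{comp.variable}: {level} (age {comp.start_age:g})")
                continue
            row = {
                "Variables": f"  {level}",
                "TLE": _fmt(exp.tle),
                "CIFLE": _fmt(exp.cifle),
                "Proportion of CIFLE (%)": _fmt(exp.proportion_cifle),
            }
            if i == 0:
                row |= {c: "Reference" for c in REPORT_COLUMNS[4:]}
            else:
                d = comp.differences.get(level)
                if d is None:
                    gaps.append(
                        f"{comp.variable}: {level} vs {comp.levels[0]} "
                        f"(age {comp.start_age:g})"
                    )
                    row |= {c: "" for c in REPORT_COLUMNS[4:]}
                else:
                    row |= {
                        "Difference in TLE (95%CI)": _fmt_ci(d.tle),
                        "Difference in CIFLE (95%CI)": _fmt_ci(d.cifle),
                        "Difference in proportion of CIFLE (95%CI)": _fmt_ci(d.proportion),
                    }
            rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS), gaps


def risk_profile_table(
    expectancies: Mapping[str, ExpectancyResult],
    differences: Mapping[str, DifferenceEstimate],
    order: Sequence[str] = ("high", "medium_high", "medium_low", "low"),
) -> pd.DataFrame:
    """Risk-profile table: rows TLE / CIFLE / Proportion, one column per
    profile plus difference-vs-high columns."""
    ref = order[0]
    cols = [f"{p} risk profile" for p in order] + [
        f"Difference of {p} vs {ref} (95%CI)" for p in order[1:]
    ]
    getters = {
        "TLE": (lambda e: e.tle, lambda d: d.tle),
        "CIFLE": (lambda e: e.cifle, lambda d: d.cifle),
        "Proportion (%)": (lambda e: e.proportion_cifle, lambda d: d.proportion),
    }
    rows = {}
    for name, (ge, gd) in getters.items():
        row = [_fmt(ge(expectancies[p])) if p in expectancies else "" for p in order]
        row += [
            _fmt_ci(gd(differences[p])) if p in differences else "" for p in order[1:]
        ]
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def write_report_tables(
    tables: Mapping[tuple[str, float], Sequence[ComparisonReport]], out_dir
) -> list[str]:
    """Write one CSV per (group label, start age); returns all gap entries."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    all_gaps: list[str] = []
    for (group, age), comps in tables.items():
        df, gaps = report_table(comps)
        df.to_csv(os.path.join(out_dir, f"expectancies_{group}_age{age:g}.csv"), index=False)
        all_gaps.extend(f"{group}/{g}" for g in gaps)
    if all_gaps:
        with open(os.path.join(out_dir, "gaps.txt"), "w") as fh:
            fh.write("\n".join(all_gaps) + "\n")
    return all_gaps


def plot_expectancy_bars(
    expectancies: Mapping[str, ExpectancyResult], ax=None, title: str | None = None
):
    """Minimal stacked-bar plot: CIFLE (bottom) and CILE (top) per group."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(expectancies) + 2, 4))
    labels = list(expectancies)
    cifle = [expectancies[k].cifle for k in labels]
    cile = [expectancies[k].cile for k in labels]
    x = np.arange(len(labels))
    ax.bar(x, cifle, label="CIFLE", color="#4c72b0")
    ax.bar(x, cile, bottom=cifle, label="CILE", color="#dd8452")
    ax.set_xticks(x, labels, rotation=30, ha="right")
    ax.set_ylabel("Expected years")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax
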