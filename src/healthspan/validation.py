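"""Simulation experiments that validate the estimation machinery.

Each experiment generates its own inputs from a seed, runs the package's own
code paths, and returns the measured quantity, so recovery of known truths
(closed forms, matrix exponentials, simulated cohorts) can be checked both
in the test suite and from a standalone script.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .cohort import SimulationConfig, generate_cohort
from .compare import bootstrap_differences
from .expectancy import AgeGrid, expectancies
from .model import (
    IllnessDeathSpec,
    IntensityParameters,
    fit,
    intensity_matrix,
    transition_probability,
)


def _constant_params(q12: float, q13: float, q23: float) -> IntensityParameters:
    return IntensityParameters(
        beta0={
            "12": math.log(q12) if q12 > 0 else -math.inf,
            "13": math.log(q13) if q13 > 0 else -math.inf,
            "23": math.log(q23) if q23 > 0 else -math.inf,
        }
    )


def transition_probability_agreement(
    n_draws: int = 1000, seed: int = 0, dt_range: tuple[float, float] = (0.25, 5.0)
) -> float:
    """Max |disagreement| between the closed-form transition probabilities,
    the matrix exponential of the generator, and high-resolution integration
    of the Kolmogorov forward equations, over random constant-rate draws.

    Includes near-degenerate draws (q23 ≈ q12 + q13) to exercise the limit
    branch of the closed form.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_draws):
        q12, q13, q23 = rng.uniform(0.01, 0.6, size=3)
        degenerate = i % 10 == 0
        if degenerate:  # force the limit branch regularly
            q23 = q12 + q13 + rng.uniform(-1e-9, 1e-9)
        dt = rng.uniform(*dt_range)
        params = _constant_params(q12, q13, q23)
        P = transition_probability(params, 80.0, 80.0 + dt)
        Q = intensity_matrix(params, 80.0)

        def kolmogorov(_, p):
            return (p.reshape(3, 3) @ Q).ravel()

        sol = solve_ivp(
            kolmogorov, (0.0, dt), np.eye(3).ravel(),
            rtol=1e-12, atol=1e-14, method="DOP853",
        )
        P_ode = sol.y[:, -1].reshape(3, 3)
        worst = max(worst, float(np.abs(P - P_ode).max()))
        if not degenerate:
            # Padé/scaling expm loses accuracy when Q is nearly defective
            # (q23 ≈ q12+q13), so it only serves as oracle away from there
            worst = max(worst, float(np.abs(P - expm(Q * dt)).max()))
    return worst


def constant_rate_expectancy_error(n_draws: int = 100, seed: int = 1) -> float:
    """Max relative error (percent) of grid-integrated CIFLE and TLE against
    the constant-rate closed forms 1/(q12+q13) and
    1/(q12+q13) + q12/((q12+q13)·q23), over random rate triples."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        q12, q13 = rng.uniform(0.05, 0.3, size=2)
        q23 = rng.uniform(0.05, 0.4)
        params = _constant_params(q12, q13, q23)
        # grid long enough that truncated mass is negligible for these rates
        grid = AgeGrid(start=65.0, stop=65.0 + 360.0, step=1.0 / 12.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = expectancies(params, None, grid)
        cifle_cf = 1.0 / (q12 + q13)
        tle_cf = cifle_cf + q12 / ((q12 + q13) * q23)
        worst = max(
            worst,
            100.0 * abs(res.cifle - cifle_cf) / cifle_cf,
            100.0 * abs(res.tle - tle_cf) / tle_cf,
        )
    return worst


# the recovery experiment's generating truth: constant rates plus one binary
# covariate with hazard ratio 1.5 on CI onset
RECOVERY_TRUTH = {
    "beta0_12": math.log(0.1),
    "beta0_13": math.log(0.05),
    "beta0_23": math.log(0.2),
    "beta_12_x": math.log(1.5),
}


def wald_coverage_experiment(
    n_subjects: int = 3000, n_replicates: int = 100, seed: int = 2
) -> dict[str, float]:
    """95% Wald interval coverage (percent) per parameter over seeded
    replicates of simulation + maximum-likelihood fit."""
    covered = {k: 0 for k in RECOVERY_TRUTH}
    spec = IllnessDeathSpec(covariates={"12": ("x",)}, age_effect=False, ref_age=80.0)
    truth = IntensityParameters(
        beta0={
            "12": RECOVERY_TRUTH["beta0_12"],
            "13": RECOVERY_TRUTH["beta0_13"],
            "23": RECOVERY_TRUTH["beta0_23"],
        },
        beta_cov={"12": {"x": RECOVERY_TRUTH["beta_12_x"]}},
        ref_age=80.0,
    )
    rng = np.random.default_rng(seed)
    n_done = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        config = SimulationConfig(
            n_subjects=n_subjects,
            true_params=truth,
            seed=rep_seed,
            covariate_probs={"x": 0.5},
            wave_offsets=(0.0, 3.0, 6.0, 9.0),
        )
        panel, _ = generate_cohort(config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(panel, spec)
        if not res.converged:
            continue
        n_done += 1
        ci = res.wald_intervals()
        for name, true_val in RECOVERY_TRUTH.items():
            lo, hi = ci[name]
            covered[name] += lo <= true_val <= hi
    return {k: 100.0 * v / max(n_done, 1) for k, v in covered.items()} | {
        "n_replicates": n_done
    }


@dataclass
class ExpectancyRecovery:
    """Fitted vs truth-table expectancies with Monte-Carlo standard errors."""

    fitted_cifle: float
    fitted_cile: float
    fitted_tle: float
    truth_cifle: float
    truth_cile: float
    truth_tle: float
    se_cifle: float
    se_cile: float
    se_tle: float
    n_subjects: int

    @property
    def max_z(self) -> float:
        return max(
            abs(self.fitted_cifle - self.truth_cifle) / self.se_cifle,
            abs(self.fitted_cile - self.truth_cile) / self.se_cile,
            abs(self.fitted_tle - self.truth_tle) / self.se_tle,
        )


def expectancy_recovery_experiment(
    n_subjects: int = 10_000, seed: int = 3, start_age: float = 65.0
) -> ExpectancyRecovery:
    """End-to-end recovery: simulate a cohort entering CI-free at 65 with
    Gompertz-type truth observed to age 110, fit the model to the panel, and
    compare life-table expectancies at 65 with the latent truth table's mean
    state-occupancy times."""
    truth = IntensityParameters(
        beta0={"12": -3.0, "13": -3.2, "23": -2.0},
        beta_age={"12": 0.08, "13": 0.09, "23": 0.07},
        ref_age=80.0,
    )
    horizon = 110.0
    config = SimulationConfig(
        n_subjects=n_subjects,
        true_params=truth,
        seed=seed,
        entry_age_range=(start_age, start_age + 1e-3),
        entry_age_bands=((start_age, start_age + 1e-3, 1.0),),
        wave_offsets=tuple(np.arange(0.0, horizon - start_age + 1e-9, 3.0)),
        missing_state_prob=0.05,
        horizon_age=horizon,
    )
    panel, tr = generate_cohort(config)
    spec = IllnessDeathSpec(covariates={}, age_effect=True, ref_age=80.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fit(panel, spec, compute_covariance=False)
    grid = AgeGrid(start=start_age, stop=horizon, step=1.0 / 12.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est = expectancies(res.params, None, grid)

    end = np.where(np.isnan(tr["death_age"]), horizon, tr["death_age"])
    onset = np.where(np.isnan(tr["onset_age"]), end, np.minimum(tr["onset_age"], end))
    entry = tr["entry_age"].to_numpy()
    t1 = onset - entry
    t2 = end - onset
    tt = end - entry
    n = len(tr)
    return ExpectancyRecovery(
        fitted_cifle=est.cifle,
        fitted_cile=est.cile,
        fitted_tle=est.tle,
        truth_cifle=float(np.mean(t1)),
        truth_cile=float(np.mean(t2)),
        truth_tle=float(np.mean(tt)),
        se_cifle=float(np.std(t1, ddof=1) / math.sqrt(n)),
        se_cile=float(np.std(t2, ddof=1) / math.sqrt(n)),
        se_tle=float(np.std(tt, ddof=1) / math.sqrt(n)),
        n_subjects=n,
    )


def bootstrap_null_experiment(
    n_repetitions: int = 50,
    B: int = 200,
    n_subjects: int = 500,
    seed: int = 4,
    start_age: float = 65.0,
) -> dict[str, float]:
    """Null calibration of the bootstrap: two groups simulated from identical
    intensities; returns the fraction of seeded repetitions in which the 95%
    interval for ΔCIFLE (and ΔTLE) contains zero."""
    truth = IntensityParameters(
        beta0={"12": math.log(0.1), "13": math.log(0.05), "23": math.log(0.2)}
    )
    spec = IllnessDeathSpec(
        covariates={"12": ("group",), "13": ("group",), "23": ("group",)},
        age_effect=False,
        ref_age=80.0,
    )
    rng = np.random.default_rng(seed)
    cover_cifle = cover_tle = 0
    n_done = 0
    for _ in range(n_repetitions):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        config = SimulationConfig(
            n_subjects=n_subjects,
            true_params=truth,
            seed=rep_seed,
            covariate_probs={"group": 0.5},
            wave_offsets=(0.0, 3.0, 6.0, 9.0),
        )
        panel, _ = generate_cohort(config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = bootstrap_differences(
                panel,
                spec,
                {"reference": {"group": 0.0}, "comparison": {"group": 1.0}},
                start_ages=(start_age,),
                B=B,
                seed=rep_seed + 1,
                grid_stop=300.0,
            )
        d = out.differences[0]
        n_done += 1
        cover_cifle += d.cifle.lower <= 0.0 <= d.cifle.upper
        cover_tle += d.tle.lower <= 0.0 <= d.tle.upper
    return {
        "coverage_cifle": 100.0 * cover_cifle / max(n_done, 1),
        "coverage_tle": 100.0 * cover_tle / max(n_done, 1),
        "n_repetitions": n_done,
    }
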