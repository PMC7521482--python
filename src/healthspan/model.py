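"""Progressive three-state illness-death model for interval-censored panel data.

States are 1 = healthy (CI-free), 2 = ill (cognitively impaired), 3 = dead.
Allowed transitions are 1→2, 1→3 and 2→3; recovery (2→1) is structurally
impossible.  Transition intensities are log-linear in age (Gompertz-type)
with proportional covariate effects,

    q_rs(a, x) = exp(beta0_rs + beta_age_rs * (a - ref_age) + beta_x_rs' x),

and the panel likelihood handles interval-censored onset, exactly observed
death ages, and right censoring.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize

TRANSITIONS = ("12", "13", "23")

#: smallest |q23 - q12 - q13| at which the generic two-exponential formula
#: for P12 is trusted; below it the analytic limit is used.
_DEGENERACY_EPS = 1e-8

#: probabilities may be clipped back into [0, 1] only within this slack;
#: larger violations indicate a numerical failure and raise.
_CLIP_EPS = 1e-12


class InvalidParametersError(ValueError):
    """Intensity parameters produce a non-finite intensity."""


class NumericFailureError(ArithmeticError):
    """A transition probability fell outside [0, 1] beyond clipping slack."""


@dataclass
class IntensityParameters:
    """Log-linear intensity parameters for the three allowed transitions.

    Parameters
    ----------
    beta0
        Baseline log-intensity (per year) for each transition at ``ref_age``.
    beta_age
        Log-linear age slope (per year of age) for each transition.  Omitted
        transitions have slope 0 (age-constant intensity).
    beta_cov
        Per-transition covariate coefficients, ``{transition: {name: coef}}``.
    ref_age
        Age (years) at which the baseline applies; centering improves the
        conditioning of the fit.
    age_band_knots, age_band_offsets
        Piecewise-constant age alternative: ascending knot ages split age
        into bands (first band below the first knot carries the baseline);
        per-transition offsets, one per knot, shift the log-intensity in the
        band starting at that knot.
    """

    beta0: dict[str, float]
    beta_age: dict[str, float] = field(default_factory=dict)
    beta_cov: dict[str, dict[str, float]] = field(default_factory=dict)
    ref_age: float = 80.0
    age_band_knots: tuple[float, ...] = ()
    age_band_offsets: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tr in TRANSITIONS:
            if tr not in self.beta0:
                raise ValueError(f"beta0 missing transition {tr!r}")
        b0 = np.asarray(list(self.beta0.values()), dtype=float)
        # -inf is a legitimate baseline (zero intensity); +inf / nan are not
        if np.any(np.isnan(b0)) or np.any(b0 == np.inf):
            raise InvalidParametersError("invalid baseline log-intensity")
        rest = list(self.beta_age.values())
        for coefs in self.beta_cov.values():
            rest.extend(coefs.values())
        if self.age_band_knots:
            if np.any(np.diff(self.age_band_knots) <= 0):
                raise ValueError("age band knots must be strictly increasing")
            for tr, offs in self.age_band_offsets.items():
                if len(offs) != len(self.age_band_knots):
                    raise ValueError(
                        f"transition {tr}: need one band offset per knot"
                    )
                rest.extend(offs)
        elif self.age_band_offsets:
            raise ValueError("age band offsets given without knots")
        if not np.all(np.isfinite(rest)):
            raise InvalidParametersError("non-finite intensity coefficient")

    def is_age_varying(self) -> bool:
        """True if any intensity changes with age."""
        return any(v != 0.0 for v in self.beta_age.values()) or any(
            o != 0.0 for offs in self.age_band_offsets.values() for o in offs
        )

    def covariate_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for tr in TRANSITIONS:
            for name in self.beta_cov.get(tr, {}):
                if name not in names:
                    names.append(name)
        return tuple(names)

    def intensity(self, transition: str, age, covariates: Mapping[str, float] | None = None):
        """Evaluate q_rs at one or more ages for a covariate profile."""
        age = np.asarray(age, dtype=float)
        eta = self.beta0[transition] + self.beta_age.get(transition, 0.0) * (
            age - self.ref_age
        )
        offs = self.age_band_offsets.get(transition)
        if offs:
            table = np.concatenate([[0.0], offs])
            eta = eta + table[np.searchsorted(self.age_band_knots, age, side="right")]
        for name, coef in self.beta_cov.get(transition, {}).items():
            eta = eta + coef * float((covariates or {}).get(name, 0.0))
        q = np.exp(eta)
        if not np.all(np.isfinite(q)):
            raise InvalidParametersError(
                f"non-finite intensity for transition {transition} at age {age}"
            )
        return q


@dataclass
class IllnessDeathSpec:
    """Model specification: which covariates act on which transition.

    ``covariates`` maps each transition to the covariate names entering its
    log-intensity.  ``age_effect`` toggles the log-linear age slope (one
    slope per transition); with it off the intensities are constant in age,
    which is exact for the piecewise-constant likelihood.  ``age_bands``
    (ascending knot ages, e.g. every 5 years) instead fits a step-function
    age effect — one offset per band above the first — as a sensitivity
    alternative to the log-linear form.
    """

    covariates: dict[str, tuple[str, ...]] = field(default_factory=dict)
    age_effect: bool = True
    ref_age: float = 80.0
    age_bands: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for tr in self.covariates:
            if tr not in TRANSITIONS:
                raise ValueError(f"unknown transition {tr!r}")
        self.covariates = {tr: tuple(self.covariates.get(tr, ())) for tr in TRANSITIONS}
        self.age_bands = tuple(float(k) for k in self.age_bands)
        if self.age_bands and np.any(np.diff(self.age_bands) <= 0):
            raise ValueError("age_bands must be strictly increasing")
        if self.age_bands and self.age_effect:
            raise ValueError("choose either the log-linear or the banded age effect")

    def covariate_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for tr in TRANSITIONS:
            for name in self.covariates[tr]:
                if name not in names:
                    names.append(name)
        return tuple(names)

    def parameter_names(self) -> list[str]:
        names = [f"beta0_{tr}" for tr in TRANSITIONS]
        if self.age_effect:
            names += [f"beta_age_{tr}" for tr in TRANSITIONS]
        for tr in TRANSITIONS:
            names += [f"beta_{tr}_age{knot:g}plus" for knot in self.age_bands]
        for tr in TRANSITIONS:
            names += [f"beta_{tr}_{c}" for c in self.covariates[tr]]
        return names

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names())

    def pack(self, params: IntensityParameters) -> np.ndarray:
        theta = [params.beta0[tr] for tr in TRANSITIONS]
        if self.age_effect:
            theta += [params.beta_age.get(tr, 0.0) for tr in TRANSITIONS]
        nb = len(self.age_bands)
        for tr in TRANSITIONS:
            theta += list(params.age_band_offsets.get(tr, (0.0,) * nb))
        for tr in TRANSITIONS:
            theta += [params.beta_cov.get(tr, {}).get(c, 0.0) for c in self.covariates[tr]]
        return np.asarray(theta, dtype=float)

    def unpack(self, theta: np.ndarray) -> IntensityParameters:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_parameters,):
            raise ValueError("theta has wrong length for this model spec")
        beta0 = dict(zip(TRANSITIONS, theta[:3]))
        pos = 3
        beta_age: dict[str, float] = {}
        if self.age_effect:
            beta_age = dict(zip(TRANSITIONS, theta[3:6]))
            pos = 6
        band_offsets: dict[str, tuple[float, ...]] = {}
        nb = len(self.age_bands)
        if nb:
            for tr in TRANSITIONS:
                band_offsets[tr] = tuple(theta[pos : pos + nb])
                pos += nb
        beta_cov: dict[str, dict[str, float]] = {}
        for tr in TRANSITIONS:
            k = len(self.covariates[tr])
            beta_cov[tr] = dict(zip(self.covariates[tr], theta[pos : pos + k]))
            pos += k
        return IntensityParameters(
            beta0=beta0, beta_age=beta_age, beta_cov=beta_cov, ref_age=self.ref_age,
            age_band_knots=self.age_bands, age_band_offsets=band_offsets,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "covariates": {tr: list(v) for tr, v in self.covariates.items()},
                    "age_effect": self.age_effect,
                    "ref_age": self.ref_age,
                    "age_bands": list(self.age_bands),
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "IllnessDeathSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            covariates={tr: tuple(v) for tr, v in raw.get("covariates", {}).items()},
            age_effect=bool(raw.get("age_effect", True)),
            ref_age=float(raw.get("ref_age", 80.0)),
            age_bands=tuple(raw.get("age_bands", ())),
        )


def intensity_matrix(
    params: IntensityParameters, age: float, covariates: Mapping[str, float] | None = None
) -> np.ndarray:
    """3×3 generator Q at a given age: rows sum to zero, absorbing third row."""
    q12 = float(params.intensity("12", age, covariates))
    q13 = float(params.intensity("13", age, covariates))
    q23 = float(params.intensity("23", age, covariates))
    return np.array(
        [
            [-(q12 + q13), q12, q13],
            [0.0, -q23, q23],
            [0.0, 0.0, 0.0],
        ]
    )


def _piece_probs(q12, q13, q23, dt):
    """Closed-form constant-rate transition probabilities over one piece.

    Returns (p11, p12, p22); p13 and p23 follow from row sums, p21 = 0.
    The two-exponential formula for p12 degenerates when q23 ≈ q12 + q13 and
    is replaced by its analytic limit q12·dt·exp(−q23·dt) there.
    """
    a = q12 + q13
    p11 = np.exp(-a * dt)
    p22 = np.exp(-q23 * dt)
    denom = q23 - a
    degenerate = np.abs(denom) < _DEGENERACY_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        generic = q12 * (p11 - p22) / np.where(degenerate, 1.0, denom)
    p12 = np.where(degenerate, q12 * dt * p22, generic)
    return p11, p12, p22


def transition_probability(
    params: IntensityParameters,
    age_from: float,
    age_to: float,
    covariates: Mapping[str, float] | None = None,
    piece_step: float = 0.25,
) -> np.ndarray:
    """Transition probability matrix P(age_from, age_to) for one profile.

    The interval is split into pieces of at most ``piece_step`` years; within
    each piece the generator is frozen at the piece midpoint and the
    constant-rate closed form applied; pieces compose by matrix product
    (Chapman–Kolmogorov).  With no age effect a single piece is exact.
    """
    if age_to < age_from:
        raise ValueError("age_to must be >= age_from")
    if age_to == age_from:
        return np.eye(3)
    total = age_to - age_from
    if params.is_age_varying():
        n_pieces = max(1, int(math.ceil(total / piece_step - 1e-12)))
    else:
        n_pieces = 1
    bounds = np.linspace(age_from, age_to, n_pieces + 1)
    mids = 0.5 * (bounds[:-1] + bounds[1:])
    dts = np.diff(bounds)
    q12 = params.intensity("12", mids, covariates)
    q13 = params.intensity("13", mids, covariates)
    q23 = params.intensity("23", mids, covariates)
    p11s, p12s, p22s = _piece_probs(q12, q13, q23, dts)
    # compose the 2x2 transient block; dead column follows from row sums
    P11, P12, P22 = 1.0, 0.0, 1.0
    for p11, p12, p22 in zip(np.atleast_1d(p11s), np.atleast_1d(p12s), np.atleast_1d(p22s)):
        P12 = P11 * p12 + P12 * p22
        P11 = P11 * p11
        P22 = P22 * p22
    P = np.array(
        [
            [P11, P12, 1.0 - P11 - P12],
            [0.0, P22, 1.0 - P22],
            [0.0, 0.0, 1.0],
        ]
    )
    if P.min() < -_CLIP_EPS or P.max() > 1.0 + _CLIP_EPS:
        raise NumericFailureError(
            f"transition probabilities outside [0,1] beyond tolerance: {P}"
        )
    return np.clip(P, 0.0, 1.0)


# ---------------------------------------------------------------------------
# panel -> likelihood intervals
# ---------------------------------------------------------------------------

_KIND_TO_STATE1 = 0
_KIND_TO_STATE2 = 1
_KIND_DEATH = 2
_KIND_ALIVE_UNKNOWN = 3


@dataclass
class CompiledPanel:
    """Panel reduced to likelihood intervals between consecutive known states.

    Each interval runs from a known living state to the next known state, an
    exact death age, or a right-censoring age.  Missing living states in
    between contribute nothing: the bridging interval spans them.
    """

    subject_ids: np.ndarray          # unique subject labels, in panel order
    subject_index: np.ndarray        # per-interval index into subject_ids
    a0: np.ndarray                   # interval start age
    a1: np.ndarray                   # interval end age
    from_state: np.ndarray           # 1 or 2
    kind: np.ndarray                 # _KIND_* codes
    X: np.ndarray                    # (n_intervals, n_covariates)
    covariate_names: tuple[str, ...]
    base_weights: np.ndarray         # per-subject weight (frequency weight)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_intervals(self) -> int:
        return len(self.a0)

    def transition_counts(self) -> dict[str, int]:
        """Directly observed transition counts by type (crude, for start values)."""
        to2 = int(np.sum((self.from_state == 1) & (self.kind == _KIND_TO_STATE2)))
        d1 = int(np.sum((self.from_state == 1) & (self.kind == _KIND_DEATH)))
        d2 = int(np.sum((self.from_state == 2) & (self.kind == _KIND_DEATH)))
        return {"12": to2, "13": d1, "23": d2}


def compile_panel(
    panel: pd.DataFrame,
    covariate_names: Sequence[str] = (),
    weights: Mapping | pd.Series | None = None,
) -> CompiledPanel:
    """Reduce a long-format panel to the interval records the likelihood needs.

    ``panel`` must carry columns ``subject_id``, ``age``, ``state`` (1, 2, 3
    or NaN for a missing living state) and ``is_death_record``; covariate
    columns are taken at the subject's first row (baseline covariates only).
    ``weights`` maps subject_id to a positive frequency weight (default 1).
    """
    required = {"subject_id", "age", "state", "is_death_record"}
    missing_cols = required - set(panel.columns)
    if missing_cols:
        raise ValueError(f"panel is missing columns: {sorted(missing_cols)}")
    sub_ids: list = []
    sub_idx: list[int] = []
    a0: list[float] = []
    a1: list[float] = []
    from_state: list[int] = []
    kind: list[int] = []
    Xrows: list[list[float]] = []
    wlist: list[float] = []

    cols = ["age", "state", "is_death_record"] + list(covariate_names)
    for j, (sid, grp) in enumerate(panel.groupby("subject_id", sort=True)):
        g = grp.sort_values("age")
        ages = g["age"].to_numpy(dtype=float)
        states = g["state"].to_numpy(dtype=float)
        is_death = g["is_death_record"].to_numpy()
        if np.any(np.diff(ages) < 0):
            raise ValueError(f"ages not increasing for subject {sid!r}")
        x = [float(g[c].iloc[0]) for c in covariate_names]
        w = 1.0 if weights is None else float(weights[sid])
        if w <= 0:
            raise ValueError(f"non-positive weight for subject {sid!r}")
        sub_ids.append(sid)
        wlist.append(w)

        cur_state: int | None = None
        cur_age = 0.0
        for age, state, dead in zip(ages, states, is_death):
            if dead:
                if cur_state is None:
                    break  # death with no prior known living state: no info
                sub_idx.append(j)
                a0.append(cur_age)
                a1.append(age)
                from_state.append(cur_state)
                kind.append(_KIND_DEATH)
                Xrows.append(x)
                cur_state = None
                break
            if np.isnan(state):
                continue
            s = int(state)
            if s == 3:
                raise ValueError(
                    "state 3 must be flagged with is_death_record=1 "
                    f"(subject {sid!r} at age {age})"
                )
            if cur_state is not None:
                sub_idx.append(j)
                a0.append(cur_age)
                a1.append(age)
                from_state.append(cur_state)
                kind.append(_KIND_TO_STATE1 if s == 1 else _KIND_TO_STATE2)
                Xrows.append(x)
            cur_state = s
            cur_age = age
        else:
            # alive at the end: a trailing missing living row is a right censor
            last_age = ages[-1]
            if cur_state is not None and np.isnan(states[-1]) and last_age > cur_age:
                sub_idx.append(j)
                a0.append(cur_age)
                a1.append(last_age)
                from_state.append(cur_state)
                kind.append(_KIND_ALIVE_UNKNOWN)
                Xrows.append(x)

    return CompiledPanel(
        subject_ids=np.asarray(sub_ids),
        subject_index=np.asarray(sub_idx, dtype=np.intp),
        a0=np.asarray(a0, dtype=float),
        a1=np.asarray(a1, dtype=float),
        from_state=np.asarray(from_state, dtype=np.int8),
        kind=np.asarray(kind, dtype=np.int8),
        X=np.asarray(Xrows, dtype=float).reshape(len(a0), len(covariate_names)),
        covariate_names=tuple(covariate_names),
        base_weights=np.asarray(wlist, dtype=float),
    )


class PanelLikelihood:
    """Weighted log-likelihood of a compiled panel under an IllnessDeathSpec.

    Vectorised over intervals: age-varying intensities are frozen at the
    midpoints of sub-pieces of at most ``piece_step`` years and the transient
    2×2 row (P_s1, P_s2) is propagated across pieces for all intervals at
    once.  Exact death ages contribute P_s1·q13 + P_s2·q23 with intensities
    evaluated at the death age (left limit); right censoring contributes
    P_s1 + P_s2.
    """

    def __init__(
        self, compiled: CompiledPanel, spec: IllnessDeathSpec, piece_step: float = 0.25
    ):
        self.compiled = compiled
        self.spec = spec
        self.piece_step = piece_step
        names = compiled.covariate_names
        # per-transition design columns as indices into the compiled X
        self._cov_idx = {
            tr: np.array([names.index(c) for c in spec.covariates[tr]], dtype=np.intp)
            for tr in TRANSITIONS
        }
        dt = compiled.a1 - compiled.a0
        self._age_varying = spec.age_effect or bool(spec.age_bands)
        if self._age_varying:
            npieces = np.maximum(1, np.ceil(dt / piece_step - 1e-12).astype(int))
        else:
            npieces = np.ones(len(dt), dtype=int)
        self._npieces = npieces
        self._max_pieces = int(npieces.max()) if len(npieces) else 0
        self._dt = dt
        self._knots = np.asarray(spec.age_bands, dtype=float)

    def _rates(self, params_flat, tr, ages, eta_cov):
        b0, bage, band = params_flat[tr]
        eta = b0 + bage * (ages - self.spec.ref_age) + eta_cov
        if band is not None:
            eta = eta + band[np.searchsorted(self._knots, ages, side="right")]
        return np.exp(eta)

    def _unpack_flat(self, theta):
        theta = np.asarray(theta, dtype=float)
        flat: dict[str, tuple] = {}
        pos = 6 if self.spec.age_effect else 3
        nb = len(self.spec.age_bands)
        bands: dict[str, np.ndarray | None] = {}
        for tr in TRANSITIONS:
            if nb:
                bands[tr] = np.concatenate([[0.0], theta[pos : pos + nb]])
                pos += nb
            else:
                bands[tr] = None
        cov_eta: dict[str, np.ndarray] = {}
        for i, tr in enumerate(TRANSITIONS):
            bage = theta[3 + i] if self.spec.age_effect else 0.0
            flat[tr] = (theta[i], bage, bands[tr])
            k = len(self.spec.covariates[tr])
            beta = theta[pos : pos + k]
            pos += k
            idx = self._cov_idx[tr]
            if k:
                cov_eta[tr] = self.compiled.X[:, idx] @ beta
            else:
                cov_eta[tr] = np.zeros(self.compiled.n_intervals)
        return flat, cov_eta

    def subject_logliks(self, theta) -> np.ndarray:
        """Per-subject log-likelihood contributions (unweighted)."""
        c = self.compiled
        flat, eta = self._unpack_flat(theta)
        n = c.n_intervals
        r1 = (c.from_state == 1).astype(float)
        r2 = 1.0 - r1
        remaining = self._npieces.copy()
        start = c.a0.copy()
        for _ in range(self._max_pieces):
            active = remaining > 0
            if not active.any():
                break
            h = np.where(active, np.minimum(self.piece_step, c.a1 - start), 0.0)
            if not self._age_varying:
                h = np.where(active, self._dt, 0.0)
            mid = start + 0.5 * h
            q12 = self._rates(flat, "12", mid, eta["12"])
            q13 = self._rates(flat, "13", mid, eta["13"])
            q23 = self._rates(flat, "23", mid, eta["23"])
            p11, p12, p22 = _piece_probs(q12, q13, q23, h)
            r2 = np.where(active, r1 * p12 + r2 * p22, r2)
            r1 = np.where(active, r1 * p11, r1)
            start = start + h
            remaining -= active
        if not np.all(np.isfinite(r1)) or not np.all(np.isfinite(r2)):
            raise InvalidParametersError("non-finite transition probability in likelihood")

        contrib = np.empty(n)
        kind = c.kind
        m = kind == _KIND_TO_STATE1
        contrib[m] = r1[m]
        m = kind == _KIND_TO_STATE2
        contrib[m] = r2[m]
        m = kind == _KIND_ALIVE_UNKNOWN
        contrib[m] = r1[m] + r2[m]
        m = kind == _KIND_DEATH
        if m.any():
            q13d = self._rates(flat, "13", c.a1[m], eta["13"][m])
            q23d = self._rates(flat, "23", c.a1[m], eta["23"][m])
            contrib[m] = r1[m] * q13d + r2[m] * q23d
        with np.errstate(divide="ignore"):
            log_contrib = np.log(contrib)
        if np.any(np.isneginf(log_contrib)):
            warnings.warn(
                "zero-probability observed path; log-likelihood is -inf",
                RuntimeWarning,
                stacklevel=2,
            )
        out = np.zeros(c.n_subjects)
        np.add.at(out, c.subject_index, log_contrib)
        return out

    def loglik(self, theta, subject_weights: np.ndarray | None = None) -> float:
        w = self.compiled.base_weights if subject_weights is None else subject_weights
        ll = self.subject_logliks(theta)
        # -inf * 0 would poison the sum through nan; mask zero-weight subjects
        if np.any(w == 0):
            ll = np.where(w == 0, 0.0, ll)
        return float(np.dot(w, ll))


def subject_loglik(
    params: IntensityParameters,
    observations: pd.DataFrame,
    spec: IllnessDeathSpec | None = None,
    weight: float = 1.0,
    piece_step: float = 0.25,
) -> float:
    """Log-likelihood of a single subject's observation sequence.

    ``observations`` uses the panel schema (columns ``subject_id``, ``age``,
    ``state``, ``is_death_record`` plus covariates).  Convenience wrapper
    around :class:`PanelLikelihood` for one subject.
    """
    if spec is None:
        spec = IllnessDeathSpec(
            covariates={tr: tuple(params.beta_cov.get(tr, {})) for tr in TRANSITIONS},
            age_effect=bool(params.beta_age)
            and any(v != 0.0 for v in params.beta_age.values()),
            ref_age=params.ref_age,
            age_bands=params.age_band_knots,
        )
    compiled = compile_panel(
        observations, covariate_names=spec.covariate_names(),
        weights={sid: weight for sid in observations["subject_id"].unique()},
    )
    lik = PanelLikelihood(compiled, spec, piece_step=piece_step)
    return lik.loglik(spec.pack(params))


@dataclass
class FitResult:
    """Maximum-likelihood fit of the illness-death model."""

    spec: IllnessDeathSpec
    params: IntensityParameters
    theta: np.ndarray
    covariance: np.ndarray | None
    loglik: float
    converged: bool
    n_iterations: int
    gradient_norm: float
    n_subjects: int
    n_intervals: int
    transition_counts: dict[str, int]
    non_identified: tuple[str, ...] = ()

    def standard_errors(self) -> dict[str, float]:
        names = self.spec.parameter_names()
        if self.covariance is None:
            return {n: float("nan") for n in names}
        se = np.sqrt(np.clip(np.diag(self.covariance), 0.0, np.inf))
        out = dict(zip(names, se))
        for tr in self.non_identified:
            out[f"beta0_{tr}"] = float("nan")
        return out

    def wald_intervals(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        se = self.standard_errors()
        names = self.spec.parameter_names()
        return {
            n: (self.theta[i] - z * se[n], self.theta[i] + z * se[n])
            for i, n in enumerate(names)
        }

    def to_json(self, path) -> None:
        names = self.spec.parameter_names()
        payload = {
            "estimates": dict(zip(names, map(float, self.theta))),
            "standard_errors": {
                k: (None if np.isnan(v) else float(v))
                for k, v in self.standard_errors().items()
            },
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "gradient_norm": self.gradient_norm,
            "n_subjects": self.n_subjects,
            "n_intervals": self.n_intervals,
            "transition_counts": self.transition_counts,
            "non_identified": list(self.non_identified),
            "spec": {
                "covariates": {tr: list(v) for tr, v in self.spec.covariates.items()},
                "age_effect": self.spec.age_effect,
                "ref_age": self.spec.ref_age,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _start_values(compiled: CompiledPanel, spec: IllnessDeathSpec) -> np.ndarray:
    """Crude-rate starting point: observed transitions over person-years."""
    counts = compiled.transition_counts()
    dt = compiled.a1 - compiled.a0
    py1 = float(np.sum(dt[compiled.from_state == 1]))
    py2 = float(np.sum(dt[compiled.from_state == 2]))
    theta = np.zeros(spec.n_parameters)
    # fall back to a bland 0.1/yr when a state contributes no person-years
    theta[0] = math.log((counts["12"] + 0.5) / py1) if py1 > 0 else math.log(0.1)
    theta[1] = math.log((counts["13"] + 0.5) / py1) if py1 > 0 else math.log(0.1)
    theta[2] = math.log((counts["23"] + 0.5) / py2) if py2 > 0 else math.log(0.1)
    return theta


def fit(
    panel: pd.DataFrame,
    spec: IllnessDeathSpec,
    weights: Mapping | pd.Series | None = None,
    piece_step: float = 0.25,
    start: np.ndarray | None = None,
    compute_covariance: bool = True,
    gtol: float = 1e-5,
    maxiter: int = 500,
) -> FitResult:
    """Fit the illness-death model to a panel by maximum likelihood.

    Quasi-Newton (BFGS) search on the weighted interval-censored panel
    log-likelihood, starting from crude occurrence/exposure rates with zero
    covariate and age effects.  The covariance matrix comes from the inverse
    of the numerically differentiated observed information at the optimum.
    Deterministic given the data and settings.
    """
    compiled = compile_panel(panel, covariate_names=spec.covariate_names(), weights=weights)
    lik = PanelLikelihood(compiled, spec, piece_step=piece_step)
    return _fit_compiled(lik, start=start, compute_covariance=compute_covariance,
                         gtol=gtol, maxiter=maxiter)


def _fit_compiled(
    lik: PanelLikelihood,
    subject_weights: np.ndarray | None = None,
    start: np.ndarray | None = None,
    compute_covariance: bool = True,
    gtol: float = 1e-5,
    maxiter: int = 500,
) -> FitResult:
    compiled, spec = lik.compiled, lik.spec
    counts = compiled.transition_counts()
    non_identified = tuple(tr for tr in TRANSITIONS if counts[tr] == 0)
    theta0 = _start_values(compiled, spec) if start is None else np.asarray(start, float)

    # optimise the mean (per unit weight) log-likelihood: finite-difference
    # gradients are then on an O(1) scale and the gtol is meaningful
    w = compiled.base_weights if subject_weights is None else subject_weights
    total_w = float(np.sum(w))
    if total_w <= 0:
        raise ValueError("total subject weight must be positive")

    def nll(theta):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            val = lik.loglik(theta, subject_weights)
        return 1e12 if not np.isfinite(val) else -val / total_w

    res = minimize(nll, theta0, method="BFGS",
                   options={"gtol": gtol, "maxiter": maxiter})
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else float("nan")
    converged = bool(res.success) or grad_norm < 100 * gtol

    cov = None
    if compute_covariance:
        from statsmodels.tools.numdiff import approx_hess

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = approx_hess(res.x, nll) * total_w
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        cov = 0.5 * (cov + cov.T)

    return FitResult(
        spec=spec,
        params=spec.unpack(res.x),
        theta=res.x,
        covariance=cov,
        loglik=float(-res.fun * total_w),
        converged=converged,
        n_iterations=int(res.nit),
        gradient_norm=grad_norm,
        n_subjects=compiled.n_subjects,
        n_intervals=compiled.n_intervals,
        transition_counts=counts,
        non_identified=non_identified,
    )
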