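"""Continuous-time multi-state Markov model engine for panel data.

The model: a subject moves among ``n_states`` states in continuous time
with intensity matrix Q whose off-diagonal entries are the transition
intensities q_rs and whose rows sum to zero.  Covariates act
multiplicatively on the intensities (proportional intensities),

    q_rs(z) = q0_rs * exp(beta_rs' z),

so exp(beta) is the intensity ratio — reported throughout as a hazard
ratio.  The transition probability matrix over an interval of length t
is the matrix exponential P(t) = expm(Q t), and the panel likelihood is
a product over consecutive observation pairs of

* P_rs(dt)                          for exactly known transient states,
* sum_{s in C} P_rs(dt)             for a terminal state censored to a set C,
* sum_{m transient} P_rm(dt) q_ms   for an exactly timed entry into an
                                    absorbing state s (the exact-death term).

Fitting maximises this likelihood by quasi-Newton ascent on the
unconstrained parameters (log intensities and betas); the covariance is
the inverse of the numerically differentiated observed information, and
Wald confidence intervals for hazard ratios are formed on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize, stats
from scipy.linalg import expm

from .records import ABSORBING_STATES, StateObservation

__all__ = [
    "Transition",
    "ModelSpec",
    "IntensityMatrix",
    "ParameterVector",
    "Subject",
    "PanelDataset",
    "FitResult",
    "LRTResult",
    "default_spec",
    "build_intensity_matrix",
    "transition_probability",
    "log_likelihood",
    "fit",
    "hazard_ratio",
    "likelihood_ratio_test",
]

Transition = Tuple[int, int]

#: Allowed moves of the five-state phase-progression model: advance by one
#: phase, reach approval from Phase III, or fail from any phase.
DEFAULT_TRANSITIONS: Tuple[Transition, ...] = (
    (1, 2), (1, 5), (2, 3), (2, 5), (3, 4), (3, 5),
)
PROGRESSION_TRANSITIONS: Tuple[Transition, ...] = ((1, 2), (2, 3), (3, 4))


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the model: states, allowed transitions, covariate wiring.

    ``covariate_attachment`` maps each transition to the covariates whose
    effects act on it.  With ``shared_effects`` a covariate has a single
    beta common to every transition it is attached to; otherwise each
    (transition, covariate) pair has its own beta.
    """

    n_states: int = 5
    transitions: Tuple[Transition, ...] = DEFAULT_TRANSITIONS
    covariates: Tuple[str, ...] = ()
    covariate_attachment: Mapping[Transition, Tuple[str, ...]] = field(
        default_factory=dict
    )
    shared_effects: bool = False
    absorbing: Tuple[int, ...] = ABSORBING_STATES
    #: absorbing states whose entry times are exactly observed
    exact_absorbing: FrozenSet[int] = frozenset(ABSORBING_STATES)
    #: when True, transient-state observations are the actual transition
    #: times (phase-entry dates are public), so a pair (r, s) contributes the
    #: exact-jump term exp(-q_r dt) q_rs; when False the states are
    #: panel-observed snapshots contributing P_rs(dt).  Observation times
    #: that coincide with the transitions make the panel term degenerate,
    #: hence exact is the default for this data scheme.
    exact_transition_times: bool = True

    def __post_init__(self) -> None:
        for (r, s) in self.transitions:
            if r in self.absorbing:
                raise ValueError(f"transition {r}->{s} leaves absorbing state {r}")
            if s <= r:
                raise ValueError(
                    f"transition {r}->{s} returns to an earlier state; the "
                    "progression model is acyclic"
                )
        for tr, covs in self.covariate_attachment.items():
            if tr not in self.transitions:
                raise ValueError(f"attachment on disallowed transition {tr}")
            for c in covs:
                if c not in self.covariates:
                    raise ValueError(f"attachment references unknown covariate {c!r}")

    # -- parameter bookkeeping -------------------------------------------

    @property
    def transient(self) -> Tuple[int, ...]:
        return tuple(s for s in range(1, self.n_states + 1) if s not in self.absorbing)

    @property
    def beta_keys(self) -> Tuple[Tuple[Union[Transition, str], str], ...]:
        """Ordered beta parameter keys: (transition | 'shared', covariate)."""
        keys: List[Tuple[Union[Transition, str], str]] = []
        if self.shared_effects:
            seen = []
            for tr in self.transitions:
                for c in self.covariate_attachment.get(tr, ()):
                    if c not in seen:
                        seen.append(c)
            keys = [("shared", c) for c in seen]
        else:
            for tr in self.transitions:
                for c in self.covariate_attachment.get(tr, ()):
                    keys.append((tr, c))
        return tuple(keys)

    @property
    def n_baseline(self) -> int:
        return len(self.transitions)

    @property
    def n_params(self) -> int:
        return self.n_baseline + len(self.beta_keys)

    @property
    def param_names(self) -> Tuple[str, ...]:
        names = [f"logq({r}->{s})" for r, s in self.transitions]
        for key, cov in self.beta_keys:
            tag = "shared" if key == "shared" else f"{key[0]}->{key[1]}"
            names.append(f"beta[{cov}]({tag})")
        return tuple(names)

    def beta_index(self, transition: Transition, covariate: str) -> int:
        """Flat-parameter index of the beta acting on (transition, covariate)."""
        key = ("shared", covariate) if self.shared_effects else (transition, covariate)
        if not self.shared_effects and covariate not in self.covariate_attachment.get(
            transition, ()
        ):
            raise KeyError(f"covariate {covariate!r} not attached to {transition}")
        try:
            return self.n_baseline + self.beta_keys.index(key)
        except ValueError:
            raise KeyError(f"no beta for {key}") from None


def default_spec(
    covariates: Sequence[str] = (),
    attach_to: Sequence[Transition] = PROGRESSION_TRANSITIONS,
    shared_effects: bool = False,
    exact_absorbing: Sequence[int] = ABSORBING_STATES,
    exact_transition_times: bool = True,
) -> ModelSpec:
    """The five-state phase-progression spec with covariates attached to
    the given transitions (default: progression transitions only)."""
    attachment = {tr: tuple(covariates) for tr in attach_to} if covariates else {}
    return ModelSpec(
        covariates=tuple(covariates),
        covariate_attachment=attachment,
        shared_effects=shared_effects,
        exact_absorbing=frozenset(exact_absorbing),
        exact_transition_times=exact_transition_times,
    )


@dataclass(frozen=True)
class ParameterVector:
    """Unconstrained parameters: log baseline intensities, one per allowed
    transition, followed by covariate log intensity ratios (betas)."""

    log_baseline: np.ndarray
    beta: np.ndarray

    def to_flat(self) -> np.ndarray:
        return np.concatenate([self.log_baseline, self.beta])

    @staticmethod
    def from_flat(x: np.ndarray, spec: ModelSpec) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        if x.shape != (spec.n_params,):
            raise ValueError(f"expected {spec.n_params} parameters, got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite parameter values")
        k = spec.n_baseline
        return ParameterVector(x[:k].copy(), x[k:].copy())


@dataclass(frozen=True)
class IntensityMatrix:
    """A validated intensity matrix Q (rows sum to zero, off-diagonals >= 0,
    absorbing rows identically zero).  Intensities are per year."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = self.q
        n = q.shape[0]
        if q.shape != (n, n):
            raise ValueError("Q must be square")
        off = q - np.diag(np.diag(q))
        if np.any(off < -1e-12):
            raise ValueError("negative off-diagonal intensity")
        if np.max(np.abs(q.sum(axis=1))) > 1e-9:
            raise ValueError("rows of Q must sum to zero")


def build_intensity_matrix(
    spec: ModelSpec,
    params: ParameterVector,
    covariates: Optional[Union[Sequence[float], Mapping[str, float]]] = None,
) -> IntensityMatrix:
    """Assemble Q for one covariate vector under proportional intensities."""
    z = _covariate_vector(spec, covariates)
    return IntensityMatrix(_q_matrix(spec, params.to_flat(), z))


def _covariate_vector(spec, covariates) -> np.ndarray:
    if covariates is None:
        return np.zeros(len(spec.covariates))
    if isinstance(covariates, Mapping):
        return np.array([float(covariates.get(c, 0.0)) for c in spec.covariates])
    z = np.asarray(covariates, dtype=float)
    if z.shape != (len(spec.covariates),):
        raise ValueError(
            f"covariate vector length {z.shape} does not match spec "
            f"({len(spec.covariates)} covariates)"
        )
    return z


def _q_matrix(spec: ModelSpec, x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Q from flat parameters and a covariate vector (internal fast path)."""
    q = np.zeros((spec.n_states, spec.n_states))
    cov_idx = {c: i for i, c in enumerate(spec.covariates)}
    for k, (r, s) in enumerate(spec.transitions):
        lin = x[k]
        for c in spec.covariate_attachment.get((r, s), ()):
            lin += x[spec.beta_index((r, s), c)] * z[cov_idx[c]]
        q[r - 1, s - 1] = np.exp(lin)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def transition_probability(
    q: Union[IntensityMatrix, np.ndarray], t: float
) -> np.ndarray:
    """P(t) = expm(Q t), via scaling-and-squaring Padé approximation.

    Makes no diagonalizability assumption on Q.  Rows of the result sum
    to one to within 1e-10 and entries are clipped to [0, 1] against
    roundoff at the boundaries.
    """
    if t < 0:
        raise ValueError(f"elapsed time must be non-negative, got {t}")
    qm = q.q if isinstance(q, IntensityMatrix) else np.asarray(q, dtype=float)
    p = expm(qm * t)
    return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Panel data containers


@dataclass
class Subject:
    """One drug's observation sequence plus its covariate values."""

    drug_id: str
    times: np.ndarray
    states: Tuple[Union[int, FrozenSet[int]], ...]
    covariates: Dict[str, float] = field(default_factory=dict)
    indication: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times/states length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"subject {self.drug_id}: times not strictly increasing")
        for s in self.states[:-1]:
            if not isinstance(s, (int, np.integer)):
                raise ValueError("censoring sets are only allowed at the final observation")
            if int(s) in ABSORBING_STATES:
                raise ValueError(
                    f"subject {self.drug_id}: observation follows absorbing state {s}"
                )


@dataclass
class PanelDataset:
    """A cohort of panel-observed subjects."""

    subjects: List[Subject]

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.times) for s in self.subjects)

    def filter(self, predicate) -> "PanelDataset":
        return PanelDataset([s for s in self.subjects if predicate(s)])

    @staticmethod
    def from_observations(
        observations: Sequence[StateObservation],
        covariates: Mapping[str, Mapping[str, float]] = None,
        indications: Mapping[str, str] = None,
    ) -> "PanelDataset":
        """Group flat StateObservation records by drug into subjects."""
        by_drug: Dict[str, List[StateObservation]] = {}
        for o in observations:
            by_drug.setdefault(o.drug_id, []).append(o)
        subjects = []
        for drug_id, obs in by_drug.items():
            obs = sorted(obs, key=lambda o: o.time)
            states = tuple(
                o.state if o.state is not None else o.censor_set for o in obs
            )
            subjects.append(
                Subject(
                    drug_id=drug_id,
                    times=np.array([o.time for o in obs]),
                    states=states,
                    covariates=dict((covariates or {}).get(drug_id, {})),
                    indication=(indications or {}).get(drug_id),
                )
            )
        return PanelDataset(subjects)


# ---------------------------------------------------------------------------
# Likelihood

_EIG_COND_MAX = 1e8


def _propagators(q: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """P(dt) for a batch of interval lengths sharing one Q.

    Uses a spectral decomposition when Q is safely diagonalizable (the
    generic case for progression models with distinct total exit rates),
    falling back to Padé scaling-and-squaring per interval otherwise.
    Agreement of the two routes is enforced in the test suite.
    """
    w, v = np.linalg.eig(q)
    use_eig = False
    if np.all(np.isfinite(w)):
        try:
            vinv = np.linalg.inv(v)
            if np.linalg.cond(v) < _EIG_COND_MAX:
                use_eig = True
        except np.linalg.LinAlgError:
            pass
    if use_eig:
        ew = np.exp(np.multiply.outer(dts, w))  # (n, k)
        p = np.einsum("ij,nj,jk->nik", v, ew, vinv).real
    else:
        p = np.stack([expm(q * t) for t in dts])
    return np.clip(p, 0.0, 1.0)


def _subject_groups(data: PanelDataset, spec: ModelSpec):
    """Group subjects by covariate vector so each group shares one Q."""
    groups: Dict[Tuple[float, ...], List[Subject]] = {}
    for s in data.subjects:
        z = tuple(float(s.covariates.get(c, 0.0)) for c in spec.covariates)
        groups.setdefault(z, []).append(s)
    return groups


def log_likelihood(
    data: PanelDataset, spec: ModelSpec, params: Union[ParameterVector, np.ndarray]
) -> float:
    """Panel log-likelihood of the cohort under the model.

    Returns ``-inf`` (with a warning naming the offending subject) when the
    data contain a transition the parameterised model gives probability
    zero, rather than raising.
    """
    x = params.to_flat() if isinstance(params, ParameterVector) else np.asarray(params)
    total = 0.0
    transient_idx = np.array([s - 1 for s in spec.transient])
    exact = spec.exact_transition_times
    for z, subjects in _subject_groups(data, spec).items():
        q = _q_matrix(spec, x, np.array(z))
        # split pairs into exact-jump terms (computed directly from Q) and
        # terms needing the interval propagator P(dt)
        pairs = []
        panel_dts, panel_idx = [], []
        for subj in subjects:
            for i in range(len(subj.times) - 1):
                s0 = int(subj.states[i])
                s1 = subj.states[i + 1]
                dt = subj.times[i + 1] - subj.times[i]
                censored = isinstance(s1, (frozenset, set))
                exact_abs = not censored and int(s1) in spec.exact_absorbing
                if not exact:  # every panel-mode term needs the propagator
                    panel_idx.append(len(pairs))
                    panel_dts.append(dt)
                pairs.append((s0, s1, dt, subj.drug_id, censored, exact_abs))
        if not pairs:
            continue
        p = _propagators(q, np.asarray(panel_dts)) if panel_dts else None
        p_of = dict(zip(panel_idx, range(len(panel_idx))))
        for k, (s0, s1, dt, drug_id, censored, exact_abs) in enumerate(pairs):
            r = s0 - 1
            if censored and exact:
                # entries and failures are always observed, so "no further
                # observation by T" means the subject is still in its last
                # entered state; the censoring set must contain it
                lik = float(np.exp(q[r, r] * dt)) if s0 in s1 else 0.0
            elif censored:
                row = p[p_of[k], r, :]
                lik = float(sum(row[s - 1] for s in s1))
            elif exact_abs and exact:
                # stayed in r over the interval, then the absorbing jump
                lik = float(np.exp(q[r, r] * dt) * q[r, int(s1) - 1])
            elif exact_abs:
                row = p[p_of[k], r, :]
                lik = float(row[transient_idx] @ q[transient_idx, int(s1) - 1])
            elif exact:
                s = int(s1) - 1
                if s == r:
                    lik = float(np.exp(q[r, r] * dt))
                else:
                    lik = float(np.exp(q[r, r] * dt) * q[r, s])
            else:
                lik = float(p[p_of[k], r, int(s1) - 1])
            if lik <= 0.0:
                warnings.warn(
                    f"zero-probability observation pair for drug {drug_id} "
                    f"(from state {s0} to {s1}); log-likelihood -inf",
                    RuntimeWarning,
                    stacklevel=2,
                )
                return -np.inf
            total += np.log(lik)
    return total


# ---------------------------------------------------------------------------
# Compiled likelihood: the same quantity as `log_likelihood`, with the data
# layout precomputed once so repeated evaluations inside the optimizer are
# array operations.  Agreement with the plain implementation is enforced in
# the test suite.


class _CompiledGroup:
    __slots__ = ("z", "r_jump", "s_jump", "dt_jump", "r_stay", "dt_stay",
                 "cens", "panel", "abs_panel", "impossible")

    def __init__(self, z):
        self.z = np.array(z)
        self.impossible = False  # data contradict the observation scheme
        self.r_jump: List[int] = []
        self.s_jump: List[int] = []
        self.dt_jump: List[float] = []
        self.r_stay: List[int] = []
        self.dt_stay: List[float] = []
        # (r, target-state indices, dts): censored terminal sets
        self.cens: Dict[Tuple[int, Tuple[int, ...]], List[float]] = {}
        # (r, s, dts): panel-observed exact states
        self.panel: Dict[Tuple[int, int], List[float]] = {}
        # (r, s, dts): exactly timed absorbing entries under panel-observed
        # transient states (sum over latent intermediate state)
        self.abs_panel: Dict[Tuple[int, int], List[float]] = {}


def _compile(data: PanelDataset, spec: ModelSpec) -> List[_CompiledGroup]:
    exact = spec.exact_transition_times
    groups = []
    for z, subjects in _subject_groups(data, spec).items():
        g = _CompiledGroup(z)
        for subj in subjects:
            for i in range(len(subj.times) - 1):
                s0 = int(subj.states[i])
                s1 = subj.states[i + 1]
                dt = float(subj.times[i + 1] - subj.times[i])
                r = s0 - 1
                if isinstance(s1, (frozenset, set)):
                    if exact:
                        # still in the last entered state (see log_likelihood)
                        if s0 not in s1:
                            g.impossible = True
                        g.r_stay.append(r)
                        g.dt_stay.append(dt)
                    else:
                        key = (r, tuple(sorted(s - 1 for s in s1)))
                        g.cens.setdefault(key, []).append(dt)
                elif int(s1) in spec.exact_absorbing:
                    if exact:
                        g.r_jump.append(r)
                        g.s_jump.append(int(s1) - 1)
                        g.dt_jump.append(dt)
                    else:
                        g.abs_panel.setdefault((r, int(s1) - 1), []).append(dt)
                elif exact:
                    if int(s1) == s0:
                        g.r_stay.append(r)
                        g.dt_stay.append(dt)
                    else:
                        g.r_jump.append(r)
                        g.s_jump.append(int(s1) - 1)
                        g.dt_jump.append(dt)
                else:
                    g.panel.setdefault((r, int(s1) - 1), []).append(dt)
        groups.append(g)
    for g in groups:
        g.r_jump = np.asarray(g.r_jump, dtype=int)
        g.s_jump = np.asarray(g.s_jump, dtype=int)
        g.dt_jump = np.asarray(g.dt_jump)
        g.r_stay = np.asarray(g.r_stay, dtype=int)
        g.dt_stay = np.asarray(g.dt_stay)
        g.cens = {k: np.asarray(v) for k, v in g.cens.items()}
        g.panel = {k: np.asarray(v) for k, v in g.panel.items()}
        g.abs_panel = {k: np.asarray(v) for k, v in g.abs_panel.items()}
    return groups


def _ll_compiled(groups: List[_CompiledGroup], spec: ModelSpec, x: np.ndarray) -> float:
    total = 0.0
    transient_idx = np.array([s - 1 for s in spec.transient])
    for g in groups:
        if g.impossible:
            return -np.inf
        q = _q_matrix(spec, x, g.z)
        qd = np.diag(q)
        if g.r_jump.size:
            rates = q[g.r_jump, g.s_jump]
            if np.any(rates <= 0.0):
                return -np.inf
            total += float(np.sum(qd[g.r_jump] * g.dt_jump) + np.sum(np.log(rates)))
        if g.r_stay.size:
            total += float(np.sum(qd[g.r_stay] * g.dt_stay))
        if not (g.cens or g.panel or g.abs_panel):
            continue
        w, v = np.linalg.eig(q)
        try:
            vinv = np.linalg.inv(v)
            spectral = np.linalg.cond(v) < _EIG_COND_MAX
        except np.linalg.LinAlgError:
            spectral = False

        def _rows(r: int, weights: np.ndarray, dts: np.ndarray) -> np.ndarray:
            """sum_s weights[s] * P_rs(dt) for a batch of dts."""
            if spectral:
                c = v[r, :] * (vinv @ weights)
                return (np.exp(np.multiply.outer(dts, w)) @ c).real
            return np.array(
                [float(expm(q * t)[r, :] @ weights) for t in dts]
            )

        for (r, targets), dts in g.cens.items():
            weights = np.zeros(spec.n_states)
            weights[list(targets)] = 1.0
            vals = _rows(r, weights, dts)
            if np.any(vals <= 0.0):
                return -np.inf
            total += float(np.sum(np.log(vals)))
        for (r, s), dts in g.panel.items():
            weights = np.zeros(spec.n_states)
            weights[s] = 1.0
            vals = _rows(r, weights, dts)
            if np.any(vals <= 0.0):
                return -np.inf
            total += float(np.sum(np.log(vals)))
        for (r, s), dts in g.abs_panel.items():
            weights = np.zeros(spec.n_states)
            weights[transient_idx] = q[transient_idx, s]
            vals = _rows(r, weights, dts)
            if np.any(vals <= 0.0):
                return -np.inf
            total += float(np.sum(np.log(vals)))
    return total


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    """Maximum-likelihood fit of a multi-state model.

    ``covariance`` is the inverse observed information on the working
    (log/linear) scale; it is ``None`` when the information matrix is
    singular, in which case confidence intervals are reported as absent.
    """

    spec: ModelSpec
    estimate: ParameterVector
    log_likelihood: float
    covariance: Optional[np.ndarray]
    converged: bool
    n_subjects: int
    n_observations: int
    message: str = ""

    @property
    def params(self) -> np.ndarray:
        return self.estimate.to_flat()

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    def std_errors(self) -> np.ndarray:
        if self.covariance is None:
            return np.full(self.n_params, np.nan)
        d = np.diag(self.covariance)
        return np.where(d >= 0, np.sqrt(np.maximum(d, 0)), np.nan)

    @property
    def hazard_ratios(self):
        """Map (transition | 'shared', covariate) -> (point, lower95, upper95)."""
        out = {}
        se = self.std_errors()
        for j, (key, cov) in enumerate(self.spec.beta_keys):
            b = self.params[self.spec.n_baseline + j]
            s = se[self.spec.n_baseline + j]
            if np.isfinite(s) and s > 0:
                ci = (np.exp(b - 1.96 * s), np.exp(b + 1.96 * s))
            else:
                ci = (None, None)
            out[(key, cov)] = (float(np.exp(b)), ci[0], ci[1])
        return out

    def intensity(
        self, transition: Transition, covariates: Optional[Mapping[str, float]] = None
    ) -> Tuple[float, Optional[float], Optional[float]]:
        """Fitted intensity q_rs(z) with a delta-method 95% Wald CI on the
        log scale."""
        if transition not in self.spec.transitions:
            raise KeyError(f"transition {transition} not in model")
        z = _covariate_vector(self.spec, covariates)
        k = self.spec.transitions.index(transition)
        grad = np.zeros(self.n_params)
        grad[k] = 1.0
        logq = self.params[k]
        cov_idx = {c: i for i, c in enumerate(self.spec.covariates)}
        for c in self.spec.covariate_attachment.get(transition, ()):
            j = self.spec.beta_index(transition, c)
            logq += self.params[j] * z[cov_idx[c]]
            grad[j] += z[cov_idx[c]]
        point = float(np.exp(logq))
        if self.covariance is None:
            return point, None, None
        var = float(grad @ self.covariance @ grad)
        if var < 0 or not np.isfinite(var):
            return point, None, None
        se = np.sqrt(var)
        return point, float(np.exp(logq - 1.96 * se)), float(np.exp(logq + 1.96 * se))


def _crude_rate_init(data: PanelDataset, spec: ModelSpec) -> np.ndarray:
    """Log crude rates: observed direct transitions / total time at risk,
    floored at 1e-6 events per year."""
    counts = {tr: 0.0 for tr in spec.transitions}
    exposure = {s: 0.0 for s in spec.transient}
    for subj in data.subjects:
        for i in range(len(subj.times) - 1):
            s0 = int(subj.states[i])
            dt = subj.times[i + 1] - subj.times[i]
            if s0 in exposure:
                exposure[s0] += dt
            s1 = subj.states[i + 1]
            if not isinstance(s1, (frozenset, set)) and (s0, int(s1)) in counts:
                counts[(s0, int(s1))] += 1.0
    x0 = np.zeros(spec.n_params)
    for k, (r, s) in enumerate(spec.transitions):
        rate = counts[(r, s)] / max(exposure[r], 1e-12)
        x0[k] = np.log(max(rate, 1e-6))
    return x0


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    hess = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def fit(
    data: PanelDataset,
    spec: ModelSpec,
    init: Optional[ParameterVector] = None,
    seed: int = 20210223,
    max_iter: int = 500,
    gtol: float = 1e-6,
    compute_covariance: bool = True,
) -> FitResult:
    """Maximum-likelihood fit by BFGS on the unconstrained parameters.

    ``init`` defaults to log crude rates (observed transition counts over
    time at risk) with betas at zero.  ``seed`` is reserved for stochastic
    restarts and recorded for reproducibility; the default optimisation is
    deterministic.
    """
    del seed  # deterministic path; retained in the signature for config plumbing
    observed = {int(s) for subj in data.subjects for s in subj.states
                if not isinstance(s, (frozenset, set))}
    for (r, s) in spec.transitions:
        if r not in observed:
            warnings.warn(
                f"no subject ever observed in state {r}; transition {r}->{s} "
                "is unidentified and its estimate will sit at the boundary",
                RuntimeWarning,
                stacklevel=2,
            )
            break

    x0 = init.to_flat() if init is not None else _crude_rate_init(data, spec)
    compiled = _compile(data, spec)

    def negll(x: np.ndarray) -> float:
        ll = _ll_compiled(compiled, spec, x)
        return 1e12 if not np.isfinite(ll) else -ll

    res = optimize.minimize(
        negll, x0, method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    xhat = res.x
    cov = None
    if compute_covariance:
        try:
            hess = _numeric_hessian(negll, xhat)
            cov = np.linalg.inv(hess)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
                cov = None
        except np.linalg.LinAlgError:
            cov = None
    # BFGS reports success=False on line-search stalls even at an optimum;
    # accept a small gradient as converged.
    grad_ok = np.max(np.abs(res.jac)) < 1e-3 * (1 + abs(res.fun)) if res.jac is not None else False
    return FitResult(
        spec=spec,
        estimate=ParameterVector.from_flat(xhat, spec),
        log_likelihood=-res.fun,
        covariance=cov,
        converged=bool(res.success or grad_ok),
        n_subjects=len(data),
        n_observations=data.n_observations,
        message=res.message,
    )


def hazard_ratio(
    fit_result: FitResult, transition: Transition, covariate: str
) -> Tuple[float, Optional[float], Optional[float]]:
    """exp(beta) with its 95% Wald CI for one (transition, covariate)."""
    spec = fit_result.spec
    j = spec.beta_index(transition, covariate)
    b = fit_result.params[j]
    se = fit_result.std_errors()[j]
    point = float(np.exp(b))
    if not np.isfinite(se) or se <= 0:
        return point, None, None
    return point, float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


def _structurally_nested(null: ModelSpec, alt: ModelSpec) -> bool:
    if null.transitions != alt.transitions:
        return False
    if set(null.beta_keys) <= set(alt.beta_keys):
        return True
    # a shared beta is nested in per-transition betas over the same wiring
    if null.shared_effects and not alt.shared_effects:
        null_pairs = {
            (tr, c)
            for tr in null.transitions
            for c in null.covariate_attachment.get(tr, ())
        }
        alt_pairs = set(alt.beta_keys)
        return null_pairs <= alt_pairs
    return False


def likelihood_ratio_test(
    fit_null: FitResult, fit_alt: FitResult, df: Optional[int] = None
) -> LRTResult:
    """Compare nested fits: statistic 2*(ll_alt - ll_null) against chi-square.

    Nesting is checked structurally from the two specs; for constraints the
    spec machinery cannot express (e.g. equality of betas across covariate
    levels) pass ``df`` explicitly, which asserts the nesting by fiat.
    """
    if df is None:
        if not _structurally_nested(fit_null.spec, fit_alt.spec):
            raise ValueError("models are not structurally nested; pass df explicitly")
        df = fit_alt.n_params - fit_null.n_params
    if df <= 0:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
    stat = max(0.0, 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood))
    return LRTResult(
        statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df))
    )
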