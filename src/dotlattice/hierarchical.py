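"""Hierarchical Bayesian logistic models of dot-lattice percepts.

The core model predicts the binary percept of the second lattice,
``y2 ~ Bernoulli(logistic(eta))`` with

    eta = beta0 + beta_AR * centered_ar + beta_R1 * r1
          + b_i0 + b_i,AR * centered_ar + b_i,R1 * r1

where ``beta_R1`` is the population hysteresis effect (attraction toward
the previous percept), ``beta_AR`` the population adaptation effect
(repulsion from the previous stimulus evidence, positive when coded on the
0°-percept), and ``b_i`` are per-participant deviations with estimated
standard deviations and a full correlation matrix.  The same machinery
fits the first-lattice proximity model (``r1 ~ centered_ar``), variants
with dropped or common (non-random) terms, sign-constrained population
effects, and two-session joint models whose individual deviations are
uncorrelated, freely correlated, or fully shared across sessions.

Inference is Hamiltonian Monte Carlo on the unconstrained parameter space
(non-centered deviations, log standard deviations, tanh-transformed
canonical partial correlations) with dual-averaging step-size adaptation
and a diagonal mass matrix.  Aggregating Bernoulli trials into binomial
cells per (participant, session, aspect ratio, previous percept) makes the
likelihood and its analytic gradient cheap, so desk-scale fits take
seconds.  The log joint density (with all normalizing constants) is
exposed for bridge-sampling marginal likelihoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import betaln

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "SamplerConfig",
    "PosteriorDraws",
    "HierarchicalLogistic",
    "build_model",
    "fit",
    "individual_effect_summaries",
    "fixed_effect_summary",
    "hdci",
]

TERMS = ("intercept", "centered_ar", "r1", "ar_by_r1")
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative default priors, all zero-centered and symmetric.

    ``fixed_scale``: SD of the normal prior on population effects (logit
    units); ``sd_scale``: scale of the half-normal prior on random-effect
    SDs; ``lkj_eta``: shape of the LKJ prior on the random-effect
    correlation matrix (1 = uniform over correlation matrices).
    """

    fixed_scale: float = 2.0
    sd_scale: float = 1.0
    lkj_eta: float = 1.0


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model variant.

    ``sign_constraint`` restricts the *population* effect of a term to one
    sign (individual deviations stay unconstrained), realized by sampling
    the constrained coefficient on a log scale.  ``sessions`` selects the
    cross-session structure of individual deviations; ``session_effect``
    names the term carrying that structure (all random terms if None).
    """

    outcome: str = "l2_percept"  # l2_percept | l1_percept
    fixed_terms: tuple[str, ...] = ("intercept", "centered_ar", "r1")
    random_terms: tuple[str, ...] = ("intercept", "centered_ar", "r1")
    sign_constraint: Mapping[str, str] = field(default_factory=dict)
    sessions: str = "single"  # single | joint_uncorrelated | joint_correlated | joint_fully_correlated
    session_effect: str | None = None
    prior_config: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self):
        if self.outcome not in ("l2_percept", "l1_percept"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        allowed = TERMS if self.outcome == "l2_percept" else ("intercept", "centered_ar")
        for t in self.fixed_terms:
            if t not in allowed:
                raise ValueError(f"term {t!r} not allowed for outcome {self.outcome}")
        extra = set(self.random_terms) - set(self.fixed_terms)
        if extra:
            raise ValueError(f"random terms {sorted(extra)} not among fixed terms")
        for t, s in self.sign_constraint.items():
            if t not in self.fixed_terms:
                raise ValueError(f"sign constraint on absent term {t!r}")
            if s not in ("positive", "negative", "none"):
                raise ValueError(f"unknown sign constraint {s!r}")
        if self.sessions not in (
            "single",
            "joint_uncorrelated",
            "joint_correlated",
            "joint_fully_correlated",
        ):
            raise ValueError(f"unknown sessions mode {self.sessions!r}")
        if self.session_effect is not None and self.session_effect not in self.random_terms:
            raise ValueError("session_effect must be one of the random terms")


@dataclass(frozen=True)
class SamplerConfig:
    """HMC settings.  ``iterations`` is the per-chain total; the first
    ``warmup`` iterations (default: half) adapt step size and mass matrix
    and are discarded.  The replication-scale configuration mirrors the
    study (4 chains x 20,000 iterations, target acceptance .8, maximum
    2^10 leapfrog steps); the package default is desk-scale."""

    chains: int = 4
    iterations: int = 1500
    warmup: int | None = None
    target_accept: float = 0.8
    max_treedepth: int = 10
    seed: int = 0
    max_leapfrog: int = 32
    divergence_tolerance: float = 0.05

    @property
    def n_warmup(self) -> int:
        w = self.iterations // 2 if self.warmup is None else self.warmup
        if not 0 <= w < self.iterations:
            raise ValueError("need iterations > warmup >= 0")
        return w


def _chol_from_z(z: np.ndarray, R: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from canonical partial
    correlations ``z`` (row-major, (...,) + (m,)); vectorized over leading axes."""
    lead = z.shape[:-1]
    L = np.zeros(lead + (R, R))
    L[..., 0, 0] = 1.0
    idx = 0
    for i in range(1, R):
        rem = np.ones(lead)
        for j in range(i):
            zij = z[..., idx]
            idx += 1
            L[..., i, j] = zij * np.sqrt(rem)
            rem = rem * (1.0 - zij**2)
        L[..., i, i] = np.sqrt(rem)
    return L


def _binomial_cells(data: pd.DataFrame, outcome: str) -> pd.DataFrame:
    y = "y2" if outcome == "l2_percept" else "r1"
    keys = ["participant", "session", "centered_ar"]
    if outcome == "l2_percept":
        keys.append("r1")
    g = data.groupby(keys, sort=True)[y].agg(["count", "sum"]).reset_index()
    if outcome == "l1_percept":
        g["r1"] = 0.0
    return g.rename(columns={"count": "n", "sum": "k"})


class HierarchicalLogistic:
    """A built model: data cells, parameter packing, log joint and gradient.

    The unconstrained parameter vector is laid out as
    ``[fixed effects | log SDs | correlation params | deviations]``; all
    transforms carry their Jacobians so ``logpost`` is the exact log joint
    density on the unconstrained space.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        if len(data) == 0:
            raise ValueError("data is empty")
        self.spec = spec
        self.prior = spec.prior_config
        cells = _binomial_cells(data, spec.outcome)
        self.participants = sorted(cells["participant"].unique())
        self.P = len(self.participants)
        pmap = {p: i for i, p in enumerate(self.participants)}
        self.joint = spec.sessions != "single"
        sessions = sorted(cells["session"].unique())
        if self.joint:
            if len(sessions) != 2:
                raise ValueError(f"joint model needs exactly 2 sessions, got {sessions}")
            counts = cells.groupby("participant")["session"].nunique()
            missing = counts[counts < 2]
            if len(missing):
                raise ValueError(
                    f"participant {missing.index[0]!r} is missing a session"
                )
        self.sessions = sessions
        self.S = 2 if self.joint else 1
        smap = {s: i for i, s in enumerate(sessions)}

        self.pidx = cells["participant"].map(pmap).to_numpy(int)
        self.sidx = (
            cells["session"].map(smap).to_numpy(int) if self.joint else np.zeros(len(cells), int)
        )
        self.n = cells["n"].to_numpy(float)
        self.k = cells["k"].to_numpy(float)
        car = cells["centered_ar"].to_numpy(float)
        r1 = cells["r1"].to_numpy(float)
        cols = {"intercept": np.ones(len(cells)), "centered_ar": car, "r1": r1,
                "ar_by_r1": car * r1}
        self.F = len(spec.fixed_terms)
        self.R = len(spec.random_terms)
        self.X = np.column_stack([cols[t] for t in spec.fixed_terms])
        self.Z = (
            np.column_stack([cols[t] for t in spec.random_terms])
            if self.R
            else np.zeros((len(cells), 0))
        )
        self._fingerprint = hash(
            (spec.outcome, tuple(self.pidx), tuple(self.sidx), tuple(self.n),
             tuple(self.k), tuple(np.round(car, 9)), tuple(np.round(r1, 9)))
        )

        # sign transforms for constrained population effects
        self.sign = np.array(
            [
                {"positive": 1.0, "negative": -1.0}.get(
                    spec.sign_constraint.get(t, "none"), 0.0
                )
                for t in spec.fixed_terms
            ]
        )  # 0.0 = unconstrained

        # cross-session structure per random term
        if self.joint:
            mode = spec.sessions.removeprefix("joint_")
            self.structure = [
                mode
                if (spec.session_effect is None or t == spec.session_effect)
                else "uncorrelated"
                for t in spec.random_terms
            ]
        else:
            self.structure = []

        # parameter packing
        self._slices: dict[str, slice] = {}
        pos = 0

        def add(name, size):
            nonlocal pos
            self._slices[name] = slice(pos, pos + size)
            pos += size

        add("beta", self.F * self.S)
        add("logtau", self.R * self.S)
        if not self.joint:
            self.m = self.R * (self.R - 1) // 2
            add("ycorr", self.m)
            self.ucols = self.R
        else:
            self.m = 0
            self.n_rho = sum(1 for s in self.structure if s == "correlated")
            add("yrho", self.n_rho)
            self.ucols = sum(1 if s == "fully_correlated" else 2 for s in self.structure)
        add("u", self.P * self.ucols)
        self.n_params = pos

        # LKJ-equivalent scaled-Beta shapes for the canonical partial correlations
        if not self.joint and self.m:
            shapes = []
            for i in range(1, self.R):
                for j in range(i):
                    shapes.append(self.prior.lkj_eta + (self.R - 2 - j) / 2.0)
            self._z_shapes = np.array(shapes)
            self._z_lnorm = betaln(self._z_shapes, self._z_shapes) + math.log(2.0)
        # u-column offsets per random term (joint layout)
        if self.joint:
            offs, o = [], 0
            for s in self.structure:
                offs.append(o)
                o += 1 if s == "fully_correlated" else 2
            self._u_offsets = offs

    # ---- packing helpers -------------------------------------------------
    def _get(self, theta: np.ndarray, name: str) -> np.ndarray:
        return theta[..., self._slices[name]]

    def param_names(self) -> list[str]:
        names = []
        for s in range(self.S):
            tag = f"_s{self.sessions[s]}" if self.joint else ""
            names += [f"beta_{t}{tag}" for t in self.spec.fixed_terms]
        for s in range(self.S):
            tag = f"_s{self.sessions[s]}" if self.joint else ""
            names += [f"sd_{t}{tag}" for t in self.spec.random_terms]
        if not self.joint:
            names += [f"ycorr_{i}" for i in range(self.m)]
        else:
            names += [f"rho_{t}" for t, s in zip(self.spec.random_terms, self.structure)
                      if s == "correlated"]
        names += [f"u_{i}" for i in range(self.P * self.ucols)]
        return names

    # ---- transforms ------------------------------------------------------
    def _beta(self, theta: np.ndarray) -> np.ndarray:
        """Population effects, shape (..., S, F)."""
        raw = self._get(theta, "beta").reshape(theta.shape[:-1] + (self.S, self.F))
        sign = self.sign
        return np.where(sign == 0.0, raw, sign * np.exp(raw))

    def _tau(self, theta: np.ndarray) -> np.ndarray:
        return np.exp(self._get(theta, "logtau")).reshape(
            theta.shape[:-1] + (self.S, self.R)
        )

    def _corr_chol(self, theta: np.ndarray) -> np.ndarray | None:
        if self.joint or self.R == 0:
            return None
        if self.m == 0:
            shape = theta.shape[:-1] + (self.R, self.R)
            L = np.zeros(shape)
            L[..., 0, 0] = 1.0
            return L
        z = np.tanh(self._get(theta, "ycorr"))
        return _chol_from_z(z, self.R)

    def _deviations(self, theta: np.ndarray) -> np.ndarray:
        """Individual deviations b, shape (..., P, S, R)."""
        lead = theta.shape[:-1]
        tau = self._tau(theta)  # (..., S, R)
        U = self._get(theta, "u").reshape(lead + (self.P, self.ucols))
        if not self.joint:
            L = self._corr_chol(theta)  # (..., R, R)
            V = np.einsum("...pj,...rj->...pr", U, L)
            b = V * tau[..., 0, :][..., None, :]
            return b[..., :, None, :]  # (..., P, 1, R)
        b = np.zeros(lead + (self.P, 2, self.R))
        if self.n_rho:
            rho_list = np.tanh(self._get(theta, "yrho"))
        ri = 0
        for r, (term_s, off) in enumerate(zip(self.structure, self._u_offsets)):
            t1 = tau[..., 0, r][..., None]
            t2 = tau[..., 1, r][..., None]
            if term_s == "fully_correlated":
                shared = U[..., :, off]
                b[..., :, 0, r] = t1 * shared
                b[..., :, 1, r] = t2 * shared
            elif term_s == "correlated":
                rho = rho_list[..., ri][..., None]
                ri += 1
                ua, ub = U[..., :, off], U[..., :, off + 1]
                b[..., :, 0, r] = t1 * ua
                b[..., :, 1, r] = t2 * (rho * ua + np.sqrt(1.0 - rho**2) * ub)
            else:
                b[..., :, 0, r] = t1 * U[..., :, off]
                b[..., :, 1, r] = t2 * U[..., :, off + 1]
        return b

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Named constrained-space view of unconstrained draws (vectorized)."""
        out: dict[str, np.ndarray] = {}
        beta = self._beta(theta)
        tau = self._tau(theta)
        for s in range(self.S):
            tag = f"_s{self.sessions[s]}" if self.joint else ""
            for f, t in enumerate(self.spec.fixed_terms):
                out[f"beta_{t}{tag}"] = beta[..., s, f]
            for r, t in enumerate(self.spec.random_terms):
                out[f"sd_{t}{tag}"] = tau[..., s, r]
        if not self.joint and self.R >= 2:
            L = self._corr_chol(theta)
            C = np.einsum("...ij,...kj->...ik", L, L)
            out["corr"] = C
            for i in range(1, self.R):
                for j in range(i):
                    ti, tj = self.spec.random_terms[i], self.spec.random_terms[j]
                    out[f"corr_{tj}_{ti}"] = C[..., i, j]
        if self.joint and self.n_rho:
            rho = np.tanh(self._get(theta, "yrho"))
            ri = 0
            for t, s in zip(self.spec.random_terms, self.structure):
                if s == "correlated":
                    out[f"rho_{t}"] = rho[..., ri]
                    ri += 1
        b = self._deviations(theta)
        for s in range(self.S):
            tag = f"_s{self.sessions[s]}" if self.joint else ""
            for r, t in enumerate(self.spec.random_terms):
                f = self.spec.fixed_terms.index(t)
                out[f"individual_{t}{tag}"] = beta[..., s, f][..., None] + b[..., :, s, r]
        return out

    # ---- density ---------------------------------------------------------
    def _eta(self, theta: np.ndarray) -> np.ndarray:
        beta = self._beta(theta)
        bsel = beta[..., self.sidx, :]  # (..., C, F) session-specific fixed part
        eta = np.einsum("cf,...cf->...c", self.X, bsel)
        if self.R:
            b = self._deviations(theta)  # (..., P, S, R)
            bcell = b[..., self.pidx, self.sidx, :]  # (..., C, R)
            eta = eta + np.einsum("cr,...cr->...c", self.Z, bcell)
        return eta

    def loglik(self, theta: np.ndarray) -> np.ndarray:
        eta = self._eta(theta)
        return (self.k * eta - self.n * np.logaddexp(0.0, eta)).sum(axis=-1)

    def logprior(self, theta: np.ndarray) -> np.ndarray:
        s_f, s_sd = self.prior.fixed_scale, self.prior.sd_scale
        raw_beta = self._get(theta, "beta").reshape(theta.shape[:-1] + (self.S, self.F))
        beta = self._beta(theta)
        lp = (-0.5 * (beta / s_f) ** 2 - math.log(s_f) - 0.5 * _LOG_2PI).sum(axis=(-1, -2))
        constrained = self.sign != 0.0
        if constrained.any():
            # half-normal on |beta| plus log-scale Jacobian
            lp = lp + (math.log(2.0) * constrained.sum() * self.S)
            lp = lp + np.where(constrained, raw_beta, 0.0).sum(axis=(-1, -2))
        logtau = self._get(theta, "logtau")
        tau = np.exp(logtau)
        lp = lp + (
            -0.5 * (tau / s_sd) ** 2 - math.log(s_sd) - 0.5 * _LOG_2PI + math.log(2.0)
            + logtau
        ).sum(axis=-1)
        if not self.joint and self.m:
            y = self._get(theta, "ycorr")
            z = np.clip(np.tanh(y), -1.0 + 1e-12, 1.0 - 1e-12)
            a = self._z_shapes
            u01 = 0.5 * (1.0 + z)
            lp = lp + (
                (a - 1.0) * (np.log(u01) + np.log1p(-u01)) - self._z_lnorm
                + np.log1p(-z**2)
            ).sum(axis=-1)
        if self.joint and getattr(self, "n_rho", 0):
            y = self._get(theta, "yrho")
            z = np.clip(np.tanh(y), -1.0 + 1e-12, 1.0 - 1e-12)
            lp = lp + (-math.log(2.0) + np.log1p(-z**2)).sum(axis=-1)
        u = self._get(theta, "u")
        lp = lp + (-0.5 * u**2 - 0.5 * _LOG_2PI).sum(axis=-1)
        return lp

    def logpost(self, theta: np.ndarray) -> np.ndarray:
        """Log joint density (likelihood x priors, all constants included)
        on the unconstrained space; this is the bridge-sampling target."""
        return self.loglik(theta) + self.logprior(theta)

    # ---- gradient --------------------------------------------------------
    def grad(self, theta: np.ndarray) -> np.ndarray:
        """Analytic gradient of ``logpost`` for the fixed-effect, SD and
        deviation blocks; central finite differences for the few
        correlation parameters."""
        theta = np.asarray(theta, dtype=float)
        g = np.zeros_like(theta)
        s_f, s_sd = self.prior.fixed_scale, self.prior.sd_scale

        beta = self._beta(theta)  # (S, F)
        tau_all = self._tau(theta)  # (S, R)
        b = self._deviations(theta)  # (P, S, R)
        bsel = beta[self.sidx, :]
        eta = self.X @ beta.T  # (C, S) -- not right for joint; compute directly
        eta = np.einsum("cf,cf->c", self.X, bsel)
        if self.R:
            bcell = b[self.pidx, self.sidx, :]
            eta = eta + np.einsum("cr,cr->c", self.Z, bcell)
        resid = self.k - self.n * (0.5 * (1.0 + np.tanh(0.5 * eta)))  # k - n*sigmoid

        # beta gradient (per session)
        gbeta = np.zeros((self.S, self.F))
        for s in range(self.S):
            mask = self.sidx == s
            gbeta[s] = self.X[mask].T @ resid[mask]
        gbeta += -beta / s_f**2
        constrained = self.sign != 0.0
        graw = np.where(constrained, gbeta * beta + 1.0, gbeta)
        g[self._slices["beta"]] = graw.ravel()

        if self.R:
            # gradient wrt deviations b: (P, S, R)
            Gb = np.zeros((len(self.participants), self.S, self.R))
            np.add.at(Gb, (self.pidx, self.sidx), self.Z * resid[:, None])
            # log tau: d/dlogtau = sum_p Gb * b (b linear in tau) + prior
            gl = np.einsum("psr,psr->sr", Gb, b)
            gl += -(tau_all**2) / s_sd**2 + 1.0
            g[self._slices["logtau"]] = gl.ravel()
            # u block
            U = self._get(theta, "u").reshape(self.P, self.ucols)
            gU = np.zeros_like(U)
            if not self.joint:
                L = self._corr_chol(theta)
                gU = (Gb[:, 0, :] * tau_all[0]) @ L
            else:
                rho_list = np.tanh(self._get(theta, "yrho")) if self.n_rho else None
                ri = 0
                for r, (term_s, off) in enumerate(zip(self.structure, self._u_offsets)):
                    t1, t2 = tau_all[0, r], tau_all[1, r]
                    if term_s == "fully_correlated":
                        gU[:, off] = t1 * Gb[:, 0, r] + t2 * Gb[:, 1, r]
                    elif term_s == "correlated":
                        rho = rho_list[ri]
                        ri += 1
                        gU[:, off] = t1 * Gb[:, 0, r] + t2 * rho * Gb[:, 1, r]
                        gU[:, off + 1] = t2 * math.sqrt(1.0 - rho**2) * Gb[:, 1, r]
                    else:
                        gU[:, off] = t1 * Gb[:, 0, r]
                        gU[:, off + 1] = t2 * Gb[:, 1, r]
            gU = gU - U
            g[self._slices["u"]] = gU.ravel()

        # correlation-transform parameters: central finite differences,
        # batched into a single vectorized logpost call
        idxs = [
            i
            for name in ("ycorr", "yrho")
            if (sl := self._slices.get(name)) is not None
            for i in range(sl.start, sl.stop)
        ]
        if idxs:
            h = 1e-5
            batch = np.tile(theta, (2 * len(idxs), 1))
            for j, i in enumerate(idxs):
                batch[2 * j, i] += h
                batch[2 * j + 1, i] -= h
            lps = self.logpost(batch)
            for j, i in enumerate(idxs):
                g[i] = (lps[2 * j] - lps[2 * j + 1]) / (2.0 * h)
        return g

    # ---- prior simulation -------------------------------------------------
    def sample_prior(self, n_draws: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Forward draws from the model prior in the named (constrained)
        space, including per-participant individual total effects."""
        s_f, s_sd = self.prior.fixed_scale, self.prior.sd_scale
        out: dict[str, np.ndarray] = {}
        beta = rng.normal(0.0, s_f, size=(n_draws, self.S, self.F))
        beta = np.where(self.sign == 0.0, beta, self.sign * np.abs(beta))
        tau = np.abs(rng.normal(0.0, s_sd, size=(n_draws, self.S, self.R)))
        if not self.joint and self.m:
            z = 2.0 * rng.beta(self._z_shapes, self._z_shapes, size=(n_draws, self.m)) - 1.0
            L = _chol_from_z(z, self.R)
        elif self.R:
            L = np.broadcast_to(np.eye(self.R), (n_draws, self.R, self.R))
        if self.joint and self.n_rho:
            rho = rng.uniform(-1.0, 1.0, size=(n_draws, self.n_rho))
        for s in range(self.S):
            tag = f"_s{self.sessions[s]}" if self.joint else ""
            for f, t in enumerate(self.spec.fixed_terms):
                out[f"beta_{t}{tag}"] = beta[:, s, f]
            for r, t in enumerate(self.spec.random_terms):
                out[f"sd_{t}{tag}"] = tau[:, s, r]
        if self.R:
            if not self.joint:
                uu = rng.standard_normal((n_draws, self.P, self.R))
                V = np.einsum("npj,nrj->npr", uu, L)
                b = V * tau[:, 0, :][:, None, :]
                b = b[:, :, None, :]
            else:
                b = np.zeros((n_draws, self.P, 2, self.R))
                ri = 0
                for r, term_s in enumerate(self.structure):
                    t1 = tau[:, 0, r][:, None]
                    t2 = tau[:, 1, r][:, None]
                    if term_s == "fully_correlated":
                        ua = rng.standard_normal((n_draws, self.P))
                        b[:, :, 0, r] = t1 * ua
                        b[:, :, 1, r] = t2 * ua
                    elif term_s == "correlated":
                        ua = rng.standard_normal((n_draws, self.P))
                        ub = rng.standard_normal((n_draws, self.P))
                        rr = rho[:, ri][:, None]
                        ri += 1
                        b[:, :, 0, r] = t1 * ua
                        b[:, :, 1, r] = t2 * (rr * ua + np.sqrt(1.0 - rr**2) * ub)
                    else:
                        b[:, :, 0, r] = t1 * rng.standard_normal((n_draws, self.P))
                        b[:, :, 1, r] = t2 * rng.standard_normal((n_draws, self.P))
            for s in range(self.S):
                tag = f"_s{self.sessions[s]}" if self.joint else ""
                for r, t in enumerate(self.spec.random_terms):
                    f = self.spec.fixed_terms.index(t)
                    out[f"individual_{t}{tag}"] = beta[:, s, f][:, None] + b[:, :, s, r]
        if not self.joint and self.R >= 2:
            out["corr"] = np.einsum("nij,nkj->nik", L, L)
        return out

    def prior_predictive_p(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Prior-predictive success probabilities at the observed cells."""
        prior = self.sample_prior(n_draws, rng)
        # rebuild eta from named draws at cell level
        beta = np.stack(
            [
                np.stack(
                    [prior[f"beta_{t}" + (f"_s{self.sessions[s]}" if self.joint else "")]
                     for t in self.spec.fixed_terms],
                    axis=-1,
                )
                for s in range(self.S)
            ],
            axis=1,
        )  # (n, S, F)
        eta = np.einsum("cf,ncf->nc", self.X, beta[:, self.sidx, :])
        for r, t in enumerate(self.spec.random_terms):
            for s in range(self.S):
                tag = f"_s{self.sessions[s]}" if self.joint else ""
                ind = prior[f"individual_{t}{tag}"]  # (n, P)
                f = self.spec.fixed_terms.index(t)
                dev = ind - beta[:, s, f][:, None]
                mask = self.sidx == s
                eta[:, mask] += self.Z[mask, r][None, :] * dev[:, self.pidx[mask]]
        return 0.5 * (1.0 + np.tanh(0.5 * eta))

    def initial_value(self, rng: np.random.Generator) -> np.ndarray:
        theta = 0.1 * rng.standard_normal(self.n_params)
        theta[self._slices["logtau"]] = math.log(0.5) + 0.1 * rng.standard_normal(
            self.R * self.S
        )
        return theta


def build_model(spec: ModelSpec, data: pd.DataFrame) -> HierarchicalLogistic:
    """Build the Bernoulli-logit multilevel model for a binary-trial table."""
    return HierarchicalLogistic(spec, data)


# ---- sampling --------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Labeled MCMC output: unconstrained draws (chain x draw x param), the
    model that maps them to named quantities, and convergence diagnostics."""

    theta: np.ndarray
    model: HierarchicalLogistic
    diagnostics: dict

    def named(self) -> dict[str, np.ndarray]:
        return self.model.unpack(self.theta)

    def get(self, name: str) -> np.ndarray:
        return self.named()[name]

    def flat(self, name: str) -> np.ndarray:
        arr = self.get(name)
        return arr.reshape((-1,) + arr.shape[2:])

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]


def _leapfrog(theta, p, eps, n_steps, grad_fn, inv_mass):
    g = grad_fn(theta)
    for _ in range(n_steps):
        p = p + 0.5 * eps * g
        theta = theta + eps * inv_mass * p
        g = grad_fn(theta)
        p = p + 0.5 * eps * g
    return theta, p, g


def _hmc_chain(model, config, chain_seed, n_keep):
    # warmup excursions can overflow exp(log tau); the resulting non-finite
    # energies are rejected by the MH step, so the warnings are benign
    old_err = np.seterr(over="ignore", invalid="ignore")
    try:
        return _hmc_chain_inner(model, config, chain_seed, n_keep)
    finally:
        np.seterr(**old_err)


def _hmc_chain_inner(model, config, chain_seed, n_keep):
    rng = np.random.default_rng(chain_seed)
    dim = model.n_params
    theta = model.initial_value(rng)
    inv_mass = np.ones(dim)
    warmup = config.n_warmup
    # dual averaging (Hoffman & Gelman)
    eps = 0.1
    mu = math.log(10.0 * eps)
    log_eps_bar, H_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    delta = config.target_accept
    max_L = min(config.max_leapfrog, 2**config.max_treedepth)

    draws = np.empty((n_keep, dim))
    divergences = 0
    win_start = max(1, int(0.15 * warmup))
    checkpoints = {int(0.5 * warmup), int(0.9 * warmup)} if warmup > 20 else set()
    acc_sum = np.zeros(dim)
    acc_sq = np.zeros(dim)
    acc_n = 0
    kept = 0
    lp = model.logpost(theta)
    total = config.iterations
    for it in range(total):
        in_warmup = it < warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        L = int(rng.integers(1, max_L + 1))
        H0 = -lp + 0.5 * float(np.sum(inv_mass * p0**2))
        theta_new, p_new, _ = _leapfrog(theta, p0, eps, L, model.grad, inv_mass)
        lp_new = model.logpost(theta_new)
        H1 = -lp_new + 0.5 * float(np.sum(inv_mass * p_new**2))
        dH = H0 - H1
        if not np.isfinite(dH):
            accept_prob, diverged = 0.0, True
        else:
            accept_prob = min(1.0, math.exp(min(dH, 0.0)))
            diverged = (H1 - H0) > 1000.0
        if diverged and not in_warmup:
            divergences += 1
        if not diverged and rng.random() < accept_prob:
            theta, lp = theta_new, lp_new
        if in_warmup:
            # step-size adaptation
            frac = 1.0 / (it + 1 + t0)
            H_bar = (1.0 - frac) * H_bar + frac * (delta - accept_prob)
            log_eps = mu - math.sqrt(it + 1.0) / gamma * H_bar
            pw = (it + 1.0) ** (-kappa)
            log_eps_bar = pw * log_eps + (1.0 - pw) * log_eps_bar
            eps = math.exp(log_eps)
            # mass-matrix accumulation
            if it >= win_start:
                acc_sum += theta
                acc_sq += theta**2
                acc_n += 1
            if (it + 1) in checkpoints and acc_n > 10:
                var = acc_sq / acc_n - (acc_sum / acc_n) ** 2
                w = acc_n / (acc_n + 5.0)
                inv_mass = w * np.maximum(var, 1e-10) + (1.0 - w) * 1e-3
                acc_sum[:] = 0.0
                acc_sq[:] = 0.0
                acc_n = 0
                mu = math.log(10.0 * eps)
                H_bar = 0.0
            if it == warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            draws[kept] = theta
            kept += 1
    return draws, divergences, eps


def fit(model: HierarchicalLogistic, config: SamplerConfig | None = None) -> PosteriorDraws:
    """Sample the posterior with HMC; deterministic for a fixed seed.

    Diagnostics include per-parameter split R-hat and bulk/tail effective
    sample sizes over the population-level quantities; the fit is flagged
    unreliable (``diagnostics['reliable'] = False``) if any split R-hat
    exceeds 1.01 or any bulk ESS falls below 400.  A divergent-transition
    fraction above ``divergence_tolerance`` is recorded as a warning in the
    diagnostics, with draws still returned.
    """
    config = config or SamplerConfig()
    n_keep = config.iterations - config.n_warmup
    ss = np.random.SeedSequence([config.seed, 101])
    chain_seeds = ss.spawn(config.chains)
    all_draws = np.empty((config.chains, n_keep, model.n_params))
    div_total = 0
    step_sizes = []
    for c in range(config.chains):
        draws, div, eps = _hmc_chain(model, config, chain_seeds[c], n_keep)
        all_draws[c] = draws
        div_total += div
        step_sizes.append(eps)

    result = PosteriorDraws(theta=all_draws, model=model, diagnostics={})
    named = result.named()
    scalar = {
        k: v
        for k, v in named.items()
        if v.ndim == 2 and (k.startswith(("beta_", "sd_", "corr_", "rho_")))
    }
    idata = az.from_dict(posterior={k: v for k, v in scalar.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata, method="bulk")
    rhat_max = float(max(rhat[k].item() for k in scalar)) if scalar else 1.0
    ess_min = float(min(ess[k].item() for k in scalar)) if scalar else float("inf")
    frac_div = div_total / max(1, config.chains * n_keep)
    warnings_list = []
    if frac_div > config.divergence_tolerance:
        warnings_list.append(
            f"divergent transitions: {frac_div:.1%} of post-warmup iterations"
        )
    result.diagnostics = {
        "rhat_max": rhat_max,
        "ess_bulk_min": ess_min,
        "divergences": div_total,
        "divergence_fraction": frac_div,
        "step_sizes": step_sizes,
        "reliable": bool(rhat_max <= 1.01 and ess_min >= 400),
        "warnings": warnings_list,
    }
    return result


# ---- summaries -------------------------------------------------------------


def hdci(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density continuous interval of a sample (shortest interval
    containing the stated posterior mass)."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(x)
    k = max(1, int(math.ceil(mass * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def fixed_effect_summary(draws: PosteriorDraws, term: str, mass: float = 0.95,
                         session: int | None = None) -> dict:
    """Posterior mean and HDCI of one population effect."""
    tag = f"_s{session}" if session is not None else ""
    x = draws.flat(f"beta_{term}{tag}")
    lo, hi = hdci(x, mass)
    return {"term": term, "mean": float(x.mean()), "hdci_low": lo, "hdci_high": hi,
            "mass": mass}


def individual_effect_summaries(
    draws: PosteriorDraws, effect: str, mass: float = 0.95, session: int | None = None
) -> pd.DataFrame:
    """Per-participant posterior mean and HDCI of the individual total
    effect (population effect + deviation).  For a common-effects model
    (no random slope for ``effect``) every participant shares the
    population summary."""
    model = draws.model
    tag = f"_s{session}" if session is not None else ""
    if effect in model.spec.random_terms:
        arr = draws.get(f"individual_{effect}{tag}")  # (chains, draws, P)
        flat = arr.reshape(-1, arr.shape[-1])
    elif effect in model.spec.fixed_terms:
        x = draws.flat(f"beta_{effect}{tag}")
        flat = np.tile(x[:, None], (1, model.P))
    else:
        raise ValueError(f"effect {effect!r} absent from the model")
    rows = []
    for i, pid in enumerate(model.participants):
        lo, hi = hdci(flat[:, i], mass)
        rows.append(
            {"participant": pid, "mean": float(flat[:, i].mean()),
             "hdci_low": lo, "hdci_high": hi}
        )
    return pd.DataFrame(rows)
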