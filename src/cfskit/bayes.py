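"""Hierarchical Bayesian analysis of repeated-measures threshold data.

Two complementary tools operate on a participants x conditions table of
normalized contrast thresholds:

**Parameter estimation** fits a robust hierarchical linear model by MCMC.
The likelihood is a t-distribution with unknown degrees of freedom nu
(uniform prior on [1, 100]) so gross outliers are down-weighted rather
than dragging the condition means. The location is additive:

    y ~ t_nu( b0 + condition_j + participant_i [+ target_k + interaction_jk], sigma )

with zero-centred normal priors on each deflection group whose spreads
carry half-Cauchy hyperpriors, so estimates within a group inform one
another. Sampling uses a Metropolis-within-Gibbs scheme built on the
scale-mixture-of-normals representation of the t likelihood: all location
parameters are drawn jointly from their exact multivariate-normal
conditional, the per-observation mixture weights from their gamma
conditional, and sigma, the group spreads and nu by univariate slice
sampling. Reported deflections are centred draw-by-draw, so each group
sums to zero exactly. Convergence is gated on split-R-hat <= 1.01.

Condition differences are summarised by highest-density intervals of
posterior contrasts; because all contrasts are functionals of a single
joint posterior, no multiple-comparison correction applies. Posterior
predictive replicates (one simulated dataset per retained draw) support
model checking.

**Model selection** computes default-prior (JZS) ANOVA Bayes factors:
each effect group receives a zero-centred normal prior with its own
scaled-g variance, g ~ InverseGamma(1/2, r^2/2) (r = 0.5 for fixed
effects, r = 1 for the participant nuisance group), the grand mean a flat
prior and sigma^2 a Jeffreys prior. The marginal likelihood is integrated
over the g's by Gauss-Legendre quadrature in log g (up to two effect
groups) or seeded prior Monte Carlo (three or more).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "RMDataset",
    "SamplerSettings",
    "PosteriorSamples",
    "ContrastResult",
    "BayesFactorResult",
    "ConvergenceError",
    "fit_one_way",
    "fit_two_way",
    "contrast_hdi",
    "posterior_predictive",
    "jzs_anova_bf",
    "bf_table",
    "MODEL_LABELS",
]

MODEL_LABELS = ("null", "mask_speed", "target_speed", "additive", "full")


class ConvergenceError(RuntimeError):
    """Raised when split-R-hat exceeds its threshold after sampling."""

    def __init__(self, offending: Mapping[str, float], threshold: float):
        self.offending = dict(offending)
        self.threshold = threshold
        msg = ", ".join(f"{k}: R-hat {v:.3f}" for k, v in self.offending.items())
        super().__init__(f"MCMC did not converge (threshold {threshold}): {msg}")


@dataclass
class RMDataset:
    """Long-format repeated-measures dataset of normalized thresholds.

    ``table`` columns: participant, condition, value, and optionally
    target_speed. The participant x condition (x target_speed) crossing
    must be complete with exactly one value per cell.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"participant", "condition", "value"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"RMDataset missing columns: {sorted(missing)}")
        if np.any(~np.isfinite(self.table["value"].to_numpy(dtype=float))):
            raise ValueError("values must be finite")
        keys = ["participant", "condition"]
        if self.has_target:
            keys.append("target_speed")
        counts = self.table.groupby(keys, sort=False).size()
        n_cells = int(np.prod([self.table[k].nunique() for k in keys]))
        if counts.min() != 1 or counts.max() != 1 or len(counts) != n_cells:
            raise ValueError("design crossing must be complete with one "
                             "value per cell")

    @property
    def has_target(self) -> bool:
        return "target_speed" in self.table.columns

    @property
    def participants(self) -> list:
        return list(pd.unique(self.table["participant"]))

    @property
    def conditions(self) -> list:
        return list(pd.unique(self.table["condition"]))

    @property
    def target_levels(self) -> list:
        if not self.has_target:
            return []
        return list(pd.unique(self.table["target_speed"]))

    def to_matrix(self, target_speed=None) -> np.ndarray:
        """Participants x conditions value matrix (one target level)."""
        tab = self.table
        if self.has_target:
            if target_speed is None:
                if len(self.target_levels) > 1:
                    raise ValueError("specify target_speed for a two-way "
                                     "dataset")
                target_speed = self.target_levels[0]
            tab = tab[tab["target_speed"] == target_speed]
        pivot = tab.pivot(index="participant", columns="condition",
                          values="value")
        return pivot.reindex(index=self.participants,
                             columns=self.conditions).to_numpy()


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC configuration for the hierarchical model fits."""

    chains: int = 4
    draws: int = 2500
    warmup: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.01
    check_convergence: bool = True
    grand_mean_prior_sd: float = 10.0
    spread_prior_scale: float = 1.0  # half-Cauchy scale for group spreads
    sigma_prior_scale: float = 1.0
    nu_bounds: tuple[float, float] = (1.0, 100.0)


@dataclass
class PosteriorSamples:
    """Posterior draws of the hierarchical model, centred for reporting.

    ``posterior`` maps parameter name to an array with leading dimensions
    (chain, draw): ``grand_mean``, ``sigma``, ``nu``, ``condition_effect``
    (J), ``subject_effect`` (I), and for the two-way model
    ``target_effect`` (K) and ``interaction`` (J, K), plus the group
    spread parameters. Deflection groups sum to zero across their levels
    in every draw.
    """

    posterior: dict[str, np.ndarray]
    coords: dict[str, list]
    diagnostics: pd.DataFrame
    model: str  # "oneway" | "twoway"
    settings: SamplerSettings

    def stacked(self, name: str) -> np.ndarray:
        """Draws of ``name`` with chain/draw flattened into one axis."""
        arr = self.posterior[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict(posterior=self.posterior)


def _slice_sample(x0: float, logp, rng: np.random.Generator, width: float = 1.0,
                  lower: float = -np.inf, upper: float = np.inf,
                  max_steps: int = 50) -> float:
    """Univariate slice sampler with stepping-out and shrinkage."""
    logy = logp(x0) - rng.exponential()
    u = rng.uniform(0.0, width)
    left, right = x0 - u, x0 + width - u
    j = max_steps
    while j > 0 and left > lower and logp(left) > logy:
        left -= width
        j -= 1
    k = max_steps
    while k > 0 and right < upper and logp(right) > logy:
        right += width
        k -= 1
    left, right = max(left, lower), min(right, upper)
    while True:
        x1 = rng.uniform(left, right)
        if logp(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _half_cauchy_logpdf(s: float, scale: float) -> float:
    return -np.log1p((s / scale) ** 2)


@dataclass
class _Design:
    y: np.ndarray
    X: np.ndarray  # N x p dense indicator design (incl. intercept col 0)
    # per deflection group: (name, column slice, n levels, per-obs level index)
    groups: list[tuple[str, slice, int, np.ndarray]]
    cond_idx: np.ndarray
    subj_idx: np.ndarray
    targ_idx: np.ndarray | None
    shape: tuple  # (J, I) or (J, I, K)


def _build_design(data: RMDataset, twoway: bool) -> _Design:
    tab = data.table
    conds = data.conditions
    parts = data.participants
    cond_idx = pd.Categorical(tab["condition"], categories=conds).codes
    subj_idx = pd.Categorical(tab["participant"], categories=parts).codes
    y = tab["value"].to_numpy(dtype=float)
    n = len(y)
    J, I = len(conds), len(parts)
    cols = [np.ones((n, 1))]
    groups: list[tuple[str, slice, int, np.ndarray]] = []
    start = 1

    def add_group(name: str, idx: np.ndarray, m: int) -> None:
        nonlocal start
        idx = np.asarray(idx)
        Z = np.zeros((n, m))
        Z[np.arange(n), idx] = 1.0
        cols.append(Z)
        groups.append((name, slice(start, start + m), m, idx))
        start += m

    add_group("condition", cond_idx, J)
    add_group("subject", subj_idx, I)
    targ_idx = None
    if twoway:
        targs = data.target_levels
        K = len(targs)
        targ_idx = pd.Categorical(tab["target_speed"], categories=targs).codes
        add_group("target", targ_idx, K)
        inter_idx = cond_idx * K + targ_idx
        add_group("interaction", inter_idx, J * K)
        shape = (J, I, K)
    else:
        shape = (J, I)
    X = np.concatenate(cols, axis=1)
    return _Design(y=y, X=X, groups=groups, cond_idx=np.asarray(cond_idx),
                   subj_idx=np.asarray(subj_idx),
                   targ_idx=None if targ_idx is None else np.asarray(targ_idx),
                   shape=shape)


def _run_chain(design: _Design, settings: SamplerSettings,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    y, X, groups = design.y, design.X, design.groups
    n, p = X.shape
    n_groups = len(groups)
    nu_lo, nu_hi = settings.nu_bounds

    # initial state
    beta = np.zeros(p)
    beta[0] = float(np.mean(y))
    sigma = float(np.std(y)) or 1.0
    spreads = np.full(n_groups, 0.5)
    nu = 30.0
    w = np.ones(n)

    total = settings.warmup + settings.draws
    out_beta = np.empty((settings.draws, p))
    out_sigma = np.empty(settings.draws)
    out_nu = np.empty(settings.draws)
    out_spreads = np.empty((settings.draws, n_groups))

    XtT = X.T.copy()
    for it in range(total):
        # --- location parameters: joint MVN conditional ---
        Xw = XtT * w  # p x n
        prec = (Xw @ X) / sigma**2
        prior_prec = np.empty(p)
        prior_prec[0] = 1.0 / settings.grand_mean_prior_sd**2
        for gi, (_, sl, _, _) in enumerate(groups):
            prior_prec[sl] = 1.0 / spreads[gi] ** 2
        prec[np.diag_indices(p)] += prior_prec
        rhs = (Xw @ y) / sigma**2
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(chol.T, np.linalg.solve(chol, rhs))
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(chol.T, z)

        resid = y - X @ beta

        # --- mixture weights (t as scale mixture of normals) ---
        rate = 0.5 * (nu + (resid / sigma) ** 2)
        w = rng.gamma(shape=0.5 * (nu + 1.0), scale=1.0 / rate)

        # --- residual scale sigma (slice in log space) ---
        sse_w = float(np.sum(w * resid**2))

        def logp_sigma(ls: float) -> float:
            s = np.exp(ls)
            return (-n * ls - 0.5 * sse_w / s**2
                    + _half_cauchy_logpdf(s, settings.sigma_prior_scale) + ls)

        sigma = float(np.exp(_slice_sample(np.log(sigma), logp_sigma, rng,
                                           width=0.5)))

        # --- group spreads (slice in log space, centred parameterisation) ---
        for gi, (_, sl, m, _) in enumerate(groups):
            ssq = float(np.sum(beta[sl] ** 2))

            def logp_spread(ls: float, _ssq=ssq, _m=m) -> float:
                s = np.exp(ls)
                return (-_m * ls - 0.5 * _ssq / s**2
                        + _half_cauchy_logpdf(s, settings.spread_prior_scale)
                        + ls)

            spreads[gi] = float(np.exp(_slice_sample(np.log(spreads[gi]),
                                                     logp_spread, rng,
                                                     width=0.7)))

        # --- ASIS interweaving: re-draw each spread with its deflections
        # held fixed on the non-centred scale (theta = spread * theta_tilde),
        # which breaks the funnel when a group's true spread is near zero ---
        mu_full = X @ beta
        for gi, (_, sl, m, idx) in enumerate(groups):
            theta = beta[sl]
            s_old = spreads[gi]
            if s_old <= 0:
                continue
            tilde = theta / s_old
            contrib = theta[idx]
            y_res = y - mu_full + contrib  # residual with this group removed
            zb = tilde[idx]
            A = float(np.sum(w * zb**2)) / sigma**2
            B = float(np.sum(w * y_res * zb)) / sigma**2

            def logp_asis(ls: float) -> float:
                s = np.exp(ls)
                return (-0.5 * A * s**2 + B * s
                        + _half_cauchy_logpdf(s, settings.spread_prior_scale)
                        + ls)

            s_new = float(np.exp(_slice_sample(np.log(s_old), logp_asis, rng,
                                               width=0.7)))
            spreads[gi] = s_new
            beta[sl] = tilde * s_new
            mu_full = mu_full + (s_new - s_old) * zb

        # --- degrees of freedom nu (slice in log space, bounded) ---
        s_lw = float(np.sum(np.log(w)))
        s_w = float(np.sum(w))

        def logp_nu(lv: float) -> float:
            v = np.exp(lv)
            h = 0.5 * v
            return (n * (h * np.log(h) - gammaln(h))
                    + (h - 1.0) * s_lw - h * s_w + lv)

        nu = float(np.exp(_slice_sample(np.log(nu), logp_nu, rng, width=0.7,
                                        lower=np.log(nu_lo),
                                        upper=np.log(nu_hi))))

        if it >= settings.warmup:
            k = it - settings.warmup
            out_beta[k] = beta
            out_sigma[k] = sigma
            out_nu[k] = nu
            out_spreads[k] = spreads

    return {"beta": out_beta, "sigma": out_sigma, "nu": out_nu,
            "spreads": out_spreads}


def _center_draws(design: _Design, raw: dict[str, np.ndarray],
                  twoway: bool) -> dict[str, np.ndarray]:
    """Identify the reported parameters by draw-wise centring.

    The raw dummy parameterisation is only softly identified by the
    priors; the reported deflections are exact sum-to-zero functions of
    the cell means, which are fully identified.
    """
    beta = raw["beta"]  # (draws, p)
    groups = {name: beta[:, sl] for name, sl, _, _ in design.groups}
    b0 = beta[:, 0]
    a = groups["condition"]
    b = groups["subject"]
    out: dict[str, np.ndarray] = {}
    subj_c = b - b.mean(axis=1, keepdims=True)
    if not twoway:
        grand = b0 + a.mean(axis=1) + b.mean(axis=1)
        out["grand_mean"] = grand
        out["condition_effect"] = a - a.mean(axis=1, keepdims=True)
        out["subject_effect"] = subj_c
    else:
        J, _, K = design.shape
        d = groups["target"]
        e = groups["interaction"].reshape(-1, J, K)
        # cell means (excluding subjects): mu_jk
        mu = (b0[:, None, None] + a[:, :, None] + d[:, None, :] + e)
        grand_cells = mu.mean(axis=(1, 2))
        out["grand_mean"] = grand_cells + b.mean(axis=1)
        out["condition_effect"] = mu.mean(axis=2) - grand_cells[:, None]
        out["target_effect"] = mu.mean(axis=1) - grand_cells[:, None]
        out["interaction"] = (mu - mu.mean(axis=2, keepdims=True)
                              - mu.mean(axis=1, keepdims=True)
                              + grand_cells[:, None, None])
        out["subject_effect"] = subj_c
    out["sigma"] = raw["sigma"]
    out["nu"] = raw["nu"]
    for gi, (name, _, _, _) in enumerate(design.groups):
        out[f"spread_{name}"] = raw["spreads"][:, gi]
    return out


def _fit(data: RMDataset, twoway: bool,
         settings: SamplerSettings | None = None) -> PosteriorSamples:
    settings = settings or SamplerSettings()
    if twoway and not data.has_target:
        raise ValueError("two-way fit requires a target_speed column")
    if len(data.participants) < 3:
        raise ValueError("need at least 3 participants")
    design = _build_design(data, twoway)

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    chains = [_run_chain(design, settings, np.random.default_rng(s))
              for s in seeds]

    centered = [_center_draws(design, c, twoway) for c in chains]
    posterior = {k: np.stack([c[k] for c in centered])
                 for k in centered[0]}

    coords = {"condition": data.conditions, "participant": data.participants}
    if twoway:
        coords["target_speed"] = data.target_levels

    idata = az.from_dict(posterior=posterior)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for name in posterior:
        r = float(np.nanmax(np.asarray(rhat[name])))
        e = float(np.nanmin(np.asarray(ess[name])))
        rows.append({"parameter": name, "rhat_max": r, "ess_min": e})
    diagnostics = pd.DataFrame(rows)

    samples = PosteriorSamples(posterior=posterior, coords=coords,
                               diagnostics=diagnostics,
                               model="twoway" if twoway else "oneway",
                               settings=settings)
    if settings.check_convergence:
        bad = {row["parameter"]: row["rhat_max"]
               for _, row in diagnostics.iterrows()
               if row["rhat_max"] > settings.rhat_threshold}
        if bad:
            raise ConvergenceError(bad, settings.rhat_threshold)
    return samples


def fit_one_way(data: RMDataset,
                settings: SamplerSettings | None = None) -> PosteriorSamples:
    """Fit the one-way (mask speed x participant) robust hierarchical model."""
    return _fit(data, twoway=False, settings=settings)


def fit_two_way(data: RMDataset,
                settings: SamplerSettings | None = None) -> PosteriorSamples:
    """Fit the two-way model with target-speed and interaction deflections."""
    return _fit(data, twoway=True, settings=settings)


@dataclass
class ContrastResult:
    """A posterior contrast over condition deflections and its HDI."""

    weights: np.ndarray
    samples: np.ndarray
    hdi: tuple[float, float]
    prob: float

    @property
    def excludes_zero(self) -> bool:
        """Decision rule: the conditions differ credibly iff the HDI
        excludes zero."""
        lo, hi = self.hdi
        return bool(lo > 0.0 or hi < 0.0)


def contrast_hdi(samples: PosteriorSamples,
                 weights: Sequence[float] | Mapping[str, float],
                 prob: float = 0.95,
                 target_level=None) -> ContrastResult:
    """HDI of a weighted combination of condition deflections.

    ``weights`` (summing to zero) may be a vector over the conditions in
    coordinate order or a mapping from condition label to weight
    (unmentioned conditions get 0). For a two-way fit, passing
    ``target_level`` contrasts the condition profile *within* that target
    speed (condition effect plus interaction); otherwise the marginal
    condition effects are contrasted. Because every contrast is read off
    the same joint posterior, computing many of them needs no
    multiplicity correction.
    """
    conds = samples.coords["condition"]
    if isinstance(weights, Mapping):
        wvec = np.array([float(weights.get(c, 0.0)) for c in conds])
    else:
        wvec = np.asarray(weights, dtype=float)
        if wvec.shape != (len(conds),):
            raise ValueError("weights length must equal number of conditions")
    if abs(wvec.sum()) > 1e-10:
        raise ValueError("contrast weights must sum to zero")
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must lie in (0, 1)")

    eff = samples.stacked("condition_effect")  # (draws, J)
    if target_level is not None:
        if samples.model != "twoway":
            raise ValueError("target_level requires a two-way fit")
        tl = list(samples.coords["target_speed"]).index(target_level)
        eff = eff + samples.stacked("interaction")[:, :, tl]
    draws = eff @ wvec
    if np.allclose(draws, draws[0]):
        lo = hi = float(draws[0])
    else:
        # narrowest interval containing ceil(prob * n) draws
        x = np.sort(draws)
        m = int(np.ceil(prob * len(x)))
        widths = x[m - 1:] - x[:len(x) - m + 1]
        k = int(np.argmin(widths))
        lo, hi = float(x[k]), float(x[k + m - 1])
    return ContrastResult(weights=wvec, samples=draws, hdi=(lo, hi), prob=prob)


def posterior_predictive(samples: PosteriorSamples, data: RMDataset,
                         prob: float = 0.95, seed: int = 0) -> dict:
    """Simulate one replicate dataset per retained posterior draw.

    Each draw generates a full dataset from the fitted t-likelihood at
    every cell's posterior location. Returns the replicate array
    (n_draws x n_obs), per-observation predictive intervals (central
    ``prob``), and the fraction of observed values they cover.
    """
    twoway = samples.model == "twoway"
    if twoway != data.has_target:
        raise ValueError("fit design does not match the dataset")
    design = _build_design(data, twoway)
    if (len(data.conditions) != len(samples.coords["condition"])
            or len(data.participants) != len(samples.coords["participant"])):
        raise ValueError("fit design does not match the dataset")

    grand = samples.stacked("grand_mean")
    cond = samples.stacked("condition_effect")
    subj = samples.stacked("subject_effect")
    sigma = samples.stacked("sigma")
    nu = samples.stacked("nu")
    mu = (grand[:, None] + cond[:, design.cond_idx]
          + subj[:, design.subj_idx])
    if twoway:
        targ = samples.stacked("target_effect")
        inter = samples.stacked("interaction")
        mu = mu + targ[:, design.targ_idx]
        mu = mu + inter[:, design.cond_idx, design.targ_idx]

    rng = np.random.default_rng(seed)
    n_draws, n_obs = mu.shape
    reps = mu + sigma[:, None] * rng.standard_t(df=nu[:, None],
                                                size=(n_draws, n_obs))
    alpha = (1.0 - prob) / 2.0
    lo = np.quantile(reps, alpha, axis=0)
    hi = np.quantile(reps, 1.0 - alpha, axis=0)
    y = design.y
    inside = (y >= lo) & (y <= hi)
    return {
        "replicates": reps,
        "interval_low": lo,
        "interval_high": hi,
        "coverage": float(inside.mean()),
        "n_replicates": int(n_draws),
        "predictive_mean": reps.mean(axis=0),
    }


# ---------------------------------------------------------------------------
# Default-prior (JZS) ANOVA Bayes factors
# ---------------------------------------------------------------------------

R_FIXED = 0.5  # prior scale for fixed-effect groups
R_NUISANCE = 1.0  # prior scale for the participant group


@dataclass
class BayesFactorResult:
    """Bayes factor of model_a vs model_b (value > 1 favours model_a)."""

    model_a: str
    model_b: str
    bf: float
    log_ml_a: float
    log_ml_b: float
    method: str


def _sum_to_zero_basis(m: int) -> np.ndarray:
    """Orthonormal m x (m-1) basis of the sum-to-zero subspace."""
    centering = np.eye(m) - np.ones((m, m)) / m
    vals, vecs = np.linalg.eigh(centering)
    return vecs[:, vals > 0.5]


def _model_groups(label: str, twoway: bool) -> list[str]:
    if label not in MODEL_LABELS:
        raise ValueError(f"unknown model label: {label!r}")
    table = {
        "null": [],
        "mask_speed": ["condition"],
        "target_speed": ["target"],
        "additive": ["condition", "target"],
        "full": ["condition", "target", "interaction"],
    }
    groups = table[label]
    if not twoway and any(g in ("target", "interaction") for g in groups):
        raise ValueError(f"model {label!r} needs a two-way dataset")
    return groups


def _effect_matrices(data: RMDataset) -> dict[str, np.ndarray]:
    """Sum-to-zero-projected design columns per effect group."""
    tab = data.table
    conds, parts = data.conditions, data.participants
    cond_idx = pd.Categorical(tab["condition"], categories=conds).codes
    subj_idx = pd.Categorical(tab["participant"], categories=parts).codes
    n = len(tab)
    out: dict[str, np.ndarray] = {}

    def onehot(idx, m):
        Z = np.zeros((n, m))
        Z[np.arange(n), idx] = 1.0
        return Z

    Qc = _sum_to_zero_basis(len(conds))
    out["condition"] = onehot(cond_idx, len(conds)) @ Qc
    Qs = _sum_to_zero_basis(len(parts))
    out["subject"] = onehot(subj_idx, len(parts)) @ Qs
    if data.has_target:
        targs = data.target_levels
        targ_idx = pd.Categorical(tab["target_speed"],
                                  categories=targs).codes
        Qt = _sum_to_zero_basis(len(targs))
        out["target"] = onehot(targ_idx, len(targs)) @ Qt
        inter_idx = np.asarray(cond_idx) * len(targs) + np.asarray(targ_idx)
        Qi = np.kron(Qc, Qt)
        out["interaction"] = onehot(inter_idx, len(conds) * len(targs)) @ Qi
    return out


def _log_marginal_given_g(ytil: np.ndarray, XtX: np.ndarray, Xty: np.ndarray,
                          yty: float, n: int, col_groups: list[np.ndarray],
                          g: np.ndarray) -> float:
    """log m(g) up to model-independent constants (Woodbury-reduced)."""
    p = XtX.shape[0]
    d = np.empty(p)
    for cols, gk in zip(col_groups, g):
        d[cols] = np.sqrt(gk)
    A = np.eye(p) + (d[:, None] * XtX) * d[None, :]
    u = d * Xty
    chol = np.linalg.cholesky(A)
    v = np.linalg.solve(chol, u)
    q = yty - float(v @ v)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return -0.5 * logdet - 0.5 * (n - 1) * np.log(q)


def _log_invgamma_half(g: np.ndarray, r: np.ndarray) -> np.ndarray:
    """log density of g ~ InverseGamma(1/2, r^2/2), elementwise summed."""
    return np.sum(0.5 * np.log(r**2 / 2.0) - gammaln(0.5)
                  - 1.5 * np.log(g) - r**2 / (2.0 * g), axis=-1)


def _log_ml(data: RMDataset, label: str, seed: int, mc_draws: int,
            gl_nodes: int) -> tuple[float, str]:
    twoway = data.has_target and len(data.target_levels) > 1
    groups = ["subject"] + _model_groups(label, twoway)
    mats = _effect_matrices(data)
    X = np.concatenate([mats[g] for g in groups], axis=1)
    r_scales = np.array([R_NUISANCE if g == "subject" else R_FIXED
                         for g in groups])
    y = data.table["value"].to_numpy(dtype=float)
    n = len(y)
    ytil = y - y.mean()
    XtX = X.T @ X
    Xty = X.T @ ytil
    yty = float(ytil @ ytil)
    col_groups = []
    start = 0
    for g in groups:
        m = mats[g].shape[1]
        col_groups.append(np.arange(start, start + m))
        start += m
    ndim = len(groups)

    if ndim <= 2:
        # Gauss-Legendre in s = log g over a wide fixed window.
        nodes, weights = np.polynomial.legendre.leggauss(gl_nodes)
        lo, hi = -15.0, 15.0
        s = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
        lw = np.log(0.5 * (hi - lo) * weights)
        grids = np.meshgrid(*([s] * ndim), indexing="ij")
        wgrids = np.meshgrid(*([lw] * ndim), indexing="ij")
        S = np.stack([gr.ravel() for gr in grids], axis=-1)
        W = np.sum(np.stack([wg.ravel() for wg in wgrids], axis=-1), axis=-1)
        G = np.exp(S)
        logvals = np.empty(len(S))
        for i in range(len(S)):
            logvals[i] = _log_marginal_given_g(ytil, XtX, Xty, yty, n,
                                               col_groups, G[i])
        logprior = _log_invgamma_half(G, r_scales[None, :])
        jac = np.sum(S, axis=-1)  # dg = g ds per dimension
        return float(logsumexp(logvals + logprior + jac + W)), "quadrature"

    # Monte Carlo over the prior for three or more g dimensions.
    rng = np.random.default_rng(seed)
    gam = rng.gamma(shape=0.5, scale=2.0 / r_scales**2,
                    size=(mc_draws, ndim))
    G = 1.0 / gam
    logvals = np.empty(mc_draws)
    for i in range(mc_draws):
        logvals[i] = _log_marginal_given_g(ytil, XtX, Xty, yty, n,
                                           col_groups, G[i])
    return float(logsumexp(logvals) - np.log(mc_draws)), "monte_carlo"


def jzs_anova_bf(data: RMDataset, model_a: str, model_b: str,
                 seed: int = 0, mc_draws: int = 20000,
                 gl_nodes: int = 81) -> BayesFactorResult:
    """Default-prior ANOVA Bayes factor of ``model_a`` against ``model_b``.

    Every model includes the participant term as a nuisance group. Labels:
    ``null``, ``mask_speed``, ``target_speed``, ``additive``, ``full``
    (the last three require a two-way dataset). Values > 1 favour
    ``model_a``; reciprocity BF(a,b) * BF(b,a) = 1 holds by construction
    up to Monte-Carlo error in the >= 3-group integrals.
    """
    # Seed the Monte-Carlo integral per model label, so the same model's
    # marginal likelihood is identical wherever it appears and
    # reciprocity/identity hold exactly.
    la, ma = _log_ml(data, model_a, seed + MODEL_LABELS.index(model_a),
                     mc_draws, gl_nodes)
    if model_b == model_a:
        lb, mb = la, ma
    else:
        lb, mb = _log_ml(data, model_b, seed + MODEL_LABELS.index(model_b),
                         mc_draws, gl_nodes)
    method = ma if ma == mb else f"{ma}/{mb}"
    return BayesFactorResult(model_a=model_a, model_b=model_b,
                             bf=float(np.exp(la - lb)),
                             log_ml_a=la, log_ml_b=lb, method=method)


def bf_table(data: RMDataset, reference: str = "full", seed: int = 0,
             mc_draws: int = 20000) -> pd.DataFrame:
    """Bayes factors of each reduced model against a reference model.

    Mirrors the conventional reporting layout in which values smaller
    than one indicate evidence for the reference (full) model.
    """
    twoway = data.has_target and len(data.target_levels) > 1
    if not twoway and _needs_target(reference):
        reference = "mask_speed"
    labels = [m for m in MODEL_LABELS if m != reference]
    if not twoway:
        labels = [m for m in labels if not _needs_target(m)]
    rows = []
    ref_lml, _ = _log_ml(data, reference, seed + MODEL_LABELS.index(reference),
                         mc_draws, 81)
    for m in labels:
        lml, method = _log_ml(data, m, seed + MODEL_LABELS.index(m),
                              mc_draws, 81)
        rows.append({"model": m,
                     "bf_vs_" + reference: float(np.exp(lml - ref_lml)),
                     "method": method})
    return pd.DataFrame(rows)


def _needs_target(label: str) -> bool:
    return label in ("target_speed", "additive", "full")
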