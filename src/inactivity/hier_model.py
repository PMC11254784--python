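"""Bayesian hierarchical probit regression for prevalence surfaces.

Observed prevalences are mapped to the probit scale and modelled with a
normal summary likelihood,

    y_i ~ Normal(mu_i, v_i + tau^2_class(i)),

where ``v_i`` is the delta-method sampling variance of probit(p_hat) and
``tau^2`` is an extra variance component absorbing design factors beyond
sample size, with separate values for national and subnational surveys.
The mean structure is

    mu_i = b0 + u_region + u_country
         + (g0 + g_region + g_country) * (year_i - reference_year)
         + spline(age_i) . (theta_global + theta_region)
         + delta_instrument(i)
         + lambda * covariate(country_i, year_i)

with zero-mean normal hierarchical priors on every region/country deviation
and weakly informative normal priors on the fixed coefficients.  Age enters
at the band midpoint through a natural cubic spline (knots at 30 and 60);
time trends are linear; GPAQ is the reference instrument (offset fixed to
zero).  Separate models are fitted per sex.

Inference.  Conditional on the variance scales, the model is exactly
linear-Gaussian, so the sampler collapses the coefficient vector
analytically: each scale (five hierarchy SDs and the two tau terms) is
slice-sampled against the exact Gaussian marginal likelihood (coefficients
integrated out via the Woodbury identity), and the full coefficient vector
is then drawn from its exact multivariate-normal conditional.  This mixes
essentially like independent sampling — there is no centred/non-centred
funnel — and split-R-hat / ESS gates are enforced on every retained
parameter via ArviZ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import linalg, stats

from .splines import natural_cubic_basis
from .survey_processing import INSTRUMENTS, SEXES, PrevalenceObservation, ValidationError
from .synthetic_world import band_midpoint


class ConvergenceError(RuntimeError):
    """Raised when MCMC diagnostics fail the configured gates."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# ---------------------------------------------------------------------------
# link-scale primitives
# ---------------------------------------------------------------------------


def probit(p):
    """Standard-normal quantile of a probability in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("probit requires 0 < p < 1")
    out = stats.norm.ppf(p)
    return float(out) if out.ndim == 0 else out


def inv_probit(x):
    """Standard-normal CDF; inverse of :func:`probit`."""
    out = stats.norm.cdf(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def delta_variance(p, n_effective):
    """Delta-method variance of probit(p_hat): p(1-p) / (n * phi(probit(p))^2)."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n_effective, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("delta_variance requires 0 < p < 1")
    if np.any(n <= 0):
        raise ValidationError("delta_variance requires n_effective > 0")
    dens = stats.norm.pdf(stats.norm.ppf(p))
    out = p * (1.0 - p) / (n * dens**2)
    return float(out) if out.ndim == 0 else out


def continuity_correct(p_obs: float, n_effective: float) -> float:
    """Pull boundary prevalences into (0, 1): 0 -> 1/(2n), 1 -> 1 - 1/(2n)."""
    if not 0.0 <= p_obs <= 1.0:
        raise ValidationError(f"p_obs={p_obs} outside [0, 1]")
    if p_obs == 0.0:
        return 1.0 / (2.0 * n_effective)
    if p_obs == 1.0:
        return 1.0 - 1.0 / (2.0 * n_effective)
    return float(p_obs)


# ---------------------------------------------------------------------------
# configuration and dataset
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Model structure, priors and MCMC settings."""

    knots: tuple[float, ...] = (30.0, 60.0)
    boundary_knots: tuple[float, float] = (18.0, 85.0)
    reference_instrument: str = "GPAQ"
    n_draws: int = 4000
    chains: int = 4
    warmup: int = 300
    seed: int = 0
    year_range: tuple[int, int] = (2000, 2022)
    reference_year: int = 2011
    include_country_slopes: bool = True
    prior_coef_sd: float = 1.0
    prior_sd_scale: float = 0.5
    prior_sd_scale_overrides: dict = field(default_factory=dict)
    rhat_max: float = 1.05
    min_ess: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if any(not lo < k < hi for k in self.knots):
            raise ValidationError("knots must lie strictly inside the boundary knots")
        if self.n_draws < 100:
            raise ValidationError("n_draws must be >= 100")
        if self.reference_instrument not in INSTRUMENTS:
            raise ValidationError(f"unknown reference instrument {self.reference_instrument!r}")

    def spline_basis(self, age) -> np.ndarray:
        """Natural cubic spline basis at the given age(s)."""
        return natural_cubic_basis(age, self.knots, self.boundary_knots)

    @property
    def n_spline(self) -> int:
        return len(self.knots) + 1

    def sd_prior_scale(self, name: str) -> float:
        return float(self.prior_sd_scale_overrides.get(name, self.prior_sd_scale))


SCALE_NAMES = (
    "sd_region_intercept",
    "sd_country_intercept",
    "sd_region_slope",
    "sd_country_slope",
    "sd_region_spline",
    "tau_national",
    "tau_subnational",
)


@dataclass
class ModelDataset:
    """Design matrices and transformed responses for one sex's fit."""

    sex: str
    observations: list[PrevalenceObservation]
    countries: list[str]
    regions: list[str]
    region_idx: np.ndarray  # region index per country
    region_of_country: dict[str, str]
    y: np.ndarray
    v_sampling: np.ndarray
    subnational: np.ndarray  # bool per observation
    X: np.ndarray
    columns: dict[str, slice]
    covariate_lookup: dict[tuple[str, int], float]
    covariate_center: float
    config: ModelConfig

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def pack(self, params: Mapping[str, np.ndarray]) -> np.ndarray:
        """Assemble a flat coefficient vector from named blocks."""
        beta = np.zeros(self.n_params)
        for name, sl in self.columns.items():
            beta[sl] = np.asarray(params[name], dtype=float).ravel()
        return beta

    def unpack(self, beta: np.ndarray) -> dict[str, np.ndarray]:
        return {name: np.array(beta[sl]) for name, sl in self.columns.items()}

    def prior_sd_vector(self, scales: Mapping[str, float]) -> np.ndarray:
        """Per-column prior SD given the current hierarchy scales."""
        sd = np.full(self.n_params, self.config.prior_coef_sd)
        sd[self.columns["region_intercept"]] = scales["sd_region_intercept"]
        sd[self.columns["country_intercept"]] = scales["sd_country_intercept"]
        sd[self.columns["region_slope"]] = scales["sd_region_slope"]
        if "country_slope" in self.columns:
            sd[self.columns["country_slope"]] = scales["sd_country_slope"]
        sd[self.columns["spline_region"]] = scales["sd_region_spline"]
        return sd

    def obs_variance(self, tau_national: float, tau_subnational: float) -> np.ndarray:
        tau2 = np.where(self.subnational, tau_subnational**2, tau_national**2)
        return self.v_sampling + tau2


def build_dataset(
    observations: Iterable[PrevalenceObservation],
    covariates,
    region_of_country: Mapping[str, str],
    config: ModelConfig = ModelConfig(),
) -> ModelDataset:
    """Assemble the model dataset for a single sex.

    ``covariates`` is a DataFrame with columns country/year/covariate.
    Responses are probit(continuity-corrected prevalence) with delta-method
    sampling variances; age enters at the band midpoint (the open-ended top
    band is closed at 97); instruments are reference-coded against GPAQ.
    """
    obs = list(observations)
    if not obs:
        raise ValidationError("build_dataset requires at least one observation")
    sexes = {o.sex for o in obs}
    if len(sexes) != 1:
        raise ValidationError(f"one sex per dataset; got {sorted(sexes)}")
    sex = obs[0].sex

    cov_lookup = {
        (str(r.country), int(r.year)): float(r.covariate) for r in covariates.itertuples()
    }
    cov_center = float(np.mean(list(cov_lookup.values())))

    countries = sorted({o.country for o in obs})
    for c in countries:
        if c not in region_of_country:
            raise ValidationError(f"country {c!r} has no region assignment")
    regions = sorted({region_of_country[c] for c in countries})
    region_idx = np.array([regions.index(region_of_country[c]) for c in countries])

    K = config.n_spline
    R, C = len(regions), len(countries)
    n = len(obs)

    y = np.empty(n)
    v = np.empty(n)
    sub = np.empty(n, dtype=bool)
    t = np.empty(n)
    B = np.empty((n, K))
    c_idx = np.empty(n, dtype=int)
    r_idx = np.empty(n, dtype=int)
    instr = np.zeros((n, len(INSTRUMENTS) - 1))
    covv = np.empty(n)
    non_ref = [i for i in INSTRUMENTS if i != config.reference_instrument]

    for i, o in enumerate(obs):
        p = continuity_correct(o.p_obs, o.n_effective)
        y[i] = probit(p)
        v[i] = delta_variance(p, o.n_effective)
        sub[i] = not o.national
        t[i] = o.year - config.reference_year
        B[i] = config.spline_basis(band_midpoint(o.age_lo, o.age_hi))
        c_idx[i] = countries.index(o.country)
        r_idx[i] = region_idx[c_idx[i]]
        if o.instrument != config.reference_instrument:
            instr[i, non_ref.index(o.instrument)] = 1.0
        key = (o.country, o.year)
        if key not in cov_lookup:
            raise ValidationError(f"missing covariate for country-year {key}")
        covv[i] = cov_lookup[key] - cov_center

    def ind(idx: np.ndarray, m: int) -> np.ndarray:
        out = np.zeros((n, m))
        out[np.arange(n), idx] = 1.0
        return out

    blocks: list[tuple[str, np.ndarray]] = [
        ("intercept", np.ones((n, 1))),
        ("region_intercept", ind(r_idx, R)),
        ("country_intercept", ind(c_idx, C)),
        ("slope", t[:, None]),
        ("region_slope", ind(r_idx, R) * t[:, None]),
    ]
    if config.include_country_slopes:
        blocks.append(("country_slope", ind(c_idx, C) * t[:, None]))
    spline_region = np.zeros((n, R * K))
    for i in range(n):
        spline_region[i, r_idx[i] * K : (r_idx[i] + 1) * K] = B[i]
    blocks += [
        ("spline", B),
        ("spline_region", spline_region),
        ("instrument", instr),
        ("covariate", covv[:, None]),
    ]

    columns: dict[str, slice] = {}
    start = 0
    mats = []
    for name, mat in blocks:
        columns[name] = slice(start, start + mat.shape[1])
        start += mat.shape[1]
        mats.append(mat)
    X = np.hstack(mats)

    return ModelDataset(
        sex=sex,
        observations=obs,
        countries=countries,
        regions=regions,
        region_idx=region_idx,
        region_of_country={c: region_of_country[c] for c in countries},
        y=y,
        v_sampling=v,
        subnational=sub,
        X=X,
        columns=columns,
        covariate_lookup=cov_lookup,
        covariate_center=cov_center,
        config=config,
    )


def log_density(dataset: ModelDataset, params: Mapping[str, np.ndarray], scales: Mapping[str, float]) -> float:
    """Log joint density (likelihood + priors) at a fixed parameter vector.

    Used as the analytically checkable core of the model: the likelihood is
    a sum of normal log-densities with variance v_i + tau^2_class(i).
    """
    beta = dataset.pack(params)
    mu = dataset.X @ beta
    var = dataset.obs_variance(scales["tau_national"], scales["tau_subnational"])
    ll = float(np.sum(stats.norm.logpdf(dataset.y, mu, np.sqrt(var))))
    prior_sd = dataset.prior_sd_vector(scales)
    lp = float(np.sum(stats.norm.logpdf(beta, 0.0, prior_sd)))
    for name in SCALE_NAMES:
        lp += float(stats.halfnorm.logpdf(scales[name], scale=dataset.config.sd_prior_scale(name)))
    return ll + lp


# ---------------------------------------------------------------------------
# the collapsed Gibbs sampler
# ---------------------------------------------------------------------------


def _slice_sample(
    logf: Callable[[float], float], x0: float, rng: np.random.Generator, w: float = 1.0, m: int = 50
) -> float:
    """Univariate slice sampler with stepping out and shrinkage (Neal 2003)."""
    f0 = logf(x0)
    logu = f0 + math.log(rng.random())
    u = rng.random()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    j = int(rng.integers(m))
    k = m - 1 - j
    while j > 0 and logf(lo) > logu:
        lo -= w
        j -= 1
    while k > 0 and logf(hi) > logu:
        hi += w
        k -= 1
    while True:
        x1 = rng.uniform(lo, hi)
        if logf(x1) > logu:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


class _MarginalPosterior:
    """Marginal posterior over the variance scales, coefficients integrated out.

    With D = v + tau^2 and prior precision P(scales), the marginal is
    y ~ N(0, D + X P^-1 X'), evaluated via the Woodbury identity:
    log|Sigma| = sum log D + log|M| - log|P| and
    y' Sigma^-1 y = y'Wy - b' M^-1 b, where W = D^-1, b = X'Wy, M = X'WX + P.
    """

    def __init__(self, dataset: ModelDataset):
        self.ds = dataset
        self._tau_key: tuple[float, float] | None = None
        self._G: np.ndarray | None = None
        self._b: np.ndarray | None = None
        self._yWy: float = 0.0
        self._logdetD: float = 0.0

    def _refresh(self, tau_n: float, tau_s: float) -> None:
        if self._tau_key == (tau_n, tau_s):
            return
        D = self.ds.obs_variance(tau_n, tau_s)
        W = 1.0 / D
        Xw = self.ds.X * W[:, None]
        self._G = self.ds.X.T @ Xw
        self._b = Xw.T @ self.ds.y
        self._yWy = float(self.ds.y @ (W * self.ds.y))
        self._logdetD = float(np.sum(np.log(D)))
        self._tau_key = (tau_n, tau_s)

    def _M(self, scales: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
        prior_sd = self.ds.prior_sd_vector(scales)
        M = self._G.copy()
        M[np.diag_indices_from(M)] += 1.0 / prior_sd**2
        return M, prior_sd

    def log_marginal(self, scales: Mapping[str, float]) -> float:
        self._refresh(scales["tau_national"], scales["tau_subnational"])
        M, prior_sd = self._M(scales)
        try:
            L = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return -np.inf
        half = linalg.solve_triangular(L, self._b, lower=True, check_finite=False)
        logdetM = 2.0 * float(np.sum(np.log(np.diag(L))))
        logdetP = -2.0 * float(np.sum(np.log(prior_sd)))
        quad = self._yWy - float(half @ half)
        n = self.ds.n_obs
        return -0.5 * (n * math.log(2 * math.pi) + self._logdetD + logdetM - logdetP + quad)

    def log_target(self, scales: dict[str, float], name: str, log_s: float) -> float:
        s = math.exp(log_s)
        if s > 1e3:
            return -np.inf
        trial = dict(scales)
        trial[name] = s
        c = self.ds.config.sd_prior_scale(name)
        prior = 0.5 * math.log(2.0 / math.pi) - math.log(c) - s * s / (2.0 * c * c)
        return self.log_marginal(trial) + prior + log_s  # + jacobian

    def draw_beta(self, scales: Mapping[str, float], rng: np.random.Generator) -> np.ndarray:
        self._refresh(scales["tau_national"], scales["tau_subnational"])
        M, _ = self._M(scales)
        L = np.linalg.cholesky(M)
        mean = linalg.cho_solve((L, True), self._b, check_finite=False)
        z = rng.standard_normal(self.ds.n_params)
        return mean + linalg.solve_triangular(L.T, z, lower=False, check_finite=False)


@dataclass
class PosteriorDraws:
    """Joint posterior draws of all model parameters, one row per draw."""

    sex: str
    countries: list[str]
    regions: list[str]
    region_idx: np.ndarray
    reference_year: int
    instrument_names: tuple[str, ...]
    intercept: np.ndarray  # (N,)
    region_intercept: np.ndarray  # (N, R)
    country_intercept: np.ndarray  # (N, C)
    slope: np.ndarray  # (N,)
    region_slope: np.ndarray  # (N, R)
    country_slope: np.ndarray  # (N, C)
    spline: np.ndarray  # (N, K)
    spline_region: np.ndarray  # (N, R, K)
    instrument_offsets: dict[str, np.ndarray]  # every instrument, reference all-zero
    covariate_coef: np.ndarray  # (N,)
    scales: dict[str, np.ndarray]
    covariate_center: float
    config: ModelConfig
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.intercept.shape[0]

    def total_country_slope(self) -> np.ndarray:
        """Per-draw total linear trend for each country: (N, C)."""
        return self.slope[:, None] + self.region_slope[:, self.region_idx] + self.country_slope

    def augment(self, new_countries: Sequence[str], region_of_country: Mapping[str, str], seed: int) -> "PosteriorDraws":
        """Extend the country axis with data-free countries.

        Each new country receives, per draw, a region-level mean plus fresh
        country-level intercept and slope deviations drawn from that draw's
        hierarchy SDs — the model's shrinkage prediction for units without
        data.  Deterministic given ``seed``.
        """
        missing = [c for c in new_countries if c not in self.countries]
        if not missing:
            return self
        for c in missing:
            r = region_of_country.get(c)
            if r is None:
                raise ValidationError(f"country {c!r} has no region assignment")
            if r not in self.regions:
                raise ValidationError(f"region {r!r} of {c!r} was not in the fitted model")
        N = self.n_draws
        countries = self.countries + list(missing)
        region_idx = np.concatenate(
            [self.region_idx, [self.regions.index(region_of_country[c]) for c in missing]]
        )
        u_new = np.empty((N, len(missing)))
        g_new = np.empty((N, len(missing)))
        for j, c in enumerate(missing):
            rng = np.random.default_rng([seed, 104729, j])
            u_new[:, j] = rng.standard_normal(N) * self.scales["sd_country_intercept"]
            g_new[:, j] = rng.standard_normal(N) * self.scales["sd_country_slope"]
        return PosteriorDraws(
            sex=self.sex,
            countries=countries,
            regions=self.regions,
            region_idx=region_idx,
            reference_year=self.reference_year,
            instrument_names=self.instrument_names,
            intercept=self.intercept,
            region_intercept=self.region_intercept,
            country_intercept=np.hstack([self.country_intercept, u_new]),
            slope=self.slope,
            region_slope=self.region_slope,
            country_slope=np.hstack([self.country_slope, g_new]),
            spline=self.spline,
            spline_region=self.spline_region,
            instrument_offsets=self.instrument_offsets,
            covariate_coef=self.covariate_coef,
            scales=self.scales,
            covariate_center=self.covariate_center,
            config=self.config,
            diagnostics=self.diagnostics,
        )


def fit(dataset: ModelDataset, config: ModelConfig | None = None) -> PosteriorDraws:
    """Sample the posterior; raises :class:`ConvergenceError` on failed gates.

    Runs ``config.chains`` independent chains with over-dispersed scale
    initialisations, keeps ``ceil(n_draws / chains)`` post-warmup draws per
    chain, trims to exactly ``n_draws``, and enforces split-R-hat and ESS
    gates on every coefficient and scale.
    """
    cfg = config or dataset.config
    if dataset.n_obs < 1:
        raise ValidationError("fit requires at least one observation")
    post = _MarginalPosterior(dataset)
    per_chain = math.ceil(cfg.n_draws / cfg.chains)

    beta_ch = np.empty((cfg.chains, per_chain, dataset.n_params))
    scale_ch = np.empty((cfg.chains, per_chain, len(SCALE_NAMES)))
    for chain in range(cfg.chains):
        rng = np.random.default_rng([cfg.seed, 7919, chain])
        scales = {
            name: max(1e-3, abs(rng.normal(0.0, cfg.sd_prior_scale(name))))
            for name in SCALE_NAMES
        }
        for it in range(cfg.warmup + per_chain):
            for name in SCALE_NAMES:
                log_s = _slice_sample(
                    lambda v, _n=name: post.log_target(scales, _n, v),
                    math.log(scales[name]),
                    rng,
                )
                scales[name] = math.exp(log_s)
            if it >= cfg.warmup:
                beta_ch[chain, it - cfg.warmup] = post.draw_beta(scales, rng)
                scale_ch[chain, it - cfg.warmup] = [scales[n] for n in SCALE_NAMES]

    diagnostics = _diagnostics(beta_ch, scale_ch)
    if diagnostics["max_rhat"] > cfg.rhat_max or diagnostics["min_ess"] < cfg.min_ess:
        raise ConvergenceError(
            f"MCMC failed convergence gates: max split-R-hat {diagnostics['max_rhat']:.4f} "
            f"(limit {cfg.rhat_max}), min ESS {diagnostics['min_ess']:.0f} (floor {cfg.min_ess})",
            diagnostics,
        )

    beta = beta_ch.reshape(-1, dataset.n_params)[: cfg.n_draws]
    sc = scale_ch.reshape(-1, len(SCALE_NAMES))[: cfg.n_draws]
    cols = dataset.columns
    R, K = len(dataset.regions), cfg.n_spline
    non_ref = [i for i in INSTRUMENTS if i != cfg.reference_instrument]
    instr_cols = beta[:, cols["instrument"]]
    offsets = {cfg.reference_instrument: np.zeros(beta.shape[0])}
    for j, name in enumerate(non_ref):
        offsets[name] = instr_cols[:, j]
    if cfg.include_country_slopes:
        country_slope = beta[:, cols["country_slope"]]
    else:
        country_slope = np.zeros((beta.shape[0], len(dataset.countries)))
    return PosteriorDraws(
        sex=dataset.sex,
        countries=list(dataset.countries),
        regions=list(dataset.regions),
        region_idx=dataset.region_idx.copy(),
        reference_year=cfg.reference_year,
        instrument_names=INSTRUMENTS,
        intercept=beta[:, cols["intercept"]].ravel(),
        region_intercept=beta[:, cols["region_intercept"]],
        country_intercept=beta[:, cols["country_intercept"]],
        slope=beta[:, cols["slope"]].ravel(),
        region_slope=beta[:, cols["region_slope"]],
        country_slope=country_slope,
        spline=beta[:, cols["spline"]],
        spline_region=beta[:, cols["spline_region"]].reshape(-1, R, K),
        instrument_offsets=offsets,
        covariate_coef=beta[:, cols["covariate"]].ravel(),
        scales={name: sc[:, j] for j, name in enumerate(SCALE_NAMES)},
        covariate_center=dataset.covariate_center,
        config=cfg,
        diagnostics=diagnostics,
    )


def _diagnostics(beta_ch: np.ndarray, scale_ch: np.ndarray) -> dict:
    import arviz as az

    idata = az.from_dict(posterior={"beta": beta_ch, "scale": scale_ch})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    max_rhat = float(
        max(np.nanmax(rhat["beta"].values), np.nanmax(rhat["scale"].values))
    )
    min_ess = float(min(np.nanmin(ess["beta"].values), np.nanmin(ess["scale"].values)))
    return {"max_rhat": max_rhat, "min_ess": min_ess}


# ---------------------------------------------------------------------------
# posterior prevalence surfaces
# ---------------------------------------------------------------------------


@dataclass
class PrevalenceSurface:
    """Posterior prevalence draws on a country x year x age-band grid."""

    sex: str
    countries: list[str]
    years: list[int]
    age_groups: list[tuple[float, float]]
    values: np.ndarray  # (n_draws, C, Y, A), prevalence in (0, 1)
    metadata: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    def sel(self, country: str, year: int, band: tuple[float, float]) -> np.ndarray:
        """Draw vector for one unit."""
        return self.values[
            :,
            self.countries.index(country),
            self.years.index(year),
            self.age_groups.index(tuple(band)),
        ]

    def year_slice(self, year: int) -> np.ndarray:
        """(n_draws, C, A) prevalence at one year."""
        return self.values[:, :, self.years.index(year), :]


def predict_surface(
    draws: PosteriorDraws,
    countries: Sequence[str],
    years: Sequence[int],
    age_groups: Sequence[tuple[float, float]],
    covariates,
    region_of_country: Mapping[str, str] | None = None,
    allow_projection: bool = False,
    augment_seed: int = 0,
) -> PrevalenceSurface:
    """Evaluate posterior prevalence on a grid, instrument at reference.

    Countries absent from the fit receive region-level shrinkage draws (see
    :meth:`PosteriorDraws.augment`).  The extra variance tau^2 is a
    measurement-level term and is *not* added to predictions.  Years outside
    the estimation range raise unless ``allow_projection`` is set.
    """
    cfg = draws.config
    lo, hi = cfg.year_range
    bad = [y for y in years if not lo <= y <= hi]
    if bad and not allow_projection:
        raise ValidationError(
            f"years {bad} outside estimation range {cfg.year_range}; pass allow_projection=True to project"
        )
    if region_of_country is not None:
        draws = draws.augment(list(countries), region_of_country, augment_seed)
    unknown = [c for c in countries if c not in draws.countries]
    if unknown:
        raise ValidationError(f"countries {unknown} unknown to the fit; supply region_of_country")

    cov_lookup = {
        (str(r.country), int(r.year)): float(r.covariate) for r in covariates.itertuples()
    }
    mids = np.array([band_midpoint(b_lo, b_hi) for b_lo, b_hi in age_groups])
    B = cfg.spline_basis(mids)  # (A, K)
    t = np.array([y - draws.reference_year for y in years])

    N = draws.n_draws
    out = np.empty((N, len(countries), len(years), len(mids)))
    total_slope = draws.total_country_slope()
    for ci, c in enumerate(countries):
        k = draws.countries.index(c)
        r = draws.region_idx[k]
        base = draws.intercept + draws.region_intercept[:, r] + draws.country_intercept[:, k]
        slope_c = total_slope[:, k]
        age_term = (draws.spline + draws.spline_region[:, r, :]) @ B.T  # (N, A)
        cov_vals = np.empty(len(years))
        for yi, y in enumerate(years):
            key = (c, y)
            if key not in cov_lookup:
                raise ValidationError(f"missing covariate for country-year {key}")
            cov_vals[yi] = cov_lookup[key] - draws.covariate_center
        mu = (
            base[:, None, None]
            + slope_c[:, None, None] * t[None, :, None]
            + age_term[:, None, :]
            + draws.covariate_coef[:, None, None] * cov_vals[None, :, None]
        )
        out[:, ci] = stats.norm.cdf(mu)
    return PrevalenceSurface(
        sex=draws.sex,
        countries=list(countries),
        years=[int(y) for y in years],
        age_groups=[tuple(b) for b in age_groups],
        values=out,
        metadata={"seed": cfg.seed, "n_draws": N, "augment_seed": augment_seed},
    )
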