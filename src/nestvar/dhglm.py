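"""Double-hierarchical location-scale model of log inter-visit intervals.

Observation model (natural logs throughout)::

    log IVI_i ~ Normal(mu_i, sigma_i)
    mu_i        = b0 + b_age*age_s_i + b_brood*brood_s_i
                  + site_{s(i)} + pair_{p(i)} + u0_{y(i)} + u1_{y(i)}*age_s_i
                  [+ u2_{y(i)}*brood_s_i]
    log sigma_i = g0 + g_age*age_s_i + g_brood*brood_s_i + v_{group(i)}

Random-effect structure is declared by a :class:`ModelSpec`; the nine-model
comparison ladder (m1a-m1i) adds site/pair/year intercepts, a year-level
age slope, and finally the covariances among the year-level effects
(u0, u1[, u2], v), realized as one joint multivariate-normal vector with a
full correlation matrix.  The across-pairs variant moves the age slope and
the sigma intercept to the pair level instead.

Posterior sampling is NUTS (see :mod:`nestvar.sampler`) on a fully
non-centered parameterization with analytic gradients; correlation matrices
are parameterized through tanh-unconstrained canonical partial correlations,
whose independent shifted-Beta priors are exactly equivalent to an LKJ(2)
prior on the correlation matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .preprocessing import ModelFrame
from .sampler import NutsConfig, nuts_chain

__all__ = [
    "ModelSpec",
    "EffectBlock",
    "PriorConfig",
    "SamplerConfig",
    "PosteriorResult",
    "ConvergenceError",
    "DhglmModel",
    "log_likelihood",
    "build_ladder",
    "across_pairs_spec",
    "fit",
    "prior_predictive",
]

# canonical ordering of within-group effect dimensions
TERM_ORDER = ("mu_intercept", "mu_age", "mu_brood", "sigma_intercept")
LKJ_ETA = 2.0


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectBlock:
    """One group-level effect block: ``terms`` jointly MVN if ``correlated``."""

    group: str  # "site" | "pair" | "year"
    terms: tuple[str, ...]
    correlated: bool

    @property
    def key(self) -> str:
        return self.group if self.correlated else f"{self.group}:{self.terms[0]}"

    @property
    def dim(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model in the comparison ladder."""

    name: str
    mean_random: frozenset[str] = frozenset()
    sigma_random: frozenset[str] = frozenset({"year"})
    correlated: bool = False
    pair_age_slope: bool = False

    def blocks(self) -> list[EffectBlock]:
        out: list[EffectBlock] = []
        if "site" in self.mean_random:
            out.append(EffectBlock("site", ("mu_intercept",), False))

        pair_terms: list[str] = []
        if "pair" in self.mean_random:
            pair_terms.append("mu_intercept")
        if self.pair_age_slope:
            pair_terms.append("mu_age")
        if "pair" in self.sigma_random:
            pair_terms.append("sigma_intercept")

        year_terms: list[str] = []
        if "year_intercept" in self.mean_random:
            year_terms.append("mu_intercept")
        if "year_age_slope" in self.mean_random:
            year_terms.append("mu_age")
        if "year_brood_slope" in self.mean_random:
            year_terms.append("mu_brood")
        if "year" in self.sigma_random:
            year_terms.append("sigma_intercept")

        for group, terms in (("pair", pair_terms), ("year", year_terms)):
            terms = tuple(sorted(terms, key=TERM_ORDER.index))
            if not terms:
                continue
            if self.correlated and len(terms) > 1:
                out.append(EffectBlock(group, terms, True))
            else:
                out.extend(EffectBlock(group, (t,), False) for t in terms)
        return out

    # -- serialization ------------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "name": self.name,
                "mean_random": sorted(self.mean_random),
                "sigma_random": sorted(self.sigma_random),
                "correlated": self.correlated,
                "pair_age_slope": self.pair_age_slope,
            }
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        d = yaml.safe_load(text)
        return cls(
            name=d["name"],
            mean_random=frozenset(d["mean_random"]),
            sigma_random=frozenset(d["sigma_random"]),
            correlated=d["correlated"],
            pair_age_slope=d["pair_age_slope"],
        )


_LADDER_MEAN_RANDOM = {
    "m1a": frozenset(),
    "m1b": frozenset({"site"}),
    "m1c": frozenset({"pair"}),
    "m1d": frozenset({"site", "pair"}),
    "m1e": frozenset({"site", "pair", "year_intercept"}),
    "m1f": frozenset({"site", "pair", "year_intercept", "year_age_slope"}),
    "m1g": frozenset({"site", "pair", "year_intercept"}),
    "m1h": frozenset({"site", "pair", "year_intercept", "year_age_slope"}),
    "m1i": frozenset({"site", "pair", "year_intercept", "year_age_slope", "year_brood_slope"}),
}


def build_ladder() -> list[ModelSpec]:
    """The nine across-year models, in increasing structural complexity.

    All share the sigma model (fixed age and brood effects plus a year
    random intercept); m1g-m1i additionally estimate the covariances among
    the year-level effects.
    """
    return [
        ModelSpec(name=n, mean_random=mr, correlated=n in ("m1g", "m1h", "m1i"))
        for n, mr in _LADDER_MEAN_RANDOM.items()
    ]


def across_pairs_spec(include_year_sigma: bool = False) -> ModelSpec:
    """The across-pairs variant: age slope nested in pair, sigma across pairs.

    ``include_year_sigma`` additionally retains a year random intercept in
    the sigma part (off by default: residual variance is attributed to
    pairs alone).
    """
    sigma = {"pair", "year"} if include_year_sigma else {"pair"}
    return ModelSpec(
        name="across_pairs",
        mean_random=frozenset({"site", "pair", "year_intercept"}),
        sigma_random=frozenset(sigma),
        correlated=True,
        pair_age_slope=True,
    )


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative defaults on the standardized-covariate scale."""

    mu_intercept_scale: float = 5.0  # Normal(mean(y), 5) on the mean intercept
    mu_slope_scale: float = 2.5
    sigma_coef_scale: float = 1.0
    sd_scale: float = 1.0  # half-Normal(0, 1) on all group SDs
    lkj_eta: float = LKJ_ETA


# ---------------------------------------------------------------------------
# correlation-matrix transform (canonical partial correlations)
# ---------------------------------------------------------------------------

def _cpc_pairs(d: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(1, d) for j in range(i)]


def _cpc_alphas(d: int, eta: float) -> np.ndarray:
    """Shifted-Beta shapes per CPC making the induced prior LKJ(eta)."""
    return np.array([eta + (d - 2 - j) / 2.0 for i, j in _cpc_pairs(d)])


def chol_from_cpc(w: np.ndarray, d: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from CPCs in (-1, 1)."""
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    k = 0
    for i in range(1, d):
        s = 0.0
        for j in range(i):
            t = np.sqrt(max(1.0 - s, 1e-14))
            L[i, j] = w[k] * t
            s += L[i, j] ** 2
            k += 1
        L[i, i] = np.sqrt(max(1.0 - s, 1e-14))
    return L


def chol_from_cpc_grad(w: np.ndarray, d: int, L: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Backpropagate dLoss/dL (G) through :func:`chol_from_cpc` to the CPCs."""
    dw = np.zeros_like(w)
    starts = np.concatenate(([0], np.cumsum(np.arange(1, d))))
    for i in range(1, d):
        base = starts[i - 1]
        s_before = np.empty(i)
        s = 0.0
        for j in range(i):
            s_before[j] = s
            s += L[i, j] ** 2
        ds = G[i, i] * (-0.5 / L[i, i])
        for j in range(i - 1, -1, -1):
            t = np.sqrt(max(1.0 - s_before[j], 1e-14))
            dL = G[i, j] + ds * 2.0 * L[i, j]
            dw[base + j] = dL * t
            dt = dL * w[base + j]
            ds = ds + dt * (-0.5 / t)
    return dw


# ---------------------------------------------------------------------------
# the model: packed parameter vector, log posterior and gradient
# ---------------------------------------------------------------------------

class DhglmModel:
    """Packed-parameter view of one (frame, spec) pair.

    Parameters live in a flat unconstrained vector theta containing, in
    order: beta_mu (3), beta_sigma (3), then per effect block the log group
    SD(s), the unconstrained CPCs (correlated blocks only) and the
    standardized group effects z (non-centered).
    """

    def __init__(self, frame: ModelFrame, spec: ModelSpec, priors: PriorConfig = PriorConfig()):
        self.frame = frame
        self.spec = spec
        self.priors = priors
        self.y = np.asarray(frame.log_ivi, float)
        if np.isnan(frame.age_s).any() or np.isnan(frame.brood_s).any():
            raise ValueError("NaN covariates in model frame")
        self.X = np.column_stack([np.ones(frame.n_obs), frame.age_s, frame.brood_s])
        self.mean_y = float(self.y.mean())
        self._mult = {
            "mu_intercept": np.ones(frame.n_obs),
            "mu_age": np.asarray(frame.age_s, float),
            "mu_brood": np.asarray(frame.brood_s, float),
            "sigma_intercept": np.ones(frame.n_obs),
        }
        self._gidx = {
            "site": np.asarray(frame.site),
            "pair": np.asarray(frame.pair),
            "year": np.asarray(frame.year),
        }
        self._glabels = {
            "site": frame.site_labels,
            "pair": frame.pair_labels,
            "year": frame.year_labels,
        }
        self.blocks = spec.blocks()

        # flat layout
        self._slices: dict[str, slice] = {}
        pos = 0

        def add(name, size):
            nonlocal pos
            self._slices[name] = slice(pos, pos + size)
            pos += size

        add("beta_mu", 3)
        add("beta_sigma", 3)
        for b in self.blocks:
            n_g = len(self._glabels[b.group])
            add(f"log_sd[{b.key}]", b.dim)
            if b.correlated:
                add(f"corr_raw[{b.key}]", b.dim * (b.dim - 1) // 2)
            add(f"z[{b.key}]", n_g * b.dim)
        self.n_params = pos

    # -- initialization -----------------------------------------------------
    def initial_point(self, rng: np.random.Generator, jitter: float = 0.5) -> np.ndarray:
        theta = 0.1 * jitter * rng.standard_normal(self.n_params)
        theta[self._slices["beta_mu"]][0] += self.mean_y
        theta[self._slices["beta_sigma"]][0] += np.log(max(self.y.std(), 1e-3))
        for b in self.blocks:
            theta[self._slices[f"log_sd[{b.key}]"]] += np.log(0.3)
        return theta

    # -- density ------------------------------------------------------------
    def _linear_predictors(self, theta: np.ndarray):
        """mu_i and log sigma_i plus per-block intermediates for the backward pass."""
        beta_mu = theta[self._slices["beta_mu"]]
        beta_sigma = theta[self._slices["beta_sigma"]]
        mu = self.X @ beta_mu
        logsig = self.X @ beta_sigma
        cache = []
        for b in self.blocks:
            gidx = self._gidx[b.group]
            n_g = len(self._glabels[b.group])
            ls = theta[self._slices[f"log_sd[{b.key}]"]]
            sd = np.exp(ls)
            Z = theta[self._slices[f"z[{b.key}]"]].reshape(n_g, b.dim)
            if b.correlated:
                w = np.tanh(theta[self._slices[f"corr_raw[{b.key}]"]])
                L = chol_from_cpc(w, b.dim)
                M = Z @ L.T
            else:
                w, L, M = None, None, Z
            E = M * sd
            for j, term in enumerate(b.terms):
                contrib = E[gidx, j] * self._mult[term]
                if term == "sigma_intercept":
                    logsig += contrib
                else:
                    mu += contrib
            cache.append((b, gidx, n_g, sd, Z, w, L, M, E))
        return mu, logsig, cache

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        pr = self.priors
        mu, logsig, cache = self._linear_predictors(theta)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            sig2 = np.exp(2.0 * logsig)
            r = self.y - mu
            q = r * r / sig2
            ll = -float(logsig.sum()) - 0.5 * float(q.sum())
        if not np.isfinite(ll):
            return -np.inf, np.zeros_like(theta)

        grad = np.zeros_like(theta)
        dmu = r / sig2
        dls_obs = q - 1.0

        beta_mu = theta[self._slices["beta_mu"]]
        beta_sigma = theta[self._slices["beta_sigma"]]
        loc = np.array([self.mean_y, 0.0, 0.0])
        scale_mu = np.array([pr.mu_intercept_scale, pr.mu_slope_scale, pr.mu_slope_scale])
        lp = ll
        lp += -0.5 * float((((beta_mu - loc) / scale_mu) ** 2).sum())
        lp += -0.5 * float(((beta_sigma / pr.sigma_coef_scale) ** 2).sum())
        grad[self._slices["beta_mu"]] = self.X.T @ dmu - (beta_mu - loc) / scale_mu**2
        grad[self._slices["beta_sigma"]] = (
            self.X.T @ dls_obs - beta_sigma / pr.sigma_coef_scale**2
        )

        for b, gidx, n_g, sd, Z, w, L, M, E in cache:
            dE = np.empty((n_g, b.dim))
            for j, term in enumerate(b.terms):
                dpred = dls_obs if term == "sigma_intercept" else dmu
                dE[:, j] = np.bincount(gidx, weights=dpred * self._mult[term], minlength=n_g)
            dsd = (dE * M).sum(axis=0)
            sd_over = sd / pr.sd_scale**2
            grad[self._slices[f"log_sd[{b.key}]"]] = dsd * sd - sd * sd_over + 1.0
            lp += float((-0.5 * (sd / pr.sd_scale) ** 2 + np.log(sd)).sum())
            dM = dE * sd
            if b.correlated:
                dZ = dM @ L
                dLmat = dM.T @ Z
                dw = chol_from_cpc_grad(w, b.dim, L, dLmat)
                alphas = _cpc_alphas(b.dim, pr.lkj_eta)
                lp += float((alphas * np.log1p(-w * w)).sum())
                grad[self._slices[f"corr_raw[{b.key}]"]] = dw * (1.0 - w * w) - 2.0 * alphas * w
            else:
                dZ = dM
            lp += -0.5 * float((Z * Z).sum())
            grad[self._slices[f"z[{b.key}]"]] = (dZ - Z).ravel()

        if not np.isfinite(lp):
            return -np.inf, np.zeros_like(theta)
        return lp, grad

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-observation Normal log density (the LOO ingredient)."""
        mu, logsig, _ = self._linear_predictors(theta)
        r = self.y - mu
        return -0.5 * np.log(2 * np.pi) - logsig - 0.5 * (r / np.exp(logsig)) ** 2

    # -- constrained view ---------------------------------------------------
    def constrain(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Named constrained parameters for one draw."""
        out = {
            "beta_mu": np.array(theta[self._slices["beta_mu"]]),
            "beta_sigma": np.array(theta[self._slices["beta_sigma"]]),
        }
        for b in self.blocks:
            n_g = len(self._glabels[b.group])
            sd = np.exp(theta[self._slices[f"log_sd[{b.key}]"]])
            Z = theta[self._slices[f"z[{b.key}]"]].reshape(n_g, b.dim)
            if b.correlated:
                w = np.tanh(theta[self._slices[f"corr_raw[{b.key}]"]])
                L = chol_from_cpc(w, b.dim)
                R = L @ L.T
                E = (Z @ L.T) * sd
                for a in range(b.dim):
                    for c in range(a + 1, b.dim):
                        out[f"corr[{b.group}:{b.terms[a]},{b.terms[c]}]"] = np.array(R[a, c])
            else:
                E = Z * sd
            for j, term in enumerate(b.terms):
                out[f"sd[{b.group}:{term}]"] = np.array(sd[j])
                out[f"effects[{b.group}:{term}]"] = E[:, j]
        return out


def log_likelihood(theta: np.ndarray, frame: ModelFrame, spec: ModelSpec) -> np.ndarray:
    """Vectorized per-observation log density for a packed parameter vector."""
    return DhglmModel(frame, spec).pointwise_loglik(np.asarray(theta, float))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class ConvergenceError(RuntimeError):
    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class SamplerConfig:
    seed: int
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    max_treedepth: int = 10
    target_accept: float = 0.9

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "chains": self.chains,
            "warmup": self.warmup,
            "draws": self.draws,
            "max_treedepth": self.max_treedepth,
            "target_accept": self.target_accept,
        }


@dataclass
class PosteriorResult:
    """Posterior draws, diagnostics and the pointwise log-likelihood matrix.

    ``draws`` maps parameter names to arrays of shape (chains, draws, ...);
    ``loglik`` has shape (chains*draws, n_obs).  ``meta`` carries whatever
    the summaries need without the original frame (group labels, covariate
    second moments, per-draw mean residual variance).
    """

    spec: ModelSpec
    config: SamplerConfig
    draws: dict[str, np.ndarray]
    loglik: np.ndarray
    diagnostics: dict
    meta: dict = field(default_factory=dict)

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one parameter with chains flattened: (chains*draws, ...)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def n_obs(self) -> int:
        return self.loglik.shape[1]

    # -- persistence --------------------------------------------------------
    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cols = {}
        chains, ndraws = next(iter(self.draws.values())).shape[:2]
        for name, arr in self.draws.items():
            flat = arr.reshape(chains * ndraws, -1)
            if flat.shape[1] == 1:
                cols[name] = flat[:, 0]
            else:
                for j in range(flat.shape[1]):
                    cols[f"{name}[{j}]"] = flat[:, j]
        import pandas as pd

        pd.DataFrame(cols).to_csv(outdir / "draws.csv", index=False)
        np.save(outdir / "loglik.npy", self.loglik)
        (outdir / "diagnostics.json").write_text(
            json.dumps(_jsonable(self.diagnostics), indent=2)
        )
        (outdir / "spec.yaml").write_text(self.spec.to_yaml())
        meta = dict(self.meta)
        meta["sampler_config"] = self.config.to_dict()
        meta["shape"] = [chains, ndraws]
        meta["param_shapes"] = {k: list(v.shape[2:]) for k, v in self.draws.items()}
        (outdir / "meta.json").write_text(json.dumps(_jsonable(meta), indent=2))

    @classmethod
    def load(cls, outdir) -> "PosteriorResult":
        import pandas as pd

        outdir = Path(outdir)
        meta = json.loads((outdir / "meta.json").read_text())
        chains, ndraws = meta.pop("shape")
        shapes = meta.pop("param_shapes")
        cfg = SamplerConfig(**meta.pop("sampler_config"))
        df = pd.read_csv(outdir / "draws.csv")
        draws = {}
        for name, shape in shapes.items():
            size = int(np.prod(shape)) if shape else 1
            if size == 1 and name in df.columns:
                flat = df[name].to_numpy()[:, None]
            else:
                flat = np.column_stack([df[f"{name}[{j}]"].to_numpy() for j in range(size)])
            draws[name] = flat.reshape(chains, ndraws, *shape)
        return cls(
            spec=ModelSpec.from_yaml((outdir / "spec.yaml").read_text()),
            config=cfg,
            draws=draws,
            loglik=np.load(outdir / "loglik.npy"),
            diagnostics=json.loads((outdir / "diagnostics.json").read_text()),
            meta=meta,
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# parameters whose convergence gates any posterior summary: fixed effects,
# group SDs, correlations and the year-level effects themselves
def _checked_params(draws: dict[str, np.ndarray]) -> list[str]:
    keep = []
    for name in draws:
        if name.startswith(("beta_", "sd[", "corr[")) or name.startswith("effects[year"):
            keep.append(name)
    return keep


def fit(
    frame: ModelFrame,
    spec: ModelSpec,
    config: SamplerConfig,
    priors: PriorConfig = PriorConfig(),
    check: bool = True,
) -> PosteriorResult:
    """Sample the posterior with NUTS and package draws plus diagnostics.

    Raises :class:`ConvergenceError` when divergences exceed 1% of draws or
    (with ``check=True``) when any reported parameter has R-hat > 1.01 or
    effective sample size < 400.
    """
    import arviz as az

    model = DhglmModel(frame, spec, priors)
    nuts = NutsConfig(
        warmup=config.warmup,
        draws=config.draws,
        max_treedepth=config.max_treedepth,
        target_accept=config.target_accept,
    )
    seeds = np.random.SeedSequence([config.seed & 0x7FFFFFFF, 2025]).spawn(config.chains)
    raw = np.empty((config.chains, config.draws, model.n_params))
    divergences = []
    for c in range(config.chains):
        rng = np.random.default_rng(seeds[c])
        q0 = model.initial_point(rng)
        res = nuts_chain(model.logp_grad, q0, nuts, rng)
        raw[c] = res["draws"]
        divergences.append(res["divergences"])

    # constrained draws
    first = model.constrain(raw[0, 0])
    draws = {
        name: np.empty((config.chains, config.draws) + np.shape(val))
        for name, val in first.items()
    }
    loglik = np.empty((config.chains * config.draws, frame.n_obs))
    resid_var = np.empty(config.chains * config.draws)
    k = 0
    for c in range(config.chains):
        for d in range(config.draws):
            con = model.constrain(raw[c, d])
            for name, val in con.items():
                draws[name][c, d] = val
            ll = model.pointwise_loglik(raw[c, d])
            loglik[k] = ll
            # mean residual variance over the observed covariate distribution
            mu, logsig, _ = model._linear_predictors(raw[c, d])
            resid_var[k] = float(np.mean(np.exp(2.0 * logsig)))
            k += 1

    checked = _checked_params(draws)
    ds = az.convert_to_dataset({n: draws[n] for n in checked})
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    diag = {
        "divergences": divergences,
        "rhat": {n: np.asarray(rhat[n]).tolist() for n in checked},
        "ess": {n: np.asarray(ess[n]).tolist() for n in checked},
    }

    total = config.chains * config.draws
    if sum(divergences) > 0.01 * total:
        raise ConvergenceError(
            f"{sum(divergences)} divergent transitions out of {total} draws", diag
        )
    if check:
        bad = []
        for n in checked:
            r = np.atleast_1d(np.asarray(rhat[n]))
            e = np.atleast_1d(np.asarray(ess[n]))
            if np.any(r > 1.01):
                bad.append(f"rhat({n}) = {float(np.max(r)):.3f}")
            if np.any(e < 400):
                bad.append(f"ess({n}) = {float(np.min(e)):.0f}")
        if bad:
            raise ConvergenceError("convergence diagnostics failed: " + "; ".join(bad), diag)

    meta = {
        "year_labels": list(frame.year_labels),
        "site_labels": list(frame.site_labels),
        "pair_labels": list(frame.pair_labels),
        "scaling": dict(frame.scaling),
        "mean_age_s_sq": float(np.mean(np.asarray(frame.age_s) ** 2)),
        "mean_brood_s_sq": float(np.mean(np.asarray(frame.brood_s) ** 2)),
        "resid_var": resid_var,
    }
    return PosteriorResult(
        spec=spec, config=config, draws=draws, loglik=loglik, diagnostics=diag, meta=meta
    )


def prior_predictive(
    spec: ModelSpec, frame: ModelFrame, n_draws: int, rng: np.random.Generator,
    priors: PriorConfig = PriorConfig(),
) -> np.ndarray:
    """Simulate log-IVI datasets from the prior (sanity checking the priors)."""
    model = DhglmModel(frame, spec, priors)
    out = np.empty((n_draws, frame.n_obs))
    for s in range(n_draws):
        theta = np.zeros(model.n_params)
        theta[model._slices["beta_mu"]] = np.array(
            [model.mean_y, 0, 0]
        ) + rng.standard_normal(3) * np.array(
            [priors.mu_intercept_scale, priors.mu_slope_scale, priors.mu_slope_scale]
        )
        theta[model._slices["beta_sigma"]] = priors.sigma_coef_scale * rng.standard_normal(3)
        for b in model.blocks:
            sd = np.abs(priors.sd_scale * rng.standard_normal(b.dim))
            theta[model._slices[f"log_sd[{b.key}]"]] = np.log(np.maximum(sd, 1e-6))
            n_g = len(model._glabels[b.group])
            theta[model._slices[f"z[{b.key}]"]] = rng.standard_normal(n_g * b.dim)
            if b.correlated:
                alphas = _cpc_alphas(b.dim, priors.lkj_eta)
                w = 2.0 * rng.beta(alphas, alphas) - 1.0
                theta[model._slices[f"corr_raw[{b.key}]"]] = np.arctanh(
                    np.clip(w, -1 + 1e-9, 1 - 1e-9)
                )
        mu, logsig, _ = model._linear_predictors(theta)
        out[s] = mu + np.exp(logsig) * rng.standard_normal(frame.n_obs)
    return out
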