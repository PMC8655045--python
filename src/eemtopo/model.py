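"""Multivariate multilevel Bayesian model of the texture parameters.

The response of one scan is the vector of the four log-transformed
ISO 25178 parameters; the model is

    Y = X B + Z U + E

with fixed effects for *area* (cut vs control) and — in model M1 — for
*erasing* (after vs before EEM), and multivariate-Gaussian random
intercepts for bone *specimen* and *measurement location*.  Residual
rows are multivariate Gaussian.  Because the responses are logs, the
``erasing`` coefficient of each parameter is a log-ratio: its
exponential is the after/before ratio reported with 95 % credibility
intervals.

The posterior is sampled with a blocked Gibbs sampler.  All full
conditionals are available in closed form: fixed effects carry
independent Normal(0, 1) priors (responses are column-centred
internally, so intercept magnitudes do not fight the prior), and the
three 4x4 covariance matrices (residual, specimen, location) carry the
Huang–Wand (2013) hierarchical inverse-Wishart prior, which induces
half-t(2) margins on the standard deviations and near-uniform priors on
the correlations.  Model comparison uses PSIS-LOO on the pointwise
conditional log-likelihood; convergence is monitored with split-R̂.

The public surface follows the statsmodels convention: build a
:class:`SurfaceTextureModel` from records or a DataFrame, call
``fit()``, and read estimates, ratios, LOO and goodness of fit off the
returned :class:`SurfaceTextureResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import records_to_dataframe
from .surfaces import TextureRecord

__all__ = [
    "ModelData",
    "build_design",
    "SurfaceTextureModel",
    "SurfaceTextureResults",
    "fit_model",
    "compare_loo",
    "posterior_ratios",
    "gof_mahalanobis",
    "descriptive_table",
]

PARAMETERS = ("Sa", "Spc", "Sha", "Smrk1")
_EFFECTS_M1 = ("intercept", "area", "erasing")
_EFFECTS_M0 = ("intercept", "area")


@dataclass
class ModelData:
    """Design matrices of the multivariate mixed model.

    ``Y`` is n_scans x 4 (natural-log parameter values); ``X`` the
    fixed-effect design (intercept, area==cut and, for M1,
    phase==after); ``Z`` the random-effect indicator matrix whose
    columns are specimen indicators followed by location indicators, so
    every row has exactly two ones.
    """

    Y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    effects: tuple[str, ...]
    specimens: list[str]
    locations: list[tuple]
    specimen_index: np.ndarray  # scan -> specimen column
    location_index: np.ndarray  # scan -> location column (0-based within location block)
    index: pd.DataFrame

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def n_specimens(self) -> int:
        return len(self.specimens)

    @property
    def n_locations(self) -> int:
        return len(self.locations)


def build_design(records: list[TextureRecord] | pd.DataFrame, model: str = "M1") -> ModelData:
    """Assemble Y, X, Z from texture records.

    Records must be complete (all four parameters finite) and strictly
    positive, since the responses are logged.  M0 has fixed effects
    (intercept, area); M1 adds the erasing effect.
    """
    if model not in ("M0", "M1"):
        raise ValueError(f"unknown model {model!r}; expected 'M0' or 'M1'")
    df = records if isinstance(records, pd.DataFrame) else records_to_dataframe(records)
    required = ["specimen", "area", "location", "phase", *PARAMETERS]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"records table lacks columns {missing_cols}")
    vals = df[list(PARAMETERS)].to_numpy(float)
    bad = ~np.isfinite(vals) | (vals <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        row = df.iloc[i]
        raise ValueError(
            f"record ({row['specimen']}, {row['area']}, {int(row['location'])}, {row['phase']}) "
            f"has non-positive or missing {PARAMETERS[j]}: log-transform undefined"
        )
    Y = np.log(vals)
    effects = _EFFECTS_M1 if model == "M1" else _EFFECTS_M0
    X = np.column_stack(
        [
            np.ones(len(df)),
            (df["area"].astype(str) == "cut").to_numpy(float),
        ]
        + ([(df["phase"].astype(str) == "after").to_numpy(float)] if model == "M1" else [])
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    specimens = sorted(df["specimen"].astype(str).unique())
    loc_keys = list(
        df[["specimen", "area", "location"]]
        .astype({"location": int})
        .apply(lambda r: (str(r["specimen"]), str(r["area"]), int(r["location"])), axis=1)
    )
    locations = sorted(set(loc_keys))
    spec_col = {s: i for i, s in enumerate(specimens)}
    loc_col = {k: i for i, k in enumerate(locations)}
    n = len(df)
    Z = np.zeros((n, len(specimens) + len(locations)))
    spec_idx = np.empty(n, dtype=int)
    loc_idx = np.empty(n, dtype=int)
    for i, (s, k) in enumerate(zip(df["specimen"].astype(str), loc_keys)):
        spec_idx[i] = spec_col[s]
        loc_idx[i] = loc_col[k]
        Z[i, spec_idx[i]] = 1.0
        Z[i, len(specimens) + loc_idx[i]] = 1.0
    return ModelData(
        Y=Y, X=X, Z=Z, effects=effects, specimens=specimens, locations=locations,
        specimen_index=spec_idx, location_index=loc_idx,
        index=df[["specimen", "area", "location", "phase"]].reset_index(drop=True),
    )


# ------------------------------------------------------------ Gibbs sampler


@dataclass
class SamplerConfig:
    chains: int = 4
    draws: int = 1000
    warmup: int = 2000
    thin: int = 1
    seed: int = 0
    prior_sd_fixed: float = 1.0
    hw_nu: float = 2.0  # Huang-Wand: half-t(nu) margins on SDs
    hw_scale: float = 1.0  # half-t scale A


def _sample_invwishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    # scipy's invwishart with an explicit seeded Generator
    return stats.invwishart.rvs(df=df, scale=scale, random_state=rng)


def _gibbs_chain(data: ModelData, cfg: SamplerConfig, chain_seed: np.random.SeedSequence):
    rng = np.random.default_rng(chain_seed)
    Y0 = data.Y
    n, p = Y0.shape
    ymean = Y0.mean(axis=0)
    Y = Y0 - ymean  # centred responses; intercept draws are shifted back on output
    X = data.X
    k = X.shape[1]
    S, L = data.n_specimens, data.n_locations
    spec_idx, loc_idx = data.specimen_index, data.location_index

    XtX = X.T @ X
    tau2 = cfg.prior_sd_fixed**2
    nu, A = cfg.hw_nu, cfg.hw_scale
    iw_df0 = nu + p - 1

    # initial values
    B = np.linalg.lstsq(X, Y, rcond=None)[0]
    Us = np.zeros((S, p))
    Ul = np.zeros((L, p))
    resid0 = Y - X @ B
    Sig_e = np.cov(resid0.T) + 1e-4 * np.eye(p)
    Sig_s = np.eye(p) * 0.1
    Sig_l = np.eye(p) * 0.1
    a_e = np.ones(p)
    a_s = np.ones(p)
    a_l = np.ones(p)

    spec_counts = np.bincount(spec_idx, minlength=S).astype(float)
    loc_counts = np.bincount(loc_idx, minlength=L).astype(float)

    keep_B = np.empty((cfg.draws, k, p))
    keep_sd_e = np.empty((cfg.draws, p))
    keep_sd_s = np.empty((cfg.draws, p))
    keep_sd_l = np.empty((cfg.draws, p))
    keep_loglik = np.empty((cfg.draws, n))
    keep_Us = np.empty((cfg.draws, S, p))
    keep_Ul = np.empty((cfg.draws, L, p))
    keep_Sig_e = np.empty((cfg.draws, p, p))
    keep_Sig_l = np.empty((cfg.draws, p, p))

    def draw_B(Ve_inv):
        R = Y - Us[spec_idx] - Ul[loc_idx]
        prec = np.kron(Ve_inv, XtX) + np.eye(k * p) / tau2
        rhs = (X.T @ R @ Ve_inv).reshape(-1, order="F")  # vec by columns
        cf = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        zdraw = np.linalg.solve(cf.T, rng.normal(size=k * p))
        return (mean + zdraw).reshape((k, p), order="F")

    def draw_U(Vg_inv, Ve_inv, resid_sum, counts):
        # groups sharing a count share the same conditional precision, so
        # one Cholesky serves all of them (locations all have 2 scans)
        m = counts.size
        out = np.empty((m, p))
        for c in np.unique(counts):
            sel = np.flatnonzero(counts == c)
            cov = np.linalg.inv(c * Ve_inv + Vg_inv)
            means = resid_sum[sel] @ (cov @ Ve_inv).T
            cf = np.linalg.cholesky(cov)
            out[sel] = means + rng.normal(size=(sel.size, p)) @ cf.T
        return out

    def draw_cov(U, a, m):
        scale = 2 * nu * np.diag(1.0 / a) + U.T @ U
        Sig = _sample_invwishart(rng, iw_df0 + m, scale)
        Sig_inv = np.linalg.inv(Sig)
        new_a = np.empty(p)
        for j in range(p):
            shape = (nu + p) / 2.0
            rate = nu * Sig_inv[j, j] + 1.0 / A**2
            new_a[j] = 1.0 / rng.gamma(shape, 1.0 / rate)
        return Sig, new_a

    total = cfg.warmup + cfg.draws * cfg.thin
    for it in range(total):
        Ve_inv = np.linalg.inv(Sig_e)
        B = draw_B(Ve_inv)
        fixed = X @ B
        # specimen effects
        R1 = Y - fixed - Ul[loc_idx]
        sums = np.zeros((S, p))
        np.add.at(sums, spec_idx, R1)
        Us = draw_U(np.linalg.inv(Sig_s), Ve_inv, sums, spec_counts)
        # location effects
        R2 = Y - fixed - Us[spec_idx]
        sums = np.zeros((L, p))
        np.add.at(sums, loc_idx, R2)
        Ul = draw_U(np.linalg.inv(Sig_l), Ve_inv, sums, loc_counts)
        # translation (recentering) moves: the likelihood is invariant to
        # shifting mass between the intercept row and the mean of a random
        # -effect block (and between the area effect and the cut-area
        # location means), so the shift has a closed-form Gaussian
        # conditional under the priors; sampling it breaks the slow random
        # walk between those blocks.
        for which in ("spec", "loc", "area"):
            if which == "spec":
                prec = np.linalg.inv(Sig_s) * S + np.eye(p) / tau2
                lin = np.linalg.inv(Sig_s) @ Us.sum(axis=0) - B[0] / tau2
            elif which == "loc":
                prec = np.linalg.inv(Sig_l) * L + np.eye(p) / tau2
                lin = np.linalg.inv(Sig_l) @ Ul.sum(axis=0) - B[0] / tau2
            else:
                if k < 2:
                    continue
                cut_locs = np.unique(loc_idx[X[:, 1] == 1.0])
                if cut_locs.size == 0:
                    continue
                prec = np.linalg.inv(Sig_l) * cut_locs.size + np.eye(p) / tau2
                lin = np.linalg.inv(Sig_l) @ Ul[cut_locs].sum(axis=0) - B[1] / tau2
            cov_c = np.linalg.inv(prec)
            c = rng.multivariate_normal(cov_c @ lin, cov_c, method="cholesky")
            if which == "spec":
                B[0] += c
                Us -= c
            elif which == "loc":
                B[0] += c
                Ul -= c
            else:
                B[1] += c
                Ul[cut_locs] -= c
        fixed = X @ B
        # covariances
        E = Y - fixed - Us[spec_idx] - Ul[loc_idx]
        Sig_e, a_e = draw_cov(E, a_e, n)
        Sig_s, a_s = draw_cov(Us, a_s, S)
        Sig_l, a_l = draw_cov(Ul, a_l, L)

        if it >= cfg.warmup and (it - cfg.warmup) % cfg.thin == 0:
            j = (it - cfg.warmup) // cfg.thin
            Bout = B.copy()
            Bout[0] += ymean  # un-centre the intercept
            keep_B[j] = Bout
            keep_sd_e[j] = np.sqrt(np.diag(Sig_e))
            keep_sd_s[j] = np.sqrt(np.diag(Sig_s))
            keep_sd_l[j] = np.sqrt(np.diag(Sig_l))
            keep_Us[j] = Us
            keep_Ul[j] = Ul
            keep_Sig_e[j] = Sig_e
            keep_Sig_l[j] = Sig_l
            # pointwise conditional log-likelihood
            cf = np.linalg.cholesky(Sig_e)
            sol = np.linalg.solve(cf, E.T)
            quad = np.sum(sol**2, axis=0)
            logdet = 2 * np.sum(np.log(np.diag(cf)))
            keep_loglik[j] = -0.5 * (p * np.log(2 * np.pi) + logdet + quad)
    return {
        "B": keep_B, "sd_resid": keep_sd_e, "sd_specimen": keep_sd_s,
        "sd_location": keep_sd_l, "log_likelihood": keep_loglik,
        "U_specimen": keep_Us, "U_location": keep_Ul,
        "Sigma_resid": keep_Sig_e, "Sigma_location": keep_Sig_l,
    }


class SurfaceTextureResults:
    """Posterior draws, diagnostics and summaries of a fitted model."""

    def __init__(self, model: "SurfaceTextureModel", chains: list[dict], config: SamplerConfig):
        self.model = model
        self.data = model.data
        self.config = config
        self._stack = {
            key: np.stack([c[key] for c in chains]) for key in chains[0]
        }  # (chain, draw, ...)
        self._idata = None

    # ------------------------------------------------------------- access

    @property
    def n_draws(self) -> int:
        """Total retained posterior draws (chains x draws per chain)."""
        s = self._stack["B"].shape
        return s[0] * s[1]

    def coefficient_draws(self, effect: str) -> np.ndarray:
        """Flattened draws of one fixed-effect row, shape (draws, 4)."""
        if effect not in self.data.effects:
            raise KeyError(f"unknown effect {effect!r}; model has {self.data.effects}")
        i = self.data.effects.index(effect)
        b = self._stack["B"][:, :, i, :]
        return b.reshape(-1, b.shape[-1])

    def to_inference_data(self):
        """arviz InferenceData with posterior and log-likelihood groups."""
        import arviz as az

        if self._idata is None:
            post = {
                "B": self._stack["B"],
                "sd_resid": self._stack["sd_resid"],
                "sd_specimen": self._stack["sd_specimen"],
                "sd_location": self._stack["sd_location"],
            }
            coords = {
                "effect": list(self.data.effects),
                "parameter": list(PARAMETERS),
            }
            dims = {
                "B": ["effect", "parameter"],
                "sd_resid": ["parameter"],
                "sd_specimen": ["parameter"],
                "sd_location": ["parameter"],
            }
            self._idata = az.from_dict(
                posterior=post,
                log_likelihood={"y": self._stack["log_likelihood"]},
                coords=coords,
                dims={**dims, "y": ["scan"]},
            )
        return self._idata

    # -------------------------------------------------------- diagnostics

    def rhat(self) -> pd.DataFrame:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = az.rhat(self.to_inference_data(), var_names=["B", "sd_resid", "sd_specimen", "sd_location"])
        return r.to_dataframe()

    @property
    def max_rhat(self) -> float:
        df = self.rhat()
        return float(np.nanmax(df.to_numpy()))

    @property
    def converged(self) -> bool:
        """R-hat <= 1.01 for all reported quantities."""
        return self.max_rhat <= 1.01

    @property
    def usable(self) -> bool:
        """Fit flagged unusable when R-hat exceeds 1.05."""
        return self.max_rhat <= 1.05

    # ----------------------------------------------------------- summaries

    def summary(self) -> pd.DataFrame:
        """Posterior means, SDs and 95 % intervals of the fixed effects and SDs."""
        rows = []
        for i, eff in enumerate(self.data.effects):
            draws = self._stack["B"][:, :, i, :].reshape(-1, 4)
            for j, par in enumerate(PARAMETERS):
                d = draws[:, j]
                rows.append(
                    {
                        "term": f"{eff}[{par}]",
                        "mean": d.mean(), "sd": d.std(ddof=1),
                        "hdi_2.5%": np.quantile(d, 0.025),
                        "hdi_97.5%": np.quantile(d, 0.975),
                    }
                )
        for key, label in [
            ("sd_resid", "sd_resid"), ("sd_specimen", "sd_specimen"), ("sd_location", "sd_location"),
        ]:
            draws = self._stack[key].reshape(-1, 4)
            for j, par in enumerate(PARAMETERS):
                d = draws[:, j]
                rows.append(
                    {
                        "term": f"{label}[{par}]",
                        "mean": d.mean(), "sd": d.std(ddof=1),
                        "hdi_2.5%": np.quantile(d, 0.025),
                        "hdi_97.5%": np.quantile(d, 0.975),
                    }
                )
        return pd.DataFrame(rows).set_index("term")

    def posterior_ratios(self, effect: str = "erasing") -> pd.DataFrame:
        """After/before ratio quantiles per parameter: exp(coefficient draws).

        The exp transform is applied after the quantiles; both orders agree
        for a monotone map, and this one is exact under interpolation.
        """
        draws = self.coefficient_draws(effect)
        q = np.exp(np.quantile(draws, [0.025, 0.5, 0.975], axis=0))
        return pd.DataFrame(
            {"q2.5": q[0], "median": q[1], "q97.5": q[2]}, index=list(PARAMETERS)
        )

    def loo(self):
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return az.loo(self.to_inference_data(), pointwise=True)

    def gof_mahalanobis(self, data: "ModelData | None" = None) -> pd.DataFrame:
        return gof_mahalanobis(self, data)

    def plot_ratios(self, effect: str = "erasing", ax=None):
        """Forest plot of the after/before ratios with 95 % intervals."""
        import matplotlib.pyplot as plt

        ratios = self.posterior_ratios(effect)
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 2.5))
        y = np.arange(len(ratios))[::-1]
        ax.hlines(y, ratios["q2.5"], ratios["q97.5"], color="0.3")
        ax.plot(ratios["median"], y, "o", color="0.1")
        ax.axvline(1.0, color="0.7", ls="--", lw=1)
        ax.set_yticks(y, ratios.index)
        ax.set_xlabel(f"after/before ratio ({effect})")
        return ax

    def simulate(self, seed: int = 0) -> np.ndarray:
        """New responses drawn from the fitted model (posterior means).

        Keeps the estimated fixed and specimen effects, draws fresh
        location effects and residuals from the posterior-mean
        covariances; returns an n x 4 log-scale response matrix.
        """
        rng = np.random.default_rng(seed)
        pred = self.fitted_values(level="specimen")
        Sl = self._stack["Sigma_location"].mean(axis=(0, 1))
        Se = self._stack["Sigma_resid"].mean(axis=(0, 1))
        u_new = rng.multivariate_normal(np.zeros(4), Sl, size=self.data.n_locations)
        e_new = rng.multivariate_normal(np.zeros(4), Se, size=self.data.n)
        return pred + u_new[self.data.location_index] + e_new

    def fitted_values(self, level: str = "location") -> np.ndarray:
        """Posterior-mean predictions on the log scale.

        ``level="location"`` conditions on both random-effect levels;
        ``level="specimen"`` stops at the specimen effects, leaving the
        location effect in the residual.
        """
        B = self._stack["B"].mean(axis=(0, 1))
        Us = self._stack["U_specimen"].mean(axis=(0, 1))
        # the stored intercept row is already un-centred, so X @ B carries
        # the response means and the centred U draws line up with it
        pred = self.data.X @ B + Us[self.data.specimen_index]
        if level == "location":
            Ul = self._stack["U_location"].mean(axis=(0, 1))
            pred = pred + Ul[self.data.location_index]
        elif level != "specimen":
            raise ValueError(f"unknown level {level!r}")
        return pred


@dataclass
class SurfaceTextureModel:
    """Multivariate multilevel model of log texture parameters.

    Parameters
    ----------
    data : ModelData
        Design built by :func:`build_design`.
    model : str
        "M0" (area only) or "M1" (area + erasing).
    """

    data: ModelData
    model_name: str = "M1"

    @classmethod
    def from_records(cls, records: list[TextureRecord], model: str = "M1") -> "SurfaceTextureModel":
        return cls(data=build_design(records, model=model), model_name=model)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: str = "M1") -> "SurfaceTextureModel":
        return cls(data=build_design(df, model=model), model_name=model)

    def fit(
        self,
        chains: int = 4,
        draws: int = 1000,
        warmup: int = 2000,
        thin: int = 1,
        seed: int = 0,
        **prior_kwargs,
    ) -> SurfaceTextureResults:
        """Run the blocked Gibbs sampler and return results.

        Defaults follow the study protocol: four chains, 2000-iteration
        warm-up, 1000 retained draws per chain (4000 posterior samples).
        """
        cfg = SamplerConfig(chains=chains, draws=draws, warmup=warmup, thin=thin, seed=seed, **prior_kwargs)
        seeds = np.random.SeedSequence(seed).spawn(chains)
        out = [_gibbs_chain(self.data, cfg, s) for s in seeds]
        return SurfaceTextureResults(self, out, cfg)


# ----------------------------------------------------- module-level helpers


def fit_model(
    data: ModelData, chains: int = 4, draws: int = 1000, warmup: int = 2000, seed: int = 0
) -> SurfaceTextureResults:
    """Functional wrapper: fit the model defined by ``data``."""
    model = SurfaceTextureModel(data=data, model_name="M1" if "erasing" in data.effects else "M0")
    return model.fit(chains=chains, draws=draws, warmup=warmup, seed=seed)


def posterior_ratios(fit: SurfaceTextureResults, effect: str = "erasing") -> pd.DataFrame:
    return fit.posterior_ratios(effect)


def compare_loo(fit0: SurfaceTextureResults, fit1: SurfaceTextureResults) -> dict:
    """PSIS-LOO comparison of two fits on identical responses.

    Returns the expected log predictive densities, their difference
    (fit1 - fit0) with its paired standard error, the preferred model
    (when |diff| > 2 SE), and a warning flag when importance weights are
    unstable (Pareto k̂ > 0.7 for more than 10 % of points).
    """
    if fit0.data.Y.shape != fit1.data.Y.shape or not np.allclose(fit0.data.Y, fit1.data.Y):
        raise ValueError("LOO comparison requires identical responses Y")
    l0, l1 = fit0.loo(), fit1.loo()
    e0 = np.asarray(l0.loo_i)
    e1 = np.asarray(l1.loo_i)
    diff_i = e1 - e0
    n = diff_i.size
    diff = float(diff_i.sum())
    se = float(np.sqrt(n * np.var(diff_i, ddof=1)))
    preferred = None
    if abs(diff) > 2 * se:
        preferred = "M1" if diff > 0 else "M0"
    bad = 0.0
    for l in (l0, l1):
        k = np.asarray(l.pareto_k)
        bad = max(bad, float(np.mean(k > 0.7)))
    return {
        "elpd_0": float(l0.elpd_loo), "elpd_1": float(l1.elpd_loo),
        "elpd_diff": diff, "se_diff": se, "preferred": preferred,
        "unstable_weights": bad > 0.10, "max_bad_k_fraction": bad,
    }


def gof_mahalanobis(fit: SurfaceTextureResults, data: ModelData | None = None) -> pd.DataFrame:
    """Scaled squared Mahalanobis residual distances vs F quantiles.

    Each observation's residual against its specimen-level prediction is
    measured in the metric of the posterior-mean location-plus-residual
    covariance.  (Conditioning all the way down to the location effects
    would shrink the residuals — each location has only two scans — and
    destroy the calibration.)  The classical scaling
    (n - p) / (p (n - 1)) makes the reference distribution F(p, n - p).
    Returns the sorted distances with their theoretical quantiles; the
    QQ slope against the F quantiles is stored in ``attrs["qq_slope"]``.
    """
    data = data if data is not None else fit.data
    if data.Y.shape != fit.data.Y.shape:
        raise ValueError("data must match the fitted design")
    n, p = data.Y.shape
    resid = data.Y - fit.fitted_values(level="specimen")
    if np.max(np.abs(resid)) < 1e-12:
        out = pd.DataFrame({"distance": np.zeros(n), "theoretical": stats.f.ppf((np.arange(1, n + 1) - 0.5) / n, p, n - p)})
        out.attrs["qq_slope"] = 0.0
        return out
    Sigma = fit._stack["Sigma_location"].mean(axis=(0, 1)) + fit._stack["Sigma_resid"].mean(axis=(0, 1))
    if np.linalg.cond(Sigma) > 1e12:
        raise ValueError("singular residual covariance")
    Si = np.linalg.inv(Sigma)
    d2 = np.einsum("ij,jk,ik->i", resid, Si, resid)
    scaled = (n - p) / (p * (n - 1)) * d2
    order = np.argsort(scaled)
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.f.ppf(probs, p, n - p)
    out = pd.DataFrame(
        {"distance": scaled[order], "theoretical": theo},
    )
    # quartile-based QQ-line slope (tail quantiles are too noisy to anchor)
    qs, qt = np.quantile(scaled, [0.25, 0.75]), stats.f.ppf([0.25, 0.75], p, n - p)
    out.attrs["qq_slope"] = float((qs[1] - qs[0]) / (qt[1] - qt[0]))
    return out


def descriptive_table(records: list[TextureRecord] | pd.DataFrame) -> pd.DataFrame:
    """Raw-value mean (SD) of each parameter per phase (before/after)."""
    df = records if isinstance(records, pd.DataFrame) else records_to_dataframe(records)
    rows = []
    for phase in ("before", "after"):
        sub = df[df["phase"].astype(str) == phase]
        if sub.empty:
            raise ValueError(f"no records in phase {phase!r}")
        for par in PARAMETERS:
            vals = sub[par].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "parameter": par, "phase": phase,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)
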