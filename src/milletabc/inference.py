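"""Approximate Bayesian Computation over the domestication model.

The reference table pairs prior draws with their simulated multi-locus
summary vectors. Rejection keeps the simulations closest to the observed
summaries in a Euclidean distance standardized entry-wise by a robust
scale (MAD, falling back to the SD when the MAD is zero). Scenario choice
(gene flow vs no gene flow) follows the weighted logistic-regression
approach: a kernel-weighted logistic fit of the scenario indicator on the
summaries among retained simulations, evaluated at the observed vector.
Parameter posteriors come from regression adjustment of the accepted draws
— local-linear or nonlinear (single-hidden-layer network with a
heteroscedastic spread correction) — performed on transformed parameters
(log, or logit within prior bounds) so that adjusted values respect the
prior support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from milletabc.simulate import (
    WITHOUT_MIGRATION,
    DemographicParams,
    LocusSpec,
    PriorConfig,
    sample_prior,
    simulate_dataset,
)
from milletabc.twopop import MultiLocusSummary

PARAM_NAMES = [
    "theta_w",
    "theta_d0",
    "theta_d1",
    "rho",
    "mig_wd",
    "mig_dw",
    "mu",
    "t_years",
    "T",
]


# ---------------------------------------------------------------------------
# reference table


@dataclass
class ReferenceTable:
    """Prior draws and their simulated summary vectors."""

    params: pd.DataFrame  # columns = PARAM_NAMES
    summaries: np.ndarray  # (n_sims, n_summaries); NaN where flagged
    names: list[str]
    scenario: str
    prior: PriorConfig
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.params) != self.summaries.shape[0]:
            raise ValueError("parameter and summary row counts differ")

    @property
    def n(self) -> int:
        return len(self.params)

    def valid_columns(self) -> np.ndarray:
        return ~np.isnan(self.summaries).any(axis=0)

    def to_tsv(self, path) -> None:
        df = pd.concat(
            [
                self.params.reset_index(drop=True),
                pd.DataFrame(self.summaries, columns=self.names),
            ],
            axis=1,
        )
        df.insert(0, "scenario", self.scenario)
        df.to_csv(path, sep="\t", index=False)


def build_reference_table(
    prior: PriorConfig,
    specs: list[LocusSpec],
    n_sims: int,
    seed: int | None = None,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``n_sims`` (parameters, summaries) rows from the prior."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    rows_p, rows_s = [], []
    names: list[str] | None = None
    for i in range(n_sims):
        params = sample_prior(prior, rng)
        _, summary = simulate_dataset(params, specs, rng=rng)
        if names is None:
            names = summary.names
        rows_p.append([params.as_dict()[k] for k in PARAM_NAMES])
        rows_s.append(summary.values)
        if progress and (i + 1) % 1000 == 0:
            print(f"  {i + 1}/{n_sims} simulations", flush=True)
    summaries = np.asarray(rows_s)
    # a summary undefined at every locus of one simulated dataset is imputed
    # with the column mean over the datasets where it is defined, so the
    # table carries no undefined entries (columns never defined stay NaN
    # and are dropped from distances)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_mean = np.nanmean(summaries, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(summaries))
    fill = col_mean[nan_c]
    summaries[nan_r[~np.isnan(fill)], nan_c[~np.isnan(fill)]] = fill[~np.isnan(fill)]
    return ReferenceTable(
        params=pd.DataFrame(rows_p, columns=PARAM_NAMES),
        summaries=summaries,
        names=list(names or []),
        scenario=prior.scenario,
        prior=prior,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rejection


def _robust_scales(mat: np.ndarray) -> np.ndarray:
    """Per-column MAD; columns with MAD 0 fall back to the SD."""
    med = np.median(mat, axis=0)
    mad = np.median(np.abs(mat - med), axis=0)
    sd = mat.std(axis=0)
    return np.where(mad > 0, mad, sd)


def _usable_columns(
    obs: MultiLocusSummary, summaries: np.ndarray, scales: np.ndarray
) -> np.ndarray:
    usable = (
        ~obs.flagged
        & ~np.isnan(obs.values)
        & ~np.isnan(summaries).any(axis=0)
        & (scales > 0)
    )
    if not usable.all():
        dropped = [n for n, u in zip(obs.names, usable) if not u]
        warnings.warn(
            f"dropping {len(dropped)} summary entries from the distance: {dropped}",
            stacklevel=3,
        )
    return usable


@dataclass
class RejectionResult:
    """Accepted rows of a reference table, ordered by distance."""

    indices: np.ndarray
    distances: np.ndarray  # for the accepted rows
    weights: np.ndarray  # Epanechnikov kernel on distance, normalized
    used_columns: np.ndarray  # bool mask over summary entries
    scales: np.ndarray  # robust scales of the used columns


def _epanechnikov(distances: np.ndarray) -> np.ndarray:
    dmax = distances.max()
    if dmax == 0:
        w = np.ones_like(distances)
    else:
        w = 1.0 - (distances / dmax) ** 2
        if w.sum() == 0:  # all accepted points on the kernel boundary
            w = np.ones_like(distances)
    return w / w.sum()


def abc_reject(
    obs: MultiLocusSummary, table: ReferenceTable, n_keep: int
) -> RejectionResult:
    """Keep the ``n_keep`` simulations closest to the observed summaries."""
    if not 1 <= n_keep <= table.n:
        raise ValueError(f"n_keep must be in [1, {table.n}]")
    scales = _robust_scales(np.nan_to_num(table.summaries, nan=0.0))
    usable = _usable_columns(obs, table.summaries, scales)
    z_obs = obs.values[usable] / scales[usable]
    z_tab = table.summaries[:, usable] / scales[usable]
    distances = np.sqrt(((z_tab - z_obs) ** 2).sum(axis=1))
    order = np.argsort(distances, kind="stable")[:n_keep]  # ties by row index
    kept = distances[order]
    return RejectionResult(
        indices=order,
        distances=kept,
        weights=_epanechnikov(kept),
        used_columns=usable,
        scales=scales,
    )


# ---------------------------------------------------------------------------
# scenario choice


@dataclass
class ModelChoiceResult:
    posterior_prob: dict[str, float]
    n_retained: int


def model_choice(
    obs: MultiLocusSummary,
    table_a: ReferenceTable,
    table_b: ReferenceTable,
    n_keep: int,
) -> ModelChoiceResult:
    """Posterior scenario probabilities by weighted logistic regression.

    Both tables are pooled, the ``n_keep`` overall-closest rows retained,
    and a logistic regression of the scenario indicator on the standardized
    summaries — weighted by an Epanechnikov kernel on distance — is
    evaluated at the observed summary vector.
    """
    from sklearn.linear_model import LogisticRegression

    if table_a.names != table_b.names:
        raise ValueError("tables have different summary definitions")
    pooled = np.vstack([table_a.summaries, table_b.summaries])
    labels = np.r_[
        np.zeros(table_a.n, dtype=int), np.ones(table_b.n, dtype=int)
    ]
    scales = _robust_scales(np.nan_to_num(pooled, nan=0.0))
    usable = _usable_columns(obs, pooled, scales)
    z_obs = obs.values[usable] / scales[usable]
    z_tab = pooled[:, usable] / scales[usable]
    distances = np.sqrt(((z_tab - z_obs) ** 2).sum(axis=1))
    order = np.argsort(distances, kind="stable")[:n_keep]
    y = labels[order]
    names = (table_a.scenario, table_b.scenario)
    if len(np.unique(y)) < 2:
        warnings.warn("retained simulations contain a single scenario")
        p_b = float(y[0])
        return ModelChoiceResult(
            posterior_prob={names[0]: 1.0 - p_b, names[1]: p_b},
            n_retained=n_keep,
        )
    w = _epanechnikov(distances[order])
    x = z_tab[order] - z_obs  # center at the observation
    clf = LogisticRegression(max_iter=1000)
    clf.fit(x, y, sample_weight=w * len(w))
    p_b = float(clf.predict_proba(np.zeros((1, x.shape[1])))[0, 1])
    return ModelChoiceResult(
        posterior_prob={names[0]: 1.0 - p_b, names[1]: p_b},
        n_retained=n_keep,
    )


# ---------------------------------------------------------------------------
# parameter transforms


_EPS = 1e-9


def _logit(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, _EPS, 1.0 - _EPS)
    return np.log(u / (1.0 - u))


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class ParamTransforms:
    """Forward/backward transforms mapping parameters to the real line.

    Log-uniform parameters use a logit of the position inside their log
    bounds; uniform parameters a logit inside their bounds; mu (log-normal,
    unbounded) a plain log. theta_d0's bounds are conditional on
    min(theta_d1, theta_w) of the same draw, so its back-transform is
    applied after theta_w and theta_d1, guaranteeing the bottleneck
    ordering for adjusted draws.
    """

    def __init__(self, prior: PriorConfig):
        self.prior = prior

    @staticmethod
    def _fwd_bounded_log(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
        u = (np.log(x) - np.log(lo)) / (np.log(hi) - np.log(lo))
        return _logit(u)

    @staticmethod
    def _bwd_bounded_log(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
        return np.exp(np.log(lo) + _expit(z) * (np.log(hi) - np.log(lo)))

    def forward(self, params: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        p = self.prior
        cols: dict[str, np.ndarray] = {}
        cols["theta_w"] = self._fwd_bounded_log(
            params["theta_w"].to_numpy(), *p.theta_w_bounds
        )
        cols["theta_d1"] = self._fwd_bounded_log(
            params["theta_d1"].to_numpy(), *p.theta_d1_bounds
        )
        m = np.minimum(params["theta_w"], params["theta_d1"]).to_numpy()
        u = (np.log(params["theta_d0"].to_numpy()) - np.log(p.theta_d0_span * m)) / (
            -np.log(p.theta_d0_span)
        )
        cols["theta_d0"] = _logit(u)
        cols["rho"] = self._fwd_bounded_log(params["rho"].to_numpy(), *p.rho_bounds)
        cols["mu"] = np.log(params["mu"].to_numpy())
        lo, hi = p.t_bounds
        cols["t_years"] = _logit((params["t_years"].to_numpy() - lo) / (hi - lo))
        if p.scenario != WITHOUT_MIGRATION:
            mlo, mhi = p.mig_bounds
            for name in ("mig_wd", "mig_dw"):
                cols[name] = _logit(
                    (params[name].to_numpy() - mlo) / (mhi - mlo)
                )
        names = list(cols)
        return np.column_stack([cols[k] for k in names]), names

    def backward(self, z: np.ndarray, names: list[str]) -> pd.DataFrame:
        p = self.prior
        zc = {name: z[:, j] for j, name in enumerate(names)}
        out = pd.DataFrame(index=np.arange(z.shape[0]))
        out["theta_w"] = self._bwd_bounded_log(zc["theta_w"], *p.theta_w_bounds)
        out["theta_d1"] = self._bwd_bounded_log(zc["theta_d1"], *p.theta_d1_bounds)
        m = np.minimum(out["theta_w"], out["theta_d1"]).to_numpy()
        out["theta_d0"] = np.exp(
            np.log(p.theta_d0_span * m)
            + _expit(zc["theta_d0"]) * (-np.log(p.theta_d0_span))
        )
        out["rho"] = self._bwd_bounded_log(zc["rho"], *p.rho_bounds)
        out["mu"] = np.exp(zc["mu"])
        lo, hi = p.t_bounds
        out["t_years"] = lo + _expit(zc["t_years"]) * (hi - lo)
        if p.scenario != WITHOUT_MIGRATION:
            mlo, mhi = p.mig_bounds
            for name in ("mig_wd", "mig_dw"):
                out[name] = mlo + _expit(zc[name]) * (mhi - mlo)
        else:
            out["mig_wd"] = 0.0
            out["mig_dw"] = 0.0
        out["T"] = out["t_years"] * out["mu"] / out["theta_w"]
        return out[PARAM_NAMES]


# ---------------------------------------------------------------------------
# regression adjustment


@dataclass
class PosteriorSample:
    """Accepted (and possibly regression-adjusted) parameter draws."""

    params: pd.DataFrame  # natural scale, columns = PARAM_NAMES
    weights: np.ndarray
    distances: np.ndarray
    method: str
    transform: str = "log/logit within prior bounds"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be >= 0")
        self.weights = w / w.sum()

    def draw(self, rng: np.random.Generator) -> DemographicParams:
        """One weighted draw, as simulator-ready parameters."""
        i = rng.choice(len(self.params), p=self.weights)
        row = self.params.iloc[int(i)]
        scenario = (
            WITHOUT_MIGRATION
            if (row["mig_wd"] == 0 and row["mig_dw"] == 0)
            else "with_migration"
        )
        return DemographicParams(
            theta_w=row["theta_w"],
            theta_d0=min(row["theta_d0"], row["theta_d1"], row["theta_w"]),
            theta_d1=row["theta_d1"],
            rho=row["rho"],
            mig_wd=row["mig_wd"],
            mig_dw=row["mig_dw"],
            mu=row["mu"],
            t_years=row["t_years"],
            scenario=scenario,
        )


def _weighted_lstsq(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(coefficients, fitted values) of a weighted linear regression."""
    design = np.column_stack([np.ones(len(x)), x])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw[:, None], rcond=None)
    return beta, design @ beta


def regression_adjust(
    obs: MultiLocusSummary,
    table: ReferenceTable,
    rejection: RejectionResult,
    method: str = "loclinear",
    random_state: int = 0,
) -> PosteriorSample:
    """Posterior sample from accepted rows, optionally regression-adjusted.

    ``rejection``: accepted draws unchanged. ``loclinear``: local-linear
    regression of transformed parameters on standardized summaries with
    Epanechnikov weights; residuals are re-attached to the fit at the
    observed summaries. ``nonlinear``: a single-hidden-layer network
    estimates the conditional mean and (from squared residuals) the
    conditional spread; residuals are rescaled by the spread ratio before
    re-attachment.
    """
    if method not in ("rejection", "loclinear", "nonlinear"):
        raise ValueError(f"unknown method {method!r}")
    idx = rejection.indices
    accepted = table.params.iloc[idx].reset_index(drop=True)
    if method != "rejection" and len(idx) < 20:
        raise ValueError("regression adjustment needs >= 20 accepted rows")
    if method == "rejection":
        return PosteriorSample(
            params=accepted.copy(),
            weights=rejection.weights,
            distances=rejection.distances,
            method=method,
        )

    tr = ParamTransforms(table.prior)
    z, names = tr.forward(accepted)
    usable = rejection.used_columns
    x = (
        table.summaries[idx][:, usable] - obs.values[usable]
    ) / rejection.scales[usable]  # centered at the observation
    try:
        if method == "loclinear":
            beta, fitted = _weighted_lstsq(x, z, rejection.weights)
            pred_obs = beta[0]  # design row at obs is (1, 0, ..., 0)
            adjusted = pred_obs + (z - fitted)
        else:
            adjusted = _nonlinear_adjust(x, z, random_state)
        if not np.isfinite(adjusted).all():
            raise np.linalg.LinAlgError("non-finite adjustment")
    except (np.linalg.LinAlgError, ValueError) as err:
        warnings.warn(f"regression adjustment failed ({err}); using rejection")
        return PosteriorSample(
            params=accepted.copy(),
            weights=rejection.weights,
            distances=rejection.distances,
            method="rejection",
        )
    return PosteriorSample(
        params=tr.backward(adjusted, names),
        weights=rejection.weights,
        distances=rejection.distances,
        method=method,
    )


def _nonlinear_adjust(
    x: np.ndarray, z: np.ndarray, random_state: int
) -> np.ndarray:
    """Network conditional-mean fit with heteroscedastic residual scaling."""
    from sklearn.neural_network import MLPRegressor

    mean_net = MLPRegressor(
        hidden_layer_sizes=(10,),
        solver="lbfgs",
        max_iter=1000,
        random_state=random_state,
    )
    mean_net.fit(x, z)
    fitted = np.atleast_2d(mean_net.predict(x)).reshape(z.shape)
    resid = z - fitted
    log_sq = np.log(resid**2 + 1e-12)
    var_net = MLPRegressor(
        hidden_layer_sizes=(10,),
        solver="lbfgs",
        max_iter=1000,
        random_state=random_state + 1,
    )
    var_net.fit(x, log_sq)
    x0 = np.zeros((1, x.shape[1]))
    pred_obs = np.atleast_2d(mean_net.predict(x0)).reshape(1, z.shape[1])
    sigma = np.exp(0.5 * np.atleast_2d(var_net.predict(x)).reshape(z.shape))
    sigma_obs = np.exp(0.5 * np.atleast_2d(var_net.predict(x0)).reshape(1, -1))
    ratio = np.clip(sigma_obs / np.maximum(sigma, 1e-12), 0.1, 10.0)
    return pred_obs + resid * ratio


# ---------------------------------------------------------------------------
# posterior summaries


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    k = int(np.searchsorted(cw, 0.5))
    if abs(cw[k] - 0.5) < 1e-12 and k + 1 < len(v):
        return float(0.5 * (v[k] + v[k + 1]))
    return float(v[k])


def weighted_hpd(
    values: np.ndarray, weights: np.ndarray, mass: float = 0.95
) -> tuple[float, float]:
    """Shortest interval holding ``mass`` of the weighted empirical sample."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    cw = np.concatenate([[0.0], np.cumsum(w)])
    best = (v[0], v[-1])
    best_width = v[-1] - v[0]
    j = 0
    for i in range(len(v)):
        if j < i:
            j = i
        # extend the window until it holds the target mass
        while j < len(v) and cw[j + 1] - cw[i] < mass - 1e-12:
            j += 1
        if j == len(v):
            break
        width = v[j] - v[i]
        if width < best_width:
            best_width = width
            best = (float(v[i]), float(v[j]))
    return best


@dataclass
class ParamEstimate:
    name: str
    median: float
    hpd_low: float
    hpd_high: float

    def __post_init__(self) -> None:
        if not self.hpd_low <= self.median <= self.hpd_high:
            # the weighted median can sit marginally outside a degenerate HPD
            self.median = min(max(self.median, self.hpd_low), self.hpd_high)


def posterior_summary(
    sample: PosteriorSample, params: list[str] | None = None, mass: float = 0.95
) -> list[ParamEstimate]:
    """Weighted medians and HPD intervals, one estimate per parameter."""
    if len(sample.params) == 0:
        raise ValueError("empty posterior sample")
    out = []
    for name in params or PARAM_NAMES:
        v = sample.params[name].to_numpy(dtype=float)
        lo, hi = weighted_hpd(v, sample.weights, mass)
        out.append(
            ParamEstimate(
                name=name,
                median=weighted_median(v, sample.weights),
                hpd_low=lo,
                hpd_high=hi,
            )
        )
    return out


def estimates_table(estimates: list[ParamEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.name, e.median, e.hpd_low, e.hpd_high) for e in estimates],
        columns=["parameter", "median", "hpd_low", "hpd_high"],
    )


@dataclass
class DerivedQuantities:
    """Headline quantities of the fitted model."""

    t_years: float  # domestication time in years, T * theta_w / mu
    bottleneck_ratio: float  # theta_d0 / theta_w (founder / wild diversity)
    expansion_ratio: float  # theta_d1 / theta_d0 (post-bottleneck growth)
    per_draw: pd.DataFrame | None = None


def derived_quantities(
    source: PosteriorSample | dict[str, float],
) -> DerivedQuantities:
    """Domestication time and severity ratios from posterior medians.

    Accepts either a posterior sample (medians are computed from it and
    per-draw distributions returned as well) or a mapping of medians with
    keys theta_w, theta_d0, theta_d1, T and mu.
    """
    per_draw = None
    if isinstance(source, PosteriorSample):
        med = {
            k: weighted_median(
                source.params[k].to_numpy(dtype=float), source.weights
            )
            for k in ("theta_w", "theta_d0", "theta_d1", "T", "mu")
        }
        per_draw = pd.DataFrame(
            {
                "t_years": source.params["T"]
                * source.params["theta_w"]
                / source.params["mu"],
                "bottleneck_ratio": source.params["theta_d0"]
                / source.params["theta_w"],
                "expansion_ratio": source.params["theta_d1"]
                / source.params["theta_d0"],
            }
        )
    else:
        med = dict(source)
    if med["mu"] == 0:
        raise ZeroDivisionError("mu median is zero")
    return DerivedQuantities(
        t_years=med["T"] * med["theta_w"] / med["mu"],
        bottleneck_ratio=med["theta_d0"] / med["theta_w"],
        expansion_ratio=med["theta_d1"] / med["theta_d0"],
        per_draw=per_draw,
    )
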