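"""Per-region Gaussian-process normative models of brain growth.

Each regional volume is modelled as a Gaussian process over three
covariates: postmenstrual age at scan (weeks), postnatal days and sex.
The kernel is a sum of an anisotropic squared-exponential, a linear kernel
(so that near-linear growth is captured without forcing the length-scales
to blow up, and so that predictive uncertainty keeps growing outside the
training ages) and white observation noise.  Targets are standardized to
zero mean and unit SD before fitting; hyperparameters maximize the log
marginal likelihood from several seeded random restarts of L-BFGS.

A subject's *atypicality index* for a region is

    z = (observed - predicted) / predictive SD,

where the predictive SD includes the noise variance, i.e. it is the total
predictive uncertainty for a new observation.  Under that convention a
held-out typical subject scores z ~ N(0, 1), so |z| > 2.6 picks out
roughly the top and bottom 0.5% of the typical population.

Right-skewed CSF-space volumes (ventricles, extracerebral CSF) can be
modelled on the log scale (``log_transform=True``); their atypicality
indices are then z-scores of log-volume, which preserves the Gaussian
tail calibration that the extreme-deviation threshold relies on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from .regions import MODELLED_REGIONS, SKEWED_REGIONS, check_region, volume_column

PMA_WINDOW = (37.0, 45.0)

# fixed covariate scalings (weeks -> ~unit range); stored implicitly in the
# model definition so persisted models reproduce predictions exactly
_PMA_CENTER, _PMA_SCALE = 40.0, 4.0
_DAYS_SCALE = 7.0
_SEX_CENTER = 0.5

_N_THETA = 6  # log of: signal var, 3 length-scales, linear var, noise var
_DEFAULT_INIT = np.log([0.4, 1.0, 1.0, 1.0, 0.3, 0.3])
_LOG_BOUNDS = (-15.0, 8.0)


class ConvergenceWarning(UserWarning):
    pass


def _scale_covariates(pma, days, sex) -> np.ndarray:
    pma = np.atleast_1d(np.asarray(pma, dtype=float))
    days = np.atleast_1d(np.asarray(days, dtype=float))
    sexn = np.atleast_1d(np.asarray(sex))
    if sexn.dtype.kind in "UO":
        sexn = (sexn == "male").astype(float)
    else:
        sexn = sexn.astype(float)
    return np.column_stack(
        [
            (pma - _PMA_CENTER) / _PMA_SCALE,
            days / _DAYS_SCALE,
            sexn - _SEX_CENTER,
        ]
    )


def _kernel(theta: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    sf2, l1, l2, l3, sl2, _ = np.exp(theta)
    ls = np.array([l1, l2, l3])
    d = (A[:, None, :] - B[None, :, :]) / ls
    K = sf2 * np.exp(-0.5 * np.einsum("ijk,ijk->ij", d, d))
    K += sl2 * (A @ B.T)
    return K


def _kernel_diag(theta: np.ndarray, A: np.ndarray, include_noise: bool) -> np.ndarray:
    sf2, _, _, _, sl2, sn2 = np.exp(theta)
    diag = sf2 + sl2 * np.einsum("ij,ij->i", A, A)
    if include_noise:
        diag = diag + sn2
    return diag


def _nll_and_grad(theta, Xs, y, jitter):
    n = len(y)
    sf2, l1, l2, l3, sl2, sn2 = np.exp(theta)
    ls = np.array([l1, l2, l3])
    diff = Xs[:, None, :] - Xs[None, :, :]
    sq = (diff / ls) ** 2
    Krbf = sf2 * np.exp(-0.5 * sq.sum(axis=2))
    Klin = sl2 * (Xs @ Xs.T)
    K = Krbf + Klin + (sn2 + jitter) * np.eye(n)
    try:
        c, low = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros_like(theta)
    alpha = cho_solve((c, low), y)
    nll = 0.5 * float(y @ alpha) + float(np.log(np.diag(c)).sum()) + 0.5 * n * np.log(2 * np.pi)
    Kinv = cho_solve((c, low), np.eye(n))
    W = Kinv - np.outer(alpha, alpha)  # 2*dnll = tr(W dK)
    grad = np.empty(_N_THETA)
    grad[0] = 0.5 * np.sum(W * Krbf)
    for k in range(3):
        grad[1 + k] = 0.5 * np.sum(W * (Krbf * sq[:, :, k]))
    grad[4] = 0.5 * np.sum(W * Klin)
    grad[5] = 0.5 * sn2 * np.trace(W)
    return nll, grad


@dataclass
class NormativeModel:
    """A fitted per-region GP normative model.

    Stores raw training covariates and volumes plus the standardization
    constants and kernel hyperparameters; the Cholesky factor of the
    training covariance is cached for fast prediction.
    """

    region: str
    log_theta: np.ndarray
    X_raw: pd.DataFrame          # columns: pma_scan, postnatal_days, sex(0/1)
    y_raw: np.ndarray            # cm^3 (or log cm^3 if log_transform)
    y_mean: float
    y_sd: float
    log_transform: bool = False
    jitter: float = 1e-8
    converged: bool = True
    log_marginal_likelihood: float = np.nan
    _L: np.ndarray = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)

    # -- derived -----------------------------------------------------------
    @property
    def theta(self) -> dict[str, float]:
        sf2, l1, l2, l3, sl2, sn2 = np.exp(self.log_theta)
        return {
            "signal_variance": sf2,
            "length_scale_pma": l1,
            "length_scale_days": l2,
            "length_scale_sex": l3,
            "linear_variance": sl2,
            "noise_variance": sn2,
        }

    @property
    def y_std(self) -> np.ndarray:
        return (self.y_raw - self.y_mean) / self.y_sd

    def _Xs(self) -> np.ndarray:
        return _scale_covariates(
            self.X_raw["pma_scan"], self.X_raw["postnatal_days"], self.X_raw["sex"]
        )

    def _factorize(self) -> None:
        Xs = self._Xs()
        n = len(Xs)
        sn2 = float(np.exp(self.log_theta[5]))
        K = _kernel(self.log_theta, Xs, Xs) + (sn2 + self.jitter) * np.eye(n)
        self._L = cholesky(K, lower=True)
        self._alpha = cho_solve((self._L, True), self.y_std)

    # -- prediction --------------------------------------------------------
    def predict(self, pma_scan, postnatal_days, sex, include_noise: bool = True):
        """Posterior predictive mean and SD on the model's target scale.

        Returns volumes in cm^3 (log cm^3 for log-transformed models).  The
        SD includes the learned observation-noise variance by default, i.e.
        it is the denominator of the atypicality index.  Queries outside
        the modelled 37-45 week PMA window raise an extrapolation warning.
        """
        if self._L is None:
            self._factorize()
        Xq = _scale_covariates(pma_scan, postnatal_days, sex)
        if not np.all(np.isfinite(Xq)):
            raise ValueError("non-finite covariates in prediction query")
        pma = np.atleast_1d(np.asarray(pma_scan, dtype=float))
        if np.any((pma < PMA_WINDOW[0]) | (pma > PMA_WINDOW[1])):
            warnings.warn(
                f"query PMA outside the modelled {PMA_WINDOW} week window; "
                "extrapolating",
                UserWarning,
                stacklevel=2,
            )
        Xs = self._Xs()
        Ks = _kernel(self.log_theta, Xq, Xs)
        mean_std = Ks @ self._alpha
        V = solve_triangular(self._L, Ks.T, lower=True)
        var = _kernel_diag(self.log_theta, Xq, include_noise) - np.einsum(
            "ij,ij->j", V, V
        )
        var = np.maximum(var, 1e-12)
        mean = self.y_mean + self.y_sd * mean_std
        sd = self.y_sd * np.sqrt(var)
        if np.ndim(pma_scan) == 0 and np.ndim(mean) == 1 and len(mean) == 1:
            return float(mean[0]), float(sd[0])
        return mean, sd

    def atypicality_index(self, volume, pma_scan, postnatal_days, sex):
        """z = (observed - predicted) / predictive SD; NaN volume -> NaN."""
        vol = np.asarray(volume, dtype=float)
        if self.log_transform:
            with np.errstate(invalid="ignore", divide="ignore"):
                obs = np.log(vol)
        else:
            obs = vol
        mean, sd = self.predict(pma_scan, postnatal_days, sex)
        return (obs - mean) / sd

    # -- persistence ---------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "region": self.region,
            "log_theta": self.log_theta.tolist(),
            "pma_scan": self.X_raw["pma_scan"].tolist(),
            "postnatal_days": self.X_raw["postnatal_days"].tolist(),
            "sex": np.asarray(self.X_raw["sex"], dtype=float).tolist(),
            "y_raw": self.y_raw.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "log_transform": self.log_transform,
            "jitter": self.jitter,
            "converged": self.converged,
            "log_marginal_likelihood": self.log_marginal_likelihood,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "NormativeModel":
        d = json.loads(text)
        X = pd.DataFrame(
            {
                "pma_scan": d["pma_scan"],
                "postnatal_days": d["postnatal_days"],
                "sex": d["sex"],
            }
        )
        return cls(
            region=d["region"],
            log_theta=np.asarray(d["log_theta"], dtype=float),
            X_raw=X,
            y_raw=np.asarray(d["y_raw"], dtype=float),
            y_mean=d["y_mean"],
            y_sd=d["y_sd"],
            log_transform=d["log_transform"],
            jitter=d["jitter"],
            converged=d["converged"],
            log_marginal_likelihood=d.get("log_marginal_likelihood", np.nan),
        )


def fit_region_model(
    cohort: pd.DataFrame,
    region: str,
    log_transform: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
    maxiter: int = 200,
    jitter: float = 1e-8,
    noise_floor: float | None = 1e-6,
    fixed_theta: np.ndarray | None = None,
) -> NormativeModel:
    """Fit one region's normative GP on a (normative) cohort table.

    Hyperparameters are chosen by maximizing the log marginal likelihood
    with L-BFGS from ``n_restarts`` seeded starting points (the first is a
    fixed sensible default, the rest are log-normal perturbations of it).
    ``noise_floor`` bounds the noise variance away from zero on the
    standardized scale; pass ``None`` to disable it (e.g. for noise-free
    interpolation checks).  ``fixed_theta`` skips optimization entirely.
    """
    check_region(region)
    col = "ttv" if region == "ttv" else volume_column(region)
    needed = [col, "pma_scan", "postnatal_days", "sex"]
    data = cohort[needed].dropna()
    if len(data) < 20:
        raise ValueError(
            f"need >= 20 training subjects with {region} present, got {len(data)}"
        )
    if np.std(data["pma_scan"].to_numpy()) == 0:
        raise ValueError("degenerate covariates: pma_scan has zero variance")

    y_raw = data[col].to_numpy(dtype=float)
    if log_transform:
        if np.any(y_raw <= 0):
            raise ValueError("log transform requires strictly positive volumes")
        y_raw = np.log(y_raw)
    y_mean, y_sd = float(np.mean(y_raw)), float(np.std(y_raw))
    if y_sd == 0:
        raise ValueError("degenerate targets: zero variance")
    y = (y_raw - y_mean) / y_sd
    X_raw = pd.DataFrame(
        {
            "pma_scan": data["pma_scan"].to_numpy(dtype=float),
            "postnatal_days": data["postnatal_days"].to_numpy(dtype=float),
            "sex": (data["sex"].to_numpy() == "male").astype(float)
            if data["sex"].dtype.kind in "UO"
            else data["sex"].to_numpy(dtype=float),
        }
    )
    Xs = _scale_covariates(X_raw["pma_scan"], X_raw["postnatal_days"], X_raw["sex"])

    if fixed_theta is not None:
        log_theta = np.asarray(fixed_theta, dtype=float)
        nll, _ = _nll_and_grad(log_theta, Xs, y, jitter)
        model = NormativeModel(
            region, log_theta, X_raw, y_raw,
            y_mean, y_sd, log_transform, jitter, True, -nll,
        )
        model._factorize()
        return model

    lo, hi = _LOG_BOUNDS
    bounds = [(lo, hi)] * _N_THETA
    if noise_floor is not None:
        bounds[5] = (np.log(noise_floor), hi)
    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for r in range(max(1, n_restarts)):
        x0 = _DEFAULT_INIT.copy()
        if r > 0:
            x0 = x0 + rng.normal(0.0, 0.7, size=_N_THETA)
        x0 = np.clip(x0, bounds[0][0], hi)
        if noise_floor is not None:
            x0[5] = max(x0[5], np.log(noise_floor))
        res = minimize(
            _nll_and_grad,
            x0,
            args=(Xs, y, jitter),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "gtol": 1e-6},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        warnings.warn(
            f"hyperparameter optimization did not converge for {region}; "
            "keeping best point found",
            ConvergenceWarning,
            stacklevel=2,
        )
    model = NormativeModel(
        region,
        np.asarray(best.x, dtype=float),
        X_raw,
        y_raw,
        y_mean,
        y_sd,
        log_transform,
        jitter,
        any_converged,
        -float(best.fun),
    )
    model._factorize()
    return model


def fit_normative_models(
    cohort: pd.DataFrame,
    regions: tuple[str, ...] = MODELLED_REGIONS,
    log_regions: tuple[str, ...] = SKEWED_REGIONS,
    seed: int = 0,
    n_restarts: int = 5,
    maxiter: int = 200,
) -> dict[str, NormativeModel]:
    """Fit all per-region models; skewed CSF spaces are fitted on log scale.

    Per-region fitting seeds are derived deterministically from ``seed``.
    """
    children = np.random.SeedSequence(seed).spawn(len(regions))
    models = {}
    for region, child in zip(regions, children):
        models[region] = fit_region_model(
            cohort,
            region,
            log_transform=region in log_regions,
            n_restarts=n_restarts,
            seed=int(child.generate_state(1)[0] % (2**31)),
            maxiter=maxiter,
        )
    return models


# ---------------------------------------------------------------------------
# cohort scoring


@dataclass
class AtypicalityProfile:
    """One subject's per-region atypicality indices and extreme flags."""

    subject_id: str
    z: dict[str, float]
    flags: dict[str, str]


class AtypicalityProfiles:
    """Cohort-level atypicality scores.

    ``z`` is a subjects x regions table of atypicality indices (NaN where a
    volume is absent, e.g. stroke-masked cortical volumes) and ``flags``
    the matching extreme-deviation labels: ``extreme_negative`` if
    z < -threshold, ``extreme_positive`` if z > threshold (strict
    inequalities), ``none`` otherwise and NaN for absent regions.
    """

    def __init__(self, z: pd.DataFrame, threshold: float):
        self.z = z
        self.threshold = float(threshold)
        flags = pd.DataFrame("none", index=z.index, columns=z.columns, dtype=object)
        flags = flags.mask(z > self.threshold, "extreme_positive")
        flags = flags.mask(z < -self.threshold, "extreme_negative")
        flags = flags.mask(z.isna(), np.nan)
        self.flags = flags

    @property
    def regions(self) -> list[str]:
        return list(self.z.columns)

    def profile(self, subject_id: str) -> AtypicalityProfile:
        zrow = self.z.loc[subject_id]
        frow = self.flags.loc[subject_id]
        present = zrow.notna()
        return AtypicalityProfile(
            subject_id,
            zrow[present].to_dict(),
            frow[present].to_dict(),
        )

    def n_extreme_per_subject(self) -> pd.Series:
        return (
            self.flags.isin(["extreme_negative", "extreme_positive"])
            .sum(axis=1)
            .astype(int)
        )


def score_cohort(
    models: Mapping[str, NormativeModel], cohort: pd.DataFrame
) -> pd.DataFrame:
    """Atypicality indices for every subject and modelled region."""
    out = {}
    for region, model in models.items():
        col = "ttv" if region == "ttv" else volume_column(region)
        out[region] = model.atypicality_index(
            cohort[col].to_numpy(dtype=float),
            cohort["pma_scan"].to_numpy(dtype=float),
            cohort["postnatal_days"].to_numpy(dtype=float),
            cohort["sex"].to_numpy(),
        )
    return pd.DataFrame(out, index=pd.Index(cohort["subject_id"], name="subject_id"))


def profile_cohort(
    models: Mapping[str, NormativeModel],
    cohort: pd.DataFrame,
    threshold: float = 2.6,
) -> AtypicalityProfiles:
    """Score a cohort and flag extreme deviations (strict |z| > threshold)."""
    return AtypicalityProfiles(score_cohort(models, cohort), threshold)
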