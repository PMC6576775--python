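"""The multi-scale occupancy model for pooled camera-trap histories.

Three nested Bernoulli scales, all on the logit link:

* occupancy ``psi`` — the species uses the landscape around the site at all
  during the season;
* availability ``theta`` — conditional on occupancy, the species is in the
  immediate vicinity of the camera array on a given occasion (day);
* detection ``p`` — conditional on availability, a given pooling method
  records the species on that occasion.

For one site with occasions t and methods s, with y the 0/1/missing pooled
history, the likelihood is

    L = psi * prod_t [ theta_t * prod_s p_ts^y (1-p_ts)^(1-y)
                       + (1-theta_t) * 1{no detection at t} ]
        + (1-psi) * 1{no detection anywhere}

Missing entries contribute no factor.  Methods are conditionally
independent given availability; this is the model's assumption, not a claim
about physically overlapping camera subsets, whose induced dependence is
absorbed by the shared availability state.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from statsmodels.tools.numdiff import approx_hess

from .detection import CATEGORY_ORDERS, MISSING, CovariateTable, PooledHistory

#: |logit| beyond which an estimate is flagged as a boundary estimate
#: (expit(6) ~ 0.9975; quasi-Newton steps stall inside |logit| ~ 8 on
#: degenerate data, so a larger cutoff would miss true boundary optima).
BOUNDARY_LOGIT = 6.0


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearPredictorSpec:
    """Terms of one linear predictor; the intercept is always present.

    ``terms`` are covariate column names; the special term ``Method`` (valid
    for p only) expands to treatment-coded indicators over the pooling
    methods.  An empty tuple is the intercept-only (".") predictor.
    """

    target: str  # 'psi' | 'theta' | 'p'
    terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.target not in ("psi", "theta", "p"):
            raise ValueError(f"unknown target {self.target!r}")
        if "Method" in self.terms and self.target != "p":
            raise ValueError("'Method' is a detection-only term")

    @classmethod
    def from_string(cls, target: str, text: str) -> "LinearPredictorSpec":
        text = text.strip()
        if text in (".", ""):
            return cls(target, ())
        return cls(target, tuple(t.strip() for t in text.split("+")))

    def __str__(self) -> str:
        return "+".join(self.terms) if self.terms else "."


@dataclass(frozen=True)
class ModelSpec:
    """A full model: predictors for psi, theta and p plus a sharing rule.

    ``sharing='psi_theta_shared'`` fits one common slope vector for the psi
    and theta covariate terms (which must be identical) with two free
    intercepts, mirroring the "single effect on occupancy and availability"
    model structure; ``'none'`` fits them separately.
    """

    psi: LinearPredictorSpec
    theta: LinearPredictorSpec
    p: LinearPredictorSpec
    sharing: str = "none"

    def __post_init__(self) -> None:
        if self.sharing not in ("none", "psi_theta_shared"):
            raise ValueError(f"unknown sharing rule {self.sharing!r}")
        if self.sharing == "psi_theta_shared" and self.psi.terms != self.theta.terms:
            raise ValueError("shared psi/theta models need identical terms")

    @classmethod
    def from_formula(cls, formula: str) -> "ModelSpec":
        """Parse e.g. ``"psi(Loss1k) theta(.) p(Method+Access)"``.

        The shared form is written ``"psi=theta(Area) p(Method)"``.
        """
        shared = re.search(r"psi\s*=\s*theta\(([^)]*)\)", formula)
        m_p = re.search(r"(?<![a-z])p\(([^)]*)\)", formula)
        if m_p is None:
            raise ValueError(f"formula {formula!r} lacks a p(...) part")
        p_spec = LinearPredictorSpec.from_string("p", m_p.group(1))
        if shared:
            terms = LinearPredictorSpec.from_string("psi", shared.group(1)).terms
            return cls(LinearPredictorSpec("psi", terms),
                       LinearPredictorSpec("theta", terms), p_spec,
                       sharing="psi_theta_shared")
        m_psi = re.search(r"psi\(([^)]*)\)", formula)
        m_theta = re.search(r"theta\(([^)]*)\)", formula)
        if m_psi is None or m_theta is None:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(
            LinearPredictorSpec.from_string("psi", m_psi.group(1)),
            LinearPredictorSpec.from_string("theta", m_theta.group(1)),
            p_spec,
        )

    @property
    def formula(self) -> str:
        if self.sharing == "psi_theta_shared":
            return f"psi=theta({self.psi}) p({self.p})"
        return f"psi({self.psi}) theta({self.theta}) p({self.p})"

    def __str__(self) -> str:
        return self.formula


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Column:
    """One design-matrix column, evaluable for fitting and for prediction."""

    name: str
    kind: str  # 'intercept' | 'num' | 'cat' | 'method'
    term: str | None = None
    level: str | None = None
    levels: tuple[str, ...] = ()  # all levels (baseline first) for cat/method
    where: str | None = None  # 'site' | 'site_method' for covariate columns


def _categorical_levels(term: str, values) -> tuple[str, ...]:
    if term in CATEGORY_ORDERS:
        order = CATEGORY_ORDERS[term]
        extra = [v for v in sorted(map(str, set(values))) if v not in order]
        return tuple(order) + tuple(extra)
    return tuple(sorted(map(str, set(values))))


def _term_columns(target: str, term: str, cov: CovariateTable,
                  method_ids: list[str]) -> list[_Column]:
    if term == "Method":
        return [
            _Column(f"p:Method[{mid}]", "method", term, mid,
                    levels=tuple(method_ids))
            for mid in method_ids[1:]
        ]
    where = cov.column_level(term)
    if where == "site_method" and target != "p":
        raise ValueError(
            f"term {term!r} is (site, method)-level and cannot enter {target}"
        )
    frame = cov.site if where == "site" else cov.site_method
    series = frame[term]
    if series.dtype == object or str(series.dtype) == "category":
        levels = _categorical_levels(term, series.dropna())
        return [
            _Column(f"{target}:{term}[{lev}]", "cat", term, lev,
                    levels=levels, where=where)
            for lev in levels[1:]
        ]
    return [_Column(f"{target}:{term}", "num", term, where=where)]


def _target_columns(spec: LinearPredictorSpec, cov: CovariateTable,
                    method_ids: list[str]) -> list[_Column]:
    cols = [_Column(f"{spec.target}:Intercept", "intercept")]
    for term in spec.terms:
        if term == ".":
            continue
        cols.extend(_term_columns(spec.target, term, cov, method_ids))
    return cols


def _site_values(col: _Column, cov: CovariateTable, site_ids: list[str]) -> np.ndarray:
    vals = cov.site[col.term].reindex(site_ids)
    if vals.isna().any():
        missing = list(vals.index[vals.isna()])
        raise ValueError(f"covariate {col.term!r} missing for sites {missing}")
    if col.kind == "cat":
        bad = set(map(str, vals)) - set(col.levels)
        if bad:
            raise ValueError(f"unseen {col.term!r} categories {sorted(bad)}")
        return (vals.astype(str) == col.level).to_numpy(dtype=float)
    return vals.to_numpy(dtype=float)


def _eval_site_matrix(cols: list[_Column], cov: CovariateTable,
                      site_ids: list[str]) -> np.ndarray:
    X = np.empty((len(site_ids), len(cols)))
    for k, col in enumerate(cols):
        X[:, k] = 1.0 if col.kind == "intercept" else _site_values(col, cov, site_ids)
    return X


def _eval_p_matrix(cols: list[_Column], cov: CovariateTable,
                   site_ids: list[str], method_ids: list[str]) -> np.ndarray:
    n, S = len(site_ids), len(method_ids)
    X = np.empty((n, S, len(cols)))
    for k, col in enumerate(cols):
        if col.kind == "intercept":
            X[:, :, k] = 1.0
        elif col.kind == "method":
            X[:, :, k] = np.array([mid == col.level for mid in method_ids],
                                  dtype=float)[None, :]
        elif col.where == "site":
            X[:, :, k] = _site_values(col, cov, site_ids)[:, None]
        else:
            idx = [(s, m) for s in site_ids for m in method_ids]
            vals = cov.site_method[col.term].reindex(idx)
            if vals.isna().any():
                missing = list(vals.index[vals.isna()])[:3]
                raise ValueError(
                    f"covariate {col.term!r} missing for (site, method) {missing}"
                )
            if col.kind == "cat":
                arr = (vals.astype(str) == col.level).to_numpy(dtype=float)
            else:
                arr = vals.to_numpy(dtype=float)
            X[:, :, k] = arr.reshape(n, S)
    return X


@dataclass
class DesignMatrices:
    """Evaluated design matrices plus the parameter packing.

    ``idx_psi``/``idx_theta``/``idx_p`` map each design column to its slot in
    the packed parameter vector; under psi/theta sharing the slope slots
    coincide, so K is smaller than the column total.
    """

    spec: ModelSpec
    site_ids: list[str]
    method_ids: list[str]
    cols_psi: list[_Column]
    cols_theta: list[_Column]
    cols_p: list[_Column]
    X_psi: np.ndarray  # (n, k_psi)
    X_theta: np.ndarray  # (n, k_theta); k_theta = 0 when theta is fixed
    X_p: np.ndarray  # (n, S, k_p)
    idx_psi: np.ndarray
    idx_theta: np.ndarray
    idx_p: np.ndarray
    K: int
    param_names: list[str]
    theta_fixed: float | None = None

    def linear_predictors(self, beta: np.ndarray):
        eta_psi = self.X_psi @ beta[self.idx_psi]
        if self.theta_fixed is None:
            eta_theta = self.X_theta @ beta[self.idx_theta]
        else:
            eta_theta = None
        eta_p = self.X_p @ beta[self.idx_p]
        return eta_psi, eta_theta, eta_p


def build_design_matrices(
    spec: ModelSpec,
    cov: CovariateTable,
    pooled: PooledHistory,
    theta_fixed: float | None = None,
) -> DesignMatrices:
    """Expand a ModelSpec into design matrices over the pooled data.

    ``theta_fixed`` pins availability at a constant probability (no theta
    parameters); with ``theta_fixed=1.0`` the model collapses to the
    single-season occupancy model.
    """
    if theta_fixed is not None:
        if spec.sharing != "none" or spec.theta.terms:
            raise ValueError("theta_fixed requires theta(.) and no sharing")
        if not 0.0 <= theta_fixed <= 1.0:
            raise ValueError("theta_fixed must be a probability")
    site_ids, method_ids = pooled.site_ids, pooled.method_ids
    cols_psi = _target_columns(spec.psi, cov, method_ids)
    cols_theta = ([] if theta_fixed is not None
                  else _target_columns(spec.theta, cov, method_ids))
    cols_p = _target_columns(spec.p, cov, method_ids)
    X_psi = _eval_site_matrix(cols_psi, cov, site_ids)
    X_theta = (np.zeros((len(site_ids), 0)) if theta_fixed is not None
               else _eval_site_matrix(cols_theta, cov, site_ids))
    X_p = _eval_p_matrix(cols_p, cov, site_ids, method_ids)

    k_psi, k_theta, k_p = len(cols_psi), len(cols_theta), len(cols_p)
    if spec.sharing == "psi_theta_shared":
        # [psi intercept, theta intercept, shared slopes..., p block]
        idx_psi = np.array([0] + list(range(2, k_psi + 1)), dtype=int)
        idx_theta = np.array([1] + list(range(2, k_psi + 1)), dtype=int)
        offset = k_psi + 1
        names = (["psi:Intercept", "theta:Intercept"]
                 + [c.name.replace("psi:", "psi=theta:") for c in cols_psi[1:]])
    else:
        idx_psi = np.arange(k_psi)
        idx_theta = np.arange(k_psi, k_psi + k_theta)
        offset = k_psi + k_theta
        names = [c.name for c in cols_psi] + [c.name for c in cols_theta]
    idx_p = np.arange(offset, offset + k_p)
    names += [c.name for c in cols_p]
    return DesignMatrices(
        spec, site_ids, method_ids, cols_psi, cols_theta, cols_p,
        X_psi, X_theta, X_p, idx_psi, idx_theta, idx_p,
        K=offset + k_p, param_names=names, theta_fixed=theta_fixed,
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _check_prob(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValueError(f"{name} outside [0, 1]")
    return arr


def site_likelihood(psi: float, theta_t, p_st, y) -> float:
    """Likelihood of one site's pooled history (occasions x methods).

    ``theta_t`` has one availability per occasion (a scalar broadcasts);
    ``p_st`` is (T, S) detection probabilities; ``y`` is the (T, S) history
    in {0, 1, MISSING}.  Occasions with at least one detection pin the
    availability state; all-zero occasions sum the unavailable and
    available-but-undetected causes; missing entries contribute no factor.
    """
    y = np.asarray(y)
    if y.ndim != 2:
        raise ValueError("y must be (occasions, methods)")
    T, S = y.shape
    psi = float(_check_prob(psi, "psi"))
    theta = np.broadcast_to(_check_prob(theta_t, "theta"), (T,))
    p = np.broadcast_to(_check_prob(p_st, "p"), (T, S))
    if not np.isin(y, [0, 1, MISSING]).all():
        raise ValueError("y values must be 0, 1 or MISSING")

    y1, y0 = y == 1, y == 0
    with np.errstate(divide="ignore"):
        det = np.where(y1, p, 1.0) * np.where(y0, 1.0 - p, 1.0)
    prod_det = det.prod(axis=1)  # prod over methods of the Bernoulli factors
    det_any = y1.any(axis=1)
    factors = np.where(det_any, theta * prod_det,
                       theta * prod_det + (1.0 - theta))
    occupied = psi * factors.prod()
    return float(occupied if det_any.any() else occupied + (1.0 - psi))


def brute_force_site_likelihood(psi: float, theta_t, p_st, y) -> float:
    """Exhaustive latent-state oracle for :func:`site_likelihood`.

    Sums Pr(z) Pr(a | z) Pr(y | z, a) over occupancy z in {0,1} and every
    availability vector a in {0,1}^T.  Exponential in T; refuses T > 12.
    """
    y = np.asarray(y)
    T, S = y.shape
    if T > 12:
        raise ValueError(f"T={T} too large for exhaustive enumeration")
    psi = float(_check_prob(psi, "psi"))
    theta = np.broadcast_to(_check_prob(theta_t, "theta"), (T,))
    p = np.broadcast_to(_check_prob(p_st, "p"), (T, S))

    total = 0.0
    for z in (0, 1):
        pz = psi if z == 1 else 1.0 - psi
        for a in itertools.product((0, 1), repeat=T):
            pr = pz
            for t in range(T):
                if z == 1:
                    pr *= theta[t] if a[t] else 1.0 - theta[t]
                elif a[t]:
                    pr = 0.0  # unoccupied sites are never available
                if pr == 0.0:
                    break
                for s in range(S):
                    if y[t, s] == MISSING:
                        continue
                    if z * a[t] == 1:
                        pr *= p[t, s] if y[t, s] == 1 else 1.0 - p[t, s]
                    elif y[t, s] == 1:
                        pr = 0.0  # detection impossible without availability
                        break
            total += pr
    return float(total)


@dataclass
class _PooledMasks:
    Y1: np.ndarray  # (n, S, T) detection indicator
    Y0: np.ndarray  # (n, S, T) observed non-detection indicator
    det_any: np.ndarray  # (n, T) any detection on the occasion
    site_det: np.ndarray  # (n,) any detection at the site


def _pooled_masks(pooled: PooledHistory) -> _PooledMasks:
    Y1 = pooled.obs == 1
    Y0 = pooled.obs == 0
    det_any = Y1.any(axis=1)
    return _PooledMasks(Y1, Y0, det_any, det_any.any(axis=1))


def _nll_from_etas(eta_psi, eta_theta, eta_p, masks: _PooledMasks,
                   theta_fixed: float | None) -> float:
    """Negative log-likelihood, accumulated in log space throughout."""
    log_p = log_expit(eta_p)  # (n, S)
    log_1mp = log_expit(-eta_p)
    # log prod over methods of the Bernoulli detection factors, per occasion
    ld = np.einsum("nst,ns->nt", masks.Y1, log_p) + np.einsum(
        "nst,ns->nt", masks.Y0, log_1mp
    )
    if theta_fixed is None:
        log_th = log_expit(eta_theta)[:, None]
        log_1mth = log_expit(-eta_theta)[:, None]
    elif theta_fixed in (0.0, 1.0):
        log_th = np.full((1, 1), -np.inf if theta_fixed == 0.0 else 0.0)
        log_1mth = np.full((1, 1), 0.0 if theta_fixed == 0.0 else -np.inf)
    else:
        log_th = np.log(np.full((1, 1), theta_fixed))
        log_1mth = np.log1p(np.full((1, 1), -theta_fixed))
    with np.errstate(invalid="ignore"):
        occ_t = np.where(masks.det_any, log_th + ld,
                         np.logaddexp(log_th + ld, log_1mth))
    occ = occ_t.sum(axis=1)  # (n,) log Pr(history | occupied)
    log_psi = log_expit(eta_psi)
    log_1mpsi = log_expit(-eta_psi)
    site_ll = np.where(masks.site_det, log_psi + occ,
                       np.logaddexp(log_psi + occ, log_1mpsi))
    return -float(site_ll.sum())


def total_negative_loglik(
    beta: np.ndarray,
    spec: ModelSpec,
    cov: CovariateTable,
    pooled: PooledHistory,
    theta_fixed: float | None = None,
) -> float:
    """-sum over sites of log site_likelihood at link-scale coefficients."""
    if pooled.n_sites == 0:
        raise ValueError("no sites: likelihood undefined")
    dm = build_design_matrices(spec, cov, pooled, theta_fixed=theta_fixed)
    masks = _pooled_masks(pooled)
    eta_psi, eta_theta, eta_p = dm.linear_predictors(np.asarray(beta, dtype=float))
    return _nll_from_etas(eta_psi, eta_theta, eta_p, masks, theta_fixed)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted model: coefficients, likelihood, curvature, diagnostics."""

    spec: ModelSpec
    betas: np.ndarray | None
    param_names: list[str]
    loglik: float
    vcov: np.ndarray | None
    converged: bool
    warnings: list[str]
    n_sites: int
    K: int
    design: DesignMatrices = field(repr=False, default=None)
    theta_fixed: float | None = None
    #: optional display name; the formula is used when unset
    model_id_override: str | None = None

    @property
    def model_id(self) -> str:
        return self.model_id_override or self.spec.formula


def fit_model(
    spec: ModelSpec,
    cov: CovariateTable,
    pooled: PooledHistory,
    n_starts: int = 10,
    seed: int = 0,
    theta_fixed: float | None = None,
    compute_vcov: bool = True,
) -> FitResult:
    """Maximum-likelihood fit by multi-start quasi-Newton minimization.

    The first start is the zero vector (all probabilities 0.5); the rest are
    drawn uniformly in [-2, 2] on the link scale from a generator seeded by
    ``seed``.  The best optimum is kept.  The variance matrix is the inverse
    of a finite-difference observed information; when that matrix is not
    positive definite, standard errors are reported as unavailable.  Link
    scale estimates beyond |eta| > 10 are flagged as boundary estimates.
    """
    if pooled.n_sites == 0:
        raise ValueError("cannot fit a model to zero sites")
    dm = build_design_matrices(spec, cov, pooled, theta_fixed=theta_fixed)
    masks = _pooled_masks(pooled)
    if not (masks.Y1.any() or masks.Y0.any()):
        raise ValueError("no informative occasions: all observations missing")

    def nll(beta: np.ndarray) -> float:
        eta_psi, eta_theta, eta_p = dm.linear_predictors(beta)
        return _nll_from_etas(eta_psi, eta_theta, eta_p, masks, theta_fixed)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(dm.K)]
    starts += [rng.uniform(-2.0, 2.0, size=dm.K) for _ in range(max(0, n_starts - 1))]

    best = None
    any_converged = False
    for x0 in starts:
        try:
            res = minimize(nll, x0, method="L-BFGS-B",
                           options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 2000})
        except (FloatingPointError, ValueError):
            continue
        if not np.isfinite(res.fun):
            continue
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    warnings: list[str] = []
    if best is None or not any_converged:
        return FitResult(spec, None, dm.param_names, -np.inf, None, False,
                         ["no start converged"], pooled.n_sites, dm.K, dm,
                         theta_fixed)

    beta = best.x
    eta_psi, eta_theta, eta_p = dm.linear_predictors(beta)
    etas = [eta_psi, eta_p.ravel()] + ([eta_theta] if eta_theta is not None else [])
    if max(float(np.abs(e).max()) for e in etas if e.size) > BOUNDARY_LOGIT:
        warnings.append(
            "boundary estimate: a linear predictor exceeds |logit| > "
            f"{BOUNDARY_LOGIT:g}; the corresponding probability is at 0 or 1"
        )

    vcov = None
    if compute_vcov:
        try:
            H = approx_hess(beta, nll)
            eigs = np.linalg.eigvalsh((H + H.T) / 2.0)
            if np.all(eigs > 0) and np.isfinite(H).all():
                vcov = np.linalg.inv((H + H.T) / 2.0)
                vcov = (vcov + vcov.T) / 2.0
            else:
                warnings.append(
                    "observed information not positive definite; "
                    "standard errors unavailable"
                )
        except (np.linalg.LinAlgError, FloatingPointError):
            warnings.append("Hessian computation failed; standard errors unavailable")

    return FitResult(spec, beta, dm.param_names, -float(best.fun), vcov, True,
                     warnings, pooled.n_sites, dm.K, dm, theta_fixed)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _profile_row(cols: list[_Column], profile: dict, method_id: str | None) -> np.ndarray:
    x = np.empty(len(cols))
    for k, col in enumerate(cols):
        if col.kind == "intercept":
            x[k] = 1.0
        elif col.kind == "method":
            x[k] = float(method_id == col.level)
        elif col.kind == "num":
            x[k] = float(profile.get(col.term, 0.0))
        else:  # categorical
            val = str(profile.get(col.term, col.levels[0]))
            if val not in col.levels:
                raise ValueError(
                    f"profile value {val!r} for {col.term!r} not among the "
                    f"training categories {list(col.levels)}"
                )
            x[k] = float(val == col.level)
    return x


def _prob_and_se(x: np.ndarray, idx: np.ndarray, fit: FitResult):
    eta = float(x @ fit.betas[idx])
    prob = float(expit(eta))
    if fit.vcov is None:
        return prob, np.nan
    g = np.zeros(fit.K)
    g[idx] += prob * (1.0 - prob) * x  # delta method through the inverse logit
    return prob, float(np.sqrt(g @ fit.vcov @ g))


@dataclass
class ProfilePrediction:
    """Probability-scale estimates at one covariate profile."""

    psi: float
    psi_se: float
    theta: float
    theta_se: float
    p: "pd.DataFrame"  # index method_id, columns estimate / se


def predict_probabilities(fit: FitResult, profile: dict | None = None) -> ProfilePrediction:
    """Probability-scale psi, theta and per-method p with delta-method SEs.

    ``profile`` gives covariate values for the prediction (defaults:
    baseline category for categoricals, 0 — the standardized mean — for
    continuous covariates).  Unknown categories are an error.
    """
    import pandas as pd

    if not fit.converged or fit.betas is None:
        raise ValueError("cannot predict from a non-converged fit")
    profile = dict(profile or {})
    dm = fit.design
    psi, psi_se = _prob_and_se(_profile_row(dm.cols_psi, profile, None),
                               dm.idx_psi, fit)
    if fit.theta_fixed is not None:
        theta, theta_se = float(fit.theta_fixed), 0.0
    else:
        theta, theta_se = _prob_and_se(_profile_row(dm.cols_theta, profile, None),
                                       dm.idx_theta, fit)
    rows = []
    for mid in dm.method_ids:
        est, se = _prob_and_se(_profile_row(dm.cols_p, profile, mid), dm.idx_p, fit)
        rows.append((mid, est, se))
    p = pd.DataFrame(rows, columns=["method", "estimate", "se"]).set_index("method")
    return ProfilePrediction(psi, psi_se, theta, theta_se, p)


def predict_site_probabilities(fit: FitResult, cov: CovariateTable | None = None):
    """Per-site psi and theta (and per site x method p) with delta SEs.

    With ``cov=None`` the training covariates are reused via the stored
    design; passing a new table re-evaluates the design columns on it.
    """
    import pandas as pd

    if not fit.converged or fit.betas is None:
        raise ValueError("cannot predict from a non-converged fit")
    dm = fit.design
    if cov is None:
        X_psi, X_theta, X_p = dm.X_psi, dm.X_theta, dm.X_p
        site_ids = dm.site_ids
    else:
        site_ids = list(cov.site.index.astype(str))
        X_psi = _eval_site_matrix(dm.cols_psi, cov, site_ids)
        X_theta = (np.zeros((len(site_ids), 0)) if fit.theta_fixed is not None
                   else _eval_site_matrix(dm.cols_theta, cov, site_ids))
        X_p = _eval_p_matrix(dm.cols_p, cov, site_ids, dm.method_ids)

    site_rows = []
    for i, s in enumerate(site_ids):
        psi, psi_se = _prob_and_se(X_psi[i], dm.idx_psi, fit)
        if fit.theta_fixed is not None:
            theta, theta_se = float(fit.theta_fixed), 0.0
        else:
            theta, theta_se = _prob_and_se(X_theta[i], dm.idx_theta, fit)
        site_rows.append((s, psi, psi_se, theta, theta_se))
    p_rows = []
    for i, s in enumerate(site_ids):
        for j, mid in enumerate(dm.method_ids):
            est, se = _prob_and_se(X_p[i, j], dm.idx_p, fit)
            p_rows.append((s, mid, est, se))
    site_df = pd.DataFrame(
        site_rows, columns=["site", "psi", "psi_se", "theta", "theta_se"]
    ).set_index("site")
    p_df = pd.DataFrame(
        p_rows, columns=["site", "method", "estimate", "se"]
    ).set_index(["site", "method"])
    return site_df, p_df


def combined_daily_detection(theta_hat: float, p_hat: float, ndigits: int = 3) -> float:
    """Daily detection probability theta * p of the equivalent single-scale
    model, rounded to report precision (3 decimals in the estimate tables)."""
    _check_prob(theta_hat, "theta_hat")
    _check_prob(p_hat, "p_hat")
    return round(float(theta_hat) * float(p_hat), ndigits)
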