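"""AICc ranking, Akaike-weight model averaging, and the staged workflow.

Model support is measured with AICc (the small-sample Akaike criterion,
with n = number of sites), models within 2 dAICc of the best are treated as
competitive, and detection estimates are averaged over the final candidate
set with unconditional standard errors that absorb between-model spread.

The staged workflow mirrors a common survey-design protocol: stage 1 asks
whether detection differs between pooling methods at all; stage 2 screens
detection covariates on top of the stage-1 winner and builds additive
combinations of the competitive ones; stage 3 compares spatial scales of a
landscape covariate and places the occupancy-level covariates on psi only,
on psi and theta as one shared effect, or on both separately.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .detection import CovariateTable, PooledHistory
from .model import (
    FitResult,
    LinearPredictorSpec,
    ModelSpec,
    fit_model,
    predict_probabilities,
)

logger = logging.getLogger(__name__)


def compute_aicc(loglik: float, K: int, n: int) -> float:
    """AICc = -2 logL + 2K + 2K(K+1)/(n - K - 1), n = number of sites."""
    if n <= K + 1:
        raise ValueError(
            f"AICc undefined: n={n} must exceed K+1={K + 1} parameters"
        )
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


@dataclass
class ModelRanking:
    """AICc-sorted model table with Akaike weights, plus the fits behind it."""

    table: pd.DataFrame  # columns model, K, loglik, AICc, dAICc, weight
    fits: dict[str, FitResult]
    notes: list[str] = field(default_factory=list)

    @property
    def best(self) -> FitResult:
        return self.fits[self.table.iloc[0]["model"]]

    def within(self, delta: float) -> list[FitResult]:
        sel = self.table[self.table["dAICc"] <= delta]
        return [self.fits[m] for m in sel["model"]]


def rank_models(fits: list[FitResult], n: int) -> ModelRanking:
    """Rank converged fits by AICc; weights w_i = exp(-d_i/2)/sum_j exp(-d_j/2).

    Non-converged fits are excluded with a logged note.  Exact AICc ties are
    broken by fewer parameters, then lexical model id.
    """
    notes: list[str] = []
    usable: list[FitResult] = []
    for f in fits:
        if f.converged:
            usable.append(f)
        else:
            notes.append(f"excluded non-converged model {f.model_id}")
            logger.warning("excluded non-converged model %s", f.model_id)
    if not usable:
        raise ValueError("no converged fits to rank")
    rows = [
        (f.model_id, f.K, f.loglik, compute_aicc(f.loglik, f.K, n)) for f in usable
    ]
    df = pd.DataFrame(rows, columns=["model", "K", "loglik", "AICc"])
    df = df.sort_values(["AICc", "K", "model"], kind="stable").reset_index(drop=True)
    if df["AICc"].duplicated().any():
        notes.append("exact AICc tie broken by smaller K, then lexical model id")
        logger.info("exact AICc tie broken by smaller K, then lexical model id")
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    rel = np.exp(-df["dAICc"] / 2.0)
    df["weight"] = rel / rel.sum()
    return ModelRanking(df, {f.model_id: f for f in usable}, notes)


def model_average(
    ranking: ModelRanking,
    quantity: str = "p",
    profile: dict | None = None,
    scale: str = "probability",
) -> pd.DataFrame:
    """Akaike-weighted average of predicted probabilities over a ranking.

    Per method (for ``quantity='p'``) or as one row (psi / theta):
    qbar = sum_i w_i qhat_i and the unconditional
    SE = sum_i w_i sqrt(SE_i^2 + (qhat_i - qbar)^2), which inflates the
    within-model SE by the between-model spread.  ``scale='link'`` averages
    on the logit scale instead and back-transforms.
    """
    if quantity not in ("p", "psi", "theta"):
        raise ValueError(f"unknown quantity {quantity!r}")
    if scale not in ("probability", "link"):
        raise ValueError(f"unknown scale {scale!r}")
    weights, ests, ses, labels = [], [], [], None
    for _, row in ranking.table.iterrows():
        fit = ranking.fits[row["model"]]
        pred = predict_probabilities(fit, profile)
        if quantity == "p":
            labels = list(pred.p.index)
            est = pred.p["estimate"].to_numpy()
            se = pred.p["se"].to_numpy()
        else:
            labels = [quantity]
            est = np.array([getattr(pred, quantity)])
            se = np.array([getattr(pred, quantity + "_se")])
        weights.append(row["weight"])
        ests.append(est)
        ses.append(se)
    w = np.asarray(weights)[:, None]
    est = np.vstack(ests)
    se = np.vstack(ses)
    if scale == "link":
        se = se / (est * (1.0 - est))
        est = logit(est)
    avg = (w * est).sum(axis=0)
    unc = (w * np.sqrt(se**2 + (est - avg) ** 2)).sum(axis=0)
    if scale == "link":
        back = expit(avg)
        unc = unc * back * (1.0 - back)
        avg = back
    out = pd.DataFrame({"estimate": avg, "se": unc},
                       index=pd.Index(labels, name="method" if quantity == "p" else "quantity"))
    return out


def select_buffer_scale(fits_by_buffer: dict[str, FitResult], n: int) -> str:
    """Pick the landscape-covariate spatial scale best supported by AICc.

    ``fits_by_buffer`` maps buffer column name -> fit, with candidate models
    identical apart from which buffer column enters.  Exact ties keep the
    earliest (smallest) buffer in the mapping order, with a logged note.
    """
    if not fits_by_buffer:
        raise ValueError("no buffer candidates")
    shapes = set()
    for buf, f in fits_by_buffer.items():
        shapes.add(f.spec.formula.replace(buf, "<Loss>"))
    if len(shapes) > 1:
        raise ValueError(f"buffer candidates differ beyond the Loss column: {shapes}")
    aiccs = {buf: compute_aicc(f.loglik, f.K, n) for buf, f in fits_by_buffer.items()
             if f.converged}
    if not aiccs:
        raise ValueError("no converged buffer candidates")
    best_val = min(aiccs.values())
    winners = [b for b, v in aiccs.items() if v == best_val]
    if len(winners) > 1:
        logger.info("buffer AICc tie between %s; keeping %s", winners, winners[0])
    return winners[0]


@dataclass
class ThreeStageConfig:
    """Settings for the staged selection workflow.

    ``detection_covariates`` are screened on p in stage 2 (site- or
    site-method-level columns); ``occupancy_covariates`` plus the winning
    ``loss_buffers`` column are placed on psi/theta in stage 3.  ``profile``
    is the covariate profile at which detection estimates are averaged
    (default: baseline categories, standardized means).
    """

    detection_covariates: tuple[str, ...] = ("Area", "Access", "DistAve",
                                             "DistMax", "DistMin")
    occupancy_covariates: tuple[str, ...] = ("Area",)
    loss_buffers: tuple[str, ...] = ("Loss100m", "Loss500m", "Loss1k", "Loss5k")
    retention_delta: float = 2.0
    max_detection_covariates: int = 3
    stages: int = 3
    n_starts: int = 3
    seed: int = 0
    profile: dict | None = None


class StageError(RuntimeError):
    """A selection stage had no converged candidates; carries the partial result."""

    def __init__(self, message: str, partial: "ThreeStageResult"):
        super().__init__(message)
        self.partial = partial


@dataclass
class ThreeStageResult:
    """Per-stage rankings, the buffer decision, and the final model outputs."""

    stage1: ModelRanking | None = None
    stage2: ModelRanking | None = None
    stage3: ModelRanking | None = None
    buffer_ranking: dict[str, float] | None = None
    best_buffer: str | None = None
    final_fit: FitResult | None = None
    estimates: pd.DataFrame | None = None
    averaged_detection: pd.DataFrame | None = None


def _spec(psi: str, theta: str, p_terms: tuple[str, ...], shared: bool = False) -> ModelSpec:
    p = LinearPredictorSpec("p", p_terms)
    if shared:
        terms = LinearPredictorSpec.from_string("psi", psi).terms
        return ModelSpec(LinearPredictorSpec("psi", terms),
                         LinearPredictorSpec("theta", terms), p,
                         sharing="psi_theta_shared")
    return ModelSpec(LinearPredictorSpec.from_string("psi", psi),
                     LinearPredictorSpec.from_string("theta", theta), p)


def estimates_table(fit: FitResult, profile: dict | None = None) -> pd.DataFrame:
    """Per-method psi/theta/p estimate table with the derived theta*p column."""
    pred = predict_probabilities(fit, profile)
    rows = []
    for mid, r in pred.p.iterrows():
        rows.append(
            (fit.model_id, mid, pred.psi, pred.psi_se, pred.theta, pred.theta_se,
             r["estimate"], r["se"], pred.theta * r["estimate"])
        )
    return pd.DataFrame(
        rows,
        columns=["model", "method", "psi", "psi_se", "theta", "theta_se",
                 "p", "p_se", "theta_p"],
    )


def run_three_stage(
    pooled: PooledHistory,
    cov: CovariateTable,
    config: ThreeStageConfig | None = None,
) -> ThreeStageResult:
    """Run the staged AICc selection workflow on pooled histories.

    Returns per-stage rankings, the chosen landscape-buffer scale, the final
    top model with its estimate table, and the model-averaged per-method
    detection probabilities over the final candidate set.  A stage with no
    converged candidate raises :class:`StageError` carrying the partial
    result.
    """
    config = config or ThreeStageConfig()
    for name in (config.detection_covariates + config.occupancy_covariates
                 + config.loss_buffers):
        if not cov.has_column(name):
            raise ValueError(f"unknown covariate {name!r} in selection config")
    if not 1 <= config.stages <= 3:
        raise ValueError("stages must be 1, 2 or 3")
    n = pooled.n_sites
    result = ThreeStageResult()

    def _fit(spec: ModelSpec) -> FitResult:
        return fit_model(spec, cov, pooled, n_starts=config.n_starts,
                         seed=config.seed)

    def _rank(fits: list[FitResult], stage: str) -> ModelRanking:
        try:
            return rank_models(fits, n)
        except ValueError as exc:
            raise StageError(f"{stage}: {exc}", result) from exc

    # Stage 1: does detection differ between pooling methods at all?
    logger.info("stage 1: p(Method) vs p(.)")
    stage1_fits = [_fit(_spec(".", ".", ())), _fit(_spec(".", ".", ("Method",)))]
    result.stage1 = _rank(stage1_fits, "stage 1")
    base_p: tuple[str, ...] = result.stage1.best.spec.p.terms
    if config.stages == 1:
        result.final_fit = result.stage1.best
        result.estimates = estimates_table(result.final_fit, config.profile)
        result.averaged_detection = model_average(result.stage1, "p", config.profile)
        return result

    # Stage 2: screen detection covariates, then additive combinations
    logger.info("stage 2: detection covariates on top of p(%s)",
                "+".join(base_p) or ".")
    stage2_fits = {base_p: result.stage1.best}
    for c in config.detection_covariates:
        terms = base_p + (c,)
        stage2_fits[terms] = _fit(_spec(".", ".", terms))
    ranking2 = _rank(list(stage2_fits.values()), "stage 2")
    important: list[str] = []
    for f in ranking2.within(config.retention_delta):
        for t in f.spec.p.terms:
            if t not in base_p and t not in important:
                important.append(t)
    important = important[: config.max_detection_covariates]
    for r in range(2, len(important) + 1):
        for combo in itertools.combinations(important, r):
            terms = base_p + combo
            if terms not in stage2_fits:
                stage2_fits[terms] = _fit(_spec(".", ".", terms))
    result.stage2 = _rank(list(stage2_fits.values()), "stage 2")
    best_p: tuple[str, ...] = result.stage2.best.spec.p.terms
    if config.stages == 2:
        result.final_fit = result.stage2.best
        result.estimates = estimates_table(result.final_fit, config.profile)
        result.averaged_detection = model_average(result.stage2, "p", config.profile)
        return result

    # Stage 3: spatial scale of the landscape covariate, then psi/theta placement
    occ_covariates = list(config.occupancy_covariates)
    buffer_fits: dict[str, FitResult] = {}
    if config.loss_buffers:
        logger.info("stage 3: comparing buffer scales %s", config.loss_buffers)
        for buf in config.loss_buffers:
            buffer_fits[buf] = _fit(_spec(buf, ".", best_p))
        result.buffer_ranking = {
            b: compute_aicc(f.loglik, f.K, n)
            for b, f in buffer_fits.items() if f.converged
        }
        result.best_buffer = select_buffer_scale(buffer_fits, n)
        occ_covariates.append(result.best_buffer)

    logger.info("stage 3: psi-only / shared / separate placement of %s",
                occ_covariates)
    stage3_fits: list[FitResult] = [_fit(_spec(".", ".", best_p))]
    for c in occ_covariates:
        if c in buffer_fits:
            stage3_fits.append(buffer_fits[c])  # psi-only fit already done
        else:
            stage3_fits.append(_fit(_spec(c, ".", best_p)))
        stage3_fits.append(_fit(_spec(c, c, best_p, shared=True)))
        stage3_fits.append(_fit(_spec(c, c, best_p)))
    result.stage3 = _rank(stage3_fits, "stage 3")
    result.final_fit = result.stage3.best
    result.estimates = estimates_table(result.final_fit, config.profile)
    result.averaged_detection = model_average(result.stage3, "p", config.profile)
    return result
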