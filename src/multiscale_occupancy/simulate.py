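"""Synthetic camera-array surveys with the model's hierarchical structure.

Two generative levels:

* **method level** — detections are drawn per pooling method, conditionally
  independent given the shared availability state.  This matches the fitted
  model exactly and is the right input for parameter-recovery studies.
* **camera level** — detections are drawn per physical camera and then
  pooled, so methods sharing cameras are positively dependent across
  occasions, as in a real T-configuration array.  The implied method-level
  detection probability is p_s = 1 - prod_{c in s} (1 - q_c).

Detections at unoccupied or unavailable site-occasions are exactly zero: the
generator produces no false positives, matching the model's assumption.
All randomness flows from one seeded generator, so a design (including its
seed) determines its output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .detection import (
    MISSING,
    CovariateTable,
    DetectionArray,
    MethodMap,
    PooledHistory,
    default_method_map,
)


def _check_prob(x, name: str) -> None:
    arr = np.asarray(x, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValueError(f"{name} outside [0, 1]")


@dataclass
class SimDesign:
    """Generating parameters for a synthetic survey.

    Defaults emulate the study conditions the analysis targets: 32 sites of
    five cameras surveyed for 16-23 daily occasions.  ``p_true`` holds one
    detection probability per pooling method (method level); ``q_true`` one
    per camera (camera level).  ``psi_coefs``/``theta_coefs``/``p_coefs``
    optionally add logit-scale covariate effects evaluated against a
    covariate table passed to the simulator.
    """

    n_sites: int = 32
    occasions: int | tuple[int, int] = (16, 23)
    level: str = "method"  # 'method' | 'camera'
    psi_true: float = 0.5
    theta_true: float = 0.5
    p_true: tuple[float, ...] | dict[str, float] = (0.3, 0.45, 0.55, 0.45, 0.55)
    q_true: tuple[float, ...] | dict[str, float] = (0.3, 0.3, 0.3, 0.3, 0.3)
    psi_coefs: dict[str, float] = field(default_factory=dict)
    theta_coefs: dict[str, float] = field(default_factory=dict)
    p_coefs: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    missing_mode: str = "camera-day"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level not in ("method", "camera"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        _check_prob(self.psi_true, "psi_true")
        _check_prob(self.theta_true, "theta_true")
        _check_prob(list(self.p_true.values()) if isinstance(self.p_true, dict)
                    else self.p_true, "p_true")
        _check_prob(list(self.q_true.values()) if isinstance(self.q_true, dict)
                    else self.q_true, "q_true")
        _check_prob(self.missing_rate, "missing_rate")


def _draw_occasions(design: SimDesign, rng: np.random.Generator) -> np.ndarray:
    if isinstance(design.occasions, int):
        if design.occasions < 1:
            raise ValueError("occasions must be >= 1")
        return np.full(design.n_sites, design.occasions, dtype=int)
    lo, hi = design.occasions
    return rng.integers(lo, hi + 1, size=design.n_sites)


def _site_ids(n: int) -> list[str]:
    return [f"s{i + 1:03d}" for i in range(n)]


def _effect_probs(base: float, coefs: dict[str, float],
                  cov: CovariateTable | None, site_ids: list[str]) -> np.ndarray:
    """Per-site probabilities from a baseline and logit-scale effects."""
    eta = np.full(len(site_ids), float(logit(base)))
    if coefs:
        if cov is None:
            raise ValueError("covariate effects given but no covariate table")
        for col, beta in coefs.items():
            eta += beta * cov.site[col].reindex(site_ids).to_numpy(dtype=float)
        return expit(eta)
    return np.full(len(site_ids), base)


def _per_unit_probs(p_true, unit_ids: list[str], what: str) -> np.ndarray:
    if isinstance(p_true, dict):
        try:
            return np.array([float(p_true[u]) for u in unit_ids])
        except KeyError as exc:
            raise ValueError(f"{what} missing entry for {exc}") from exc
    arr = np.asarray(p_true, dtype=float)
    if arr.shape != (len(unit_ids),):
        raise ValueError(f"{what} needs one probability per unit "
                         f"({len(unit_ids)}), got shape {arr.shape}")
    return arr


def _latent_states(design: SimDesign, cov: CovariateTable | None,
                   site_ids: list[str], occasions: np.ndarray,
                   rng: np.random.Generator):
    psi = _effect_probs(design.psi_true, design.psi_coefs, cov, site_ids)
    theta = _effect_probs(design.theta_true, design.theta_coefs, cov, site_ids)
    n, maxT = len(site_ids), int(occasions.max())
    z = (rng.random(n) < psi).astype(np.int8)
    a = ((rng.random((n, maxT)) < theta[:, None]) & (z[:, None] == 1)).astype(np.int8)
    return psi, theta, z, a


def _mask_padding(obs: np.ndarray, occasions: np.ndarray) -> None:
    for i, T in enumerate(occasions):
        obs[i, :, T:] = MISSING


def simulate_method_level(
    design: SimDesign,
    method_map: MethodMap | None = None,
    cov: CovariateTable | None = None,
) -> tuple[PooledHistory, dict]:
    """Draw pooled histories directly at the method level.

    Per site z ~ Bern(psi); per occasion a_t ~ Bern(theta) given z = 1; per
    method y ~ Bern(p_s) given z a_t = 1, else 0 — conditionally independent
    across methods.  Returns the history plus a truth record holding every
    latent draw and the generating probabilities.
    """
    if design.level != "method":
        raise ValueError("design.level must be 'method'")
    mmap = method_map or default_method_map()
    rng = np.random.default_rng(design.seed)
    site_ids = _site_ids(design.n_sites)
    occasions = _draw_occasions(design, rng)
    psi, theta, z, a = _latent_states(design, cov, site_ids, occasions, rng)
    p_s = _per_unit_probs(design.p_true, mmap.method_ids, "p_true")
    n, S, maxT = design.n_sites, len(mmap.methods), int(occasions.max())
    active = (z[:, None, None] * a[:, None, :]) == 1  # (n, S, T) availability
    y = ((rng.random((n, S, maxT)) < p_s[None, :, None]) & active).astype(np.int8)
    if design.missing_rate > 0:
        miss = rng.random((n, S, maxT)) < design.missing_rate
        y[miss] = MISSING
    _mask_padding(y, occasions)
    pooled = PooledHistory(site_ids, mmap.method_ids, occasions, y)
    truth = {"psi": psi, "theta": theta, "p": p_s, "z": z, "a": a,
             "occasions": occasions, "seed": design.seed}
    return pooled, truth


def simulate_camera_level(
    design: SimDesign,
    method_map: MethodMap | None = None,
    cov: CovariateTable | None = None,
) -> tuple[DetectionArray, dict]:
    """Draw per-camera histories; pooling then induces method dependence.

    Cameras detect independently given availability with per-camera
    probabilities q_c, so a method's implied detection probability is
    p_s = 1 - prod_{c in s}(1 - q_c), recorded in the truth record.
    """
    if design.level != "camera":
        raise ValueError("design.level must be 'camera'")
    mmap = method_map or default_method_map()
    cameras = sorted({c for m in mmap.methods for c in m.cameras})
    rng = np.random.default_rng(design.seed)
    site_ids = _site_ids(design.n_sites)
    occasions = _draw_occasions(design, rng)
    psi, theta, z, a = _latent_states(design, cov, site_ids, occasions, rng)
    q = _per_unit_probs(design.q_true, cameras, "q_true")
    n, C, maxT = design.n_sites, len(cameras), int(occasions.max())
    active = (z[:, None, None] * a[:, None, :]) == 1
    y = ((rng.random((n, C, maxT)) < q[None, :, None]) & active).astype(np.int8)
    _mask_padding(y, occasions)
    d = DetectionArray(site_ids, cameras, occasions, y)
    if design.missing_rate > 0:
        d = inject_missing(d, design.missing_rate, design.missing_mode,
                           seed=int(rng.integers(2**31)))
    qmap = dict(zip(cameras, q))
    implied_p = {
        m.method_id: 1.0 - float(np.prod([1.0 - qmap[c] for c in m.cameras]))
        for m in mmap.methods
    }
    truth = {"psi": psi, "theta": theta, "q": q, "cameras": cameras,
             "implied_p": implied_p, "z": z, "a": a, "occasions": occasions,
             "seed": design.seed}
    return d, truth


def inject_missing(
    d: DetectionArray,
    rate: float,
    mode: str = "camera-day",
    seed: int = 0,
) -> DetectionArray:
    """Blank out observations as missing visits.

    ``camera-day`` turns individual active camera-days MISSING with the
    given probability (snow burial, intermittent battery); ``whole-camera``
    blanks entire camera histories (total unit failure).  Original values
    are unrecoverable by design.
    """
    _check_prob(rate, "rate")
    if mode not in ("camera-day", "whole-camera"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    obs = d.obs.copy()
    if mode == "camera-day":
        miss = rng.random(obs.shape) < rate
        obs[miss] = MISSING
    else:
        failed = rng.random((d.n_sites, d.n_cameras)) < rate
        obs[failed, :] = MISSING
    _mask_padding(obs, d.occasions)
    return DetectionArray(list(d.site_ids), list(d.camera_labels),
                          d.occasions.copy(), obs)


@dataclass
class CovariateSimSpec:
    """Distributions for the synthetic covariate table.

    Area frequencies follow the three-study-area design (12, 12 and 8 sites
    out of 32); access is split evenly between plowed-road and snowmobile
    sites; per-camera distance to the access feature is uniform over the
    field range 10-320 m, with per-method DistMin/DistAve/DistMax derived
    from the member cameras so their ordering holds by construction; tree
    loss proportions are Beta(2, 8) on [0, 1] at every buffer scale.
    """

    area_freqs: dict[str, float] = field(
        default_factory=lambda: {"SL": 12 / 32, "TN": 12 / 32, "ML": 8 / 32})
    access_freqs: dict[str, float] = field(
        default_factory=lambda: {"RD": 0.5, "SM": 0.5})
    loss_beta: tuple[float, float] = (2.0, 8.0)
    loss_columns: tuple[str, ...] = ("Loss100m", "Loss500m", "Loss1k", "Loss5k")
    dist_range: tuple[float, float] = (10.0, 320.0)

    def __post_init__(self) -> None:
        for name, freqs in (("area_freqs", self.area_freqs),
                            ("access_freqs", self.access_freqs)):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sum to {total}, not 1")


def _allocate_counts(freqs: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation: deterministic integer counts per level."""
    raw = {k: f * n for k, f in freqs.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    by_frac = sorted(freqs, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in by_frac[:short]:
        counts[k] += 1
    return counts


def simulate_covariates(
    n_sites: int,
    method_map: MethodMap | None = None,
    spec: CovariateSimSpec | None = None,
    seed: int = 0,
) -> CovariateTable:
    """Generate an internally consistent covariate table for n_sites sites."""
    mmap = method_map or default_method_map()
    spec = spec or CovariateSimSpec()
    rng = np.random.default_rng(seed)
    site_ids = _site_ids(n_sites)

    def categorical(freqs: dict[str, float]) -> np.ndarray:
        counts = _allocate_counts(freqs, n_sites)
        values = np.array([lev for lev, c in counts.items() for _ in range(c)])
        rng.shuffle(values)
        return values

    site = pd.DataFrame(index=pd.Index(site_ids, name="site"))
    site["Area"] = categorical(spec.area_freqs)
    site["Access"] = categorical(spec.access_freqs)
    a, b = spec.loss_beta
    for col in spec.loss_columns:
        site[col] = rng.beta(a, b, size=n_sites)

    cameras = sorted({c for m in mmap.methods for c in m.cameras})
    lo, hi = spec.dist_range
    dist = pd.DataFrame(rng.uniform(lo, hi, size=(n_sites, len(cameras))),
                        index=site_ids, columns=cameras)
    rows = []
    for s in site_ids:
        for m in mmap.methods:
            d = dist.loc[s, list(m.cameras)].to_numpy(dtype=float)
            rows.append((s, m.method_id, d.mean(), d.max(), d.min()))
    sm = pd.DataFrame(rows, columns=["site", "method", "DistAve", "DistMax",
                                     "DistMin"]).set_index(["site", "method"])
    return CovariateTable(site, sm)


def write_truth(truth: dict, path) -> None:
    """Persist a truth record as plain YAML (arrays become lists)."""
    import yaml

    def clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        return v

    with open(path, "w") as fh:
        yaml.safe_dump({k: clean(v) for k, v in truth.items()}, fh,
                       sort_keys=False)
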