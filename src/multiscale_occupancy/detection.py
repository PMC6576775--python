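"""Detection-history data model, I/O, pooling, and covariate handling.

A survey consists of sites, each holding a small array of co-located
cameras whose images are collapsed to one 0/1 record per camera per day
("occasion").  A *method* is a named subset of the cameras; pooling a
method's member histories by logical OR yields the detection history the
multi-scale occupancy model consumes.  Occasions on which a camera was
inactive (failure, snow burial) are *missing visits* and carry no
information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: Integer code for a missing visit in observation arrays.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, MISSING})

#: Fixed level order (baseline first) for the standard categorical covariates.
CATEGORY_ORDERS: dict[str, tuple[str, ...]] = {
    "Area": ("SL", "TN", "ML"),
    "Access": ("RD", "SM"),
}


class ValidationError(ValueError):
    """Raised when input data violate the detection-data contracts."""


def _as_obs_array(obs, n_sites: int, n_units: int, what: str) -> np.ndarray:
    arr = np.asarray(obs, dtype=np.int8)
    if arr.shape[:2] != (n_sites, n_units):
        raise ValidationError(
            f"{what} observation array has shape {arr.shape}, expected "
            f"({n_sites}, {n_units}, T)"
        )
    bad = ~np.isin(arr, list(_VALID_CODES))
    if bad.any():
        i, j, t = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"{what} value {arr[i, j, t]} at (site index {i}, unit index {j}, "
            f"occasion {t + 1}) is not one of 0, 1, missing"
        )
    return arr


@dataclass(eq=False)
class DetectionArray:
    """Site x camera x occasion ternary observations (0 / 1 / MISSING).

    Sites may differ in their number of survey occasions; ``obs`` is padded
    to the longest site with MISSING beyond each site's ``occasions`` count.
    A camera that never recorded (hardware failure) is representable as an
    all-MISSING row.
    """

    site_ids: list[str]
    camera_labels: list[str]
    occasions: np.ndarray  # (n_sites,) ints >= 1
    obs: np.ndarray  # (n_sites, n_cameras, max_T) int8 in {0, 1, MISSING}

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        self.camera_labels = [str(c) for c in self.camera_labels]
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("duplicate site ids")
        if len(set(self.camera_labels)) != len(self.camera_labels):
            raise ValidationError("duplicate camera labels")
        self.occasions = np.asarray(self.occasions, dtype=int)
        if self.occasions.shape != (len(self.site_ids),):
            raise ValidationError("occasions must have one entry per site")
        if (self.occasions < 1).any():
            raise ValidationError("every site needs at least one occasion")
        self.obs = _as_obs_array(self.obs, len(self.site_ids),
                                 len(self.camera_labels), "camera")
        if self.obs.shape[2] < self.occasions.max():
            raise ValidationError("obs shorter than the longest site's occasions")
        # padding beyond each site's occasion count must be MISSING
        for i, T in enumerate(self.occasions):
            if (self.obs[i, :, T:] != MISSING).any():
                raise ValidationError(
                    f"site {self.site_ids[i]} has non-missing values beyond "
                    f"its {T} occasions"
                )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_cameras(self) -> int:
        return len(self.camera_labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DetectionArray)
            and self.site_ids == other.site_ids
            and self.camera_labels == other.camera_labels
            and np.array_equal(self.occasions, other.occasions)
            and np.array_equal(self.obs, other.obs)
        )


@dataclass(frozen=True)
class Method:
    """One pooling method: a camera subset with a spacing tag."""

    method_id: str
    cameras: tuple[str, ...]
    spacing: str = "n/a"  # 'short' (100 m), 'long' (150 m) or 'n/a'

    @property
    def n_cameras(self) -> int:
        return len(self.cameras)


@dataclass(frozen=True)
class MethodMap:
    """Ordered collection of pooling methods."""

    methods: tuple[Method, ...]

    def __post_init__(self) -> None:
        ids = [m.method_id for m in self.methods]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate method ids")
        for m in self.methods:
            if m.spacing not in ("short", "long", "n/a"):
                raise ValidationError(
                    f"method {m.method_id}: spacing {m.spacing!r} not one of "
                    "'short', 'long', 'n/a'"
                )
            if len(set(m.cameras)) != len(m.cameras):
                raise ValidationError(f"method {m.method_id}: repeated camera")

    @property
    def method_ids(self) -> list[str]:
        return [m.method_id for m in self.methods]

    def validate_against(self, d: DetectionArray) -> None:
        known = set(d.camera_labels)
        for m in self.methods:
            unknown = [c for c in m.cameras if c not in known]
            if unknown:
                raise ValidationError(
                    f"method {m.method_id} references unknown camera(s) "
                    f"{unknown}; array has {sorted(known)}"
                )


def default_method_map() -> MethodMap:
    """The five-method T-configuration map.

    m1 = camera A alone; m2 = B,C (100 m apart); m3 = A,B,C (100 m);
    m4 = D,E (150 m); m5 = B,D,E (150 m).
    """
    return MethodMap(
        (
            Method("m1", ("A",), "n/a"),
            Method("m2", ("B", "C"), "short"),
            Method("m3", ("A", "B", "C"), "short"),
            Method("m4", ("D", "E"), "long"),
            Method("m5", ("B", "D", "E"), "long"),
        )
    )


@dataclass(eq=False)
class PooledHistory:
    """Site x method x occasion observations derived from a DetectionArray."""

    site_ids: list[str]
    method_ids: list[str]
    occasions: np.ndarray
    obs: np.ndarray  # (n_sites, n_methods, max_T)

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        self.method_ids = [str(m) for m in self.method_ids]
        self.occasions = np.asarray(self.occasions, dtype=int)
        self.obs = _as_obs_array(self.obs, len(self.site_ids),
                                 len(self.method_ids), "method")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_methods(self) -> int:
        return len(self.method_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PooledHistory)
            and self.site_ids == other.site_ids
            and self.method_ids == other.method_ids
            and np.array_equal(self.occasions, other.occasions)
            and np.array_equal(self.obs, other.obs)
        )


def pool_histories(d: DetectionArray, m: MethodMap) -> PooledHistory:
    """Pool per-camera histories into per-method histories by logical OR.

    For each method and occasion: 1 if any member camera detected, MISSING
    if *all* member cameras are missing, else 0 (any active camera makes
    the occasion informative).
    """
    m.validate_against(d)
    idx = {c: k for k, c in enumerate(d.camera_labels)}
    n, _, T = d.obs.shape
    out = np.empty((n, len(m.methods), T), dtype=np.int8)
    for j, meth in enumerate(m.methods):
        sub = d.obs[:, [idx[c] for c in meth.cameras], :]
        any_one = (sub == 1).any(axis=1)
        all_missing = (sub == MISSING).all(axis=1)
        out[:, j, :] = np.where(any_one, 1, np.where(all_missing, MISSING, 0))
    return PooledHistory(d.site_ids, m.method_ids, d.occasions.copy(), out)


def naive_summaries(d: DetectionArray) -> dict[str, int]:
    """Design-free tallies: units and trap-nights with detections, effort.

    Returns the number of cameras with at least one detection, the number of
    camera-trap-nights with a detection, and the total active trap-nights
    (missing visits excluded).  These are the raw-detection summaries one
    reports alongside model-based estimates.
    """
    return {
        "cameras_with_detection": int((d.obs == 1).any(axis=2).sum()),
        "trap_nights_with_detection": int((d.obs == 1).sum()),
        "active_trap_nights": int((d.obs != MISSING).sum()),
    }


# ---------------------------------------------------------------------------
# Detection-history I/O (long and wide delimited text)
# ---------------------------------------------------------------------------

def _parse_value(raw, where: str) -> int:
    if pd.isna(raw) or (isinstance(raw, str) and raw.strip().upper() in ("", "NA")):
        return MISSING
    try:
        v = int(float(raw))
    except (TypeError, ValueError):
        v = None
    if v not in (0, 1):
        raise ValidationError(f"value {raw!r} at {where} is not 0, 1 or NA")
    return v


def read_detections(path, layout: str = "long") -> DetectionArray:
    """Read a detection CSV.

    ``long`` layout: columns site, camera, occasion, value (value in 0/1/NA;
    occasions are 1-based; absent rows are missing visits).  ``wide`` layout:
    columns site, camera, occ_1..occ_T.
    """
    df = pd.read_csv(path, dtype={"site": str, "camera": str})
    if layout == "long":
        return _detections_from_long(df)
    if layout == "wide":
        return _detections_from_wide(df)
    raise ValueError(f"unknown layout {layout!r}")


def _detections_from_long(df: pd.DataFrame) -> DetectionArray:
    required = {"site", "camera", "occasion", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(f"long layout needs columns {sorted(required)}")
    dup = df.duplicated(subset=["site", "camera", "occasion"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate record for site {r['site']}, camera {r['camera']}, "
            f"occasion {r['occasion']}"
        )
    sites = sorted(df["site"].unique())
    cameras = sorted(df["camera"].unique())
    occ = df.groupby("site")["occasion"].max().astype(int)
    occasions = np.array([occ[s] for s in sites])
    obs = np.full((len(sites), len(cameras), int(occasions.max())), MISSING,
                  dtype=np.int8)
    si = {s: i for i, s in enumerate(sites)}
    ci = {c: j for j, c in enumerate(cameras)}
    for row in df.itertuples(index=False):
        t = int(row.occasion)
        if t < 1:
            raise ValidationError(f"occasion {t} at site {row.site} is not >= 1")
        where = f"site {row.site}, camera {row.camera}, occasion {t}"
        obs[si[row.site], ci[row.camera], t - 1] = _parse_value(row.value, where)
    return DetectionArray(sites, cameras, occasions, obs)


def _detections_from_wide(df: pd.DataFrame) -> DetectionArray:
    occ_cols = [c for c in df.columns if c.startswith("occ_")]
    if not occ_cols or not {"site", "camera"}.issubset(df.columns):
        raise ValidationError("wide layout needs site, camera and occ_* columns")
    occ_cols = sorted(occ_cols, key=lambda c: int(c.split("_")[1]))
    if df.duplicated(subset=["site", "camera"]).any():
        raise ValidationError("duplicate (site, camera) row in wide layout")
    sites = sorted(df["site"].unique())
    cameras = sorted(df["camera"].unique())
    obs = np.full((len(sites), len(cameras), len(occ_cols)), MISSING, dtype=np.int8)
    si = {s: i for i, s in enumerate(sites)}
    ci = {c: j for j, c in enumerate(cameras)}
    occasions = np.zeros(len(sites), dtype=int)
    for _, row in df.iterrows():
        for t, col in enumerate(occ_cols):
            where = f"site {row['site']}, camera {row['camera']}, occasion {t + 1}"
            v = _parse_value(row[col], where)
            obs[si[row["site"]], ci[row["camera"]], t] = v
            if v != MISSING:
                occasions[si[row["site"]]] = max(occasions[si[row["site"]]], t + 1)
    occasions[occasions == 0] = len(occ_cols)  # all-missing site: keep full span
    # re-blank padding beyond per-site occasion counts
    for i in range(len(sites)):
        obs[i, :, occasions[i]:] = MISSING
    return DetectionArray(sites, cameras, occasions, obs)


def _write_long(site_ids, unit_ids, occasions, obs, unit_col, path) -> None:
    rows = []
    for i, s in enumerate(site_ids):
        for j, u in enumerate(unit_ids):
            for t in range(int(occasions[i])):
                v = obs[i, j, t]
                rows.append((s, u, t + 1, "NA" if v == MISSING else int(v)))
    pd.DataFrame(rows, columns=["site", unit_col, "occasion", "value"]).to_csv(
        path, index=False
    )


def write_detections(d: DetectionArray, path) -> None:
    """Write a DetectionArray as long-format CSV (NA for missing visits)."""
    _write_long(d.site_ids, d.camera_labels, d.occasions, d.obs, "camera", path)


def write_pooled(p: PooledHistory, path) -> None:
    """Write a PooledHistory as long-format CSV with a method column."""
    _write_long(p.site_ids, p.method_ids, p.occasions, p.obs, "method", path)


def read_pooled(path) -> PooledHistory:
    """Read a pooled long-format CSV (site, method, occasion, value)."""
    df = pd.read_csv(path, dtype={"site": str, "method": str})
    df = df.rename(columns={"method": "camera"})
    d = _detections_from_long(df)
    return PooledHistory(d.site_ids, d.camera_labels, d.occasions, d.obs)


# ---------------------------------------------------------------------------
# Method-map I/O
# ---------------------------------------------------------------------------

def read_method_map(path) -> MethodMap:
    """Read a method map from YAML: a list of {id, cameras, spacing}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["methods"] if isinstance(doc, dict) else doc
    methods = []
    for e in entries:
        methods.append(
            Method(str(e["id"]), tuple(str(c) for c in e["cameras"]),
                   str(e.get("spacing", "n/a")))
        )
    return MethodMap(tuple(methods))


def write_method_map(m: MethodMap, path) -> None:
    doc = {
        "methods": [
            {"id": x.method_id, "cameras": list(x.cameras), "spacing": x.spacing}
            for x in m.methods
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

@dataclass
class CovariateTable:
    """Site-level and (site, method)-level covariates.

    ``site`` is indexed by site id (e.g. Area, Access, Loss100m..Loss5k);
    ``site_method`` is indexed by (site, method) and holds per-method
    quantities such as the mean/min/max distance from the access feature to
    the method's member cameras.
    """

    site: pd.DataFrame
    site_method: pd.DataFrame | None = None
    scalers: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.site = self.site.copy()
        self.site.index = self.site.index.astype(str)
        if self.site.index.has_duplicates:
            raise ValidationError("covariate table: duplicate site rows")
        if self.site_method is not None:
            self.site_method = self.site_method.copy()
            if self.site_method.index.has_duplicates:
                raise ValidationError("covariate table: duplicate (site, method) rows")

    def has_column(self, name: str) -> bool:
        return name in self.site.columns or (
            self.site_method is not None and name in self.site_method.columns
        )

    def column_level(self, name: str) -> str:
        """'site' or 'site_method', depending on where the column lives."""
        if name in self.site.columns:
            return "site"
        if self.site_method is not None and name in self.site_method.columns:
            return "site_method"
        raise KeyError(f"no covariate column named {name!r}")


def zscore_covariates(
    cov: CovariateTable,
    columns: list[str],
    scalers: dict[str, tuple[float, float]] | None = None,
) -> tuple[CovariateTable, dict[str, tuple[float, float]]]:
    """Standardize continuous columns to mean 0, sd 1 (sample sd, ddof=1).

    Returns a new table plus the scaler record {column: (mean, sd)}.  Pass
    ``scalers`` to re-apply a previously fitted transform (e.g. to simulated
    data standardized with the field-data scalers).  A constant column is an
    error: its z-score is undefined.
    """
    site = cov.site.copy()
    sm = cov.site_method.copy() if cov.site_method is not None else None
    out_scalers = dict(cov.scalers)
    for col in columns:
        frame = site if col in site.columns else sm
        if frame is None or col not in frame.columns:
            raise KeyError(f"no covariate column named {col!r}")
        vals = frame[col].astype(float)
        if scalers is not None and col in scalers:
            mean, sd = scalers[col]
        else:
            mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValidationError(f"column {col!r} is constant; z-score undefined")
        frame[col] = (vals - mean) / sd
        out_scalers[col] = (mean, sd)
    return CovariateTable(site, sm, out_scalers), out_scalers


def read_covariates(path) -> CovariateTable:
    """Read covariates from one CSV.

    Columns: ``site`` plus covariates, with an optional ``method`` column;
    rows with a blank method form the site-level block, rows with a method
    the (site, method)-level block.
    """
    df = pd.read_csv(path, dtype={"site": str})
    if "site" not in df.columns:
        raise ValidationError("covariate CSV needs a 'site' column")
    if "method" in df.columns:
        is_site = df["method"].isna() | (df["method"].astype(str).str.strip() == "")
        site_df = df[is_site].drop(columns=["method"]).dropna(axis=1, how="all")
        site_df = site_df.set_index("site")
        sm = df[~is_site].dropna(axis=1, how="all")
        sm_df = None
        if len(sm):
            sm["method"] = sm["method"].astype(str)
            sm_df = sm.set_index(["site", "method"])
        return CovariateTable(site_df, sm_df)
    return CovariateTable(df.set_index("site"))


def write_covariates(cov: CovariateTable, path) -> None:
    site = cov.site.reset_index().rename(columns={"index": "site"})
    if "site" not in site.columns:
        site = site.rename(columns={site.columns[0]: "site"})
    if cov.site_method is None:
        site.to_csv(path, index=False, na_rep="NA")
        return
    site.insert(1, "method", "")
    sm = cov.site_method.reset_index()
    sm.columns = ["site", "method"] + list(sm.columns[2:])
    pd.concat([site, sm], ignore_index=True).to_csv(path, index=False, na_rep="NA")
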