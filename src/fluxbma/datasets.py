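"""Chamber dataset container and flat-CSV round trip.

One long-format CSV row per site x replicate with the header
``site_id,x_m,y_m,replicate,n2o_flux,moisture,temperature,no3,ph,sand,silt,clay``.
Fluxes are analysed on the log scale; zeros are handled by log(y + c) with
c = half the smallest positive flux (configurable), recorded in metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import SiteCoordinates

logger = logging.getLogger(__name__)

#: canonical covariate order (K = 7)
COVARIATES = ("moisture", "temperature", "no3", "ph", "sand", "silt", "clay")

CSV_COLUMNS = ("site_id", "x_m", "y_m", "replicate", "n2o_flux") + COVARIATES


@dataclass(frozen=True)
class ChamberDataset:
    """Replicated point-referenced chamber fluxes with covariates.

    ``y`` holds log-transformed fluxes log(flux + shift); ``flux`` keeps the
    natural scale. ``X`` is (Q, M, K) in :data:`COVARIATES` order.
    """

    coords: SiteCoordinates
    flux: np.ndarray  # (Q, M) natural scale, ug N2O-N m^-2 hr^-1
    y: np.ndarray  # (Q, M) log scale
    X: np.ndarray  # (Q, M, K)
    log_shift: float  # additive constant c of log(flux + c)

    def __post_init__(self):
        q, m = self.flux.shape
        if self.y.shape != (q, m) or self.X.shape[:2] != (q, m):
            raise ValueError("flux, y, X shapes disagree")
        if self.X.shape[2] != len(COVARIATES):
            raise ValueError(f"expected K={len(COVARIATES)} covariates")
        if q * m < self.X.shape[2] + 2:
            raise ValueError("too few observations for K+2 parameters")
        if np.isnan(self.y).any():
            raise ValueError("missing log-fluxes after validation")

    @property
    def n_sites(self) -> int:
        return self.flux.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.flux.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[2]

    def design_matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten to (y_vec, X_design with leading intercept column,
        site_index) in site-major order."""
        q, m, k = self.X.shape
        y = self.y.reshape(q * m)
        xmat = np.column_stack([np.ones(q * m), self.X.reshape(q * m, k)])
        site_idx = np.repeat(np.arange(q), m)
        return y, xmat, site_idx


def default_log_shift(flux: np.ndarray) -> float:
    """c = half the smallest positive flux if zeros are present, else 0."""
    pos = flux[flux > 0]
    if flux.min() > 0:
        return 0.0
    if pos.size == 0:
        raise ValueError("all fluxes are zero; cannot choose a log shift")
    return float(pos.min() / 2.0)


def from_arrays(
    coords: SiteCoordinates,
    flux: np.ndarray,
    covariates: np.ndarray,
    log_shift: float | None = None,
) -> ChamberDataset:
    flux = np.asarray(flux, dtype=float)
    if np.any(flux < 0):
        raise ValueError("negative fluxes are not valid chamber measurements")
    if log_shift is None:
        log_shift = default_log_shift(flux)
        if log_shift > 0:
            logger.info("zero fluxes present; log shift c = %.6g", log_shift)
    y = np.log(flux + log_shift)
    return ChamberDataset(coords=coords, flux=flux, y=y, X=np.asarray(covariates, float), log_shift=float(log_shift))


def read_chamber_csv(path, log_shift: float | None = None) -> ChamberDataset:
    """Read and validate the flat chamber CSV.

    Requires a rectangular site x replicate layout, non-negative fluxes and
    consistent site coordinates across replicates. Logs a validation report.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"chamber CSV missing column(s): {', '.join(missing)}")
    if df[list(CSV_COLUMNS)].isna().any().any():
        n_missing = int(df[list(CSV_COLUMNS)].isna().sum().sum())
        raise ValueError(f"chamber CSV has {n_missing} missing cell(s)")
    if (df["n2o_flux"] < 0).any():
        bad = df.loc[df["n2o_flux"] < 0, "site_id"].tolist()
        raise ValueError(f"negative fluxes at site(s) {bad}")

    sites = np.sort(df["site_id"].unique())
    reps = np.sort(df["replicate"].unique())
    counts = df.groupby("site_id")["replicate"].nunique()
    if counts.nunique() != 1 or len(df) != len(sites) * len(reps):
        raise ValueError(
            "non-rectangular site x replicate layout: every site needs the "
            "same replicate set"
        )
    xy = df.groupby("site_id")[["x_m", "y_m"]].nunique()
    if (xy > 1).any().any():
        raise ValueError("site coordinates differ across replicates")

    df = df.sort_values(["site_id", "replicate"])
    q, m = len(sites), len(reps)
    first = df.drop_duplicates("site_id").sort_values("site_id")
    coords = SiteCoordinates(
        site_id=first["site_id"].to_numpy(),
        x=first["x_m"].to_numpy(float),
        y=first["y_m"].to_numpy(float),
    )
    flux = df["n2o_flux"].to_numpy(float).reshape(q, m)
    covs = df[list(COVARIATES)].to_numpy(float).reshape(q, m, len(COVARIATES))
    ds = from_arrays(coords, flux, covs, log_shift=log_shift)
    logger.info(
        "chamber CSV: %d sites x %d replicates, 0 missing cells, log shift %.6g",
        q, m, ds.log_shift,
    )
    return ds


def to_dataframe(ds: ChamberDataset) -> pd.DataFrame:
    q, m, k = ds.X.shape
    rows = {
        "site_id": np.repeat(ds.coords.site_id, m),
        "x_m": np.repeat(ds.coords.x, m),
        "y_m": np.repeat(ds.coords.y, m),
        "replicate": np.tile(np.arange(1, m + 1), q),
        "n2o_flux": ds.flux.reshape(q * m),
    }
    for j, name in enumerate(COVARIATES):
        rows[name] = ds.X[:, :, j].reshape(q * m)
    return pd.DataFrame(rows)


def write_chamber_csv(ds: ChamberDataset, path) -> None:
    to_dataframe(ds).to_csv(path, index=False, float_format="%.10g")


def with_log_shift(ds: ChamberDataset, log_shift: float) -> ChamberDataset:
    return replace(ds, log_shift=float(log_shift), y=np.log(ds.flux + log_shift))
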