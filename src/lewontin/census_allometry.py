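"""Census population sizes from macroecological allometries.

Population density estimates are unavailable for most species, so density is
predicted from body mass through the Damuth-style abundance-body-size
relationship (log-linear decline of density with mass), and body mass is in
turn predicted from body length through a log-linear length-mass allometry
when no mass measurement exists. Census size is then the product of the
predicted density and the geodesic range area,

    N_c = D * R,

with D in individuals per km^2 and R in km^2. Both regressions are ordinary
least squares on the log10 scale; uncertainty can be propagated by
Monte-Carlo draws from the coefficient covariance plus the residual scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError, InvalidArgumentError

__all__ = [
    "AllometryFit",
    "fit_loglog_allometry",
    "predict_mass_from_length",
    "predict_density",
    "census_size",
    "synthetic_density_table",
    "default_density_fit",
    "default_length_mass_fit",
    "estimate_census_sizes",
]


@dataclass
class AllometryFit:
    """A log10-log10 linear fit: log10 y = intercept + slope * log10 x."""

    intercept: float
    slope: float
    residual_sd: float
    n_obs: int
    cov: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def predict_log10(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.log10(x)


def fit_loglog_allometry(x, y) -> AllometryFit:
    """Least-squares fit of log10 y on log10 x.

    Raises ``InvalidArgumentError`` for non-positive values and
    ``InsufficientDataError`` for fewer than 3 observations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise InvalidArgumentError("x and y must have equal length")
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 observations, got {len(x)}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise InvalidArgumentError("allometry variables must be strictly positive")
    design = sm.add_constant(np.log10(x))
    res = sm.OLS(np.log10(y), design).fit()
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return AllometryFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        residual_sd=resid_sd,
        n_obs=len(x),
        cov=np.asarray(res.cov_params()),
    )


def _predict_power_law(value: float, fit: AllometryFit, rng: np.random.Generator | None):
    log10_pred = fit.predict_log10(value)
    if rng is not None:
        coef = rng.multivariate_normal([fit.intercept, fit.slope], fit.cov)
        log10_pred = coef[0] + coef[1] * np.log10(value) + rng.normal(0.0, fit.residual_sd)
    return 10.0**log10_pred


def predict_mass_from_length(
    length_cm, fit: AllometryFit, draw: int | None = None
) -> float | np.ndarray:
    """Predict body mass (g) from body length (cm).

    With ``draw`` (a seed), a single posterior-predictive draw is returned:
    coefficients sampled from their covariance plus lognormal residual
    noise. Without it, the point prediction ``10^(a + b log10 length)``.
    """
    length_cm = np.asarray(length_cm, float)
    if np.any(length_cm <= 0):
        raise InvalidArgumentError("length must be > 0")
    rng = np.random.default_rng(draw) if draw is not None else None
    return _predict_power_law(length_cm, fit, rng)


def predict_density(mass_g, fit: AllometryFit, draw: int | None = None) -> float | np.ndarray:
    """Predict population density (individuals/km^2) from body mass (g)."""
    mass_g = np.asarray(mass_g, float)
    if np.any(mass_g <= 0):
        raise InvalidArgumentError("mass must be > 0")
    rng = np.random.default_rng(draw) if draw is not None else None
    return _predict_power_law(mass_g, fit, rng)


def census_size(density_km2, range_km2) -> float | np.ndarray:
    """Census size N_c = D * R (individuals)."""
    density_km2 = np.asarray(density_km2, float)
    range_km2 = np.asarray(range_km2, float)
    if np.any(density_km2 <= 0) or np.any(range_km2 <= 0):
        raise InvalidArgumentError("density and range must be > 0")
    return density_km2 * range_km2


# Stand-in coefficients for the refit density-mass (Damuth) relationship:
# log10 density [ind/km^2] = 4.23 - 0.78 * log10 mass [g]. Overridable by
# supplying a training table to fit_loglog_allometry.
DEFAULT_DENSITY_COEF = (4.23, -0.78, 0.5)
DEFAULT_LENGTH_MASS_COEF = (-1.2, 2.9, 0.2)
DAMUTH_TABLE_SIZE = 696


def synthetic_density_table(
    n: int = DAMUTH_TABLE_SIZE, seed: int = 20210819
) -> pd.DataFrame:
    """A synthetic Damuth-style training table (mass_g, density_km2).

    Masses are log-uniform over 1e-3 g to 1e7 g (mites to whales) and
    densities follow the default coefficients with lognormal scatter. This
    is a synthetic stand-in for a literature compilation of density-mass
    measurements, generated programmatically so the default density fit is
    reproducible without any download.
    """
    rng = np.random.default_rng(seed)
    log10_mass = rng.uniform(-3, 7, n)
    a, b, sd = DEFAULT_DENSITY_COEF
    log10_density = a + b * log10_mass + rng.normal(0.0, sd, n)
    return pd.DataFrame({"mass_g": 10.0**log10_mass, "density_km2": 10.0**log10_density})


def default_density_fit() -> AllometryFit:
    """Density-mass fit trained on the packaged synthetic table."""
    table = synthetic_density_table()
    return fit_loglog_allometry(table["mass_g"], table["density_km2"])


def default_length_mass_fit() -> AllometryFit:
    """Length-mass allometry with near-cubic scaling (no training table)."""
    a, b, sd = DEFAULT_LENGTH_MASS_COEF
    return AllometryFit(intercept=a, slope=b, residual_sd=sd, n_obs=0)


def estimate_census_sizes(
    taxa: pd.DataFrame,
    length_mass_fit: AllometryFit | None = None,
    density_fit: AllometryFit | None = None,
) -> pd.DataFrame:
    """Fill mass, density, and N_c columns of a taxon table.

    Taxa with an observed ``mass_g`` keep it (``mass_predicted`` False);
    others get mass predicted from ``length_cm``. Density is predicted from
    mass, and ``N_c = density_km2 * range_km2`` wherever both are present.
    """
    length_mass_fit = length_mass_fit or default_length_mass_fit()
    density_fit = density_fit or default_density_fit()
    out = taxa.copy()
    if "mass_g" not in out:
        out["mass_g"] = np.nan
    observed = out["mass_g"].notna()
    out["mass_predicted"] = ~observed
    needs_mass = ~observed & out.get("length_cm", pd.Series(np.nan, index=out.index)).notna()
    if needs_mass.any():
        out.loc[needs_mass, "mass_g"] = predict_mass_from_length(
            out.loc[needs_mass, "length_cm"].to_numpy(), length_mass_fit
        )
    has_mass = out["mass_g"].notna()
    out.loc[has_mass, "density_km2"] = predict_density(
        out.loc[has_mass, "mass_g"].to_numpy(), density_fit
    )
    if "range_km2" in out:
        both = has_mass & out["range_km2"].notna()
        out.loc[both, "N_c"] = census_size(
            out.loc[both, "density_km2"].to_numpy(), out.loc[both, "range_km2"].to_numpy()
        )
    return out
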