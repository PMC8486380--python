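"""Biomass plausibility checks for census-size estimates.

Census sizes are validated by the carbon biomass they imply: for species i
with wet body mass m_i (g) and census size N_i, the implied sample biomass
in a phylum is ``b = 0.15 * sum_i m_i N_i`` converted to gigatonnes of
carbon, where 0.15 = (1 - 0.7) * 0.5 converts wet mass to carbon mass (70%
water content; carbon is 50% of dry mass). Per phylum, the sample biomass b
is compared to the global carbon biomass B: proportions of each, the factor
by which the sample over-represents the phylum, the sampled fraction of
described species f = n/T, and the ratio b / (f B) — the sample biomass
relative to what a random sample of n of the phylum's T species would
carry.
"""

from __future__ import annotations

from importlib import resources
import logging

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "WET_TO_CARBON",
    "wet_to_carbon",
    "sample_biomass",
    "expected_sample_biomass",
    "biomass_table",
    "load_reference_biomass",
]

logger = logging.getLogger(__name__)

#: Wet mass -> carbon mass conversion: (1 - water fraction) * carbon fraction
#: = (1 - 0.7) * 0.5 = 0.15 (animal bodies are ~70% water; carbon is ~50%
#: of dry mass).
WATER_FRACTION = 0.7
CARBON_FRACTION_OF_DRY = 0.5
WET_TO_CARBON = 0.15

G_PER_GT = 1e15


def wet_to_carbon(mass_wet_g):
    """Convert wet body mass (g) to carbon mass (g): factor 0.15."""
    mass_wet_g = np.asarray(mass_wet_g, float)
    if np.any(mass_wet_g < 0):
        raise InvalidArgumentError("mass must be >= 0")
    out = WET_TO_CARBON * mass_wet_g
    return out[()] if out.ndim else float(out)


def sample_biomass(taxa: pd.DataFrame) -> float:
    """Implied carbon biomass of a set of taxa, in Gt C.

    Each taxon contributes ``mass_g * N_c`` of wet biomass; taxa missing
    either value are skipped with a warning.
    """
    required = {"mass_g", "N_c"}
    if required - set(taxa.columns):
        raise InvalidArgumentError(f"missing columns: {sorted(required - set(taxa.columns))}")
    ok = taxa["mass_g"].notna() & taxa["N_c"].notna()
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("sample_biomass: skipping %d taxa lacking mass or N_c", n_skipped)
    if not ok.any():
        logger.warning("sample_biomass: no usable taxa; returning 0")
        return 0.0
    wet = float((taxa.loc[ok, "mass_g"] * taxa.loc[ok, "N_c"]).sum())
    return wet_to_carbon(wet) / G_PER_GT


def expected_sample_biomass(B_gtc: float, n: int, T: int) -> float:
    """Expected biomass of n species sampled at random from a phylum: B*n/T."""
    if T <= 0:
        raise InvalidArgumentError("T must be > 0")
    if n < 0 or n > T:
        raise InvalidArgumentError("need 0 <= n <= T")
    if B_gtc < 0:
        raise InvalidArgumentError("B must be >= 0")
    return B_gtc * n / T


def biomass_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Derive the biomass-consistency columns from per-phylum inputs.

    Parameters
    ----------
    rows
        DataFrame with columns ``phylum``, ``total_species`` (T, described
        species on Earth), ``biomass_gtc`` (B, global carbon biomass),
        ``sample_biomass_gtc`` (b, carbon biomass implied by the sample's
        census sizes), ``n_species`` (n, species sampled).

    Returns
    -------
    DataFrame with added columns ``prop_B`` (= B / sum B), ``prop_b``
    (= b / sum b), ``factor_overrep`` (= prop_b / prop_B), ``f`` (= n / T)
    and ``ratio`` (= b / (f B)). Proportions sum to one.
    """
    required = {"phylum", "total_species", "biomass_gtc", "sample_biomass_gtc", "n_species"}
    if required - set(rows.columns):
        raise InvalidArgumentError(f"missing columns: {sorted(required - set(rows.columns))}")
    if len(rows) < 1:
        raise InvalidArgumentError("need at least one phylum")
    out = rows.copy()
    B = out["biomass_gtc"].to_numpy(float)
    b = out["sample_biomass_gtc"].to_numpy(float)
    T = out["total_species"].to_numpy(float)
    n = out["n_species"].to_numpy(float)
    if B.sum() <= 0 or b.sum() <= 0:
        raise InvalidArgumentError("total biomass must be positive")
    if np.any(T <= 0):
        raise InvalidArgumentError("total_species must be positive")
    out["prop_B"] = B / B.sum()
    out["prop_b"] = b / b.sum()
    out["factor_overrep"] = out["prop_b"] / out["prop_B"]
    out["f"] = n / T
    out["ratio"] = b / (out["f"] * B)
    return out


def load_reference_biomass() -> pd.DataFrame:
    """Packaged per-phylum reference: described species counts and global
    carbon biomass, with the sample biomass and species counts of the
    172-taxon compilation."""
    path = resources.files("lewontin.data").joinpath("biomass_reference.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)
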