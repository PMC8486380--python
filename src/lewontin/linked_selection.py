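"""Expected diversity under background selection and recurrent hitchhiking.

The combined model predicts pairwise diversity at a neutral site as

    pi = theta / (1/B(U, L) + 2 N S(gamma, J, L)),        theta = 4 N mu,

where ``B(U, L) = exp(-U / L)`` is the background-selection reduction for a
deleterious mutation rate U (per diploid genome per generation) and
recombination map length L (Morgans), and ``S = gamma J / L`` is the
pairwise coalescence rate caused by recurrent selective sweeps: gamma
adaptive substitutions per generation genome-wide, each trapping a lineage
pair with probability J, diluted by map length. Predicted diversity is then
passed through the four-alleles mutation model, pi = theta_eff/(1 + 4
theta_eff/3), which caps heterozygosity at 3/4.

Defaults are strong-selection parameter estimates for Drosophila
melanogaster: U = 1.6, gamma = alpha m / 2T = 2.26e-3 substitutions per
generation (alpha = 0.42 of substitutions beneficial, divergence time T =
4.2e7 generations at ten generations per year), J = 4.5e-4, an autosomal
target of G = 9.66e7 bp, and mutation rates spanning 1e-9 to 1e-8 per bp
per generation.

All scalar operations are pure and vectorize elementwise over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "SelectionParams",
    "DiversityPrediction",
    "DROSOPHILA_DEFAULTS",
    "bgs_factor",
    "sweep_rate",
    "reduction_factor",
    "four_alleles_pi",
    "predicted_pi",
    "gamma_from_divergence",
    "nu_bp",
    "prediction_band",
    "ne_tilde",
    "fst_subpop_het",
]


@dataclass
class SelectionParams:
    """Linked-selection parameters; defaults are the Drosophila bundle."""

    U: float = 1.6                    # deleterious mutations / diploid genome / gen
    gamma: float = 2.26e-3            # adaptive substitutions / gen, genome-wide
    J: float = 4.5e-4                 # P(lineage pair coalesces | sweep)
    alpha_adaptive: float = 0.42      # fraction of substitutions beneficial
    G: float = 9.66e7                 # autosomal target length, bp
    T_gen: float = 4.2e7              # divergence time, generations
    m_subs: float = 4.52e5            # substitutions on the divergence path
    Ne_mode: str = "use_Nc"           # {"use_Nc", "fixed_Ne"}
    fixed_Ne: float = 1e6
    mu_lo: float = 1e-9
    mu_hi: float = 1e-8
    #: D. melanogaster map length (Morgans) used for the within-species
    #: reduction computation; provisional, see docs/methods.md.
    dmel_map_length: float = 1.05
    sweep_form: str = "ratio"         # "ratio": S = gamma*J/L; "product": gamma*L*J

    def __post_init__(self) -> None:
        if self.U < 0 or self.gamma < 0:
            raise InvalidArgumentError("U and gamma must be >= 0")
        if not (0 <= self.J <= 1) or not (0 <= self.alpha_adaptive <= 1):
            raise InvalidArgumentError("J and alpha_adaptive must be in [0, 1]")
        if not (0 < self.mu_lo <= self.mu_hi):
            raise InvalidArgumentError("mu range must be positive and ordered")
        if self.Ne_mode not in ("use_Nc", "fixed_Ne"):
            raise InvalidArgumentError("Ne_mode must be 'use_Nc' or 'fixed_Ne'")
        if self.sweep_form not in ("ratio", "product"):
            raise InvalidArgumentError("sweep_form must be 'ratio' or 'product'")


DROSOPHILA_DEFAULTS = SelectionParams()


@dataclass
class DiversityPrediction:
    """Per-taxon linked-selection prediction at the two mutation-rate bounds."""

    species_id: str
    B: float
    S: float
    R: float
    pi_lo: float
    pi_hi: float


def bgs_factor(U, L):
    """Background-selection reduction factor B = exp(-U / L)."""
    U = np.asarray(U, float)
    L = np.asarray(L, float)
    if np.any(L <= 0):
        raise InvalidArgumentError("map length L must be > 0")
    if np.any(U < 0):
        raise InvalidArgumentError("U must be >= 0")
    return np.exp(-U / L)[()] if np.ndim(U) or np.ndim(L) else float(np.exp(-U / L))


def sweep_rate(gamma, J, L, form: str = "ratio"):
    """Pairwise coalescence rate due to sweeps, S = gamma * J / L.

    ``form='product'`` evaluates gamma * L * J instead, for sensitivity
    analysis against the alternative reading of the rate's functional form.
    """
    gamma = np.asarray(gamma, float)
    J = np.asarray(J, float)
    L = np.asarray(L, float)
    if np.any(L <= 0):
        raise InvalidArgumentError("map length L must be > 0")
    if np.any(gamma < 0) or np.any((J < 0) | (J > 1)):
        raise InvalidArgumentError("gamma >= 0 and J in [0,1] required")
    if form == "ratio":
        out = gamma * J / L
    elif form == "product":
        out = gamma * L * J
    else:
        raise InvalidArgumentError("form must be 'ratio' or 'product'")
    return out[()] if out.ndim else float(out)


def reduction_factor(N, U, L, gamma, J, form: str = "ratio"):
    """Total diversity reduction R = 1 / (1/B + 2 N S).

    Equals B when there are no sweeps, and approaches 1/(2 N S) when sweep
    coalescence dominates drift.
    """
    N = np.asarray(N, float)
    if np.any(N < 1):
        raise InvalidArgumentError("N must be >= 1")
    B = bgs_factor(U, L)
    S = sweep_rate(gamma, J, L, form=form)
    out = 1.0 / (1.0 / B + 2.0 * N * S)
    out = np.asarray(out)
    return out[()] if out.ndim else float(out)


def four_alleles_pi(theta):
    """Four-alleles model: pi = theta / (1 + 4 theta / 3), capped at 3/4."""
    theta = np.asarray(theta, float)
    if np.any(theta < 0):
        raise InvalidArgumentError("theta must be >= 0")
    out = theta / (1.0 + 4.0 * theta / 3.0)
    return out[()] if out.ndim else float(out)


def predicted_pi(N_c, mu, params: SelectionParams, L, four_alleles: bool = True):
    """Predicted diversity under BGS + recurrent hitchhiking.

    theta_eff = 4 N mu R(N, U, L, gamma, J) is passed through the
    four-alleles map (disable with ``four_alleles=False`` for raw theta
    work). N is the census size unless ``params.Ne_mode == 'fixed_Ne'``.
    Monotone increasing in N_c, saturating below
    ``four_alleles_pi(2 mu / S)``.
    """
    N_c = np.asarray(N_c, float)
    mu = np.asarray(mu, float)
    if np.any(N_c <= 0) or np.any(mu <= 0):
        raise InvalidArgumentError("N_c and mu must be > 0")
    N = params.fixed_Ne if params.Ne_mode == "fixed_Ne" else N_c
    R = reduction_factor(N, params.U, L, params.gamma, params.J, form=params.sweep_form)
    theta_eff = 4.0 * N * mu * R
    out = four_alleles_pi(theta_eff) if four_alleles else theta_eff
    out = np.asarray(out)
    return out[()] if out.ndim else float(out)


def gamma_from_divergence(alpha_adaptive, m, T_gen):
    """Adaptive substitutions per generation, gamma = alpha * m / (2 T).

    ``m`` counts substitutions accumulated between two species along both
    branches, hence the factor of two in the per-lineage rate.
    """
    if np.any(np.asarray(T_gen) <= 0):
        raise InvalidArgumentError("T_gen must be > 0")
    alpha_adaptive = np.asarray(alpha_adaptive, float)
    if np.any((alpha_adaptive < 0) | (alpha_adaptive > 1)):
        raise InvalidArgumentError("alpha_adaptive must be in [0, 1]")
    out = alpha_adaptive * np.asarray(m, float) / (2.0 * np.asarray(T_gen, float))
    out = np.asarray(out)
    return out[()] if out.ndim else float(out)


def nu_bp(gamma, G):
    """Beneficial substitutions per basepair per generation, nu = gamma / G."""
    if np.any(np.asarray(G) <= 0):
        raise InvalidArgumentError("G must be > 0")
    out = np.asarray(gamma, float) / np.asarray(G, float)
    out = np.asarray(out)
    return out[()] if out.ndim else float(out)


def ne_tilde(pi, mu):
    """Diversity-implied effective population size, Ne = pi / (4 mu)."""
    pi = np.asarray(pi, float)
    mu = np.asarray(mu, float)
    if np.any((pi <= 0) | (pi >= 0.75)):
        raise InvalidArgumentError("pi must be in (0, 0.75)")
    if np.any(mu <= 0):
        raise InvalidArgumentError("mu must be > 0")
    out = pi / (4.0 * mu)
    return out[()] if out.ndim else float(out)


def fst_subpop_het(F_ST, H_T):
    """Subpopulation heterozygosity H_S = (1 - F_ST) H_T."""
    F_ST = np.asarray(F_ST, float)
    H_T = np.asarray(H_T, float)
    if np.any((F_ST < 0) | (F_ST > 1)) or np.any((H_T < 0) | (H_T > 1)):
        raise InvalidArgumentError("F_ST and H_T must be in [0, 1]")
    out = (1.0 - F_ST) * H_T
    return out[()] if out.ndim else float(out)


def prediction_band(
    taxa: pd.DataFrame,
    params: SelectionParams = DROSOPHILA_DEFAULTS,
    n_grid: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-taxon diversity predictions and the pooled envelope over N_c.

    For each taxon with census size and map length, computes B, S, R and the
    predicted diversity at the two mutation-rate bounds. The envelope is the
    raw pointwise min/max of the per-taxon prediction curves over a log10
    N_c grid spanning the observed range (no smoothing; leave that to
    plotting). Taxa with missing map length are skipped and listed.

    Returns
    -------
    (per_taxon, envelope, skipped)
    """
    required = {"species", "N_c", "map_length_M"}
    missing_cols = required - set(taxa.columns)
    if missing_cols:
        raise InvalidArgumentError(f"taxa table missing columns: {sorted(missing_cols)}")
    usable = taxa[taxa["map_length_M"].notna() & taxa["N_c"].notna()]
    skipped = sorted(set(taxa["species"]) - set(usable["species"]))

    rows = []
    for _, row in usable.iterrows():
        N, L = float(row["N_c"]), float(row["map_length_M"])
        Ne = params.fixed_Ne if params.Ne_mode == "fixed_Ne" else N
        rows.append(
            {
                "species": row["species"],
                "B": bgs_factor(params.U, L),
                "S": sweep_rate(params.gamma, params.J, L, form=params.sweep_form),
                "R": reduction_factor(
                    Ne, params.U, L, params.gamma, params.J, form=params.sweep_form
                ),
                "pi_lo": predicted_pi(N, params.mu_lo, params, L),
                "pi_hi": predicted_pi(N, params.mu_hi, params, L),
            }
        )
    per_taxon = pd.DataFrame(rows)

    log_nc = np.log10(usable["N_c"].to_numpy(float))
    grid = np.logspace(log_nc.min(), log_nc.max(), n_grid)
    lo = np.full(n_grid, np.inf)
    hi = np.full(n_grid, -np.inf)
    for L in usable["map_length_M"].to_numpy(float):
        lo = np.minimum(lo, predicted_pi(grid, params.mu_lo, params, L))
        hi = np.maximum(hi, predicted_pi(grid, params.mu_hi, params, L))
    envelope = pd.DataFrame({"N_c": grid, "pi_lo": lo, "pi_hi": hi})
    return per_taxon, envelope, skipped
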