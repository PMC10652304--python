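"""Electrostatic model of oxidation-induced folding destabilization.

A composition-only, screened-Coulomb model of how adding or removing a
single elementary charge (e.g. by carbonylation of a lysine) perturbs a
protein's folding free energy.  The protein is reduced to its counts of
positively charged (Arg, Lys), negatively charged (Asp, Glu) and variably
charged (His) residues and its length ``N``.  Native and denatured net
charges differ only through the histidine protonation fraction; native and
denatured radii of gyration follow Flory power laws in ``N``.  The folding
free-energy change is the difference of Debye-Hueckel self-energy terms of
the two states, in units of kT.

Because the model sees composition only, its output is invariant under any
permutation of the sequence; no structural information enters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProteinRecord, read_fasta

__all__ = [
    "ChargeComposition",
    "ModelConstants",
    "StabilityResult",
    "count_charges",
    "net_charges",
    "flory_radii",
    "delta_delta_g",
    "susceptibility",
    "proteome_map",
]

POSITIVE_RESIDUES = frozenset("RK")
NEGATIVE_RESIDUES = frozenset("DE")
VARIABLE_RESIDUES = frozenset("H")


@dataclass(frozen=True)
class ChargeComposition:
    """Counts of charged residues and total length of one protein."""

    c_positive: int  # Arg + Lys
    c_negative: int  # Asp + Glu
    c_variable: int  # His
    n_residues: int

    def __post_init__(self) -> None:
        if min(self.c_positive, self.c_negative, self.c_variable) < 0:
            raise ValueError("charge counts must be non-negative")
        if self.c_positive + self.c_negative + self.c_variable > self.n_residues:
            raise ValueError("charged residues exceed sequence length")


@dataclass(frozen=True)
class ModelConstants:
    """Physical constants of the screened-Coulomb stability model.

    Defaults emulate cytoplasmic conditions in water near 37 C.  All
    energies are expressed in kT, so temperature never appears explicitly.

    Attributes
    ----------
    bjerrum_length :
        Distance (Angstrom) at which two unit charges interact with
        energy kT.
    inverse_debye :
        Inverse Debye screening length (1/Angstrom) set by the ionic
        strength of the solvent.
    native_his_fraction, denatured_his_fraction :
        Expected protonation (charge) fraction of histidine in the folded
        and unfolded state.
    flory_* :
        Prefactors (Angstrom) and exponents of the Flory scaling laws for
        the native and denatured radii of gyration.
    """

    bjerrum_length: float = 7.13
    inverse_debye: float = 0.03
    native_his_fraction: float = 0.4
    denatured_his_fraction: float = 0.1
    flory_native_prefactor: float = 2.24
    flory_native_exponent: float = 0.392
    flory_denatured_prefactor: float = 1.927
    flory_denatured_exponent: float = 0.598

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value!r}")


DEFAULT_CONSTANTS = ModelConstants()

Aggregation = Literal["mean", "max", "plus", "minus"]


@dataclass(frozen=True)
class StabilityResult:
    """Per-protein output of the stability model (charges in e, radii in A,
    energies in kT)."""

    protein_id: str
    n_residues: int
    q_native: float
    q_denatured: float
    r_native: float
    r_denatured: float
    ddg_plus: float
    ddg_minus: float
    susceptibility: float


def count_charges(sequence: str) -> ChargeComposition:
    """Count charged residues in an amino-acid sequence.

    Case-insensitive.  Ambiguity and non-standard codes (B, Z, X, U, O, *)
    count toward length but carry no charge.
    """
    seq = sequence.upper()
    pos = sum(seq.count(aa) for aa in POSITIVE_RESIDUES)
    neg = sum(seq.count(aa) for aa in NEGATIVE_RESIDUES)
    var = seq.count("H")
    return ChargeComposition(pos, neg, var, len(seq))


def net_charges(
    comp: ChargeComposition, constants: ModelConstants = DEFAULT_CONSTANTS
) -> tuple[float, float]:
    """Native and denatured net charge (Q_n, Q_d) in elementary charges.

    Histidine contributes its expected fractional charge, which differs
    between the folded and unfolded states.
    """
    q_n = comp.c_positive + constants.native_his_fraction * comp.c_variable - comp.c_negative
    q_d = comp.c_positive + constants.denatured_his_fraction * comp.c_variable - comp.c_negative
    return q_n, q_d


def flory_radii(
    n_residues: int | np.ndarray, constants: ModelConstants = DEFAULT_CONSTANTS
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Flory-scaling radii of gyration (R_n, R_d) in Angstrom."""
    n = np.asarray(n_residues, dtype=float)
    if np.any(n < 1):
        raise ValueError("n_residues must be >= 1")
    r_n = constants.flory_native_prefactor * n**constants.flory_native_exponent
    r_d = constants.flory_denatured_prefactor * n**constants.flory_denatured_exponent
    if np.isscalar(n_residues) or np.ndim(n_residues) == 0:
        return float(r_n), float(r_d)
    return r_n, r_d


def _self_energy_term(q: float, r: float, charge_delta: int, constants: ModelConstants) -> float:
    # screened Born-like self-energy change of one state on a +/-1 charge step
    lb, kappa = constants.bjerrum_length, constants.inverse_debye
    return lb * (charge_delta * 2.0 * q + 1.0) / (2.0 * r * (1.0 + kappa * r))


def delta_delta_g(
    q_native: float,
    q_denatured: float,
    r_native: float,
    r_denatured: float,
    charge_delta: int,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Folding free-energy change (kT) on adding (+1) or removing (-1) a charge.

    Computed as the denatured-state self-energy term minus the native-state
    term:

        ddG/kT = I_b (±2 Q_d + 1) / (2 R_d (1 + kappa R_d))
               - I_b (±2 Q_n + 1) / (2 R_n (1 + kappa R_n))

    with the sign of the 2Q term set by ``charge_delta``.
    """
    if charge_delta not in (+1, -1):
        raise ValueError("charge_delta must be +1 or -1")
    if r_native <= 0 or r_denatured <= 0:
        raise ValueError("radii must be positive")
    return _self_energy_term(q_denatured, r_denatured, charge_delta, constants) - _self_energy_term(
        q_native, r_native, charge_delta, constants
    )


def susceptibility(
    record: ProteinRecord | str,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    aggregation: Aggregation = "mean",
) -> StabilityResult:
    """Oxidative-destabilization susceptibility of one protein.

    Evaluates the free-energy change for both a charge gain and a charge
    loss and aggregates their magnitudes (default: mean).  Averaging the
    signed values instead would collapse to a charge-independent constant,
    so magnitudes are the meaningful summary.
    """
    if isinstance(record, str):
        record = ProteinRecord("protein", record)
    if len(record.sequence) == 0:
        raise ValueError("empty sequence")
    comp = count_charges(record.sequence)
    q_n, q_d = net_charges(comp, constants)
    r_n, r_d = flory_radii(comp.n_residues, constants)
    ddg_plus = delta_delta_g(q_n, q_d, r_n, r_d, +1, constants)
    ddg_minus = delta_delta_g(q_n, q_d, r_n, r_d, -1, constants)
    mags = (abs(ddg_plus), abs(ddg_minus))
    if aggregation == "mean":
        susc = float(np.mean(mags))
    elif aggregation == "max":
        susc = float(max(mags))
    elif aggregation == "plus":
        susc = abs(ddg_plus)
    elif aggregation == "minus":
        susc = abs(ddg_minus)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return StabilityResult(
        protein_id=record.protein_id,
        n_residues=comp.n_residues,
        q_native=q_n,
        q_denatured=q_d,
        r_native=r_n,
        r_denatured=r_d,
        ddg_plus=ddg_plus,
        ddg_minus=ddg_minus,
        susceptibility=susc,
    )


def proteome_map(
    fasta: str | Iterable[ProteinRecord],
    constants: ModelConstants = DEFAULT_CONSTANTS,
    aggregation: Aggregation = "mean",
    top_quartile_q: float = 0.75,
) -> pd.DataFrame:
    """Susceptibility map of a whole proteome.

    Parameters
    ----------
    fasta :
        FASTA path or an iterable of records.
    top_quartile_q :
        Quantile of the susceptibility distribution above which a protein
        is flagged ``top_quartile`` (default: upper quartile).

    Returns
    -------
    DataFrame indexed by protein id with columns ``n_residues``,
    ``q_native``, ``q_denatured``, ``r_native``, ``r_denatured``,
    ``ddg_plus``, ``ddg_minus``, ``susceptibility``, ``density`` (Gaussian
    KDE of the (net charge, length) cloud, NaN when degenerate) and the
    boolean ``top_quartile`` flag.  ``df.attrs['density_quartiles']`` holds
    the density levels enclosing quartiles of the proteome mass, usable as
    contour levels.
    """
    records = list(read_fasta(fasta)) if isinstance(fasta, str) else list(fasta)
    if len(records) < 4:
        raise ValueError("need at least 4 records for quartile estimation")
    rows = []
    for rec in records:
        try:
            res = susceptibility(rec, constants, aggregation)
        except ValueError as exc:
            warnings.warn(f"skipping record {rec.protein_id!r}: {exc}", stacklevel=2)
            continue
        rows.append(res)
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("protein_id")
    df = df.sort_index()

    pts = np.vstack([df["q_native"].to_numpy(float), df["n_residues"].to_numpy(float)])
    try:
        kde = stats.gaussian_kde(pts)
        density = kde(pts)
        quartile_levels = np.quantile(density, [0.25, 0.5, 0.75])
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn(
            "degenerate (net charge, length) distribution; density undefined",
            stacklevel=2,
        )
        density = np.full(df.shape[0], np.nan)
        quartile_levels = np.array([np.nan, np.nan, np.nan])
    df["density"] = density

    susc = df["susceptibility"].to_numpy(float)
    if np.ptp(susc) == 0:
        warnings.warn("all susceptibilities identical; top-quartile flag is all-False",
                      stacklevel=2)
        df["top_quartile"] = False
    else:
        df["top_quartile"] = susc > np.quantile(susc, top_quartile_q)
    df.attrs["density_quartiles"] = quartile_levels
    return df
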