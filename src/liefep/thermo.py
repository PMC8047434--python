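"""Physical constants, affinity conversion and model-evaluation statistics.

Everything downstream (LIE predictions, Zwanzig accumulation) works in
kcal/mol, so the thermal energy kT and the gas constant R are carried in
those units.  Experimental inhibition constants Ki (reported in μM) are
converted to binding free energies via ΔG = RT·ln(Ki) with Ki expressed in
mol/L, i.e. the standard-state 1 M reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Molar gas constant in kcal mol^-1 K^-1 (CODATA, 4 significant figures).
GAS_CONSTANT_KCAL = 1.9872e-3

#: Default temperature (K) for Ki -> ΔG conversion of assay data.
DEFAULT_TEMPERATURE = 298.0


class InvalidInputError(ValueError):
    """Raised when an operation receives physically or structurally invalid input."""


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and gas constant defining the thermal energy scale.

    Attributes
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive.
    gas_constant : float
        Gas constant in kcal mol^-1 K^-1.
    """

    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise InvalidInputError(f"temperature must be > 0 K, got {self.temperature}")
        if not (self.gas_constant > 0):
            raise InvalidInputError(f"gas constant must be > 0, got {self.gas_constant}")

    @property
    def kT(self) -> float:
        """Thermal energy RT in kcal/mol."""
        return self.gas_constant * self.temperature


@dataclass
class AffinityRecord:
    """One compound's experimental affinity and calculated binding free energy.

    ``ki`` is in μM; ``censored`` marks assay non-binders whose Ki exceeds
    the detection limit (``ki`` then holds the limit, e.g. 100 for ">100 μM")
    so that ``dg_exp`` is only an upper-affinity bound.
    """

    compound_id: str
    ki: float | None = None
    censored: bool = False
    dg_exp: float | None = None
    dg_calc: float | None = None
    dg_calc_sem: float | None = None


@dataclass
class EvaluationReport:
    """Agreement statistics between calculated and experimental free energies."""

    n_pairs: int
    mue: float
    pearson_r: float | None
    per_pair_errors: list[float] = field(default_factory=list)
    pearson_defined: bool = True


def ki_to_dg(ki_uM: float, thermo: ThermoParams | None = None) -> float:
    """Convert an inhibition constant Ki (μM) to a binding free energy (kcal/mol).

    ΔG = RT ln(Ki / 1 M).  A 1 M Ki maps to 0; tighter binding (smaller Ki)
    gives a more negative ΔG.

    Parameters
    ----------
    ki_uM : float
        Inhibition constant in micromolar. Must be positive.
    thermo : ThermoParams, optional
        Temperature/gas-constant pair; defaults to 298 K.

    Returns
    -------
    float
        Binding free energy in kcal/mol.
    """
    thermo = thermo or ThermoParams()
    if ki_uM is None or not math.isfinite(ki_uM) or ki_uM <= 0:
        raise InvalidInputError(f"Ki must be a positive finite number in μM, got {ki_uM!r}")
    return thermo.kT * math.log(ki_uM * 1e-6)


def mean_sem(values) -> tuple[float, float | None]:
    """Mean and standard error of the mean of a sample.

    SEM uses the sample (ddof=1) standard deviation over sqrt(n); for a
    single observation the SEM is undefined and returned as ``None``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidInputError("mean_sem requires a non-empty 1-D sample")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("mean_sem requires finite values")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, None
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, sem


def evaluate(pairs) -> EvaluationReport:
    """Mean unsigned error and Pearson correlation of (calc, exp) pairs.

    Parameters
    ----------
    pairs : iterable of (float, float)
        Calculated and experimental free energies, censored records already
        excluded by the caller.

    Returns
    -------
    EvaluationReport
        Signed errors are calc − exp. Pearson R is ``None`` (and flagged)
        when either coordinate has zero variance or fewer than two pairs
        are supplied.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("evaluate requires at least one (calc, exp) pair")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidInputError("pairs must be (calc, exp) tuples")
    calc, exp = arr[:, 0], arr[:, 1]
    errors = calc - exp
    mue = float(np.mean(np.abs(errors)))
    r: float | None
    defined = True
    if len(arr) < 2 or np.ptp(calc) == 0 or np.ptp(exp) == 0:
        r, defined = None, False
    else:
        r = float(stats.pearsonr(calc, exp).statistic)
    return EvaluationReport(
        n_pairs=len(arr),
        mue=mue,
        pearson_r=r,
        per_pair_errors=[float(e) for e in errors],
        pearson_defined=defined,
    )


def classify_censored(records: list[AffinityRecord]) -> dict[str, list[str]]:
    """Split censored compounds by whether the calculated ΔG respects the bound.

    A censored record carries ``dg_exp`` as a lower bound on the (algebraic)
    binding free energy: the compound binds *worse* than the bound.  The
    calculation agrees when ``dg_calc >= dg_exp``.
    """
    above, below = [], []
    for rec in records:
        if not rec.censored:
            continue
        if rec.dg_calc is None or rec.dg_exp is None:
            continue
        (above if rec.dg_calc >= rec.dg_exp else below).append(rec.compound_id)
    return {"consistent_with_bound": above, "violates_bound": below}
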