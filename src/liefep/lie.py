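"""Linear interaction energy (LIE) binding-affinity estimation.

The LIE model estimates an absolute binding free energy from the change in
average ligand–surrounding interaction energies between the protein-bound
and water-solvated states:

    ΔG_bind = α·Δ⟨U_vdW⟩ + β·Δ⟨U_el⟩ + γ

α scales the nonpolar (van der Waals) term and is conventionally fixed at
0.18; β scales the polar (electrostatic) term and γ is a constant offset.
In binding sites with strong electrostatics (e.g. a catalytic Zn²⁺), β and
γ are calibrated empirically against a series of measured affinities, which
is what :func:`lie_fit` does.

Uncertainties follow the replicate convention: each state is sampled in
independent replicate simulations, the estimator of ⟨U⟩ is the mean of
per-replicate means, and the SEM is taken across replicate means so that
within-replicate autocorrelation does not bias the error bar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .thermo import InvalidInputError, mean_sem

DEFAULT_ALPHA = 0.18

STATES = ("bound", "free")


class DegenerateFitError(InvalidInputError):
    """Raised when the calibration design matrix is rank deficient."""


@dataclass
class EnergySeries:
    """Per-replicate time series of ligand–surrounding interaction energies.

    One instance holds the van der Waals and electrostatic energy samples of
    a single replicate simulation of one compound in one state ('bound' in
    the protein or 'free' in water), in kcal/mol.
    """

    compound_id: str
    state: str
    replicate_id: int
    u_vdw: np.ndarray
    u_el: np.ndarray

    def __post_init__(self) -> None:
        self.u_vdw = np.asarray(self.u_vdw, dtype=float)
        self.u_el = np.asarray(self.u_el, dtype=float)
        if self.state not in STATES:
            raise InvalidInputError(f"state must be one of {STATES}, got {self.state!r}")
        if self.u_vdw.shape != self.u_el.shape or self.u_vdw.ndim != 1 or self.u_vdw.size < 1:
            raise InvalidInputError("u_vdw and u_el must be equal-length 1-D arrays of length >= 1")
        if not (np.all(np.isfinite(self.u_vdw)) and np.all(np.isfinite(self.u_el))):
            raise InvalidInputError("energy samples must be finite")


@dataclass
class StateDelta:
    """Bound-minus-free interaction-energy differences for one compound."""

    compound_id: str
    d_vdw: float
    d_el: float
    d_vdw_sem: float | None
    d_el_sem: float | None
    n_replicates_bound: int
    n_replicates_free: int


@dataclass
class LIEModel:
    """Calibrated (α, β, γ) coefficient triple.

    ``fixed`` records which coefficients were held constant during
    calibration; ``calibration_ids`` and ``fit_mue`` document provenance.
    """

    alpha: float = DEFAULT_ALPHA
    beta_lie: float = 0.5
    gamma: float = 0.0
    fixed: dict = field(default_factory=lambda: {"alpha": True, "beta_lie": True, "gamma": True})
    calibration_ids: list[str] = field(default_factory=list)
    fit_mue: float | None = None


def _replicate_means(series: Sequence[EnergySeries], state: str, compound_id: str):
    sel = [s for s in series if s.state == state]
    if not sel:
        raise InvalidInputError(f"no replicates supplied for state {state!r}")
    ids = [s.replicate_id for s in sel]
    if len(set(ids)) != len(ids):
        raise InvalidInputError(f"duplicate replicate ids in state {state!r}: {ids}")
    for s in sel:
        if s.compound_id != compound_id:
            raise InvalidInputError(
                f"mixed compound ids: {s.compound_id!r} vs {compound_id!r}"
            )
    vdw = np.array([s.u_vdw.mean() for s in sel])
    el = np.array([s.u_el.mean() for s in sel])
    return vdw, el


def state_delta(bound: Iterable[EnergySeries], free: Iterable[EnergySeries]) -> StateDelta:
    """Bound-minus-free Δ⟨U⟩ for both energy components, with replicate SEMs.

    Per-replicate time averages are computed first; the state average is the
    mean over replicates and the SEM is taken across those replicate means.
    SEMs of the two states combine in quadrature. With a single replicate in
    both states the SEM is undefined (``None``).
    """
    bound = list(bound)
    free = list(free)
    if not bound or not free:
        raise InvalidInputError("need at least one replicate per state")
    compound_id = bound[0].compound_id
    b_vdw, b_el = _replicate_means(bound, "bound", compound_id)
    f_vdw, f_el = _replicate_means(free, "free", compound_id)

    def _delta(b: np.ndarray, f: np.ndarray) -> tuple[float, float | None]:
        mb, sb = mean_sem(b)
        mf, sf = mean_sem(f)
        if sb is None and sf is None:
            sem = None
        else:
            sem = math.hypot(sb or 0.0, sf or 0.0)
        return mb - mf, sem

    d_vdw, s_vdw = _delta(b_vdw, f_vdw)
    d_el, s_el = _delta(b_el, f_el)
    return StateDelta(
        compound_id=compound_id,
        d_vdw=d_vdw,
        d_el=d_el,
        d_vdw_sem=s_vdw,
        d_el_sem=s_el,
        n_replicates_bound=len(bound),
        n_replicates_free=len(free),
    )


def lie_predict(model: LIEModel, delta: StateDelta) -> tuple[float, float | None]:
    """Predict ΔG_bind (kcal/mol) for one compound from its state deltas.

    Returns ``(dg, sem)`` where the SEM propagates the delta uncertainties
    linearly: sqrt(α²·sem_vdW² + β²·sem_el²).
    """
    dg = model.alpha * delta.d_vdw + model.beta_lie * delta.d_el + model.gamma
    if delta.d_vdw_sem is None or delta.d_el_sem is None:
        sem = None
    else:
        sem = math.hypot(model.alpha * delta.d_vdw_sem, model.beta_lie * delta.d_el_sem)
    return dg, sem


def lie_fit(
    deltas: Sequence[StateDelta],
    affinities,
    *,
    alpha: float = DEFAULT_ALPHA,
    fit_alpha: bool = False,
    fit_beta: bool = True,
    fit_gamma: bool = True,
    beta_lie: float = 0.5,
    gamma: float = 0.0,
) -> LIEModel:
    """Least-squares calibration of the free LIE coefficients.

    Censored affinity records are excluded.  The free coefficients among
    (α, β, γ) are chosen to minimize Σ(ΔG_pred − ΔG_exp)²; fixed ones keep
    the supplied value.  Ordinary (unweighted) least squares.

    Parameters
    ----------
    deltas : sequence of StateDelta
        Calibration compounds' interaction-energy differences.
    affinities : mapping or sequence of AffinityRecord
        Experimental ΔG per compound id (censored records dropped).

    Raises
    ------
    DegenerateFitError
        If there are fewer calibration points than free coefficients, or
        the design matrix is rank deficient (e.g. all d_el identical while
        β is free).
    """
    if hasattr(affinities, "items"):
        dg_exp_map = dict(affinities)
    else:
        dg_exp_map = {
            rec.compound_id: rec.dg_exp
            for rec in affinities
            if not rec.censored and rec.dg_exp is not None
        }
    usable = [d for d in deltas if d.compound_id in dg_exp_map]
    if not usable:
        raise InvalidInputError("no uncensored calibration compounds")
    y = np.array([dg_exp_map[d.compound_id] for d in usable], dtype=float)

    cols, names = [], []
    if fit_alpha:
        cols.append(np.array([d.d_vdw for d in usable]))
        names.append("alpha")
    else:
        y = y - alpha * np.array([d.d_vdw for d in usable])
    if fit_beta:
        cols.append(np.array([d.d_el for d in usable]))
        names.append("beta_lie")
    else:
        y = y - beta_lie * np.array([d.d_el for d in usable])
    if fit_gamma:
        cols.append(np.ones(len(usable)))
        names.append("gamma")
    else:
        y = y - gamma

    if not cols:
        raise InvalidInputError("at least one coefficient must be free to fit")
    X = np.column_stack(cols)
    if len(usable) < X.shape[1]:
        raise DegenerateFitError(
            f"{len(usable)} calibration compounds cannot determine {X.shape[1]} coefficients"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateFitError("rank-deficient calibration design (collinear or constant columns)")

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = dict(zip(names, coef))

    model = LIEModel(
        alpha=float(fitted.get("alpha", alpha)),
        beta_lie=float(fitted.get("beta_lie", beta_lie)),
        gamma=float(fitted.get("gamma", gamma)),
        fixed={
            "alpha": not fit_alpha,
            "beta_lie": not fit_beta,
            "gamma": not fit_gamma,
        },
        calibration_ids=[d.compound_id for d in usable],
    )
    preds = np.array([lie_predict(model, d)[0] for d in usable])
    model.fit_mue = float(np.mean(np.abs(preds - np.array([dg_exp_map[d.compound_id] for d in usable]))))
    return model
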