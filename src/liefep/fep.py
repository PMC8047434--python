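"""Free-energy perturbation: Zwanzig accumulation, legs, cycles, diagnostics.

An alchemical transformation A→B is discretized into λ-windows with
potentials U_λ = (1−λ)·U_A + λ·U_B.  The free-energy increment between
neighboring windows is estimated by exponential averaging (Zwanzig):

    δG(m → m+1) = −kT · ln ⟨ exp(−(U_{m+1} − U_m)/kT) ⟩_m

and the leg free energy is the sum of increments over windows and stages
("subperturbations": e.g. charge annihilation, soft-core switching for a
residue mutation).  Relative binding free energies come from the usual
thermodynamic cycle, ΔΔG = ΔG_bound(A→B) − ΔG_free(A→B) for ligand
transformations and ΔG_holo − ΔG_apo for receptor mutations.

Convergence diagnostics: per-stage hysteresis is the absolute discrepancy
between forward (A→B) and reverse (B→A) accumulation of the same stage;
cycle closure is the signed sum of ΔΔG edges around a closed cycle of
transformations, zero for exact free energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .thermo import InvalidInputError, ThermoParams, mean_sem

#: Default number of λ-windows (uniform schedule including both endpoints).
DEFAULT_N_WINDOWS = 51

#: Documented stage-count range for residue side-chain annihilation paths.
RESIDUE_STAGE_RANGE = (4, 11)


class IncompleteLegError(InvalidInputError):
    """A window lacks gap samples in the requested accumulation direction."""


class InvalidCycleError(InvalidInputError):
    """Edge set does not form a single closed cycle."""


def lambda_schedule(n_windows: int = DEFAULT_N_WINDOWS) -> np.ndarray:
    """Uniformly spaced λ values in [0, 1], endpoints included."""
    if n_windows < 2:
        raise InvalidInputError("need at least 2 windows")
    return np.linspace(0.0, 1.0, n_windows)


@dataclass
class FEPWindow:
    """Energy-gap samples collected at one λ-window.

    ``gaps_forward`` holds samples of U_{m+1} − U_m (absent on the last
    window of a stage); ``gaps_reverse`` holds U_{m−1} − U_m (absent on the
    first).
    """

    lambda_m: float
    gaps_forward: np.ndarray | None = None
    gaps_reverse: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda_m <= 1.0):
            raise InvalidInputError(f"lambda must lie in [0, 1], got {self.lambda_m}")
        for attr in ("gaps_forward", "gaps_reverse"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size == 0:
                    raise InvalidInputError(f"{attr} present but empty")
                if not np.all(np.isfinite(v)):
                    raise InvalidInputError(f"{attr} contains non-finite samples")
                setattr(self, attr, v)


@dataclass
class Subperturbation:
    """One ordered stage of λ-windows (λ running 0 → 1)."""

    label: str
    windows: list[FEPWindow]

    def __post_init__(self) -> None:
        lams = [w.lambda_m for w in self.windows]
        if len(lams) < 2:
            raise InvalidInputError(f"stage {self.label!r} needs >= 2 windows")
        if any(b <= a for a, b in zip(lams, lams[1:])):
            raise InvalidInputError(f"stage {self.label!r}: λ values must be strictly increasing")
        if lams[0] != 0.0 or lams[-1] != 1.0:
            raise InvalidInputError(f"stage {self.label!r}: λ must start at 0 and end at 1")


@dataclass
class FEPLeg:
    """All stages of one transformation in one environment and replicate."""

    transformation_id: str
    environment: str
    replicate_id: int
    subperturbations: list[Subperturbation]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.subperturbations]
        if len(set(labels)) != len(labels):
            raise InvalidInputError(f"duplicate stage labels in leg: {labels}")
        if not labels:
            raise InvalidInputError("leg has no subperturbations")


@dataclass
class TransformationResult:
    """A ΔΔG edge of a thermodynamic cycle, with uncertainty and diagnostics.

    Sign convention: ddg is B − A (destabilizing transformations positive).
    """

    a_label: str
    b_label: str
    ddg: float
    ddg_sem: float | None = None
    hysteresis_total: float | None = None
    per_stage_hysteresis: dict | None = None
    compound_id: str | None = None

    def __post_init__(self) -> None:
        if self.ddg_sem is not None and self.ddg_sem < 0:
            raise InvalidInputError("SEM must be non-negative")
        if self.hysteresis_total is not None and self.hysteresis_total < 0:
            raise InvalidInputError("hysteresis must be non-negative")


@dataclass
class MutationResult:
    """Combined wt→mut binding shift obtained via the shared Ala intermediate."""

    position: str
    wt_to_ala: float
    mut_to_ala: float
    combined_wt_to_mut: float
    combined_sem: float | None = None
    compound_id: str | None = None


def zwanzig_increment(gaps, thermo: ThermoParams) -> float:
    """Free-energy increment −kT·ln⟨exp(−ΔU/kT)⟩ from energy-gap samples.

    Evaluated with a log-sum-exp so that large |ΔU|/kT cannot overflow.
    """
    arr = np.asarray(gaps, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidInputError("zwanzig_increment requires a non-empty 1-D sample")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("energy gaps must be finite")
    kT = thermo.kT
    # -kT * [logsumexp(-ΔU/kT) - log n]
    return float(-kT * (logsumexp(-arr / kT) - math.log(arr.size)))


def accumulate_leg(leg: FEPLeg, thermo: ThermoParams, direction: str = "forward") -> float:
    """Total leg free energy on the A→B scale, accumulated in one direction.

    Forward accumulation sums Zwanzig increments over each window's forward
    gaps; reverse accumulation estimates the B→A free energy from the
    reverse gaps and returns its negative, so both directions report on the
    A→B scale and agree exactly for noiseless gaps.
    """
    if direction not in ("forward", "reverse"):
        raise InvalidInputError(f"direction must be 'forward' or 'reverse', got {direction!r}")
    total = 0.0
    for stage in leg.subperturbations:
        total += _stage_dg(stage, thermo, direction)
    return total


def _stage_dg(stage: Subperturbation, thermo: ThermoParams, direction: str) -> float:
    """Stage ΔG on the A→B scale for one accumulation direction."""
    if direction == "forward":
        dg = 0.0
        for w in stage.windows[:-1]:
            if w.gaps_forward is None:
                raise IncompleteLegError(
                    f"stage {stage.label!r}: window λ={w.lambda_m} has no forward gaps"
                )
            dg += zwanzig_increment(w.gaps_forward, thermo)
        return dg
    # reverse: accumulate B→A over reverse gaps, report as A→B
    dg_ba = 0.0
    for w in stage.windows[1:]:
        if w.gaps_reverse is None:
            raise IncompleteLegError(
                f"stage {stage.label!r}: window λ={w.lambda_m} has no reverse gaps"
            )
        dg_ba += zwanzig_increment(w.gaps_reverse, thermo)
    return -dg_ba


def hysteresis(leg: FEPLeg, thermo: ThermoParams) -> tuple[dict, float]:
    """Per-stage and total forward/reverse discrepancy of a leg.

    Each stage contributes |ΔG_forward(A→B) + ΔG_reverse(B→A)|; the total is
    the sum over stages.  Zero for perfectly converged (noiseless) sampling.
    """
    per_stage: dict[str, float] = {}
    for stage in leg.subperturbations:
        fwd = _stage_dg(stage, thermo, "forward")
        rev_ab = _stage_dg(stage, thermo, "reverse")  # = -(B→A)
        per_stage[stage.label] = abs(fwd - rev_ab)
    return per_stage, sum(per_stage.values())


def _env_stats(dgs) -> tuple[float, float | None, int]:
    vals = list(dgs)
    if not vals:
        raise InvalidInputError("empty replicate set")
    mean, sem = mean_sem(vals)
    return mean, sem, len(vals)


def _combine(a_label: str, b_label: str, plus_dgs, minus_dgs, **kw) -> TransformationResult:
    m_plus, s_plus, _ = _env_stats(plus_dgs)
    m_minus, s_minus, _ = _env_stats(minus_dgs)
    if s_plus is None or s_minus is None:
        sem = None
    else:
        sem = math.hypot(s_plus, s_minus)
    return TransformationResult(a_label=a_label, b_label=b_label,
                                ddg=m_plus - m_minus, ddg_sem=sem, **kw)


def relative_binding(a_label: str, b_label: str, bound_dgs, free_dgs) -> TransformationResult:
    """Relative binding free energy ΔΔG = ⟨ΔG_bound⟩ − ⟨ΔG_free⟩ over replicates.

    ``bound_dgs`` / ``free_dgs`` are per-replicate accumulated A→B leg free
    energies; SEMs combine in quadrature.
    """
    return _combine(a_label, b_label, bound_dgs, free_dgs)


def residue_ddg(position_a: str, position_b: str, holo_dgs, apo_dgs,
                compound_id: str | None = None) -> TransformationResult:
    """Binding shift of a receptor mutation: ΔΔG = ⟨ΔG_holo⟩ − ⟨ΔG_apo⟩.

    Positive values mean the mutation destabilizes ligand binding.
    """
    return _combine(position_a, position_b, holo_dgs, apo_dgs, compound_id=compound_id)


def combine_mutation_cycles(wt_to_ala: TransformationResult,
                            mut_to_ala: TransformationResult) -> MutationResult:
    """Join two Ala-intermediate cycles into a direct wt→mut binding shift.

    Both inputs must annihilate to the same alanine intermediate (same
    b_label) for the same ligand; then

        ΔΔG(wt→mut) = ΔΔG(wt→Ala) − ΔΔG(mut→Ala)

    with SEMs combined in quadrature.
    """
    if wt_to_ala.b_label != mut_to_ala.b_label:
        raise InvalidInputError(
            f"cycles do not share an intermediate: {wt_to_ala.b_label!r} vs {mut_to_ala.b_label!r}"
        )
    if (wt_to_ala.compound_id is not None and mut_to_ala.compound_id is not None
            and wt_to_ala.compound_id != mut_to_ala.compound_id):
        raise InvalidInputError(
            f"cycles refer to different ligands: {wt_to_ala.compound_id!r} vs {mut_to_ala.compound_id!r}"
        )
    ddg = wt_to_ala.ddg - mut_to_ala.ddg
    if wt_to_ala.ddg_sem is None or mut_to_ala.ddg_sem is None:
        sem = None
    else:
        sem = math.hypot(wt_to_ala.ddg_sem, mut_to_ala.ddg_sem)
    return MutationResult(
        position=wt_to_ala.b_label,
        wt_to_ala=wt_to_ala.ddg,
        mut_to_ala=mut_to_ala.ddg,
        combined_wt_to_mut=ddg,
        combined_sem=sem,
        compound_id=wt_to_ala.compound_id or mut_to_ala.compound_id,
    )


def cycle_closure(edges: Sequence[TransformationResult]) -> float:
    """Signed sum of ΔΔG around a single closed cycle of transformations.

    Edge orientation is resolved from the labels: traversing an edge along
    its A→B direction adds +ddg, against it adds −ddg.  The traversal starts
    at the first edge's A node and follows its stated direction, so the
    returned sign is reproducible for a given edge order.

    Raises
    ------
    InvalidCycleError
        If the edges do not form exactly one closed cycle (open paths,
        branches, or disconnected components).
    """
    if len(edges) < 2:
        raise InvalidCycleError("a cycle needs at least 2 edges")
    adj: dict[str, list[tuple[int, str]]] = {}
    for i, e in enumerate(edges):
        if e.a_label == e.b_label:
            raise InvalidCycleError(f"self-loop edge {e.a_label}->{e.b_label}")
        adj.setdefault(e.a_label, []).append((i, e.b_label))
        adj.setdefault(e.b_label, []).append((i, e.a_label))
    if len(adj) != len(edges):
        raise InvalidCycleError(
            f"{len(edges)} edges over {len(adj)} nodes do not form a single cycle"
        )
    for node, nbrs in adj.items():
        if len(nbrs) != 2:
            raise InvalidCycleError(f"node {node!r} has degree {len(nbrs)}, expected 2")

    start = edges[0].a_label
    total = 0.0
    node = start
    used: set[int] = set()
    for _ in range(len(edges)):
        nxt = next(((i, other) for i, other in adj[node] if i not in used), None)
        if nxt is None:
            raise InvalidCycleError("disconnected edge set")
        i, other = nxt
        used.add(i)
        total += edges[i].ddg if edges[i].a_label == node else -edges[i].ddg
        node = other
    if node != start or len(used) != len(edges):
        raise InvalidCycleError("edges do not close into a single cycle")
    return total


def check_residue_stage_count(leg_or_n) -> bool:
    """Whether a residue-mutation leg's stage count lies in the documented 4–11 range."""
    n = leg_or_n if isinstance(leg_or_n, int) else len(leg_or_n.subperturbations)
    lo, hi = RESIDUE_STAGE_RANGE
    return lo <= n <= hi
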