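"""Synthetic fixtures with exactly known ground truth.

Three generators stand in for the molecular-dynamics sampling that real
LIE/FEP studies consume, each with a closed-form answer the estimators must
recover:

* :func:`gen_lie_series` — stationary AR(1) interaction-energy time series
  with replicate structure, whose population means (hence the true LIE ΔG)
  are specified exactly;
* :func:`gen_gaussian_gaps` — i.i.d. Gaussian energy-gap windows, for which
  Zwanzig's exponential average has the closed form
  δG = μ − σ²/(2kT) per window;
* :func:`metropolis_sample` — a Metropolis chain on λ-coupled harmonic
  potentials U_λ = (1−λ)U_A + λU_B, whose free-energy difference is
  ΔA = (kT/2)·ln(k_B/k_A) independent of the minima positions;
* :func:`gen_cycle_dataset` — ΔΔG edges derived from per-ligand true free
  energies plus Gaussian noise, so every closed cycle closes exactly at
  zero noise.

All generators derive per-compound / per-window child streams from one root
seed via ``numpy.random.SeedSequence.spawn``, so generation order cannot
change the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fep import FEPLeg, FEPWindow, Subperturbation, TransformationResult, lambda_schedule
from .lie import DEFAULT_ALPHA, EnergySeries
from .thermo import AffinityRecord, InvalidInputError, ThermoParams


class InvalidSpecError(InvalidInputError):
    """Raised when a synthetic-data specification is inconsistent."""


# ---------------------------------------------------------------------------
# LIE interaction-energy series


@dataclass
class LIESyntheticSpec:
    """Ground truth for a synthetic LIE calibration set.

    ``compounds`` maps compound id -> (true d_vdw, true d_el) in kcal/mol;
    the true model (alpha, beta_lie, gamma) converts them to binding free
    energies.  Energy samples are stationary AR(1) with marginal standard
    deviation ``sample_noise_sd`` and lag-1 autocorrelation ``phi``
    (MD interaction energies are strongly autocorrelated).  Experimental
    affinities carry independent Gaussian scatter ``affinity_noise_sd``.
    """

    compounds: Mapping[str, tuple[float, float]]
    alpha: float = DEFAULT_ALPHA
    beta_lie: float = 0.4
    gamma: float = -2.0
    sample_noise_sd: float = 2.0
    phi: float = 0.9
    affinity_noise_sd: float = 0.0
    n_replicates: int = 10
    samples_per_replicate: int = 2000
    free_baseline: tuple[float, float] = (-15.0, -40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_noise_sd < 0 or self.affinity_noise_sd < 0:
            raise InvalidSpecError("noise standard deviations must be >= 0")
        if not (0 <= abs(self.phi) < 1):
            raise InvalidSpecError(f"AR(1) coefficient must satisfy |phi| < 1, got {self.phi}")
        if self.n_replicates < 1 or self.samples_per_replicate < 1:
            raise InvalidSpecError("need >= 1 replicate and >= 1 sample per replicate")

    def true_dg(self, compound_id: str) -> float:
        d_vdw, d_el = self.compounds[compound_id]
        return self.alpha * d_vdw + self.beta_lie * d_el + self.gamma


def _ar1(rng: np.random.Generator, mean: float, sd: float, phi: float, n: int) -> np.ndarray:
    """Stationary AR(1) series with marginal N(mean, sd^2)."""
    if sd == 0:
        return np.full(n, mean)
    x = np.empty(n)
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    x[0] = rng.normal(mean, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = mean + phi * (x[t - 1] - mean) + eps[t - 1]
    return x


def gen_lie_series(
    spec: LIESyntheticSpec, thermo: ThermoParams | None = None
) -> tuple[list[EnergySeries], list[AffinityRecord]]:
    """Generate replicate energy series plus ground-truth affinity records.

    Returns all bound and free replicates for every compound, and one
    :class:`AffinityRecord` per compound whose ``dg_exp`` is the true model
    ΔG (plus ``affinity_noise_sd`` scatter) and whose Ki is the exact
    inverse of the ΔG conversion at ``thermo``.
    """
    thermo = thermo or ThermoParams()
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(spec.compounds))
    series: list[EnergySeries] = []
    records: list[AffinityRecord] = []
    for (cid, (d_vdw, d_el)), child in zip(spec.compounds.items(), children):
        rng = np.random.default_rng(child)
        means = {
            "free": spec.free_baseline,
            "bound": (spec.free_baseline[0] + d_vdw, spec.free_baseline[1] + d_el),
        }
        for state in ("bound", "free"):
            m_vdw, m_el = means[state]
            for rep in range(spec.n_replicates):
                series.append(
                    EnergySeries(
                        compound_id=cid,
                        state=state,
                        replicate_id=rep,
                        u_vdw=_ar1(rng, m_vdw, spec.sample_noise_sd, spec.phi,
                                   spec.samples_per_replicate),
                        u_el=_ar1(rng, m_el, spec.sample_noise_sd, spec.phi,
                                  spec.samples_per_replicate),
                    )
                )
        dg = spec.true_dg(cid)
        if spec.affinity_noise_sd > 0:
            dg = dg + rng.normal(0.0, spec.affinity_noise_sd)
        ki_uM = math.exp(dg / thermo.kT) * 1e6
        records.append(AffinityRecord(compound_id=cid, ki=ki_uM, censored=False, dg_exp=dg))
    return series, records


# ---------------------------------------------------------------------------
# Gaussian energy-gap windows


@dataclass
class GaussianGapSpec:
    """Per-transition Gaussian gap distributions with known exact ΔG.

    ``mu``/``sigma`` give the mean and sd of the forward gap U_{m+1} − U_m
    sampled in state m, one entry per transition.  The implied exact free
    energy is Σ(μ − σ²/(2kT)).
    """

    mu: Sequence[float]
    sigma: Sequence[float]
    n_samples: int = 1000
    kT: float = 0.5925
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 1 or self.mu.size == 0:
            raise InvalidSpecError("mu and sigma must be equal-length non-empty vectors")
        if np.any(self.sigma < 0):
            raise InvalidSpecError("sigma must be >= 0")
        if self.n_samples < 1 or self.kT <= 0:
            raise InvalidSpecError("need n_samples >= 1 and kT > 0")

    @property
    def exact_dg(self) -> float:
        """Closed-form Zwanzig limit Σ(μ_m − σ_m²/(2kT))."""
        return float(np.sum(self.mu - self.sigma**2 / (2.0 * self.kT)))


def gen_gaussian_gaps(spec: GaussianGapSpec) -> tuple[list[FEPWindow], float]:
    """Draw i.i.d. gap samples for every window; return windows and exact ΔG.

    Reverse gaps are drawn from the conjugate distribution: if the forward
    gap in state m is N(μ, σ²), the same gap sampled in state m+1 is
    N(μ − σ²/kT, σ²), so the reverse gap (its negative) is N(σ²/kT − μ, σ²).
    This makes reverse accumulation consistent with −ΔG(B→A) = ΔG(A→B) and
    hysteresis vanish in expectation.
    """
    n_trans = len(spec.mu)
    lams = lambda_schedule(n_trans + 1)
    streams = np.random.SeedSequence(spec.seed).spawn(n_trans)
    fwd = [None] * (n_trans + 1)
    rev = [None] * (n_trans + 1)
    for m, child in enumerate(streams):
        rng = np.random.default_rng(child)
        mu, sig = float(spec.mu[m]), float(spec.sigma[m])
        fwd[m] = rng.normal(mu, sig, spec.n_samples) if sig > 0 else np.full(spec.n_samples, mu)
        rev_mu = sig**2 / spec.kT - mu
        rev[m + 1] = (rng.normal(rev_mu, sig, spec.n_samples) if sig > 0
                      else np.full(spec.n_samples, rev_mu))
    windows = [
        FEPWindow(lambda_m=float(lams[m]), gaps_forward=fwd[m], gaps_reverse=rev[m])
        for m in range(n_trans + 1)
    ]
    return windows, spec.exact_dg


# ---------------------------------------------------------------------------
# Metropolis-sampled harmonic λ-path


@dataclass
class HarmonicPathSpec:
    """λ-coupled harmonic oscillators A and B with analytic ΔA.

    U_A = k_A/2 (x − x_A)², U_B = k_B/2 (x − x_B)²; the mixed potential is
    U_λ = (1−λ)U_A + λU_B.  The classical configurational free-energy
    difference is ΔA = (kT/2)·ln(k_B/k_A), independent of x_A and x_B.
    Units: k in kcal/mol/Å², x in Å, kT in kcal/mol.
    """

    k_A: float = 1.0
    k_B: float = 4.0
    x_A: float = 0.0
    x_B: float = 0.0
    kT: float = 0.596
    n_windows: int = 51
    samples_per_window: int = 5000
    mc_step_size: float = 1.0
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_A <= 0 or self.k_B <= 0:
            raise InvalidSpecError("force constants must be > 0")
        if self.mc_step_size <= 0:
            raise InvalidSpecError("Metropolis step size must be > 0")
        if self.n_windows < 2 or self.samples_per_window < 1 or self.burn_in < 0:
            raise InvalidSpecError("invalid window/sample counts")
        if self.kT <= 0:
            raise InvalidSpecError("kT must be > 0")

    @property
    def exact_dg(self) -> float:
        """Analytic ΔA = (kT/2)·ln(k_B/k_A)."""
        return 0.5 * self.kT * math.log(self.k_B / self.k_A)

    def potential(self, lam: float, x: np.ndarray | float):
        ua = 0.5 * self.k_A * (x - self.x_A) ** 2
        ub = 0.5 * self.k_B * (x - self.x_B) ** 2
        return (1.0 - lam) * ua + lam * ub


def _metropolis_chain(spec: HarmonicPathSpec, lam: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Sample the λ-window potential; returns (positions, acceptance rate)."""
    k_eff = (1 - lam) * spec.k_A + lam * spec.k_B
    x = ((1 - lam) * spec.k_A * spec.x_A + lam * spec.k_B * spec.x_B) / k_eff
    u = spec.potential(lam, x)
    n_total = spec.burn_in + spec.samples_per_window
    steps = rng.uniform(-spec.mc_step_size, spec.mc_step_size, n_total)
    log_u = np.log(rng.uniform(size=n_total))
    xs = np.empty(spec.samples_per_window)
    accepted = 0
    for i in range(n_total):
        x_new = x + steps[i]
        u_new = spec.potential(lam, x_new)
        if (u - u_new) / spec.kT > log_u[i]:
            x, u = x_new, u_new
            accepted += 1
        if i >= spec.burn_in:
            xs[i - spec.burn_in] = x
    return xs, accepted / n_total


def metropolis_sample(spec: HarmonicPathSpec) -> tuple[FEPLeg, dict]:
    """Metropolis-sample every λ-window of the harmonic path into a FEP leg.

    At each window the chain equilibrates for ``burn_in`` steps, then
    records forward and reverse energy gaps to the neighboring windows for
    every retained position.  Returns the leg (single stage labelled
    ``harmonic``) and an info dict with per-window acceptance rates and
    sampled positions.
    """
    lams = lambda_schedule(spec.n_windows)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_windows)
    windows: list[FEPWindow] = []
    acceptance: list[float] = []
    positions: list[np.ndarray] = []
    for m, (lam, child) in enumerate(zip(lams, streams)):
        xs, acc = _metropolis_chain(spec, float(lam), np.random.default_rng(child))
        acceptance.append(acc)
        positions.append(xs)
        u_here = spec.potential(float(lam), xs)
        fwd = spec.potential(float(lams[m + 1]), xs) - u_here if m + 1 < spec.n_windows else None
        rev = spec.potential(float(lams[m - 1]), xs) - u_here if m > 0 else None
        windows.append(FEPWindow(lambda_m=float(lam), gaps_forward=fwd, gaps_reverse=rev))
    leg = FEPLeg(
        transformation_id=f"harmonic:{spec.k_A}->{spec.k_B}",
        environment="model",
        replicate_id=0,
        subperturbations=[Subperturbation(label="harmonic", windows=windows)],
    )
    return leg, {"acceptance": acceptance, "positions": positions}


# ---------------------------------------------------------------------------
# Cycle datasets


def gen_cycle_dataset(
    true_dg: Mapping[str, float],
    edges: Sequence[tuple[str, str]],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[TransformationResult]:
    """ΔΔG edges consistent with per-ligand true free energies, plus noise.

    Each directed edge (a, b) gets ddg = ΔG(b) − ΔG(a) + N(0, noise_sd).
    At zero noise every closed cycle over these edges closes exactly.
    """
    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be >= 0")
    for a, b in edges:
        if a not in true_dg or b not in true_dg:
            raise InvalidSpecError(f"edge ({a}, {b}) references unknown ligand labels")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = []
    for a, b in edges:
        ddg = true_dg[b] - true_dg[a]
        if noise_sd > 0:
            ddg += rng.normal(0.0, noise_sd)
        out.append(TransformationResult(a_label=a, b_label=b, ddg=float(ddg),
                                        ddg_sem=noise_sd if noise_sd > 0 else 0.0))
    return out
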