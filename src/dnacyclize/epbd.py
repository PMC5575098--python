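"""Nonlinear-lattice model of DNA breathing and its Metropolis sampler.

The double helix is represented as a quasi-two-dimensional lattice: base pair
``n`` carries two transverse displacements, ``u_n`` (right strand) and ``v_n``
(left strand), measuring hydrogen-bond stretch away from equilibrium.  The
potential is

    V = sum_n  U(u_n, v_n) + W(u_{n-1}, u_n; v_{n-1}, v_n)

with a Morse on-site term U = D_n (exp(-a_n (u_n - v_n)) - 1)^2 combining the
hydrogen bonding and backbone electrostatics of the pair (two hydrogen bonds
for A:T, three for G:C, hence D and a come in two base-pair classes), and a
quasi-harmonic stacking term

    W = K_u/2 (u_n - u_{n-1})^2 + K_v/2 (v_n - v_{n-1})^2
        + rho/4 exp(-beta [ (u_n - v_n) + (u_{n-1} - v_{n-1}) ])
          ( sqrt(K_u) (u_n - u_{n-1}) - sqrt(K_v) (v_n - v_{n-1}) )^2

whose anharmonic factor weakens stacking once either neighbour leaves the
stack.  The stacking constants may depend on the dinucleotide and on the
strand.  The lattice is periodic (site 1 stacks on site N), consistent with
the ring topology used by the chain model.

A base pair is *open* when its stretch y_n = u_n - v_n exceeds a threshold
(2.5 Å by default, the local-melting criterion); the Metropolis sampler
estimates the per-base-pair probability of that event, which downstream
becomes the probability that the base pair acts as a single-stranded hinge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import _kernels
from .params_io import (
    ALPHABET,
    BOLTZMANN_EV,
    COMPLEMENT,
    DNASequence,
    OpeningProfile,
)

__all__ = [
    "EPBDParameters",
    "MCMCSettings",
    "LatticeState",
    "morse_energy",
    "stacking_energy",
    "total_potential",
    "metropolis_sweep",
    "sample_opening_profile",
    "set_mismatch",
]

ALL_DINUCLEOTIDES = tuple(a + b for a in ALPHABET for b in ALPHABET)

#: Classic lattice-model constants (eV, Å).  The dinucleotide stacking table
#: defaults to a uniform 0.025 eV/Å²; sequence-dependent tables fitted to
#: melting data can be supplied via :meth:`EPBDParameters.from_yaml`.
_DEFAULT_D = {"AT": 0.05, "GC": 0.075}
_DEFAULT_A = {"AT": 4.2, "GC": 6.9}
_DEFAULT_K = 0.025


def _pair_class(base: str) -> str:
    return "AT" if base in "AT" else "GC"


@dataclass(frozen=True)
class EPBDParameters:
    """Potential parameters.

    ``morse_d`` / ``morse_a`` map the base-pair class (``"AT"``/``"GC"``) to
    the Morse depth (eV) and inverse width (1/Å).  ``stack_k`` maps each of
    the 16 dinucleotides to a stacking constant (eV/Å²); the right-strand
    constant of the bond entering site ``n`` is looked up with the sequence
    dinucleotide ``(n-1, n)`` and the left-strand one with its complement
    read along the opposite strand.  ``rho`` (dimensionless) and ``beta_anh``
    (1/Å) control the anharmonic stacking barrier.
    """

    morse_d: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_D))
    morse_a: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_A))
    stack_k: Mapping[str, float] = field(
        default_factory=lambda: {d: _DEFAULT_K for d in ALL_DINUCLEOTIDES}
    )
    rho: float = 2.0
    beta_anh: float = 0.35

    def __post_init__(self) -> None:
        for cls in ("AT", "GC"):
            if self.morse_d.get(cls, 0.0) <= 0 or self.morse_a.get(cls, 0.0) <= 0:
                raise ValueError(f"Morse parameters for {cls} must be positive")
        if self.morse_d["GC"] <= self.morse_d["AT"]:
            raise ValueError("G:C pairs must bind more strongly than A:T (D_GC > D_AT)")
        missing = [d for d in ALL_DINUCLEOTIDES if d not in self.stack_k]
        if missing:
            raise ValueError(f"stacking table missing dinucleotides: {missing}")
        if any(self.stack_k[d] <= 0 for d in ALL_DINUCLEOTIDES):
            raise ValueError("stacking constants must be positive")
        if self.rho < 0 or self.beta_anh <= 0:
            raise ValueError("need rho >= 0 and beta_anh > 0")

    # -- per-sequence parameter vectors ------------------------------------
    def site_arrays(self, bases: str) -> tuple[np.ndarray, np.ndarray]:
        """Morse (D, a) per site."""
        d = np.array([self.morse_d[_pair_class(b)] for b in bases])
        a = np.array([self.morse_a[_pair_class(b)] for b in bases])
        return d, a

    def bond_arrays(self, bases: str) -> tuple[np.ndarray, np.ndarray]:
        """Stacking constants (K_u, K_v) for the periodic bond entering each
        site: bond ``n`` couples sites ``n-1`` and ``n`` (0-based, cyclic)."""
        n = len(bases)
        ku = np.empty(n)
        kv = np.empty(n)
        for j in range(n):
            prev = bases[(j - 1) % n]
            cur = bases[j]
            ku[j] = self.stack_k[prev + cur]
            # the left strand runs antiparallel: same bond read 5'->3' on the
            # complementary strand
            kv[j] = self.stack_k[COMPLEMENT[cur] + COMPLEMENT[prev]]
        return ku, kv

    # -- config round-trip --------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "EPBDParameters":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = {}
        if "morse_d" in raw:
            kwargs["morse_d"] = {k.upper(): float(v) for k, v in raw["morse_d"].items()}
        if "morse_a" in raw:
            kwargs["morse_a"] = {k.upper(): float(v) for k, v in raw["morse_a"].items()}
        if "stack_k" in raw:
            base = {d: _DEFAULT_K for d in ALL_DINUCLEOTIDES}
            base.update({k.upper(): float(v) for k, v in raw["stack_k"].items()})
            kwargs["stack_k"] = base
        for key in ("rho", "beta_anh"):
            if key in raw:
                kwargs[key] = float(raw[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "morse_d": dict(self.morse_d),
            "morse_a": dict(self.morse_a),
            "stack_k": dict(self.stack_k),
            "rho": self.rho,
            "beta_anh": self.beta_anh,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler schedule and physical settings.

    ``proposal_width`` is the half-width (Å) of the symmetric uniform
    single-site displacement proposal; ``y_max`` caps the pair stretch so the
    flat dissociated plateau of the Morse potential cannot host unbounded
    drift.  ``opening_threshold`` is the stretch (Å) beyond which a base pair
    counts as locally melted.
    """

    temperature: float = 300.0
    n_equilibration: int = 2_000
    n_sampling: int = 20_000
    proposal_width: float = 0.3
    thinning: int = 2
    seed: int = 0
    opening_threshold: float = 2.5
    y_max: float = 50.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_equilibration < 0 or self.n_sampling <= 0 or self.thinning <= 0:
            raise ValueError("sweep counts must be positive")
        if self.proposal_width <= 0 or self.opening_threshold <= 0 or self.y_max <= 0:
            raise ValueError("widths and thresholds must be positive")


@dataclass
class LatticeState:
    """Strand displacements (Å) for all base pairs."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float).copy()
        self.v = np.asarray(self.v, dtype=float).copy()
        if self.u.shape != self.v.shape or self.u.ndim != 1:
            raise ValueError("u and v must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("displacements must be finite")

    @classmethod
    def zeros(cls, n: int) -> "LatticeState":
        return cls(np.zeros(n), np.zeros(n))

    @property
    def stretch(self) -> np.ndarray:
        return self.u - self.v


def _bases_of(seq: DNASequence | str) -> str:
    return seq.bases if isinstance(seq, DNASequence) else str(seq).upper()


# ---------------------------------------------------------------------------
# Energies


def morse_energy(u_n: float, v_n: float, d_n: float, a_n: float) -> float:
    """On-site Morse energy D (exp(-a y) - 1)^2 with y = u_n - v_n."""
    e = np.expm1(-a_n * (u_n - v_n))
    return d_n * e * e


def stacking_energy(
    u_prev: float,
    u_n: float,
    v_prev: float,
    v_n: float,
    k_u: float,
    k_v: float,
    rho: float,
    beta_anh: float,
) -> float:
    """Quasi-harmonic stacking energy of one inter-base-pair bond."""
    du = u_n - u_prev
    dv = v_n - v_prev
    cross = np.sqrt(k_u) * du - np.sqrt(k_v) * dv
    anh = 0.25 * rho * np.exp(-beta_anh * ((u_n - v_n) + (u_prev - v_prev)))
    return 0.5 * k_u * du * du + 0.5 * k_v * dv * dv + anh * cross * cross


def total_potential(
    state: LatticeState, seq: DNASequence | str, params: EPBDParameters
) -> float:
    """Lattice potential: sum of Morse terms and periodic stacking bonds."""
    bases = _bases_of(seq)
    n = len(bases)
    if state.u.shape[0] != n:
        raise ValueError(f"state length {state.u.shape[0]} != sequence length {n}")
    d, a = params.site_arrays(bases)
    ku, kv = params.bond_arrays(bases)
    total = 0.0
    for j in range(n):
        jm = (j - 1) % n
        total += morse_energy(state.u[j], state.v[j], d[j], a[j])
        total += stacking_energy(
            state.u[jm], state.u[j], state.v[jm], state.v[j],
            ku[j], kv[j], params.rho, params.beta_anh,
        )
    return total


# ---------------------------------------------------------------------------
# Sampling


def _run_mcmc(
    bases: str,
    params: EPBDParameters,
    settings: MCMCSettings,
    state: LatticeState | None,
    n_equil: int,
    n_sample: int,
    rng: np.random.Generator | None,
):
    d, a = params.site_arrays(bases)
    ku, kv = params.bond_arrays(bases)
    if state is None:
        state = LatticeState.zeros(len(bases))
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    inv_kt = 1.0 / (BOLTZMANN_EV * settings.temperature)
    counts, n_samples, n_acc, n_prop = _kernels.epbd_mcmc(
        rng,
        state.u,
        state.v,
        d,
        a,
        ku,
        kv,
        params.rho,
        params.beta_anh,
        inv_kt,
        settings.proposal_width,
        settings.y_max,
        n_equil,
        n_sample,
        settings.thinning,
        settings.opening_threshold,
    )
    return state, counts, n_samples, n_acc, n_prop


def metropolis_sweep(
    state: LatticeState,
    seq: DNASequence | str,
    params: EPBDParameters,
    settings: MCMCSettings,
    rng: np.random.Generator,
) -> LatticeState:
    """Advance the lattice by one Metropolis sweep (N u-proposals then N
    v-proposals) and return the new state; the input state is not modified."""
    new = LatticeState(state.u, state.v)
    _run_mcmc(_bases_of(seq), params, settings, new, 0, 1, rng)
    return new


def sample_opening_profile(
    seq: DNASequence | str,
    params: EPBDParameters | None = None,
    settings: MCMCSettings | None = None,
) -> OpeningProfile:
    """Estimate per-base-pair opening probabilities by Metropolis MCMC.

    ``p_n`` is the fraction of sampled lattice states whose stretch
    ``u_n - v_n`` exceeds ``settings.opening_threshold``.  Annotated mismatch
    positions are then forced to probability one (a mismatched pair is
    modelled as permanently single-stranded).  Emits a warning (not an error)
    when the Metropolis acceptance rate falls outside [0.2, 0.6].
    """
    params = params or EPBDParameters()
    settings = settings or MCMCSettings()
    bases = _bases_of(seq)
    _, counts, n_samples, n_acc, n_prop = _run_mcmc(
        bases, params, settings, None, settings.n_equilibration, settings.n_sampling, None
    )
    rate = n_acc / max(n_prop, 1)
    if not 0.2 <= rate <= 0.6:
        warnings.warn(
            f"Metropolis acceptance rate {rate:.2f} outside [0.2, 0.6]; "
            "consider adjusting proposal_width",
            RuntimeWarning,
            stacklevel=2,
        )
    profile = OpeningProfile(counts / n_samples, source="epbd_mcmc")
    if isinstance(seq, DNASequence):
        for pos in sorted(seq.mismatch_positions):
            profile = set_mismatch(profile, pos)
    return profile


def set_mismatch(profile: OpeningProfile, position: int) -> OpeningProfile:
    """Return a profile with the 1-based ``position`` forced open (p = 1)."""
    if not 1 <= position <= len(profile):
        raise IndexError(f"position {position} outside [1, {len(profile)}]")
    p = profile.probabilities.copy()
    p[position - 1] = 1.0
    return OpeningProfile(p, source=profile.source)
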