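"""Jacobson-Stockmayer J-factor estimation from chain ensembles.

The J-factor (mol/L) measures the propensity of a linear DNA of N base pairs
to close into a ring.  It factorizes into three closure probabilities
evaluated by direct Monte Carlo over sampled chains,

    J = (4 pi / N_A) * W(r ~ 0) * Gamma_r(cos gamma ~ 1) * Phi_{r,cos gamma}(phi ~ 0),

where W is the probability density (per liter) of finding the two chain ends
coincident, Gamma the conditional density (per unit cos gamma) of the first
and last base-pair normals being aligned given coincident ends, and Phi the
conditional density (per radian) of torsional register phi ~ 0 given both.
Each density is estimated from the fraction of chains passing a finite
observation window, divided by the window size:

    W_hat     = (n_r / n_total) / V_c,            V_c = 4/3 pi r_c^3  (liters)
    Gamma_hat = (n_gamma / n_r) / (1 - c_gamma)
    Phi_hat   = (n_phi / n_gamma) / (2 arccos(c_phi))

with default thresholds r_c = 30 Å, c_gamma = c_phi = 0.86.  With these
normalizations an ideal flexible chain (uniform orientations, uniform
torsional register) recovers the classic Jacobson-Stockmayer expression
J = W(0)/N_A, and the estimator checks out against the Shimada-Yamakawa
worm-like-chain closed form (see :func:`shimada_yamakawa_j`).

Two modes share the machinery: the pure rigid-base-pair model ("cso", every
base pair duplex) and the coupled model ("cso_epbd"), where each chain first
draws a hinge mask from a per-base-pair opening profile and open base pairs
adopt single-strand fluctuation widths.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import _kernels
from .chain_mc import FlexibilityModel, _REORTH_EVERY
from .params_io import (
    ANGSTROM3_TO_LITER,
    AVOGADRO,
    DNASequence,
    OpeningProfile,
    TrinucleotideStepTable,
    extend_periodic,
    ring_step_matrix,
)

__all__ = [
    "ClosureThresholds",
    "CyclizationCounts",
    "JFactorEstimate",
    "accumulate_counts",
    "jfactor_from_counts",
    "torsion_free_j",
    "estimate_jfactor",
    "free_energy_equivalent",
    "shimada_yamakawa_j",
]

DEFAULT_CHUNK_SIZE = 65_536


@dataclass(frozen=True)
class ClosureThresholds:
    """Observation windows for the three nested closure gates."""

    r_c: float = 30.0
    c_gamma: float = 0.86
    c_phi: float = 0.86

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        for name in ("c_gamma", "c_phi"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class CyclizationCounts:
    """Nested closure counts: n_total >= n_r >= n_gamma >= n_phi."""

    n_total: int
    n_r: int
    n_gamma: int
    n_phi: int

    def __post_init__(self) -> None:
        if not self.n_total >= self.n_r >= self.n_gamma >= self.n_phi >= 0:
            raise ValueError(
                f"count nesting violated: {self.n_total} >= {self.n_r} >= "
                f"{self.n_gamma} >= {self.n_phi} >= 0"
            )

    def __add__(self, other: "CyclizationCounts") -> "CyclizationCounts":
        return CyclizationCounts(
            self.n_total + other.n_total,
            self.n_r + other.n_r,
            self.n_gamma + other.n_gamma,
            self.n_phi + other.n_phi,
        )


@dataclass(frozen=True)
class JFactorEstimate:
    """J-factor in mol/L with counts, uncertainty and provenance."""

    j: float
    stderr: float
    counts: CyclizationCounts
    mode: str
    insufficient_sampling: bool
    settings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "J": self.j,
            "stderr": self.stderr,
            "counts": {
                "n_total": self.counts.n_total,
                "n_r": self.counts.n_r,
                "n_gamma": self.counts.n_gamma,
                "n_phi": self.counts.n_phi,
            },
            "mode": self.mode,
            "insufficient_sampling": self.insufficient_sampling,
            "settings": self.settings,
        }
        return json.dumps(doc, indent=2)


def accumulate_counts(
    observables: Iterable[tuple[float, float, float]] | tuple[np.ndarray, np.ndarray, np.ndarray],
    thresholds: ClosureThresholds | None = None,
) -> CyclizationCounts:
    """Count chains through the nested closure gates.

    ``observables`` is either an iterable of ``(r, cos_gamma, cos_phi)``
    triples or a tuple of three aligned arrays.  A chain enters the gamma
    gate only if it passed the r gate, and the phi gate only if it passed
    both; the result is independent of chain order.
    """
    thresholds = thresholds or ClosureThresholds()
    if isinstance(observables, tuple) and len(observables) == 3 and np.ndim(observables[0]) == 1:
        r, cosg, cosp = (np.asarray(x, dtype=float) for x in observables)
    else:
        arr = np.asarray(list(observables), dtype=float)
        if arr.size == 0:
            return CyclizationCounts(0, 0, 0, 0)
        arr = np.atleast_2d(arr)
        r, cosg, cosp = arr[:, 0], arr[:, 1], arr[:, 2]
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(cosg)) and np.all(np.isfinite(cosp))):
        raise ValueError("closure observables must be finite")
    pass_r = r < thresholds.r_c
    pass_g = pass_r & (cosg > thresholds.c_gamma)
    pass_p = pass_g & (cosp > thresholds.c_phi)
    return CyclizationCounts(
        int(r.size), int(pass_r.sum()), int(pass_g.sum()), int(pass_p.sum())
    )


def _estimator_factors(
    counts: CyclizationCounts, thresholds: ClosureThresholds
) -> tuple[float, float, float]:
    v_c = (4.0 / 3.0) * math.pi * thresholds.r_c**3 * ANGSTROM3_TO_LITER
    w = counts.n_r / counts.n_total / v_c
    gamma = (
        (counts.n_gamma / counts.n_r) / (1.0 - thresholds.c_gamma)
        if counts.n_r
        else 0.0
    )
    phi_width = 2.0 * math.acos(thresholds.c_phi)
    phi = (counts.n_phi / counts.n_gamma) / phi_width if counts.n_gamma else 0.0
    return w, gamma, phi


def jfactor_from_counts(
    counts: CyclizationCounts,
    thresholds: ClosureThresholds | None = None,
    mode: str = "cso",
    settings: dict | None = None,
) -> JFactorEstimate:
    """Turn nested counts into a J-factor estimate with a binomial error.

    The relative error combines the three conditional binomial stages in
    quadrature on log J; with no fully closed chain the estimate is zero and
    flagged as insufficient sampling.
    """
    thresholds = thresholds or ClosureThresholds()
    if counts.n_total <= 0:
        raise ValueError("n_total must be positive")
    w, gamma, phi = _estimator_factors(counts, thresholds)
    j = (4.0 * math.pi / AVOGADRO) * w * gamma * phi
    insufficient = counts.n_phi == 0
    if insufficient:
        stderr = 0.0
    else:
        var_log = 0.0
        for k, n in (
            (counts.n_r, counts.n_total),
            (counts.n_gamma, counts.n_r),
            (counts.n_phi, counts.n_gamma),
        ):
            var_log += 1.0 / k - 1.0 / n
        stderr = j * math.sqrt(var_log)
    return JFactorEstimate(
        j=j,
        stderr=stderr,
        counts=counts,
        mode=mode,
        insufficient_sampling=insufficient,
        settings=settings or {},
    )


def torsion_free_j(
    counts: CyclizationCounts, thresholds: ClosureThresholds | None = None
) -> float:
    """Torsion-relaxed J-factor (mol/L): ends coincident and normals aligned,
    torsional register averaged.  Equals ``(2 / N_A) W_hat Gamma_hat`` and is
    directly comparable to the tangent-aligned worm-like-chain closed form."""
    thresholds = thresholds or ClosureThresholds()
    if counts.n_total <= 0:
        raise ValueError("n_total must be positive")
    w, gamma, _ = _estimator_factors(counts, thresholds)
    return (2.0 / AVOGADRO) * w * gamma


# ---------------------------------------------------------------------------
# End-to-end estimation


def _chunk_rng(seed: int, chunk_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(chunk_index,))
    return np.random.Generator(np.random.PCG64(ss))


def estimate_jfactor(
    seq: DNASequence,
    table: TrinucleotideStepTable,
    flex: FlexibilityModel | None = None,
    thresholds: ClosureThresholds | None = None,
    profile: OpeningProfile | None = None,
    n_chains: int = 100_000,
    seed: int = 0,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    chunk_index_start: int = 0,
) -> JFactorEstimate:
    """Estimate the J-factor of one sequence by direct chain Monte Carlo.

    The sequence is periodically extended (first two base pairs appended) so
    all N ring steps have trinucleotide context; per chain a hinge mask is
    drawn from the opening profile (annotated mismatch positions are forced
    to probability one first), step angles are sampled with state-dependent
    widths, the chain is built, and its closure observables are gated.  With
    ``profile=None`` every hinge probability is zero and the pure
    rigid-base-pair model is recovered exactly (the hinge uniforms are still
    consumed, so a zero profile and no profile give bit-identical results).

    Chains are processed in chunks of ``chunk_size``; chunk ``k`` (counting
    from ``chunk_index_start``) draws from an independent substream keyed by
    ``(seed, k)``, so partitioning the chains across processes at chunk
    granularity and summing the counts reproduces a single run exactly.
    """
    flex = flex or FlexibilityModel()
    if flex.duplex_cov is not None:
        raise NotImplementedError(
            "the streaming estimator supports diagonal angular fluctuations only"
        )
    thresholds = thresholds or ClosureThresholds()
    if n_chains <= 0:
        raise ValueError("n_chains must be positive")

    mode = "cso" if profile is None else "cso_epbd"
    n = len(seq)
    if profile is not None and len(profile) != n:
        raise ValueError(f"profile length {len(profile)} != sequence length {n}")
    if profile is None:
        profile = OpeningProfile(np.zeros(n), source="none")
    for pos in sorted(seq.mismatch_positions):
        p = profile.probabilities.copy()
        p[pos - 1] = 1.0
        profile = OpeningProfile(p, source=profile.source)
        if mode == "cso":
            mode = "cso_epbd"

    seq_ext, profile_ext = extend_periodic(seq, profile)
    theta = ring_step_matrix(seq, table)
    theta[:, :3] = np.deg2rad(theta[:, :3])
    # step s (0-based) enters extended base pair s + 2 (1-based)
    p_step = np.ascontiguousarray(profile_ext.probabilities[1 : n + 1])
    sd_ds = flex.rms_rad(False)
    sd_ss = flex.rms_rad(True)

    counts = CyclizationCounts(0, 0, 0, 0)
    n_chunks = (n_chains + chunk_size - 1) // chunk_size
    for k in range(n_chunks):
        m = min(chunk_size, n_chains - k * chunk_size)
        rng = _chunk_rng(seed, chunk_index_start + k)
        r = np.empty(m)
        cosg = np.empty(m)
        cosp = np.empty(m)
        _kernels.simulate_closure(
            rng, m, theta, p_step, sd_ds, sd_ss, _REORTH_EVERY, r, cosg, cosp
        )
        counts = counts + accumulate_counts((r, cosg, cosp), thresholds)

    settings = {
        "sequence": seq.id,
        "length_bp": n,
        "n_chains": int(n_chains),
        "seed": int(seed),
        "chunk_size": int(chunk_size),
        "chunk_index_start": int(chunk_index_start),
        "r_c": thresholds.r_c,
        "c_gamma": thresholds.c_gamma,
        "c_phi": thresholds.c_phi,
        "profile_source": profile.source,
    }
    return jfactor_from_counts(counts, thresholds, mode=mode, settings=settings)


# ---------------------------------------------------------------------------
# Diagnostics and closed forms


def free_energy_equivalent(
    profile: OpeningProfile,
) -> tuple[np.ndarray, float, int]:
    """Descriptive per-site opening free energy, in units of k_B T.

    Reports ``-ln p_n`` per site and the mean over sites with ``p_n > 0``
    (sites with p = 0 are +inf and excluded; their count is returned).  This
    is a diagnostic reading of the profile only — it is not used anywhere in
    the J-factor computation.
    """
    p = profile.probabilities
    with np.errstate(divide="ignore"):
        g = -np.log(p)
    finite = np.isfinite(g)
    mean = float(g[finite].mean()) if finite.any() else math.inf
    return g, mean, int((~finite).sum())


def shimada_yamakawa_j(
    n_bp: float, lp_bp: float, rise: float = 3.4
) -> float:
    """Closed-form worm-like-chain ring-closure J-factor (mol/L).

    Torsion-relaxed, tangent-aligned closure of an ideal worm-like chain of
    contour length ``n_bp * rise`` and persistence length ``lp_bp * rise``:

        J = 896.32 / (4 pi nu^5) * exp(-14.054 / nu + 0.246 nu) / (N_A l_p^3)

    with ``nu`` the contour length in persistence lengths.  The expression is
    an interpolation accurate for roughly ``1 < nu < 10``; it peaks near
    ``nu ~ 3.4``.
    """
    if n_bp <= 0 or lp_bp <= 0 or rise <= 0:
        raise ValueError("n_bp, lp_bp and rise must be positive")
    nu = n_bp / lp_bp
    lp3_liter = (lp_bp * rise) ** 3 * ANGSTROM3_TO_LITER
    density = 896.32 / (4.0 * math.pi * nu**5) * math.exp(-14.054 / nu + 0.246 * nu)
    return density / (AVOGADRO * lp3_liter)
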