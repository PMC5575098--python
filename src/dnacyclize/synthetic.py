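"""Synthetic fixtures: sequences, step tables, opening profiles and panels.

Everything here is generated, reproducible test material — stand-ins for
externally measured inputs (experimental J-factor panels, fitted step
parameter tables, lattice-simulation opening profiles) that a user would
normally supply.  The generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chain_mc import FlexibilityModel, step_decay_factor
from .jfactor import estimate_jfactor, shimada_yamakawa_j
from .params_io import (
    ALL_TRINUCLEOTIDES,
    ALPHABET,
    DNASequence,
    OpeningProfile,
    TrinucleotideStepTable,
)

__all__ = [
    "random_sequence",
    "straight_step_table",
    "circle_step_table",
    "toy_step_table",
    "synthetic_profile",
    "effective_persistence_length",
    "SyntheticPanel",
    "make_synthetic_panel",
]

#: Canonical B-DNA geometry used by the straight fixture.
B_DNA_TWIST = 34.3
B_DNA_RISE = 3.4


def random_sequence(
    length: int, gc: float = 0.5, rng: np.random.Generator | None = None, id: str = "random"
) -> DNASequence:
    """Random sequence of a given length and expected GC content."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = "".join(rng.choice(list(ALPHABET), size=length, p=p))
    return DNASequence(id, bases)


def _uniform_table(tilt, roll, twist, shift, slide, rise) -> TrinucleotideStepTable:
    row = [tilt, roll, twist, shift, slide, rise]
    return TrinucleotideStepTable({t: row for t in ALL_TRINUCLEOTIDES})


def straight_step_table(
    twist: float = B_DNA_TWIST, rise: float = B_DNA_RISE
) -> TrinucleotideStepTable:
    """Intrinsically straight fixture: zero tilt/roll/shift/slide everywhere."""
    return _uniform_table(0.0, 0.0, twist, 0.0, 0.0, rise)


def circle_step_table(n_steps: int, rise: float = B_DNA_RISE) -> TrinucleotideStepTable:
    """Planar-circle fixture: constant roll 360/n_steps deg, no tilt/twist."""
    if n_steps < 3:
        raise ValueError("need at least 3 steps for a circle")
    return _uniform_table(0.0, 360.0 / n_steps, 0.0, 0.0, 0.0, rise)


def toy_step_table(
    seed: int = 0,
    angle_jitter: float = 2.0,
    twist_jitter: float = 1.0,
    displacement_jitter: float = 0.1,
) -> TrinucleotideStepTable:
    """Random sequence-dependent table around B-DNA geometry.

    Tilt/roll get independent N(0, angle_jitter^2) degree offsets per
    trinucleotide (intrinsic curvature), twist N(34.3, twist_jitter^2),
    shift/slide N(0, displacement_jitter^2) Å, rise N(3.4, displacement_jitter^2)
    clipped positive.
    """
    rng = np.random.default_rng(seed)
    entries = {}
    for tri in ALL_TRINUCLEOTIDES:
        entries[tri] = [
            rng.normal(0.0, angle_jitter),
            rng.normal(0.0, angle_jitter),
            rng.normal(B_DNA_TWIST, twist_jitter),
            rng.normal(0.0, displacement_jitter),
            rng.normal(0.0, displacement_jitter),
            max(rng.normal(B_DNA_RISE, displacement_jitter), 0.5),
        ]
    return TrinucleotideStepTable(entries)


def synthetic_profile(
    seq: DNASequence,
    rng: np.random.Generator | None = None,
    baseline: tuple[float, float] = (1e-5, 1e-3),
    hotspot: float = 1e-2,
    window: int = 5,
    at_fraction: float = 0.8,
) -> OpeningProfile:
    """Opening profile with AT-rich hotspots.

    Base pairs get a log-uniform baseline probability in ``baseline``;
    positions whose centred ``window`` contains at least ``at_fraction`` A/T
    bases are boosted towards ``hotspot`` (AT-rich tracts breathe more).
    Annotated mismatch positions are set to probability one.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = len(seq)
    lo, hi = baseline
    p = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), n)
    is_at = np.array([b in "AT" for b in seq.bases], dtype=float)
    half = window // 2
    for i in range(n):
        a, b = max(0, i - half), min(n, i + half + 1)
        if is_at[a:b].mean() >= at_fraction:
            p[i] = hotspot * 10.0 ** rng.uniform(-0.5, 0.0)
    for pos in seq.mismatch_positions:
        p[pos - 1] = 1.0
    return OpeningProfile(np.clip(p, 0.0, 1.0), source="synthetic")


def effective_persistence_length(
    profile: OpeningProfile, flex: FlexibilityModel | None = None
) -> float:
    """Persistence length (bp) of the hinge-diluted chain.

    Mixes the per-step normal-correlation decay factors of the duplex and
    single-strand states with the per-site opening probabilities:
    ``lambda_n = (1 - p_n) lambda_ds + p_n lambda_ss`` and
    ``L_p = -1 / mean(ln lambda_n)``.
    """
    flex = flex or FlexibilityModel()
    lam_ds = step_decay_factor(flex.duplex[0], flex.duplex[1])
    lam_ss = step_decay_factor(flex.single_strand[0], flex.single_strand[1])
    p = profile.probabilities
    lam = (1.0 - p) * lam_ds + p * lam_ss
    return float(-1.0 / np.mean(np.log(lam)))


@dataclass(frozen=True)
class SyntheticPanel:
    """A reproducible benchmark panel: sequences, profiles, and a table with
    toy experimental J-factors (columns: id, length, J_exp, J_cso,
    J_cso_epbd)."""

    sequences: list[DNASequence]
    profiles: list[OpeningProfile]
    records: pd.DataFrame


def make_synthetic_panel(
    n_seqs: int = 24,
    length_range: tuple[int, int] = (50, 325),
    gc_range: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
    noise_sd_decades: float = 0.5,
    j_source: str = "closed_form",
    flex: FlexibilityModel | None = None,
    n_chains: int = 200_000,
    table: TrinucleotideStepTable | None = None,
) -> SyntheticPanel:
    """Generate a self-contained benchmark panel.

    Toy "experimental" J-factors are the coupled-model prediction perturbed
    by lognormal noise of ``noise_sd_decades`` decades.  With
    ``j_source="closed_form"`` (default) model J-factors come from the
    worm-like-chain closed form evaluated at the duplex persistence length
    (pure chain model) or the hinge-diluted effective persistence length
    (coupled model) — fast and exact enough for benchmark plumbing.  With
    ``j_source="simulation"`` they are Monte Carlo estimates with
    ``n_chains`` chains each (slow; short stiff sequences may yield zero
    counts, such records keep J = 0 and are skipped by the benchmark reader).
    """
    if j_source not in ("closed_form", "simulation"):
        raise ValueError("j_source must be 'closed_form' or 'simulation'")
    flex = flex or FlexibilityModel()
    rng = np.random.default_rng(seed)
    table = table or straight_step_table()

    lam_ds = step_decay_factor(flex.duplex[0], flex.duplex[1])
    lp_ds = -1.0 / math.log(lam_ds)

    sequences, profiles, rows = [], [], []
    for i in range(n_seqs):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        gc = float(rng.uniform(*gc_range))
        seq = random_sequence(length, gc, rng, id=f"syn{i:03d}")
        prof = synthetic_profile(seq, rng)
        if j_source == "closed_form":
            j_cso = shimada_yamakawa_j(length, lp_ds)
            j_mix = shimada_yamakawa_j(length, effective_persistence_length(prof, flex))
        else:
            j_cso = estimate_jfactor(
                seq, table, flex, n_chains=n_chains, seed=int(rng.integers(2**31))
            ).j
            j_mix = estimate_jfactor(
                seq, table, flex, profile=prof, n_chains=n_chains,
                seed=int(rng.integers(2**31)),
            ).j
        j_exp = j_mix * 10.0 ** rng.normal(0.0, noise_sd_decades)
        sequences.append(seq)
        profiles.append(prof)
        rows.append(
            {"id": seq.id, "length": length, "J_exp": j_exp, "J_cso": j_cso,
             "J_cso_epbd": j_mix}
        )
    return SyntheticPanel(sequences, profiles, pd.DataFrame(rows))
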