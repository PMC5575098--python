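"""Benchmark statistics: order-of-magnitude agreement between computed and
experimental J-factors, pooled and stratified by sequence length.

The headline statistic is the fraction of sequences whose computed J-factor
falls within k orders of magnitude of the experimental value,
``|log10(J_calc / J_exp)| <= k``, reported as a curve over k for each model
and for three strata: all sequences, ultra-short ones (< 100 bp) and the
rest (>= 100 bp; a sequence of exactly 100 bp counts as long).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chain_mc import FlexibilityModel
from .jfactor import ClosureThresholds, estimate_jfactor
from .params_io import DNASequence, OpeningProfile, TrinucleotideStepTable

__all__ = [
    "BenchmarkRecord",
    "ComparisonSummary",
    "within_order_fraction",
    "comparison_curve",
    "run_benchmark",
    "DEFAULT_K_GRID",
    "LENGTH_SPLIT_BP",
]

#: Length (bp) splitting the short and long strata; exactly this length is long.
LENGTH_SPLIT_BP = 100

DEFAULT_K_GRID = tuple(np.round(np.arange(0.0, 6.01, 0.25), 2))


@dataclass(frozen=True)
class BenchmarkRecord:
    """One benchmarked sequence: experimental and computed J-factors (mol/L)."""

    id: str
    length: int
    j_experimental: float
    j_cso: float | None = None
    j_cso_epbd: float | None = None

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ValueError(f"{self.id}: implausible length {self.length}")
        for name in ("j_experimental", "j_cso", "j_cso_epbd"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v <= 0):
                raise ValueError(f"{self.id}: {name} must be positive, got {v}")


@dataclass(frozen=True)
class ComparisonSummary:
    """Tidy fraction-within-k table: columns model, stratum, k, fraction, n."""

    table: pd.DataFrame

    def fraction(self, model: str, stratum: str, k: float) -> float:
        t = self.table
        row = t[(t.model == model) & (t.stratum == stratum) & (np.isclose(t.k, k))]
        if row.empty:
            raise KeyError(f"no entry for {model}/{stratum}/k={k}")
        return float(row.fraction.iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        doc = {
            f"{m}|{s}": g.sort_values("k")[["k", "fraction"]].to_dict("list")
            for (m, s), g in self.table.groupby(["model", "stratum"])
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def within_order_fraction(
    j_calc: Sequence[float], j_exp: Sequence[float], k: float
) -> float:
    """Fraction of pairs with |log10(J_calc / J_exp)| <= k."""
    calc = np.asarray(j_calc, dtype=float)
    exp = np.asarray(j_exp, dtype=float)
    if calc.shape != exp.shape or calc.ndim != 1 or calc.size == 0:
        raise ValueError("j_calc and j_exp must be equal-length non-empty vectors")
    for name, arr in (("j_calc", calc), ("j_exp", exp)):
        bad = np.where(~(np.isfinite(arr) & (arr > 0)))[0]
        if bad.size:
            raise ValueError(f"{name}: non-positive J at record index {int(bad[0])}")
    return float((np.abs(np.log10(calc / exp)) <= k).mean())


def comparison_curve(
    j_calc: Sequence[float], j_exp: Sequence[float], k_grid: Sequence[float] = DEFAULT_K_GRID
) -> pd.DataFrame:
    """Fraction-within-k curve over a grid of k values."""
    return pd.DataFrame(
        {"k": list(k_grid),
         "fraction": [within_order_fraction(j_calc, j_exp, k) for k in k_grid]}
    )


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "id": [r.id for r in records],
                "length": [r.length for r in records],
                "J_exp": [r.j_experimental for r in records],
                "J_cso": [r.j_cso for r in records],
                "J_cso_epbd": [r.j_cso_epbd for r in records],
            }
        )
    required = {"id", "length", "J_exp"}
    if not required.issubset(df.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    return df


def run_benchmark(
    records: pd.DataFrame | Sequence[BenchmarkRecord],
    k_grid: Sequence[float] = DEFAULT_K_GRID,
    recompute: dict | None = None,
) -> ComparisonSummary:
    """Benchmark computed against experimental J-factors.

    ``records`` carries columns id, length, J_exp and per-model J columns
    (J_cso, J_cso_epbd); records without a usable experimental J are skipped
    with a warning.  Alternatively ``recompute`` may supply the ingredients
    for a fresh Monte Carlo pass:
    ``{"sequences": [...], "table": ..., "profiles": [...], "n_chains": ...,
    "seed": ..., "flex": ..., "thresholds": ...}`` — the models are then
    re-estimated per sequence and the resulting J columns replace any given
    ones (a model J of zero, i.e. no closed chain, is recorded but skipped in
    the curves with a warning).
    """
    df = _records_frame(records)

    if recompute is not None:
        seqs: Sequence[DNASequence] = recompute["sequences"]
        table: TrinucleotideStepTable = recompute["table"]
        profiles: Sequence[OpeningProfile | None] = recompute.get(
            "profiles", [None] * len(seqs)
        )
        flex: FlexibilityModel | None = recompute.get("flex")
        thresholds: ClosureThresholds | None = recompute.get("thresholds")
        n_chains = int(recompute.get("n_chains", 100_000))
        seed = int(recompute.get("seed", 0))
        by_id = {s.id: (s, p) for s, p in zip(seqs, profiles)}
        j_cso, j_mix = [], []
        for i, rec_id in enumerate(df["id"]):
            seq, prof = by_id[rec_id]
            j_cso.append(
                estimate_jfactor(
                    seq, table, flex, thresholds, None, n_chains, seed + 2 * i
                ).j
            )
            j_mix.append(
                estimate_jfactor(
                    seq, table, flex, thresholds, prof, n_chains, seed + 2 * i + 1
                ).j
            )
        df["J_cso"] = j_cso
        df["J_cso_epbd"] = j_mix

    usable = df["J_exp"].apply(lambda v: v is not None and np.isfinite(v) and v > 0)
    if (~usable).any():
        warnings.warn(
            f"skipping {int((~usable).sum())} record(s) without experimental J",
            RuntimeWarning,
            stacklevel=2,
        )
    df = df[usable]
    if df.empty:
        raise ValueError("no records with experimental J-factors")

    strata = {
        "all": np.ones(len(df), dtype=bool),
        "short": (df["length"] < LENGTH_SPLIT_BP).to_numpy(),
        "long": (df["length"] >= LENGTH_SPLIT_BP).to_numpy(),
    }
    models = [m for m in ("J_cso", "J_cso_epbd") if m in df.columns and df[m].notna().any()]
    rows = []
    for model in models:
        vals = df[model].to_numpy(dtype=float)
        ok = np.isfinite(vals) & (vals > 0)
        if (~ok).any():
            warnings.warn(
                f"{model}: skipping {int((~ok).sum())} record(s) with zero/invalid J",
                RuntimeWarning,
                stacklevel=2,
            )
        for stratum, mask in strata.items():
            m = mask & ok
            if not m.any():
                continue
            jc = vals[m]
            je = df["J_exp"].to_numpy(dtype=float)[m]
            for k in k_grid:
                rows.append(
                    {
                        "model": model.removeprefix("J_"),
                        "stratum": stratum,
                        "k": float(k),
                        "fraction": within_order_fraction(jc, je, k),
                        "n": int(m.sum()),
                    }
                )
    return ComparisonSummary(pd.DataFrame(rows))
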