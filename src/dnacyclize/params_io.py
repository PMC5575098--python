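"""Sequences, step-parameter tables, opening profiles, and physical constants.

All coordinates are 1-based and inclusive, matching the base-pair indexing
conventional for DNA cyclization work.  File formats are plain text: FASTA for
sequences (via Biopython) and tab-separated tables (UTF-8, ``#`` comments) for
trinucleotide step parameters and per-base-pair opening profiles.

The ring topology used throughout the package is handled here as well: a
sequence of N base pairs is periodically extended by copying its first two
base pairs to the end, which guarantees that every base-pair step of the
closed ring has a full trinucleotide context and an opening probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AVOGADRO",
    "BOLTZMANN_EV",
    "ANGSTROM3_TO_LITER",
    "ALPHABET",
    "COMPLEMENT",
    "DNASequence",
    "TrinucleotideStepTable",
    "OpeningProfile",
    "STEP_FIELDS",
    "read_sequences",
    "read_mismatch_annotations",
    "load_step_table",
    "write_step_table",
    "read_profile",
    "write_profile",
    "extend_periodic",
    "ring_step_matrix",
]

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23
#: Boltzmann constant, eV/K.
BOLTZMANN_EV = 8.617333262e-5
#: Volume conversion used when turning per-Å³ densities into per-liter ones.
ANGSTROM3_TO_LITER = 1e-27

ALPHABET = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Column order of a base-pair step parameter record: three rotations
#: (degrees) followed by three displacements (Å).
STEP_FIELDS = ("tilt", "roll", "twist", "shift", "slide", "rise")

ALL_TRINUCLEOTIDES = tuple(
    a + b + c for a in ALPHABET for b in ALPHABET for c in ALPHABET
)


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass(frozen=True)
class DNASequence:
    """A validated DNA duplex sequence.

    Parameters
    ----------
    id:
        Free-text label.
    bases:
        Uppercase string over ``ACGT``; at least 3 base pairs.
    mismatch_positions:
        1-based positions carrying a non-complementary base pair (for example
        a C:C mismatch).  A mismatched base pair is treated as permanently
        open (opening probability one) by the coupled model.
    """

    id: str
    bases: str
    mismatch_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        if len(self.bases) < 3:
            raise ValueError(
                f"sequence {self.id!r}: need at least 3 base pairs, got {len(self.bases)}"
            )
        for i, b in enumerate(self.bases, start=1):
            if b not in ALPHABET:
                raise ValueError(
                    f"sequence {self.id!r}: invalid symbol {b!r} at position {i}"
                )
        object.__setattr__(self, "mismatch_positions", frozenset(self.mismatch_positions))
        for p in self.mismatch_positions:
            if not 1 <= p <= len(self.bases):
                raise ValueError(
                    f"sequence {self.id!r}: mismatch position {p} outside [1, {len(self.bases)}]"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, position: int) -> str:
        """Return the base at a 1-based position."""
        if not 1 <= position <= len(self.bases):
            raise IndexError(f"position {position} outside [1, {len(self.bases)}]")
        return self.bases[position - 1]


class TrinucleotideStepTable:
    """Equilibrium base-pair step parameters keyed by trinucleotide context.

    Each of the 64 XYZ trinucleotides maps to the six equilibrium step
    parameters (tilt°, roll°, twist°, shift Å, slide Å, rise Å) of the step
    *entering* the central base pair Y, i.e. the step from the base pair
    preceding Y to Y itself.  These equilibrium values encode the intrinsic
    (static) curvature of the duplex; thermal fluctuations around them are the
    business of :mod:`dnacyclize.chain_mc`.
    """

    def __init__(self, entries: Mapping[str, Sequence[float]]):
        table = {}
        for tri, vals in entries.items():
            tri = tri.upper()
            if len(tri) != 3 or any(b not in ALPHABET for b in tri):
                raise ValueError(f"invalid trinucleotide key {tri!r}")
            arr = np.asarray(vals, dtype=float)
            if arr.shape != (6,):
                raise ValueError(f"{tri}: expected 6 step parameters, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{tri}: non-finite step parameters")
            if tri in table:
                raise ValueError(f"duplicate trinucleotide {tri}")
            table[tri] = arr
        missing = [t for t in ALL_TRINUCLEOTIDES if t not in table]
        if missing:
            raise ValueError(
                f"incomplete step table: missing {len(missing)} trinucleotide(s): "
                + ", ".join(missing[:8])
                + ("..." if len(missing) > 8 else "")
            )
        extra = [t for t in table if t not in ALL_TRINUCLEOTIDES]
        if extra:  # pragma: no cover - guarded by key validation above
            raise ValueError(f"unexpected keys: {extra}")
        for tri, arr in table.items():
            if arr[5] <= 0:
                raise ValueError(f"{tri}: rise must be positive, got {arr[5]}")
        self._table = table

    def lookup(self, trinucleotide: str) -> np.ndarray:
        """Six equilibrium step parameters for an XYZ context (copy)."""
        return self._table[trinucleotide.upper()].copy()

    def __getitem__(self, trinucleotide: str) -> np.ndarray:
        return self.lookup(trinucleotide)

    def __len__(self) -> int:
        return len(self._table)

    def items(self):
        return self._table.items()


@dataclass(frozen=True)
class OpeningProfile:
    """Per-base-pair probability of the single-stranded (open) state.

    ``probabilities[n-1]`` is the probability that base pair ``n`` is found
    transiently melted ("breathing"), estimated from lattice Monte Carlo,
    read from a file, or synthesized.  Values live in [0, 1].
    """

    probabilities: np.ndarray
    source: str = "file"

    def __post_init__(self) -> None:
        arr = np.asarray(self.probabilities, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("profile must be a non-empty 1-D probability vector")
        if np.any(~np.isfinite(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
            raise ValueError("opening probabilities must lie in [0, 1]")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "probabilities", arr)

    def __len__(self) -> int:
        return self.probabilities.size


# ---------------------------------------------------------------------------
# Sequence I/O


def _detect_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "fasta" if line.startswith(">") else "plain"
    raise ParseError(f"{path}: empty file")


def read_sequences(
    path: str | Path,
    format: str = "auto",
    mismatches: str | Path | Mapping[str, Iterable[int]] | None = None,
) -> list[DNASequence]:
    """Read DNA sequences from FASTA or plain text.

    Plain text carries one sequence per line, optionally preceded by an
    identifier and a tab.  ``mismatches`` may be a sidecar TSV path (columns:
    sequence id, 1-based position, type) or an already-parsed mapping from id
    to positions.
    """
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt not in ("fasta", "plain"):
        raise ValueError(f"unknown sequence format {fmt!r}")

    if mismatches is None:
        mm: Mapping[str, Iterable[int]] = {}
    elif isinstance(mismatches, (str, Path)):
        mm = read_mismatch_annotations(mismatches)
    else:
        mm = mismatches

    records: list[tuple[str, str, int]] = []  # id, bases, line number
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append((rec.id, str(rec.seq), 0))
        if not records:
            raise ParseError(f"{path}: no FASTA records found")
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "\t" in line:
                    name, seq = line.split("\t", 1)
                    seq = seq.strip()
                else:
                    name, seq = f"seq{len(records) + 1}", line
                if not seq:
                    raise ParseError(f"{path}:{lineno}: record without a sequence")
                records.append((name, seq, lineno))
        if not records:
            raise ParseError(f"{path}: no sequences found")

    out = []
    for name, seq, lineno in records:
        try:
            out.append(
                DNASequence(name, seq, frozenset(mm.get(name, frozenset())))
            )
        except ValueError as exc:
            where = f"{path}:{lineno}" if lineno else f"{path} record {name!r}"
            raise ParseError(f"{where}: {exc}") from exc
    return out


def read_mismatch_annotations(path: str | Path) -> dict[str, set[int]]:
    """Parse a mismatch sidecar TSV: sequence id, 1-based position[, type]."""
    out: dict[str, set[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
            try:
                pos = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position {parts[1]!r}") from exc
            out.setdefault(parts[0], set()).add(pos)
    return out


# ---------------------------------------------------------------------------
# Step table I/O


def load_step_table(
    path: str | Path, columns: Sequence[str] | None = None
) -> TrinucleotideStepTable:
    """Load a 64-row trinucleotide step-parameter table from TSV.

    The default layout is ``trinucleotide`` followed by the six values in
    :data:`STEP_FIELDS` order.  ``columns`` may rename/reorder the value
    columns of a header-carrying file (a permutation of ``STEP_FIELDS``),
    which keeps the reader tolerant to externally supplied tables.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    # Accept an optional header row naming the columns.
    first = [str(x).strip().lower() for x in df.iloc[0]]
    if any(f in first for f in STEP_FIELDS) or "trinucleotide" in first:
        header = first
        df = df.iloc[1:].reset_index(drop=True)
    else:
        header = ["trinucleotide", *STEP_FIELDS]
    if df.shape[1] != 7:
        raise ParseError(f"{path}: expected 7 columns, found {df.shape[1]}")
    order = list(columns) if columns is not None else header[1:]
    if sorted(order) != sorted(STEP_FIELDS):
        raise ParseError(
            f"{path}: value columns must be a permutation of {STEP_FIELDS}, got {order}"
        )
    entries: dict[str, list[float]] = {}
    for _, row in df.iterrows():
        tri = str(row.iloc[0]).strip().upper()
        try:
            vals = {name: float(row.iloc[1 + i]) for i, name in enumerate(order)}
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric step value in row {tri!r}") from exc
        if tri in entries:
            raise ParseError(f"{path}: duplicate trinucleotide {tri}")
        entries[tri] = [vals[f] for f in STEP_FIELDS]
    try:
        return TrinucleotideStepTable(entries)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_step_table(table: TrinucleotideStepTable, path: str | Path) -> None:
    """Write a step table in the layout :func:`load_step_table` reads back."""
    with open(path, "w") as fh:
        fh.write("# trinucleotide step parameters; 1-based step enters the central base pair\n")
        fh.write("trinucleotide\t" + "\t".join(STEP_FIELDS) + "\n")
        for tri in ALL_TRINUCLEOTIDES:
            vals = table.lookup(tri)
            fh.write(tri + "\t" + "\t".join(repr(float(v)) for v in vals) + "\n")


# ---------------------------------------------------------------------------
# Opening profile I/O


def write_profile(profile: OpeningProfile, seq: DNASequence, path: str | Path) -> None:
    """Write a profile as TSV: 1-based position, base, probability.

    Probabilities are serialized with ``repr`` so a write/read cycle is
    bit-exact.  The profile and sequence lengths must agree (the profile of an
    already periodically extended sequence is written against the extended
    sequence).
    """
    if len(profile) != len(seq):
        raise ValueError(
            f"profile length {len(profile)} != sequence length {len(seq)}"
        )
    with open(path, "w") as fh:
        fh.write(f"# opening profile for {seq.id}; positions are 1-based\n")
        fh.write("position\tbase\tprobability\n")
        for n, (b, p) in enumerate(zip(seq.bases, profile.probabilities), start=1):
            fh.write(f"{n}\t{b}\t{float(p)!r}\n")


def read_profile(path: str | Path) -> OpeningProfile:
    """Read a TSV opening profile written by :func:`write_profile`."""
    path = Path(path)
    probs: list[float] = []
    positions: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "position":
                continue
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                positions.append(int(parts[0]))
                probs.append(float(parts[2]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not probs:
        raise ParseError(f"{path}: empty profile")
    if positions != list(range(1, len(positions) + 1)):
        raise ParseError(f"{path}: positions must run 1..N without gaps")
    return OpeningProfile(np.asarray(probs), source="file")


# ---------------------------------------------------------------------------
# Periodic extension and ring step assembly


def extend_periodic(
    seq: DNASequence, profile: OpeningProfile | None = None
) -> tuple[DNASequence, OpeningProfile | None]:
    """Append copies of base pairs 1 and 2 to the end of the sequence.

    The two extra base pairs give every step of the closed ring a full
    trinucleotide context and an opening probability.  Mismatch annotations
    are copied onto the periodic images as well.
    """
    n = len(seq)
    mm = set(seq.mismatch_positions)
    for p in (1, 2):
        if p in mm:
            mm.add(n + p)
    ext = DNASequence(seq.id, seq.bases + seq.bases[:2], frozenset(mm))
    if profile is None:
        return ext, None
    if len(profile) != n:
        raise ValueError(f"profile length {len(profile)} != sequence length {n}")
    p = np.concatenate([profile.probabilities, profile.probabilities[:2]])
    return ext, OpeningProfile(p, source=profile.source)


def ring_step_matrix(seq: DNASequence, table: TrinucleotideStepTable) -> np.ndarray:
    """Equilibrium step parameters for the N steps of the closed ring.

    Row ``s`` (0-based, ``s = 0..N-1``) is the step entering base pair
    ``s + 2`` of the periodically extended sequence; its trinucleotide context
    is ``(base_{c-1}, base_c, base_{c+1})`` where ``c`` is the central base
    pair, taken cyclically over the original N-base-pair sequence.  Angles in
    degrees, displacements in Å, columns in :data:`STEP_FIELDS` order.
    """
    n = len(seq)
    bases = seq.bases
    out = np.empty((n, 6))
    for s in range(n):
        c = (s + 1) % n  # 0-based central base pair of the step
        tri = bases[(c - 1) % n] + bases[c] + bases[(c + 1) % n]
        out[s] = table.lookup(tri)
    return out
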