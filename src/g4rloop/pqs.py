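"""Potential G-quadruplex-forming sequences (PQS) built from linker-length codes.

A PQS construct is written as uniform runs of guanine (default GGG) separated
by thymidine linkers.  Constructs are named by the string of linker lengths:
``"111"`` is GGG T GGG T GGG T GGG, ``"123"`` is GGG T GGG TT GGG TTT GGG.
A code of length *n* therefore describes *n + 1* G-runs, and an intramolecular
G4 (IG4) on the non-template strand requires at least four G-runs, i.e. a
code of at least three digits.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import InsufficientDataError, InvalidCodeError, SequenceParseError

__all__ = [
    "PQSDesign",
    "build_pqs",
    "parse_pqs",
    "loop_variance",
    "write_fasta",
    "read_fasta",
]


@dataclass(frozen=True)
class PQSDesign:
    """A PQS construct and the sequence features used as correlates.

    Attributes
    ----------
    code : str
        Linker-length code; each digit is the thymidine linker length between
        two consecutive G-runs.
    sequence : str
        Realized DNA sequence (G-runs joined by T-linkers).
    g_run_length : int
        Number of guanines per run (3 for all constructs studied here).
    loop_lengths : tuple of int
        Linker lengths, one per digit of ``code``.
    mean_loop_length : float
    loop_variance : float
        Population variance of the loop lengths (see :func:`loop_variance`).
    n_g_runs : int
    gc_density : float
        (#G + #C) / sequence length.
    ig4_competent : bool
        True iff the construct carries >= 4 G-runs and can fold an
        intramolecular DNA G4.
    metadata : dict
        Optional context (e.g. promoter/spacer annotations); never affects
        the sequence itself.
    """

    code: str
    sequence: str
    g_run_length: int
    loop_lengths: tuple
    mean_loop_length: float
    loop_variance: float
    n_g_runs: int
    gc_density: float
    ig4_competent: bool
    metadata: dict = field(default_factory=dict, compare=False)


def _validate_code(code: str) -> None:
    if not code:
        raise InvalidCodeError("empty code: at least one linker digit is required")
    for ch in code:
        if not ch.isdigit():
            raise InvalidCodeError(
                f"invalid character {ch!r} in code {code!r}: digits 1-9 only"
            )
        if ch == "0":
            raise InvalidCodeError(
                f"invalid digit '0' in code {code!r}: linkers must be >= 1 nt"
            )


def build_pqs(code: str, g_run_length: int = 3, **metadata) -> PQSDesign:
    """Construct a :class:`PQSDesign` from a linker-length code.

    Parameters
    ----------
    code : str
        Non-empty string of digits 1-9, one per thymidine linker.
    g_run_length : int, default 3
        Guanines per G-run; must be >= 2.

    Examples
    --------
    >>> build_pqs("111").sequence
    'GGGTGGGTGGGTGGG'
    >>> build_pqs("11").ig4_competent
    False
    """
    _validate_code(code)
    if g_run_length < 2:
        raise InvalidCodeError(f"g_run_length must be >= 2, got {g_run_length}")
    loops = tuple(int(ch) for ch in code)
    g_run = "G" * g_run_length
    sequence = g_run + "".join("T" * n + g_run for n in loops)
    n_g_runs = len(code) + 1
    mean_loop = sum(loops) / len(loops)
    var = statistics.pvariance(loops)
    gc = (sequence.count("G") + sequence.count("C")) / len(sequence)
    return PQSDesign(
        code=code,
        sequence=sequence,
        g_run_length=g_run_length,
        loop_lengths=loops,
        mean_loop_length=mean_loop,
        loop_variance=var,
        n_g_runs=n_g_runs,
        gc_density=gc,
        ig4_competent=n_g_runs >= 4,
        metadata=dict(metadata),
    )


def parse_pqs(sequence: str) -> PQSDesign:
    """Invert :func:`build_pqs`: recover the linker code from a sequence.

    The sequence must consist of G-runs of one uniform length separated by
    T-only linkers of 1-9 nt.  Any other base (including adenine-substituted
    linkers) is rejected with the offending position.
    """
    seq = sequence.upper()
    if not seq:
        raise SequenceParseError("empty sequence")
    for i, ch in enumerate(seq):
        if ch not in "GT":
            raise SequenceParseError(
                f"unexpected base {ch!r} at position {i}: template allows only "
                "G-runs and thymidine linkers"
            )
    if seq[0] != "G" or seq[-1] != "G":
        pos = 0 if seq[0] != "G" else len(seq) - 1
        raise SequenceParseError(f"sequence must start and end with a G-run (position {pos})")

    # split into alternating G and T runs
    runs = []  # (base, length, start)
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            runs.append((seq[start], i - start, start))
            start = i
    g_runs = [r for r in runs if r[0] == "G"]
    t_runs = [r for r in runs if r[0] == "T"]
    g_len = g_runs[0][1]
    if g_len < 2:
        raise SequenceParseError(
            f"G-run of length {g_len} at position {g_runs[0][2]}: runs must be >= 2 nt"
        )
    for base, length, pos in g_runs:
        if length != g_len:
            raise SequenceParseError(
                f"unequal G-run of length {length} at position {pos} (expected {g_len})"
            )
    if not t_runs:
        raise SequenceParseError("no linkers found: need at least two G-runs")
    for base, length, pos in t_runs:
        if length > 9:
            raise SequenceParseError(
                f"linker of length {length} at position {pos}: single-digit codes "
                "support linkers of 1-9 nt"
            )
    code = "".join(str(length) for _, length, _ in t_runs)
    design = build_pqs(code, g_run_length=g_len)
    if design.sequence != seq:
        # unreachable under the checks above; guards future template changes
        raise SequenceParseError("sequence does not match the G-run/T-linker template")
    return design


def loop_variance(design: PQSDesign, sample: bool = False) -> float:
    """Variance of the loop lengths of a construct.

    Population variance (divide by *n*) by default; pass ``sample=True`` for
    the *n - 1* denominator.  Constructs with a single loop have zero
    population variance; the sample variance is then undefined.
    """
    loops = design.loop_lengths
    if sample:
        if len(loops) < 2:
            raise InsufficientDataError(
                f"sample variance needs >= 2 loops, got {len(loops)}"
            )
        return statistics.variance(loops)
    return statistics.pvariance(loops)


def write_fasta(designs: Iterable[PQSDesign], path) -> int:
    """Write constructs to FASTA, record id = linker code. Returns count."""
    records = [
        SeqRecord(Seq(d.sequence), id=d.code, description=f"g_run_length={d.g_run_length}")
        for d in designs
    ]
    return SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list:
    """Read PQS constructs from FASTA; sequences must match the template."""
    designs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        design = parse_pqs(str(rec.seq))
        if rec.id and rec.id != design.code:
            design.metadata["fasta_id"] = rec.id
        designs.append(design)
    return designs
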