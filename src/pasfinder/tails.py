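"""Detection and trimming of terminal poly(A)/poly(T) runs on RNA-seq reads.

Reads that fail genome alignment but start or end with a homopolymer of
adenosines (or thymidines, for reverse-complemented 3' ends) are candidate
polyadenylated reads: their non-templated tail marks the position where the
transcript was cleaved and polyadenylated.  This module finds such terminal
runs under a mismatch budget, trims them, and reports the calls so that the
trimmed bodies can be re-aligned to locate cleavage sites.

A *tail* is defined as the longest end-anchored window of the read such that

* the outermost (terminal) base of the read equals the tail base,
* the innermost base of the window equals the tail base (a run never ends on
  a mismatch),
* the number of non-tail bases in the window is at most
  ``floor(mismatch_fraction * window_length)`` (``N`` counts as a mismatch),
* the window length is at least ``min_run`` (default 10 nt).

Reads whose trimmed bodies are shorter than ``min_trimmed_length``
(default 20 nt) are discarded.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from Bio.SeqRecord import SeqRecord

SIDE_5 = "5prime"
SIDE_3 = "3prime"

#: (side, base) combinations examined for non-strand-specific libraries.
NSS_CONFIGS: Tuple[Tuple[str, str], ...] = (
    (SIDE_5, "T"),
    (SIDE_5, "A"),
    (SIDE_3, "A"),
    (SIDE_3, "T"),
)


class ConfigurationError(ValueError):
    """Raised when library mode and read pairing are inconsistent."""


@dataclass(frozen=True)
class TailParameters:
    """Thresholds governing tail detection and trimming.

    min_run:
        minimum qualifying run length in nt (default 10).
    mismatch_fraction:
        allowed fraction of non-tail bases inside the run (default 0.10).
    min_trimmed_length:
        reads whose body after trimming is shorter than this are discarded
        (default 20 nt).
    library_mode:
        ``"nss"`` (non-strand-specific: all four end/base configurations are
        tested) or ``"ss"`` (strand-specific: mate 1 may carry a 5' poly(T),
        mate 2 a 3' poly(A)).
    """

    min_run: int = 10
    mismatch_fraction: float = 0.10
    min_trimmed_length: int = 20
    library_mode: str = "nss"

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not 0.0 <= self.mismatch_fraction < 0.5:
            raise ValueError("mismatch_fraction must be in [0, 0.5)")
        if self.min_trimmed_length < 1:
            raise ValueError("min_trimmed_length must be >= 1")
        if self.library_mode not in ("nss", "ss"):
            raise ValueError("library_mode must be 'nss' or 'ss'")


DEFAULT_PARAMS = TailParameters()


@dataclass(frozen=True)
class TailCall:
    """One detected terminal homopolymer run on a read."""

    read_id: str
    side: str  # SIDE_5 | SIDE_3
    base: str  # "A" | "T"
    run_length: int
    mismatches: int
    trimmed_length: int


def detect_tail(
    sequence: str,
    side: str,
    base: str,
    params: TailParameters = DEFAULT_PARAMS,
    read_id: str = "",
) -> Optional[TailCall]:
    """Find the longest qualifying terminal run anchored at ``side``.

    Returns ``None`` when no window satisfies the mismatch budget, the
    end-on-base rule and the ``min_run`` threshold.  ``N`` bases always count
    as mismatches.
    """
    if side not in (SIDE_5, SIDE_3):
        raise ValueError(f"invalid side: {side!r}")
    if base not in ("A", "T"):
        raise ValueError(f"invalid tail base: {base!r}")
    seq = sequence.upper()
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    # outermost base must be the tail base
    outer = seq[-1] if side == SIDE_3 else seq[0]
    if outer != base:
        return None
    best: Optional[Tuple[int, int]] = None
    mismatches = 0
    for length in range(1, n + 1):
        inner = seq[n - length] if side == SIDE_3 else seq[length - 1]
        if inner != base:
            mismatches += 1
            continue
        if length >= params.min_run and mismatches <= math.floor(
            params.mismatch_fraction * length
        ):
            best = (length, mismatches)
    if best is None:
        return None
    run_length, mm = best
    return TailCall(
        read_id=read_id,
        side=side,
        base=base,
        run_length=run_length,
        mismatches=mm,
        trimmed_length=n - run_length,
    )


def classify_read(
    record: SeqRecord,
    params: TailParameters = DEFAULT_PARAMS,
    mate: Optional[int] = None,
    single_end_rule: Optional[str] = None,
) -> List[TailCall]:
    """Report every qualifying tail configuration for one read.

    Non-strand-specific mode tests all four (end, base) cases; at most one
    call per read end can qualify, so the result holds 0-2 calls.
    Strand-specific mode tests only the configuration allowed for the given
    mate: mate 1 may start with a poly(T), mate 2 may end with a poly(A).
    For unpaired strand-specific input, ``single_end_rule`` must name the
    rule to apply (``"mate1"`` or ``"mate2"``), otherwise a
    :class:`ConfigurationError` is raised.
    """
    seq = str(record.seq)
    if params.library_mode == "nss":
        configs = NSS_CONFIGS
    else:
        if mate is None:
            if single_end_rule == "mate1":
                mate = 1
            elif single_end_rule == "mate2":
                mate = 2
            else:
                raise ConfigurationError(
                    "strand-specific mode requires paired input or an "
                    "explicit single_end_rule ('mate1' or 'mate2')"
                )
        if mate == 1:
            configs = ((SIDE_5, "T"),)
        elif mate == 2:
            configs = ((SIDE_3, "A"),)
        else:
            raise ConfigurationError(f"mate must be 1 or 2, got {mate}")
    calls = []
    for side, base in configs:
        call = detect_tail(seq, side, base, params, read_id=record.id)
        if call is not None:
            calls.append(call)
    return calls


def trim_tail(
    record: SeqRecord, call: TailCall, params: TailParameters = DEFAULT_PARAMS
) -> Optional[SeqRecord]:
    """Remove the called run from its end of the read.

    Returns the trimmed record (qualities kept aligned to the remaining
    bases) or ``None`` when the remainder is shorter than
    ``min_trimmed_length``.
    """
    n = len(record)
    if call.run_length + call.trimmed_length != n:
        raise ValueError("tail call does not match this read's length")
    if call.trimmed_length < params.min_trimmed_length:
        return None
    if call.side == SIDE_3:
        trimmed = record[: n - call.run_length]
    else:
        trimmed = record[call.run_length :]
    trimmed.id = record.id
    trimmed.description = ""
    return trimmed


def extract_polyadenylated(
    records: Iterable[SeqRecord],
    params: TailParameters = DEFAULT_PARAMS,
    mate: Optional[int] = None,
    single_end_rule: Optional[str] = None,
) -> Tuple[List[SeqRecord], Dict[str, TailCall], Dict[str, int]]:
    """Classify and trim a stream of reads.

    Reads with qualifying tails at both ends are ambiguous (one read cannot
    evidence two cleavage events) and are excluded, as are reads whose
    trimmed body is too short.  Returns the retained trimmed reads, a
    read_id -> TailCall table, and a stats dict with the funnel counts
    ``total / candidate / ambiguous / too_short / retained``.
    """
    trimmed_reads: List[SeqRecord] = []
    calls: Dict[str, TailCall] = {}
    stats = {"total": 0, "candidate": 0, "ambiguous": 0, "too_short": 0, "retained": 0}
    for record in records:
        stats["total"] += 1
        found = classify_read(record, params, mate=mate, single_end_rule=single_end_rule)
        if not found:
            continue
        stats["candidate"] += 1
        if len({c.side for c in found}) > 1:
            stats["ambiguous"] += 1
            continue
        call = found[0]
        body = trim_tail(record, call, params)
        if body is None:
            stats["too_short"] += 1
            continue
        calls[record.id] = call
        trimmed_reads.append(body)
        stats["retained"] += 1
    return trimmed_reads, calls, stats


_TAILCALL_FIELDS = ("read_id", "side", "base", "run_length", "mismatches", "trimmed_length")


def write_tailcalls(calls: Iterable[TailCall], path: str) -> None:
    """Write TailCalls as a TSV report."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TAILCALL_FIELDS)
        for c in calls:
            writer.writerow(
                [c.read_id, c.side, c.base, c.run_length, c.mismatches, c.trimmed_length]
            )


def read_tailcalls(path: str) -> Dict[str, TailCall]:
    """Load a TailCall TSV back into a read_id -> TailCall dict."""
    out: Dict[str, TailCall] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["read_id"]] = TailCall(
                read_id=row["read_id"],
                side=row["side"],
                base=row["base"],
                run_length=int(row["run_length"]),
                mismatches=int(row["mismatches"]),
                trimmed_length=int(row["trimmed_length"]),
            )
    return out
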