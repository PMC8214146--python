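"""Peak-list reading and ranked-output writing.

The peak/fragment list dialect is a tab-delimited file with a header and
the five required columns ``fragment``, ``mz``, ``charge``, ``intensity``
and ``gscore`` (a few common aliases such as ``m/z`` and ``G-score`` are
accepted); extra columns are tolerated and ignored.  Row order is
preserved because the ranking model's top-N fragment selection takes the
first N rows as provided.
"""
from __future__ import annotations

import csv
from pathlib import Path

from .fragments import ObservedPeak
from .ranking import RankResult

__all__ = ["read_peak_list", "write_peak_list", "write_ranking"]

_ALIASES = {
    "fragment": "fragment",
    "annotation": "fragment",
    "mz": "mz",
    "m/z": "mz",
    "charge": "charge",
    "z": "charge",
    "intensity": "intensity",
    "i": "intensity",
    "gscore": "gscore",
    "g-score": "gscore",
    "g score": "gscore",
}
_REQUIRED = ("fragment", "mz", "charge", "intensity", "gscore")


def read_peak_list(path: str | Path) -> list[ObservedPeak]:
    """Read a peak/fragment list, preserving row order.

    Malformed rows raise ``ValueError`` naming the offending line number.
    """
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty peak list") from None
        columns: dict[str, int] = {}
        for idx, name in enumerate(header):
            key = _ALIASES.get(name.strip().lower())
            if key is not None and key not in columns:
                columns[key] = idx
        missing = [c for c in _REQUIRED if c not in columns]
        if missing:
            raise ValueError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        peaks: list[ObservedPeak] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) <= max(columns.values()):
                raise ValueError(f"{path}, line {lineno}: too few columns")
            try:
                peak = ObservedPeak(
                    annotation=row[columns["fragment"]].strip(),
                    mz=float(row[columns["mz"]]),
                    charge=int(row[columns["charge"]]),
                    intensity=float(row[columns["intensity"]]),
                    gscore=float(row[columns["gscore"]]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
            peaks.append(peak)
    if not peaks:
        raise ValueError(f"{path}: no peaks")
    return peaks


def write_peak_list(peaks: list[ObservedPeak], path: str | Path) -> None:
    """Write peaks in the same dialect ``read_peak_list`` consumes."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["fragment", "mz", "charge", "intensity", "gscore"])
        for p in peaks:
            writer.writerow(
                [p.annotation, f"{p.mz:.6f}", p.charge,
                 f"{p.intensity:.4f}", f"{p.gscore:.4f}"]
            )


def write_ranking(results: list[RankResult], path: str | Path) -> None:
    """Write the ranked output: rank span, sequence, score; descending."""
    if not results:
        raise ValueError("no results to write")
    path = Path(path)
    ordered = sorted(results, key=lambda r: (-r.score, r.rank_lo, str(r.sequence)))
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["rank", "sequence", "score"])
        for r in ordered:
            writer.writerow([r.rank_span, str(r.sequence), f"{r.score:.10e}"])
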