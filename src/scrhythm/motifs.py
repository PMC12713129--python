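"""E-box motif scanning along promoter sequences.

The canonical E-box CACGTG is its own reverse complement, so forward-strand
scanning covers both strands and each site is reported once. The
non-canonical class CANNTG is also strand-symmetric as a pattern class
(the reverse complement of CAxyTG is CAy'x'TG), so scanning the forward
strand and collapsing duplicate positions yields one hit per site there as
well. Coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from scrhythm.io import FormatError

CANONICAL = "CACGTG"
MOTIF_LEN = 6
ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int           # 0-based
    strand: str
    matched: str
    motif_class: str     # "canonical" | "non_canonical"

    @property
    def end(self) -> int:
        return self.start + len(self.matched)


def _is_ebox_window(window: str) -> bool:
    return (
        window.startswith("CA")
        and window.endswith("TG")
        and "N" not in window
    )


def scan_ebox(
    seq: str,
    seq_id: str = "seq",
    include_noncanonical: bool = False,
) -> list[MotifHit]:
    """Scan a sequence for E-box motifs; hits are sorted by start.

    By default only the canonical CACGTG is reported. With
    ``include_noncanonical=True`` every CANNTG window is reported, classed
    as canonical or non-canonical. Overlapping hits are all reported; N
    never matches. Raises :class:`FormatError` on characters outside ACGTN.
    """
    seq = seq.upper()
    bad = set(seq) - ALPHABET
    if bad:
        raise FormatError(f"invalid characters in sequence: {sorted(bad)}")
    hits: list[MotifHit] = []
    for i in range(len(seq) - MOTIF_LEN + 1):
        window = seq[i:i + MOTIF_LEN]
        if window == CANONICAL:
            hits.append(MotifHit(seq_id, i, "+", window, "canonical"))
        elif include_noncanonical and _is_ebox_window(window):
            hits.append(MotifHit(seq_id, i, "+", window, "non_canonical"))
    return hits


def scan_fasta(
    records: dict[str, str], include_noncanonical: bool = False
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for seq_id, seq in records.items():
        hits.extend(scan_ebox(seq, seq_id, include_noncanonical))
    return hits


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": h.seq_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "matched": h.matched,
                "motif_class": h.motif_class,
            }
            for h in hits
        ],
        columns=["seq_id", "start", "end", "strand", "matched", "motif_class"],
    )


def write_bed(hits: list[MotifHit], path: str | Path) -> Path:
    """Write hits as BED6: chrom, start, end, name=class, score=0, strand."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.motif_class}\t0\t{h.strand}\n"
            )
    return path
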