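"""Residue conservation on pre-aligned ortholog groups.

The conservation score of a reference-sequence position is the fraction of
alignment rows (reference included) carrying exactly the reference residue
at the mapped column; gap rows count in the denominator.  The relative score
(rrcr) is the mid-rank percentile of a site's score within the scores of its
flanking residues (+-20 by default, site excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import kolmogorov


@dataclass
class OrthologAlignment:
    """A pre-computed MSA of one ortholog group with a designated reference row."""

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.n_total < 2:
            raise ValueError("alignment needs at least 2 rows")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(widths)}")
        if self.reference_id not in self.ids:
            raise ValueError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def n_total(self) -> int:
        return len(self.rows)

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]

    @property
    def reference_ungapped_length(self) -> int:
        return sum(1 for c in self.reference_row if c != "-")


@dataclass
class ConservationProfile:
    """Per-site conservation score plus its flanking reference distribution."""

    rcr: float
    flanking_rcrs: list[float] = field(default_factory=list)
    rrcr: float = float("nan")


def read_alignment_fasta(path, reference_id: str) -> OrthologAlignment:
    """Load an aligned FASTA file as an OrthologAlignment."""
    from .io_data import read_fasta

    records = read_fasta(path)
    return OrthologAlignment(
        ids=[r.id for r in records],
        rows=[r.sequence for r in records],
        reference_id=reference_id,
    )


def map_reference_position(aln: OrthologAlignment, ref_pos: int) -> int:
    """Return the 1-based alignment column holding the ref_pos-th non-gap
    character of the reference row."""
    if ref_pos < 1:
        raise ValueError(f"ref_pos must be >= 1, got {ref_pos}")
    seen = 0
    for col, ch in enumerate(aln.reference_row, start=1):
        if ch != "-":
            seen += 1
            if seen == ref_pos:
                return col
    raise ValueError(
        f"ref_pos {ref_pos} exceeds ungapped reference length "
        f"{aln.reference_ungapped_length}"
    )


def compute_rcr(aln: OrthologAlignment, ref_pos: int) -> float:
    """Fraction of rows matching the reference residue at the mapped column.

    Exact letter match; S and T are distinct; gap rows count toward the
    denominator but never the numerator.
    """
    col = map_reference_position(aln, ref_pos) - 1
    ref_char = aln.reference_row[col]
    n_match = sum(1 for row in aln.rows if row[col] == ref_char)
    return n_match / aln.n_total


def compute_rrcr(aln: OrthologAlignment, ref_pos: int, flank: int = 20) -> ConservationProfile:
    """Site conservation relative to its flanking region.

    The reference window spans [ref_pos - flank, ref_pos + flank] on the
    ungapped reference sequence, truncated at the termini; the site itself is
    excluded from the percentile reference distribution.  Percentile uses
    mid-rank tie handling so a uniformly conserved window scores 0.5.
    """
    length = aln.reference_ungapped_length
    if length < 2:
        raise ValueError("reference sequence shorter than 2 residues")
    site_rcr = compute_rcr(aln, ref_pos)
    lo = max(1, ref_pos - flank)
    hi = min(length, ref_pos + flank)
    flanking = [compute_rcr(aln, p) for p in range(lo, hi + 1) if p != ref_pos]
    below = sum(1 for v in flanking if v < site_rcr)
    ties = sum(1 for v in flanking if v == site_rcr)
    rrcr = (below + 0.5 * ties) / len(flanking)
    return ConservationProfile(rcr=site_rcr, flanking_rcrs=flanking, rrcr=rrcr)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    D = sup |ECDF_a - ECDF_b|; p from the Kolmogorov distribution with
    effective n = n_a * n_b / (n_a + n_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
    cdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
    d = float(np.abs(cdf_a - cdf_b).max())
    en = a.size * b.size / (a.size + b.size)
    p = float(kolmogorov(np.sqrt(en) * d))
    return d, min(1.0, p)


def motif_conservation(aln: OrthologAlignment, positions) -> float:
    """Mean conservation score over a motif occurrence's fixed positions
    (1-based reference positions, central residue included)."""
    positions = list(positions)
    if not positions:
        raise ValueError("motif occurrence has no fixed positions")
    return float(np.mean([compute_rcr(aln, p) for p in positions]))
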