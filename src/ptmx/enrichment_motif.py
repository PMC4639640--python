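"""GO term enrichment and overrepresented-motif extraction.

Enrichment: per-term two-tailed Fisher exact test on the 2x2 table of
annotated/unannotated counts in foreground vs background protein sets, with
Bonferroni correction over the terms tested (those annotating at least one
foreground protein) and a fold-ratio filter.

Motif extraction: iterative position/residue fixation on fixed-width windows
centred on S/T.  At every step the (offset, residue) pair with the smallest
binomial tail probability — observed foreground count against the current
background frequency — is fixed, the window sets are restricted to matches,
and the loop repeats until no pair is simultaneously significant and
supported by the minimum count.  Each emitted motif's foreground matches are
removed and extraction restarts on the remainder.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom, fisher_exact

from .conservation import OrthologAlignment, motif_conservation
from .features import DEFAULT_FLANK, extract_window
from .io_data import GOAnnotationMap, SiteCatalog

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 1e-6
DEFAULT_MIN_COUNT = 20
DEFAULT_CONSERVATION_CUTOFF = 0.4
DEFAULT_RATIO_THRESHOLD = 4.0
DEFAULT_ALPHA = 0.05


@dataclass
class EnrichmentRow:
    term: str
    fg_count: int
    fg_total: int
    bg_count: int
    bg_total: int
    ratio: float
    p_raw: float
    p_bonferroni: float
    passes: bool


def fisher_enrichment(
    fg_proteins,
    bg_proteins,
    go: GOAnnotationMap,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentRow]:
    """Per-term enrichment of fg_proteins against bg_proteins.

    Terms tested are those annotating at least one foreground protein.
    Unannotated proteins still count in the totals.  Rows come back sorted
    by corrected p-value, then term id.
    """
    fg = sorted(set(fg_proteins))
    bg = sorted(set(bg_proteins))
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    tested = sorted({t for p in fg for t in go.terms_of(p)})
    n_tested = len(tested)
    rows = []
    for term in tested:
        fg_count = sum(1 for p in fg if term in go.terms_of(p))
        bg_count = sum(1 for p in bg if term in go.terms_of(p))
        table = [
            [fg_count, len(fg) - fg_count],
            [bg_count, len(bg) - bg_count],
        ]
        _, p = fisher_exact(table, alternative="two-sided")
        fg_frac = fg_count / len(fg)
        bg_frac = bg_count / len(bg)
        ratio = fg_frac / bg_frac if bg_frac > 0 else float("inf")
        p_bonf = min(1.0, p * n_tested)
        rows.append(
            EnrichmentRow(
                term=term,
                fg_count=fg_count,
                fg_total=len(fg),
                bg_count=bg_count,
                bg_total=len(bg),
                ratio=ratio,
                p_raw=float(p),
                p_bonferroni=float(p_bonf),
                passes=bool(ratio > ratio_threshold and p_bonf < alpha),
            )
        )
    rows.sort(key=lambda r: (r.p_bonferroni, r.term))
    return rows


@dataclass(frozen=True)
class MotifPattern:
    """Fixed-width motif: offset (relative to the centre) -> residue letter.

    String form uses 'x' wildcards with the centre bracketed and flanking
    wildcards trimmed, e.g. "Pxx[S]" or "[T]xxxxxxxxxP".
    """

    fixed: tuple[tuple[int, str], ...]
    flank: int = DEFAULT_FLANK

    def __post_init__(self):
        offsets = dict(self.fixed)
        if 0 not in offsets:
            raise ValueError("motif centre (offset 0) must be fixed")
        if offsets[0] not in ("S", "T"):
            raise ValueError("motif centre must be S or T")
        object.__setattr__(self, "fixed", tuple(sorted(offsets.items())))

    @property
    def fixed_map(self) -> dict[int, str]:
        return dict(self.fixed)

    @property
    def center(self) -> str:
        return self.fixed_map[0]

    @property
    def width(self) -> int:
        return 2 * self.flank + 1

    def to_string(self) -> str:
        fixed = self.fixed_map
        lo = min(fixed)
        hi = max(fixed)
        out = []
        for off in range(lo, hi + 1):
            ch = fixed.get(off, "x")
            out.append(f"[{ch}]" if off == 0 else ch)
        return "".join(out)

    @classmethod
    def from_string(cls, text: str, flank: int = DEFAULT_FLANK) -> "MotifPattern":
        tokens = re.findall(r"\[[A-Z]\]|[A-Zx]", text)
        if "".join(tokens) != text:
            raise ValueError(f"cannot parse motif string {text!r}")
        centre_idx = [i for i, t in enumerate(tokens) if t.startswith("[")]
        if len(centre_idx) != 1:
            raise ValueError(f"motif {text!r} must bracket exactly one centre residue")
        c = centre_idx[0]
        fixed = {}
        for i, tok in enumerate(tokens):
            letter = tok.strip("[]")
            if letter != "x":
                fixed[i - c] = letter
        return cls(fixed=tuple(fixed.items()), flank=flank)

    def matches(self, window: str) -> bool:
        """Does a (2*flank+1)-character centred window match every fixed position?"""
        if len(window) != self.width:
            raise ValueError(f"window length {len(window)} != motif width {self.width}")
        return all(window[off + self.flank] == ch for off, ch in self.fixed)


@dataclass
class MotifxStep:
    offset: int
    residue: str
    p_value: float
    fg_count: int


@dataclass
class ExtractedMotif:
    pattern: MotifPattern
    fg_matches: int
    bg_matches: int
    steps: list[MotifxStep]


def motifx_extract(
    fg_windows,
    bg_windows,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_count: int = DEFAULT_MIN_COUNT,
    flank: int = DEFAULT_FLANK,
) -> list[ExtractedMotif]:
    """Extract overrepresented motifs from centred windows, motif-x style.

    Foreground and background windows must have width 2*flank+1 and S/T
    centres; S-centred and T-centred windows are processed separately.
    Returns motifs in extraction order (strongest first within each centre).
    """
    width = 2 * flank + 1
    for w in list(fg_windows) + list(bg_windows):
        if len(w) != width:
            raise ValueError(f"window {w!r} does not have width {width}")
    motifs: list[ExtractedMotif] = []
    for centre in ("S", "T"):
        fg = [w for w in fg_windows if w[flank] == centre]
        bg = [w for w in bg_windows if w[flank] == centre]
        motifs.extend(
            _extract_for_centre(fg, bg, centre, p_threshold, min_count, flank)
        )
    return motifs


def _extract_for_centre(fg, bg, centre, p_threshold, min_count, flank):
    motifs: list[ExtractedMotif] = []
    while len(fg) >= min_count:
        cur_fg, cur_bg = list(fg), list(bg)
        fixed = {0: centre}
        steps: list[MotifxStep] = []
        while True:
            best = _best_fixation(cur_fg, cur_bg, fixed, min_count, flank)
            if best is None or best.p_value >= p_threshold:
                break
            fixed[best.offset] = best.residue
            steps.append(best)
            col = best.offset + flank
            cur_fg = [w for w in cur_fg if w[col] == best.residue]
            cur_bg = [w for w in cur_bg if w[col] == best.residue]
        if not steps:
            break
        pattern = MotifPattern(fixed=tuple(fixed.items()), flank=flank)
        motifs.append(
            ExtractedMotif(
                pattern=pattern,
                fg_matches=len(cur_fg),
                bg_matches=len(cur_bg),
                steps=steps,
            )
        )
        fg = [w for w in fg if not pattern.matches(w)]
    return motifs


def _best_fixation(cur_fg, cur_bg, fixed, min_count, flank):
    """Smallest-p (offset, residue) candidate; ties resolve to the lower
    offset then the alphabetically first residue."""
    if not cur_fg or not cur_bg:
        return None
    n_fg = len(cur_fg)
    n_bg = len(cur_bg)
    best: MotifxStep | None = None
    for offset in range(-flank, flank + 1):
        if offset in fixed:
            continue
        col = offset + flank
        fg_counts: dict[str, int] = {}
        for w in cur_fg:
            fg_counts[w[col]] = fg_counts.get(w[col], 0) + 1
        for residue in sorted(fg_counts):
            if residue == "*" or fg_counts[residue] < min_count:
                continue
            f_bg = sum(1 for w in cur_bg if w[col] == residue) / n_bg
            p = float(binom.sf(fg_counts[residue] - 1, n_fg, f_bg))
            if best is None or p < best.p_value:
                best = MotifxStep(
                    offset=offset, residue=residue, p_value=p,
                    fg_count=fg_counts[residue],
                )
    return best


@dataclass
class MotifOccurrence:
    protein_id: str
    position: int  # 1-based centre position
    fixed_positions: list[int]  # 1-based positions of all fixed residues
    conservation: float | None = None
    retained: bool = False


@dataclass
class MotifResult:
    motif: ExtractedMotif
    occurrences: list[MotifOccurrence] = field(default_factory=list)
    surviving_proteins: list[str] = field(default_factory=list)
    enrichment: list[EnrichmentRow] = field(default_factory=list)
    functional: bool = False


def find_occurrences(pattern: MotifPattern, proteins, flank: int = DEFAULT_FLANK):
    """All centred-window matches of a motif across a protein collection."""
    occurrences = []
    for prot in proteins:
        for pos in range(1, len(prot.sequence) + 1):
            if prot.sequence[pos - 1] != pattern.center:
                continue
            window = extract_window(prot.sequence, pos, flank)
            if pattern.matches(window):
                occurrences.append(
                    MotifOccurrence(
                        protein_id=prot.id,
                        position=pos,
                        fixed_positions=sorted(pos + off for off, _ in pattern.fixed),
                    )
                )
    return occurrences


def motif_pipeline(
    catalog: SiteCatalog,
    proteins,
    msas: dict[str, OrthologAlignment],
    go: GOAnnotationMap,
    conservation_cutoff: float = DEFAULT_CONSERVATION_CUTOFF,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_count: int = DEFAULT_MIN_COUNT,
    flank: int = DEFAULT_FLANK,
    alpha: float = DEFAULT_ALPHA,
) -> list[MotifResult]:
    """Cross-talk motif discovery with conservation filtering and enrichment.

    Foreground = windows around cross-talk sites; background = every
    S/T-centred window in the protein collection.  Occurrences with mean
    fixed-position conservation < conservation_cutoff are dropped
    (strictly-below removal, so a score exactly at the cutoff is retained);
    proteins keeping at least one occurrence are enriched against the
    proteins carrying any catalogued site.  A motif with any term at
    corrected p < alpha is flagged functional.
    """
    seq_by_id = {p.id: p.sequence for p in proteins}
    fg_windows = [
        extract_window(seq_by_id[pid], pos, flank)
        for pid, pos in catalog.crosstalk_sites
        if pid in seq_by_id
    ]
    bg_windows = [
        extract_window(p.sequence, pos, flank)
        for p in proteins
        for pos in range(1, len(p.sequence) + 1)
        if p.sequence[pos - 1] in ("S", "T")
    ]
    extracted = motifx_extract(
        fg_windows, bg_windows, p_threshold=p_threshold,
        min_count=min_count, flank=flank,
    )
    site_proteins = sorted({pid for pid, _ in catalog.positions})
    results = []
    for motif in extracted:
        occurrences = find_occurrences(motif.pattern, proteins, flank)
        for occ in occurrences:
            aln = msas.get(occ.protein_id)
            if aln is None:
                logger.warning(
                    "no MSA for protein %s; motif occurrence at %d skipped",
                    occ.protein_id, occ.position,
                )
                continue
            occ.conservation = motif_conservation(aln, occ.fixed_positions)
            occ.retained = occ.conservation >= conservation_cutoff
        surviving = sorted({o.protein_id for o in occurrences if o.retained})
        enrichment = (
            fisher_enrichment(surviving, site_proteins, go, alpha=alpha)
            if surviving else []
        )
        functional = any(r.p_bonferroni < alpha for r in enrichment)
        results.append(
            MotifResult(
                motif=motif,
                occurrences=occurrences,
                surviving_proteins=surviving,
                enrichment=enrichment,
                functional=functional,
            )
        )
    return results
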