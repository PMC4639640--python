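"""Sequence / site-table / GO-annotation input, site classification and sampling.

Positions are 1-based inclusive in every public interface; 0-based indices
are internal only and never leak.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

logger = logging.getLogger(__name__)

MODIFICATIONS = frozenset({"phospho", "oglcnac"})
SITE_RESIDUES = frozenset({"S", "T"})

CROSSTALK = "crosstalk"
PHOSPHO_ONLY = "phospho_only"
OGLCNAC_ONLY = "oglcnac_only"

#: default negative/positive sampling ratio per classifier basis
DEFAULT_NEG_POS_RATIO = {"phos_based": 10.0, "glcnac_based": 2.0}


class FastaError(ValueError):
    """Raised for structurally invalid FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PTMSiteRecord:
    """One modification event at a 1-based position of a protein."""

    protein_id: str
    position: int
    residue: str
    modification: str

    def __post_init__(self) -> None:
        if self.residue not in SITE_RESIDUES:
            raise ValueError(
                f"site {self.protein_id}:{self.position}: residue must be S or T, "
                f"got {self.residue!r}"
            )
        if self.modification not in MODIFICATIONS:
            raise ValueError(
                f"site {self.protein_id}:{self.position}: unknown modification "
                f"{self.modification!r}"
            )
        if self.position < 1:
            raise ValueError(
                f"site {self.protein_id}:{self.position}: position must be >= 1"
            )


class SiteCatalog:
    """All accepted PTM sites, partitioned into cross-talk / single-PTM classes.

    A distinct (protein_id, position) pair is ``crosstalk`` iff both
    modification types were recorded at that exact position, otherwise
    ``phospho_only`` or ``oglcnac_only``.
    """

    def __init__(self, sites, rejected=None):
        self.sites: list[PTMSiteRecord] = list(sites)
        self.rejected: list[tuple[dict, str]] = list(rejected or [])
        mods: dict[tuple[str, int], set[str]] = {}
        residues: dict[tuple[str, int], str] = {}
        for s in self.sites:
            key = (s.protein_id, s.position)
            mods.setdefault(key, set()).add(s.modification)
            prev = residues.setdefault(key, s.residue)
            if prev != s.residue:
                raise ValueError(
                    f"conflicting residue letters at {s.protein_id}:{s.position}: "
                    f"{prev} vs {s.residue}"
                )
        self._residue = residues
        self._class: dict[tuple[str, int], str] = {}
        for key, m in mods.items():
            if m == MODIFICATIONS:
                self._class[key] = CROSSTALK
            elif m == {"phospho"}:
                self._class[key] = PHOSPHO_ONLY
            else:
                self._class[key] = OGLCNAC_ONLY

    def class_of(self, protein_id: str, position: int) -> str:
        return self._class[(protein_id, position)]

    def residue_of(self, protein_id: str, position: int) -> str:
        return self._residue[(protein_id, position)]

    @property
    def positions(self) -> list[tuple[str, int]]:
        """All distinct (protein_id, position) pairs, sorted."""
        return sorted(self._class)

    def sites_in_class(self, cls: str) -> list[tuple[str, int]]:
        return sorted(k for k, v in self._class.items() if v == cls)

    @property
    def crosstalk_sites(self):
        return self.sites_in_class(CROSSTALK)

    @property
    def phospho_only_sites(self):
        return self.sites_in_class(PHOSPHO_ONLY)

    @property
    def oglcnac_only_sites(self):
        return self.sites_in_class(OGLCNAC_ONLY)


@dataclass
class GOAnnotationMap:
    """protein_id -> set of GO term ids, plus the sorted term universe."""

    mapping: dict[str, set[str]]
    universe: list[str] = field(default_factory=list)

    @classmethod
    def from_pairs(cls, pairs) -> "GOAnnotationMap":
        mapping: dict[str, set[str]] = {}
        terms: set[str] = set()
        for pid, term in pairs:
            mapping.setdefault(pid, set()).add(term)
            terms.add(term)
        return cls(mapping=mapping, universe=sorted(terms))

    def terms_of(self, protein_id: str) -> set[str]:
        return self.mapping.get(protein_id, set())


@dataclass
class TrainingSet:
    """Ordered labeled site instances for one classifier basis."""

    instances: list[tuple[str, int]]
    labels: list[int]
    basis: str
    neg_pos_ratio: float
    achieved_ratio: float

    def __len__(self) -> int:
        return len(self.instances)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords.

    Sequences are upper-cased.  Duplicate ids, empty ids, empty sequences and
    sequence data before the first header are reported with the offending
    line number.
    """
    path = Path(path)
    _validate_fasta_structure(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def _validate_fasta_structure(path: Path) -> None:
    header_line = None
    has_seq = False
    saw_any = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header_line is not None and not has_seq:
                    raise FastaError(f"{path}:{header_line}: record has no sequence")
                if not line[1:].split():
                    raise FastaError(f"{path}:{lineno}: empty FASTA header")
                header_line, has_seq, saw_any = lineno, False, True
            else:
                if header_line is None:
                    raise FastaError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                has_seq = True
    if saw_any and not has_seq:
        raise FastaError(f"{path}:{header_line}: record has no sequence")


def read_site_table(path, proteins) -> SiteCatalog:
    """Read a TSV site table and validate each row against the sequences.

    Expected columns: protein_id, position (1-based), residue, modification.
    Rows whose protein is unknown, whose position is out of bounds or whose
    residue letter disagrees with the sequence are rejected, logged and
    counted (``catalog.rejected``).  Duplicate identical rows collapse.
    """
    seq_by_id = {p.id: p.sequence for p in proteins}
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["protein_id", "position", "residue", "modification"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: site table missing columns {missing}")

    accepted: dict[PTMSiteRecord, None] = {}
    rejected: list[tuple[dict, str]] = []
    for row in df.itertuples(index=False):
        d = {
            "protein_id": row.protein_id,
            "position": int(row.position),
            "residue": str(row.residue).upper(),
            "modification": str(row.modification),
        }
        seq = seq_by_id.get(d["protein_id"])
        if seq is None:
            rejected.append((d, "unknown protein"))
            continue
        if not 1 <= d["position"] <= len(seq):
            rejected.append((d, f"position out of bounds (length {len(seq)})"))
            continue
        if seq[d["position"] - 1] != d["residue"]:
            rejected.append(
                (d, f"residue mismatch: sequence has {seq[d['position'] - 1]!r}")
            )
            continue
        try:
            rec = PTMSiteRecord(**d)
        except ValueError as exc:
            rejected.append((d, str(exc)))
            continue
        accepted[rec] = None  # dict preserves order, collapses duplicates

    for d, reason in rejected:
        logger.warning(
            "rejected site row %s:%s (%s): %s",
            d["protein_id"], d["position"], d["residue"], reason,
        )
    if rejected:
        logger.warning("rejected %d site rows in total", len(rejected))
    return SiteCatalog(accepted, rejected=rejected)


_ALIGNER = None


def _global_aligner() -> PairwiseAligner:
    # fixed simple scheme: match +1, mismatch -1, gap -2
    global _ALIGNER
    if _ALIGNER is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -2
        a.extend_gap_score = -2
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity = matched positions / alignment length."""
    aln = _global_aligner().align(a, b)[0]
    matches = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        matches = matches + sum(
            1 for x, y in zip(a[s1:e1], b[s2:e2]) if x == y
        )
    return matches / aln.length


def redundancy_reduce(proteins, identity_threshold: float = 0.7, seed: int = 0):
    """Greedy identity clustering with a seeded random representative per cluster.

    Proteins are processed by descending length (ties by id).  Each protein
    joins the first cluster whose founder shares pairwise identity >=
    ``identity_threshold``, otherwise it founds a new cluster.

    Returns ``(representatives, assignment)`` where assignment maps
    protein_id -> cluster index.
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("redundancy_reduce requires at least one protein")
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(proteins, key=lambda p: (-len(p.sequence), p.id))
    founders: list[ProteinRecord] = []
    clusters: list[list[ProteinRecord]] = []
    assignment: dict[str, int] = {}
    for prot in ordered:
        for idx, founder in enumerate(founders):
            if pairwise_identity(prot.sequence, founder.sequence) >= identity_threshold:
                clusters[idx].append(prot)
                assignment[prot.id] = idx
                break
        else:
            founders.append(prot)
            clusters.append([prot])
            assignment[prot.id] = len(clusters) - 1
    rng = random.Random(seed)
    representatives = [rng.choice(members) for members in clusters]
    logger.info(
        "redundancy reduction: %d proteins -> %d clusters at identity >= %.2f",
        len(proteins), len(clusters), identity_threshold,
    )
    return representatives, assignment


def build_training_set(
    catalog: SiteCatalog,
    basis: str,
    neg_pos_ratio: float | Fraction | None = None,
    seed: int = 0,
) -> TrainingSet:
    """Assemble a ratio-controlled labeled site list.

    All cross-talk sites are positives.  Negatives (phospho_only for
    phos_based, oglcnac_only for glcnac_based) are drawn uniformly without
    replacement to reach ``round(ratio * n_positives)``; if too few exist,
    all are used and the achieved ratio is logged as a warning.
    """
    if basis not in DEFAULT_NEG_POS_RATIO:
        raise ValueError(f"unknown basis {basis!r}")
    if neg_pos_ratio is None:
        neg_pos_ratio = DEFAULT_NEG_POS_RATIO[basis]
    neg_pos_ratio = float(neg_pos_ratio)
    if neg_pos_ratio <= 0:
        raise ValueError("neg_pos_ratio must be positive")

    positives = catalog.crosstalk_sites
    if not positives:
        raise ValueError("catalog contains no crosstalk sites")
    pool = (
        catalog.phospho_only_sites if basis == "phos_based"
        else catalog.oglcnac_only_sites
    )
    wanted = round(neg_pos_ratio * len(positives))
    rng = random.Random(seed)
    if wanted >= len(pool):
        negatives = list(pool)
        if wanted > len(pool):
            logger.warning(
                "only %d negatives available for %d requested; achieved ratio %.3f",
                len(pool), wanted, len(pool) / len(positives),
            )
    else:
        negatives = rng.sample(pool, wanted)
    instances = list(positives) + sorted(negatives)
    labels = [1] * len(positives) + [0] * len(negatives)
    return TrainingSet(
        instances=instances,
        labels=labels,
        basis=basis,
        neg_pos_ratio=neg_pos_ratio,
        achieved_ratio=len(negatives) / len(positives),
    )


def read_go_annotations(path, dialect: str = "tsv2col") -> GOAnnotationMap:
    """Read protein -> GO term annotations.

    dialect "tsv2col": two tab-separated columns (protein_id, term), no
    header required (a header row whose second field does not look like data
    is kept as data — callers should not include one).
    dialect "gaf": GAF 2.x, '!' comment lines skipped, columns 2 and 5 used.
    """
    pairs: list[tuple[str, str]] = []
    if dialect == "tsv2col":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
                pairs.append((parts[0], parts[1]))
    elif dialect == "gaf":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                if raw.startswith("!") or not raw.strip():
                    continue
                parts = raw.rstrip("\n").split("\t")
                if len(parts) < 5:
                    raise ValueError(f"{path}:{lineno}: GAF line has fewer than 5 columns")
                pairs.append((parts[1], parts[4]))
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return GOAnnotationMap.from_pairs(pairs)
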