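"""Binary feature construction: sparse-encoded sequence windows + GO indicators."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_data import GOAnnotationMap, TrainingSet

logger = logging.getLogger(__name__)

#: 20 standard amino acids (alphabetical) followed by the padding symbol.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY*"
_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}

DEFAULT_FLANK = 10


def extract_window(sequence: str, position: int, flank: int = DEFAULT_FLANK) -> str:
    """Return the (2*flank+1)-residue window centred on a 1-based position,
    '*'-padded where the window runs past either terminus."""
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    centre = sequence[position - 1]
    if centre not in ("S", "T"):
        logger.warning("window centre at position %d is %r, not S/T", position, centre)
    i = position - 1
    left = sequence[max(0, i - flank): i]
    right = sequence[i + 1: i + 1 + flank]
    return "*" * (flank - len(left)) + left + centre + right + "*" * (flank - len(right))


def encode_window(window: str) -> np.ndarray:
    """Sparse-encode a window: one 21-bit one-hot block per position.

    Block alphabet is ALPHABET (A..Y then '*').  Characters outside the
    alphabet map to '*' with a logged warning.  Output length is
    ``len(window) * 21`` and contains exactly ``len(window)`` ones.
    """
    vec = np.zeros(len(window) * len(ALPHABET), dtype=np.uint8)
    for pos, ch in enumerate(window):
        idx = _INDEX.get(ch)
        if idx is None:
            logger.warning("character %r not in alphabet; encoding as '*'", ch)
            idx = _INDEX["*"]
        vec[pos * len(ALPHABET) + idx] = 1
    return vec


def window_feature_names(flank: int = DEFAULT_FLANK) -> list[str]:
    """Column names "pos{offset}:{letter}" matching encode_window layout."""
    return [
        f"pos{offset:+d}:{letter}"
        for offset in range(-flank, flank + 1)
        for letter in ALPHABET
    ]


@dataclass
class FeatureMatrix:
    """Binary site-by-feature matrix: sequence block then GO indicator block."""

    rows: list[tuple[str, int]]
    values: np.ndarray
    column_names: list[str]
    n_seq_cols: int

    @property
    def sequence_block(self) -> np.ndarray:
        return self.values[:, : self.n_seq_cols]

    @property
    def go_block(self) -> np.ndarray:
        return self.values[:, self.n_seq_cols:]

    @property
    def go_column_names(self) -> list[str]:
        return self.column_names[self.n_seq_cols:]


def assemble_features(
    sites: TrainingSet,
    proteins,
    go: GOAnnotationMap,
    flank: int = DEFAULT_FLANK,
) -> FeatureMatrix:
    """Build the full feature matrix for a training set.

    Row order follows the training set.  The GO block of a row depends only
    on the site's protein; proteins absent from the annotation map get an
    all-zero GO block.
    """
    seq_by_id = {p.id: p.sequence for p in proteins}
    width = 2 * flank + 1
    n_seq_cols = width * len(ALPHABET)
    go_index = {term: j for j, term in enumerate(go.universe)}

    values = np.zeros((len(sites.instances), n_seq_cols + len(go.universe)), dtype=np.uint8)
    go_cache: dict[str, np.ndarray] = {}
    for i, (pid, pos) in enumerate(sites.instances):
        seq = seq_by_id.get(pid)
        if seq is None:
            raise ValueError(f"no sequence available for protein {pid!r}")
        values[i, :n_seq_cols] = encode_window(extract_window(seq, pos, flank))
        row = go_cache.get(pid)
        if row is None:
            row = np.zeros(len(go.universe), dtype=np.uint8)
            for term in go.terms_of(pid):
                row[go_index[term]] = 1
            go_cache[pid] = row
        values[i, n_seq_cols:] = row

    return FeatureMatrix(
        rows=list(sites.instances),
        values=values,
        column_names=window_feature_names(flank) + list(go.universe),
        n_seq_cols=n_seq_cols,
    )


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    """Serialize as TSV: two id columns then one column per feature."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\t" + "\t".join(fm.column_names) + "\n")
        for (pid, pos), row in zip(fm.rows, fm.values):
            fh.write(f"{pid}\t{pos}\t" + "\t".join(map(str, row)) + "\n")


def write_sparse_triplets(fm: FeatureMatrix, path) -> None:
    """Sparse triplet serialization for matrices with large GO blocks.

    Layout: three '#'-prefixed header lines (shape, row ids as
    ``protein:position``, column names), then one ``row<TAB>col<TAB>1`` line
    per set bit, indices 0-based.
    """
    rows, cols = np.nonzero(fm.values)
    with open(path, "w") as fh:
        fh.write(f"#shape\t{fm.values.shape[0]}\t{fm.values.shape[1]}\t{fm.n_seq_cols}\n")
        fh.write("#rows\t" + "\t".join(f"{pid}:{pos}" for pid, pos in fm.rows) + "\n")
        fh.write("#columns\t" + "\t".join(fm.column_names) + "\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r}\t{c}\t1\n")


def read_sparse_triplets(path) -> FeatureMatrix:
    with open(path) as fh:
        _, n_rows, n_cols, n_seq_cols = fh.readline().rstrip("\n").split("\t")
        row_ids = fh.readline().rstrip("\n").split("\t")[1:]
        column_names = fh.readline().rstrip("\n").split("\t")[1:]
        values = np.zeros((int(n_rows), int(n_cols)), dtype=np.uint8)
        for line in fh:
            r, c, v = line.split("\t")
            values[int(r), int(c)] = int(v)
    rows = []
    for token in row_ids:
        pid, _, pos = token.rpartition(":")
        rows.append((pid, int(pos)))
    return FeatureMatrix(
        rows=rows, values=values, column_names=column_names,
        n_seq_cols=int(n_seq_cols),
    )


def read_feature_matrix(path, n_seq_cols: int | None = None) -> FeatureMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        column_names = header[2:]
        rows: list[tuple[str, int]] = []
        data: list[list[int]] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append((parts[0], int(parts[1])))
            data.append([int(v) for v in parts[2:]])
    if n_seq_cols is None:
        n_seq_cols = sum(1 for c in column_names if c.startswith("pos"))
    return FeatureMatrix(
        rows=rows,
        values=np.asarray(data, dtype=np.uint8),
        column_names=column_names,
        n_seq_cols=n_seq_cols,
    )
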