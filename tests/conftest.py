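import numpy as np
import pytest

from ptmx.conservation import OrthologAlignment
from ptmx.io_data import ProteinRecord, PTMSiteRecord, SiteCatalog


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_catalog(n_crosstalk=5, n_phospho=100, n_oglcnac=10):
    """One long all-S protein per class; positions 1..n on each."""
    sites = []
    proteins = []
    specs = [
        ("CT", n_crosstalk, ("phospho", "oglcnac")),
        ("PH", n_phospho, ("phospho",)),
        ("OG", n_oglcnac, ("oglcnac",)),
    ]
    for prefix, count, mods in specs:
        if count == 0:
            continue
        pid = f"{prefix}1"
        proteins.append(ProteinRecord(pid, "S" * max(count, 1)))
        for pos in range(1, count + 1):
            for mod in mods:
                sites.append(PTMSiteRecord(pid, pos, "S", mod))
    return proteins, SiteCatalog(sites)


def column_alignment(column_fractions, ref_letter="S", n_rows=10, other="A"):
    """Build an MSA whose per-column match fraction (including the reference)
    is exactly column_fractions[i] * n_rows rows."""
    length = len(column_fractions)
    rows = []
    for r in range(n_rows):
        chars = []
        for frac in column_fractions:
            n_match = round(frac * n_rows)
            assert n_match >= 1, "reference always matches itself"
            chars.append(ref_letter if r < n_match else other)
        rows.append("".join(chars))
    ids = ["REF"] + [f"sp{i}" for i in range(1, n_rows)]
    return OrthologAlignment(ids=ids, rows=rows, reference_id="REF")


@pytest.fixture
def catalog_small():
    return make_catalog()
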