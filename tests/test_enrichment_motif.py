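from fractions import Fraction
from math import comb

import numpy as np
import pytest

from ptmx.enrichment_motif import (
    MotifPattern,
    find_occurrences,
    fisher_enrichment,
    motif_pipeline,
    motifx_extract,
)
from ptmx.io_data import GOAnnotationMap, ProteinRecord, PTMSiteRecord, SiteCatalog

from conftest import column_alignment


def fisher_two_tailed_oracle(a, b, c, d):
    """Exact rational enumeration of all tables with fixed margins: sum the
    hypergeometric probabilities of tables as or less probable than observed."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)

    def pmf(x):
        return Fraction(comb(row1, x) * comb(n - row1, col1 - x), denom)

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        if pmf(x) <= p_obs:
            total += pmf(x)
    return float(total)


def make_go(mapping):
    return GOAnnotationMap.from_pairs(
        [(pid, t) for pid, terms in mapping.items() for t in terms]
    )


class TestFisherEnrichment:
    def test_untested_terms_excluded(self):
        go = make_go({"F1": {"GO:A"}, "B1": {"GO:B"}})
        rows = fisher_enrichment(["F1"], ["B1", "B2"], go)
        assert [r.term for r in rows] == ["GO:A"]

    def test_self_comparison_nothing_passes(self):
        go = make_go({"P1": {"GO:A"}, "P2": {"GO:A", "GO:B"}})
        rows = fisher_enrichment(["P1", "P2"], ["P1", "P2"], go)
        assert all(r.ratio == 1.0 for r in rows)
        assert not any(r.passes for r in rows)

    def test_derived_table(self):
        # fg: 8/10 with term; bg: 10/100 with term -> ratio 8
        fg = [f"F{i}" for i in range(10)]
        bg = [f"B{i}" for i in range(100)]
        mapping = {p: {"GO:X"} for p in fg[:8]} | {p: {"GO:X"} for p in bg[:10]}
        rows = fisher_enrichment(fg, bg, make_go(mapping))
        row = rows[0]
        assert row.ratio == pytest.approx(8.0)
        assert row.p_raw == pytest.approx(
            fisher_two_tailed_oracle(8, 2, 10, 90), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(15))
    def test_enumeration_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 61))
        n_fg = int(r.integers(1, n))
        n_bg = n - n_fg
        if n_bg == 0:
            n_fg, n_bg = n - 1, 1
        a = int(r.integers(0, n_fg + 1))
        c = int(r.integers(0, n_bg + 1))
        fg = [f"F{i}" for i in range(n_fg)]
        bg = [f"B{i}" for i in range(n_bg)]
        mapping = {p: {"GO:X"} for p in fg[:a]} | {p: {"GO:X"} for p in bg[:c]}
        if a == 0:
            return  # term annotates nothing in fg -> not tested
        rows = fisher_enrichment(fg, bg, make_go(mapping))
        assert rows[0].p_raw == pytest.approx(
            fisher_two_tailed_oracle(a, n_fg - a, c, n_bg - c), abs=1e-12
        )

    def test_bonferroni_never_decreases_and_passes_implies_raw(self):
        r = np.random.default_rng(3)
        fg = [f"F{i}" for i in range(12)]
        bg = [f"B{i}" for i in range(60)]
        mapping = {}
        for p in fg + bg:
            mapping[p] = {f"GO:{int(t)}" for t in r.integers(0, 8, size=3)}
        rows = fisher_enrichment(fg, bg, make_go(mapping))
        for row in rows:
            assert row.p_bonferroni >= row.p_raw
            assert row.p_bonferroni <= 1.0
            if row.passes:
                assert row.p_raw < 0.05 and row.ratio > 4

    def test_empty_fg_error(self):
        with pytest.raises(ValueError):
            fisher_enrichment([], ["B1"], make_go({"B1": {"GO:A"}}))


class TestMotifPattern:
    @pytest.mark.parametrize("text", ["Pxx[S]", "[T]xxxxxxxxxP", "[S]", "RxR[T]xK"])
    def test_string_roundtrip(self, text):
        assert MotifPattern.from_string(text).to_string() == text

    def test_centre_required(self):
        with pytest.raises(ValueError):
            MotifPattern(fixed=((3, "P"),))
        with pytest.raises(ValueError):
            MotifPattern.from_string("PxxS")

    def test_centre_must_be_st(self):
        with pytest.raises(ValueError):
            MotifPattern.from_string("[A]")

    def test_matches(self):
        pat = MotifPattern.from_string("Pxx[S]")
        w_hit = "A" * 7 + "P" + "AA" + "S" + "A" * 10
        w_miss = "A" * 10 + "S" + "A" * 10
        assert pat.matches(w_hit)
        assert not pat.matches(w_miss)


def windows_from(rng, n, centre="S", fixed=None, letters="ACDEFGHIKLMNPQRVWY"):
    out = []
    for _ in range(n):
        w = list(rng.choice(list(letters), size=21))
        w[10] = centre
        for off, ch in (fixed or {}).items():
            w[10 + off] = ch
        out.append("".join(w))
    return out


class TestMotifxExtract:
    def test_planted_dominant_position(self, rng):
        fg = windows_from(rng, 60, fixed={3: "P"})
        bg = windows_from(rng, 500)
        motifs = motifx_extract(fg, bg, p_threshold=1e-6, min_count=20)
        assert motifs
        assert motifs[0].steps[0].offset == 3
        assert motifs[0].steps[0].residue == "P"

    def test_null_composition_no_motifs(self, rng):
        fg = windows_from(rng, 100)
        bg = windows_from(rng, 1000)
        assert motifx_extract(fg, bg, p_threshold=1e-6, min_count=20) == []

    def test_fg_below_min_count_empty(self, rng):
        fg = windows_from(rng, 5, fixed={3: "P"})
        bg = windows_from(rng, 100)
        assert motifx_extract(fg, bg, min_count=20) == []

    def test_emitted_motifs_meet_min_count(self, rng):
        fg = windows_from(rng, 200, fixed={-2: "K"}) + windows_from(rng, 100)
        bg = windows_from(rng, 2000)
        for m in motifx_extract(fg, bg, p_threshold=1e-6, min_count=20):
            assert m.fg_matches >= 20

    def test_two_planted_motifs_recovered_in_strength_order(self, rng):
        n = 500
        fg = (
            windows_from(rng, int(n * 0.4), centre="S", fixed={-3: "P"})
            + windows_from(rng, int(n * 0.3), centre="S", fixed={4: "R"})
            + windows_from(rng, int(n * 0.3), centre="S")
        )
        bg = windows_from(rng, 3000, centre="S")
        motifs = motifx_extract(fg, bg, p_threshold=1e-6, min_count=20)
        strings = [m.pattern.to_string() for m in motifs]
        assert strings[0] == "Pxx[S]"
        assert "[S]xxxR" in strings[1:]


class TestMotifPipeline:
    def _setup(self, conservation_fraction, n_rows=10):
        rng = np.random.default_rng(7)
        proteins, sites = [], []
        msas = {}
        for i in range(30):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNQVWY"), size=41))
            seq = seq[:17] + "P" + seq[18:20] + "S" + seq[21:]  # Pxx[S] at pos 21
            pid = f"P{i}"
            proteins.append(ProteinRecord(pid, seq))
            sites.append(PTMSiteRecord(pid, 21, "S", "phospho"))
            sites.append(PTMSiteRecord(pid, 21, "S", "oglcnac"))
            msas[pid] = _uniform_alignment(seq, conservation_fraction, n_rows)
        # background-only proteins: plenty of S-centred windows, no P at -3 bias
        for i in range(40):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNQVWYS"), size=41))
            prot = ProteinRecord(f"BG{i}", seq)
            proteins.append(prot)
            msas[prot.id] = _uniform_alignment(seq, conservation_fraction, n_rows)
        catalog = SiteCatalog(sites)
        go = make_go({p.id: {"GO:A"} for p in proteins[:15]})
        return catalog, proteins, msas, go

    def test_full_conservation_nothing_filtered(self):
        catalog, proteins, msas, go = self._setup(1.0)
        results = motif_pipeline(
            catalog, proteins, msas, go, p_threshold=1e-4, min_count=10
        )
        assert results
        res = results[0]
        assert all(o.retained for o in res.occurrences if o.conservation is not None)
        assert set(res.surviving_proteins) <= {o.protein_id for o in res.occurrences}

    def test_conservation_below_cutoff_all_filtered(self):
        catalog, proteins, msas, go = self._setup(0.39, n_rows=100)
        results = motif_pipeline(
            catalog, proteins, msas, go, p_threshold=1e-4, min_count=10
        )
        assert results
        assert results[0].surviving_proteins == []
        assert results[0].enrichment == []

    def test_boundary_exactly_at_cutoff_retained(self):
        catalog, proteins, msas, go = self._setup(0.4, n_rows=10)
        results = motif_pipeline(
            catalog, proteins, msas, go, p_threshold=1e-4, min_count=10
        )
        assert results[0].surviving_proteins  # 0.4 is retained (strict < removal)

    def test_missing_msa_skips_occurrence(self, caplog):
        catalog, proteins, msas, go = self._setup(1.0)
        del msas[proteins[0].id]
        with caplog.at_level("WARNING"):
            results = motif_pipeline(
                catalog, proteins, msas, go, p_threshold=1e-4, min_count=10
            )
        assert any("no MSA" in r.message for r in caplog.records)
        assert proteins[0].id not in results[0].surviving_proteins


def _uniform_alignment(seq, fraction, n_rows):
    """MSA where every column's match fraction is exactly `fraction`."""
    n_match = round(fraction * n_rows)
    rows = []
    for r in range(n_rows):
        if r < n_match:
            rows.append(seq)
        else:
            rows.append("".join("W" if c != "W" else "Y" for c in seq))
    ids = [f"sp{r}" for r in range(n_rows)]
    ids[0] = "REF"
    return __import__("ptmx.conservation", fromlist=["OrthologAlignment"]).OrthologAlignment(
        ids=ids, rows=rows, reference_id="REF"
    )


def test_find_occurrences_reports_fixed_positions():
    pat = MotifPattern.from_string("Pxx[S]")
    prots = [
        ProteinRecord("P1", "AAAAPAAS" + "A" * 13),
        ProteinRecord("P2", "SAAAA" + "A" * 16),  # P would fall before residue 1
    ]
    occ = find_occurrences(pat, prots)
    assert [(o.protein_id, o.position) for o in occ] == [("P1", 8)]
    assert occ[0].fixed_positions == [5, 8]
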