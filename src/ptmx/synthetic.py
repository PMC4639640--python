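"""Seeded synthetic-data generator with known ground truth.

Produces protein sequences with planted cross-talk sites, GO annotations
whose informative terms track the cross-talk label with a configurable flip
probability, sequence motifs planted at controlled prevalence, and ortholog
MSAs with controlled per-column conservation — everything the other modules
consume, with the truth recorded alongside.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .conservation import OrthologAlignment
from .enrichment_motif import MotifPattern
from .features import DEFAULT_FLANK
from .io_data import ProteinRecord, PTMSiteRecord, SiteCatalog

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    n_crosstalk: int = 150
    n_phospho_only: int = 300
    n_oglcnac_only: int = 150
    length_range: tuple[int, int] = (60, 80)
    n_go_noise: int = 1990
    n_go_informative: int = 10
    epsilon: float = 0.15
    go_noise_rate: float = 0.1
    #: (motif string, prevalence among cross-talk sites); prevalences summed <= 1
    motifs: tuple[tuple[str, float], ...] = (("Pxx[S]", 0.4),)
    n_species: int = 10
    site_conservation: float = 0.9
    flank_conservation: float = 0.6
    gap_rate: float = 0.05
    mixed_proteins: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.n_crosstalk, self.n_phospho_only, self.n_oglcnac_only) < 0:
            raise ValueError("site counts must be non-negative")
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must lie in [0, 0.5)")
        for pattern, prevalence in self.motifs:
            if not 0 <= prevalence <= 1:
                raise ValueError(f"motif prevalence {prevalence} outside [0, 1]")
            MotifPattern.from_string(pattern)  # validates syntax
        if sum(p for _, p in self.motifs) > 1:
            raise ValueError("motif prevalences must sum to <= 1")
        if self.length_range[0] < 2 * DEFAULT_FLANK + 1:
            raise ValueError(
                f"minimum protein length must be >= {2 * DEFAULT_FLANK + 1}"
            )
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "length_range" in raw:
            raw["length_range"] = tuple(raw["length_range"])
        if "motifs" in raw:
            raw["motifs"] = tuple((m["pattern"], m["prevalence"]) for m in raw["motifs"])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    informative_terms: list[str]
    motif_sites: dict[str, list[tuple[str, int]]]
    site_conservation: float
    flank_conservation: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    proteins: list[ProteinRecord]
    catalog: SiteCatalog
    go_pairs: list[tuple[str, str]]
    msas: dict[str, OrthologAlignment]
    truth: SyntheticTruth

    @property
    def crosstalk_proteins(self) -> set[str]:
        return {pid for pid, _ in self.catalog.crosstalk_sites}


def simulate_proteins(config: SimulationConfig, rng: np.random.Generator):
    """Generate proteins carrying one site each (or shared proteins when
    mixed_proteins is set), planting motifs on cross-talk sites.

    Residues are i.i.d. uniform over the 20 amino acids away from planted
    motif positions; every site centre is S or T.
    """
    classes = (
        ["crosstalk"] * config.n_crosstalk
        + ["phospho_only"] * config.n_phospho_only
        + ["oglcnac_only"] * config.n_oglcnac_only
    )
    motif_patterns = [
        (MotifPattern.from_string(pat), pat, prev) for pat, prev in config.motifs
    ]
    for pattern, pat_str, _ in motif_patterns:
        if max(abs(off) for off, _ in pattern.fixed) > DEFAULT_FLANK:
            raise ValueError(f"motif {pat_str!r} wider than the site window")

    proteins: list[ProteinRecord] = []
    sites: list[PTMSiteRecord] = []
    motif_sites: dict[str, list[tuple[str, int]]] = {pat: [] for _, pat, _ in motif_patterns}
    lo, hi = config.length_range

    n_sites = len(classes)
    if config.mixed_proteins:
        # two sites per protein, classes interleaved across proteins
        site_protein = [i // 2 for i in range(n_sites)]
        n_proteins = site_protein[-1] + 1 if site_protein else 0
    else:
        site_protein = list(range(n_sites))
        n_proteins = n_sites

    seqs: list[list[str]] = []
    site_pos: dict[int, list[int]] = {}
    for p in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seqs.append(list(rng.choice(list(AMINO_ACIDS), size=length)))
        site_pos[p] = []

    for i, cls in enumerate(classes):
        p = site_protein[i]
        seq = seqs[p]
        # interior placement keeps planted motifs inside the sequence;
        # windows of co-hosted sites are kept disjoint when possible
        for _ in range(200):
            pos = int(rng.integers(DEFAULT_FLANK + 1, len(seq) - DEFAULT_FLANK + 1))
            if all(abs(pos - q) > 2 * DEFAULT_FLANK for q in site_pos[p]):
                break
        else:
            pos = next(
                q for q in range(DEFAULT_FLANK + 1, len(seq) - DEFAULT_FLANK + 1)
                if q not in site_pos[p]
            )
        site_pos[p].append(pos)
        pid = f"SYN{p + 1:05d}"

        planted = None
        if cls == "crosstalk" and motif_patterns:
            u = rng.random()
            acc = 0.0
            for pattern, pat_str, prev in motif_patterns:
                acc += prev
                if u < acc:
                    planted = (pattern, pat_str)
                    break
        if planted is not None:
            pattern, pat_str = planted
            for off, letter in pattern.fixed:
                seq[pos - 1 + off] = letter
            motif_sites[pat_str].append((pid, pos))
            residue = pattern.center
        else:
            residue = "S" if rng.random() < 0.5 else "T"
            seq[pos - 1] = residue

        mods = {
            "crosstalk": ("phospho", "oglcnac"),
            "phospho_only": ("phospho",),
            "oglcnac_only": ("oglcnac",),
        }[cls]
        for mod in mods:
            sites.append(PTMSiteRecord(pid, pos, residue, mod))

    for p in range(n_proteins):
        proteins.append(ProteinRecord(id=f"SYN{p + 1:05d}", sequence="".join(seqs[p])))
    return proteins, SiteCatalog(sites), motif_sites


def simulate_go(config: SimulationConfig, catalog: SiteCatalog,
                protein_ids, rng: np.random.Generator):
    """Per-protein GO annotations: informative terms follow the cross-talk
    label with flip probability epsilon; noise terms are independent
    Bernoulli(go_noise_rate)."""
    n_terms = config.n_go_noise + config.n_go_informative
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    informative_idx = rng.choice(n_terms, size=config.n_go_informative, replace=False)
    informative = sorted(term_ids[i] for i in informative_idx)
    informative_set = set(informative)
    crosstalk_proteins = {pid for pid, _ in catalog.crosstalk_sites}

    pairs: list[tuple[str, str]] = []
    for pid in protein_ids:
        is_pos = pid in crosstalk_proteins
        for term in term_ids:
            if term in informative_set:
                p_present = 1 - config.epsilon if is_pos else config.epsilon
            else:
                p_present = config.go_noise_rate
            if rng.random() < p_present:
                pairs.append((pid, term))
    return pairs, informative


def simulate_msa(
    sequence: str,
    reference_id: str,
    rng: np.random.Generator,
    n_species: int = 10,
    site_positions=(),
    site_conservation: float = 0.9,
    flank_conservation: float = 0.6,
    gap_rate: float = 0.05,
) -> OrthologAlignment:
    """One ortholog alignment: the ungapped reference plus n_species - 1 rows
    whose columns keep the reference letter at the configured rate, otherwise
    substitute uniformly among the other 19 letters; gaps overwrite cells at
    gap_rate."""
    length = len(sequence)
    site_set = set(site_positions)
    rates = np.array(
        [site_conservation if (i + 1) in site_set else flank_conservation
         for i in range(length)]
    )
    ids = [reference_id]
    rows = [sequence]
    others = {c: [a for a in AMINO_ACIDS if a != c] for c in AMINO_ACIDS}
    for s in range(n_species - 1):
        keep = rng.random(length) < rates
        gap = rng.random(length) < gap_rate
        chars = []
        for i, ch in enumerate(sequence):
            if gap[i]:
                chars.append("-")
            elif keep[i]:
                chars.append(ch)
            else:
                pool = others.get(ch, list(AMINO_ACIDS))
                chars.append(pool[int(rng.integers(len(pool)))])
        ids.append(f"{reference_id}_sp{s + 1}")
        rows.append("".join(chars))
    return OrthologAlignment(ids=ids, rows=rows, reference_id=reference_id)


def simulate_msas(config: SimulationConfig, proteins, catalog: SiteCatalog,
                  rng: np.random.Generator) -> dict[str, OrthologAlignment]:
    positions_by_protein: dict[str, list[int]] = {}
    for pid, pos in catalog.positions:
        positions_by_protein.setdefault(pid, []).append(pos)
    return {
        prot.id: simulate_msa(
            prot.sequence,
            prot.id,
            rng,
            n_species=config.n_species,
            site_positions=positions_by_protein.get(prot.id, ()),
            site_conservation=config.site_conservation,
            flank_conservation=config.flank_conservation,
            gap_rate=config.gap_rate,
        )
        for prot in proteins
    }


def simulate_bundle(config: SimulationConfig, outdir=None) -> SyntheticBundle:
    """Generate the full dataset bundle and optionally write it to disk."""
    rng = np.random.default_rng(config.seed)
    proteins, catalog, motif_sites = simulate_proteins(config, rng)
    go_pairs, informative = simulate_go(
        config, catalog, [p.id for p in proteins], rng
    )
    msas = simulate_msas(config, proteins, catalog, rng)
    truth = SyntheticTruth(
        informative_terms=informative,
        motif_sites=motif_sites,
        site_conservation=config.site_conservation,
        flank_conservation=config.flank_conservation,
    )
    bundle = SyntheticBundle(
        config=config, proteins=proteins, catalog=catalog,
        go_pairs=go_pairs, msas=msas, truth=truth,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "proteins.fasta", "w") as fh:
        for prot in bundle.proteins:
            fh.write(f">{prot.id}\n{prot.sequence}\n")
    with open(outdir / "sites.tsv", "w") as fh:
        fh.write("protein_id\tposition\tresidue\tmodification\n")
        for s in bundle.catalog.sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.residue}\t{s.modification}\n")
    with open(outdir / "go.tsv", "w") as fh:
        for pid, term in bundle.go_pairs:
            fh.write(f"{pid}\t{term}\n")
    msa_dir = outdir / "msa"
    msa_dir.mkdir(exist_ok=True)
    with open(outdir / "msa_manifest.tsv", "w") as fh:
        fh.write("protein_id\tmsa_file\treference_id\n")
        for pid, aln in bundle.msas.items():
            fname = f"{pid}.aln.fasta"
            fh.write(f"{pid}\tmsa/{fname}\t{aln.reference_id}\n")
            with open(msa_dir / fname, "w") as mfh:
                for rid, row in zip(aln.ids, aln.rows):
                    mfh.write(f">{rid}\n{row}\n")
    with open(outdir / "truth.json", "w") as fh:
        fh.write(bundle.truth.to_json())
    with open(outdir / "config.yaml", "w") as fh:
        cfg = dataclasses.asdict(bundle.config)
        cfg["length_range"] = list(bundle.config.length_range)
        cfg["motifs"] = [
            {"pattern": pat, "prevalence": prev} for pat, prev in bundle.config.motifs
        ]
        yaml.safe_dump(cfg, fh)
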