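"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators emulate the study design the pipeline targets:

* a proteome with family-specific consensus motifs planted among random
  decoys, plus the PSSM models that recover them;
* a small genome with gene models whose TSS-flanking windows carry planted
  heat shock element (HSE) arrays of known unit count, type and position,
  on a background kept free of accidental arrays by rejection sampling;
* an FPKM expression matrix over a stress design (control, low/high
  temperature, low/high salinity at 1, 24 and 48 h; three replicates) with
  planted log2 fold-change time courses, including extreme inductions in
  the 10^3-10^4-fold range, under lognormal replicate noise.

Every planted feature appears in exactly one truth-table row, and identical
configuration plus seed yields byte-identical output files.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .families import PSSM, ProteinRecord, build_pssm

__all__ = [
    "PlantedFamily",
    "PlantedHSE",
    "PlantedProfile",
    "SyntheticConfig",
    "ProteomeFixture",
    "PromoterFixture",
    "ExpressionFixture",
    "generate_proteome",
    "generate_promoters",
    "generate_expression",
    "default_config",
    "default_planted_hses",
    "default_planted_profiles",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

CONDITIONS = ("C", "LT", "HT", "LS", "HS")
TIMES_H = (1, 24, 48)
N_REPLICATES = 3


@dataclass(frozen=True)
class PlantedFamily:
    """A gene family planted into the synthetic proteome.

    Each member receives exactly one copy of ``motif`` at a random position;
    ``fixed_lengths`` pins the length of selected members (1-based member
    ordinal -> length), e.g. to plant an Hsp100-weight protein under the
    Hsp70 motif.
    """

    name: str
    motif: str
    n_members: int
    length_range: tuple[int, int] = (200, 600)
    fixed_lengths: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError(f"family {self.name}: n_members must be >= 1")


@dataclass(frozen=True)
class PlantedHSE:
    """One HSE array planted into a promoter.

    ``offset_from_tss`` is the TSS-relative position of the array's first
    base (negative = upstream); ``start_type`` is ``head`` (first unit GAA
    core) or ``tail`` (TTC core).  ``flanking_n_chars`` optionally pins the
    1st/5th base of every unit (2*n_units characters).
    """

    gene_id: str
    n_units: int
    start_type: str
    offset_from_tss: int
    flanking_n_chars: str | None = None

    def __post_init__(self) -> None:
        if self.n_units < 3:
            raise ValueError("planted HSE needs >= 3 units")
        if self.start_type not in {"head", "tail"}:
            raise ValueError("start_type must be 'head' or 'tail'")
        if self.flanking_n_chars is not None and len(self.flanking_n_chars) != 2 * self.n_units:
            raise ValueError("flanking_n_chars must give 2 bases per unit")


@dataclass(frozen=True)
class PlantedProfile:
    """A planted log2 fold-change time course for one gene under one condition."""

    gene_id: str
    condition: str
    log2fc: tuple[float, float, float]  # at 1, 24, 48 h
    baseline_fpkm: float = 20.0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS or self.condition == "C":
            raise ValueError(f"condition must be a treatment, got {self.condition!r}")
        if self.baseline_fpkm <= 0:
            raise ValueError("baseline_fpkm must be positive")


@dataclass
class SyntheticConfig:
    """Configuration shared by the three generators."""

    seed: int = 0
    n_decoy_proteins: int = 150
    decoy_length_range: tuple[int, int] = (80, 600)
    planted_families: list[PlantedFamily] = field(default_factory=list)
    promoter_length_up: int = 1000
    promoter_length_down: int = 1000
    planted_hses: list[PlantedHSE] = field(default_factory=list)
    min_units: int = 3
    planted_profiles: list[PlantedProfile] = field(default_factory=list)
    n_null_genes: int = 70
    baseline_fpkm_range: tuple[float, float] = (5.0, 200.0)
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.promoter_length_up <= 0 or self.promoter_length_down <= 0:
            raise ValueError("promoter windows must be positive")


# ---------------------------------------------------------------------------
# Defaults mirroring the study conditions
# ---------------------------------------------------------------------------

# Invented but plausible consensus motifs for the six profile families
# (the Hsp40 one is a J-domain-like consensus).
DEFAULT_FAMILY_MOTIFS = {
    "Hsp20": "AVNTFAPEELSVKV",
    "Hsp40": "DLYKKLALKWHPDKN",
    "Hsp60": "AGDGTTTATVLAQAI",
    "Hsp70": "IDLGTTNSCVAVMEG",
    "Hsp90": "ELISNASDALDKIRY",
    "Hsf": "VPAFLTKLWTLVEDS",
}

# Family sizes of the C. savignyi Hsp/Hsf complement; the ninth Hsp70-motif
# member is pinned at 879 residues so its molecular weight falls in the
# 100 kD class and exercises the Hsp100 reassignment.
DEFAULT_FAMILY_SIZES = {
    "Hsp20": (3, (90, 250)),
    "Hsp40": (6, (210, 420)),
    "Hsp60": (10, (530, 620)),
    "Hsp70": (9, (480, 790)),
    "Hsp90": (3, (700, 830)),
    "Hsf": (1, (450, 500)),
}


def _default_families() -> list[PlantedFamily]:
    fams = []
    for name, (n, length_range) in DEFAULT_FAMILY_SIZES.items():
        fixed = {9: 879} if name == "Hsp70" else {}
        fams.append(
            PlantedFamily(name, DEFAULT_FAMILY_MOTIFS[name], n, length_range, fixed)
        )
    return fams


def default_planted_hses(
    seed: int = 0,
    n_genes: int = 29,
    n_total: int = 58,
    n_tail: int = 36,
    upstream: int = 1000,
) -> list[PlantedHSE]:
    """HSE plant at the scale of the C. savignyi survey: 58 arrays (36 tail,
    22 head) across 29 promoters, unit counts 3-5 with a five-unit maximum.

    Placement is deterministic given ``seed``: arrays are laid out upstream
    of the TSS on a fixed lattice per gene so planted arrays never overlap.
    """
    if n_total % n_genes and n_total // n_genes * n_genes + n_genes < n_total:
        raise ValueError("cannot distribute arrays over genes")
    rng = np.random.default_rng(seed)
    types = ["tail"] * n_tail + ["head"] * (n_total - n_tail)
    rng.shuffle(types)
    unit_cycle = itertools.cycle([3, 3, 4, 3, 5, 4, 3, 3, 5, 3])
    plants: list[PlantedHSE] = []
    per_gene = [n_total // n_genes] * n_genes
    for i in range(n_total - sum(per_gene)):
        per_gene[i] += 1
    t = iter(types)
    for g in range(n_genes):
        gene_id = f"hspgene_{g + 1:02d}"
        # fixed non-overlapping anchor slots in the upstream window
        anchors = [-(upstream - 120) + k * 320 for k in range(per_gene[g])]
        for anchor in anchors:
            n_units = next(unit_cycle)
            jitter = int(rng.integers(0, 40))
            offset = max(-upstream, anchor + jitter)
            plants.append(PlantedHSE(gene_id, n_units, next(t), offset))
    return plants


def default_planted_profiles(seed: int = 0) -> list[PlantedProfile]:
    """Expression plant emulating the observed stress-response structure.

    One extreme heat-inducible gene (~4734-fold at 1 h of high temperature),
    a 12-gene low-temperature cluster peaking at 24 h, a 10-gene
    high-temperature cluster induced at 1 h, held to 24 h and recovering at
    48 h, a 3-gene low-salinity down-then-up cluster and a 4-gene
    high-salinity gradual-induction cluster.
    """
    rng = np.random.default_rng(seed)

    def baseline() -> float:
        return float(10 ** rng.uniform(0.8, 2.2))

    profiles: list[PlantedProfile] = []
    extreme = float(np.log2(4734.0))
    profiles.append(
        PlantedProfile("hsp70_like_4", "HT", (extreme, 7.0, 2.5), baseline())
    )
    for i in range(12):
        profiles.append(
            PlantedProfile(f"lt_gene_{i + 1:02d}", "LT", (0.0, 3.0, 0.0), baseline())
        )
    for i in range(10):
        profiles.append(
            PlantedProfile(f"ht_gene_{i + 1:02d}", "HT", (2.5, 2.5, 0.0), baseline())
        )
    for i in range(3):
        profiles.append(
            PlantedProfile(f"ls_gene_{i + 1:02d}", "LS", (-2.5, 0.0, 2.5), baseline())
        )
    for i in range(4):
        profiles.append(
            PlantedProfile(f"hs_gene_{i + 1:02d}", "HS", (2.0, 4.0, 4.0), baseline())
        )
    return profiles


def default_config(seed: int = 0) -> SyntheticConfig:
    """Default fixture configuration mirroring the study conditions."""
    return SyntheticConfig(
        seed=seed,
        planted_families=_default_families(),
        planted_hses=default_planted_hses(seed),
        planted_profiles=default_planted_profiles(seed),
    )


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------


@dataclass
class ProteomeFixture:
    proteins: list[ProteinRecord]
    truth: pd.DataFrame  # protein_id, family, motif_start (1-based)
    models: dict[str, PSSM]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def generate_proteome(
    config: SyntheticConfig, outdir: str | Path | None = None
) -> ProteomeFixture:
    """Emit a proteome FASTA, a planted-family truth table and PSSM models.

    Each planted member contains exactly one copy of its family consensus in
    otherwise random sequence; decoys are resampled until they contain no
    planted motif as a substring.
    """
    rng = np.random.default_rng(config.seed)
    families = config.planted_families or _default_families()
    motifs = [f.motif.upper() for f in families]
    proteins: list[ProteinRecord] = []
    truth_rows = []
    for fam in families:
        lo, hi = fam.length_range
        for k in range(1, fam.n_members + 1):
            length = fam.fixed_lengths.get(k, int(rng.integers(lo, hi + 1)))
            if len(fam.motif) > length:
                raise ValueError(
                    f"family {fam.name}: motif longer than member length {length}"
                )
            while True:
                seq = _random_protein(rng, length - len(fam.motif))
                pos = int(rng.integers(0, len(seq) + 1))
                full = seq[:pos] + fam.motif.upper() + seq[pos:]
                # exactly one motif copy, and no other family's motif
                if full.count(fam.motif.upper()) == 1 and not any(
                    m != fam.motif.upper() and m in full for m in motifs
                ):
                    break
            pid = f"{fam.name.lower()}_m{k:02d}"
            proteins.append(ProteinRecord(pid, f"planted {fam.name} member", full))
            truth_rows.append(
                {"protein_id": pid, "family": fam.name, "motif_start": pos + 1}
            )
    lo, hi = config.decoy_length_range
    for d in range(1, config.n_decoy_proteins + 1):
        while True:
            seq = _random_protein(rng, int(rng.integers(lo, hi + 1)))
            if not any(m in seq for m in motifs):
                break
        proteins.append(ProteinRecord(f"decoy_{d:04d}", "decoy", seq))
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "family", "motif_start"])
    models = {
        fam.name: build_pssm(fam.name, fam.motif, seed=config.seed + 7919 + i)
        for i, fam in enumerate(families)
    }
    fixture = ProteomeFixture(proteins, truth, models)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(proteins, outdir / "proteome.fa")
        truth.to_csv(outdir / "proteome_truth.tsv", sep="\t", index=False)
        model_dir = outdir / "pssm_models"
        model_dir.mkdir(exist_ok=True)
        for name, model in models.items():
            model.to_json(model_dir / f"{name}.json")
    return fixture


def _write_fasta(records: Sequence[ProteinRecord], path: Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id} {rec.description}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Promoters with planted HSE arrays
# ---------------------------------------------------------------------------

# Independent of the scanner implementation: enumerate alternating-core
# arrays of >= min_units on a fixed phase lattice.
def _arrays_in(seq: str, min_units: int) -> list[tuple[int, int, str]]:
    """(start, n_units, type) of every maximal alternating array in ``seq``."""
    found = []
    upper = seq.upper()
    for phase in range(5):
        codes = []
        for p in range(phase, len(seq) - 4, 5):
            core = upper[p + 1 : p + 4]
            codes.append((p, core if core in ("GAA", "TTC") else None))
        i = 0
        while i < len(codes):
            p, core = codes[i]
            if core is None:
                i += 1
                continue
            j = i
            expect = core
            while j < len(codes) and codes[j][1] == expect:
                expect = "TTC" if expect == "GAA" else "GAA"
                j += 1
            run = j - i
            if run >= min_units:
                found.append((p, run, "head" if core == "GAA" else "tail"))
            i = j
    return sorted(found)


@dataclass
class PromoterFixture:
    genome: dict[str, str]
    genes: pd.DataFrame  # gene_id, contig, start, end, strand, n_exons
    truth: pd.DataFrame  # gene_id, offset_from_tss, n_units, hse_type, sequence
    genome_path: Path | None = None
    gff_path: Path | None = None


def _build_hse(plant: PlantedHSE, rng: np.random.Generator) -> str:
    cores = []
    core = "GAA" if plant.start_type == "head" else "TTC"
    for _ in range(plant.n_units):
        cores.append(core)
        core = "TTC" if core == "GAA" else "GAA"
    flanks = plant.flanking_n_chars or "".join(
        rng.choice(list(NT_ALPHABET), size=2 * plant.n_units)
    )
    return "".join(
        flanks[2 * i] + cores[i] + flanks[2 * i + 1] for i in range(plant.n_units)
    )


def generate_promoters(
    config: SyntheticConfig, outdir: str | Path | None = None
) -> PromoterFixture:
    """Emit a genome FASTA + GFF3 whose promoters carry the planted HSEs.

    One contig per gene; strand is drawn at random and the planted promoter
    content is embedded in the transcription orientation (reverse-complemented
    on the minus strand).  The background is resampled until the promoter
    window contains exactly the planted arrays and nothing else, so a scan of
    a 0-plant fixture must report 0 matches.  Gene models also carry planted
    exon chains for gene-structure summaries.
    """
    rng = np.random.default_rng(config.seed + 104729)
    up, down = config.promoter_length_up, config.promoter_length_down
    plants_by_gene: dict[str, list[PlantedHSE]] = {}
    for plant in config.planted_hses:
        if not -up <= plant.offset_from_tss <= down - 5 * plant.n_units:
            raise ValueError(
                f"{plant.gene_id}: offset {plant.offset_from_tss} does not fit window"
            )
        plants_by_gene.setdefault(plant.gene_id, []).append(plant)
    for gene_id, plants in plants_by_gene.items():
        spans = sorted(
            (p.offset_from_tss, p.offset_from_tss + 5 * p.n_units) for p in plants
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"{gene_id}: planted arrays overlap")

    margin = 500
    gene_len = 800
    genome: dict[str, str] = {}
    gene_rows = []
    truth_rows = []
    gene_ids = sorted(plants_by_gene) or [
        p.gene_id for p in config.planted_hses
    ]
    if not gene_ids:  # negative-control fixture still gets genes to scan
        gene_ids = [f"hspgene_{i + 1:02d}" for i in range(5)]
    for g, gene_id in enumerate(gene_ids):
        plants = sorted(
            plants_by_gene.get(gene_id, []), key=lambda p: p.offset_from_tss
        )
        expected = []
        for _ in range(200):  # rejection sampling for background purity
            prom = list(rng.choice(list(NT_ALPHABET), size=up + down))
            expected = []
            for plant in plants:
                arr = _build_hse(plant, rng)
                start = up + plant.offset_from_tss
                prom[start : start + len(arr)] = list(arr)
                expected.append(
                    (start, plant.n_units, plant.start_type, arr, plant)
                )
            prom_seq = "".join(prom)
            if _arrays_in(prom_seq, config.min_units) == sorted(
                (s, n, t) for s, n, t, _, _ in expected
            ):
                break
        else:
            raise RuntimeError(f"{gene_id}: could not achieve background purity")

        strand = "+" if rng.random() < 0.5 else "-"
        contig = f"contig_{g + 1:02d}"
        contig_len = up + down + gene_len + 2 * margin
        backbone = list(rng.choice(list(NT_ALPHABET), size=contig_len))
        if strand == "+":
            tss0 = margin + up  # 0-based TSS position
            backbone[tss0 - up : tss0 + down] = list(prom_seq)
            start, end = tss0 + 1, tss0 + gene_len  # 1-based gene body
        else:
            tss0 = contig_len - margin - up - 1
            rc = prom_seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            backbone[tss0 + 1 - down : tss0 + 1 + up] = list(rc)
            end = tss0 + 1
            start = end - gene_len + 1
        genome[contig] = "".join(backbone)
        n_exons = int(rng.integers(1, 9))
        gene_rows.append(
            {
                "gene_id": gene_id,
                "contig": contig,
                "start": start,
                "end": end,
                "strand": strand,
                "n_exons": n_exons,
            }
        )
        for _, n_units, hse_type, arr, plant in expected:
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "offset_from_tss": plant.offset_from_tss,
                    "n_units": n_units,
                    "hse_type": hse_type,
                    "sequence": arr,
                }
            )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "contig", "start", "end", "strand", "n_exons"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "offset_from_tss", "n_units", "hse_type", "sequence"],
    )
    fixture = PromoterFixture(genome, genes, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome_path = outdir / "genome.fa"
        with open(genome_path, "w") as fh:
            for contig, seq in genome.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        gff_path = outdir / "genes.gff3"
        _write_gff3(genes, gff_path)
        truth.to_csv(outdir / "hse_truth.tsv", sep="\t", index=False)
        fixture.genome_path = genome_path
        fixture.gff_path = gff_path
    return fixture


def _write_gff3(genes: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            fh.write(
                f"{row.contig}\thspkit\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )
            # evenly spaced exon chain inside the gene body
            n = int(row.n_exons)
            span = row.end - row.start + 1
            exon_len = max(span // (2 * n), 1)
            for e in range(n):
                ex_start = row.start + e * (span // n)
                ex_end = min(ex_start + exon_len - 1, row.end)
                fh.write(
                    f"{row.contig}\thspkit\texon\t{ex_start}\t{ex_end}\t.\t"
                    f"{row.strand}\t.\tID={row.gene_id}.e{e + 1};Parent={row.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionFixture:
    fpkm: pd.DataFrame  # genes x samples
    samples: pd.DataFrame  # sample_id, condition, time_h, replicate
    truth: pd.DataFrame  # gene_id, condition, time_h, log2fc, baseline_fpkm


def generate_expression(
    config: SyntheticConfig, outdir: str | Path | None = None
) -> ExpressionFixture:
    """Emit an FPKM matrix with planted log2 fold-change time courses.

    Per-replicate FPKM is ``baseline * 2**(log2fc + N(0, noise_sd))`` with
    log2fc = 0 in controls and in every (gene, condition) pair without a
    plant.  Null genes (no plant anywhere) are appended for specificity
    checks.  All values are non-negative by construction.
    """
    rng = np.random.default_rng(config.seed + 15485863)
    profiles = config.planted_profiles
    lo, hi = config.baseline_fpkm_range
    if lo <= 0:
        raise ValueError("baselines must be positive")
    baselines: dict[str, float] = {}
    planted: dict[tuple[str, str, int], float] = {}
    for p in profiles:
        baselines.setdefault(p.gene_id, p.baseline_fpkm)
        for t, lfc in zip(TIMES_H, p.log2fc):
            planted[(p.gene_id, p.condition, t)] = lfc
    for i in range(1, config.n_null_genes + 1):
        baselines.setdefault(f"null_gene_{i:03d}", float(10 ** rng.uniform(np.log10(lo), np.log10(hi))))
    gene_ids = list(baselines)

    sample_rows = []
    for cond in CONDITIONS:
        for t in TIMES_H:
            for r in range(1, N_REPLICATES + 1):
                sample_rows.append(
                    {
                        "sample_id": f"{cond}_{t}h_r{r}",
                        "condition": cond,
                        "time_h": t,
                        "replicate": r,
                    }
                )
    samples = pd.DataFrame(sample_rows)

    lfc_matrix = np.zeros((len(gene_ids), len(samples)))
    for gi, gene in enumerate(gene_ids):
        for si, srow in enumerate(samples.itertuples()):
            lfc_matrix[gi, si] = planted.get((gene, srow.condition, srow.time_h), 0.0)
    base = np.array([baselines[g] for g in gene_ids])[:, None]
    noise = rng.normal(0.0, config.noise_sd, size=lfc_matrix.shape)
    values = base * 2.0 ** (lfc_matrix + noise)
    fpkm = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                        columns=samples["sample_id"].tolist())

    truth_rows = []
    for gene in gene_ids:
        for cond in CONDITIONS[1:]:
            for t in TIMES_H:
                truth_rows.append(
                    {
                        "gene_id": gene,
                        "condition": cond,
                        "time_h": t,
                        "log2fc": planted.get((gene, cond, t), 0.0),
                        "baseline_fpkm": baselines[gene],
                    }
                )
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "condition", "time_h", "log2fc", "baseline_fpkm"]
    )
    fixture = ExpressionFixture(fpkm, samples, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fpkm.round(6).to_csv(outdir / "fpkm.tsv", sep="\t")
        samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        truth.round(6).to_csv(outdir / "expression_truth.tsv", sep="\t", index=False)
    return fixture
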