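"""Identification and classification of Hsp/Hsf gene families from domain evidence.

Candidate heat shock proteins (Hsp20/40/60/70/90) and the heat shock
transcription factor (Hsf) are recognized by hits of six Pfam profiles
(PF00011, PF01556, PF00118, PF00012, PF00183, PF00447) against a proteome.
Hits can come from a HMMER3 ``domtblout`` table or from the built-in PSSM
scanner, pass a strict E-value filter (default ``E < 1e-6``), and are reduced
to one best family model per protein.  Because the Hsp100 family shares high
sequence similarity with Hsp70 and is typically recovered by the Hsp70
profile, proteins hit by the Hsp70 model whose theoretical molecular weight
reaches the 100 kD class are reassigned to Hsp100.

Theoretical molecular weight uses average isotopic residue masses (one water
added per chain); the isoelectric point is the pH of zero net charge under
the Bjellqvist pK set, located by bisection.
"""

from __future__ import annotations

import json
import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "DomainHit",
    "FamilyRecord",
    "PSSM",
    "FAMILY_MODELS",
    "read_fasta",
    "read_domtblout",
    "write_domtblout",
    "scan_pssm",
    "build_pssm",
    "filter_and_validate",
    "compute_mw",
    "compute_pi",
    "net_charge",
    "classify_family",
    "assign_families",
    "records_to_table",
    "intron_exon_summary",
    "gene_structures_from_gff",
    "load_reference_table",
    "replay_reference_classification",
]

# Pfam accession -> family label for the six profiles used in the search.
FAMILY_MODELS = {
    "PF00011": "Hsp20",
    "PF01556": "Hsp40",
    "PF00118": "Hsp60",
    "PF00012": "Hsp70",
    "PF00183": "Hsp90",
    "PF00447": "Hsf",
}

_FAMILY_NAMES = {v.lower(): v for v in FAMILY_MODELS.values()}
_FAMILY_NAMES["hsp100"] = "Hsp100"

#: Expasy-compatible average isotopic residue masses (Da).
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524
# Unknown residue X contributes the mean residue mass of the 20 standard ones.
_X_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry."""

    protein_id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r} has an empty sequence")


@dataclass(frozen=True)
class DomainHit:
    """One profile-vs-protein match; the unit of family evidence.

    ``e_value`` is the full-sequence E-value, ``env_start``/``env_end`` are
    1-based inclusive residue coordinates of the domain envelope.
    """

    protein_id: str
    model_name: str
    e_value: float
    bit_score: float
    env_start: int
    env_end: int


@dataclass
class FamilyRecord:
    """A validated Hsp/Hsf gene with systematic name and protein properties."""

    gene_name: str
    protein_id: str
    family: str
    length_aa: int
    mw_da: float
    pi: float | None
    genomic_locus: tuple[str, int, int, str] | None = None
    intron_count: int | None = None
    localization: str | None = None


_NAME_RE = re.compile(r"^(Cs|Cr)(Hsp20|Hsp40|Hsp60|Hsp70|Hsp90|Hsp100|Hsf)(-[0-9]+)?$")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, rec.description, str(rec.seq)))
    return records


# ---------------------------------------------------------------------------
# HMMER3 domtblout I/O
# ---------------------------------------------------------------------------

_DOMTBL_MIN_FIELDS = 23


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER3 per-domain tabular (``domtblout``) file.

    Captures the full-sequence E-value (column 7), the full-sequence bit
    score and the domain envelope coordinates.  ``#`` comment lines are
    skipped; row order is preserved.  An empty file yields an empty list.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_FIELDS:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= {_DOMTBL_MIN_FIELDS} "
                    f"columns, got {len(fields)}"
                )
            hits.append(
                DomainHit(
                    protein_id=fields[0],
                    model_name=fields[3],
                    e_value=float(fields[6]),
                    bit_score=float(fields[7]),
                    env_start=int(fields[19]),
                    env_end=int(fields[20]),
                )
            )
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the HMMER3 domtblout column layout (unused columns dashed)."""
    with open(path, "w") as fh:
        fh.write("# target name  accession  tlen  query name  accession  qlen  "
                 "E-value  score  bias  #  of  c-Evalue  i-Evalue  score  bias  "
                 "from  to  from  to  from  to  acc  description\n")
        for h in hits:
            cols = [
                h.protein_id, "-", "0", h.model_name, "-", "0",
                f"{h.e_value:.3g}", f"{h.bit_score:.1f}", "0.0",
                "1", "1", f"{h.e_value:.3g}", f"{h.e_value:.3g}",
                f"{h.bit_score:.1f}", "0.0",
                "1", "1", str(h.env_start), str(h.env_end),
                str(h.env_start), str(h.env_end), "0.99", "-",
            ]
            fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------------------
# PSSM scanning (download-free profile search over the same downstream path)
# ---------------------------------------------------------------------------


@dataclass
class PSSM:
    """Ungapped position-specific scoring model with Karlin–Altschul statistics.

    ``matrix`` is motif-length x 20 natural-log odds; ``lam``/``k`` are the
    extreme-value parameters fitted on random-sequence score samples at model
    build time, so a best-window score S on a length-n protein converts to an
    E-value ``K * m * n * exp(-lambda * S)``.
    """

    name: str
    matrix: np.ndarray
    consensus: str
    lam: float
    k: float

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def _encode(self, sequence: str) -> np.ndarray:
        idx = np.fromiter(
            (_AA_INDEX.get(aa, 20) for aa in sequence.upper()),
            dtype=np.int64,
            count=len(sequence),
        )
        return idx

    def window_scores(self, sequence: str) -> np.ndarray:
        """Log-odds score of every window; unknown residues score 0."""
        m = self.length
        idx = self._encode(sequence)
        if len(idx) < m:
            raise ValueError("sequence shorter than model")
        padded = np.hstack([self.matrix, np.zeros((m, 1))])  # col 20 = unknown
        windows = np.lib.stride_tricks.sliding_window_view(idx, m)
        return padded[np.arange(m), windows].sum(axis=1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "consensus": self.consensus,
            "alphabet": AA_ALPHABET,
            "lambda": self.lam,
            "k": self.k,
            "matrix": [[round(v, 6) for v in row] for row in self.matrix.tolist()],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PSSM":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            name=payload["name"],
            matrix=np.asarray(payload["matrix"], dtype=float),
            consensus=payload["consensus"],
            lam=payload["lambda"],
            k=payload["k"],
        )


def build_pssm(
    name: str,
    motif: str,
    seed: int,
    match_prob: float = 0.6,
    n_calib: int = 1000,
    calib_len: int = 400,
) -> PSSM:
    """Build a log-odds PSSM for a consensus motif and calibrate its E-values.

    Each column gives probability ``match_prob`` to the consensus residue and
    spreads the rest uniformly; the background is uniform over the 20 standard
    residues.  (K, lambda) come from a Gumbel fit to best-window scores on
    ``n_calib`` random background sequences, seed-fixed for reproducibility.
    """
    motif = motif.upper()
    bad = set(motif) - set(AA_ALPHABET)
    if bad:
        raise ValueError(f"motif contains non-standard residues: {sorted(bad)}")
    m = len(motif)
    bg = 1.0 / 20.0
    matrix = np.full((m, 20), math.log(((1.0 - match_prob) / 19.0) / bg))
    for i, aa in enumerate(motif):
        matrix[i, _AA_INDEX[aa]] = math.log(match_prob / bg)
    model = PSSM(name=name, matrix=matrix, consensus=motif, lam=1.0, k=1.0)

    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AA_ALPHABET.encode(), dtype="S1")
    maxima = np.empty(n_calib)
    for i in range(n_calib):
        seq = b"".join(rng.choice(alphabet, size=calib_len)).decode()
        maxima[i] = model.window_scores(seq).max()
    loc, scale = stats.gumbel_r.fit(maxima)
    lam = 1.0 / scale
    k = math.exp(lam * loc) / (m * calib_len)
    model.lam = lam
    model.k = k
    return model


def scan_pssm(
    proteins: Iterable[ProteinRecord],
    models: Mapping[str, PSSM] | Sequence[PSSM],
    e_threshold: float = 1e-6,
) -> list[DomainHit]:
    """Score every protein against every PSSM, returning hits with E <= threshold.

    Each (protein, model) pair contributes at most its best window.  Proteins
    shorter than a model are skipped for that model (logged, not an error).
    Hits are returned sorted by E-value.
    """
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    if isinstance(models, Mapping):
        model_list = list(models.values())
    else:
        model_list = list(models)
    hits: list[DomainHit] = []
    for protein in proteins:
        n = len(protein.sequence)
        for model in model_list:
            if n < model.length:
                log.debug(
                    "protein %s shorter than model %s; skipped",
                    protein.protein_id, model.name,
                )
                continue
            scores = model.window_scores(protein.sequence)
            pos = int(scores.argmax())
            s = float(scores[pos])
            e_value = model.k * model.length * n * math.exp(-model.lam * s)
            if e_value <= e_threshold:
                hits.append(
                    DomainHit(
                        protein_id=protein.protein_id,
                        model_name=model.name,
                        e_value=e_value,
                        bit_score=s / math.log(2.0),
                        env_start=pos + 1,
                        env_end=pos + model.length,
                    )
                )
    hits.sort(key=lambda h: h.e_value)
    return hits


# ---------------------------------------------------------------------------
# Filtering and family assignment
# ---------------------------------------------------------------------------


def filter_and_validate(
    hits: Sequence[DomainHit], e_threshold: float = 1e-6
) -> list[DomainHit]:
    """Apply the strict E-value cut and keep one best model per protein.

    Hits with ``e_value < e_threshold`` (strictly) survive.  Multiple hits of
    the same model on a protein collapse to the best-E one; a protein hit by
    several family models keeps only the best-E model (ties broken by higher
    bit score, then lexicographic model name).  Output preserves the first
    appearance order of proteins.  The operation is idempotent.
    """
    kept = [h for h in hits if h.e_value < e_threshold]
    best: dict[str, DomainHit] = {}
    order: list[str] = []
    for hit in kept:
        prev = best.get(hit.protein_id)
        if prev is None:
            best[hit.protein_id] = hit
            order.append(hit.protein_id)
            continue
        if (hit.e_value, -hit.bit_score, hit.model_name) < (
            prev.e_value, -prev.bit_score, prev.model_name
        ):
            best[hit.protein_id] = hit
    return [best[pid] for pid in order]


def _validate_sequence(sequence: str, allow_x: bool = True) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    for aa in seq:
        if aa in AVERAGE_RESIDUE_MASS:
            continue
        if aa == "X" and allow_x:
            continue
        raise ValueError(f"unknown residue {aa!r}")
    return seq


def compute_mw(sequence: str) -> float:
    """Theoretical average molecular weight in Daltons.

    Sum of average isotopic residue masses plus one water (18.01524 Da);
    ``X`` contributes the mean residue mass.
    """
    seq = _validate_sequence(sequence)
    return sum(AVERAGE_RESIDUE_MASS.get(aa, _X_MASS) for aa in seq) + WATER_MASS


def net_charge(sequence: str, ph: float) -> float:
    """Net protein charge at a given pH (Bjellqvist pK set, termini included)."""
    seq = _validate_sequence(sequence).replace("X", "")
    if not seq:
        raise ValueError("sequence contains no standard residues")
    return IsoelectricPoint(seq).charge_at_pH(ph)


def compute_pi(sequence: str, tolerance: float = 1e-4) -> float:
    """Isoelectric point: the pH of zero net charge, by bisection on [0, 14]."""
    seq = _validate_sequence(sequence).replace("X", "")
    if not seq:
        raise ValueError("sequence contains no standard residues")
    ip = IsoelectricPoint(seq)
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        charge = ip.charge_at_pH(mid)
        if abs(charge) < tolerance:
            return mid
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return mid


def normalize_model(model_name: str) -> str:
    """Map a model identifier (Pfam accession or family label) to a family."""
    name = model_name.strip()
    acc = re.search(r"PF\d{5}", name)
    if acc and acc.group(0) in FAMILY_MODELS:
        return FAMILY_MODELS[acc.group(0)]
    base = re.sub(r"\(.*\)$", "", name).strip().lower()
    if base in _FAMILY_NAMES:
        return _FAMILY_NAMES[base]
    raise ValueError(f"unrecognized family model {model_name!r}")


#: Default molecular-weight threshold (Da) above which an Hsp70-profile hit
#: is reassigned to the Hsp100 family.  Chosen between the largest genuine
#: Hsp70 (~87 kD) and the 100 kD class the reassignment targets.
MW_REASSIGN_THRESHOLD = 95_000.0


def classify_family(
    model_family: str, mw_da: float, mw_reassign_threshold: float = MW_REASSIGN_THRESHOLD
) -> str:
    """Final family for a hit: the model's family, except heavy Hsp70 -> Hsp100."""
    if model_family == "Hsp70" and mw_da >= mw_reassign_threshold:
        return "Hsp100"
    return model_family


def assign_families(
    validated_hits: Sequence[DomainHit],
    proteins: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
    species_prefix: str = "Cs",
    mw_reassign_threshold: float = MW_REASSIGN_THRESHOLD,
    loci: Mapping[str, tuple[str, int, int, str]] | None = None,
    intron_counts: Mapping[str, int] | None = None,
    localizations: Mapping[str, str] | None = None,
) -> list[FamilyRecord]:
    """Turn one-hit-per-protein evidence into named :class:`FamilyRecord` rows.

    Families follow each hit's model, with the molecular-weight reassignment
    of heavy Hsp70-profile proteins to Hsp100.  Systematic names are
    ``<prefix><family>-<ordinal>`` with ordinals assigned deterministically in
    input order; a family with a single member carries no ordinal suffix.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.protein_id: p for p in proteins}
    drafts: list[tuple[DomainHit, str, ProteinRecord, float, float]] = []
    for hit in validated_hits:
        protein = proteins[hit.protein_id]
        mw = compute_mw(protein.sequence)
        pi = compute_pi(protein.sequence)
        family = classify_family(
            normalize_model(hit.model_name), mw, mw_reassign_threshold
        )
        drafts.append((hit, family, protein, mw, pi))

    family_sizes = Counter(family for _, family, *_ in drafts)
    ordinal: Counter[str] = Counter()
    records: list[FamilyRecord] = []
    for hit, family, protein, mw, pi in drafts:
        ordinal[family] += 1
        if family_sizes[family] == 1:
            gene_name = f"{species_prefix}{family}"
        else:
            gene_name = f"{species_prefix}{family}-{ordinal[family]}"
        assert _NAME_RE.match(gene_name), gene_name
        records.append(
            FamilyRecord(
                gene_name=gene_name,
                protein_id=protein.protein_id,
                family=family,
                length_aa=len(protein.sequence),
                mw_da=mw,
                pi=pi,
                genomic_locus=(loci or {}).get(protein.protein_id),
                intron_count=(intron_counts or {}).get(protein.protein_id),
                localization=(localizations or {}).get(protein.protein_id),
            )
        )
    return records


def records_to_table(records: Sequence[FamilyRecord]) -> pd.DataFrame:
    """Family records as a summary table (one row per gene)."""
    rows = []
    for r in records:
        contig, start, end, strand = r.genomic_locus or (None, None, None, None)
        rows.append(
            {
                "gene_name": r.gene_name,
                "gene_id": r.protein_id,
                "family": r.family,
                "aa": r.length_aa,
                "mw_kd": round(r.mw_da / 1000.0, 3),
                "pi": None if r.pi is None else round(r.pi, 2),
                "contig": contig,
                "start": start,
                "end": end,
                "strand": strand,
                "intron_count": r.intron_count,
                "localization": r.localization,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene structure
# ---------------------------------------------------------------------------


def intron_exon_summary(
    exons: Sequence[tuple[int, int]], strand: str | None = None
) -> tuple[int, int]:
    """Exon and intron counts from sorted, non-overlapping exon intervals.

    Intervals are 1-based inclusive.  A single-exon gene has zero introns;
    otherwise ``introns = exons - 1``.
    """
    if not exons:
        raise ValueError("gene model has no exons")
    prev_end = None
    for start, end in exons:
        if start > end:
            raise ValueError(f"exon interval ({start}, {end}) is inverted")
        if prev_end is not None and start <= prev_end:
            raise ValueError("overlapping or unsorted exons in gene model")
        prev_end = end
    n_exons = len(exons)
    return n_exons, n_exons - 1


def gene_structures_from_gff(gff_path: str | Path) -> dict[str, tuple[int, int]]:
    """Per-gene (exon_count, intron_count) from a GFF3 with exon features."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    out: dict[str, tuple[int, int]] = {}
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        if exons:
            out[gene.id] = intron_exon_summary(exons, gene.strand)
    return out


# ---------------------------------------------------------------------------
# Packaged reference table
# ---------------------------------------------------------------------------


def load_reference_table() -> pd.DataFrame:
    """Load the packaged *C. savignyi* Hsp/Hsf reference summary.

    Curated summary of the 32 validated genes (gene id, originating profile
    model, protein length, molecular weight in kD, pI where reported, locus
    and predicted localization).  The Hsp100 entry's originating model is the
    Hsp70 profile, which is what the molecular-weight reassignment acts on.
    """
    path = Path(__file__).parent / "data" / "cs_hsp_families.tsv"
    return pd.read_csv(path, sep="\t")


def replay_reference_classification(
    mw_reassign_threshold: float = MW_REASSIGN_THRESHOLD,
) -> pd.DataFrame:
    """Re-run family assignment over the packaged reference table.

    Uses each entry's originating profile model and reported molecular weight
    only; returns the table with an ``assigned_family`` column.
    """
    table = load_reference_table().copy()
    table["assigned_family"] = [
        classify_family(normalize_model(model), mw_kd * 1000.0, mw_reassign_threshold)
        for model, mw_kd in zip(table["source_model"], table["mw_kd"])
    ]
    return table
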