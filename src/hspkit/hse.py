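"""Heat shock element (HSE) detection in TSS-flanking promoter regions.

An HSE is an array of contiguous, strictly alternating inverted repeats of
the pentamer ``nGAAn``: each 5-bp unit carries a ``GAA`` or ``TTC`` core at
positions 2-4, and adjacent units must carry opposite cores (the minimal
functional element being ``nnGAAnnTTCnnGAAnn``, three alternating units).
An array whose first unit has a GAA core is a *head*-type HSE; one starting
with a TTC core is *tail*-type.  Head/tail labels are meaningful in the
transcription orientation of the promoter, which is how regions are
extracted here.

The scanner reports maximal arrays only: a five-unit array is one match,
never also its sub-arrays.  Because the unit lattice can sit at any of five
phase offsets, maximal arrays in different phases may overlap and are all
reported.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PromoterRegion",
    "HSEMatch",
    "HSESummary",
    "extract_promoters",
    "scan_hse",
    "scan_promoters",
    "summarize_hse",
    "write_bed",
    "matches_to_table",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterRegion:
    """A TSS-flanking window oriented 5'->3' in the direction of transcription.

    ``tss_offset`` is the index within ``sequence`` of the TSS base (TSS = 0
    in promoter coordinates; the first upstream base is -1).  ``genomic_start``
    and ``genomic_end`` give the 0-based half-open genomic slice the sequence
    was taken from (before reverse-complementing on the minus strand).
    """

    gene_id: str
    sequence: str
    tss_offset: int
    upstream: int
    downstream: int
    contig: str | None = None
    genomic_start: int | None = None
    genomic_end: int | None = None
    strand: str = "+"
    truncated: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.tss_offset <= len(self.sequence):
            raise ValueError(
                f"{self.gene_id}: tss_offset {self.tss_offset} outside sequence"
            )


@dataclass(frozen=True)
class HSEMatch:
    """One maximal pentamer-unit array.

    ``start`` indexes the promoter sequence; ``start_tss_rel`` is the signed
    TSS-relative position of the array's first base (negative = upstream).
    """

    gene_id: str
    start: int
    start_tss_rel: int
    n_units: int
    hse_type: str  # "head" or "tail"
    matched_seq: str

    @property
    def length(self) -> int:
        return 5 * self.n_units

    @property
    def end_tss_rel(self) -> int:
        return self.start_tss_rel + self.length - 1


@dataclass
class HSESummary:
    """Counts and positional statistics of HSE matches."""

    total: int
    n_head: int
    n_tail: int
    n_upstream: int
    n_downstream: int
    max_units: int
    per_gene: pd.DataFrame
    per_family: pd.DataFrame
    closest_family: str | None


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------


def extract_promoters(
    genome_fasta: str | Path,
    gff_path: str | Path,
    upstream: int = 1000,
    downstream: int = 1000,
) -> list[PromoterRegion]:
    """Extract TSS-flanking windows for every ``gene`` feature in a GFF3.

    The TSS is the gene start on the plus strand and the gene end on the
    minus strand (1-based GFF coordinates).  Minus-strand windows are
    reverse-complemented so the returned sequence reads 5'->3' relative to
    transcription.  Windows hitting a contig edge are truncated and flagged,
    never padded.
    """
    import gffutils
    from pyfaidx import Fasta

    if upstream <= 0 or downstream <= 0:
        raise ValueError("promoter windows must be positive")
    genome = Fasta(str(genome_fasta))
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    regions: list[PromoterRegion] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in {"+", "-"}:
            raise ValueError(f"gene {gene.id}: strand must be + or -")
        if gene.seqid not in genome:
            raise KeyError(f"gene {gene.id}: contig {gene.seqid!r} not in genome")
        contig_len = len(genome[gene.seqid])
        if gene.strand == "+":
            tss0 = gene.start - 1
            want_start, want_end = tss0 - upstream, tss0 + downstream
        else:
            tss0 = gene.end - 1
            want_start, want_end = tss0 + 1 - downstream, tss0 + 1 + upstream
        g_start = max(0, want_start)
        g_end = min(contig_len, want_end)
        truncated = (g_start != want_start) or (g_end != want_end)
        raw = str(genome[gene.seqid][g_start:g_end])
        if gene.strand == "+":
            sequence = raw
            tss_offset = tss0 - g_start
        else:
            sequence = reverse_complement(raw)
            tss_offset = g_end - 1 - tss0
        regions.append(
            PromoterRegion(
                gene_id=gene.id,
                sequence=sequence,
                tss_offset=tss_offset,
                upstream=upstream,
                downstream=downstream,
                contig=gene.seqid,
                genomic_start=g_start,
                genomic_end=g_end,
                strand=gene.strand,
                truncated=truncated,
            )
        )
    return regions


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

_CORES = {"GAA": "head", "TTC": "tail"}
_OPPOSITE = {"GAA": "TTC", "TTC": "GAA"}


def _unit_core(seq: str, pos: int) -> str | None:
    """Exact core (GAA/TTC) of the pentamer starting at ``pos``, or None."""
    core = seq[pos + 1 : pos + 4]
    return core if core in _CORES else None


def _near_core(core: str, target: str) -> bool:
    """True when ``core`` differs from ``target`` in at most one position."""
    return sum(a != b for a, b in zip(core, target)) <= 1


def scan_hse(
    region: PromoterRegion | str,
    min_units: int = 3,
    gene_id: str = "",
    tss_offset: int | None = None,
    allow_gap_units: int = 0,
    mismatch_tolerance: int = 0,
) -> list[HSEMatch]:
    """Find maximal alternating nGAAn/nTTCn arrays of >= ``min_units`` units.

    For each of the five phase offsets, maximal runs of consecutive pentamer
    units whose positions 2-4 are exactly ``GAA`` or ``TTC`` with strict
    alternation are reported (maximal munch; no sub-run is emitted).  Runs in
    different phases may overlap and are all reported, sorted by start.
    ``N`` never matches a core position.

    ``allow_gap_units`` permits up to that many skipped 5-bp slots of
    arbitrary sequence inside one array (each skipped slot consumes one
    alternation step but does not count toward ``n_units``); terminal slots
    must be real units.  ``mismatch_tolerance`` allows at most that many
    units after the first whose core deviates from the expected alternating
    core by one base.  Both default to 0, i.e. the strict grammar.
    """
    if isinstance(region, PromoterRegion):
        seq = region.sequence
        gene_id = gene_id or region.gene_id
        tss_offset = region.tss_offset if tss_offset is None else tss_offset
    else:
        seq = region
    tss_offset = tss_offset or 0
    if min_units < 1:
        raise ValueError("min_units must be >= 1")
    upper = seq.upper()
    n = len(seq)
    matches: list[HSEMatch] = []
    for phase in range(5):
        slots = list(range(phase, n - 4, 5))
        cores = [_unit_core(upper, p) for p in slots]
        i = 0
        while i < len(slots):
            if cores[i] is None:
                i += 1
                continue
            # greedy extension from slot i
            expected = _OPPOSITE[cores[i]]
            first_core = cores[i]
            units = 1
            gaps_left = allow_gap_units
            mismatches_left = mismatch_tolerance
            last_real = i
            j = i + 1
            while j < len(slots):
                core = cores[j]
                if core == expected:
                    units += 1
                    last_real = j
                elif (
                    mismatches_left > 0
                    and core is None
                    and _near_core(upper[slots[j] + 1 : slots[j] + 4], expected)
                    and set(upper[slots[j] + 1 : slots[j] + 4]) <= set("ACGT")
                ):
                    mismatches_left -= 1
                    units += 1
                    last_real = j
                elif gaps_left > 0:
                    gaps_left -= 1
                else:
                    break
                expected = _OPPOSITE[expected]
                j += 1
            if units >= min_units:
                start = slots[i]
                end = slots[last_real] + 5
                matches.append(
                    HSEMatch(
                        gene_id=gene_id,
                        start=start,
                        start_tss_rel=start - tss_offset,
                        n_units=units,
                        hse_type=_CORES[first_core],
                        matched_seq=seq[start:end],
                    )
                )
            i = last_real + 1
    matches.sort(key=lambda m: (m.start, -m.n_units))
    return matches


def scan_promoters(
    regions: Iterable[PromoterRegion], min_units: int = 3, **kwargs
) -> list[HSEMatch]:
    """Scan every promoter region; matches pooled and sorted per gene order."""
    out: list[HSEMatch] = []
    for region in regions:
        out.extend(scan_hse(region, min_units=min_units, **kwargs))
    return out


# ---------------------------------------------------------------------------
# Summaries and export
# ---------------------------------------------------------------------------


def summarize_hse(
    matches: Sequence[HSEMatch], family_map: Mapping[str, str] | None = None
) -> HSESummary:
    """Totals, head/tail split, per-gene and per-family aggregates.

    Distance to the TSS is the TSS-relative position of a match's first base;
    per-family closeness uses the median absolute distance.  Matches starting
    at or downstream of the TSS are tallied separately from upstream ones.
    """
    family_map = dict(family_map or {})
    if family_map:
        for m in matches:
            if m.gene_id not in family_map:
                raise KeyError(f"gene {m.gene_id!r} has no family assignment")
    n_head = sum(1 for m in matches if m.hse_type == "head")
    n_tail = sum(1 for m in matches if m.hse_type == "tail")
    n_down = sum(1 for m in matches if m.start_tss_rel >= 0)
    per_gene_rows = []
    by_gene: dict[str, list[HSEMatch]] = {}
    for m in matches:
        by_gene.setdefault(m.gene_id, []).append(m)
    for gene_id, ms in by_gene.items():
        per_gene_rows.append(
            {
                "gene_id": gene_id,
                "family": family_map.get(gene_id),
                "n_hse": len(ms),
                "max_units": max(m.n_units for m in ms),
                "min_abs_tss_dist": min(abs(m.start_tss_rel) for m in ms),
            }
        )
    per_gene = pd.DataFrame(
        per_gene_rows,
        columns=["gene_id", "family", "n_hse", "max_units", "min_abs_tss_dist"],
    )
    per_family_rows = []
    if family_map:
        by_family: dict[str, list[HSEMatch]] = {}
        for m in matches:
            by_family.setdefault(family_map[m.gene_id], []).append(m)
        for family, ms in sorted(by_family.items()):
            per_family_rows.append(
                {
                    "family": family,
                    "n_hse": len(ms),
                    "median_abs_tss_dist": statistics.median(
                        abs(m.start_tss_rel) for m in ms
                    ),
                }
            )
    per_family = pd.DataFrame(
        per_family_rows, columns=["family", "n_hse", "median_abs_tss_dist"]
    )
    closest = None
    if per_family_rows:
        closest = min(per_family_rows, key=lambda r: r["median_abs_tss_dist"])["family"]
    return HSESummary(
        total=len(matches),
        n_head=n_head,
        n_tail=n_tail,
        n_upstream=len(matches) - n_down,
        n_downstream=n_down,
        max_units=max((m.n_units for m in matches), default=0),
        per_gene=per_gene,
        per_family=per_family,
        closest_family=closest,
    )


def matches_to_table(matches: Sequence[HSEMatch]) -> pd.DataFrame:
    """Matches as a TSS-relative table (1-based inclusive start/end)."""
    return pd.DataFrame(
        [
            {
                "gene_id": m.gene_id,
                "start_tss_rel": m.start_tss_rel,
                "end_tss_rel": m.end_tss_rel,
                "n_units": m.n_units,
                "hse_type": m.hse_type,
                "matched_seq": m.matched_seq,
            }
            for m in matches
        ],
        columns=[
            "gene_id", "start_tss_rel", "end_tss_rel",
            "n_units", "hse_type", "matched_seq",
        ],
    )


def write_bed(
    matches: Sequence[HSEMatch],
    regions: Mapping[str, PromoterRegion] | Sequence[PromoterRegion],
    path: str | Path,
) -> None:
    """Write matches as BED6 in genome coordinates (0-based half-open).

    Name is ``gene|type|units``, score the unit count, strand the gene's.
    Minus-strand promoter coordinates are mapped back through the
    reverse-complemented window.
    """
    if not isinstance(regions, Mapping):
        regions = {r.gene_id: r for r in regions}
    with open(path, "w") as fh:
        for m in matches:
            region = regions[m.gene_id]
            if region.contig is None or region.genomic_start is None:
                raise ValueError(
                    f"region {m.gene_id!r} lacks genomic coordinates for BED export"
                )
            if region.strand == "+":
                g_start = region.genomic_start + m.start
            else:
                g_start = region.genomic_end - m.start - m.length
            fh.write(
                "\t".join(
                    [
                        region.contig,
                        str(g_start),
                        str(g_start + m.length),
                        f"{m.gene_id}|{m.hse_type}|{m.n_units}",
                        str(m.n_units),
                        region.strand,
                    ]
                )
                + "\n"
            )
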