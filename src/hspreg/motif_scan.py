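"""Cis-regulatory motif scanning for hsp70 promoters and 3'UTRs.

Detects the element classes annotated in this system:

* HSE (heat-shock element): a run of >= 3 contiguous 5-mers whose central
  trinucleotide (positions 2-4) alternates between GAA and TTC.  Positions 1
  and 5 of each pentamer are unconstrained ("n" in nGAAn/nTTCn), matching
  the observation that they are the least constrained positions of the HSF
  binding unit.  Runs are maximal: not extendable by another valid,
  alternating pentamer on either side.
* GAGA sites: literal GAGAG (G+, sense) and CTCTC (G-, antisense).
* TATA box: IUPAC consensus TATAWAWR (annotation only).
* ARE (AU-rich element): the AUUUA pentamer, scanned as ATTTA on the DNA
  sense strand.  Overlapping hits are all reported.

Also provides exact-match in-silico PCR for printed primer pairs.

Coordinates are 0-based half-open on the ungapped sequence.  TSS-relative
coordinates use the promoter convention with no position 0: the TSS is +1
and the base immediately upstream is -1.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .errors import (
    AlphabetError,
    AmbiguousAmpliconError,
    GapError,
    NoAmpliconError,
    ParameterError,
)
from .io_formats import AlignedSequenceSet, normalize_sequence


class MotifKind(str, enum.Enum):
    HSE = "HSE"
    GAGA_PLUS = "GAGA_PLUS"
    GAGA_MINUS = "GAGA_MINUS"
    TATA = "TATA"
    ARE = "ARE"
    TSS = "TSS"


@dataclass(frozen=True)
class MotifAnnotation:
    """A located regulatory element on an ungapped sequence."""

    kind: MotifKind
    start: int
    end: int
    unit_count: int = 0
    tss_relative_start: Optional[int] = None
    note: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ParameterError(f"motif end must exceed start ({self.start}, {self.end})")
        if self.kind is MotifKind.HSE:
            if self.unit_count < 2 or self.end - self.start != 5 * self.unit_count:
                raise ParameterError(
                    f"HSE spans 5 x unit_count bases (got span {self.end - self.start}, "
                    f"units {self.unit_count})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_ungapped(sequence: str) -> str:
    seq = normalize_sequence(sequence)
    if "-" in seq:
        raise GapError("scanners require an ungapped sequence; remove '-' first")
    return seq


def _core_type(seq: str, pos: int, max_mismatches: int = 0) -> Optional[str]:
    """Classify the pentamer starting at ``pos`` by its central trinucleotide."""
    core = seq[pos + 1 : pos + 4]
    if len(core) < 3:
        return None
    mg = sum(a != b for a, b in zip(core, "GAA"))
    mt = sum(a != b for a, b in zip(core, "TTC"))
    if mg <= max_mismatches and mg < mt:
        return "G"
    if mt <= max_mismatches and mt < mg:
        return "T"
    return None


def scan_hse(sequence: str, min_units: int = 3, max_core_mismatches: int = 0) -> List[MotifAnnotation]:
    """Find maximal runs of alternating nGAAn/nTTCn pentamer units.

    A run is a sequence of contiguous 5-mers at offsets p, p+5, p+10, ...
    whose cores alternate between GAA and TTC (either phase may start).
    Runs with at least ``min_units`` units are reported once, with their
    unit count; runs are maximal (not extendable left or right by another
    valid alternating unit).
    """
    if min_units < 2:
        raise ParameterError("min_units must be >= 2")
    seq = _check_ungapped(sequence)
    n = len(seq)
    cores = [_core_type(seq, p, max_core_mismatches) for p in range(max(n - 4, 0))]

    def alternates(p: int, q: int) -> bool:
        return (
            0 <= p < len(cores)
            and 0 <= q < len(cores)
            and cores[p] is not None
            and cores[q] is not None
            and cores[p] != cores[q]
        )

    hits = []
    for p in range(len(cores)):
        if cores[p] is None:
            continue
        if alternates(p - 5, p):
            continue  # extendable left: not a run start
        k = 1
        while alternates(p + 5 * (k - 1), p + 5 * k):
            k += 1
        if k >= min_units:
            hits.append(MotifAnnotation(MotifKind.HSE, p, p + 5 * k, unit_count=k))
    return sorted(hits, key=lambda a: a.start)


def scan_fixed_motif(sequence: str, motif: str, kind: MotifKind) -> List[MotifAnnotation]:
    """All (possibly overlapping) exact occurrences of a literal motif."""
    if len(motif) < 4:
        raise ParameterError("fixed motifs must be at least 4 bp")
    seq = _check_ungapped(sequence)
    motif = normalize_sequence(motif)
    m = len(motif)
    return [
        MotifAnnotation(kind, i, i + m)
        for i in range(len(seq) - m + 1)
        if seq[i : i + m] == motif
    ]


def scan_gaga(sequence: str) -> List[MotifAnnotation]:
    """GAGAG (G+) and CTCTC (G-) sites, merged and sorted by position."""
    hits = scan_fixed_motif(sequence, "GAGAG", MotifKind.GAGA_PLUS)
    hits += scan_fixed_motif(sequence, "CTCTC", MotifKind.GAGA_MINUS)
    return sorted(hits, key=lambda a: a.start)


def scan_are(sequence: str) -> List[MotifAnnotation]:
    """AU-rich element pentamers (AUUUA on mRNA, ATTTA on the DNA sense strand)."""
    return scan_fixed_motif(sequence, "ATTTA", MotifKind.ARE)


_TATA_RE = re.compile("TATA[AT]A[AT][AG]")


def scan_tata(sequence: str) -> List[MotifAnnotation]:
    """TATA-box consensus matches (TATAWAWR); annotation only."""
    seq = _check_ungapped(sequence)
    hits = []
    for i in range(len(seq) - 7):
        if _TATA_RE.match(seq, i, i + 8):
            hits.append(MotifAnnotation(MotifKind.TATA, i, i + 8))
    return hits


def tss_relative(position: int, tss: int) -> int:
    """Map an ungapped 0-based position to TSS-relative coordinates.

    The TSS itself is +1; the base immediately upstream is -1 (no 0).
    """
    return position - tss + 1 if position >= tss else position - tss


def tss_relative_inverse(relative: int, tss: int) -> int:
    if relative == 0:
        raise ParameterError("TSS-relative coordinates have no position 0")
    return relative + tss - 1 if relative > 0 else relative + tss


def scan_all(sequence: str, tss: Optional[int] = None, min_units: int = 3) -> List[MotifAnnotation]:
    """Run every scanner on an ungapped sequence; sorted by start.

    Adjacent HSEs separated by fewer than 5 bp are flagged in ``note``
    because the boundary between one long element and two close elements is
    a convention, not an observable.
    """
    anns = (
        scan_hse(sequence, min_units=min_units)
        + scan_gaga(sequence)
        + scan_tata(sequence)
        + scan_are(sequence)
    )
    anns.sort(key=lambda a: (a.start, a.kind.value))
    out = []
    prev_hse_end = None
    for a in anns:
        note = a.note
        if a.kind is MotifKind.HSE:
            if prev_hse_end is not None and a.start - prev_hse_end < 5:
                note = "close_to_previous_hse"
            prev_hse_end = a.end
        rel = tss_relative(a.start, tss) if tss is not None else None
        out.append(
            MotifAnnotation(a.kind, a.start, a.end, a.unit_count, rel, note)
        )
    return out


def annotate_region(aln: AlignedSequenceSet, tss_column: int) -> Dict[str, List[MotifAnnotation]]:
    """Annotate every sequence of an alignment with all motif scanners.

    ``tss_column`` is a 0-based alignment column; it is mapped to each
    sequence's ungapped coordinate system before scanning, so annotations
    carry both ungapped-absolute and TSS-relative starts.
    """
    if not (0 <= tss_column < aln.length):
        raise ParameterError(
            f"tss_column {tss_column} outside alignment of length {aln.length}"
        )
    result = {}
    for rec in aln:
        ungapped_tss = sum(1 for ch in rec.sequence[:tss_column] if ch != "-")
        result[rec.id] = scan_all(rec.ungapped, tss=ungapped_tss)
    return result


_IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().replace("U", "T").translate(_COMPLEMENT)[::-1]


def _primer_sites(template: str, primer: str) -> List[int]:
    """Start positions where the primer matches exactly; IUPAC codes in the
    template are expanded (the primer itself must be unambiguous ACGT)."""
    sites = []
    m = len(primer)
    for i in range(len(template) - m + 1):
        window = template[i : i + m]
        if all(p in _IUPAC.get(t, "") for p, t in zip(primer, window)):
            sites.append(i)
    return sites


@dataclass(frozen=True)
class AmpliconResult:
    """A predicted PCR product on a template (0-based half-open)."""

    fwd_start: int
    rev_end: int
    length: int
    product_sequence: str

    def __post_init__(self):
        if self.length != self.rev_end - self.fwd_start:
            raise ParameterError("amplicon length must equal rev_end - fwd_start")


def in_silico_pcr(template: str, fwd_primer: str, rev_primer: str) -> AmpliconResult:
    """Predict the PCR product of an exact-match primer pair on a template.

    The forward primer must match the template; the reverse complement of
    the reverse primer must match downstream.  The product spans from the
    first base of the forward site to the last base of the reverse site.
    Only minimal (innermost) primer pairings count as products; zero
    products raise :class:`NoAmpliconError` and more than one raise
    :class:`AmbiguousAmpliconError` listing all of them.
    """
    tpl = template.upper().replace("U", "T").replace("-", "")
    bad = sorted({ch for ch in tpl if ch not in _IUPAC})
    if bad:
        raise AlphabetError(f"template contains non-IUPAC characters: {bad}")
    fwd = normalize_sequence(fwd_primer.replace(" ", ""))
    rev = normalize_sequence(rev_primer.replace(" ", ""))
    fwd_sites = _primer_sites(tpl, fwd)
    rev_sites = _primer_sites(tpl, reverse_complement(rev))
    products = []
    for r in rev_sites:
        # closest forward site whose 3' end is at or before the reverse site
        upstream = [f for f in fwd_sites if f + len(fwd) <= r]
        if not upstream:
            continue
        f = max(upstream)
        # innermost pairing only: no other reverse site between f and r
        if any(f + len(fwd) <= r2 < r for r2 in rev_sites):
            continue
        end = r + len(rev)
        products.append(AmpliconResult(f, end, end - f, tpl[f:end]))
    if not products:
        raise NoAmpliconError("no amplicon: primer pair does not delimit a product")
    if len(products) > 1:
        spans = ", ".join(f"{p.fwd_start}-{p.rev_end} ({p.length} bp)" for p in products)
        raise AmbiguousAmpliconError(f"multiple products: {spans}", products)
    return products[0]


def annotations_to_bed(annotations: Dict[str, List[MotifAnnotation]]) -> str:
    """Render per-sequence annotations as BED (0-based half-open) text."""
    lines = []
    for seq_id, anns in annotations.items():
        for a in anns:
            name = a.kind.value + (f"[{a.unit_count}]" if a.kind is MotifKind.HSE else "")
            lines.append(f"{seq_id}\t{a.start}\t{a.end}\t{name}\t0\t+")
    return "\n".join(lines) + ("\n" if lines else "")


def annotations_to_table(annotations: Dict[str, List[MotifAnnotation]]):
    """Tidy per-line table of annotations (1-based inclusive user coordinates)."""
    import pandas as pd

    rows = []
    for seq_id, anns in annotations.items():
        for a in anns:
            rows.append(
                {
                    "sequence": seq_id,
                    "kind": a.kind.value,
                    "start": a.start + 1,
                    "end": a.end,
                    "unit_count": a.unit_count,
                    "tss_relative_start": a.tss_relative_start,
                    "note": a.note,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sequence", "kind", "start", "end", "unit_count", "tss_relative_start", "note"],
    )
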