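"""Differentiation statistics between two arrangements on haplotype alignments.

Implements, on gap-free (complete-deletion) alignments:

* site classification into monomorphic / fixed-difference / shared
  polymorphism / exclusive polymorphism of either population;
* Dxy, the average number of nucleotide substitutions per site between
  populations (mean cross-population pairwise Hamming distance per
  analysed site);
* Hudson's Fst = 1 - Hw/Hb, with Hw the (by default unweighted) mean of
  the two within-population mean pairwise per-site diversities and Hb = Dxy;
* Hudson's nearest-neighbour statistic Snn with a label-permutation test.

Gap handling follows complete deletion: after restricting the alignment to
the sequences under comparison, every column containing a gap or N in any
retained sequence is removed.  A strict mode deletes columns gapped in any
sequence of the full alignment instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    DegenerateAlignmentError,
    GapError,
    ParameterError,
    UndefinedFstError,
)
from .io_formats import AlignedSequenceSet, SequenceRecord


@dataclass(frozen=True)
class PopulationSplit:
    """Disjoint id lists defining the two populations being compared."""

    pop1_ids: tuple
    pop2_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "pop1_ids", tuple(self.pop1_ids))
        object.__setattr__(self, "pop2_ids", tuple(self.pop2_ids))
        if not self.pop1_ids or not self.pop2_ids:
            raise ParameterError("both populations must be non-empty")
        overlap = set(self.pop1_ids) & set(self.pop2_ids)
        if overlap:
            raise ParameterError(f"populations overlap: {sorted(overlap)}")

    @property
    def all_ids(self) -> tuple:
        return self.pop1_ids + self.pop2_ids

    def swapped(self) -> "PopulationSplit":
        return PopulationSplit(self.pop2_ids, self.pop1_ids)


@dataclass(frozen=True)
class SiteClassCounts:
    """Per-column classification of a gap-free two-population alignment."""

    sp1_sf2: int  # polymorphic in pop1, fixed in pop2
    sp2_sf1: int  # polymorphic in pop2, fixed in pop1
    shared: int  # polymorphic in both
    fixed_diff: int  # fixed for different alleles
    monomorphic: int
    analysed_sites: int

    def __post_init__(self):
        parts = (self.sp1_sf2, self.sp2_sf1, self.shared, self.fixed_diff, self.monomorphic)
        if any(v < 0 for v in parts):
            raise ParameterError("site class counts must be non-negative")
        if sum(parts) != self.analysed_sites:
            raise ParameterError(
                f"site classes {parts} do not sum to analysed_sites {self.analysed_sites}"
            )


@dataclass(frozen=True)
class DifferentiationResult:
    """One comparison row: counts plus Dxy, Fst, Snn and its permutation P."""

    region: str
    copy: str
    counts: SiteClassCounts
    dxy: float
    fst: Optional[float]
    snn: float
    snn_p: float
    n_permutations: int


def complete_deletion(
    aln: AlignedSequenceSet,
    ids: Optional[Iterable[str]] = None,
    strict: bool = False,
) -> AlignedSequenceSet:
    """Remove every column containing a gap or N in any analysed sequence.

    ``ids`` restricts the alignment first (default: all sequences).  With
    ``strict=True`` columns gapped in *any* sequence of the full alignment
    are removed even if those sequences are excluded from the comparison.
    """
    sub = aln.subset(ids) if ids is not None else aln
    ref = aln if strict else sub
    mask_matrix = ref.matrix()
    keep = ~np.any((mask_matrix == "-") | (mask_matrix == "N"), axis=0)
    if not keep.any():
        raise DegenerateAlignmentError("complete deletion removed every column")
    records = []
    for r in sub:
        arr = np.array(list(r.sequence), dtype="<U1")[keep]
        records.append(
            SequenceRecord(
                id=r.id,
                sequence="".join(arr),
                line_id=r.line_id,
                arrangement=r.arrangement,
                gene_copy=r.gene_copy,
            )
        )
    return AlignedSequenceSet(tuple(records))


def _split_matrices(aln: AlignedSequenceSet, split: PopulationSplit):
    mat = aln.matrix()
    if np.any((mat == "-") | (mat == "N")):
        raise GapError("gap or N present; run complete_deletion first")
    index = {rid: i for i, rid in enumerate(aln.ids)}
    try:
        i1 = [index[r] for r in split.pop1_ids]
        i2 = [index[r] for r in split.pop2_ids]
    except KeyError as exc:
        raise ParameterError(f"split id not in alignment: {exc}") from None
    return mat, np.array(i1), np.array(i2)


def classify_sites(aln: AlignedSequenceSet, split: PopulationSplit) -> SiteClassCounts:
    """Assign every column to exactly one class.

    Multi-allelic columns are classified by within-population variability
    exactly like bi-allelic ones.
    """
    mat, i1, i2 = _split_matrices(aln, split)
    sp1_sf2 = sp2_sf1 = shared = fixed = mono = 0
    for col in range(mat.shape[1]):
        a1 = set(mat[i1, col])
        a2 = set(mat[i2, col])
        p1 = len(a1) > 1
        p2 = len(a2) > 1
        if p1 and p2:
            shared += 1
        elif p1:
            sp1_sf2 += 1
        elif p2:
            sp2_sf1 += 1
        elif a1 == a2:
            mono += 1
        else:
            fixed += 1
    return SiteClassCounts(sp1_sf2, sp2_sf1, shared, fixed, mono, mat.shape[1])


def pairwise_diff_matrix(aln: AlignedSequenceSet) -> np.ndarray:
    """Symmetric matrix of pairwise Hamming distances in sites."""
    mat = aln.matrix()
    if np.any((mat == "-") | (mat == "N")):
        raise GapError("gap or N present; run complete_deletion first")
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(int)


def dxy(aln: AlignedSequenceSet, split: PopulationSplit) -> float:
    """Average number of nucleotide substitutions per site between populations."""
    mat, i1, i2 = _split_matrices(aln, split)
    L = mat.shape[1]
    if L == 0:
        raise DegenerateAlignmentError("no analysed sites")
    diffs = (mat[i1][:, None, :] != mat[i2][None, :, :]).sum(axis=2)
    return float(diffs.mean() / L)


def _within_diversity(mat: np.ndarray, idx: np.ndarray) -> float:
    """Mean pairwise per-site diversity inside one population (>= 2 members)."""
    n = len(idx)
    if n < 2:
        raise ParameterError("within-population diversity needs >= 2 sequences")
    sub = mat[idx]
    d = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean() / mat.shape[1])


def hudson_fst(aln: AlignedSequenceSet, split: PopulationSplit, weighted: bool = False) -> float:
    """Hudson's Fst = 1 - Hw/Hb.

    Hw averages the two within-population diversities; ``weighted=True``
    weights them by the number of pairs in each population instead of the
    default unweighted mean (the two coincide for equal sample sizes).
    """
    mat, i1, i2 = _split_matrices(aln, split)
    h1 = _within_diversity(mat, i1)
    h2 = _within_diversity(mat, i2)
    if weighted:
        w1 = len(i1) * (len(i1) - 1) / 2
        w2 = len(i2) * (len(i2) - 1) / 2
        hw = (w1 * h1 + w2 * h2) / (w1 + w2)
    else:
        hw = (h1 + h2) / 2.0
    hb = dxy(aln, split)
    if hb == 0:
        raise UndefinedFstError(
            "between-population diversity is zero; Fst undefined "
            "(populations indistinguishable and invariant)"
        )
    return float(1.0 - hw / hb)


def _snn_from_distances(dist: np.ndarray, labels: np.ndarray) -> float:
    """Snn from a precomputed distance matrix and boolean population labels.

    For each sequence, its nearest neighbours are all other sequences at the
    minimal distance (ties included); the sequence contributes the fraction
    of those neighbours belonging to its own population.
    """
    n = dist.shape[0]
    total = 0.0
    for i in range(n):
        row = np.delete(dist[i], i)
        others = np.delete(np.arange(n), i)
        m = row.min()
        nn = others[row == m]
        total += float(np.mean(labels[nn] == labels[i]))
    return total / n


def snn(aln: AlignedSequenceSet, split: PopulationSplit) -> float:
    """Hudson's nearest-neighbour statistic in [0, 1]."""
    mat, i1, i2 = _split_matrices(aln, split)
    if len(i1) + len(i2) < 3:
        raise ParameterError("Snn needs at least 3 sequences")
    order = np.concatenate([i1, i2])
    sub = mat[order]
    dist = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
    labels = np.array([0] * len(i1) + [1] * len(i2))
    return _snn_from_distances(dist, labels)


def snn_permutation_test(
    aln: AlignedSequenceSet,
    split: PopulationSplit,
    n_permutations: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Observed Snn and its permutation P-value.

    Labels are permuted uniformly at random preserving group sizes;
    p = (1 + #{permuted Snn >= observed}) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    mat, i1, i2 = _split_matrices(aln, split)
    if len(i1) + len(i2) < 3:
        raise ParameterError("Snn needs at least 3 sequences")
    order = np.concatenate([i1, i2])
    sub = mat[order]
    dist = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
    labels = np.array([0] * len(i1) + [1] * len(i2))
    observed = _snn_from_distances(dist, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _snn_from_distances(dist, perm) >= observed:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return observed, p


def differentiate(
    aln: AlignedSequenceSet,
    split: PopulationSplit,
    region: str = "region",
    copy: str = "NA",
    n_permutations: int = 1000,
    seed: int = 0,
    strict_deletion: bool = False,
    weighted_hw: bool = False,
) -> DifferentiationResult:
    """Full differentiation summary for one region x gene-copy comparison."""
    clean = complete_deletion(aln, ids=split.all_ids, strict=strict_deletion)
    counts = classify_sites(clean, split)
    d = dxy(clean, split)
    try:
        f = hudson_fst(clean, split, weighted=weighted_hw)
    except UndefinedFstError:
        f = None
    s, p = snn_permutation_test(clean, split, n_permutations=n_permutations, seed=seed)
    return DifferentiationResult(region, copy, counts, d, f, s, p, n_permutations)


def concatenate_copies(
    aln_a: AlignedSequenceSet, aln_b: AlignedSequenceSet
) -> AlignedSequenceSet:
    """Join each line's A and B sequences end to end (before gap deletion).

    Records are matched by ``line_id``; lines missing from either alignment
    are dropped.
    """
    by_line_b = {r.line_id: r for r in aln_b}
    records = []
    for ra in aln_a:
        rb = by_line_b.get(ra.line_id)
        if rb is None:
            continue
        records.append(
            SequenceRecord(
                id=f"{ra.line_id}_conc",
                sequence=ra.sequence + rb.sequence,
                line_id=ra.line_id,
                arrangement=ra.arrangement,
                gene_copy="NA",
            )
        )
    if len(records) < 2:
        raise DegenerateAlignmentError("fewer than 2 lines shared between copies")
    return AlignedSequenceSet(tuple(records))


def pool_copies(aln_a: AlignedSequenceSet, aln_b: AlignedSequenceSet) -> AlignedSequenceSet:
    """Alternative concatenation scheme: pool A and B haplotypes as separate
    sequences of one alignment (requires equal alignment lengths)."""
    records = [
        SequenceRecord(f"{r.id}_A", r.sequence, r.line_id, r.arrangement, r.gene_copy)
        for r in aln_a
    ] + [
        SequenceRecord(f"{r.id}_B", r.sequence, r.line_id, r.arrangement, r.gene_copy)
        for r in aln_b
    ]
    return AlignedSequenceSet(tuple(records))


def _split_for(aln: AlignedSequenceSet, split_by: str = "arrangement") -> PopulationSplit:
    """Derive a two-population split from record arrangements (OST vs O347)."""
    from .io_formats import Arrangement

    pop1 = [r.id for r in aln if r.arrangement is Arrangement.OST]
    pop2 = [r.id for r in aln if r.arrangement is Arrangement.O347]
    return PopulationSplit(tuple(pop1), tuple(pop2))


def differentiation_table(
    regions: Sequence[tuple],
    n_permutations: int = 1000,
    seed: int = 0,
    include_concatenated: bool = True,
    concat_scheme: str = "per_line",
    strict_deletion: bool = False,
    weighted_hw: bool = False,
) -> List[DifferentiationResult]:
    """One differentiation row per (region, copy), plus a concatenated row
    per region built by joining each line's A and B sequences end to end
    (``concat_scheme='pooled'`` pools the copies as extra haplotypes
    instead).

    ``regions`` is a sequence of ``(aln, split, region, copy)`` tuples.
    Each row uses its own sub-seed derived from ``seed`` so adding rows does
    not perturb earlier ones.
    """
    if concat_scheme not in ("per_line", "pooled"):
        raise ParameterError(f"unknown concat_scheme {concat_scheme!r}")
    results = []
    row = 0
    by_region = {}
    for aln, split, region, copy in regions:
        results.append(
            differentiate(
                aln,
                split,
                region=region,
                copy=copy,
                n_permutations=n_permutations,
                seed=seed + row,
                strict_deletion=strict_deletion,
                weighted_hw=weighted_hw,
            )
        )
        row += 1
        by_region.setdefault(region, {})[copy] = (aln, split)
    if include_concatenated:
        for region, copies in by_region.items():
            if "A" not in copies or "B" not in copies:
                continue
            aln_a, _ = copies["A"]
            aln_b, _ = copies["B"]
            if concat_scheme == "per_line":
                conc = concatenate_copies(aln_a, aln_b)
            else:
                conc = pool_copies(aln_a, aln_b)
            split = _split_for(conc)
            results.append(
                differentiate(
                    conc,
                    split,
                    region=region,
                    copy="concatenated",
                    n_permutations=n_permutations,
                    seed=seed + row,
                    strict_deletion=strict_deletion,
                    weighted_hw=weighted_hw,
                )
            )
            row += 1
    return results


def results_to_table(results: Sequence[DifferentiationResult]):
    """Render results with the published comparison-table column set."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "Region": r.region,
                "Gene copy": r.copy,
                "SP1SF2": r.counts.sp1_sf2,
                "SP2SF1": r.counts.sp2_sf1,
                "Shared": r.counts.shared,
                "Fixed": r.counts.fixed_diff,
                "Sites": r.counts.analysed_sites,
                "Dxy": r.dxy,
                "Fst": r.fst,
                "Snn": r.snn,
                "P": r.snn_p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Region",
            "Gene copy",
            "SP1SF2",
            "SP2SF1",
            "Shared",
            "Fixed",
            "Sites",
            "Dxy",
            "Fst",
            "Snn",
            "P",
        ],
    )
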