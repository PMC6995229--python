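"""Synthetic alignments, promoters and qPCR datasets with known ground truth.

Every generator emits a :class:`SyntheticTruth` record describing the
dataset exactly (planted site classes, planted motif annotations, realized
random effects, full configuration), so downstream modules can be tested
for exact recovery without any external data.

Sequence backgrounds are drawn uniformly over {A,C,G,T} and then repaired
so that no spontaneous motif signal remains: alternating GAA/TTC pentamer
core runs of length >= 3 and the literal motifs GAGAG, CTCTC, ATTTA and
TATAWAWR are excluded outside planted footprints.  Planted motifs are
inserted verbatim; planted polymorphisms and gap columns occupy distinct
random columns outside motif footprints.

Expression data are simulated under the nested model
y = mu + arrangement + line(arrangement) + sex + arrangement:sex + error
on the delta-Ct scale by default (relative expression 2**(-dCt) is then
log-normal, which is exactly why the permutation tests exist); a
``response_scale='relative'`` mode draws normal homoscedastic relative
expression directly, for calibration checks where the parametric F null
must hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import CapacityError, MotifOverlapError, ParameterError
from .io_formats import (
    AlignedSequenceSet,
    Arrangement,
    CtRecord,
    Gene,
    GeneCopy,
    SequenceRecord,
    Sex,
)
from .motif_scan import (
    MotifAnnotation,
    MotifKind,
    scan_all,
    scan_are,
    scan_gaga,
    scan_hse,
    scan_tata,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedMotif:
    """Specification of one motif to synthesize into a background sequence."""

    kind: MotifKind
    position: int
    unit_count: int = 0  # HSE only
    phase: str = "GAA"  # first HSE core

    @property
    def length(self) -> int:
        if self.kind is MotifKind.HSE:
            if self.unit_count < 2:
                raise ParameterError("planted HSE needs unit_count >= 2")
            return 5 * self.unit_count
        if self.kind is MotifKind.TATA:
            return 8
        if self.kind is MotifKind.TSS:
            return 1
        return 5  # GAGA and ARE pentamers

    def footprint(self) -> range:
        return range(self.position, self.position + self.length)


@dataclass
class SeqSimConfig:
    """Configuration for two-population haplotype alignments.

    Defaults mirror the study conditions: 6 haplotypes per arrangement over
    a regulatory-region-sized alignment.
    """

    n_pop1: int = 6
    n_pop2: int = 6
    length: int = 550
    n_fixed_diff: int = 0
    n_excl_poly_pop1: int = 0
    n_excl_poly_pop2: int = 0
    n_shared_poly: int = 0
    gap_columns: int = 0
    planted_motifs: Tuple[PlantedMotif, ...] = ()
    gene_copy: str = "NA"
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_fixed_diff,
            self.n_excl_poly_pop1,
            self.n_excl_poly_pop2,
            self.n_shared_poly,
            self.gap_columns,
        )
        if any(c < 0 for c in counts):
            raise ParameterError("site counts must be >= 0")
        if self.n_pop1 < 2 or self.n_pop2 < 2:
            raise ParameterError("each population needs >= 2 haplotypes")


@dataclass
class ExprSimConfig:
    """Configuration for nested-design qPCR datasets.

    Effect sizes and standard deviations are in Ct cycles when
    ``response_scale='ct'`` (default) and in relative-expression units when
    ``response_scale='relative'``.  The default design matches the study:
    2 arrangements x 6 lines x 2 sexes x 3 biological replicates, with the
    same fraction of replicates missing completely at random as the 67-of-72
    dataset analysed.
    """

    n_lines_per_arrangement: int = 6
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    grand_mean_dct: float = 5.0
    arrangement_effect: float = 0.0
    sex_effect: float = 0.0
    interaction_effect: float = 0.0
    sd_line: float = 0.15
    sd_error: float = 0.3
    sd_tech: float = 0.1
    reference_ct_mean: float = 20.0
    reference_sd: float = 0.5
    missing_fraction: float = 5.0 / 72.0
    response_scale: str = "ct"
    seed: int = 0

    def __post_init__(self):
        if min(self.sd_line, self.sd_error, self.sd_tech, self.reference_sd) < 0:
            raise ParameterError("standard deviations must be >= 0")
        if not (0 <= self.missing_fraction < 1):
            raise ParameterError("missing_fraction must be in [0, 1)")
        if self.response_scale not in ("ct", "relative"):
            raise ParameterError(f"unknown response_scale {self.response_scale!r}")
        if min(self.n_lines_per_arrangement, self.n_bio_reps, self.n_tech_reps) < 1:
            raise ParameterError("design sizes must be >= 1")


@dataclass
class SyntheticTruth:
    """Exact description of an emitted synthetic dataset."""

    config: dict
    site_classes: Dict[int, str] = field(default_factory=dict)
    motifs: Tuple[MotifAnnotation, ...] = ()
    line_effects: Dict[str, float] = field(default_factory=dict)
    delta_ct: Dict[tuple, float] = field(default_factory=dict)
    dropped_replicates: Tuple[tuple, ...] = ()
    warnings: Tuple[str, ...] = ()

    def to_jsonable(self) -> dict:
        """JSON-serializable view (tuple keys flattened to strings)."""
        import dataclasses

        return {
            "config": self.config,
            "site_class_counts": self.class_counts(),
            "site_classes": {str(k): v for k, v in self.site_classes.items()},
            "motifs": [dataclasses.asdict(m) for m in self.motifs],
            "line_effects": self.line_effects,
            "delta_ct": {"|".join(map(str, k)): v for k, v in self.delta_ct.items()},
            "dropped_replicates": [list(d) for d in self.dropped_replicates],
            "warnings": list(self.warnings),
        }

    def class_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for cls in self.site_classes.values():
            out[cls] = out.get(cls, 0) + 1
        return out


# ---------------------------------------------------------------------------
# sequence backgrounds
# ---------------------------------------------------------------------------


def _spurious_hits(seq: str, footprints: set) -> List[Tuple[int, int]]:
    """Spans of motif signal lying (at least partly) outside planted footprints."""
    hits = []
    anns = scan_hse(seq, min_units=3) + scan_gaga(seq) + scan_are(seq) + scan_tata(seq)
    for a in anns:
        span = set(range(a.start, a.end))
        if not span <= footprints:
            hits.append((a.start, a.end))
    return hits


def _clean_sequence(rng, length: int, footprints: Optional[set] = None, template=None, max_rounds: int = 200) -> str:
    """A random (or given) sequence repaired until free of spontaneous motifs.

    Only positions outside ``footprints`` are ever mutated, so a planted
    motif can never be destroyed by the repair loop.
    """
    footprints = footprints or set()
    if template is None:
        chars = rng.choice(_BASES, size=length).tolist()
    else:
        chars = list(template)
    for _ in range(max_rounds):
        hits = _spurious_hits("".join(chars), footprints)
        if not hits:
            return "".join(chars)
        for start, end in hits:
            mutable = [p for p in range(start, end) if p not in footprints]
            if not mutable:  # fully inside footprints; handled by caller
                continue
            p = int(rng.choice(mutable))
            current = chars[p]
            chars[p] = str(rng.choice([b for b in "ACGT" if b != current]))
    raise CapacityError("could not generate a motif-free background; sequence too dense")


def _motif_string(rng, planted: PlantedMotif) -> str:
    if planted.kind is MotifKind.HSE:
        if planted.phase not in ("GAA", "TTC"):
            raise ParameterError("HSE phase must be GAA or TTC")
        cores = ["GAA", "TTC"] if planted.phase == "GAA" else ["TTC", "GAA"]
        units = []
        for u in range(planted.unit_count):
            flank1 = str(rng.choice(_BASES))
            flank2 = str(rng.choice(_BASES))
            units.append(flank1 + cores[u % 2] + flank2)
        return "".join(units)
    if planted.kind is MotifKind.GAGA_PLUS:
        return "GAGAG"
    if planted.kind is MotifKind.GAGA_MINUS:
        return "CTCTC"
    if planted.kind is MotifKind.ARE:
        return "ATTTA"
    if planted.kind is MotifKind.TATA:
        return "TATAAATA"  # one instance of the TATAWAWR consensus
    if planted.kind is MotifKind.TSS:
        return ""
    raise ParameterError(f"cannot synthesize motif kind {planted.kind}")


def _plant_motifs(rng, sequence: str, planted: Sequence[PlantedMotif]):
    chars = list(sequence)
    footprints: set = set()
    truth: List[MotifAnnotation] = []
    for pm in sorted(planted, key=lambda p: p.position):
        fp = set(pm.footprint())
        if fp & footprints:
            raise MotifOverlapError(f"planted motif at {pm.position} overlaps another")
        if pm.kind is not MotifKind.TSS and (pm.position < 0 or pm.position + pm.length > len(chars)):
            raise CapacityError(f"motif at {pm.position} does not fit in length {len(chars)}")
        footprints |= fp
        text = _motif_string(rng, pm)
        for offset, ch in enumerate(text):
            chars[pm.position + offset] = ch
        if pm.kind is not MotifKind.TSS:
            truth.append(
                MotifAnnotation(
                    pm.kind,
                    pm.position,
                    pm.position + pm.length,
                    unit_count=pm.unit_count if pm.kind is MotifKind.HSE else 0,
                )
            )
    return "".join(chars), footprints, tuple(truth)


def generate_promoter(cfg: SeqSimConfig) -> Tuple[str, SyntheticTruth]:
    """One ungapped promoter sequence with planted motifs and motif-free
    background; the truth lists the planted annotations in scan order."""
    rng = np.random.default_rng(cfg.seed)
    background = _clean_sequence(rng, cfg.length)
    seq, footprints, truth_motifs = _plant_motifs(rng, background, cfg.planted_motifs)
    seq = _clean_sequence(rng, cfg.length, footprints=footprints, template=seq)
    tss = next(
        (pm.position for pm in cfg.planted_motifs if pm.kind is MotifKind.TSS), None
    )
    truth = SyntheticTruth(config=asdict(cfg), motifs=truth_motifs)
    if tss is not None:
        truth.config["tss_position"] = tss
    return seq, truth


#: A promoter layout shaped like the hsp70 proximal promoter of this system:
#: four HSEs with unit counts (3, 4, 4, 3) from distal to proximal, three
#: GAGA sites, a TATA box, and the TSS at position 290 of a 550 bp region.
HSP70_PROMOTER_LAYOUT: Tuple[PlantedMotif, ...] = (
    PlantedMotif(MotifKind.HSE, 40, unit_count=3),
    PlantedMotif(MotifKind.GAGA_MINUS, 70),
    PlantedMotif(MotifKind.HSE, 90, unit_count=4, phase="TTC"),
    PlantedMotif(MotifKind.GAGA_PLUS, 130),
    PlantedMotif(MotifKind.HSE, 150, unit_count=4),
    PlantedMotif(MotifKind.GAGA_MINUS, 190),
    PlantedMotif(MotifKind.HSE, 210, unit_count=3, phase="TTC"),
    PlantedMotif(MotifKind.TATA, 258),
    PlantedMotif(MotifKind.TSS, 290),
)

#: A 3'UTR layout shaped like the hsp70A copy: two ARE pentamers in a ~200 bp
#: region downstream of the stop codon.
HSP70_UTR_A_LAYOUT: Tuple[PlantedMotif, ...] = (
    PlantedMotif(MotifKind.ARE, 40),
    PlantedMotif(MotifKind.ARE, 120),
)

#: The hsp70B-copy analogue with a single ARE.
HSP70_UTR_B_LAYOUT: Tuple[PlantedMotif, ...] = (PlantedMotif(MotifKind.ARE, 80),)


def generate_haplotypes(cfg: SeqSimConfig) -> Tuple[AlignedSequenceSet, SyntheticTruth]:
    """Two-population alignment with planted site classes, gaps and motifs."""
    rng = np.random.default_rng(cfg.seed)
    n1, n2, L = cfg.n_pop1, cfg.n_pop2, cfg.length
    background = _clean_sequence(rng, L)
    seq, footprints, truth_motifs = _plant_motifs(rng, background, cfg.planted_motifs)
    seq = _clean_sequence(rng, L, footprints=footprints, template=seq)

    n_sites = (
        cfg.n_fixed_diff
        + cfg.n_excl_poly_pop1
        + cfg.n_excl_poly_pop2
        + cfg.n_shared_poly
        + cfg.gap_columns
    )
    free = [c for c in range(L) if c not in footprints]
    if n_sites > len(free):
        raise CapacityError(
            f"{n_sites} variable/gap columns requested but only {len(free)} "
            f"non-motif columns available"
        )
    chosen = rng.choice(len(free), size=n_sites, replace=False)
    columns = [free[i] for i in chosen]

    mat = np.array([list(seq)] * (n1 + n2), dtype="<U1")
    pop1_rows = np.arange(n1)
    pop2_rows = np.arange(n1, n1 + n2)
    site_classes: Dict[int, str] = {}
    cursor = 0

    def alt_base(current: str) -> str:
        return str(rng.choice([b for b in "ACGT" if b != current]))

    for _ in range(cfg.n_fixed_diff):
        col = columns[cursor]
        cursor += 1
        mat[pop2_rows, col] = alt_base(seq[col])
        site_classes[col] = "fixed_diff"
    for pop_rows, label, count in (
        (pop1_rows, "sp1_sf2", cfg.n_excl_poly_pop1),
        (pop2_rows, "sp2_sf1", cfg.n_excl_poly_pop2),
    ):
        for _ in range(count):
            col = columns[cursor]
            cursor += 1
            k = int(rng.integers(1, len(pop_rows)))
            carriers = rng.choice(pop_rows, size=k, replace=False)
            mat[carriers, col] = alt_base(seq[col])
            site_classes[col] = label
    for _ in range(cfg.n_shared_poly):
        col = columns[cursor]
        cursor += 1
        b = alt_base(seq[col])
        k1 = int(rng.integers(1, n1))
        k2 = int(rng.integers(1, n2))
        mat[rng.choice(pop1_rows, size=k1, replace=False), col] = b
        mat[rng.choice(pop2_rows, size=k2, replace=False), col] = b
        site_classes[col] = "shared"
    for _ in range(cfg.gap_columns):
        col = columns[cursor]
        cursor += 1
        k = int(rng.integers(1, n1 + n2))
        rows = rng.choice(n1 + n2, size=k, replace=False)
        mat[rows, col] = "-"
        site_classes[col] = "gap"
    for col in range(L):
        site_classes.setdefault(col, "monomorphic")

    records = []
    for i in range(n1 + n2):
        pop = 1 if i < n1 else 2
        idx = i + 1 if pop == 1 else i - n1 + 1
        arrangement = Arrangement.OST if pop == 1 else Arrangement.O347
        records.append(
            SequenceRecord(
                id=f"{arrangement.value}_L{idx}",
                sequence="".join(mat[i]),
                line_id=f"{arrangement.value}_L{idx}",
                arrangement=arrangement,
                gene_copy=cfg.gene_copy,
            )
        )
    aln = AlignedSequenceSet(tuple(records))
    truth = SyntheticTruth(
        config=asdict(cfg), site_classes=site_classes, motifs=truth_motifs
    )
    return aln, truth


# ---------------------------------------------------------------------------
# expression data
# ---------------------------------------------------------------------------


def generate_ct_dataset(cfg: ExprSimConfig) -> Tuple[List[CtRecord], SyntheticTruth]:
    """Nested-design Ct table simulated under the study's linear model.

    Arrangement/sex effects are coded so the stated effect is the full
    difference between levels (added to the O347 / male / O347-male cell).
    Missing biological replicates are deleted completely at random, with a
    fixed count of round(missing_fraction x total).
    """
    rng = np.random.default_rng(cfg.seed)
    arrangements = (Arrangement.OST, Arrangement.O347)
    lines = [
        (f"{arr.value}_L{j + 1}", arr)
        for arr in arrangements
        for j in range(cfg.n_lines_per_arrangement)
    ]
    line_effects = {
        name: float(rng.normal(0.0, cfg.sd_line)) for name, _arr in lines
    }
    cells = [
        (name, arr, sex, rep)
        for name, arr in lines
        for sex in (Sex.F, Sex.M)
        for rep in range(1, cfg.n_bio_reps + 1)
    ]
    n_drop = int(round(cfg.missing_fraction * len(cells)))
    drop_idx = set(rng.choice(len(cells), size=n_drop, replace=False)) if n_drop else set()

    records: List[CtRecord] = []
    truth_dct: Dict[tuple, float] = {}
    dropped = []
    kept_cells: Dict[tuple, int] = {}
    for idx, (name, arr, sex, rep) in enumerate(cells):
        if idx in drop_idx:
            dropped.append((name, sex.value, rep))
            continue
        kept_cells[(name, sex)] = kept_cells.get((name, sex), 0) + 1
        signal = (
            (cfg.arrangement_effect if arr is Arrangement.O347 else 0.0)
            + line_effects[name]
            + (cfg.sex_effect if sex is Sex.M else 0.0)
            + (cfg.interaction_effect if (arr is Arrangement.O347 and sex is Sex.M) else 0.0)
            + float(rng.normal(0.0, cfg.sd_error))
        )
        if cfg.response_scale == "ct":
            dct = cfg.grand_mean_dct + signal
        else:
            rel = cfg.grand_mean_dct + signal
            if rel <= 0:
                raise CapacityError(
                    "relative-scale simulation produced a non-positive response; "
                    "increase the mean or decrease the spread"
                )
            dct = float(-np.log2(rel))
        ref_true = float(rng.normal(cfg.reference_ct_mean, cfg.reference_sd))
        target_true = ref_true + dct
        truth_dct[(name, sex.value, rep)] = dct
        for tech in range(1, cfg.n_tech_reps + 1):
            records.append(
                CtRecord(
                    line_id=name,
                    arrangement=arr,
                    sex=sex,
                    bio_rep=rep,
                    tech_rep=tech,
                    gene=Gene.TARGET,
                    ct=target_true + float(rng.normal(0.0, cfg.sd_tech)),
                )
            )
            records.append(
                CtRecord(
                    line_id=name,
                    arrangement=arr,
                    sex=sex,
                    bio_rep=rep,
                    tech_rep=tech,
                    gene=Gene.REFERENCE,
                    ct=ref_true + float(rng.normal(0.0, cfg.sd_tech)),
                )
            )
    warnings = []
    for name, _arr in lines:
        for sex in (Sex.F, Sex.M):
            if kept_cells.get((name, sex), 0) == 0:
                warnings.append(f"line {name} sex {sex.value}: all replicates dropped")
    truth = SyntheticTruth(
        config=asdict(cfg),
        line_effects=line_effects,
        delta_ct=truth_dct,
        dropped_replicates=tuple(dropped),
        warnings=tuple(warnings),
    )
    return records, truth
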