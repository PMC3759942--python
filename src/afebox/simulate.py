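"""Synthetic bacterial chromosomes with planted operator instances.

Generates a single-contig genome (configurable length and GC), lays out
non-overlapping CDS features on both strands in diverging / converging /
tandem arrangements, and splices motif instances sampled from the
palindrome-template emission models at known positions in chosen genomic
contexts (sense intergenic, coding, convergent intergenic).  The planted
positions and their expected context types form the ground truth against
which scan sensitivity, merge behaviour and context classification are
benchmarked.

The background is i.i.d. mononucleotide (matching the scanner's
background model); a first-order Markov option exists for robustness
tests.  Given identical config and seed the outputs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from afebox.context import (
    DEFAULT_WINDOW,
    GeneAnnotation,
    IGRegion,
    classify_pbs,
    compute_intergenic,
    write_gff3,
)
from afebox.palindromes import builtin_template, enumerate_variants, revcomp
from afebox.profiles import build_profile

__all__ = [
    "PlantSpec",
    "SimulationConfig",
    "TruthRecord",
    "SimulatedGenome",
    "RecoveryReport",
    "simulate_genome",
    "benchmark_recovery",
    "standard_benchmark_config",
]

CONTEXTS = ("sense_IG", "coding", "convergent_IG")


@dataclass(frozen=True)
class PlantSpec:
    """How many instances of which template to plant in which context.

    ``sharpness`` interpolates the per-position emission between the
    template profile (1.0, consensus-sharp: fixed positions literal,
    wildcards uniform) and the genome background (0.0, unrecoverable).
    """

    template_id: str
    context: str
    count: int
    sharpness: float = 1.0

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}")
        if not 0.0 <= self.sharpness <= 1.0:
            raise ValueError("sharpness must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic chromosome.

    Defaults emulate a desk-scale slice of an acidophile chromosome:
    100 kb at 58% GC (the At. ferrooxidans-like regime), 75 genes of
    0.6-1.5 kb separated by 80-250 bp intergenic gaps (roughly 90%
    coding, as in real bacterial chromosomes), junction arrangements
    drawn evenly from diverging/converging/tandem.
    """

    seed: int = 0
    genome_length: int = 100_000
    gc_content: float = 0.58
    n_genes: int | None = None  # None: fill the chromosome
    gene_length: tuple[int, int] = (600, 1500)
    ig_length: tuple[int, int] = (80, 250)
    arrangement_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # div, conv, tandem
    plants: tuple[PlantSpec, ...] = ()
    background: str = "iid"  # or "markov1"
    contig: str = "synth_chr"
    plant_margin: int = 60  # min distance between planted instances

    def __post_init__(self) -> None:
        if abs(sum(self.arrangement_mix) - 1.0) > 1e-9:
            raise ValueError("arrangement_mix fractions must sum to 1")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")


@dataclass(frozen=True)
class TruthRecord:
    """One planted instance with its expected context classification."""

    instance_id: str
    template_id: str
    contig: str
    start: int
    end: int
    strand: str
    context: str
    expected_type: str  # I / II / III per the context rules

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class SimulatedGenome:
    """A generated chromosome with annotation and planted-instance truth."""

    config: SimulationConfig
    sequence: str
    annotations: tuple[GeneAnnotation, ...]
    ig_regions: tuple[IGRegion, ...]
    truth: tuple[TruthRecord, ...]

    @property
    def contig(self) -> str:
        return self.config.contig

    def genome(self) -> dict[str, str]:
        return {self.contig: self.sequence}

    def to_fasta(self) -> str:
        lines = [f">{self.contig}"]
        for i in range(0, len(self.sequence), 70):
            lines.append(self.sequence[i : i + 70])
        return "\n".join(lines) + "\n"

    def to_gff3(self) -> str:
        return write_gff3(list(self.annotations), {self.contig: len(self.sequence)})

    def truth_tsv(self) -> str:
        lines = ["instance_id\ttemplate_id\tcontig\tstart\tend\tstrand\tcontext\texpected_type"]
        for t in self.truth:
            lines.append(
                f"{t.instance_id}\t{t.template_id}\t{t.contig}\t{t.start}\t{t.end}\t{t.strand}\t{t.context}\t{t.expected_type}"
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class _Interval:
    """Minimal PBS-like stand-in for classifying a planted interval."""

    pbs_id: str
    contig: str
    start: int
    end: int

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def _background_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _sample_background(rng: np.random.Generator, length: int, gc: float, kind: str) -> np.ndarray:
    p = _background_probs(gc)
    if kind == "iid":
        return rng.choice(4, size=length, p=p)
    if kind == "markov1":
        # mild CpG-style depletion on top of the stationary composition
        trans = np.tile(p, (4, 1))
        trans[1, 2] *= 0.5  # C->G depleted
        trans += 1e-3
        trans /= trans.sum(axis=1, keepdims=True)
        out = np.empty(length, dtype=np.int64)
        out[0] = rng.choice(4, p=p)
        for i in range(1, length):
            out[i] = rng.choice(4, p=trans[out[i - 1]])
        return out
    raise ValueError(f"unknown background kind {kind!r}")


def _layout_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    pos = int(rng.integers(cfg.ig_length[0], cfg.ig_length[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    labels = ("diverging", "converging", "tandem")
    n_target = cfg.n_genes if cfg.n_genes is not None else 10**9
    i = 0
    while i < n_target:
        glen = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
        if pos + glen + cfg.ig_length[0] > cfg.genome_length:
            if cfg.n_genes is None:
                break
            raise ValueError(
                f"infeasible packing: placed {i} of {cfg.n_genes} genes in {cfg.genome_length} bp"
            )
        genes.append(
            GeneAnnotation(
                gene_id=f"gene_{i + 1:03d}", contig=cfg.contig,
                start=pos, end=pos + glen, strand=strand,
                product=f"hypothetical protein {i + 1}",
            )
        )
        pos += glen + int(rng.integers(cfg.ig_length[0], cfg.ig_length[1] + 1))
        i += 1
        # choose the arrangement of the junction to the NEXT gene; the next
        # strand is derived from the current one, so when the sampled type
        # is unreachable the realized junction differs from the sample
        jt = labels[int(rng.choice(3, p=np.asarray(cfg.arrangement_mix)))]
        if jt == "tandem":
            pass  # same strand
        elif jt == "diverging":
            strand = "+"  # realised diverging only if current gene is '-'
        else:
            strand = "-"
    return genes


def _template_emissions(template_id: str, gc: float, sharpness: float) -> np.ndarray:
    profile = build_profile(enumerate_variants(builtin_template(template_id)), pseudocount=0.0)
    bg = _background_probs(gc)
    return sharpness * profile.emissions + (1.0 - sharpness) * bg[None, :]


def _eligible_positions(
    spec: PlantSpec,
    length: int,
    ig_regions: list[IGRegion],
    annotations: list[GeneAnnotation],
    genome_length: int,
) -> list[tuple[int, int]]:
    """Candidate (start, end) intervals whose classification matches the
    requested context; margin of 5 bp from region boundaries."""
    margin = 5
    spots: list[tuple[int, int]] = []
    if spec.context == "sense_IG":
        regions = [r for r in ig_regions if r.is_sense]
    elif spec.context == "convergent_IG":
        regions = [
            r for r in ig_regions
            if not r.is_sense
            and r.left_gene is not None and r.left_gene.strand == "+"
            and r.right_gene is not None and r.right_gene.strand == "-"
        ]
    else:  # coding: middle of genes, away from every start-codon zone
        regions = []
        for a in annotations:
            lo, hi = a.start + 60, a.end - 60
            if hi - lo >= length + 2 * margin:
                regions.append(IGRegion(a.contig, lo, hi, None, None, False))
    for r in regions:
        lo, hi = r.start + margin, r.end - margin - length
        if hi > lo:
            spots.append((lo, hi))
    return spots


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate sequence, annotation and truth table for one chromosome."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _layout_genes(cfg, rng)
    ig_regions = compute_intergenic(genes, cfg.genome_length, contig=cfg.contig)
    codes = _sample_background(rng, cfg.genome_length, cfg.gc_content, cfg.background)

    truth: list[TruthRecord] = []
    placed: list[tuple[int, int]] = []
    inst = 0
    for spec in cfg.plants:
        template = builtin_template(spec.template_id)
        L = len(template.pattern)
        em = _template_emissions(spec.template_id, cfg.gc_content, spec.sharpness)
        spots = _eligible_positions(spec, L, ig_regions, genes, cfg.genome_length)
        if not spots:
            raise ValueError(f"no eligible region for plant {spec}")
        for _k in range(spec.count):
            start = None
            for _try in range(500):
                lo, hi = spots[int(rng.integers(len(spots)))]
                cand = int(rng.integers(lo, hi + 1))
                if all(
                    cand + L + cfg.plant_margin <= s or e + cfg.plant_margin <= cand
                    for s, e in placed
                ):
                    # the planted interval must classify as its expected type
                    iv = _Interval("plant", cfg.contig, cand, cand + L)
                    call = classify_pbs(iv, list(ig_regions), genes, DEFAULT_WINDOW)
                    want = {"sense_IG": "I", "coding": "III", "convergent_IG": "III"}[spec.context]
                    if call.context_type == want:
                        start = cand
                        break
            if start is None:
                raise ValueError(
                    f"infeasible packing: could not place instance {inst + 1} of {spec}"
                )
            site = np.array([rng.choice(4, p=em[j]) for j in range(L)])
            strand = "+" if rng.random() < 0.5 else "-"
            site_str = "".join("ACGT"[b] for b in site)
            if strand == "-":
                site_str = revcomp(site_str)
            codes[start : start + L] = np.array(["ACGT".index(c) for c in site_str])
            placed.append((start, start + L))
            iv = _Interval("plant", cfg.contig, start, start + L)
            call = classify_pbs(iv, list(ig_regions), genes, DEFAULT_WINDOW)
            inst += 1
            truth.append(
                TruthRecord(
                    instance_id=f"plant_{inst:03d}", template_id=spec.template_id,
                    contig=cfg.contig, start=start, end=start + L, strand=strand,
                    context=spec.context, expected_type=call.context_type,
                )
            )
    seq = "".join("ACGT"[b] for b in codes)
    return SimulatedGenome(
        config=cfg, sequence=seq, annotations=tuple(genes),
        ig_regions=tuple(ig_regions), truth=tuple(sorted(truth, key=lambda t: t.start)),
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Benchmark outcome: how well the pipeline recovered planted truth."""

    n_truth: int
    n_recovered: int
    sensitivity: float
    false_merges: int
    n_classified_correct: int
    classification_accuracy: float
    recovered_ids: tuple[str, ...] = field(default=(), hash=False)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def benchmark_recovery(
    truth: list[TruthRecord],
    pbss: list,
    context_calls: list | dict | None = None,
    min_overlap_fraction: float = 0.5,
) -> RecoveryReport:
    """Score recovery of planted instances by the PBS catalog.

    A truth instance is recovered when some PBS covers at least
    ``min_overlap_fraction`` of its interval.  A false merge is a PBS
    overlapping two planted instances that do not overlap each other.
    Classification accuracy compares, over recovered instances, the
    context type of the best-covering PBS with the expected type.
    """
    calls: dict[str, str] = {}
    if context_calls is not None:
        items = context_calls.values() if isinstance(context_calls, dict) else context_calls
        calls = {c.pbs_id: c.context_type for c in items}

    recovered: list[str] = []
    correct = 0
    n_class = 0
    for t in truth:
        span = t.end - t.start
        best, best_ov = None, 0
        for p in pbss:
            if p.contig != t.contig:
                continue
            ov = _overlap((p.start, p.end), t.interval)
            if ov > best_ov:
                best, best_ov = p, ov
        if best is not None and best_ov >= min_overlap_fraction * span:
            recovered.append(t.instance_id)
            if best.pbs_id in calls:
                n_class += 1
                if calls[best.pbs_id] == t.expected_type:
                    correct += 1

    false_merges = 0
    for p in pbss:
        touched = [
            t for t in truth
            if t.contig == p.contig and _overlap((p.start, p.end), t.interval) > 0
        ]
        for i in range(len(touched)):
            for j in range(i + 1, len(touched)):
                if _overlap(touched[i].interval, touched[j].interval) == 0:
                    false_merges += 1

    n = len(truth)
    return RecoveryReport(
        n_truth=n,
        n_recovered=len(recovered),
        sensitivity=len(recovered) / n if n else 0.0,
        false_merges=false_merges,
        n_classified_correct=correct,
        classification_accuracy=correct / n_class if n_class else 0.0,
        recovered_ids=tuple(recovered),
    )


def standard_benchmark_config(seed: int = 0) -> SimulationConfig:
    """The standard recovery benchmark: 100 kb, 30 consensus-sharp plants
    spread across contexts and templates."""
    plants = (
        PlantSpec("SP13", "sense_IG", 4), PlantSpec("SP15", "sense_IG", 3),
        PlantSpec("MP18", "sense_IG", 4), PlantSpec("MP20", "sense_IG", 3),
        PlantSpec("LP30", "sense_IG", 4),
        PlantSpec("MP18", "coding", 3), PlantSpec("LP30", "coding", 3),
        PlantSpec("SP13", "coding", 2),
        PlantSpec("MP20", "convergent_IG", 2), PlantSpec("LP30", "convergent_IG", 2),
    )
    return SimulationConfig(seed=seed, plants=plants)
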