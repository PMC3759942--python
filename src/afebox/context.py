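"""Genomic context of predicted binding sites.

Intergenic (IG) regions are the complement of the annotated CDS intervals.
An IG region is a *sense* IG region when at least one flanking gene reads
away from it into its own body, i.e. the gene's start codon abuts the
region boundary; the gap between the stop codons of converging genes is
not sense.  PBSs are classified into three mutually exclusive context
types:

* Type I   - the PBS overlaps (>= 1 bp) a sense IG region;
* Type II  - not Type I, and the PBS centre lies within a strand-aware
  window around some gene's start codon (default 200 bp upstream to 50 bp
  downstream);
* Type III - everything else.

Candidate selection keeps all Type I PBSs, keeps a Type II PBS only when a
sigma-70 promoter prediction falls inside its flanked window, and always
discards Type III.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GeneAnnotation",
    "IGRegion",
    "ContextCall",
    "compute_intergenic",
    "classify_pbs",
    "density_by_type",
    "total_intergenic_bp",
    "total_start_zone_bp",
    "select_candidates",
    "read_gff3",
    "write_gff3",
    "ig_to_bed",
    "context_calls_to_tsv",
]

DEFAULT_WINDOW = (-200, 50)


@dataclass(frozen=True)
class GeneAnnotation:
    """A CDS feature with strand-aware start codon.

    ``start``/``end`` are 0-based half-open genomic coordinates;
    ``start_codon_pos`` is the genomic position of the first base of the
    start codon (the A of ATG): the 5' boundary of the interval on the
    feature's strand.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad CDS interval [{self.start},{self.end})")

    @property
    def start_codon_pos(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class IGRegion:
    """An intergenic interval with senseness and nullable flanking genes."""

    contig: str
    start: int
    end: int
    left_gene: GeneAnnotation | None
    right_gene: GeneAnnotation | None
    is_sense: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class ContextCall:
    """Context classification of one PBS."""

    pbs_id: str
    context_type: str  # "I", "II" or "III"
    nearest_start_gene: str | None
    distance_center_to_start: int | None  # signed bp; negative = upstream
    overlapped_ig: tuple[int, int] | None
    associated_genes: tuple[str, ...] = field(default=())


def compute_intergenic(
    annotations: list[GeneAnnotation],
    contig_length: int,
    contig: str | None = None,
    slack: int = 0,
) -> list[IGRegion]:
    """Intergenic regions (complement of CDS) for one contig, with senseness.

    ``slack`` loosens the abutting requirement: a flanking gene makes the
    region sense if its start codon lies within ``slack`` bp of the region
    boundary (default 0: exact abutment, which is automatic for complement
    regions when the gene reads away from the gap).

    Raises on overlapping CDS intervals or intervals outside the contig.
    """
    if contig is None:
        contigs = {a.contig for a in annotations}
        if len(contigs) > 1:
            raise ValueError("annotations span multiple contigs; pass contig=")
        contig = contigs.pop() if contigs else "contig_1"
    anns = sorted(
        (a for a in annotations if a.contig == contig), key=lambda a: (a.start, a.end)
    )
    for a in anns:
        if a.end > contig_length:
            raise ValueError(f"{a.gene_id}: CDS [{a.start},{a.end}) outside contig (len {contig_length})")
    for a, b in zip(anns, anns[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping CDS: {a.gene_id} [{a.start},{a.end}) and {b.gene_id} [{b.start},{b.end})")

    regions: list[IGRegion] = []
    bounds: list[tuple[int, int, GeneAnnotation | None, GeneAnnotation | None]] = []
    prev_end = 0
    prev_gene: GeneAnnotation | None = None
    for a in anns:
        if a.start > prev_end:
            bounds.append((prev_end, a.start, prev_gene, a))
        prev_end = a.end
        prev_gene = a
    if contig_length > prev_end:
        bounds.append((prev_end, contig_length, prev_gene, None))

    for start, end, left, right in bounds:
        sense = False
        # right gene reads away on + iff its start codon (left boundary)
        # abuts the region end
        if right is not None and right.strand == "+" and right.start - end <= slack:
            sense = True
        # left gene reads away on - iff its start codon (right boundary)
        # abuts the region start
        if left is not None and left.strand == "-" and start - left.end <= slack:
            sense = True
        regions.append(
            IGRegion(contig=contig, start=start, end=end, left_gene=left,
                     right_gene=right, is_sense=sense)
        )
    return regions


def _signed_distance(center: int, gene: GeneAnnotation) -> int:
    """Centre-to-start-codon distance in the gene's reading direction.

    Negative means the centre lies upstream of the start codon.
    """
    s = gene.start_codon_pos
    return center - s if gene.strand == "+" else s - center


def classify_pbs(
    pbs,
    ig_regions: list[IGRegion],
    annotations: list[GeneAnnotation],
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> ContextCall:
    """Classify one PBS as Type I, II or III.

    Type I uses any-overlap of the PBS interval with a sense IG region;
    Type II uses the PBS centre against the strand-aware start-codon
    window.  ``associated_genes`` lists, for Type I, the genes reading away
    from the overlapped sense IG (both genes of a diverging pair share one
    PBS); for Type II, the genes whose window contains the centre.
    """
    contig_anns = [a for a in annotations if a.contig == pbs.contig]
    center = pbs.center
    nearest: GeneAnnotation | None = None
    nearest_d: int | None = None
    for a in contig_anns:
        d = _signed_distance(center, a)
        if nearest_d is None or abs(d) < abs(nearest_d):
            nearest, nearest_d = a, d

    overlapped = None
    for ig in ig_regions:
        if ig.contig == pbs.contig and ig.overlaps(pbs.start, pbs.end):
            overlapped = ig
            break

    sense_igs = [
        ig for ig in ig_regions
        if ig.contig == pbs.contig and ig.is_sense and ig.overlaps(pbs.start, pbs.end)
    ]
    if sense_igs:
        genes: list[str] = []
        for ig in sense_igs:
            if ig.right_gene is not None and ig.right_gene.strand == "+":
                genes.append(ig.right_gene.gene_id)
            if ig.left_gene is not None and ig.left_gene.strand == "-":
                genes.append(ig.left_gene.gene_id)
        return ContextCall(
            pbs_id=pbs.pbs_id, context_type="I",
            nearest_start_gene=nearest.gene_id if nearest else None,
            distance_center_to_start=nearest_d,
            overlapped_ig=(sense_igs[0].start, sense_igs[0].end),
            associated_genes=tuple(dict.fromkeys(genes)),
        )

    in_window = [
        a for a in contig_anns if window[0] <= _signed_distance(center, a) <= window[1]
    ]
    if in_window:
        best = min(in_window, key=lambda a: abs(_signed_distance(center, a)))
        return ContextCall(
            pbs_id=pbs.pbs_id, context_type="II",
            nearest_start_gene=best.gene_id,
            distance_center_to_start=_signed_distance(center, best),
            overlapped_ig=(overlapped.start, overlapped.end) if overlapped else None,
            associated_genes=tuple(a.gene_id for a in in_window),
        )
    return ContextCall(
        pbs_id=pbs.pbs_id, context_type="III",
        nearest_start_gene=nearest.gene_id if nearest else None,
        distance_center_to_start=nearest_d,
        overlapped_ig=(overlapped.start, overlapped.end) if overlapped else None,
        associated_genes=(),
    )


def total_intergenic_bp(ig_regions: list[IGRegion]) -> int:
    """Total intergenic bases (tIG)."""
    return sum(r.length for r in ig_regions)


def total_start_zone_bp(
    annotations: list[GeneAnnotation],
    contig_lengths: dict[str, int],
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> int:
    """Total bases in the union of strand-aware start-codon zones (t250Z).

    Each gene contributes the inclusive window [start+window0, start+window1]
    in its reading direction; overlapping zones are unioned before totaling
    and clipped to contig bounds.
    """
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for a in annotations:
        s = a.start_codon_pos
        if a.strand == "+":
            lo, hi = s + window[0], s + window[1] + 1
        else:
            lo, hi = s - window[1], s - window[0] + 1
        L = contig_lengths[a.contig]
        lo, hi = max(0, lo), min(L, hi)
        if lo < hi:
            per_contig.setdefault(a.contig, []).append((lo, hi))
    total = 0
    for ivs in per_contig.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total


def density_by_type(
    counts: dict[str, int],
    genome_length: int,
    tIG: int,
    t250Z: int,
) -> dict[str, float | None]:
    """PBSs per megabase of DNA available to each context type.

    Denominators: Type I = tIG; Type II = t250Z - tIG; Type III =
    genome_length - t250Z.  The three denominators sum to the genome
    length.  A non-positive denominator yields ``None`` (undefined), never
    infinity.
    """
    if tIG > genome_length or t250Z > genome_length:
        raise ValueError("tIG and t250Z must not exceed genome_length")
    denoms = {"I": tIG, "II": t250Z - tIG, "III": genome_length - t250Z}
    out: dict[str, float | None] = {}
    for typ, denom in denoms.items():
        n = counts.get(typ, 0)
        out[typ] = None if denom <= 0 else n / denom * 1e6
    return out


def select_candidates(
    context_calls: list[ContextCall],
    promoter_predictions: dict[str, list],
) -> list[str]:
    """PBS ids passing the context + promoter filter.

    All Type I PBSs are selected.  A Type II PBS is selected only if at
    least one sigma-70 prediction was found in its flanked window
    (``promoter_predictions`` maps pbs_id to the predictions computed on
    PBS +/- 100 bp).  Type III is never selected.
    """
    selected: list[str] = []
    for call in context_calls:
        if call.context_type == "I":
            selected.append(call.pbs_id)
        elif call.context_type == "II" and promoter_predictions.get(call.pbs_id):
            selected.append(call.pbs_id)
    return selected


# ---------------------------------------------------------------------------
# GFF3 I/O


def read_gff3(path_or_text: str, from_string: bool = False) -> list[GeneAnnotation]:
    """Read CDS features from a GFF3 file (or text) into annotations.

    Gene id comes from the ID or locus_tag attribute, product text from the
    product or Note attribute.  GFF3 coordinates (1-based inclusive) are
    converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        path_or_text,
        dbfn=":memory:",
        from_string=from_string,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    anns: list[GeneAnnotation] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gid = (feat.attributes.get("ID") or feat.attributes.get("locus_tag") or [feat.id])[0]
        product = (feat.attributes.get("product") or feat.attributes.get("Note") or [""])[0]
        anns.append(
            GeneAnnotation(
                gene_id=gid,
                contig=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                product=product,
            )
        )
    return anns


def write_gff3(annotations: list[GeneAnnotation], contig_lengths: dict[str, int]) -> str:
    """Serialise annotations as GFF3 text (CDS features, 1-based inclusive)."""
    lines = ["##gff-version 3"]
    for contig, length in sorted(contig_lengths.items()):
        lines.append(f"##sequence-region {contig} 1 {length}")
    for a in sorted(annotations, key=lambda a: (a.contig, a.start)):
        attrs = f"ID={a.gene_id}"
        if a.product:
            attrs += f";product={a.product}"
        lines.append(
            f"{a.contig}\tafebox\tCDS\t{a.start + 1}\t{a.end}\t.\t{a.strand}\t0\t{attrs}"
        )
    return "\n".join(lines) + "\n"


def ig_to_bed(ig_regions: list[IGRegion]) -> str:
    lines = []
    for i, r in enumerate(ig_regions):
        name = f"IG_{i + 1:04d}_{'sense' if r.is_sense else 'nonsense'}"
        lines.append(f"{r.contig}\t{r.start}\t{r.end}\t{name}\t0\t.")
    return "\n".join(lines) + ("\n" if lines else "")


def context_calls_to_tsv(calls: list[ContextCall]) -> str:
    lines = ["pbs_id\tcontext_type\tnearest_start_gene\tdistance_center_to_start\toverlapped_ig\tassociated_genes"]
    for c in calls:
        ig = f"{c.overlapped_ig[0]}-{c.overlapped_ig[1]}" if c.overlapped_ig else "."
        d = c.distance_center_to_start if c.distance_center_to_start is not None else "."
        genes = ";".join(c.associated_genes) if c.associated_genes else "."
        lines.append(f"{c.pbs_id}\t{c.context_type}\t{c.nearest_start_gene or '.'}\t{d}\t{ig}\t{genes}")
    return "\n".join(lines) + "\n"
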