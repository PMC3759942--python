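"""Merging model hits into predicted binding sites (PBSs).

A PBS is a genome fragment covered by one or more model hits on either
strand.  Hits of the A/B models carry the SP label, C/D the MP label and E
the LP label; hits overlapping by at least 1 bp (strand ignored) are merged
by single linkage and each merge is one PBS.  A PBS whose label set has one
element is a single site, two a double site, three a triple site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from afebox.profiles import Hit

__all__ = ["PBS", "group_hits", "tally_site_classes", "pbs_to_tsv", "pbs_to_bed"]


@dataclass(frozen=True)
class PBS:
    """A merged run of overlapping hits with the union of their labels."""

    pbs_id: str
    contig: str
    start: int
    end: int
    member_hits: tuple[Hit, ...] = field(hash=False)
    set_labels: frozenset[str] = field(hash=False)

    @property
    def center(self) -> int:
        """Floor of the interval midpoint, used for distance reporting."""
        return (self.start + self.end) // 2

    @property
    def best_score(self) -> float:
        return max(h.score for h in self.member_hits)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def group_hits(hits: list[Hit]) -> list[PBS]:
    """Single-linkage merge of hits overlapping by >= 1 bp on either strand.

    The PBS interval is the union of its member hit intervals; labels are
    the union of member set labels.  Output is ordered by (contig, start)
    and ids are assigned in that order, so the result is independent of the
    input hit order.
    """
    out: list[PBS] = []
    by_contig: dict[str, list[Hit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig, []).append(h)
    clusters: list[list[Hit]] = []
    for contig in sorted(by_contig):
        chits = sorted(by_contig[contig], key=lambda h: (h.start, h.end, h.model_id, h.strand))
        cur: list[Hit] = []
        cur_end = -1
        for h in chits:
            if cur and h.start < cur_end:
                cur.append(h)
                cur_end = max(cur_end, h.end)
            else:
                if cur:
                    clusters.append(cur)
                cur = [h]
                cur_end = h.end
        if cur:
            clusters.append(cur)
    for i, members in enumerate(clusters):
        start = min(h.start for h in members)
        end = max(h.end for h in members)
        out.append(
            PBS(
                pbs_id=f"PBS_{i + 1:04d}",
                contig=members[0].contig,
                start=start,
                end=end,
                member_hits=tuple(members),
                set_labels=frozenset(h.set_label for h in members),
            )
        )
    return out


def tally_site_classes(pbss: list[PBS]) -> dict:
    """Counts of single/double/triple sites and of each label combination.

    Returns ``{"single": n1, "double": n2, "triple": n3,
    "by_labels": {"SP": ..., "MP+LP": ..., ...}}``; the three class counts
    partition the PBS list.
    """
    class_names = {1: "single", 2: "double", 3: "triple"}
    classes = Counter(class_names[len(p.set_labels)] for p in pbss)
    by_labels = Counter("+".join(sorted(p.set_labels)) for p in pbss)
    return {
        "single": classes.get("single", 0),
        "double": classes.get("double", 0),
        "triple": classes.get("triple", 0),
        "by_labels": dict(sorted(by_labels.items())),
    }


def pbs_to_tsv(pbss: list[PBS]) -> str:
    lines = ["pbs_id\tcontig\tstart\tend\tcenter\tset_labels\tmodel_ids\tbest_score_bits"]
    for p in pbss:
        models = ",".join(sorted({h.model_id for h in p.member_hits}))
        labels = ",".join(sorted(p.set_labels))
        lines.append(
            f"{p.pbs_id}\t{p.contig}\t{p.start}\t{p.end}\t{p.center}\t{labels}\t{models}\t{p.best_score:.6f}"
        )
    return "\n".join(lines) + "\n"


def pbs_to_bed(pbss: list[PBS]) -> str:
    lines = []
    for p in pbss:
        lines.append(
            f"{p.contig}\t{p.start}\t{p.end}\t{p.pbs_id}\t{round(p.best_score * 100)}\t."
        )
    return "\n".join(lines) + ("\n" if lines else "")
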