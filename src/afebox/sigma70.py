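"""Sigma-70 promoter element prediction.

Locates putative -35/-10 element pairs with a mismatch-tolerant log-odds
score built from the literature consensus hexamers (TTGACA and TATAAT,
classic compilation frequencies) and a spacer of 15-19 bp.  Both strands
are scanned; overlapping placements are resolved best-first.  Predictions
are reported as "sigma-70-like", a deliberately simple stand-in for a full
promoter predictor: no transcription-start-site model, no alternative
sigma factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PromoterPrediction",
    "predict_sigma70",
    "max_promoter_score",
    "default_threshold",
    "overlap_category",
    "MINUS35_PWM",
    "MINUS10_PWM",
    "SPACER_RANGE",
]

SPACER_RANGE = (15, 19)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _pwm(consensus: str, strengths: list[float]) -> np.ndarray:
    """Per-position probabilities: the consensus base gets its compiled
    frequency, the remainder is spread evenly over the other three bases."""
    m = np.empty((len(consensus), 4))
    for i, (b, p) in enumerate(zip(consensus, strengths)):
        m[i, :] = (1.0 - p) / 3.0
        m[i, _BASE_INDEX[b]] = p
    return m


# Consensus-base frequencies from the classic E. coli sigma-70 promoter
# compilations (values rounded to two digits).
MINUS35_PWM = _pwm("TTGACA", [0.78, 0.82, 0.68, 0.58, 0.52, 0.54])
MINUS10_PWM = _pwm("TATAAT", [0.82, 0.89, 0.52, 0.59, 0.49, 0.89])

_LO35 = np.log2(MINUS35_PWM / 0.25)
_LO10 = np.log2(MINUS10_PWM / 0.25)


@dataclass(frozen=True)
class PromoterPrediction:
    """A scored -35/-10 placement.

    Hexamer intervals are 0-based half-open in the coordinates of the
    scanned sequence's forward strand; on strand "-" the -35 element lies
    to the right of the -10 element in forward coordinates.  The spacer is
    the gap between the hexamers (15-19 bp).
    """

    contig: str
    minus35: tuple[int, int]
    minus10: tuple[int, int]
    spacer: int
    score: float
    strand: str

    def __post_init__(self) -> None:
        if not SPACER_RANGE[0] <= self.spacer <= SPACER_RANGE[1]:
            raise ValueError(f"spacer {self.spacer} outside {SPACER_RANGE}")

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.minus35[0], self.minus10[0]), max(self.minus35[1], self.minus10[1]))


def max_promoter_score() -> float:
    """Highest achievable combined -35 + -10 score in bits."""
    return float(_LO35.max(axis=1).sum() + _LO10.max(axis=1).sum())


def default_threshold(fraction: float = 0.6) -> float:
    """Default acceptance threshold: a fraction of the maximum score."""
    return fraction * max_promoter_score()


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _hexamer_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    n = len(codes) - 6 + 1
    padded = np.vstack([lo.T, np.zeros(6)]).T  # ambiguous base scores 0
    s = np.zeros(n)
    for j in range(6):
        s += padded[j, codes[j : j + n]]
    return s


def predict_sigma70(
    seq: str,
    threshold: float | None = None,
    contig: str = "seq",
) -> list[PromoterPrediction]:
    """Scan both strands for -35/-10 pairs with spacer 15-19.

    Every placement is scored as the sum of the two hexamer log-odds
    scores; placements with combined score >= threshold are returned
    best-first after greedy removal of overlapping placements (overlap
    judged on the full -35..-10 span, across strands).  Sequences shorter
    than 27 bp (6 + 15 + 6) yield no predictions.
    """
    if threshold is None:
        threshold = default_threshold()
    if len(seq) < 27:
        return []
    codes = _encode(seq)
    comp = np.where(codes < 4, 3 - codes, 4)

    cands: list[tuple[float, int, int, str]] = []  # (score, pos35, spacer, strand)
    s35_f = _hexamer_scores(codes, _LO35)
    s10_f = _hexamer_scores(codes, _LO10)
    n = len(s35_f)
    for spacer in range(SPACER_RANGE[0], SPACER_RANGE[1] + 1):
        off = 6 + spacer
        m = n - off
        if m <= 0:
            continue
        comb = s35_f[:m] + s10_f[off : off + m]
        for pos in np.nonzero(comb >= threshold)[0]:
            cands.append((float(comb[pos]), int(pos), spacer, "+"))
    # minus strand: rev_codes is the minus strand 5'->3'; reversing the
    # window-score array re-indexes it by the window's forward-strand start,
    # so s35_m[i] scores the minus-strand hexamer occupying [i, i+6).
    rev_codes = comp[::-1]
    s35_m = _hexamer_scores(rev_codes, _LO35)[::-1]
    s10_m = _hexamer_scores(rev_codes, _LO10)[::-1]
    for spacer in range(SPACER_RANGE[0], SPACER_RANGE[1] + 1):
        off = 6 + spacer
        m = n - off
        if m <= 0:
            continue
        # on minus strand the -10 is upstream (left in forward coords)
        comb = s35_m[off : off + m] + s10_m[:m]
        for pos in np.nonzero(comb >= threshold)[0]:
            cands.append((float(comb[pos]), int(pos), spacer, "-"))

    cands.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    out: list[PromoterPrediction] = []
    occupied: list[tuple[int, int]] = []
    for score, pos, spacer, strand in cands:
        span = (pos, pos + 12 + spacer)
        if any(span[0] < oe and os_ < span[1] for os_, oe in occupied):
            continue
        occupied.append(span)
        if strand == "+":
            minus35 = (pos, pos + 6)
            minus10 = (pos + 6 + spacer, pos + 12 + spacer)
        else:
            minus10 = (pos, pos + 6)
            minus35 = (pos + 6 + spacer, pos + 12 + spacer)
        out.append(
            PromoterPrediction(
                contig=contig, minus35=minus35, minus10=minus10,
                spacer=spacer, score=score, strand=strand,
            )
        )
    return out


def overlap_category(pbs, prediction: PromoterPrediction, near_bp: int = 10) -> str:
    """Relation of a PBS interval to a promoter prediction.

    Returns "overlaps -35" (takes precedence), "overlaps -10", "near"
    (within ``near_bp`` of either hexamer without intersecting) or "none".
    """
    start, end = pbs.start, pbs.end

    def intersects(iv: tuple[int, int]) -> bool:
        return start < iv[1] and iv[0] < end

    def distance(iv: tuple[int, int]) -> int:
        if intersects(iv):
            return 0
        return iv[0] - end + 1 if iv[0] >= end else start - iv[1] + 1

    if intersects(prediction.minus35):
        return "overlaps -35"
    if intersects(prediction.minus10):
        return "overlaps -10"
    if distance(prediction.minus35) <= near_bp or distance(prediction.minus10) <= near_bp:
        return "near"
    return "none"


def promoters_to_tsv(preds: list[PromoterPrediction]) -> str:
    lines = ["contig\tminus35_start\tminus35_end\tminus10_start\tminus10_end\tspacer\tstrand\tscore_bits"]
    for p in preds:
        lines.append(
            f"{p.contig}\t{p.minus35[0]}\t{p.minus35[1]}\t{p.minus10[0]}\t{p.minus10[1]}\t{p.spacer}\t{p.strand}\t{p.score:.6f}"
        )
    return "\n".join(lines) + "\n"
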