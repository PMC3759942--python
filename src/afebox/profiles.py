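"""Ungapped log-odds profiles and both-strand genome scanning.

The training alignments are fixed-length and ungapped, so insert/delete
states of a profile HMM are degenerate; each model is therefore an ungapped
position-wise emission profile scored as a log2-odds sum against a
mononucleotide background, scanned with a sliding window on both strands.
This is a re-implementation of glocal multi-hit profile search for the
fixed-length case, not an emulation of HMMER bit scores.

Hits are selected greedily by descending score among all above-threshold
windows; a window overlapping an already-accepted hit of the same model (on
either strand) is discarded, so accepted hits of one model never overlap.
For perfectly dyad-symmetric models the forward and reverse scores of a
window coincide; such same-locus opposite-strand duplicates are collapsed
to a single forward-strand hit at scan time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from afebox.palindromes import (
    SET_LABEL_FOR_MODEL,
    VariantAlignment,
    builtin_templates,
    enumerate_variants,
    revcomp,
)

__all__ = [
    "ProfileModel",
    "Hit",
    "build_profile",
    "builtin_profiles",
    "score_window",
    "scan_genome",
    "genome_background",
    "calibrate_threshold",
    "hits_to_bed",
    "hits_to_tsv",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
#: Tolerance used when deciding that forward and reverse scores at one locus
#: are the palindromic duplicate of each other.
_STRAND_TIE_TOL = 1e-9


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A,C,G,T -> 0..3; anything else -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ProfileModel:
    """Position-wise emission profile with background, scored in bits.

    ``emissions`` is a (length, 4) array of per-position probabilities over
    A,C,G,T; ``background`` a length-4 probability vector.  ``model_id`` is
    the profile letter A-E and ``set_label`` the palindrome module SP/MP/LP.
    """

    model_id: str
    set_label: str
    emissions: np.ndarray = field(hash=False)
    background: np.ndarray = field(hash=False)
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        em = np.asarray(self.emissions, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if em.ndim != 2 or em.shape[1] != 4:
            raise ValueError("emissions must be (length, 4)")
        if not np.allclose(em.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("emission columns must each sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        object.__setattr__(self, "emissions", em)
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.emissions.shape[0]

    def log_odds(self) -> np.ndarray:
        """(length, 5) log2-odds matrix; column 4 (ambiguous base) scores 0."""
        lo = np.zeros((self.length, 5))
        with np.errstate(divide="ignore"):  # zero emissions score -inf
            lo[:, :4] = np.log2(self.emissions / self.background[None, :])
        return lo

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.emissions.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.log_odds()[:, :4].max(axis=1).sum())


@dataclass(frozen=True, order=True)
class Hit:
    """A scored genomic match of one profile model.

    Coordinates are 0-based half-open on the forward strand regardless of
    the matched strand; ``end - start`` equals the model length.
    """

    contig: str
    start: int
    end: int
    model_id: str
    strand: str
    score: float

    @property
    def set_label(self) -> str:
        return SET_LABEL_FOR_MODEL[self.model_id]

    def overlaps(self, other: "Hit") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end


def build_profile(
    alignment: VariantAlignment,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    model_id: str | None = None,
    set_label: str | None = None,
) -> ProfileModel:
    """Estimate per-position emissions from a variant alignment.

    emission(i, b) = (count(i, b) + pseudocount) / (n_seqs + 4 * pseudocount).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    seqs = alignment.sequences
    if not seqs:
        raise ValueError("empty alignment")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    counts = np.zeros((width, 4))
    for s in seqs:
        codes = _encode(s)
        if (codes == 4).any():
            raise ValueError(f"non-ACGT character in alignment sequence {s!r}")
        np.add.at(counts, (np.arange(width), codes), 1.0)
    em = (counts + pseudocount) / (len(seqs) + 4.0 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    from afebox.palindromes import MODEL_FOR_TEMPLATE

    mid = model_id if model_id is not None else MODEL_FOR_TEMPLATE.get(alignment.template_id, "?")
    lbl = set_label if set_label is not None else SET_LABEL_FOR_MODEL.get(mid, "?")
    return ProfileModel(
        model_id=mid, set_label=lbl, emissions=em, background=bg, pseudocount=pseudocount
    )


def builtin_profiles(
    pseudocount: float = 1.0, background: np.ndarray | None = None
) -> list[ProfileModel]:
    """Profiles A-E built from the five built-in templates."""
    return [
        build_profile(enumerate_variants(t), pseudocount=pseudocount, background=background)
        for t in builtin_templates()
    ]


def genome_background(genome: dict[str, str] | str) -> np.ndarray:
    """Strand-symmetrised mononucleotide frequencies of a genome.

    A/T and C/G counts are averaged so the background is identical on both
    strands.  Ambiguous bases are ignored; an all-ambiguous (or empty)
    genome falls back to the uniform background.
    """
    seqs = genome.values() if isinstance(genome, dict) else [genome]
    counts = np.zeros(4)
    for s in seqs:
        codes = _encode(s)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    at = (counts[0] + counts[3]) / 2.0
    cg = (counts[1] + counts[2]) / 2.0
    sym = np.array([at, cg, cg, at])
    return sym / sym.sum()


def score_window(model: ProfileModel, window: str, strand: str = "+") -> float:
    """Log2-odds score of one window in bits.

    For strand "-" the window is reverse-complemented before scoring.
    Ambiguous (N) bases contribute 0 bits.
    """
    if len(window) != model.length:
        raise ValueError(f"window length {len(window)} != model length {model.length}")
    if strand == "-":
        window = revcomp(window)
    codes = _encode(window)
    return float(model.log_odds()[np.arange(model.length), codes].sum())


def _window_scores(model: ProfileModel, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every window on + and - strand, indexed by forward start."""
    L = model.length
    n = len(codes) - L + 1
    lo = model.log_odds()
    fwd = np.zeros(n)
    for j in range(L):
        fwd += lo[j, codes[j : j + n]]
    # minus strand: score of revcomp(window) on the forward profile, i.e.
    # position j of the profile reads complement of codes[start + L - 1 - j]
    comp = np.where(codes < 4, 3 - codes, 4)
    rev = np.zeros(n)
    for j in range(L):
        rev += lo[j, comp[L - 1 - j : L - 1 - j + n]]
    return fwd, rev


def scan_genome(
    model: ProfileModel,
    genome: dict[str, str] | str,
    threshold: float = 0.0,
) -> list[Hit]:
    """Both-strand sliding-window scan with greedy non-overlap selection.

    Every window on both strands is evaluated; above-threshold windows are
    accepted in order of descending score, discarding any window that
    overlaps an already-accepted hit of this model regardless of strand.
    Same-locus opposite-strand duplicates (equal scores within 1e-9, the
    palindromic case) are collapsed to a single forward-strand hit.
    Contigs shorter than the model yield no hits.
    """
    contigs = genome if isinstance(genome, dict) else {"contig_1": genome}
    hits: list[Hit] = []
    for contig in sorted(contigs):
        seq = contigs[contig]
        if len(seq) < model.length:
            continue
        codes = _encode(seq)
        fwd, rev = _window_scores(model, codes)
        cands: list[tuple[float, int, str]] = []
        pal_dup = np.abs(fwd - rev) <= _STRAND_TIE_TOL
        fwd_eff = np.where(pal_dup, np.maximum(fwd, rev), fwd)
        for pos in np.nonzero(fwd_eff >= threshold)[0]:
            cands.append((float(fwd_eff[pos]), int(pos), "+"))
        for pos in np.nonzero(rev >= threshold)[0]:
            if not pal_dup[pos]:
                cands.append((float(rev[pos]), int(pos), "-"))
        # descending score; ties broken by position then strand for determinism
        cands.sort(key=lambda c: (-c[0], c[1], c[2]))
        occupied: list[tuple[int, int]] = []
        accepted: list[Hit] = []
        for score, pos, strand in cands:
            s, e = pos, pos + model.length
            if any(s < oe and os_ < e for os_, oe in occupied):
                continue
            occupied.append((s, e))
            accepted.append(
                Hit(contig=contig, start=s, end=e, model_id=model.model_id,
                    strand=strand, score=score)
            )
        hits.extend(sorted(accepted, key=lambda h: (h.start, h.strand)))
    return hits


def calibrate_threshold(
    model: ProfileModel,
    genome: dict[str, str] | str,
    q: float = 1e-5,
    seed: int = 0,
) -> float:
    """Score threshold from a dinucleotide-shuffled copy of the genome.

    Returns the (1 - q)-quantile of all both-strand window scores on the
    shuffled genome, i.e. a per-window false-positive rate of about ``q``
    under a null that preserves dinucleotide composition.
    """
    contigs = genome if isinstance(genome, dict) else {"contig_1": genome}
    rng = np.random.default_rng(seed)
    scores = []
    for contig in sorted(contigs):
        shuffled = _dinucleotide_shuffle(contigs[contig], rng)
        if len(shuffled) < model.length:
            continue
        fwd, rev = _window_scores(model, _encode(shuffled))
        scores.append(fwd)
        scores.append(rev)
    if not scores:
        raise ValueError("genome too short to calibrate")
    allscores = np.concatenate(scores)
    return float(np.quantile(allscores, 1.0 - q))


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Eulerian-walk shuffle preserving dinucleotide counts (Altschul-Erickson
    style, implemented by repeated edge shuffling with last-edge fixing)."""
    if len(seq) < 3:
        return seq
    succ: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        succ.setdefault(a, []).append(b)
    for a in succ:
        rng.shuffle(succ[a])
    # make the walk from seq[0] consume every edge: move one edge into the
    # final slot of each vertex so the walk ends at the original terminal.
    # Simple retry loop; for genomic alphabets this converges immediately
    # almost always.
    for _attempt in range(20):
        trial = {a: list(v) for a, v in succ.items()}
        out = [seq[0]]
        cur = seq[0]
        ok = True
        while trial.get(cur):
            cur = trial[cur].pop()
            out.append(cur)
        if len(out) == len(seq):
            return "".join(out)
        for a in succ:
            rng.shuffle(succ[a])
    return "".join(out) if len(out) == len(seq) else seq


def hits_to_bed(hits: list[Hit]) -> str:
    """BED6 text; the score column is bits x 100, rounded."""
    lines = []
    for h in hits:
        lines.append(
            f"{h.contig}\t{h.start}\t{h.end}\t{h.model_id}\t{round(h.score * 100)}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_tsv(hits: list[Hit]) -> str:
    """Full-precision TSV of hits."""
    lines = ["contig\tstart\tend\tmodel_id\tset_label\tstrand\tscore_bits"]
    for h in hits:
        lines.append(
            f"{h.contig}\t{h.start}\t{h.end}\t{h.model_id}\t{h.set_label}\t{h.strand}\t{h.score:.6f}"
        )
    return "\n".join(lines) + "\n"
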