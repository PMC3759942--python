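"""Motif refinement: ZOOPS EM discovery, exact PSSM p-values, database rescan.

``discover_motif`` re-estimates a single ungapped motif from the selected
PBS neighbourhoods with expectation-maximisation under the ZOOPS model
(zero or one occurrence per sequence, both strands).  ``mast_scan`` then
rescans a database of intergenic regions with the discovered PSSM,
assigning each sequence an e-value derived from the exact distribution of
discretised PSSM scores under the background (dynamic-programming
convolution), with the per-sequence p-value using the independence
approximation 1 - (1 - p)^m over the m scored window positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MotifModel",
    "MotifOccurrence",
    "ScoreDistribution",
    "discover_motif",
    "exact_score_distribution",
    "mast_scan",
    "consensus_and_logo",
    "write_meme",
    "occurrences_to_tsv",
    "logo_to_tsv",
]

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CG"): "S", frozenset("AT"): "W", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MotifModel:
    """An ungapped motif with emissions, log-odds PSSM and located sites."""

    width: int
    emissions: np.ndarray = field(hash=False)
    background: np.ndarray = field(hash=False)
    sites: tuple[tuple[str, int, str], ...] = field(hash=False)  # (seq_id, offset, strand)
    llr: float = 0.0
    llr_history: tuple[float, ...] = field(default=(), hash=False)
    gamma: float = 0.5

    def __post_init__(self) -> None:
        em = np.asarray(self.emissions, dtype=float)
        if em.shape != (self.width, 4):
            raise ValueError("emissions must be (width, 4)")
        if not np.allclose(em.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("emission columns must sum to 1")
        if self.width < 4:
            raise ValueError("width must be >= 4")
        object.__setattr__(self, "emissions", em)

    @property
    def pssm(self) -> np.ndarray:
        """(width, 4) log2-odds scoring matrix."""
        return np.log2(self.emissions / self.background[None, :])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.emissions.argmax(axis=1))


@dataclass(frozen=True)
class MotifOccurrence:
    """Best-scoring motif match of one database sequence."""

    sequence_id: str
    offset: int
    strand: str
    score: float
    position_pvalue: float
    sequence_pvalue: float
    evalue: float

    def __post_init__(self) -> None:
        for p in (self.position_pvalue, self.sequence_pvalue):
            if not 0.0 <= p <= 1.0:
                raise ValueError("p-values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# ZOOPS EM


def _window_log_lr(codes: np.ndarray, log_odds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood-ratio of every width-W window on + and - strand."""
    W = log_odds.shape[0]
    n = len(codes) - W + 1
    padded = np.vstack([log_odds.T, np.zeros(W)]).T
    fwd = np.zeros(n)
    for j in range(W):
        fwd += padded[j, codes[j : j + n]]
    comp = np.where(codes < 4, 3 - codes, 4)
    rev = np.zeros(n)
    for j in range(W):
        rev += padded[j, comp[W - 1 - j : W - 1 - j + n]]
    return fwd, rev


def _zoops_em(
    seq_codes: list[np.ndarray],
    theta0: np.ndarray,
    background: np.ndarray,
    pseudocount: float,
    max_iter: int,
    tol: float,
    gamma0: float = 0.5,
) -> tuple[np.ndarray, float, list[float], float, list[tuple[int, int, str, float]]]:
    """Run ZOOPS EM from one initial emission matrix.

    Returns (theta, llr, llr_history, gamma, per-sequence best sites).
    The iteration stops when the relative LLR improvement drops below
    ``tol`` or the LLR would decrease (MAP smoothing can shave the raw
    likelihood), so the recorded history is non-decreasing.
    """
    W = theta0.shape[0]
    theta = theta0.copy()
    gamma = gamma0
    lbg = np.log(background)
    history: list[float] = []
    best: tuple[np.ndarray, float, float] = (theta, -np.inf, gamma)
    comps = [np.where(c < 4, 3 - c, 4) for c in seq_codes]
    for _it in range(max_iter):
        log_odds = np.log(theta) - lbg[None, :]
        llr = 0.0
        post: list[tuple[np.ndarray, np.ndarray]] = []
        for codes in seq_codes:
            m = len(codes) - W + 1
            fwd, rev = _window_log_lr(codes, log_odds)
            all_lr = np.concatenate([fwd, rev])
            prior = gamma / (2.0 * m)
            mx = max(all_lr.max(), 0.0)
            denom = (1.0 - gamma) * math.exp(-mx) + prior * np.exp(all_lr - mx).sum()
            llr += mx + math.log(denom)
            z = prior * np.exp(all_lr - mx) / denom
            post.append((z[:m], z[m:]))
        if history and llr < history[-1]:
            break
        history.append(llr)
        best = (theta.copy(), llr, gamma)
        if len(history) > 1:
            prev = history[-2]
            if abs(llr - prev) <= tol * max(1.0, abs(prev)):
                break
        # M-step (bincount over the 5-letter alphabet; code 4 = ambiguous,
        # dropped from the counts)
        counts = np.full((W, 4), pseudocount)
        q_sum = 0.0
        for codes, comp, (zf, zr) in zip(seq_codes, comps, post):
            m = len(zf)
            for j in range(W):
                counts[j] += np.bincount(codes[j : j + m], weights=zf, minlength=5)[:4]
                counts[j] += np.bincount(
                    comp[W - 1 - j : W - 1 - j + m], weights=zr, minlength=5
                )[:4]
            q_sum += zf.sum() + zr.sum()
        theta = counts / counts.sum(axis=1, keepdims=True)
        gamma = min(max(q_sum / len(seq_codes), 1e-6), 1.0 - 1e-6)

    theta, llr, gamma = best
    # locate sites under the final model
    log_odds = np.log(theta) - lbg[None, :]
    sites: list[tuple[int, int, str, float]] = []
    for i, codes in enumerate(seq_codes):
        m = len(codes) - W + 1
        fwd, rev = _window_log_lr(codes, log_odds)
        all_lr = np.concatenate([fwd, rev])
        prior = gamma / (2.0 * m)
        mx = max(all_lr.max(), 0.0)
        denom = (1.0 - gamma) * math.exp(-mx) + prior * np.exp(all_lr - mx).sum()
        q_i = (prior * np.exp(all_lr - mx).sum()) / denom  # P(sequence has a site)
        k = int(all_lr.argmax())
        off, strand = (k, "+") if k < m else (k - m, "-")
        sites.append((i, off, strand, q_i))
    return theta, llr, history, gamma, sites


def discover_motif(
    seqs: list[str] | dict[str, str],
    width: int | None = None,
    width_range: tuple[int, int] | None = None,
    mode: str = "ZOOPS",
    seed: int = 0,
    pseudocount: float = 0.25,
    n_seeds: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
    site_posterior_min: float = 0.5,
) -> MotifModel:
    """EM motif discovery on both strands (ZOOPS or OOPS).

    EM is restarted from ``n_seeds`` subsequence-derived initialisations
    (seed windows sampled reproducibly from the input given ``seed``); the
    restart with the best final log-likelihood ratio wins.  With
    ``width_range`` the motif width maximising a BIC-penalised LLR
    (LLR - (3W/2) ln(total windows)) is returned.  Sites are reported for
    sequences whose posterior probability of containing a site exceeds
    ``site_posterior_min`` (always reported under OOPS).
    """
    if mode not in ("ZOOPS", "OOPS"):
        raise ValueError("mode must be ZOOPS or OOPS")
    if isinstance(seqs, dict):
        ids = list(seqs)
        strings = [seqs[i] for i in ids]
    else:
        ids = [f"seq_{i}" for i in range(len(seqs))]
        strings = list(seqs)
    if len(strings) < 2:
        raise ValueError("need at least 2 sequences")

    if width is None and width_range is None:
        width_range = (13, 30)
    widths = [width] if width is not None else list(range(width_range[0], width_range[1] + 1))
    widths = [w for w in widths if all(len(s) >= w for s in strings)]
    if not widths:
        raise ValueError("all candidate widths exceed the shortest sequence")

    codes_all = [_encode(s) for s in strings]
    counts = np.zeros(4)
    for c in codes_all:
        counts += np.bincount(c[c < 4], minlength=4)
    background = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    background = np.clip(background, 1e-3, None)
    background /= background.sum()

    rng = np.random.default_rng(seed)
    best_model: MotifModel | None = None
    best_pen = -np.inf
    total_windows = sum(2 * (len(s) - min(widths) + 1) for s in strings)
    for W in widths:
        seeds = []
        for _ in range(n_seeds):
            i = int(rng.integers(len(strings)))
            off = int(rng.integers(len(strings[i]) - W + 1))
            seeds.append(codes_all[i][off : off + W])
        # two-phase: a short EM burst per seed, then converge the best seed
        best_seed: tuple[float, np.ndarray, float] | None = None
        for sd in seeds:
            theta0 = np.full((W, 4), 0.1)
            for j, b in enumerate(sd):
                if b < 4:
                    theta0[j, b] = 0.7
            theta0 /= theta0.sum(axis=1, keepdims=True)
            th, llr0, _h, g0, _s = _zoops_em(
                codes_all, theta0, background, pseudocount, min(20, max_iter), tol
            )
            if best_seed is None or llr0 > best_seed[0]:
                best_seed = (llr0, th, g0)
        theta, llr, history, gamma, raw_sites = _zoops_em(
            codes_all, best_seed[1], background, pseudocount, max_iter, tol,
            gamma0=best_seed[2],
        )
        # phase-shift move: EM often locks one or two columns off the true
        # register; restart from column-shifted models and keep improvements
        improved = True
        while improved:
            improved = False
            for s in (-2, -1, 1, 2):
                shifted = _shift_theta(theta, s, background)
                res = _zoops_em(
                    codes_all, shifted, background, pseudocount, max_iter, tol,
                    gamma0=gamma,
                )
                if res[1] > llr + 1e-6:
                    theta, llr, history, gamma, raw_sites = res
                    improved = True
                    break
        if mode == "OOPS":
            keep = raw_sites
        else:
            keep = [s for s in raw_sites if s[3] >= site_posterior_min]
        sites = tuple((ids[i], off, strand) for i, off, strand, _q in keep)
        model = MotifModel(
            width=W, emissions=theta, background=background, sites=sites,
            llr=llr, llr_history=tuple(history), gamma=gamma,
        )
        pen = llr - 1.5 * W * math.log(max(total_windows, 2))
        if pen > best_pen:
            best_pen, best_model = pen, model
    return best_model


def _shift_theta(theta: np.ndarray, shift: int, background: np.ndarray) -> np.ndarray:
    """Slide emission columns by ``shift``; vacated columns get background."""
    W = theta.shape[0]
    out = np.tile(background, (W, 1))
    if shift >= 0:
        out[: W - shift] = theta[shift:]
    else:
        out[-shift:] = theta[: W + shift]
    return out


# ---------------------------------------------------------------------------
# Exact score distribution


@dataclass(frozen=True)
class ScoreDistribution:
    """Distribution of integerised PSSM scores under the background.

    Scores are discretised per position as round(score / granularity) and
    summed; ``probs[k]`` is the probability of integer score
    ``min_int + k``.
    """

    granularity: float
    min_int: int
    probs: np.ndarray = field(hash=False)

    def sf_int(self, int_score: int) -> float:
        """P(integer score >= int_score)."""
        k = int_score - self.min_int
        if k <= 0:
            return 1.0
        if k >= len(self.probs):
            return 0.0
        return float(self.probs[k:].sum())

    def sf(self, score: float) -> float:
        """P(score >= given value), on the discretised scale."""
        return self.sf_int(int(round(score / self.granularity)))

    @property
    def support(self) -> np.ndarray:
        return (np.arange(len(self.probs)) + self.min_int) * self.granularity


def integerize_pssm(pssm: np.ndarray, granularity: float) -> np.ndarray:
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    return np.round(np.asarray(pssm, dtype=float) / granularity).astype(np.int64)


def exact_score_distribution(
    pssm: np.ndarray, background: np.ndarray, granularity: float = 0.01
) -> ScoreDistribution:
    """Exact distribution of the discretised PSSM score under the background.

    Dynamic-programming convolution over positions: after integerising
    each cell to round(score/granularity), the distribution of the sum is
    convolved column by column.  Total probability is 1 up to float error.
    """
    ip = integerize_pssm(pssm, granularity)
    bg = np.asarray(background, dtype=float)
    min_sum = int(ip.min(axis=1).sum())
    max_sum = int(ip.max(axis=1).sum())
    probs = np.zeros(max_sum - min_sum + 1)
    # running support [cur_min, cur_min + len(cur) - 1]
    cur = np.array([1.0])
    cur_min = 0
    for row in ip:
        lo, hi = int(row.min()), int(row.max())
        nxt = np.zeros(len(cur) + hi - lo)
        for b in range(4):
            shift = int(row[b]) - lo
            nxt[shift : shift + len(cur)] += bg[b] * cur
        cur = nxt
        cur_min += lo
    probs[cur_min - min_sum : cur_min - min_sum + len(cur)] = cur
    return ScoreDistribution(granularity=granularity, min_int=min_sum, probs=probs)


# ---------------------------------------------------------------------------
# MAST-like database rescan


def mast_scan(
    pssm: np.ndarray | MotifModel,
    ig_database: dict[str, str],
    evalue_cutoff: float = 10.0,
    background: np.ndarray | None = None,
    granularity: float = 0.01,
) -> list[MotifOccurrence]:
    """Rescan a sequence database with a PSSM and report per-sequence e-values.

    Per sequence: best both-strand window score -> position p-value from
    the exact discretised score distribution -> sequence p-value
    1 - (1 - p)^m over the m scored windows -> e-value = sequence p-value
    x database size.  Occurrences with e-value < cutoff are returned in
    ascending e-value order.  Sequences shorter than the motif width are
    skipped with a log notice.
    """
    if isinstance(pssm, MotifModel):
        if background is None:
            background = pssm.background
        matrix = pssm.pssm
    else:
        matrix = np.asarray(pssm, dtype=float)
        if background is None:
            background = np.full(4, 0.25)
    W = matrix.shape[0]
    dist = exact_score_distribution(matrix, background, granularity)
    imat = integerize_pssm(matrix, granularity)
    n_db = len(ig_database)
    occs: list[MotifOccurrence] = []
    for seq_id in sorted(ig_database):
        seq = ig_database[seq_id]
        if len(seq) < W:
            logger.info("mast_scan: sequence %s shorter than motif width, skipped", seq_id)
            continue
        codes = _encode(seq)
        fwd, rev = _int_window_scores(codes, imat)
        m = len(fwd) * 2
        all_scores = np.concatenate([fwd, rev])
        k = int(all_scores.argmax())
        n = len(fwd)
        off, strand = (k, "+") if k < n else (k - n, "-")
        best_int = int(all_scores[k])
        p_pos = dist.sf_int(best_int)
        p_seq = -math.expm1(m * math.log1p(-min(p_pos, 1.0 - 1e-16)))
        p_seq = min(max(p_seq, 0.0), 1.0)
        evalue = p_seq * n_db
        if evalue < evalue_cutoff:
            occs.append(
                MotifOccurrence(
                    sequence_id=seq_id, offset=off, strand=strand,
                    score=best_int * granularity,
                    position_pvalue=p_pos, sequence_pvalue=p_seq, evalue=evalue,
                )
            )
    occs.sort(key=lambda o: (o.evalue, o.sequence_id))
    return occs


def _int_window_scores(codes: np.ndarray, imat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    W = imat.shape[0]
    n = len(codes) - W + 1
    padded = np.hstack([imat, np.zeros((W, 1), dtype=np.int64)])
    fwd = np.zeros(n, dtype=np.int64)
    for j in range(W):
        fwd += padded[j, codes[j : j + n]]
    comp = np.where(codes < 4, 3 - codes, 4)
    rev = np.zeros(n, dtype=np.int64)
    for j in range(W):
        rev += padded[j, comp[W - 1 - j : W - 1 - j + n]]
    return fwd, rev


# ---------------------------------------------------------------------------
# Consensus and logo


def consensus_and_logo(sites: list[str]) -> tuple[str, np.ndarray]:
    """Plurality consensus and per-column information content in bits.

    Ties map to the IUPAC ambiguity code of the tied base set; information
    content is 2 + sum_b f_b log2 f_b under the uniform background
    (0 log 0 := 0).
    """
    if not sites:
        raise ValueError("need at least one site")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("sites must have equal lengths")
    counts = np.zeros((width, 4))
    for s in sites:
        codes = _encode(s)
        for j, b in enumerate(codes):
            if b < 4:
                counts[j, b] += 1
    consensus = []
    ic = np.zeros(width)
    for j in range(width):
        col = counts[j]
        tot = col.sum()
        if tot == 0:
            consensus.append("N")
            continue
        mx = col.max()
        tied = frozenset("ACGT"[b] for b in range(4) if col[b] == mx)
        consensus.append(_IUPAC[tied])
        f = col / tot
        nz = f[f > 0]
        ic[j] = 2.0 + float((nz * np.log2(nz)).sum())
    return "".join(consensus), ic


# ---------------------------------------------------------------------------
# Serialisation


def write_meme(model: MotifModel, name: str = "motif_1") -> str:
    """MEME minimal text format (version, alphabet, background, matrix)."""
    bg = model.background
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}",
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {model.width} nsites= {max(len(model.sites), 1)} E= 0",
    ]
    for row in model.emissions:
        lines.append(" ".join(f"{p:.6f}" for p in row))
    return "\n".join(lines) + "\n"


def occurrences_to_tsv(occs: list[MotifOccurrence]) -> str:
    lines = ["sequence_id\toffset\tstrand\tscore_bits\tposition_pvalue\tsequence_pvalue\tevalue"]
    for o in occs:
        lines.append(
            f"{o.sequence_id}\t{o.offset}\t{o.strand}\t{o.score:.4f}\t{o.position_pvalue:.4g}\t{o.sequence_pvalue:.4g}\t{o.evalue:.4g}"
        )
    return "\n".join(lines) + "\n"


def logo_to_tsv(consensus: str, ic: np.ndarray) -> str:
    lines = ["column\tconsensus\tinformation_bits"]
    for j, (c, b) in enumerate(zip(consensus, ic)):
        lines.append(f"{j + 1}\t{c}\t{b:.4f}")
    return "\n".join(lines) + "\n"
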