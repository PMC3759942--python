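"""Palindrome templates of the afe-box operator and combinatorial variant
enumeration.

The afe-box is a 30-bp operator with two alternative centres of dyad
symmetry: a large palindrome (LP) whose two halves are themselves short
palindromes (SP) that are inverted repeats of each other, and a central
18-20 bp lux-box-like medium palindrome (MP).  Five fixed-length templates
capture this modular structure; palindromic (fixed) positions are kept
literal and non-palindromic positions are wildcards, so that exhaustive
wildcard expansion yields the training alignment for each profile model.

Wildcard alphabet: ``N`` = {A,C,G,T}, ``Y`` = {C,T} (pyrimidine),
``R`` = {A,G} (purine).  No other IUPAC codes are supported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "PalindromeTemplate",
    "VariantAlignment",
    "builtin_templates",
    "enumerate_variants",
    "revcomp",
    "MODEL_FOR_TEMPLATE",
    "SET_LABEL_FOR_MODEL",
    "WILDCARD_EXPANSIONS",
]

_COMPLEMENT = str.maketrans("ACGTNYRacgtnyr", "TGCANRYtgcanry")

#: Expansion sets for the supported wildcard symbols, in lexicographic order.
WILDCARD_EXPANSIONS: dict[str, tuple[str, ...]] = {
    "N": ("A", "C", "G", "T"),
    "Y": ("C", "T"),
    "R": ("A", "G"),
}

#: Profile-model letter for each template id.  A/B derive from the SP
#: sequences, C/D from the MP sequence, E from the LP sequence; the
#: assignment within the A/B and C/D pairs is a convention (they are merged
#: into the SP and MP sets downstream, so it cannot affect results).
MODEL_FOR_TEMPLATE: dict[str, str] = {
    "SP13": "A",
    "SP15": "B",
    "MP18": "C",
    "MP20": "D",
    "LP30": "E",
}

#: Set label (palindrome module) for each profile-model letter.
SET_LABEL_FOR_MODEL: dict[str, str] = {
    "A": "SP",
    "B": "SP",
    "C": "MP",
    "D": "MP",
    "E": "LP",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (case kept).

    Wildcards complement as N->N, Y->R, R->Y so templates can be
    reverse-complemented too.
    """
    bad = set(seq.upper()) - set("ACGTNYR")
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PalindromeTemplate:
    """A fixed-length palindrome pattern with annotated arm structure.

    Attributes
    ----------
    id:
        One of SP13, SP15, MP18, MP20, LP30 (length in bp is the suffix).
    pattern:
        String over {A,C,G,T,N,Y,R}; literal positions are the conserved
        palindromic arms, wildcards the variable spacer/flank positions.
    arms:
        ``[((start, end), role), ...]`` with 0-based half-open intervals and
        role in {"arm_left", "spacer", "arm_right"}.
    set_label:
        Palindrome module the template belongs to: SP, MP or LP.
    symmetry_center:
        Centre of dyad symmetry in pattern coordinates (fractional for
        even-length patterns).
    """

    id: str
    pattern: str
    arms: list[tuple[tuple[int, int], str]] = field(hash=False)
    set_label: str = field(default="")
    symmetry_center: float = field(default=0.0)

    def __post_init__(self) -> None:
        for (a, b), role in self.arms:
            if not (0 <= a < b <= len(self.pattern)):
                raise ValueError(f"arm interval ({a},{b}) outside pattern")

    @property
    def model_id(self) -> str:
        """Profile-model letter (A-E) assigned to this template."""
        return MODEL_FOR_TEMPLATE[self.id]

    def fixed_positions(self) -> list[int]:
        """Indices of literal (non-wildcard) positions."""
        return [i for i, c in enumerate(self.pattern) if c in "ACGT"]

    def wildcard_positions(self) -> list[int]:
        return [i for i, c in enumerate(self.pattern) if c not in "ACGT"]


@dataclass(frozen=True)
class VariantAlignment:
    """Exhaustive, duplicate-free expansion of a template's wildcards."""

    template_id: str
    sequences: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.sequences)

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    def to_fasta(self) -> str:
        """Aligned-FASTA text (all rows equal length, no gaps)."""
        return "".join(
            f">{self.template_id}_v{i:04d}\n{s}\n" for i, s in enumerate(self.sequences)
        )


def builtin_templates() -> list[PalindromeTemplate]:
    """The five afe-box-derived palindrome templates.

    SP13  TGACA-NNN-TGTCA            13 bp, short palindrome core
    SP15  Y-TGACA-NNN-TGTCA-R        15 bp, SP with pyrimidine/purine flanks
    MP18  GCTGTCAA-NN-TTGACAGC       18 bp, lux-box-like medium palindrome
    MP20  AGCTGTCAA-NN-TTGACAGCT     20 bp, extended medium palindrome
    LP30  TGACAAGCTGTCA-NNNN-TGACAGCTTGTCA   30 bp large palindrome
    """

    def t(tid, pattern, arms, label):
        return PalindromeTemplate(
            id=tid,
            pattern=pattern,
            arms=arms,
            set_label=label,
            symmetry_center=len(pattern) / 2.0,
        )

    return [
        t("SP13", "TGACANNNTGTCA",
          [((0, 5), "arm_left"), ((5, 8), "spacer"), ((8, 13), "arm_right")], "SP"),
        t("SP15", "YTGACANNNTGTCAR",
          [((0, 6), "arm_left"), ((6, 9), "spacer"), ((9, 15), "arm_right")], "SP"),
        t("MP18", "GCTGTCAANNTTGACAGC",
          [((0, 8), "arm_left"), ((8, 10), "spacer"), ((10, 18), "arm_right")], "MP"),
        t("MP20", "AGCTGTCAANNTTGACAGCT",
          [((0, 9), "arm_left"), ((9, 11), "spacer"), ((11, 20), "arm_right")], "MP"),
        t("LP30", "TGACAAGCTGTCANNNNTGACAGCTTGTCA",
          [((0, 13), "arm_left"), ((13, 17), "spacer"), ((17, 30), "arm_right")], "LP"),
    ]


def builtin_template(template_id: str) -> PalindromeTemplate:
    """Look up one built-in template by id (SP13, SP15, MP18, MP20, LP30)."""
    for t in builtin_templates():
        if t.id == template_id:
            return t
    raise KeyError(f"unknown template id {template_id!r}")


def enumerate_variants(template: PalindromeTemplate) -> VariantAlignment:
    """Expand every wildcard position combinatorially.

    The expansion is exhaustive and duplicate-free; the order is
    deterministic lexicographic (positions left to right, each wildcard's
    alphabet in A<C<G<T order), so alignments are byte-reproducible.
    """
    pattern = template.pattern
    choices: list[tuple[str, ...]] = []
    for c in pattern:
        if c in "ACGT":
            choices.append((c,))
        elif c in WILDCARD_EXPANSIONS:
            choices.append(WILDCARD_EXPANSIONS[c])
        else:
            raise ValueError(f"unknown wildcard symbol {c!r} in template {template.id}")
    seqs = tuple("".join(p) for p in itertools.product(*choices))
    return VariantAlignment(template_id=template.id, sequences=seqs)


def templates_table(templates: list[PalindromeTemplate] | None = None) -> str:
    """Plain-text table of templates (id, pattern, arms, set label)."""
    templates = templates if templates is not None else builtin_templates()
    lines = ["id\tpattern\tset_label\tarms"]
    for t in templates:
        arms = ";".join(f"{a}-{b}:{role}" for (a, b), role in t.arms)
        lines.append(f"{t.id}\t{t.pattern}\t{t.set_label}\t{arms}")
    return "\n".join(lines) + "\n"
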