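"""Strand-collapsed trinucleotide substitution classes.

Every single-nucleotide variant is binned by its mutational context: the
reference trinucleotide centred on the variant site, together with the
alternate allele.  Because a substitution and its reverse complement are
the same mutational event, contexts whose middle base is a purine (A/G)
are reverse-complemented so that every stored class has a pyrimidine
(C or T) in the middle.  That leaves 32 trinucleotides x 3 alternate
alleles = 96 classes.

CpG sites mutate at a rate that depends strongly on methylation, so the
four CpG C>T classes (ACG>T, CCG>T, GCG>T, TCG>T) are each subdivided by
an ordinal methylation level (0 = low, 1 = medium, 2 = high).  This
replaces 4 classes with 12, adding 8 for a total of 104.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import ContextError

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Collapsed trinucleotides whose C>T substitution is methylation-split.
CPG_CT_CONTEXTS = ("ACG", "CCG", "GCG", "TCG")
METHYLATION_LEVELS = (0, 1, 2)


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ContextLabel:
    """A strand-collapsed substitution class.

    Attributes
    ----------
    context : str
        Trinucleotide with a pyrimidine middle base.
    alt : str
        Alternate allele on the collapsed strand.
    methylation : int, optional
        Methylation level (0/1/2); only ever set for CpG C>T classes.
    """

    context: str
    alt: str
    methylation: Optional[int] = None

    def __post_init__(self):
        if len(self.context) != 3 or any(b not in BASES for b in self.context):
            raise ContextError(f"invalid trinucleotide {self.context!r}")
        if self.context[1] not in PYRIMIDINES:
            raise ContextError(
                f"collapsed context must have a pyrimidine middle base, got {self.context!r}"
            )
        if self.alt not in BASES:
            raise ContextError(f"invalid alternate allele {self.alt!r}")
        if self.alt == self.context[1]:
            raise ContextError("alternate allele equals the reference middle base")
        if self.methylation is not None:
            if not is_methylation_split(self.context, self.alt):
                raise ContextError(
                    "methylation level only applies to CpG C>T classes, "
                    f"got {self.context}>{self.alt}"
                )
            if self.methylation not in METHYLATION_LEVELS:
                raise ContextError(f"invalid methylation level {self.methylation!r}")

    def __str__(self) -> str:
        s = f"{self.context}>{self.alt}"
        if self.methylation is not None:
            s += f"|m{self.methylation}"
        return s

    @classmethod
    def parse(cls, label: str) -> "ContextLabel":
        meth = None
        if "|m" in label:
            label, m = label.split("|m")
            meth = int(m)
        ctx, alt = label.split(">")
        return cls(ctx, alt, meth)


def is_methylation_split(context: str, alt: str) -> bool:
    """True for the four CpG C>T classes that carry a methylation level."""
    return context in CPG_CT_CONTEXTS and alt == "T"


def collapse(context3: str, alt: str) -> tuple[str, str]:
    """Collapse a (trinucleotide, alt) pair onto the pyrimidine strand."""
    context3 = context3.upper()
    alt = alt.upper()
    if len(context3) != 3 or any(b not in BASES for b in context3) or alt not in BASES:
        raise ContextError(f"unassignable context {context3!r}>{alt!r}")
    if context3[1] in PYRIMIDINES:
        return context3, alt
    return revcomp(context3), complement(alt)


def assign_context(
    context3: str,
    ref: str,
    alt: str,
    methylation_level: Optional[int] = None,
) -> ContextLabel:
    """Assign the collapsed context class of one variant.

    ``ref`` must equal the middle base of ``context3``; the methylation
    level is attached only when the collapsed class is CpG C>T.
    """
    if ref != context3[1:2]:
        raise ContextError(
            f"reference allele {ref!r} does not match context middle base of {context3!r}"
        )
    if ref == alt:
        raise ContextError("ref equals alt")
    ctx, a = collapse(context3, alt)
    meth = methylation_level if is_methylation_split(ctx, a) else None
    if meth is not None and pd.isna(meth):
        meth = None
    return ContextLabel(ctx, a, int(meth) if meth is not None else None)


def enumerate_context_labels(methylation: bool = True) -> list[ContextLabel]:
    """All collapsed classes: 96 plain, or 104 with methylation splitting."""
    labels = []
    for left in BASES:
        for mid in "CT":
            for right in BASES:
                ctx = left + mid + right
                for alt in BASES:
                    if alt == mid:
                        continue
                    if methylation and is_methylation_split(ctx, alt):
                        for lvl in METHYLATION_LEVELS:
                            labels.append(ContextLabel(ctx, alt, lvl))
                    else:
                        labels.append(ContextLabel(ctx, alt))
    return labels


def _collapse_map() -> dict[tuple[str, str], tuple[str, str]]:
    table = {}
    for left in BASES:
        for mid in BASES:
            for right in BASES:
                ctx = left + mid + right
                for alt in BASES:
                    if alt == mid:
                        continue
                    table[(ctx, alt)] = collapse(ctx, alt)
    return table


_COLLAPSE_MAP = _collapse_map()


def context_label_strings(
    context3: Iterable[str],
    alt: Iterable[str],
    methylation_level: Optional[Iterable] = None,
) -> pd.Series:
    """Vectorised collapsed-class labels (as strings) for a table of variants.

    Entries whose context cannot be assigned (ambiguous bases) come back
    as NA; callers decide whether to raise or drop.
    """
    ctx = pd.Series(context3).astype(str).str.upper()
    a = pd.Series(alt, index=ctx.index).astype(str).str.upper()
    pairs = pd.Series(list(zip(ctx, a)), index=ctx.index)
    collapsed = pairs.map(_COLLAPSE_MAP)
    out = pd.Series(pd.NA, index=ctx.index, dtype=object)
    ok = collapsed.notna()
    if ok.any():
        cc = collapsed[ok].str[0]
        ca = collapsed[ok].str[1]
        labels = cc + ">" + ca
        split = cc.isin(CPG_CT_CONTEXTS) & (ca == "T")
        if methylation_level is not None:
            meth = pd.Series(methylation_level, index=ctx.index)[ok]
            has = split & meth.notna()
            labels = labels.where(
                ~has, labels + "|m" + meth.where(meth.isna(), meth).astype("Int64").astype(str)
            )
        out[ok] = labels
    return out
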