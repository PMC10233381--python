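"""Rule-based filtering of candidate pre-miRNA hairpins.

A candidate arrives as a sequence, a dot-bracket secondary structure, a free
energy and the coordinates of the mature-arm read
(:class:`~rbpcoreg.io_formats.HairpinRecord`).  :func:`classify_hairpin`
evaluates eleven explicit structural criteria and reports, for each, the
observed value, the threshold and a pass flag, plus the overall verdict
(pass iff all eleven pass):

1.  nucleotides in any one stem bulge <= 12
2.  base pairs in the stem >= 16
3.  free energy <= -15 kcal/mol
4.  hairpin length (both stems + terminal loop) >= 50 nt
5.  terminal loop length <= 20 nt
6.  nucleotides in any one bulge touching the mature region <= 8
7.  nucleotides in any one *biased* (single-strand) bulge touching the
    mature region <= 4
8.  biased bulges touching the mature region <= 2
9.  unpaired positions ("errors") inside the mature region <= 7
10. paired positions inside the mature region >= 12
11. percent of the mature region lying in the stem >= 80

Structural glosses (the source pipeline publishes no formal definitions):
the *stem* is everything between the outermost and innermost base pair on
both strands, terminal loop excluded; the *terminal loop* is the unpaired
run enclosed by the innermost pair; a *bulge* is a maximal unpaired run
inside the stem, on one strand (biased) or both (internal loop), and its
size counts nucleotides on both strands.  Only single stem-loops are
classified; branched (multiloop) structures raise
:class:`HairpinStructureError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import HairpinRecord

__all__ = [
    "HairpinStructureError",
    "CriterionResult",
    "HairpinVerdict",
    "parse_pairs",
    "classify_hairpin",
    "CRITERION_NAMES",
]


class HairpinStructureError(ValueError):
    """The structure is not a single stem-loop (branched / multiloop)."""


@dataclass(frozen=True)
class CriterionResult:
    criterion: int  # 1..11
    name: str
    observed: float
    threshold: float
    comparator: str  # "<=" or ">="
    passed: bool


@dataclass(frozen=True)
class HairpinVerdict:
    hairpin_id: str
    criteria: tuple  # of CriterionResult, in order 1..11
    overall: bool

    def result(self, k: int) -> CriterionResult:
        return self.criteria[k - 1]

    @property
    def failed(self) -> list[int]:
        return [c.criterion for c in self.criteria if not c.passed]


CRITERION_NAMES = {
    1: "max_stem_bulge_nt",
    2: "stem_base_pairs",
    3: "free_energy",
    4: "hairpin_length",
    5: "terminal_loop_length",
    6: "max_mature_bulge_nt",
    7: "max_mature_biased_bulge_nt",
    8: "mature_biased_bulges",
    9: "mature_errors",
    10: "mature_base_pairs",
    11: "pct_mature_in_stem",
}


def parse_pairs(structure: str) -> list[tuple[int, int]]:
    """Base pairs from a dot-bracket string, sorted by opening position."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced brackets")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced brackets")
    return sorted(pairs)


@dataclass(frozen=True)
class _Bulge:
    positions5: tuple  # unpaired positions on the 5' strand
    positions3: tuple  # unpaired positions on the 3' strand

    @property
    def size(self) -> int:
        return len(self.positions5) + len(self.positions3)

    @property
    def biased(self) -> bool:
        return (len(self.positions5) > 0) != (len(self.positions3) > 0)

    @property
    def positions(self) -> tuple:
        return self.positions5 + self.positions3


def _anatomy(structure: str):
    """Pairs, stem positions, terminal loop and bulges of a single stem-loop."""
    pairs = parse_pairs(structure)
    if pairs:
        last_open = max(i for i, ch in enumerate(structure) if ch == "(")
        first_close = min(i for i, ch in enumerate(structure) if ch == ")")
        if last_open > first_close:
            raise HairpinStructureError(
                "branched structure: more than one terminal loop (multiloop)"
            )
        (i0, j0), (i_in, j_in) = pairs[0], pairs[-1]
        loop = tuple(range(i_in + 1, j_in))
        stem = set(range(i0, i_in + 1)) | set(range(j_in, j0 + 1))
        span = j0 - i0 + 1
        bulges = []
        for (ia, ja), (ib, jb) in zip(pairs, pairs[1:]):
            gap5 = tuple(range(ia + 1, ib))
            gap3 = tuple(range(jb + 1, ja))
            if gap5 or gap3:
                bulges.append(_Bulge(positions5=gap5, positions3=gap3))
    else:
        loop, stem, span, bulges = (), set(), 0, []
    return pairs, stem, loop, span, bulges


def classify_hairpin(h: HairpinRecord) -> HairpinVerdict:
    """Evaluate all eleven structural criteria on one hairpin candidate."""
    pairs, stem, loop, span, bulges = _anatomy(h.structure)
    mature = set(range(h.mature_start, h.mature_end))
    paired_positions = {i for p in pairs for i in p}

    mature_bulges = [b for b in bulges if mature & set(b.positions)]
    mature_biased = [b for b in mature_bulges if b.biased]

    c1 = max((b.size for b in bulges), default=0)
    c2 = len(pairs)
    c3 = h.free_energy
    c4 = span
    c5 = len(loop)
    c6 = max((b.size for b in mature_bulges), default=0)
    c7 = max((b.size for b in mature_biased), default=0)
    c8 = len(mature_biased)
    c9 = len(mature - paired_positions)
    c10 = len(mature & paired_positions)
    c11 = 100.0 * len(mature & stem) / len(mature)

    spec = [
        (1, c1, 12, "<="),
        (2, c2, 16, ">="),
        (3, c3, -15.0, "<="),
        (4, c4, 50, ">="),
        (5, c5, 20, "<="),
        (6, c6, 8, "<="),
        (7, c7, 4, "<="),
        (8, c8, 2, "<="),
        (9, c9, 7, "<="),
        (10, c10, 12, ">="),
        (11, c11, 80.0, ">="),
    ]
    results = []
    for k, obs, thr, cmp_ in spec:
        ok = obs <= thr if cmp_ == "<=" else obs >= thr
        results.append(
            CriterionResult(
                criterion=k, name=CRITERION_NAMES[k],
                observed=float(obs), threshold=float(thr),
                comparator=cmp_, passed=bool(ok),
            )
        )
    return HairpinVerdict(
        hairpin_id=h.id, criteria=tuple(results), overall=all(r.passed for r in results)
    )
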