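"""Readers and writers for every external file the pipeline touches.

All downstream modules operate on the in-memory domain types defined here
(:class:`RankedTargets`, :class:`GeneSet`, :class:`EdgeTable`,
:class:`HairpinRecord`) or in :mod:`rbpcoreg.interactome`
(:class:`~rbpcoreg.interactome.LfqMatrix`).  Formats are deliberately plain
text: GMT and RNK as used by GSEA tooling, Vienna-style dot-bracket records
for hairpins, and TSV matrices for LFQ intensities and miRNA-target edges.

Conventions fixed here and relied on everywhere else:

* gene/protein/miRNA identifiers are opaque, case-sensitive strings;
* RNK ordering is score descending, ties broken by gene id ascending;
* an empty LFQ cell means *not detected*; a literal ``0`` means *detected at
  zero intensity* and is kept (with a warning) — the two are never conflated.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "RankedTargets",
    "GeneSet",
    "EdgeTable",
    "HairpinRecord",
    "read_gmt",
    "write_gmt",
    "read_rnk",
    "write_rnk",
    "read_vienna",
    "write_vienna",
    "read_edge_table",
    "write_edge_table",
    "read_lfq_table",
    "write_lfq_table",
    "write_tsv",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankedTargets:
    """An ordered, scored gene list (e.g. a ranked HITS-CLIP target list).

    ``entries`` is a list of ``(gene_id, score, rank)`` with scores
    non-increasing and ranks 1-based and contiguous.
    """

    entries: tuple
    name: str = "ranked"

    def __post_init__(self) -> None:
        genes = [g for g, _, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise FormatError(f"{self.name}: duplicate gene ids in ranked list")
        scores = [s for _, s, _ in self.entries]
        for a, b in zip(scores, scores[1:]):
            if b > a:
                raise FormatError(f"{self.name}: scores must be non-increasing")
        ranks = [r for _, _, r in self.entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise FormatError(f"{self.name}: ranks must be 1..N contiguous")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s, _ in self.entries], dtype=float)

    def rank_of(self, gene: str) -> int:
        for g, _, r in self.entries:
            if g == gene:
                return r
        raise KeyError(gene)


@dataclass(frozen=True)
class GeneSet:
    """An unordered query set of gene ids (e.g. another RBP's targets)."""

    name: str
    members: frozenset
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r}: empty member list")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EdgeTable:
    """miRNA → target edges, optionally tagged with a prediction source."""

    edges: frozenset  # of (mirna_id, target_id, source)

    def __post_init__(self) -> None:
        # frozenset already guarantees no duplicate triples
        for e in self.edges:
            if len(e) != 3:
                raise FormatError(f"edge {e!r} is not a (mirna, target, source) triple")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def mirnas(self) -> set:
        return {m for m, _, _ in self.edges}

    @property
    def targets(self) -> set:
        return {t for _, t, _ in self.edges}


_DOTBRACKET = re.compile(r"^[.()]+$")


@dataclass(frozen=True)
class HairpinRecord:
    """A candidate pre-miRNA hairpin.

    ``structure`` is a dot-bracket string the same length as ``sequence``;
    ``free_energy`` is in kcal/mol; ``mature_start``/``mature_end`` locate the
    mature-arm read on the sequence, 0-based half-open.
    """

    id: str
    sequence: str
    structure: str
    free_energy: float
    mature_start: int
    mature_end: int

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise FormatError(
                f"hairpin {self.id}: structure length {len(self.structure)} != "
                f"sequence length {len(self.sequence)}"
            )
        if not set(self.sequence) <= set("ACGU"):
            raise FormatError(f"hairpin {self.id}: sequence must be over A/C/G/U")
        if not _DOTBRACKET.match(self.structure):
            raise FormatError(f"hairpin {self.id}: structure must be dot-bracket")
        depth = 0
        for ch in self.structure:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise FormatError(f"hairpin {self.id}: unbalanced brackets")
        if depth != 0:
            raise FormatError(f"hairpin {self.id}: unbalanced brackets")
        if not (0 <= self.mature_start < self.mature_end <= len(self.sequence)):
            raise FormatError(
                f"hairpin {self.id}: mature coordinates "
                f"[{self.mature_start}, {self.mature_end}) out of range"
            )

    @property
    def mature_length(self) -> int:
        return self.mature_end - self.mature_start


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: one gene set per line, ``name TAB description TAB gene...``.

    Duplicate genes within a line are collapsed with a logged warning; a line
    with fewer than three fields is a :class:`FormatError` naming the line.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                logger.warning(
                    "%s: line %d (%s): %d duplicate gene(s) collapsed",
                    path, lineno, name, len(genes) - len(set(genes)),
                )
            sets.append(GeneSet(name=name, description=desc, members=frozenset(genes)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    """Write gene sets in canonical GMT form (members sorted)."""
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# RNK
# ---------------------------------------------------------------------------


def read_rnk(path, name: str | None = None) -> RankedTargets:
    """Read a two-column RNK file (``gene TAB score``) into a ranked list.

    Entries are sorted by score descending with ties broken by gene id
    ascending, so the result is a function of the multiset of input lines
    only.  Duplicate genes and non-numeric scores are errors.
    """
    pairs: list[tuple[str, float]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            gene, raw = fields
            if gene in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate gene {gene!r}")
            seen.add(gene)
            try:
                score = float(raw)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric score {raw!r}") from exc
            pairs.append((gene, score))
    return rank_pairs(pairs, name=name or Path(path).stem)


def rank_pairs(pairs: Iterable[tuple[str, float]], name: str = "ranked") -> RankedTargets:
    """Order (gene, score) pairs by score desc, gene asc, and assign ranks."""
    ordered = sorted(pairs, key=lambda gs: (-gs[1], gs[0]))
    entries = tuple((g, float(s), i + 1) for i, (g, s) in enumerate(ordered))
    return RankedTargets(entries=entries, name=name)


def write_rnk(ranked: RankedTargets, path) -> None:
    with open(path, "w") as fh:
        for gene, score, _ in ranked.entries:
            fh.write(f"{gene}\t{score:g}\n")


# ---------------------------------------------------------------------------
# Vienna-style hairpin records
# ---------------------------------------------------------------------------

_VIENNA_HEADER = re.compile(r"^>(\S+)\s+mature=(\d+)\.\.(\d+)\s*$")
_VIENNA_STRUCT = re.compile(r"^([.()]+)\s+\((\s*-?\d+(?:\.\d+)?)\)\s*$")


def read_vienna(path) -> list[HairpinRecord]:
    """Read 3-line hairpin records.

    Each record is ``>id mature=start..end`` (0-based half-open), the RNA
    sequence, then the dot-bracket structure with the free energy in trailing
    parentheses, e.g. ``((((....)))) (-30.0)``.
    """
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 3 != 0:
        raise FormatError(f"{path}: expected 3-line records, got {len(lines)} lines")
    for i in range(0, len(lines), 3):
        head, seq, struct_line = lines[i : i + 3]
        m = _VIENNA_HEADER.match(head)
        if not m:
            raise FormatError(f"{path}: bad header at record {i // 3 + 1}: {head!r}")
        ms = _VIENNA_STRUCT.match(struct_line)
        if not ms:
            raise FormatError(
                f"{path}: bad structure/energy line at record {i // 3 + 1}: {struct_line!r}"
            )
        records.append(
            HairpinRecord(
                id=m.group(1),
                sequence=seq,
                structure=ms.group(1),
                free_energy=float(ms.group(2)),
                mature_start=int(m.group(2)),
                mature_end=int(m.group(3)),
            )
        )
    return records


def write_vienna(records: Iterable[HairpinRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id} mature={r.mature_start}..{r.mature_end}\n")
            fh.write(r.sequence + "\n")
            fh.write(f"{r.structure} ({r.free_energy:.1f})\n")


# ---------------------------------------------------------------------------
# edge tables
# ---------------------------------------------------------------------------


def read_edge_table(path) -> EdgeTable:
    """Read a 2-3 column TSV of ``mirna TAB target [TAB source]`` edges."""
    edges = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                mirna, target = fields
                source = ""
            elif len(fields) == 3:
                mirna, target, source = fields
            else:
                raise FormatError(f"{path}: line {lineno}: expected 2 or 3 fields")
            edges.add((mirna, target, source))
    return EdgeTable(edges=frozenset(edges))


def write_edge_table(table: EdgeTable, path) -> None:
    with open(path, "w") as fh:
        for mirna, target, source in sorted(table.edges):
            fh.write(f"{mirna}\t{target}\t{source}\n")


# ---------------------------------------------------------------------------
# LFQ matrices
# ---------------------------------------------------------------------------

_LFQ_COL = re.compile(r"^(.+)_([^_]+)_(lfq|peptides)$")


def read_lfq_table(path):
    """Read a protein x sample LFQ TSV into an :class:`~rbpcoreg.interactome.LfqMatrix`.

    Columns are named ``<group>_<replicate>_lfq`` and
    ``<group>_<replicate>_peptides``; rows are proteins.  An empty intensity
    cell is *missing* (not detected); a literal ``0`` is kept as a zero
    intensity with a warning.  Negative intensities are errors.
    """
    from .interactome import LfqMatrix  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    samples: list[tuple[str, str]] = []
    lfq_cols: dict[tuple[str, str], str] = {}
    pep_cols: dict[tuple[str, str], str] = {}
    for col in df.columns:
        m = _LFQ_COL.match(col)
        if not m:
            raise FormatError(f"{path}: unparsable column header {col!r}")
        group, rep, kind = m.groups()
        key = (group, rep)
        if kind == "lfq":
            lfq_cols[key] = col
        else:
            pep_cols[key] = col
        if key not in samples:
            samples.append(key)
    if set(lfq_cols) != set(pep_cols):
        raise FormatError(f"{path}: lfq/peptides columns do not pair up")
    if len({g for g, _ in samples}) < 2:
        raise FormatError(f"{path}: header must declare at least 2 groups")

    proteins = list(df.index)
    n, k = len(proteins), len(samples)
    intensity = np.full((n, k), np.nan)
    peptides = np.zeros((n, k), dtype=int)
    n_zero = 0
    for j, key in enumerate(samples):
        raw_i = df[lfq_cols[key]].to_numpy()
        raw_p = df[pep_cols[key]].to_numpy()
        for i in range(n):
            cell = raw_i[i].strip()
            if cell != "":
                val = float(cell)
                if val < 0:
                    raise FormatError(
                        f"{path}: negative intensity {val} for protein "
                        f"{proteins[i]!r} in {lfq_cols[key]}"
                    )
                if val == 0:
                    n_zero += 1
                intensity[i, j] = val
            pc = raw_p[i].strip()
            peptides[i, j] = int(pc) if pc else 0
    if n_zero:
        logger.warning(
            "%s: %d cell(s) with literal 0 intensity kept as detected-at-zero", path, n_zero
        )
    return LfqMatrix(proteins=proteins, samples=samples, intensity=intensity, peptides=peptides)


def write_lfq_table(matrix, path) -> None:
    """Write an LfqMatrix back to the TSV dialect read by :func:`read_lfq_table`."""
    cols: dict[str, list] = {}
    for j, (group, rep) in enumerate(matrix.samples):
        lfq = []
        for v in matrix.intensity[:, j]:
            lfq.append("" if np.isnan(v) else f"{v:g}")
        cols[f"{group}_{rep}_lfq"] = lfq
        cols[f"{group}_{rep}_peptides"] = [str(p) for p in matrix.peptides[:, j]]
    out = pd.DataFrame(cols, index=matrix.proteins)
    out.index.name = "protein"
    out.to_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write a result table as TSV with an optional ``#`` provenance header."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
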