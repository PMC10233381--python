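import numpy as np
import pytest
from hypothesis import settings

from rbpcoreg.interactome import LfqMatrix
from rbpcoreg.io_formats import GeneSet, rank_pairs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_ranked():
    """The 4-gene hand-checkable ranked list g1:4 > g2:3 > g3:2 > g4:1."""
    return rank_pairs([("g1", 4.0), ("g2", 3.0), ("g3", 2.0), ("g4", 1.0)], name="toy")


@pytest.fixture
def geneset():
    def make(*genes):
        return GeneSet(name="s", members=frozenset(genes))

    return make


def make_lfq(rows, n_bait=6, n_control=6, peptides_default=3):
    """Build an LfqMatrix from {protein: (bait_values, control_values)}.

    Values are lists with None for missing; peptide counts default to
    ``peptides_default`` wherever an intensity is present.
    """
    proteins = list(rows)
    samples = [("bait", str(r + 1)) for r in range(n_bait)] + [
        ("control", str(r + 1)) for r in range(n_control)
    ]
    n, k = len(proteins), len(samples)
    intensity = np.full((n, k), np.nan)
    peptides = np.zeros((n, k), dtype=int)
    for i, pid in enumerate(proteins):
        bait, ctrl = rows[pid][:2]
        pep_override = rows[pid][2] if len(rows[pid]) > 2 else None
        for j, v in enumerate(list(bait) + list(ctrl)):
            if v is not None:
                intensity[i, j] = v
                peptides[i, j] = (
                    pep_override[j] if pep_override is not None else peptides_default
                )
    return LfqMatrix(proteins=proteins, samples=samples, intensity=intensity, peptides=peptides)


def brute_force_es(genes, scores, members, p):
    """Independent O(N^2) enrichment-score oracle.

    Recomputes both running sums from scratch at every prefix (no shared
    cumulative state with the implementation under test) and returns
    (es, rank_at_max) with the earliest extremum of largest magnitude.
    """
    n = len(genes)
    hits = [g in members for g in genes]
    n_h = sum(hits)
    assert 0 < n_h < n
    n_r = sum(abs(s) ** p for s, h in zip(scores, hits) if h)
    devs = []
    for i in range(n):
        if n_r > 0:
            p_hit = sum(
                abs(scores[j]) ** p / n_r for j in range(i + 1) if hits[j]
            )
        else:
            p_hit = sum(1.0 / n_h for j in range(i + 1) if hits[j])
        p_miss = sum(1.0 / (n - n_h) for j in range(i + 1) if not hits[j])
        devs.append(p_hit - p_miss)
    # earliest position within tie tolerance of the largest magnitude
    top = max(abs(d) for d in devs)
    for i, d in enumerate(devs):
        if abs(d) >= top - 1e-9:
            return d, i + 1
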