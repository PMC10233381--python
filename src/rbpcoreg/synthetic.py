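"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the statistical structure one analysis stage
assumes, and returns truth metadata sufficient to score recovery without
re-deriving it:

* :func:`simulate_ip_lfq` — a bait-vs-IgG LFQ matrix (six biological
  replicates per arm by default) with log-normal background intensities,
  planted interactors multiplied by a chosen fold change in the bait arm,
  and IgG intensities masked missing at a chosen rate;
* :func:`simulate_ranked_overlap` — a strictly-decreasing ranked gene list
  and a query set concentrated in a chosen top percentile of it;
* :func:`simulate_mirna_counts` — negative-binomial miRNA counts for a
  3/3 KO/WT male and 3/2 KO/WT female design, with planted knockouts whose
  fold change inverts between the sexes;
* :func:`simulate_edges` — a bipartite miRNA-target edge table with planted
  co-binding multiplicities over a Poisson background;
* :func:`simulate_hairpin` — hairpin fixtures passing all eleven structural
  criteria or violating exactly one, built arm-by-arm from an explicit
  pairing plan (no thermodynamic folding; the free energy is an assigned
  attribute).

All generators are pure functions of their configuration and seed; the
single seed fans out to per-generator substreams so adding one generator
never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import EdgeTable, GeneSet, HairpinRecord, RankedTargets
from .interactome import LfqMatrix
from .hairpin import classify_hairpin

__all__ = [
    "SimConfig",
    "MIRNA_DESIGN",
    "simulate_ip_lfq",
    "simulate_ranked_overlap",
    "simulate_mirna_counts",
    "simulate_edges",
    "simulate_hairpin",
]

# sample layout of the emulated miRNA-seq study: 3 KO / 3 WT males, 3 KO / 2 WT females
MIRNA_DESIGN: tuple = (
    ("KO_F_1", ("KO", "F")),
    ("KO_F_2", ("KO", "F")),
    ("KO_F_3", ("KO", "F")),
    ("KO_M_1", ("KO", "M")),
    ("KO_M_2", ("KO", "M")),
    ("KO_M_3", ("KO", "M")),
    ("WT_M_1", ("WT", "M")),
    ("WT_M_2", ("WT", "M")),
    ("WT_M_3", ("WT", "M")),
    ("WT_F_1", ("WT", "F")),
    ("WT_F_2", ("WT", "F")),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for all generators.

    Defaults encode the emulated designs: 6 bait vs 6 IgG LC-MS/MS runs with
    a 3-fold planted enrichment at 20% replicate CV and 30% IgG missingness;
    a ranked list in which 54% of a query set sits in the top decile; a
    small two-sex miRNA-seq knockout with a 2-fold sex-inverted effect; and
    a co-binding edge table over a sparse Poisson background.
    """

    seed: int = 0
    # IP-MS
    n_proteins: int = 1000
    n_interactors: int = 50
    interactor_fc: float = 3.0
    lfq_noise_cv: float = 0.2
    missing_rate_control: float = 0.3
    n_bait: int = 6
    n_control: int = 6
    lfq_mu_log: float = math.log(1e7)
    lfq_sigma_log: float = 1.0
    # ranked overlap
    n_genes: int = 1000
    set_size: int = 100
    concentration_percentile: float = 10.0
    concentration_fraction: float = 0.54
    # miRNA
    n_mirnas: int = 600
    n_de_mirnas: int = 49
    de_effect: float = 2.0
    sex_divergent: bool = True
    mirna_dispersion: float = 0.1
    # edges
    n_targets: int = 500
    planted_cobind: tuple = ()  # of (target_id, multiplicity)
    background_edge_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.n_interactors > self.n_proteins:
            raise ValueError("n_interactors must be <= n_proteins")
        if self.set_size > self.n_genes:
            raise ValueError("set_size must be <= n_genes")
        if self.n_de_mirnas > self.n_mirnas:
            raise ValueError("n_de_mirnas must be <= n_mirnas")
        if self.interactor_fc < 1.0:
            raise ValueError("interactor_fc must be >= 1")
        if not (0.0 < self.concentration_percentile <= 100.0):
            raise ValueError("concentration_percentile must be in (0, 100]")
        if not (0.0 <= self.concentration_fraction <= 1.0):
            raise ValueError("concentration_fraction must be in [0, 1]")
        for _, mult in self.planted_cobind:
            if mult > self.n_mirnas:
                raise ValueError("planted co-binding multiplicity exceeds n_mirnas")


_STREAMS = {"ip": 1, "overlap": 2, "mirna": 3, "edges": 4, "hairpin": 5}


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(cfg_seed) % (2**31), spawn_key=(_STREAMS[stream],))
    )


def _lognormal_cv_factors(rng, cv: float, shape) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the given coefficient of variation."""
    if cv == 0.0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=shape)


# ---------------------------------------------------------------------------
# IP-MS LFQ
# ---------------------------------------------------------------------------


def simulate_ip_lfq(cfg: SimConfig) -> tuple[LfqMatrix, set]:
    """Bait-vs-IgG LFQ matrix with planted interactors; returns (matrix, truth ids)."""
    rng = _rng(cfg.seed, "ip")
    n = cfg.n_proteins
    proteins = [f"P{i + 1:05d}" for i in range(n)]
    planted_idx = np.sort(rng.choice(n, size=cfg.n_interactors, replace=False))
    planted = {proteins[i] for i in planted_idx}

    samples = [("bait", str(r + 1)) for r in range(cfg.n_bait)] + [
        ("control", str(r + 1)) for r in range(cfg.n_control)
    ]
    k = len(samples)
    base = rng.lognormal(mean=cfg.lfq_mu_log, sigma=cfg.lfq_sigma_log, size=n)
    noise = _lognormal_cv_factors(rng, cfg.lfq_noise_cv, (n, k))
    intensity = base[:, None] * noise
    intensity[planted_idx, : cfg.n_bait] *= cfg.interactor_fc

    # mask IgG intensities missing at the configured rate
    miss = rng.random((n, cfg.n_control)) < cfg.missing_rate_control
    intensity[:, cfg.n_bait :][miss] = np.nan

    peptides = 1 + rng.poisson(2.0, size=(n, k))
    peptides[planted_idx, : cfg.n_bait] = 2 + rng.poisson(
        3.0, size=(cfg.n_interactors, cfg.n_bait)
    )
    peptides[np.isnan(intensity)] = 0

    m = LfqMatrix(proteins=proteins, samples=samples, intensity=intensity, peptides=peptides)
    return m, planted


# ---------------------------------------------------------------------------
# ranked overlap
# ---------------------------------------------------------------------------


def simulate_ranked_overlap(cfg: SimConfig) -> tuple[RankedTargets, GeneSet, dict]:
    """A ranked list plus a query set concentrated in its top percentile.

    ``ceil(concentration_fraction * set_size)`` members are placed uniformly
    at random within the top ``concentration_percentile`` of ranks, the rest
    uniformly over the remaining ranks.  Truth metadata records the planted
    member ranks.
    """
    rng = _rng(cfg.seed, "overlap")
    n = cfg.n_genes
    genes = [f"G{i + 1:05d}" for i in range(n)]
    # strictly decreasing scores with a realistic heavy top end
    scores = 1000.0 * np.exp(-5.0 * np.arange(n) / n)
    region = int(math.floor(cfg.concentration_percentile / 100.0 * n))
    n_top = int(math.ceil(cfg.concentration_fraction * cfg.set_size))
    if n_top > region:
        raise ValueError(
            f"concentration region of {region} ranks cannot hold {n_top} planted members"
        )
    if cfg.set_size - n_top > n - region:
        raise ValueError("remainder of the query set does not fit outside the region")
    top_ranks = rng.choice(region, size=n_top, replace=False)  # 0-based
    rest_ranks = region + rng.choice(n - region, size=cfg.set_size - n_top, replace=False)
    member_ranks = np.sort(np.concatenate([top_ranks, rest_ranks]))
    members = frozenset(genes[i] for i in member_ranks)
    ranked = RankedTargets(
        entries=tuple((g, float(s), i + 1) for i, (g, s) in enumerate(zip(genes, scores))),
        name="synthetic_basis",
    )
    query = GeneSet(name="synthetic_query", members=members, description="planted overlap")
    truth = {
        "member_ranks": [int(r) + 1 for r in member_ranks],
        "n_planted_top": int(n_top),
        "region_size": int(region),
    }
    return ranked, query, truth


# ---------------------------------------------------------------------------
# miRNA counts
# ---------------------------------------------------------------------------


def simulate_mirna_counts(
    cfg: SimConfig, design: Sequence = MIRNA_DESIGN
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Negative-binomial miRNA counts with sex-divergent planted knockouts.

    Returns ``(counts, design_map, truth)``: counts are miRNA x sample;
    ``design_map`` maps sample name to (genotype, sex); truth lists each
    planted miRNA with its per-sex linear fold change.  Planted miRNAs have
    KO/WT fold change ``de_effect`` in males and, when ``sex_divergent``,
    ``1/de_effect`` in females.  Library sizes are drawn within 2x of each
    other.
    """
    rng = _rng(cfg.seed, "mirna")
    mirnas = [f"miR-{i + 1:04d}" for i in range(cfg.n_mirnas)]
    de_idx = np.sort(rng.choice(cfg.n_mirnas, size=cfg.n_de_mirnas, replace=False))
    de_set = {mirnas[i] for i in de_idx}

    rel = rng.lognormal(mean=math.log(200.0), sigma=1.0, size=cfg.n_mirnas)
    rel = rel / rel.sum()
    lib = rng.uniform(8e5, 1.6e6, size=len(design))

    counts = np.zeros((cfg.n_mirnas, len(design)), dtype=int)
    fc_male = cfg.de_effect
    fc_female = 1.0 / cfg.de_effect if cfg.sex_divergent else cfg.de_effect
    disp = cfg.mirna_dispersion
    for j, (_sample, (genotype, sex)) in enumerate(design):
        mu = rel * lib[j]
        if genotype == "KO":
            eff = np.ones(cfg.n_mirnas)
            eff[de_idx] = fc_male if sex == "M" else fc_female
            mu = mu * eff
        if disp > 0:
            r = 1.0 / disp
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))
        else:
            counts[:, j] = rng.poisson(mu)

    frame = pd.DataFrame(counts, index=mirnas, columns=[s for s, _ in design])
    design_map = {s: gt_sex for s, gt_sex in design}
    truth = pd.DataFrame(
        {
            "mirna": mirnas,
            "is_de": [m in de_set for m in mirnas],
            "fc_male": [fc_male if m in de_set else 1.0 for m in mirnas],
            "fc_female": [fc_female if m in de_set else 1.0 for m in mirnas],
        }
    )
    if cfg.de_effect == 1.0:
        truth["is_de"] = False  # no planted signal at unit effect
    return frame, design_map, truth


# ---------------------------------------------------------------------------
# miRNA-target edges
# ---------------------------------------------------------------------------


def simulate_edges(cfg: SimConfig) -> tuple[EdgeTable, set, dict]:
    """Bipartite edge table with planted co-binding multiplicities.

    Returns ``(edges, selected_mirnas, truth)``.  The selected pool holds
    ``n_de_mirnas`` miRNAs; each planted target receives exactly its
    multiplicity of distinct selected-miRNA edges, background targets
    receive Poisson(``background_edge_rate``) edges to arbitrary miRNAs.
    """
    rng = _rng(cfg.seed, "edges")
    mirnas = [f"miR-{i + 1:04d}" for i in range(cfg.n_mirnas)]
    selected = set(mirnas[: cfg.n_de_mirnas])
    selected_list = sorted(selected)
    planted = dict(cfg.planted_cobind)
    for t, mult in planted.items():
        if mult > len(selected_list):
            raise ValueError(
                f"planted multiplicity {mult} for {t!r} exceeds selected pool "
                f"size {len(selected_list)}"
            )
    edges = set()
    for t, mult in planted.items():
        picks = rng.choice(len(selected_list), size=mult, replace=False)
        for i in picks:
            edges.add((selected_list[i], t, "planted"))
    background = [
        f"T{i + 1:05d}" for i in range(cfg.n_targets)
        if f"T{i + 1:05d}" not in planted
    ]
    for t in background:
        k = rng.poisson(cfg.background_edge_rate)
        if k > 0:
            picks = rng.choice(cfg.n_mirnas, size=min(k, cfg.n_mirnas), replace=False)
            for i in picks:
                edges.add((mirnas[i], t, "background"))
    truth = {"planted": dict(planted), "selected": sorted(selected)}
    return EdgeTable(edges=frozenset(edges)), selected, truth


# ---------------------------------------------------------------------------
# hairpin fixtures
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _render(
    segments: Sequence[tuple],
    loop_len: int,
    rng: np.random.Generator,
) -> str:
    """Dot-bracket from an outer-to-inner stem plan.

    Segments: ``("pair", n)``, ``("bulge5", n)``, ``("bulge3", n)``,
    ``("iloop", n5, n3)``.
    """
    five = []
    three = []
    for seg in segments:
        kind = seg[0]
        if kind == "pair":
            five.append("(" * seg[1])
            three.append(")" * seg[1])
        elif kind == "bulge5":
            five.append("." * seg[1])
        elif kind == "bulge3":
            three.append("." * seg[1])
        elif kind == "iloop":
            five.append("." * seg[1])
            three.append("." * seg[2])
        else:
            raise ValueError(f"unknown segment kind {kind!r}")
    return "".join(five) + "." * loop_len + "".join(reversed(three))


def _sequence_for(structure: str, rng: np.random.Generator) -> str:
    from .hairpin import parse_pairs

    bases = list(rng.choice(list("ACGU"), size=len(structure)))
    for i, j in parse_pairs(structure):
        bases[j] = _COMPLEMENT[bases[i]]
    return "".join(bases)


# each plan: (segments, loop_len, free_energy, (mature_start, mature_end))
# all-pass baseline: a perfect 25-bp stem, 6-nt loop, mature = first 22 nt, -30 kcal/mol
_BASE_PLAN = ([("pair", 25)], 6, -30.0, (0, 22))

_VIOLATION_PLANS: dict = {
    # 13-nt bulge on the 3' arm, away from the mature region
    1: ([("pair", 12), ("bulge3", 13), ("pair", 13)], 6, -30.0, (0, 22)),
    # only 15 base pairs; bulges pad the hairpin back over the length floor
    2: ([("pair", 5), ("bulge5", 3), ("pair", 5), ("bulge3", 11), ("pair", 5)],
        6, -30.0, (0, 18)),
    # free energy above the -15 kcal/mol cutoff
    3: ([("pair", 25)], 6, -14.0, (0, 22)),
    # hairpin span of 49 nt (< 50)
    4: ([("pair", 21)], 7, -30.0, (0, 18)),
    # 21-nt terminal loop (> 20)
    5: ([("pair", 25)], 21, -30.0, (0, 22)),
    # 9-nt symmetric internal loop (5+4) touching the mature region
    6: ([("pair", 10), ("iloop", 5, 4), ("pair", 15)], 6, -30.0, (0, 22)),
    # 5-nt single-strand bulge inside the mature region
    7: ([("pair", 10), ("bulge5", 5), ("pair", 15)], 6, -30.0, (0, 22)),
    # three single-strand bulges inside the mature region
    8: ([("pair", 5), ("bulge5", 2), ("pair", 5), ("bulge5", 2), ("pair", 5),
         ("bulge5", 2), ("pair", 10)], 6, -30.0, (0, 22)),
    # eight unpaired mature positions via two symmetric internal loops
    9: ([("pair", 8), ("iloop", 4, 4), ("pair", 8), ("iloop", 4, 4), ("pair", 9)],
        6, -30.0, (0, 24)),
    # a 13-nt mature arm holding only 11 base pairs
    10: ([("pair", 11), ("bulge5", 2), ("pair", 14)], 6, -30.0, (0, 13)),
    # mature region overhanging 5 nt into the terminal loop (77% in stem)
    11: ([("pair", 25)], 6, -30.0, (8, 30)),
}


def simulate_hairpin(violate: int | None = None, seed: int = 0) -> HairpinRecord:
    """A hairpin fixture passing all eleven criteria, or failing exactly one.

    ``violate=None`` returns an all-pass record; ``violate=k`` (1-11)
    returns a record whose classification fails criterion ``k`` and no
    other.  The construction is verified against :func:`classify_hairpin`
    before the record is returned.
    """
    if violate is not None and violate not in _VIOLATION_PLANS:
        raise ValueError(f"violate must be None or 1..11, got {violate!r}")
    segments, loop_len, energy, mature = (
        _BASE_PLAN if violate is None else _VIOLATION_PLANS[violate]
    )
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(_STREAMS["hairpin"],))
    )
    structure = _render(segments, loop_len, rng)
    sequence = _sequence_for(structure, rng)
    record = HairpinRecord(
        id=f"hp_pass" if violate is None else f"hp_violate_c{violate}",
        sequence=sequence,
        structure=structure,
        free_energy=energy,
        mature_start=mature[0],
        mature_end=mature[1],
    )
    verdict = classify_hairpin(record)
    expected = [] if violate is None else [violate]
    if verdict.failed != expected:
        raise AssertionError(
            f"hairpin plan for violate={violate} fails criteria {verdict.failed}, "
            f"expected {expected}"
        )
    return record
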