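"""Call bait interactors from IP-MS label-free quantification matrices.

The calling rule mirrors standard affinity-purification mass-spec practice
with an IgG negative control:

1. *detection* — the protein must carry at least ``min_unique_peptides``
   unique peptides with a present LFQ intensity in at least
   ``min_bait_detections`` of the ``n_bait`` bait pull-downs (default 5/6);
2. *enrichment* — the ratio of mean detected bait intensity to mean detected
   control intensity must exceed ``fc_threshold`` (default 1.5); a protein
   never detected in the control gets an infinite ratio and passes, since
   absence from IgG is the strongest possible enrichment evidence;
3. *significance* — a one-way ANOVA across replicate groups with a
   permutation p-value and a permutation-based FDR (SAM/Perseus style) must
   give q below ``alpha`` (default 0.05).

Every protein receives an :class:`InteractorCall` with explicit tags for the
rules it failed, so filter funnels can be reported exactly.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LfqMatrix",
    "CallParams",
    "InteractorCall",
    "AnovaResult",
    "call_interactors",
    "anova_permutation_fdr",
    "region_overlap",
    "quantifiable_filter",
    "oneway_f",
]


@dataclass(frozen=True)
class LfqMatrix:
    """Protein x sample LFQ intensities plus unique-peptide counts.

    ``samples`` is a list of ``(group, replicate)`` labels; ``intensity`` is a
    float array with ``nan`` for *not detected*; ``peptides`` is an integer
    array of unique-peptide counts.
    """

    proteins: list
    samples: list  # of (group, replicate)
    intensity: np.ndarray
    peptides: np.ndarray

    def __post_init__(self) -> None:
        n, k = len(self.proteins), len(self.samples)
        if self.intensity.shape != (n, k) or self.peptides.shape != (n, k):
            raise ValueError("LfqMatrix dimensions inconsistent")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensity < 0):
                raise ValueError("LFQ intensities must be non-negative")
        if len(set(self.proteins)) != n:
            raise ValueError("duplicate protein ids")

    @property
    def groups(self) -> list:
        seen: list = []
        for g, _ in self.samples:
            if g not in seen:
                seen.append(g)
        return seen

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([j for j, (g, _) in enumerate(self.samples) if g == group], dtype=int)

    def row(self, protein: str) -> int:
        return self.proteins.index(protein)


@dataclass(frozen=True)
class CallParams:
    """Thresholds for interactor calling (defaults follow the 6-vs-6 whole-brain design)."""

    min_unique_peptides: int = 2
    min_bait_detections: int = 5
    n_bait: int = 6
    fc_threshold: float = 1.5
    alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    min_replicate_groups_quant: int = 2
    bait_group: str = "bait"
    control_group: str = "control"

    def __post_init__(self) -> None:
        if self.min_bait_detections > self.n_bait:
            raise ValueError("min_bait_detections must be <= n_bait")


@dataclass(frozen=True)
class InteractorCall:
    protein_id: str
    n_detected_bait: int
    fold_change: float  # may be +inf (absent from control) or nan (absent from bait)
    f_stat: float
    p_value: float
    q_value: float
    called: bool
    reasons: tuple = ()


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    q_value: float
    skipped: bool = False
    skip_reason: str = ""


# ---------------------------------------------------------------------------
# one-way ANOVA F with explicit degenerate-case handling
# ---------------------------------------------------------------------------


def oneway_f(groups: Sequence[np.ndarray]) -> float:
    """One-way ANOVA F statistic.

    Zero within-group variance with a between-group difference gives
    ``+inf``; identical data everywhere gives ``0.0``.  (scipy's ``f_oneway``
    warns and returns nan in these degenerate cases, which the permutation
    null needs to rank consistently.)
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = int(ns.sum())
    if k < 2 or n <= k:
        raise ValueError("need >=2 groups and more observations than groups")
    means = np.array([float(np.mean(g)) for g in groups])
    grand = float(sum(float(np.sum(g)) for g in groups)) / n
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(float(np.sum((g - m) ** 2)) for g, m in zip(groups, means)))
    if ssw == 0.0:
        return math.inf if ssb > 0.0 else 0.0
    return (ssb / (k - 1)) / (ssw / (n - k))


def _protein_rng(seed: int, protein_id: str) -> np.random.Generator:
    # per-protein substream keyed by the id, so results are invariant to row order
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(zlib.crc32(str(protein_id).encode()),))
    )


def _two_group_masks_exhaustive(n: int, n1: int) -> np.ndarray:
    combos = list(combinations(range(n), n1))
    masks = np.zeros((len(combos), n), dtype=bool)
    for b, idx in enumerate(combos):
        masks[b, list(idx)] = True
    return masks


def _two_group_perm_f(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Vectorized F over label assignments for the 2-group case."""
    n = values.size
    n1 = int(masks[0].sum())
    n2 = n - n1
    total = float(values.sum())
    grand = total / n
    ss_tot = float(np.sum((values - grand) ** 2))
    sum1 = masks @ values
    mean1 = sum1 / n1
    mean2 = (total - sum1) / n2
    ssb = n1 * (mean1 - grand) ** 2 + n2 * (mean2 - grand) ** 2
    ssw = ss_tot - ssb
    ssw = np.where(np.abs(ssw) < 1e-12 * max(ss_tot, 1.0), 0.0, ssw)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / 1.0) / (ssw / (n - 2))
    f = np.where(ssw == 0.0, np.where(ssb > 0.0, np.inf, 0.0), f)
    return f


def _label_perm_f(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """F for each row of a label-assignment matrix (general k groups)."""
    out = np.empty(labels.shape[0])
    for b in range(labels.shape[0]):
        lab = labels[b]
        groups = [values[lab == g] for g in np.unique(lab)]
        out[b] = oneway_f(groups)
    return out


def _n_assignments(ns: Sequence[int]) -> int:
    n = sum(ns)
    total = 1
    rem = n
    for s in ns:
        total *= math.comb(rem, s)
        rem -= s
    return total


def _null_f_distribution(
    groups: Sequence[np.ndarray], n_permutations: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Permuted-label F values for one protein.

    Returns ``(f_values, exhaustive)``.  The null is enumerated exhaustively
    when the number of distinct label assignments is at most
    ``n_permutations`` (the identity assignment is then part of the null);
    otherwise ``n_permutations`` random shuffles are drawn.
    """
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ns = [len(g) for g in groups]
    n = values.size
    total = _n_assignments(ns)
    if total <= n_permutations:
        if len(ns) == 2:
            masks = _two_group_masks_exhaustive(n, ns[0])
            return _two_group_perm_f(values, masks), True
        from sympy.utilities.iterables import multiset_permutations

        base = np.concatenate([np.full(sz, i) for i, sz in enumerate(ns)])
        labels = np.array(list(multiset_permutations(list(base))))
        return _label_perm_f(values, labels), True
    # Monte Carlo: column permutations via argsort of random keys
    keys = rng.random((n_permutations, n))
    order = np.argsort(keys, axis=1)
    if len(ns) == 2:
        masks = np.zeros((n_permutations, n), dtype=bool)
        rows = np.arange(n_permutations)[:, None]
        masks[rows, order[:, : ns[0]]] = True
        return _two_group_perm_f(values, masks), False
    base = np.concatenate([np.full(sz, i) for i, sz in enumerate(ns)])
    labels = base[np.argsort(order, axis=1)]
    return _label_perm_f(values, labels), False


def anova_permutation_fdr(
    values: Mapping[str, Sequence[np.ndarray]],
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict[str, AnovaResult]:
    """Permutation one-way ANOVA with permutation-based FDR across proteins.

    ``values`` maps protein id to its per-group replicate vectors (missing
    observations already removed).  For each protein the group labels are
    permuted within that protein; the p-value is the fraction of permuted F
    statistics at least as large as the observed one (exact fraction under
    exhaustive enumeration, add-one Monte Carlo estimate otherwise).

    The q-value follows the SAM-style permutation FDR: for a protein with
    observed statistic ``F_i``,

        q_i = E_perm[ #{proteins whose permuted F >= F_i} ] /
                      #{proteins whose observed F >= F_i}

    monotonized by cumulative minimum from the largest observed F and capped
    at 1.  Proteins with fewer than two groups carrying >=2 observations are
    skipped with a reason rather than raising.
    """
    observed: dict[str, float] = {}
    skipped: dict[str, str] = {}
    null_f: dict[str, np.ndarray] = {}
    p_values: dict[str, float] = {}

    for pid in values:
        groups = [np.asarray(g, dtype=float) for g in values[pid]]
        groups = [g[~np.isnan(g)] for g in groups]
        if any(g.size == 0 for g in groups):
            skipped[pid] = "group-all-missing"
            continue
        if len(groups) < 2 or any(g.size < 2 for g in groups):
            skipped[pid] = "insufficient-replicates"
            continue
        f_obs = oneway_f(groups)
        rng = _protein_rng(seed, pid)
        fnull, exhaustive = _null_f_distribution(groups, n_permutations, rng)
        count = int(np.sum(fnull >= f_obs))
        if exhaustive:
            p = count / fnull.size
        else:
            p = (1 + count) / (1 + fnull.size)
        observed[pid] = f_obs
        null_f[pid] = fnull
        p_values[pid] = p

    # permutation FDR across proteins: pooled null with per-protein weight 1/B_j
    tested = list(observed)
    q_values: dict[str, float] = {}
    if tested:
        pooled = np.concatenate([null_f[pid] for pid in tested])
        weights = np.concatenate(
            [np.full(null_f[pid].size, 1.0 / null_f[pid].size) for pid in tested]
        )
        order = np.argsort(pooled)
        pooled_sorted = pooled[order]
        w_sorted = weights[order]
        # cumulative weight of null values >= x, queried by searchsorted
        tail_w = np.concatenate([np.cumsum(w_sorted[::-1])[::-1], [0.0]])
        obs = np.array([observed[pid] for pid in tested])
        obs_sorted = np.sort(obs)
        raw = {}
        for pid in tested:
            f_i = observed[pid]
            lo = np.searchsorted(pooled_sorted, f_i, side="left")
            numer = tail_w[lo]
            denom = obs.size - np.searchsorted(obs_sorted, f_i, side="left")
            raw[pid] = min(1.0, numer / denom) if denom > 0 else 1.0
        # monotonize: larger F never gets a larger q, i.e. q_i = min of the raw
        # estimates over all proteins with F <= F_i (cumulative min walking up
        # from the smallest F)
        by_f_asc = sorted(tested, key=lambda pid: observed[pid])
        running = 1.0
        q_desc = {}
        for pid in by_f_asc:
            running = min(running, raw[pid])
            q_desc[pid] = running
        # proteins sharing an F value share the monotonized q
        for pid in tested:
            q_values[pid] = min(q_desc[p2] for p2 in tested if observed[p2] == observed[pid])

    out: dict[str, AnovaResult] = {}
    for pid in values:
        if pid in skipped:
            out[pid] = AnovaResult(
                f_stat=math.nan, p_value=math.nan, q_value=math.nan,
                skipped=True, skip_reason=skipped[pid],
            )
        else:
            out[pid] = AnovaResult(
                f_stat=observed[pid], p_value=p_values[pid], q_value=q_values[pid]
            )
    return out


# ---------------------------------------------------------------------------
# interactor calling
# ---------------------------------------------------------------------------


def call_interactors(m: LfqMatrix, params: CallParams | None = None) -> list[InteractorCall]:
    """Apply the detection / fold-change / significance gates to every protein.

    Returns one :class:`InteractorCall` per protein (in matrix order) with
    ``reasons`` naming each failed gate: ``detection``, ``fold_change``,
    ``significance`` or ``anova:<skip reason>``.
    """
    params = params or CallParams()
    if params.bait_group not in m.groups:
        raise ValueError(f"bait group {params.bait_group!r} missing from matrix")
    if params.control_group not in m.groups:
        raise ValueError(f"control group {params.control_group!r} missing from matrix")
    bait_idx = m.group_indices(params.bait_group)
    ctrl_idx = m.group_indices(params.control_group)
    if bait_idx.size != params.n_bait:
        raise ValueError(
            f"bait group has {bait_idx.size} replicates, expected n_bait={params.n_bait}"
        )

    anova_input: dict[str, list[np.ndarray]] = {}
    for i, pid in enumerate(m.proteins):
        bait = m.intensity[i, bait_idx]
        ctrl = m.intensity[i, ctrl_idx]
        anova_input[pid] = [bait[~np.isnan(bait)], ctrl[~np.isnan(ctrl)]]
    anova = anova_permutation_fdr(
        anova_input, n_permutations=params.n_permutations, seed=params.seed
    )

    calls = []
    for i, pid in enumerate(m.proteins):
        bait = m.intensity[i, bait_idx]
        ctrl = m.intensity[i, ctrl_idx]
        peps = m.peptides[i, bait_idx]
        detected = (~np.isnan(bait)) & (peps >= params.min_unique_peptides)
        n_det = int(detected.sum())

        bait_vals = bait[~np.isnan(bait)]
        ctrl_vals = ctrl[~np.isnan(ctrl)]
        if bait_vals.size == 0:
            fc = math.nan
        elif ctrl_vals.size == 0:
            fc = math.inf  # absent from IgG: strongest enrichment evidence
        else:
            mc = float(np.mean(ctrl_vals))
            fc = math.inf if mc == 0 else float(np.mean(bait_vals)) / mc

        a = anova[pid]
        reasons = []
        if n_det < params.min_bait_detections:
            reasons.append("detection")
        if not (fc > params.fc_threshold):  # nan fails too
            reasons.append("fold_change")
        if a.skipped:
            reasons.append(f"anova:{a.skip_reason}")
        elif not (a.q_value < params.alpha):
            reasons.append("significance")
        calls.append(
            InteractorCall(
                protein_id=pid,
                n_detected_bait=n_det,
                fold_change=fc,
                f_stat=a.f_stat,
                p_value=a.p_value,
                q_value=a.q_value,
                called=not reasons,
                reasons=tuple(reasons),
            )
        )
    return calls


def calls_to_frame(calls: Iterable[InteractorCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [c.protein_id for c in calls],
            "n_detected": [c.n_detected_bait for c in calls],
            "fc": [c.fold_change for c in calls],
            "F": [c.f_stat for c in calls],
            "p": [c.p_value for c in calls],
            "q": [c.q_value for c in calls],
            "called": [c.called for c in calls],
            "reasons": [",".join(c.reasons) for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# region set algebra and quantifiability
# ---------------------------------------------------------------------------


def region_overlap(sets: Mapping[str, set]) -> tuple[dict, dict]:
    """Label each protein with the exact combination of regions containing it.

    Returns ``(labels, counts)`` where ``labels`` maps protein id to a
    frozenset of region names and ``counts`` maps each observed combination
    to its protein count.
    """
    import logging

    if len(sets) < 2:
        raise ValueError("need at least 2 named region sets")
    for name, s in sets.items():
        if not s:
            logging.getLogger(__name__).warning("region set %r is empty", name)
    labels: dict = {}
    for name, members in sets.items():
        for pid in members:
            labels.setdefault(pid, set()).add(name)
    labels = {pid: frozenset(regs) for pid, regs in labels.items()}
    counts: dict = {}
    for combo in labels.values():
        counts[combo] = counts.get(combo, 0) + 1
    return labels, counts


def quantifiable_filter(m: LfqMatrix, params: CallParams | None = None) -> set:
    """Proteins detected (>=1 present intensity) in >= `min_replicate_groups_quant` groups."""
    params = params or CallParams()
    retained = set()
    group_cols = {g: m.group_indices(g) for g in m.groups}
    for i, pid in enumerate(m.proteins):
        n_groups = sum(
            1 for g, idx in group_cols.items() if np.any(~np.isnan(m.intensity[i, idx]))
        )
        if n_groups >= params.min_replicate_groups_quant:
            retained.add(pid)
    return retained
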