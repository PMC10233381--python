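"""Per-sex miRNA differential expression and miRNA-target co-binding.

The experimental design emulated throughout is a small knockout-vs-wild-type
miRNA-seq study with both sexes (3 KO and 3 WT males, 3 KO and 2 WT
females).  Counts are normalized to counts-per-million (CPM), tested per sex
with a two-sided Welch t on log2(CPM + 1), and a miRNA is called
*sex-divergent* when it is significant in at least one sex and its fold
changes point in opposite directions in males and females.  Dysregulated
miRNAs additionally require more than a 25% change of the linear KO/WT CPM
ratio in either direction.  Downstream, mRNA targets are prioritized by
their *co-binding count* — the number of distinct dysregulated miRNAs
predicted to bind them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import EdgeTable
from .hairpin import classify_hairpin, HairpinVerdict  # re-exported: part of this arm

__all__ = [
    "normalize_cpm",
    "differential_mirna",
    "select_dysregulated",
    "CoBindingResult",
    "cobinding_counts",
    "prioritize_targets",
    "sex_concordance",
    "filter_read_lengths",
    "classify_hairpin",
]


def normalize_cpm(
    counts: pd.DataFrame, library_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """Counts-per-million: ``1e6 * count / library_size`` per sample column.

    Library sizes default to column sums; a zero library size is an error.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        bad = list(library_sizes.index[library_sizes <= 0])
        raise ValueError(f"non-positive library size for sample(s) {bad}")
    return counts * 1e6 / library_sizes


def _inv_trigamma(x: float) -> float:
    """Solve psi'(y) = x for y > 0 (Newton iteration, as in eBayes fitting)."""
    if x <= 0:
        return math.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def _moderated_t_pvalues(
    deltas: np.ndarray, s2: np.ndarray, df: float, se_scale: float
) -> np.ndarray:
    """Empirical-Bayes moderated t-test p-values across genes.

    Per-gene residual variances ``s2`` (each on ``df`` degrees of freedom)
    are shrunk toward a common prior fitted by moments of ``log s2``
    (scaled inverse-chi-square with parameters ``d0``, ``s0^2``); the t
    statistic uses the posterior variance and gains ``d0`` degrees of
    freedom.  ``se_scale`` is ``sqrt(1/n1 + 1/n2)``.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 3:
        # too few genes to fit a prior: ordinary pooled t
        with np.errstate(divide="ignore", invalid="ignore"):
            t = deltas / np.sqrt(s2 * se_scale**2)
        return 2.0 * stats.t.sf(np.abs(t), df=df)
    z = np.log(s2[ok])
    bias = float(special.digamma(df / 2.0)) - math.log(df / 2.0)
    excess = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = math.inf
        log_s0 = float(np.mean(z)) - bias
    else:
        d0 = 2.0 * _inv_trigamma(excess)
        log_s0 = (
            float(np.mean(z)) - bias - (math.log(d0 / 2.0) - float(special.digamma(d0 / 2.0)))
        )
    s0_sq = math.exp(log_s0)
    if math.isinf(d0):
        post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        post = (d0 * s0_sq + df * np.where(ok, s2, 0.0)) / (d0 + df)
        df_total = d0 + df
    t = deltas / np.sqrt(post * se_scale**2)
    if math.isinf(df_total):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df=df_total)


def _welch_or_permutation(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t p-value; exact mean-difference permutation when degenerate."""
    if a.size < 2 or b.size < 2:
        return math.nan
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return 1.0
        pooled = np.concatenate([a, b])
        obs = abs(np.mean(a) - np.mean(b))
        n = pooled.size
        count = total = 0
        for idx in combinations(range(n), a.size):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            d = abs(pooled[mask].mean() - pooled[~mask].mean())
            count += d >= obs - 1e-12
            total += 1
        return count / total
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def differential_mirna(
    cpm: pd.DataFrame,
    design: Mapping[str, tuple],
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    ko_label: str = "KO",
    wt_label: str = "WT",
    method: str = "moderated",
    divergence: str = "interaction",
) -> pd.DataFrame:
    """Per-sex KO-vs-WT differential expression of every miRNA.

    ``design`` maps sample (column) name to ``(genotype, sex)``.  Returns a
    tidy frame with one row per (miRNA, sex): mean CPMs, linear and log2 fold
    change (KO/WT, pseudocounted), percent change ``100*|fc - 1|``, the
    p-value of the configured test on log2(CPM + pseudocount), a
    ``testable`` flag (both cells with >=2 replicates), and a per-miRNA
    ``divergent`` flag.

    The divergence predicate is configurable.  ``divergence="interaction"``
    (default) calls a miRNA divergent when the sex-by-genotype interaction
    contrast ``(KO-WT)_male - (KO-WT)_female`` is significant and the
    per-sex fold changes have strictly opposite signs — the interaction
    directly tests the male-female difference that the flag is about.
    ``divergence="per-sex"`` instead requires significance of the KO-WT
    contrast in at least one sex (plus opposite signs).

    ``method="moderated"`` (default) is an empirical-Bayes moderated t that
    shrinks per-miRNA variances toward a common prior fitted across miRNAs —
    the standard choice at 2-3 replicates per cell, where per-gene variance
    estimates are too unstable for a plain t-test.  ``method="welch"`` is a
    per-miRNA two-sided Welch t (exact mean-difference permutation when both
    groups are constant).
    """
    if method not in ("moderated", "welch"):
        raise ValueError(f"unknown method {method!r}")
    if divergence not in ("interaction", "per-sex"):
        raise ValueError(f"unknown divergence predicate {divergence!r}")
    for col in cpm.columns:
        if col not in design:
            raise ValueError(f"sample {col!r} missing from design")
    sexes = sorted({sx for _, sx in design.values()})
    mirnas = list(cpm.index)
    rows = []
    per_mirna: dict[str, dict[str, tuple]] = {m: {} for m in mirnas}

    moderated_p: dict[str, np.ndarray] = {}
    interaction_p: np.ndarray | None = None
    if method == "moderated":
        # one linear model over all genotype x sex cells: residual variance is
        # pooled across cells (then shrunk across miRNAs), contrasts are per sex
        cells: dict[tuple, np.ndarray] = {}
        for cell in sorted({gs for gs in design.values()}):
            cols = [c for c in cpm.columns if design[c] == cell]
            if cols:
                cells[cell] = np.log2(cpm[cols].to_numpy(dtype=float) + pseudocount)
        df_resid = sum(m.shape[1] - 1 for m in cells.values())
        ss = np.zeros(len(mirnas))
        for m in cells.values():
            ss += ((m - m.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        if df_resid >= 1:
            s2 = ss / df_resid
            per_sex_delta: dict[str, np.ndarray] = {}
            per_sex_w: dict[str, float] = {}
            for sex in sexes:
                ko_cell, wt_cell = (ko_label, sex), (wt_label, sex)
                if ko_cell not in cells or wt_cell not in cells:
                    continue
                n1, n2 = cells[ko_cell].shape[1], cells[wt_cell].shape[1]
                if n1 < 2 or n2 < 2:
                    continue
                deltas = cells[ko_cell].mean(axis=1) - cells[wt_cell].mean(axis=1)
                per_sex_delta[sex] = deltas
                per_sex_w[sex] = 1.0 / n1 + 1.0 / n2
                moderated_p[sex] = _moderated_t_pvalues(
                    deltas, s2, df_resid, math.sqrt(per_sex_w[sex])
                )
            if len(per_sex_delta) == 2:
                # sex-by-genotype interaction: (KO-WT)_sex1 - (KO-WT)_sex2
                s1, s2x = sorted(per_sex_delta)
                interaction_p = _moderated_t_pvalues(
                    per_sex_delta[s1] - per_sex_delta[s2x],
                    s2,
                    df_resid,
                    math.sqrt(per_sex_w[s1] + per_sex_w[s2x]),
                )

    welch_stats: dict[str, tuple] = {}
    for sex in sexes:
        ko_cols = [c for c in cpm.columns if design[c] == (ko_label, sex)]
        wt_cols = [c for c in cpm.columns if design[c] == (wt_label, sex)]
        ko = cpm[ko_cols].to_numpy(dtype=float)
        wt = cpm[wt_cols].to_numpy(dtype=float)
        n1, n2 = ko.shape[1], wt.shape[1]
        testable = n1 >= 2 and n2 >= 2
        mean_ko = ko.mean(axis=1) if n1 else np.full(len(mirnas), math.nan)
        mean_wt = wt.mean(axis=1) if n2 else np.full(len(mirnas), math.nan)
        fc = (mean_ko + pseudocount) / (mean_wt + pseudocount)
        log2fc = np.log2(fc)
        if not testable:
            pvals = np.full(len(mirnas), math.nan)
        elif method == "moderated":
            pvals = moderated_p.get(sex, np.full(len(mirnas), math.nan))
        else:
            lko = np.log2(ko + pseudocount)
            lwt = np.log2(wt + pseudocount)
            pvals = np.array(
                [_welch_or_permutation(lko[i], lwt[i]) for i in range(len(mirnas))]
            )
            welch_stats[sex] = (
                lko.mean(axis=1) - lwt.mean(axis=1),
                [(lko.var(axis=1, ddof=1), n1), (lwt.var(axis=1, ddof=1), n2)],
            )
        for i, mirna in enumerate(mirnas):
            per_mirna[mirna][sex] = (float(log2fc[i]), float(pvals[i]), testable)
            rows.append(
                {
                    "mirna": mirna,
                    "sex": sex,
                    "mean_wt_cpm": float(mean_wt[i]),
                    "mean_ko_cpm": float(mean_ko[i]),
                    "linear_fc": float(fc[i]),
                    "log2_fc": float(log2fc[i]),
                    "pct_change": 100.0 * abs(float(fc[i]) - 1.0),
                    "p_value": float(pvals[i]),
                    "testable": testable,
                }
            )
    table = pd.DataFrame(rows)

    if method == "welch" and len(welch_stats) == 2:
        # Welch-Satterthwaite interaction contrast across the four cells
        (d1, comp1), (d2, comp2) = (welch_stats[s] for s in sorted(welch_stats))
        comps = comp1 + comp2
        var_sum = sum(v / n for v, n in comps)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_int = (d1 - d2) / np.sqrt(var_sum)
            df_int = var_sum**2 / sum((v / n) ** 2 / (n - 1) for v, n in comps)
        interaction_p = 2.0 * stats.t.sf(np.abs(t_int), df=df_int)
        interaction_p = np.where(np.isfinite(interaction_p), interaction_p, 1.0)

    int_p_by_mirna = (
        dict(zip(mirnas, interaction_p)) if interaction_p is not None else {}
    )
    divergent = {}
    for mirna, by_sex in per_mirna.items():
        if len(by_sex) >= 2:
            (l1, p1, t1), (l2, p2, t2) = [by_sex[s] for s in sexes[:2]]
            if divergence == "interaction" and mirna in int_p_by_mirna:
                pi = int_p_by_mirna[mirna]
                sig = bool(not math.isnan(pi) and pi < alpha)
            else:
                sig = (t1 and not math.isnan(p1) and p1 < alpha) or (
                    t2 and not math.isnan(p2) and p2 < alpha
                )
            divergent[mirna] = bool(sig and (np.sign(l1) * np.sign(l2) < 0))
        else:
            divergent[mirna] = False
    table["divergent"] = table["mirna"].map(divergent)
    if interaction_p is not None:
        table["p_interaction"] = table["mirna"].map(int_p_by_mirna)
    return table


def select_dysregulated(
    table: pd.DataFrame,
    pct_threshold: float = 25.0,
    alpha: float = 0.05,
    gate: str = "auto",
) -> set:
    """miRNAs with > ``pct_threshold`` % change in either direction in >=1 sex.

    The significance gate is configurable: ``"divergent"`` requires the
    per-miRNA sex-divergence flag, ``"significant"`` requires p < alpha in at
    least one sex, ``"auto"`` uses divergence when the table covers both
    sexes and plain significance otherwise.
    """
    if gate == "auto":
        gate = "divergent" if table["sex"].nunique() >= 2 else "significant"
    selected = set()
    for mirna, grp in table.groupby("mirna", sort=False):
        big_change = bool((grp["pct_change"] > pct_threshold).any())
        if not big_change:
            continue
        if gate == "divergent":
            ok = bool(grp["divergent"].any())
        elif gate == "significant":
            ok = bool((grp["p_value"] < alpha).any())
        else:
            raise ValueError(f"unknown gate {gate!r}")
        if ok:
            selected.add(mirna)
    return selected


@dataclass(frozen=True)
class CoBindingResult:
    target_id: str
    cobind_count: int
    prioritized: bool


def cobinding_counts(
    edges: EdgeTable, selected_mirnas: set, min_cobind: int = 1
) -> list[CoBindingResult]:
    """Distinct selected-miRNA edge counts per target, targets with 0 omitted.

    Multiple sources for the same (miRNA, target) pair collapse to one edge.
    ``prioritized`` flags ``cobind_count >= min_cobind``.
    """
    partners: dict[str, set] = {}
    for mirna, target, _source in edges.edges:
        if mirna in selected_mirnas:
            partners.setdefault(target, set()).add(mirna)
    return [
        CoBindingResult(target_id=t, cobind_count=len(ms), prioritized=len(ms) >= min_cobind)
        for t, ms in sorted(partners.items())
    ]


def prioritize_targets(results: Iterable[CoBindingResult], min_cobind: int) -> set:
    """Targets whose co-binding count reaches ``min_cobind``."""
    if min_cobind < 1:
        raise ValueError("min_cobind must be >= 1")
    return {r.target_id for r in results if r.cobind_count >= min_cobind}


def sex_concordance(
    target_changes: Mapping[str, Mapping[str, float]],
    reference: Mapping[str, float],
    relation: str = "same",
) -> tuple[dict, int]:
    """Score each target's per-sex change directions against a reference.

    ``target_changes`` maps target -> {sex: signed change}; ``reference``
    maps sex -> signed change.  With ``relation="same"`` a target is
    concordant when its sign matches the reference in every sex; with
    ``"opposite"`` when it negates it in every sex.  Targets missing a
    reference sex are flagged unevaluable (``None``).  Returns the per-target
    flags and the concordant count.
    """
    if relation not in ("same", "opposite"):
        raise ValueError(f"unknown relation {relation!r}")
    want = 1.0 if relation == "same" else -1.0
    flags: dict = {}
    for target, per_sex in target_changes.items():
        if any(sex not in per_sex for sex in reference):
            flags[target] = None
            continue
        ok = all(
            np.sign(per_sex[sex]) == want * np.sign(ref) and np.sign(ref) != 0
            for sex, ref in reference.items()
        )
        flags[target] = bool(ok)
    return flags, sum(1 for v in flags.values() if v)


def filter_read_lengths(
    sequences: Iterable[str] | Mapping[str, int],
    min_len: int = 18,
    max_len: int = 26,
) -> set:
    """Unique small-RNA reads kept for mapping: length 18-26 nt inclusive.

    Accepts either raw sequences (filtered by their own length) or a mapping
    of read id to length (filtered by the value).
    """
    if isinstance(sequences, Mapping):
        return {rid for rid, ln in sequences.items() if min_len <= ln <= max_len}
    return {s for s in sequences if min_len <= len(s) <= max_len}
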