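"""Cell-fate classification and the gated statistical decision tree.

Follicle precursor cells resolve into discrete fates readable from two
markers: Eya (high in main-body follicle cells) and Cas (high in polar and
stalk cells).  On normalized intensities the four threshold combinations
map to precursor (low/low), main body (Eya high / Cas low), polar or stalk
(Eya low / Cas high) and double positive (high/high).

Group comparisons follow a variance-gated tree:

* two groups — F-test on variances; similar variance -> two-tailed unpaired
  t-test, different variance -> two-tailed Mann-Whitney;
* three or more groups — Brown-Forsythe test; similar variance -> ordinary
  one-way ANOVA with Tukey's multiple comparisons, different variance ->
  Kruskal-Wallis with Dunn's multiple comparisons (Bonferroni-adjusted,
  tie-corrected).

Clonal composition of polar/stalk units (all-mutant vs mixed) is compared
between genotypes with Fisher's exact test (two-sided probability-mass
definition).  Box-plot summaries use the Tukey whisker convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


FATE_STATES = (
    "precursor_low_low",
    "main_body_high_low",
    "polar_stalk_low_high",
    "double_positive_high_high",
)


def classify_fate(eya_norm, cas_norm, thresholds=(0.5, 0.5)):
    """Map normalized (Eya, Cas) to one of the four fate states.

    "High" means value >= threshold (boundary counts as high).  Accepts
    scalars or arrays; every cell maps to exactly one state.
    """
    t_eya, t_cas = thresholds
    eya = np.asarray(eya_norm, dtype=float)
    cas = np.asarray(cas_norm, dtype=float)
    if np.any(eya < 0) or np.any(cas < 0):
        raise ValueError("normalized intensities must be >= 0")
    eya_hi = eya >= t_eya
    cas_hi = cas >= t_cas
    states = np.where(
        eya_hi & cas_hi, "double_positive_high_high",
        np.where(eya_hi, "main_body_high_low",
                 np.where(cas_hi, "polar_stalk_low_high", "precursor_low_low")),
    )
    return states.item() if states.ndim == 0 else states


def auto_thresholds(eya_norm, cas_norm, min_cells: int = 50):
    """Data-driven high/low thresholds from bimodal marker distributions.

    At the stage where the two markers are fully resolved, each marker's
    distribution is bimodal; the threshold is placed at the density minimum
    between the two largest modes of a Gaussian KDE.  A unimodal marker
    falls back to 0.5 with a warning.  Duplicating the dataset leaves the
    thresholds unchanged (the KDE is scale- and copy-invariant).
    """
    out = []
    for name, v in (("eya", eya_norm), ("cas", cas_norm)):
        v = np.asarray(v, dtype=float)
        if len(v) < min_cells:
            raise ValueError(f"need >= {min_cells} cells to set thresholds, have {len(v)}")
        out.append(_valley_threshold(v, name))
    return tuple(out)


def _valley_threshold(v: np.ndarray, name: str) -> float:
    kde = sps.gaussian_kde(v)
    grid = np.linspace(v.min(), v.max(), 512)
    dens = kde(grid)
    interior = np.arange(1, len(grid) - 1)
    peaks = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    if len(peaks) < 2:
        warnings.warn(f"{name}: distribution not bimodal; falling back to threshold 0.5",
                      stacklevel=3)
        return 0.5
    top2 = sorted(peaks[np.argsort(dens[peaks])[-2:]])
    valley = top2[0] + int(np.argmin(dens[top2[0]: top2[1] + 1]))
    return float(grid[valley])


# --------------------------------------------------------------------------
# gated hypothesis tests
# --------------------------------------------------------------------------


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    gate_name: str = ""
    gate_p: float | None = None
    n_per_group: tuple = ()
    alpha: float = 0.05
    pairwise: dict = field(default_factory=dict)  # (i, j) -> adjusted p
    letters: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _f_test_variances(a, b):
    """Two-sided F-test for equality of two variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return np.nan, 1.0
    if vb == 0 or va == 0:
        return np.inf, 0.0
    if va >= vb:
        f, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = min(2 * sps.f.sf(f, dfn, dfd), 1.0)
    return f, p


def compare_two_groups(values_a, values_b, alpha: float = 0.05,
                       gate_alpha: float | None = None) -> TestResult:
    """F-test-gated two-group comparison (unpaired t or Mann-Whitney).

    Similar variances (F-test p >= gate alpha) -> two-tailed unpaired
    t-test; different variances -> two-tailed Mann-Whitney.  Both groups
    constant and equal is reported as p = 1 (no evidence of a difference).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    gate_alpha = alpha if gate_alpha is None else gate_alpha
    f_stat, f_p = _f_test_variances(a, b)
    if np.var(a) == 0 and np.var(b) == 0 and a[0] == b[0]:
        return TestResult("unpaired_t", 0.0, 1.0, "f_test", f_p, (len(a), len(b)), alpha)
    if f_p < gate_alpha:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney"
    else:
        stat, p = sps.ttest_ind(a, b)
        name = "unpaired_t"
    return TestResult(name, float(stat), float(p), "f_test", float(f_p),
                      (len(a), len(b)), alpha)


def compare_multi_groups(groups, alpha: float = 0.05,
                         gate_alpha: float | None = None) -> TestResult:
    """Brown-Forsythe-gated multi-group comparison.

    Similar variances -> one-way ANOVA + Tukey HSD; different variances ->
    Kruskal-Wallis + Dunn's test with Bonferroni adjustment.  Per-pair
    adjusted p-values and a compact letter display (groups sharing a letter
    are not significantly different) are returned.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 3:
        raise ValueError("need >= 3 groups (use compare_two_groups for two)")
    if any(len(g) < 3 for g in gs):
        raise ValueError("each group needs n >= 3")
    gate_alpha = alpha if gate_alpha is None else gate_alpha

    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        pairs = {p: 1.0 for p in itertools.combinations(range(len(gs)), 2)}
        return TestResult("kruskal_wallis", 0.0, 1.0, "brown_forsythe", 1.0,
                          tuple(len(g) for g in gs), alpha, pairs, ["a"] * len(gs))

    bf_stat, bf_p = sps.levene(*gs, center="median")
    if bf_p < gate_alpha:
        h_stat, h_p = sps.kruskal(*gs)
        pairs = dunn_test(gs)
        name = "kruskal_wallis_dunn"
        stat, p = float(h_stat), float(h_p)
    else:
        f_stat, f_p = sps.f_oneway(*gs)
        pairs = _tukey_pairs(gs)
        name = "anova_tukey"
        stat, p = float(f_stat), float(f_p)
    letters = letter_display(len(gs), pairs, alpha)
    return TestResult(name, stat, p, "brown_forsythe", float(bf_p),
                      tuple(len(g) for g in gs), alpha, pairs, letters)


def _tukey_pairs(gs):
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(gs)
    labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(gs)])
    res = pairwise_tukeyhsd(values, labels)
    out = {}
    for (i, j), p in zip(itertools.combinations(range(len(gs)), 2), res.pvalues):
        out[(i, j)] = float(p)
    return out


def dunn_test(groups) -> dict:
    """Dunn's post-hoc z-tests on pooled ranks, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    the tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided p-values
    are multiplied by the number of pairs (capped at 1).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(gs)
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in gs:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(range(len(gs)), 2))
    m = len(pairs)
    out = {}
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
        if se == 0:
            out[(i, j)] = 1.0
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / se
        out[(i, j)] = float(min(2 * sps.norm.sf(abs(z)) * m, 1.0))
    return out


def letter_display(n_groups: int, pairwise_p: dict, alpha: float = 0.05) -> list[str]:
    """Compact letter display: groups sharing a letter are not distinguishable.

    Greedy insert-and-absorb over the non-significance graph: each maximal
    clique of mutually non-different groups gets one letter.
    """
    # insert-and-absorb: start from one class holding every group, split it
    # on each significant pair, then drop classes contained in another
    cliques: list[set] = [set(range(n_groups))]
    for (i, j), p in sorted(pairwise_p.items()):
        if p >= alpha:
            continue
        for c in [c for c in cliques if i in c and j in c]:
            cliques.remove(c)
            cliques.extend([c - {i}, c - {j}])
    uniq: list[set] = []
    for c in cliques:
        if c and not any(c < d for d in cliques) and c not in uniq:
            uniq.append(c)
    cliques = sorted(uniq, key=lambda c: (min(c), -len(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(n_groups)]
    for letter, c in zip(alphabet, cliques):
        for g in sorted(c):
            letters[g] += letter
    return letters


def fold_change_ci(mutant_values, control_values, confidence: float = 0.95):
    """Fold change (ratio of means) with a delta-method CI.

    The estimate is mean(mutant) / mean(control); because both means carry
    sampling error, the CI is built on the log ratio with
    se^2 = se_m^2 / mean_m^2 + se_c^2 / mean_c^2 and exponentiated back.
    Returns ``(fold, (lo, hi))``.
    """
    m = np.asarray(mutant_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if len(m) < 2 or len(c) < 2:
        raise ValueError("need >= 2 values per arm for a fold-change CI")
    mm, cm = m.mean(), c.mean()
    if mm <= 0 or cm <= 0:
        raise ValueError("fold change undefined for non-positive means")
    se_log = np.sqrt(m.var(ddof=1) / (len(m) * mm**2) + c.var(ddof=1) / (len(c) * cm**2))
    t = sps.t.ppf(0.5 + confidence / 2.0, df=len(m) + len(c) - 2)
    fold = mm / cm
    return float(fold), (float(fold * np.exp(-t * se_log)), float(fold * np.exp(t * se_log)))


# --------------------------------------------------------------------------
# clonal composition
# --------------------------------------------------------------------------


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (probability-mass method).

    The p-value sums hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed the observed
    table's.  A zero margin carries no information and returns p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2x2 integer array")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def clone_composition(units_a, units_b) -> np.ndarray:
    """Count fully-mutant vs mixed units per genotype group.

    Each unit is an iterable of per-cell clone labels ("mutant",
    "control", or "unassigned").  A unit is "fully labelled" when every
    cell is mutant; any unlabeled cell makes the unit mixed (warned).
    Returns the 2x2 table [[full_a, mixed_a], [full_b, mixed_b]].
    """
    def count(units):
        full = mixed = 0
        for unit in units:
            labels = list(unit)
            if not labels:
                raise ValueError("empty polar/stalk unit")
            if any(l == "unassigned" for l in labels):
                warnings.warn("unit with unlabeled cell counted as mixed", stacklevel=3)
                mixed += 1
            elif all(l == "mutant" for l in labels):
                full += 1
            else:
                mixed += 1
        return full, mixed

    fa, ma = count(units_a)
    fb, mb = count(units_b)
    return np.array([[fa, ma], [fb, mb]], dtype=int)


def proportion_summary(flags, replicate_ids, group_labels=None):
    """Per-replicate fractions, then across-replicate mean +- sd per group.

    Returns {group: (mean, sd, per-replicate fractions)}; empty replicates
    are excluded with a warning; a group with a single replicate raises.
    """
    flags = np.asarray(flags, dtype=bool)
    reps = np.asarray(replicate_ids)
    groups = np.asarray(group_labels) if group_labels is not None else np.zeros(len(flags), int)
    out = {}
    for g in np.unique(groups):
        fracs = []
        for r in np.unique(reps[groups == g]):
            sel = (groups == g) & (reps == r)
            if sel.sum() == 0:
                warnings.warn(f"group {g}: empty replicate {r} excluded", stacklevel=2)
                continue
            fracs.append(flags[sel].mean())
        if len(fracs) < 2:
            raise ValueError(f"group {g}: need >= 2 replicate samples, have {len(fracs)}")
        fracs = np.asarray(fracs)
        out[g] = (float(fracs.mean()), float(fracs.std(ddof=1)), fracs)
    return out


# --------------------------------------------------------------------------
# Tukey box-plot summary
# --------------------------------------------------------------------------


def tukey_box_stats(values) -> dict:
    """Box-plot summary with Tukey whiskers.

    Quartiles use linear interpolation; whiskers reach the most extreme
    data inside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]; points beyond are outliers.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 1:
        raise ValueError("need at least one value")
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "q1": float(q1), "median": float(q2), "q3": float(q3),
        "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
        "outliers": np.sort(v[(v < lo_fence) | (v > hi_fence)]),
    }
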