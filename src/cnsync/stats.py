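"""Group comparisons and table rendering used throughout the package.

These are thin wrappers over scipy's standard tests — one-way ANOVA with
Tukey's HSD, the two-sample t-test, and Kruskal-Wallis with pairwise
Wilcoxon rank-sum — plus a compact-letter-display (CLD) builder so that
summary tables can carry the usual superscript letters: groups sharing a
letter are not significantly different at the chosen alpha.  A second
letter tier (x, y, ...) can be requested for trends at 0.05 < P < 0.10;
it is off by default.

No multiple-testing correction is applied across metrics: each reported
metric is compared on its own.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

METHODS = ("anova_tukey", "ttest", "kw_wilcoxon")


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Sample mean and standard error (sd with n-1 denominator / sqrt(n))."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("mean_sem needs at least two values")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


@dataclass
class CompareResult:
    """Outcome of a group comparison."""

    method: str
    groups: tuple[str, ...]
    p_global: float
    p_pairwise: dict[tuple[str, str], float]
    letters: dict[str, str]
    secondary_letters: dict[str, str] | None = None

    def distinct_classes(self) -> int:
        """Number of distinct letter patterns (1 means no separation)."""
        return len(set(self.letters.values()))


def _validate_groups(data: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(data) < 2:
        raise ValueError("need at least two groups to compare")
    out = {}
    for name, vals in data.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs at least two values")
        out[str(name)] = arr
    return out


def _cld(order: Sequence[str], significant: set[frozenset[str]],
         alphabet: str = string.ascii_lowercase) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    ``order`` lists groups from highest to lowest mean; each returned
    letter string is sorted so the display is deterministic and invariant
    (up to letter names) under group relabeling.
    """
    columns: list[set[str]] = [set(order)]
    for pair in sorted(significant, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop empties, duplicates, and columns contained in another
        uniq: list[set[str]] = []
        for col in new_columns:
            if col and col not in uniq:
                uniq.append(col)
        columns = [c for c in uniq if not any(c < other for other in uniq)]
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda col: min(rank[g] for g in col) if col else len(order))
    letters: dict[str, list[str]] = {g: [] for g in order}
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


@lru_cache(maxsize=64)
def _tukey_critical_q(alpha: float, k: int, df: int) -> float:
    """Studentized-range critical value (cached; the ppf is expensive)."""
    return float(studentized_range.ppf(1.0 - alpha, k, df))


def _tukey_q_stats(samples: dict[str, np.ndarray]
                   ) -> tuple[dict[tuple[str, str], float], int, int]:
    """Tukey-Kramer studentized-range statistic per pair, plus (k, df)."""
    names = list(samples)
    k = len(names)
    sizes = {n: samples[n].size for n in names}
    df = sum(sizes.values()) - k
    mse = sum((sizes[n] - 1) * samples[n].var(ddof=1) for n in names) / df
    qs = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(mse / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
            qs[(a, b)] = abs(samples[a].mean() - samples[b].mean()) / se
    return qs, k, df


def _pairwise_p(samples: dict[str, np.ndarray], method: str,
                pvalues: bool) -> tuple[float, dict, dict]:
    """Global p, pairwise p-values, and pairwise test statistics.

    For ``anova_tukey`` the returned statistics are studentized-range
    values, which :func:`group_compare` compares against the cached
    critical value — this keeps the 'was this pair significant' decision
    exact while letting callers skip the per-pair p-value integration
    (``pvalues=False``) in tight simulation loops.
    """
    names = list(samples)
    arrays = [samples[n] for n in names]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all observations identical: nothing to separate
        pairs = {(a, b): 1.0 for i, a in enumerate(names) for b in names[i + 1:]}
        return 1.0, pairs, {}
    if all(np.ptp(arr) == 0 for arr in arrays):
        # no within-group variability: groups separate by exact means
        pairs = {
            (a, b): 1.0 if samples[a][0] == samples[b][0] else 0.0
            for i, a in enumerate(names) for b in names[i + 1:]
        }
        return 0.0, pairs, {}

    pairs: dict[tuple[str, str], float] = {}
    if method == "anova_tukey":
        p_global = float(sps.f_oneway(*arrays).pvalue)
        qs, k, df = _tukey_q_stats(samples)
        if pvalues:
            pair_keys = list(qs)
            pvals = studentized_range.sf([qs[p] for p in pair_keys], k, df)
            pairs = {p: float(v) for p, v in zip(pair_keys, pvals)}
        else:
            pairs = {p: np.nan for p in qs}
        return p_global, pairs, qs
    elif method == "ttest":
        if len(names) != 2:
            raise ValueError("ttest requires exactly two groups")
        p_global = float(sps.ttest_ind(*arrays).pvalue)
        pairs[(names[0], names[1])] = p_global
    elif method == "kw_wilcoxon":
        p_global = float(sps.kruskal(*arrays).pvalue)
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                res = sps.mannwhitneyu(arrays[i], arrays[j],
                                       alternative="two-sided")
                pairs[(a, names[j])] = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return p_global, pairs, {}


def group_compare(data: Mapping[str, Sequence[float]],
                  method: str = "anova_tukey", *, alpha: float = 0.05,
                  secondary: bool = False, secondary_alpha: float = 0.10,
                  pvalues: bool = True) -> CompareResult:
    """Compare groups and assign compact letters.

    Parameters
    ----------
    data
        Mapping of group label to numeric values (each group n >= 2).
    method
        ``anova_tukey`` (one-way ANOVA, Tukey HSD pairwise),
        ``ttest`` (two groups), or ``kw_wilcoxon`` (Kruskal-Wallis with
        pairwise two-sided Wilcoxon rank-sum).
    alpha
        Significance level for the primary letter tier (a, b, c ...).
    secondary
        Also emit a trend tier (x, y, ...) separating groups at
        ``secondary_alpha``.
    pvalues
        With ``anova_tukey``, skip the pairwise p-value integrals (the
        letters are unchanged — significance is decided on the
        studentized-range statistic either way).  p_pairwise is NaN.
    """
    samples = _validate_groups(data)
    p_global, pairs, qstats = _pairwise_p(samples, method, pvalues)
    order = sorted(samples, key=lambda g: -samples[g].mean())

    def significant(level: float) -> set[frozenset[str]]:
        if qstats:  # Tukey: exact decision from the critical value
            k = len(samples)
            df = sum(arr.size for arr in samples.values()) - k
            crit = _tukey_critical_q(level, k, df)
            return {frozenset(p) for p, q in qstats.items() if q > crit}
        return {frozenset(p) for p, pv in pairs.items() if pv < level}

    letters = _cld(order, significant(alpha))
    secondary_letters = None
    if secondary:
        secondary_letters = _cld(order, significant(secondary_alpha),
                                 alphabet="xyzuvw")
    return CompareResult(
        method=method,
        groups=tuple(samples),
        p_global=p_global,
        p_pairwise=pairs,
        letters=letters,
        secondary_letters=secondary_letters,
    )


def rate_correlation(rates_a: Sequence[float],
                     rates_b: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation between two aligned rate vectors."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size != b.size:
        raise ValueError("rate vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least three paired rates")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a rate vector; correlation undefined")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def format_mean_sem(mean: float, sem: float, letters: str = "") -> str:
    """``mean ± SEM`` with 3 / 2 significant figures and optional letters."""
    text = f"{mean:.3g} ± {sem:.2g}"
    return f"{text} {letters}".strip()


def render_tables(results: Mapping[str, pd.DataFrame], out_dir,
                  required: Sequence[str] | None = None) -> dict[str, str]:
    """Write each result table as a CSV with deterministic layout.

    ``required`` names tables that must be present; a missing one raises
    ``KeyError`` naming it.  Column order is taken from each frame as
    given, rows are written as-is, and the line terminator is fixed so
    identical inputs produce byte-identical files.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if required:
        for name in required:
            if name not in results:
                raise KeyError(f"missing metric table {name!r}")
    paths: dict[str, str] = {}
    for name in results:
        path = out / f"{name}.csv"
        results[name].to_csv(path, index=False, lineterminator="\n")
        paths[name] = str(path)
    return paths
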