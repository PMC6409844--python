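"""Group-comparison and correlation statistics for concentration panels.

Two classical procedures support the index tables: Pearson correlation
across the element panel (with the two-level 0.05/0.01 significance
flagging used in survey reports) and one-way ANOVA across (site,
compartment) groups followed by Tukey's HSD, summarised as a compact
letter display — groups sharing a letter do not differ significantly.

The F statistic, Tukey p-values and Pearson r/p come from scipy; the
pairing of observations by replicate index, the flagging convention and
the compact-letter merge are defined here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, MissingGroupError
from .panel import Compartment, ConcentrationPanel, normalize_element

#: Flag values used in correlation matrices.
FLAG_NS, FLAG_P05, FLAG_P01, FLAG_NA = "ns", "p05", "p01", "na"


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations over an element panel.

    ``r``, ``p``, ``flags`` and ``n`` are element × element DataFrames;
    undefined pairs (fewer than 3 complete observation pairs, or an element
    with zero variance) carry NaN and the flag ``"na"`` rather than a
    fabricated value.
    """

    elements: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    flags: pd.DataFrame
    n: pd.DataFrame


def _flag(p: float, alpha_levels: tuple[float, float] = (0.05, 0.01)) -> str:
    if not np.isfinite(p):
        return FLAG_NA
    loose, strict = max(alpha_levels), min(alpha_levels)
    if p <= strict:
        return FLAG_P01
    if p <= loose:
        return FLAG_P05
    return FLAG_NS


def pearson_matrix(
    panel: ConcentrationPanel,
    scope: tuple[str, Compartment | str],
    alpha_levels: tuple[float, float] = (0.05, 0.01),
    correction: str = "none",
) -> CorrelationMatrix:
    """Pearson r / two-sided p over all element pairs within one scope.

    Observations are paired by replicate index within the (site,
    compartment) scope.  p-values use the exact t transform with n − 2
    degrees of freedom (via :func:`scipy.stats.pearsonr`).  With
    ``correction="bonferroni"`` p-values are multiplied by the number of
    off-diagonal pairs (capped at 1) before flagging.
    """
    if correction not in ("none", "bonferroni"):
        raise DomainError(f"unknown correction {correction!r}")
    site, comp = scope[0], Compartment(scope[1])
    elements = panel.elements
    # replicate × element table for the scope
    wide: dict[str, dict[int, float]] = {e: {} for e in elements}
    found = False
    for rec in panel:
        if rec.site == site and rec.compartment == comp:
            wide[rec.element][rec.replicate] = rec.value
            found = True
    if not found:
        raise MissingGroupError(
            f"no records for site={site!r}, compartment={comp.value!r}"
        )
    k = len(elements)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i, j in itertools.combinations(range(k), 2):
        xi, xj = wide[elements[i]], wide[elements[j]]
        shared = sorted(set(xi) & set(xj))
        n[i, j] = n[j, i] = len(shared)
        if len(shared) < 3:
            continue
        x = np.array([xi[rep] for rep in shared])
        y = np.array([xj[rep] for rep in shared])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue  # zero variance: r undefined
        res = sps.pearsonr(x, y)
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
    np.fill_diagonal(n, max((len(v) for v in wide.values()), default=0))
    p_flag = p.copy()
    if correction == "bonferroni":
        m = k * (k - 1) // 2
        off = ~np.eye(k, dtype=bool)
        p_flag[off] = np.minimum(1.0, p_flag[off] * m)
    flags = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(k):
            flags[i, j] = _flag(p_flag[i, j], alpha_levels) if i != j else FLAG_P01
    idx = pd.Index(elements, name="element")
    return CorrelationMatrix(
        elements=tuple(elements),
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p_flag, index=idx, columns=idx),
        flags=pd.DataFrame(flags, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


# -- one-way ANOVA with compact letter display ----------------------------

@dataclass
class GroupComparison:
    """One-way ANOVA over (site, compartment) groups for one element."""

    element: str
    groups: tuple[tuple[str, str], ...]
    means: tuple[float, ...]
    anova_F: float
    anova_p: float
    letters: dict[tuple[str, str], str]


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """F statistic and p-value of the standard one-way decomposition.

    Degenerate variance structures are resolved explicitly: all values
    equal → (0, 1); zero within-group variance but distinct means →
    (inf, 0).
    """
    concat = np.concatenate(groups)
    grand = concat.mean()
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def compact_letter_display(
    means: Sequence[float], significant: np.ndarray
) -> list[str]:
    """Letter labels from a pairwise significance matrix.

    Groups are ranked by descending mean; every maximal run of consecutive
    ranks whose members are all pairwise non-significant receives one
    letter, assigned in rank order (so the highest-mean group always
    carries "a").  Significantly different pairs never share a letter.
    """
    k = len(means)
    order = sorted(range(k), key=lambda i: -means[i])
    intervals: list[tuple[int, int]] = []
    for start in range(k):
        end = start
        while end + 1 < k and all(
            not significant[order[a], order[b]]
            for a in range(start, end + 2)
            for b in range(a + 1, end + 2)
        ):
            end += 1
        intervals.append((start, end))
    # keep maximal intervals only
    maximal = [
        (s, e)
        for s, e in intervals
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in intervals)
    ]
    maximal.sort()
    letters_by_rank = ["" for _ in range(k)]
    for letter_idx, (s, e) in enumerate(maximal):
        letter = chr(ord("a") + letter_idx)
        for rank in range(s, e + 1):
            letters_by_rank[rank] += letter
    out = ["" for _ in range(k)]
    for rank, grp in enumerate(order):
        out[grp] = letters_by_rank[rank]
    return out


def one_way_anova_letters(
    panel: ConcentrationPanel, element: str, alpha: float = 0.05
) -> GroupComparison:
    """ANOVA across all (site, compartment) groups of one element, with letters.

    Pairwise comparisons use Tukey's HSD at ``alpha``; every group needs at
    least two replicates, and at least two groups must be present.
    """
    element = normalize_element(element)
    group_keys: list[tuple[str, str]] = []
    for site in panel.sites:
        for comp in panel.compartments:
            try:
                panel.values_for(site, comp, element)
            except MissingGroupError:
                continue
            group_keys.append((site, comp.value))
    if len(group_keys) < 2:
        raise DomainError(f"need >= 2 groups for ANOVA on {element!r}")
    values = []
    for key in group_keys:
        v = panel.values_for(key[0], key[1], element)
        if len(v) < 2:
            raise DomainError(
                f"group (site={key[0]!r}, compartment={key[1]!r}) has fewer than "
                f"2 replicates for {element!r}"
            )
        values.append(v)
    means = [float(v.mean()) for v in values]
    f, p = anova_oneway(values)
    k = len(values)
    significant = np.zeros((k, k), dtype=bool)
    if math.isinf(f):
        # no within-group noise: any mean difference is significant
        for i, j in itertools.combinations(range(k), 2):
            significant[i, j] = significant[j, i] = means[i] != means[j]
    elif f > 0:
        hsd = sps.tukey_hsd(*values)
        for i, j in itertools.combinations(range(k), 2):
            sig = hsd.pvalue[i, j] <= alpha
            significant[i, j] = significant[j, i] = sig
    letters = compact_letter_display(means, significant)
    return GroupComparison(
        element=element,
        groups=tuple(group_keys),
        means=tuple(means),
        anova_F=f,
        anova_p=p,
        letters={key: letters[i] for i, key in enumerate(group_keys)},
    )
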