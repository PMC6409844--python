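"""Contamination and bioaccumulation indices.

The four indices used to grade heavy-metal burden at a surveyed site and
the soil-to-organism transfer:

* contamination factor  CF = C_metal / C_background  (per site, per element,
  on soil concentrations),
* pollution load index  PLI = (CF_1 · CF_2 · … · CF_n)^(1/n), the geometric
  mean of a site's contamination factors,
* degree of contamination  DC = Σ CF_i, with category bands proportional to
  the number of elements n,
* bioconcentration factor  BCF = C_biota / C_soil, with BCF ≥ 1 read as
  bioaccumulation,

plus the between-site concentration ratio for the biota compartment.
Classification bands follow the standard sediment-quality conventions; the
open boundaries of the published CF bands are resolved as half-open
intervals closed on the left ([1,3), [3,6), [6,∞)) so that classification
is total and deterministic; the BCF rule is inclusive (≥ 1) and PLI exactly
1 is "baseline".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .panel import BackgroundTable, Compartment, ConcentrationPanel

logger = logging.getLogger(__name__)


class CFCategory(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    CONSIDERABLE = "considerable"
    VERY_HIGH = "very_high"


class PLICategory(str, Enum):
    PERFECTION = "perfection"
    BASELINE = "baseline"
    DETERIORATED = "deteriorated"


class DCCategory(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    CONSIDERABLE = "considerable"
    VERY_HIGH = "very_high"


# -- scalar operations -----------------------------------------------------

def contamination_factor(c_metal: float, c_background: float) -> float:
    """CF = C_metal / C_background (both mg/g dry weight)."""
    if not c_background > 0:
        raise DomainError(f"background concentration must be > 0, got {c_background!r}")
    if c_metal < 0:
        raise DomainError(f"metal concentration must be >= 0, got {c_metal!r}")
    return c_metal / c_background


def classify_cf(cf: float) -> CFCategory:
    """Contamination-factor category: <1 low, [1,3) moderate, [3,6) considerable, ≥6 very high."""
    if cf < 0:
        raise DomainError(f"CF must be >= 0, got {cf!r}")
    if cf < 1:
        return CFCategory.LOW
    if cf < 3:
        return CFCategory.MODERATE
    if cf < 6:
        return CFCategory.CONSIDERABLE
    return CFCategory.VERY_HIGH


def classify_cf_two_way(cf: float) -> str:
    """Coarse split sometimes used in reporting: "moderate" (CF < 3) vs "high" (CF ≥ 3)."""
    return "high" if classify_cf(cf) in (CFCategory.CONSIDERABLE, CFCategory.VERY_HIGH) else "moderate"


def pollution_load_index(cfs: Sequence[float]) -> float:
    """Geometric mean of contamination factors, computed in log space.

    Any zero CF drives the index to 0 (the geometric-mean limit); an empty
    list is a domain error.
    """
    if len(cfs) == 0:
        raise DomainError("PLI needs at least one contamination factor")
    arr = np.asarray(cfs, dtype=float)
    if np.any(arr < 0):
        raise DomainError("contamination factors must be >= 0")
    if np.any(arr == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(arr))))


def classify_pli(pli: float) -> PLICategory:
    """0 → perfection; (0, 1] → baseline; > 1 → progressive deterioration."""
    if pli < 0:
        raise DomainError(f"PLI must be >= 0, got {pli!r}")
    if pli == 0:
        return PLICategory.PERFECTION
    if pli <= 1:
        return PLICategory.BASELINE
    return PLICategory.DETERIORATED


def classify_dc(dc: float, n: int) -> DCCategory:
    """DC bands scale with the element count n: <n, [n,2n), [2n,4n), ≥4n."""
    if n < 1:
        raise DomainError(f"element count must be >= 1, got {n!r}")
    if dc < 0:
        raise DomainError(f"DC must be >= 0, got {dc!r}")
    if dc < n:
        return DCCategory.LOW
    if dc < 2 * n:
        return DCCategory.MODERATE
    if dc < 4 * n:
        return DCCategory.CONSIDERABLE
    return DCCategory.VERY_HIGH


def degree_of_contamination(cfs: Sequence[float]) -> tuple[float, DCCategory]:
    """Sum of a site's contamination factors and its category."""
    if len(cfs) == 0:
        raise DomainError("DC needs at least one contamination factor")
    arr = np.asarray(cfs, dtype=float)
    if np.any(arr < 0):
        raise DomainError("contamination factors must be >= 0")
    dc = float(np.sum(arr))
    return dc, classify_dc(dc, len(arr))


def bioconcentration_factor(c_biota: float, c_soil: float) -> tuple[float, bool]:
    """BCF = C_biota / C_soil; bioaccumulation when BCF ≥ 1."""
    if not c_soil > 0:
        raise DomainError(f"soil concentration must be > 0, got {c_soil!r}")
    if c_biota < 0:
        raise DomainError(f"biota concentration must be >= 0, got {c_biota!r}")
    bcf = c_biota / c_soil
    return bcf, bcf >= 1.0


def site_ratio(c_site1: float, c_site2: float) -> float:
    """Concentration ratio between two sites (site 1 over site 2)."""
    if not c_site2 > 0:
        raise DomainError(f"denominator concentration must be > 0, got {c_site2!r}")
    return c_site1 / c_site2


# -- whole-panel report ----------------------------------------------------

@dataclass
class IndexReport:
    """All indices for one survey; the in-memory form of the index tables.

    Attributes
    ----------
    cf:
        DataFrame ``site, element, cf, cf_category`` (soil compartment).
    site_summary:
        DataFrame ``site, n_elements, pli, pli_category, dc, dc_category``.
    bcf:
        DataFrame ``site, element, bcf, bioaccumulating``.
    ratio:
        DataFrame ``element, ratio`` of biota concentrations between
        ``ratio_pair`` (empty when no pair applies).
    warnings:
        Human-readable notes about skipped cells (missing background,
        zero soil concentration...).
    """

    cf: pd.DataFrame
    site_summary: pd.DataFrame
    bcf: pd.DataFrame
    ratio: pd.DataFrame
    ratio_pair: tuple[str, str] | None = None
    warnings: list[str] = field(default_factory=list)


def build_index_report(
    panel: ConcentrationPanel,
    background: BackgroundTable,
    ratio_pair: tuple[str, str] | None = None,
) -> IndexReport:
    """Compute CF/PLI/DC (soil), BCF and the between-site biota ratio.

    Group means over replicates are used throughout (the survey convention
    when replicates exist).  Elements missing from the background table are
    skipped for CF/PLI/DC with a logged warning; per-site PLI and DC are
    aggregated over the covered elements only.  When ``ratio_pair`` is
    omitted and the panel holds exactly two sites, they are used in panel
    order.
    """
    warnings: list[str] = []
    means = panel.means().set_index(["site", "compartment", "element"])["mean"]
    sites = panel.sites
    has_soil = Compartment.SOIL in panel.compartments
    has_biota = Compartment.BIOTA in panel.compartments

    cf_rows, summary_rows = [], []
    if has_soil:
        for site in sites:
            cfs = []
            for elem in panel.elements:
                if (site, "soil", elem) not in means.index:
                    continue
                if elem not in background:
                    msg = f"no background for {elem}; CF skipped at {site}"
                    if msg not in warnings:
                        warnings.append(msg)
                        logger.warning(msg)
                    continue
                cf = contamination_factor(
                    means[(site, "soil", elem)], background[elem]
                )
                cfs.append(cf)
                cf_rows.append(
                    {
                        "site": site,
                        "element": elem,
                        "cf": cf,
                        "cf_category": classify_cf(cf).value,
                    }
                )
            if cfs:
                pli = pollution_load_index(cfs)
                dc, dc_cat = degree_of_contamination(cfs)
                summary_rows.append(
                    {
                        "site": site,
                        "n_elements": len(cfs),
                        "pli": pli,
                        "pli_category": classify_pli(pli).value,
                        "dc": dc,
                        "dc_category": dc_cat.value,
                    }
                )
            else:
                warnings.append(f"no background coverage at {site}; PLI/DC skipped")
    else:
        warnings.append("panel has no soil compartment; CF/PLI/DC skipped")

    bcf_rows = []
    if has_soil and has_biota:
        for site in sites:
            if (site, "biota", panel.elements[0]) not in means.index or (
                site,
                "soil",
                panel.elements[0],
            ) not in means.index:
                warnings.append(f"site {site} lacks a compartment; BCF skipped there")
                continue
            for elem in panel.elements:
                c_soil = means[(site, "soil", elem)]
                c_biota = means[(site, "biota", elem)]
                if c_soil <= 0:
                    msg = f"soil mean for {elem} at {site} is 0; BCF undefined"
                    warnings.append(msg)
                    logger.warning(msg)
                    continue
                bcf, accumulating = bioconcentration_factor(c_biota, c_soil)
                bcf_rows.append(
                    {
                        "site": site,
                        "element": elem,
                        "bcf": bcf,
                        "bioaccumulating": accumulating,
                    }
                )
    else:
        warnings.append("panel lacks a compartment; BCF skipped")

    ratio_rows = []
    if ratio_pair is None and len(sites) == 2 and has_biota:
        ratio_pair = (sites[0], sites[1])
    if ratio_pair is not None and has_biota:
        s1, s2 = ratio_pair
        for elem in panel.elements:
            if (s1, "biota", elem) not in means.index or (s2, "biota", elem) not in means.index:
                warnings.append(f"biota data missing for {elem}; ratio skipped")
                continue
            c2 = means[(s2, "biota", elem)]
            if c2 <= 0:
                warnings.append(f"biota mean for {elem} at {s2} is 0; ratio undefined")
                continue
            ratio_rows.append(
                {"element": elem, "ratio": site_ratio(means[(s1, "biota", elem)], c2)}
            )

    return IndexReport(
        cf=pd.DataFrame(cf_rows, columns=["site", "element", "cf", "cf_category"]),
        site_summary=pd.DataFrame(
            summary_rows,
            columns=["site", "n_elements", "pli", "pli_category", "dc", "dc_category"],
        ),
        bcf=pd.DataFrame(bcf_rows, columns=["site", "element", "bcf", "bioaccumulating"]),
        ratio=pd.DataFrame(ratio_rows, columns=["element", "ratio"]),
        ratio_pair=ratio_pair,
        warnings=warnings,
    )
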