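"""Packaged data: the printed survey tables and related helpers.

The harvester-termite survey printed four data tables for its 16-element
panel at two Saudi sites (Site I, Riyadh; Site II, Taif): per-group mean ±
SE concentrations, the CF/PLI/DC index table, and the BCF / between-site
ratio table.  Replicate-level data were never published, so the
concentration fixture stores each printed mean as a single ``replicate=1``
record and the SEs as side metadata; the printed index tables are display
fixtures for comparison, not recomputation inputs (their background
concentrations were not published either).

Six of the sixteen printed BCF/ratio rows are arithmetically inconsistent
with the printed means; :data:`CONSISTENT_RATIO_ELEMENTS` and
:data:`CONSISTENT_BCF_CELLS` list the cells that do recompute.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from . import io as _io
from .panel import DEFAULT_PANEL, BackgroundTable, ConcentrationPanel
from .synthetic import SyntheticConfig

#: Elements whose printed between-site termite ratio recomputes from the
#: printed termite means (the remaining six rows carry transcription errors).
CONSISTENT_RATIO_ELEMENTS: tuple[str, ...] = (
    "Be", "Ba", "Ca", "Cr", "Cu", "Mg", "Ni", "Pb", "V", "Zn",
)

#: (element, site) BCF cells verified consistent with the printed means.
CONSISTENT_BCF_CELLS: tuple[tuple[str, str], ...] = (("Pb", "Site I"),)

SITE_I, SITE_II = "Site I", "Site II"


def _data_path(name: str):
    return resources.files("bioload").joinpath("data", name)


def table2_panel() -> ConcentrationPanel:
    """The printed mean concentrations as a 64-record panel (replicate=1)."""
    with resources.as_file(_data_path("table2_concentrations.csv")) as p:
        return _io.read_concentrations(p, panel=DEFAULT_PANEL)


def table2_se() -> pd.DataFrame:
    """Printed standard errors: columns site, compartment, element, se_mg_per_g."""
    with resources.as_file(_data_path("table2_se.csv")) as p:
        return pd.read_csv(p)


def table3_display() -> pd.DataFrame:
    """The printed CF/PLI/DC table (display only; not recomputable)."""
    with resources.as_file(_data_path("table3_indices.csv")) as p:
        return pd.read_csv(p)


def table4_bcf_ratio() -> pd.DataFrame:
    """The printed BCF and between-site ratio table, indexed by element."""
    with resources.as_file(_data_path("table4_bcf_ratio.csv")) as p:
        return pd.read_csv(p).set_index("element")


def unit_background() -> BackgroundTable:
    """All-ones background table (CF equals the raw concentration).

    The survey's true background concentrations were never published;
    this placeholder keeps the CF/PLI/DC machinery runnable and clearly
    labelled as not the survey's values.
    """
    with resources.as_file(_data_path("unit_background.csv")) as p:
        return _io.read_background(p)


def study_config(
    dispersion: float = 0.3, n_replicates: int = 3, seed: int = 0
) -> SyntheticConfig:
    """Synthetic-data config emulating the surveyed study conditions.

    Soil medians are the printed Site I soil means; enrichment factors are
    the printed Site I BCF column; the Site II effect is the geometric mean
    of the printed soil Site II / Site I concentration ratios, giving the
    two-site, two-compartment, 16-element layout of the survey.  The
    default log-scale dispersion of 0.3 sits in the middle of the printed
    SE/mean range at three replicates per group, the package's reading of
    the survey's per-colony analytical replication.
    """
    means = table2_panel().means().set_index(["site", "compartment", "element"])["mean"]
    soil_median = {e: means[(SITE_I, "soil", e)] for e in DEFAULT_PANEL}
    bcf1 = table4_bcf_ratio()["bcf_site1"]
    enrichment = {e: float(bcf1[e]) for e in DEFAULT_PANEL}
    ratios = [means[(SITE_II, "soil", e)] / means[(SITE_I, "soil", e)] for e in DEFAULT_PANEL]
    site2 = float(np.exp(np.mean(np.log(ratios))))
    return SyntheticConfig(
        elements=DEFAULT_PANEL,
        soil_median=soil_median,
        enrichment=enrichment,
        site_effect={SITE_I: 1.0, SITE_II: site2},
        dispersion=dispersion,
        n_replicates=n_replicates,
        seed=seed,
    )


def synthetic_reference_standin(seed: int = 1_2_3) -> str:
    """SYNTHETIC stand-in for the deposited 12S rRNA barcode sequence.

    This is NOT the deposited GenBank sequence — only its two printed
    summary statistics are matched: length 407 bases with 139 G+C
    (34.15% GC, the printed 34.2% at that length's resolution).  The bases
    are a seeded random permutation and carry no biological signal; use the
    real accession FASTA wherever sequence content matters.
    """
    rng = np.random.default_rng(seed)
    n, gc = 407, 139
    bases = np.array(["G"] * (gc // 2) + ["C"] * (gc - gc // 2)
                     + ["A"] * ((n - gc) // 2) + ["T"] * (n - gc - (n - gc) // 2))
    return "".join(rng.permutation(bases))
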