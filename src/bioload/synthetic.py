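"""Synthetic concentration panels with the structure the analysis assumes.

Concentrations are generated from a multiplicative lognormal model:

    value(site s, compartment k, element e, replicate) =
        soil_median[e] · site_effect[s] · enrichment[e]^{[k = biota]} · exp(z)

with z drawn from a multivariate normal whose covariance is
diag(σ) · R · diag(σ) for per-element log-scale dispersions σ and a target
log-scale correlation matrix R.  Under this model every survey statistic is
well defined: the configured ``enrichment`` is the true bioconcentration
factor (biota/soil ratio), ``site_effect`` a pure between-site fold change
that cancels out of BCF, and R the correlation that the Pearson screening
should recover on log concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, MissingGroupError
from .panel import Compartment, ConcentrationPanel, ConcentrationRecord


def _per_element(
    value: float | Mapping[str, float] | Sequence[float],
    elements: tuple[str, ...],
    name: str,
) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(elements) - set(value)
        if missing:
            raise ConfigError(f"{name} missing for elements {sorted(missing)}")
        return {e: float(value[e]) for e in elements}
    if np.isscalar(value):
        return {e: float(value) for e in elements}
    seq = list(value)
    if len(seq) != len(elements):
        raise ConfigError(f"{name} has length {len(seq)}, expected {len(elements)}")
    return {e: float(v) for e, v in zip(elements, seq)}


@dataclass
class SyntheticConfig:
    """Generative parameters for :func:`generate_panel`.

    Parameters
    ----------
    elements:
        Ordered element panel.
    soil_median:
        Per-element median soil concentration at a site with unit site
        effect, mg/g dry weight (scalar broadcast allowed).
    enrichment:
        Per-element true biota/soil factor (the generative BCF).
    site_effect:
        Ordered mapping site label → multiplicative factor applied to both
        compartments.
    dispersion:
        Per-element lognormal σ on the natural-log scale.
    correlation:
        Element × element target correlation of log concentrations
        (``None`` → identity).  Must be symmetric PSD with unit diagonal.
    n_replicates:
        Replicates per (site, compartment, element) group.
    seed:
        Seed for the deterministic random stream.
    """

    elements: tuple[str, ...]
    soil_median: Mapping[str, float] | Sequence[float] | float
    enrichment: Mapping[str, float] | Sequence[float] | float
    site_effect: Mapping[str, float] = field(
        default_factory=lambda: {"Site I": 1.0, "Site II": 1.0}
    )
    dispersion: Mapping[str, float] | Sequence[float] | float = 0.3
    correlation: np.ndarray | None = None
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        self.elements = tuple(self.elements)
        if not self.elements:
            raise ConfigError("element panel is empty")
        self.soil_median = _per_element(self.soil_median, self.elements, "soil_median")
        self.enrichment = _per_element(self.enrichment, self.elements, "enrichment")
        self.dispersion = _per_element(self.dispersion, self.elements, "dispersion")
        if any(v <= 0 for v in self.soil_median.values()):
            raise ConfigError("soil_median must be > 0")
        if any(v < 0 for v in self.enrichment.values()):
            raise ConfigError("enrichment must be >= 0")
        if any(v < 0 for v in self.dispersion.values()):
            raise ConfigError("dispersion must be >= 0")
        self.site_effect = {str(s): float(v) for s, v in dict(self.site_effect).items()}
        if any(v <= 0 for v in self.site_effect.values()):
            raise ConfigError("site_effect must be > 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            k = len(self.elements)
            if c.shape != (k, k):
                raise ConfigError(f"correlation must be {k}x{k}, got {c.shape}")
            if not np.allclose(c, c.T, atol=1e-10):
                raise ConfigError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-10):
                raise ConfigError("correlation matrix must have unit diagonal")
            if np.min(np.linalg.eigvalsh((c + c.T) / 2)) < -1e-10:
                raise ConfigError("correlation matrix must be positive semi-definite")
            self.correlation = c


def generate_panel(config: SyntheticConfig) -> ConcentrationPanel:
    """Draw a concentration panel from the lognormal model; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    k = len(config.elements)
    sigma = np.array([config.dispersion[e] for e in config.elements])
    corr = np.eye(k) if config.correlation is None else config.correlation
    cov = np.outer(sigma, sigma) * corr
    records: list[ConcentrationRecord] = []
    for site, s_eff in config.site_effect.items():
        for comp in (Compartment.SOIL, Compartment.BIOTA):
            z = rng.multivariate_normal(np.zeros(k), cov, size=config.n_replicates)
            for rep in range(config.n_replicates):
                for idx, elem in enumerate(config.elements):
                    base = config.soil_median[elem] * s_eff
                    if comp is Compartment.BIOTA:
                        base *= config.enrichment[elem]
                    records.append(
                        ConcentrationRecord(
                            site, comp, elem, rep + 1, base * np.exp(z[rep, idx])
                        )
                    )
    return ConcentrationPanel(records, panel=config.elements)


def recover_parameters(panel: ConcentrationPanel) -> pd.DataFrame:
    """Estimate per-element enrichment and log-scale dispersion from a panel.

    Enrichment is the ratio of geometric means, biota over soil, pooled
    across sites (a shared site effect cancels in the ratio); dispersion is
    the pooled within-group standard deviation of log concentrations.
    Zero values are excluded from the geometric means.

    Returns a DataFrame indexed by element with columns ``enrichment`` and
    ``dispersion``.
    """
    comps = set(panel.compartments)
    for needed in (Compartment.SOIL, Compartment.BIOTA):
        if needed not in comps:
            raise MissingGroupError(f"panel lacks the {needed.value!r} compartment")
    rows = {}
    frame = panel.to_frame()
    for elem in panel.elements:
        sub = frame[frame["element"] == elem]
        logs = {}
        for comp in ("soil", "biota"):
            vals = sub.loc[sub["compartment"] == comp, "value"].to_numpy()
            vals = vals[vals > 0]
            logs[comp] = np.log(vals)
        enrich = float(np.exp(np.mean(logs["biota"]) - np.mean(logs["soil"])))
        # pooled within-(site, compartment) variance of log values
        ss, dof = 0.0, 0
        for (_, _), grp in sub.groupby(["site", "compartment"]):
            v = grp["value"].to_numpy()
            v = np.log(v[v > 0])
            if len(v) >= 2:
                ss += float(np.sum((v - v.mean()) ** 2))
                dof += len(v) - 1
        rows[elem] = {
            "enrichment": enrich,
            "dispersion": float(np.sqrt(ss / dof)) if dof else 0.0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").loc[list(panel.elements)]
    out.index.name = "element"
    return out
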