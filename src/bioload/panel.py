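"""Domain containers for element-concentration surveys.

A survey measures a panel of elements in several compartments (bulk soil and
biota tissue) at one or more sites, with one value per analytical replicate,
all in mg/g dry weight.  :class:`ConcentrationPanel` is the tidy in-memory
form of such a table; :class:`BackgroundTable` holds the per-element
reference (background) concentrations that contamination factors are
computed against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, MissingGroupError, SchemaError

#: The 16-element panel used throughout the harvester-termite survey.
DEFAULT_PANEL: tuple[str, ...] = (
    "Al", "Be", "Ba", "Ca", "Cd", "Co", "Cr", "Cu",
    "Fe", "Mg", "Mn", "Mo", "Ni", "Pb", "V", "Zn",
)


class Compartment(str, Enum):
    """Where a sample was taken: bulk soil or organism tissue."""

    SOIL = "soil"
    BIOTA = "biota"


def normalize_element(symbol: str) -> str:
    """Normalize an element symbol to canonical case (``"AL"`` → ``"Al"``)."""
    s = symbol.strip()
    if not s:
        raise SchemaError("empty element symbol")
    return s[0].upper() + s[1:].lower()


@dataclass(frozen=True)
class ConcentrationRecord:
    """One measured concentration (mg/g dry weight)."""

    site: str
    compartment: Compartment
    element: str
    replicate: int
    value: float

    def __post_init__(self):
        object.__setattr__(self, "compartment", Compartment(self.compartment))
        object.__setattr__(self, "element", normalize_element(self.element))
        object.__setattr__(self, "value", float(self.value))
        if not math.isfinite(self.value) or self.value < 0:
            raise DomainError(
                f"concentration must be finite and >= 0, got {self.value!r} "
                f"({self.site}/{self.compartment.value}/{self.element})"
            )
        if int(self.replicate) != self.replicate or self.replicate < 1:
            raise DomainError(f"replicate must be an integer >= 1, got {self.replicate!r}")
        object.__setattr__(self, "replicate", int(self.replicate))


class ConcentrationPanel:
    """A collection of :class:`ConcentrationRecord` over a fixed element panel.

    Every (site, compartment) group must cover the same ordered element
    panel; group summaries (mean, SE over replicates) are available through
    :meth:`group_mean_se` and :meth:`means`.

    Parameters
    ----------
    records:
        Iterable of records (or ``(site, compartment, element, replicate,
        value)`` tuples).
    panel:
        Declared ordered element panel.  If omitted it is inferred from the
        records in order of first appearance; if given, every record's
        element must belong to it.
    """

    def __init__(
        self,
        records: Iterable[ConcentrationRecord | tuple],
        panel: Iterable[str] | None = None,
    ):
        recs = [
            r if isinstance(r, ConcentrationRecord) else ConcentrationRecord(*r)
            for r in records
        ]
        if not recs:
            raise SchemaError("a ConcentrationPanel needs at least one record")
        if panel is None:
            seen: dict[str, None] = {}
            for r in recs:
                seen.setdefault(r.element, None)
            self.panel = tuple(seen)
        else:
            self.panel = tuple(normalize_element(e) for e in panel)
            extra = {r.element for r in recs} - set(self.panel)
            if extra:
                raise SchemaError(
                    f"elements outside the declared panel: {sorted(extra)}"
                )
        self.records = tuple(recs)
        self._validate()

    def _validate(self) -> None:
        keys = set()
        for r in self.records:
            key = (r.site, r.compartment, r.element, r.replicate)
            if key in keys:
                raise SchemaError(f"duplicate record for {key}")
            keys.add(key)
        coverage: dict[tuple[str, Compartment], set[str]] = {}
        for r in self.records:
            coverage.setdefault((r.site, r.compartment), set()).add(r.element)
        panels = {frozenset(v) for v in coverage.values()}
        if len(panels) > 1:
            raise SchemaError(
                "every (site, compartment) group must cover the same element panel"
            )

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ConcentrationRecord]:
        return iter(self.records)

    @property
    def sites(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.site, None)
        return tuple(seen)

    @property
    def compartments(self) -> tuple[Compartment, ...]:
        seen: dict[Compartment, None] = {}
        for r in self.records:
            seen.setdefault(r.compartment, None)
        return tuple(seen)

    @property
    def elements(self) -> tuple[str, ...]:
        return self.panel

    def to_frame(self) -> pd.DataFrame:
        """Tidy DataFrame with columns site, compartment, element, replicate, value."""
        return pd.DataFrame(
            {
                "site": [r.site for r in self.records],
                "compartment": [r.compartment.value for r in self.records],
                "element": [r.element for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "value": [r.value for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, panel: Iterable[str] | None = None) -> "ConcentrationPanel":
        required = {"site", "compartment", "element", "replicate", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"frame is missing columns: {sorted(missing)}")
        records = [
            ConcentrationRecord(
                row.site, row.compartment, row.element, row.replicate, row.value
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(records, panel=panel)

    def values_for(
        self, site: str, compartment: Compartment | str, element: str
    ) -> np.ndarray:
        """Replicate values for one group, ordered by replicate index."""
        comp = Compartment(compartment)
        elem = normalize_element(element)
        vals = sorted(
            (r.replicate, r.value)
            for r in self.records
            if r.site == site and r.compartment == comp and r.element == elem
        )
        if not vals:
            raise MissingGroupError(
                f"no records for site={site!r}, compartment={comp.value!r}, "
                f"element={elem!r}"
            )
        return np.array([v for _, v in vals], dtype=float)

    def group_mean_se(
        self, site: str, compartment: Compartment | str, element: str
    ) -> tuple[float, float | None]:
        """Mean and standard error over replicates of one group.

        The SE (sample standard deviation over √n) is only defined for
        groups with at least two replicates; otherwise ``None`` is returned
        in its place.
        """
        vals = self.values_for(site, compartment, element)
        mean = float(np.mean(vals))
        if len(vals) < 2:
            return mean, None
        se = float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
        return mean, se

    def means(self) -> pd.DataFrame:
        """Per-group summaries: one row per (site, compartment, element).

        Columns ``n``, ``mean`` and ``se`` (NaN where fewer than two
        replicates). Row order follows sites/compartments by first
        appearance and elements by panel order.
        """
        rows = []
        present = {(r.site, r.compartment) for r in self.records}
        for site in self.sites:
            for comp in self.compartments:
                if (site, comp) not in present:
                    continue
                for elem in self.panel:
                    vals = self.values_for(site, comp, elem)
                    mean, se = self.group_mean_se(site, comp, elem)
                    rows.append(
                        {
                            "site": site,
                            "compartment": comp.value,
                            "element": elem,
                            "n": len(vals),
                            "mean": mean,
                            "se": np.nan if se is None else se,
                        }
                    )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BackgroundTable:
    """Per-element background (reference) concentrations, mg/g dry weight."""

    backgrounds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for elem, value in dict(self.backgrounds).items():
            v = float(value)
            if not math.isfinite(v) or v <= 0:
                raise DomainError(
                    f"background for {elem!r} must be finite and > 0, got {value!r}"
                )
            clean[normalize_element(elem)] = v
        object.__setattr__(self, "backgrounds", clean)

    def __contains__(self, element: str) -> bool:
        return normalize_element(element) in self.backgrounds

    def __getitem__(self, element: str) -> float:
        return self.backgrounds[normalize_element(element)]

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self.backgrounds)
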