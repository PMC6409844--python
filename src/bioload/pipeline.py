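"""End-to-end reporting pipeline: ingest → indices → statistics → tables.

One validated :class:`RunConfig` drives a reproducible run that mirrors the
survey's printed tables: a mean ± SE concentration summary (with compact
significance letters when replicates permit), the CF/PLI/DC table, the
BCF/ratio table, per-scope correlation matrices, and a machine-readable
JSON summary.  Every output carries the configuration hash and seed, and
re-running an identical configuration is byte-stable (floats are printed
at 4 decimals in the CSVs; the JSON keeps full precision).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DomainError, MissingGroupError
from .indices import build_index_report
from .io import read_background, read_concentrations
from .stats import one_way_anova_letters, pearson_matrix

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.4f"


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    concentrations: Path
    background: Path
    out_dir: Path
    site_ratio: tuple[str, str] | None = None
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    correction: str = "none"
    panel: tuple[str, ...] | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        self.concentrations = Path(self.concentrations)
        self.background = Path(self.background)
        self.out_dir = Path(self.out_dir)
        for p in (self.concentrations, self.background):
            if not p.is_file():
                raise ConfigError(f"input file not found: {p}")
        if self.correction not in ("none", "bonferroni"):
            raise ConfigError(f"unknown correction {self.correction!r}")
        if isinstance(self.site_ratio, str):
            parts = self.site_ratio.split(":")
            if len(parts) != 2:
                raise ConfigError("site_ratio must look like 'Site A:Site B'")
            self.site_ratio = (parts[0].strip(), parts[1].strip())
        self.alpha_levels = tuple(float(a) for a in self.alpha_levels)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"run config {path} must be a mapping")
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the configuration (first 12 hex digits of SHA-256)."""
        # out_dir and log level are excluded: they do not change the analysis
        payload = {
            "concentrations": str(self.concentrations),
            "background": str(self.background),
            "site_ratio": self.site_ratio,
            "alpha_levels": self.alpha_levels,
            "correction": self.correction,
            "panel": self.panel,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(frame: pd.DataFrame, path: Path, stamp: str) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {stamp}\n")
        frame.to_csv(fh, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute a full run; returns the JSON-summary dict (also written to disk).

    Raises the underlying error (annotated with the failing stage in the
    log) so callers can map it to an exit status.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    log_path = config.out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("bioload")
    root.addHandler(handler)
    root.setLevel(config.log_level.upper())
    stamp = f"bioload {__version__} config={config.digest()} seed={config.seed}"
    stage = "ingest"
    try:
        panel = read_concentrations(config.concentrations, panel=config.panel)
        background = read_background(config.background)

        stage = "summary"
        summary = panel.means()
        letters_col = []
        letter_cache: dict[str, dict[tuple[str, str], str]] = {}
        for row in summary.itertuples(index=False):
            letters = ""
            elem = row.element
            if elem not in letter_cache:
                try:
                    cmp_res = one_way_anova_letters(
                        panel, elem, alpha=max(config.alpha_levels)
                    )
                    letter_cache[elem] = cmp_res.letters
                except (DomainError, MissingGroupError):
                    letter_cache[elem] = {}
            letters = letter_cache[elem].get((row.site, row.compartment), "")
            letters_col.append(letters)
        summary = summary.assign(letters=letters_col)
        _write_csv(summary, config.out_dir / "summary_concentrations.csv", stamp)

        stage = "indices"
        report = build_index_report(panel, background, ratio_pair=config.site_ratio)
        cf = report.cf.merge(report.site_summary, on="site", how="left")
        cf = cf[
            ["site", "element", "cf", "cf_category", "pli", "pli_category",
             "dc", "dc_category"]
        ]
        _write_csv(cf, config.out_dir / "indices_cf_pli_dc.csv", stamp)
        bcf_wide = report.bcf.pivot(index="element", columns="site", values="bcf")
        bcf_wide = bcf_wide.reindex(panel.elements)
        bcf_wide.columns = [f"bcf_{c}" for c in bcf_wide.columns]
        if not report.ratio.empty:
            bcf_wide = bcf_wide.join(report.ratio.set_index("element"))
        _write_csv(
            bcf_wide.reset_index(), config.out_dir / "bcf_ratio.csv", stamp
        )

        stage = "stats"
        n_by_scope: dict[tuple[str, str], int] = {}
        for rec in panel:
            key = (rec.site, rec.compartment.value)
            n_by_scope[key] = max(n_by_scope.get(key, 0), rec.replicate)
        correlations = []
        for (site, comp), n_reps in sorted(n_by_scope.items()):
            if n_reps < 3:
                report.warnings.append(
                    f"scope ({site}, {comp}) has {n_reps} replicate(s); "
                    "correlation matrix skipped (needs >= 3)"
                )
                continue
            cm = pearson_matrix(
                panel, (site, comp), alpha_levels=config.alpha_levels,
                correction=config.correction,
            )
            tag = f"{site.replace(' ', '_')}_{comp}"
            _write_csv(
                cm.r.reset_index(), config.out_dir / f"correlation_{tag}_r.csv", stamp
            )
            _write_csv(
                cm.flags.reset_index(),
                config.out_dir / f"correlation_{tag}_flags.csv",
                stamp,
            )
            correlations.append(tag)

        stage = "summary-json"
        out = {
            "version": __version__,
            "config_hash": config.digest(),
            "seed": config.seed,
            "sites": {
                row.site: {
                    "n_elements": int(row.n_elements),
                    "pli": row.pli,
                    "pli_category": row.pli_category,
                    "dc": row.dc,
                    "dc_category": row.dc_category,
                }
                for row in report.site_summary.itertuples(index=False)
            },
            "ratio_pair": list(report.ratio_pair) if report.ratio_pair else None,
            "correlation_scopes": correlations,
            "warnings": report.warnings,
        }
        with (config.out_dir / "summary.json").open("w", encoding="utf-8") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("run complete: %s", config.out_dir)
        return out
    except Exception:
        logger.exception("stage %r failed", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
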