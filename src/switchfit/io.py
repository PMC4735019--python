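"""Readers, writers, run configuration and the end-to-end trait pipeline.

Data travel as tab-delimited text with headers; reports are JSON.  Every
artifact embeds the seed, a hash of the canonical configuration, and the
package version, so a report can always be traced to the run that made it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mixfit import bin_trait, bootstrap_fit, fit_double_gaussian, fit_single_gaussian
from .polyphenism import (
    age_sex_normalize,
    bin_sensitivity,
    normalize_to_wildtype,
    summarize,
    tail_outliers,
)
from .simulate import COHORT_COLUMNS

logger = logging.getLogger("switchfit")

__all__ = [
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "run_pipeline",
    "ConfigError",
]

DEFAULT_COLUMN_MAP = {
    "trait": "trait",
    "genotype": "genotype",
    "sex": "sex",
    "litter": "litter_id",
    "era": "site_or_era",
    "weight": "weight",
    "age_group": "age_group",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of one trait-pipeline run."""

    cohort_path: str
    out_dir: str
    bin_width: float = 0.5
    normalize: str = "none"          # none | wildtype | age-sex
    normalize_scope: str = "global"  # for wildtype normalization
    age_sex_method: str = "median"
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    use_weights: bool = False
    ci: float = 0.95
    bootstrap_B: int = 0             # 0 disables the bootstrap
    bin_scan_widths: Optional[list] = None
    seed: int = 0
    verbosity: str = "INFO"

    _KNOWN = {
        "cohort_path", "out_dir", "bin_width", "normalize", "normalize_scope",
        "age_sex_method", "column_map", "use_weights", "ci", "bootstrap_B",
        "bin_scan_widths", "seed", "verbosity",
    }

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a YAML or JSON config file; unknown keys are rejected."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        data.update(overrides)
        unknown = set(data) - cls._KNOWN
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_KNOWN", None)
        return d

    def digest(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cohort I/O


def read_cohort(path, column_map: Optional[dict] = None) -> tuple[pd.DataFrame, dict]:
    """Read a delimited cohort file into the standard column layout.

    Returns ``(cohort, validation)`` where validation records the rows read
    and the rows dropped for a non-finite trait (with their line numbers).
    """
    column_map = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", float_precision="round_trip",
                      keep_default_na=False, na_values=[])
    if raw.empty:
        raise ConfigError(f"{path} contains no data rows")
    trait_col = column_map["trait"]
    missing = [c for c in (trait_col,) if c not in raw.columns]
    if missing:
        raise ConfigError(f"{path} is missing mapped column(s): {missing}")

    trait = pd.to_numeric(raw[trait_col], errors="coerce")
    bad = ~np.isfinite(trait)
    dropped = [
        {"row": int(i) + 2, "reason": f"non-finite trait {raw[trait_col].iloc[i]!r}"}
        for i in np.where(bad)[0]
    ]  # +2: header line plus 1-based numbering
    for d in dropped:
        logger.warning("dropping line %d: %s", d["row"], d["reason"])

    out = pd.DataFrame({"trait": trait[~bad].astype(float)})
    if "individual_id" in raw.columns:
        out["individual_id"] = raw.loc[~bad, "individual_id"].astype(str)
    else:
        out["individual_id"] = [f"row{i}" for i in np.where(~bad)[0]]
    for key, std in [
        ("genotype", "genotype"), ("sex", "sex"), ("litter", "litter_id"),
        ("era", "site_or_era"), ("age_group", "age_group"),
    ]:
        col = column_map.get(key)
        out[std] = raw.loc[~bad, col].astype(str) if col in raw.columns else ""
    wcol = column_map.get("weight")
    out["weight"] = (
        pd.to_numeric(raw.loc[~bad, wcol], errors="coerce").fillna(1.0)
        if wcol in raw.columns else 1.0
    )
    if "true_class" in raw.columns:
        out["true_class"] = raw.loc[~bad, "true_class"].astype(str)
    else:
        out["true_class"] = ""
    out = out.reset_index(drop=True)[COHORT_COLUMNS]
    validation = {"n_read": int(len(raw)), "n_kept": int(len(out)), "dropped": dropped}
    return out, validation


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Genes-in-rows delimited expression matrix."""
    m = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if m.index.duplicated().any():
        raise ConfigError("duplicate gene labels in expression matrix")
    if m.columns.duplicated().any():
        raise ConfigError("duplicate sample labels in expression matrix")
    return m


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_gmt(path) -> dict:
    """Read gene sets from a GMT file (name -> list of genes)."""
    from gseapy.parser import read_gmt as _read_gmt

    return _read_gmt(str(path))


def write_gmt(genesets: dict, path, descriptions: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        for name, genes in genesets.items():
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Run normalize → bin → fit → summarize and write the JSON report.

    Optional stages (bootstrap intervals, bin-width scan) run when the
    config asks for them.  The returned dict is exactly what is written to
    ``<out_dir>/report.json``; identical config + seed gives byte-identical
    output.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort, validation = read_cohort(config.cohort_path, config.column_map)
    logger.info("read %d individuals (%d dropped)",
                validation["n_kept"], len(validation["dropped"]))

    if config.normalize == "wildtype":
        cohort = normalize_to_wildtype(cohort, scope=config.normalize_scope)
    elif config.normalize == "age-sex":
        cohort = age_sex_normalize(cohort, method=config.age_sex_method)
    elif config.normalize != "none":
        raise ConfigError(f"unknown normalization {config.normalize!r}")

    values = cohort["trait"].to_numpy()
    weights = cohort["weight"].to_numpy() if config.use_weights else None
    binned = bin_trait(values, weights=weights, bin_width=config.bin_width)
    fit1 = fit_single_gaussian(binned)
    fit2 = fit_double_gaussian(binned, seed=config.seed)
    report = summarize(fit2, fit1, binned, values, em_seed=config.seed)
    report.outlier_summary = tail_outliers(fit2, binned, ci_level=config.ci)

    if config.bootstrap_B:
        boot = bootstrap_fit(
            values, k=2, B=config.bootstrap_B, seed=config.seed,
            bin_width=config.bin_width, level=config.ci,
        )
        report.on_rate_ci = boot.intervals.get("heavy_fraction")
        report.effect_size_ci = boot.intervals.get("effect_size_pct")

    bundle = {
        "report": report.to_dict(),
        "fit_single": fit1.to_dict(),
        "fit_double": fit2.to_dict(),
        "validation": validation,
        "provenance": {
            "config": config.to_dict(),
            "config_hash": config.digest(),
            "seed": config.seed,
            "version": __version__,
        },
    }
    if config.bin_scan_widths:
        scan = bin_sensitivity(values, config.bin_scan_widths, em_seed=config.seed)
        bundle["bin_sensitivity"] = json.loads(scan.to_json(orient="records"))

    (out_dir / "report.json").write_text(
        json.dumps(bundle, indent=2, sort_keys=True, default=_jsonify) + "\n"
    )
    return bundle


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
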