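"""CSV readers/writers and directory-level experiment persistence.

All tables are UTF-8 CSV with a header row; units are embedded in column
names (μM as ``concentration_uM``, protein ``ug``, rates
``rate_nmol_per_ug_per_day``).  A manifest records the scenario
parameters, the seed and per-file checksums so a run is traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .syndata import SyntheticExperiment, SyntheticScenario, default_scenarios

__all__ = [
    "TableFormatError",
    "read_table",
    "read_medium_table",
    "write_experiment",
    "read_experiment",
    "write_results",
]

#: mandatory columns per table kind
TABLE_SCHEMAS = {
    "standards": ["metabolite", "level", "concentration_uM", "area"],
    "cellfree": ["well", "metabolite", "area"],
    "spent": ["donor", "oxygen", "metabolite", "area"],
    "protein": ["donor", "oxygen", "day", "ug"],
    "mid_areas": ["donor", "oxygen", "tracer", "metabolite", "mass_shift", "area"],
    "secreted_citrate": ["donor", "oxygen", "tracer", "mass_shift", "area"],
    "pool_intensity": ["donor", "oxygen", "metabolite", "intensity"],
    "growth": ["donor", "oxygen", "time_h", "count"],
}


class TableFormatError(ValueError):
    """A table is missing mandatory columns or is empty."""


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Strictly parse one of the pipeline's CSV dialects."""
    path = Path(path)
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path)
    if df.empty:
        raise TableFormatError(f"{path}: empty input table")
    missing = set(TABLE_SCHEMAS[kind]) - set(df.columns)
    if missing:
        raise TableFormatError(
            f"{path}: missing mandatory column(s) {sorted(missing)} for kind {kind!r}"
        )
    return df


def read_medium_table(path: str | Path, name: str = "") -> "MediumComposition":
    """Two-column medium table (metabolite, concentration_uM) -> composition.

    Cross-checks magnitudes against the default medium registry and warns
    when a value is ~1000× off — the signature of mM entered in a μM
    column.
    """
    import warnings

    from .netmodel import MediumComposition, default_medium

    df = pd.read_csv(path)
    if df.empty:
        raise TableFormatError(f"{path}: empty input table")
    missing = {"metabolite", "concentration_uM"} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    registry = default_medium().concentrations
    conc = {}
    for _, row in df.iterrows():
        met, value = str(row["metabolite"]), float(row["concentration_uM"])
        ref = registry.get(met)
        if ref and value > 0 and not (ref / 50.0 <= value <= ref * 50.0):
            warnings.warn(
                f"{path}: {met} = {value} μM is far from the registry value "
                f"{ref} μM — possible mM/μM unit mix-up",
                stacklevel=2,
            )
        conc[met] = value
    return MediumComposition(concentrations=conc, name=name or Path(path).stem)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_experiment(exp: SyntheticExperiment, outdir: str | Path) -> Path:
    """Write every measurement table, the ground-truth ledger and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "standards": exp.standards,
        "cellfree": exp.cellfree,
        "spent": exp.spent,
        "protein": exp.protein,
        "mid_areas": exp.mid_areas,
        "secreted_citrate": exp.secreted_citrate,
        "pool_intensity": exp.pool_intensity,
        "growth": exp.growth,
    }
    files = {}
    for kind, df in tables.items():
        path = outdir / f"{kind}.csv"
        df.to_csv(path, index=False)
        files[f"{kind}.csv"] = _checksum(path)
    (outdir / "truth.json").write_text(json.dumps(exp.truth, indent=1, sort_keys=True))
    files["truth.json"] = _checksum(outdir / "truth.json")
    manifest = {
        "software_version": __version__,
        "seed": exp.seed,
        "n_donors": exp.n_donors,
        "tracers": list(exp.tracers),
        "scenarios": [
            {
                k: (dict(v) if isinstance(v, dict) else v)
                for k, v in dataclasses.asdict(sc).items()
            }
            for sc in exp.scenarios
        ],
        "files": files,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return outdir


def read_experiment(indir: str | Path) -> SyntheticExperiment:
    """Reload an experiment written by :func:`write_experiment`."""
    indir = Path(indir)
    manifest = yaml.safe_load((indir / "manifest.yaml").read_text())
    tables = {kind: read_table(indir / f"{kind}.csv", kind) for kind in TABLE_SCHEMAS}
    truth = json.loads((indir / "truth.json").read_text())
    scenarios = tuple(
        SyntheticScenario(**sc) for sc in manifest["scenarios"]
    )
    return SyntheticExperiment(
        scenarios=scenarios,
        seed=int(manifest["seed"]),
        n_donors=int(manifest["n_donors"]),
        tracers=tuple(manifest["tracers"]),
        truth=truth,
        **tables,
    )


def write_results(results, outdir: str | Path, seed: int | None = None) -> Path:
    """Write every pipeline output table plus the summary report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"software_version": __version__}
    if seed is not None:
        prov["seed"] = seed
    for name, df in (
        ("exchange_rates", results.exchange_rates),
        ("rate_summary", results.rate_summary),
        ("glucose_to_lactate", results.glucose_to_lactate),
        ("corrected_mids", results.corrected_mids),
        ("attribution", results.attribution_table),
        ("secreted_provenance", results.secreted_provenance),
        ("volcano", results.volcano),
    ):
        out = df.copy()
        for key, val in prov.items():
            out[key] = val
        out.to_csv(outdir / f"{name}.csv", index=False)
    report = {
        "options": dataclasses.asdict(results.options),
        "summary": results.summary,
    } | prov
    (outdir / "summary.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return outdir
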