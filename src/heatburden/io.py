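"""Reading and writing the CSV table dialect, bundles, configs and manifests.

A bundle directory holds one CSV per table (index columns first, then
``Result``), a ``metadata.json`` with each table's unit and index
declaration, the policy table as ``decisions.csv``, uncertain inputs as
``distributions.json`` and a ready-to-run ``config.yaml``.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import CityInputs
from .tables import VALUE, DecisionTable, IndexedTable, TableError
from .uncertainty import InputDistribution, MonetizationWeights

METADATA_FILE = "metadata.json"
DECISIONS_FILE = "decisions.csv"
DISTRIBUTIONS_FILE = "distributions.json"
CONFIG_FILE = "config.yaml"


def read_table(path: str | Path, indices: list[str] | None = None,
               unit: str = "1", name: str = "",
               decisions: tuple[str, ...] = ()) -> IndexedTable:
    """Read one table CSV, validating structure with row-numbered errors."""
    path = Path(path)
    if not path.exists():
        raise TableError(f"table file not found: {path}")
    df = pd.read_csv(path)
    if VALUE not in df.columns:
        raise TableError(f"{path}: missing '{VALUE}' column")
    if indices is not None:
        missing = [c for c in indices if c not in df.columns]
        if missing:
            raise TableError(f"{path}: missing declared index columns {missing}")
        df = df[list(indices) + [VALUE]]
    vals = pd.to_numeric(df[VALUE], errors="coerce")
    if vals.isna().any():
        rows = (df.index[vals.isna()] + 2).tolist()[:5]  # 1-based incl. header
        raise TableError(f"{path}: non-numeric Result in file rows {rows}")
    idx = [c for c in df.columns if c != VALUE]
    if idx:
        dup = df.duplicated(subset=idx)
        if dup.any():
            rows = (df.index[dup] + 2).tolist()[:5]
            raise TableError(f"{path}: duplicate index tuples in file rows {rows}")
    return IndexedTable(df, unit=unit, name=name or path.stem,
                        decisions=decisions)


def write_table(table: IndexedTable, path: str | Path) -> None:
    cols = table.index_cols + [VALUE]
    table.data[cols].to_csv(path, index=False)


def read_decisions(path: str | Path) -> DecisionTable:
    df = pd.read_csv(Path(path), dtype={"Selector": str}, keep_default_na=False)
    df["Selector"] = [DecisionTable.decode_selector(s) for s in df["Selector"]]
    df["Value"] = pd.to_numeric(df["Value"])
    return DecisionTable(df)


def write_decisions(decisions: DecisionTable, path: str | Path) -> None:
    df = decisions.rows.copy()
    df["Selector"] = [DecisionTable.encode_selector(s) for s in df["Selector"]]
    df.to_csv(path, index=False)


def read_distributions(path: str | Path) -> list[InputDistribution]:
    entries = json.loads(Path(path).read_text())
    return [InputDistribution(
        name=e["name"], target=e["target"], dist=e["dist"],
        params=tuple(e["params"]), selector=e.get("selector", {}),
        change=e.get("change", "replace"),
        lower=e.get("lower"), upper=e.get("upper")) for e in entries]


def write_distributions(dists: list[InputDistribution], path: str | Path) -> None:
    Path(path).write_text(json.dumps([asdict(d) for d in dists], indent=1))


def write_bundle(inputs: CityInputs, outdir: str | Path,
                 decisions: DecisionTable | None = None,
                 distributions: list[InputDistribution] | None = None,
                 weights: MonetizationWeights | None = None,
                 seed: int | None = None) -> Path:
    """Write a complete input bundle (tables, metadata, policies, config)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "name": inputs.name,
        "horizon": list(inputs.horizon),
        "age_threshold": inputs.age_threshold,
        "demand_floor": inputs.demand_floor,
        "erf_form": inputs.erf_form,
        "counterfactual": inputs.counterfactual,
        "tables": {},
    }
    for tname, table in inputs.tables.items():
        fname = f"{tname}.csv"
        write_table(table, outdir / fname)
        meta["tables"][tname] = {
            "file": fname, "unit": table.unit,
            "indices": table.index_cols,
            "decisions": list(table.decisions),
        }
    (outdir / METADATA_FILE).write_text(json.dumps(meta, indent=1))
    if decisions is not None:
        write_decisions(decisions, outdir / DECISIONS_FILE)
    if distributions:
        write_distributions(distributions, outdir / DISTRIBUTIONS_FILE)
    config = {
        "bundle": ".",
        "mode": "deterministic",
        "n_iter": 1000,
        "seed": 1 if seed is None else int(seed),
        "output": "output",
        "weights": asdict(weights or MonetizationWeights()),
    }
    (outdir / CONFIG_FILE).write_text(yaml.safe_dump(config, sort_keys=False))
    return outdir


def read_bundle(bundle_dir: str | Path):
    """Read a bundle directory back into (CityInputs, DecisionTable|None, dists)."""
    bundle_dir = Path(bundle_dir)
    meta_path = bundle_dir / METADATA_FILE
    if not meta_path.exists():
        raise TableError(f"not a bundle directory (no {METADATA_FILE}): {bundle_dir}")
    meta = json.loads(meta_path.read_text())
    tables = {}
    for tname, entry in meta["tables"].items():
        tables[tname] = read_table(
            bundle_dir / entry["file"], indices=entry["indices"],
            unit=entry["unit"], name=tname,
            decisions=tuple(entry.get("decisions", ())))
    inputs = CityInputs(
        tables=tables, horizon=tuple(meta["horizon"]),
        age_threshold=meta.get("age_threshold", 30),
        demand_floor=meta.get("demand_floor", 20.0),
        erf_form=meta.get("erf_form", "loglinear"),
        counterfactual=meta.get("counterfactual", 0.0),
        name=meta.get("name", bundle_dir.name))
    decisions = None
    if (bundle_dir / DECISIONS_FILE).exists():
        decisions = read_decisions(bundle_dir / DECISIONS_FILE)
    dists: list[InputDistribution] = []
    if (bundle_dir / DISTRIBUTIONS_FILE).exists():
        dists = read_distributions(bundle_dir / DISTRIBUTIONS_FILE)
    return inputs, decisions, dists


@dataclass
class RunConfig:
    """Declarative run configuration (one YAML file per run)."""

    bundle: Path
    mode: str = "deterministic"
    n_iter: int = 1000
    seed: int | None = None
    output: Path = Path("output")
    weights: MonetizationWeights | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise TableError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        bundle = (path.parent / raw.get("bundle", ".")).resolve()
        if not bundle.exists():
            raise TableError(f"bundle directory not found: {bundle}")
        weights = raw.get("weights")
        mode = raw.get("mode", "deterministic")
        seed = raw.get("seed")
        if mode == "monte_carlo" and seed is None:
            raise TableError("seed is mandatory when mode is monte_carlo")
        return cls(
            bundle=bundle, mode=mode,
            n_iter=int(raw.get("n_iter", 1000)),
            seed=None if seed is None else int(seed),
            output=(path.parent / raw.get("output", "output")),
            weights=MonetizationWeights(**weights) if weights else
            MonetizationWeights())


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir: Path, config_path: Path | None, seed: int | None,
                   extra: dict | None = None) -> Path:
    """A JSON record sufficient to reproduce the run bit for bit."""
    from . import __version__
    manifest = {
        "heatburden_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
    }
    if config_path is not None:
        manifest["config"] = str(config_path)
        manifest["config_sha256"] = _file_sha256(Path(config_path))
    if extra:
        manifest.update(extra)
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
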