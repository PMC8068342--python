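"""Configuration loading, yield-table writers, event logs, run metadata."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .induction import (
    ClusterPopulation,
    DamageYields,
    YIELD_CLASSES,
    classify_population,
)
from ._kernels import CLASS_NAMES

#: yield-table column order (class columns then derived totals)
TABLE_COLUMNS = list(YIELD_CLASSES) + ["Total SSB", "Total DSB", "Total Damage"]


class ConfigError(ValueError):
    """Invalid run configuration; message carries the offending field."""


def load_config(path) -> dict:
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunMetadata:
    """Provenance record referenced by every output file."""

    tool_version: str
    config_hash: str
    root_seed: Optional[int]
    stage_seeds: dict = field(default_factory=dict)
    survival_factors: dict = field(default_factory=dict)
    cluster_counts: dict = field(default_factory=dict)
    started: str = field(default_factory=lambda: time.strftime(
        "%Y-%m-%dT%H:%M:%S"))
    finished: str = ""

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def yields_to_row(yields: DamageYields, decimals: int = 2,
                  combined: bool = False) -> dict:
    """One yield-table row in the conventional column order.

    With ``combined`` each column holds a single ``value ± se`` string;
    otherwise paired ``<col>`` / ``<col>_se`` numeric columns are emitted.
    """
    d = yields.to_dict()
    row = {}
    for col in TABLE_COLUMNS:
        v, se = round(d[col], decimals), round(d[f"{col}_se"], decimals)
        if combined:
            row[col] = f"{v:.{decimals}f} ± {se:.{decimals}f}"
        else:
            row[col] = v
            row[f"{col}_se"] = se
    return row


def write_yields_tsv(rows, path, decimals: int = 2,
                     combined: bool = False) -> None:
    """Write yield rows (dicts of condition labels + DamageYields) as TSV."""
    records = []
    for labels, yields in rows:
        rec = dict(labels)
        rec.update(yields_to_row(yields, decimals=decimals,
                                 combined=combined))
        records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def read_yields_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cluster_log(pop: ClusterPopulation, path,
                      class_codes=None) -> None:
    """JSONL event log: one cluster per line with lesions and class."""
    if class_codes is None:
        class_codes = classify_population(pop)
    with open(path, "w") as fh:
        for i in range(len(pop)):
            i0, i1 = pop.offsets[i], pop.offsets[i + 1]
            fh.write(json.dumps({
                "positions": pop.positions[i0:i1].tolist(),
                "strands": pop.strands[i0:i1].tolist(),
                "kinds": ["strand-break" if b else "base-damage"
                          for b in pop.is_break[i0:i1]],
                "class": CLASS_NAMES[class_codes[i]],
            }) + "\n")
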