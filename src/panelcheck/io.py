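"""Plain-text readers/writers: TSV count matrices and sample sheets, JSON config."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .syndata import GeneratorConfig

__all__ = [
    "write_counts", "read_counts",
    "write_annotations", "read_annotations",
    "write_config", "read_config",
]


def write_counts(counts: pd.DataFrame, path) -> None:
    """Write a genes x samples integer count matrix as TSV (first column gene_id)."""
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{path}: counts must be nonnegative")
    return counts


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_config(config: GeneratorConfig, path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=1) + "\n")


def read_config(path) -> GeneratorConfig:
    return GeneratorConfig.from_dict(json.loads(Path(path).read_text()))
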