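"""File formats: expression matrices (TSV/CSV), GMT gene sets, Kd tables, YAML configs.

The canonical on-disk matrix layout is genes in rows (first column = gene id,
header = sample ids), tab-separated. Numeric output is serialized with 8
significant digits so reruns diff cleanly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.8g"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    ``is_counts`` distinguishes raw non-negative integer counts (which must be
    size-factor normalized before scoring) from values already on a
    normalized/log2 scale.
    """

    data: pd.DataFrame
    is_counts: bool = False

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.data.index]
        return replace(self, data=self.data.loc[present])

    def validate(self) -> "ExpressionMatrix":
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.is_counts:
            vals = self.data.to_numpy()
            if (vals < 0).any():
                raise ValueError("count matrix contains negative values")
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("count matrix contains non-integer values")
        return self


def read_expression(path, counts: bool | None = None) -> ExpressionMatrix:
    """Read a genes-in-rows expression table (TSV, or CSV by extension).

    The counts flag is inferred (all values integral and non-negative) unless
    given explicitly. Non-numeric cells are reported with their coordinates.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {raw.index[r]!r}, sample {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )
    if numeric.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if counts is None:
        vals = numeric.to_numpy()
        counts = bool((vals >= 0).all() and np.allclose(vals, np.round(vals)))
    numeric.index.name = None
    numeric.columns.name = None
    return ExpressionMatrix(numeric, is_counts=counts).validate()


def write_expression(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix.data.to_csv(path, sep=sep, float_format=FLOAT_FORMAT, index_label="gene")


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ...

    Gene order is preserved; duplicate genes within a set are dropped with a
    warning. A line with fewer than three fields is an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name = fields[0]
            genes: list[str] = []
            seen = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.warning("gene set %s: duplicate gene %s dropped", name, g)
                    continue
                seen.add(g)
                genes.append(g)
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_kd_matrix(path) -> pd.DataFrame:
    """Read an inhibitor x kinase Kd table (µM); blank cells mean 'not tested'."""
    kd = pd.read_csv(path, index_col=0)
    if (kd.to_numpy() <= 0).any():
        raise ValueError("Kd values must be positive where present")
    return kd


def write_kd_matrix(kd: pd.DataFrame, path) -> None:
    kd.to_csv(path, float_format=FLOAT_FORMAT, index_label="inhibitor")


def read_table(path) -> pd.DataFrame:
    """Generic annotation/survival CSV reader."""
    return pd.read_csv(path)


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    seed: int = 0
    output_dir: str = "cmskit_out"
    p_threshold: float = 1e-6
    kd_cutoff: float = 3.0
    q_cutoff: float = 0.001
    call_threshold: float = 0.5
    paths: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    _KNOWN = {
        "seed",
        "output_dir",
        "p_threshold",
        "kd_cutoff",
        "q_cutoff",
        "call_threshold",
        "paths",
        "params",
    }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "p_threshold": self.p_threshold,
            "kd_cutoff": self.kd_cutoff,
            "q_cutoff": self.q_cutoff,
            "call_threshold": self.call_threshold,
            "paths": self.paths,
            "params": self.params,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
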