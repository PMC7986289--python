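"""Delimited-matrix readers/writers and run configuration.

All matrices are plain TSV/CSV (delimiter chosen by extension) with the
first row and first column carrying names.  Output tables start with header
comment lines recording the tool version, a configuration hash and the
seed, so any table can be traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .model import OmicsDataset

logger = logging.getLogger("ctsridge")


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(path, orientation: str = "as_is") -> pd.DataFrame:
    """Read a named numeric matrix from delimited text.

    ``orientation="transpose"`` flips the matrix after reading (to bring a
    file into the internal convention).  Duplicate row/column names and
    non-numeric cells are rejected.
    """
    sep = _sep_for(path)
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split(sep)[1:]
                break
        else:
            raise ValueError(f"{path}: empty file")
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate column names")
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate row names")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from None
    if orientation == "transpose":
        df = df.T
    elif orientation != "as_is":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df


def write_matrix(df: pd.DataFrame, path, metadata: Optional[dict] = None,
                 index=True):
    """Write a matrix/table with reproducibility header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    from . import __version__
    lines = [f"# ctsridge {__version__}"]
    for k, v in (metadata or {}).items():
        lines.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep=_sep_for(path), index=index)


def read_dataset(y_path, w_path, x_path, c_path=None) -> OmicsDataset:
    """Assemble an OmicsDataset from matrix files.

    Y is markers x samples; W, X, C are samples x columns.  Sample-name
    mismatches raise an alignment error naming the missing samples.
    """
    expression = read_matrix(y_path)
    composition = read_matrix(w_path)
    traits = read_matrix(x_path)
    covariates = read_matrix(c_path) if c_path else None
    return OmicsDataset.from_frames(expression, composition, traits,
                                    covariates)


@dataclass
class RunConfig:
    """Configuration of a fit run; mirrors the CLI flags."""

    y: Optional[str] = None
    w: Optional[str] = None
    x: Optional[str] = None
    c: Optional[str] = None
    genotypes: Optional[str] = None
    scale: str = "logit"
    methods: list = field(default_factory=lambda: ["nls.logit.ridge"])
    procedure: str = "fixed_p"
    threshold: float = 2.4e-7
    seed: int = 0
    out_dir: str = "."
    verbosity: int = 0

    def __post_init__(self):
        from .estimator import METHODS
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def metadata(self) -> dict:
        return {"config": self.config_hash(), "seed": self.seed}
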