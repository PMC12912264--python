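"""Readers and writers for the tabular formats shared by all pipeline stages.

Formats
-------
* Intensity table: TSV/CSV with columns ``protein_id``, ``gene``,
  ``unique_peptides``, ``bait_1..bait_n``, ``ctrl_1..ctrl_n``.  Missing
  intensities are written as ``NA`` and held in memory as NaN — distinct from
  an observed 0, which proteomics search engines also emit.
* Gene list: plain text, one symbol per line, ``#`` comments allowed.
* Edge list: SIF-compatible TSV ``node_a<TAB>node_b[<TAB>evidence]``,
  undirected with set semantics.

All writers prepend a provenance header (``# key: value`` comment lines)
carrying the package version, config hash and seed when available; all
readers skip ``#`` lines.

Gene symbols are treated case-sensitively throughout: mouse ``Jup`` and
human ``JUP`` are different strings, and any cross-species harmonization is
the caller's responsibility (see :mod:`desmokit.compare` for the alias-map
mechanism).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IntensityTable",
    "EdgeList",
    "RunConfig",
    "read_intensity_table",
    "write_intensity_table",
    "read_gene_list",
    "write_gene_list",
    "read_edge_list",
    "write_edge_list",
    "read_frap_traces",
    "write_frap_traces",
]

logger = logging.getLogger(__name__)

_META_COLUMNS = ("protein_id", "gene", "unique_peptides")


class FormatError(ValueError):
    """A file does not conform to the declared layout (missing/extra columns)."""


class ValidationError(ValueError):
    """A file parses but carries values that violate the table invariants."""


@dataclass
class IntensityTable:
    """Protein x replicate abundance table for a bait-vs-control design.

    Parameters
    ----------
    df
        DataFrame with the meta columns ``protein_id``, ``gene``,
        ``unique_peptides`` followed by ``bait_1..bait_n`` and
        ``ctrl_1..ctrl_n`` intensity columns.  Intensities are non-negative
        finite reals or NaN (absent).
    n_replicates_per_condition
        Number of replicate columns per condition.
    """

    df: pd.DataFrame
    n_replicates_per_condition: int

    def __post_init__(self) -> None:
        n = self.n_replicates_per_condition
        if n < 1:
            raise ValidationError("n_replicates_per_condition must be >= 1")
        missing = [c for c in _META_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"intensity table lacks required columns: {missing}")
        expected = list(_META_COLUMNS) + self.bait_columns + self.control_columns
        missing = [c for c in expected if c not in self.df.columns]
        if missing:
            raise FormatError(f"intensity table lacks replicate columns: {missing}")
        bad_rows: list[str] = []
        if self.df["protein_id"].duplicated().any():
            dups = self.df.loc[self.df["protein_id"].duplicated(), "protein_id"]
            raise ValidationError(f"duplicate protein_id values: {sorted(set(dups))}")
        pep = self.df["unique_peptides"]
        if not np.issubdtype(pep.dtype, np.integer):
            if not np.allclose(pep, pep.astype(int), equal_nan=False):
                raise ValidationError("unique_peptides must be integers")
            self.df["unique_peptides"] = pep.astype(int)
        if (self.df["unique_peptides"] < 0).any():
            bad = self.df.loc[self.df["unique_peptides"] < 0, "protein_id"].tolist()
            bad_rows.append(f"negative unique_peptides for {bad}")
        inten = self.df[self.intensity_columns].to_numpy(dtype=float)
        if np.isinf(inten).any():
            bad_rows.append("non-finite intensity values present")
        with np.errstate(invalid="ignore"):
            if (inten < 0).any():
                idx = np.where((inten < 0).any(axis=1))[0]
                bad = self.df.iloc[idx]["protein_id"].tolist()
                bad_rows.append(f"negative intensities for {bad}")
        if bad_rows:
            raise ValidationError("; ".join(bad_rows))
        self.df = self.df.reset_index(drop=True)

    @property
    def bait_columns(self) -> list[str]:
        return [f"bait_{i}" for i in range(1, self.n_replicates_per_condition + 1)]

    @property
    def control_columns(self) -> list[str]:
        return [f"ctrl_{i}" for i in range(1, self.n_replicates_per_condition + 1)]

    @property
    def intensity_columns(self) -> list[str]:
        return self.bait_columns + self.control_columns

    def __len__(self) -> int:
        return len(self.df)

    def bait_matrix(self) -> np.ndarray:
        """Bait intensities as a (proteins x replicates) float array."""
        return self.df[self.bait_columns].to_numpy(dtype=float)

    def control_matrix(self) -> np.ndarray:
        """Control intensities as a (proteins x replicates) float array."""
        return self.df[self.control_columns].to_numpy(dtype=float)


@dataclass
class EdgeList:
    """Undirected gene-symbol interaction edges with optional evidence tags.

    Edges are stored as sorted 2-tuples with set semantics; self-loops are
    rejected at construction.
    """

    edges: set[tuple[str, str]] = field(default_factory=set)
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    @staticmethod
    def canonical(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, evidence: str = "") -> bool:
        """Add an undirected edge; returns False for self-loops/duplicates."""
        if not a or not b:
            raise ValidationError("edge endpoints must be non-empty symbols")
        if a == b:
            return False
        key = self.canonical(a, b)
        if key in self.edges:
            return False
        self.edges.add(key)
        if evidence:
            self.evidence[key] = evidence
        return True

    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.canonical(*pair) in self.edges


@dataclass
class RunConfig:
    """Pipeline thresholds and seeds, serializable to a single YAML file."""

    fc_min: float = 10.0
    p_max: float = 0.001
    min_unique_peptides: int = 2
    qc_r2_min: float = 0.85
    qc_plateau_dev_max: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fc_min", "p_max", "min_unique_peptides", "qc_r2_min",
                     "qc_plateau_dev_max"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _provenance_header(config: RunConfig | None) -> str:
    from desmokit import __version__

    lines = [f"# desmokit_version: {__version__}"]
    if config is not None:
        lines.append(f"# config_hash: {config.config_hash()}")
        lines.append(f"# seed: {config.seed}")
    return "\n".join(lines) + "\n"


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise FormatError(f"unknown dialect {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_intensity_table(path: str | Path, dialect: str | None = None) -> IntensityTable:
    """Read a bait-vs-control intensity table from TSV or CSV.

    Raises :class:`FormatError` for missing columns and
    :class:`ValidationError` for malformed values; malformed numerics are
    rejected, never coerced.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, comment="#", na_values=["NA"],
                     keep_default_na=False, dtype={"protein_id": str, "gene": str})
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path.name}")
    bait = sorted(c for c in df.columns if c.startswith("bait_"))
    ctrl = sorted(c for c in df.columns if c.startswith("ctrl_"))
    if not bait or len(bait) != len(ctrl):
        raise FormatError(
            f"expected matching bait_*/ctrl_* replicate columns, got {bait} / {ctrl}")
    for col in ["unique_peptides"] + bait + ctrl:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric value in column {col!r}: {exc}") from exc
    return IntensityTable(df=df, n_replicates_per_condition=len(bait))


def write_intensity_table(table: IntensityTable, path: str | Path,
                          config: RunConfig | None = None,
                          dialect: str | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path, dialect)
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        table.df.to_csv(fh, sep=sep, index=False, na_rep="NA")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list; case preserved, de-duplicated."""
    symbols: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    unique = set(symbols)
    n_dup = len(symbols) - len(unique)
    if n_dup:
        logger.info("gene list %s: dropped %d duplicate entries", path, n_dup)
    if not unique:
        logger.warning("gene list %s is empty", path)
    return unique


def write_gene_list(genes: Iterable[str], path: str | Path,
                    config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        for g in sorted(genes):
            fh.write(g + "\n")


def read_frap_traces(path: str | Path):
    """Read FRAP traces from CSV columns (trace_id, time_s, value)."""
    from .frap import FrapTrace

    df = pd.read_csv(path, comment="#")
    for col in ("trace_id", "time_s", "value"):
        if col not in df.columns:
            raise FormatError(f"trace CSV lacks column {col!r}")
    traces = []
    for tid, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("time_s")
        traces.append(FrapTrace(grp["time_s"].to_numpy(float),
                                grp["value"].to_numpy(float),
                                replicate=str(tid)))
    return traces


def write_frap_traces(traces, path: str | Path,
                      config: RunConfig | None = None) -> None:
    rows = []
    for i, tr in enumerate(traces):
        tid = tr.replicate or f"trace_{i:03d}"
        for t, v in zip(tr.times, tr.values):
            rows.append((tid, t, v))
    df = pd.DataFrame(rows, columns=["trace_id", "time_s", "value"])
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, index=False)


def read_edge_list(path: str | Path) -> EdgeList:
    """Read a SIF-like TSV edge list; de-duplicates, drops self-loops."""
    out = EdgeList()
    n_self = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected >=2 tab-separated columns")
        a, b = parts[0].strip(), parts[1].strip()
        evidence = parts[2].strip() if len(parts) > 2 else ""
        if a == b:
            n_self += 1
            continue
        out.add(a, b, evidence)
    if n_self:
        logger.warning("edge list %s: dropped %d self-loop(s)", path, n_self)
    return out


def write_edge_list(edges: EdgeList, path: str | Path,
                    config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        for a, b in sorted(edges.edges):
            ev = edges.evidence.get((a, b), "")
            fh.write(f"{a}\t{b}\t{ev}\n" if ev else f"{a}\t{b}\n")
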