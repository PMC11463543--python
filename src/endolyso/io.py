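"""Readers, writers, and run configuration shared by every pipeline stage.

All tabular formats are tab-delimited UTF-8 text with a header row.  Protein
identifiers are opaque strings throughout: mapping between gene symbols and
accessions is the data producer's job.  Missing intensities are encoded as
absent (empty field / NaN), never as zero; a zero intensity on input is
treated as missing because everything downstream lives in log2 space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger("endolyso")

CONDITIONS = ("tagged", "control")
IP_TYPES = ("endo", "lyso")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Thresholds and run-level settings for an analysis.

    Parameters
    ----------
    lfc_cutoff : float
        Minimum log2 fold change (tagged vs untagged control) for an
        enrichment call, in log2 units.  Default 1.0.
    q_cutoff : float
        Maximum BH-adjusted q-value for an enrichment call.  Default 0.01.
    iptm_cutoff : float
        ipTM threshold for the complex-prediction screen; a peptide passes
        only with score strictly above this value.  Default 0.6.
    rng_seed : int
        Seed for every stochastic step of a run.
    paths : mapping
        Named input/output paths.
    stages : mapping
        Boolean stage toggles.
    """

    lfc_cutoff: float = 1.0
    q_cutoff: float = 0.01
    iptm_cutoff: float = 0.6
    rng_seed: int = 0
    paths: Mapping[str, str] = field(default_factory=dict)
    stages: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lfc_cutoff > 0:
            raise ValueError(f"lfc_cutoff must be > 0, got {self.lfc_cutoff}")
        if not 0 < self.q_cutoff < 1:
            raise ValueError(f"q_cutoff must be in (0, 1), got {self.q_cutoff}")
        if not 0 < self.iptm_cutoff < 1:
            raise ValueError(f"iptm_cutoff must be in (0, 1), got {self.iptm_cutoff}")
        self.rng_seed = int(self.rng_seed)

    # Flat ``key = value`` text format; nested maps use dotted keys.
    def to_file(self, path: str | Path) -> None:
        lines = [
            f"lfc_cutoff = {self.lfc_cutoff!r}",
            f"q_cutoff = {self.q_cutoff!r}",
            f"iptm_cutoff = {self.iptm_cutoff!r}",
            f"rng_seed = {self.rng_seed}",
        ]
        for k in sorted(self.paths):
            lines.append(f"path.{k} = {self.paths[k]}")
        for k in sorted(self.stages):
            lines.append(f"stage.{k} = {str(bool(self.stages[k])).lower()}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kw: dict = {"paths": {}, "stages": {}}
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("path."):
                kw["paths"][key[5:]] = value
            elif key.startswith("stage."):
                kw["stages"][key[6:]] = value == "true"
            elif key == "rng_seed":
                kw[key] = int(value)
            elif key in ("lfc_cutoff", "q_cutoff", "iptm_cutoff"):
                kw[key] = float(value)
            else:
                raise ValueError(f"unknown config key {key!r} in {path}")
        return cls(**kw)

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Experimental design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignTable:
    """Channel-to-condition mapping for a multiplexed organelle-IP experiment.

    Wraps a DataFrame with columns ``channel``, ``condition`` (tagged or
    control), ``ip_type`` (endo or lyso), ``cell_state``, ``replicate``.
    Every (ip_type, cell_state) stratum needs at least two tagged and two
    control channels for the two-group statistics to be defined.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"channel", "condition", "ip_type", "cell_state", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.frame["channel"].duplicated().any():
            dups = self.frame.loc[self.frame["channel"].duplicated(), "channel"].tolist()
            raise ValueError(f"duplicate channel ids in design: {dups}")
        bad = set(self.frame["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        for (ip, state), grp in self.frame.groupby(["ip_type", "cell_state"]):
            n_tag = (grp["condition"] == "tagged").sum()
            n_ctl = (grp["condition"] == "control").sum()
            if n_tag < 2 or n_ctl < 2:
                raise ValueError(
                    f"stratum ({ip}, {state}) has {n_tag} tagged / {n_ctl} control "
                    "channels; need >= 2 of each"
                )

    @property
    def channels(self) -> list[str]:
        return self.frame["channel"].tolist()

    def strata(self) -> list[tuple[str, str]]:
        return sorted(set(zip(self.frame["ip_type"], self.frame["cell_state"])))

    def stratum_channels(self, ip_type: str, cell_state: str) -> tuple[list[str], list[str]]:
        """Channels of one stratum, split (tagged, control)."""
        sub = self.frame[(self.frame["ip_type"] == ip_type)
                         & (self.frame["cell_state"] == cell_state)]
        tagged = sub.loc[sub["condition"] == "tagged", "channel"].tolist()
        control = sub.loc[sub["condition"] == "control", "channel"].tolist()
        return tagged, control

    def to_file(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"channel": str}))


# ---------------------------------------------------------------------------
# Intensity matrix
# ---------------------------------------------------------------------------

@dataclass
class IntensityMatrix:
    """Protein-by-channel reporter intensities plus their design table.

    ``values`` is a DataFrame indexed by protein id with one column per
    channel, ordered as in the design; missing measurements are NaN.
    ``log2`` records whether values are on the log2 scale.
    """

    values: pd.DataFrame
    design: DesignTable
    log2: bool = False

    def __post_init__(self) -> None:
        want = self.design.channels
        missing = [c for c in want if c not in self.values.columns]
        if missing:
            raise ValueError(f"intensity matrix missing design channels: {missing}")
        self.values = self.values[want]
        self.values.index.name = "protein"
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein ids: {sorted(set(dups))}")

    @property
    def proteins(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_file(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "protein"
        out.to_csv(path, sep="\t", float_format="%.17g")


def read_intensity_table(path: str | Path, design: DesignTable) -> IntensityMatrix:
    """Read a protein-by-channel TSV into an :class:`IntensityMatrix`.

    The first column holds protein identifiers; one numeric column per
    channel named in the design must be present (extra columns are ignored
    with a log line).  Non-finite or negative intensities become missing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in design.channels if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing channel column(s) {missing}")
    extra = [c for c in df.columns if c not in design.channels]
    if extra:
        log.info("[io] %s: ignoring %d non-design column(s): %s", path, len(extra), extra)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate protein ids {dups}")
    vals = df[design.channels].apply(pd.to_numeric, errors="coerce")
    vals = vals.where(np.isfinite(vals) & (vals >= 0))
    vals = vals.where(vals != 0)  # zero intensity treated as missing
    vals.index = vals.index.astype(str)
    return IntensityMatrix(values=vals, design=design)


# ---------------------------------------------------------------------------
# Sequences and gene sets
# ---------------------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with optional transmembrane topology.

    ``topology`` is a list of 1-based inclusive (start, end) spans of
    transmembrane segments, used to restrict motif scans to the cytosolic
    tail downstream of the last span.
    """

    id: str
    seq: str
    topology: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.seq) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read FASTA records; the id is the first whitespace token of the header."""
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        log.warning("[io] %s: empty FASTA file", path)
        return []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(f"{path}:{lineno}: expected FASTA header, got {line[:40]!r}")
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinSequence(id=rec.id, seq=str(rec.seq).upper()))
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i:i + width] + "\n")


@dataclass
class GeneSetCollection:
    """Named protein sets over a background universe (flat, no hierarchy)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is not None:
            for name, members in self.sets.items():
                stray = members - self.universe
                if stray:
                    raise ValueError(f"set {name!r} not contained in universe: "
                                     f"{sorted(stray)[:5]}...")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one line per set — name, description, then members."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        log.warning("[io] %s: empty GMT file", path)
        return GeneSetCollection(sets={}, descriptions={})
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: GMT line needs name and description")
        name, description, *members = parts
        sets[name] = frozenset(m for m in members if m)
        desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            description = collection.descriptions.get(name, "")
            fh.write("\t".join([name, description] + members) + "\n")


def write_table(frame: pd.DataFrame, path: str | Path, sort_by: str | list[str] | None = None) -> None:
    """Deterministic TSV writer: stable column order, optional stable row sort."""
    out = frame.copy()
    if sort_by is not None:
        out = out.sort_values(sort_by, kind="stable")
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
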