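"""Reading and writing popoolation2-style sync tables and population manifests.

A sync file has one row per genomic site::

    2R <tab> 2302 <tab> N <tab> 0:7:0:0:0:0 <tab> 0:8:0:0:0:0 ...

with one colon-separated count 6-tuple per population in the fixed base
order A:T:C:G:N:deletion.  Coordinates are 1-based.  The manifest binds
the column order to population identities (treatment, replicate, pool
size in chromosomes).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: fixed column order of a sync count tuple
SYNC_BASES = ("A", "T", "C", "G", "N", "del")

#: treatments that label ancestral (un-replicated) populations
ANCESTRAL_TREATMENTS = ("GA", "AS", "AC")

#: experimental treatments, each with 5 replicate populations
EXPERIMENTAL_TREATMENTS = ("Salt", "Cad", "Temp", "Spatial")


class SyncParseError(ValueError):
    """Malformed sync or manifest input; message names the offending line."""


@dataclass(frozen=True)
class PopulationInfo:
    name: str
    treatment: str
    replicate: int | None = None
    pool_size: int = 140

    def __post_init__(self):
        if self.pool_size <= 0:
            raise ValueError(f"pool_size must be > 0 for population {self.name!r}")


@dataclass
class PopulationManifest:
    """Ordered collection of populations; order == sync column order."""

    populations: list[PopulationInfo] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.populations)

    def __iter__(self) -> Iterator[PopulationInfo]:
        return iter(self.populations)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.populations]

    def index(self, name: str) -> int:
        for i, p in enumerate(self.populations):
            if p.name == name:
                return i
        raise KeyError(f"population {name!r} not in manifest")

    def indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=np.intp)

    def treatment(self, label: str) -> list[str]:
        """Names of the populations of one treatment, replicate order."""
        pops = [p for p in self.populations if p.treatment == label]
        pops.sort(key=lambda p: (p.replicate if p.replicate is not None else 0))
        return [p.name for p in pops]

    def validate(self) -> None:
        seen = set()
        for p in self.populations:
            if p.name in seen:
                raise ValueError(f"duplicate population name {p.name!r}")
            seen.add(p.name)
        for t in EXPERIMENTAL_TREATMENTS:
            reps = [p.replicate for p in self.populations if p.treatment == t]
            if reps and sorted(reps) != [1, 2, 3, 4, 5]:
                raise ValueError(
                    f"treatment {t!r} must have replicates 1..5, got {sorted(reps)}"
                )
        for t in ANCESTRAL_TREATMENTS:
            for p in self.populations:
                if p.treatment == t and p.replicate is not None:
                    raise ValueError(f"ancestral population {p.name!r} cannot have a replicate")

    # -- serialisation ---------------------------------------------------
    @classmethod
    def read_tsv(cls, path_or_stream) -> "PopulationManifest":
        df = pd.read_csv(path_or_stream, sep="\t", dtype={"population": str, "treatment": str})
        pops = []
        for _, row in df.iterrows():
            rep = row.get("replicate")
            rep = None if pd.isna(rep) else int(rep)
            pops.append(
                PopulationInfo(
                    name=str(row["population"]),
                    treatment=str(row["treatment"]),
                    replicate=rep,
                    pool_size=int(row.get("pool_size", 140)),
                )
            )
        m = cls(pops)
        m.validate()
        return m

    def write_tsv(self, path_or_stream) -> None:
        df = pd.DataFrame(
            {
                "population": [p.name for p in self.populations],
                "treatment": [p.treatment for p in self.populations],
                "replicate": [p.replicate for p in self.populations],
                "pool_size": [p.pool_size for p in self.populations],
            }
        )
        df.to_csv(path_or_stream, sep="\t", index=False)

    @classmethod
    def default_experiment(cls, pool_size: int = 140) -> "PopulationManifest":
        """The 23-population layout: GA, AS, AC and 4 treatments x 5 replicates."""
        pops = [PopulationInfo(t, t, None, pool_size) for t in ANCESTRAL_TREATMENTS]
        for t in EXPERIMENTAL_TREATMENTS:
            for r in range(1, 6):
                pops.append(PopulationInfo(f"{t}{r}", t, r, pool_size))
        return cls(pops)


@dataclass
class SiteCounts:
    """One genomic site: per-population A/T/C/G/N/del read counts."""

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray  # (n_pops, 6) non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 6:
            raise ValueError("counts must have shape (n_pops, 6)")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SiteCounts)
            and self.chrom == other.chrom
            and self.pos == other.pos
            and self.ref == other.ref
            and np.array_equal(self.counts, other.counts)
        )


class SyncTable:
    """Column-major container for a whole sync table.

    Arrays: ``chrom`` (object), ``pos`` (int64), ``ref`` (object) of length
    n_sites, and ``counts`` of shape (n_sites, n_pops, 6).
    """

    def __init__(self, chrom, pos, ref, counts, manifest: PopulationManifest):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.counts = np.asarray(counts, dtype=np.int64)
        self.manifest = manifest
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == n and self.counts.shape[:1] == (n,)):
            raise ValueError("inconsistent array lengths")
        if n and self.counts.shape[1:] != (len(manifest), 6):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match manifest with "
                f"{len(manifest)} populations"
            )

    def __len__(self) -> int:
        return len(self.pos)

    def __getitem__(self, i) -> SiteCounts:
        return SiteCounts(str(self.chrom[i]), int(self.pos[i]), str(self.ref[i]), self.counts[i])

    def __iter__(self) -> Iterator[SiteCounts]:
        for i in range(len(self)):
            yield self[i]

    @property
    def coverage(self) -> np.ndarray:
        """(n_sites, n_pops) total read depth."""
        return self.counts.sum(axis=2)

    @classmethod
    def from_sites(cls, sites: Iterable[SiteCounts], manifest: PopulationManifest) -> "SyncTable":
        sites = list(sites)
        n_pops = len(manifest)
        for s in sites:
            if s.counts.shape[0] != n_pops:
                raise SyncParseError(
                    f"site {s.chrom}:{s.pos} has {s.counts.shape[0]} populations, "
                    f"manifest has {n_pops}"
                )
        if not sites:
            return cls([], [], [], np.zeros((0, n_pops, 6), dtype=np.int64), manifest)
        return cls(
            [s.chrom for s in sites],
            [s.pos for s in sites],
            [s.ref for s in sites],
            np.stack([s.counts for s in sites]),
            manifest,
        )


def _as_text_stream(path_or_stream, mode="r"):
    if hasattr(path_or_stream, "read") or hasattr(path_or_stream, "write"):
        return path_or_stream, False
    return open(path_or_stream, mode), True


def read_sync(path_or_stream, manifest: PopulationManifest) -> SyncTable:
    """Parse a sync table, binding count columns to the manifest order.

    Raises :class:`SyncParseError` (naming the line number) on a wrong
    column count, a malformed count tuple, or a position < 1.
    """
    stream, close = _as_text_stream(path_or_stream)
    n_pops = len(manifest)
    chroms, poss, refs, counts = [], [], [], []
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_pops:
                raise SyncParseError(
                    f"line {lineno}: expected {3 + n_pops} columns "
                    f"(3 + {n_pops} populations), got {len(fields)}"
                )
            try:
                pos = int(fields[1])
            except ValueError:
                raise SyncParseError(f"line {lineno}: position {fields[1]!r} is not an integer")
            if pos < 1:
                raise SyncParseError(f"line {lineno}: position {pos} < 1")
            row = np.empty((n_pops, 6), dtype=np.int64)
            for j, tup in enumerate(fields[3:]):
                parts = tup.split(":")
                if len(parts) != 6:
                    raise SyncParseError(
                        f"line {lineno}: population column {j + 1} has "
                        f"{len(parts)} fields, expected 6 (A:T:C:G:N:del)"
                    )
                try:
                    vals = [int(x) for x in parts]
                except ValueError:
                    raise SyncParseError(
                        f"line {lineno}: non-integer count in column {j + 1}: {tup!r}"
                    )
                if any(v < 0 for v in vals):
                    raise SyncParseError(f"line {lineno}: negative count in column {j + 1}")
                row[j] = vals
            chroms.append(fields[0])
            poss.append(pos)
            refs.append(fields[2])
            counts.append(row)
    finally:
        if close:
            stream.close()
    if not chroms:
        return SyncTable([], [], [], np.zeros((0, n_pops, 6), dtype=np.int64), manifest)
    return SyncTable(chroms, poss, refs, np.stack(counts), manifest)


def write_sync(table_or_sites, path_or_stream, manifest: PopulationManifest | None = None) -> None:
    """Emit tab-separated sync lines (deterministic formatting)."""
    if isinstance(table_or_sites, SyncTable):
        table = table_or_sites
        manifest = manifest or table.manifest
    else:
        if manifest is None:
            raise ValueError("manifest required when writing a site sequence")
        table = SyncTable.from_sites(table_or_sites, manifest)
    stream, close = _as_text_stream(path_or_stream, "w")
    try:
        for i in range(len(table)):
            tups = ":".join
            cols = "\t".join(tups(map(str, row)) for row in table.counts[i])
            prefix = f"{table.chrom[i]}\t{table.pos[i]}\t{table.ref[i]}"
            stream.write(prefix + ("\t" + cols if cols else "") + "\n")
    finally:
        if close:
            stream.close()


def sync_to_string(table: SyncTable) -> str:
    buf = io.StringIO()
    write_sync(table, buf)
    return buf.getvalue()
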