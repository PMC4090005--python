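"""File formats and core domain records.

All genomic coordinates are 0-based, half-open internally.  Reads come in
as BED6; for a minus-strand alignment the first *sequenced* base is the
last base of the interval, so its scored position is ``end - 1`` (see
:data:`REVERSE_READ_POSITION`).  Coverage tracks are exchanged as bedGraph,
gene annotation and the various gene tables as headered TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

#: Convention for the scored position of a reverse-strand BED interval:
#: the first sequenced base of a minus read is the interval's last base,
#: i.e. ``end - 1`` in 0-based coordinates.
REVERSE_READ_POSITION = "end-1"


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed records violate a domain invariant."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcription start and termination sites.

    For minus-strand genes ``tss > tts`` in genomic coordinates; ``length``
    is always ``abs(tts - tss)``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.tss == self.tts:
            raise ValidationError(f"gene {self.gene_id}: tss == tts")
        if self.strand == "+" and self.tts < self.tss:
            raise ValidationError(f"gene {self.gene_id}: + strand but tts < tss")
        if self.strand == "-" and self.tts > self.tss:
            raise ValidationError(f"gene {self.gene_id}: - strand but tts > tss")

    @property
    def length(self) -> int:
        return abs(self.tts - self.tss)


@dataclass(frozen=True)
class AlignedRead:
    """A single aligned read, scored at its first sequenced base."""

    chrom: str
    pos: int
    strand: str


@dataclass(frozen=True)
class NucleosomeRecord:
    """A nucleosome interval with its gene-relative index.

    Indices follow the yeast convention: -2/-1 reside in the promoter, +1
    is the TSS nucleosome, +2, +3, ... lie downstream.  Index 0 does not
    exist.
    """

    gene_id: str
    index: int
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.index == 0:
            raise ValidationError(f"nucleosome of {self.gene_id}: index 0 is invalid")
        if self.end <= self.start:
            raise ValidationError(
                f"nucleosome {self.gene_id}/{self.index}: end <= start"
            )


@dataclass
class CoverageTrack:
    """Per-base signal over named chromosomes for one sample.

    ``scale`` is ``"linear"`` (nonnegative read-derived signal) or
    ``"log2"``.  ``data`` maps chromosome name to a float vector.
    """

    data: dict[str, np.ndarray]
    name: str = ""
    scale: str = "linear"
    fragment_length: int | None = None
    meta: dict = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            data={c: v.copy() for c, v in self.data.items()},
            name=self.name,
            scale=self.scale,
            fragment_length=self.fragment_length,
            meta=dict(self.meta),
        )

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}


# ---------------------------------------------------------------------------
# gene annotation


GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tts"]


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read a gene annotation TSV with columns gene_id/chrom/strand/tss/tts.

    Raises :class:`ParseError` on malformed coordinates (naming the line)
    and :class:`ValidationError` on duplicate gene ids.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = set(GENE_COLUMNS) - set(header)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        idx = {c: header.index(c) for c in GENE_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                tss = int(parts[idx["tss"]])
                tts = int(parts[idx["tts"]])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed coordinates") from exc
            gid = parts[idx["gene_id"]]
            if gid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            genes.append(
                GeneModel(gid, parts[idx["chrom"]], parts[idx["strand"]], tss, tts)
            )
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tts}\n")


# ---------------------------------------------------------------------------
# reads (BED6)


def read_reads(
    path: str | Path, chrom_sizes: dict[str, int] | None = None
) -> Iterator[AlignedRead]:
    """Stream aligned reads from a BED6 file.

    The scored position is the first sequenced base: ``start`` for plus
    reads and ``end - 1`` for minus reads.  If ``chrom_sizes`` is given,
    reads on unknown chromosomes raise :class:`ValidationError`.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 BED columns")
            chrom, start, end, _name, _score, strand = parts[:6]
            if chrom_sizes is not None and chrom not in chrom_sizes:
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed coordinates") from exc
            pos = s if strand == "+" else e - 1
            yield AlignedRead(chrom, pos, strand)


def write_reads(reads: Iterable[AlignedRead], path: str | Path, read_length: int = 40) -> None:
    """Write reads as BED6, inverting the first-sequenced-base convention."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            if r.strand == "+":
                s, e = r.pos, r.pos + read_length
            else:
                s, e = r.pos - read_length + 1, r.pos + 1
            fh.write(f"{r.chrom}\t{s}\t{e}\tr{i}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph tracks


def write_bedgraph(track: CoverageTrack, path: str | Path, skip_zero: bool = False) -> None:
    """Write a track as 4-column bedGraph with equal-value runs merged.

    Raises :class:`ValidationError` if the track contains NaN or inf.
    """
    with open(path, "w") as fh:
        for chrom in track.data:
            values = np.asarray(track.data[chrom], dtype=float)
            if not np.all(np.isfinite(values)):
                raise ValidationError(f"track {track.name!r}: non-finite values on {chrom}")
            if len(values) == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts, ends):
                v = values[s]
                if skip_zero and v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")


def read_bedgraph(path: str | Path, chrom_sizes: dict[str, int]) -> CoverageTrack:
    """Read a bedGraph into dense per-base vectors of the given sizes."""
    data = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts
            if chrom not in data:
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            data[chrom][int(start): int(end)] = float(value)
    return CoverageTrack(data=data, name=str(path))


# ---------------------------------------------------------------------------
# typed tables


def read_table(path: str | Path, kind: str) -> pd.DataFrame | list:
    """Read one of the auxiliary TSV tables.

    kind:
      - ``nucleosomes``: columns gene_id/index/chrom/start/end ->
        list of :class:`NucleosomeRecord`
      - ``orthologs``: columns gene_id_a/gene_id_b (one-to-one) -> DataFrame
      - ``classes``: columns gene_id/class_name -> DataFrame (membership rows)
      - ``compendium``: condition x gene matrix, first column condition id ->
        DataFrame (conditions x genes)
    """
    if kind == "nucleosomes":
        df = pd.read_csv(path, sep="\t")
        _require(df, ["gene_id", "index", "chrom", "start", "end"], path)
        recs = [
            NucleosomeRecord(r.gene_id, int(r.index), r.chrom, int(r.start), int(r.end))
            for r in df.itertuples(index=False)
        ]
        keys = {(r.gene_id, r.index) for r in recs}
        if len(keys) != len(recs):
            raise ValidationError(f"{path}: duplicate (gene_id, index) pairs")
        return recs
    if kind == "orthologs":
        df = pd.read_csv(path, sep="\t")
        _require(df, ["gene_id_a", "gene_id_b"], path)
        for col in ("gene_id_a", "gene_id_b"):
            if df[col].duplicated().any():
                dupes = df.loc[df[col].duplicated(), col].tolist()[:5]
                raise ValidationError(
                    f"{path}: ortholog map not one-to-one in {col}: {dupes}"
                )
        return df
    if kind == "classes":
        df = pd.read_csv(path, sep="\t")
        _require(df, ["gene_id", "class_name"], path)
        return df
    if kind == "compendium":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return df
    raise ValueError(f"unknown table kind {kind!r}")


def write_table(obj, path: str | Path, kind: str) -> None:
    if kind == "nucleosomes":
        df = pd.DataFrame(
            [(r.gene_id, r.index, r.chrom, r.start, r.end) for r in obj],
            columns=["gene_id", "index", "chrom", "start", "end"],
        )
        df.to_csv(path, sep="\t", index=False)
    elif kind in ("orthologs", "classes"):
        obj.to_csv(path, sep="\t", index=False)
    elif kind == "compendium":
        obj.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown table kind {kind!r}")


def classes_to_sets(df: pd.DataFrame) -> dict[str, set[str]]:
    """Collapse a membership table into class_name -> set of gene ids."""
    return {name: set(sub["gene_id"]) for name, sub in df.groupby("class_name")}


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
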