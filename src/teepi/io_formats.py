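"""Readers and writers for the on-disk formats the pipeline touches.

Everything genomic is 0-based half-open internally (BED convention); GFF
input is converted on read.  Missing signal is represented as NaN, never 0:
assembly gaps and contig edges must not masquerade as histone-mark depletion.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BODY_PARTS = ("head", "gut", "ovary")
MARKS = ("H3K9me3", "H3K27ac")

CARRIER = "carrier"
NON_CARRIER = "non-carrier"
UNKNOWN = "unknown"


class ParseError(ValueError):
    """A malformed record in an input file; message names the line."""


class ConsistencyError(ValueError):
    """Cross-file references that do not resolve."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"require 0 <= start < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TEInsertion:
    """A polymorphic transposable-element insertion across the cohort.

    ``interval`` maps each carrier strain to the TE span in that strain's
    coordinates; ``presence`` maps every strain to carrier / non-carrier /
    unknown status.
    """

    te_id: str
    family: str
    order: str  # LTR, LINE, DNA, other
    interval: dict[str, GenomicInterval]
    presence: dict[str, str]
    length_class: str = "fragment"  # full-length | fragment
    population_frequency: float = float("nan")

    @property
    def carriers(self) -> list[str]:
        return [s for s, v in self.presence.items() if v == CARRIER]

    @property
    def non_carriers(self) -> list[str]:
        return [s for s, v in self.presence.items() if v == NON_CARRIER]

    @property
    def is_polymorphic(self) -> bool:
        return bool(self.carriers) and bool(self.non_carriers)


@dataclass
class SignalTrack:
    """Binned fold-enrichment for one strain x body part x mark x replicate.

    ``values[chrom]`` is a float array over bins of width ``bin_bp``;
    NaN marks bins with no underlying data.
    """

    strain: str
    body_part: str
    mark: str
    replicate: int
    values: dict[str, np.ndarray] = field(default_factory=dict)
    bin_bp: int = 10

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[chrom]


@dataclass(frozen=True)
class PafRecord:
    query: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target: str
    target_len: int
    target_start: int
    target_end: int
    n_match: int
    block_len: int
    mapq: int
    primary: bool = True

    @property
    def query_coverage(self) -> float:
        return (self.query_end - self.query_start) / self.query_len


# ---------------------------------------------------------------------------
# TE annotations (BED6+2: name, family, order) + presence matrix
# ---------------------------------------------------------------------------

def read_te_annotations(path: str | Path, presence_path: str | Path) -> list[TEInsertion]:
    """Read a BED6+ TE annotation file together with its presence matrix.

    The BED file carries one row per TE with columns
    chrom/start/end/te_id/score/strand/family/order; the presence matrix is a
    TSV with te_id rows, strain columns and carrier/non-carrier/unknown cells.
    Coordinates in the BED file refer to the annotation's reference strain
    (the matrix says which strains actually carry the insertion).
    """
    presence = pd.read_csv(presence_path, sep="\t", index_col=0, dtype=str)
    if presence.index.duplicated().any():
        dupes = presence.index[presence.index.duplicated()].tolist()
        raise ConsistencyError(f"duplicate te_id in presence matrix: {dupes}")
    bad = ~presence.isin([CARRIER, NON_CARRIER, UNKNOWN]) & presence.notna()
    if bad.to_numpy().any():
        raise ParseError("presence matrix cells must be carrier/non-carrier/unknown")

    tes: list[TEInsertion] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(
                    f"{path}:{lineno}: expected >=8 tab-separated fields, got {len(fields)}"
                )
            chrom, start, end, te_id, _score, strand, family, order = fields[:8]
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if te_id in seen:
                raise ConsistencyError(f"{path}:{lineno}: duplicate te_id {te_id!r}")
            seen.add(te_id)
            if te_id not in presence.index:
                raise ConsistencyError(f"te_id {te_id!r} missing from presence matrix")
            pres = presence.loc[te_id].fillna(UNKNOWN).to_dict()
            interval = {s: iv for s, v in pres.items() if v == CARRIER}
            extra = dict(zip(["length_class", "population_frequency"], fields[8:10]))
            tes.append(
                TEInsertion(
                    te_id=te_id,
                    family=family,
                    order=order,
                    interval=interval,
                    presence=pres,
                    length_class=extra.get("length_class", "fragment"),
                    population_frequency=float(extra.get("population_frequency", "nan")),
                )
            )
    missing = set(presence.index) - seen
    if missing:
        raise ConsistencyError(
            f"presence matrix te_ids missing from BED: {sorted(missing)[:5]}"
        )
    return tes


def write_te_annotations(
    tes: Iterable[TEInsertion], path: str | Path, presence_path: str | Path,
    reference_strain: str | None = None,
) -> None:
    """Inverse of :func:`read_te_annotations` (coordinates of one strain)."""
    rows = []
    pres_rows = {}
    for te in tes:
        strain = reference_strain or te.carriers[0]
        iv = te.interval[strain]
        rows.append(
            [iv.chrom, iv.start, iv.end, te.te_id, 0, iv.strand, te.family, te.order,
             te.length_class, te.population_frequency]
        )
        pres_rows[te.te_id] = te.presence
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    pd.DataFrame.from_dict(pres_rows, orient="index").rename_axis("te_id").to_csv(
        presence_path, sep="\t"
    )


# ---------------------------------------------------------------------------
# bedGraph signal
# ---------------------------------------------------------------------------

def read_signal_track(
    path: str | Path,
    bin_bp: int = 10,
    *,
    strain: str = "",
    body_part: str = "",
    mark: str = "",
    replicate: int = 0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> SignalTrack:
    """Read a bedGraph into fixed-width bins.

    Each bin's value is the coverage-weighted mean of the bedGraph intervals
    overlapping it; bins with no data are NaN.  Intervals must be
    non-overlapping per chromosome and values non-negative.
    """
    starts: dict[str, list] = {}
    ends: dict[str, list] = {}
    vals: dict[str, list] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields")
            chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if v < 0:
                raise ParseError(f"{path}:{lineno}: negative signal value {v}")
            if e <= s:
                raise ParseError(f"{path}:{lineno}: empty or inverted interval")
            starts.setdefault(chrom, []).append(s)
            ends.setdefault(chrom, []).append(e)
            vals.setdefault(chrom, []).append(v)

    values: dict[str, np.ndarray] = {}
    for chrom in starts:
        s = np.asarray(starts[chrom], dtype=np.int64)
        e = np.asarray(ends[chrom], dtype=np.int64)
        v = np.asarray(vals[chrom], dtype=np.float64)
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if np.any(s[1:] < e[:-1]):
            raise ParseError(f"overlapping bedGraph intervals on {chrom} in {path}")
        length = chrom_lengths[chrom] if chrom_lengths else int(e[-1])
        values[chrom] = bin_intervals(s, e, v, length, bin_bp)
    return SignalTrack(strain, body_part, mark, replicate, values, bin_bp)


def bin_intervals(
    starts: np.ndarray, ends: np.ndarray, values: np.ndarray, length: int, bin_bp: int
) -> np.ndarray:
    """Coverage-weighted binning of sorted non-overlapping intervals."""
    n_bins = -(-length // bin_bp)
    weighted = np.zeros(n_bins, dtype=np.float64)
    covered = np.zeros(n_bins, dtype=np.float64)
    for s, e, v in zip(starts, ends, values):
        b0, b1 = s // bin_bp, (e - 1) // bin_bp
        if b0 == b1:
            w = e - s
            weighted[b0] += v * w
            covered[b0] += w
            continue
        w0 = (b0 + 1) * bin_bp - s
        weighted[b0] += v * w0
        covered[b0] += w0
        w1 = e - b1 * bin_bp
        weighted[b1] += v * w1
        covered[b1] += w1
        if b1 - b0 > 1:
            weighted[b0 + 1 : b1] += v * bin_bp
            covered[b0 + 1 : b1] += bin_bp
    out = np.full(n_bins, np.nan)
    has = covered > 0
    out[has] = weighted[has] / covered[has]
    return out


def write_signal_track(track: SignalTrack, path: str | Path) -> None:
    """Write binned signal back to bedGraph (one line per non-NaN bin run)."""
    with open(path, "w") as fh:
        for chrom, arr in track.values.items():
            b = track.bin_bp
            finite = np.isfinite(arr)
            idx = np.flatnonzero(finite)
            if idx.size == 0:
                continue
            # merge consecutive equal-valued bins
            breaks = np.flatnonzero(
                (np.diff(idx) != 1) | (np.diff(arr[idx]) != 0)
            )
            run_starts = np.concatenate([[0], breaks + 1])
            run_ends = np.concatenate([breaks, [idx.size - 1]])
            for rs, re in zip(run_starts, run_ends):
                fh.write(
                    f"{chrom}\t{idx[rs] * b}\t{(idx[re] + 1) * b}\t{arr[idx[rs]]:g}\n"
                )


# ---------------------------------------------------------------------------
# PAF alignments
# ---------------------------------------------------------------------------

def read_alignments_paf(path: str | Path) -> dict[str, list[PafRecord]]:
    """Parse a PAF file and group records by query name.

    Fields 1-12 are required; the ``tp:A:`` tag, when present, distinguishes
    primary (P) from secondary (S) alignments.
    """
    grouped: dict[str, list[PafRecord]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: PAF needs >=12 fields")
            primary = True
            for tag in fields[12:]:
                if tag.startswith("tp:A:"):
                    primary = tag[5:] == "P"
            rec = PafRecord(
                query=fields[0],
                query_len=int(fields[1]),
                query_start=int(fields[2]),
                query_end=int(fields[3]),
                strand=fields[4],
                target=fields[5],
                target_len=int(fields[6]),
                target_start=int(fields[7]),
                target_end=int(fields[8]),
                n_match=int(fields[9]),
                block_len=int(fields[10]),
                mapq=int(fields[11]),
                primary=primary,
            )
            grouped.setdefault(rec.query, []).append(rec)
    return grouped


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene x sample count TSV.

    Sample columns are named ``strain_bodypart_rep``; returns the integer
    count matrix and a metadata frame (sample, strain, body_part, replicate).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ConsistencyError(
            f"duplicate gene ids: {df.index[df.index.duplicated()].tolist()[:5]}"
        )
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)) or np.isnan(arr).any():
            raise ParseError("counts must be integers")
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise ParseError("counts must be non-negative")
    counts = pd.DataFrame(arr, index=df.index, columns=df.columns)
    meta = parse_sample_names(df.columns)
    return counts, meta


def parse_sample_names(names: Iterable[str]) -> pd.DataFrame:
    rows = []
    for name in names:
        parts = name.rsplit("_", 2)
        if len(parts) != 3:
            raise ParseError(f"sample name {name!r} is not strain_bodypart_rep")
        strain, body_part, rep = parts
        rows.append((name, strain, body_part, int(rep)))
    return pd.DataFrame(rows, columns=["sample", "strain", "body_part", "replicate"])


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a deterministic column order."""
    records.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


# ---------------------------------------------------------------------------
# Genes (GFF3 subset) and FASTA
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A minimal gene model: body plus optional CDS/UTR sub-features.

    Sub-feature lists hold (start, end) tuples in 0-based half-open
    coordinates; genes lacking them fall back to distance-only positional
    categories downstream.
    """

    gene_id: str
    interval: GenomicInterval
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def has_structure(self) -> bool:
        return bool(self.cds or self.utr5 or self.utr3)


def read_genes_gff(path: str | Path) -> list[GeneModel]:
    """Read gene/CDS/UTR features from a GFF3 file (1-based closed on disk)."""
    genes: dict[str, GeneModel] = {}
    sub: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{lineno}: GFF needs 9 fields")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = f[:9]
            start0, end0 = int(start) - 1, int(end)
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID") or attr.get("gene_id")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene without ID")
                genes[gid] = GeneModel(gid, GenomicInterval(chrom, start0, end0, strand))
            elif ftype in {"CDS", "five_prime_UTR", "three_prime_UTR"}:
                parent = attr.get("Parent") or attr.get("gene_id")
                if parent:
                    sub.append((parent, ftype, start0, end0))
    for parent, ftype, s, e in sub:
        g = genes.get(parent)
        if g is None:
            continue
        {"CDS": g.cds, "five_prime_UTR": g.utr5, "three_prime_UTR": g.utr3}[ftype].append((s, e))
    return list(genes.values())


def write_genes_gff(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tteepi\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={g.gene_id}\n"
            )
            for ftype, feats in (
                ("five_prime_UTR", g.utr5), ("CDS", g.cds), ("three_prime_UTR", g.utr3)
            ):
                for s, e in feats:
                    fh.write(
                        f"{iv.chrom}\tteepi\t{ftype}\t{s + 1}\t{e}\t.\t{iv.strand}\t.\tParent={g.gene_id}\n"
                    )


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
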