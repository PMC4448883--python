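"""Read-level preprocessing and fixed-window counting.

ChIP-seq normalization works on per-window read counts. This module reads
aligned reads from BED, applies the two standard preprocessing steps
(capping PCR duplicates at a fixed number of reads per starting position,
and shifting read starts towards the fragment midpoint), and counts reads
into a fixed-size window partition of the genome.

Coordinates follow the BED convention throughout: 0-based, half-open.
Windows on a chromosome of length ``l`` with size ``b`` are the half-open
intervals ``[k*b, (k+1)*b)``; the terminal window is truncated at the
chromosome end but keeps its index, so read counts are conserved.

Read collections are plain :class:`pandas.DataFrame` objects with columns
``chrom`` (str), ``start`` (int) and ``strand`` (``'+'``/``'-'``); the
:class:`AlignedRead` named tuple and :func:`reads_from_records` exist for
building small collections by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

READ_COLUMNS = ["chrom", "start", "strand"]


class BedError(ValueError):
    """A BED record could not be parsed or failed validation."""


class AlignedRead(NamedTuple):
    """A single uniquely aligned read, reduced to its 5' start position."""

    chrom: str
    start: int
    strand: str = "+"


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths; defines the window grid.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs. Names must be unique and lengths
        positive.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        if not chroms:
            raise ValueError("genome must contain at least one chromosome")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for _, l in chroms):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        """Total genome length L."""
        return sum(l for _, l in self.chromosomes)

    def n_windows(self, window_size: int) -> int:
        """Number of windows G_b for window size b (``ceil(length/b)`` summed)."""
        b = int(window_size)
        if b < 1:
            raise ValueError("window_size must be >= 1")
        return sum(-(-l // b) for _, l in self.chromosomes)

    def window_offsets(self, window_size: int) -> dict[str, int]:
        """Genome-wide index of the first window of each chromosome."""
        b = int(window_size)
        offsets: dict[str, int] = {}
        acc = 0
        for name, length in self.chromosomes:
            offsets[name] = acc
            acc += -(-length // b)
        return offsets

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        """Load a two-column chromosome-sizes table (name, length)."""
        tab = pd.read_csv(path, sep="\t", header=None, comment="#",
                          usecols=[0, 1], names=["name", "length"])
        return cls(list(tab.itertuples(index=False, name=None)))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.chromosomes).to_csv(path, sep="\t", header=False, index=False)


def reads_from_records(records: Iterable[tuple]) -> pd.DataFrame:
    """Build a read table from ``(chrom, start[, strand])`` tuples."""
    rows = []
    for rec in records:
        if len(rec) == 2:
            rows.append(AlignedRead(rec[0], rec[1]))
        else:
            rows.append(AlignedRead(rec[0], rec[1], rec[2]))
    df = pd.DataFrame(rows, columns=READ_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    return df


def read_bed(path, genome: GenomeLayout) -> pd.DataFrame:
    """Read aligned reads from a BED3/BED6 file (plain or gzip).

    Only the chromosome, start and (optional, column 6) strand are used.
    Records on chromosomes not present in ``genome`` are skipped; their
    number is recorded in ``result.attrs['n_skipped']``. A record whose
    start falls outside its chromosome raises :class:`BedError` naming the
    offending line.
    """
    try:
        tab = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise BedError(f"cannot read BED file {path}: {exc}") from exc
    if tab.shape[1] < 3:
        raise BedError(f"{path}: BED requires at least 3 columns, found {tab.shape[1]}")

    chrom = tab.iloc[:, 0].astype(str)
    try:
        start = pd.to_numeric(tab.iloc[:, 1], errors="raise").astype(np.int64)
    except (ValueError, TypeError):
        bad = pd.to_numeric(tab.iloc[:, 1], errors="coerce").isna()
        line = int(np.argmax(bad.to_numpy())) + 1
        raise BedError(f"{path}, line {line}: non-integer start field") from None
    if tab.shape[1] >= 6:
        strand = tab.iloc[:, 5].astype(str).where(tab.iloc[:, 5].isin(["+", "-"]), "+")
    else:
        strand = pd.Series("+", index=tab.index)

    reads = pd.DataFrame({"chrom": chrom, "start": start, "strand": strand})
    known = reads["chrom"].isin(genome.names)
    n_skipped = int((~known).sum())
    reads = reads[known]

    lengths = reads["chrom"].map(genome.lengths).to_numpy()
    bad = (reads["start"].to_numpy() < 0) | (reads["start"].to_numpy() >= lengths)
    if bad.any():
        line = int(reads.index[np.argmax(bad)]) + 1
        raise BedError(
            f"{path}, line {line}: start {int(reads['start'].iloc[int(np.argmax(bad))])} "
            "outside chromosome bounds"
        )
    if reads.empty:
        raise BedError(f"{path}: no usable records on the given genome")

    reads = reads.reset_index(drop=True)
    reads.attrs["n_skipped"] = n_skipped
    return reads


def write_bed(reads: pd.DataFrame, path) -> None:
    """Write reads as BED6 (1 bp features; score column fixed at 0)."""
    out = pd.DataFrame({
        "chrom": reads["chrom"],
        "start": reads["start"],
        "end": reads["start"] + 1,
        "name": ".",
        "score": 0,
        "strand": reads["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def cap_duplicates(reads: pd.DataFrame, max_per_position: int = 2,
                   strand_aware: bool = True) -> pd.DataFrame:
    """Retain at most ``max_per_position`` reads per starting position.

    PCR amplification can leave many identical reads at one genomic
    position; standard practice keeps only the first few. Retention is
    deterministic: the first occurrences in input order win. With
    ``strand_aware`` (default) reads at the same base on opposite strands
    are counted separately.
    """
    if max_per_position < 1:
        raise ValueError("max_per_position must be >= 1")
    key = ["chrom", "start", "strand"] if strand_aware else ["chrom", "start"]
    keep = reads.groupby(key, sort=False).cumcount() < max_per_position
    return reads[keep].reset_index(drop=True)


def shift_reads(reads: pd.DataFrame, fragment_length: int,
                genome: GenomeLayout) -> pd.DataFrame:
    """Shift read starts towards their 3' end by half the fragment length.

    A sequenced read marks only the 5' end of its DNA fragment; shifting by
    ``fragment_length // 2`` re-centres counts on the fragment midpoint.
    Plus-strand reads move right, minus-strand reads move left; positions
    are clamped into the chromosome. ``fragment_length=0`` is the identity.
    """
    if fragment_length < 0:
        raise ValueError("fragment_length must be >= 0")
    half = fragment_length // 2
    if half == 0:
        return reads.copy()
    out = reads.copy()
    delta = np.where(out["strand"].to_numpy() == "-", -half, half)
    lengths = out["chrom"].map(genome.lengths).to_numpy()
    out["start"] = np.clip(out["start"].to_numpy() + delta, 0, lengths - 1)
    return out


@dataclass
class WindowCounts:
    """Per-window ChIP and Input read counts on the genome-wide window grid.

    Arrays are flat over all windows, in chromosome order (use
    :meth:`GenomeLayout.window_offsets` to locate a chromosome). Strand
    split counts are optional and, when present, sum to the unstranded
    arrays.
    """

    genome: GenomeLayout
    window_size: int
    chip: np.ndarray
    input: np.ndarray
    chip_plus: np.ndarray | None = None
    chip_minus: np.ndarray | None = None
    input_plus: np.ndarray | None = None
    input_minus: np.ndarray | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.genome.n_windows(self.window_size)
        if len(self.chip) != n or len(self.input) != n:
            raise ValueError(f"count arrays must have length G_b = {n}")
        self.chip = np.asarray(self.chip, dtype=np.int64)
        self.input = np.asarray(self.input, dtype=np.int64)

    @property
    def n_windows(self) -> int:
        return len(self.chip)

    @property
    def n_chip(self) -> int:
        return int(self.chip.sum())

    @property
    def n_input(self) -> int:
        return int(self.input.sum())

    @property
    def n_total(self) -> int:
        return self.n_chip + self.n_input

    @property
    def total(self) -> np.ndarray:
        """Per-window N_tot(w) = N_ch(w) + N_in(w)."""
        return self.chip + self.input

    @property
    def stranded(self) -> bool:
        return self.chip_plus is not None

    @classmethod
    def from_arrays(cls, chip, input, window_size: int = 100, **kw) -> "WindowCounts":
        """Build counts over a single synthetic chromosome (unit fixtures)."""
        chip = np.asarray(chip, dtype=np.int64)
        genome = GenomeLayout([("chrSyn", len(chip) * window_size)])
        return cls(genome, window_size, chip, np.asarray(input, dtype=np.int64), **kw)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: chrom, window_start, window_end, chip, input[, strands]."""
        rows = []
        for name, length in self.genome.chromosomes:
            nw = -(-length // self.window_size)
            starts = np.arange(nw, dtype=np.int64) * self.window_size
            ends = np.minimum(starts + self.window_size, length)
            rows.append(pd.DataFrame({"chrom": name, "window_start": starts,
                                      "window_end": ends}))
        frame = pd.concat(rows, ignore_index=True)
        frame["chip"] = self.chip
        frame["input"] = self.input
        if self.stranded:
            frame["chip_plus"] = self.chip_plus
            frame["chip_minus"] = self.chip_minus
            frame["input_plus"] = self.input_plus
            frame["input_minus"] = self.input_minus
        return frame

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, genome: GenomeLayout | None = None) -> "WindowCounts":
        frame = pd.read_csv(path, sep="\t")
        window_size = int((frame["window_end"] - frame["window_start"]).max())
        if genome is None:
            lengths = frame.groupby("chrom", sort=False)["window_end"].max()
            genome = GenomeLayout(list(lengths.items()))
        kw = {}
        if "chip_plus" in frame.columns:
            for col in ("chip_plus", "chip_minus", "input_plus", "input_minus"):
                kw[col] = frame[col].to_numpy(np.int64)
        return cls(genome, window_size, frame["chip"].to_numpy(np.int64),
                   frame["input"].to_numpy(np.int64), **kw)


def _bin_starts(reads: pd.DataFrame, window_size: int, genome: GenomeLayout,
                offsets: dict[str, int], n_windows: int) -> np.ndarray:
    chrom_offset = reads["chrom"].map(offsets).to_numpy(np.int64)
    idx = chrom_offset + reads["start"].to_numpy(np.int64) // window_size
    return np.bincount(idx, minlength=n_windows).astype(np.int64)


def count_windows(chip_reads: pd.DataFrame, input_reads: pd.DataFrame,
                  window_size: int, genome: GenomeLayout,
                  stranded: bool = False) -> WindowCounts:
    """Count reads into fixed-size windows for both samples.

    Each read is assigned to the window containing its (possibly shifted)
    start: window index ``start // window_size`` within its chromosome.
    With ``stranded=True`` plus/minus-strand counts are produced as well
    (needed by the CCAT estimator).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    offsets = genome.window_offsets(window_size)
    n = genome.n_windows(window_size)
    kw = {}
    if stranded:
        for prefix, reads in (("chip", chip_reads), ("input", input_reads)):
            plus = reads[reads["strand"] != "-"]
            minus = reads[reads["strand"] == "-"]
            kw[f"{prefix}_plus"] = _bin_starts(plus, window_size, genome, offsets, n)
            kw[f"{prefix}_minus"] = _bin_starts(minus, window_size, genome, offsets, n)
        chip = kw["chip_plus"] + kw["chip_minus"]
        inp = kw["input_plus"] + kw["input_minus"]
    else:
        chip = _bin_starts(chip_reads, window_size, genome, offsets, n)
        inp = _bin_starts(input_reads, window_size, genome, offsets, n)
    return WindowCounts(genome, window_size, chip, inp, **kw)
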