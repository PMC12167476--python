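"""Collapse sequencing reads to per-guide counts and build count tables.

Counting is exact: the read substring at a fixed offset must equal a
library spacer letter-for-letter (no mismatches).  Reads matching no
spacer — including reads too short to contain one — are tallied as
unmatched, so matched + unmatched always equals the number of reads.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from lncscreen.library_model import LibraryDesign


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the approximate record index."""


@dataclass
class CountTable:
    """Guide x sample matrix of non-negative integer counts.

    One sample is the designated reference (the plasmid pool) against
    which endpoint fold changes are computed.
    """

    guide_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    reference_sample: str
    _guide_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.guide_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.guide_ids)} guides, {len(self.sample_ids)} samples)"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_id")
        if len(set(self.guide_ids)) != len(self.guide_ids):
            raise ValueError("duplicate guide_id")
        if self.reference_sample not in self.sample_ids:
            raise ValueError(f"reference sample {self.reference_sample!r} not among samples")
        self._guide_index = {g: i for i, g in enumerate(self.guide_ids)}

    @property
    def n_guides(self) -> int:
        return len(self.guide_ids)

    def sample_column(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.guide_ids, name="guide_id"),
                            columns=self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        """Write counts TSV with the reference flagged in a header comment."""
        with open(path, "w") as fh:
            fh.write(f"#reference={self.reference_sample}\n")
            self.to_frame().to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, reference_sample: str | None = None) -> "CountTable":
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#reference="):
                ref = first.strip().split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t", index_col=0)
            else:
                ref = None
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", index_col=0, comment="#")
        ref = reference_sample or ref
        if ref is None:
            raise ValueError("no reference sample recorded in file or given")
        return cls(
            guide_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            counts=df.to_numpy(),
            reference_sample=ref,
        )


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_spacers(
    reads: str | Path | IO[str] | Iterable[tuple[str, str, str]],
    library: LibraryDesign,
    trim5: int = 0,
    spacer_len: int | None = None,
    revcomp: bool = False,
) -> tuple[dict[str, int], int]:
    """Count exact spacer matches in a FASTQ stream.

    Each read contributes to at most one guide: the substring
    ``[trim5, trim5 + spacer_len)`` must equal a library spacer exactly.
    With ``revcomp`` the reverse complement of the read is also searched
    (forward match wins).  Returns ``(per-guide counts, unmatched)``.

    ``reads`` may be a path (plain or ``.gz``), an open text handle, or an
    iterable of ``(title, sequence, quality)`` tuples.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    if trim5 < 0:
        raise ValueError("trim5 must be >= 0")
    lengths = {len(g.spacer) for g in library}
    if spacer_len is None:
        if len(lengths) != 1:
            raise ValueError(f"library has mixed spacer lengths {sorted(lengths)}; pass spacer_len")
        spacer_len = lengths.pop()
    elif spacer_len not in lengths:
        raise ValueError(f"spacer_len {spacer_len} matches no library spacer length {sorted(lengths)}")

    spacer_to_guide = {g.spacer: g.guide_id for g in library if len(g.spacer) == spacer_len}
    counts = {g.guide_id: 0 for g in library}
    unmatched = 0
    lo, hi = trim5, trim5 + spacer_len

    close = False
    if isinstance(reads, (str, Path)):
        fh = _open_maybe_gzip(reads)
        records: Iterable[tuple[str, str, str]] = _iter_fastq(fh)
        close = True
    elif hasattr(reads, "read"):
        records = _iter_fastq(reads)  # type: ignore[arg-type]
    else:
        records = reads  # pre-parsed tuples

    try:
        for _title, seq, _qual in records:
            sub = seq[lo:hi].upper()
            gid = spacer_to_guide.get(sub) if len(sub) == spacer_len else None
            if gid is None and revcomp:
                rc = _revcomp(seq.upper())
                gid = spacer_to_guide.get(rc[lo:hi]) if len(rc) >= hi else None
            if gid is None:
                unmatched += 1
            else:
                counts[gid] += 1
    finally:
        if close:
            fh.close()
    return counts, unmatched


def _iter_fastq(handle: IO[str]) -> Iterable[tuple[str, str, str]]:
    it = FastqGeneralIterator(handle)
    i = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqParseError(f"malformed FASTQ at record {i}: {exc}") from exc
        yield rec
        i += 1


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def assemble_count_table(
    sample_counts: Mapping[str, Mapping[str, int]],
    library: LibraryDesign,
    reference_sample: str,
) -> CountTable:
    """Assemble per-sample count maps into a CountTable.

    Guides absent from a map get count 0; column order follows the input
    mapping order; unknown guide ids are an error.
    """
    sample_ids = list(sample_counts)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id")
    if reference_sample not in sample_ids:
        raise ValueError(f"reference sample {reference_sample!r} not among samples")
    known = set(library.guide_ids)
    mat = np.zeros((len(library), len(sample_ids)), dtype=np.int64)
    gindex = {g: i for i, g in enumerate(library.guide_ids)}
    for j, sid in enumerate(sample_ids):
        unknown = sorted(set(sample_counts[sid]) - known)
        if unknown:
            raise ValueError(f"sample {sid!r} has unknown guide ids: {unknown[:10]}")
        for gid, c in sample_counts[sid].items():
            mat[gindex[gid], j] = c
    return CountTable(
        guide_ids=list(library.guide_ids),
        sample_ids=sample_ids,
        counts=mat,
        reference_sample=reference_sample,
    )
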