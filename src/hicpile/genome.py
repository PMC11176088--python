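"""Genome coordinate plumbing: chromosome sizes and genomic ranges.

All coordinates are 0-based half-open base pairs. Bins of size ``binsize``
tile each chromosome from its start; the last bin of a chromosome may be
short. Genome-wide bin ids are chromosome-local bin indices shifted by a
per-chromosome offset, in the order the chromosomes were declared — that
order is authoritative for all downstream sorting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Tuple

__all__ = ["ChromSizes", "GenomicRange"]


class ChromSizes:
    """Ordered chromosome name -> length (bp) table.

    Parameters
    ----------
    items:
        Iterable of ``(name, length)`` pairs. Names must be unique and
        lengths positive.
    """

    def __init__(self, items: Iterable[Tuple[str, int]]):
        names, lengths = [], []
        for name, length in items:
            name = str(name)
            length = int(length)
            if name in names:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            names.append(name)
            lengths.append(length)
        self._names = tuple(names)
        self._lengths = tuple(lengths)
        self._index = {n: i for i, n in enumerate(names)}

    @property
    def names(self) -> Tuple[str, ...]:
        return self._names

    @property
    def lengths(self) -> Tuple[int, ...]:
        return self._lengths

    def __len__(self) -> int:
        return len(self._names)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(zip(self._names, self._lengths))

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> int:
        try:
            return self._lengths[self._index[name]]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ChromSizes)
            and self._names == other._names
            and self._lengths == other._lengths
        )

    def __repr__(self) -> str:
        inner = ", ".join(f"{n}={l}" for n, l in self)
        return f"ChromSizes({inner})"

    # ------------------------------------------------------------------ bins
    def n_bins(self, binsize: int, chrom: str | None = None) -> int:
        """Number of bins at ``binsize`` for one chromosome or the genome."""
        if binsize <= 0:
            raise ValueError("binsize must be positive")
        if chrom is not None:
            return -(-self[chrom] // binsize)
        return sum(-(-l // binsize) for l in self._lengths)

    def offsets(self, binsize: int) -> dict:
        """Genome-wide bin id of the first bin of each chromosome."""
        out, acc = {}, 0
        for n, l in self:
            out[n] = acc
            acc += -(-l // binsize)
        return out

    def bin_span(self, chrom: str, binsize: int) -> Tuple[int, int]:
        """Half-open genome-wide bin interval covering ``chrom``."""
        off = self.offsets(binsize)[chrom]
        return off, off + self.n_bins(binsize, chrom)

    def bin_id(self, chrom: str, pos: int, binsize: int) -> int:
        """Genome-wide bin id containing base-pair position ``pos``."""
        length = self[chrom]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom!r} (length {length})")
        return self.offsets(binsize)[chrom] + pos // binsize

    def bin_chrom(self, gw_bin: int, binsize: int) -> Tuple[str, int]:
        """Map a genome-wide bin id back to ``(chrom, local_bin)``."""
        acc = 0
        for n, l in self:
            nb = -(-l // binsize)
            if gw_bin < acc + nb:
                return n, gw_bin - acc
            acc += nb
        raise ValueError(f"bin id {gw_bin} beyond genome ({acc} bins)")

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_file(cls, path) -> "ChromSizes":
        """Read a UCSC-style two-column chrom.sizes text file."""
        items = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
                items.append((fields[0], int(fields[1])))
        return cls(items)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for n, l in self:
                fh.write(f"{n}\t{l}\n")


@dataclass(frozen=True)
class GenomicRange:
    """A 0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid range {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2
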