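"""Sequence alignments, FASTA/PHYLIP I/O, and site-pattern compression.

Gaps (``-``), ``N``/``?`` and IUPAC ambiguity codes are treated as (partially)
missing data: a tip contributes a partial-likelihood row with ones for every
state compatible with the observed symbol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import AlignIO, SeqIO

__all__ = [
    "Alignment",
    "SitePatterns",
    "BASES",
    "compress_patterns",
    "empirical_frequencies",
]

BASES = "ACGT"

# symbol -> compatible-state row (A, C, G, T)
_IUPAC_ROWS = {
    "A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "T": (0, 0, 0, 1),
    "U": (0, 0, 0, 1),
    "R": (1, 0, 1, 0), "Y": (0, 1, 0, 1), "S": (0, 1, 1, 0), "W": (1, 0, 0, 1),
    "K": (0, 0, 1, 1), "M": (1, 1, 0, 0),
    "B": (0, 1, 1, 1), "D": (1, 0, 1, 1), "H": (1, 1, 0, 1), "V": (1, 1, 1, 0),
    "N": (1, 1, 1, 1), "-": (1, 1, 1, 1), "?": (1, 1, 1, 1), ".": (1, 1, 1, 1),
    "X": (1, 1, 1, 1),
}
_SYMBOLS = "".join(_IUPAC_ROWS)
SYMBOL_ROWS = np.array([_IUPAC_ROWS[s] for s in _SYMBOLS], dtype=float)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _s in enumerate(_SYMBOLS):
    _CODE[ord(_s)] = _i
    _CODE[ord(_s.lower())] = _i


class Alignment:
    """A multiple sequence alignment over DNA symbols.

    Stores sequences as a ``(n_taxa, n_sites)`` uint8 code matrix plus the
    taxon order; all sequences must have equal length.
    """

    def __init__(self, taxa, codes: np.ndarray):
        self.taxa = list(taxa)
        self.codes = np.asarray(codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be (n_taxa, n_sites)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        self._index = {t: i for i, t in enumerate(self.taxa)}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dict(cls, seqs: dict) -> "Alignment":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        n = lengths.pop() if lengths else 0
        codes = np.empty((len(taxa), n), dtype=np.uint8)
        for i, t in enumerate(taxa):
            raw = np.frombuffer(seqs[t].encode("ascii"), dtype=np.uint8)
            c = _CODE[raw]
            if (c == 255).any():
                bad = chr(raw[int(np.argmax(c == 255))])
                raise ValueError(f"unknown sequence symbol {bad!r} in {t}")
            codes[i] = c
        return cls(taxa, codes)

    @classmethod
    def read(cls, path_or_handle, fmt: str = "fasta") -> "Alignment":
        """Read an alignment (``fasta`` or relaxed ``phylip``)."""
        if fmt == "fasta":
            records = SeqIO.parse(path_or_handle, "fasta")
            return cls.from_dict({r.id: str(r.seq) for r in records})
        elif fmt == "phylip":
            aln = AlignIO.read(path_or_handle, "phylip-relaxed")
            return cls.from_dict({r.id: str(r.seq) for r in aln})
        raise ValueError(f"unsupported alignment format: {fmt}")

    # -- basics ------------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def sequence(self, taxon: str) -> str:
        return "".join(_SYMBOLS[c] for c in self.codes[self._index[taxon]])

    def to_dict(self) -> dict:
        return {t: self.sequence(t) for t in self.taxa}

    def write(self, handle, fmt: str = "fasta"):
        if isinstance(handle, str):
            with open(handle, "w") as fh:
                return self.write(fh, fmt)
        if fmt == "fasta":
            for t in self.taxa:
                handle.write(f">{t}\n{self.sequence(t)}\n")
        elif fmt == "phylip":
            handle.write(f" {self.n_taxa} {self.length}\n")
            width = max(len(t) for t in self.taxa) + 2
            for t in self.taxa:
                handle.write(t.ljust(width) + self.sequence(t) + "\n")
        else:
            raise ValueError(f"unsupported alignment format: {fmt}")

    def take_taxa(self, taxa) -> np.ndarray:
        missing = [t for t in taxa if t not in self._index]
        if missing:
            raise KeyError(f"taxa absent from alignment: {missing}")
        rows = [self._index[t] for t in taxa]
        return self.codes[rows]

    def __repr__(self):
        return f"<Alignment {self.n_taxa} taxa x {self.length} sites>"


@dataclass
class SitePatterns:
    """Unique alignment columns with multiplicities, over a fixed taxon order."""

    taxa: list
    codes: np.ndarray          # (n_taxa, n_patterns) uint8
    weights: np.ndarray        # (n_patterns,) positive ints
    n_sites: int

    @property
    def n_patterns(self) -> int:
        return self.codes.shape[1]

    def tip_partials(self) -> np.ndarray:
        """Partial-likelihood rows per tip: (n_taxa, n_patterns, 4)."""
        return SYMBOL_ROWS[self.codes]

    def __post_init__(self):
        if int(self.weights.sum()) != self.n_sites:
            raise ValueError("pattern weights do not sum to alignment length")


def compress_patterns(aln: Alignment, taxa) -> SitePatterns:
    """Collapse alignment columns (restricted to ``taxa``) to unique patterns.

    The likelihood of the compressed patterns, weighted by their counts,
    equals the likelihood over the raw columns.
    """
    sub = aln.take_taxa(taxa)
    if sub.shape[1] == 0:
        return SitePatterns(list(taxa), sub.copy(), np.zeros(0, dtype=np.int64), 0)
    cols = np.ascontiguousarray(sub.T)
    view = cols.view([("", cols.dtype)] * cols.shape[1]).ravel()
    # canonical (lexicographic) pattern order: invariant to column order
    _, first, counts = np.unique(view, return_index=True, return_counts=True)
    return SitePatterns(
        list(taxa), sub[:, first], counts.astype(np.int64), aln.length
    )


def empirical_frequencies(aln: Alignment, taxa, pseudo: float = 0.0) -> np.ndarray:
    """Observed A/C/G/T proportions over ``taxa`` (gaps/ambiguity excluded).

    ``pseudo`` adds a small pseudocount to every base, guarding degenerate
    partitions (e.g. all-A data) for downstream log/optimization use.
    """
    sub = aln.take_taxa(taxa)
    counts = np.array([(sub == _CODE[ord(b)]).sum() for b in BASES], dtype=float)
    # U counts as T
    counts[3] += (sub == _CODE[ord("U")]).sum()
    counts += pseudo
    total = counts.sum()
    if total <= 0:
        raise ValueError("no countable A/C/G/T characters in selection")
    return counts / total
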