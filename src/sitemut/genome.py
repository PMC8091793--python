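"""In-memory reference genome with FASTA IO.

Chromosome sequences are held as uint8 base-code arrays (A=0, C=1, G=2, T=3,
N=4), which the position-level machinery indexes directly.  Whole chromosomes
are materialised in memory; this suits the megabase-scale genomes the package
targets (simulated cohorts, per-region extracts of a reference).
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np

from . import trinuc


class Genome:
    """Mapping of chromosome name to base-code array."""

    def __init__(self, codes: Mapping[str, np.ndarray]):
        self._codes = {c: np.asarray(a, dtype=np.uint8) for c, a in codes.items()}

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str]) -> "Genome":
        return cls({c: trinuc.encode(s) for c, s in seqs.items()})

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls.from_sequences({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chroms(self) -> list[str]:
        return list(self._codes)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self._codes.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._codes

    def codes(self, chrom: str) -> np.ndarray:
        """Base-code array of a chromosome (read-only view)."""
        return self._codes[chrom]

    def seq(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open substring of a chromosome."""
        return trinuc.decode(self._codes[chrom][start:end])

    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self._codes.items():
                fh.write(f">{chrom}\n")
                s = trinuc.decode(arr)
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")

    def reverse_complement(self) -> "Genome":
        """Reverse-complemented copy (used for strand-symmetry checks)."""
        return Genome({c: trinuc.COMPLEMENT[a[::-1]] for c, a in self._codes.items()})
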