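"""Repeat-expansion oligo sequences with CpG 5-methylcytosine bookkeeping.

The hexanucleotide repeat expansion in *C9orf72* is written in run-length
notation, e.g. ``(GGGGCC)3GGGG`` for the 22-mer used throughout this package.
Because IUPAC has no one-letter code for 5-methylcytosine, methylation state
is carried as a per-position boolean flag alongside the plain A/C/G/T string,
and serialized as FASTA plus a JSON sidecar listing methylated positions.

All coordinates are 0-based; a CpG site is identified by the index of its C.
Only the given strand is scanned (the methylated oligo in the motivating
experiments is the coding, G-rich strand itself).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGT")

_REPEAT_RE = re.compile(r"^\(([ACGT]+)\)(\d+)([ACGT]*)$")


class InvalidAlphabetError(ValueError):
    """A base outside {A, C, G, T} was supplied."""


class InvalidSiteError(ValueError):
    """A methylation position does not index a cytosine."""


@dataclass(frozen=True)
class OligoSequence:
    """A DNA oligo with optional per-position 5mC flags.

    Parameters
    ----------
    bases : str
        Sequence 5'->3' over {A, C, G, T}.
    methyl_flags : tuple of bool
        True at positions carrying a 5-methylcytosine; must be C positions.
    name : str
        Free-text label, e.g. ``"C9-22mer"``.
    """

    bases: str
    methyl_flags: tuple[bool, ...] = field(default=())
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("sequence must have length >= 1")
        bad = set(self.bases) - ALPHABET
        if bad:
            raise InvalidAlphabetError(
                f"invalid characters {sorted(bad)} in sequence {self.name!r}"
            )
        flags = self.methyl_flags
        if not flags:
            object.__setattr__(self, "methyl_flags", (False,) * len(self.bases))
        elif len(flags) != len(self.bases):
            raise ValueError("methyl_flags length must match sequence length")
        else:
            for i, f in enumerate(flags):
                if f and self.bases[i] != "C":
                    raise InvalidSiteError(
                        f"methyl flag at position {i} but base is {self.bases[i]!r}"
                    )

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    @property
    def methylated_positions(self) -> list[int]:
        return [i for i, f in enumerate(self.methyl_flags) if f]


def expand_repeat(notation: str, n: int, suffix: str = "", name: str = "") -> OligoSequence:
    """Expand ``notation`` repeated ``n`` times followed by ``suffix``.

    ``expand_repeat("GGGGCC", 3, "GGGG")`` yields the 22-nt C9-22mer.
    A full run-length string like ``"(GGGGCC)3GGGG"`` may be given as
    ``notation`` with ``n`` omitted (see :func:`parse_repeat_notation`).
    """
    if n < 0:
        raise ValueError("repeat count must be >= 0")
    for part, label in ((notation, "repeat unit"), (suffix, "suffix")):
        bad = set(part) - ALPHABET
        if bad:
            raise InvalidAlphabetError(f"invalid characters {sorted(bad)} in {label}")
    return OligoSequence(bases=notation * n + suffix, name=name)


def parse_repeat_notation(text: str, name: str = "") -> OligoSequence:
    """Parse a run-length string such as ``"(GGGGCC)3GGGG"``."""
    m = _REPEAT_RE.match(text.strip().upper())
    if m is None:
        # plain sequence is accepted too
        return OligoSequence(bases=text.strip().upper(), name=name or text)
    unit, count, suffix = m.group(1), int(m.group(2)), m.group(3)
    return expand_repeat(unit, count, suffix, name=name or text)


def find_cpg_sites(seq: OligoSequence | str) -> list[int]:
    """0-based positions of every C immediately followed by G, ascending."""
    s = str(seq)
    return [i for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G"]


def apply_methylation(seq: OligoSequence, positions: Iterable[int]) -> OligoSequence:
    """Return a copy of ``seq`` with 5mC flags set at ``positions``.

    Every position must index a C; the letter sequence is unchanged.
    """
    flags = list(seq.methyl_flags)
    for p in positions:
        if p < 0 or p >= len(seq):
            raise InvalidSiteError(f"position {p} out of range for length {len(seq)}")
        if seq.bases[p] != "C":
            raise InvalidSiteError(
                f"position {p} is {seq.bases[p]!r}, not C; cannot methylate"
            )
        flags[p] = True
    return OligoSequence(bases=seq.bases, methyl_flags=tuple(flags), name=seq.name)


def c9_22mer(methylated: bool = False) -> OligoSequence:
    """The (GGGGCC)3GGGG 22-mer, optionally 5mC-flagged at all CpG sites."""
    seq = expand_repeat("GGGGCC", 3, "GGGG", name="mC9-22mer" if methylated else "C9-22mer")
    if methylated:
        seq = apply_methylation(seq, find_cpg_sites(seq))
    return seq


def write_fasta(seq: OligoSequence, path: str | Path, sidecar: bool = True) -> None:
    """Write FASTA; methylation goes to ``<path>.methyl.json`` if flagged."""
    path = Path(path)
    rec = SeqRecord(Seq(seq.bases), id=seq.name or "oligo", description="")
    SeqIO.write([rec], str(path), "fasta")
    if sidecar and any(seq.methyl_flags):
        sidecar_path = path.with_suffix(path.suffix + ".methyl.json")
        sidecar_path.write_text(
            json.dumps(
                {"name": seq.name, "methylated_positions": seq.methylated_positions},
                indent=2,
            )
        )


def read_fasta(path: str | Path) -> OligoSequence:
    """Read the first record of a FASTA file, picking up a methylation sidecar."""
    path = Path(path)
    rec = next(SeqIO.parse(str(path), "fasta"))
    seq = OligoSequence(bases=str(rec.seq).upper(), name=rec.id)
    sidecar_path = path.with_suffix(path.suffix + ".methyl.json")
    if sidecar_path.exists():
        info = json.loads(sidecar_path.read_text())
        seq = apply_methylation(seq, info.get("methylated_positions", []))
    return seq


def g_tracts(seq: OligoSequence | str, min_len: int = 2) -> list[tuple[int, int]]:
    """Maximal runs of G as half-open (start, stop) intervals, length >= min_len."""
    s = str(seq)
    tracts = []
    i = 0
    while i < len(s):
        if s[i] == "G":
            j = i
            while j < len(s) and s[j] == "G":
                j += 1
            if j - i >= min_len:
                tracts.append((i, j))
            i = j
        else:
            i += 1
    return tracts
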