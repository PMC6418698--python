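"""Minimal HGVS parsing for the notations this pipeline consumes.

Only the two notations that appear in annotated variant tables are
handled: three-letter protein substitutions / nonsense changes
(``p.Glu904*``, ``p.Asp1810Asn``) and coding-DNA substitutions with an
optional intronic offset (``c.4206+1G>C``, ``c.100-3C>G``).  Parsed values
round-trip to canonical text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["ProteinChange", "CodingChange", "HgvsError", "parse_hgvs_p", "parse_hgvs_c"]


class HgvsError(ValueError):
    """Raised for notation that cannot be parsed."""


AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

_P_RE = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|\*)\)?$")
_C_RE = re.compile(r"^c\.(\d+)([+-]\d+)?([ACGT]+)>([ACGT]+)$")


@dataclass(frozen=True)
class ProteinChange:
    """A protein-level substitution: reference residue, index, alternate.

    ``alt_aa`` is ``"*"`` for nonsense (stop-gained) changes.
    """

    ref_aa: str
    residue: int
    alt_aa: str

    @property
    def is_stop_gained(self) -> bool:
        return self.alt_aa == "*"

    def __str__(self) -> str:
        alt = "*" if self.alt_aa == "*" else AA_1TO3[self.alt_aa]
        return f"p.{AA_1TO3[self.ref_aa]}{self.residue}{alt}"


@dataclass(frozen=True)
class CodingChange:
    """A coding-DNA substitution with a signed intronic offset (0 = exonic)."""

    position: int
    offset: int
    ref: str
    alt: str

    def __str__(self) -> str:
        off = "" if self.offset == 0 else f"{self.offset:+d}"
        return f"c.{self.position}{off}{self.ref}>{self.alt}"


def parse_hgvs_p(text: str) -> ProteinChange:
    """Parse a three-letter HGVS protein substitution (``*`` = stop).

    >>> parse_hgvs_p("p.Glu904*")
    ProteinChange(ref_aa='E', residue=904, alt_aa='*')
    """
    m = _P_RE.match(text.strip())
    if not m:
        raise HgvsError(f"unparseable HGVS p. notation: {text!r}")
    ref3, idx, alt3 = m.groups()
    if ref3 not in AA_3TO1:
        raise HgvsError(f"unknown amino-acid token {ref3!r} in {text!r}")
    if alt3 != "*" and alt3 not in AA_3TO1:
        raise HgvsError(f"unknown amino-acid token {alt3!r} in {text!r}")
    alt = "*" if alt3 == "*" else AA_3TO1[alt3]
    return ProteinChange(ref_aa=AA_3TO1[ref3], residue=int(idx), alt_aa=alt)


def parse_hgvs_c(text: str) -> CodingChange:
    """Parse a coding-DNA HGVS substitution with an optional ±offset.

    >>> parse_hgvs_c("c.4206+1G>C")
    CodingChange(position=4206, offset=1, ref='G', alt='C')
    """
    m = _C_RE.match(text.strip())
    if not m:
        raise HgvsError(f"unparseable HGVS c. notation: {text!r}")
    pos, off, ref, alt = m.groups()
    return CodingChange(position=int(pos), offset=int(off or 0), ref=ref, alt=alt)
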