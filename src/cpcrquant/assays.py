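"""Amplicon geometry for the two competitive-PCR assays.

A competitive PCR (cPCR) assay co-amplifies an unknown *target* with a
size-modified internal standard (the *competitor*) that shares the same
primer sites.  The two products are distinguished on an agarose gel by
length; the competitor is always the shorter fragment so it migrates
farther.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AmpliconSpec:
    """A single PCR fragment: the target or its competitor.

    Parameters
    ----------
    name
        Human-readable fragment name.
    length_bp
        Amplified fragment size in base pairs.
    role
        Either ``"target"`` or ``"competitor"``.
    """

    name: str
    length_bp: int
    role: str

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"fragment length must be positive, got {self.length_bp}")
        if self.role not in ("target", "competitor"):
            raise ValueError(f"role must be 'target' or 'competitor', got {self.role!r}")


@dataclass(frozen=True)
class AmpliconPair:
    """Target/competitor pair defining one cPCR assay.

    ``cycles`` is the thermocycling count used when simulating the assay
    (34 for the methanogen 16S assay, 30 for the protozoa 18S assay).
    """

    taxon: str
    target: AmpliconSpec
    competitor: AmpliconSpec
    cycles: int = 30

    def __post_init__(self) -> None:
        if self.target.length_bp <= self.competitor.length_bp:
            raise ValueError(
                "target must be the longer fragment "
                f"({self.target.length_bp} vs {self.competitor.length_bp} bp)"
            )

    @property
    def length_ratio(self) -> float:
        """Target/competitor length ratio (the raw-intensity mode bias factor)."""
        return self.target.length_bp / self.competitor.length_bp


#: Methanogen 16S rRNA assay: 296 bp target vs 196 bp competitor, 34 cycles.
METHANOGEN = AmpliconPair(
    taxon="methanogen",
    target=AmpliconSpec("methanogen-16S-target", 296, "target"),
    competitor=AmpliconSpec("methanogen-16S-competitor", 196, "competitor"),
    cycles=34,
)

#: Protozoa 18S rRNA assay: 360 bp target vs 235 bp competitor, 30 cycles.
PROTOZOA = AmpliconPair(
    taxon="protozoa",
    target=AmpliconSpec("protozoa-18S-target", 360, "target"),
    competitor=AmpliconSpec("protozoa-18S-competitor", 235, "competitor"),
    cycles=30,
)

ASSAYS: dict[str, AmpliconPair] = {"methanogen": METHANOGEN, "protozoa": PROTOZOA}
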