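"""RNA nearest-neighbor stacking free energies.

The duplex-stability features treat the 19-nt antisense strand as fully
paired to its complement, so the free energy of the dinucleotide step
5'-XY-3' (paired with 3'-X'Y'-5') is a single table lookup.  The default
table is the Watson-Crick nearest-neighbor set of Xia et al. (1998),
deltaG(37 degC) in kcal/mol.  Because the two strands are complementary,
a step and its reverse complement share one parameter (e.g. AA == UU).

The table is swappable: any mapping covering all 16 dinucleotides can be
passed wherever an ``NNParameterTable`` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

_DINUCLEOTIDES = [a + b for a in "ACGU" for b in "ACGU"]

# Xia et al. 1998 Watson-Crick stacks, deltaG37 in kcal/mol, keyed by the
# 5'->3' dinucleotide of the given strand (complement implied).
XIA1998_STACKS: dict[str, float] = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}


@dataclass(frozen=True)
class NNParameterTable:
    """Nearest-neighbor stack free energies (kcal/mol), all 16 steps."""

    stack_dG: Mapping[str, float] = field(default_factory=lambda: dict(XIA1998_STACKS))
    source_name: str = "Xia et al. 1998 Watson-Crick dG37"

    def __post_init__(self) -> None:
        missing = [d for d in _DINUCLEOTIDES if d not in self.stack_dG]
        if missing:
            raise ValueError(f"missing stack entries: {missing}")

    def __getitem__(self, dinucleotide: str) -> float:
        try:
            return self.stack_dG[dinucleotide]
        except KeyError:
            raise KeyError(
                f"no stack entry for {dinucleotide!r} in table "
                f"{self.source_name!r}"
            ) from None


DEFAULT_NN_TABLE = NNParameterTable()
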