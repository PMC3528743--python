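"""Core data containers for siRNA efficacy modeling.

An siRNA is represented by its 19-nt antisense (guide) strand written
5'->3'.  Efficacy values are on a normalized [0, 1] scale where *lower*
values mean stronger silencing (residual target expression after
knockdown).  A ``DomainDataset`` bundles the numeric design matrix and
output vector for one domain (one target mRNA or one experimental
platform) in the transfer-learning setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

SIRNA_LENGTH = 19
RNA_ALPHABET = frozenset("ACGU")

#: efficacy below this value marks an siRNA as "active" (strong knockdown)
ACTIVE_THRESHOLD = 0.3


class SequenceError(ValueError):
    """Raised for sequences that fail siRNA validation."""


def normalize_sequence(raw: str, length: int | None = SIRNA_LENGTH) -> str:
    """Normalize a nucleotide string to the RNA alphabet.

    Uppercases and converts T->U (DNA-alphabet input is accepted).
    Ambiguity codes are rejected rather than treated as wildcards.

    Parameters
    ----------
    raw
        Input sequence, DNA or RNA alphabet, any case.
    length
        Required length (19 for the siRNA context); ``None`` disables the
        length check.

    Raises
    ------
    SequenceError
        On empty input, wrong length, or characters outside {A, C, G, U}.
    """
    if not raw:
        raise SequenceError("empty sequence")
    seq = raw.strip().upper().replace("T", "U")
    if length is not None and len(seq) != length:
        raise SequenceError(
            f"expected a {length}-nt sequence, got {len(seq)} nt: {raw!r}"
        )
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise SequenceError(
            f"invalid characters {sorted(bad)} in sequence {raw!r} "
            "(ambiguity codes are not accepted)"
        )
    return seq


@dataclass(frozen=True)
class SirnaRecord:
    """One siRNA: 19-nt antisense sequence plus measured efficacy.

    ``efficacy`` may be ``None`` for prediction-only records.
    """

    id: str
    antisense: str
    efficacy: Optional[float] = None
    target_accession: Optional[str] = None
    domain_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "antisense", normalize_sequence(self.antisense))
        if self.efficacy is not None and not (0.0 <= self.efficacy <= 1.0):
            raise ValueError(
                f"efficacy {self.efficacy} outside [0, 1] for record {self.id!r}"
            )

    @property
    def is_active(self) -> bool:
        """Whether this siRNA is an active silencer (efficacy < 0.3)."""
        if self.efficacy is None:
            raise ValueError("record has no efficacy value")
        return self.efficacy < ACTIVE_THRESHOLD


@dataclass
class DomainDataset:
    """A named domain's feature matrix and output vector.

    role is "target" for the scarce dataset of interest and "source" for
    datasets mined for transferable samples.
    """

    name: str
    X: np.ndarray
    y: np.ndarray
    role: str = "source"
    feature_names: Optional[list[str]] = None
    records: Optional[Sequence[SirnaRecord]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"{self.name}: X has {self.X.shape[0]} rows but y has "
                f"{self.y.shape[0]} entries"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, indices: np.ndarray, role: str | None = None) -> "DomainDataset":
        """Row-subset view of this domain (records carried along if present)."""
        indices = np.asarray(indices)
        recs = None
        if self.records is not None:
            recs = [self.records[i] for i in indices]
        return DomainDataset(
            name=self.name,
            X=self.X[indices],
            y=self.y[indices],
            role=role or self.role,
            feature_names=self.feature_names,
            records=recs,
        )
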