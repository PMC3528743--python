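"""siRNA feature engine: compositional, motif, thermodynamic and
structural descriptors of the 19-nt antisense strand.

Positions are 1-based from the 5' end (NT1..NT19) and all windows are
closed intervals, so "dG in NT[1,2]" is the single stack at positions
1-2 and "UCUG in NT[1..19]" counts overlapping occurrences of that
tetramer anywhere in the strand.

Feature families
----------------
positional_base   "U @ NT1" -- base identity indicators.
kmer_count        "CC in NT[1..19]" -- overlapping motif counts.
gc_content        real-valued G+C fraction of a window.
gc_threshold      "GC content <0.55" -- strict-inequality indicators.
thermo            nearest-neighbor stack sums ("SUM of dG", "dG in
                  NT[1,2]") and 5'/3' end-asymmetry differences
                  ("dG(NT[1,2]) - dG(NT[18,19])").
structural        intramolecular self-folding: maximum base-pair count
                  of the strand ("Folding in NT[1..19]"), per-position
                  pairing indicators ("NT18 forms bond"), and G-run
                  indicators ("G stretch of length >= 3").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Iterable, Sequence

import numpy as np

from .nn_params import DEFAULT_NN_TABLE, NNParameterTable
from .records import SIRNA_LENGTH, SirnaRecord, normalize_sequence

Window = tuple[int, int]  # 1-based closed interval

FULL_WINDOW: Window = (1, SIRNA_LENGTH)

#: Watson-Crick plus G.U wobble pairs allowed in self-folding
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)

DEFAULT_MIN_LOOP = 3
DEFAULT_GC_THRESHOLDS = (0.35, 0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70, 0.75)


def _check_window(window: Window, n: int) -> None:
    lo, hi = window
    if not (1 <= lo <= hi <= n):
        raise ValueError(f"window {window} outside [1, {n}]")


def _slice(seq: str, window: Window) -> str:
    lo, hi = window
    return seq[lo - 1 : hi]


# ---------------------------------------------------------------------------
# single-feature operations
# ---------------------------------------------------------------------------

def positional_base(seq: str, position: int, base: str) -> int:
    """1 iff the base at 1-based ``position`` (from the 5' end) is ``base``."""
    if not (1 <= position <= len(seq)):
        raise ValueError(f"position {position} out of range 1..{len(seq)}")
    return int(seq[position - 1] == base)


def kmer_count(seq: str, kmer: str, window: Window = FULL_WINDOW) -> int:
    """Overlapping occurrence count of ``kmer`` within ``window``."""
    if not kmer:
        raise ValueError("empty k-mer")
    _check_window(window, len(seq))
    sub = _slice(seq, window)
    k = len(kmer)
    if k > len(sub):
        raise ValueError(f"k-mer {kmer!r} longer than window {window}")
    return sum(1 for i in range(len(sub) - k + 1) if sub[i : i + k] == kmer)


def gc_content(seq: str, window: Window = FULL_WINDOW) -> float:
    """(#G + #C) / window length."""
    _check_window(window, len(seq))
    sub = _slice(seq, window)
    return (sub.count("G") + sub.count("C")) / len(sub)


def gc_threshold(
    seq: str, threshold: float, direction: str, window: Window = FULL_WINDOW
) -> int:
    """1 iff the GC content satisfies the strict inequality.

    ``direction`` is "<" or ">" (e.g. "GC content <0.55").
    """
    gc = gc_content(seq, window)
    if direction == "<":
        return int(gc < threshold)
    if direction == ">":
        return int(gc > threshold)
    raise ValueError(f"direction must be '<' or '>', got {direction!r}")


def stack_dg(
    seq: str, window: Window = FULL_WINDOW, table: NNParameterTable = DEFAULT_NN_TABLE
) -> float:
    """Sum of nearest-neighbor stack free energies over ``window``.

    A window spanning m positions contributes m-1 consecutive
    dinucleotide stacks; "SUM of dG" is the full NT[1..19] window
    (18 stacks), "dG in NT[1,2]" is the single terminal stack.
    """
    lo, hi = window
    _check_window(window, len(seq))
    if hi - lo < 1:
        raise ValueError(f"window {window} must span >= 2 positions")
    return float(sum(table[seq[i : i + 2]] for i in range(lo - 1, hi - 1)))


def sum_dg_kmers(
    seq: str, k: int = 4, table: NNParameterTable = DEFAULT_NN_TABLE
) -> float:
    """Sum of window free energies over every k-mer window ("SUM of dG4").

    Each contiguous k-position window NT[i..i+k-1] contributes its k-1
    stack terms; the windows overlap, so interior stacks are counted in
    several windows.
    """
    n = len(seq)
    if k < 2 or k > n:
        raise ValueError(f"k={k} out of range for length-{n} sequence")
    return float(sum(stack_dg(seq, (i, i + k - 1), table) for i in range(1, n - k + 2)))


def end_asymmetry(
    seq: str,
    five_prime_window: Window,
    three_prime_window: Window,
    table: NNParameterTable = DEFAULT_NN_TABLE,
) -> float:
    """Stability difference between the 5' and 3' ends of the strand.

    stack_dg(five_prime_window) - stack_dg(three_prime_window); efficient
    siRNAs typically show a less stable 5' antisense end.
    """
    return stack_dg(seq, five_prime_window, table) - stack_dg(
        seq, three_prime_window, table
    )


def self_fold(seq: str, min_loop: int = DEFAULT_MIN_LOOP) -> tuple[int, np.ndarray]:
    """Maximum intramolecular base pairing of a single strand.

    Nussinov-style dynamic program maximizing Watson-Crick + G.U pairs
    with hairpin loops of at least ``min_loop`` unpaired bases.  Returns
    the maximum pair count and a 0/1 per-position "forms bond" vector
    from one deterministic optimal traceback (pairing is preferred over
    leaving a base unpaired; among equally good partners the 5'-most is
    taken).
    """
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")
    max_pairs, paired = _self_fold_cached(seq, min_loop)
    return max_pairs, np.array(paired, dtype=int)


@lru_cache(maxsize=4096)
def _self_fold_cached(seq: str, min_loop: int) -> tuple[int, tuple[int, ...]]:
    n = len(seq)
    N = np.zeros((n, n), dtype=int)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if (seq[i], seq[k]) in CANONICAL_PAIRS:
                    inner = N[i + 1, k - 1] if k - 1 > i else 0
                    rest = N[k + 1, j] if k + 1 <= j else 0
                    best = max(best, 1 + inner + rest)
            N[i, j] = best

    paired = np.zeros(n, dtype=int)

    def trace(i: int, j: int) -> None:
        while i < j:
            target = N[i, j]
            if target == 0:
                return
            chosen = None
            for k in range(i + min_loop + 1, j + 1):
                if (seq[i], seq[k]) in CANONICAL_PAIRS:
                    inner = N[i + 1, k - 1] if k - 1 > i else 0
                    rest = N[k + 1, j] if k + 1 <= j else 0
                    if 1 + inner + rest == target:
                        chosen = k
                        break
            if chosen is None:
                i += 1  # base i stays unpaired
                continue
            paired[i] = paired[chosen] = 1
            if chosen - 1 > i:
                trace(i + 1, chosen - 1)
            i = chosen + 1

    if n > 1:
        trace(0, n - 1)
    max_pairs = int(N[0, n - 1]) if n > 1 else 0
    return max_pairs, tuple(int(v) for v in paired)


def g_stretch(seq: str, min_len: int = 3) -> int:
    """1 iff the sequence contains a run of >= ``min_len`` consecutive G."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return int("G" * min_len in seq)


# ---------------------------------------------------------------------------
# feature catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDefinition:
    feature_id: int
    name: str
    family: str
    compute: Callable[[str], float]


@dataclass
class FeatureCatalog:
    """Ordered list of feature definitions; features are addressed by name."""

    definitions: list[FeatureDefinition]
    nn_table: NNParameterTable = field(default=DEFAULT_NN_TABLE)

    def __post_init__(self) -> None:
        names = [d.name for d in self.definitions]
        if len(set(names)) != len(names):
            dupes = {n for n in names if names.count(n) > 1}
            raise ValueError(f"duplicate feature names: {sorted(dupes)}")
        for i, d in enumerate(self.definitions):
            if d.feature_id != i:
                raise ValueError("feature_id must be a dense 0-based ordering")

    def __len__(self) -> int:
        return len(self.definitions)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.definitions]

    def index_of(self, name: str) -> int:
        for d in self.definitions:
            if d.name == name:
                return d.feature_id
        raise KeyError(f"no feature named {name!r}")


def _fmt_window(window: Window) -> str:
    lo, hi = window
    if hi - lo == 1:
        return f"NT[{lo},{hi}]"
    return f"NT[{','.join(str(i) for i in range(lo, hi + 1))}]"


def default_catalog(
    kmer_lengths: Iterable[int] = (1, 2),
    extra_kmers: Iterable[str] = (),
    gc_thresholds: Sequence[float] = DEFAULT_GC_THRESHOLDS,
    nn_table: NNParameterTable = DEFAULT_NN_TABLE,
    min_loop: int = DEFAULT_MIN_LOOP,
) -> FeatureCatalog:
    """Build the default siRNA feature catalog (146 features).

    Enumerates positional base indicators (4 x 19), overlapping k-mer
    counts for the configured k-mer lengths plus any explicitly listed
    motifs, GC content with strict threshold indicators in both
    directions, the nearest-neighbor thermodynamic terms and 5'/3'
    asymmetry differences, and the self-folding / G-stretch structural
    features.
    """
    defs: list[FeatureDefinition] = []

    def add(name: str, family: str, fn: Callable[[str], float]) -> None:
        defs.append(FeatureDefinition(len(defs), name, family, fn))

    for pos in range(1, SIRNA_LENGTH + 1):
        for base in "ACGU":
            add(
                f"{base} @ NT{pos}",
                "positional_base",
                lambda s, p=pos, b=base: positional_base(s, p, b),
            )

    kmers: list[str] = []
    for k in kmer_lengths:
        kmers.extend("".join(t) for t in itertools.product("ACGU", repeat=k))
    for km in extra_kmers:
        km = normalize_sequence(km, length=None)
        if km not in kmers:
            kmers.append(km)
    for km in kmers:
        add(
            f"{km} in NT[1..19]",
            "kmer_count",
            lambda s, m=km: kmer_count(s, m),
        )

    add("GC content in NT[1..19]", "gc_content", gc_content)
    for t in gc_thresholds:
        add(
            f"GC content <{t:g}",
            "gc_threshold",
            lambda s, th=t: gc_threshold(s, th, "<"),
        )
    for t in gc_thresholds:
        add(
            f"GC content >{t:g}",
            "gc_threshold",
            lambda s, th=t: gc_threshold(s, th, ">"),
        )

    thermo_windows: list[tuple[str, Window]] = [
        ("dG in NT[1,2]", (1, 2)),
        ("dG in NT[18,19]", (18, 19)),
        ("dG in NT[1..4]", (1, 4)),
        ("dG in NT[16..19]", (16, 19)),
    ]
    for name, win in thermo_windows:
        add(name, "thermo", lambda s, w=win: stack_dg(s, w, nn_table))
    add("SUM of dG", "thermo", lambda s: stack_dg(s, FULL_WINDOW, nn_table))
    add("SUM of dG4", "thermo", lambda s: sum_dg_kmers(s, 4, nn_table))

    asym: list[tuple[Window, Window]] = [
        ((1, 2), (18, 19)),
        ((1, 4), (18, 19)),
        ((1, 2), (16, 19)),
        ((1, 4), (16, 19)),
    ]
    for five, three in asym:
        add(
            f"dG({_fmt_window(five)}) - dG({_fmt_window(three)})",
            "thermo",
            lambda s, a=five, b=three: end_asymmetry(s, a, b, nn_table),
        )

    add(
        "Folding in NT[1..19]",
        "structural",
        lambda s: self_fold(s, min_loop)[0],
    )
    for pos in range(1, SIRNA_LENGTH + 1):
        add(
            f"NT{pos} forms bond",
            "structural",
            lambda s, p=pos: int(self_fold(s, min_loop)[1][p - 1]),
        )
    add("G stretch of length >= 3", "structural", lambda s: g_stretch(s, 3))

    return FeatureCatalog(defs, nn_table)


@dataclass
class FeatureMatrix:
    """Numeric design matrix: one row per record, one column per feature."""

    values: np.ndarray
    catalog: FeatureCatalog
    record_ids: list[str]

    @property
    def feature_names(self) -> list[str]:
        return self.catalog.names


def compute_features(seq: str, catalog: FeatureCatalog) -> np.ndarray:
    """Feature vector of one validated sequence under ``catalog``.

    The self-folding DP is memoized, so the "Folding" count and the 19
    "NTi forms bond" indicators all come from one optimal structure.
    """
    row = np.empty(len(catalog))
    for d in catalog.definitions:
        row[d.feature_id] = d.compute(seq)
    return row


def build_feature_matrix(
    records: Sequence[SirnaRecord], catalog: FeatureCatalog | None = None
) -> FeatureMatrix:
    """Compute the design matrix for a list of validated records."""
    if catalog is None:
        catalog = default_catalog()
    if not records:
        return FeatureMatrix(
            np.empty((0, len(catalog))), catalog, record_ids=[]
        )
    values = np.vstack([compute_features(r.antisense, catalog) for r in records])
    return FeatureMatrix(values, catalog, record_ids=[r.id for r in records])
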