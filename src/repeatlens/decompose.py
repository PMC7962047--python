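"""Error-tolerant decomposition of a repeat tract into triplet motif runs.

A circular-consensus read at ~QV20 carries roughly one error per hundred
bases, so a naive codon walk over the tract desynchronises at the first
indel.  The decomposer here walks codons greedily in the best reading frame
and, on a codon outside the motif alphabet, tries small shifts of the
reading point to re-synchronise; the skipped or duplicated bases are charged
as a single OTHER unit so that isolated errors do not bias the unit count.
A full dynamic-programming alternative exists as a test oracle only: greedy
is linear-time on multi-kilobase tracts and the property suite quantifies
the residual disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .patterns import (
    CTG,
    OTHER,
    InterruptionInventory,
    MotifRun,
    PatternError,
    canonical_string,
    inventory_from_units,
    merge_runs,
    pattern_from_units,
)

DEFAULT_ALPHABET = ("CTG", "CCG", "CAG", "CTC")


class NoisyReadError(ValueError):
    """Raised when a call is too noisy to be rendered as a pattern string."""


@dataclass(frozen=True)
class DecomposerConfig:
    motif_alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    max_noise_fraction: float = 0.1
    resync_window: int = 2  # nt

    def __post_init__(self) -> None:
        if len(set(self.motif_alphabet)) != len(self.motif_alphabet):
            raise ValueError("motif alphabet must be pairwise distinct")
        for m in self.motif_alphabet:
            if len(m) != 3:
                raise ValueError(f"alphabet motif {m!r} is not a triplet")


@dataclass
class RepeatCall:
    """Per-read decomposition result."""

    read_id: str
    total_units: int
    runs: tuple[MotifRun, ...]
    inventory: InterruptionInventory
    noise_units: int
    frame_offset: int
    units: list[str] = field(repr=False, default_factory=list)

    @property
    def noise_fraction(self) -> float:
        return self.noise_units / self.total_units if self.total_units else 0.0

    def is_noisy(self, config: DecomposerConfig | None = None) -> bool:
        config = config or DecomposerConfig()
        return self.noise_fraction > config.max_noise_fraction


def choose_frame(tract: str, alphabet: tuple[str, ...] = DEFAULT_ALPHABET) -> int:
    """Reading-frame offset (0, 1 or 2) for the codon walk.

    The tract's 5' boundary comes from flank anchoring, so the correct frame
    is the one that reads alphabet codons earliest: the offset whose first
    pair of consecutive in-alphabet codons starts closest to the 5' end wins
    (a mid-tract indel switches the frame regime, which a global codon count
    would mis-vote on).  Tracts with no confirmed pair fall back to the
    offset maximising in-alphabet codons.  Ties break toward the smaller
    offset for determinism.
    """
    aset = frozenset(alphabet)
    confirmed: list[tuple[int, int]] = []
    counts = []
    for off in (0, 1, 2):
        count = 0
        first_pair = None
        for i in range(off, len(tract) - 2, 3):
            good = tract[i : i + 3] in aset
            count += good
            if good and first_pair is None and tract[i + 3 : i + 6] in aset and i + 6 <= len(tract):
                first_pair = i
        counts.append(count)
        if first_pair is not None:
            confirmed.append((first_pair, off))
    if confirmed:
        return min(confirmed)[1]
    best = max(range(3), key=lambda off: (counts[off], -off))
    return best


def decompose(tract: str, config: DecomposerConfig | None = None, read_id: str = "") -> RepeatCall:
    """Classify the tract's codons into motif units, re-syncing across errors.

    On a codon outside the alphabet, the reading point is shifted by
    +-1..resync_window nt; a shift is accepted when it resumes two
    consecutive alphabet codons, and the bases consumed become one OTHER
    unit.  Boundary conventions: a frame offset of 2 charges the two leading
    bases as one OTHER unit, as does a 2-nt trailing remainder (a broken
    terminal unit); single stray bases are ignored.
    """
    config = config or DecomposerConfig()
    aset = frozenset(config.motif_alphabet)
    L = len(tract)
    if L < 3:
        inv = inventory_from_units([])
        return RepeatCall(read_id, 0, (), inv, 0, 0)

    frame = choose_frame(tract, config.motif_alphabet)
    units: list[str] = []
    if frame == 2:  # two leading bases = one broken unit
        units.append(OTHER)
    pos = frame
    deltas = [d for step in range(1, config.resync_window + 1) for d in (step, -step)]
    while pos + 3 <= L:
        codon = tract[pos : pos + 3]
        if codon in aset:
            units.append(codon)
            pos += 3
            continue
        resumed = None
        for need_two in (True, False):  # prefer shifts confirmed by two codons
            for d in deltas:
                q = pos + 3 + d
                if q <= pos or q + 3 > L:
                    continue
                if tract[q : q + 3] not in aset:
                    continue
                if need_two and (q + 6 > L or tract[q + 3 : q + 6] not in aset):
                    continue
                resumed = q
                break
            if resumed is not None:
                break
        consumed = (resumed - pos) if resumed is not None else 3
        # charge one OTHER unit per ~3 consumed nt; a single consumed nt is a
        # pure insertion and no unit at all
        units.extend([OTHER] * round(consumed / 3))
        pos = resumed if resumed is not None else pos + 3
    if L - pos == 2:  # broken terminal unit
        units.append(OTHER)

    runs = merge_runs(units)
    inv = inventory_from_units(units)
    return RepeatCall(
        read_id=read_id,
        total_units=len(units),
        runs=runs,
        inventory=inv,
        noise_units=inv.other_units,
        frame_offset=frame,
        units=units,
    )


def call_pattern(call: RepeatCall, config: DecomposerConfig | None = None) -> str:
    """Canonical pattern string for a call; OTHER runs are dropped.

    Refuses to render calls whose noise fraction exceeds the configured
    maximum — those reads are flagged rather than given a pattern.
    """
    config = config or DecomposerConfig()
    if call.is_noisy(config):
        raise NoisyReadError(
            f"read {call.read_id!r}: noise fraction {call.noise_fraction:.3f} exceeds "
            f"{config.max_noise_fraction}"
        )
    clean = [u for u in call.units if u != OTHER]
    if not clean:
        raise PatternError(f"read {call.read_id!r}: no alphabet units to render")
    return canonical_string(pattern_from_units(clean, label=call.read_id))


def interruption_count(call: RepeatCall, motif: str) -> int:
    """Units of a given interruption motif in a call (0 for CTG-only reads)."""
    if motif == CTG:
        raise ValueError("CTG is the repeat motif, not an interruption")
    return call.inventory.count(motif)
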