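"""31-bit acoustic tag-code messages: bit layout, CRC-8, validation, mimic codes.

Acoustic microtransmitters of the JSATS family emit a uniquely coded 31-bit
message whose final 8 bits carry a cyclic redundancy check (CRC) over the tag
identifier.  A receiver accepts a decoded word only when the recomputed CRC
matches the embedded one; because the check is 8 bits wide, a uniformly random
word still validates with probability 1/256, which is the origin of the
false-positive decodes the downstream filter cascade removes.

The true over-the-air bit layout and CRC parameters of commercial hardware are
not public.  This module fixes a concrete, self-consistent layout — a 7-bit
sync pattern, a 16-bit tag identifier (65,536 codes) and an 8-bit CRC, 31 bits
total — with the standard CRC-8 generator x^8 + x^2 + x + 1 (0x07), zero
initial value, MSB-first, no reflection, no output XOR.  All parameters are
configurable; no interoperability with real hardware is implied.

A "mimic" tag-code arises when bit corruption of a real transmission yields a
different identifier whose corrupted CRC still matches: because the CRC is
linear over bit-XOR, an error pattern e = (e_id, e_crc) turns any valid
codeword into another valid codeword exactly when crc(e_id) == e_crc
(a *zero-syndrome* pattern), independent of the source identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CrcConfig",
    "MessageLayout",
    "MimicRelation",
    "DEFAULT_LAYOUT",
    "crc8",
    "crc8_bits",
    "encode",
    "validate_decode",
    "validate_words",
    "random_valid_ids",
    "mimic_candidates",
    "mimic_table",
    "format_tag_id",
    "parse_tag_id",
]


@dataclass(frozen=True)
class CrcConfig:
    """Parameters of an 8-bit CRC in the unreflected, zero-init configuration."""

    poly: int = 0x07
    init: int = 0x00
    width: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.poly < (1 << self.width):
            raise ValueError("polynomial must fit in the CRC width (implicit leading 1)")
        if not 0 <= self.init < (1 << self.width):
            raise ValueError("init must fit in the CRC width")

    @property
    def table(self) -> np.ndarray:
        return _crc_table(self.poly, self.width)


@lru_cache(maxsize=None)
def _crc_table(poly: int, width: int) -> np.ndarray:
    """Byte-indexed lookup table for MSB-first CRC updates (width 8 only)."""
    if width != 8:
        raise ValueError("lookup table is only built for 8-bit CRCs")
    top = 1 << (width - 1)
    mask = (1 << width) - 1
    table = np.empty(256, dtype=np.uint32)
    for byte in range(256):
        reg = byte
        for _ in range(8):
            reg = ((reg << 1) ^ poly) & mask if reg & top else (reg << 1) & mask
        table[byte] = reg
    return table


@dataclass(frozen=True)
class MessageLayout:
    """Bit layout of the 31-bit tag message: sync | id | crc (MSB first)."""

    sync_bits: int = 7
    id_bits: int = 16
    crc_bits: int = 8
    sync_pattern: int = 0b1110010  # Barker-7 sequence
    crc: CrcConfig = field(default_factory=CrcConfig)

    def __post_init__(self) -> None:
        if self.total_bits != 31:
            raise ValueError("sync + id + crc widths must total 31 bits")
        if (1 << self.id_bits) < 65_000:
            raise ValueError("id space must hold at least 65,000 tag-codes")
        if self.crc.width != self.crc_bits:
            raise ValueError("CRC configuration width must match crc_bits")
        if not 0 <= self.sync_pattern < (1 << self.sync_bits):
            raise ValueError("sync pattern must fit in sync_bits")

    @property
    def total_bits(self) -> int:
        return self.sync_bits + self.id_bits + self.crc_bits

    @property
    def n_codes(self) -> int:
        return 1 << self.id_bits


DEFAULT_LAYOUT = MessageLayout()


def _as_bits(payload: str | Sequence[int]) -> list[int]:
    if isinstance(payload, str):
        if set(payload) - {"0", "1"}:
            raise ValueError("bit string may contain only '0' and '1'")
        return [int(ch) for ch in payload]
    bits = list(payload)
    if any(b not in (0, 1) for b in bits):
        raise ValueError("bit sequence entries must be 0 or 1")
    return bits


def crc8_bits(payload: str | Sequence[int], config: CrcConfig | None = None) -> int:
    """CRC over an arbitrary-length bit sequence, MSB first.

    This is the widened form used for cross-checking against published check
    values of byte-oriented CRC-8 (e.g. the 72-bit payload b"123456789").
    """
    cfg = config or CrcConfig()
    bits = _as_bits(payload)
    top = 1 << (cfg.width - 1)
    mask = (1 << cfg.width) - 1
    reg = cfg.init
    for b in bits:
        reg ^= b << (cfg.width - 1)
        reg = ((reg << 1) ^ cfg.poly) & mask if reg & top else (reg << 1) & mask
    return reg


def crc8(payload: int | str | Sequence[int], layout: MessageLayout = DEFAULT_LAYOUT) -> int:
    """Checksum of a tag-identifier payload of exactly ``layout.id_bits`` bits.

    ``payload`` may be the integer identifier or an explicit bit sequence.
    Deterministic, and linear over bit-XOR in this (unreflected, zero-init)
    configuration: ``crc8(a ^ b) == crc8(a) ^ crc8(b)``.
    """
    if isinstance(payload, (int, np.integer)):
        if not 0 <= payload < (1 << layout.id_bits):
            raise ValueError(f"identifier must be in [0, 2^{layout.id_bits})")
        bits = [(int(payload) >> (layout.id_bits - 1 - i)) & 1 for i in range(layout.id_bits)]
    else:
        bits = _as_bits(payload)
        if len(bits) != layout.id_bits:
            raise ValueError(f"payload must be exactly {layout.id_bits} bits")
    return crc8_bits(bits, layout.crc)


def encode(tag_id: int, layout: MessageLayout = DEFAULT_LAYOUT) -> int:
    """31-bit codeword sync|id|crc for a tag identifier."""
    if not 0 <= tag_id < layout.n_codes:
        raise ValueError(f"identifier must be in [0, {layout.n_codes})")
    check = crc8(tag_id, layout)
    return (
        (layout.sync_pattern << (layout.id_bits + layout.crc_bits))
        | (tag_id << layout.crc_bits)
        | check
    )


def _word_from_input(codeword: int | str, layout: MessageLayout) -> int:
    if isinstance(codeword, str):
        if len(codeword) != layout.total_bits:
            raise ValueError(f"codeword must be {layout.total_bits} bits")
        return int(codeword, 2)
    word = int(codeword)
    if not 0 <= word < (1 << layout.total_bits):
        raise ValueError(f"codeword must be a {layout.total_bits}-bit word")
    return word


def validate_decode(
    codeword: int | str, layout: MessageLayout = DEFAULT_LAYOUT
) -> tuple[int, bool]:
    """Extract (identifier, is_valid) from a received 31-bit word.

    Validity compares the recomputed CRC of the id field with the embedded CRC
    field only — the acceptance test real receivers apply after demodulation.
    A uniformly random word therefore validates with probability 2^-crc_bits
    (1/256 for the default layout).
    """
    word = _word_from_input(codeword, layout)
    crc_field = word & ((1 << layout.crc_bits) - 1)
    tag_id = (word >> layout.crc_bits) & ((1 << layout.id_bits) - 1)
    return tag_id, crc8(tag_id, layout) == crc_field


def validate_words(words: np.ndarray, layout: MessageLayout = DEFAULT_LAYOUT) -> np.ndarray:
    """Vectorized validity check for an array of 31-bit words.

    Table-driven two-byte CRC update over the 16-bit id field; equivalent to
    ``validate_decode`` element-wise.
    """
    if layout.id_bits != 16 or layout.crc.width != 8:
        return np.array([validate_decode(int(w), layout)[1] for w in words])
    w = np.asarray(words, dtype=np.uint64)
    table = layout.crc.table
    crc_field = (w & np.uint64((1 << layout.crc_bits) - 1)).astype(np.uint32)
    tag = (w >> np.uint64(layout.crc_bits)) & np.uint64(0xFFFF)
    hi = (tag >> np.uint64(8)).astype(np.intp)
    lo = (tag & np.uint64(0xFF)).astype(np.intp)
    init = np.uint32(layout.crc.init)
    crc = table[(table[init ^ hi] ^ lo)]
    return crc == crc_field


def random_valid_ids(
    n: int, rng: np.random.Generator, layout: MessageLayout = DEFAULT_LAYOUT
) -> np.ndarray:
    """Identifiers of ``n`` random words that happen to pass validation.

    Emulates the id content of environmental false-positive decodes: uniform
    random words are drawn, the ~1/256 that validate are kept, and their id
    fields returned (uniform over the id space by CRC linearity).
    """
    out: list[np.ndarray] = []
    got = 0
    while got < n:
        batch = rng.integers(0, 1 << layout.total_bits, size=max(4096, 300 * (n - got)))
        ok = validate_words(batch, layout)
        ids = (batch[ok] >> layout.crc_bits) & ((1 << layout.id_bits) - 1)
        out.append(ids)
        got += ids.size
    return np.concatenate(out)[:n].astype(np.uint32)


@dataclass(frozen=True)
class MimicRelation:
    """One corruption pattern linking a source tag-code to a mimic tag-code.

    ``error_pattern`` lists flipped bit positions within the (id << crc_bits) |
    crc portion of the codeword, LSB = position 0.  Applying the pattern to the
    source codeword yields a word that still validates and decodes to
    ``mimic_id``.
    """

    source_id: int
    mimic_id: int
    error_pattern: tuple[int, ...]
    weight: int


@lru_cache(maxsize=None)
def _zero_syndrome_patterns(layout: MessageLayout, max_weight: int) -> tuple[int, ...]:
    """All nonzero error patterns e over id+crc bits with crc(e_id) == e_crc.

    By CRC linearity these are exactly the patterns that map every valid
    codeword onto another valid codeword.
    """
    nbits = layout.id_bits + layout.crc_bits
    patterns: list[int] = []
    for w in range(1, max_weight + 1):
        for positions in combinations(range(nbits), w):
            e = 0
            for p in positions:
                e |= 1 << p
            e_id = e >> layout.crc_bits
            e_crc = e & ((1 << layout.crc_bits) - 1)
            if crc8(e_id, layout) == e_crc:
                patterns.append(e)
    return tuple(patterns)


def mimic_candidates(
    tag_id: int, max_weight: int, layout: MessageLayout = DEFAULT_LAYOUT
) -> list[MimicRelation]:
    """Every distinct tag-code reachable from ``tag_id`` by flipping at most
    ``max_weight`` bits of the id+crc fields such that the corrupted word still
    validates.

    The relation is symmetric (XOR patterns are involutions) and irreflexive
    (a zero-syndrome pattern with a null id part must also have a null crc
    part).  Sync-bit corruption is assumed to prevent decoding altogether and
    is excluded from the search space.
    """
    if max_weight < 0:
        raise ValueError("max_weight must be >= 0")
    if not 0 <= tag_id < layout.n_codes:
        raise ValueError(f"identifier must be in [0, {layout.n_codes})")
    relations = []
    for e in _zero_syndrome_patterns(layout, max_weight):
        e_id = e >> layout.crc_bits
        mimic_id = tag_id ^ e_id
        positions = tuple(p for p in range(layout.id_bits + layout.crc_bits) if e >> p & 1)
        relations.append(
            MimicRelation(
                source_id=tag_id,
                mimic_id=mimic_id,
                error_pattern=positions,
                weight=len(positions),
            )
        )
    return relations


def mimic_table(
    tag_ids: Iterable[int], max_weight: int, layout: MessageLayout = DEFAULT_LAYOUT
) -> dict[int, set[int]]:
    """Map each id to the set of its mimic ids at corruption weight <= max_weight."""
    return {
        tid: {r.mimic_id for r in mimic_candidates(tid, max_weight, layout)}
        for tid in tag_ids
    }


def format_tag_id(tag_id: int) -> str:
    """Render an identifier as the 4-hex-digit uppercase string used in CSVs."""
    if not 0 <= tag_id < 1 << 16:
        raise ValueError("identifier must fit in 16 bits")
    return f"{tag_id:04X}"


def parse_tag_id(text: str) -> int:
    return int(text, 16)
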