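"""The 103-dimensional qualitative siRNA representation.

Two blocks: 84 one-hot sequence codes (21 guide positions x 4 channels in the
order A, C, G, U — the 3' overhang positions 20-21 included) and 19 trihedral
rule codes for the core positions. A rule code is +1 when the nucleotide at
that position prefers high knockdown efficacy under the majority-compiled
positional design rules, -1 when it prefers low efficacy, and 0 when no
published rule applies. The compiled rule table ships as package data with
per-cell provider provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .sequence_io import CORE_LENGTH, GUIDE_LENGTH, RNA_ALPHABET

CHANNELS = "ACGU"
N_SEQUENCE_CODES = GUIDE_LENGTH * 4  # 84
N_RULE_CODES = CORE_LENGTH  # 19
N_QUAL_FEATURES = N_SEQUENCE_CODES + N_RULE_CODES  # 103

RULE_TABLE_RESOURCE = "rule_table.tsv"


@dataclass(frozen=True)
class RuleTable:
    """Majority-compiled positional codes: (position 1-19, nucleotide) -> {-1,0,+1}."""

    codes: dict[tuple[int, str], int]
    providers: dict[tuple[int, str], tuple[str, ...]]

    def __post_init__(self) -> None:
        expected = {(p, n) for p in range(1, CORE_LENGTH + 1) for n in CHANNELS}
        if set(self.codes) != expected:
            raise ValueError("rule table must cover all 76 (position, nucleotide) cells")
        bad = {c for c in self.codes.values() if c not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"rule codes outside {{-1,0,1}}: {bad}")

    def code(self, position: int, nucleotide: str) -> int:
        """The code for ``nucleotide`` at 1-based guide ``position``."""
        try:
            return self.codes[(position, nucleotide)]
        except KeyError:
            raise ValueError(
                f"no rule-table cell for position {position}, nucleotide {nucleotide!r}"
            ) from None


def load_rule_table(path: str | Path | None = None) -> RuleTable:
    """Load the positional rule-code TSV; default is the packaged compiled table."""
    if path is None:
        text = (resources.files("sirnafusion.data") / RULE_TABLE_RESOURCE).read_text()
    else:
        text = Path(path).read_text()
    codes: dict[tuple[int, str], int] = {}
    providers: dict[tuple[int, str], tuple[str, ...]] = {}
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("position\t"):
            continue
        fields = line.split("\t")
        pos, nuc, code = int(fields[0]), fields[1], int(fields[2])
        prov = tuple(fields[3].split(",")) if len(fields) > 3 and fields[3] else ()
        codes[(pos, nuc)] = code
        providers[(pos, nuc)] = prov
    return RuleTable(codes=codes, providers=providers)


def one_hot_sequence(guide: str) -> np.ndarray:
    """84-dim one-hot encoding of the full 21-mer, position-major, channels A,C,G,U."""
    if len(guide) != GUIDE_LENGTH:
        raise ValueError(f"guide must be {GUIDE_LENGTH} nt, got {len(guide)}")
    out = np.zeros(N_SEQUENCE_CODES)
    for i, nuc in enumerate(guide):
        channel = CHANNELS.find(nuc)
        if channel < 0:
            raise ValueError(f"non-ACGU nucleotide {nuc!r} at position {i + 1}")
        out[4 * i + channel] = 1.0
    return out


def decode_one_hot(codes: np.ndarray) -> str:
    """Inverse of :func:`one_hot_sequence`."""
    blocks = np.asarray(codes).reshape(GUIDE_LENGTH, 4)
    if not np.all(blocks.sum(axis=1) == 1):
        raise ValueError("each position block must contain exactly one 1")
    return "".join(CHANNELS[int(np.argmax(b))] for b in blocks)


def rule_codes(guide_core: str, table: RuleTable | None = None) -> np.ndarray:
    """The 19 positional rule codes of the core under the compiled rule table."""
    table = table or load_rule_table()
    if len(guide_core) != CORE_LENGTH:
        raise ValueError(f"guide core must be {CORE_LENGTH} nt, got {len(guide_core)}")
    bad = set(guide_core) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGU characters in core: {sorted(bad)}")
    return np.array(
        [table.code(i + 1, nuc) for i, nuc in enumerate(guide_core)], dtype=float
    )


def qual_feature_names() -> list[str]:
    names = [
        f"pos{i + 1}={c}" for i in range(GUIDE_LENGTH) for c in CHANNELS
    ]
    names += [f"rule pos{i + 1}" for i in range(CORE_LENGTH)]
    assert len(names) == N_QUAL_FEATURES
    return names


def build_qual_vector(guide: str, table: RuleTable | None = None) -> np.ndarray:
    """Concatenate [sequence codes | rule codes] into the 103-dim vector."""
    return np.concatenate([one_hot_sequence(guide), rule_codes(guide[:CORE_LENGTH], table)])
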