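"""Reading, validating and locating siRNA records on their target mRNAs.

An siRNA here is a 21-nt guide (antisense) strand: a 19-nt core that base-pairs
with the target mRNA plus a 2-nt 3' overhang at positions 20-21. Positions are
1-based along the guide 5'->3' in user-facing reports; internal mRNA coordinates
are 0-based half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

RNA_ALPHABET = frozenset("ACGU")
GUIDE_LENGTH = 21
CORE_LENGTH = 19

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class SirnaFormatError(ValueError):
    """Malformed input file or record."""


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert DNA T to RNA U."""
    return seq.strip().upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SirnaRecord:
    """One siRNA guide strand with (optionally) its observed knockdown efficacy.

    Parameters
    ----------
    id : str
        Record identifier.
    guide : str
        21-nt guide (antisense) sequence 5'->3'; positions 1-19 are the core,
        20-21 the 3' overhang. Normalized to uppercase RNA on construction.
    target_id : str
        Identifier of the targeted mRNA.
    efficacy : float or None
        Observed knockdown in percent, in [0, 100]; ``None`` for unlabeled
        prediction input.
    site_start : int or None
        Optional explicit 0-based start of the binding site on the target,
        overriding sequence search.
    """

    id: str
    guide: str
    target_id: str
    efficacy: float | None = None
    site_start: int | None = None

    def __post_init__(self) -> None:
        guide = normalize_rna(self.guide)
        object.__setattr__(self, "guide", guide)
        if len(guide) != GUIDE_LENGTH:
            raise SirnaFormatError(
                f"record {self.id!r}: guide must be {GUIDE_LENGTH} nt "
                f"(19-nt core + 2-nt 3' overhang), got {len(guide)}"
            )
        bad = set(guide) - RNA_ALPHABET
        if bad:
            raise SirnaFormatError(
                f"record {self.id!r}: non-ACGU characters {sorted(bad)} in guide"
            )
        if self.efficacy is not None and not 0.0 <= float(self.efficacy) <= 100.0:
            raise SirnaFormatError(
                f"record {self.id!r}: efficacy {self.efficacy} outside [0, 100]"
            )

    @property
    def core(self) -> str:
        """The 19-nt core (positions 1-19) that pairs with the mRNA."""
        return self.guide[:CORE_LENGTH]

    @property
    def overhang(self) -> str:
        """The 2-nt 3' overhang (positions 20-21)."""
        return self.guide[CORE_LENGTH:]


@dataclass(frozen=True)
class MrnaContext:
    """The binding site of an siRNA on its target and the flanking neighborhood.

    ``binding_site`` is the 0-based half-open interval covered by the guide's
    19-nt core; ``neighborhood`` extends it by ``window`` nt on each side,
    clipped to the transcript ends.
    """

    target_id: str
    sequence: str
    binding_site: tuple[int, int]
    neighborhood: tuple[int, int]

    @property
    def site_seq(self) -> str:
        return self.sequence[self.binding_site[0]: self.binding_site[1]]

    @property
    def neighborhood_seq(self) -> str:
        return self.sequence[self.neighborhood[0]: self.neighborhood[1]]


class BindingSiteNotFoundError(LookupError):
    """The reverse complement of the guide core does not occur in the mRNA."""


def parse_fasta(path: str | Path) -> dict[str, str]:
    """Read mRNA sequences from a FASTA file into an id -> RNA-sequence map.

    Sequences are uppercased and T->U normalized; the id is the first
    whitespace token of the header line.
    """
    sequences: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                if not header:
                    raise SirnaFormatError(f"{path}:{lineno}: empty FASTA header")
                current = header.split()[0]
                if current in sequences:
                    raise SirnaFormatError(
                        f"{path}:{lineno}: duplicate sequence id {current!r}"
                    )
                sequences[current] = []
            else:
                if current is None:
                    raise SirnaFormatError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                chunk = normalize_rna(line)
                bad = set(chunk) - RNA_ALPHABET
                if bad:
                    raise SirnaFormatError(
                        f"{path}:{lineno}: non-ACGTU characters {sorted(bad)}"
                    )
                sequences[current].append(chunk)
    result = {name: "".join(parts) for name, parts in sequences.items()}
    for name, seq in result.items():
        if not seq:
            raise SirnaFormatError(f"{path}: record {name!r} has an empty sequence")
    return result


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i: i + width] + "\n")


_TABLE_COLUMNS = ("id", "guide", "target_id", "efficacy")


def parse_sirna_table(path: str | Path) -> list[SirnaRecord]:
    """Read siRNA records from a TSV with columns id, guide, target_id, efficacy.

    The efficacy column may be empty for unlabeled records; an optional
    ``site_start`` column (1-based) pins the binding site explicitly.
    Row-level validation errors are collected and reported together.
    """
    records: list[SirnaRecord] = []
    errors: list[str] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _TABLE_COLUMNS[:3] if c not in header]
        if missing:
            raise SirnaFormatError(f"{path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                eff_text = (row.get("efficacy") or "").strip()
                efficacy = float(eff_text) if eff_text else None
                start_text = (row.get("site_start") or "").strip()
                site_start = int(start_text) - 1 if start_text else None
                records.append(
                    SirnaRecord(
                        id=row["id"].strip(),
                        guide=row["guide"],
                        target_id=row["target_id"].strip(),
                        efficacy=efficacy,
                        site_start=site_start,
                    )
                )
            except (SirnaFormatError, ValueError, KeyError) as exc:
                errors.append(f"{path}:{lineno}: {exc}")
    if errors:
        raise SirnaFormatError("; ".join(errors))
    return records


def write_sirna_table(records: list[SirnaRecord], path: str | Path) -> None:
    """Write records as the standard TSV; inverse of :func:`parse_sirna_table`."""
    any_site = any(r.site_start is not None for r in records)
    cols = list(_TABLE_COLUMNS) + (["site_start"] if any_site else [])
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for r in records:
            row = [r.id, r.guide, r.target_id,
                   "" if r.efficacy is None else repr(float(r.efficacy))]
            if any_site:
                row.append("" if r.site_start is None else str(r.site_start + 1))
            writer.writerow(row)


def locate_binding_site(
    record: SirnaRecord, mrna: str, window: int = 20
) -> MrnaContext:
    """Find the guide core's binding site on the target mRNA.

    The site is the leftmost exact occurrence of the reverse complement of the
    19-nt core; a ``site_start`` carried by the record overrides the search.
    The neighborhood is the site extended by ``window`` nt on each side,
    clipped at the transcript ends.
    """
    mrna = normalize_rna(mrna)
    if len(mrna) < CORE_LENGTH:
        raise SirnaFormatError(
            f"mRNA shorter than the {CORE_LENGTH}-nt core ({len(mrna)} nt)"
        )
    target = reverse_complement(record.core)
    if record.site_start is not None:
        start = record.site_start
        if mrna[start: start + CORE_LENGTH] != target:
            raise BindingSiteNotFoundError(
                f"record {record.id!r}: explicit site at {start + 1} (1-based) "
                "is not complementary to the guide core"
            )
    else:
        start = mrna.find(target)
        if start < 0:
            raise BindingSiteNotFoundError(
                f"record {record.id!r}: reverse complement of the guide core "
                f"not found in target {record.target_id!r}"
            )
    end = start + CORE_LENGTH
    neighborhood = (max(0, start - window), min(len(mrna), end + window))
    return MrnaContext(
        target_id=record.target_id,
        sequence=mrna,
        binding_site=(start, end),
        neighborhood=neighborhood,
    )
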