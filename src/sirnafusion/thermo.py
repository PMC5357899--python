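"""Nearest-neighbor duplex thermodynamics and siRNA-mRNA interaction energies.

The guide's duplex stability is summarized by the classic nearest-neighbor
model: a stacking free energy dG (kcal/mol, 37 C) for each of the 18 adjacent
dinucleotides of the 19-nt core read along the antisense strand 5'->3' and
assumed fully Watson-Crick paired, their sum dG_duplex, and the 5'/3' terminal
asymmetry ddG that governs which strand RISC loads.

The siRNA-mRNA interaction is described by three energies in the RNAup
decomposition: the cost of opening the binding region in the siRNA (dG_s) and
in the mRNA (dG_m), and the hybridization energy gained by pairing (dG_h).
The adapter shells out to ViennaRNA's RNAup when available; a perfect-
complement nearest-neighbor fallback sets dG_h only, with dG_s = dG_m = 0.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .sequence_io import (
    CORE_LENGTH,
    MrnaContext,
    RNA_ALPHABET,
    SirnaRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)

N_STACKS = CORE_LENGTH - 1  # 18
#: stacks fully inside each terminal 5-mer of the core
TERMINAL_WINDOW_STACKS = 4

DEFAULT_PARAMS_RESOURCE = "nn_freier1986.tsv"


@dataclass(frozen=True)
class NearestNeighborTable:
    """Watson-Crick dinucleotide stacking parameters plus duplex initiation.

    ``stacks`` maps every 5'->3' dinucleotide (16 keys) to its stacking dG in
    kcal/mol; the paired strand is implied by complementarity.
    """

    stacks: dict[str, float]
    initiation: float
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = {a + b for a in "ACGU" for b in "ACGU"} - set(self.stacks)
        if missing:
            raise ValueError(f"nearest-neighbor table missing stacks: {sorted(missing)}")

    def stack(self, dinucleotide: str) -> float:
        try:
            return self.stacks[dinucleotide]
        except KeyError:
            raise ValueError(f"invalid dinucleotide {dinucleotide!r}") from None


def load_nn_table(path: str | Path | None = None) -> NearestNeighborTable:
    """Load a nearest-neighbor parameter TSV; default is the packaged Freier-1986 set."""
    if path is None:
        source = resources.files("sirnafusion.data") / DEFAULT_PARAMS_RESOURCE
        text = source.read_text()
    else:
        text = Path(path).read_text()
    stacks: dict[str, float] = {}
    initiation = 0.0
    name = "custom"
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("# name"):
            name = line.split("\t")[-1].strip()
        elif line.startswith("# init"):
            initiation = float(line.split("\t")[-1])
        elif line and not line.startswith("#"):
            _, dinuc, value = line.split("\t")
            stacks[dinuc] = float(value)
    return NearestNeighborTable(stacks=stacks, initiation=initiation, name=name)


@dataclass(frozen=True)
class ThermoProfile:
    """Stability profile of one guide core: 18 stack dGs, their sum, and ddG."""

    stack_dg: tuple[float, ...]
    duplex_dg: float
    end_asymmetry: float


@dataclass(frozen=True)
class InteractionEnergies:
    """RNAup-style decomposition of the siRNA-mRNA interaction (kcal/mol).

    ``dg_s``/``dg_m`` are the (non-negative) opening costs of the binding
    region in the siRNA and mRNA; ``dg_h`` the hybridization energy gained.
    """

    dg_s: float
    dg_m: float
    dg_h: float

    @property
    def total(self) -> float:
        return self.dg_s + self.dg_m + self.dg_h


def _check_core(core: str) -> str:
    if len(core) != CORE_LENGTH:
        raise ValueError(f"guide core must be {CORE_LENGTH} nt, got {len(core)}")
    bad = set(core) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGU characters in core: {sorted(bad)}")
    return core


def stack_energies(core: str, params: NearestNeighborTable | None = None) -> list[float]:
    """The 18 Watson-Crick stacking dGs of adjacent core dinucleotides, 5'->3'."""
    params = params or load_nn_table()
    _check_core(core)
    return [params.stack(core[i: i + 2]) for i in range(N_STACKS)]


def duplex_energy(core: str, params: NearestNeighborTable | None = None) -> float:
    """dG_duplex: the sum of all 18 stack energies of the core."""
    return float(sum(stack_energies(core, params)))


def end_asymmetry(core: str, params: NearestNeighborTable | None = None) -> float:
    """ddG: 5'-terminal minus 3'-terminal duplex-formation free energy.

    Each terminal window covers the 5 outermost core nucleotides, i.e. the 4
    stacks fully inside it; a negative ddG means the 5' end of the guide is
    the more stable one.
    """
    stacks = stack_energies(core, params)
    five_prime = sum(stacks[:TERMINAL_WINDOW_STACKS])
    three_prime = sum(stacks[-TERMINAL_WINDOW_STACKS:])
    return float(five_prime - three_prime)


def thermo_profile(core: str, params: NearestNeighborTable | None = None) -> ThermoProfile:
    params = params or load_nn_table()
    stacks = stack_energies(core, params)
    return ThermoProfile(
        stack_dg=tuple(stacks),
        duplex_dg=float(sum(stacks)),
        end_asymmetry=end_asymmetry(core, params),
    )


def hybridization_energy(
    guide_core: str, site: str, params: NearestNeighborTable | None = None
) -> float:
    """dG_h of a perfectly complementary guide/site duplex.

    Nearest-neighbor sum plus the duplex initiation term. The site must be the
    exact reverse complement of the core; for imperfect duplexes use the RNAup
    adapter (:func:`interaction_energies`).
    """
    params = params or load_nn_table()
    _check_core(guide_core)
    if site != reverse_complement(guide_core):
        raise ValueError(
            "site is not the exact complement of the guide core; "
            "use the RNAup backend for imperfect duplexes"
        )
    return params.initiation + duplex_energy(guide_core, params)


# e.g. "(-6.31 = -32.20 + 17.80 + 8.09)"
_DECOMP_RE = re.compile(
    r"\(\s*(-?\d+\.?\d*)\s*=\s*(-?\d+\.?\d*)\s*\+\s*(-?\d+\.?\d*)"
    r"(?:\s*\+\s*(-?\d+\.?\d*))?\s*\)"
)

_DECOMP_TOLERANCE = 0.01


def parse_rnaup_output(text: str) -> tuple[InteractionEnergies, float]:
    """Parse an RNAup result text into interaction energies plus the total.

    RNAup prints ``(TOTAL = DG_INTERACTION + DG_UNPAIR_TARGET
    [+ DG_UNPAIR_QUERY])``: the interaction term maps to ``dg_h``, the target
    (long-sequence) unpairing cost to ``dg_m`` and the query unpairing cost to
    ``dg_s`` (0 when RNAup omits it). The total is checked against the sum of
    parts to 0.01 kcal/mol; larger drift is logged, not fatal.
    """
    match = _DECOMP_RE.search(text)
    if match is None:
        raise ValueError("no RNAup energy decomposition '(total = ...)' found")
    total = float(match.group(1))
    dg_h = float(match.group(2))
    dg_m = float(match.group(3))
    dg_s = float(match.group(4)) if match.group(4) is not None else 0.0
    if abs(total - (dg_h + dg_m + dg_s)) > _DECOMP_TOLERANCE:
        logger.warning(
            "RNAup decomposition inconsistent: total %.2f vs parts %.2f",
            total, dg_h + dg_m + dg_s,
        )
    return InteractionEnergies(dg_s=dg_s, dg_m=dg_m, dg_h=dg_h), total


def render_rnaup_output(energies: InteractionEnergies) -> str:
    """Render the energy decomposition in RNAup's dialect (test/round-trip aid)."""
    return (
        f"((((&))))   1,4  :   1,4  "
        f"({energies.total:.2f} = {energies.dg_h:.2f} + "
        f"{energies.dg_m:.2f} + {energies.dg_s:.2f})"
    )


class RnaupNotAvailableError(RuntimeError):
    """The external RNAup binary was required but is not on PATH."""


def _run_rnaup(guide: str, mrna: str) -> str:
    exe = shutil.which("RNAup")
    if exe is None:
        raise RnaupNotAvailableError(
            "RNAup binary not found on PATH; install ViennaRNA or use "
            "backend='fallback'"
        )
    fasta = f">target\n{mrna}\n>query\n{guide}\n"
    with tempfile.TemporaryDirectory() as tmp:
        proc = subprocess.run(
            [exe, "-b", "--interaction_first"],
            input=fasta, capture_output=True, text=True, cwd=tmp,
        )
    if proc.returncode != 0:
        raise RuntimeError(f"RNAup failed (exit {proc.returncode}): {proc.stderr.strip()}")
    return proc.stdout


def interaction_energies(
    record: SirnaRecord,
    context: MrnaContext,
    backend: str = "fallback",
    params: NearestNeighborTable | None = None,
    cache: "EnergyCache | None" = None,
) -> InteractionEnergies:
    """Compute (dG_s, dG_m, dG_h) for one siRNA against its target.

    backend ``"rnaup"`` runs ViennaRNA's RNAup on (guide, mRNA) and parses its
    decomposition; ``"fallback"`` assumes a fully accessible, perfectly
    complementary site: dG_h from the nearest-neighbor sum and dG_s = dG_m = 0.
    A cache hit (keyed on guide/target/site) short-circuits either backend.
    """
    if cache is not None:
        hit = cache.get(record.guide, context.target_id, context.binding_site[0])
        if hit is not None:
            return hit
    if backend == "rnaup":
        out = _run_rnaup(record.guide, context.sequence)
        energies, _ = parse_rnaup_output(out)
    elif backend == "fallback":
        dg_h = hybridization_energy(record.core, context.site_seq, params)
        energies = InteractionEnergies(dg_s=0.0, dg_m=0.0, dg_h=dg_h)
    else:
        raise ValueError(f"unknown interaction backend {backend!r}")
    if cache is not None:
        cache.put(record.guide, context.target_id, context.binding_site[0], energies)
    return energies


class EnergyCache:
    """TSV-backed cache of interaction energies keyed by (guide, target, site)."""

    _COLS = ("guide", "target_id", "site_start", "dg_s", "dg_m", "dg_h")

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self._store: dict[tuple[str, str, int], InteractionEnergies] = {}
        if self.path is not None and self.path.exists():
            for line in self.path.read_text().splitlines()[1:]:
                guide, target, start, s, m, h = line.split("\t")
                self._store[(guide, target, int(start))] = InteractionEnergies(
                    dg_s=float(s), dg_m=float(m), dg_h=float(h)
                )

    def get(self, guide: str, target_id: str, site_start: int) -> InteractionEnergies | None:
        return self._store.get((guide, target_id, site_start))

    def put(self, guide: str, target_id: str, site_start: int,
            energies: InteractionEnergies) -> None:
        self._store[(guide, target_id, site_start)] = energies

    def save(self, path: str | Path | None = None) -> None:
        target = Path(path) if path is not None else self.path
        if target is None:
            raise ValueError("no path given for the energy cache")
        lines = ["\t".join(self._COLS)]
        for (guide, tid, start), e in sorted(self._store.items()):
            lines.append(f"{guide}\t{tid}\t{start}\t{e.dg_s}\t{e.dg_m}\t{e.dg_h}")
        target.write_text("\n".join(lines) + "\n")
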