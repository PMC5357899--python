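"""The 275-dimensional quantitative siRNA representation.

Four feature groups, concatenated in a frozen canonical order:

==========================  =========  ============
group                       dimension  vector slice
==========================  =========  ============
guide k-mer frequencies     4+16+64    0:84
stability profile           18+1+1     84:104
siRNA-mRNA interaction      3          104:107
mRNA global k-mers          4+16+64    107:191
binding-site neighborhood   4+16+64    191:275
==========================  =========  ============

k-mer blocks are proper distributions over overlapping windows (lexicographic
order, A<C<G<U); guide frequencies are computed on the 19-nt core.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .sequence_io import MrnaContext, SirnaRecord
from .thermo import InteractionEnergies, N_STACKS, ThermoProfile

ALPHABET = "ACGU"

N_QUANT_FEATURES = 275

STACK_SLICE = slice(84, 102)
DUPLEX_INDEX = 102


def _kmers(k: int) -> list[str]:
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def kmer_frequencies(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer frequencies of an RNA string, k in {1, 2, 3}.

    Returns a length-4^k distribution in lexicographic order; each of the
    L-k+1 windows contributes 1/(L-k+1).
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    n_windows = len(seq) - k + 1
    if n_windows < 1:
        raise ValueError(f"sequence of length {len(seq)} too short for {k}-mers")
    index = {kmer: i for i, kmer in enumerate(_kmers(k))}
    out = np.zeros(4 ** k)
    for i in range(n_windows):
        window = seq[i: i + k]
        try:
            out[index[window]] += 1.0
        except KeyError:
            raise ValueError(f"non-ACGU window {window!r} at offset {i}") from None
    return out / n_windows


def _kmer_block(seq: str) -> np.ndarray:
    return np.concatenate([kmer_frequencies(seq, k) for k in (1, 2, 3)])


def feature_names() -> list[str]:
    """The 275 quantitative feature identifiers, in canonical vector order."""
    names: list[str] = []
    for k in (1, 2, 3):
        names += [f"{kmer}% of siRNA" for kmer in _kmers(k)]
    names += [f"ΔG position {i}-{i + 1}" for i in range(1, N_STACKS + 1)]
    names += ["ΔG_duplex", "ΔΔG", "ΔG_s", "ΔG_m", "ΔG_h"]
    for region in ("mRNA", "neighbourhood"):
        for k in (1, 2, 3):
            names += [f"{kmer}% of {region}" for kmer in _kmers(k)]
    assert len(names) == N_QUANT_FEATURES
    return names


def build_quant_vector(
    record: SirnaRecord,
    context: MrnaContext,
    thermo: ThermoProfile,
    interact: InteractionEnergies,
) -> np.ndarray:
    """Assemble one 275-dimensional quantitative feature vector."""
    neighborhood = context.neighborhood_seq
    if len(neighborhood) < 3:
        raise ValueError("binding-site neighborhood shorter than 3 nt")
    vector = np.concatenate([
        _kmer_block(record.core),
        np.asarray(thermo.stack_dg, dtype=float),
        [thermo.duplex_dg, thermo.end_asymmetry],
        [interact.dg_s, interact.dg_m, interact.dg_h],
        _kmer_block(context.sequence),
        _kmer_block(neighborhood),
    ])
    assert vector.shape == (N_QUANT_FEATURES,)
    return vector
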